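"""Seed-based coactivation-pattern (CAP) analysis of 4D BOLD data.

Frames where a spherical seed region's z-scored mean signal exceeds a
threshold are clustered with k-means into recurring spatial coactivation
patterns; k is chosen by consensus clustering (1 − PAC stability over
subsample replicates).  Unselected frames form the non-active state CAP₀.
The resulting state sequence yields the temporal metrics occurrences,
resilience, in-/out-degree and betweenness centrality, and per-window
persistence probabilities on a grid matched to the fMRS sliding windows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from sklearn.cluster import KMeans

__all__ = [
    "SeedSpec",
    "StateSequence",
    "CapSet",
    "CapTemporalMetrics",
    "seed_timecourse",
    "select_frames",
    "choose_k_consensus",
    "fit_caps",
    "match_templates",
    "temporal_metrics",
    "persistence_curve",
    "map_windows_to_frames",
]


@dataclass(frozen=True)
class SeedSpec:
    """Spherical seed region in scanner/template mm coordinates."""

    center_mm: tuple
    radius_mm: float = 10.0
    space: str = "MNI"

    def __post_init__(self) -> None:
        if self.radius_mm <= 0:
            raise ValueError("seed radius must be positive")


@dataclass
class StateSequence:
    """Per-frame CAP labels: 0 = non-active (seed below threshold), 1..K = CAPs."""

    labels: np.ndarray
    k: int

    @property
    def n_frames(self) -> int:
        return self.labels.size


@dataclass
class CapSet:
    """Spatial CAP maps and the metadata of their extraction."""

    k: int
    maps: np.ndarray          # (K, nx, ny, nz): mean of raw assigned frames
    z_maps: np.ndarray        # (K, nx, ny, nz): mean / SE across assigned frames
    consensus_stats: dict | None = None   # candidate k -> stability (1 - PAC)
    template_matches: list | None = None


@dataclass(frozen=True)
class CapTemporalMetrics:
    """Temporal metrics for one CAP (CAP₀ included).

    occurrences_pct — % of frames spent in the state;
    resilience — self-transition count / (T−1);
    in_degree — entries from other states / (T−1);
    out_degree — exits toward other states / (T−1);
    betweenness — normalized betweenness centrality in the directed
    transition-count graph with distance 1/count.
    """

    cap: int
    occurrences_pct: float
    resilience: float
    in_degree: float
    out_degree: float
    betweenness: float


def sphere_mask(shape: tuple, affine: np.ndarray, center_mm, radius_mm: float) -> np.ndarray:
    """Voxels whose center lies within ``radius_mm`` of ``center_mm``."""
    idx = np.stack(np.meshgrid(*[np.arange(s) for s in shape], indexing="ij"), axis=-1)
    homog = np.concatenate([idx, np.ones(shape + (1,))], axis=-1)
    mm = homog @ affine.T
    dist = np.linalg.norm(mm[..., :3] - np.asarray(center_mm, dtype=float), axis=-1)
    return dist <= radius_mm


def seed_timecourse(volume4d: np.ndarray, affine: np.ndarray, seed: SeedSpec) -> np.ndarray:
    """Mean signal in the seed sphere per frame, z-scored over the session."""
    mask = sphere_mask(volume4d.shape[:3], affine, seed.center_mm, seed.radius_mm)
    if not mask.any():
        raise ValueError("seed sphere contains no voxels on this grid")
    tc = volume4d[mask].mean(axis=0)
    sd = tc.std(ddof=0)
    if sd == 0:
        raise ValueError("seed time course has zero variance; cannot z-score")
    return (tc - tc.mean()) / sd


def select_frames(seed_z: np.ndarray, threshold: float = 1.0,
                  two_sided: bool = False) -> np.ndarray:
    """Indices of frames where the seed z-score exceeds the threshold.

    Default is the positive tail only (activation CAPs); ``two_sided`` selects
    on |z| instead.
    """
    z = np.asarray(seed_z, dtype=float)
    sel = np.nonzero(np.abs(z) > threshold if two_sided else z > threshold)[0]
    if sel.size == 0:
        raise ValueError("no frames exceed the seed threshold; lower it")
    return sel


def _row_normalize(frames: np.ndarray) -> np.ndarray:
    x = frames - frames.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(x, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return x / norms


def choose_k_consensus(
    frames: np.ndarray,
    k_range=range(2, 9),
    n_subsamples: int = 100,
    subsample_frac: float = 0.8,
    seed: int = 0,
    pac_bounds: tuple = (0.1, 0.9),
) -> tuple[int, dict]:
    """Select the number of CAPs by consensus clustering.

    For each candidate k, k-means is run on ``n_subsamples`` random row
    subsamples; the consensus matrix holds, for each frame pair, the fraction
    of co-sampled replicates in which the pair co-clustered.  Stability is
    1 − PAC, where PAC is the proportion of off-diagonal consensus entries in
    the ambiguous band ``pac_bounds``.  The k with the highest stability wins.
    Exact ties go to the larger k: merging well-separated clusters is also
    perfectly stable (under-clustering leaves no ambiguous pairs), so among
    equally stable candidates only the finest partition recovers planted
    structure.  Identical frames degenerate to k = 1.
    """
    frames = np.asarray(frames, dtype=float)
    n = frames.shape[0]
    if np.allclose(frames, frames[0]):
        warnings.warn("all frames identical; consensus degenerates to k=1")
        return 1, {int(k): 1.0 for k in k_range}
    if n < max(k_range) * 5:
        raise ValueError("too few frames for consensus over the requested k range")
    X = _row_normalize(frames)
    rng = np.random.default_rng(seed)
    m = max(int(round(subsample_frac * n)), max(k_range) + 1)
    iu = np.triu_indices(n, k=1)

    stats: dict[int, float] = {}
    for k in k_range:
        co = np.zeros((n, n))
        both = np.zeros((n, n))
        for rep in range(n_subsamples):
            rows = rng.choice(n, size=m, replace=False)
            km = KMeans(n_clusters=k, n_init=5,
                        random_state=int(rng.integers(2**31)))
            labels = km.fit_predict(X[rows])
            same = labels[:, None] == labels[None, :]
            both[np.ix_(rows, rows)] += 1.0
            co[np.ix_(rows, rows)] += same
        with np.errstate(invalid="ignore", divide="ignore"):
            consensus = np.where(both > 0, co / np.maximum(both, 1), 0.0)
        vals = consensus[iu][both[iu] > 0]
        pac = float(np.mean((vals > pac_bounds[0]) & (vals < pac_bounds[1])))
        stats[int(k)] = 1.0 - pac
    best = max(sorted(stats), key=lambda k: (stats[k], k))
    return best, stats


def fit_caps(
    frames: np.ndarray,
    k: int,
    selected_idx: np.ndarray,
    n_frames_total: int,
    grid_shape: tuple | None = None,
    seed: int = 0,
    n_init: int = 20,
) -> tuple[CapSet, StateSequence]:
    """Cluster selected frames into k CAPs and map labels onto the timeline.

    Frames are row-normalized to zero mean and unit norm before Euclidean
    k-means, making the assignment correlation-driven.  CAP maps are the
    arithmetic means of the *raw* assigned frames; z-maps divide by the
    standard error across assigned frames.  Timeline labels are 0 for
    unselected frames and 1..K otherwise (clusters reindexed by descending
    size for determinism).
    """
    frames = np.asarray(frames, dtype=float)
    if k < 1:
        raise ValueError("k must be >= 1")
    flat = frames.reshape(frames.shape[0], -1)
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    raw_labels = km.fit_predict(_row_normalize(flat))

    # deterministic CAP numbering: by descending cluster size, then centroid order
    sizes = np.bincount(raw_labels, minlength=k)
    order = np.argsort(-sizes, kind="stable")
    remap = np.empty(k, dtype=int)
    remap[order] = np.arange(1, k + 1)
    cap_labels = remap[raw_labels]

    maps, z_maps = [], []
    for cap in range(1, k + 1):
        members = flat[cap_labels == cap]
        mean = members.mean(axis=0)
        if members.shape[0] > 1:
            se = members.std(axis=0, ddof=1) / np.sqrt(members.shape[0])
        else:
            se = np.zeros_like(mean)
        with np.errstate(invalid="ignore", divide="ignore"):
            z = np.where(se > 0, mean / se, 0.0)
        maps.append(mean)
        z_maps.append(z)
    shape = grid_shape if grid_shape is not None else frames.shape[1:]
    maps = np.asarray(maps).reshape((k,) + tuple(shape))
    z_maps = np.asarray(z_maps).reshape((k,) + tuple(shape))

    labels = np.zeros(n_frames_total, dtype=int)
    labels[np.asarray(selected_idx)] = cap_labels
    return CapSet(k=k, maps=maps, z_maps=z_maps), StateSequence(labels=labels, k=k)


def match_templates(caps: CapSet, templates: dict, r_threshold: float = 0.3) -> list:
    """Match each CAP z-map to named template maps by Pearson correlation.

    A match is accepted only when r strictly exceeds ``r_threshold``.  Returns
    one dict per CAP: ``{"cap", "template", "r", "accepted"}``.
    """
    results = []
    for i in range(caps.k):
        cap_map = caps.z_maps[i].ravel()
        best_name, best_r = None, -np.inf
        for name, tmpl in templates.items():
            t = np.asarray(tmpl, dtype=float)
            if t.shape != caps.z_maps[i].shape:
                raise ValueError(
                    f"template {name!r} grid {t.shape} does not match CAP grid "
                    f"{caps.z_maps[i].shape}; resample before matching")
            r = float(np.corrcoef(cap_map, t.ravel())[0, 1])
            if r > best_r:
                best_name, best_r = name, r
        results.append({"cap": i + 1, "template": best_name, "r": best_r,
                        "accepted": bool(best_r > r_threshold)})
    caps.template_matches = results
    return results


def temporal_metrics(seq: StateSequence) -> list:
    """Temporal metrics per CAP, CAP₀ included.

    With T frames and T−1 transitions: occurrences are the percentage of frames
    in the state; resilience, in-degree and out-degree are self-transitions,
    entries and exits as fractions of all T−1 transitions.  Betweenness is the
    normalized betweenness centrality of the state's node in the directed
    transition graph weighted by transition counts (shortest paths use
    distance = 1/count); with K+1 state nodes the normalization divides by
    K(K−1) ordered node pairs.
    """
    labels = np.asarray(seq.labels)
    T = labels.size
    if T < 2:
        raise ValueError("need at least 2 frames")
    n_states = seq.k + 1
    counts = np.zeros((n_states, n_states))
    for a, b in zip(labels[:-1], labels[1:]):
        counts[a, b] += 1
    n_trans = T - 1

    G = nx.DiGraph()
    G.add_nodes_from(range(n_states))
    for a in range(n_states):
        for b in range(n_states):
            if a != b and counts[a, b] > 0:
                G.add_edge(a, b, distance=1.0 / counts[a, b])
    btw = nx.betweenness_centrality(G, weight="distance", normalized=True)

    out = []
    for m in range(n_states):
        out.append(CapTemporalMetrics(
            cap=m,
            occurrences_pct=100.0 * float(np.sum(labels == m)) / T,
            resilience=float(counts[m, m]) / n_trans,
            in_degree=float(counts[:, m].sum() - counts[m, m]) / n_trans,
            out_degree=float(counts[m, :].sum() - counts[m, m]) / n_trans,
            betweenness=float(btw[m]),
        ))
    return out


def map_windows_to_frames(n_fmrs_pairs: int, grid_windows, n_frames: int) -> list:
    """Map fMRS sliding windows onto the fMRI frame timeline.

    Each fMRS window's (start, end) pair range is rescaled proportionally to
    the session's frame count and rounded, giving one frame range per window —
    same window count, window length and step scaled by n_frames/n_pairs.
    """
    scale = n_frames / n_fmrs_pairs
    out = []
    for a, b in grid_windows:
        fa = int(round(a * scale))
        fb = int(round(b * scale))
        if fa < 0 or fb > n_frames:
            raise ValueError("mapped window falls outside the frame timeline")
        out.append((fa, max(fb, fa + 2)))
    return out


def persistence_curve(seq: StateSequence, cap_id: int, frame_windows) -> np.ndarray:
    """Per-window persistence probability of one CAP.

    Within each frame window, persistence = self-transitions of the CAP divided
    by all transitions that start in the CAP; windows where the CAP never
    starts a transition score 0.
    """
    labels = np.asarray(seq.labels)
    probs = []
    for a, b in frame_windows:
        if a < 0 or b > labels.size:
            raise ValueError("window outside the timeline")
        seg = labels[a:b]
        starts = seg[:-1] == cap_id
        n_start = int(starts.sum())
        if n_start == 0:
            probs.append(0.0)
        else:
            stay = int(np.sum(starts & (seg[1:] == cap_id)))
            probs.append(stay / n_start)
    return np.asarray(probs)
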