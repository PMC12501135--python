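"""End-to-end orchestration: synthetic cohort -> spectral quantification ->
kinetics -> visibility features / CAP dynamics -> behavior -> PLSC -> stats.

A run is driven by a single validated configuration mapping, executes stages
in dependency order into a run directory, and writes a manifest recording
parameters, per-stage status and a SHA-256 hash of every output file, so an
identical configuration reproduces identical hashes.
"""

from __future__ import annotations

import copy
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import behavior as beh
from . import capstates, coupling, inference, kinetics, synthgen, visgraph
from .io import write_curve_tsv, write_trials

__all__ = ["PipelineConfig", "default_config", "run_pipeline", "PipelineError"]

CONDITIONS = ("rest", "0back", "1back", "2back")

DEFAULT_CONFIG: dict = {
    "seed": 1,
    "n_subjects": 12,
    "spectro_mode": "concentration",   # or "spectral": full ON/OFF simulation + fitting
    "window": {
        "window_pairs": 60,
        "step_pairs": 3,
        "target_frames_rest": 12,
        "outlier_z": 2.0,
    },
    "mrs": {
        "noise_sd": 0.04,
        "outlier_rate": 0.02,
        # relative Glx plateau per condition (load-dependent excitatory response)
        "glx_level": {"rest": 1.0, "0back": 1.04, "1back": 1.08, "2back": 1.15},
        "glx_rise_s": 120.0,
        # biphasic GABA: initial increase then decline during task
        "gaba_peak_level": 1.05,
        "gaba_peak_s": 150.0,
        "gaba_end_level": 0.98,
        "subject_sd": 0.02,            # between-subject jitter of effect levels
    },
    "bold": {
        "grid": [8, 8, 8],
        "voxel_size_mm": 3.0,
        "seed_center_mm": [10.5, 10.5, 10.5],
        "seed_radius_mm": 10.0,
        "noise_sd": 0.6,
        "n_caps": 4,
        "stay_prob": {"rest": 0.55, "0back": 0.6, "1back": 0.65, "2back": 0.75},
        "seed_boost": 2.5,
    },
    "cap": {
        "z_threshold": 1.0,
        "two_sided": False,
        "k_min": 2,
        "k_max": 6,
        "n_subsamples": 30,
        "subsample_frac": 0.8,
        "fixed_k": None,               # skip consensus when set
    },
    "behavior": {
        "hit_rate": {"0back": 0.97, "1back": 0.9, "2back": 0.78},
        "fa_rate": {"0back": 0.02, "1back": 0.06, "2back": 0.12},
        "rt_mean_ms": {"0back": 480.0, "1back": 560.0, "2back": 640.0},
        "rt_sd_ms": 90.0,
        "hit_floor": 0.0,
    },
    "plsc": {"n_perm": 1000, "n_boot": 10000},
    "stats": {"adjust": "fdr_bh"},
}


class PipelineError(RuntimeError):
    """A stage failed; the manifest written so far names it."""


@dataclass
class PipelineConfig:
    """Validated pipeline configuration (see ``default_config`` for the schema)."""

    data: dict

    def __getitem__(self, key):
        return self.data[key]


def default_config() -> dict:
    return copy.deepcopy(DEFAULT_CONFIG)


# nested dicts that are per-condition value maps, not config sections
_LEAF_DICTS = {"glx_level", "stay_prob", "hit_rate", "fa_rate", "rt_mean_ms"}


def _validate(user: dict, schema: dict, path: str = "") -> dict:
    out = {}
    for key, default in schema.items():
        here = f"{path}.{key}" if path else key
        if key in user:
            value = user[key]
            if isinstance(default, dict) and key not in _LEAF_DICTS:
                if not isinstance(value, dict):
                    raise ValueError(f"config key {here} must be a mapping")
                out[key] = _validate(value, default, here)
            else:
                out[key] = value
        else:
            out[key] = copy.deepcopy(default)
    unknown = set(user) - set(schema)
    if unknown:
        raise ValueError(f"unknown config key(s) at {path or 'top level'}: {sorted(unknown)}")
    return out


def load_config(user: dict | None = None) -> PipelineConfig:
    """Merge a user mapping over the defaults, rejecting unknown keys."""
    return PipelineConfig(_validate(user or {}, DEFAULT_CONFIG))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _subject_profiles(cfg: dict, condition: str, subject: int, seed: int):
    mrs = cfg["mrs"]
    rng = np.random.default_rng(seed)
    jitter = rng.normal(0.0, mrs["subject_sd"], size=3)
    if condition == "rest":
        glx_shape = synthgen.flat()
        gaba_shape = synthgen.flat()
    else:
        level = max(mrs["glx_level"][condition] + jitter[0], 0.5)
        glx_shape = synthgen.ramp_plateau(mrs["glx_rise_s"], level)
        total_s = synthgen.SessionDesign.for_condition(condition).session_seconds
        gaba_shape = synthgen.biphasic(
            mrs["gaba_peak_s"],
            max(mrs["gaba_peak_level"] + jitter[1], 0.5),
            max(mrs["gaba_end_level"] + jitter[2], 0.5),
            total_s,
        )
    return synthgen.KineticProfile(
        condition=condition, glx_shape=glx_shape, gaba_shape=gaba_shape,
        noise_sd=mrs["noise_sd"], outlier_rate=mrs["outlier_rate"],
        seed=int(rng.integers(2**31)),
    )


def _condition_grid(cfg: dict, condition: str) -> kinetics.WindowGrid:
    design = synthgen.SessionDesign.for_condition(condition)
    w = cfg["window"]
    target = w["target_frames_rest"] if condition == "rest" else None
    return kinetics.window_indices(design.n_on_off_pairs, w["window_pairs"],
                                   w["step_pairs"], target_frames=target)


def _stage_kinetics(cfg, run_dir, seeds):
    """Simulate metabolite series (optionally full spectra) and build curves."""
    curves = {}
    rows = []
    auc_rows = []
    rng = np.random.default_rng(seeds["mrs"])
    for subject in range(cfg["n_subjects"]):
        for condition in CONDITIONS:
            design = synthgen.SessionDesign.for_condition(condition)
            profile = _subject_profiles(cfg, condition, subject,
                                        int(rng.integers(2**31)))
            series = synthgen.simulate_metabolite_series(profile, design)
            grid = _condition_grid(cfg, condition)
            if cfg["spectro_mode"] == "spectral":
                session = synthgen.simulate_edited_session(
                    series, seed=int(rng.integers(2**31)))
                curve = kinetics.curve_from_session(session, grid,
                                                    cfg["window"]["outlier_z"])
            else:
                curve = kinetics.curve_from_series(series, grid,
                                                   cfg["window"]["outlier_z"])
            curves[(subject, condition)] = curve
            for f in range(curve.n_frames):
                rows.append({
                    "subject": subject, "session": condition, "frame": f,
                    "gaba": curve.gaba[f], "glx": curve.glx[f],
                    "eib": curve.eib[f], "eib_norm": curve.eib_norm[f],
                    "outlier": bool(curve.outlier_mask[f]),
                })
            auc_rows.append({"subject": subject, "session": condition,
                             "auc": curve.auc})
    write_curve_tsv(rows, run_dir / "kinetics_curves.tsv")
    write_curve_tsv(auc_rows, run_dir / "kinetics_auc.tsv")
    return curves, pd.DataFrame(auc_rows)


def _stage_visgraph(curves, run_dir):
    rows = []
    for (subject, condition), curve in curves.items():
        feats = visgraph.visibility_features(curve.eib_norm)
        rows.append({"subject": subject, "session": condition,
                     "mean_out_degree": feats.mean_out_degree,
                     "kld": feats.kld})
    df = pd.DataFrame(rows)
    write_curve_tsv(rows, run_dir / "visgraph_features.tsv")
    return df


def _build_markov_model(cfg, condition, seed):
    b = cfg["bold"]
    K = b["n_caps"]
    n_states = K + 1
    stay = b["stay_prob"][condition]
    # CAP0 dominates (seed mostly below threshold, as in resting BOLD): the
    # non-active state is sticky, and active states mostly decay back to it
    P = np.zeros((n_states, n_states))
    P[0, 0] = 0.85
    P[0, 1:] = 0.15 / K
    for m in range(1, n_states):
        P[m, m] = stay
        P[m, 0] = 0.9 * (1.0 - stay)
        others = [s for s in range(1, n_states) if s != m]
        P[m, others] = 0.1 * (1.0 - stay) / max(K - 1, 1)
    grid = tuple(b["grid"])
    rng = np.random.default_rng(12345)  # fixed pattern geometry across runs
    patterns = np.zeros((n_states,) + grid)
    for s in range(1, n_states):
        patterns[s] = rng.normal(0.0, 1.0, grid)
        patterns[s] /= np.linalg.norm(patterns[s]) / np.sqrt(np.prod(grid))
        patterns[s] *= 2.0
    return synthgen.MarkovStateModel(
        transition_matrix=P, emission_patterns=patterns,
        emission_noise_sd=b["noise_sd"], seed_coupled=tuple(range(1, n_states)),
        seed_boost=b["seed_boost"], seed=seed,
    )


def _stage_caps(cfg, run_dir, seeds):
    """Per-session BOLD simulation, concatenated CAP extraction, and metrics."""
    b = cfg["bold"]
    cap_cfg = cfg["cap"]
    rng = np.random.default_rng(seeds["bold"])
    seed_spec = capstates.SeedSpec(tuple(b["seed_center_mm"]), b["seed_radius_mm"])

    segments = []      # (subject, condition, n_frames, selected local idx, frames)
    for subject in range(cfg["n_subjects"]):
        for condition in CONDITIONS:
            design = synthgen.SessionDesign.for_condition(condition)
            n_frames = int(design.session_seconds / design.tr_s)
            model = _build_markov_model(cfg, condition, int(rng.integers(2**31)))
            vol, _, affine = synthgen.simulate_bold_session(
                model, n_frames, b["seed_center_mm"], b["seed_radius_mm"],
                b["voxel_size_mm"])
            z = capstates.seed_timecourse(vol, affine, seed_spec)
            sel = capstates.select_frames(z, cap_cfg["z_threshold"],
                                          cap_cfg["two_sided"])
            frames = vol[..., sel].reshape(-1, sel.size).T
            segments.append((subject, condition, n_frames, sel, frames))

    all_frames = np.vstack([s[4] for s in segments])
    offsets = np.cumsum([0] + [s[2] for s in segments])
    global_sel = np.concatenate([
        off + s[3] for off, s in zip(offsets[:-1], segments)
    ])
    total_frames = int(offsets[-1])

    if cap_cfg["fixed_k"]:
        k, stats = int(cap_cfg["fixed_k"]), None
    else:
        k, stats = capstates.choose_k_consensus(
            all_frames, range(cap_cfg["k_min"], cap_cfg["k_max"] + 1),
            n_subsamples=cap_cfg["n_subsamples"],
            subsample_frac=cap_cfg["subsample_frac"], seed=seeds["consensus"])
    caps, seq = capstates.fit_caps(all_frames, k, global_sel, total_frames,
                                   grid_shape=tuple(b["grid"]), seed=seeds["kmeans"])
    caps.consensus_stats = stats

    metric_rows, persistence_rows = [], []
    for i, (subject, condition, n_frames, sel, _) in enumerate(segments):
        labels = seq.labels[offsets[i]:offsets[i + 1]]
        sub_seq = capstates.StateSequence(labels=labels, k=k)
        for m in capstates.temporal_metrics(sub_seq):
            metric_rows.append({"subject": subject, "session": condition,
                                "cap": m.cap,
                                "occurrences_pct": m.occurrences_pct,
                                "resilience": m.resilience,
                                "in_degree": m.in_degree,
                                "out_degree": m.out_degree,
                                "betweenness": m.betweenness})
        grid = _condition_grid(cfg, condition)
        frame_windows = capstates.map_windows_to_frames(
            grid.n_pairs, grid.windows, n_frames)
        persistence = capstates.persistence_curve(sub_seq, cap_id=1,
                                                  frame_windows=frame_windows)
        for w, p in enumerate(persistence):
            persistence_rows.append({"subject": subject, "session": condition,
                                     "window": w, "persistence": p})

    metrics = pd.DataFrame(metric_rows)
    write_curve_tsv(metric_rows, run_dir / "cap_metrics.tsv")
    write_curve_tsv(persistence_rows, run_dir / "cap_persistence.tsv")
    np.save(run_dir / "cap_maps.npy", caps.maps)  # scratch-free small array
    return metrics, pd.DataFrame(persistence_rows), k


def _stage_behavior(cfg, run_dir, seeds):
    bcfg = cfg["behavior"]
    rng = np.random.default_rng(seeds["behavior"])
    rows = []
    for subject in range(cfg["n_subjects"]):
        for condition in ("0back", "1back", "2back"):
            design = synthgen.SessionDesign.for_condition(condition)
            trials = synthgen.simulate_behavior_session(
                design, bcfg["hit_rate"][condition], bcfg["fa_rate"][condition],
                bcfg["rt_mean_ms"][condition], bcfg["rt_sd_ms"],
                seed=int(rng.integers(2**31)))
            scored = beh.score_session(trials, hit_floor=bcfg["hit_floor"])
            write_trials(trials, run_dir / f"trials_s{subject:02d}_{condition}.tsv")
            grid = _condition_grid(cfg, condition)
            curve, auc = beh.windowed_performance_auc(
                scored, grid.windows, design.n_on_off_pairs)
            congruent = scored["type"] == "congruent"
            sdt = beh.dprime_loglinear(
                int((congruent & scored["responded"]).sum()), int(congruent.sum()),
                int((~congruent & scored["responded"]).sum()), int((~congruent).sum()))
            rows.append({"subject": subject, "session": condition,
                         "dprime": sdt.dprime, "hit_rate": sdt.hit_rate,
                         "fa_rate": sdt.fa_rate,
                         "mean_score": float(scored["score"].mean()),
                         "auc": auc})
    df = pd.DataFrame(rows)
    write_curve_tsv(rows, run_dir / "behavior_summary.tsv")
    return df


def _stage_plsc(cfg, run_dir, cap_metrics, eib_features, seeds):
    fpn = cap_metrics[cap_metrics["cap"] == 1].drop(columns=["cap"])
    # a metric that does not vary across subjects in some session (e.g. a
    # structurally zero betweenness under a hub-dominated transition graph)
    # cannot be z-scored; drop it rather than impute
    usable, dropped = [], []
    for m in coupling.CAP_METRICS:
        sds = fpn.groupby("session")[m].std(ddof=1)
        (usable if (sds > 0).all() else dropped).append(m)
    if not usable:
        raise ValueError("no CAP metric varies across subjects")
    X, Y = coupling.assemble_blocks(fpn, eib_features, cap_features=tuple(usable))
    res = coupling.plsc_significance(X, Y, n_perm=cfg["plsc"]["n_perm"],
                                     n_boot=cfg["plsc"]["n_boot"],
                                     seed=seeds["plsc"])
    out = {
        "dropped_cap_metrics": dropped,
        "explained_cov_pct": res.explained_cov_pct.tolist(),
        "perm_p": res.perm_p.tolist(),
        "score_correlation": res.score_correlation.tolist(),
        "x_names": res.x_names,
        "y_names": res.y_names,
        "x_loadings_lc1": res.x_loadings[:, 0].tolist(),
        "y_loadings_lc1": res.y_loadings[:, 0].tolist(),
    }
    (run_dir / "plsc_result.json").write_text(json.dumps(out, indent=1))
    return res


def _stage_stats(cfg, run_dir, auc_df, persistence_df):
    def kw(df, value):
        groups = [df.loc[df["session"] == c, value].to_numpy() for c in CONDITIONS]
        return inference.kruskal_wallis_mrd(groups, labels=list(CONDITIONS),
                                            adjust=cfg["stats"]["adjust"])
    auc_test = kw(auc_df, "auc")
    pers_test = kw(persistence_df, "persistence")
    out = {}
    for name, t in [("eib_auc", auc_test), ("cap_persistence", pers_test)]:
        out[name] = {
            "H": t.statistic, "df": t.df, "n": t.n, "p": t.p,
            "report": t.report(),
            "posthoc": [{"pair": list(ph.pair),
                         "mean_rank_difference": ph.mean_rank_difference,
                         "p_adjusted": ph.p_adjusted} for ph in t.posthoc],
        }
    (run_dir / "stats.json").write_text(json.dumps(out, indent=1))
    return auc_test, pers_test


def run_pipeline(config: PipelineConfig | dict, out_dir: str | Path) -> dict:
    """Execute every stage into ``out_dir`` and return the manifest."""
    cfg = config.data if isinstance(config, PipelineConfig) else load_config(config).data
    run_dir = Path(out_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(cfg["seed"])
    children = ss.spawn(6)
    seeds = {name: int(child.generate_state(1)[0] % 2**31)
             for name, child in zip(
                 ["mrs", "bold", "consensus", "kmeans", "behavior", "plsc"],
                 children)}

    manifest = {"config": cfg, "seeds": seeds, "stages": {}, "outputs": {}}

    def record(stage, fn, *args, **kwargs):
        try:
            result = fn(*args, **kwargs)
        except Exception as exc:
            manifest["stages"][stage] = {"status": "failed", "error": str(exc)}
            _finalize(manifest, run_dir)
            raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
        manifest["stages"][stage] = {"status": "ok"}
        return result

    curves, auc_df = record("kinetics", _stage_kinetics, cfg, run_dir, seeds)
    eib_features = record("visgraph", _stage_visgraph, curves, run_dir)
    cap_metrics, persistence_df, k = record("caps", _stage_caps, cfg, run_dir, seeds)
    manifest["stages"]["caps"]["k"] = k
    record("behavior", _stage_behavior, cfg, run_dir, seeds)
    record("plsc", _stage_plsc, cfg, run_dir, cap_metrics, eib_features, seeds)
    record("stats", _stage_stats, cfg, run_dir, auc_df, persistence_df)
    _finalize(manifest, run_dir)
    return manifest


def _finalize(manifest: dict, run_dir: Path) -> None:
    for path in sorted(run_dir.glob("*")):
        if path.name == "manifest.json" or path.is_dir():
            continue
        manifest["outputs"][path.name] = _sha256(path)
    (run_dir / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
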