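"""Synthetic-data generators for the full analysis chain.

Three generators produce every input the pipeline consumes, with known ground
truth:

* edited-MRS sessions — interleaved editing-ON/OFF spectra whose GABA+ (3.0 ppm)
  and Glx (~3.75 ppm) peak areas follow programmable load-dependent kinetics,
  plus a water-reference spectrum and voxel tissue fractions;
* BOLD-like 4D volumes — a latent Markov chain over coactivation states emits
  spatial patterns per frame, with the seed region coupled to chosen states;
* n-back behavioral sessions — 4 blocks x 44 trials with 9 congruent trials per
  block and load-dependent hit/false-alarm rates and RT distributions.

Every generator is a pure function of its parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .spectro import EditedSession, Spectrum, TissueFractions

__all__ = [
    "KineticProfile",
    "MarkovStateModel",
    "SessionDesign",
    "PeakParams",
    "MetaboliteSeries",
    "simulate_metabolite_series",
    "simulate_edited_session",
    "simulate_bold_session",
    "simulate_behavior_session",
    "flat",
    "step",
    "ramp_plateau",
    "biphasic",
]

# Seconds per ON/OFF pair: one pair spans two TRs of 2 s each.
PAIR_SECONDS = 4.0


# ---------------------------------------------------------------------------
# kinetic shape library (relative concentration multipliers, baseline 1.0)

def flat() -> Callable[[np.ndarray], np.ndarray]:
    """Constant relative concentration (no task modulation)."""
    return lambda t: np.ones_like(np.asarray(t, dtype=float))


def step(after_s: float, level: float) -> Callable[[np.ndarray], np.ndarray]:
    """Step from 1.0 to ``level`` at ``after_s`` seconds."""
    def shape(t):
        t = np.asarray(t, dtype=float)
        return np.where(t > after_s, level, 1.0)
    return shape


def ramp_plateau(rise_s: float, level: float) -> Callable[[np.ndarray], np.ndarray]:
    """Linear rise from 1.0 to ``level`` over ``rise_s`` seconds, then plateau.

    Mimics the rapid excitatory (Glx) response to sustained working-memory load.
    """
    def shape(t):
        t = np.asarray(t, dtype=float)
        frac = np.clip(t / rise_s, 0.0, 1.0)
        return 1.0 + (level - 1.0) * frac
    return shape


def biphasic(peak_s: float, peak_level: float, end_level: float,
             total_s: float) -> Callable[[np.ndarray], np.ndarray]:
    """Rise to ``peak_level`` at ``peak_s``, then linear decline to ``end_level``.

    Models the biphasic GABAergic pattern: an initial increase followed by a
    slower decline over the acquisition.
    """
    def shape(t):
        t = np.asarray(t, dtype=float)
        up = 1.0 + (peak_level - 1.0) * np.clip(t / peak_s, 0.0, 1.0)
        frac_down = np.clip((t - peak_s) / max(total_s - peak_s, 1e-9), 0.0, 1.0)
        down = peak_level + (end_level - peak_level) * frac_down
        return np.where(t <= peak_s, up, down)
    return shape


# ---------------------------------------------------------------------------
# domain types

@dataclass
class KineticProfile:
    """Ground-truth metabolite kinetics for one session.

    Shapes are unitless multipliers of the baseline concentration, evaluated at
    each ON/OFF pair's midpoint time.  ``noise_sd`` is Gaussian noise as a
    fraction of baseline; with probability ``outlier_rate`` a pair is replaced
    by an extreme value (|z| > 4 relative to the noise scale).
    """

    condition: str
    glx_shape: Callable[[np.ndarray], np.ndarray] = field(default_factory=flat)
    gaba_shape: Callable[[np.ndarray], np.ndarray] = field(default_factory=flat)
    glx_baseline: float = 10.0
    gaba_baseline: float = 2.0
    noise_sd: float = 0.0
    outlier_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.glx_baseline <= 0 or self.gaba_baseline <= 0:
            raise ValueError("baseline concentrations must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not 0.0 <= self.outlier_rate < 0.5:
            raise ValueError("outlier_rate must lie in [0, 0.5)")


@dataclass
class SessionDesign:
    """Acquisition design constants for one session.

    Paper-faithful values: 4 blocks of 44 trials with 9 congruent each,
    2 s stimulus + 0.5 s inter-stimulus crosshair, TR = 2 s, and 96 ON/OFF
    pairs at rest (192 averages) or 112 during task (224 averages).
    """

    condition: str = "rest"
    n_blocks: int = 4
    trials_per_block: int = 44
    congruent_per_block: int = 9
    stim_duration_s: float = 2.0
    isi_s: float = 0.5
    n_on_off_pairs: int = 96
    tr_s: float = 2.0

    def __post_init__(self) -> None:
        if self.congruent_per_block > self.trials_per_block:
            raise ValueError("congruent_per_block cannot exceed trials_per_block")

    @classmethod
    def for_condition(cls, condition: str) -> "SessionDesign":
        """Paper-faithful design: 96 pairs at rest, 112 during task."""
        return cls(condition=condition,
                   n_on_off_pairs=96 if condition == "rest" else 112)

    @property
    def trial_duration_s(self) -> float:
        return self.stim_duration_s + self.isi_s

    @property
    def session_seconds(self) -> float:
        return self.n_on_off_pairs * PAIR_SECONDS


@dataclass
class MarkovStateModel:
    """Latent state model generating BOLD-like frames.

    State 0 is the non-active state and emits zeros; states 1..K emit their
    spatial patterns.  ``seed_coupled`` lists states during which the seed
    region's mean signal is elevated by ``seed_boost``.
    """

    transition_matrix: np.ndarray
    emission_patterns: np.ndarray  # (K+1, nx, ny, nz)
    emission_noise_sd: float = 0.0
    seed_coupled: tuple = ()
    seed_boost: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        P = np.asarray(self.transition_matrix, dtype=float)
        self.transition_matrix = P
        self.emission_patterns = np.asarray(self.emission_patterns, dtype=float)
        if P.ndim != 2 or P.shape[0] != P.shape[1]:
            raise ValueError("transition_matrix must be square")
        if np.any(P < 0) or np.any(np.abs(P.sum(axis=1) - 1.0) > 1e-12):
            raise ValueError("transition_matrix rows must be stochastic (sum to 1)")
        if self.emission_patterns.shape[0] != P.shape[0]:
            raise ValueError("need one emission pattern per state")

    @property
    def n_states(self) -> int:
        return self.transition_matrix.shape[0]


@dataclass(frozen=True)
class PeakParams:
    """Spectral peak parameterisation for the edited-session generator.

    ``gaba_area_per_unit`` / ``glx_area_per_unit`` are the ON−OFF difference
    peak areas produced by one concentration unit.  The GABA+ peak appears in
    the ON spectra only; the Glx doublet appears in both ON and OFF with
    amplitudes whose difference carries the configured area.
    """

    gaba_center_ppm: float = 3.0
    gaba_sigma_ppm: float = 0.04
    gaba_area_per_unit: float = 1.0
    glx_center_ppm: float = 3.75
    glx_split_ppm: float = 0.08
    glx_sigma_ppm: float = 0.035
    glx_area_per_unit: float = 1.0
    glx_off_fraction: float = 0.5  # OFF carries this fraction of the ON amplitude
    water_center_ppm: float = 4.68
    water_sigma_ppm: float = 0.06
    water_area: float = 1000.0
    spectral_noise_sd: float = 0.0
    ppm_min: float = 0.5
    ppm_max: float = 10.5
    n_points: int = 2048


@dataclass
class MetaboliteSeries:
    """Per-pair ground-truth and noisy concentrations for one session."""

    condition: str
    times_s: np.ndarray
    glx_true: np.ndarray
    gaba_true: np.ndarray
    glx: np.ndarray
    gaba: np.ndarray
    outlier_pairs: np.ndarray  # boolean, pairs replaced by extreme values


# ---------------------------------------------------------------------------
# generators

def pair_midpoint_times(n_pairs: int) -> np.ndarray:
    """Midpoint acquisition time of each ON/OFF pair: (k − 0.5) · 4 s."""
    return (np.arange(1, n_pairs + 1) - 0.5) * PAIR_SECONDS


def simulate_metabolite_series(profile: KineticProfile,
                               design: SessionDesign) -> MetaboliteSeries:
    """Evaluate the kinetic shapes at each pair midpoint and add noise/outliers.

    The noiseless value of pair k is ``baseline * shape((k − 0.5) · 4 s)``.
    Gaussian noise with SD ``noise_sd * baseline`` is added independently per
    pair and metabolite; with probability ``outlier_rate`` a pair's value is
    replaced by an extreme excursion at |z| = 6 on the noise scale (a nominal
    scale of 5% of baseline is used when noise_sd = 0 so outliers remain
    injectable in noiseless runs).
    """
    t = pair_midpoint_times(design.n_on_off_pairs)
    glx_true = profile.glx_baseline * np.asarray(profile.glx_shape(t), dtype=float)
    gaba_true = profile.gaba_baseline * np.asarray(profile.gaba_shape(t), dtype=float)
    if np.any(glx_true <= 0) or np.any(gaba_true <= 0):
        raise ValueError("kinetic shapes must evaluate to positive concentrations")

    rng = np.random.default_rng(profile.seed)
    glx = glx_true + rng.normal(0.0, profile.noise_sd * profile.glx_baseline, t.size)
    gaba = gaba_true + rng.normal(0.0, profile.noise_sd * profile.gaba_baseline, t.size)

    outliers = rng.random(t.size) < profile.outlier_rate
    if outliers.any():
        signs = rng.choice([-1.0, 1.0], size=int(outliers.sum()))
        glx_scale = max(profile.noise_sd, 0.05) * profile.glx_baseline
        gaba_scale = max(profile.noise_sd, 0.05) * profile.gaba_baseline
        glx[outliers] = glx_true[outliers] + signs * 6.0 * glx_scale
        gaba[outliers] = gaba_true[outliers] + signs * 6.0 * gaba_scale

    return MetaboliteSeries(
        condition=profile.condition,
        times_s=t,
        glx_true=glx_true,
        gaba_true=gaba_true,
        glx=glx,
        gaba=gaba,
        outlier_pairs=outliers,
    )


def _gauss_area(ppm: np.ndarray, area: float, center: float, sigma: float) -> np.ndarray:
    amp = area / (sigma * np.sqrt(2.0 * np.pi))
    return amp * np.exp(-0.5 * ((ppm - center) / sigma) ** 2)


def simulate_edited_session(
    series: MetaboliteSeries,
    peaks: PeakParams = PeakParams(),
    fractions: TissueFractions = TissueFractions(0.6, 0.3, 0.1),
    seed: int = 0,
) -> EditedSession:
    """Render a metabolite series into interleaved ON/OFF spectra.

    Each pair yields one ON and one OFF spectrum on a shared ppm axis.  The
    ON−OFF difference contains a GABA+ Gaussian at 3.0 ppm and a symmetric Glx
    doublet near 3.75 ppm with areas ``concentration x area_per_unit``.  A
    single water-reference spectrum accompanies the session.
    """
    ppm = np.linspace(peaks.ppm_min, peaks.ppm_max, peaks.n_points)
    if ppm.size < 2 or peaks.ppm_min >= peaks.ppm_max:
        raise ValueError("ppm axis must be strictly monotone")
    rng = np.random.default_rng(seed)
    half = peaks.glx_split_ppm / 2.0

    on_spectra, off_spectra = [], []
    for g_conc, x_conc in zip(series.gaba, series.glx):
        gaba_peak = _gauss_area(ppm, g_conc * peaks.gaba_area_per_unit,
                                peaks.gaba_center_ppm, peaks.gaba_sigma_ppm)
        # Glx doublet: ON carries (1 + f), OFF carries f of the per-line area,
        # so the difference area equals conc * area_per_unit exactly.
        glx_line_area = x_conc * peaks.glx_area_per_unit / 2.0
        doublet = (_gauss_area(ppm, 1.0, peaks.glx_center_ppm - half, peaks.glx_sigma_ppm)
                   + _gauss_area(ppm, 1.0, peaks.glx_center_ppm + half, peaks.glx_sigma_ppm))
        on = gaba_peak + (1.0 + peaks.glx_off_fraction) * glx_line_area * doublet
        off = peaks.glx_off_fraction * glx_line_area * doublet
        if peaks.spectral_noise_sd > 0:
            on = on + rng.normal(0.0, peaks.spectral_noise_sd, ppm.size)
            off = off + rng.normal(0.0, peaks.spectral_noise_sd, ppm.size)
        on_spectra.append(Spectrum(ppm, on, kind="ON"))
        off_spectra.append(Spectrum(ppm, off, kind="OFF"))

    water = Spectrum(
        ppm,
        _gauss_area(ppm, peaks.water_area, peaks.water_center_ppm, peaks.water_sigma_ppm),
        kind="WATER",
    )
    return EditedSession(condition=series.condition, on=on_spectra, off=off_spectra,
                         water=water, fractions=fractions)


def simulate_bold_session(
    model: MarkovStateModel,
    n_frames: int,
    seed_center_mm: Sequence[float],
    seed_radius_mm: float = 10.0,
    voxel_size_mm: float = 3.0,
    initial_state: int | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sample a state path and emit one spatial volume per frame.

    Returns ``(volume4d, true_states, affine)`` where ``volume4d`` has shape
    ``(nx, ny, nz, n_frames)`` and the affine maps voxel indices to mm with
    isotropic ``voxel_size_mm`` spacing.  Whenever the current state is
    seed-coupled, the voxels within ``seed_radius_mm`` of ``seed_center_mm``
    gain ``seed_boost``.
    """
    if n_frames < 2:
        raise ValueError("n_frames must be at least 2")
    grid_shape = model.emission_patterns.shape[1:]
    affine = np.diag([voxel_size_mm] * 3 + [1.0])
    centers = np.stack(np.meshgrid(*[np.arange(s) for s in grid_shape],
                                   indexing="ij"), axis=-1) * voxel_size_mm
    dist = np.linalg.norm(centers - np.asarray(seed_center_mm, dtype=float), axis=-1)
    seed_mask = dist <= seed_radius_mm
    if not seed_mask.any():
        raise ValueError("seed sphere does not intersect the voxel grid")

    rng = np.random.default_rng(model.seed)
    K1 = model.n_states
    states = np.empty(n_frames, dtype=int)
    states[0] = initial_state if initial_state is not None else rng.integers(K1)
    for t in range(1, n_frames):
        states[t] = rng.choice(K1, p=model.transition_matrix[states[t - 1]])

    vol = model.emission_patterns[states].astype(float)  # (T, nx, ny, nz)
    if model.emission_noise_sd > 0:
        vol = vol + rng.normal(0.0, model.emission_noise_sd, vol.shape)
    if model.seed_boost != 0.0 and model.seed_coupled:
        coupled = np.isin(states, np.asarray(model.seed_coupled))
        vol[coupled] += model.seed_boost * seed_mask
    return np.moveaxis(vol, 0, -1), states, affine


def simulate_behavior_session(
    design: SessionDesign,
    hit_rate: float,
    fa_rate: float,
    rt_mean_ms: float = 550.0,
    rt_sd_ms: float = 90.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Generate one n-back session's trial table.

    Exactly ``congruent_per_block`` congruent trials are placed at random
    positions within each block.  Congruent trials are responded to with
    probability ``hit_rate``; incongruent trials draw a false alarm with
    probability ``fa_rate``.  RTs are Gaussian (truncated at 150 ms) and
    present only for responded trials.

    Columns: ``trial block type responded rt_ms`` (rt_ms is NaN without a
    response).
    """
    if not (0.0 <= hit_rate <= 1.0 and 0.0 <= fa_rate <= 1.0):
        raise ValueError("hit_rate and fa_rate must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    rows = []
    trial_no = 0
    for block in range(1, design.n_blocks + 1):
        congruent_pos = rng.choice(design.trials_per_block,
                                   size=design.congruent_per_block, replace=False)
        is_congruent = np.zeros(design.trials_per_block, dtype=bool)
        is_congruent[congruent_pos] = True
        for pos in range(design.trials_per_block):
            trial_no += 1
            congruent = bool(is_congruent[pos])
            p_resp = hit_rate if congruent else fa_rate
            responded = bool(rng.random() < p_resp)
            rt = float(max(rng.normal(rt_mean_ms, rt_sd_ms), 150.0)) if responded else np.nan
            rows.append({
                "trial": trial_no,
                "block": block,
                "type": "congruent" if congruent else "incongruent",
                "responded": responded,
                "rt_ms": rt,
            })
    return pd.DataFrame(rows)
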