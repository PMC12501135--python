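"""Sliding-window metabolite kinetics: dynamic frames, normalization, cleaning
and area-under-curve summaries, plus static per-session concentrations.

A window of 60 ON/OFF pairs (4 min of acquisition) is shifted in steps of
3 pairs (12 s).  A 112-pair task session yields 18 dynamic frames; the 96-pair
resting session is trimmed by 3 leading pairs so that it yields 12 frames of
the same length.  Each frame's spectra are averaged and fitted, giving per-frame
GABA+, Glx and EIB; curves are normalized to their first frame, frames that
deviate from the curve median by more than a robust-z threshold are replaced by
the median of their neighbours, and the trapezoidal AUC of (normalized − 1)
summarizes the kinetic excursion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import spectro
from .spectro import Concentration, EditedSession, TissueFractions
from .synthgen import MetaboliteSeries, PAIR_SECONDS

__all__ = [
    "WindowGrid",
    "ConcentrationCurve",
    "window_indices",
    "eib_curve",
    "curve_from_series",
    "curve_from_session",
    "curve_auc",
    "static_concentration",
    "interpolate_outliers",
]

DEFAULT_WINDOW_PAIRS = 60
DEFAULT_STEP_PAIRS = 3


@dataclass(frozen=True)
class WindowGrid:
    """Sliding-window layout over ON/OFF pair indices (half-open ranges)."""

    n_pairs: int
    window_pairs: int
    step_pairs: int
    trim_leading_pairs: int
    windows: tuple  # tuple[(start, end), ...]

    @property
    def n_windows(self) -> int:
        return len(self.windows)

    @property
    def step_seconds(self) -> float:
        return self.step_pairs * PAIR_SECONDS


def _n_full_windows(n_pairs: int, trim: int, window: int, step: int) -> int:
    usable = n_pairs - trim
    if usable < window:
        return 0
    return (usable - window) // step + 1


def window_indices(
    n_pairs: int,
    window_pairs: int = DEFAULT_WINDOW_PAIRS,
    step_pairs: int = DEFAULT_STEP_PAIRS,
    target_frames: int | None = None,
) -> WindowGrid:
    """Enumerate sliding windows over a session's pairs.

    Without ``target_frames`` the grid starts at pair 0.  With it, the smallest
    number of leading pairs is discarded so that exactly ``target_frames`` full
    windows fit — the mechanism used to reduce the 96-pair resting session to
    the 12 frames shared across conditions.
    """
    if n_pairs < window_pairs:
        raise ValueError(f"need at least {window_pairs} pairs, got {n_pairs}")
    trim = 0
    if target_frames is not None:
        max_frames = _n_full_windows(n_pairs, 0, window_pairs, step_pairs)
        if target_frames > max_frames or target_frames < 1:
            raise ValueError(
                f"target_frames={target_frames} unachievable: "
                f"at most {max_frames} windows fit in {n_pairs} pairs")
        # discard exactly the leading pairs the target grid cannot cover, so
        # the last window ends flush at the final pair (96 pairs -> trim 3
        # leading pairs -> 12 windows over pairs 3..96)
        trim = n_pairs - (window_pairs + (target_frames - 1) * step_pairs)
        if _n_full_windows(n_pairs, trim, window_pairs, step_pairs) != target_frames:
            raise ValueError(
                f"target_frames={target_frames} unachievable with step {step_pairs}")
    n_win = _n_full_windows(n_pairs, trim, window_pairs, step_pairs)
    windows = tuple(
        (trim + i * step_pairs, trim + i * step_pairs + window_pairs)
        for i in range(n_win)
    )
    return WindowGrid(n_pairs=n_pairs, window_pairs=window_pairs,
                      step_pairs=step_pairs, trim_leading_pairs=trim,
                      windows=windows)


@dataclass
class ConcentrationCurve:
    """Per-window concentration estimates for one session.

    ``gaba``, ``glx`` and ``eib`` are the raw per-frame values after outlier
    interpolation; ``*_norm`` are divided by the first frame (so frame 0 is
    exactly 1).  ``outlier_mask`` marks frames replaced during cleaning of the
    EIB curve.
    """

    condition: str
    grid: WindowGrid
    gaba: np.ndarray
    glx: np.ndarray
    eib: np.ndarray
    gaba_norm: np.ndarray
    glx_norm: np.ndarray
    eib_norm: np.ndarray
    outlier_mask: np.ndarray

    @property
    def n_frames(self) -> int:
        return self.eib.size

    @property
    def auc(self) -> float:
        return curve_auc(self)


def interpolate_outliers(values: np.ndarray, z: float = 2.0) -> tuple[np.ndarray, np.ndarray]:
    """Median interpolation of outlier frames.

    A frame is an outlier when it deviates from the curve median by more than
    ``z`` robust SDs (1.4826 x MAD).  Outliers are replaced by the median of
    their two neighbours (a single neighbour at the endpoints), using the
    original neighbour values so the operation is order-independent.  Returns
    (cleaned, mask).  When the MAD is zero no frame is flagged.
    """
    x = np.asarray(values, dtype=float)
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    robust_sd = 1.4826 * mad
    if robust_sd == 0:
        return x.copy(), np.zeros(x.size, dtype=bool)
    mask = np.abs(x - med) > z * robust_sd
    cleaned = x.copy()
    for i in np.nonzero(mask)[0]:
        neighbours = [x[j] for j in (i - 1, i + 1) if 0 <= j < x.size]
        cleaned[i] = float(np.median(neighbours))
    return cleaned, mask


def _normalize(values: np.ndarray) -> np.ndarray:
    if values[0] <= 0:
        raise ValueError("cannot normalize: first-frame value is non-positive")
    out = values / values[0]
    out[0] = 1.0  # exact by contract
    return out


def _assemble_curve(condition: str, grid: WindowGrid, gaba: np.ndarray,
                    glx: np.ndarray, outlier_z: float) -> ConcentrationCurve:
    # EIB is computed per frame from that frame's fits, THEN cleaned and
    # normalized; it is never re-derived from the normalized metabolite curves.
    eib_raw = glx / gaba
    gaba_c, _ = interpolate_outliers(gaba, outlier_z)
    glx_c, _ = interpolate_outliers(glx, outlier_z)
    eib_c, mask = interpolate_outliers(eib_raw, outlier_z)
    return ConcentrationCurve(
        condition=condition,
        grid=grid,
        gaba=gaba_c,
        glx=glx_c,
        eib=eib_c,
        gaba_norm=_normalize(gaba_c),
        glx_norm=_normalize(glx_c),
        eib_norm=_normalize(eib_c),
        outlier_mask=mask,
    )


def curve_from_series(series: MetaboliteSeries, grid: WindowGrid,
                      outlier_z: float = 2.0) -> ConcentrationCurve:
    """Concentration-input mode: average per-pair values within each window."""
    if grid.n_pairs != series.glx.size:
        raise ValueError("grid inconsistent with series length")
    gaba = np.array([series.gaba[a:b].mean() for a, b in grid.windows])
    glx = np.array([series.glx[a:b].mean() for a, b in grid.windows])
    return _assemble_curve(series.condition, grid, gaba, glx, outlier_z)


def curve_from_session(session: EditedSession, grid: WindowGrid,
                       outlier_z: float = 2.0,
                       mm_correct: bool = False) -> ConcentrationCurve:
    """Spectral mode: average each window's ON and OFF spectra, fit the
    difference, and quantify against the session's water reference."""
    if grid.n_pairs != session.n_pairs:
        raise ValueError("grid inconsistent with session length")
    water_area = _water_area(session)
    gaba, glx = [], []
    for a, b in grid.windows:
        diff = _window_diff(session, a, b)
        fit = spectro.fit_diff_spectrum(diff)
        conc = spectro.quantify_concentration(fit, water_area, session.fractions,
                                              mm_correct=mm_correct)
        gaba.append(conc.gaba_plus)
        glx.append(conc.glx)
    return _assemble_curve(session.condition, grid, np.asarray(gaba),
                           np.asarray(glx), outlier_z)


def eib_curve(data, grid: WindowGrid, outlier_z: float = 2.0) -> ConcentrationCurve:
    """Build the per-window EIB curve from either an EditedSession (spectral
    mode) or a MetaboliteSeries (concentration-input mode)."""
    if isinstance(data, EditedSession):
        return curve_from_session(data, grid, outlier_z)
    if isinstance(data, MetaboliteSeries):
        return curve_from_series(data, grid, outlier_z)
    raise TypeError("eib_curve expects an EditedSession or MetaboliteSeries")


def curve_auc(curve: ConcentrationCurve, which: str = "eib") -> float:
    """Trapezoidal integral of (normalized − 1) with unit frame spacing.

    Positive values indicate a net excursion above baseline.
    """
    norm = {"eib": curve.eib_norm, "glx": curve.glx_norm,
            "gaba": curve.gaba_norm}[which]
    if norm.size < 2:
        raise ValueError("AUC needs at least 2 frames")
    return float(np.trapezoid(norm - 1.0))


def _window_diff(session: EditedSession, a: int, b: int):
    on_mean = np.mean([s.intensity for s in session.on[a:b]], axis=0)
    off_mean = np.mean([s.intensity for s in session.off[a:b]], axis=0)
    ppm = session.on[0].ppm
    from .spectro import Spectrum
    return Spectrum(ppm, on_mean - off_mean, kind="DIFF")


def _water_area(session: EditedSession) -> float:
    # numeric integral of the water-reference spectrum over its full axis
    w = session.water
    sign = 1.0 if w.ascending else -1.0
    return float(sign * np.trapezoid(w.intensity, w.ppm))


def static_concentration(session: EditedSession,
                         mm_correct: bool = False) -> Concentration:
    """Whole-session concentration: all ON averaged, all OFF averaged, one
    difference fit, one quantification.  The resting-state value serves as the
    subject-specific baseline."""
    diff = _window_diff(session, 0, session.n_pairs)
    fit = spectro.fit_diff_spectrum(diff)
    return spectro.quantify_concentration(fit, _water_area(session),
                                          session.fractions, mm_correct=mm_correct)
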