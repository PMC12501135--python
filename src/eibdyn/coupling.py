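"""Partial least squares correlation (PLSC) between CAP temporal features and
EIB visibility-graph features.

PLSC decomposes the cross-block covariance R = Yᵀ X / (n − 1) of two z-scored
feature blocks by SVD, R = U S Vᵀ.  Each latent component pairs an X-side
loading vector (column of V) with a Y-side loading vector (column of U);
subject scores are the projections X V and Y U.  Component significance comes
from permutation of Y's rows (null distribution of the singular values) and
loading stability from bootstrap resampling of subjects with percentile CIs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

__all__ = [
    "FeatureBlock",
    "PlscResult",
    "assemble_blocks",
    "plsc_fit",
    "plsc_significance",
    "CAP_METRICS",
    "EIB_FEATURES",
    "SESSIONS",
]

SESSIONS = ("rest", "0back", "1back", "2back")
CAP_METRICS = ("occurrences_pct", "resilience", "in_degree", "out_degree", "betweenness")
EIB_FEATURES = ("mean_out_degree", "kld")


@dataclass
class FeatureBlock:
    """Subjects x features matrix, column z-scored, with named columns."""

    values: np.ndarray
    column_names: list
    subjects: list

    @property
    def shape(self) -> tuple:
        return self.values.shape


def _zscore_columns(values: np.ndarray, names) -> np.ndarray:
    mean = values.mean(axis=0)
    sd = values.std(axis=0, ddof=1)
    bad = np.nonzero(sd == 0)[0]
    if bad.size:
        raise ValueError(f"constant column(s): {[names[i] for i in bad]}")
    return (values - mean) / sd


def assemble_blocks(cap_metrics: pd.DataFrame, eib_features: pd.DataFrame,
                    sessions=SESSIONS, cap_features=CAP_METRICS,
                    eib_feature_names=EIB_FEATURES,
                    ) -> tuple[FeatureBlock, FeatureBlock]:
    """Build the X (CAP) and Y (EIB) blocks from long-form per-subject tables.

    ``cap_metrics`` columns: subject, session, plus the five CAP temporal
    metrics; ``eib_features`` columns: subject, session, mean_out_degree, kld.
    Column order is metric-major, session-minor (e.g. occurrences_pct_rest,
    occurrences_pct_0back, ...).  Every subject must have every session; a
    missing cell raises, listing the offending (subject, session) pairs, and a
    constant column raises naming the column (no silent imputation either way).
    """
    subjects = sorted(set(cap_metrics["subject"]) & set(eib_features["subject"]))
    if set(cap_metrics["subject"]) != set(eib_features["subject"]):
        raise ValueError("CAP and EIB tables cover different subject sets")

    def build(table, features):
        missing = []
        cols = []
        names = []
        idx = table.set_index(["subject", "session"]).sort_index()
        for feat in features:
            for ses in sessions:
                names.append(f"{feat}_{ses}")
                col = []
                for subj in subjects:
                    try:
                        col.append(float(idx.loc[(subj, ses), feat]))
                    except KeyError:
                        missing.append((subj, ses))
                        col.append(np.nan)
                cols.append(col)
        if missing:
            raise ValueError(f"missing subject-session cells: {sorted(set(missing))}")
        values = np.asarray(cols).T
        return FeatureBlock(values=_zscore_columns(values, names),
                            column_names=names, subjects=list(subjects))

    return build(cap_metrics, cap_features), build(eib_features, eib_feature_names)


@dataclass
class PlscResult:
    """Latent components of the cross-block covariance decomposition."""

    singular_values: np.ndarray
    explained_cov_pct: np.ndarray
    x_loadings: np.ndarray          # (p_x, n_comp) columns of V
    y_loadings: np.ndarray          # (p_y, n_comp) columns of U
    x_scores: np.ndarray            # X @ V
    y_scores: np.ndarray            # Y @ U
    score_correlation: np.ndarray   # Pearson r per component
    perm_p: np.ndarray | None = None
    x_loading_ci: np.ndarray | None = None   # (p_x, n_comp, 2)
    y_loading_ci: np.ndarray | None = None
    x_loading_reliable: np.ndarray | None = None
    y_loading_reliable: np.ndarray | None = None
    x_names: list | None = None
    y_names: list | None = None


def _svd_cross_cov(X: np.ndarray, Y: np.ndarray):
    n = X.shape[0]
    R = Y.T @ X / (n - 1)
    U, s, Vt = np.linalg.svd(R, full_matrices=False)
    return U, s, Vt.T


def plsc_fit(X: FeatureBlock | np.ndarray, Y: FeatureBlock | np.ndarray) -> PlscResult:
    """Decompose the cross-block covariance into latent components.

    Sign convention: within each component the X loading of largest magnitude
    is made positive (the Y loading flips with it so scores stay paired).
    """
    Xv = X.values if isinstance(X, FeatureBlock) else np.asarray(X, dtype=float)
    Yv = Y.values if isinstance(Y, FeatureBlock) else np.asarray(Y, dtype=float)
    if Xv.shape[0] != Yv.shape[0] or Xv.shape[0] < 3:
        raise ValueError("X and Y need the same number of rows, at least 3")
    U, s, V = _svd_cross_cov(Xv, Yv)
    if np.allclose(s, 0):
        warnings.warn("cross-covariance has rank 0; all components are null")
    for i in range(s.size):
        j = int(np.argmax(np.abs(V[:, i])))
        if V[j, i] < 0:
            V[:, i] *= -1
            U[:, i] *= -1
    x_scores = Xv @ V
    y_scores = Yv @ U
    total = float(np.sum(s**2))
    explained = 100.0 * s**2 / total if total > 0 else np.zeros_like(s)
    r = np.array([
        pearsonr(x_scores[:, i], y_scores[:, i])[0]
        if np.std(x_scores[:, i]) > 0 and np.std(y_scores[:, i]) > 0 else 0.0
        for i in range(s.size)
    ])
    return PlscResult(
        singular_values=s,
        explained_cov_pct=explained,
        x_loadings=V,
        y_loadings=U,
        x_scores=x_scores,
        y_scores=y_scores,
        score_correlation=r,
        x_names=getattr(X, "column_names", None),
        y_names=getattr(Y, "column_names", None),
    )


def plsc_significance(
    X: FeatureBlock | np.ndarray,
    Y: FeatureBlock | np.ndarray,
    n_perm: int = 1000,
    n_boot: int = 10_000,
    seed: int = 0,
) -> PlscResult:
    """Permutation p-values and bootstrap loading CIs for the PLSC components.

    Permutation: Y's rows are shuffled, the decomposition refit, and component
    i's null statistic is the i-th singular value; p uses the add-one estimator
    (1 + #{null ≥ observed}) / (1 + n_perm), never exactly zero.  Bootstrap:
    subjects are resampled with replacement, loadings sign-aligned to the
    original by inner product, and percentile 95% CIs reported; a loading is
    reliable when its CI excludes zero.
    """
    if n_perm < 100:
        warnings.warn("fewer than 100 permutations gives unstable p-values")
    Xv = X.values if isinstance(X, FeatureBlock) else np.asarray(X, dtype=float)
    Yv = Y.values if isinstance(Y, FeatureBlock) else np.asarray(Y, dtype=float)
    res = plsc_fit(X, Y)
    rng = np.random.default_rng(seed)
    n = Xv.shape[0]
    n_comp = res.singular_values.size

    exceed = np.zeros(n_comp)
    for _ in range(n_perm):
        perm = rng.permutation(n)
        _, s_null, _ = _svd_cross_cov(Xv, Yv[perm])
        exceed += s_null >= res.singular_values
    res.perm_p = (1.0 + exceed) / (1.0 + n_perm)

    if n_boot == 0:
        return res
    boot_x = np.empty((n_boot, *res.x_loadings.shape))
    boot_y = np.empty((n_boot, *res.y_loadings.shape))
    for b in range(n_boot):
        rows = rng.integers(n, size=n)
        try:
            Ub, sb, Vb = _svd_cross_cov(Xv[rows], Yv[rows])
        except np.linalg.LinAlgError:
            boot_x[b] = np.nan
            boot_y[b] = np.nan
            continue
        for i in range(n_comp):
            sign = np.sign(res.x_loadings[:, i] @ Vb[:, i]) or 1.0
            boot_x[b, :, i] = sign * Vb[:, i]
            boot_y[b, :, i] = sign * Ub[:, i]
    res.x_loading_ci = np.stack(
        [np.nanpercentile(boot_x, 2.5, axis=0), np.nanpercentile(boot_x, 97.5, axis=0)],
        axis=-1)
    res.y_loading_ci = np.stack(
        [np.nanpercentile(boot_y, 2.5, axis=0), np.nanpercentile(boot_y, 97.5, axis=0)],
        axis=-1)
    res.x_loading_reliable = (res.x_loading_ci[..., 0] > 0) | (res.x_loading_ci[..., 1] < 0)
    res.y_loading_reliable = (res.y_loading_ci[..., 0] > 0) | (res.y_loading_ci[..., 1] < 0)
    return res
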