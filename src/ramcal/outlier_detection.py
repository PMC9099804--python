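"""PCA-based outlier screening of preprocessed spectra.

Two complementary diagnostics: Hotelling's T² flags samples far from the
training cloud *within* the PCA score space (F-distribution confidence
boundary), DmodX flags samples with unusually large residual *off* the model
plane. A row is flagged when it exceeds either limit; flags are auditable
and reversible — flagged rows are excluded from calibration but stay in the
dataset.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA


@dataclass
class PCAModel:
    center: np.ndarray
    loadings: np.ndarray       # (n_components, n_channels), orthonormal rows
    scores: np.ndarray         # (n_train, n_components)
    variances: np.ndarray      # per-component score variance (ddof=1)
    n_components: int
    n_train: int
    s0: float                  # pooled training residual sd

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return (X - self.center) @ self.loadings.T

    def residual(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float)) - self.center
        return X - self.transform(X + self.center) @ self.loadings


def fit_pca(X: np.ndarray, n_components: int) -> PCAModel:
    """Principal component analysis of the centered spectra matrix."""
    X = np.asarray(X, dtype=float)
    n, k = X.shape
    if n_components > min(n - 1, k):
        raise ValueError("n_components exceeds the data rank bound")
    if np.allclose(X.std(axis=0), 0):
        raise ValueError("degenerate (constant) data matrix")
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X)
    variances = scores.var(axis=0, ddof=1)
    model = PCAModel(center=pca.mean_, loadings=pca.components_,
                     scores=scores, variances=variances,
                     n_components=n_components, n_train=n, s0=0.0)
    resid = model.residual(X)
    dof = max((n - n_components - 1) * (k - n_components), 1)
    model.s0 = float(np.sqrt(np.sum(resid ** 2) / dof))
    return model


def pick_n_components(X: np.ndarray, explained: float = 0.99, cap: int = 10) -> int:
    """Smallest component count explaining >= ``explained`` variance, capped."""
    X = np.asarray(X, dtype=float)
    limit = min(X.shape[0] - 1, X.shape[1], cap)
    pca = PCA(n_components=limit, svd_solver="full").fit(X)
    cum = np.cumsum(pca.explained_variance_ratio_)
    return int(np.searchsorted(cum, explained) + 1) if cum[-1] >= explained else limit


def hotelling_t2(model: PCAModel, score_row: np.ndarray) -> float:
    """T² = sum_a t_a^2 / s_a^2 over the retained components."""
    if np.any(model.variances <= 0):
        raise ValueError("zero component variance")
    t = np.asarray(score_row, dtype=float)
    return float(np.sum(t ** 2 / model.variances))


def t2_limit(model: PCAModel, alpha: float = 0.05) -> float:
    """F-based confidence boundary: A(n-1)/(n-A) * F_{1-alpha}(A, n-A)."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    a, n = model.n_components, model.n_train
    if n <= a:
        raise ValueError("need more training rows than components")
    return a * (n - 1) / (n - a) * stats.f.ppf(1 - alpha, a, n - a)


def dmodx(model: PCAModel, x_row: np.ndarray) -> float:
    """Normalized distance to the model: residual sd of the observation
    after projection, divided by the pooled training residual sd s0."""
    resid = model.residual(np.atleast_2d(x_row))[0]
    k = resid.size
    s_i = np.sqrt(np.sum(resid ** 2) / max(k - model.n_components, 1))
    return float(s_i / model.s0) if model.s0 > 0 else 0.0


def screen_outliers(X: np.ndarray, metadata: pd.DataFrame | None = None,
                    alpha: float = 0.05, n_components: int | None = None,
                    dmodx_confirm: float = 2.0, dmodx_crit: float = 3.0,
                    t2_extreme_factor: float = 5.0,
                    refine_passes: int = 1,
                    warn_fraction: float = 0.05) -> tuple[pd.DataFrame, dict]:
    """Screen preprocessed spectra for multivariate outliers.

    Two-stage rule: rows outside the T² boundary at ``alpha`` are outlier
    *candidates* and are confirmed when their DmodX also exceeds
    ``dmodx_confirm``; independently, a DmodX above the harder
    ``dmodx_crit`` flags a row on its own (an observation can sit near the
    score-space center yet far off the model plane), and a T² beyond
    ``t2_extreme_factor`` times the boundary is flagged without
    confirmation — an action limit far outside the confidence ellipse.
    Merely-unconfirmed T² candidates are logged but not flagged — legitimate extreme samples (the
    spiked arms of the score cloud) would otherwise be discarded.

    After the first pass the PCA is refit on the unflagged rows and every
    row re-scored (``refine_passes`` times): a cluster of similar artifacts
    would otherwise contribute its own principal component and mask itself.
    Emits a warning when the flagged fraction reaches ``warn_fraction``; a
    healthy run stays well below 5%.
    """
    X = np.asarray(X, dtype=float)
    keep = np.ones(X.shape[0], dtype=bool)
    for _pass in range(refine_passes + 1):
        flags = _screen_once(X, X[keep], alpha, n_components,
                             dmodx_confirm, dmodx_crit, t2_extreme_factor)
        new_keep = ~flags["flagged"].to_numpy()
        if np.array_equal(new_keep, keep):
            break
        keep = new_keep

    if metadata is not None and "record_id" in metadata:
        flags.insert(0, "record_id", metadata["record_id"].to_numpy())

    fraction = float(flags["flagged"].mean())
    if fraction >= warn_fraction:
        warnings.warn(f"outlier fraction {fraction:.1%} >= {warn_fraction:.0%}",
                      stacklevel=2)
    summary = {"n": int(len(flags)), "n_flagged": int(flags["flagged"].sum()),
               "fraction": fraction,
               "n_components": int(flags.attrs["n_components"]),
               "t2_limit": float(flags["t2_limit"].iloc[0]),
               "dmodx_crit": dmodx_crit, "alpha": alpha}
    return flags, summary


def _screen_once(X_all: np.ndarray, X_train: np.ndarray, alpha: float,
                 n_components: int | None, dmodx_confirm: float,
                 dmodx_crit: float, t2_extreme_factor: float) -> pd.DataFrame:
    if n_components is None:
        n_components = pick_n_components(X_train)
    model = fit_pca(X_train, n_components)
    limit = t2_limit(model, alpha)
    scores_all = model.transform(X_all)

    rows = []
    for i in range(X_all.shape[0]):
        t2 = hotelling_t2(model, scores_all[i])
        dx = dmodx(model, X_all[i])
        confirmed = t2 > limit and dx > dmodx_confirm
        dx_out = dx > dmodx_crit
        t2_extreme = t2 > t2_extreme_factor * limit
        if confirmed and dx_out:
            reason = "t2+dmodx"
        elif confirmed:
            reason = "t2_confirmed"
        elif t2_extreme:
            reason = "t2_extreme"
        elif dx_out:
            reason = "dmodx"
        elif t2 > limit:
            reason = "t2_candidate"  # logged, not flagged
        else:
            reason = ""
        rows.append({"t2": t2, "t2_limit": limit, "dmodx": dx,
                     "flagged": bool(confirmed or dx_out or t2_extreme),
                     "reason": reason})
    flags = pd.DataFrame(rows)
    flags.attrs["n_components"] = n_components
    return flags
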