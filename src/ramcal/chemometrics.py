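"""PLS1 (NIPALS) and OPLS regression — the calibration core.

OPLS splits the spectral variation into exactly one y-predictive component
and ``n_ortho`` components orthogonal to y (Trygg-Wold construction). Its
predictions coincide with those of a PLS1 model with ``1 + n_ortho``
components; the orthogonal split exists for interpretability, not extra
predictive power, and that equivalence is the central algebra check of the
test suite.

Conventions, fixed: the X-block is mean-centered only; the y-block is
centered and scaled to unit variance. Both are stored on the model for exact
inversion at prediction time.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

NIPALS_TOL = 1e-10
NIPALS_MAX_ITER = 500


@dataclass
class PLS1Model:
    x_center: np.ndarray
    y_center: float
    y_scale: float
    weights: np.ndarray     # (n_components, n_channels), deflated-X weights
    loadings: np.ndarray    # (n_components, n_channels)
    q: np.ndarray           # (n_components,) inner regression coefficients
    n_components: int

    def predict(self, X_new: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X_new, dtype=float)) - self.x_center
        yhat = np.zeros(X.shape[0])
        for a in range(self.n_components):
            t = X @ self.weights[a]
            yhat += t * self.q[a]
            X = X - np.outer(t, self.loadings[a])
        return yhat * self.y_scale + self.y_center


@dataclass
class OPLSModel:
    """Fitted OPLS calibration for one analyte.

    ``w`` (unit norm) and ``p``/``b`` define the single predictive
    component; ``w_ortho``/``p_ortho`` hold the y-orthogonal filter applied
    before projection. ``region_mask`` records which spectral channels the
    model consumes.
    """

    x_center: np.ndarray
    y_center: float
    y_scale: float
    w_ortho: np.ndarray      # (n_ortho, n_channels)
    p_ortho: np.ndarray      # (n_ortho, n_channels)
    w: np.ndarray            # (n_channels,), unit norm
    p: np.ndarray            # (n_channels,)
    b: float                 # regression scalar on the predictive score
    analyte: str = ""
    region_mask: np.ndarray | None = None
    n_train: int = 0
    y_range: tuple[float, float] = (0.0, 0.0)

    @property
    def n_ortho(self) -> int:
        return self.w_ortho.shape[0]

    def filter_orthogonal(self, X_new: np.ndarray) -> np.ndarray:
        """Remove the modeled y-orthogonal variation from centered rows."""
        X = np.atleast_2d(np.asarray(X_new, dtype=float)) - self.x_center
        for w_o, p_o in zip(self.w_ortho, self.p_ortho):
            t_o = X @ w_o
            X = X - np.outer(t_o, p_o)
        return X

    def predict(self, X_new: np.ndarray) -> np.ndarray:
        X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
        if X_new.shape[1] != self.x_center.size:
            raise ValueError(
                f"channel mismatch: model expects {self.x_center.size}, "
                f"got {X_new.shape[1]}")
        Xf = self.filter_orthogonal(X_new)
        t = Xf @ self.w
        return t * self.b * self.y_scale + self.y_center

    def to_json(self) -> str:
        payload = {
            "analyte": self.analyte, "n_ortho": int(self.n_ortho),
            "n_train": int(self.n_train), "y_range": list(self.y_range),
            "x_center": self.x_center.tolist(),
            "y_center": self.y_center, "y_scale": self.y_scale,
            "w_ortho": self.w_ortho.tolist(), "p_ortho": self.p_ortho.tolist(),
            "w": self.w.tolist(), "p": self.p.tolist(), "b": self.b,
            "region_mask": (self.region_mask.tolist()
                            if self.region_mask is not None else None),
        }
        return json.dumps(payload)

    @classmethod
    def from_json(cls, text: str) -> "OPLSModel":
        d = json.loads(text)
        return cls(
            x_center=np.array(d["x_center"]), y_center=d["y_center"],
            y_scale=d["y_scale"],
            w_ortho=np.array(d["w_ortho"]).reshape(d["n_ortho"], -1)
            if d["n_ortho"] else np.empty((0, len(d["w"]))),
            p_ortho=np.array(d["p_ortho"]).reshape(d["n_ortho"], -1)
            if d["n_ortho"] else np.empty((0, len(d["w"]))),
            w=np.array(d["w"]), p=np.array(d["p"]), b=d["b"],
            analyte=d["analyte"],
            region_mask=np.array(d["region_mask"], dtype=bool)
            if d["region_mask"] is not None else None,
            n_train=d["n_train"], y_range=tuple(d["y_range"]))


def _center_scale(X: np.ndarray, y: np.ndarray):
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.shape[0] != y.size:
        raise ValueError("X rows and y length differ")
    x_center = X.mean(axis=0)
    y_center = float(y.mean())
    y_scale = float(y.std(ddof=1)) if y.size > 1 else 0.0
    if y_scale <= 0:
        raise ValueError("y has zero variance; cannot scale")
    return X - x_center, (y - y_center) / y_scale, x_center, y_center, y_scale


def fit_pls1(X: np.ndarray, y: np.ndarray, n_components: int) -> PLS1Model:
    """PLS1 by NIPALS deflation (mean-centered X, autoscaled y).

    For a single response the per-component weight has the closed form
    w = X'y / ||X'y||; deflation of X then makes the iteration exact in one
    pass, so no inner loop is needed.
    """
    Xc, yc, x_center, y_center, y_scale = _center_scale(X, y)
    n, k = Xc.shape
    if n_components > min(n - 1, k):
        raise ValueError("n_components too large for the data")
    W, P, Q = [], [], []
    for _ in range(n_components):
        xy = Xc.T @ yc
        norm = np.linalg.norm(xy)
        if norm < NIPALS_TOL:
            raise ValueError("residual X carries no covariance with y; "
                             "reduce n_components")
        w = xy / norm
        t = Xc @ w
        tt = float(t @ t)
        p = Xc.T @ t / tt
        q = float(yc @ t / tt)
        Xc = Xc - np.outer(t, p)
        W.append(w); P.append(p); Q.append(q)
    return PLS1Model(x_center, y_center, y_scale,
                     np.array(W).reshape(n_components, k),
                     np.array(P).reshape(n_components, k),
                     np.array(Q), n_components)


def fit_opls(X: np.ndarray, y: np.ndarray, n_ortho: int,
             analyte: str = "", region_mask: np.ndarray | None = None) -> OPLSModel:
    """Fit an OPLS model with one predictive and ``n_ortho`` orthogonal
    components (Trygg-Wold).

    Each orthogonal weight is the part of the current X-loading that is
    orthogonal to the predictive weight w; its score is therefore
    uncorrelated with y by construction, and deflating it strips systematic
    y-orthogonal variation (fluorescence residue, matrix effects) before the
    single predictive projection.
    """
    Xc, yc, x_center, y_center, y_scale = _center_scale(X, y)
    n, k = Xc.shape
    if n_ortho < 0:
        raise ValueError("n_ortho must be >= 0")
    if n_ortho + 1 > min(n - 1, k):
        raise ValueError("n_ortho too large for the rank of X")

    def _w_of(Xd):
        xy = Xd.T @ yc
        norm = np.linalg.norm(xy)
        if norm < NIPALS_TOL:
            raise ValueError("X carries no covariance with y")
        return xy / norm

    # w is invariant under orthogonal deflation in exact arithmetic; it is
    # refreshed from the deflated X each round to keep the orthogonal scores
    # y-orthogonal to machine precision
    w = _w_of(Xc)

    W_o, P_o = [], []
    for _ in range(n_ortho):
        t = Xc @ w
        p = Xc.T @ t / float(t @ t)
        w_o = p - float(w @ p) * w
        w_o -= float(w @ w_o) * w  # re-orthogonalize: cancellation in the
        norm_o = np.linalg.norm(w_o)  # first pass is amplified when the
        if norm_o < NIPALS_TOL:       # orthogonal part is small
            raise ValueError("no y-orthogonal variation left to extract")
        w_o /= norm_o
        w_o -= float(w @ w_o) * w
        t_o = Xc @ w_o
        p_o = Xc.T @ t_o / float(t_o @ t_o)
        Xc = Xc - np.outer(t_o, p_o)
        W_o.append(w_o); P_o.append(p_o)
        w = _w_of(Xc)

    t = Xc @ w
    tt = float(t @ t)
    p = Xc.T @ t / tt
    b = float(yc @ t / tt)

    model = OPLSModel(
        x_center=x_center, y_center=y_center, y_scale=y_scale,
        w_ortho=np.array(W_o).reshape(n_ortho, k),
        p_ortho=np.array(P_o).reshape(n_ortho, k),
        w=w, p=p, b=b, analyte=analyte, region_mask=region_mask,
        n_train=n, y_range=(float(np.min(y)), float(np.max(y))))

    # by-construction invariant: orthogonal scores carry no y-information
    Xc0 = np.asarray(X, dtype=float) - x_center
    for w_o, p_o in zip(model.w_ortho, model.p_ortho):
        t_o = Xc0 @ w_o
        if abs(t_o @ yc) > 1e-8 * max(np.linalg.norm(t_o) * np.linalg.norm(yc), 1e-300):
            raise AssertionError("orthogonal score correlates with y")
        Xc0 = Xc0 - np.outer(t_o, p_o)
    return model


def select_components(X: np.ndarray, y: np.ndarray, cv_splits,
                      max_ortho: int = 6, overfit_gap: float = 0.3):
    """Choose ``n_ortho`` by cross-validation.

    For every candidate count, fits fold models over ``cv_splits`` (an
    iterable of (train_idx, test_idx)) and the full-data model, computing Q²
    and R². Returns the candidate maximizing Q² subject to the overfit guard
    R² - Q² <= ``overfit_gap`` (ties toward fewer components). When every
    candidate violates the guard, the smallest-gap candidate is returned
    flagged.
    """
    from .validation import r2_q2

    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    cv_splits = list(cv_splits)
    metrics = []
    for n_o in range(max_ortho + 1):
        try:
            full = fit_opls(X, y, n_o)
        except ValueError:
            break
        y_cal = full.predict(X)
        y_cv = np.full_like(y, np.nan)
        ok = True
        for train, test in cv_splits:
            try:
                m = fit_opls(X[train], y[train], n_o)
            except ValueError:
                ok = False
                break
            y_cv[test] = m.predict(X[test])
        if not ok:
            break
        stats = r2_q2(y, y_cal, y_cv)
        metrics.append({"n_ortho": n_o, "r2": stats["r2"], "q2": stats["q2"],
                        "gap": stats["r2"] - stats["q2"]})
    if not metrics:
        raise ValueError("no candidate component count could be fitted")

    admissible = [m for m in metrics if m["gap"] <= overfit_gap]
    if admissible:
        best = max(admissible, key=lambda m: (m["q2"], -m["n_ortho"]))
        flagged = False
    else:
        best = min(metrics, key=lambda m: m["gap"])
        flagged = True
    return best["n_ortho"], {"candidates": metrics, "overfit_flagged": flagged}
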