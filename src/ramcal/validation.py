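"""Leave-vessel-out cross-validation and model reporting.

Whole vessels (complete fed-batch runs) are held out together so that the
cross-validation error measures transfer to genuinely unseen batches, not
interpolation within a batch. Q² is computed from the pooled held-out
predictions. Reports mirror the usual calibration summary: concentration
range, n, "1 + x" component count, R², Q², RMSEE, RMSEcv and the overfit
flag (R² - Q² > 0.3).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chemometrics import fit_opls, select_components
from .preprocessing import (DEFAULT_REGIONS, PreprocessConfig, preprocess_pipeline,
                            region_mask)

OVERFIT_GAP = 0.3


@dataclass
class CVPlan:
    """Vessel -> cross-validation group assignment (groups 1..k)."""

    groups: dict[int, int]
    k: int

    def __post_init__(self) -> None:
        sizes = pd.Series(list(self.groups.values())).value_counts()
        if sizes.max() - sizes.min() > 1:
            raise ValueError("CV groups must be balanced (sizes differ by <= 1)")

    def splits(self, vessel_ids: np.ndarray):
        """(train_idx, test_idx) pairs over sample rows, leaving out one
        vessel group at a time. Asserts train/test vessel disjointness."""
        vessel_ids = np.asarray(vessel_ids)
        for g in sorted(set(self.groups.values())):
            test_vessels = {v for v, gg in self.groups.items() if gg == g}
            test = np.isin(vessel_ids, list(test_vessels))
            train = ~test
            assert not (set(vessel_ids[train]) & set(vessel_ids[test])), \
                "leave-vessel-out violated: vessel in both folds"
            if test.any() and train.any():
                yield np.where(train)[0], np.where(test)[0]


@dataclass
class ModelReport:
    analyte: str
    y_min: float
    y_max: float
    n: int
    n_ortho: int
    r2: float
    q2: float
    rmsee: float
    rmsecv: float
    overfit: bool
    spiked: bool

    @property
    def components(self) -> str:
        return f"1 + {self.n_ortho}"

    def as_row(self) -> dict:
        return {"analyte": self.analyte,
                "range": f"{self.y_min:.2f}-{self.y_max:.2f}",
                "n": self.n, "components": self.components,
                "R2": round(self.r2, 3), "Q2": round(self.q2, 3),
                "RMSEE": round(self.rmsee, 4), "RMSEcv": round(self.rmsecv, 4),
                "overfit": self.overfit, "spiked": self.spiked}


def make_cv_groups(vessel_ids, k: int = 4, seed: int | None = None) -> CVPlan:
    """Deal vessels into ``k`` balanced groups.

    Vessels are sorted by id and dealt round-robin (deterministic); passing a
    seed permutes the vessel order first.
    """
    vessels = sorted(set(int(v) for v in vessel_ids))
    if k < 2:
        raise ValueError("need at least 2 CV groups")
    if k > len(vessels):
        raise ValueError("more groups than vessels")
    order = np.array(vessels)
    if seed is not None:
        order = np.random.default_rng(seed).permutation(order)
    groups = {int(v): (i % k) + 1 for i, v in enumerate(order)}
    return CVPlan(groups=groups, k=k)


def rmsee(y_obs, y_cal) -> float:
    """Root mean square error of estimation: sqrt(sum((y - y_cal)^2)/n)."""
    y_obs = np.asarray(y_obs, dtype=float)
    y_cal = np.asarray(y_cal, dtype=float)
    if y_obs.size == 0 or y_obs.shape != y_cal.shape:
        raise ValueError("need equal, nonzero-length vectors")
    return float(np.sqrt(np.mean((y_obs - y_cal) ** 2)))


def rmsecv(y_obs, y_cvpred) -> float:
    """Root mean square error of cross-validation (same form as rmsee,
    applied to the pooled held-out predictions)."""
    return rmsee(y_obs, y_cvpred)


def r2_q2(y_obs, y_cal, y_cvpred) -> dict[str, float]:
    """Goodness of fit and prediction: 1 - SS_res/SS_tot about the mean of
    the observed values, with calibrated and cross-validated residuals."""
    y_obs = np.asarray(y_obs, dtype=float)
    ss_tot = float(np.sum((y_obs - y_obs.mean()) ** 2))
    if ss_tot <= 0:
        raise ValueError("zero total sum of squares")
    r2 = 1.0 - float(np.sum((y_obs - np.asarray(y_cal, dtype=float)) ** 2)) / ss_tot
    q2 = 1.0 - float(np.sum((y_obs - np.asarray(y_cvpred, dtype=float)) ** 2)) / ss_tot
    return {"r2": r2, "q2": q2}


def overfit_flag(r2: float, q2: float) -> bool:
    """True when R² - Q² exceeds 0.3 — outliers or an overfitted model."""
    return (r2 - q2) > OVERFIT_GAP


def calibrate(X: np.ndarray, meta: pd.DataFrame, axis: np.ndarray, analyte: str,
              plan: CVPlan, *, include_spiked: bool = True,
              max_ortho: int = 6, n_ortho: int | None = None,
              regions: dict | None = None,
              exclude: np.ndarray | None = None) -> dict:
    """Leave-vessel-out calibration of one analyte on a preprocessed matrix.

    Selects the usable rows (reference value present; spiked rows optional;
    ``exclude`` drops e.g. outlier-flagged rows), restricts X to the
    analyte's spectral regions, picks ``n_ortho`` by cross-validation unless
    given, then produces pooled CV predictions and the full-data model.
    """
    regions = regions or DEFAULT_REGIONS
    keep = meta[f"reference_{analyte}"].notna().to_numpy()
    if not include_spiked:
        keep &= (meta["kind"] == "unspiked").to_numpy()
    if exclude is not None:
        keep &= ~np.asarray(exclude, dtype=bool)
    idx = np.where(keep)[0]
    if idx.size < plan.k:
        raise ValueError(f"too few usable samples for {analyte!r}")

    mask = region_mask(np.asarray(axis, dtype=float), regions[analyte])
    Xa = np.asarray(X, dtype=float)[np.ix_(idx, np.where(mask)[0])]
    y = meta.loc[idx, f"reference_{analyte}"].to_numpy(dtype=float)
    vessels = meta.loc[idx, "vessel_id"].to_numpy()

    splits = list(plan.splits(vessels))
    if len(splits) < 2:
        raise ValueError("need at least two non-empty CV groups")

    selection_info = None
    if n_ortho is None:
        n_ortho, selection_info = select_components(Xa, y, splits, max_ortho)

    y_cv = np.full(y.shape, np.nan)
    for train, test in splits:
        fold = fit_opls(Xa[train], y[train], n_ortho)
        y_cv[test] = fold.predict(Xa[test])
    model = fit_opls(Xa, y, n_ortho, analyte=analyte, region_mask=mask)
    y_cal = model.predict(Xa)

    covered = ~np.isnan(y_cv)
    stats = r2_q2(y_obs=y[covered], y_cal=y_cal[covered], y_cvpred=y_cv[covered])
    report = ModelReport(
        analyte=analyte, y_min=float(y.min()), y_max=float(y.max()),
        n=int(idx.size), n_ortho=int(n_ortho),
        r2=stats["r2"], q2=stats["q2"],
        rmsee=rmsee(y, y_cal), rmsecv=rmsecv(y[covered], y_cv[covered]),
        overfit=overfit_flag(stats["r2"], stats["q2"]),
        spiked=bool(include_spiked))
    return {"model": model, "report": report, "rows": idx,
            "y_obs": y, "y_cal": y_cal, "y_cvpred": y_cv,
            "selection": selection_info}


def cross_validate(records, analyte: str, plan: CVPlan,
                   config: PreprocessConfig | None = None, **kwargs) -> dict:
    """Convenience wrapper: run the shared preprocessing pass on raw sample
    records, then calibrate one analyte with leave-vessel-out CV."""
    X, meta, _log = preprocess_pipeline(records, config)
    return calibrate(X, meta, records[0].axis, analyte, plan, **kwargs)


def compare_spiked_unspiked(X, meta, axis, analyte, plan, **kwargs
                            ) -> tuple[ModelReport, ModelReport]:
    """Fit the unspiked-only and unspiked+spiked calibrations side by side.

    Spiking extends the calibration range beyond the process's native span
    and breaks analyte/batch-age correlations; for narrow-range analytes the
    spiked model predicts markedly better.
    """
    unspiked = calibrate(X, meta, axis, analyte, plan,
                         include_spiked=False, **kwargs)
    spiked = calibrate(X, meta, axis, analyte, plan,
                       include_spiked=True, **kwargs)
    return unspiked["report"], spiked["report"]


def holdout_trajectory(X, meta, axis, vessel_id: int, analyte: str,
                       *, n_ortho: int | None = None, max_ortho: int = 6,
                       regions: dict | None = None) -> tuple[pd.DataFrame, float]:
    """Train with one vessel fully excluded; predict its daily trajectory.

    Returns the per-day observed/predicted series of the held-out vessel's
    unspiked samples and the trajectory RMSE.
    """
    vessels = meta["vessel_id"].to_numpy()
    if vessel_id not in set(int(v) for v in vessels):
        raise ValueError(f"vessel {vessel_id} not in dataset")
    regions = regions or DEFAULT_REGIONS
    mask = region_mask(np.asarray(axis, dtype=float), regions[analyte])

    usable = meta[f"reference_{analyte}"].notna().to_numpy()
    train = usable & (vessels != vessel_id)
    assert vessel_id not in set(meta.loc[train, "vessel_id"]), \
        "held-out vessel leaked into training"
    test = (usable & (vessels == vessel_id)
            & (meta["kind"] == "unspiked").to_numpy())

    Xr = np.asarray(X, dtype=float)[:, mask]
    y_train = meta.loc[train, f"reference_{analyte}"].to_numpy(dtype=float)
    if n_ortho is None:
        plan = make_cv_groups(meta.loc[train, "vessel_id"], k=4)
        splits = plan.splits(meta.loc[train, "vessel_id"].to_numpy())
        n_ortho, _ = select_components(Xr[train], y_train, splits, max_ortho)
    model = fit_opls(Xr[train], y_train, n_ortho, analyte=analyte)

    pred = model.predict(Xr[test])
    obs = meta.loc[test, f"reference_{analyte}"].to_numpy(dtype=float)
    series = pd.DataFrame({"day": meta.loc[test, "day"].to_numpy(),
                           "observed": obs, "predicted": pred}
                          ).sort_values("day", ignore_index=True)
    return series, rmsee(series["observed"], series["predicted"])


def build_report(X, meta, axis, plan, analytes=None, **kwargs) -> pd.DataFrame:
    """Table-1-style summary: per analyte, the unspiked and spiked models."""
    from .experiment_design import ANALYTES

    rows = []
    for analyte in (analytes or ANALYTES):
        unspiked, spiked = compare_spiked_unspiked(X, meta, axis, analyte,
                                                   plan, **kwargs)
        rows.append(unspiked.as_row())
        rows.append(spiked.as_row())
    return pd.DataFrame(rows)
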