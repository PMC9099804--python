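"""Spectral pre-treatment: screening, dark subtraction, replicate averaging,
asymmetric-least-squares baseline removal, water-band normalization and
per-analyte region selection.

The fixed order of the shared pipeline is: screen raw -> average replicates ->
AsLS baseline correction -> water-band normalization. Region selection is
applied per analyte at model-fit time so one preprocessing pass serves all
calibration models.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.linalg import spsolve


@dataclass
class Spectrum:
    """One Raman measurement: wavenumber axis (cm^-1, ascending) + intensity."""

    axis: np.ndarray
    intensity: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.axis = np.asarray(self.axis, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.axis.shape != self.intensity.shape:
            raise ValueError("axis and intensity lengths differ")
        if not np.all(np.isfinite(self.axis)):
            raise ValueError("non-finite wavenumbers")
        if np.any(np.diff(self.axis) <= 0):
            raise ValueError("wavenumber axis must be strictly ascending")


@dataclass
class PreprocessConfig:
    """Knobs of the shared pre-treatment pass.

    asls_lambda is the second-difference smoothness penalty of the baseline,
    asls_p the asymmetry (weight of points above the baseline, 0 < p < 1).
    The water band at 1650 cm^-1 acts as internal intensity standard; its
    statistic (area by default, height optionally) is divided out.
    """

    asls_lambda: float = 1e5
    asls_p: float = 0.001
    asls_iterations: int = 10
    water_center: float = 1650.0
    water_half_width: float = 50.0
    water_statistic: str = "area"  # "area" | "height"
    min_total_intensity: float = 1000.0
    min_water_band_ratio: float = 1.05
    snv_derivative: bool = False  # alternative pre-treatment, off by default
    regions: dict[str, list[tuple[float, float]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.asls_lambda <= 0:
            raise ValueError("asls_lambda must be > 0")
        if not 0 < self.asls_p < 1:
            raise ValueError("asls_p must be in (0, 1)")
        if self.water_statistic not in ("area", "height"):
            raise ValueError("water_statistic must be 'area' or 'height'")


#: Per-analyte spectral windows (cm^-1) matched to the synthetic
#: pure-component bands; self-consistent stand-ins, configuration-driven.
DEFAULT_REGIONS: dict[str, list[tuple[float, float]]] = {
    "glucose": [(480, 560), (880, 940), (1080, 1160)],
    "lactate": [(790, 870), (1020, 1070)],
    "glutamine": [(740, 820), (1370, 1440)],
    "glutamate": [(920, 1000), (1310, 1390)],
    "titer": [(980, 1030), (1420, 1480)],
}


def screen_raw(spectrum: Spectrum, config: PreprocessConfig) -> tuple[bool, str | None]:
    """Raw-intensity screen for aberrant measurements.

    Fails with ``empty_chamber`` when the total intensity is below the
    configured floor (no scattering medium in the chamber) and with
    ``weak_water_band`` when the water band does not stand out against the
    spectrum's median intensity (air bubble in the laser focus).
    """
    total = float(np.sum(spectrum.intensity))
    if total < config.min_total_intensity:
        return False, "empty_chamber"
    stat = _water_band_statistic(spectrum, config, normalize_by="median")
    if stat < config.min_water_band_ratio:
        return False, "weak_water_band"
    return True, None


def subtract_dark(spectrum: Spectrum, dark: Spectrum) -> Spectrum:
    """Pointwise dark-scan subtraction (identical axes required)."""
    if not np.array_equal(spectrum.axis, dark.axis):
        raise ValueError("dark scan axis does not match spectrum axis")
    return replace(spectrum, intensity=spectrum.intensity - dark.intensity,
                   meta=dict(spectrum.meta))


def average_replicates(spectra: Sequence[Spectrum]) -> Spectrum:
    """Arithmetic mean of replicate sub-spectra of one sample.

    Averaging n replicates improves the signal-to-noise ratio by sqrt(n);
    the ``averages`` metadata accumulates accordingly.
    """
    if len(spectra) == 0:
        raise ValueError("no spectra to average")
    first = spectra[0]
    sample_ids = {s.meta.get("sample_id") for s in spectra}
    if len(sample_ids) > 1:
        raise ValueError(f"mixed sample ids in replicate set: {sample_ids}")
    for s in spectra[1:]:
        if not np.array_equal(s.axis, first.axis):
            raise ValueError("replicate axes differ")
    mean = np.mean([s.intensity for s in spectra], axis=0)
    meta = dict(first.meta)
    meta["averages"] = int(sum(s.meta.get("averages", 1) for s in spectra))
    return Spectrum(first.axis, mean, meta)


def asls_baseline(intensity: np.ndarray, lam: float = 1e5, p: float = 0.001,
                  n_iter: int = 10) -> np.ndarray:
    """Asymmetric least-squares baseline (Eilers-type).

    Iteratively reweighted penalized least squares: solve
    ``(W + lam * D2' D2) z = W y`` where points above the running baseline
    get weight ``p`` and points below get ``1 - p``, with a second-difference
    smoothness penalty ``lam``. Small ``p`` forces the baseline under the
    peaks while following the smooth fluorescence background.
    """
    y = np.asarray(intensity, dtype=float)
    if y.ndim != 1 or y.size < 3:
        raise ValueError("need a 1-D intensity vector of length >= 3")
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite intensities")
    if lam <= 0 or not 0 < p < 1:
        raise ValueError("require lam > 0 and 0 < p < 1")

    n = y.size
    d2 = sp.diags([1.0, -2.0, 1.0], [0, -1, -2], shape=(n, n - 2), format="csc")
    penalty = lam * (d2 @ d2.T)
    w = np.ones(n)
    z = y
    for _ in range(n_iter):
        W = sp.diags(w, format="csc")
        z = spsolve((W + penalty).tocsc(), w * y)
        w = np.where(y > z, p, 1.0 - p)
    return z


def correct_baseline(spectrum: Spectrum, config: PreprocessConfig) -> Spectrum:
    """Subtract the AsLS baseline estimated from the spectrum itself."""
    base = asls_baseline(spectrum.intensity, config.asls_lambda,
                         config.asls_p, config.asls_iterations)
    return replace(spectrum, intensity=spectrum.intensity - base,
                   meta=dict(spectrum.meta))


def _water_window(axis: np.ndarray, config: PreprocessConfig) -> np.ndarray:
    lo = config.water_center - config.water_half_width
    hi = config.water_center + config.water_half_width
    mask = (axis >= lo) & (axis <= hi)
    if not mask.any():
        raise ValueError("water-band window lies outside the wavenumber axis")
    return mask


def _water_band_statistic(spectrum: Spectrum, config: PreprocessConfig,
                          normalize_by: str | None = None) -> float:
    mask = _water_window(spectrum.axis, config)
    window = spectrum.intensity[mask]
    if config.water_statistic == "height":
        stat = float(np.max(window))
    else:
        stat = float(np.trapezoid(window, spectrum.axis[mask]))
    if normalize_by == "median":
        med = float(np.median(spectrum.intensity))
        if med <= 0:
            return 0.0
        # compare mean in-window level against the spectrum-wide median
        denom = med * (2 * config.water_half_width if config.water_statistic == "area" else 1.0)
        return stat / denom
    return stat


def normalize_water_band(spectrum: Spectrum, config: PreprocessConfig) -> Spectrum:
    """Divide the spectrum by its water-band statistic (area or height).

    The water band near 1650 cm^-1 serves as an internal standard: dividing
    by it cancels multiplicative disturbances (optical sampling volume,
    bubbles partially obscuring the focus, laser drift). After normalization
    the band statistic equals one, making the map idempotent.
    """
    stat = _water_band_statistic(spectrum, config)
    if stat <= 0:
        raise ValueError("nonpositive water-band statistic; spectrum should "
                         "have failed raw screening")
    return replace(spectrum, intensity=spectrum.intensity / stat,
                   meta=dict(spectrum.meta))


def snv_first_derivative(spectrum: Spectrum) -> Spectrum:
    """Standard-normal-variate scaling followed by a first difference.

    Alternative pre-treatment kept for comparison; the AsLS + water-band
    route is the default.
    """
    y = spectrum.intensity
    y = (y - y.mean()) / y.std(ddof=1)
    dy = np.gradient(y, spectrum.axis)
    return replace(spectrum, intensity=dy, meta=dict(spectrum.meta))


def select_regions(spectrum: Spectrum, analyte: str,
                   config: PreprocessConfig) -> tuple[np.ndarray, np.ndarray]:
    """Concatenate the channels inside the analyte's configured windows."""
    regions = config.regions or DEFAULT_REGIONS
    if analyte not in regions:
        raise KeyError(f"no spectral regions configured for analyte {analyte!r}")
    mask = region_mask(spectrum.axis, regions[analyte])
    if not mask.any():
        raise ValueError(f"regions for {analyte!r} do not intersect the axis")
    return spectrum.intensity[mask], spectrum.axis[mask]


def region_mask(axis: np.ndarray, intervals: Iterable[tuple[float, float]]) -> np.ndarray:
    """Boolean channel mask for a union of [lo, hi] wavenumber intervals."""
    mask = np.zeros(axis.shape, dtype=bool)
    for lo, hi in intervals:
        mask |= (axis >= lo) & (axis <= hi)
    return mask


def preprocess_pipeline(records: Sequence, config: PreprocessConfig | None = None,
                        ) -> tuple[np.ndarray, pd.DataFrame, pd.DataFrame]:
    """Shared pre-treatment pass over SampleRecords.

    Screens each record's replicate-averaged raw spectrum, then baseline-
    corrects and water-band-normalizes the survivors. Returns the sample x
    channel matrix ``X``, the aligned metadata table and the screening log.
    """
    if len(records) == 0:
        raise ValueError("no records to preprocess")
    config = config or PreprocessConfig()

    rows, meta_rows, log_rows = [], [], []
    for rec in records:
        avg = average_replicates(rec.replicate_spectra())
        ok, reason = screen_raw(avg, config)
        log_rows.append({"record_id": rec.record_id,
                         "verdict": "pass" if ok else "fail",
                         "reason": reason or ""})
        if not ok:
            continue
        if config.snv_derivative:
            treated = snv_first_derivative(avg)
        else:
            treated = normalize_water_band(correct_baseline(avg, config), config)
        rows.append(treated.intensity)
        meta_rows.append(rec.meta_row())

    if not rows:
        raise ValueError("every record failed raw screening")
    X = np.vstack(rows)
    meta = pd.DataFrame(meta_rows).reset_index(drop=True)
    log = pd.DataFrame(log_rows)
    return X, meta, log
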