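"""Synthetic fed-batch Raman datasets with the statistical structure the
calibration workflow assumes.

The generator plays the role of the wet-lab study: per-vessel metabolite and
titer trajectories over a 14-day fed-batch run, daily unspiked + spiked
samples, and Raman spectra built as a linear superposition of analyte bands
on top of a dominant water band, a batch-age-growing fluorescence background,
multiplicative gain jitter and detector noise. Reference-analyzer readings
carry a configurable relative error. Everything is reproducible from a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .experiment_design import (ANALYTES, SpikeEvent, spiked_concentration)
from .preprocessing import Spectrum

DEFAULT_AXIS = np.arange(200.0, 3300.0 + 1e-9, 2.0)  # cm^-1


@dataclass
class KineticParams:
    """Fed-batch trajectory parameters (concentrations g/L, days, cells/mL).

    Glucose follows consume-and-bolus-feed dynamics, lactate shifts from
    production to consumption mid-run, glutamine decays, glutamate slowly
    accumulates, and titer accumulates with integrated viable cell density
    (VCD). Per-vessel multiplicative perturbations derive from the DoE
    factors plus a small seeded lognormal jitter.
    """

    initial: dict[str, float] = field(default_factory=lambda: {
        "glucose": 6.2, "lactate": 2.0, "glutamine": 2.35,
        "glutamate": 0.75, "titer": 0.0})
    glucose_consumption: float = 1.25   # g/L/day at peak VCD
    feed_bolus: dict[int, float] = field(default_factory=lambda: {
        d: 2.0 for d in range(3, 15)})  # max g/L glucose added per feed day
    lactate_production: float = 1.70    # g/L/day at peak VCD, before shift
    lactate_consumption: float = 0.80   # g/L/day at peak VCD, after shift
    lactate_shift_day: int = 7
    glutamine_decay: float = 0.035      # 1/day first-order consumption
    glutamine_uptake: float = 0.045     # g/L/day at peak VCD
    glutamate_production: float = 0.135  # g/L/day at peak VCD
    titer_rate: float = 0.42            # g/L/day at peak VCD
    peak_vcd: float = 13.8e6            # cells/mL
    vcd_peak_day: float = 8.0
    vcd_width: float = 4.5              # days
    vessel_jitter_sd: float = 0.03      # lognormal sd on per-vessel rates
    seed: int = 0


@dataclass
class PureComponentLibrary:
    """Gaussian Raman bands per analyte (center cm^-1, sigma cm^-1,
    amplitude counts per g/L) plus the broad water band used as internal
    standard. Band positions are configuration, chosen so that no analyte's
    band set is a scalar multiple of another's."""

    bands: dict[str, list[tuple[float, float, float]]] = field(
        default_factory=lambda: {
            "glucose": [(520, 10, 0.45), (911, 12, 0.65), (1125, 14, 1.0)],
            "lactate": [(830, 12, 0.95), (1044, 10, 0.55)],
            "glutamine": [(781, 10, 0.5), (1410, 12, 0.8)],
            "glutamate": [(960, 10, 0.5), (1350, 12, 0.75)],
            "titer": [(1003, 8, 0.9), (1450, 14, 0.6)],
        })
    water_center: float = 1650.0
    water_sigma: float = 42.0
    water_amplitude: float = 60.0

    def profile(self, analyte: str, axis: np.ndarray) -> np.ndarray:
        """Unit-concentration band profile of one analyte on a given axis."""
        if analyte not in self.bands:
            raise KeyError(f"analyte {analyte!r} missing from library")
        out = np.zeros_like(axis, dtype=float)
        for center, sigma, amp in self.bands[analyte]:
            out += amp * np.exp(-0.5 * ((axis - center) / sigma) ** 2)
        return out

    def water_band(self, axis: np.ndarray) -> np.ndarray:
        return self.water_amplitude * np.exp(
            -0.5 * ((axis - self.water_center) / self.water_sigma) ** 2)


@dataclass
class NoiseModel:
    """Disturbance model: detector shot/read noise (counts, per channel and
    sub-spectrum), fluorescence background growing linearly with batch age,
    per-sample multiplicative gain jitter, reference-assay relative error,
    and an optional mixing-bias factor applied to the spectral (not the
    reference) concentration of spiked samples."""

    detector_sd: float = 0.05
    fluor_amplitude_day0: float = 4.0    # counts at the low-wavenumber end
    fluor_growth_per_day: float = 0.30   # relative growth per day
    fluor_decay_cm: float = 1200.0       # spectral decay constant
    gain_jitter_sd: float = 0.05
    reference_cv: dict[str, float] = field(
        default_factory=lambda: {a: 0.02 for a in ANALYTES})
    mixing_bias: float = 1.0
    seed: int = 0

    def fluorescence(self, axis: np.ndarray, batch_age: float) -> np.ndarray:
        amp = self.fluor_amplitude_day0 * (1.0 + self.fluor_growth_per_day * batch_age)
        return amp * np.exp(-(axis - axis[0]) / self.fluor_decay_cm)


@dataclass
class SampleRecord:
    """Joined unit of analysis: replicate spectra + reference values +
    vessel/day/spike annotations. ``truth`` holds the noise-free
    concentrations (g/L; titer in normalized units), ``reference`` the
    assay readings actually used for model building (NaN where the assay
    does not run on that cadence)."""

    record_id: str
    vessel_id: int
    day: int
    kind: str                       # "unspiked" | "spiked"
    axis: np.ndarray
    replicates: np.ndarray          # (n_replicates, n_channels)
    truth: dict[str, float]
    reference: dict[str, float]
    analyte_spiked: str | None = None
    spike: SpikeEvent | None = None

    def replicate_spectra(self) -> list[Spectrum]:
        return [
            Spectrum(self.axis, row,
                     {"sample_id": self.record_id, "vessel_id": self.vessel_id,
                      "day": self.day, "kind": self.kind, "averages": 1,
                      "replicate": i})
            for i, row in enumerate(self.replicates)
        ]

    def meta_row(self) -> dict:
        row = {"record_id": self.record_id, "vessel_id": self.vessel_id,
               "day": self.day, "kind": self.kind,
               "analyte_spiked": self.analyte_spiked or ""}
        for a in ANALYTES:
            row[f"reference_{a}"] = self.reference.get(a, np.nan)
            row[f"truth_{a}"] = self.truth.get(a, np.nan)
        return row


def _vessel_perturbations(design: pd.DataFrame, kinetics: KineticParams
                          ) -> pd.DataFrame:
    """Per-vessel multiplicative factors on the kinetic rates.

    DoE factors act deterministically (higher inoculation density -> faster
    metabolism; glucose feed target scales the bolus), on top of a seeded
    lognormal vessel-to-vessel jitter.
    """
    rng = np.random.default_rng(kinetics.seed)
    rows = []
    dens = design["inoculation_density"]
    dens_rel = (dens - dens.mean()) / max(dens.max() - dens.min(), 1e-12) \
        if dens.max() > dens.min() else dens * 0.0
    for i, vessel in enumerate(design["vessel_id"]):
        jit = rng.lognormal(0.0, kinetics.vessel_jitter_sd, size=3)
        rows.append({
            "vessel_id": vessel,
            "rate_factor": float((1.0 + 0.10 * dens_rel.iloc[i]) * jit[0]),
            "feed_factor": float(jit[1]),  # scales the vessel's feed target
            "vcd_factor": float((1.0 + 0.06 * dens_rel.iloc[i]) * jit[2]),
        })
    return pd.DataFrame(rows)


def simulate_trajectories(design: pd.DataFrame, kinetics: KineticParams | None = None,
                          n_days: int = 14) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Daily noise-free concentration trajectories per vessel.

    Returns a tidy concentration table (vessel_id, day, analyte, value g/L;
    titer normalized to the run maximum) and the VCD table (cells/mL).
    Concentrations are clipped at zero (with a warning) should a parameter
    choice drive them negative.
    """
    import warnings

    kinetics = kinetics or KineticParams()
    if len(design) == 0 or n_days < 1:
        raise ValueError("need a nonempty design and n_days >= 1")
    perts = _vessel_perturbations(design, kinetics).set_index("vessel_id")
    days = np.arange(1, n_days + 1)

    conc_rows, vcd_rows = [], []
    clipped = False
    for vessel in design["vessel_id"]:
        p = perts.loc[vessel]
        vcd = kinetics.peak_vcd * p["vcd_factor"] * np.exp(
            -0.5 * ((days - kinetics.vcd_peak_day) / kinetics.vcd_width) ** 2)
        r = vcd / kinetics.peak_vcd  # relative metabolic activity

        target = float(design.loc[design["vessel_id"] == vessel,
                                  "glucose_feed_target"].iloc[0]) * p["feed_factor"]
        c = {a: kinetics.initial[a] for a in ANALYTES}
        for di, day in enumerate(days):
            if di > 0:
                act = r[di - 1] * p["rate_factor"]
                # sampling precedes feeding: after the previous day's sample,
                # a bolus (capped) tops glucose up to the vessel's target, then
                # the culture consumes until the next sample
                cap = kinetics.feed_bolus.get(int(day) - 1, 0.0)
                bolus = min(cap, max(0.0, target - c["glucose"]))
                c["glucose"] += bolus - kinetics.glucose_consumption * act
                if day <= kinetics.lactate_shift_day:
                    c["lactate"] += kinetics.lactate_production * act
                else:
                    c["lactate"] -= kinetics.lactate_consumption * act
                c["glutamine"] -= (kinetics.glutamine_decay * c["glutamine"]
                                   + kinetics.glutamine_uptake * act)
                c["glutamate"] += kinetics.glutamate_production * act
                c["titer"] += kinetics.titer_rate * act
            for a in ANALYTES:
                if c[a] < 0:
                    clipped = True
                    c[a] = 0.0
                conc_rows.append({"vessel_id": vessel, "day": int(day),
                                  "analyte": a, "value": c[a]})
            vcd_rows.append({"vessel_id": vessel, "day": int(day),
                             "vcd": float(vcd[di])})
    if clipped:
        warnings.warn("negative concentrations clipped at 0", stacklevel=2)

    conc = pd.DataFrame(conc_rows)
    # titer normalized to the run maximum (dimensionless 0..1)
    titer_max = conc.loc[conc["analyte"] == "titer", "value"].max()
    if titer_max > 0:
        conc.loc[conc["analyte"] == "titer", "value"] /= titer_max
    conc.attrs["titer_scale"] = float(titer_max)
    return conc, pd.DataFrame(vcd_rows)


def synthesize_spectrum(concentrations: dict[str, float],
                        library: PureComponentLibrary,
                        noise: NoiseModel,
                        batch_age: float,
                        axis: np.ndarray = DEFAULT_AXIS,
                        rng: np.random.Generator | None = None,
                        gain: float | None = None) -> Spectrum:
    """Forward model of one sub-spectrum.

    intensity = gain * [ sum_a c_a * profile_a + water_band + fluorescence ]
                + detector noise

    ``gain`` may be passed explicitly so that replicates of one sample share
    their multiplicative jitter while drawing independent detector noise.
    """
    axis = np.asarray(axis, dtype=float)
    if np.any(np.diff(axis) <= 0):
        raise ValueError("axis must be strictly ascending")
    rng = rng or np.random.default_rng(noise.seed)
    clean = library.water_band(axis) + noise.fluorescence(axis, batch_age)
    for analyte, c in concentrations.items():
        if c < 0:
            raise ValueError(f"negative concentration for {analyte}")
        clean = clean + c * library.profile(analyte, axis)
    if gain is None:
        gain = float(rng.lognormal(0.0, noise.gain_jitter_sd)) \
            if noise.gain_jitter_sd > 0 else 1.0
    intensity = gain * clean
    if noise.detector_sd > 0:
        intensity = intensity + rng.normal(0.0, noise.detector_sd, size=axis.size)
    return Spectrum(axis, intensity, {"batch_age": batch_age, "gain": gain})


def generate_dataset(design: pd.DataFrame,
                     kinetics: KineticParams | None = None,
                     library: PureComponentLibrary | None = None,
                     noise: NoiseModel | None = None,
                     schedule: pd.DataFrame | None = None,
                     spike_events: list[SpikeEvent] | None = None,
                     axis: np.ndarray = DEFAULT_AXIS,
                     n_replicates: int = 5,
                     seed: int = 0) -> list[SampleRecord]:
    """Full synthetic study: one SampleRecord per schedule event.

    Spiked records take ``spiked_concentration`` of the targeted analyte as
    truth and dilute every other analyte by the same volume balance. The
    reference readings add the configured assay error; the titer reference
    follows its slower cadence (even days, plus titer-spiked samples). The
    optional mixing-bias factor perturbs only the spectral concentration of
    the spiked analyte, emulating imperfect mixing of sample and stock.
    """
    from .experiment_design import assign_spike_scheme, build_schedule

    kinetics = kinetics or KineticParams(seed=seed)
    library = library or PureComponentLibrary()
    noise = noise or NoiseModel(seed=seed)
    if schedule is None:
        schedule = build_schedule(n_vessels=len(design))
    if spike_events is None:
        spike_events = assign_spike_scheme(design, seed=seed)
    n_days = int(schedule["day"].max())

    conc, _vcd = simulate_trajectories(design, kinetics, n_days=n_days)
    titer_scale = conc.attrs.get("titer_scale", 1.0)
    lookup = conc.set_index(["vessel_id", "day", "analyte"])["value"]
    spikes = {(e.vessel_id, e.day): e for e in spike_events}
    rng = np.random.default_rng(seed)

    records: list[SampleRecord] = []
    for row in schedule.itertuples(index=False):
        vessel, day, kind = int(row.vessel_id), int(row.day), str(row.kind)
        base = {a: float(lookup.loc[(vessel, day, a)]) for a in ANALYTES}
        spike = None
        if kind == "spiked":
            spike = spikes.get((vessel, day))
            if spike is None:
                raise ValueError(f"no spike assigned for vessel {vessel} day {day}")
            truth = {}
            for a in ANALYTES:
                # titer trajectories are normalized; run the volume balance
                # on the physical scale and renormalize
                scale = titer_scale if a == "titer" else 1.0
                c_stock = spike.c_stock if a == spike.analyte else 0.0
                truth[a] = spiked_concentration(
                    base[a] * scale, spike.v_sample, c_stock,
                    spike.v_spike_nominal, spike.pipette_offset) / scale
        else:
            truth = dict(base)

        spectral = dict(truth)
        spectral["titer"] = spectral["titer"] * titer_scale  # g/L for the forward model
        if spike is not None and noise.mixing_bias != 1.0:
            spectral[spike.analyte] *= noise.mixing_bias

        gain = float(rng.lognormal(0.0, noise.gain_jitter_sd)) \
            if noise.gain_jitter_sd > 0 else 1.0
        reps = np.vstack([
            synthesize_spectrum(spectral, library, noise, batch_age=day,
                                axis=axis, rng=rng, gain=gain).intensity
            for _ in range(n_replicates)
        ])

        reference = {}
        for a in ANALYTES:
            cv = noise.reference_cv.get(a, 0.0)
            noisy = truth[a] * (1.0 + rng.normal(0.0, cv)) if cv > 0 else truth[a]
            titer_measured = (day % 2 == 0) or (spike is not None
                                                and spike.analyte == "titer")
            if a == "titer" and not titer_measured:
                noisy = np.nan
            reference[a] = float(noisy)

        records.append(SampleRecord(
            record_id=f"V{vessel:02d}D{day:02d}{'S' if kind == 'spiked' else 'U'}",
            vessel_id=vessel, day=day, kind=kind, axis=axis,
            replicates=reps, truth=truth, reference=reference,
            analyte_spiked=spike.analyte if spike else None, spike=spike))
    return records


def corrupt_with_artifacts(records: list[SampleRecord],
                           fraction_empty: float = 0.0,
                           fraction_bubble: float = 0.0,
                           attenuation: float = 0.3,
                           seed: int = 0) -> tuple[list[SampleRecord], dict[str, list[int]]]:
    """Inject measurement artifacts: empty chambers (near-zero signal) and
    air bubbles (globally attenuated signal). Returns the corrupted copy and
    the injected indices, so tests can verify the screens catch them."""
    if not 0 <= fraction_empty <= 1 or not 0 <= fraction_bubble <= 1:
        raise ValueError("artifact fractions must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n = len(records)
    n_empty = int(round(fraction_empty * n))
    n_bubble = int(round(fraction_bubble * n))
    chosen = rng.choice(n, size=min(n, n_empty + n_bubble), replace=False)
    empty_idx = sorted(int(i) for i in chosen[:n_empty])
    bubble_idx = sorted(int(i) for i in chosen[n_empty:n_empty + n_bubble])

    out = list(records)
    for i in empty_idx:
        out[i] = replace(records[i], replicates=records[i].replicates * 1e-4)
    for i in bubble_idx:
        rec = records[i]
        # a bubble displaces the aqueous phase from the focal volume, so it
        # predominantly removes water-derived signal: attenuation is deepest
        # at the 1650 cm^-1 band and fades toward the spectral edges. The
        # distorted band shape survives intensity screening at mild
        # attenuation but leaves a large off-model residual.
        profile = 1.0 - (1.0 - attenuation) * np.exp(
            -0.5 * ((rec.axis - 1650.0) / 200.0) ** 2)
        out[i] = replace(rec, replicates=rec.replicates * profile)
    return out, {"empty": empty_idx, "bubble": bubble_idx}
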