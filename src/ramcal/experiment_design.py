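"""Run design for a 24-vessel fed-batch spiking study.

Encodes the experiment layout as pure, deterministic computations: the DoE
factor table (16 varied vessels + 8 identical controls), the daily
unspiked/spiked sampling schedule, the spike mass balance, and the
acquisition-time bookkeeping of the spectrometer (integration time x
averages = one fixed sub-spectrum duration).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

ANALYTES = ("glucose", "lactate", "glutamine", "glutamate", "titer")

#: Placeholder DoE factor levels; the varied-vs-constant structure is the
#: contract, the numeric levels are configuration.
DEFAULT_FACTOR_LEVELS: dict[str, list[float]] = {
    "inoculation_density": [3.0e5, 5.0e5],  # cells/mL
    "glucose_feed_target": [4.0, 6.0],      # g/L
    "ph_setpoint": [6.9, 7.1],
    "do_setpoint": [40.0, 60.0],            # % air saturation
}

DEFAULT_CONTROL_SETPOINTS: dict[str, float] = {
    "inoculation_density": 4.0e5,
    "glucose_feed_target": 5.0,
    "ph_setpoint": 7.0,
    "do_setpoint": 50.0,
}

#: Two stock solutions per analyte (low, high), g/L, inside the 4-32 g/L
#: envelope used for spiking.
DEFAULT_STOCKS: dict[str, tuple[float, float]] = {
    "glucose": (16.0, 32.0),
    "lactate": (12.0, 24.0),
    "glutamine": (8.0, 16.0),
    "glutamate": (8.0, 16.0),
    "titer": (10.0, 20.0),
}

DESIGN_COLUMNS = [
    "vessel_id",
    "group",
    "inoculation_density",
    "glucose_feed_target",
    "ph_setpoint",
    "do_setpoint",
]


class ConfigurationError(ValueError):
    """Raised when a design/schedule configuration is inconsistent."""


@dataclass(frozen=True)
class SpikeEvent:
    """One spiking action: a known volume of analyte stock added to a sample."""

    vessel_id: int
    day: int
    analyte: str
    stock_level: str            # "low" | "high"
    c_stock: float              # g/L
    v_spike_nominal: float      # uL
    v_sample: float = 140.0     # uL
    pipette_offset: float = 0.0  # uL, signed

    def __post_init__(self) -> None:
        if self.analyte not in ANALYTES:
            raise ConfigurationError(f"unknown analyte {self.analyte!r}")
        if self.c_stock <= 0:
            raise ConfigurationError("c_stock must be > 0")
        if self.v_spike_nominal <= 0 or self.v_sample <= 0:
            raise ConfigurationError("spike and sample volumes must be > 0")


@dataclass(frozen=True)
class AcquisitionSettings:
    """Spectrometer bookkeeping: each sub-spectrum lasts a fixed wall time."""

    integration_time: float          # seconds
    averages: int
    sub_spectrum_time: float = 60.0  # seconds
    replicates_per_sample: int = 5
    laser_wavelength_nm: float = 785.0
    laser_power_mW: float = 495.0

    def __post_init__(self) -> None:
        if self.integration_time <= 0:
            raise ConfigurationError("integration_time must be > 0")
        if self.averages < 1 or self.replicates_per_sample < 1:
            raise ConfigurationError("averages and replicates must be >= 1")


def build_design(
    n_doe: int = 16,
    n_control: int = 8,
    factor_levels: dict[str, list[float]] | None = None,
    control_setpoints: dict[str, float] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Build the vessel design table: ``n_doe`` DoE rows + ``n_control`` controls.

    DoE rows are a balanced fractional assignment of the factor levels:
    the full factorial is enumerated, shuffled deterministically by ``seed``
    and cycled until ``n_doe`` rows are assigned. Control rows all carry
    ``control_setpoints``.
    """
    if n_doe < 0 or n_control < 0:
        raise ConfigurationError("vessel counts must be >= 0")
    factor_levels = factor_levels or DEFAULT_FACTOR_LEVELS
    control_setpoints = control_setpoints or DEFAULT_CONTROL_SETPOINTS
    for name, levels in factor_levels.items():
        if len(levels) == 0:
            raise ConfigurationError(f"factor {name!r} has no levels")

    factors = list(factor_levels)
    combos = list(itertools.product(*(factor_levels[f] for f in factors)))
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(combos))

    rows = []
    for i in range(n_doe):
        combo = combos[order[i % len(combos)]]
        rows.append({"group": "doe", **dict(zip(factors, combo))})
    for _ in range(n_control):
        rows.append({"group": "control", **control_setpoints})

    table = pd.DataFrame(rows)
    table.insert(0, "vessel_id", np.arange(1, len(table) + 1))
    return table[[c for c in DESIGN_COLUMNS if c in table.columns]]


def build_schedule(
    n_vessels: int = 24,
    n_days: int = 14,
    spike_days: set[int] | frozenset[int] = frozenset(range(6, 14)),
) -> pd.DataFrame:
    """Daily sampling schedule: one unspiked sample per vessel per day, plus
    one spiked sample per vessel on each configured spiking day.

    The default (24 vessels, 14 days, spiking on days 6-13) schedules
    24*(14+8) = 528 spectra.
    """
    if n_days < 1:
        raise ConfigurationError("n_days must be >= 1")
    spike_days = set(spike_days)
    if not spike_days <= set(range(1, n_days + 1)):
        raise ConfigurationError("spike days must lie within the run (1..n_days)")

    events = [
        {"vessel_id": v, "day": d, "kind": "unspiked"}
        for v in range(1, n_vessels + 1)
        for d in range(1, n_days + 1)
    ]
    events += [
        {"vessel_id": v, "day": d, "kind": "spiked"}
        for v in range(1, n_vessels + 1)
        for d in sorted(spike_days)
    ]
    schedule = pd.DataFrame(events, columns=["vessel_id", "day", "kind"])
    return schedule.sort_values(["day", "vessel_id", "kind"], ignore_index=True)


def daily_sample_count(schedule: pd.DataFrame, day: int) -> int:
    """Number of scheduled samples (unspiked + spiked) on a given batch day."""
    if len(schedule) == 0:
        return 0
    return int((schedule["day"] == day).sum())


def spiked_concentration(
    c_unspiked: float,
    v_sample: float,
    c_stock: float,
    v_spike_nominal: float,
    pipette_offset: float = 0.0,
) -> float:
    """Mass balance for the analyte concentration after spiking.

    The effective delivered volume is the nominal volume plus a signed,
    pre-determined pipetting offset::

        c_spiked = (c_unspiked*V_sample + c_stock*V_eff) / (V_sample + V_eff)

    The result is a convex combination of ``c_unspiked`` and ``c_stock``.
    """
    if v_sample <= 0:
        raise ValueError("v_sample must be > 0")
    if c_unspiked < 0 or c_stock < 0:
        raise ValueError("concentrations must be >= 0")
    v_eff = v_spike_nominal + pipette_offset
    if v_eff < 0:
        raise ValueError("effective spike volume is negative")
    return (c_unspiked * v_sample + c_stock * v_eff) / (v_sample + v_eff)


def averaging_count(integration_time: float, sub_spectrum_time: float = 60.0) -> int:
    """Number of exposures averaged into one sub-spectrum.

    The operator adapts the averaging so that integration_time x averages
    fills the fixed sub-spectrum duration (0.2 s -> 300, 1 s -> 60).
    """
    if integration_time <= 0 or sub_spectrum_time <= 0:
        raise ValueError("times must be > 0")
    return max(1, round(sub_spectrum_time / integration_time))


def assign_spike_scheme(
    design: pd.DataFrame,
    spike_days: set[int] | frozenset[int] = frozenset(range(6, 14)),
    analytes: tuple[str, ...] = ANALYTES,
    stocks: dict[str, tuple[float, float]] | None = None,
    v_sample: float = 140.0,
    v_min: float = 20.0,
    v_max: float = 60.0,
    pipette_offsets: dict[float, float] | None = None,
    seed: int = 0,
) -> list[SpikeEvent]:
    """Assign one spike per vessel per spiking day by deterministic rotation.

    The rotation cycles through every (analyte, stock level, volume) cell so
    that over the run each analyte is spiked at both stock concentrations and
    several volumes across multiple vessels, breaking the correlation between
    analyte concentration and batch maturity. ``seed`` sets the rotation
    phase per vessel.
    """
    if len(analytes) == 0 or len(spike_days) == 0:
        raise ConfigurationError("need at least one analyte and one spike day")
    stocks = stocks or DEFAULT_STOCKS
    pipette_offsets = pipette_offsets or {}
    volumes = np.linspace(v_min, v_max, 3)
    cells = [
        (a, lvl, v)
        for a in analytes
        for lvl in ("low", "high")
        for v in volumes
    ]
    rng = np.random.default_rng(seed)
    vessels = sorted(design["vessel_id"].tolist())
    phases = {v: int(rng.integers(0, len(cells))) for v in vessels}

    events: list[SpikeEvent] = []
    for di, day in enumerate(sorted(spike_days)):
        for vi, vessel in enumerate(vessels):
            a, lvl, vol = cells[(phases[vessel] + vi + di * 7) % len(cells)]
            c_lo, c_hi = stocks[a]
            events.append(
                SpikeEvent(
                    vessel_id=vessel,
                    day=day,
                    analyte=a,
                    stock_level=lvl,
                    c_stock=c_lo if lvl == "low" else c_hi,
                    v_spike_nominal=float(vol),
                    v_sample=v_sample,
                    pipette_offset=float(pipette_offsets.get(float(vol), 0.0)),
                )
            )
    return events


def spike_events_frame(events: list[SpikeEvent]) -> pd.DataFrame:
    """Tabular view of a spike scheme (one row per SpikeEvent)."""
    return pd.DataFrame([vars(e) for e in events])
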