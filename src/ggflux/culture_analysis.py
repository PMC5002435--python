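"""Growth rates, strain growth ratios, specific GG-consumption rates (qGG)
and intracellular osmolyte concentrations from batch-culture measurements.

Conventions: time in days, OD at 730 nm, extracellular glycerol in mmol/L.
Biomass is converted at 0.2 gDW/L per OD₇₃₀ unit and intracellular volume at
1 µL per mg dry weight.  qGG assumes one glycerol released per GG cleaved,
so the extracellular glycerol accumulation rate per biomass equals the
specific GG-utilization flux.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "CultureTimeSeries",
    "IntervalEstimate",
    "ConversionConstants",
    "CultureDataError",
    "growth_rate",
    "growth_ratio",
    "estimate_qGG",
    "intracellular_concentration",
    "read_culture_csv",
    "write_culture_csv",
]

HOURS_PER_DAY = 24.0


class CultureDataError(ValueError):
    """Invalid culture measurements for the requested computation."""


@dataclass
class ConversionConstants:
    """Culture-to-cell unit conversions.

    ``dw_per_od``: g dry weight per liter per OD₇₃₀ unit (default 0.2);
    ``volume_per_dw``: µL intracellular volume per mg dry weight (default 1).
    """

    dw_per_od: float = 0.2
    volume_per_dw: float = 1.0

    def __post_init__(self) -> None:
        if self.dw_per_od <= 0 or self.volume_per_dw <= 0:
            raise ValueError("conversion constants must be strictly positive")


@dataclass
class CultureTimeSeries:
    """Timestamped OD₇₃₀ and (optional) extracellular glycerol for one culture.

    ``samples`` is an ordered list of (time_days, od730, glycerol_mM) with
    strictly increasing times; glycerol may be None where not measured.
    """

    strain: str
    condition: str
    samples: list[tuple[float, float, float | None]]
    replicate_id: str = "r1"

    def __post_init__(self) -> None:
        times = [s[0] for s in self.samples]
        if any(t1 <= t0 for t0, t1 in zip(times, times[1:])):
            raise CultureDataError("sample times must be strictly increasing")
        if any(s[1] < 0 for s in self.samples):
            raise CultureDataError("OD values must be non-negative")

    @property
    def times(self) -> np.ndarray:
        return np.array([s[0] for s in self.samples])

    @property
    def od(self) -> np.ndarray:
        return np.array([s[1] for s in self.samples])

    @property
    def glycerol(self) -> np.ndarray:
        return np.array([np.nan if s[2] is None else s[2] for s in self.samples])

    def window(self, interval: tuple[float, float]) -> "CultureTimeSeries":
        t0, t1 = interval
        sub = [s for s in self.samples if t0 - 1e-12 <= s[0] <= t1 + 1e-12]
        if len(sub) < 2:
            raise CultureDataError(
                f"interval {interval} covers fewer than 2 samples of "
                f"{self.strain}/{self.replicate_id}"
            )
        return CultureTimeSeries(self.strain, self.condition, sub, self.replicate_id)

    def value_at(self, t: float, column: int) -> float:
        for s in self.samples:
            if abs(s[0] - t) <= 1e-9:
                val = s[column]
                if val is None:
                    raise CultureDataError(f"no measurement at t={t} in column {column}")
                return float(val)
        raise CultureDataError(f"no sample at t={t} d in {self.strain}/{self.replicate_id}")


@dataclass
class IntervalEstimate:
    """Per-interval growth rate, qGG and ratio-to-reference with uncertainty."""

    interval: tuple[float, float]
    mu: float | None = None               # 1/day
    qGG: float | None = None              # mmol gDW^-1 h^-1
    ratio_percent: float | None = None
    sd: float | None = None
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.interval[0] >= self.interval[1]:
            raise ValueError(f"interval must be ordered, got {self.interval}")


# ---------------------------------------------------------------------------
# rates and ratios
# ---------------------------------------------------------------------------


def growth_rate(series: CultureTimeSeries, interval: tuple[float, float]) -> float:
    """Exponential growth rate µ = ln(OD(t1)/OD(t0)) / (t1 − t0), in d⁻¹.

    Negative values are permitted (declining OD); zero or negative OD at an
    endpoint is an error.
    """
    t0, t1 = interval
    od0 = series.value_at(t0, 1)
    od1 = series.value_at(t1, 1)
    if od0 <= 0 or od1 <= 0:
        raise CultureDataError(
            f"growth rate needs positive OD at both endpoints, got {od0}, {od1}"
        )
    return math.log(od1 / od0) / (t1 - t0)


def growth_ratio(series: list[CultureTimeSeries] | CultureTimeSeries,
                 reference: list[CultureTimeSeries] | CultureTimeSeries,
                 interval: tuple[float, float]) -> tuple[float, float]:
    """Percent growth-rate ratio of strain to reference, mean ± sd.

    Ratios are computed over all strain-replicate × reference-replicate
    pairings and summarized as mean ± population sd (0 when only one
    pairing exists).  Negative ratios are reported as-is; they arise when OD
    transiently drops and are not meaningful as growth comparisons.
    """
    strains = [series] if isinstance(series, CultureTimeSeries) else list(series)
    refs = [reference] if isinstance(reference, CultureTimeSeries) else list(reference)
    ratios = []
    for s in strains:
        mu_s = growth_rate(s, interval)
        for r in refs:
            mu_r = growth_rate(r, interval)
            if mu_r == 0:
                raise CultureDataError(
                    "reference growth rate is zero; ratio undefined"
                )
            ratios.append(100.0 * mu_s / mu_r)
    arr = np.array(ratios)
    return float(arr.mean()), float(arr.std())


def estimate_qGG(series: CultureTimeSeries, interval: tuple[float, float],
                 constants: ConversionConstants | None = None,
                 biomass_mean: str = "trapezoid") -> IntervalEstimate:
    """Specific GG-utilization flux from extracellular glycerol accumulation.

    qGG = Δ[glycerol, mmol/L] / (mean biomass [gDW/L] × Δt [h]), where mean
    biomass is dw_per_od × the trapezoidal mean OD over the interval
    (``biomass_mean='endpoints'`` uses the two endpoint ODs instead).  One
    glycerol per GG cleaved is assumed.  Decreasing glycerol yields qGG = 0
    with a ``glycerol_decreased`` flag (re-uptake is not modeled).
    """
    consts = constants or ConversionConstants()
    t0, t1 = interval
    win = series.window(interval)
    if np.isnan(win.glycerol).any():
        raise CultureDataError("glycerol must be measured throughout the interval")
    if (win.od <= 0).any():
        raise CultureDataError("OD must be positive throughout the interval")
    g0 = series.value_at(t0, 2)
    g1 = series.value_at(t1, 2)
    flags: list[str] = []
    if g1 < g0:
        return IntervalEstimate(interval=interval, qGG=0.0,
                                flags=["glycerol_decreased"])
    if biomass_mean == "trapezoid":
        mean_od = float(np.trapezoid(win.od, win.times)) / (t1 - t0)
    elif biomass_mean == "endpoints":
        mean_od = 0.5 * (series.value_at(t0, 1) + series.value_at(t1, 1))
    else:
        raise ValueError(f"unknown biomass_mean {biomass_mean!r}")
    biomass = consts.dw_per_od * mean_od                # gDW/L
    dt_hours = (t1 - t0) * HOURS_PER_DAY
    q = (g1 - g0) / (biomass * dt_hours)
    return IntervalEstimate(interval=interval, qGG=float(q), flags=flags)


def intracellular_concentration(amount_umol: float, sample_volume_l: float,
                                od730: float,
                                constants: ConversionConstants | None = None,
                                ) -> float:
    """Intracellular concentration in mmol/L from an extracted amount.

    Intracellular volume [L] = sample volume × OD₇₃₀ × dw_per_od [g/L] ×
    volume_per_dw [µL/mg] × 1e−6; µmol over that volume gives mmol/L.
    """
    consts = constants or ConversionConstants()
    if amount_umol <= 0 or sample_volume_l <= 0:
        raise ValueError("amount and sample volume must be positive")
    if od730 <= 0:
        raise CultureDataError("OD must be positive to compute cell volume")
    # g/L * µL/mg = 1e3 µL of cell volume per liter of culture per OD unit... keep
    # explicit: dry weight [mg] = volume[L] * od * dw_per_od[g/L] * 1e3
    dry_weight_mg = sample_volume_l * od730 * consts.dw_per_od * 1e3
    volume_ul = dry_weight_mg * consts.volume_per_dw
    volume_l = volume_ul * 1e-6
    return amount_umol * 1e-3 / volume_l  # mmol per liter


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

_CSV_COLUMNS = ["strain", "condition", "replicate", "time_days", "od730", "glycerol_mM"]


def read_culture_csv(path: str | Path) -> list[CultureTimeSeries]:
    """Read culture series from CSV/TSV with columns strain, condition,
    replicate, time_days, od730, glycerol_mM (glycerol may be blank)."""
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in _CSV_COLUMNS[:5] if c not in df.columns]
    if missing:
        raise CultureDataError(f"culture table lacks columns: {missing}")
    if "glycerol_mM" not in df.columns:
        df["glycerol_mM"] = np.nan
    out = []
    for (strain, condition, rep), grp in df.groupby(
            ["strain", "condition", "replicate"], sort=True):
        grp = grp.sort_values("time_days")
        samples = [
            (float(t), float(od), None if pd.isna(g) else float(g))
            for t, od, g in zip(grp["time_days"], grp["od730"], grp["glycerol_mM"])
        ]
        out.append(CultureTimeSeries(strain=str(strain), condition=str(condition),
                                     samples=samples, replicate_id=str(rep)))
    return out


def write_culture_csv(series_list: list[CultureTimeSeries], path: str | Path) -> None:
    rows = []
    for s in series_list:
        for t, od, g in s.samples:
            rows.append({"strain": s.strain, "condition": s.condition,
                         "replicate": s.replicate_id, "time_days": t,
                         "od730": od, "glycerol_mM": "" if g is None else g})
    pd.DataFrame(rows, columns=_CSV_COLUMNS).to_csv(path, index=False)
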