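"""Turbidostat steady-state detection and physiological summaries.

In a turbidostat the feedback loop holds optical density constant, so
at steady state the dilution rate D equals the specific growth rate mu
(h^-1).  A steady state is a trailing stretch of the 1-min process log
in which dilution rate, OD730 and dissolved O2 each stay within 10% of
their window mean (measured as maximum absolute deviation over mean,
the stricter of the plausible readings) for at least three residence
times (tau = 1/D).

From a steady window the module derives: growth rate and doubling
time; the carbon-mole specific growth rate using an elemental biomass
formula; the specific net O2 production rate from an off-gas plus
dissolved-O2 mass balance; the O2 sensitivity coefficient (absolute
slope of mu versus pO2); and the photosynthetic quotient (slope of
Cmol growth rate versus net O2 rate across steady states).  Flow
cytometry gating and background-corrected ROS fluorescence with
Tukey's HSD round out the physiology surface.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

logger = logging.getLogger(__name__)

R_L_ATM = 0.0820574  # L atm mol^-1 K^-1

ATOMIC_MASS = {"C": 12.011, "H": 1.008, "O": 15.999, "N": 14.007}

LOG_CHANNELS = (
    "time_h",
    "dilution_rate",
    "od730",
    "dissolved_o2_uM",
    "offgas_o2_frac",
    "offgas_co2_frac",
)

STABILITY_CHANNELS = ("dilution_rate", "od730", "dissolved_o2_uM")


class PhysiologyError(ValueError):
    pass


def grams_per_cmol(composition: Mapping[str, float]) -> float:
    """Formula weight of one carbon-mole of biomass, g Cmol^-1."""
    return sum(ATOMIC_MASS[el] * stoich for el, stoich in composition.items())


@dataclass(frozen=True)
class GasConfig:
    """Constants for gas and biomass conversions.

    ``air_sat_conc_uM`` is the dissolved-O2 concentration in
    equilibrium with air at the 52 degC culture temperature; together
    with ``atm_o2_fraction`` = 0.21 it anchors the Henry-law
    proportionality used for pO2 -> concentration and percent air
    saturation.  The biomass composition defaults to the generic
    CH1.8O0.5N0.2 formula (24.63 g per Cmol).
    """

    atm_o2_fraction: float = 0.21
    air_sat_conc_uM: float = 130.3
    biomass_composition: Mapping[str, float] = field(
        default_factory=lambda: {"C": 1.0, "H": 1.8, "O": 0.5, "N": 0.2}
    )
    pressure_atm: float = 1.0
    gas_temp_K: float = 298.15

    def __post_init__(self) -> None:
        if not (0 < self.atm_o2_fraction < 1):
            raise PhysiologyError("atm_o2_fraction must be in (0, 1)")
        if self.air_sat_conc_uM <= 0:
            raise PhysiologyError("air_sat_conc_uM must be positive")

    @property
    def grams_per_cmol(self) -> float:
        return grams_per_cmol(self.biomass_composition)


@dataclass
class TurbidostatLog:
    """A 1-min process log plus reactor metadata.

    ``df`` columns: time_h, dilution_rate (h^-1), od730,
    dissolved_o2_uM, offgas_o2_frac, offgas_co2_frac.
    """

    df: pd.DataFrame
    condition: str
    gas_flow_L_h: float
    volume_L: float
    biomass_g_L: float
    inlet_o2_frac: float
    inlet_co2_frac: float = 0.05
    temperature_C: float = 52.0

    def __post_init__(self) -> None:
        missing = [c for c in LOG_CHANNELS if c not in self.df.columns]
        if missing:
            raise PhysiologyError(f"log missing channels: {missing}")
        t = self.df["time_h"].to_numpy()
        if len(t) >= 2:
            steps = np.diff(t)
            if (steps <= 0).any():
                raise PhysiologyError("log time must be strictly increasing")
            if not np.allclose(steps, steps[0], rtol=1e-6):
                raise PhysiologyError("log cadence must be uniform")
        if (self.df["dilution_rate"].to_numpy() < 0).any():
            raise PhysiologyError("dilution rate must be >= 0")

    def __len__(self) -> int:
        return len(self.df)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        meta = {
            "condition": self.condition,
            "gas_flow_L_h": self.gas_flow_L_h,
            "volume_L": self.volume_L,
            "biomass_g_L": self.biomass_g_L,
            "inlet_o2_frac": self.inlet_o2_frac,
            "inlet_co2_frac": self.inlet_co2_frac,
            "temperature_C": self.temperature_C,
        }
        with open(path, "w", encoding="utf-8", newline="") as fh:
            for key, value in meta.items():
                fh.write(f"#{key}={value}\n")
            self.df.to_csv(fh, index=False)


def load_turbidostat_log(path: str | Path) -> TurbidostatLog:
    meta: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        pos = fh.tell()
        while True:
            line = fh.readline()
            if line.startswith("#"):
                key, _, value = line[1:].strip().partition("=")
                meta[key] = value
                pos = fh.tell()
            else:
                fh.seek(pos)
                break
        df = pd.read_csv(fh)
    return TurbidostatLog(
        df=df,
        condition=meta.get("condition", ""),
        gas_flow_L_h=float(meta["gas_flow_L_h"]),
        volume_L=float(meta["volume_L"]),
        biomass_g_L=float(meta["biomass_g_L"]),
        inlet_o2_frac=float(meta["inlet_o2_frac"]),
        inlet_co2_frac=float(meta.get("inlet_co2_frac", 0.05)),
        temperature_C=float(meta.get("temperature_C", 52.0)),
    )


@dataclass(frozen=True)
class SteadyStateWindow:
    """A qualifying trailing stretch of the log (row indices, end exclusive)."""

    start: int
    end: int
    tau_h: float
    spreads: Mapping[str, float]

    @property
    def n_rows(self) -> int:
        return self.end - self.start


def min_window_rows(tau_h: float, cadence_min: float = 1.0) -> int:
    """Minimum row count for a steady window: floor of 3 residence times."""
    return int(np.floor(3.0 * tau_h * 60.0 / cadence_min))


def _relative_spread(x: np.ndarray) -> float:
    mean = x.mean()
    if mean == 0:
        return 0.0 if (x == 0).all() else np.inf
    return float(np.abs(x - mean).max() / abs(mean))


def detect_steady_state(
    log: TurbidostatLog, threshold: float = 0.10
) -> SteadyStateWindow | None:
    """Find the maximal trailing steady-state window.

    Scans candidate start rows from the beginning of the log and
    returns the longest trailing window in which each stability channel
    (dilution rate, OD730, dissolved O2) deviates from its window mean
    by less than ``threshold`` (relative) and whose span covers at
    least three residence times at the window-mean dilution rate.
    Returns None (with a logged diagnostic naming the failing channel)
    if no window qualifies.
    """
    df = log.df
    n = len(df)
    channels = {c: df[c].to_numpy(dtype=float) for c in STABILITY_CHANNELS}
    t = df["time_h"].to_numpy()
    cadence_min = (t[1] - t[0]) * 60.0 if n >= 2 else 1.0
    worst: tuple[float, str] | None = None
    for start in range(n):
        spreads = {c: _relative_spread(x[start:]) for c, x in channels.items()}
        failing = {c: s for c, s in spreads.items() if s >= threshold}
        if failing:
            if worst is None:
                worst = max(failing.items(), key=lambda kv: kv[1])[::-1]
            continue
        d_mean = channels["dilution_rate"][start:].mean()
        if d_mean <= 0:
            continue
        tau = 1.0 / d_mean
        if n - start < min_window_rows(tau, cadence_min):
            logger.info(
                "steady-state window at row %d spans %d rows, below the "
                "3-residence-time minimum of %d",
                start, n - start, min_window_rows(tau, cadence_min),
            )
            return None
        return SteadyStateWindow(start=start, end=n, tau_h=tau, spreads=spreads)
    channel, spread = ("dilution_rate", np.inf) if worst is None else (worst[1], worst[0])
    logger.info(
        "no steady-state window: channel %s spread %.3f exceeds %.2f",
        channel, spread, threshold,
    )
    return None


@dataclass(frozen=True)
class GrowthRate:
    mu: float  # h^-1
    sd: float
    doubling_time_h: float


def growth_rate(log: TurbidostatLog, window: SteadyStateWindow) -> GrowthRate:
    """mu = mean dilution rate over the steady window (turbidostat identity)."""
    d = log.df["dilution_rate"].to_numpy()[window.start : window.end]
    mu = float(d.mean())
    if mu <= 0:
        raise PhysiologyError(f"non-positive growth rate {mu}")
    return GrowthRate(mu=mu, sd=float(d.std(ddof=1)), doubling_time_h=float(np.log(2) / mu))


def cmol_rate(mu: float, gas: GasConfig) -> float:
    """Specific growth rate on a carbon-mole basis, Cmmol h^-1 g^-1 CDW."""
    if mu < 0:
        raise PhysiologyError("mu must be >= 0")
    return mu * 1000.0 / gas.grams_per_cmol


def net_o2_rate(
    log: TurbidostatLog, window: SteadyStateWindow, gas: GasConfig
) -> float:
    """Specific net O2 production rate, mmol O2 h^-1 g^-1 CDW.

    Two export routes out of the well-mixed reactor are summed: the gas
    phase (molar off-gas flow times the O2 mole-fraction rise over the
    inlet, via the ideal gas law) and the liquid effluent (dilution
    rate times the dissolved O2 concentration), normalized by the
    biomass inventory X*V.
    """
    if log.biomass_g_L <= 0:
        raise PhysiologyError("biomass concentration must be positive")
    rows = slice(window.start, window.end)
    y_out = float(log.df["offgas_o2_frac"].to_numpy()[rows].mean())
    d_mean = float(log.df["dilution_rate"].to_numpy()[rows].mean())
    c_dis = float(log.df["dissolved_o2_uM"].to_numpy()[rows].mean())
    molar_conc = gas.pressure_atm / (R_L_ATM * gas.gas_temp_K)  # mol / L gas
    gas_term = log.gas_flow_L_h * (y_out - log.inlet_o2_frac) * molar_conc * 1000.0
    liquid_term = d_mean * c_dis * log.volume_L * 1e-3  # uM * L -> mmol
    return (gas_term + liquid_term) / (log.biomass_g_L * log.volume_L)


def _ols_slope(x: np.ndarray, y: np.ndarray):
    X = sm.add_constant(x)
    fit = sm.OLS(y, X).fit()
    return float(fit.params[1]), float(fit.bse[1]), float(fit.params[0])


def photosynthetic_quotient(points: Sequence[tuple[float, float]]):
    """OLS slope of mu_Cmol on q_O2 across steady states, with its SE.

    The slope is the photosynthetic quotient: Cmol of biomass fixed
    per mol of net O2 produced.
    """
    if len(points) < 2:
        raise PhysiologyError("photosynthetic quotient needs >= 2 points")
    q = np.array([p[0] for p in points], dtype=float)
    mu_c = np.array([p[1] for p in points], dtype=float)
    if len(np.unique(q)) < 2:
        raise PhysiologyError("photosynthetic quotient needs >= 2 distinct q_O2 values")
    slope, se, _ = _ols_slope(q, mu_c)
    return slope, se


@dataclass(frozen=True)
class SensitivityFit:
    """Absolute slope of mu versus pO2 (h^-1 atm^-1) with its SE."""

    slope_abs: float
    se: float
    intercept: float
    n_points: int


def o2_sensitivity(points: Sequence[tuple[float, float]]) -> SensitivityFit:
    """Fit mu against pO2 and report the sensitivity coefficient |slope|."""
    if len(points) < 3:
        raise PhysiologyError("sensitivity fit needs >= 3 points")
    po2 = np.array([p[0] for p in points], dtype=float)
    mu = np.array([p[1] for p in points], dtype=float)
    if len(np.unique(po2)) < 3:
        raise PhysiologyError("sensitivity fit needs >= 3 distinct pO2 values")
    slope, se, intercept = _ols_slope(po2, mu)
    return SensitivityFit(
        slope_abs=abs(slope), se=se, intercept=intercept, n_points=len(points)
    )


def dissolved_o2(pO2: float, gas: GasConfig) -> float:
    """Dissolved O2 concentration (uM) in equilibrium with an inlet pO2."""
    if pO2 < 0:
        raise PhysiologyError("pO2 must be >= 0")
    return gas.air_sat_conc_uM * pO2 / gas.atm_o2_fraction


def percent_air_saturation(pO2: float, gas: GasConfig) -> float:
    """Dissolved O2 as percent of air saturation (linear in pO2)."""
    if pO2 < 0:
        raise PhysiologyError("pO2 must be >= 0")
    return 100.0 * pO2 / gas.atm_o2_fraction


# ---------------------------------------------------------------------------
# Flow cytometry

@dataclass(frozen=True)
class Gate:
    """Rectangular size/complexity gate, optionally fluorescence-refined."""

    fsc: tuple[float, float]
    ssc: tuple[float, float]
    red_min: float | None = None
    green_min: float | None = None

    def contains(self, events: pd.DataFrame) -> np.ndarray:
        mask = (
            (events["fsc"].to_numpy() >= self.fsc[0])
            & (events["fsc"].to_numpy() <= self.fsc[1])
            & (events["ssc"].to_numpy() >= self.ssc[0])
            & (events["ssc"].to_numpy() <= self.ssc[1])
        )
        if self.red_min is not None:
            mask &= events["red_fl"].to_numpy() >= self.red_min
        if self.green_min is not None:
            mask &= events["green_fl"].to_numpy() >= self.green_min
        return mask

    def overlaps(self, other: "Gate") -> bool:
        def _overlap(a, b):
            return a[0] <= b[1] and b[0] <= a[1]

        return _overlap(self.fsc, other.fsc) and _overlap(self.ssc, other.ssc)


def facs_composition(
    events: pd.DataFrame, gates: Mapping[str, Gate]
) -> dict[str, float]:
    """Percentage of events falling in each gate, plus the ungated rest.

    Gates must be pairwise non-overlapping rectangles in (FSC, SSC) so
    every event is uniquely assignable.
    """
    names = list(gates)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            if gates[a].overlaps(gates[b]):
                raise PhysiologyError(f"gates {a!r} and {b!r} overlap")
    total = len(events)
    if total == 0:
        raise PhysiologyError("no events")
    out: dict[str, float] = {}
    gated = np.zeros(total, dtype=bool)
    for name, gate in gates.items():
        mask = gate.contains(events)
        out[name] = 100.0 * mask.sum() / total
        gated |= mask
    out["ungated"] = 100.0 * (~gated).sum() / total
    return out


# ---------------------------------------------------------------------------
# ROS-RNS plates

@dataclass
class RosSummary:
    group_stats: pd.DataFrame  # index group, columns mean / sd / n
    pairwise: pd.DataFrame  # group_a, group_b, diff, p_value, significant
    alpha: float


def ros_corrected(plate: pd.DataFrame, alpha: float = 0.01) -> RosSummary:
    """Background-corrected ROS fluorescence with all-pairs Tukey HSD.

    ``plate`` rows carry columns group, replicate, treated, control;
    the corrected value is treated - control per matched replicate
    (dye-treated minus solvent-only control, removing nonspecific
    fluorescence).  Group means and SDs are reported along with
    Tukey's studentized-range comparisons at the given alpha
    (Tukey-Kramer for unequal group sizes, as implemented by
    scipy.stats.tukey_hsd).
    """
    required = {"group", "replicate", "treated", "control"}
    missing = required - set(plate.columns)
    if missing:
        raise PhysiologyError(f"plate missing columns: {sorted(missing)}")
    if plate[["treated", "control"]].isna().any().any():
        raise PhysiologyError("unmatched treated/control wells (missing values)")
    corrected = plate.assign(corrected=plate["treated"] - plate["control"])
    groups = {g: sub["corrected"].to_numpy() for g, sub in corrected.groupby("group")}
    for g, values in groups.items():
        if len(values) < 2:
            raise PhysiologyError(f"group {g!r} has fewer than 2 replicates")
    names = sorted(groups)
    stats_df = pd.DataFrame(
        {
            "mean": [groups[g].mean() for g in names],
            "sd": [groups[g].std(ddof=1) for g in names],
            "n": [len(groups[g]) for g in names],
        },
        index=pd.Index(names, name="group"),
    )
    rows = []
    if len(names) >= 2:
        res = stats.tukey_hsd(*[groups[g] for g in names])
        for i, a in enumerate(names):
            for j in range(i + 1, len(names)):
                b = names[j]
                p = float(res.pvalue[i, j])
                rows.append(
                    {
                        "group_a": a,
                        "group_b": b,
                        "diff": float(groups[a].mean() - groups[b].mean()),
                        "p_value": p,
                        "significant": p < alpha,
                    }
                )
    return RosSummary(group_stats=stats_df, pairwise=pd.DataFrame(rows), alpha=alpha)
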