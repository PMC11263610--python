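"""First-order dissipation kinetics at the sediment-water interface.

Fits the linearised first-order model ``ln C_t = ln C_0 - k t`` to pooled
replicate concentration series, derives half-life (DT50) ranges from
``k +/- SE``, confidence intervals for ``k``, dissipation percentages, and
the biodegradation fraction ``B,t % = D_biotic,t % - D_abiotic,t %`` with
1-sigma quadrature error propagation.

Two CI conventions are supported (see :func:`ci95`):

``paper``
    half-width ``z * SE / sqrt(n)`` -- a deliberately narrowed comparison
    interval used by the reference microcosm study this package emulates.
``standard``
    half-width ``z * SE`` -- the usual large-sample regression CI for the
    slope; this is the interval with nominal ~95% coverage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ConcentrationSeries",
    "KineticFit",
    "DissipationRecord",
    "fit_first_order",
    "ci95",
    "dt50_range",
    "dissipation",
    "biodegradation_fraction",
    "compare_rates",
    "series_from_frame",
    "kinetics_table",
    "InsufficientDataError",
]

Z95 = 1.96

CiMode = Literal["paper", "standard"]


class InsufficientDataError(ValueError):
    """Raised when a series has too few positive observations to fit."""


@dataclass(frozen=True)
class ConcentrationSeries:
    """Replicated concentrations of one compound over time.

    observations are ``(t_days, conc_uM, replicate)`` tuples; at least one
    observation at t=0 is required so dissipation has a reference point.
    """

    compound: str
    phase: str = "system"  # water | sediment | system
    regime: str = "biotic"  # biotic | abiotic
    condition_type: str = "ONE"  # ONE | MIX
    observations: tuple = field(default_factory=tuple)

    def __post_init__(self):
        obs = tuple((float(t), float(c), r) for t, c, r in self.observations)
        object.__setattr__(self, "observations", obs)
        if any(t < 0 for t, _, _ in obs):
            raise ValueError("negative time in concentration series")
        if any(c < 0 for _, c, _ in obs):
            raise ValueError("negative concentration in series")
        if obs and not any(t == 0 for t, _, _ in obs):
            raise ValueError("series lacks a t=0 observation")

    @property
    def times(self) -> np.ndarray:
        return np.array([t for t, _, _ in self.observations])

    @property
    def concentrations(self) -> np.ndarray:
        return np.array([c for _, c, _ in self.observations])

    def at_time(self, t: float) -> np.ndarray:
        """Replicate concentrations measured at time ``t``."""
        return np.array([c for tt, c, _ in self.observations if tt == t])


@dataclass(frozen=True)
class KineticFit:
    """First-order fit result for one concentration series."""

    k: float
    se: float
    n: int
    ci95: tuple[float, float]
    dt50_range: tuple[float, float]
    r_squared: float
    dissipating: bool = True

    def rounded(self) -> dict:
        """Reporting-layer rounding: rates to 3 decimals, DT50 to days."""
        lo, hi = self.dt50_range
        return {
            "k": float(np.round(self.k, 3)),
            "se": float(np.round(self.se, 3)),
            "n": self.n,
            "ci95_low": float(np.round(self.ci95[0], 3)),
            "ci95_high": float(np.round(self.ci95[1], 3)),
            "dt50_low": float(np.round(lo)) if math.isfinite(lo) else math.inf,
            "dt50_high": float(np.round(hi)) if math.isfinite(hi) else math.inf,
            "r_squared": float(np.round(self.r_squared, 3)),
        }


@dataclass(frozen=True)
class DissipationRecord:
    """Percent dissipated at time t, and the share attributed to biology."""

    compound: str
    t: float
    d_pct: float = np.nan
    sd: float = np.nan
    b_pct: float = np.nan
    b_sd: float = np.nan
    condition_type: str = "ONE"


def ci95(k: float, se: float, n: int, z: float = Z95, mode: CiMode = "paper") -> tuple[float, float]:
    """95% confidence interval for a dissipation rate.

    mode='paper' divides the regression SE by sqrt(n) once more
    (half-width z*SE/sqrt(n)); mode='standard' uses z*SE.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if se < 0:
        raise ValueError("se must be >= 0")
    hw = z * se / math.sqrt(n) if mode == "paper" else z * se
    return (k - hw, k + hw)


def dt50_range(k: float, se: float) -> tuple[float, float]:
    """Half-life range (days): ln2/(k+se) to ln2/(k-se).

    Unrounded; the upper bound is infinite when k <= se (rate not
    distinguishable from zero at 1 sigma).
    """
    if k <= 0:
        raise ValueError("DT50 undefined for non-positive rate")
    if se < 0:
        raise ValueError("se must be >= 0")
    low = math.log(2) / (k + se)
    high = math.log(2) / (k - se) if k > se else math.inf
    return (low, high)


def fit_first_order(series: ConcentrationSeries, drop_zeros: bool = True) -> KineticFit:
    """OLS of ln C on t over all replicate points pooled; k = -slope.

    Zero (and, defensively, negative) concentrations are excluded from the
    log fit when ``drop_zeros``; fewer than 3 usable points raises
    :class:`InsufficientDataError`. A non-positive estimated rate is
    flagged non-dissipating and its DT50 reported as unbounded.
    """
    t = series.times
    c = series.concentrations
    if drop_zeros:
        keep = c > 0
    else:
        keep = np.ones_like(c, dtype=bool)
        if np.any(c <= 0):
            raise ValueError("non-positive concentration in log fit; use drop_zeros")
    t, c = t[keep], c[keep]
    n = int(len(c))
    if n < 3:
        raise InsufficientDataError(f"need >= 3 positive observations, got {n}")
    res = stats.linregress(t, np.log(c))
    k = -float(res.slope)
    se = float(res.stderr)
    r2 = float(res.rvalue**2)
    if k <= 0:
        return KineticFit(k=k, se=se, n=n, ci95=ci95(k, se, n),
                          dt50_range=(math.inf, math.inf), r_squared=r2,
                          dissipating=False)
    return KineticFit(k=k, se=se, n=n, ci95=ci95(k, se, n),
                      dt50_range=dt50_range(k, se), r_squared=r2)


def dissipation(series: ConcentrationSeries, t: float) -> DissipationRecord:
    """Percent dissipated at time t relative to t=0, with 1-sigma SD.

    d_pct = 100 * (1 - mean C_t / mean C_0); the SD is propagated from the
    replicate standard deviations of C_t and C_0 (first order, 1 sigma).
    """
    c0 = series.at_time(0.0)
    ct = series.at_time(t)
    if c0.size == 0 or ct.size == 0:
        raise ValueError(f"no replicate measurements at t=0 and t={t}")
    m0, mt = float(c0.mean()), float(ct.mean())
    if m0 == 0:
        raise ValueError("mean initial concentration is zero")
    s0 = float(c0.std(ddof=1)) if c0.size > 1 else 0.0
    st = float(ct.std(ddof=1)) if ct.size > 1 else 0.0
    d = 100.0 * (1.0 - mt / m0)
    # var(d) = (100/m0)^2 var(mt-term) + (100*mt/m0^2)^2 var(m0-term)
    sd = 100.0 * math.sqrt((st / m0) ** 2 + (mt * s0 / m0**2) ** 2)
    return DissipationRecord(compound=series.compound, t=t, d_pct=d, sd=sd,
                             condition_type=series.condition_type)


def biodegradation_fraction(d_biotic: DissipationRecord,
                            d_abiotic: DissipationRecord) -> DissipationRecord:
    """Biotic contribution B,t % = D_biotic,t % - D_abiotic,t %.

    The SD combines both 1-sigma errors in quadrature. Values are kept
    unrounded; round to integer percent at the reporting layer.
    """
    if (d_biotic.compound != d_abiotic.compound
            or d_biotic.t != d_abiotic.t
            or d_biotic.condition_type != d_abiotic.condition_type):
        raise ValueError("mismatched dissipation records")
    b = d_biotic.d_pct - d_abiotic.d_pct
    b_sd = math.sqrt(d_biotic.sd**2 + d_abiotic.sd**2)
    return DissipationRecord(compound=d_biotic.compound, t=d_biotic.t,
                             d_pct=d_biotic.d_pct, sd=d_biotic.sd,
                             b_pct=b, b_sd=b_sd,
                             condition_type=d_biotic.condition_type)


def compare_rates(fit_a: KineticFit, fit_b: KineticFit) -> str:
    """'distinct' when the CI95 intervals do not overlap, else 'overlapping'."""
    a_lo, a_hi = fit_a.ci95
    b_lo, b_hi = fit_b.ci95
    return "distinct" if (a_hi < b_lo or b_hi < a_lo) else "overlapping"


# ---------------------------------------------------------------------------
# Tabular layer

LONG_COLUMNS = ["compound", "phase", "regime", "condition_type",
                "replicate", "t_days", "conc_uM"]


def series_from_frame(frame: pd.DataFrame) -> list[ConcentrationSeries]:
    """Group a long-format concentration table into ConcentrationSeries."""
    missing = [c for c in LONG_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"concentration table missing columns: {missing}")
    out = []
    keys = ["compound", "phase", "regime", "condition_type"]
    for (compound, phase, regime, ctype), grp in frame.groupby(keys, sort=True):
        obs = tuple(zip(grp["t_days"], grp["conc_uM"], grp["replicate"]))
        out.append(ConcentrationSeries(compound=compound, phase=phase,
                                       regime=regime, condition_type=ctype,
                                       observations=obs))
    return out


def kinetics_table(frame: pd.DataFrame, phase: str = "system",
                   final_time: float | None = None) -> pd.DataFrame:
    """Fit every compound x condition_type x regime series of one phase.

    Returns one row per fit with rounded k, SE, n, CI95, DT50 range plus the
    final-timepoint dissipation percentages and the biodegradation fraction
    (biotic minus abiotic, quadrature SD), mirroring the layout used to
    report microcosm dissipation studies.
    """
    sub = frame[frame["phase"] == phase]
    series = {(s.compound, s.condition_type, s.regime): s
              for s in series_from_frame(sub)}
    rows = []
    for (compound, ctype) in sorted({(c, x) for c, x, _ in series}):
        row: dict = {"compound": compound, "condition_type": ctype, "phase": phase}
        recs = {}
        for regime in ("abiotic", "biotic"):
            s = series.get((compound, ctype, regime))
            if s is None:
                continue
            # formation curves (e.g. transformation products, zero at t=0)
            # are not first-order dissipation; skip them
            if s.at_time(0.0).size == 0 or s.at_time(0.0).mean() == 0:
                continue
            try:
                fit = fit_first_order(s)
            except InsufficientDataError:
                continue
            r = fit.rounded()
            row.update({f"k_{regime}": r["k"], f"se_{regime}": r["se"],
                        f"n_{regime}": r["n"],
                        f"ci95_{regime}_low": r["ci95_low"],
                        f"ci95_{regime}_high": r["ci95_high"],
                        f"dt50_{regime}_low": r["dt50_low"],
                        f"dt50_{regime}_high": r["dt50_high"]})
            tmax = final_time if final_time is not None else max(s.times)
            recs[regime] = dissipation(s, tmax)
            row[f"d_{regime}_pct"] = float(np.round(recs[regime].d_pct))
            row[f"d_{regime}_sd"] = float(np.round(recs[regime].sd))
        if {"abiotic", "biotic"} <= recs.keys():
            b = biodegradation_fraction(recs["biotic"], recs["abiotic"])
            row["b_pct"] = float(np.round(b.b_pct))
            row["b_sd"] = float(np.round(b.b_sd))
        if recs:  # skip species with no fittable dissipation series
            rows.append(row)
    return pd.DataFrame(rows)
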