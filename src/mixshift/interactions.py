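"""Fold changes, interaction coefficients, and mixture-effect classification.

The central question: does a micropollutant mixture shift a taxon's relative
abundance the way the sum of the single-compound exposures would (additive),
more (synergism), or less (antagonism)?

Per taxon and stratum (matrix x timepoint), with CTRL the matched unexposed
condition and relative abundances averaged over replicates:

    FC = (mean_sample + 0.001) / (mean_control + 0.001)
    IC = FC - 1
    IC_ADD = max(-1, IC_MFN + IC_MET + IC_TER)

IC_MIX (from the mixture condition) is then compared with IC_ADD under a
conservative relative uncertainty (default +/-64%, the third quartile of
replicate relative errors): each value v spans [v - r|v|, v + r|v|];
overlapping intervals mean additive, a larger-magnitude IC_MIX means
synergism, a smaller one antagonism ("repressing" same direction,
"opposing" when the two coefficients disagree in sign).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal, Mapping

import numpy as np
import pandas as pd

from .community import AbundanceTable, RANKS

__all__ = [
    "FCRecord",
    "InteractionCall",
    "ContributionRecord",
    "null_replicate_rule",
    "fold_change",
    "interaction_coefficient",
    "additive_ic",
    "classify_interaction",
    "interaction_calls",
    "contribution_ranking",
    "contribution_table",
    "interaction_summary",
    "heatmap_export",
    "replicate_relative_error_q3",
    "CATEGORIES",
    "PSEUDOCOUNT",
    "DEFAULT_REL_ERR",
    "ONE_CONDITIONS",
]

PSEUDOCOUNT = 0.001
DEFAULT_REL_ERR = 0.64
ONE_CONDITIONS = ("MFN", "MET", "TER")
CATEGORIES = ("additive", "synergism", "antagonism_repressing",
              "antagonism_opposing")

Category = Literal["additive", "synergism", "antagonism_repressing",
                   "antagonism_opposing"]


@dataclass(frozen=True)
class FCRecord:
    taxon: str
    level: str
    matrix: str
    timepoint: str
    condition: str
    fc: float
    n_used: int

    @property
    def log10_fc(self) -> float:
        return math.log10(self.fc)


@dataclass(frozen=True)
class InteractionCall:
    taxon: str
    level: str
    matrix: str
    timepoint: str
    ic_mix: float
    ic_add: float
    rel_err: float
    category: Category
    intervals: tuple[float, float, float, float]  # mix_lo, mix_hi, add_lo, add_hi


@dataclass(frozen=True)
class ContributionRecord:
    taxon: str
    level: str
    matrix: str
    timepoint: str
    winner: str
    abs_gaps: Mapping[str, float]


def null_replicate_rule(values: Iterable[float]) -> tuple[float, int]:
    """Mean abundance across replicates with the single-null exclusion.

    When exactly one of three replicate values is zero the group is treated
    as a duplicate: the mean is taken over the two non-zero values. Any
    other pattern (no zeros, several zeros, group size != 3) averages all
    values. Returns (mean, n_used).
    """
    v = np.asarray(list(values), dtype=float)
    if v.size < 2:
        raise ValueError("need >= 2 replicate values")
    if v.size == 3 and int(np.sum(v == 0)) == 1:
        used = v[v != 0]
        return float(used.mean()), 2
    return float(v.mean()), int(v.size)


def fold_change(table: AbundanceTable, level: str,
                conditions: Iterable[str] = ONE_CONDITIONS + ("MIX",),
                control: str = "CTRL") -> list[FCRecord]:
    """Per-taxon fold changes in relative abundance versus matched control.

    The table is aggregated to ``level``, converted to per-sample relative
    abundances, replicate-averaged with :func:`null_replicate_rule`, and
    compared against the control group of the same (matrix, timepoint) with
    a 0.001 pseudo-count on numerator and denominator.
    """
    agg = table.aggregate(level)
    rel = agg.relative_abundance()
    meta = agg.metadata
    records: list[FCRecord] = []
    for (matrix, timepoint), stratum in meta.groupby(["matrix", "timepoint"], sort=True):
        ctrl_ids = stratum.loc[stratum["condition"] == control, "sample_id"]
        if ctrl_ids.empty:
            raise ValueError(f"missing {control} samples for stratum "
                             f"(matrix={matrix}, timepoint={timepoint})")
        ctrl_mat = rel[list(ctrl_ids)]
        for cond in conditions:
            ids = stratum.loc[stratum["condition"] == cond, "sample_id"]
            if ids.empty:
                continue
            cond_mat = rel[list(ids)]
            for taxon in rel.index:
                m_s, n_used = null_replicate_rule(cond_mat.loc[taxon].to_numpy())
                m_c, _ = null_replicate_rule(ctrl_mat.loc[taxon].to_numpy())
                fc = (m_s + PSEUDOCOUNT) / (m_c + PSEUDOCOUNT)
                records.append(FCRecord(taxon=taxon, level=level, matrix=matrix,
                                        timepoint=timepoint, condition=cond,
                                        fc=fc, n_used=n_used))
    return records


def interaction_coefficient(fc: float) -> float:
    """IC = FC - 1; the signed shift in relative abundance vs control."""
    if fc <= 0:
        raise ValueError("fold change must be positive")
    return fc - 1.0


def additive_ic(ic_mfn: float, ic_met: float, ic_ter: float) -> float:
    """Additive expectation: sum of the three single-compound ICs, floored
    at -1 (a taxon cannot lose more than its whole control abundance)."""
    return max(-1.0, ic_mfn + ic_met + ic_ter)


def _interval(v: float, rel_err: float) -> tuple[float, float]:
    hw = rel_err * abs(v)
    return (v - hw, v + hw)


def classify_interaction(ic_mix: float, ic_add: float,
                         rel_err: float = DEFAULT_REL_ERR,
                         signed_rule: bool = False) -> Category:
    """Categorise a mixture effect against its additive expectation.

    Each coefficient v gets a relative uncertainty band [v - r|v|, v + r|v|].
    Overlapping bands -> additive. Disjoint bands with strictly opposite
    signs -> antagonism (opposing). Otherwise the magnitudes decide:
    |IC_MIX| > |IC_ADD| -> synergism, else antagonism (repressing). A zero
    value has a degenerate band and is sign-compatible with either sign.

    ``signed_rule`` switches the non-opposing comparison to the literal
    signed reading (IC_MIX > IC_ADD -> synergism); the two rules coincide
    for sign-compatible pairs of positive sign and for all published
    worked examples.
    """
    mix_lo, mix_hi = _interval(ic_mix, rel_err)
    add_lo, add_hi = _interval(ic_add, rel_err)
    if mix_lo <= add_hi and add_lo <= mix_hi:
        return "additive"
    if ic_mix * ic_add < 0:  # strictly opposite signs (zero compatible with both)
        return "antagonism_opposing"
    if signed_rule:
        return "synergism" if ic_mix > ic_add else "antagonism_repressing"
    return "synergism" if abs(ic_mix) > abs(ic_add) else "antagonism_repressing"


def interaction_calls(fcs: Iterable[FCRecord], rel_err: float = DEFAULT_REL_ERR,
                      signed_rule: bool = False) -> list[InteractionCall]:
    """Build one InteractionCall per taxon x matrix x timepoint from FC records.

    Requires FC records for all three single-compound conditions and MIX;
    taxa missing a condition in a stratum are skipped.
    """
    keyed: dict[tuple, dict[str, FCRecord]] = {}
    for r in fcs:
        keyed.setdefault((r.taxon, r.level, r.matrix, r.timepoint), {})[r.condition] = r
    calls = []
    for (taxon, level, matrix, timepoint), group in sorted(keyed.items()):
        if not set(ONE_CONDITIONS + ("MIX",)) <= group.keys():
            continue
        ics = {c: interaction_coefficient(group[c].fc) for c in ONE_CONDITIONS}
        ic_add = additive_ic(ics["MFN"], ics["MET"], ics["TER"])
        ic_mix = max(-1.0, interaction_coefficient(group["MIX"].fc))
        cat = classify_interaction(ic_mix, ic_add, rel_err, signed_rule)
        calls.append(InteractionCall(
            taxon=taxon, level=level, matrix=matrix, timepoint=timepoint,
            ic_mix=ic_mix, ic_add=ic_add, rel_err=rel_err, category=cat,
            intervals=_interval(ic_mix, rel_err) + _interval(ic_add, rel_err)))
    return calls


def contribution_ranking(fc_one: Mapping[str, float], fc_mix: float,
                         tie_tol: float = 1e-9) -> tuple[str, dict[str, float]]:
    """Which single compound best explains the mixture fold change.

    winner = argmin over {MFN, MET, TER} of |FC_one - FC_mix|; two-way ties
    within ``tie_tol`` yield a binary-combination label (e.g. MET_TER),
    a three-way tie yields ALL.
    """
    missing = [c for c in ONE_CONDITIONS if c not in fc_one]
    if missing:
        raise ValueError(f"missing single-compound FC for {missing}")
    gaps = {c: abs(fc_one[c] - fc_mix) for c in ONE_CONDITIONS}
    best = min(gaps.values())
    tied = [c for c in ONE_CONDITIONS if gaps[c] - best <= tie_tol]
    winner = "ALL" if len(tied) == 3 else "_".join(tied)
    return winner, gaps


def contribution_table(fcs: Iterable[FCRecord],
                       tie_tol: float = 1e-9) -> list[ContributionRecord]:
    """Apply :func:`contribution_ranking` across all taxa/strata; taxa with
    a missing condition are skipped."""
    keyed: dict[tuple, dict[str, FCRecord]] = {}
    for r in fcs:
        keyed.setdefault((r.taxon, r.level, r.matrix, r.timepoint), {})[r.condition] = r
    out = []
    for (taxon, level, matrix, timepoint), group in sorted(keyed.items()):
        if not set(ONE_CONDITIONS + ("MIX",)) <= group.keys():
            continue
        winner, gaps = contribution_ranking(
            {c: group[c].fc for c in ONE_CONDITIONS}, group["MIX"].fc, tie_tol)
        out.append(ContributionRecord(taxon=taxon, level=level, matrix=matrix,
                                      timepoint=timepoint, winner=winner,
                                      abs_gaps=gaps))
    return out


def interaction_summary(calls: Iterable[InteractionCall]) -> pd.DataFrame:
    """Percentage of each category per level x matrix (plus taxon counts)."""
    calls = list(calls)
    if not calls:
        raise ValueError("no interaction calls to summarise")
    df = pd.DataFrame([{"level": c.level, "matrix": c.matrix,
                        "category": c.category} for c in calls])
    rows = []
    for (level, matrix), grp in df.groupby(["level", "matrix"], sort=True):
        n = len(grp)
        row = {"level": level, "matrix": matrix, "n_taxa": n}
        for cat in CATEGORIES:
            row[f"pct_{cat}"] = 100.0 * float((grp["category"] == cat).sum()) / n
        rows.append(row)
    return pd.DataFrame(rows)


def heatmap_export(fcs: Iterable[FCRecord], level: str,
                   figure_path: str | None = None) -> pd.DataFrame:
    """Taxa x (matrix, condition) matrix of log10 FC at one level.

    Positive cells mark an increase vs control, negative a decrease. When
    ``figure_path`` is given a diverging-palette heatmap is rendered there.
    """
    recs = [r for r in fcs if r.level == level]
    if not recs:
        raise ValueError(f"no fold-change records at level {level!r}")
    df = pd.DataFrame([{"taxon": r.taxon, "matrix": r.matrix,
                        "timepoint": r.timepoint, "condition": r.condition,
                        "log10_fc": r.log10_fc} for r in recs])
    mat = df.pivot_table(index="taxon", columns=["matrix", "condition"],
                         values="log10_fc", aggfunc="mean", sort=True)
    if figure_path is not None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        fig, ax = plt.subplots(
            figsize=(1.0 + 0.5 * mat.shape[1], 1.0 + 0.25 * mat.shape[0]))
        vmax = float(np.nanmax(np.abs(mat.to_numpy()))) or 1.0
        im = ax.imshow(mat.to_numpy(), cmap="RdBu_r", vmin=-vmax, vmax=vmax,
                       aspect="auto")
        ax.set_xticks(range(mat.shape[1]),
                      ["/".join(c) for c in mat.columns], rotation=90)
        ax.set_yticks(range(mat.shape[0]), mat.index)
        fig.colorbar(im, ax=ax, label="log10 FC vs CTRL")
        fig.tight_layout()
        fig.savefig(figure_path, dpi=150)
        plt.close(fig)
    return mat


def replicate_relative_error_q3(table: AbundanceTable) -> float:
    """Third quartile of replicate relative errors of relative abundances.

    For every taxon x replicate group (matrix, timepoint, condition), the
    relative deviation |x_rep - mean| / mean is collected over replicates of
    taxa present in the group; Q3 of the pooled distribution is the
    empirical basis for the conservative interval width used by
    :func:`classify_interaction`.
    """
    rel = table.relative_abundance()
    meta = table.metadata
    devs = []
    for _, grp in meta.groupby(["matrix", "timepoint", "condition"], sort=True):
        sub = rel[list(grp["sample_id"])].to_numpy()
        means = sub.mean(axis=1)
        present = means > 0
        with np.errstate(invalid="ignore", divide="ignore"):
            d = np.abs(sub[present] - means[present, None]) / means[present, None]
        devs.append(d.ravel())
    if not devs:
        raise ValueError("empty table")
    return float(np.quantile(np.concatenate(devs), 0.75))
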