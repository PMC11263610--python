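"""Synthetic microcosm experiments with known ground truth.

Emulates the design of a sediment-water interface microcosm study: three
micropollutants (metformin-like, metolachlor-like, terbutryn-like) spiked
singly (ONE) or as a mixture (MIX) into biotic and sterilised (abiotic)
microcosms, with first-order dissipation sampled on days 0/15/30/50/70, and
16S-style ASV count tables for 2 matrices (sediment, water) x 2 timepoints
(d0, d70) x 5 conditions (CTRL, MFN, MET, TER, MIX) x replicates.

Community counts are drawn multinomially from an expected composition built
as  baseline x matrix_multiplier x time_multiplier x exp(condition effect);
the mixture condition follows a per-taxon rule (additive on the log scale,
or a planted deviation from additivity). Because planted effects live on
the absolute scale while the downstream analysis observes relative
abundances, the ground-truth table stores the EXPECTED relative-abundance
fold changes and interaction coefficients (pseudo-count included) together
with the interaction category they imply, so recovery tests compare against
a reachable target.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import expm

from . import refdata
from .community import AbundanceTable, RANKS

__all__ = [
    "TPSpec",
    "CompoundSpec",
    "TaxonEffect",
    "SyntheticSpec",
    "simulate_concentrations",
    "simulate_community",
    "expected_relative_abundance",
    "default_compounds",
    "default_spec",
    "interaction_benchmark_spec",
    "write_outputs",
    "MATRICES",
    "TIMEPOINTS",
    "CONDITIONS",
    "MIX_RULES",
]

MATRICES = ("sediment", "water")
TIMEPOINTS = ("d0", "d70")
CONDITIONS = ("CTRL", "MFN", "MET", "TER", "MIX")
ONE_CONDITIONS = ("MFN", "MET", "TER")
MIX_RULES = ("additive", "synergistic", "antagonistic_repressing",
             "antagonistic_opposing")


@dataclass(frozen=True)
class TPSpec:
    """One transformation product in a first-order decay chain."""
    name: str
    k_form: float  # per day, formation from the upstream species
    k_decay: float  # per day, onward decay

    def __post_init__(self):
        if self.k_form < 0 or self.k_decay < 0:
            raise ValueError("TP rates must be >= 0")


@dataclass(frozen=True)
class CompoundSpec:
    """Kinetic and partitioning parameters of one micropollutant."""
    name: str
    k_biotic: float  # per day
    k_abiotic: float  # per day
    water_fraction: float  # share of total mass in the water phase
    c0: float = refdata.SPIKE_C0_UM  # uM
    noise_sd: float = 0.1  # relative measurement SD
    tp_chain: tuple[TPSpec, ...] = ()

    def __post_init__(self):
        if self.k_biotic < 0 or self.k_abiotic < 0:
            raise ValueError("rates must be >= 0")
        if not 0.0 <= self.water_fraction <= 1.0:
            raise ValueError("water_fraction must be in [0, 1]")
        if self.c0 < 0:
            raise ValueError("C0 must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass(frozen=True)
class TaxonEffect:
    """Planted response of one taxon to the exposure design.

    condition_log_effects maps each single-compound condition to a
    log-scale multiplicative effect vs CTRL; the mixture follows mix_rule:
    additive uses exp(sum of the three log effects), synergistic /
    antagonistic_repressing scale that summed log effect by mix_scale
    (> 1 / < 1), antagonistic_opposing inverts its sign (times mix_scale).
    """
    taxon_index: int
    matrix_multiplier: dict = field(default_factory=dict)  # matrix -> mult
    time_multiplier: float = 1.0  # applied at d70
    condition_log_effects: dict = field(default_factory=dict)
    mix_rule: str = "additive"
    mix_scale: float = 1.0
    baseline_weight: float | None = None  # optional fixed share of total mass

    def __post_init__(self):
        if self.mix_scale <= 0:
            raise ValueError("mix_scale must be > 0")
        if self.mix_rule not in MIX_RULES:
            raise ValueError(f"unknown mix_rule {self.mix_rule!r}")
        if self.condition_log_effects and set(self.condition_log_effects) != set(ONE_CONDITIONS):
            raise ValueError("condition_log_effects must cover exactly MFN, MET, TER")
        if any(m <= 0 for m in self.matrix_multiplier.values()):
            raise ValueError("matrix multipliers must be > 0")
        if self.time_multiplier <= 0:
            raise ValueError("time_multiplier must be > 0")

    def log_effect(self, condition: str) -> float:
        if condition == "CTRL" or not self.condition_log_effects:
            return 0.0
        if condition in ONE_CONDITIONS:
            return float(self.condition_log_effects[condition])
        s = float(sum(self.condition_log_effects.values()))
        if self.mix_rule == "additive":
            return s
        if self.mix_rule in ("synergistic", "antagonistic_repressing"):
            return self.mix_scale * s
        return -self.mix_scale * s  # antagonistic_opposing


@dataclass(frozen=True)
class SyntheticSpec:
    """Full description of one synthetic microcosm experiment."""
    seed: int
    compounds: tuple[CompoundSpec, ...]
    n_taxa: int
    n_replicates: int = 3
    n_replicates_abiotic: int = 2
    depth_mean: int = 50_000
    depth_dispersion: float = 0.1  # lognormal sigma of per-sample depth
    conditions: tuple[str, ...] = CONDITIONS
    matrices: tuple[str, ...] = MATRICES
    timepoints: tuple[str, ...] = TIMEPOINTS
    taxon_effects: tuple[TaxonEffect, ...] = ()
    baseline_sigma: float = 2.0  # lognormal sigma of baseline abundances
    replicate_sigma: float = 0.0  # extra per-replicate lognormal noise
    sampling_days: tuple[float, ...] = refdata.SAMPLING_DAYS

    def __post_init__(self):
        if self.n_taxa < 1:
            raise ValueError("n_taxa must be >= 1")
        if self.depth_mean <= 0:
            raise ValueError("depth_mean must be > 0")
        if self.depth_dispersion <= 0:
            raise ValueError("depth_dispersion must be > 0")
        for eff in self.taxon_effects:
            if not 0 <= eff.taxon_index < self.n_taxa:
                raise ValueError(f"taxon_index {eff.taxon_index} out of range")


# ---------------------------------------------------------------------------
# Concentrations

def _tp_profile(compound: CompoundSpec, k_parent: float,
                days: np.ndarray) -> dict[str, np.ndarray]:
    """Noise-free concentrations of a sequential first-order decay chain."""
    if not compound.tp_chain:
        return {}
    species = [compound.name] + [tp.name for tp in compound.tp_chain]
    m = len(species)
    a = np.zeros((m, m))
    a[0, 0] = -k_parent
    for i, tp in enumerate(compound.tp_chain, start=1):
        a[i, i - 1] = tp.k_form
        a[i, i] = -tp.k_decay
    c0 = np.zeros(m)
    c0[0] = compound.c0
    prof = np.stack([expm(a * t) @ c0 for t in days], axis=1)
    return {name: prof[i] for i, name in enumerate(species[1:], start=1)}


def simulate_concentrations(spec: SyntheticSpec,
                            include_tp: bool = False) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Noisy first-order dissipation series for every compound.

    Returns (long concentration table, ground-truth rate table). For each
    compound x regime (biotic/abiotic rate) x condition type (ONE, MIX) x
    replicate, total mass follows C0*exp(-k t)*(1+eps), eps ~ N(0,
    noise_sd), truncated at 0; phase rows split the noisy total by
    water_fraction (water/sediment), with 'system' carrying the total.
    Biotic series have ``n_replicates`` replicates, abiotic
    ``n_replicates_abiotic`` (sterilised microcosms are run leaner).
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 11]))
    days = np.asarray(spec.sampling_days, dtype=float)
    rows, truth = [], []
    for compound in spec.compounds:
        for regime, k in (("biotic", compound.k_biotic),
                          ("abiotic", compound.k_abiotic)):
            n_rep = spec.n_replicates if regime == "biotic" else spec.n_replicates_abiotic
            tps = _tp_profile(compound, k, days) if include_tp else {}
            for ctype in ("ONE", "MIX"):
                truth.append({"compound": compound.name, "regime": regime,
                              "condition_type": ctype, "k_true": k,
                              "water_fraction": compound.water_fraction})
                for rep in range(1, n_rep + 1):
                    clean = compound.c0 * np.exp(-k * days)
                    eps = (rng.normal(0.0, compound.noise_sd, size=days.size)
                           if compound.noise_sd > 0 else np.zeros(days.size))
                    total = np.maximum(clean * (1.0 + eps), 0.0)
                    for phase, frac in (("water", compound.water_fraction),
                                        ("sediment", 1.0 - compound.water_fraction),
                                        ("system", 1.0)):
                        for t, c in zip(days, total * frac):
                            rows.append({"compound": compound.name, "phase": phase,
                                         "regime": regime, "condition_type": ctype,
                                         "replicate": rep, "t_days": t,
                                         "conc_uM": c})
                    for tp_name, tp_clean in tps.items():
                        tp_eps = (rng.normal(0.0, compound.noise_sd, size=days.size)
                                  if compound.noise_sd > 0 else np.zeros(days.size))
                        tp_total = np.maximum(tp_clean * (1.0 + tp_eps), 0.0)
                        for t, c in zip(days, tp_total):
                            rows.append({"compound": tp_name, "phase": "system",
                                         "regime": regime, "condition_type": ctype,
                                         "replicate": rep, "t_days": t,
                                         "conc_uM": c})
    return pd.DataFrame(rows), pd.DataFrame(truth)


# ---------------------------------------------------------------------------
# Community

def _effects_arrays(spec: SyntheticSpec) -> dict:
    """Dense per-taxon effect arrays from the sparse TaxonEffect list."""
    n = spec.n_taxa
    arr = {
        "matrix_mult": {m: np.ones(n) for m in spec.matrices},
        "time_mult": np.ones(n),
        "log_effect": {c: np.zeros(n) for c in spec.conditions},
        "mix_rule": np.array(["additive"] * n, dtype=object),
        "planted": np.zeros(n, dtype=bool),
        "baseline_weight": np.full(n, np.nan),
    }
    for eff in spec.taxon_effects:
        i = eff.taxon_index
        for m, v in eff.matrix_multiplier.items():
            arr["matrix_mult"][m][i] = v
        arr["time_mult"][i] = eff.time_multiplier
        for c in spec.conditions:
            if c != "CTRL":
                arr["log_effect"][c][i] = eff.log_effect(c)
        arr["mix_rule"][i] = eff.mix_rule
        arr["planted"][i] = bool(eff.condition_log_effects) and any(
            v != 0 for v in eff.condition_log_effects.values())
        if eff.baseline_weight is not None:
            arr["baseline_weight"][i] = eff.baseline_weight
    return arr


def _baseline(spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    """Heavy-tailed baseline composition (lognormal, renormalised), with
    fixed shares honoured for taxa that pin ``baseline_weight``."""
    w = rng.lognormal(0.0, spec.baseline_sigma, size=spec.n_taxa)
    arr = _effects_arrays(spec)["baseline_weight"]
    pinned = ~np.isnan(arr)
    w = w / w.sum()
    if pinned.any():
        total_pinned = float(arr[pinned].sum())
        if total_pinned >= 1.0:
            raise ValueError("pinned baseline weights sum to >= 1")
        w[~pinned] *= (1.0 - total_pinned) / w[~pinned].sum()
        w[pinned] = arr[pinned]
    return w


def expected_relative_abundance(spec: SyntheticSpec) -> dict[tuple, np.ndarray]:
    """Expected (infinite-depth, noise-free) composition per sample group.

    Returns {(matrix, timepoint, condition): per-taxon proportions}.
    Deterministic in spec.seed (the baseline draw is the generator's first
    random stream).
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 23]))
    base = _baseline(spec, rng)
    arr = _effects_arrays(spec)
    out = {}
    for matrix in spec.matrices:
        for timepoint in spec.timepoints:
            for condition in spec.conditions:
                e = base * arr["matrix_mult"][matrix]
                if timepoint == "d70":
                    e = e * arr["time_mult"]
                e = e * np.exp(arr["log_effect"][condition])
                out[(matrix, timepoint, condition)] = e / e.sum()
    return out


def _synthetic_taxonomy(spec: SyntheticSpec, rng: np.random.Generator) -> pd.DataFrame:
    """Plausible seven-rank lineages with progressive unassignment."""
    n = spec.n_taxa
    n_phyla = max(3, n // 8)
    phyla = rng.integers(0, n_phyla, size=n)
    rows = []
    assign_prob = {"Class": 0.98, "Order": 0.95, "Family": 0.90,
                   "Genus": 0.70, "Species": 0.15}
    for i in range(n):
        kingdom = "Archaea" if rng.random() < 0.06 else "Bacteria"
        lineage = {"Kingdom": kingdom, "Phylum": f"Phylum_{phyla[i]:02d}"}
        parent = phyla[i]
        alive = True
        for rank in ("Class", "Order", "Family", "Genus", "Species"):
            alive = alive and rng.random() < assign_prob[rank]
            if alive:
                parent = parent * 7 + int(rng.integers(0, 7))
                lineage[rank] = f"{rank}_{parent % 9973:04d}"
            else:
                lineage[rank] = ""
        rows.append(lineage)
    tax = pd.DataFrame(rows, columns=list(RANKS))
    tax.index = [f"ASV_{i:04d}" for i in range(n)]
    return tax


def simulate_community(spec: SyntheticSpec) -> tuple[AbundanceTable, pd.DataFrame]:
    """Draw an ASV count table for the full microcosm design plus a tidy
    ground-truth table.

    Counts for each sample are multinomial at a per-sample lognormal depth
    around ``depth_mean``; optional ``replicate_sigma`` adds per-replicate
    lognormal wobble to the expected composition. The ground-truth table
    has one row per taxon x matrix x timepoint with the planted mix_rule
    and the expected relative-abundance FC/IC values (pseudo-count 0.001
    applied, compositional renormalisation included) and the interaction
    category those expected values imply.
    """
    from .interactions import PSEUDOCOUNT, additive_ic, classify_interaction

    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 37]))
    expected = expected_relative_abundance(spec)
    arr = _effects_arrays(spec)
    taxa = [f"ASV_{i:04d}" for i in range(spec.n_taxa)]
    counts = {}
    meta_rows = []
    mu_depth = math.log(spec.depth_mean)
    for matrix in spec.matrices:
        for timepoint in spec.timepoints:
            for condition in spec.conditions:
                e = expected[(matrix, timepoint, condition)]
                for rep in range(1, spec.n_replicates + 1):
                    sid = f"{matrix[:3]}_{timepoint}_{condition}_r{rep}"
                    p = e
                    if spec.replicate_sigma > 0:
                        p = e * rng.lognormal(0.0, spec.replicate_sigma, size=e.size)
                        p = p / p.sum()
                    depth = max(1, int(round(rng.lognormal(mu_depth, spec.depth_dispersion))))
                    counts[sid] = rng.multinomial(depth, p)
                    meta_rows.append({"sample_id": sid, "matrix": matrix,
                                      "timepoint": timepoint,
                                      "condition": condition, "replicate": rep,
                                      "regime": "biotic"})
    counts_df = pd.DataFrame(counts, index=taxa)
    taxonomy = _synthetic_taxonomy(spec, rng)
    metadata = pd.DataFrame(meta_rows)
    table = AbundanceTable(counts=counts_df, taxonomy=taxonomy, metadata=metadata)

    truth_rows = []
    for matrix in spec.matrices:
        for timepoint in spec.timepoints:
            comp = {c: expected[(matrix, timepoint, c)] for c in spec.conditions}
            for i, taxon in enumerate(taxa):
                fc = {c: (comp[c][i] + PSEUDOCOUNT) / (comp["CTRL"][i] + PSEUDOCOUNT)
                      for c in spec.conditions if c != "CTRL"}
                ic = {c: fc[c] - 1.0 for c in fc}
                ic_add = additive_ic(ic["MFN"], ic["MET"], ic["TER"])
                ic_mix = max(-1.0, ic["MIX"])
                category = classify_interaction(ic_mix, ic_add)
                truth_rows.append({
                    "taxon": taxon, "matrix": matrix, "timepoint": timepoint,
                    "mix_rule": arr["mix_rule"][i], "planted": bool(arr["planted"][i]),
                    "expected_fc_mfn": fc["MFN"], "expected_fc_met": fc["MET"],
                    "expected_fc_ter": fc["TER"], "expected_fc_mix": fc["MIX"],
                    "expected_ic_add": ic_add, "expected_ic_mix": ic_mix,
                    "expected_category": category,
                })
    return table, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# Factories

def default_compounds() -> tuple[CompoundSpec, ...]:
    """Three compounds with the partitioning and rates of the reference
    microcosm study: hydrophilic MFN (water only, strongly biodegraded),
    MET (even split, mostly abiotic dissipation), recalcitrant TER
    (sediment-bound, slow)."""
    f = refdata.REFERENCE_FITS
    return (
        CompoundSpec("MFN", k_biotic=f[("MFN", "ONE", "biotic")]["k"],
                     k_abiotic=f[("MFN", "ONE", "abiotic")]["k"],
                     water_fraction=1.0,
                     tp_chain=(TPSpec("GUA", k_form=0.04, k_decay=0.08),)),
        CompoundSpec("MET", k_biotic=f[("MET", "ONE", "biotic")]["k"],
                     k_abiotic=f[("MET", "ONE", "abiotic")]["k"],
                     water_fraction=0.5,
                     tp_chain=(TPSpec("NOA", k_form=0.02, k_decay=0.01),)),
        CompoundSpec("TER", k_biotic=f[("TER", "ONE", "biotic")]["k"],
                     k_abiotic=f[("TER", "ONE", "abiotic")]["k"],
                     water_fraction=0.2,
                     tp_chain=(TPSpec("TerOH", k_form=0.003, k_decay=0.002),
                               TPSpec("TerDesE", k_form=0.001, k_decay=0.001))),
    )


def default_spec(seed: int, n_taxa: int = 120, depth_mean: int = 50_000) -> SyntheticSpec:
    """Study-design default: community structured mainly by matrix, then
    incubation time, then contamination.

    Taxa alternate between water and sediment specialists (log-scale
    matrix multiplier +/-1.8, SD 0.6) -- sediment and water host largely
    distinct communities; incubation shifts every taxon with a moderate
    directional drift (+/-0.55, SD 0.3) as communities adjust to
    laboratory conditions; single-compound condition effects are weak and
    centred (N(0, 0.15)) and the mixture is additive. This hierarchy of
    effect scales mirrors the qualitative factor ranking reported for such
    microcosms (matrix > time > contamination).
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 101]))
    effects = []
    for i in range(n_taxa):
        beta = dict(zip(ONE_CONDITIONS, rng.normal(0.0, 0.15, size=3)))
        matrix_dir = 1.0 if i % 2 == 0 else -1.0
        time_dir = 1.0 if i % 3 == 0 else -1.0
        effects.append(TaxonEffect(
            taxon_index=i,
            matrix_multiplier={"water": float(rng.lognormal(1.8 * matrix_dir, 0.6))},
            time_multiplier=float(rng.lognormal(0.55 * time_dir, 0.3)),
            condition_log_effects={c: float(v) for c, v in beta.items()},
            mix_rule="additive"))
    return SyntheticSpec(seed=seed, compounds=default_compounds(),
                         n_taxa=n_taxa, depth_mean=depth_mean,
                         taxon_effects=tuple(effects))


def interaction_benchmark_spec(seed: int, per_category: int = 10,
                               n_background: int = 50,
                               depth_mean: int = 100_000) -> SyntheticSpec:
    """Community with planted, well-separated interaction categories.

    ``per_category`` taxa are planted for each of additive, synergistic,
    antagonistic_repressing and antagonistic_opposing. Additive,
    repressing and opposing taxa are pinned at a 0.4-0.6% baseline share
    so the 0.001 pseudo-count does not swamp their fold changes; planted
    synergism follows the emergence regime seen for such data -- taxa
    nearly absent in control and single-compound conditions that appear in
    the mixture -- so they are pinned rare (0.004-0.007% baseline) with
    small single-compound effects and a large mix_scale. Effect magnitude
    ranges were chosen so the expected-value classification (pseudo-count
    and compositional renormalisation included) separates cleanly; see the
    methods note for why synergism and repression are planted in the
    increase direction only (the -1 floor on IC_ADD makes their
    decrease-direction counterparts non-identifiable by construction).
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 211]))
    n_taxa = n_background + 4 * per_category
    effects = []
    idx = n_background
    for cat in MIX_RULES:
        for j in range(per_category):
            weight = float(rng.uniform(0.004, 0.006))
            sign = 1.0 if (cat in ("synergistic", "antagonistic_repressing")
                           or j % 2 == 0) else -1.0
            if cat == "additive":
                beta = sign * rng.uniform(0.4, 0.7, size=3)
                scale = 1.0
            elif cat == "synergistic":
                weight = float(rng.uniform(5e-5, 1e-4))
                beta = sign * rng.uniform(0.3, 0.5, size=3)
                scale = 3.5
            elif cat == "antagonistic_repressing":
                beta = sign * rng.uniform(0.5, 0.8, size=3)
                scale = 0.3
            else:  # antagonistic_opposing
                beta = sign * rng.uniform(0.5, 0.8, size=3)
                scale = 1.0
            effects.append(TaxonEffect(
                taxon_index=idx,
                condition_log_effects=dict(zip(ONE_CONDITIONS, map(float, beta))),
                mix_rule=cat, mix_scale=scale, baseline_weight=weight))
            idx += 1
    return SyntheticSpec(seed=seed, compounds=default_compounds(),
                         n_taxa=n_taxa, depth_mean=depth_mean,
                         depth_dispersion=0.1,
                         taxon_effects=tuple(effects))


# ---------------------------------------------------------------------------
# Output

def write_outputs(spec: SyntheticSpec, out_dir, include_tp: bool = True) -> dict:
    """Write counts/taxonomy/metadata/concentrations/truth TSVs; returns
    the paths."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    conc, conc_truth = simulate_concentrations(spec, include_tp=include_tp)
    table, truth = simulate_community(spec)
    paths = {
        "counts": out / "counts.tsv",
        "taxonomy": out / "taxonomy.tsv",
        "metadata": out / "metadata.tsv",
        "concentrations": out / "concentrations.tsv",
        "kinetic_truth": out / "kinetic_truth.tsv",
        "truth": out / "truth.tsv",
    }
    table.counts.to_csv(paths["counts"], sep="\t", index_label="taxon")
    table.taxonomy.to_csv(paths["taxonomy"], sep="\t", index_label="taxon")
    table.metadata.to_csv(paths["metadata"], sep="\t", index=False)
    conc.to_csv(paths["concentrations"], sep="\t", index=False)
    conc_truth.to_csv(paths["kinetic_truth"], sep="\t", index=False)
    truth.to_csv(paths["truth"], sep="\t", index=False)
    return {k: str(v) for k, v in paths.items()}
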