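"""ASV-table processing and community statistics.

Containers and operations for taxa x samples count tables with a seven-rank
taxonomy and microcosm sample metadata (matrix, timepoint, condition,
replicate): replicate-prevalence filtering, taxonomic aggregation with
grouping of unassigned lineages, alpha diversity, rarefaction, Bray-Curtis
dissimilarity, mean-distance UPGMA dendrograms, and PERMANOVA with
strata-restricted (or exhaustive) permutations.

PERMANOVA is implemented here directly (sequential sums of squares on the
Gower-centred inner-product matrix) because restricted permutation schemes
and exact enumeration are needed; library implementations serve only as
cross-checks in the test suite.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix, TreeNode
from skbio.diversity import alpha as _alpha

__all__ = [
    "RANKS",
    "AbundanceTable",
    "PermanovaResult",
    "prevalence_filter",
    "aggregate",
    "alpha_diversity",
    "rarefy_curve",
    "bray_curtis",
    "mean_distance_dendrogram",
    "permanova",
]

RANKS = ("Kingdom", "Phylum", "Class", "Order", "Family", "Genus", "Species")

METADATA_COLUMNS = ("sample_id", "matrix", "timepoint", "condition", "replicate")


def _is_assigned(value) -> bool:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return False
    s = str(value).strip()
    return s not in ("", "NA", "nan", "unassigned", "Unassigned")


@dataclass(frozen=True)
class AbundanceTable:
    """Taxa x samples integer counts with taxonomy and sample metadata.

    counts: DataFrame indexed by taxon id, columns are sample ids.
    taxonomy: DataFrame indexed by taxon id with the seven ranks (deeper
        ranks may be unassigned: empty/NaN).
    metadata: DataFrame with sample_id, matrix, timepoint, condition,
        replicate (one row per sample, unique combination).
    """

    counts: pd.DataFrame
    taxonomy: pd.DataFrame
    metadata: pd.DataFrame

    def __post_init__(self):
        if self.counts.index.has_duplicates or self.counts.columns.has_duplicates:
            raise ValueError("duplicate taxon or sample ids")
        vals = self.counts.to_numpy()
        if vals.size and (np.any(vals < 0) or not np.allclose(vals, np.round(vals))):
            raise ValueError("counts must be non-negative integers")
        missing = [c for c in METADATA_COLUMNS if c not in self.metadata.columns]
        if missing:
            raise ValueError(f"metadata missing columns: {missing}")
        unknown = set(self.counts.columns) - set(self.metadata["sample_id"])
        if unknown:
            raise ValueError(f"samples absent from metadata: {sorted(unknown)}")
        key = self.metadata[["matrix", "timepoint", "condition", "replicate"]]
        if key.duplicated().any():
            raise ValueError("metadata rows are not unique on "
                             "(matrix, timepoint, condition, replicate)")
        if not set(self.taxonomy.index) >= set(self.counts.index):
            raise ValueError("taxa absent from taxonomy")

    @property
    def n_taxa(self) -> int:
        return self.counts.shape[0]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def relative_abundance(self) -> pd.DataFrame:
        """Total-sum-scaled per-sample proportions."""
        totals = self.counts.sum(axis=0)
        if (totals == 0).any():
            bad = list(totals.index[totals == 0])
            raise ValueError(f"zero-sum samples: {bad}")
        return self.counts / totals

    # convenience wrappers over the module-level operations
    def prevalence_filter(self, min_replicates: int = 2) -> "AbundanceTable":
        return prevalence_filter(self, min_replicates)

    def aggregate(self, level: str) -> "AbundanceTable":
        return aggregate(self, level)


def prevalence_filter(table: AbundanceTable, min_replicates: int = 2) -> AbundanceTable:
    """Drop taxa never seen in >= min_replicates replicates of any one
    (matrix, timepoint, condition) group.

    Mirrors the replicate-prevalence rule used for amplicon microcosm data:
    an ASV detected in a single replicate of every group is treated as
    spurious and discarded. Idempotent.
    """
    meta = table.metadata
    groups = [list(g["sample_id"]) for _, g in
              meta.groupby(["matrix", "timepoint", "condition"], sort=True)]
    groups = [g for g in groups if set(g) & set(table.counts.columns)]
    if not groups:
        return table
    max_size = max(len(g) for g in groups)
    if min_replicates > max_size:
        raise ValueError(f"min_replicates={min_replicates} exceeds the largest "
                         f"replicate group ({max_size})")
    keep = np.zeros(table.n_taxa, dtype=bool)
    present = table.counts > 0
    for g in groups:
        cols = [c for c in g if c in present.columns]
        keep |= (present[cols].sum(axis=1) >= min_replicates).to_numpy()
    kept = table.counts.index[keep]
    return AbundanceTable(counts=table.counts.loc[kept],
                          taxonomy=table.taxonomy.loc[kept],
                          metadata=table.metadata)


def aggregate(table: AbundanceTable, level: str) -> AbundanceTable:
    """Sum counts by lineage truncated at ``level``.

    ``level`` is one of the seven ranks or "ASV" (identity). Taxa whose
    assignment stops above the requested rank are grouped by their deepest
    assigned lineage under a label ``unclassified <name>``, so per-sample
    totals are conserved exactly.
    """
    if level == "ASV":
        return table
    if level not in RANKS:
        raise ValueError(f"unknown rank {level!r}")
    depth = RANKS.index(level)
    labels = {}
    lineages = {}
    for taxon, row in table.taxonomy.iterrows():
        vals = [row.get(r) for r in RANKS]
        assigned = [i for i, v in enumerate(vals) if _is_assigned(v)]
        deepest = max([i for i in assigned if i <= depth], default=-1)
        prefix = tuple(str(vals[i]) for i in range(deepest + 1))
        if deepest == depth:
            label = str(vals[depth])
        elif deepest >= 0:
            label = f"unclassified {vals[deepest]}"
        else:
            label = "unclassified"
        labels[taxon] = (prefix, label)
        lineages[(prefix, label)] = prefix
    key = pd.Series({t: labels[t] for t in table.counts.index})
    counts = table.counts.groupby(key.reindex(table.counts.index)).sum()
    # readable unique row names: disambiguate identical labels from
    # different lineages with the lineage head
    names = {}
    seen: dict[str, int] = {}
    for prefix, label in counts.index:
        name = label
        if name in seen:
            seen[name] += 1
            name = f"{label} ({'|'.join(prefix[:-1]) or seen[name]})"
        else:
            seen[name] = 0
        names[(prefix, label)] = name
    tax_rows = {}
    for key_, prefix in lineages.items():
        row = {r: (prefix[i] if i < len(prefix) else "") for i, r in enumerate(RANKS)}
        tax_rows[names[key_]] = row
    counts.index = [names[k] for k in counts.index]
    counts = counts.sort_index()
    taxonomy = pd.DataFrame.from_dict(tax_rows, orient="index").loc[counts.index]
    return AbundanceTable(counts=counts, taxonomy=taxonomy, metadata=table.metadata)


# ---------------------------------------------------------------------------
# Alpha diversity

ALPHA_METRICS = ("observed", "chao1", "ace", "shannon", "simpson_diversity",
                 "inv_simpson", "pielou", "simpson_evenness", "camargo",
                 "goods_coverage")


def _camargo(counts: np.ndarray) -> float:
    """Camargo evenness: 1 - sum_{i<j} |p_i - p_j| / S over observed taxa."""
    c = counts[counts > 0]
    s = c.size
    if s == 0:
        return np.nan
    if s == 1:
        return 1.0
    p = c / c.sum()
    diff = np.abs(p[:, None] - p[None, :])
    return float(1.0 - diff[np.triu_indices(s, k=1)].sum() / s)


def _alpha_one(counts: np.ndarray, metrics: Sequence[str]) -> dict:
    c = np.asarray(counts, dtype=int)
    out = {}
    observed = int((c > 0).sum())
    total = int(c.sum())
    for m in metrics:
        try:
            if total == 0:
                val = np.nan
            elif m == "observed":
                val = observed
            elif m == "chao1":
                val = _alpha.chao1(c, bias_corrected=True)
            elif m == "ace":
                val = _alpha.ace(c, rare_threshold=10)
            elif m == "shannon":
                val = _alpha.shannon(c)  # natural log
            elif m == "simpson_diversity":
                val = _alpha.simpson(c)  # 1 - D
            elif m == "inv_simpson":
                val = _alpha.inv_simpson(c)
            elif m == "pielou":
                val = np.nan if observed < 2 else _alpha.pielou_e(c)
            elif m == "simpson_evenness":
                val = _alpha.simpson_e(c)
            elif m == "camargo":
                val = _camargo(c)
            elif m == "goods_coverage":
                val = 1.0 - int((c == 1).sum()) / total
            else:
                raise ValueError(f"unknown metric {m!r}")
        except (ZeroDivisionError, FloatingPointError, ValueError) as err:
            if "unknown metric" in str(err):
                raise
            val = np.nan
        out[m] = float(val) if val is not None else np.nan
    return out


def alpha_diversity(table: AbundanceTable,
                    metrics: Sequence[str] = ALPHA_METRICS) -> pd.DataFrame:
    """Per-sample richness, evenness and diversity profile.

    Undefined values (all-zero sample, single-taxon Pielou, ...) are NaN.
    Shannon uses natural log; Simpson diversity is 1 - D (the inverse form
    is reported alongside as ``inv_simpson``).
    """
    rows = {sid: _alpha_one(table.counts[sid].to_numpy(), metrics)
            for sid in table.sample_ids}
    return pd.DataFrame.from_dict(rows, orient="index")[list(metrics)]


def rarefy_curve(table: AbundanceTable, depths: Sequence[int],
                 n_draws: int = 50, seed: int | None = None,
                 metrics: Sequence[str] = ("observed", "chao1", "shannon",
                                           "pielou", "simpson_diversity"),
                 ) -> pd.DataFrame:
    """Mean alpha metrics over repeated subsamples without replacement.

    Returns a tidy frame (sample_id, depth, metric, value). Depths larger
    than a sample's total are skipped for that sample with a warning.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for sid in table.sample_ids:
        counts = table.counts[sid].to_numpy().astype(int)
        total = int(counts.sum())
        for depth in depths:
            if depth > total:
                warnings.warn(f"depth {depth} exceeds total {total} for "
                              f"sample {sid}; skipped")
                continue
            acc = {m: 0.0 for m in metrics}
            for _ in range(n_draws):
                sub = rng.multivariate_hypergeometric(counts, depth)
                vals = _alpha_one(sub, metrics)
                for m in metrics:
                    acc[m] += vals[m]
            for m in metrics:
                rows.append({"sample_id": sid, "depth": depth, "metric": m,
                             "value": acc[m] / n_draws})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Beta diversity

def bray_curtis(table: AbundanceTable, normalize: bool = True) -> DistanceMatrix:
    """Bray-Curtis dissimilarity between samples.

    Computed on total-sum-scaled relative abundances by default (so
    sequencing-depth differences do not masquerade as composition shifts);
    ``normalize=False`` uses raw counts.
    """
    if len(table.sample_ids) < 2:
        raise ValueError("need >= 2 samples")
    mat = (table.relative_abundance() if normalize else table.counts).to_numpy().T
    if not normalize and np.any(mat.sum(axis=1) == 0):
        raise ValueError("zero-sum sample: Bray-Curtis undefined")
    dm = squareform(pdist(mat, metric="braycurtis"))
    return DistanceMatrix(dm, ids=table.sample_ids)


def mean_distance_dendrogram(dist: DistanceMatrix, metadata: pd.DataFrame,
                             grouping: Sequence[str] = ("matrix", "timepoint",
                                                        "condition"),
                             linkage: str = "average",
                             ) -> tuple[DistanceMatrix, TreeNode]:
    """Collapse a sample distance matrix to group means and cluster (UPGMA).

    Between-group distance is the mean over all cross pairs; the diagonal is
    zero (within-group means, excluding self-pairs, are not used by the
    clustering). Returns the group-mean matrix and the tree (Newick via
    ``str(tree)``), with leaf names joining the grouping values with '_'.
    """
    meta = metadata.set_index("sample_id").loc[list(dist.ids)]
    labels = meta[list(grouping)].astype(str).agg("_".join, axis=1)
    names = sorted(labels.unique())
    if not names:
        raise ValueError("no groups")
    d = dist.data
    idx = {g: np.flatnonzero((labels == g).to_numpy()) for g in names}
    gmat = np.zeros((len(names), len(names)))
    for i, a in enumerate(names):
        for j in range(i + 1, len(names)):
            block = d[np.ix_(idx[a], idx[names[j]])]
            gmat[i, j] = gmat[j, i] = float(block.mean())
    gdm = DistanceMatrix(gmat, ids=names)
    if len(names) == 1:
        return gdm, TreeNode(name=names[0])
    link = hierarchy.linkage(squareform(gmat, checks=False), method=linkage)
    tree = TreeNode.from_linkage_matrix(link, names)
    return gdm, tree


# ---------------------------------------------------------------------------
# PERMANOVA

@dataclass(frozen=True)
class PermanovaResult:
    factor: str
    r2: float
    f_stat: float
    p_value: float
    df: int
    n_permutations: int
    strata: str | None = None


def _gower_center(d: np.ndarray) -> np.ndarray:
    a = -0.5 * d**2
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    return j @ a @ j


def _hat(x: np.ndarray) -> np.ndarray:
    q, _ = np.linalg.qr(x)
    return q @ q.T


def _design_matrices(meta: pd.DataFrame, terms: Sequence[str]) -> tuple[list, list]:
    """Cumulative hat matrices for sequential (type-I) sums of squares."""
    n = len(meta)
    x = np.ones((n, 1))
    hats = [_hat(x)]
    dfs = []
    rank = 1
    for term in terms:
        if term not in meta.columns:
            raise ValueError(f"unknown factor {term!r}")
        dummies = pd.get_dummies(meta[term].astype(str), drop_first=True)
        x = np.hstack([x, dummies.to_numpy(dtype=float)])
        new_rank = np.linalg.matrix_rank(x)
        if new_rank <= rank:
            raise ValueError(f"rank-deficient design: term {term!r} is aliased "
                             f"with preceding terms")
        dfs.append(new_rank - rank)
        rank = new_rank
        hats.append(_hat(x))
    return hats, dfs


def _term_stats(g_batch: np.ndarray, hats: list, dfs: list,
                df_res: int) -> tuple[np.ndarray, np.ndarray]:
    """Sequential SS and pseudo-F per term for a batch of (permuted) G.

    g_batch: (m, n, n). Returns (ss_terms (m, k), f (m, k)).
    """
    n = g_batch.shape[1]
    traces = [np.einsum("ij,mij->m", h, g_batch) for h in hats]
    ss_total = np.einsum("mii->m", g_batch)
    ss_terms = np.stack([traces[i + 1] - traces[i] for i in range(len(dfs))], axis=1)
    ss_res = ss_total - traces[-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ss_terms / np.asarray(dfs)) / (ss_res / df_res)[:, None]
    return ss_terms, f


def _strata_blocks(meta: pd.DataFrame, strata: str | None) -> list[np.ndarray]:
    if strata is None:
        return [np.arange(len(meta))]
    if strata not in meta.columns:
        raise ValueError(f"unknown strata factor {strata!r}")
    return [np.flatnonzero((meta[strata] == v).to_numpy())
            for v in meta[strata].unique()]


def _sample_permutations(blocks: list[np.ndarray], n: int, m: int,
                         rng: np.random.Generator) -> np.ndarray:
    perms = np.tile(np.arange(n), (m, 1))
    for b in blocks:
        for row in perms:
            row[b] = row[b[rng.permutation(len(b))]]
    return perms


def _all_permutations(blocks: list[np.ndarray], n: int) -> np.ndarray:
    per_block = [list(itertools.permutations(range(len(b)))) for b in blocks]
    total = int(np.prod([len(p) for p in per_block]))
    if total > 200_000:
        raise ValueError(f"exhaustive enumeration infeasible: {total} permutations")
    perms = np.empty((total, n), dtype=int)
    for row, combo in enumerate(itertools.product(*per_block)):
        p = np.arange(n)
        for b, local in zip(blocks, combo):
            p[b] = b[list(local)]
        perms[row] = p
    return perms


def permanova(dist: DistanceMatrix | np.ndarray, metadata: pd.DataFrame,
              terms: Sequence[str], n_permutations: int | str = 9999,
              strata: str | None = None, seed: int | None = None,
              ) -> list[PermanovaResult]:
    """PERMANOVA with sequential sums of squares on a distance matrix.

    Partitions the total sum of squared distances (via the Gower-centred
    inner-product matrix) over ``terms`` fitted in order; pseudo-F per term
    uses the residual of the full model. Significance is assessed by
    permuting sample identities -- only within levels of ``strata`` when
    given, or exhaustively when ``n_permutations='exact'`` (p then includes
    the identity permutation: #(F_perm >= F_obs)/N). With sampled
    permutations p = (1 + #(F_perm >= F_obs)) / (1 + n_permutations);
    ``n_permutations=0`` skips the test (p = NaN).

    Returns one :class:`PermanovaResult` per term plus a Residual row; the
    R-squared values (terms + residual) sum to 1.
    """
    if isinstance(dist, DistanceMatrix):
        ids = list(dist.ids)
        d = dist.data
    else:
        d = np.asarray(dist, dtype=float)
        ids = list(metadata["sample_id"])
    meta = metadata.set_index("sample_id").loc[ids].reset_index()
    for term in terms:
        if meta[term].value_counts().min() < 2:
            raise ValueError(f"factor {term!r} has a level with < 2 samples")
    n = d.shape[0]
    g = _gower_center(d)
    hats, dfs = _design_matrices(meta, terms)
    df_model = int(sum(dfs))
    df_res = n - 1 - df_model
    if df_res <= 0:
        raise ValueError("no residual degrees of freedom")
    ss_total = float(np.trace(g))
    ss_obs, f_obs = _term_stats(g[None], hats, dfs, df_res)
    ss_obs, f_obs = ss_obs[0], f_obs[0]
    ss_res = ss_total - float(ss_obs.sum())

    blocks = _strata_blocks(meta, strata)
    if n_permutations == "exact":
        perms = _all_permutations(blocks, n)
        n_perm_eff = perms.shape[0]
        exact = True
    elif int(n_permutations) > 0:
        rng = np.random.default_rng(seed)
        perms = _sample_permutations(blocks, n, int(n_permutations), rng)
        n_perm_eff = int(n_permutations)
        exact = False
    else:
        perms = None
        n_perm_eff = 0
        exact = False

    if perms is not None:
        geq = np.zeros(len(terms))
        for start in range(0, perms.shape[0], 512):
            chunk = perms[start:start + 512]
            g_perm = g[chunk[:, :, None], chunk[:, None, :]]
            _, f_perm = _term_stats(g_perm, hats, dfs, df_res)
            geq += (f_perm >= f_obs[None, :] - 1e-12).sum(axis=0)
        if exact:
            p_values = geq / n_perm_eff
        else:
            p_values = (1.0 + geq) / (1.0 + n_perm_eff)
    else:
        p_values = [np.nan] * len(terms)

    results = [PermanovaResult(factor=t, r2=float(ss_obs[i] / ss_total),
                               f_stat=float(f_obs[i]), p_value=float(p_values[i]),
                               df=int(dfs[i]), n_permutations=n_perm_eff,
                               strata=strata)
               for i, t in enumerate(terms)]
    results.append(PermanovaResult(factor="Residual",
                                   r2=float(ss_res / ss_total),
                                   f_stat=np.nan, p_value=np.nan, df=df_res,
                                   n_permutations=n_perm_eff, strata=strata))
    return results


def permanova_frame(results: Iterable[PermanovaResult]) -> pd.DataFrame:
    return pd.DataFrame([{"factor": r.factor, "df": r.df, "r2": r.r2,
                          "f_stat": r.f_stat, "p_value": r.p_value,
                          "n_permutations": r.n_permutations,
                          "strata": r.strata} for r in results])
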