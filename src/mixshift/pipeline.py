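"""Configuration, validation and orchestration of a full analysis run.

Canonical interchange is TSV (taxa x samples counts, seven-rank taxonomy,
sample metadata, long-format concentrations) plus JSON for the run
configuration and manifest. Every analytic output starts with
'#'-prefixed header lines carrying the config hash and seed, so two runs
with identical config and seed are byte-identical and self-describing.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .community import (RANKS, AbundanceTable, alpha_diversity, bray_curtis,
                        mean_distance_dendrogram, permanova, permanova_frame,
                        prevalence_filter)
from .interactions import (contribution_table, fold_change, heatmap_export,
                           interaction_calls, interaction_summary)
from .kinetics import LONG_COLUMNS, kinetics_table

log = logging.getLogger("mixshift")

__all__ = ["RunConfig", "ValidationIssue", "validate_inputs", "run_pipeline",
           "read_counts", "read_taxonomy", "read_metadata", "read_table",
           "read_concentrations", "write_tsv"]


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to reproduce one pipeline run."""

    counts: str
    taxonomy: str
    metadata: str
    out_dir: str
    concentrations: str | None = None
    levels: tuple[str, ...] = ("Phylum", "ASV")
    rel_err: float = 0.64
    ci_mode: str = "paper"
    permutations: int = 9999
    permanova_terms: tuple[str, ...] = ("matrix", "timepoint", "condition")
    strata: str | None = None
    min_replicates: int = 2
    seed: int = 0
    render_heatmaps: bool = False

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        raw = json.loads(Path(path).read_text())
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        for key in ("levels", "permanova_terms"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass(frozen=True)
class ValidationIssue:
    severity: str  # "fatal" | "warning"
    field: str
    message: str


def read_counts(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    return df


def read_taxonomy(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col=0,
                       keep_default_na=False)


def read_metadata(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def read_concentrations(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def read_table(counts_path, taxonomy_path, metadata_path) -> AbundanceTable:
    return AbundanceTable(counts=read_counts(counts_path),
                          taxonomy=read_taxonomy(taxonomy_path),
                          metadata=read_metadata(metadata_path))


def write_tsv(df: pd.DataFrame, path, config_hash: str, seed: int,
              index: bool = False, index_label=None) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# mixshift {__version__}\n# config_hash: {config_hash}\n"
                 f"# seed: {seed}\n")
        df.to_csv(fh, sep="\t", index=index, index_label=index_label)


def validate_inputs(config: RunConfig) -> list[ValidationIssue]:
    """Schema and sanity checks; fatal issues abort before any computation."""
    issues: list[ValidationIssue] = []
    paths = {"counts": config.counts, "taxonomy": config.taxonomy,
             "metadata": config.metadata}
    if config.concentrations:
        paths["concentrations"] = config.concentrations
    for name, p in paths.items():
        if not Path(p).is_file():
            issues.append(ValidationIssue("fatal", name, f"file not found: {p}"))
    if any(i.severity == "fatal" for i in issues):
        return issues

    counts = read_counts(config.counts)
    taxonomy = read_taxonomy(config.taxonomy)
    metadata = read_metadata(config.metadata)
    num = counts.select_dtypes("number")
    if num.shape != counts.shape:
        issues.append(ValidationIssue("fatal", "counts", "non-numeric cells"))
    else:
        if (counts.to_numpy() < 0).any():
            issues.append(ValidationIssue("fatal", "counts", "negative counts"))
        if not (counts.to_numpy() == counts.to_numpy().round()).all():
            issues.append(ValidationIssue("fatal", "counts", "non-integer counts"))
    missing_ranks = [r for r in RANKS if r not in taxonomy.columns]
    if missing_ranks:
        issues.append(ValidationIssue("fatal", "taxonomy",
                                      f"missing ranks: {missing_ranks}"))
    missing_tax = set(counts.index) - set(taxonomy.index)
    if missing_tax:
        issues.append(ValidationIssue("fatal", "taxonomy",
                                      f"{len(missing_tax)} taxa lack a lineage"))
    need = {"sample_id", "matrix", "timepoint", "condition", "replicate"}
    if not need <= set(metadata.columns):
        issues.append(ValidationIssue("fatal", "metadata",
                                      f"missing columns: {sorted(need - set(metadata.columns))}"))
    else:
        orphan = set(counts.columns) - set(metadata["sample_id"])
        if orphan:
            issues.append(ValidationIssue("fatal", "metadata",
                                          f"samples without metadata: {sorted(orphan)}"))
        sizes = metadata.groupby(["matrix", "timepoint", "condition"]).size()
        if len(sizes) and sizes.nunique() > 1:
            issues.append(ValidationIssue("warning", "metadata",
                                          "unbalanced replicate groups: "
                                          f"{sizes.min()}-{sizes.max()} samples"))
        for (matrix, timepoint), grp in metadata.groupby(["matrix", "timepoint"]):
            if "CTRL" not in set(grp["condition"]):
                issues.append(ValidationIssue(
                    "fatal", "metadata",
                    f"no CTRL samples for stratum (matrix={matrix}, "
                    f"timepoint={timepoint})"))
    if config.concentrations:
        conc = read_concentrations(config.concentrations)
        missing_cols = [c for c in LONG_COLUMNS if c not in conc.columns]
        if missing_cols:
            issues.append(ValidationIssue("fatal", "concentrations",
                                          f"missing columns: {missing_cols}"))
        else:
            means = (conc.groupby(["compound", "phase", "regime",
                                   "condition_type", "t_days"])["conc_uM"]
                     .mean().reset_index())
            for key, grp in means.groupby(["compound", "phase", "regime",
                                           "condition_type"]):
                g = grp.sort_values("t_days")["conc_uM"].to_numpy()
                if g.size > 1 and g[-1] > 1.05 * g[0] and g[0] > 0:
                    issues.append(ValidationIssue(
                        "warning", "concentrations",
                        f"mean concentration increases over time for {key}"))
    return issues


def run_pipeline(config: RunConfig) -> dict:
    """Execute filter -> aggregate -> diversity -> distances -> PERMANOVA ->
    FC/IC classification -> contributor ranking, writing all outputs plus a
    machine-readable manifest into the run directory.

    Raises ValueError on fatal validation issues before touching any
    output. Returns the manifest dict.
    """
    issues = validate_inputs(config)
    fatal = [i for i in issues if i.severity == "fatal"]
    for issue in issues:
        log.log(logging.ERROR if issue.severity == "fatal" else logging.WARNING,
                "%s: %s", issue.field, issue.message)
    if fatal:
        raise ValueError("; ".join(f"{i.field}: {i.message}" for i in fatal))

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    h = config.hash()
    seed = config.seed
    outputs: dict[str, str] = {}

    def emit(df, name, **kw):
        write_tsv(df, out / name, h, seed, **kw)
        outputs[name] = str(out / name)

    table = read_table(config.counts, config.taxonomy, config.metadata)
    n_before = table.n_taxa
    table = prevalence_filter(table, config.min_replicates)
    log.info("prevalence filter: %d -> %d taxa", n_before, table.n_taxa)

    emit(alpha_diversity(table), "alpha.tsv", index=True, index_label="sample_id")
    dm = bray_curtis(table)
    emit(pd.DataFrame(dm.data, index=dm.ids, columns=dm.ids),
         "bray_curtis.tsv", index=True, index_label="sample_id")
    gdm, tree = mean_distance_dendrogram(dm, table.metadata)
    (out / "dendrogram.nwk").write_text(str(tree))
    outputs["dendrogram.nwk"] = str(out / "dendrogram.nwk")
    res = permanova(dm, table.metadata, terms=list(config.permanova_terms),
                    n_permutations=config.permutations, strata=config.strata,
                    seed=seed)
    emit(permanova_frame(res), "permanova.tsv")

    fc_frames, call_frames, contrib_frames = [], [], []
    all_calls = []
    for level in config.levels:
        fcs = fold_change(table, level)
        fc_frames.append(pd.DataFrame(
            [{"level": r.level, "taxon": r.taxon, "matrix": r.matrix,
              "timepoint": r.timepoint, "condition": r.condition, "fc": r.fc,
              "log10_fc": r.log10_fc, "n_used": r.n_used} for r in fcs]))
        calls = interaction_calls(fcs, rel_err=config.rel_err)
        all_calls.extend(calls)
        call_frames.append(pd.DataFrame(
            [{"level": c.level, "taxon": c.taxon, "matrix": c.matrix,
              "timepoint": c.timepoint, "ic_mix": c.ic_mix, "ic_add": c.ic_add,
              "rel_err": c.rel_err, "category": c.category,
              "mix_low": c.intervals[0], "mix_high": c.intervals[1],
              "add_low": c.intervals[2], "add_high": c.intervals[3]}
             for c in calls]))
        contribs = contribution_table(fcs)
        contrib_frames.append(pd.DataFrame(
            [{"level": c.level, "taxon": c.taxon, "matrix": c.matrix,
              "timepoint": c.timepoint, "winner": c.winner,
              **{f"gap_{k.lower()}": v for k, v in c.abs_gaps.items()}}
             for c in contribs]))
        mat = heatmap_export(
            fcs, level,
            figure_path=str(out / f"heatmap_{level}.png") if config.render_heatmaps else None)
        flat = mat.copy()
        flat.columns = ["/".join(c) for c in flat.columns]
        emit(flat, f"heatmap_{level}.tsv", index=True, index_label="taxon")
        if config.render_heatmaps:
            outputs[f"heatmap_{level}.png"] = str(out / f"heatmap_{level}.png")
    emit(pd.concat(fc_frames, ignore_index=True), "fc.tsv")
    emit(pd.concat(call_frames, ignore_index=True), "interactions.tsv")
    emit(pd.concat(contrib_frames, ignore_index=True), "contributions.tsv")
    emit(interaction_summary(all_calls), "summary.tsv")

    if config.concentrations:
        conc = read_concentrations(config.concentrations)
        emit(kinetics_table(conc), "kinetics.tsv")

    manifest = {
        "package": "mixshift", "version": __version__,
        "config": asdict(config), "config_hash": h, "seed": seed,
        "n_taxa_input": n_before, "n_taxa_after_filter": table.n_taxa,
        "outputs": sorted(outputs),
        "warnings": [f"{i.field}: {i.message}" for i in issues
                     if i.severity == "warning"],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  sort_keys=True) + "\n")
    return manifest
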