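import numpy as np
import pandas as pd
import pytest

from mixshift.community import AbundanceTable, RANKS


def make_metadata(matrices=("sediment",), timepoints=("d0",),
                  conditions=("CTRL", "MFN"), n_replicates=3):
    rows = []
    for m in matrices:
        for t in timepoints:
            for c in conditions:
                for r in range(1, n_replicates + 1):
                    rows.append({"sample_id": f"{m[:3]}_{t}_{c}_r{r}",
                                 "matrix": m, "timepoint": t, "condition": c,
                                 "replicate": r})
    return pd.DataFrame(rows)


def make_taxonomy(taxa, phylum="Phylum_A"):
    rows = {t: {r: "" for r in RANKS} for t in taxa}
    for t in taxa:
        rows[t]["Kingdom"] = "Bacteria"
        rows[t]["Phylum"] = phylum
    df = pd.DataFrame.from_dict(rows, orient="index")
    return df.reindex(columns=list(RANKS))


@pytest.fixture
def toy_table():
    """3 taxa x (CTRL, MFN) x 3 replicates, one matrix/timepoint."""
    meta = make_metadata()
    counts = pd.DataFrame(
        {sid: [10, 5, 5] for sid in meta["sample_id"]},
        index=["ASV_a", "ASV_b", "ASV_c"])
    return AbundanceTable(counts=counts, taxonomy=make_taxonomy(counts.index),
                          metadata=meta)


@pytest.fixture(scope="session")
def benchmark_run():
    """One planted-interaction benchmark community, simulated once."""
    from mixshift import synth
    spec = synth.interaction_benchmark_spec(11)
    table, truth = synth.simulate_community(spec)
    return spec, table, truth
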