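"""Shared fixtures for the rhizopipe test suite."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from rhizopipe.data_model import (CountMatrix, SampleFrame, TaxonomyTable,
                                  RANKS)

settings.register_profile(
    "ci", derandomize=True, deadline=None, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


def make_meta(rows):
    """Build a SampleFrame from (sample, fraction, genotype, species,
    ancestry, ploidy, d_genome, replicate) tuples."""
    cols = ["fraction", "genotype", "species", "ancestry", "ploidy",
            "d_genome", "replicate"]
    table = pd.DataFrame([r[1:] for r in rows], columns=cols,
                         index=[r[0] for r in rows])
    table.index.name = "sample_id"
    return SampleFrame(table)


def make_taxonomy(entries):
    """Build a TaxonomyTable from {otu: dict-of-overrides} entries."""
    rows = {}
    for otu, overrides in entries.items():
        row = {c: "" for c in RANKS}
        row.update(is_host_plant=False, is_organelle=False)
        row.update(overrides)
        rows[otu] = row
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "otu_id"
    return TaxonomyTable(table)


@pytest.fixture
def tiny_counts():
    df = pd.DataFrame({"S1": [5, 1], "S2": [0, 3]},
                      index=["OTU_1", "OTU_2"])
    df.index.name = "otu_id"
    return CountMatrix(df, "prokaryote16S")


@pytest.fixture
def two_line_meta():
    """One species, two lines x 4 replicates (rhizosphere)."""
    rows = []
    for line in ("L1", "L2"):
        for rep in range(1, 5):
            rows.append((f"{line}_r{rep}", "rhizosphere", line,
                         "T. aestivum", "modern", 6, "artificial", rep))
    return make_meta(rows)
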