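import numpy as np
import pandas as pd
import pytest

from teimmune import (GeneRecord, RecombinationMap, SimConfig, TECatalog)


@pytest.fixture
def small_config():
    return SimConfig(seed=11, te_count=300, n_strains_per_pop=20,
                     vials_per_group=4)


def make_catalog(rows):
    """Build a TECatalog from (chrom, start, end, is_ine1, repeat_flanked) tuples."""
    df = pd.DataFrame([{
        "id": f"te{i}", "family": "roo", "te_class": "LTR",
        "chrom": c, "start": s, "end": e, "length_bp": e - s + 1,
        "completeness": "truncated", "is_reference": True,
        "is_ine1": ine1, "repeat_flanked_or_nested": rep,
    } for i, (c, s, e, ine1, rep) in enumerate(rows)],
        columns=["id", "family", "te_class", "chrom", "start", "end",
                 "length_bp", "completeness", "is_reference", "is_ine1",
                 "repeat_flanked_or_nested"])
    return TECatalog(df)


def make_map(intervals, dialect="map_A"):
    """RecombinationMap from (chrom, start, end, rate) tuples (half-open)."""
    return RecombinationMap(
        pd.DataFrame(intervals, columns=["chrom", "start", "end", "rate"]),
        dialect=dialect)


def make_gene(gene_id, chrom, start, end, strand="+", cds=None,
              immune=False):
    cds = cds if cds is not None else [(start, end)]
    return GeneRecord(gene_id=gene_id, symbol=gene_id, chrom=chrom,
                      start=start, end=end, strand=strand,
                      transcripts={f"{gene_id}_t1": cds},
                      immune_flag=immune,
                      evidence=frozenset({"expression"}) if immune else frozenset())


@pytest.fixture
def toy_survival():
    """Six-record toy set with censoring for hand product-limit checks."""
    return pd.DataFrame({
        "fly": [f"f{i}" for i in range(6)],
        "vial": ["v1"] * 3 + ["v2"] * 3,
        "group": ["g"] * 6,
        "treatment": ["infected"] * 6,
        "time": [2.0, 3.0, 4.0, 4.0, 5.0, 6.0],
        "event": [1, 0, 1, 1, 0, 1],
    })
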