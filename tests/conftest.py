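import numpy as np
import pandas as pd
import pytest

from paskit.pathway_db import GeneRole, PathwayCollection, PathwayDef


@pytest.fixture
def tiny_db() -> PathwayCollection:
    """Three small hand-built pathways with mixed roles and one overlap."""
    return PathwayCollection(
        [
            PathwayDef(
                "Growth",
                "proliferation",
                (GeneRole("gA", 1.0), GeneRole("gB", 0.5), GeneRole("gC", -1.0)),
            ),
            PathwayDef(
                "Growth",
                "arrest",
                (GeneRole("gC", 1.0), GeneRole("gD", -0.5)),
            ),
            PathwayDef("Stress", "main", (GeneRole("gE", 1.0), GeneRole("gF", 0.0))),
        ]
    )


@pytest.fixture
def toy_design() -> pd.DataFrame:
    rows = [
        ("ref1", "sham", 0.0, 1, 1),
        ("ref2", "sham", 0.0, 2, 1),
        ("ref3", "sham", 0.0, 3, 1),
        ("case1", "ALPPS", 4.0, 1, 0),
        ("case2", "ALPPS", 4.0, 2, 0),
    ]
    return pd.DataFrame(
        rows,
        columns=["sample_id", "procedure", "timepoint_h", "replicate", "is_reference"],
    ).set_index("sample_id")


@pytest.fixture
def toy_counts(toy_design) -> pd.DataFrame:
    rng = np.random.default_rng(42)
    genes = [f"g{c}" for c in "ABCDEF"]
    values = rng.integers(50, 200, size=(len(genes), len(toy_design)))
    return pd.DataFrame(values, index=pd.Index(genes, name="gene_id"),
                        columns=toy_design.index)
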