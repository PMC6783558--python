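import numpy as np
import pandas as pd
import pytest

from ripresil.tables_io import CountTable, validate_metadata


@pytest.fixture
def tiny_table() -> CountTable:
    """3 taxa x 2 samples with column sums 10/10."""
    counts = pd.DataFrame(
        [[5, 0], [3, 2], [2, 8]],
        index=["tA", "tB", "tC"],
        columns=["S1", "S2"],
    )
    return CountTable(counts)


@pytest.fixture
def otu_table() -> CountTable:
    """5 OTUs across 3 genera plus 1 unresolved-at-genus OTU."""
    counts = pd.DataFrame(
        {
            "S1": [4, 6, 1, 2, 7],
            "S2": [0, 3, 5, 5, 1],
        },
        index=["otu1", "otu2", "otu3", "otu4", "otu5"],
    )
    taxonomy = pd.Series(
        {
            "otu1": "d__Archaea;p__Euryarchaeota;c__Mb;o__Mb;f__Mb;g__Methanosaeta",
            "otu2": "d__Archaea;p__Euryarchaeota;c__Mb;o__Mb;f__Mb;g__Methanosaeta",
            "otu3": "d__Archaea;p__Euryarchaeota;c__Mb;o__Mb;f__Mb;g__Methanobacterium",
            "otu4": "d__Archaea;p__Thaumarchaeota;c__Ns;o__Ns;f__Ns;g__Nitrososphaera",
            "otu5": "d__Archaea;p__Thaumarchaeota;c__Ns;o__Ns;f__Ns",
        }
    )
    return CountTable(counts, taxonomy)


@pytest.fixture
def two_area_metadata() -> pd.DataFrame:
    rows = []
    for area in ("NA", "AA"):
        for group, n in (("reference", 4), ("flooding", 13), ("recovery", 7)):
            for i in range(n):
                rows.append(
                    {
                        "sample_id": f"{area}_{group}_{i + 1:02d}",
                        "area": area,
                        "group": group,
                        "elevation_m": 175.5 if group == "reference" else 160.0,
                        "flooding_duration_days": 0.0 if group == "reference" else 100.0,
                    }
                )
    return validate_metadata(pd.DataFrame(rows))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20826)
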