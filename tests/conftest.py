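import numpy as np
import pandas as pd
import pytest

from beeallele import amr, synthio


@pytest.fixture
def samples_sheet():
    rows = [
        (f"{col}_{st}_1", col, st)
        for col in ("colony1", "colony2", "colony3")
        for st in ("reproductive", "sterile")
    ]
    return pd.DataFrame(rows, columns=["sample", "colony", "status"])


@pytest.fixture
def genes_frame():
    return pd.DataFrame(
        {
            "gene_id": ["gA", "gB", "gC"],
            "chrom": ["LG1", "LG1", "LG2"],
            "start": [100, 150, 100],
            "end": [200, 400, 300],
        }
    )


def make_window(reads, positions=None):
    """Build an EpireadWindow from a list of C/T strings (complete reads)."""
    mat = np.array(
        [[1.0 if c == "C" else 0.0 for c in read] for read in reads]
    )
    w = mat.shape[1]
    if positions is None:
        positions = 1000 + 50 * np.arange(w)
    return amr.EpireadWindow(
        chrom="chr1",
        cpg_indices=np.arange(w),
        cpg_positions=np.asarray(positions),
        reads=mat,
    )


@pytest.fixture
def cc_tt_window():
    """10 fully methylated + 10 fully unmethylated reads over 3 CpGs."""
    return make_window(["CCC"] * 10 + ["TTT"] * 10)
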