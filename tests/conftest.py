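import numpy as np
import pandas as pd
import pytest

from fitmr import CANONICAL_COLUMNS, HarmonisedSet, SummaryTable


def make_table(rows, label="trait", trait_type="continuous"):
    """Build a SummaryTable from (id, chrom, pos, ea, oa, eaf, beta, se, p, n) tuples."""
    df = pd.DataFrame(rows, columns=CANONICAL_COLUMNS)
    return SummaryTable(label, trait_type, df)


@pytest.fixture
def three_variant_table():
    return make_table([
        ("rs1", "1", 1_000_000, "A", "G", 0.30, 0.10, 0.01, 1e-10, 50_000),
        ("rs2", "1", 1_500_000, "C", "T", 0.20, -0.08, 0.01, 1e-9, 50_000),
        ("rs3", "1", 3_000_000, "G", "A", 0.40, 0.12, 0.01, 1e-12, 50_000),
    ])


@pytest.fixture
def simple_harmonised():
    """Two-variant set with ratios 0.5 (se 0.1) and 0.7 (se 0.2)."""
    return HarmonisedSet.from_arrays(
        beta_exp=[1.0, 1.0], se_exp=[0.01, 0.01],
        beta_out=[0.5, 0.7], se_out=[0.1, 0.2])


def harmonised_from(bx, sx, by, sy, **kw):
    return HarmonisedSet.from_arrays(bx, sx, by, sy, **kw)
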