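import pandas as pd
import pytest

from hlapop.nomenclature import load_g_groups


@pytest.fixture(scope="session")
def g_table():
    """Small hand-written G-group table used across consensus tests."""
    lines = [
        "# comment line",
        "A*;01:01:01:01/01:01:02/01:01:38N;01:01:01G",
        "A*;02:01:01/02:01:02;02:01:01G",
        "B*;07:02:01;",
        "B*;51:01:01/51:01:02;51:01:01G",
        "C*;04:01:01;04:01:01G",
    ]
    return load_g_groups(lines)


def make_genotypes(rows):
    """rows: (sample_id, locus, a1, a2[, tool[, platform]]) tuples."""
    out = []
    for r in rows:
        r = list(r) + ["NA"] * (6 - len(r))
        out.append(
            dict(zip(
                ["sample_id", "locus", "allele1", "allele2", "tool",
                 "platform"], r))
        )
    return pd.DataFrame(out)


@pytest.fixture
def genotypes_factory():
    return make_genotypes
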