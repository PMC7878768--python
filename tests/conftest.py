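import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from omicsmr import LdMatrix, SumstatsTable

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_table(trait_id="trait", trait_kind="risk_factor", **columns) -> SumstatsTable:
    """Build a SumstatsTable from parallel per-SNP lists with sane defaults."""
    snp = columns["snp"]
    k = len(snp)
    defaults = {
        "a1": ["A"] * k,
        "a2": ["G"] * k,
        "freq": [0.3] * k,
        "b": [0.1] * k,
        "se": [0.02] * k,
        "p": [1e-9] * k,
        "n": [10_000] * k,
    }
    defaults.update(columns)
    return SumstatsTable(trait_id, trait_kind, pd.DataFrame(defaults))


def ld_from_r(snp_ids, r) -> LdMatrix:
    return LdMatrix(list(snp_ids), np.asarray(r, dtype=float))


@pytest.fixture
def ma_file(tmp_path):
    """Write .ma text content to a temp file and return its path."""

    def _write(text, name="stats.ma"):
        path = tmp_path / name
        path.write_text(text)
        return path

    return _write
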