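import numpy as np
import pandas as pd
import pytest

from haplostat import Alignment


@pytest.fixture
def toy4() -> Alignment:
    """Four 10-bp sequences: two identical, two variants (S=2, Pi=7/6)."""
    return Alignment.from_dict(
        {
            "s1": "AAAAAAAAAA",
            "s2": "AAAAAAAAAT",
            "s3": "AAAAAAAATT",
            "s4": "AAAAAAAAAA",
        }
    )


@pytest.fixture
def toy4_meta() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": ["s1", "s2", "s3", "s4"],
            "population": ["p1", "p1", "p2", "p2"],
            "region": ["EA", "EA", "WS", "WS"],
            "subregion": ["", "", "", ""],
            "lat": [-66.0, -66.0, -74.0, -74.0],
            "lon": [140.0, 140.1, -30.0, -30.1],
            "depth_m": [200.0, 210.0, 300.0, 310.0],
        }
    )


@pytest.fixture
def write_fasta(tmp_path):
    def _write(seqs: dict[str, str], name: str = "aln.fasta"):
        path = tmp_path / name
        with open(path, "w") as fh:
            for rid, seq in seqs.items():
                fh.write(f">{rid}\n{seq}\n")
        return path

    return _write


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
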