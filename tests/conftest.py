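import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from offscan.pam_scan import CandidateSite

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_sites(rng: np.random.Generator, n: int, k: int) -> list[CandidateSite]:
    """Random candidate set: n spacers of length k with dummy coordinates."""
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    return [
        CandidateSite(
            site_id=i,
            chrom="chr1",
            start=i * (k + 3),
            strand="+",
            spacer=bases[rng.integers(0, 4, size=k)].tobytes().decode(),
            pam_seq="AGG",
        )
        for i in range(n)
    ]


def random_dna(rng: np.random.Generator, n: int) -> str:
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    return bases[rng.integers(0, 4, size=n)].tobytes().decode()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260930)
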