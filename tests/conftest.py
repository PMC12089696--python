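import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from slicetally.synthdata import (  # noqa: E402
    ItdSpec, Spike, SyntheticSpec, make_fixture,
)


@pytest.fixture(scope="session")
def study_spec() -> SyntheticSpec:
    """The default spiked study: SNV/INS/DEL at set VAFs plus one ITD."""
    return SyntheticSpec(
        seed=3,
        spikes=(
            Spike("chr1", 1150, "SNV", 0.5, depth=200),
            Spike("chr1", 1420, "INS", 0.3, depth=100, ins_seq="TTG"),
            Spike("chr2", 2150, "DEL", 0.4, depth=100, del_len=4),
        ),
        itd=ItdSpec("chr1", 5000, length=60, supporting_reads=40),
    )


@pytest.fixture(scope="session")
def fixture_paths(study_spec, tmp_path_factory):
    """Full generated fixture tree (reference, GFF3, tx FASTA, BAMs, truth)."""
    out = tmp_path_factory.mktemp("fixture")
    return make_fixture(study_spec, out, spaces=("genomic", "transcriptome"))
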