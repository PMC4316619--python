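import numpy as np
import pytest

from tlrpopgen.alignment import HaplotypeAlignment
from tlrpopgen.synthetic import StudySpec, generate_study_dataset


def make_alignment(haps, outgroup, lineages=None, coding=False, locus_id="toy",
                   frame_offset=0):
    """Small literal alignment from strings."""
    n = len(haps)
    if lineages is None:
        lineages = ["ingroup"] * n
    return HaplotypeAlignment(
        locus_id=locus_id,
        samples=tuple(f"s{i}" for i in range(n)),
        lineages=tuple(lineages),
        haplotypes=np.array([list(h) for h in haps]),
        outgroup=np.array(list(outgroup)),
        coding=coding,
        frame_offset=frame_offset,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


#: small study spec for fast end-to-end unit tests
SMALL_SPEC = StudySpec(
    n_lineage_a=10,
    n_lineage_b=8,
    n_neutral=6,
    neutral_length=300,
    coding_loci=(
        ("tlrA", 120, "constraint", 0.25),
        ("tlrB", 120, "constraint", 0.0),
        ("tlrC", 120, "sweep_like", 0.25),
    ),
)


@pytest.fixture(scope="session")
def small_study(tmp_path_factory):
    out = tmp_path_factory.mktemp("study")
    pairs = generate_study_dataset(str(out), SMALL_SPEC, seed=42)
    return out, pairs, SMALL_SPEC
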