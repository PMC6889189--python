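import numpy as np
import pytest

from indelfuse.callset_io import InDelCall, RepeatAnnotation
from indelfuse.matching import MatchCriterion
from indelfuse.synthdata import make_fixture


@pytest.fixture(scope="session")
def criterion():
    return MatchCriterion()


@pytest.fixture(scope="session")
def toy_reference():
    rng = np.random.default_rng(11)
    return {
        "chr1": "".join("ACGT"[i] for i in rng.integers(0, 4, size=20_000)),
        "chr2": "".join("ACGT"[i] for i in rng.integers(0, 4, size=10_000)),
    }


@pytest.fixture(scope="session")
def toy_annotation():
    return RepeatAnnotation.from_intervals(
        [
            ("chr1", 100, 160, "SimpleRepeat"),
            ("chr1", 120, 140, "LTR"),  # nested inside the SimpleRepeat
            ("chr1", 500, 600, "LINE"),
            ("chr1", 1000, 1030, "Helitron"),
            ("chr2", 50, 80, "LowComplexity"),
            ("chr2", 300, 400, "TIR"),
        ]
    )


def make_call(
    caller="alpha",
    chrom="chr1",
    pos=5000,
    vtype="DEL",
    size=2,
    reads=10,
    repeat_class="NonRepeat",
    region_length=0,
):
    if vtype == "DEL":
        ref, alt = "A" * size, ""
    else:
        ref, alt = "", "A" * size
    return InDelCall(
        caller=caller,
        chrom=chrom,
        pos=pos,
        ref_allele=ref,
        alt_allele=alt,
        vtype=vtype,
        size=size,
        reads=reads,
        repeat_class=repeat_class,
        region_length=region_length,
    )


@pytest.fixture(scope="session")
def dominant_pair_fixture():
    return make_fixture("dominant-pair", seed=7, n_indels=1500, genome_length=400_000)


@pytest.fixture(scope="session")
def group_dependent_fixture():
    return make_fixture(
        "group-dependent-best", seed=7, n_indels=1500, genome_length=400_000
    )


@pytest.fixture(scope="session")
def separable_reads_fixture():
    return make_fixture(
        "separable-reads", seed=7, n_indels=1200, genome_length=400_000
    )


@pytest.fixture(scope="session")
def jittered_fixture():
    return make_fixture(
        "jittered-repeats", seed=7, n_indels=800, genome_length=300_000
    )
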