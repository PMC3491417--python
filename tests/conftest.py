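import numpy as np
import pytest

from ervkit.methylation import BisulfiteCloneSet, Clone
from ervkit.model import CgiInterval, ErvRecord, GeneRecord, GenomeModel


@pytest.fixture
def genome():
    return GenomeModel((("chr1", 1_000_000), ("chr2", 800_000)))


@pytest.fixture
def plus_gene():
    # TSS at 50_000, TTS at 60_000
    return GeneRecord("geneA", "chr1", "+", 50_000, 60_000)


@pytest.fixture
def minus_gene():
    # TSS at 90_000, TTS at 80_000
    return GeneRecord("geneB", "chr1", "-", 90_000, 80_000)


@pytest.fixture
def full_length_erv():
    # + strand: 5' LTR leftmost
    return ErvRecord("iap1", "IAP", "full_length", "chr1", 40_000, 45_000, "+",
                     ltr5=(40_000, 40_400), ltr3=(44_600, 45_000))


@pytest.fixture
def solo_erv():
    return ErvRecord("etn1", "ETn/MusD", "solo", "chr1", 70_000, 70_400, "+",
                     ltr5=(70_000, 70_400))


def make_clone_set(fractions, n_cpgs=10, region_id="r1", tissue="liver",
                   n_noncpg_c=40, error_sets=None):
    """Clone set whose per-clone methylated fractions are as requested.

    Each clone gets a distinct non-conversion error set by default so QC
    dedup never collapses them.
    """
    clones = []
    for k, f in enumerate(fractions):
        n_meth = round(f * n_cpgs)
        calls = tuple([True] * n_meth + [False] * (n_cpgs - n_meth))
        errors = error_sets[k] if error_sets is not None else frozenset({k})
        clones.append(Clone(calls, frozenset(errors), n_noncpg_c,
                            clone_id=f"{region_id}_c{k}"))
    return BisulfiteCloneSet(region_id, tissue, tuple(clones))


@pytest.fixture
def clone_factory():
    return make_clone_set
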