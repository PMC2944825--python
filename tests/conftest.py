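import numpy as np
import pytest

from domainsnp.domain_scan import (
    PatternDefinition,
    PatternElement,
    ProfileDefinition,
    parse_pattern,
)
from domainsnp.io_formats import AA_INDEX, AMINO_ACIDS, ProteinRecord, SnpRecord
from domainsnp.synthetic_data import GeneratorConfig, generate_universe


def make_profile(domain_id, consensus, high=4.0, low=-2.0, gap_open=-5.0,
                 gap_extend=-1.0, cutoff=None, extra=()):
    """Profile scoring ``high`` for each consensus residue, ``low``
    elsewhere; ``extra`` adds (row, letter, score) overrides."""
    L = len(consensus)
    scores = np.full((L, 20), low)
    for i, aa in enumerate(consensus):
        scores[i, AA_INDEX[aa]] = high
    for row, letter, score in extra:
        scores[row, AA_INDEX[letter]] = score
    if cutoff is None:
        cutoff = 0.7 * high * L
    return ProfileDefinition(domain_id, scores, gap_open, gap_extend, cutoff)


@pytest.fixture(scope="session")
def toy_universe():
    """Three proteins, one pattern + one profile domain, five SNPs whose
    classifications were fixed by hand when the fixture was built:
    2 domain-altering, 2 in-domain benign, 1 outside."""
    pattern = parse_pattern("M-K-x-V.", "DPAT")
    # profile consensus ACD; row 3 also admits E at a slightly lower score,
    # so a D->E substitution is benign while C->W erases the domain
    profile = make_profile(
        "DPRO", "ACD", high=4.0, cutoff=8.0, extra=[(2, "E", 3.5)]
    )
    proteome = [
        ProteinRecord("P1", "AMKAVGGGGG"),  # pattern at 2-5
        ProteinRecord("P2", "GGACDGGGGG"),  # profile at 3-5, score 12
        ProteinRecord("P3", "ACDGGGGGGG"),  # profile at 1-3, score 12
    ]
    snps = [
        SnpRecord("rs1", "P1", 3, "K", "R"),  # breaks exact K -> pattern_loss
        SnpRecord("rs2", "P1", 4, "A", "G"),  # wildcard position -> benign
        SnpRecord("rs3", "P2", 4, "C", "W"),  # DD = 6/12 -> altering
        SnpRecord("rs4", "P2", 8, "G", "A"),  # outside any match
        SnpRecord("rs5", "P3", 3, "D", "E"),  # DD = 0.5/12 -> benign
    ]
    return {
        "proteome": proteome,
        "domains": [pattern, profile],
        "pattern": pattern,
        "profile": profile,
        "snps": snps,
    }


@pytest.fixture(scope="session")
def default_universe():
    """One default-condition synthetic universe, shared read-only."""
    return generate_universe(GeneratorConfig(seed=7))


def random_pattern(rng, max_expansions=200):
    """A random pattern with modest expansion count, for oracle checks."""
    n_el = int(rng.integers(1, 5))
    elements = []
    expansions = 1
    for _ in range(n_el):
        kind = ["exact", "any_of", "none_of", "wildcard"][int(rng.integers(4))]
        if kind == "exact":
            residues = frozenset(AMINO_ACIDS[int(rng.integers(20))])
        elif kind == "any_of":
            k = int(rng.integers(1, 4))
            residues = frozenset(
                AMINO_ACIDS[int(i)] for i in rng.choice(20, size=k, replace=False)
            )
        elif kind == "none_of":
            k = int(rng.integers(1, 6))
            residues = frozenset(
                AMINO_ACIDS[int(i)] for i in rng.choice(20, size=k, replace=False)
            )
        else:
            residues = frozenset()
        lo = int(rng.integers(0, 3))
        hi = lo + int(rng.integers(0, 3))
        if hi == 0:
            lo = hi = 1
        if expansions * (hi - lo + 1) > max_expansions:
            lo = hi = max(1, lo)
        expansions *= hi - lo + 1
        elements.append(PatternElement(kind, residues, lo, hi))
    n_anchor = bool(rng.random() < 0.15)
    c_anchor = bool(rng.random() < 0.15)
    return PatternDefinition("RND", tuple(elements), n_anchor, c_anchor)


def random_sequence(rng, lo=1, hi=20):
    length = int(rng.integers(lo, hi + 1))
    return "".join(AMINO_ACIDS[int(i)] for i in rng.integers(0, 20, size=length))
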