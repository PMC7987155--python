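import numpy as np
import pytest

from regulon_rewire import motif_model as mm


@pytest.fixture
def toy_pssm() -> mm.PSSM:
    """Unsmoothed 5-mer motif: GANTC with the N position free.

    Four conserved positions contribute 2 bits each, the free position 0,
    so IC = 8 bits exactly; only the 4 GANTC words score finitely (8.0).
    """
    return mm.build_pssm(["GAATC", "GACTC", "GAGTC", "GATTC"], pseudocount=0.0)


@pytest.fixture
def uniform_pssm() -> mm.PSSM:
    """L=2 motif whose frequencies equal the uniform background (IC = 0)."""
    sites = [a + b for a in "ACGT" for b in "ACGT"]
    return mm.build_pssm(sites, pseudocount=0.0)


def random_pssm(rng: np.random.Generator, length: int, n_sites: int = 12,
                pseudocount: float = 0.25) -> mm.PSSM:
    """A PSSM from random site collections, biased enough to have IC > 0."""
    bases = np.array(list("ACGT"))
    consensus = rng.integers(0, 4, size=length)
    sites = []
    for _ in range(n_sites):
        idx = np.where(rng.random(length) < 0.7, consensus, rng.integers(0, 4, size=length))
        sites.append("".join(bases[idx]))
    return mm.build_pssm(sites, pseudocount=pseudocount)
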