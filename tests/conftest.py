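import numpy as np
import pandas as pd
import pytest

from microkin import AlleleFrequencySet
from microkin.io import reference_forensics, reference_frequencies, reference_panel


@pytest.fixture(scope="session")
def ref_freqs():
    """The packaged 29-locus frequency sets (renormalised)."""
    return reference_frequencies()


@pytest.fixture(scope="session")
def ref_panel():
    return reference_panel()


@pytest.fixture(scope="session")
def ref_forensics():
    return reference_forensics()


@pytest.fixture
def toy_freqs2():
    """One biallelic locus at p = q = 0.5."""
    return AlleleFrequencySet("L1", {"A": 0.5, "B": 0.5})


@pytest.fixture
def toy_freqs3():
    """One tri-allelic locus with unequal frequencies."""
    return AlleleFrequencySet("L2", {"A": 0.5, "B": 0.3, "C": 0.2})


@pytest.fixture
def toy_panel(toy_freqs2, toy_freqs3):
    return {"L1": toy_freqs2, "L2": toy_freqs3}


@pytest.fixture
def genotype_table():
    """Tiny hand-built genotype table: 4 samples at two loci."""
    rows = []
    for s, (g1, g2) in enumerate(
        [(("A", "B"), ("C", "C")), (("A", "A"), ("C", "D")), (("A", "B"), ("C", "D")), (("C", "C"), ("D", "D"))]
    ):
        rows.append({"sample": f"s{s}", "locus": "L1", "allele1": g1[0], "allele2": g1[1]})
        rows.append({"sample": f"s{s}", "locus": "L2", "allele1": g2[0], "allele2": g2[1]})
    return pd.DataFrame(rows)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
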