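import numpy as np
import pytest

from polyte import (DosageMatrix, PolyTELocus, PopulationPanel,
                    serial_founder_preset, simulate)


def make_loci(n, family="ALU", chrom="1"):
    return [PolyTELocus(chrom, 100 + 10 * i, family) for i in range(n)]


def make_matrix(dosage, samples=None, families=None):
    dosage = np.asarray(dosage)
    n, L = dosage.shape
    samples = samples or [f"S{i}" for i in range(n)]
    if families is None:
        loci = make_loci(L)
    else:
        loci = [PolyTELocus("1", 100 + 10 * i, f)
                for i, f in enumerate(families)]
    return DosageMatrix(samples, loci, dosage)


def make_panel(assignment, group_map):
    """assignment: sample -> population."""
    return PopulationPanel(dict(assignment), dict(group_map))


@pytest.fixture(scope="session")
def preset_result():
    """The serial-founder dataset used by the qualitative end-to-end checks:
    three ancestral groups of 100 individuals over 2,000 loci plus two
    admixed cohorts, fixed seed."""
    return simulate(serial_founder_preset(seed=11))


@pytest.fixture(scope="session")
def small_result():
    """A cheaper simulated dataset for unit-level pipeline tests."""
    return simulate(serial_founder_preset(seed=5, n_loci=400,
                                          n_individuals_per_group=40,
                                          n_admixed=12))
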