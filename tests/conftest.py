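import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from netphen import (
    GenotypeRecord,
    LocusSpec,
    ctla4_loci,
    report_order,
    validate_loci,
)


@pytest.fixture(scope="session")
def loci():
    """The six-locus CTLA-4 panel."""
    return ctla4_loci()


@pytest.fixture(scope="session")
def toy_loci():
    """A minimal three-locus panel with differing cycle/report orders."""
    return validate_loci(
        [
            LocusSpec("L1", "rs1", "A", "G", 0, 1),
            LocusSpec("L2", "rs2", "C", "T", 1, 0),
            LocusSpec("L3", "rs3", "T", "C", 2, 2),
        ]
    )


def record_from_haplotypes(h1, h2, loci, sample_id="S1", cohort="unknown",
                           **kwargs):
    """Build a GenotypeRecord from two report-order haplotype strings."""
    ordered = report_order(loci)
    genotypes = {l.name: (a1, a2) for l, a1, a2 in zip(ordered, h1, h2)}
    return GenotypeRecord(
        sample_id=sample_id, cohort=cohort, genotypes=genotypes, **kwargs
    ).validate(loci)


@pytest.fixture(scope="session")
def make_record():
    return record_from_haplotypes


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
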