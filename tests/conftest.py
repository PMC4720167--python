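import numpy as np
import pytest

from pieacq import AcquisitionConfig, MixtureConfig, PeptideSpecies, generate_mixture
from pieacq.chemistry import PROTON_MASS


def make_peptide(
    peptide_id="P1|p0000",
    protein_id="P1",
    sequence="AAAAAAK",
    charge=2,
    mz=500.0,
    rt_apex=10.0,
    rt_sigma=0.3,
    amplitude=1000.0,
    n_missed=0,
) -> PeptideSpecies:
    """Hand-built peptide species with a prescribed m/z (mass back-computed
    to keep the m/z-mass invariant)."""
    mass = mz * charge - charge * PROTON_MASS
    return PeptideSpecies(
        peptide_id=peptide_id,
        protein_id=protein_id,
        sequence=sequence,
        n_missed_cleavages=n_missed,
        charge=charge,
        monoisotopic_mass=mass,
        mz=mz,
        rt_apex=rt_apex,
        rt_sigma=rt_sigma,
        peak_amplitude=amplitude,
        channel_fractions=(0.5, 0.5),
    )


@pytest.fixture(scope="session")
def small_mixture():
    """A compact but non-trivial seeded mixture for unit tests."""
    return generate_mixture(MixtureConfig(n_proteins=10, seed=42))


@pytest.fixture
def fast_config():
    """Short-run acquisition config for quick simulations."""
    return AcquisitionConfig(run_length=15.0)


@pytest.fixture
def rng():
    return np.random.default_rng(987654)
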