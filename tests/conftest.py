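"""Shared fixtures: small synthetic fibrils and simulated pulls."""

import numpy as np
import pytest

from fibrilkit.synthetic import FecSimSpec, IdealFibrilSpec, make_ideal_fibril


@pytest.fixture(scope="session")
def ubend_stack():
    """24-residue poly-Ala U-bend layer stacked 5-fold (flat, noiseless)."""
    spec = IdealFibrilSpec(
        sequence="A" * 24, rise=4.76, twist=-3.96, n_layers=5, template="U_bend"
    )
    return make_ideal_fibril(spec)


@pytest.fixture(scope="session")
def warped_stack():
    """64-residue layer with a 2 A two-period sinusoidal warp.

    Two full periods over the U-bend path make the warp orthogonal to
    any plane tilt, so the best-fit and normal-plane RMSDs both equal
    the RMS of the applied displacement field.
    """
    spec = IdealFibrilSpec(
        sequence="A" * 64,
        rise=4.8,
        twist=-1.8,
        n_layers=5,
        template="U_bend",
        warp=(2.0, 32.0),
    )
    return make_ideal_fibril(spec)


@pytest.fixture(scope="session")
def mixed_sequence_stack():
    """Mixed-sequence S-fold stack exercising Cbeta placement and I/O."""
    spec = IdealFibrilSpec(
        sequence="AYQNQLVFGS" * 4,
        rise=4.81,
        twist=-1.31,
        n_layers=7,
        template="S_fold",
    )
    return make_ideal_fibril(spec)


@pytest.fixture(scope="session")
def single_rip_pull():
    """One programmed rip: 20 residues at 12 pN, noise sigma 0.2, seed 1."""
    spec = FecSimSpec(segments=((20, 12.0),), noise_sigma=0.2, seed=1)
    from fibrilkit.synthetic import simulate_fec

    return spec, simulate_fec(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
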