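import pytest
from hypothesis import settings

settings.register_profile("default", derandomize=True, max_examples=50)
settings.load_profile("default")

from ccmelt import fixtures, synthgen  # noqa: E402
from ccmelt.seqcore import assign_heptad  # noqa: E402


@pytest.fixture(scope="session")
def tpm1_region():
    return fixtures.tpm1_region()


@pytest.fixture(scope="session")
def tpm3_region():
    return fixtures.tpm3_region()


@pytest.fixture(scope="session")
def tpm1_fragment():
    return fixtures.tpm1_fragment()


@pytest.fixture(scope="session")
def tpm3_fragment():
    return fixtures.tpm3_fragment()


@pytest.fixture(scope="session")
def tpm1_annotation(tpm1_region):
    return assign_heptad(tpm1_region, 92, "a")


@pytest.fixture
def melt_factory():
    """Factory for synthetic two-state melting curves."""

    def make(tm=50.0, dh=400.0, noise_sd=0.0, seed=0, grid=None, **kwargs):
        params = synthgen.TwoStateParams(
            tm_true=tm,
            dh_vh=dh,
            noise_sd=noise_sd,
            seed=seed,
            **({"temperature_grid": grid} if grid is not None else {}),
        )
        return synthgen.simulate_melt(params, **kwargs)

    return make


@pytest.fixture(scope="session")
def small_coiled_coil():
    """A 35-residue two-chain coiled coil (5 heptads) for geometry tests."""
    seq = "A" * 35
    return synthgen.build_coiled_coil(
        seq, synthgen.CrickParams(n_residues=35), first_position=1
    )
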