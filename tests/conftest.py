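import pytest

import cropgate as cg
from cropgate.soc import SocParameters, equilibrium_state


@pytest.fixture()
def factors():
    """Fresh default factor table per test (tests may mutate it freely)."""
    return cg.load_factors()


@pytest.fixture()
def coeffs(factors):
    return factors.crop_coefficients


@pytest.fixture()
def soc_params(factors):
    return SocParameters.from_factors(factors)


@pytest.fixture(scope="session")
def all_fixture_patterns():
    return {label: cg.builtin_fixture(label) for label in cg.FIXTURE_LABELS}


@pytest.fixture(scope="session")
def reference_equilibrium():
    """Equilibrium SOC state of the reference rotation (R-F-R), default factors."""
    f = cg.load_factors()
    return equilibrium_state(
        cg.builtin_fixture("R-F-R"), SocParameters.from_factors(f), f.crop_coefficients, f
    )


@pytest.fixture(scope="session")
def fixture_reports(reference_equilibrium):
    """Full footprint reports for all five built-in rotations (default factors)."""
    f = cg.load_factors()
    return {
        label: cg.assemble_report(cg.builtin_fixture(label), f, initial_soc=reference_equilibrium)
        for label in cg.FIXTURE_LABELS
    }
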