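import numpy as np
import pytest

from sctdose import PhantomConfig, generate_phantom


@pytest.fixture(scope="session")
def small_phantom():
    """Desk-scale noisy phantom shared across the suite."""
    return generate_phantom(PhantomConfig.small(seed=3))


@pytest.fixture(scope="session")
def nominal_phantom():
    """Noiseless phantom painted with the stratification nominal HUs."""
    from sctdose.phantom import NOMINAL_HU_MEANS

    return generate_phantom(PhantomConfig.small(
        seed=5, hu_means=dict(NOMINAL_HU_MEANS), hu_noise_sd=0.0,
        n_calcifications=0))


@pytest.fixture(scope="session")
def planned_case(small_phantom):
    """Ground-truth planning run (dose + frozen plan) on the small phantom."""
    from dataclasses import replace

    from sctdose.dose_engine import plan_on_ct

    dose, plan = plan_on_ct(small_phantom.ct, small_phantom.plan,
                            small_phantom.structures.masks["PTV60"])
    return replace(small_phantom, plan=plan), dose


@pytest.fixture(scope="session")
def nominal_planned_case(nominal_phantom):
    from dataclasses import replace

    from sctdose.dose_engine import plan_on_ct

    dose, plan = plan_on_ct(nominal_phantom.ct, nominal_phantom.plan,
                            nominal_phantom.structures.masks["PTV60"])
    return replace(nominal_phantom, plan=plan), dose
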