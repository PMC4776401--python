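import pytest

from glufa import (
    FitConfig,
    build_params,
    fit_subject,
    fixture,
    synth_subject,
)

UNIT_SIGMA2 = {
    (p, c): 1.0 for p in ("FSIGT", "MT") for c in ("glucose", "ffa")
}


@pytest.fixture(scope="session")
def aa_c3_subject():
    """Noiseless synthetic subject generated from the AA-C3 fixture."""
    return synth_subject("AA-C3", noise_cv=0.0)


@pytest.fixture(scope="session")
def aa_c3_params():
    """(Mod1Params, RaSet) of the AA-C3 generating fixture."""
    return build_params("MOD1", "C3", fixture("AA-C3").values)


@pytest.fixture(scope="session")
def aa_c3_recovery(aa_c3_subject):
    """Noiseless AA-C3 fit from a 1.5x-perturbed start with unit variances."""
    cfg = FitConfig(
        reference=fixture("AA-C3").values,
        start_multipliers=(1.5,),
        variances="unit",
    )
    return fit_subject(aa_c3_subject, "MOD1", "C3", cfg)
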