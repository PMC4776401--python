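"""Objective assembly, bounds, and subject fitting."""

import numpy as np
import pytest

from glufa import (
    COMBINATIONS,
    FitConfig,
    build_params,
    default_bounds,
    fit_subject,
    fixture,
    free_param_names,
    objective,
    synth_subject,
)
from glufa.errors import InvalidInputError
from glufa.fitting import model_channels, resolve_sigma2

UNIT = {(p, c): 1.0 for p in ("FSIGT", "MT") for c in ("glucose", "ffa")}


class TestCombinations:
    @pytest.mark.parametrize(
        "cid, protocols, ra_g, ra_f",
        [
            ("C1", ("FSIGT", "MT"), "none", "none"),
            ("C2", ("FSIGT", "MT"), "type1", "type1"),
            ("C3", ("FSIGT", "MT"), "type1", "none"),
            ("C4", ("FSIGT", "MT"), "type2", "none"),
            ("S1", ("FSIGT",), "none", "none"),
            ("S2", ("MT",), "type1", "none"),
            ("S3", ("MT",), "type2", "none"),
        ],
    )
    def test_registry(self, cid, protocols, ra_g, ra_f):
        c = COMBINATIONS[cid]
        assert c.protocols == protocols
        assert c.ra_glucose == ra_g and c.ra_ffa == ra_f


class TestParamLayout:
    def test_free_parameter_counts(self):
        # fixed parameters (A_lipo, A_Cl, t_0F, m_F) are excluded
        assert len(free_param_names("MOD1", "C1")) == 10
        assert len(free_param_names("MOD1", "C3")) == 13
        assert len(free_param_names("MOD1", "C4")) == 12
        assert len(free_param_names("MOD1", "C2")) == 15
        assert len(free_param_names("MOD2", "C3")) == 13
        assert len(free_param_names("MOD3", "C1")) == 9
        assert len(free_param_names("MOD3", "C2")) == 11

    def test_build_params_applies_fixing_convention(self):
        mp, ra = build_params("MOD1", "C3", fixture("AA-C3").values)
        assert mp.A_lipo == 2.0 and mp.A_Cl == 2.0
        vals = fixture("AA-C2").values
        _, ra2 = build_params("MOD1", "C2", vals)
        assert ra2.ffa.t_0F == 60.0 and ra2.ffa.m_F == 300.0

    def test_mod3_contributes_only_ffa(self):
        assert model_channels("MOD3") == ("ffa",)
        assert model_channels("MOD1") == ("glucose", "ffa")


class TestObjective:
    def test_zero_for_generating_parameters(self, aa_c3_subject):
        # model output generated the data, so residuals vanish identically
        assert objective(
            fixture("AA-C3").values, aa_c3_subject, "MOD1", "C3", sigma2=UNIT
        ) == pytest.approx(0.0, abs=1e-12)

    def test_weighted_arithmetic_and_sigma_scaling(self, aa_c3_subject):
        vals = dict(fixture("AA-C3").values)
        vals["Delta_G"] *= 1.2
        base = objective(vals, aa_c3_subject, "MOD1", "C3", sigma2=UNIT)
        assert base > 0
        doubled = {k: 2.0 * v for k, v in UNIT.items()}
        assert objective(
            vals, aa_c3_subject, "MOD1", "C3", sigma2=doubled
        ) == pytest.approx(base / 2.0, rel=1e-12)

    def test_residual_counts(self, aa_c3_subject):
        # 21 fitted FSIGT times + 13 MT times, two channels each
        from glufa.fitting import _residual_context, _weighted_residuals

        combo = COMBINATIONS["C3"]
        ctx = _residual_context(aa_c3_subject, "MOD1", combo)
        r = _weighted_residuals(
            fixture("AA-C3").values, aa_c3_subject, "MOD1", combo, UNIT, ctx,
            None, 1e-8,
        )
        assert r.size == 2 * 21 + 2 * 13 == 68


class TestBounds:
    def test_five_times_reference_upper_bound(self):
        ref = fixture("AA-C3").values
        names = free_param_names("MOD1", "C3")
        lb, ub = default_bounds("MOD1", "C3", ref)
        i = names.index("S_I")
        assert ub[i] == pytest.approx(5 * 3.2e-4)
        assert np.all(lb <= 1e-8) and np.all(lb >= 0.0)

    def test_delay_capped_by_protocol_window(self):
        ref = dict(fixture("AA-MOD3-C1").values, t_DelayLip=200.0)
        names = free_param_names("MOD3", "C1")
        _, ub = default_bounds("MOD3", "C1", ref)
        assert ub[names.index("t_DelayLip")] == 360.0

    def test_missing_reference_rejected(self):
        with pytest.raises(InvalidInputError):
            default_bounds("MOD1", "C3", {"S_G": 0.01})


@pytest.fixture(scope="module")
def mod3_fit():
    subject = synth_subject("AA-MOD3-C1", noise_cv=0.0)
    cfg = FitConfig(
        reference=fixture("AA-MOD3-C1").values,
        start_multipliers=(1.25,),
        variances="unit",
        check_identifiability=False,
    )
    return subject, fit_subject(subject, "MOD3", "C1", cfg)


class TestFitSubject:
    def test_mod3_noiseless_fit_reaches_near_zero_objective(self, mod3_fit):
        _, fit = mod3_fit
        assert fit.converged
        assert fit.objective < 1e-4
        assert fit.n_data == 21 + 13
        assert fit.k_free == 9

    def test_refit_from_optimum_is_idempotent(self, mod3_fit):
        subject, fit = mod3_fit
        cfg = FitConfig(
            reference=fit.params,
            start_multipliers=(1.0,),
            variances="unit",
            check_identifiability=False,
        )
        again = fit_subject(subject, "MOD3", "C1", cfg)
        assert again.objective <= fit.objective + 1e-8

    def test_reproducible_given_same_configuration(self):
        subject = synth_subject("AA-MOD3-C1", noise_cv=0.05, seed=42)
        cfg = dict(
            reference=fixture("AA-MOD3-C1").values,
            start_multipliers=(1.25,),
            check_identifiability=False,
        )
        a = fit_subject(subject, "MOD3", "C1", FitConfig(**cfg))
        b = fit_subject(subject, "MOD3", "C1", FitConfig(**cfg))
        assert a.objective == b.objective
        assert a.params == b.params

    def test_missing_protocol_rejected(self):
        subject = synth_subject("AA-C3", noise_cv=0.0)
        del subject.series[("FSIGT", "glucose")]
        del subject.series[("FSIGT", "ffa")]
        del subject.series[("FSIGT", "insulin")]
        cfg = FitConfig(reference=fixture("AA-C3").values)
        with pytest.raises(InvalidInputError):
            fit_subject(subject, "MOD1", "C3", cfg)

    def test_unit_variance_mode(self):
        subject = synth_subject("AA-MOD3-C1", noise_cv=0.02, seed=1)
        s2 = resolve_sigma2(subject, "MOD3", COMBINATIONS["C1"], "unit")
        assert all(v == 1.0 for v in s2.values())
        s2_ssa = resolve_sigma2(subject, "MOD3", COMBINATIONS["C1"], "ssa")
        assert all(v > 0 for v in s2_ssa.values())
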