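"""Mixed-model assembly, model equivalences, REML machinery and the RLRT."""

import numpy as np
import pandas as pd
import pytest

from gamrel.ginverse import build_inverse
from gamrel.pedigree import Representation, parse_pedigree
from gamrel.pomodel import (
    ModelError,
    VarianceComponents,
    assemble_and_solve,
    build_design,
    derived_parameters,
    fit_reml,
    hessian_standard_errors,
    reml_loglik,
    residual_weight,
    rlrt,
)
from gamrel.simulate import SimulationConfig, simulate_dataset

from conftest import P1_TEXT, recode

VC = VarianceComponents(1.0, 1.0, 0.5, 1.0)


@pytest.fixture(scope="module")
def sim():
    cfg = SimulationConfig(n_founders=25, n_generations=4, n_matings=12,
                           litter_mean=4, sigma_s2=1.0, sigma_d2=0.8,
                           sigma_sd=0.4, sigma_e2=1.0, seed=42)
    ped, meta, effects, phen = simulate_dataset(cfg)
    return ped, phen


class TestVarianceComponents:
    def test_invariants(self):
        assert VC.sigma_i2 == pytest.approx(1.0)
        assert VC.r == pytest.approx(0.5)
        a1, a2, a3 = VC.alpha()
        np.testing.assert_allclose(np.array([[a1, a2], [a2, a3]]) @ VC.Sigma,
                                   np.eye(2), atol=1e-12)

    def test_non_psd_rejected(self):
        with pytest.raises(ModelError, match="PSD"):
            VarianceComponents(1.0, 1.0, 1.5, 1.0)

    def test_nonpositive_rejected(self):
        with pytest.raises(ModelError):
            VarianceComponents(0.0, 1.0, 0.0, 1.0)


class TestResidualWeight:
    def test_gametic_weight_is_one(self):
        assert residual_weight("gametic", 0.0, 0.0, VC) == 1.0

    def test_reduced_unit_variances(self):
        vc = VarianceComponents(1.0, 1.0, 0.0, 1.0)
        assert residual_weight("reduced", 0.0, 0.0, vc) == pytest.approx(0.5)

    def test_fully_inbred_parents_leave_no_sampling_variance(self):
        vc = VarianceComponents(1.0, 1.0, 0.0, 1.0)
        assert residual_weight("reduced", 1.0 - 1e-9, 1.0 - 1e-9, vc) == pytest.approx(1.0)


class TestBuildDesign:
    def test_gametic_row_links_own_slots(self, p1):
        phen = pd.DataFrame({"id": [4], "y": [1.0]})
        d = build_design(p1, phen)
        assert d.equations[0].kind == "gametic"
        assert d.Zs.toarray().tolist() == [[0, 0, 0, 1, 0]]
        assert d.Zd.toarray().tolist() == [[0, 0, 0, 0, 1]]

    def test_reduced_row_links_parent_tas(self):
        ped = parse_pedigree("1 0 0 1\n2 0 0 1\n3 1 2 1\n4 1 3 1\n")
        phen = pd.DataFrame({"id": [4], "y": [1.0]})
        d = build_design(ped, phen)
        eq = d.equations[0]
        assert eq.kind == "reduced" and eq.F_sire == 0.0 and eq.F_dam == 0.0
        assert d.Zs.toarray().tolist() == [[1, 0, 0, 0]]   # sire 1's TA
        assert d.Zd.toarray().tolist() == [[0, 0, 1, 0]]   # dam 3's TA

    def test_mixed_row_sire_gametic_dam_ta(self):
        ped = parse_pedigree("1 0 0 2\n2 0 0 1\n3 1 2 1\n")
        phen = pd.DataFrame({"id": [3], "y": [1.0]})
        d = build_design(ped, phen)
        assert d.equations[0].kind == "mixed-dam-ta"
        assert d.Zs.toarray().tolist() == [[0.5, 0.5, 0, 0]]  # sire's gametic pair
        assert d.Zd.toarray().tolist() == [[0, 0, 1, 0]]      # dam's TA

    def test_unknown_parent_cannot_form_reduced_row(self):
        ped = parse_pedigree("1 0 0 1\n2 1 0 1\n")
        with pytest.raises(ModelError, match="unknown parent"):
            build_design(ped, pd.DataFrame({"id": [2], "y": [0.5]}))

    def test_empty_phenotypes_rejected(self, p1):
        with pytest.raises(ModelError, match="no records"):
            build_design(p1, pd.DataFrame({"id": [], "y": []}))

    def test_rank_deficient_fixed_effects_reported(self, p1):
        phen = pd.DataFrame({"id": [4], "y": [1.0], "x": [2.0], "z": [4.0]})
        with pytest.raises(ModelError, match="aliased"):
            build_design(p1, phen, covariates=["x", "z"])

    def test_reduced_policy_prunes_final_progeny(self, sim):
        ped, phen = sim
        d = build_design(ped, phen, factors=["generation"], equations="reduced")
        assert d.n_pruned == len(phen)
        assert d.eidx.m == d.ped.u + 2 * d.ped.v
        assert all(e.kind != "gametic" for e in d.equations)


class TestModelEquivalence:
    """The generalized model is an equivalent reparameterization of the
    classical gametic model; reduced rows with correct weights are an
    equivalent marginal model for final progeny."""

    def test_classical_and_generalized_agree(self, sim):
        ped, phen = sim
        d_gen = build_design(ped, phen, factors=["generation"])
        s_gen = assemble_and_solve(d_gen, build_inverse(ped), VC)
        classical = recode(ped, Representation.GAMETIC)
        d_cls = build_design(classical, phen, factors=["generation"])
        s_cls = assemble_and_solve(d_cls, build_inverse(classical), VC)
        assert s_gen.logL == pytest.approx(s_cls.logL, abs=1e-6)
        np.testing.assert_allclose(s_gen.beta, s_cls.beta, atol=1e-8)
        # transmitting abilities map through K': TA = mean of the gametic pair
        sol_g = s_gen.solutions().set_index("id")
        sol_c = s_cls.solutions().set_index("id")
        np.testing.assert_allclose(sol_g["ahat_s"], sol_c.loc[sol_g.index, "ahat_s"],
                                   atol=1e-8)

    def test_reduced_rows_with_true_weights_agree(self, sim):
        ped, phen = sim
        d_gen = build_design(ped, phen, factors=["generation"])
        d_red = build_design(ped, phen, factors=["generation"], equations="reduced")
        logL_gen = reml_loglik(d_gen, build_inverse(ped), VC)
        logL_red = reml_loglik(d_red, build_inverse(d_red.ped), VC)
        assert logL_red == pytest.approx(logL_gen, abs=1e-6)

    def test_perfect_correlation_collapses_to_mendelian(self, sim):
        ped, phen = sim
        d = build_design(ped, phen, factors=["generation"])
        ginv = build_inverse(ped)
        vc = VarianceComponents(1.0, 1.0, 1.0 - 1e-10, 1.0)
        s = assemble_and_solve(d, ginv, vc)
        np.testing.assert_allclose(s.a_s, s.a_d, atol=1e-4)

    def test_mendelian_deviations_identically_zero(self, sim):
        ped, phen = sim
        d = build_design(ped, phen, factors=["generation"])
        s = assemble_and_solve(d, build_inverse(ped),
                               VarianceComponents(1.0, 1.0, 1.0, 1.0),
                               model="mendelian")
        assert np.all(s.solutions()["imprinting_deviation"] == 0.0)

    def test_scaling_relation_of_loglik(self, sim):
        # scaling y by sqrt(c) and all variances by c shifts logL by
        # -(n - p)/2 * log(c)
        ped, phen = sim
        d1 = build_design(ped, phen, factors=["generation"])
        ginv = build_inverse(ped)
        c = 4.0
        phen2 = phen.assign(y=phen["y"] * np.sqrt(c))
        d2 = build_design(ped, phen2, factors=["generation"])
        vc2 = VarianceComponents(c * VC.sigma_s2, c * VC.sigma_d2,
                                 c * VC.sigma_sd, c * VC.sigma_e2)
        l1 = reml_loglik(d1, ginv, VC)
        l2 = reml_loglik(d2, ginv, vc2)
        nstar = d1.n - d1.X.shape[1]
        assert l2 == pytest.approx(l1 - 0.5 * nstar * np.log(c), abs=1e-8)


class TestREML:
    def test_fit_runs_and_improves_on_start(self, sim):
        ped, phen = sim
        d = build_design(ped, phen, factors=["generation"])
        ginv = build_inverse(ped)
        start = VarianceComponents(0.5, 0.5, 0.1, 0.5)
        res = fit_reml(d, ginv, model="imprinting", start=start)
        assert res.logL >= reml_loglik(d, ginv, start) - 1e-9
        assert res.vc.sigma_i2 >= 0.0

    def test_mendelian_nested_in_imprinting(self, sim):
        ped, phen = sim
        d = build_design(ped, phen, factors=["generation"])
        ginv = build_inverse(ped)
        res_m = fit_reml(d, ginv, model="mendelian")
        res_i = fit_reml(d, ginv, model="imprinting")
        stat, p = rlrt(res_i.logL, res_m.logL)
        assert stat >= 0.0 and 0.0 <= p <= 1.0

    def test_litter_component_estimated(self):
        cfg = SimulationConfig(n_founders=20, n_generations=3, n_matings=12,
                               litter_mean=5, sigma_c2=0.8, seed=9)
        ped, meta, effects, phen = simulate_dataset(cfg)
        d = build_design(ped, phen, factors=["generation"], group="litter")
        res = fit_reml(d, build_inverse(ped), model="mendelian")
        assert res.vc.sigma_c2 is not None and res.vc.sigma_c2 > 0

    def test_hessian_standard_errors_positive(self, sim):
        ped, phen = sim
        d = build_design(ped, phen, factors=["generation"])
        ginv = build_inverse(ped)
        res = fit_reml(d, ginv, model="mendelian")
        se = hessian_standard_errors(d, ginv, res)
        assert set(se) == {"sigma_s2", "sigma_e2"}
        assert all(np.isfinite(v) and v > 0 for v in se.values())


class TestRLRT:
    def test_reported_test_statistics(self):
        stat1, p1_ = rlrt(-17868.840, -17891.870)
        assert stat1 == pytest.approx(46.06, abs=1e-9)
        assert p1_ == pytest.approx(9.96e-11, rel=5e-3)
        stat2, p2 = rlrt(-17875.270, -17894.640)
        assert stat2 == pytest.approx(38.74, abs=1e-9)
        assert p2 == pytest.approx(3.87e-9, rel=5e-3)

    def test_equal_likelihoods(self):
        stat, p = rlrt(-10.0, -10.0)
        assert stat == 0.0 and p == 1.0

    def test_negative_statistic_clipped(self):
        with pytest.warns(UserWarning, match="clipped"):
            stat, p = rlrt(-11.0, -10.0)
        assert stat == 0.0 and p == 1.0


class TestDerivedParameters:
    def test_no_imprinting_when_components_equal(self):
        vc = VarianceComponents(1.0, 1.0, 1.0, 1.0)
        assert derived_parameters(vc)["sigma_i2"] == pytest.approx(0.0)

    def test_imprinting_variance_identity(self):
        vc = VarianceComponents(2.0, 1.0, 0.5, 1.0)
        d = derived_parameters(vc)
        assert d["sigma_i2"] == pytest.approx(2.0)
        assert d["h2"] == pytest.approx(3.0 / 4.0)

    def test_r_and_i2_jointly_pin_the_variance_ratio(self):
        # with r = 0.819, i2 = 0.314 the ratio k^2 = s2_s/s2_d solves
        # 0.686 k^2 - 1.638 k + 0.686 = 0, giving ~3.41 or its inverse ~0.29
        r, i2 = 0.819, 0.314
        roots = np.roots([1 - i2, -2 * r, 1 - i2])
        for k in roots:
            vc = VarianceComponents(float(k**2), 1.0, float(r * k), 1.0)
            d = derived_parameters(vc)
            assert d["i2"] == pytest.approx(i2, abs=1e-9)
            assert d["r"] == pytest.approx(r, abs=1e-9)
        assert sorted(np.round(roots**2, 2)) == [0.29, 3.41]

    def test_litter_share(self):
        vc = VarianceComponents(1.0, 1.0, 0.5, 1.0, 1.0)
        d = derived_parameters(vc)
        assert d["c2"] == pytest.approx(0.25)
        assert d["sigma_p2"] == pytest.approx(4.0)
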