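"""Fitting, sensitivity and statistics tests."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

import placentaflux as pf
from placentaflux.calibrate import FitError


def _grid(params, geometry, variant, **kw):
    return pf.predict_grid(params, geometry, variant, **kw).sort_values(
        ["f_m", "f_f"])


class TestFitTargets:
    def test_transfer_cannot_exceed_uptake(self):
        with pytest.raises(ValueError, match="transfer exceeds"):
            pf.FitTargets(uptake=1e-11, transfer=2e-11)
        with pytest.raises(ValueError):
            pf.FitTargets(uptake=0.0, transfer=0.0)

    def test_vector_targets_accepted(self):
        t = pf.FitTargets(uptake=np.full(9, 2e-11), transfer=np.full(9, 3e-12))
        u, tr = t.vectors
        assert u.shape == tr.shape == (9,)


class TestFitRates:
    def test_round_trip_recovers_generating_parameters(self, geometry):
        """Per-condition targets from a known parameter set identify all
        three free rates (the protocol transients break the BM-rate /
        clearance degeneracy)."""
        truth = dataclasses.replace(
            pf.TransporterParams().with_bm_vmax(1.4e-7),
            v_ex_mvm=2.4e-6, k_metab=8e-5)
        variant = pf.ModelVariant.transport_metabolism()
        g = _grid(truth, geometry, variant)
        targets = pf.FitTargets(uptake=g["uptake"].to_numpy(),
                                transfer=g["transfer"].to_numpy())
        fit = pf.fit_rates(targets)
        assert fit.v_ex_mvm == pytest.approx(truth.v_ex_mvm, rel=0.05)
        assert fit.v_fa_bm == pytest.approx(truth.v_fa_bm, rel=0.05)
        assert fit.k_metab == pytest.approx(truth.k_metab, rel=0.05)

    def test_balanced_targets_fit_without_metabolism(self, geometry):
        """uptake == transfer targets are consistent with k_metab = 0."""
        truth = pf.TransporterParams(k_metab=0.0)
        variant = pf.ModelVariant.transport()
        g = _grid(truth, geometry, variant)
        targets = pf.FitTargets(uptake=g["uptake"].to_numpy(),
                                transfer=g["transfer"].to_numpy())
        fit = pf.fit_rates(targets, fixed=truth, free=("v_ex_mvm", "v_bm"),
                           variant=variant)
        assert fit.k_metab == 0.0
        assert fit.v_ex_mvm == pytest.approx(truth.v_ex_mvm, rel=0.05)

    def test_mostly_metabolized_fit(self, geometry):
        """Targets with transfer/uptake = 0.15 produce a fitted model whose
        steady state metabolizes ~85% of uptake."""
        targets = pf.FitTargets(uptake=2.2e-11, transfer=0.15 * 2.2e-11)
        fit = pf.fit_rates(targets)
        ss = pf.steady_state(fit, pf.SubstratePools.tracer(),
                             pf.CompartmentGeometry(),
                             pf.ModelVariant.transport_metabolism(),
                             14e-3, 6e-3)
        uptake = pf.compute_uptake(2.7e-9, ss.a_m, 14e-3)
        metab = fit.k_metab * ss.a_s
        assert metab / uptake == pytest.approx(0.85, abs=0.05)

    def test_infeasible_targets_rejected(self):
        with pytest.raises(ValueError):
            pf.fit_rates(pf.FitTargets(uptake=1e-11, transfer=5e-11))


class TestFitVdif:
    def test_round_trip(self, geometry):
        truth = 1.5e-3
        params = dataclasses.replace(pf.TransporterParams(), v_dif=truth)
        g = _grid(params, geometry, pf.ModelVariant.diffusion())
        v = pf.fit_vdif(g["uptake"].mean())
        assert v == pytest.approx(truth, rel=0.01)

    def test_zero_target(self):
        assert pf.fit_vdif(0.0) == 0.0

    def test_linear_in_target_in_weak_extraction_regime(self, geometry):
        """Far below the flow limit the diffusion model's uptake is linear
        in the permeability, so the recovered V_dif scales with the target."""
        v1 = pf.fit_vdif(1e-13)
        v2 = pf.fit_vdif(2e-13)
        assert v2 == pytest.approx(2 * v1, rel=0.03)

    def test_flow_limited_supremum_rejected(self):
        # diffusion cannot exceed the flow limit F_m*F_f/(F_m+F_f)*A_in
        with pytest.raises(FitError, match="supremum"):
            pf.fit_vdif(2.2e-11)


class TestSensitivity:
    def test_factor_one_gives_unit_ratios(self, params, geometry):
        res = pf.sensitivity(params, factor=1.0)
        assert np.allclose(res.table["uptake_ratio"], 1.0, rtol=1e-9)
        assert np.allclose(res.table["transfer_ratio"], 1.0, rtol=1e-9)

    def test_uptake_invariant_under_v_over_k_scaling(self, geometry):
        """In the trace-linear regime uptake depends on the MVM exchanger
        only through the Vmax/K ratio."""
        base = pf.TransporterParams()
        variant = pf.ModelVariant.transport_metabolism()
        u0 = _grid(base, geometry, variant)["uptake"].mean()
        scaled = dataclasses.replace(base, v_ex_mvm=3 * base.v_ex_mvm,
                                     k_ex=3 * base.k_ex)
        u1 = _grid(scaled, geometry, variant)["uptake"].mean()
        assert u1 == pytest.approx(u0, rel=1e-4)

    def test_bm_exchanger_has_no_effect_on_uptake(self, params, geometry):
        """Without fetal counter-substrate the BM exchanger carries no
        efflux; varying its Vmax leaves maternal uptake unchanged."""
        res = pf.sensitivity(params, factor=5.0, parameters=("v_ex_bm",))
        assert np.allclose(res.table["uptake_ratio"], 1.0, atol=1e-6)


class TestRegression:
    def test_perfect_and_orthogonal(self):
        x = np.arange(9, dtype=float)
        assert pf.regress_model_vs_data(x, x) == pytest.approx(1.0)
        y = np.array([1, -1, 1, -1, 1, -1, 1, -1, 1], dtype=float)
        x2 = np.array([1, 1, -1, -1, 1, 1, -1, -1, 0], dtype=float)
        assert abs(np.cov(x2, y)[0, 1]) < 0.2  # near-zero covariance
        assert pf.regress_model_vs_data(x2, y) < 0.05

    def test_short_input_rejected(self):
        with pytest.raises(ValueError):
            pf.regress_model_vs_data([1.0, 2.0], [1.0, 2.0])


def _dataset_from_conditions(rows):
    df = pd.DataFrame(rows)
    return pf.PerfusionDataset(samples=pd.DataFrame(), conditions=df,
                               masses=np.full(df["placenta"].nunique(), 42.0))


def _factorial_conditions(rng, effect):
    rows = []
    for placenta in range(5):
        for f_m in (10e-3, 14e-3, 18e-3):
            for f_f in (3e-3, 6e-3, 9e-3):
                base = 1.0 + effect(f_m, f_f)
                rows.append({"placenta": placenta, "f_m": f_m, "f_f": f_f,
                             "uptake": base * (1 + 0.05 * rng.standard_normal()),
                             "transfer": base})
    return rows


class TestFlowAnova:
    def test_pure_maternal_effect_detected(self):
        rng = np.random.default_rng(0)
        ds = _dataset_from_conditions(
            _factorial_conditions(rng, lambda m, f: 30.0 * m))
        table = pf.flow_anova(ds, "uptake")
        assert table.loc["maternal_flow", "PR(>F)"] < 0.05
        assert table.loc["fetal_flow", "PR(>F)"] > 0.05

    def test_null_response_type_i_control(self):
        """Under a pure-noise response the maternal effect is a false
        positive at roughly the nominal rate, not systematically."""
        hits = 0
        for seed in range(40):
            rng = np.random.default_rng(seed)
            ds = _dataset_from_conditions(
                _factorial_conditions(rng, lambda m, f: 0.0))
            if pf.flow_anova(ds, "uptake").loc["maternal_flow", "PR(>F)"] < 0.05:
                hits += 1
        assert hits <= 7  # ~5% nominal; binomial(40, 0.05) upper tail

    def test_constant_response_has_no_effects(self):
        rows = _factorial_conditions(np.random.default_rng(1),
                                     lambda m, f: 0.0)
        for r in rows:
            r["uptake"] = 1.0
        table = pf.flow_anova(_dataset_from_conditions(rows), "uptake")
        assert table["PR(>F)"].iloc[:3].isna().all()

    def test_requires_multiple_placentas(self):
        rows = [r for r in _factorial_conditions(np.random.default_rng(2),
                                                 lambda m, f: 0.0)
                if r["placenta"] == 0]
        with pytest.raises(ValueError, match="placentas"):
            pf.flow_anova(_dataset_from_conditions(rows))
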