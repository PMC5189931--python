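"""Kinetic rate laws, control integration and ODE integration."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from emtensemble.dynamics import (
    Condition,
    apply_condition,
    compile_model,
    hill_transfer,
    integrate_control,
    mass_action_rate,
    nominal_parameters,
    rhs,
    saturation_rate,
    simulate,
    steady_state,
    transcription_rate,
    translation_rate,
)
from emtensemble.network import parse_model_definition


class TestHillTransfer:
    def test_zero_input_gives_zero(self):
        assert hill_transfer(0.0, 5.0, 2.0) == 0.0

    @pytest.mark.parametrize("order", [0.5, 1.0, 2.0, 4.0])
    def test_half_saturation_identity(self, order):
        assert hill_transfer(5.0, 5.0, order) == pytest.approx(0.5)

    def test_strictly_monotone_on_grid(self):
        xs = np.linspace(0.0, 50.0, 100)
        fs = np.array([hill_transfer(x, 5.0, 2.0) for x in xs])
        assert np.all(np.diff(fs) > 0)

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            hill_transfer(-1.0, 5.0, 1.0)

    @given(
        x=st.floats(0, 1e6),
        half=st.floats(1e-6, 1e6),
        order=st.floats(0.1, 6),
    )
    @settings(max_examples=200, deadline=None)
    def test_bounded_in_unit_interval(self, x, half, order):
        f = hill_transfer(x, half, order)
        assert 0.0 <= f <= 1.0


class TestIntegrateControl:
    def test_no_factors_gives_exactly_one(self):
        assert integrate_control([], "min") == 1.0
        assert integrate_control([], "max") == 1.0

    def test_min_rule(self):
        assert integrate_control([0.2, 0.8], "min") == 0.2

    def test_max_matches_brute_force_scan(self, rng):
        for _ in range(50):
            vals = rng.uniform(0, 1, size=rng.integers(1, 8)).tolist()
            best = vals[0]
            for v in vals[1:]:
                if v > best:
                    best = v
            assert integrate_control(vals, "max") == best

    def test_out_of_range_value_rejected(self):
        with pytest.raises(ValueError):
            integrate_control([1.2], "min")


class TestRateLaws:
    def test_saturation_half_and_limit(self):
        assert saturation_rate(2.0, 3.0, 4.0, 4.0) == pytest.approx(3.0)
        full = saturation_rate(2.0, 3.0, 400.0, 4.0)
        assert full == pytest.approx(6.0, rel=0.01)

    def test_saturation_spot_value(self):
        assert saturation_rate(2.0, 3.0, 1.0, 4.0) == pytest.approx(1.2)

    def test_saturation_rejects_negative(self):
        with pytest.raises(ValueError):
            saturation_rate(1.0, -1.0, 1.0, 1.0)

    def test_mass_action_examples(self):
        assert mass_action_rate(1.0, [2.0, 3.0], [-1, -1]) == pytest.approx(6.0)
        assert mass_action_rate(5.0, [0.0, 3.0], [-1, -1]) == 0.0

    def test_mass_action_higher_order_matches_loop_oracle(self):
        x, s = [2.0, 3.0], [-2, -1]
        expected = 1.0
        for xi, si in zip(x, s):
            for _ in range(-si):
                expected *= xi
        assert mass_action_rate(1.0, x, s) == pytest.approx(expected)
        assert expected == 12.0

    def test_transcription_limits(self):
        assert transcription_rate(0.0, 1.0, 5.0, 10.0, 1.0) == 0.0
        assert transcription_rate(2.0, 1.0, 5.0, 10.0, 0.0) == 0.0
        sat = transcription_rate(10000.0, 1.5, 5.0, 10.0, 1.0)
        assert sat == pytest.approx(7.5, rel=1e-3)

    def test_translation_limits(self):
        assert translation_rate(0.0, 1.0, 15.0, 0.25) == 0.0
        assert translation_rate(0.25, 2.0, 15.0, 0.25) == pytest.approx(15.0)
        assert translation_rate(1.0, 1.0, 12.0, 3.0) == pytest.approx(3.0)


class TestRhs:
    def test_isolated_gene_analytic_steady_state(self, toy_gene_model):
        p = nominal_parameters(toy_gene_model)
        cm = compile_model(toy_gene_model)
        p.mu = 0.0
        g = "Target"
        # the activator is fixed at 5 with kappa 50 -> u = 5/55
        u = 5.0 / 55.0
        G = 2.0
        rT = u * p.alpha[g] * p.vmax_t * G / (p.KT + G)
        m_star = (rT + p.lambda_const[g]) / (p.delta[g] * p.kdm)
        rX = p.beta[g] * p.vmax_x * m_star / (p.KX + m_star)
        p_star = rX / (p.gamma[g] * p.kdp)
        x = cm.x0.copy()
        x[cm.index[g + "_mRNA"]] = m_star
        x[cm.index[g]] = p_star
        dx = rhs(0.0, x, cm, p)
        assert np.all(np.abs(dx) < 1e-10)

    def test_binding_pair_conserves_total_moiety(self, toy_binding_model):
        p = nominal_parameters(toy_binding_model)
        p.mu = 0.0
        traj = simulate(toy_binding_model, p, Condition(t_end=20.0))
        total_a = traj.series("A") + traj.series("C")
        total_b = traj.series("B") + traj.series("C")
        np.testing.assert_allclose(total_a, total_a[0], rtol=1e-6)
        np.testing.assert_allclose(total_b, total_b[0], rtol=1e-6)

    def test_rhs_matches_per_reaction_reference(self, model, compiled, nominal, rng):
        """Independent oracle: reassemble the derivative from the parsed
        declarations with the scalar rate laws."""
        from emtensemble.dynamics import factor_key
        from emtensemble.network import gene_species_names

        cm, p = compiled, nominal
        x = cm.x0 * rng.uniform(0.5, 1.5, size=cm.n_state)
        got = rhs(0.0, x, cm, p)

        val = dict(zip(cm.names, x))
        # control coefficients
        v = {r.id: 1.0 for r in model.reactions}
        u = {g: 1.0 for g in model.genes}
        for c in model.controls:
            outs = []
            for f in c.factors:
                xv = 1.0
                for n in f.species:
                    xv *= val[n]
                key = factor_key(c.target, f.species, f.direction)
                h = hill_transfer(xv, p.control_half[key], p.control_order[key])
                outs.append(1.0 - h if f.direction == "inhibition" else h)
            agg = integrate_control(outs, c.rule)
            if c.target in v:
                v[c.target] = agg
            else:
                u[c.target] = agg
        expected = np.zeros(cm.n_state)
        for r in model.reactions:
            if r.rate_law == "catalytic":
                sub = r.reactants[0][0]
                rate = saturation_rate(
                    p.k[r.id], val[r.enzyme], val[sub], p.ksat[r.id]
                )
            else:
                rate = mass_action_rate(
                    p.k[r.id],
                    [val[n] for n, _ in r.reactants],
                    [c for _, c in r.reactants],
                )
            rate *= v[r.id]
            for n, coeff in r.reactants + r.products:
                expected[cm.index[n]] += coeff * rate
        for i, name in enumerate(cm.names):
            expected[i] -= p.mu * val[name]
            expected[i] /= cm.tau[i]
        for g in model.genes:
            locus, mrna, prot = gene_species_names(g)
            expected[cm.index[mrna]] += (
                transcription_rate(val[locus], p.alpha[g], p.vmax_t, p.KT, u[g])
                - p.delta[g] * p.kdm * val[mrna]
                + p.lambda_const[g]
            )
            expected[cm.index[prot]] += (
                translation_rate(val[mrna], p.beta[g], p.vmax_x, p.KX)
                - p.gamma[g] * p.kdp * val[prot]
            )
        expected[cm.fixed] = 0.0
        np.testing.assert_allclose(got, expected, rtol=1e-10, atol=1e-12)

    def test_dimension_mismatch_rejected(self, compiled, nominal):
        with pytest.raises(ValueError, match="state length"):
            rhs(0.0, np.ones(3), compiled, nominal)


class TestApplyCondition:
    def test_empty_condition_is_identity(self, compiled, nominal):
        p, x0 = apply_condition(compiled, nominal, Condition())
        np.testing.assert_array_equal(x0, compiled.x0)
        assert p.k == nominal.k
        assert p.lambda_const == nominal.lambda_const

    def test_ligand_dose_sets_initial_value(self, compiled, nominal):
        p, x0 = apply_condition(
            compiled, nominal, Condition(doses={"TGFB12": 10.0})
        )
        assert x0[compiled.index["TGFB12"]] == 10.0  # 1 a.u. == 1 nM

    def test_unknown_inhibitor_rejected(self):
        with pytest.raises(ValueError, match="unknown inhibitor"):
            Condition(inhibitors={"aspirin": 1.0})

    def test_unknown_gene_rejected(self, compiled, nominal):
        with pytest.raises(ValueError, match="unknown gene"):
            apply_condition(
                compiled, nominal, Condition(expression_mods={"MYC": 2.0})
            )

    def test_yreg1_knockout_decays_by_48h(self, compiled, nominal):
        untreated = simulate(compiled, nominal, Condition())
        ko = simulate(
            compiled, nominal, Condition(expression_mods={"YREG1": 0.0})
        )
        # protein decay is set by gamma_YREG1 * kdp (~7.5 h half-life):
        # ~48 h of pure decay leaves ~1.5% of the untreated level
        assert ko.endpoint("YREG1") < 0.02 * untreated.endpoint("YREG1")
        assert ko.endpoint("YREG1_mRNA") < 0.01 * untreated.endpoint("YREG1_mRNA")


class TestSimulate:
    def test_closed_system_stays_identically_zero(self, toy_binding_model):
        p = nominal_parameters(toy_binding_model)
        p.mu = 0.0
        cm = compile_model(toy_binding_model)
        x0 = cm.x0.copy()
        cm.x0 = np.zeros_like(cm.x0)
        try:
            traj = simulate(cm, p, Condition(t_end=10.0))
            assert np.all(traj.states == 0.0)
        finally:
            cm.x0 = x0

    def test_endpoint_invariant_under_tolerance_tightening(self, compiled, nominal):
        cond = Condition(doses={"TGFB12": 10.0})
        a = simulate(compiled, nominal, cond)
        b = simulate(compiled, nominal, cond, rtol=5e-7, atol=5e-10)
        rel = np.abs(a.states[-1] - b.states[-1]) / np.maximum(
            np.abs(b.states[-1]), 1e-6
        )
        assert rel.max() < 1e-3

    def test_endpoint_invariant_under_grid_refinement(self, compiled, nominal):
        cond = Condition(doses={"VEGFA": 50.0})
        coarse = simulate(compiled, nominal, cond, t_eval=np.linspace(0, 48, 5))
        fine = simulate(compiled, nominal, cond, t_eval=np.linspace(0, 48, 193))
        rel = np.abs(coarse.states[-1] - fine.states[-1]) / np.maximum(
            np.abs(fine.states[-1]), 1e-6
        )
        assert rel.max() < 1e-3

    def test_untreated_is_quasi_steady(self, compiled, nominal):
        traj = simulate(compiled, nominal, Condition())
        x = traj.states[-1]
        dx = rhs(48.0, x, compiled, nominal, Condition())
        assert np.linalg.norm(dx) < 1e-4 * np.linalg.norm(x)

    def test_nominal_steady_state_on_physiological_scales(self, compiled, nominal):
        x, res = steady_state(compiled, nominal)
        assert res < 1e-4
        prot = [x[compiled.index[g]] for g in compiled.genes]
        mrna = [x[compiled.index[g + "_mRNA"]] for g in compiled.genes]
        assert min(prot) >= 10.0 and max(prot) <= 1000.0
        assert min(mrna) >= 0.01 and max(mrna) <= 1.0

    def test_states_stay_nonnegative(self, compiled, nominal):
        traj = simulate(compiled, nominal, Condition(doses={"TGFB12": 10.0}))
        assert traj.states.min() >= 0.0
        assert np.all(np.diff(traj.times) > 0)
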