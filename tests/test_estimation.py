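"""Pareto ranking, annealing moves, ensembles and cross-validation."""

import itertools

import numpy as np
import pytest

from emtensemble.estimation import (
    Archive,
    Candidate,
    CVPartition,
    POETsConfig,
    ParameterSpace,
    anneal_accept,
    compare_to_control,
    crossvalidate,
    make_partitions,
    pareto_rank,
    perturb,
    random_control,
    run_poets,
    select_ensemble,
)
from emtensemble.objectives import evaluate_objectives
from emtensemble.synthetic import (
    NoiseModel,
    default_conditions,
    default_protocols,
    generate_dataset,
)


def brute_force_ranks(E):
    n = len(E)
    ranks = np.zeros(n, dtype=int)
    for i, j in itertools.product(range(n), repeat=2):
        if i == j:
            continue
        if np.all(E[i] <= E[j]) and np.any(E[i] < E[j]):
            ranks[j] += 1
    return ranks


@pytest.fixture(scope="module")
def small_problem(model, nominal):
    """Three objectives from a known truth for fast orchestration tests."""
    protocols = default_protocols()[:3]
    conds = default_conditions()
    objs = generate_dataset(nominal, protocols, NoiseModel(cv=0.05, seed=1), model)
    return objs, conds


class TestPerturb:
    def test_zero_fraction_is_identity(self, nominal, rng):
        out = perturb(nominal, 0.0, rng)
        space = ParameterSpace(nominal)
        np.testing.assert_array_equal(
            space.to_vector(out), space.to_vector(nominal)
        )

    def test_factors_within_bounds_monte_carlo(self, nominal):
        rng = np.random.default_rng(1)
        space = ParameterSpace(nominal)
        key_idx = 0
        nom_val = space.to_vector(nominal)[key_idx]
        draws = np.array(
            [
                space.to_vector(perturb(nominal, 0.3, rng))[key_idx]
                for _ in range(10_000)
            ]
        )
        ratios = draws / nom_val
        assert ratios.min() >= 0.7 - 1e-12
        assert ratios.max() <= 1.3 + 1e-12
        # draws should nearly fill the admissible interval
        assert ratios.min() < 0.705 and ratios.max() > 1.295

    def test_correction_factors_stay_in_admissible_box(self, nominal):
        rng = np.random.default_rng(2)
        p = nominal.copy()
        for g in p.alpha:
            p.alpha[g] = 9.9
        out = perturb(p, 0.3, rng)
        assert all(0.1 <= v <= 10.0 for v in out.alpha.values())

    def test_seeded_determinism_is_bitwise(self, nominal):
        a = perturb(nominal, 0.3, np.random.default_rng(7))
        b = perturb(nominal, 0.3, np.random.default_rng(7))
        space = ParameterSpace(nominal)
        assert space.to_vector(a).tobytes() == space.to_vector(b).tobytes()


class TestParetoRank:
    def test_single_candidate_is_rank_zero(self):
        assert pareto_rank([[1.0, 2.0]]).tolist() == [0]

    def test_mutual_nondomination(self):
        assert pareto_rank([[1.0, 2.0], [2.0, 1.0]]).tolist() == [0, 0]

    def test_chain_of_domination(self):
        E = [[1, 1], [2, 2], [3, 3]]
        assert pareto_rank(E).tolist() == [0, 1, 2]

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            n = rng.integers(2, 30)
            m = rng.integers(2, 6)
            E = rng.integers(0, 5, size=(n, m)).astype(float)
            np.testing.assert_array_equal(pareto_rank(E), brute_force_ranks(E))

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            pareto_rank(np.ones(3))


class TestAnnealAccept:
    def test_equal_rank_always_accepts(self, rng):
        assert all(anneal_accept(3, 3, 0.01, rng) for _ in range(100))

    def test_improvement_always_accepts(self, rng):
        assert all(anneal_accept(0, 5, 1e-6, rng) for _ in range(100))

    def test_zero_temperature_limit_rejects_worsening(self):
        rng = np.random.default_rng(0)
        hits = sum(anneal_accept(2, 1, 1e-9, rng) for _ in range(1000))
        assert hits == 0

    def test_unit_gap_acceptance_near_boltzmann(self):
        rng = np.random.default_rng(11)
        n = 2000
        hits = sum(anneal_accept(2, 1, 1.0, rng) for _ in range(n))
        p = np.exp(-1)
        sigma = np.sqrt(p * (1 - p) / n)
        assert abs(hits / n - p) < 3 * sigma


class TestArchive:
    def test_eviction_prefers_dominated_members(self):
        arch = Archive(capacity=2)
        arch.insert(Candidate(None, np.array([1.0, 1.0]), step=0))
        arch.insert(Candidate(None, np.array([5.0, 5.0]), step=1))
        arch.insert(Candidate(None, np.array([0.5, 2.0]), step=2))
        errs = {tuple(c.errors) for c in arch.candidates}
        assert (5.0, 5.0) not in errs  # the dominated member left
        assert all(c.rank == 0 for c in arch.candidates)


class TestRunPoets:
    def test_zero_steps_returns_nominal_archive(
        self, model, nominal, small_problem
    ):
        objs, conds = small_problem
        cfg = POETsConfig(seed=1, steps=0)
        arch, log = run_poets(model, objs, conds, cfg, nominal)
        assert len(arch.candidates) == 1
        assert log == []
        space = ParameterSpace(nominal)
        np.testing.assert_array_equal(
            space.to_vector(arch.candidates[0].params), space.to_vector(nominal)
        )

    def test_same_seed_gives_identical_archives(self, model, nominal, small_problem):
        objs, conds = small_problem
        cfg = POETsConfig(seed=5, steps=12, capacity=20)
        a1, log1 = run_poets(model, objs, conds, cfg, nominal)
        a2, log2 = run_poets(model, objs, conds, cfg, nominal)
        assert log1 == log2
        space = ParameterSpace(nominal)
        for c1, c2 in zip(a1.candidates, a2.candidates):
            assert (
                space.to_vector(c1.params).tobytes()
                == space.to_vector(c2.params).tobytes()
            )
            np.testing.assert_array_equal(c1.errors, c2.errors)

    def test_front_is_never_lost(self, model, nominal, small_problem):
        """Archive elitism: the best-seen front survives insertion pressure."""
        objs, conds = small_problem
        cfg = POETsConfig(seed=9, steps=25, capacity=8)
        arch, _ = run_poets(model, objs, conds, cfg, nominal)
        assert len(arch.candidates) <= 8
        assert arch.front()
        ranks = pareto_rank(arch.error_matrix())
        assert any(r == 0 for r in ranks)


class TestCrossValidation:
    def test_partitions_cover_each_objective_once(self):
        parts = make_partitions([1, 2, 3, 4, 5])
        assert len(parts) == 5
        held = [p.validation_id for p in parts]
        assert sorted(held) == [1, 2, 3, 4, 5]
        for p in parts:
            assert sorted(p.train_ids + [p.validation_id]) == [1, 2, 3, 4, 5]
            assert p.validation_id not in p.train_ids

    def test_matches_manually_scripted_loop(self, model, nominal, small_problem):
        objs, conds = small_problem
        cfg = POETsConfig(seed=21, steps=6, capacity=10)
        results = crossvalidate(model, objs, conds, cfg, nominal)
        assert len(results) == 3
        by_id = {o.id: o for o in objs}
        for i, res in enumerate(results):
            sub = [by_id[j] for j in res.partition.train_ids]
            manual_cfg = POETsConfig(**{**cfg.__dict__, "seed": cfg.seed + i})
            arch, _ = run_poets(model, sub, conds, manual_cfg, nominal)
            np.testing.assert_array_equal(
                res.archive.error_matrix(), arch.error_matrix()
            )
            held = by_id[res.partition.validation_id]
            manual_pred = np.array(
                [
                    evaluate_objectives(c.params, [held], model, conds)[0]
                    for c in arch.front()
                ]
            )
            np.testing.assert_array_equal(res.prediction_errors, manual_pred)


class TestSelectEnsemble:
    def _toy_results(self):
        import types

        cands = [
            Candidate("p0", np.array([1.0, 1.0]), rank=0, step=0),
            Candidate("p1", np.array([0.5, 2.0]), rank=0, step=1),
            Candidate("p2", np.array([3.0, 3.0]), rank=2, step=2),
        ]
        # bypass ParameterSet packing with a tiny namespace standing in
        for i, c in enumerate(cands):
            ns = types.SimpleNamespace()
            c.params = ns
        arch = Archive(candidates=cands, capacity=10)
        res = types.SimpleNamespace(
            archive=arch,
            prediction_errors=np.array([0.1, 0.2]),
            training_errors=np.array([2.0, 2.5]),
        )
        return res

    def test_everything_returned_at_loose_thresholds(
        self, model, nominal, small_problem
    ):
        objs, conds = small_problem
        cfg = POETsConfig(seed=3, steps=8, capacity=10)
        results = crossvalidate(model, objs, conds, cfg, nominal)
        all_cands = sum(len(r.archive.candidates) for r in results)
        selected = select_ensemble(results, max_rank=10**9, error_quantile=1.0)
        assert len(selected) <= all_cands
        assert len(selected) >= max(len(r.archive.front()) for r in results)

    def test_quantile_tightening_is_monotone(self, model, nominal, small_problem):
        objs, conds = small_problem
        cfg = POETsConfig(seed=3, steps=8, capacity=10)
        results = crossvalidate(model, objs, conds, cfg, nominal)
        sizes = [
            len(select_ensemble(results, max_rank=0, error_quantile=q))
            for q in (1.0, 0.8, 0.5)
        ]
        assert sizes[0] >= sizes[1] >= sizes[2]


class TestRandomControl:
    def test_size_and_determinism(self, nominal):
        fam1 = random_control(nominal, 100, np.random.default_rng(8))
        fam2 = random_control(nominal, 100, np.random.default_rng(8))
        assert len(fam1) == 100
        space = ParameterSpace(nominal)
        assert (
            space.to_vector(fam1[3]).tobytes() == space.to_vector(fam2[3]).tobytes()
        )

    def test_control_is_far_worse_than_truth(
        self, model, nominal, small_problem
    ):
        objs, conds = small_problem
        truth_err = evaluate_objectives(nominal, objs, model, conds).sum()
        rng = np.random.default_rng(17)
        fam = random_control(nominal, 5, rng)
        ctrl = [
            evaluate_objectives(p, objs, model, conds).sum() for p in fam
        ]
        assert np.median(ctrl) > 10 * truth_err


class TestCompareToControl:
    def test_identical_samples_not_significant(self):
        with pytest.warns(UserWarning):
            stat, p, sig = compare_to_control([1, 2, 3], [1, 2, 3])
        assert p == 1.0
        assert not sig

    def test_fully_separated_samples_hit_minimal_p(self):
        trained = [1.0, 2.0, 3.0, 4.0, 5.0]
        control = [10.0, 11.0, 12.0, 13.0, 14.0]
        _, p, sig = compare_to_control(trained, control)
        # most extreme two-sided p for n = m = 5 without ties
        assert p == pytest.approx(2 / 252, rel=1e-9)
        assert sig

    def test_small_sample_matches_exhaustive_enumeration(self):
        trained = [1.0, 4.0, 6.0]
        control = [2.0, 7.0, 9.0]
        _, p, _ = compare_to_control(trained, control)
        # enumerate all rank assignments of the pooled sample
        pooled = np.array(trained + control)
        obs = sum(
            (t > c) for t in trained for c in control
        )  # observed U statistic
        count = 0
        total = 0
        for comb in itertools.combinations(range(6), 3):
            a = pooled[list(comb)]
            b = pooled[[i for i in range(6) if i not in comb]]
            u = sum((x > y) for x in a for y in b)
            total += 1
            if min(u, 9 - u) <= min(obs, 9 - obs):
                count += 1
        assert p == pytest.approx(count / total, rel=1e-9)
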