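import itertools

import numpy as np
import pytest

from replimeta import (
    CovariateMeta,
    InvalidInputError,
    SimulationConfig,
    enumerate_location_models,
    information_criterion,
    select_two_stage,
    simulate_dataset,
)
from replimeta.selection import ModelSpec, RankedModel

from conftest import build_dataset


def _cands(n_free, requires_pairs):
    metas = []
    for i in range(requires_pairs):
        metas.append(CovariateMeta(f"count{i}", "continuous"))
        metas.append(CovariateMeta(f"share{i}", "continuous", requires=f"count{i}"))
    metas.extend(CovariateMeta(f"free{i}", "continuous") for i in range(n_free))
    return metas


class TestEnumeration:
    def test_no_candidates_gives_forced_only(self):
        specs = enumerate_location_models([], forced=("se_o",))
        assert specs == [ModelSpec(location_set=("se_o",), forced_location=("se_o",))]

    def test_one_requires_pair_gives_three_specs(self):
        specs = enumerate_location_models(_cands(0, 1))
        sets = {frozenset(s.location_set) for s in specs}
        assert sets == {frozenset(), frozenset({"count0"}), frozenset({"count0", "share0"})}

    @pytest.mark.parametrize("n_free, pairs", [(2, 1), (3, 2), (0, 3), (5, 0)])
    def test_count_matches_closed_form_and_brute_force(self, n_free, pairs):
        """|admissible subsets| = 3^pairs * 2^free, checked two ways."""
        metas = _cands(n_free, pairs)
        specs = enumerate_location_models(metas)
        assert len(specs) == 3**pairs * 2**n_free
        # independent oracle: filter the unconstrained power set directly
        names = [m.name for m in metas]
        need = {m.name: m.requires for m in metas if m.requires}
        count = sum(
            all(req in sub for dep, req in need.items() if dep in sub)
            for r in range(len(names) + 1)
            for sub in map(set, itertools.combinations(names, r))
        )
        assert len(specs) == count
        assert len({tuple(sorted(s.location_set)) for s in specs}) == len(specs)

    def test_unknown_requires_errors(self):
        with pytest.raises(InvalidInputError, match="ghost"):
            enumerate_location_models(
                [CovariateMeta("a", "continuous", requires="ghost")]
            )

    def test_cyclic_requires_errors(self):
        metas = [
            CovariateMeta("a", "continuous", requires="b"),
            CovariateMeta("b", "continuous", requires="a"),
        ]
        with pytest.raises(InvalidInputError, match="cyclic"):
            enumerate_location_models(metas)

    def test_requires_satisfied_by_forced_covariate(self):
        metas = [CovariateMeta("share", "continuous", requires="count")]
        specs = enumerate_location_models(metas, forced=("count",))
        assert {frozenset(s.location_set) for s in specs} == {
            frozenset({"count"}),
            frozenset({"count", "share"}),
        }


class TestInformationCriterion:
    @pytest.mark.parametrize(
        "loglik, k, aic", [(-10.0, 5, 30.0), (0.0, 2, 4.0), (-10.0, 5, 30.0)]
    )
    def test_aic_definition(self, loglik, k, aic):
        class Stub:
            pass

        stub = Stub()
        stub.loglik, stub.k, stub.n_used = loglik, k, 20
        assert information_criterion(stub, "aic") == pytest.approx(aic)
        assert information_criterion(stub, "bic") == pytest.approx(
            -2 * loglik + k * np.log(20)
        )

    def test_k_rules_for_location_and_location_scale(self, case_like):
        from replimeta import fit_location_additive, fit_ls_additive

        loc = fit_location_additive(case_like, ["se_o", "nb_authors_o", "share_male_o"])
        assert loc.k == 3 + 2
        ls = fit_ls_additive(case_like, ["se_o", "nb_authors_o"], ["se_o"])
        assert ls.k == 2 + 1 + 2


def _selection_dataset(seed, n=120, beta_true=0.9):
    rng_seed = int(seed)
    cfg = SimulationConfig(
        n_pairs=n,
        flavor="multiplicative",
        true_location={"intercept": 0.15, "good": beta_true},
        true_scale={"intercept": 0.3},
        covariate_generators={
            name: {"dist": "normal", "mu": 0.0, "sd": 1.0}
            for name in ("good", "noise1", "noise2", "noise3", "noise4")
        },
        seed=rng_seed,
    )
    return simulate_dataset(cfg)


class TestTwoStageSelection:
    def test_stage2_with_singleton_pool_keeps_stage1_winner(self):
        ds = _selection_dataset(0, n=60)
        stage1, stage2 = select_two_stage(ds, [], "multiplicative", "aic", forced=("se_o",))
        assert stage1.best.location_set == ("se_o",)
        assert stage2.best.location_set == ("se_o",)
        assert stage1.n_models_evaluated == 1

    def test_criterion_invariant_to_candidate_order_and_row_permutation(self):
        ds = _selection_dataset(1, n=80)
        cands = [CovariateMeta(n, "continuous") for n in ("good", "noise1", "noise2")]
        s1_a, s2_a = select_two_stage(ds, cands, "multiplicative", "aic")
        s1_b, s2_b = select_two_stage(ds, cands[::-1], "multiplicative", "aic")
        assert frozenset(s1_a.best.location_set) == frozenset(s1_b.best.location_set)
        assert s1_a.ranked[0].criterion_value == pytest.approx(
            s1_b.ranked[0].criterion_value, abs=1e-9
        )
        shuffled = ds.subset(np.random.default_rng(0).permutation(ds.pairs))
        s1_c, _ = select_two_stage(shuffled, cands, "multiplicative", "aic")
        assert frozenset(s1_c.best.location_set) == frozenset(s1_a.best.location_set)
        assert s1_c.ranked[0].criterion_value == pytest.approx(
            s1_a.ranked[0].criterion_value, abs=1e-9
        )

    def test_ranked_list_is_sorted_and_counts_logged(self):
        ds = _selection_dataset(2, n=80)
        cands = [CovariateMeta(n, "continuous") for n in ("good", "noise1")]
        stage1, stage2 = select_two_stage(ds, cands, "additive", "aic")
        values1 = [r.criterion_value for r in stage1.ranked]
        assert values1 == sorted(values1)
        assert stage1.n_models_evaluated == 4
        # stage 2: location subsets of the winner pool x scale subsets
        n_loc = 2 ** len([c for c in stage1.best.location_set])
        assert stage2.n_models_evaluated == len(
            {tuple(sorted(r.spec.location_set)) for r in stage2.ranked}
        ) * len({tuple(sorted(r.spec.scale_set)) for r in stage2.ranked})

    def test_stage1_recovers_true_covariate(self):
        """Selection consistency: the truly associated covariate is kept.

        One strong location covariate among four pure-noise candidates;
        across 40 seeded replicates the stage-1 AIC winner must include
        it at least 95% of the time.
        """
        cands = [
            CovariateMeta(n, "continuous")
            for n in ("good", "noise1", "noise2", "noise3", "noise4")
        ]
        hits = 0
        n_rep = 40
        for seed in range(n_rep):
            ds = _selection_dataset(seed, n=120)
            stage1, _ = select_two_stage(ds, cands, "multiplicative", "aic")
            hits += "good" in stage1.best.location_set
        assert hits / n_rep >= 0.95
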