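import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import sdmax
from sdmax import EvalConfig
from sdmax.evaluate import _make_folds


def brute_force_auc(pres, bg):
    wins = sum(1.0 if p > b else 0.5 if p == b else 0.0
               for p, b in itertools.product(pres, bg))
    return wins / (len(pres) * len(bg))


def brute_force_threshold(pres, bg):
    pres, bg = np.asarray(pres, float), np.asarray(bg, float)
    best = None
    for tau in np.unique(np.concatenate([pres, bg])):
        sens = (pres >= tau).mean()
        spec = (bg < tau).mean()
        if best is None or sens + spec > best[1] + 1e-15:
            best = (tau, sens + spec, sens, spec)
    return best


class TestAuc:
    def test_exhaustive_pair_count_example(self):
        # pairs: (0.9 beats all three) + (0.4 beats 0.3, 0.1) = 5 of 6
        assert sdmax.auc([0.9, 0.4], [0.5, 0.3, 0.1]) == pytest.approx(5 / 6)

    def test_perfect_separation(self):
        assert sdmax.auc([3, 4, 5], [0, 1, 2]) == 1.0

    def test_identical_multisets_are_chance(self):
        assert sdmax.auc([1, 2, 3], [1, 2, 3]) == 0.5

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            sdmax.auc([], [1.0])

    @settings(deadline=None, max_examples=50)
    @given(
        st.lists(st.integers(0, 10), min_size=1, max_size=20),
        st.lists(st.integers(0, 10), min_size=1, max_size=20),
    )
    def test_matches_exhaustive_pair_count(self, pres, bg):
        assert sdmax.auc(pres, bg) == pytest.approx(brute_force_auc(pres, bg))

    @settings(deadline=None, max_examples=30)
    @given(st.integers(0, 10_000))
    def test_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        pres, bg = rng.normal(1, 1, 20), rng.normal(0, 1, 50)
        a0 = sdmax.auc(pres, bg)
        assert sdmax.auc(np.exp(pres), np.exp(bg)) == pytest.approx(a0)
        assert sdmax.auc(3 * pres + 2, 3 * bg + 2) == pytest.approx(a0)


class TestSelectThreshold:
    def test_perfect_separation_takes_min_presence(self):
        tau, sens, spec = sdmax.select_threshold([3.0, 4.0], [0.0, 1.0])
        assert tau == 3.0 and sens == 1.0 and spec == 1.0

    def test_all_scores_equal_degenerate(self):
        tau, sens, spec = sdmax.select_threshold([2.0, 2.0], [2.0])
        assert tau == 2.0 and sens == 1.0 and spec == 0.0

    @settings(deadline=None, max_examples=50)
    @given(st.integers(0, 10_000))
    def test_matches_exhaustive_scan(self, seed):
        rng = np.random.default_rng(seed)
        pres = rng.choice(np.linspace(0, 1, 11), size=rng.integers(1, 25))
        bg = rng.choice(np.linspace(0, 1, 11), size=rng.integers(1, 25))
        tau, sens, spec = sdmax.select_threshold(pres, bg)
        b_tau, b_score, b_sens, b_spec = brute_force_threshold(pres, bg)
        assert sens + spec == pytest.approx(b_score)
        assert tau == b_tau  # smallest qualifying threshold on ties


class TestFolds:
    def test_sizes_differ_by_at_most_one_and_partition(self):
        folds = _make_folds(23, 10, seed=1)
        sizes = [len(f) for f in folds]
        assert max(sizes) - min(sizes) <= 1
        assert sorted(np.concatenate(folds)) == list(range(23))

    def test_ten_presences_k10_gives_singletons(self):
        folds = _make_folds(10, 10, seed=0)
        assert [len(f) for f in folds] == [1] * 10

    def test_deterministic_under_seed(self):
        a, b = _make_folds(50, 10, 7), _make_folds(50, 10, 7)
        assert all(np.array_equal(x, y) for x, y in zip(a, b))


class TestKfoldCV:
    def test_strong_signal_gives_high_auc(self, virtual_species):
        rep = sdmax.kfold_cv(
            virtual_species["presences"],
            virtual_species["background"],
            {"classes": ("linear",), "beta0": 0.05},
            EvalConfig(k_folds=5, seed=2),
        )
        assert len(rep.fold_auc) == 5
        assert all(0.0 <= a <= 1.0 for a in rep.fold_auc)
        assert rep.mean_auc > 0.9
        assert 0.0 <= rep.threshold <= 1.0
        assert rep.sensitivity > 0.5 and rep.specificity > 0.5

    def test_k_exceeding_presences_rejected(self, virtual_species):
        pres = virtual_species["presences"].take(np.arange(5))
        with pytest.raises(ValueError, match="exceeds"):
            sdmax.kfold_cv(pres, virtual_species["background"],
                           config=EvalConfig(k_folds=10))


class TestPercentContribution:
    def test_single_variable_gets_everything(self, virtual_species):
        spec = sdmax.FeatureSpec.from_background(
            virtual_species["background"], layers=["env1"], classes=("linear",))
        P = spec.build(virtual_species["presences"])
        B = spec.build(virtual_species["background"])
        _, trace = sdmax.fit_maxent(P, B, spec, beta0=0.05)
        pc = sdmax.percent_contribution(trace)
        assert pc.index.tolist() == ["env1"]
        assert pc.sum() == pytest.approx(100.0, abs=0.1)

    def test_sums_to_hundred_and_noise_is_small(self, fitted_model):
        pc = sdmax.percent_contribution(
            fitted_model["trace"], layers=fitted_model["spec"].layers)
        assert pc.sum() == pytest.approx(100.0, abs=0.1)
        assert (pc >= 0).all()
        # env3/env4 have zero generating coefficients
        assert pc["env3"] < 10.0 and pc["env4"] < 10.0

    def test_empty_trace_gives_zeros(self):
        pc = sdmax.percent_contribution(sdmax.FitTrace(), layers=["a", "b"])
        assert pc.tolist() == [0.0, 0.0]


class TestPermutationImportance:
    def test_sums_to_hundred_and_noise_is_small(self, fitted_model, virtual_species):
        pi = sdmax.permutation_importance(
            fitted_model["model"],
            virtual_species["presences"],
            virtual_species["background"],
            repeats=5, seed=3)
        assert pi.sum() == pytest.approx(100.0, abs=0.1)
        assert pi["env3"] < 10.0 and pi["env4"] < 10.0

    def test_zero_coefficient_variable_has_zero_drop(self, fitted_model, virtual_species):
        # force an exact zero on a noise layer: permuting it cannot move AUC
        model = fitted_model["model"]
        lam = model.lam.copy()
        lam[model.spec.layers.index("env3")] = 0.0
        from dataclasses import replace
        zeroed_model = replace(model, lam=lam)
        pi = sdmax.permutation_importance(
            zeroed_model, virtual_species["presences"], virtual_species["background"],
            repeats=3, seed=0)
        assert pi["env3"] == pytest.approx(0.0, abs=1e-9)

    def test_deterministic_under_seed(self, fitted_model, virtual_species):
        args = (fitted_model["model"], virtual_species["presences"],
                virtual_species["background"])
        a = sdmax.permutation_importance(*args, repeats=3, seed=5)
        b = sdmax.permutation_importance(*args, repeats=3, seed=5)
        assert a.equals(b)


class TestJackknife:
    def test_single_variable_without_is_null_gain(self, virtual_species):
        jack = sdmax.jackknife(
            virtual_species["presences"], virtual_species["background"],
            layers=["env1"], model_settings={"classes": ("linear",), "beta0": 0.05})
        assert jack.loc["env1", "gain_without"] == 0.0
        assert jack.loc["env1", "gain_only"] == jack.loc["env1", "gain_full"]

    def test_noise_variable_adds_nothing_and_only_bounded_by_full(self, virtual_species):
        jack = sdmax.jackknife(
            virtual_species["presences"], virtual_species["background"],
            layers=["env1", "env2", "env3"],
            model_settings={"classes": ("linear",), "beta0": 0.05})
        full = jack["gain_full"].iloc[0]
        assert abs(jack.loc["env3", "gain_without"] - full) < 0.05 * full
        # a nested model cannot beat the full model on training gain
        assert (jack["gain_only"] <= full + 1e-6).all()
        # the informative variable is hurt by exclusion
        assert jack.loc["env1", "gain_without"] < full


def test_importance_table_layout(fitted_model, virtual_species):
    pc = sdmax.percent_contribution(
        fitted_model["trace"], layers=fitted_model["spec"].layers)
    pi = sdmax.permutation_importance(
        fitted_model["model"], virtual_species["presences"],
        virtual_species["background"], repeats=2, seed=0)
    jack = sdmax.jackknife(
        virtual_species["presences"], virtual_species["background"],
        model_settings={"classes": ("linear",), "beta0": 0.05})
    table = sdmax.importance_table(pc, pi, jack)
    assert list(table.columns) == ["PC", "PI", "gain_only", "gain_without"]
    assert set(table.index) == {"env1", "env2", "env3", "env4"}
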