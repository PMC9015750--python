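import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import norm

from medireader import irt, synth


def fine_grid_eap(responses, items, n=10_001, lo=-6.0, hi=6.0):
    """Independent EAP oracle: dense-grid numerical integration."""
    theta = np.linspace(lo, hi, n)
    post = norm.pdf(theta)
    for u, it in zip(responses, items):
        p = it.c + (1 - it.c) / (1 + np.exp(-it.a * (theta - it.b)))
        post = post * (p if u == 1 else 1 - p)
    post = post / post.sum()
    return float(post @ theta)


class TestProbCorrect:
    def test_at_difficulty_probability_is_midpoint(self):
        # logistic(0) = 1/2, so P = c + (1-c)/2 = (1+c)/2
        for a in (0.5, 1.0, 2.3):
            item = irt.Item("i", a, 0.7, 0.2)
            assert irt.prob_correct(item, 0.7) == pytest.approx(0.6)

    def test_lower_asymptote(self):
        item = irt.Item("i", 1.0, 0.0, 0.25)
        assert irt.prob_correct(item, -50.0) == pytest.approx(0.25, abs=1e-9)
        assert irt.prob_correct(item, 50.0) == pytest.approx(1.0, abs=1e-9)

    def test_closed_form_value(self):
        # independent arithmetic: 0.2 + 0.8/(1+exp(-1.5*0.5)) = 0.74334295934...
        item = irt.Item("i", 1.5, 0.5, 0.2)
        expected = 0.2 + 0.8 / (1 + math.exp(-0.75))
        assert irt.prob_correct(item, 1.0) == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(0.7433, abs=5e-5)

    @given(a=st.floats(0.1, 4), b=st.floats(-3, 3), c=st.floats(0, 0.49),
           t1=st.floats(-5, 5), t2=st.floats(-5, 5))
    @settings(max_examples=200, deadline=None)
    def test_strictly_increasing_and_bounded(self, a, b, c, t1, t2):
        item = irt.Item("i", a, b, c)
        p1, p2 = irt.prob_correct(item, t1), irt.prob_correct(item, t2)
        assert c < p1 < 1
        if t2 - t1 > 1e-9:      # resolvable gap at double precision
            assert p1 < p2

    def test_invalid_c_rejected(self):
        with pytest.raises(ValueError):
            irt.Item("i", 1.0, 0.0, 1.0)


class TestItemInformation:
    def test_2pl_reduction_peak(self):
        # c=0 at theta=b: P=Q=1/2 so I = a^2/4
        for a in (0.8, 1.7):
            item = irt.Item("i", a, -0.3, 0.0)
            assert irt.item_information(item, -0.3) == pytest.approx(a * a / 4)

    def test_matches_independent_formula(self):
        item = irt.Item("i", 1.5, 0.5, 0.2)
        theta = 1.0
        p = 0.2 + 0.8 / (1 + math.exp(-1.5 * (theta - 0.5)))
        expected = 1.5 ** 2 * ((1 - p) / p) * (p - 0.2) ** 2 / 0.8 ** 2
        assert irt.item_information(item, theta) == pytest.approx(
            expected, abs=1e-10)

    @given(a=st.floats(0.1, 4), b=st.floats(-3, 3), c=st.floats(0, 0.49),
           t=st.floats(-6, 6))
    @settings(max_examples=100, deadline=None)
    def test_nonnegative(self, a, b, c, t):
        assert irt.item_information(irt.Item("i", a, b, c), t) >= 0


class TestEAP:
    def test_no_items_returns_prior(self):
        est = irt.estimate_ability_eap([], [])
        assert est.theta == 0.0 and est.se == 1.0 and est.n_items == 0

    def test_matches_fine_grid_oracle(self):
        items = [irt.Item("a", 1.0, 0.0, 0.2)] * 2
        est = irt.estimate_ability_eap([1, 1], items)
        assert est.theta == pytest.approx(fine_grid_eap([1, 1], items),
                                          abs=1e-4)

    def test_matches_oracle_on_random_item_sets(self):
        rng = np.random.default_rng(11)
        for _ in range(25):
            k = int(rng.integers(1, 6))
            items = [irt.Item(str(i), rng.uniform(0.5, 2.5),
                              rng.uniform(-2, 2), rng.uniform(0, 0.3))
                     for i in range(k)]
            resp = list(rng.integers(0, 2, size=k))
            est = irt.estimate_ability_eap(resp, items)
            assert est.theta == pytest.approx(fine_grid_eap(resp, items),
                                              abs=1e-4)

    def test_monotone_in_responses(self):
        items = [irt.Item("a", 1.0, 0.0, 0.2)] * 2
        hi = irt.estimate_ability_eap([1, 1], items).theta
        lo = irt.estimate_ability_eap([0, 0], items).theta
        assert hi > lo

    def test_flipping_any_response_raises_theta(self):
        rng = np.random.default_rng(5)
        items = [irt.Item(str(i), rng.uniform(0.7, 2), rng.uniform(-1.5, 1.5),
                          rng.uniform(0, 0.25)) for i in range(6)]
        resp = [0, 1, 0, 1, 0, 0]
        base = irt.estimate_ability_eap(resp, items).theta
        for i, u in enumerate(resp):
            if u == 0:
                flipped = list(resp)
                flipped[i] = 1
                assert irt.estimate_ability_eap(flipped, items).theta > base

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            irt.estimate_ability_eap([1], [])

    def test_missing_responses_skipped(self):
        items = [irt.Item("a", 1.0, 0.0, 0.0), irt.Item("b", 1.0, 0.0, 0.0)]
        est = irt.estimate_ability_eap([1, None], items)
        assert est.n_items == 1


class TestClassifyLiteracy:
    @pytest.mark.parametrize("theta,expected", [
        (1.2, "high"),     # above average ability
        (-0.5, "low"),     # below average ability
        (0.0, "high"),     # boundary: average classifies high (documented)
    ])
    def test_threshold_rule(self, theta, expected):
        est = irt.AbilityEstimate(theta=theta, se=0.5, n_items=10)
        assert irt.classify_literacy(est) == expected


class TestCalibration:
    def test_degenerate_columns_excluded(self):
        rng = np.random.default_rng(0)
        vals = rng.integers(0, 2, size=(40, 3)).astype(float)
        vals[:, 1] = 1.0   # everyone answers item 2 correctly
        m = irt.ResponseMatrix([f"p{i}" for i in range(40)],
                               ["i1", "i2", "i3"], vals)
        model = irt.ThreePLModel(m)
        assert model.excluded_items == ["i2"]
        res = model.fit(irt.EMConfig(max_iter=20))
        assert [it.id for it in res.items] == ["i1", "i3"]

    def test_loglik_monotone_on_small_fixture(self):
        spec = synth.SynthSpec(seed=2, irt=synth.IRTSpec(n_items=8,
                                                         n_persons=150))
        items = synth.make_item_bank(spec)
        matrix, _ = synth.make_responses(items, 150, seed=42)
        res = irt.calibrate_3pl_em(matrix, irt.EMConfig(max_iter=40))
        assert np.all(np.diff(res.loglik_path) >= -1e-6)

    def test_parameter_recovery_single_seed(self):
        """EM recovers simulation truth on a 2000x30 matrix (one seed here;
        the full three-seed sweep runs in the acceptance suite)."""
        spec = synth.SynthSpec(seed=1)
        items = synth.make_item_bank(spec)
        matrix, _ = synth.make_responses(items, 2000, seed=101)
        res = irt.calibrate_3pl_em(matrix)
        est = res.params_frame()
        true_a = np.array([it.a for it in items])
        true_b = np.array([it.b for it in items])
        rmse_b = float(np.sqrt(np.mean((est["b"].values - true_b) ** 2)))
        r_a = float(np.corrcoef(est["a"].values, true_a)[0, 1])
        assert rmse_b <= 0.3
        assert r_a >= 0.8

    def test_summary_and_scores(self):
        spec = synth.SynthSpec(seed=2, irt=synth.IRTSpec(n_items=6,
                                                         n_persons=120))
        items = synth.make_item_bank(spec)
        matrix, _ = synth.make_responses(items, 120, seed=9)
        res = irt.calibrate_3pl_em(matrix, irt.EMConfig(max_iter=30))
        text = res.summary()
        assert "3PL" in text and "log-likelihood" in text
        scores = res.score_persons()
        assert set(scores["literacy"]) <= {"low", "high"}
        assert len(scores) == 120

    def test_too_small_matrix_rejected(self):
        with pytest.raises(ValueError):
            irt.ThreePLModel(irt.ResponseMatrix(["p1"], ["i1", "i2"],
                                                [[0.0, 1.0]]))


class TestShortenTest:
    @staticmethod
    def brute_force_best(items, n, grid=irt.QuadratureGrid(), a_min=0.2):
        survivors = [it for it in items if it.a > a_min]
        nodes = grid.nodes
        best, best_val = None, -1.0
        for combo in itertools.combinations(survivors, n):
            val = float(np.mean(
                sum(irt.item_information(it, nodes) for it in combo)))
            if val > best_val:
                best, best_val = combo, val
        return {it.id for it in best}

    def test_all_items_returned_when_n_equals_bank(self):
        items = [irt.Item(f"q{i}", 1.0 + 0.1 * i, 0.0, 0.1) for i in range(4)]
        assert set(irt.shorten_test(items, 4)) == {it.id for it in items}

    def test_matches_brute_force_on_five_items(self):
        rng = np.random.default_rng(3)
        items = [irt.Item(f"q{i}", rng.uniform(0.4, 2.5),
                          rng.uniform(-2, 2), rng.uniform(0, 0.3))
                 for i in range(5)]
        assert set(irt.shorten_test(items, 2)) == self.brute_force_best(items, 2)

    def test_matches_brute_force_on_random_small_banks(self):
        rng = np.random.default_rng(17)
        for _ in range(10):
            size = int(rng.integers(3, 7))
            items = [irt.Item(f"q{i}", rng.uniform(0.05, 2.5),
                              rng.uniform(-2, 2), rng.uniform(0, 0.3))
                     for i in range(size)]
            n = int(rng.integers(1, max(2, sum(it.a > 0.2 for it in items))))
            assert set(irt.shorten_test(items, n)) == \
                self.brute_force_best(items, n)

    def test_nondiscriminating_items_never_selected(self):
        items = [irt.Item("dead", 0.0, 0.0, 0.0)] + \
            [irt.Item(f"q{i}", 1.0, 0.0, 0.1) for i in range(3)]
        assert "dead" not in irt.shorten_test(items, 3)

    def test_invalid_n_rejected(self):
        items = [irt.Item("q", 1.0, 0.0, 0.0)]
        with pytest.raises(ValueError):
            irt.shorten_test(items, 0)


def test_item_bank_csv_round_trip(tmp_path):
    items = [irt.Item("q1", 1.2, -0.5, 0.15), irt.Item("q2", 0.9, 0.3, 0.0)]
    p = tmp_path / "items.csv"
    irt.save_items(items, p)
    loaded = irt.load_items(p)
    assert loaded == items
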