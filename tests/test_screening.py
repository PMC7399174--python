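import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import synlogic as sl
from synlogic.screening import ScreenError, ScreenRecord


def record(single_a, single_b, combo, pair=("A", "B")):
    return ScreenRecord(cell_line="AGS", drug_a=pair[0], drug_b=pair[1],
                        single_a=single_a, single_b=single_b, combo=combo)


class TestHsaExcess:
    def test_worked_2x2_grid(self):
        rec = record({1: 0.8, 2: 0.6}, {1: 0.9, 2: 0.7},
                     {(1, 1): 0.7, (1, 2): 0.5, (2, 1): 0.5, (2, 2): 0.3})
        res = sl.hsa_excess(rec)
        assert res.excess.loc[1, 1] == pytest.approx(-0.1)
        assert res.excess.loc[1, 2] == pytest.approx(-0.2)
        assert res.excess.loc[2, 1] == pytest.approx(-0.1)
        assert res.excess.loc[2, 2] == pytest.approx(-0.3)
        assert res.mean == pytest.approx(-0.175)

    def test_combination_equal_to_stronger_single_gives_zero(self):
        sa, sb = {1: 0.8, 2: 0.5}, {1: 0.9, 2: 0.6}
        combo = {(a, b): min(sa[a], sb[b]) for a in sa for b in sb}
        assert sl.hsa_excess(record(sa, sb, combo)).mean == pytest.approx(0.0)

    def test_invariant_under_drug_swap(self):
        rec = record({1: 0.8, 2: 0.6}, {1: 0.9, 2: 0.7},
                     {(1, 1): 0.75, (1, 2): 0.52, (2, 1): 0.44, (2, 2): 0.31})
        assert sl.hsa_excess(rec).mean == pytest.approx(sl.hsa_excess(rec.swapped()).mean)

    def test_missing_single_agent_dose_named(self):
        rec = record({1: 0.8}, {1: 0.9}, {(1, 2): 0.5})
        with pytest.raises(ScreenError, match="dose 2"):
            sl.hsa_excess(rec)

    def test_planted_depth_recovered_exactly(self):
        panel = sl.make_panel({"D1": "T1", "D2": "T2", "D3": "T3"})
        recs = sl.gen_screen(panel, {("D1", "D2")}, excess_depth=-0.2,
                             noise_sd=0.0, seed=5)
        means = {r.pair: sl.hsa_excess(r).mean for r in recs}
        assert means[("D1", "D2")] == pytest.approx(-0.2)
        assert means[("D1", "D3")] == pytest.approx(0.0)


class TestBinarize:
    @pytest.mark.parametrize("mean,call", [
        (-0.11, True),    # cutoff is inclusive
        (-0.109, False),  # just above the cutoff
        (-0.175, True),
        (0.0, False),
    ])
    def test_cutoff_boundary(self, mean, call):
        obs = sl.binarize({("A", "B"): mean})
        assert obs.calls[("A", "B")] is call

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(-0.5, 0.3), min_size=1, max_size=12),
           st.floats(-0.3, -0.02), st.floats(-0.3, -0.02))
    def test_monotone_in_cutoff(self, means, c1, c2):
        lo, hi = sorted((c1, c2))
        pairs = {("D", f"P{i}"): m for i, m in enumerate(means)}
        strict = sl.binarize(pairs, cutoff=lo).calls
        loose = sl.binarize(pairs, cutoff=hi).calls
        assert all(loose[p] for p in strict if strict[p])


class TestConfusion:
    def test_printed_gastric_line_metrics(self):
        cm = sl.ConfusionSummary(tp=8, fp=9, tn=128, fn=7)
        rep = cm.report()
        assert rep["sensitivity_pct"] == 53.3
        assert rep["ppv_pct"] == 47.1
        assert rep["npv_pct"] == 94.8
        assert rep["mcc"] == 0.44

    def test_perfect_prediction(self):
        cm = sl.ConfusionSummary(tp=5, fp=0, tn=10, fn=0)
        assert cm.mcc == 1.0 and cm.sensitivity == 1.0 and cm.ppv == 1.0

    def test_independent_product_gives_zero_mcc(self):
        cm = sl.ConfusionSummary(tp=2, fp=4, tn=2, fn=1)  # tp*tn == fp*fn
        assert cm.mcc == pytest.approx(0.0)

    def test_zero_denominator_is_nan(self):
        cm = sl.ConfusionSummary(tp=0, fp=0, tn=5, fn=0)
        assert math.isnan(cm.sensitivity) and math.isnan(cm.ppv)

    @pytest.mark.parametrize("seed", range(5))
    def test_mcc_matches_sklearn(self, seed):
        from sklearn.metrics import matthews_corrcoef

        rng = np.random.default_rng(seed)
        y_true = rng.integers(0, 2, size=60)
        y_pred = rng.integers(0, 2, size=60)
        tp = int(np.sum((y_true == 1) & (y_pred == 1)))
        fp = int(np.sum((y_true == 0) & (y_pred == 1)))
        tn = int(np.sum((y_true == 0) & (y_pred == 0)))
        fn = int(np.sum((y_true == 1) & (y_pred == 0)))
        cm = sl.ConfusionSummary(tp=tp, fp=fp, tn=tn, fn=fn)
        assert cm.mcc == pytest.approx(matthews_corrcoef(y_true, y_pred))

    def test_na_pairs_excluded(self):
        predicted = {("A", "B"): True, ("A", "C"): None, ("B", "C"): False}
        observed = {("A", "B"): True, ("A", "C"): True, ("B", "C"): False}
        cm = sl.confusion(predicted, observed)
        assert (cm.tp, cm.fp, cm.tn, cm.fn) == (1, 0, 1, 0)

    def test_disjoint_universes_rejected(self):
        with pytest.raises(ScreenError, match="disjoint"):
            sl.confusion({("A", "B"): True}, {("C", "D"): True})

    def test_pair_order_normalized(self):
        cm = sl.confusion({("B", "A"): True}, {("A", "B"): True})
        assert cm.tp == 1


class TestRandomBaseline:
    def test_zero_predictions(self):
        rb = sl.random_baseline(0, (152, 9), reps=1000, seed=0)
        assert rb.expected_tp == 0 and rb.expected_tn == 152 - 9

    def test_closed_form_and_scipy_cross_check(self):
        from scipy.stats import hypergeom

        rb = sl.random_baseline(30, (152, 9), reps=50_000, seed=11)
        assert rb.analytic_tp == pytest.approx(30 * 9 / 152)
        assert rb.analytic_tp == pytest.approx(hypergeom(152, 9, 30).mean())
        assert abs(rb.expected_tp - rb.analytic_tp) < 3 * rb.tp_std_error

    @pytest.mark.parametrize("n_total,k,n_pred", [(152, 9, 30), (153, 8, 15),
                                                  (153, 17, 14), (40, 5, 10)])
    def test_monte_carlo_within_three_standard_errors(self, n_total, k, n_pred):
        rb = sl.random_baseline(n_pred, (n_total, k), reps=50_000, seed=3)
        assert abs(rb.expected_tp - rb.analytic_tp) < 3 * rb.tp_std_error

    def test_expected_counts_sum_to_universe(self):
        rb = sl.random_baseline(14, (153, 17), reps=2000, seed=1)
        total = (rb.expected_tp + rb.expected_fp + rb.expected_tn + rb.expected_fn)
        assert total == pytest.approx(153)

    def test_overdrawn_rejected(self):
        with pytest.raises(ScreenError):
            sl.random_baseline(200, (152, 9))

    def test_seed_reproducibility(self):
        a = sl.random_baseline(30, (152, 9), reps=5000, seed=42)
        b = sl.random_baseline(30, (152, 9), reps=5000, seed=42)
        assert a.expected_tp == b.expected_tp


class TestScreenIO:
    def test_csv_round_trip(self, tmp_path, bundle):
        path = tmp_path / "screen.csv"
        sl.write_screen_csv(list(bundle.screen_records), path)
        back = sl.read_screen_csv(path)
        orig = {r.pair: sl.hsa_excess(r).mean for r in bundle.screen_records}
        again = {r.pair: sl.hsa_excess(r).mean for r in back}
        assert {p: pytest.approx(m) for p, m in orig.items()} == again

    def test_score_screen_recovers_planted_calls(self, bundle, observed):
        assert {p for p, c in observed.calls.items() if c} == set(bundle.planted_synergies)
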