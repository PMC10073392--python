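import numpy as np
import pandas as pd
import pytest

from wpaimc import reference_tables as ref
from wpaimc.thresholds import (
    auc_band,
    classification_metrics,
    consensus_threshold,
    default_cutoff_grid,
    ecdf_by_group,
    fit_logistic_auc,
    misclassification_rate,
    optimal_cutoff,
    roc_grid,
)


def make_change_data(rng, n=120, effect=-18.0, p=0.35, noise=10.0):
    responder = rng.random(n) < p
    change = rng.normal(-3, noise, n) + effect * responder
    return responder, change


class TestFitLogisticAuc:
    def test_auc_equals_pairwise_concordance_oracle(self, rng):
        responder, change = make_change_data(rng, n=60)
        _, _, auc, _, _ = fit_logistic_auc(responder, change)
        # O(n^2) oracle: responder below non-responder counts 1, tie 1/2
        num = tot = 0.0
        for cr in change[responder]:
            for cn in change[~responder]:
                num += 1.0 if cr < cn else (0.5 if cr == cn else 0.0)
                tot += 1
        assert auc == pytest.approx(num / tot, abs=1e-12)

    def test_perfect_separation(self, rng):
        change = rng.normal(0, 10, 40)
        responder = change < np.median(change)
        _, _, auc, band, converged = fit_logistic_auc(responder, change)
        assert auc == 1.0 and band == "outstanding"
        assert not converged

    def test_chance_labels(self, rng):
        responder = rng.random(4000) < 0.5
        change = rng.normal(0, 10, 4000)
        *_, auc, _, _ = fit_logistic_auc(responder, change)
        assert auc == pytest.approx(0.5, abs=0.03)

    def test_auc_invariant_under_monotone_transform(self, rng):
        responder, change = make_change_data(rng)
        *_, a1, _, _ = fit_logistic_auc(responder, change)
        *_, a2, _, _ = fit_logistic_auc(responder, np.exp(change / 20.0))
        assert a1 == pytest.approx(a2, abs=1e-12)

    def test_requires_both_classes(self):
        with pytest.raises(ValueError):
            fit_logistic_auc([True] * 12, list(range(12)))

    @pytest.mark.parametrize("auc,label", [
        (0.55, "poor"), (0.75, "good"), (0.85, "excellent"), (0.95, "outstanding"),
    ])
    def test_auc_bands(self, auc, label):
        assert auc_band(auc) == label


class TestRocGrid:
    def test_published_row_reconstruction(self):
        """A 2x2 rebuilt from the published sensitivity/specificity and
        responder counts reproduces the printed PPV, NPV, Youden and phi."""
        # presenteeism vs MSQ-RFR at cut-off -19.99: 80 responders, 204 non
        row = classification_metrics(tp=53, fn=27, tn=154, fp=50)
        assert row.sensitivity == pytest.approx(0.6625, abs=5e-5)
        assert row.specificity == pytest.approx(0.7549, abs=5e-5)
        assert row.ppv == pytest.approx(0.5146, abs=5e-5)
        assert row.npv == pytest.approx(0.8508, abs=5e-5)
        assert row.youden == pytest.approx(0.4174, abs=1e-4)
        assert row.phi == pytest.approx(0.3905, abs=5e-5)

    def test_perfect_classifier(self):
        responder = np.array([True] * 5 + [False] * 5)
        change = np.array([-30.0] * 5 + [5.0] * 5)
        g = roc_grid(responder, change, cutoffs=[-10.0])
        assert g.loc[0, "youden"] == 1.0 and g.loc[0, "phi"] == 1.0

    def test_prediction_convention_le(self):
        # equality with the cutoff counts as predicted responder
        g = roc_grid(np.array([True, False]), np.array([-20.0, 0.0]),
                     cutoffs=[-20.0])
        assert g.loc[0, "tp"] == 1 and g.loc[0, "fn"] == 0

    def test_monotone_sens_spec_in_cutoff(self, rng):
        responder, change = make_change_data(rng)
        g = roc_grid(responder, change)
        assert (np.diff(g["sensitivity"]) >= -1e-12).all()
        assert (np.diff(g["specificity"]) <= 1e-12).all()

    def test_phi_equals_pearson_of_binaries(self, rng):
        responder, change = make_change_data(rng, n=80)
        g = roc_grid(responder, change, cutoffs=[-20.0, -10.0, 0.0])
        for _, row in g.iterrows():
            pred = change <= row["cutoff"]
            r = np.corrcoef(pred.astype(float), responder.astype(float))[0, 1]
            assert row["phi"] == pytest.approx(r, abs=1e-12)

    def test_default_grid_includes_coarse_and_observed(self, rng):
        change = np.array([-33.3, -12.2, 4.4])
        grid = default_cutoff_grid(change)
        assert {-60.0, -50.0, -20.0, 0.0} <= set(grid)
        assert {-33.3, -12.2, 4.4} <= set(grid)

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            roc_grid([True, True], [-1.0, -2.0])


class TestOptimalCutoff:
    def test_argmax_youden(self):
        g = pd.DataFrame({"cutoff": [-30.0, -20.0, -10.0],
                          "youden": [0.3470, 0.3720, 0.3360]})
        assert optimal_cutoff(g) == -20.0

    def test_single_row(self):
        g = pd.DataFrame({"cutoff": [-25.0], "youden": [0.1]})
        assert optimal_cutoff(g) == -25.0

    def test_tie_breaks_toward_smallest_magnitude(self):
        g = pd.DataFrame({"cutoff": [-30.0, -10.0], "youden": [0.4, 0.4]})
        assert optimal_cutoff(g) == -10.0


class TestConsensus:
    def test_published_presenteeism_grids_give_minus_20(self):
        grids = {
            a: g for a, g in ref.roc_reference().query(
                "domain == 'presenteeism'").groupby("anchor")
        }
        value, detail = consensus_threshold(grids, grid_step=10.0)
        assert value == -20.0
        assert set(detail["anchor"]) == {"MHD50", "MSQ_RFP", "MSQ_RFR"}
        assert (detail["youden"] >= 0.34).all()

    def test_single_anchor_equals_rounded_optimal(self):
        g = pd.DataFrame({"cutoff": [-28.7, -19.2, -9.6],
                          "youden": [0.2, 0.5, 0.3],
                          "phi": [0.2, 0.5, 0.3],
                          "sensitivity": [0.5, 0.6, 0.7],
                          "specificity": [0.9, 0.8, 0.6]})
        value, _ = consensus_threshold({"A": g})
        assert value == -20.0

    def test_constructed_max_min_at_minus_30(self):
        def mk(yi_by_cut):
            return pd.DataFrame({
                "cutoff": list(yi_by_cut), "youden": list(yi_by_cut.values()),
                "phi": 0.3, "sensitivity": 0.5, "specificity": 0.8})
        grids = {
            "A": mk({-30.0: 0.50, -20.0: 0.20}),
            "B": mk({-30.0: 0.45, -20.0: 0.60}),
        }
        value, _ = consensus_threshold(grids)
        assert value == -30.0

    def test_disjoint_supports_error(self):
        a = pd.DataFrame({"cutoff": [-40.0], "youden": [0.3],
                          "phi": [0.1], "sensitivity": [0.5], "specificity": [0.5]})
        b = pd.DataFrame({"cutoff": [-10.0], "youden": [0.3],
                          "phi": [0.1], "sensitivity": [0.5], "specificity": [0.5]})
        with pytest.raises(ValueError, match="disjoint"):
            consensus_threshold({"A": a, "B": b})


class TestMisclassification:
    def test_one_minus_specificity(self):
        g = pd.DataFrame({"cutoff": [-19.97], "specificity": [0.6270]})
        assert misclassification_rate(g, -20.0) == pytest.approx(0.373)

    def test_direct_count_ratio(self):
        row = classification_metrics(tp=53, fn=27, tn=154, fp=50, cutoff=-20.0)
        g = pd.DataFrame([row.__dict__])
        assert misclassification_rate(g, -20.0) == pytest.approx(50 / 204)

    def test_perfect_specificity(self):
        g = pd.DataFrame({"cutoff": [-20.0], "specificity": [1.0]})
        assert misclassification_rate(g, -20.0) == 0.0


class TestEcdf:
    def test_single_value_group(self):
        curves = ecdf_by_group(np.array([-5.0, 1.0, 2.0]),
                               np.array([True, False, False]))
        resp = curves[True]
        assert resp["x"].tolist() == [-5.0] and resp["F"].tolist() == [1.0]

    def test_gap_equals_youden_identity(self, rng):
        responder, change = make_change_data(rng, n=90)
        g = roc_grid(responder, change)
        curves = ecdf_by_group(change, responder)

        def F(curve, x):
            below = curve[curve["x"] <= x]
            return 0.0 if below.empty else float(below["F"].iloc[-1])

        for c in (-25.0, -10.0, 0.0):
            gap = F(curves[True], c) - F(curves[False], c)
            yi = g.loc[(g["cutoff"] - c).abs().idxmin(), "youden"]
            g_at = roc_grid(responder, change, cutoffs=[c])
            assert gap == pytest.approx(g_at.loc[0, "youden"], abs=1e-12)

    def test_max_gap_equals_max_youden(self, rng):
        """Youden-optimal cut-off is the Kolmogorov-Smirnov point of the
        two group eCDFs."""
        responder, change = make_change_data(rng, n=150)
        g = roc_grid(responder, change, cutoffs=np.unique(change))
        curves = ecdf_by_group(change, responder)
        xs = np.unique(change)
        gaps = []
        for x in xs:
            Ft = float(curves[True].loc[curves[True]["x"] <= x, "F"].max() or 0)
            Fn_ser = curves[False].loc[curves[False]["x"] <= x, "F"]
            Fn = float(Fn_ser.iloc[-1]) if len(Fn_ser) else 0.0
            Ft_ser = curves[True].loc[curves[True]["x"] <= x, "F"]
            Ft = float(Ft_ser.iloc[-1]) if len(Ft_ser) else 0.0
            gaps.append(Ft - Fn)
        assert max(gaps) == pytest.approx(g["youden"].max(), abs=1e-12)
        assert xs[int(np.argmax(gaps))] == optimal_cutoff(g)
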