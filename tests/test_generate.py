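import numpy as np
import pandas as pd
import pytest

from wpaimc.anchors import anchor_status_table
from wpaimc.diary import summarize_diary
from wpaimc.generate import (
    ANCHOR_DATE,
    ConfigError,
    GeneratorConfig,
    apply_missingness,
    generate_trial,
)


class TestConfig:
    @pytest.mark.parametrize("bad", [
        dict(n_subjects=-1), dict(placebo_fraction=1.5),
        dict(cm_fraction=-0.1), dict(missing_item_rate=2.0),
        dict(baseline_sds={"presenteeism": -1.0}),
    ])
    def test_invalid_config_rejected(self, bad):
        with pytest.raises(ConfigError):
            generate_trial(GeneratorConfig(**bad))

    def test_yaml_roundtrip(self, tmp_path):
        p = tmp_path / "cfg.yaml"
        p.write_text("n_subjects: 12\nseed: 9\ntreatment_effect: 0.5\n")
        cfg = GeneratorConfig.from_yaml(p)
        assert (cfg.n_subjects, cfg.seed, cfg.treatment_effect) == (12, 9, 0.5)


class TestGenerateTrial:
    def test_empty_trial(self):
        d = generate_trial(GeneratorConfig(n_subjects=0))
        assert d.visits.empty and d.diary.empty

    def test_seed_determinism(self):
        cfg = GeneratorConfig(n_subjects=40, seed=7)
        a, b = generate_trial(cfg), generate_trial(cfg)
        assert a.visits.to_csv() == b.visits.to_csv()
        assert a.diary.to_csv() == b.diary.to_csv()
        c = generate_trial(GeneratorConfig(n_subjects=40, seed=8))
        assert a.visits.to_csv() != c.visits.to_csv()

    def test_default_moments_match_published_baseline(self):
        """Baseline presenteeism and MHD means land near the published
        overall-population moments at the trial's size."""
        d = generate_trial(GeneratorConfig(seed=31))  # n = 444
        base = d.visits[d.visits["visit"] == "baseline"]
        pres = 10.0 * base["q5_presenteeism_0_10"].dropna()
        assert pres.mean() == pytest.approx(42.75, abs=3.0)
        summary = summarize_diary(d.diary, ANCHOR_DATE)
        mhd = summary[(summary["period"] == "baseline") & ~summary["missing"]]
        assert mhd["mhd_adjusted"].mean() == pytest.approx(13.12, abs=0.8)

    def test_unemployed_have_no_work_items(self, default_trial):
        v = default_trial.visits
        unemp = v[~v["employed"]]
        assert len(unemp) > 0
        for col in ("q2_hours_missed_migraine", "q4_hours_worked",
                    "q5_presenteeism_0_10"):
            assert unemp[col].isna().all()
        assert unemp["q6_activity_0_10"].notna().all()

    def test_item_ranges_valid(self, default_trial):
        v = default_trial.visits
        for col in ("q5_presenteeism_0_10", "q6_activity_0_10"):
            vals = v[col].dropna()
            assert vals.between(0, 10).all()
            assert (vals == vals.astype(int)).all()
        for col in ("q2_hours_missed_migraine", "q3_hours_missed_other",
                    "q4_hours_worked"):
            assert (v[col].dropna() >= 0).all()

    def test_treatment_effect_raises_mhd_responder_rate(self):
        """A larger treatment effect strictly increases active-arm MHD50
        response (averaged over seeds)."""
        from wpaimc.pipeline import _subject_table

        rates = []
        for effect in (0.0, 0.8, 1.6):
            per_seed = []
            for seed in (1, 2, 3):
                d = generate_trial(GeneratorConfig(
                    n_subjects=150, seed=seed, treatment_effect=effect))
                subj, _ = _subject_table(d)
                st = anchor_status_table(subj)
                act = subj.loc[subj["arm"] == "active", "subject_id"]
                sub = st[(st["anchor"] == "MHD50")
                         & st["subject_id"].isin(act)]
                per_seed.append(sub["responder"].mean())
            rates.append(np.mean(per_seed))
        assert rates[0] < rates[1] < rates[2]

    def test_moment_calibration_improves_with_n(self):
        """Generated baseline means converge toward the configured moments
        within standard-error bounds."""
        d = generate_trial(GeneratorConfig(n_subjects=2000, seed=5))
        base = d.visits[d.visits["visit"] == "baseline"]
        act = 10.0 * base["q6_activity_0_10"]
        se = 23.91 / np.sqrt(len(act))
        # allow truncation/rounding bias of ~1.5 units plus 4 SEs
        assert abs(act.mean() - 50.97) < 1.5 + 4 * se
        assert base["msq_rfp"].mean() == pytest.approx(63.78, abs=1.5 + 4 * se)


class TestApplyMissingness:
    def test_rate_zero_is_identity(self, default_trial):
        out = apply_missingness(default_trial, 0.0, seed=1, diary_rate=0.0)
        pd.testing.assert_frame_equal(out.visits, default_trial.visits)
        pd.testing.assert_frame_equal(out.diary, default_trial.diary)

    def test_rate_one_blanks_all_month3_items(self, default_trial):
        out = apply_missingness(default_trial, 1.0, seed=1)
        m3 = out.visits[out.visits["visit"] == "month3"]
        assert m3["q6_activity_0_10"].isna().all()
        base = out.visits[out.visits["visit"] == "baseline"]
        assert base["q6_activity_0_10"].notna().all()

    def test_rate_within_binomial_bounds(self, default_trial):
        out = apply_missingness(default_trial, 0.1, seed=3)
        m3_before = default_trial.visits[default_trial.visits["visit"] == "month3"]
        m3_after = out.visits[out.visits["visit"] == "month3"]
        n = int(m3_before["q6_activity_0_10"].notna().sum())
        k = int(m3_after["q6_activity_0_10"].isna().sum())
        # 99% binomial interval around n * 0.1
        sd = np.sqrt(n * 0.1 * 0.9)
        assert abs(k - 0.1 * n) < 2.6 * sd

    def test_invalid_rate(self, default_trial):
        with pytest.raises(ConfigError):
            apply_missingness(default_trial, 1.2, seed=0)
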