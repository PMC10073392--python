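"""Synthetic two-visit migraine trial generator.

Emulates a CONQUER-like placebo-controlled preventive-treatment trial at the
level needed by the validation pipeline: a visit table with the six WPAI
items and MSQ Role Function domain scores at baseline and Month 3, and a
daily headache diary covering the 30-day baseline window and the Month-3
window (days 61-90 after randomization).

Subjects are assigned an arm (1:1 by default), an episodic/chronic migraine
subtype, and an employment flag.  Baseline domain scores are drawn from
truncated normals matched to the published baseline moments, correlated
across measures through a latent severity factor (WPAI and migraine days
load positively, MSQ negatively), and WPAI items are constructed backwards
from the target scores.  Improvement from baseline
to Month 3 is driven by a single subject-level latent factor shared across
all measures (plus measure-specific noise), which is what makes WPAI change
correlate with the anchors; the active arm receives an extra
``treatment_effect`` shift on the factor.  ``true_mwpc`` sets the built-in
meaningful-change point: the WPAI loadings are scaled so that the expected
WPAI improvement of a subject right at the MSQ-RFP responder boundary equals
``true_mwpc`` % units, which threshold-recovery tests can then look for.

Diary days are simulated marginally: each day is a migraine headache day with
probability MHD/30 (a quarter of those as probable migraine), a non-migraine
headache day with probability (HD - MHD)/30, with features drawn to satisfy
(or fail) the migraine definition accordingly.  Only monthly counts matter
downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

__all__ = [
    "GeneratorConfig", "TrialData", "generate_trial", "apply_missingness",
    "write_dataset", "read_dataset",
]

ANCHOR_DATE = pd.Timestamp("2020-01-01")

#: published overall-population baseline moments (mean, sd)
DEFAULT_MOMENTS = {
    "presenteeism": (42.75, 23.24),
    "absenteeism": (9.37, 17.85),
    "activity": (50.97, 23.91),
    "msq_rfr": (45.05, 17.16),
    "msq_rfp": (63.78, 19.15),
    "mhd_em": (9.30, 2.84),
    "mhd_cm": (18.58, 4.72),
}

#: latent-factor loadings (units of the measure per 1 sd of the factor)
DEFAULT_LOADINGS = {
    "presenteeism": 15.0,
    "activity": 15.0,
    "msq_rfr": 16.0,
    "msq_rfp": 15.0,
    "mhd": 4.0,
}

#: share of each baseline measure's sd carried by the latent severity factor
#: (signed: WPAI and MHD load positively, MSQ negatively)
BASELINE_SEVERITY_LOADING = 0.5

#: measure-specific change noise (sd, same units as the measure)
DEFAULT_NOISE = {
    "presenteeism": 14.0,
    "activity": 14.0,
    "msq_rfr": 13.0,
    "msq_rfp": 13.0,
    "mhd": 3.0,
}


class ConfigError(ValueError):
    """Invalid generator configuration."""


@dataclass(frozen=True)
class GeneratorConfig:
    n_subjects: int = 444
    placebo_fraction: float = 0.5
    cm_fraction: float = 183 / 444
    employed_fraction: float = 315 / 444
    baseline_means: dict = field(
        default_factory=lambda: {k: v[0] for k, v in DEFAULT_MOMENTS.items()})
    baseline_sds: dict = field(
        default_factory=lambda: {k: v[1] for k, v in DEFAULT_MOMENTS.items()})
    latent_improvement_loading: dict = field(
        default_factory=lambda: dict(DEFAULT_LOADINGS))
    noise_sd: dict = field(default_factory=lambda: dict(DEFAULT_NOISE))
    treatment_effect: float = 0.9
    true_mwpc: float = 20.0
    missing_item_rate: float = 0.08
    missing_diary_rate: float = 0.02
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 0:
            raise ConfigError(f"n_subjects must be >= 0, got {self.n_subjects}")
        for name in ("placebo_fraction", "cm_fraction", "employed_fraction",
                     "missing_item_rate", "missing_diary_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        for k, v in self.baseline_sds.items():
            if v < 0:
                raise ConfigError(f"baseline sd for {k} must be >= 0, got {v}")
        if self.true_mwpc <= 0:
            raise ConfigError("true_mwpc must be a positive improvement magnitude")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GeneratorConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def with_seed(self, seed: int) -> "GeneratorConfig":
        return replace(self, seed=seed)


@dataclass
class TrialData:
    """A generated dataset: visit table plus daily diary table."""

    visits: pd.DataFrame
    diary: pd.DataFrame


VISIT_COLUMNS = [
    "subject_id", "arm", "subtype", "employed", "visit",
    "q1_employed", "q2_hours_missed_migraine", "q3_hours_missed_other",
    "q4_hours_worked", "q5_presenteeism_0_10", "q6_activity_0_10",
    "msq_rfr", "msq_rfp",
]

DIARY_COLUMNS = [
    "subject_id", "date", "headache", "duration_ge_30min", "unilateral",
    "pulsating", "mod_severe", "aggravation", "nausea_vomiting",
    "photophobia", "phonophobia",
]


def _truncnorm(rng, mean, sd, lo, hi, size=None):
    if sd == 0:
        return np.full(size if size is not None else (), float(np.clip(mean, lo, hi)))
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size,
                               random_state=rng)


def _migraine_day_features(rng) -> dict:
    """Feature flags satisfying the full migraine definition."""
    chars = np.zeros(4, dtype=bool)
    chars[rng.choice(4, size=rng.integers(2, 5), replace=False)] = True
    nausea = rng.random() < 0.6
    photo_phono = (not nausea) or rng.random() < 0.4
    return _day(True, True, chars, nausea, photo_phono, photo_phono)


def _probable_day_features(rng) -> dict:
    """One feature short of the full definition."""
    if rng.random() < 0.5:  # one characteristic short, symptoms present
        chars = np.zeros(4, dtype=bool)
        chars[rng.integers(4)] = True
        nausea = rng.random() < 0.6
        pp = not nausea
        return _day(True, True, chars, nausea, pp, pp)
    chars = np.zeros(4, dtype=bool)  # characteristics ok, no symptoms
    chars[rng.choice(4, size=rng.integers(2, 5), replace=False)] = True
    return _day(True, True, chars, False, False, False)


def _nonmigraine_day_features(rng) -> dict:
    """A headache day failing the migraine definition by two features."""
    if rng.random() < 0.2:  # too short
        return _day(True, False, np.zeros(4, bool), False, False, False)
    chars = np.zeros(4, dtype=bool)
    if rng.random() < 0.5:
        chars[rng.integers(4)] = True
    return _day(True, True, chars, False, False, False)


def _day(headache, dur, chars, nausea, photo, phono) -> dict:
    return {
        "headache": headache, "duration_ge_30min": dur,
        "unilateral": bool(chars[0]), "pulsating": bool(chars[1]),
        "mod_severe": bool(chars[2]), "aggravation": bool(chars[3]),
        "nausea_vomiting": nausea, "photophobia": photo, "phonophobia": phono,
    }


def _simulate_period(rng, mhd_target, hd_target, offsets, subject_id):
    """One 30-day diary window with the requested expected day counts."""
    rows = []
    p_mig = np.clip(mhd_target / 30.0, 0, 1)
    p_hd = np.clip(hd_target / 30.0, p_mig, 1)
    for off in offsets:
        u = rng.random()
        if u < p_mig:
            feats = (_probable_day_features(rng) if rng.random() < 0.25
                     else _migraine_day_features(rng))
        elif u < p_hd:
            feats = _nonmigraine_day_features(rng)
        else:
            feats = _day(False, False, np.zeros(4, bool), False, False, False)
        rows.append({
            "subject_id": subject_id,
            "date": (ANCHOR_DATE + pd.Timedelta(days=int(off))).date().isoformat(),
            **feats,
        })
    return rows


def _wpai_items(rng, employed, presenteeism, absenteeism, activity):
    """Construct item responses whose derived scores hit the targets."""
    q6 = int(np.clip(round(activity / 10.0), 0, 10))
    if not employed:
        return {"q1_employed": False, "q2_hours_missed_migraine": np.nan,
                "q3_hours_missed_other": np.nan, "q4_hours_worked": np.nan,
                "q5_presenteeism_0_10": np.nan, "q6_activity_0_10": q6}
    q5 = int(np.clip(round(presenteeism / 10.0), 0, 10))
    q4 = float(np.round(np.clip(rng.normal(36.0, 8.0), 4.0, 60.0) * 2) / 2)
    a = min(absenteeism / 100.0, 0.9)
    q2 = float(np.round(q4 * a / (1.0 - a), 1))
    q3 = float(np.round(rng.exponential(1.0), 1))
    return {"q1_employed": True, "q2_hours_missed_migraine": q2,
            "q3_hours_missed_other": q3, "q4_hours_worked": q4,
            "q5_presenteeism_0_10": q5, "q6_activity_0_10": q6}


def generate_trial(config: GeneratorConfig) -> TrialData:
    """Generate a complete synthetic trial dataset.

    Deterministic given the config (including its seed).  Returns a visit
    table (two rows per subject) and a daily diary covering the baseline and
    Month-3 windows.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    means, sds = config.baseline_means, config.baseline_sds
    lam = dict(config.latent_improvement_loading)
    # scale WPAI loadings so the expected WPAI improvement at the MSQ-RFP
    # responder boundary equals true_mwpc
    wpai_scale = (config.true_mwpc / 20.0)
    noise = config.noise_sd

    visit_rows: list[dict] = []
    diary_rows: list[dict] = []

    for i in range(config.n_subjects):
        sid = f"S{i + 1:04d}"
        arm = "placebo" if rng.random() < config.placebo_fraction else "active"
        is_cm = rng.random() < config.cm_fraction
        employed = rng.random() < config.employed_fraction

        # latent baseline severity shared across measures (worse = larger)
        sev = rng.normal()
        w = BASELINE_SEVERITY_LOADING
        res = np.sqrt(1.0 - w * w)

        def _baseline(key, lo, hi, sign):
            return float(_truncnorm(
                rng, means[key] + sign * w * sds[key] * sev,
                res * sds[key], lo, hi))

        if is_cm:
            mhd_b = _baseline("mhd_cm", 8, 29, +1)
            hd_b = min(29.0, max(15.0, mhd_b + rng.poisson(3.0)))
        else:
            mhd_b = _baseline("mhd_em", 4, 14, +1)
            hd_b = min(14.0, mhd_b + rng.poisson(1.5))
        subtype = "CM" if is_cm else "EM"

        pres_b = _baseline("presenteeism", 0, 100, +1)
        abs_b = _baseline("absenteeism", 0, 95, +1)
        act_b = _baseline("activity", 0, 100, +1)
        rfr_b = _baseline("msq_rfr", 0, 100, -1)
        rfp_b = _baseline("msq_rfp", 0, 100, -1)

        f = rng.normal() + (config.treatment_effect if arm == "active" else 0.0)

        d_pres = -(wpai_scale * lam["presenteeism"] * f + rng.normal(0, noise["presenteeism"]))
        d_abs = -(0.3 * wpai_scale * lam["presenteeism"] * f + rng.normal(0, 0.5 * noise["presenteeism"]))
        d_act = -(wpai_scale * lam["activity"] * f + rng.normal(0, noise["activity"]))
        d_rfr = lam["msq_rfr"] * f + rng.normal(0, noise["msq_rfr"])
        d_rfp = lam["msq_rfp"] * f + rng.normal(0, noise["msq_rfp"])
        d_mhd = lam["mhd"] * f + rng.normal(0, noise["mhd"])

        pres_3 = float(np.clip(pres_b + d_pres, 0, 100))
        abs_3 = float(np.clip(abs_b + d_abs, 0, 95))
        act_3 = float(np.clip(act_b + d_act, 0, 100))
        rfr_3 = float(np.clip(rfr_b + d_rfr, 0, 100))
        rfp_3 = float(np.clip(rfp_b + d_rfp, 0, 100))
        mhd_3 = float(np.clip(mhd_b - d_mhd, 0, 29))
        hd_3 = min(29.0, max(mhd_3, hd_b - d_mhd))

        for visit, pres, ab, act, rfr, rfp in (
            ("baseline", pres_b, abs_b, act_b, rfr_b, rfp_b),
            ("month3", pres_3, abs_3, act_3, rfr_3, rfp_3),
        ):
            visit_rows.append({
                "subject_id": sid, "arm": arm, "subtype": subtype,
                "employed": employed, "visit": visit,
                **_wpai_items(rng, employed, pres, ab, act),
                "msq_rfr": round(rfr, 2), "msq_rfp": round(rfp, 2),
            })

        diary_rows += _simulate_period(rng, mhd_b, hd_b, range(-30, 0), sid)
        diary_rows += _simulate_period(rng, mhd_3, hd_3, range(61, 91), sid)

    visits = pd.DataFrame(visit_rows, columns=VISIT_COLUMNS)
    diary = pd.DataFrame(diary_rows, columns=DIARY_COLUMNS)
    return TrialData(visits=visits, diary=diary)


_MISSABLE_ITEMS = [
    "q2_hours_missed_migraine", "q3_hours_missed_other", "q4_hours_worked",
    "q5_presenteeism_0_10", "q6_activity_0_10",
]


def apply_missingness(
    data: TrialData, item_rate: float, seed: int, diary_rate: float = 0.0
) -> TrialData:
    """Blank Month-3 WPAI items and drop diary days completely at random.

    Each non-missing Month-3 item cell is set missing independently with
    probability ``item_rate``; each diary day is removed with probability
    ``diary_rate``.  Deterministic under the seed.
    """
    for name, rate in (("item_rate", item_rate), ("diary_rate", diary_rate)):
        if not 0 <= rate <= 1:
            raise ConfigError(f"{name} must be in [0, 1], got {rate}")
    rng = np.random.default_rng(seed)
    visits = data.visits.copy()
    mask_rows = visits["visit"] == "month3"
    for col in _MISSABLE_ITEMS:
        eligible = mask_rows & visits[col].notna()
        hit = rng.random(len(visits)) < item_rate
        sel = eligible & hit
        if sel.any():
            visits[col] = visits[col].astype(float)
            visits.loc[sel, col] = np.nan
    keep = rng.random(len(data.diary)) >= diary_rate
    diary = data.diary[keep].reset_index(drop=True)
    return TrialData(visits=visits, diary=diary)


def write_dataset(data: TrialData, outdir: str | Path) -> tuple[Path, Path]:
    """Write visits.csv and diary.csv; returns the two paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    vpath, dpath = outdir / "visits.csv", outdir / "diary.csv"
    data.visits.to_csv(vpath, index=False)
    data.diary.to_csv(dpath, index=False)
    return vpath, dpath


def read_dataset(visits_path: str | Path, diary_path: str | Path) -> TrialData:
    """Load a dataset from the visits.csv / diary.csv pair."""
    visits = pd.read_csv(visits_path)
    missing = set(VISIT_COLUMNS) - set(visits.columns)
    if missing:
        raise ValueError(f"visits table missing columns: {sorted(missing)}")
    diary = pd.read_csv(diary_path)
    missing = set(DIARY_COLUMNS) - set(diary.columns)
    if missing:
        raise ValueError(f"diary table missing columns: {sorted(missing)}")
    return TrialData(visits=visits, diary=diary)
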