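"""Episode construction, Weibull TD likelihood, prediction and Kaplan-Meier."""

import numpy as np
import pandas as pd
import pytest

import glaucodrive as gd
from glaucodrive.survival import NoEventsError, WeibullTDModel, build_episodes


def subjects_frame(rows):
    return pd.DataFrame(rows, columns=["subject_id", "event", "event_time", "followup_years"])


def visits_frame(rows):
    return pd.DataFrame(rows, columns=["subject_id", "time", "x"])


@pytest.fixture(scope="module")
def toy_tables():
    subjects = subjects_frame(
        [("s1", True, 0.8, 0.8), ("s2", False, 1.0, 1.0), ("s3", False, 0.5, 0.5)]
    )
    visits = visits_frame(
        [
            ("s1", 0.0, 1.0), ("s1", 0.5, 2.0),
            ("s2", 0.0, 3.0), ("s2", 0.5, 4.0), ("s2", 1.0, 5.0),
            ("s3", 0.0, 5.0),
        ]
    )
    return subjects, visits


class TestBuildEpisodes:
    def test_event_subject_split_at_visits(self, toy_tables):
        ep = build_episodes(*toy_tables, covariates=["x"])
        s1 = ep.data[ep.data["subject_id"] == "s1"]
        assert list(zip(s1["start"], s1["stop"], s1["event"])) == [
            (0.0, 0.5, False),
            (0.5, 0.8, True),
        ]
        # covariates carried forward from the covering visit
        mean, sd = ep.standardization["x"]
        np.testing.assert_allclose(s1["x"], (np.array([1.0, 2.0]) - mean) / sd)

    def test_censored_subject_has_no_event_row(self, toy_tables):
        ep = build_episodes(*toy_tables, covariates=["x"])
        s2 = ep.data[ep.data["subject_id"] == "s2"]
        assert len(s2) == 2 and not s2["event"].any()
        assert s2["stop"].iloc[-1] == 1.0

    def test_time_at_risk_conserved(self, toy_tables):
        ep = build_episodes(*toy_tables, covariates=["x"])
        per_subject = ep.data.groupby("subject_id").apply(
            lambda d: (d["stop"] - d["start"]).sum(), include_groups=False
        )
        # s3 contributes no follow-up beyond baseline
        assert per_subject["s1"] == pytest.approx(0.8)
        assert per_subject["s2"] == pytest.approx(1.0)

    def test_baseline_zscores_standardized(self, small_cohort):
        ep = gd.episodes_from_cohort(small_cohort, ["rt_low", "curve_coherence"])
        base = ep.baseline()
        for c in ["rt_low", "curve_coherence"]:
            assert base[c].mean() == pytest.approx(0.0, abs=1e-10)
            assert base[c].std(ddof=1) == pytest.approx(1.0, abs=1e-10)

    def test_flip_sign_makes_worse_positive(self, small_cohort):
        # coherence is flipped so +1 z-unit means 1 SD *lower* coherence
        ep = gd.episodes_from_cohort(small_cohort, ["curve_coherence"])
        base = ep.baseline()
        raw = pd.concat([s.visits.iloc[[0]] for s in small_cohort if s.group == "glaucoma"])
        worst = raw["curve_coherence"].idxmin()
        assert base["curve_coherence"].max() == pytest.approx(
            -(raw["curve_coherence"].min() - ep.standardization["curve_coherence"][0])
            / ep.standardization["curve_coherence"][1]
        )

    def test_visit_after_event_rejected(self):
        subjects = subjects_frame([("s1", True, 0.4, 0.4), ("s2", False, 1.0, 1.0)])
        visits = visits_frame(
            [("s1", 0.0, 1.0), ("s1", 0.5, 2.0), ("s2", 0.0, 3.0)]
        )
        with pytest.raises(ValueError, match="after follow-up end"):
            build_episodes(subjects, visits, ["x"])

    def test_missing_baseline_covariate_drops_subject(self, toy_tables):
        subjects, visits = toy_tables
        visits = visits.copy()
        visits.loc[(visits["subject_id"] == "s2") & (visits["time"] == 0.0), "x"] = np.nan
        with pytest.warns(UserWarning, match="missing baseline"):
            ep = build_episodes(subjects, visits, ["x"])
        assert "s2" not in set(ep.data["subject_id"])


def random_episodes(rng, n_subjects=40, with_cov=True):
    rows = []
    for i in range(n_subjects):
        t, sid = 0.0, f"s{i}"
        n_ep = rng.integers(1, 4)
        for j in range(n_ep):
            dur = rng.uniform(0.2, 1.0)
            rows.append(
                {
                    "subject_id": sid,
                    "start": t,
                    "stop": t + dur,
                    "event": bool(j == n_ep - 1 and rng.uniform() < 0.4),
                    "x": rng.normal() if with_cov else 0.0,
                }
            )
            t += dur
    return pd.DataFrame(rows)


def subdivide(df, rng):
    rows = []
    for r in df.itertuples(index=False):
        r = r._asdict()
        if rng.uniform() < 0.7:
            mid = rng.uniform(r["start"], r["stop"])
            first = dict(r, stop=mid, event=False)
            second = dict(r, start=mid)
            rows += [first, second]
        else:
            rows.append(r)
    return pd.DataFrame(rows)


class TestWeibullLikelihood:
    def test_invariant_to_episode_subdivision(self, rng):
        df = random_episodes(rng)
        split = subdivide(df, rng)
        m1 = WeibullTDModel(df, covariates=["x"])
        m2 = WeibullTDModel(split, covariates=["x"])
        for _ in range(5):
            params = np.array([rng.normal(), rng.normal(), rng.normal(0, 0.5)])
            a, b = m1.loglik(params), m2.loglik(params)
            assert abs(a - b) <= 1e-10 * max(1.0, abs(a))

    def test_score_matches_finite_differences(self, rng):
        df = random_episodes(rng)
        m = WeibullTDModel(df, covariates=["x"])
        params = np.array([0.3, -0.5, 0.2])
        g = m.score(params)
        eps = 1e-6
        for i in range(3):
            d = np.zeros(3)
            d[i] = eps
            fd = (m.loglik(params + d) - m.loglik(params - d)) / (2 * eps)
            assert g[i] == pytest.approx(fd, rel=1e-5, abs=1e-7)

    def test_exponential_special_case_closed_form(self, rng):
        # data generated with constant hazard (shape 1): the fitted shape CI
        # covers 1 and the rate matches events / time-at-risk
        n = 500
        true_lam = 0.5
        t_event = rng.exponential(1 / true_lam, size=n)
        t_cens = rng.uniform(0.5, 3.0, size=n)
        obs = np.minimum(t_event, t_cens)
        event = t_event <= t_cens
        df = pd.DataFrame(
            {
                "subject_id": [f"s{i}" for i in range(n)],
                "start": 0.0,
                "stop": obs,
                "event": event,
            }
        )
        fit = WeibullTDModel(df, covariates=[]).fit()
        lo, hi = fit.shape_ci
        assert lo <= 1.0 <= hi
        closed_form = event.sum() / obs.sum()
        assert fit.scale == pytest.approx(closed_form, rel=0.10)

    def test_binary_covariate_hr_recovery(self, rng):
        n = 2000
        x = (np.arange(n) % 2).astype(float)
        lam0, hr = 0.3, 2.0
        t_event = rng.exponential(1 / (lam0 * hr**x))
        t_cens = np.full(n, 3.0)
        df = pd.DataFrame(
            {
                "subject_id": [f"s{i}" for i in range(n)],
                "start": 0.0,
                "stop": np.minimum(t_event, t_cens),
                "event": t_event <= t_cens,
                "x": x,
            }
        )
        fit = WeibullTDModel(df, covariates=["x"]).fit()
        assert 1.8 <= fit.hr_table["hr"].iloc[0] <= 2.2

    def test_zero_events_raises(self, rng):
        df = random_episodes(rng)
        df["event"] = False
        with pytest.raises(NoEventsError):
            WeibullTDModel(df, covariates=["x"]).fit()


@pytest.fixture(scope="module")
def fitted():
    cohort = gd.generate_cohort(gd.CohortConfig(n_glaucoma=80, n_controls=0, seed=7))
    ep = gd.episodes_from_cohort(cohort, ["rt_low"])
    return gd.WeibullTDModel(ep).fit()


class TestPrediction:
    def test_survival_starts_at_one(self, fitted):
        curve = fitted.predict_survival([(0.0, [0.5]), (1.0, [1.0])], horizon=3.0)
        assert curve.survival[0] == pytest.approx(1.0)
        assert np.all(np.diff(curve.survival) <= 1e-12)

    def test_baseline_closed_form_at_z_zero(self, fitted):
        curve = fitted.predict_survival([(0.0, [0.0])], horizon=2.0)
        expected = np.exp(-fitted.scale * curve.times**fitted.shape)
        np.testing.assert_allclose(curve.survival, expected, atol=1e-12)

    def test_proportional_hazards_shift_property(self, fitted):
        beta = float(fitted.beta.iloc[0])
        base = fitted.predict_survival([(0.0, [0.2]), (0.7, [0.9])], horizon=2.5)
        delta_z = 0.8
        shifted = fitted.predict_survival(
            [(0.0, [0.2 + delta_z]), (0.7, [0.9 + delta_z])], horizon=2.5
        )
        np.testing.assert_allclose(
            shifted.survival, base.survival ** np.exp(beta * delta_z), rtol=1e-10
        )

    def test_invalid_history_rejected(self, fitted):
        with pytest.raises(ValueError):
            fitted.predict_survival([(0.5, [0.0])], horizon=1.0)
        with pytest.raises(ValueError):
            fitted.predict_survival([(0.0, [0.0])], horizon=-1.0)


def km_oracle(durations, events):
    """Brute-force product over risk sets at each distinct event time."""
    times = sorted(set(t for t, d in zip(durations, events) if d))
    surv, out = 1.0, {}
    for t in times:
        at_risk = sum(u >= t for u in durations)
        d = sum(1 for u, e in zip(durations, events) if e and u == t)
        surv *= 1 - d / at_risk
        out[t] = surv
    return out


class TestKaplanMeier:
    def test_no_censoring_closed_form(self):
        durations = np.arange(1.0, 11.0)
        curve = gd.kaplan_meier(durations, np.ones(10, dtype=bool))
        for k, t in enumerate(durations, start=1):
            idx = np.searchsorted(curve.times, t)
            assert curve.survival[idx] == pytest.approx((10 - k) / 10)

    def test_all_censored_is_flat_one(self):
        curve = gd.kaplan_meier([1.0, 2.0, 3.0], [False] * 3)
        np.testing.assert_allclose(curve.survival, 1.0)

    def test_matches_brute_force_oracle(self, rng):
        durations = np.round(rng.uniform(0.1, 3.0, size=60), 1)
        events = rng.uniform(size=60) < 0.6
        curve = gd.kaplan_meier(durations, events)
        oracle = km_oracle(list(durations), list(events))
        for t, s in oracle.items():
            idx = np.searchsorted(curve.times, t)
            assert curve.survival[idx] == pytest.approx(s, abs=1e-10)
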