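"""Milestone detection, product-limit curves, log-rank and Cox fits,
checked against hand computations and brute-force oracles."""

import numpy as np
import pandas as pd
import pytest

from ch4subtype.survival import (
    MilestoneCriteria,
    cox_fit,
    detect_milestones,
    detect_milestones_table,
    km_estimate,
    logrank_test,
)

CRIT = MilestoneCriteria()


def _events(times, flags, ids=None):
    ids = ids if ids is not None else [f"s{i}" for i in range(len(times))]
    return pd.DataFrame({"subject_id": ids, "time": times, "event": flags})


# --------------------------------------------------------------------------
# milestone detection
# --------------------------------------------------------------------------

class TestDetect:
    def test_moca_crossing(self, toy_visits):
        ev = detect_milestones(toy_visits, CRIT)
        assert ev.event and ev.time == 12.0
        assert ev.first_milestone_type == "moca_lt_cutoff"
        assert not ev.at_baseline

    def test_no_milestone_censors_at_last_visit(self, toy_visits):
        v = toy_visits.copy()
        v["moca"] = [25, 24, 23]
        ev = detect_milestones(v, CRIT)
        assert not ev.event and ev.time == 12.0
        assert ev.first_milestone_type == "none"

    def test_earliest_criterion_wins(self, toy_visits):
        v = toy_visits.copy()
        v["moca"] = [25, 24, 19]       # would fire at month 12
        v.loc[1, "updrs_1_2"] = 3       # hallucinations fire at month 6
        ev = detect_milestones(v, CRIT)
        assert ev.time == 6.0 and ev.first_milestone_type == "updrs_1_2"

    def test_baseline_event_kept_and_flagged(self, toy_visits):
        v = toy_visits.copy()
        v.loc[0, "moca"] = 19
        ev = detect_milestones(v, CRIT)
        assert ev.event and ev.time == 0.0 and ev.at_baseline

    def test_exhaustive_scan_oracle(self, rng):
        """First-passage time matches an independent per-criterion scan."""
        for _ in range(50):
            k = int(rng.integers(2, 8))
            v = pd.DataFrame({
                "subject_id": ["x"] * k,
                "visit_month": np.arange(k) * 6.0,
                "moca": rng.integers(15, 30, k),
                "updrs_1_1": rng.integers(0, 5, k),
                "updrs_1_2": rng.integers(0, 5, k),
                "updrs_1_5": rng.integers(0, 5, k),
                "dementia_clinical": rng.random(k) < 0.1,
                "dementia_composite": rng.random(k) < 0.1,
            })
            hit = (
                (v["moca"] < 21) | (v["updrs_1_1"] >= 3) | (v["updrs_1_2"] >= 3)
                | (v["updrs_1_5"] >= 3) | v["dementia_clinical"]
                | v["dementia_composite"]
            )
            ev = detect_milestones(v, CRIT)
            if hit.any():
                assert ev.event
                assert ev.time == float(v.loc[hit.idxmax(), "visit_month"])
            else:
                assert not ev.event and ev.time == v["visit_month"].iloc[-1]

    def test_monotone_in_cutoffs(self, toy_visits):
        """Loosening the MoCA cutoff never delays the event."""
        strict = detect_milestones(toy_visits, MilestoneCriteria(moca_cutoff=21))
        loose = detect_milestones(toy_visits, MilestoneCriteria(moca_cutoff=24))
        assert loose.time <= strict.time

    def test_empty_and_unsorted_rejected(self, toy_visits):
        with pytest.raises(ValueError):
            detect_milestones(toy_visits.iloc[:0], CRIT)
        with pytest.raises(ValueError, match="increasing"):
            detect_milestones(toy_visits.iloc[::-1], CRIT)


# --------------------------------------------------------------------------
# Kaplan-Meier
# --------------------------------------------------------------------------

class TestKM:
    def test_no_censoring_equals_empirical_survival(self):
        km = km_estimate(_events([1.0, 2.0, 3.0], [True, True, True]))
        s = dict(zip(km["time"], km["survival"]))
        assert s[1.0] == pytest.approx(2 / 3)
        assert s[2.0] == pytest.approx(1 / 3)
        assert s[3.0] == pytest.approx(0.0)

    def test_early_censor_leaves_curve_at_one(self):
        km = km_estimate(_events([5.0, 8.0], [False, True]))
        before = km[km["time"] < 8.0]["survival"]
        assert np.all(before == 1.0)

    def test_product_limit_hand_computation(self):
        # events at 2 and 4, censor at 3: S(4) = (1 - 1/3)(1 - 1/1) = 0
        km = km_estimate(_events([2.0, 3.0, 4.0], [True, False, True]))
        s = dict(zip(km["time"], km["survival"]))
        assert s[2.0] == pytest.approx(2 / 3)
        assert s[4.0] == pytest.approx(0.0)

    def test_curve_starts_at_one_and_never_rises(self, pdmci):
        cohort, _, _ = pdmci
        km = km_estimate(cohort.rename(columns={"event_time": "time"}))
        assert km["survival"].iloc[0] == 1.0
        assert np.all(np.diff(km["survival"]) <= 1e-12)
        assert np.all(np.diff(km["at_risk"]) < 0)

    def test_negative_times_rejected(self):
        with pytest.raises(ValueError):
            km_estimate(_events([-1.0, 2.0], [True, True]))


# --------------------------------------------------------------------------
# log-rank
# --------------------------------------------------------------------------

def logrank_oracle(ta, ea, tb, eb):
    """Brute-force observed-minus-expected tabulation over event times."""
    times = sorted(set(list(ta[ea]) + list(tb[eb])))
    O_E = V = 0.0
    for t in times:
        na = np.sum(ta >= t)
        nb = np.sum(tb >= t)
        da = np.sum((ta == t) & ea)
        db = np.sum((tb == t) & eb)
        n, d = na + nb, da + db
        if n < 2:
            continue
        expected_a = d * na / n
        O_E += da - expected_a
        V += d * (na / n) * (nb / n) * (n - d) / (n - 1)
    return O_E ** 2 / V


class TestLogrank:
    def test_identical_groups_give_null(self):
        g = _events([1.0, 2.0, 3.0], [True, True, True])
        chi2, p = logrank_test(g, g)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_brute_force_oracle_on_tiny_instances(self, seed):
        rng = np.random.default_rng(seed)
        na, nb = 3, 3
        ta = rng.choice([1.0, 2.0, 3.0, 4.0, 5.0, 6.0], na, replace=False)
        tb = rng.choice([1.5, 2.5, 3.5, 4.5, 5.5, 6.5], nb, replace=False)
        ea = rng.random(na) < 0.8
        eb = rng.random(nb) < 0.8
        if ea.sum() + eb.sum() < 2:
            ea[:] = True
        chi2, _ = logrank_test(
            _events(ta, ea), _events(tb, eb)
        )
        assert chi2 == pytest.approx(logrank_oracle(ta, ea, tb, eb), abs=1e-8)

    def test_empty_group_rejected(self):
        g = _events([1.0], [True])
        with pytest.raises(ValueError):
            logrank_test(g, g.iloc[:0])


# --------------------------------------------------------------------------
# Cox
# --------------------------------------------------------------------------

def cox_grid_oracle(times, events, x):
    """Grid-search maximizer of the (no-ties) Cox partial likelihood."""
    def pll(beta):
        ll = 0.0
        for i in np.where(events)[0]:
            risk = times >= times[i]
            ll += beta * x[i] - np.log(np.sum(np.exp(beta * x[risk])))
        return ll
    grid = np.arange(-5, 5, 1e-3)
    return grid[np.argmax([pll(b) for b in grid])]


class TestCox:
    def test_toy_fit_matches_grid_search_partial_likelihood(self):
        times = np.array([1.0, 2.0, 3.0, 4.0])
        events = np.array([True, True, True, False])
        x = np.array([1.0, 0.0, 1.0, 0.0])
        res = cox_fit(
            _events(times, events),
            pd.DataFrame({"subject_id": [f"s{i}" for i in range(4)], "x": x}),
            covariate_cols=("x",),
        )
        beta_hat = np.log(res.table.loc["x", "hr"])
        assert beta_hat == pytest.approx(cox_grid_oracle(times, events, x), abs=2e-3)

    def test_constant_covariate_unidentifiable(self):
        with pytest.raises(ValueError, match="identical"):
            cox_fit(
                _events([1.0, 2.0, 3.0], [True, True, True]),
                pd.DataFrame({"subject_id": ["s0", "s1", "s2"], "x": [1.0, 1.0, 1.0]}),
                covariate_cols=("x",),
            )

    def test_age_rescaling_rescales_coefficient_inversely(self, pdmci):
        cohort, _, _ = pdmci
        events = cohort[["subject_id", "event_time", "event"]].rename(
            columns={"event_time": "time"})
        cov = cohort[["subject_id", "age", "sex", "moca"]].copy()
        cov["low_ch4"] = (cohort["ch4_gmd"] < cohort["ch4_gmd"].median()).astype(int)
        b1 = cox_fit(events, cov).table.loc["age", "coef"]
        cov2 = cov.copy()
        cov2["age"] = cov2["age"] * 10.0
        b2 = cox_fit(events, cov2).table.loc["age", "coef"]
        assert b2 == pytest.approx(b1 / 10.0, rel=1e-4)

    def test_breslow_ties_close_to_efron_on_grid_data(self, pdmci):
        cohort, _, _ = pdmci
        events = cohort[["subject_id", "event_time", "event"]].rename(
            columns={"event_time": "time"})
        cov = cohort[["subject_id", "age", "sex", "moca"]].copy()
        cov["low_ch4"] = (cohort["ch4_gmd"] < cohort["ch4_gmd"].median()).astype(int)
        efron = cox_fit(events, cov, ties="efron")
        breslow = cox_fit(events, cov, ties="breslow")
        assert breslow.ties == "breslow"
        assert breslow.table.loc["low_ch4", "coef"] == pytest.approx(
            efron.table.loc["low_ch4", "coef"], abs=0.15
        )
        lo, hi = efron.table.loc["low_ch4", ["ci_low", "ci_high"]]
        assert lo <= efron.table.loc["low_ch4", "hr"] <= hi

    def test_too_few_events_rejected(self):
        with pytest.raises(ValueError, match="events"):
            cox_fit(
                _events([1.0, 2.0], [True, False]),
                pd.DataFrame({"subject_id": ["s0", "s1"], "x": [0.0, 1.0]}),
                covariate_cols=("x",),
            )


def test_detect_table_round_trips_generator_events(pdmci):
    """Milestone detection on the visit table reproduces the cohort's
    observed event times and indicators exactly."""
    cohort, visits, _ = pdmci
    events = detect_milestones_table(visits, CRIT)
    merged = cohort[["subject_id", "event_time", "event"]].merge(
        events, on="subject_id", suffixes=("_true", "_det"))
    assert np.array_equal(merged["event_true"].to_numpy(),
                          merged["event_det"].to_numpy())
    assert np.allclose(merged["event_time"].to_numpy(), merged["time"].to_numpy())


def test_km_plot_writes_figure(tmp_path, pdmci):
    from ch4subtype.survival import plot_km

    cohort, _, truth = pdmci
    ev = cohort[["subject_id", "event_time", "event"]].rename(
        columns={"event_time": "time"})
    out = tmp_path / "km.png"
    fig = plot_km({"low": ev[truth.latent_low], "normal": ev[~truth.latent_low]},
                  path=out)
    assert out.exists() and out.stat().st_size > 0
    assert len(fig.axes[0].lines) == 2
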