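"""Percentile thresholds and the three-way subtype rule."""

import itertools

import numpy as np
import pandas as pd
import pytest

from ch4subtype.subtyping import (
    SubtypeInputs,
    SubtypeThresholds,
    assign_subtype,
    assign_subtypes_table,
    composite_motor_score,
    compute_thresholds,
)


def _uniform_cohort(rng, n):
    """Four independent continuous uniform burden axes, one duration bin."""
    return pd.DataFrame({
        "updrs2": rng.uniform(0, 52, n),
        "updrs3": np.zeros(n),
        "scopa_aut": rng.uniform(0, 69, n),
        "rbdsq": rng.uniform(0, 13, n),
        "moca": rng.uniform(0, 30, n),
        "disease_duration": np.ones(n),
    })


def single_bin_thresholds(motor=30.0, scopa=20.0, rbdsq=6.0, cognitive=6.0):
    return SubtypeThresholds(
        bin_edges=[],
        percentiles=[{"motor": motor, "scopa_aut": scopa,
                      "rbdsq": rbdsq, "cognitive": cognitive}],
        n_per_bin=[100],
    )


class TestCompositeMotor:
    @pytest.mark.parametrize("u2,u3,expected", [(5, 22, 27), (0, 0, 0), (7.0, 27.0, 34.0)])
    def test_sum(self, u2, u3, expected):
        assert composite_motor_score(u2, u3) == expected

    def test_missing_raises(self):
        with pytest.raises(ValueError):
            composite_motor_score(None, 10)
        with pytest.raises(ValueError):
            composite_motor_score(np.nan, 10)


class TestThresholds:
    def test_constant_score_threshold_equals_constant(self, rng):
        cohort = _uniform_cohort(rng, 60)
        cohort["scopa_aut"] = 12.0
        thr = compute_thresholds(cohort)
        assert all(p["scopa_aut"] == 12.0 for p in thr.percentiles)

    def test_linear_interpolation_quantile(self, rng):
        cohort = _uniform_cohort(rng, 100)
        cohort["updrs2"] = np.arange(1.0, 101.0)[: len(cohort)]
        cohort["updrs3"] = 0.0
        thr = compute_thresholds(cohort)
        # 75th percentile of 1..100 under linear interpolation
        assert thr.percentiles[0]["motor"] == pytest.approx(75.25)

    def test_deterministic(self, rng):
        cohort = _uniform_cohort(rng, 80)
        a, b = compute_thresholds(cohort), compute_thresholds(cohort)
        assert a.percentiles == b.percentiles and a.bin_edges == b.bin_edges

    def test_small_bin_raises_with_bin_named(self, rng):
        cohort = _uniform_cohort(rng, 50)
        cohort["disease_duration"] = np.linspace(0.1, 5, 50)
        with pytest.raises(ValueError, match="bin"):
            compute_thresholds(cohort, duration_bins=[4.9])

    def test_duration_binning_routes_to_matching_bin(self, rng):
        cohort = _uniform_cohort(rng, 200)
        cohort["disease_duration"] = rng.uniform(0, 4, 200)
        thr = compute_thresholds(cohort, duration_bins=[2.0])
        assert thr.n_bins == 2
        assert thr.bin_index(0.5) == 0 and thr.bin_index(3.0) == 1
        with pytest.raises(ValueError):
            thr.bin_index(-1.0)

    def test_json_round_trip(self, tmp_path, rng):
        cohort = _uniform_cohort(rng, 90)
        cohort["disease_duration"] = rng.uniform(0, 3, 90)
        thr = compute_thresholds(cohort, duration_bins=[1.0, 2.0])
        path = tmp_path / "thr.json"
        thr.to_json(path)
        back = SubtypeThresholds.from_json(path)
        assert back.percentiles == thr.percentiles
        assert back.bin_edges == thr.bin_edges


def _inputs(motor2, scopa, rbdsq, moca, duration=1.0):
    return SubtypeInputs(updrs2=motor2, updrs3=0.0, scopa_aut=scopa,
                         rbdsq=rbdsq, moca=moca, disease_duration=duration)


class TestAssign:
    def test_all_below_is_mild(self):
        thr = single_bin_thresholds()
        lab = assign_subtype(_inputs(10.0, 5.0, 2.0, 28.0), thr)
        assert lab.label == "mild_motor_predominant"

    def test_motor_plus_one_nonmotor_is_malignant(self):
        thr = single_bin_thresholds()
        lab = assign_subtype(_inputs(40.0, 25.0, 2.0, 28.0), thr)
        assert lab.label == "diffuse_malignant"
        assert lab.exceedances == {
            "motor": True, "scopa_aut": True, "rbdsq": False, "cognitive": False,
        }

    def test_all_three_nonmotor_without_motor_is_malignant(self):
        thr = single_bin_thresholds()
        lab = assign_subtype(_inputs(10.0, 25.0, 8.0, 20.0), thr)
        assert lab.label == "diffuse_malignant"

    def test_exact_ties_fall_to_intermediate(self):
        thr = single_bin_thresholds(motor=30.0, scopa=20.0, rbdsq=6.0, cognitive=6.0)
        lab = assign_subtype(_inputs(30.0, 20.0, 6.0, 24.0), thr)  # 30-24=6 burden
        assert lab.label == "intermediate"

    def test_out_of_range_scores_rejected(self):
        with pytest.raises(ValueError):
            _inputs(60.0, 5.0, 2.0, 35.0)
        with pytest.raises(ValueError):
            SubtypeInputs(updrs2=5, updrs3=10, scopa_aut=5, rbdsq=2, moca=25,
                          disease_duration=-1.0)


def flag_rule(motor_above, nm_above, motor_below, nm_below):
    """Exceedance-flag enumeration oracle for the label rule."""
    n_above = sum(nm_above)
    if (motor_above and n_above >= 1) or n_above == 3:
        return "diffuse_malignant"
    if motor_below and all(nm_below):
        return "mild_motor_predominant"
    return "intermediate"


def test_partition_and_scalar_vector_agreement(rng):
    """Labels partition all valid inputs; table path matches scalar path."""
    n = 4000
    cohort = _uniform_cohort(rng, n)
    thr = compute_thresholds(cohort)
    table = assign_subtypes_table(cohort, thr)
    assert set(table["subtype"].unique()) <= {
        "diffuse_malignant", "intermediate", "mild_motor_predominant"
    }
    idx = rng.choice(n, size=200, replace=False)
    for i in idx:
        row = cohort.iloc[int(i)]
        lab = assign_subtype(
            SubtypeInputs(row["updrs2"], row["updrs3"], row["scopa_aut"],
                          row["rbdsq"], row["moca"], row["disease_duration"]),
            thr,
        )
        assert lab.label == table["subtype"].iloc[int(i)]
        # and both agree with the enumeration oracle on the flags
        motor = row["updrs2"] + row["updrs3"]
        vals = {"motor": motor, "scopa_aut": row["scopa_aut"],
                "rbdsq": row["rbdsq"], "cognitive": 30 - row["moca"]}
        t = thr.percentiles[0]
        nm = ["scopa_aut", "rbdsq", "cognitive"]
        assert lab.label == flag_rule(
            vals["motor"] > t["motor"], [vals[a] > t[a] for a in nm],
            vals["motor"] < t["motor"], [vals[a] < t[a] for a in nm],
        )


def test_expected_frequencies_from_flag_enumeration():
    """Exact enumeration over the 16 flag combinations at P(exceed)=0.25."""
    p_mal = p_mild = 0.0
    for flags in itertools.product([True, False], repeat=4):
        motor, nm = flags[0], flags[1:]
        prob = np.prod([0.25 if f else 0.75 for f in flags])
        label = flag_rule(motor, nm, not motor, [not f for f in nm])
        if label == "diffuse_malignant":
            p_mal += prob
        elif label == "mild_motor_predominant":
            p_mild += prob
    assert p_mild == pytest.approx(0.75 ** 4)
    assert p_mal == pytest.approx(0.25 * (1 - 0.75 ** 3) + 0.75 * 0.25 ** 3)


def test_monotone_in_burden(rng):
    """Raising burden on one axis never moves a label toward mild."""
    order = {"mild_motor_predominant": 0, "intermediate": 1, "diffuse_malignant": 2}
    thr = single_bin_thresholds()
    for _ in range(300):
        base = _inputs(
            float(rng.uniform(0, 52)), float(rng.uniform(0, 69)),
            float(rng.uniform(0, 13)), float(rng.uniform(0, 30)),
        )
        before = order[assign_subtype(base, thr).label]
        bumped = SubtypeInputs(
            updrs2=min(base.updrs2 + rng.uniform(0, 10), 52.0),
            updrs3=base.updrs3,
            scopa_aut=min(base.scopa_aut + rng.uniform(0, 10), 69.0),
            rbdsq=base.rbdsq, moca=base.moca,
            disease_duration=base.disease_duration,
        )
        after = order[assign_subtype(bumped, thr).label]
        assert after >= before
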