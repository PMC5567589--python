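import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import hemipark as hp
from hemipark import gait as g
from hemipark import synthetic as syn

from oracles import brute_force_split_plot


def simple_run(stride=8.0, stance=0.3, swing=0.2, n_steps=4, print_area=1.5):
    """Steady synthetic run with identical parameters for all paws."""
    events = []
    cycle = stance + swing
    for paw in syn.PAWS:
        t0 = 0.5 * cycle if paw in ("CH", "IF") else 0.0
        for k in range(n_steps):
            events.append(
                syn.FootfallEvent(
                    paw, t0 + k * cycle, t0 + k * cycle + stance,
                    k * stride, 1.0 if paw in ("CF", "IF") else -1.0, print_area,
                )
            )
    return syn.GaitRun("r1", events)


class TestCompliance:
    def test_long_run_noncompliant(self):
        run = simple_run(stance=1.2, swing=0.8, n_steps=4)  # ~7 s
        res = g.run_compliance(run)
        assert not res.compliant
        assert any("duration" in r for r in res.reasons)

    def test_speed_variation_limit(self):
        # accelerating run: strides double in the second half
        events = []
        for paw in syn.PAWS:
            x, t = 0.0, 0.5 if paw in ("CH", "IF") else 0.0
            for k in range(6):
                stride = 3.0 if k < 3 else 12.0
                events.append(syn.FootfallEvent(paw, t, t + 0.3, x, 0.0, 1.0))
                t += 0.5
                x += stride
        run = syn.GaitRun("acc", events)
        res = g.run_compliance(run)
        assert res.speed_variation_pct > 60
        assert not res.compliant

    def test_steady_run_compliant(self):
        res = g.run_compliance(simple_run())
        assert res.compliant and res.reasons == []

    def test_insufficient_steps(self):
        run = simple_run(n_steps=1)
        res = g.run_compliance(run)
        assert not res.compliant
        assert res.reasons == ["insufficient steps"]


class TestGaitParams:
    def test_step_arithmetic(self):
        # same-paw contacts at x=0 and x=8, lift at 0.5 s, next contact 0.7 s
        events = []
        for paw in syn.PAWS:
            events += [
                syn.FootfallEvent(paw, 0.0, 0.5, 0.0, 0.0, 1.0),
                syn.FootfallEvent(paw, 0.7, 1.2, 8.0, 0.0, 1.0),
            ]
        steps, _ = g.compute_gait_params(syn.GaitRun("r", events))
        cf = steps[steps.paw == "CF"].iloc[0]
        assert cf.swing_duration == pytest.approx(0.2)
        assert cf.stance_duration == pytest.approx(0.5)
        assert cf.stride_length == pytest.approx(8.0)
        assert cf.swing_speed == pytest.approx(40.0)
        assert cf.body_speed == pytest.approx(8.0 / 0.7)

    def test_cadence(self):
        run = simple_run(stance=0.3, swing=0.2, n_steps=4)
        _, globals_ = g.compute_gait_params(run)
        # 16 contacts in the run window
        assert globals_["number_of_steps"] == 16
        assert globals_["cadence"] == pytest.approx(16 / g._run_duration(run))

    def test_swing_speed_identity(self):
        steps, _ = g.compute_gait_params(simple_run())
        np.testing.assert_allclose(
            steps.swing_speed * steps.swing_duration, steps.stride_length, atol=1e-12
        )

    def test_overlapping_events_rejected(self):
        events = [
            syn.FootfallEvent("CF", 0.0, 0.6, 0.0, 0.0, 1.0),
            syn.FootfallEvent("CF", 0.5, 1.0, 5.0, 0.0, 1.0),
        ]
        with pytest.raises(ValueError, match="overlap"):
            g.compute_gait_params(syn.GaitRun("bad", events))


class TestAggregate:
    def test_single_run_equals_its_means(self):
        run = simple_run()
        paw, glob, n = g.aggregate_animal([run], "a1")
        steps, globals_ = g.compute_gait_params(run)
        assert n == 1
        cf = paw[paw.paw == "CF"].iloc[0]
        assert cf.stride_length == pytest.approx(
            steps[steps.paw == "CF"].stride_length.mean()
        )
        assert glob["average_speed"] == pytest.approx(globals_["average_speed"])

    def test_two_identical_runs_same_mean(self):
        run = simple_run()
        run2 = syn.GaitRun("r2", run.events, run.walkway_length_cm)
        one, _, _ = g.aggregate_animal([run], "a1")
        two, _, _ = g.aggregate_animal([run, run2], "a1")
        pd.testing.assert_frame_equal(one, two)

    def test_noncompliant_runs_excluded(self):
        good = simple_run()
        bad = simple_run(stance=1.2, swing=0.8)
        _, _, n = g.aggregate_animal([good, bad], "a1")
        assert n == 1

    def test_no_compliant_runs_raises(self):
        with pytest.raises(ValueError, match="no compliant"):
            g.aggregate_animal([simple_run(stance=1.2, swing=0.8)], "a1")


def toy_table():
    """4 animals x 2 groups x 4 paws with planted effects."""
    rows = []
    vals = {
        ("s1", "g1"): [1.0, 2.0, 3.0, 4.0],
        ("s2", "g1"): [2.0, 2.5, 3.5, 4.5],
        ("s3", "g2"): [3.0, 3.0, 2.0, 1.0],
        ("s4", "g2"): [4.0, 3.5, 2.5, 1.5],
    }
    for (sid, grp), v in vals.items():
        for paw, x in zip(syn.PAWS, v):
            rows.append({"animal_id": sid, "group": grp, "paw": paw, "y": x})
    return pd.DataFrame(rows)


class TestMixedAnova:
    def test_df_structure_13_animals(self, default_cohort):
        _, records = default_cohort
        rng = np.random.default_rng(1)
        runs = {
            r.subject_id: hp.simulate_gait_runs(r, hp.GaitModel(), rng=rng)
            for r in records
        }
        table, _ = g.build_param_table(runs, {r.subject_id: r.group for r in records})
        res = g.mixed_anova(table, "swing_speed")
        assert (res.table.loc["treatment", ["df1", "df2"]] == [1, 11]).all()
        assert (res.table.loc["paw", ["df1", "df2"]] == [3, 33]).all()
        assert (res.table.loc["interaction", ["df1", "df2"]] == [3, 33]).all()

    def test_matches_bruteforce_decomposition(self):
        table = toy_table()
        res = g.mixed_anova(table, "y")
        ss = brute_force_split_plot(table.y, table.animal_id, table.group, table.paw)
        assert res.table.loc["treatment", "SS"] == pytest.approx(ss["treatment"])
        assert res.table.loc["paw", "SS"] == pytest.approx(ss["within_factor"])
        assert res.table.loc["interaction", "SS"] == pytest.approx(ss["interaction"])
        assert res.table.loc["subjects_within_groups", "SS"] == pytest.approx(ss["subjects"])
        assert res.table.loc["paw_x_subjects", "SS"] == pytest.approx(ss["error_within"])

    def test_ss_conservation(self, default_cohort):
        _, records = default_cohort
        rng = np.random.default_rng(2)
        runs = {
            r.subject_id: hp.simulate_gait_runs(r, hp.GaitModel(), rng=rng)
            for r in records
        }
        table, _ = g.build_param_table(runs, {r.subject_id: r.group for r in records})
        res = g.mixed_anova(table, "stride_length")
        wide = table.pivot_table(index="animal_id", columns="paw", values="stride_length")
        total = float(((wide.to_numpy() - wide.to_numpy().mean()) ** 2).sum())
        assert res.table["SS"].sum() == pytest.approx(total, rel=1e-9)

    def test_matches_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        table = toy_table()
        res = g.mixed_anova(table, "y")
        ref = pingouin.mixed_anova(
            data=table, dv="y", within="paw", subject="animal_id", between="group"
        ).set_index("Source")
        assert res.table.loc["treatment", "F"] == pytest.approx(ref.loc["group", "F"])
        assert res.table.loc["paw", "F"] == pytest.approx(ref.loc["paw", "F"])
        assert res.table.loc["interaction", "F"] == pytest.approx(ref.loc["Interaction", "F"])

    def test_null_calibration(self):
        # no group or paw effects: p should be super-threshold most of the time
        rng = np.random.default_rng(3)
        n_sig = 0
        for _ in range(40):
            rows = []
            for i in range(13):
                grp = "g1" if i < 7 else "g2"
                for paw in syn.PAWS:
                    rows.append(
                        {"animal_id": f"s{i}", "group": grp, "paw": paw,
                         "y": rng.normal()}
                    )
            res = g.mixed_anova(pd.DataFrame(rows), "y")
            if res.table.loc["treatment", "p"] < 0.05:
                n_sig += 1
        assert n_sig <= 8  # ~5% expected over 40 null draws

    def test_missing_cell_rejected(self):
        table = toy_table().iloc[:-1]
        with pytest.raises(ValueError, match="incomplete"):
            g.mixed_anova(table, "y")


class TestFDist:
    def test_treatment_effect_tail(self):
        assert round(g.fdist_pvalue(7.2, 1, 11), 4) == 0.0213

    def test_zero_f(self):
        assert g.fdist_pvalue(0.0, 3, 33) == 1.0

    @given(st.floats(0.1, 5.0), st.integers(3, 30))
    @settings(max_examples=25, deadline=None)
    def test_f_t_identity(self, t, df):
        from scipy import stats

        p_f = g.fdist_pvalue(t**2, 1, df)
        p_t = 2 * stats.t.sf(abs(t), df)
        assert p_f == pytest.approx(p_t, rel=1e-9)


class TestPosthoc:
    def test_identical_groups_nothing_significant(self):
        rng = np.random.default_rng(4)
        rows = []
        for i in range(12):
            grp = "g1" if i < 6 else "g2"
            for paw in syn.PAWS:
                rows.append({"animal_id": f"s{i}", "group": grp, "paw": paw,
                             "y": 1.0 + 0.01 * rng.normal()})
        out = g.posthoc_pairwise(pd.DataFrame(rows), "y")
        assert not out[out.family == "between_groups"].significant.any()

    def test_cf_only_deficit_detected(self):
        # strong planted CF-only group difference
        rng = np.random.default_rng(5)
        detected, others_clean = 0, 0
        for rep in range(10):
            rows = []
            for i in range(13):
                grp = "lesion" if i < 7 else "sham"
                for paw in syn.PAWS:
                    y = rng.normal(scale=0.5)
                    if grp == "lesion" and paw == "CF":
                        y -= 3.0
                    rows.append({"animal_id": f"s{i}", "group": grp, "paw": paw, "y": y})
            out = g.posthoc_pairwise(pd.DataFrame(rows), "y")
            between = out[out.family == "between_groups"].set_index("comparison")
            cf = between[between.index.str.contains("@ CF")]
            rest = between[~between.index.str.contains("@ CF")]
            detected += int(cf.significant.all())
            others_clean += int(not rest.significant.any())
        assert detected >= 8
        assert others_clean >= 8

    def test_holm_dominates_raw(self):
        table = toy_table()
        raw = g.posthoc_pairwise(table, "y", scheme="none")
        holm = g.posthoc_pairwise(table, "y", scheme="holm")
        assert np.all(holm.p_adj.to_numpy() >= raw.p_adj.to_numpy() - 1e-12)


class TestCorrelate:
    def test_p_from_r_published_style_values(self):
        assert round(g.p_from_r(0.88, 13), 4) == 0.0001
        assert round(g.p_from_r(0.83, 13), 4) == 0.0004

    def test_p_from_r_zero(self):
        assert g.p_from_r(0.0, 13) == pytest.approx(1.0)

    @given(st.floats(0.05, 0.95), st.floats(0.05, 0.95), st.integers(5, 50))
    @settings(max_examples=30, deadline=None)
    def test_p_monotone_in_abs_r(self, r1, r2, n):
        lo, hi = sorted((r1, r2))
        if hi - lo > 1e-6:
            assert g.p_from_r(hi, n) < g.p_from_r(lo, n)

    @given(st.floats(0.2, 0.9), st.integers(5, 40), st.integers(5, 40))
    @settings(max_examples=30, deadline=None)
    def test_p_monotone_in_n(self, r, n1, n2):
        lo, hi = sorted((n1, n2))
        if lo != hi:
            assert g.p_from_r(r, hi) < g.p_from_r(r, lo)

    def test_correlate_matches_p_from_r(self, rng):
        x = rng.normal(size=13)
        y = 0.8 * x + rng.normal(size=13) * 0.4
        res = g.correlate(x, y)
        assert res.p == pytest.approx(g.p_from_r(res.r, 13))
        assert res.n == 13

    def test_zero_variance_rejected(self, rng):
        with pytest.raises(ValueError, match="variance"):
            g.correlate(np.ones(6), rng.normal(size=6))
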