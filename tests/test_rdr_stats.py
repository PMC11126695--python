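"""RDR arithmetic, per-pair mixed-model inference, FDR and LOSO."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import rdrkit as rk
from rdrkit.rdr_stats import OBSERVATION_COLUMNS, summaries_to_frame

positive = st.floats(min_value=1e-6, max_value=1.0)


class TestComputeRdr:
    def test_equal_ratios_zero(self):
        assert rk.compute_rdr(0.1, 0.1, 0.1, 0.1) == 0.0

    def test_hand_value(self):
        # (0.2/0.4)/(0.1/0.05) = 0.25
        assert rk.compute_rdr(0.1, 0.05, 0.2, 0.4) == pytest.approx(
            np.log10(0.25), abs=1e-12)

    def test_zero_abundance_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            rk.compute_rdr(0.1, 0.0, 0.2, 0.4)

    @given(positive, positive, positive, positive)
    @settings(max_examples=100, deadline=None)
    def test_antisymmetry(self, da, db, ra, rb):
        assert rk.compute_rdr(da, db, ra, rb) == pytest.approx(
            -rk.compute_rdr(db, da, rb, ra), abs=1e-12)

    @given(positive, positive, positive, positive, positive, positive)
    @settings(max_examples=100, deadline=None)
    def test_additivity_along_chain(self, da, db, dc, ra, rb, rc):
        ab = rk.compute_rdr(da, db, ra, rb)
        bc = rk.compute_rdr(db, dc, rb, rc)
        ac = rk.compute_rdr(da, dc, ra, rc)
        assert ab + bc == pytest.approx(ac, abs=1e-12)

    @given(positive, positive, positive, positive,
           st.floats(min_value=1e-3, max_value=1e3))
    @settings(max_examples=100, deadline=None)
    def test_sample_rescaling_invariance(self, da, db, ra, rb, c):
        base = rk.compute_rdr(da, db, ra, rb)
        assert rk.compute_rdr(c * da, c * db, ra, rb) == pytest.approx(
            base, abs=1e-12)
        assert rk.compute_rdr(da, db, c * ra, c * rb) == pytest.approx(
            base, abs=1e-12)

    def test_scale_law(self):
        base = rk.compute_rdr(0.1, 0.05, 0.2, 0.4)
        doubled = rk.compute_rdr(0.1, 0.05, 0.4, 0.4)
        assert doubled - base == pytest.approx(np.log10(2), abs=1e-12)


def _tiny_table(samples, taxa, rows):
    values = pd.DataFrame(rows, index=samples, columns=taxa, dtype=float)
    values = values.div(values.sum(axis=1), axis=0)
    return rk.AbundanceTable(values=values, is_relative=True)


class TestEnumerate:
    def setup_method(self):
        taxa = ["tA", "tB", "tC", "tD"]
        self.table = _tiny_table(
            ["d1", "p1", "q1", "d2", "p2", "q2"], taxa,
            [[0.2, 0.3, 0.1, 0.4],   # donor 1
             [0.0, 0.0, 0.0, 1.0],   # pre 1: tA, tB, tC can colonize
             [0.3, 0.2, 0.2, 0.3],   # post 1: all three colonize
             [0.3, 0.4, 0.0, 0.3],   # donor 2
             [0.0, 0.0, 0.5, 0.5],   # pre 2: tA, tB can colonize
             [0.1, 0.5, 0.2, 0.2]])  # post 2: both colonize
        self.triads = [
            rk.Triad("e1", "d1", "p1", "q1", "S1", "D1", "st1"),
            rk.Triad("e2", "d2", "p2", "q2", "S2", "D2", "st2"),
        ]
        self.profiles = {t.experiment_id: rk.classify_colonization(t, self.table)
                         for t in self.triads}

    def test_three_colonizers_give_three_pairs(self):
        obs = rk.enumerate_pair_observations(self.triads[:1], self.profiles,
                                             self.table)
        assert len(obs) == 3
        assert set(zip(obs.taxon_a, obs.taxon_b)) == {
            ("tA", "tB"), ("tA", "tC"), ("tB", "tC")}

    def test_pair_shared_across_experiments(self):
        obs = rk.enumerate_pair_observations(self.triads, self.profiles,
                                             self.table)
        ab = obs[(obs.taxon_a == "tA") & (obs.taxon_b == "tB")]
        assert len(ab) == 2
        assert set(ab.experiment_id) == {"e1", "e2"}

    def test_single_colonizer_yields_nothing(self):
        table = _tiny_table(["d", "p", "q"], ["tA", "tB"],
                            [[0.5, 0.5], [0.0, 1.0], [0.5, 0.5]])
        triad = rk.Triad("e", "d", "p", "q", "S", "D", "st")
        profiles = {"e": rk.classify_colonization(triad, table)}
        assert len(rk.enumerate_pair_observations([triad], profiles, table)) == 0

    def test_values_match_direct_formula(self):
        obs = rk.enumerate_pair_observations(self.triads[:1], self.profiles,
                                             self.table)
        row = obs[(obs.taxon_a == "tA") & (obs.taxon_b == "tC")].iloc[0]
        expected = rk.compute_rdr(
            self.table.values.loc["d1", "tA"], self.table.values.loc["d1", "tC"],
            self.table.values.loc["q1", "tA"], self.table.values.loc["q1", "tC"])
        assert row.rdr == pytest.approx(expected, abs=1e-12)

    def test_reclosure_invariance(self):
        """Dropping an uninvolved taxon and re-closing leaves RDRs unchanged."""
        obs_full = rk.enumerate_pair_observations(self.triads[:1],
                                                  self.profiles, self.table)
        sub = self.table.values.drop(columns="tD")
        sub = sub.div(sub.sum(axis=1), axis=0)
        table2 = rk.AbundanceTable(values=sub, is_relative=True)
        profiles2 = {t.experiment_id: rk.classify_colonization(t, table2)
                     for t in self.triads}
        obs_sub = rk.enumerate_pair_observations(self.triads[:1], profiles2,
                                                 table2)
        merged = obs_full.merge(obs_sub, on=["taxon_a", "taxon_b"],
                                suffixes=("_full", "_sub"))
        assert len(merged) == 3
        assert np.allclose(merged.rdr_full, merged.rdr_sub, atol=1e-12)


def make_obs(rdrs, studies=None, subjects=None, donors=None,
             pair=("tA", "tB")):
    n = len(rdrs)
    studies = studies or [f"st{i % 2}" for i in range(n)]
    subjects = subjects or [f"S{i}" for i in range(n)]
    donors = donors or [f"D{i}" for i in range(n)]
    return pd.DataFrame(
        [(pair[0], pair[1], f"e{i}", studies[i], subjects[i], donors[i],
          float(rdrs[i])) for i in range(n)], columns=OBSERVATION_COLUMNS)


class TestPrevalenceFilter:
    def test_both_thresholds_required(self):
        obs = make_obs([0.1] * 10, studies=["st1"] * 10)
        assert rk.filter_prevalent_pairs(obs) == set()

    def test_boundary_inclusive(self):
        obs = make_obs([0.1] * 10, studies=["st1"] * 5 + ["st2"] * 5)
        assert rk.filter_prevalent_pairs(obs) == {("tA", "tB")}

    def test_empty(self):
        assert rk.filter_prevalent_pairs(make_obs([])) == set()


class TestFitPairModel:
    def test_all_zero_observations(self):
        s = rk.fit_pair_model(make_obs([0.0] * 8))
        assert s.mean_rdr == 0.0
        assert s.p_value == pytest.approx(1.0)
        assert s.dominant is None

    def test_refuses_single_observation(self):
        with pytest.raises(ValueError, match="observations"):
            rk.fit_pair_model(make_obs([0.5]))

    def test_planted_intercept_recovered(self):
        """Intercept +0.5 with 30 observations: estimate in [0.4, 0.6] and
        p < 0.01 in at least 95% of replicates."""
        rng = np.random.default_rng(11)
        n_rep, good = 200, 0
        for _ in range(n_rep):
            obs = rk.simulate_pair_observations(
                0.5, sigma_u=0.1, sigma_e=0.1, n_subjects=15,
                n_timepoints=2, rng=rng)
            s = rk.fit_pair_model(obs)
            good += (0.4 <= s.mean_rdr <= 0.6) and (s.p_value < 0.01)
        assert good / n_rep >= 0.95

    def test_ttest_fallback_without_grouping_repeats(self):
        rng = np.random.default_rng(3)
        obs = make_obs(rng.normal(0.3, 0.1, 12))
        s = rk.fit_pair_model(obs)
        assert s.model == "ttest"
        assert s.mean_rdr == pytest.approx(obs.rdr.mean())

    def test_crossed_model_used_with_repeats(self):
        rng = np.random.default_rng(4)
        n = 24
        obs = make_obs(rng.normal(0.2, 0.1, n),
                       subjects=[f"S{i // 2}" for i in range(n)],
                       donors=[f"D{i % 4}" for i in range(n)])
        s = rk.fit_pair_model(obs)
        assert s.model == "mixed"

    def test_dominant_sign_rule(self):
        s = rk.PairSummary("tA", "tB", 0.4, 0.001, 10, 2)
        assert s.dominant == "tA"
        s2 = rk.PairSummary("tA", "tB", -0.4, 0.001, 10, 2)
        assert s2.dominant == "tB"


class TestFdr:
    def test_hand_bh_case(self):
        q = rk.fdr_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_second_hand_case(self):
        q = rk.fdr_adjust([0.005, 0.04, 0.04, 0.1])
        assert np.allclose(q, [0.02, 0.04 * 4 / 3, 0.04 * 4 / 3, 0.1])

    def test_single_p_passthrough(self):
        assert rk.fdr_adjust([0.037]).tolist() == [0.037]

    def test_monotone_in_rank(self):
        rng = np.random.default_rng(5)
        p = np.sort(rng.random(50))
        q = rk.fdr_adjust(p.tolist())
        assert (np.diff(q) >= -1e-15).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            rk.fdr_adjust([0.5, 1.2])

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1,
                    max_size=40))
    @settings(max_examples=100, deadline=None)
    def test_rejections_match_classic_step_up(self, ps):
        """q < alpha reproduces the classic BH step-up rejection set."""
        alpha = 0.1
        q = rk.fdr_adjust(ps)
        p = np.asarray(ps)
        order = np.argsort(p, kind="stable")
        m = len(p)
        k = 0
        for rank, idx in enumerate(order, start=1):
            if p[idx] <= alpha * rank / m:
                k = rank
        classic = set(order[:k].tolist())
        rejected = {i for i in range(m) if q[i] <= alpha + 1e-12}
        assert rejected == classic


class TestDifferentialCalls:
    def summary(self, p):
        return rk.PairSummary("tA", "tB", 0.2, p, 10, 2)

    def test_below_threshold_called(self):
        called = rk.call_differential_pairs([self.summary(0.09)])
        assert len(called) == 1

    def test_boundary_excluded(self):
        called = rk.call_differential_pairs([self.summary(0.1)])
        assert called == []

    def test_empty(self):
        assert rk.call_differential_pairs([]) == []


class TestLeaveOneStudyOut:
    def test_uniform_sign_gives_full_agreement(self):
        obs = make_obs([0.5] * 12, studies=[f"st{i % 3}" for i in range(12)])
        frame, frac = rk.leave_one_study_out(obs, {("tA", "tB")})
        assert frac == 1.0
        assert len(frame) == 3

    def test_one_contrarian_study_in_four(self):
        rdrs = [1.0] * 18 + [-1.0] * 2
        studies = (["stA"] * 6 + ["stB"] * 6 + ["stC"] * 6 + ["stD"] * 2)
        obs = make_obs(rdrs, studies=studies)
        frame, frac = rk.leave_one_study_out(obs, {("tA", "tB")})
        assert frac == pytest.approx(0.75)

    def test_single_study_pair_skipped(self, caplog):
        obs = make_obs([0.5] * 6, studies=["st1"] * 6)
        with caplog.at_level("WARNING"):
            frame, frac = rk.leave_one_study_out(obs, {("tA", "tB")})
        assert len(frame) == 0
        assert np.isnan(frac)


class TestPhylumDominance:
    def make_summaries(self):
        pairs = [("gA", "gB", 0.5), ("gA", "gC", 0.5), ("gA", "gD", 0.5),
                 ("gA", "gE", -0.5), ("gB", "gC", 0.3)]
        out = []
        for a, b, m in pairs:
            s = rk.PairSummary(a, b, m, 0.001, 10, 2, q_value=0.001,
                               is_differential=True)
            out.append(s)
        return out

    def test_rates_counted(self):
        meta = pd.DataFrame({"phylum": ["P1", "P1", "P2", "P2", "P2"]},
                            index=["gA", "gB", "gC", "gD", "gE"])
        rates, tests = rk.phylum_dominance_rates(self.make_summaries(), meta)
        ga = rates.set_index("taxon").loc["gA"]
        assert ga["n_pairs"] == 4
        assert ga["dominance_rate"] == pytest.approx(0.75)
        assert "gZ" not in rates["taxon"].tolist()

    def test_identical_rate_vectors_not_significant(self):
        meta = pd.DataFrame({"phylum": ["P1", "P2"]}, index=["gA", "gB"])
        s = rk.PairSummary("gA", "gB", 0.5, 0.001, 10, 2, q_value=0.001,
                           is_differential=True)
        s2 = rk.PairSummary("gA", "gB", -0.5, 0.001, 10, 2, q_value=0.001,
                            is_differential=True)
        rates, tests = rk.phylum_dominance_rates([s, s2], meta)
        assert (tests["p_value"] >= 0.3).all()


def test_summaries_frame_columns():
    s = rk.PairSummary("tA", "tB", 0.2, 0.01, 12, 3, q_value=0.02,
                       is_differential=True)
    frame = summaries_to_frame([s])
    assert frame.loc[0, "dominant"] == "tA"
    assert frame.loc[0, "n_studies"] == 3
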