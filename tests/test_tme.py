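"""TIL handling, expression normalization/scoring, group tests, clustering."""

import logging

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from statsmodels.stats.multitest import multipletests

from immunomri import (
    classify_immune_response,
    combine_til_reads,
    differential_signature_test,
    hierarchical_cluster,
    normalize_expression,
    pair_cocluster_fraction,
    score_signatures,
)
from immunomri.tme import build_til_records, qc_filter_samples

from oracles import by_adjust_bruteforce, geomean_normalize_bruteforce


class TestTilReads:
    def test_identical_reads(self):
        assert combine_til_reads(2, 2) == 2.0

    def test_midpoint_preserves_half_integers(self):
        assert combine_til_reads(1, 2) == 1.5

    def test_discordant_reads_average_and_warn(self, caplog):
        logging.getLogger("immunomri").setLevel(logging.WARNING)
        with caplog.at_level(logging.WARNING, logger="immunomri.tme"):
            assert combine_til_reads(0, 9) == 4.5
        assert any("discordant" in r.message for r in caplog.records)

    @pytest.mark.parametrize("bad", [-1, 10, 3.5])
    def test_out_of_range_rejected(self, bad):
        with pytest.raises(ValueError):
            combine_til_reads(bad, 2)


class TestResponseClassification:
    @pytest.mark.parametrize("pre,post,responder,delta", [
        (1, 3, True, 2),    # strict increase beyond one decile
        (1, 2, False, 1),   # exactly one decile: not a responder
        (8, 8, False, 0),   # stable TIL-rich tumor stays non-responder
        (3, 1, False, -2),
    ])
    def test_threshold(self, pre, post, responder, delta):
        flag, d = classify_immune_response(pre, post)
        assert flag is responder
        assert d == delta

    @given(pre=st.integers(0, 9), post=st.integers(0, 8))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_raising_post_never_unmakes_a_responder(self, pre, post):
        flag_lo, _ = classify_immune_response(pre, post)
        flag_hi, _ = classify_immune_response(pre, post + 1)
        assert flag_hi >= flag_lo

    def test_missing_timepoint_is_non_evaluable(self):
        reads = pd.DataFrame({
            "patient": ["A", "A", "A", "A", "B", "B"],
            "timepoint": ["pre", "pre", "post", "post", "pre", "pre"],
            "reader": [1, 2, 1, 2, 1, 2],
            "decile": [1, 1, 4, 4, 2, 2],
        })
        recs = {r.patient: r for r in build_til_records(reads)}
        assert recs["A"].responder is True
        assert recs["B"].responder is None and not recs["B"].evaluable


class TestNormalization:
    def test_arithmetic_identity(self):
        m = pd.DataFrame({"s1": [8.0, 8.0, 16.0]}, index=["hk1", "hk2", "g"])
        out = normalize_expression(m, ["hk1", "hk2"])
        assert out.loc["g", "s1"] == pytest.approx(1.0)  # log2(16/8)
        assert out.loc["hk1", "s1"] == pytest.approx(0.0)

    def test_gene_equal_to_housekeepers_normalizes_to_zero(self, rng):
        vals = rng.uniform(2, 20, 4)
        m = pd.DataFrame({f"s{j}": [vals[j]] * 3 for j in range(4)},
                         index=["hk1", "hk2", "g"])
        out = normalize_expression(m, ["hk1", "hk2"])
        assert np.allclose(out.loc["g"], 0.0)

    def test_matches_bruteforce_oracle(self, rng):
        genes = [f"hk{i}" for i in range(3)] + [f"g{i}" for i in range(7)]
        m = pd.DataFrame(rng.uniform(1, 100, (10, 5)), index=genes,
                         columns=[f"s{j}" for j in range(5)])
        out = normalize_expression(m, ["hk0", "hk1", "hk2"])
        ref = geomean_normalize_bruteforce(m, ["hk0", "hk1", "hk2"])
        assert np.allclose(out.to_numpy(), ref.to_numpy())

    def test_sample_scaling_invariance(self, rng):
        genes = ["hk1", "hk2", "g1", "g2"]
        m = pd.DataFrame(rng.uniform(1, 50, (4, 3)), index=genes,
                         columns=["a", "b", "c"])
        scaled = m.copy()
        scaled["b"] *= 11.0  # whole-sample scale, housekeepers included
        a = normalize_expression(m, ["hk1", "hk2"])
        b = normalize_expression(scaled, ["hk1", "hk2"])
        assert np.allclose(a.to_numpy(), b.to_numpy())

    def test_nonpositive_housekeeper_names_culprit(self):
        m = pd.DataFrame({"s1": [0.0, 5.0, 3.0]}, index=["hk1", "hk2", "g"])
        with pytest.raises(ValueError, match="hk1.*s1"):
            normalize_expression(m, ["hk1", "hk2"])


class TestQcFilter:
    def test_blacklist_and_low_signal_excluded(self, rng):
        m = pd.DataFrame(rng.uniform(100, 500, (4, 4)),
                         index=["hk1", "hk2", "g1", "g2"],
                         columns=["s1", "s2", "s3", "s4"])
        m.loc[["hk1", "hk2"], "s3"] = 2.0  # mean log2 hk = 1 < floor of 4
        kept, excluded = qc_filter_samples(m, ["hk1", "hk2"], blacklist=["s1"])
        assert excluded == ["s1", "s3"]
        assert list(kept.columns) == ["s2", "s4"]

    def test_clean_matrix_untouched(self, rng):
        m = pd.DataFrame(rng.uniform(100, 500, (3, 3)),
                         index=["hk1", "hk2", "g"], columns=list("abc"))
        kept, excluded = qc_filter_samples(m, ["hk1", "hk2"])
        assert excluded == [] and kept.shape == m.shape


class TestSignatureScores:
    def _norm(self, rng, n_genes=12, n_samples=6):
        genes = [f"g{i}" for i in range(n_genes)]
        return pd.DataFrame(rng.normal(0, 1, (n_genes, n_samples)), index=genes,
                            columns=[f"s{j}" for j in range(n_samples)])

    def test_single_gene_set_with_constant(self, rng):
        norm = self._norm(rng)
        scores = score_signatures(norm, {"solo": ["g3"]}, {"solo": 2.5})
        assert np.allclose(scores.loc["solo"], norm.loc["g3"] + 2.5)

    def test_constant_shift_equivariance(self, rng):
        norm = self._norm(rng)
        sets = {"a": ["g0", "g1"], "b": ["g2", "g3", "g4"]}
        base = score_signatures(norm, sets, 0.0)
        shifted = score_signatures(norm, sets, 1.7)
        assert np.allclose(shifted.to_numpy() - base.to_numpy(), 1.7)

    def test_matches_loop_oracle(self, rng):
        norm = self._norm(rng)
        sets = {"a": ["g0", "g5", "g9"], "b": ["g1", "g2"]}
        scores = score_signatures(norm, sets)
        for name, genes in sets.items():
            for s in norm.columns:
                expected = sum(norm.loc[g, s] for g in genes) / len(genes)
                assert scores.loc[name, s] == pytest.approx(expected)

    def test_missing_genes_scored_over_intersection(self, rng):
        norm = self._norm(rng)
        scores = score_signatures(norm, {"a": ["g0", "NOT_THERE"]})
        assert np.allclose(scores.loc["a"], norm.loc["g0"])
        with pytest.raises(ValueError, match="no genes"):
            score_signatures(norm, {"a": ["NOPE"]})


class TestDifferentialTest:
    def _scores(self, rng, shift=0.0, n_sig=5, per_group=6):
        cols = [f"a{j}" for j in range(per_group)] + [f"b{j}" for j in range(per_group)]
        vals = rng.normal(0, 1, (n_sig, 2 * per_group))
        vals[:, per_group:] += shift
        return pd.DataFrame(vals, index=[f"sig{i}" for i in range(n_sig)], columns=cols), \
            ["A"] * per_group + ["B"] * per_group

    def test_null_identity(self, rng):
        scores, labels = self._scores(rng)
        scores.iloc[0] = np.tile([1.0, 2.0, 3.0, 1.0, 2.0, 3.0], 2)[:12]
        res = differential_signature_test(scores, labels)
        assert (res["p_raw"] >= 0).all() and (res["p_raw"] <= 1).all()
        assert abs(res.loc["sig0", "t"]) < 1e-6

    def test_large_shift_detected(self, rng):
        scores, labels = self._scores(rng, shift=5.0)
        res = differential_signature_test(scores, labels)
        assert (res["p_by"] < 0.01).all()
        assert (res["group_diff"] > 0).all()

    def test_by_adjustment_hand_example(self):
        # m = 3: adjusted = raw * (m/rank) * (1 + 1/2 + 1/3), step-up, capped
        raw = np.array([0.01, 0.02, 0.03])
        c3 = 1 + 0.5 + 1 / 3
        expected = np.minimum.accumulate(
            (raw * 3 / np.array([1, 2, 3]) * c3)[::-1])[::-1]
        got = multipletests(raw, method="fdr_by")[1]
        assert np.allclose(got, np.minimum(expected, 1.0))
        assert np.allclose(by_adjust_bruteforce(raw), got)

    def test_by_dominates_raw_and_bh(self, rng):
        p = rng.uniform(0, 1, 40)
        by = multipletests(p, method="fdr_by")[1]
        bh = multipletests(p, method="fdr_bh")[1]
        assert (by >= p - 1e-15).all()
        assert (by >= bh - 1e-15).all()

    def test_degenerate_signature_p_one(self, rng):
        scores, labels = self._scores(rng)
        scores.iloc[2] = 4.2  # constant everywhere
        res = differential_signature_test(scores, labels)
        assert res.loc["sig2", "p_raw"] == 1.0
        assert res.loc["sig2", "t"] == 0.0

    def test_needs_two_groups_of_two(self, rng):
        scores, _ = self._scores(rng)
        with pytest.raises(ValueError, match="two groups"):
            differential_signature_test(scores, ["A"] * 12)
        with pytest.raises(ValueError, match="at least two"):
            differential_signature_test(scores, ["A"] + ["B"] * 11)


class TestClustering:
    def _blobs(self, rng, sep=8.0, n_per=6, n_sig=4):
        cols = [f"s{j}" for j in range(2 * n_per)]
        vals = rng.normal(0, 1, (n_sig, 2 * n_per))
        vals[:, n_per:] += sep
        return pd.DataFrame(vals, index=[f"sig{i}" for i in range(n_sig)], columns=cols)

    def test_separated_blobs_recovered(self, rng):
        scores = self._blobs(rng)
        res = hierarchical_cluster(scores)
        labels = res.labels
        first = set(labels.iloc[:6])
        second = set(labels.iloc[6:])
        assert first == {"immune-quiescent"} and second == {"immune-activated"}

    def test_duplicate_sample_merges_first(self, rng):
        scores = self._blobs(rng)
        scores["dup"] = scores["s0"]
        res = hierarchical_cluster(scores)
        i, j = list(scores.columns).index("s0"), list(scores.columns).index("dup")
        a, b = sorted((res.linkage[0, 0], res.linkage[0, 1]))
        assert (int(a), int(b)) == tuple(sorted((i, j)))
        assert res.linkage[0, 2] == 0.0

    def test_constant_matrix_rejected(self):
        scores = pd.DataFrame(np.ones((3, 5)), columns=[f"s{j}" for j in range(5)])
        with pytest.raises(ValueError, match="constant"):
            hierarchical_cluster(scores)

    def test_cocluster_fraction_on_constructed_pairs(self, rng):
        # patient effect dominates: each patient's two samples nearly coincide
        n_pat, n_sig = 6, 4
        cols, pat = [], {}
        vals = []
        for p in range(n_pat):
            center = rng.normal(0, 5, n_sig)
            for tp in ("pre", "post"):
                s = f"P{p}_{tp}"
                cols.append(s)
                pat[s] = f"P{p}"
                vals.append(center + rng.normal(0, 0.01, n_sig))
        scores = pd.DataFrame(np.array(vals).T, columns=cols)
        res = hierarchical_cluster(scores)
        assert pair_cocluster_fraction(res, pat) == 1.0
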