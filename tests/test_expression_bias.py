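"""Bias calling, consistency, synchrony and the statistical helpers."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import homeophase as hp
from homeophase.expression_bias import (
    NEUTRAL,
    NOT_EXPRESSED,
    TOWARD_H,
    TOWARD_L,
)
from homeophase.io_model import SUBGENOME_H, SUBGENOME_L


class TestCallBias:
    @pytest.mark.parametrize(
        "a, b, direction, silenced",
        [
            (10, 5, "toward_a", False),  # ratio exactly 2: inclusive threshold
            (10, 6, NEUTRAL, False),
            (10, 0.4, "toward_a", True),
            (0.5, 0.2, NOT_EXPRESSED, False),
            (5, 10, "toward_b", False),
            (0.4, 10, "toward_b", True),
            (7, 7, NEUTRAL, False),
        ],
    )
    def test_cases(self, a, b, direction, silenced):
        got_dir, got_sil, _ = hp.call_bias(a, b)
        assert (got_dir, got_sil) == (direction, silenced)

    def test_log2fc(self):
        _, _, fc = hp.call_bias(8, 2)
        assert fc == pytest.approx(2.0)
        _, _, fc = hp.call_bias(8, 0)
        assert math.isnan(fc)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            hp.call_bias(-1, 2)

    def test_swap_symmetry(self):
        """Swapping the copies mirrors the direction and negates log2fc."""
        rng = np.random.default_rng(12)
        for _ in range(200):
            a, b = rng.uniform(0, 20, size=2)
            d1, s1, f1 = hp.call_bias(a, b)
            d2, s2, f2 = hp.call_bias(b, a)
            mirror = {"toward_a": "toward_b", "toward_b": "toward_a"}
            assert d2 == mirror.get(d1, d1)
            assert s1 == s2
            if not (math.isnan(f1) or math.isnan(f2)):
                assert f2 == pytest.approx(-f1)

    def test_table_swap_symmetry(self, small_genome):
        """Flipping every pair's subgenome labels flips all table calls."""
        params = small_genome.params
        expr, _ = hp.simulate_expression(params, small_genome, seed=3)
        labels = small_genome.truth.gene_subgenome
        flipped = {
            g: SUBGENOME_H if s == SUBGENOME_L else SUBGENOME_L for g, s in labels.items()
        }
        calls = hp.call_bias_table(expr, small_genome.pairs, labels)
        mirrored = hp.call_bias_table(expr, small_genome.pairs, flipped)
        mirror = {TOWARD_H: TOWARD_L, TOWARD_L: TOWARD_H}
        assert (
            mirrored["direction"] == calls["direction"].map(lambda d: mirror.get(d, d))
        ).all()
        both = ~(calls["log2fc"].isna() | mirrored["log2fc"].isna())
        assert np.allclose(mirrored.loc[both, "log2fc"], -calls.loc[both, "log2fc"])


class TestFilterExpressedPairs:
    def test_rules(self):
        df = pd.DataFrame(
            {"48h": [0.5, 0.5, 1.2, 5.0], "96h": [0.2, 0.9, 0.3, 5.0]},
            index=["a1", "a2", "b1", "b2"],
        )
        expr = hp.ExpressionMatrix(df)
        pairs = [hp.HomoeologPair("pa", "c", "a1", "a2"),
                 hp.HomoeologPair("pb", "c", "b1", "b2")]
        retained, removed = hp.filter_expressed_pairs(expr, pairs)
        assert [p.pair_id for p in removed] == ["pa"]
        assert [p.pair_id for p in retained] == ["pb"]

    def test_missing_gene_rejected(self):
        expr = hp.ExpressionMatrix(pd.DataFrame({"48h": [1.0]}, index=["a1"]))
        pairs = [hp.HomoeologPair("pa", "c", "a1", "zz")]
        with pytest.raises(KeyError):
            hp.filter_expressed_pairs(expr, pairs)

    def test_removed_count_matches_truth(self, default_genome, default_expression):
        expr, truth = default_expression
        _, removed = hp.filter_expressed_pairs(expr, default_genome.pairs)
        assert {p.pair_id for p in removed} == truth.all_silent_pairs


class TestConsistencySynchrony:
    def _calls(self, directions):
        return pd.DataFrame(
            {
                "pair_id": ["p"] * len(directions),
                "timepoint": [f"t{i}" for i in range(len(directions))],
                "direction": directions,
            }
        )

    @pytest.mark.parametrize(
        "dirs, expected",
        [
            ([TOWARD_H] * 3, "consistent_h"),
            ([TOWARD_L] * 3, "consistent_l"),
            ([TOWARD_H, NEUTRAL, TOWARD_H], "mixed"),
            ([NEUTRAL] * 3, "neutral"),
            ([TOWARD_H, NOT_EXPRESSED, TOWARD_H], "consistent_h"),
            ([NOT_EXPRESSED] * 3, "not_assessable"),
        ],
    )
    def test_consistency_classes(self, dirs, expected):
        out = hp.consistency(self._calls(dirs))
        assert out.loc[0, "class"] == expected

    def test_gap_flagging(self):
        out = hp.consistency(self._calls([TOWARD_H, NOT_EXPRESSED, TOWARD_H]))
        assert bool(out.loc[0, "had_gaps"]) and out.loc[0, "n_evaluated"] == 2

    def _expr(self, a, b):
        df = pd.DataFrame([a, b], index=["ga", "gb"],
                          columns=[f"t{i}" for i in range(len(a))])
        return hp.ExpressionMatrix(df.astype(float))

    @pytest.mark.parametrize(
        "a, b, expected",
        [
            ([1, 2, 3], [10, 20, 30], "synchronized"),
            ([1, 2, 3], [3, 2, 1], "unsynchronized"),
            ([1, 1, 1], [5, 9, 2], "synchronized"),  # zero deltas act as wildcards
            ([0, 0, 0], [1, 2, 3], "not_assessable"),
        ],
    )
    def test_sign_concordance(self, a, b, expected):
        pairs = [hp.HomoeologPair("p", "c", "ga", "gb")]
        out = hp.synchrony(self._expr(a, b), pairs)
        assert out.loc[0, "class"] == expected

    def test_pearson_method(self):
        pairs = [hp.HomoeologPair("p", "c", "ga", "gb")]
        out = hp.synchrony(self._expr([1, 2, 3], [2, 4, 6.2]), pairs, method="pearson")
        assert out.loc[0, "class"] == "synchronized"
        out = hp.synchrony(self._expr([1, 2, 3], [3, 2, 1]), pairs, method="pearson")
        assert out.loc[0, "class"] == "unsynchronized"

    def test_degenerate_flag(self):
        pairs = [hp.HomoeologPair("p", "c", "ga", "gb")]
        out = hp.synchrony(self._expr([1, 1, 2], [5, 9, 11]), pairs)
        assert bool(out.loc[0, "degenerate"])


def enumerate_fisher_p(table) -> float:
    """Exhaustive two-sided Fisher p over all tables with fixed margins."""
    (a, b), (c, d) = table
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    lo, hi = max(0, c1 - r2), min(r1, c1)
    pmf = {k: stats.hypergeom.pmf(k, n, r1, c1) for k in range(lo, hi + 1)}
    observed = pmf[a]
    return float(sum(p for p in pmf.values() if p <= observed * (1 + 1e-7)))


class TestStatisticalHelpers:
    def test_chisq_null_and_arithmetic(self):
        stat, df, p = hp.chisq_gof([50, 50], [0.5, 0.5])
        assert stat == 0 and p == pytest.approx(1.0)
        stat, _, _ = hp.chisq_gof([10, 0], [0.5, 0.5])
        assert stat == pytest.approx(10.0)

    def test_chisq_zero_expected_rejected(self):
        with pytest.raises(ValueError):
            hp.chisq_gof([5, 5], [1.0, 0.0])

    def test_chisq_type_i_error_calibrated(self):
        """Monte-Carlo rejection rate under the null lands near alpha."""
        rng = np.random.default_rng(2024)
        probs = np.array([0.2, 0.3, 0.5])
        counts = rng.multinomial(120, probs, size=10_000)
        expected = 120 * probs
        statistic = ((counts - expected) ** 2 / expected).sum(axis=1)
        pvals = stats.chi2.sf(statistic, df=2)
        rate = (pvals < 0.05).mean()
        assert 0.04 <= rate <= 0.06
        # spot-check the helper against the vectorised statistic
        stat, df, p = hp.chisq_gof(counts[0], probs)
        assert stat == pytest.approx(statistic[0]) and p == pytest.approx(pvals[0])

    @pytest.mark.parametrize(
        "table, expected",
        [
            ([[2, 0], [0, 2]], 1 / 3),
            ([[5, 5], [5, 5]], 1.0),
        ],
    )
    def test_fisher_known_values(self, table, expected):
        _, p = hp.fisher_2x2(table)
        assert p == pytest.approx(expected, rel=1e-9)

    def test_fisher_negative_rejected(self):
        with pytest.raises(ValueError):
            hp.fisher_2x2([[1, -1], [0, 2]])

    def test_fisher_matches_enumeration_small_margins(self):
        """Every 2x2 table with margins <= 8 agrees with brute-force enumeration."""
        for a, b, c, d in itertools.product(range(9), repeat=4):
            if a + b > 8 or c + d > 8 or a + c > 8 or b + d > 8:
                continue
            if a + b == 0 or c + d == 0:
                continue
            _, p = hp.fisher_2x2([[a, b], [c, d]])
            assert p == pytest.approx(enumerate_fisher_p([[a, b], [c, d]]), rel=1e-6, abs=1e-12)

    def test_bh_monotone_in_rank(self):
        rng = np.random.default_rng(5)
        p = rng.uniform(size=50)
        q = hp.bh_adjust(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()
        assert (q >= p - 1e-12).all()


class TestStrataReport:
    def _calls(self, rows):
        return pd.DataFrame(
            rows, columns=["pair_id", "timepoint", "direction", "silenced",
                           "log2fc", "rpkm_h", "rpkm_l"]
        )

    def test_empty_stratum(self):
        calls = self._calls([("p1", "t0", NEUTRAL, False, 0.0, 5, 5)])
        report = hp.strata_bias_report(calls, cutoffs=[100])
        row = report.iloc[0]
        assert row["toward_h"] == row["toward_l"] == 0 and np.isnan(row["p_50_50"])

    def test_balanced_counts_p_one(self):
        calls = self._calls(
            [("p1", "t0", TOWARD_H, False, 2.0, 300, 60),
             ("p2", "t0", TOWARD_L, False, -2.0, 70, 280)]
        )
        report = hp.strata_bias_report(calls, cutoffs=[50])
        assert report.iloc[0]["p_50_50"] == pytest.approx(1.0)

    def test_silenced_counted_separately(self):
        calls = self._calls(
            [("p1", "t0", TOWARD_H, True, np.nan, 300, 0.2),
             ("p2", "t0", TOWARD_H, False, 3.0, 400, 40)]
        )
        report = hp.strata_bias_report(calls, cutoffs=[50])
        row = report.iloc[0]
        assert row["silenced"] == 1 and row["toward_h"] == 1

    def test_mean_membership_option(self):
        calls = self._calls(
            [("p1", "t0", TOWARD_H, False, 2.0, 90, 20),
             ("p2", "t0", TOWARD_L, False, -2.0, 20, 30)]
        )
        by_max = hp.strata_bias_report(calls, cutoffs=[50])
        by_mean = hp.strata_bias_report(calls, cutoffs=[50], membership="mean")
        assert by_max.iloc[0]["toward_h"] == 1
        assert by_mean.iloc[0]["toward_h"] + by_mean.iloc[0]["toward_l"] == 1
        with pytest.raises(ValueError):
            hp.strata_bias_report(calls, membership="median")

    def test_simulated_high_expression_excess_detected(self, default_genome,
                                                       default_expression):
        """On synthetic data an injected toward_h excess in a stratum is significant."""
        expr, _ = default_expression
        labels = default_genome.truth.gene_subgenome
        calls = hp.call_bias_table(expr, default_genome.pairs, labels)
        # inject a known excess: flip 70% of toward_l calls above RPKM 50
        rng = np.random.default_rng(8)
        high = calls[["rpkm_h", "rpkm_l"]].max(axis=1) > 50
        flip = high & (calls["direction"] == TOWARD_L) & (rng.random(len(calls)) < 0.7)
        calls.loc[flip, "direction"] = TOWARD_H
        report = hp.strata_bias_report(calls, cutoffs=[50])
        assert (report["p_50_50"] < 0.05).all()
        assert (report["toward_h"] > report["toward_l"]).all()


class TestPathwayAndTerms:
    def _setup(self, n_term=40, n_bg=400, term_bias=0.8, bg_bias=0.5, seed=0):
        rng = np.random.default_rng(seed)
        pairs = []
        rows = []
        gene_terms = {}
        for i in range(n_term + n_bg):
            pid = f"p{i}"
            pairs.append(hp.HomoeologPair(pid, "c", f"x{i}", f"y{i}"))
            in_term = i < n_term
            if in_term:
                gene_terms[f"x{i}"] = {"pathway"}
            p_l = term_bias if in_term else bg_bias
            for tp in ("t0", "t1"):
                direction = TOWARD_L if rng.random() < p_l else TOWARD_H
                fc = -2.0 if direction == TOWARD_L else 2.0
                rows.append((pid, tp, direction, False, fc, 10.0, 10.0))
        calls = pd.DataFrame(
            rows, columns=["pair_id", "timepoint", "direction", "silenced",
                           "log2fc", "rpkm_h", "rpkm_l"]
        )
        return calls, pairs, hp.AnnotationTable(gene_terms=gene_terms)

    def test_biased_term_detected(self):
        calls, pairs, annotation = self._setup()
        out = hp.pathway_bias(calls, pairs, annotation)
        toward_l = out[(out["term"] == "pathway") & (out["direction"] == TOWARD_L)]
        assert (toward_l["p"] < 0.05).any()

    def test_all_neutral_no_signal(self):
        calls, pairs, annotation = self._setup()
        calls["direction"] = NEUTRAL
        calls["log2fc"] = 0.1
        out = hp.pathway_bias(calls, pairs, annotation)
        assert ((out["log2fc_median"] > -1) & (out["log2fc_median"] < 1)).all()
        assert (out["q"] > 0.05).all()

    def test_single_pair_term_uses_fisher(self):
        calls, pairs, annotation = self._setup(n_term=1, n_bg=30)
        out = hp.pathway_bias(calls, pairs, annotation)
        assert (out["test"] == "fisher").all()

    def test_compartment_mismatch_excluded(self):
        calls, pairs, annotation = self._setup(n_term=5, n_bg=10)
        compartments = {"x0": "chloroplast", "y0": "mitochondrion"}
        out = hp.pathway_bias(calls, pairs, annotation, compartments=compartments)
        assert (out["n_term_pairs"] == 4).all()  # p0 dropped

    def test_term_frequency_logratio(self):
        annotation = hp.AnnotationTable(
            gene_terms={"a": {"T1"}, "b": {"T1", "T2"}, "c": {"T2"}, "d": {"T1"}}
        )
        out = hp.term_frequency_logratio({"a", "b"}, {"c", "d"}, annotation).set_index("term")
        assert out.loc["T1", "freq_a"] == 1.0 and out.loc["T1", "freq_b"] == 0.5
        assert out.loc["T1", "log_ratio"] == pytest.approx(1.0)
        # brute-force recount oracle
        assert out.loc["T2", "freq_a"] == pytest.approx(1 / 2)
        assert out.loc["T2", "freq_b"] == pytest.approx(1 / 2)
        assert out.loc["T2", "log_ratio"] == pytest.approx(0.0)

    def test_identical_groups_all_zero(self):
        annotation = hp.AnnotationTable(gene_terms={"a": {"T1"}, "b": {"T2"}})
        out = hp.term_frequency_logratio({"a", "b"}, {"a", "b"}, annotation)
        assert np.allclose(out["log_ratio"], 0.0)

    def test_one_sided_term_flagged_infinite(self):
        annotation = hp.AnnotationTable(gene_terms={"a": {"T1"}})
        out = hp.term_frequency_logratio({"a"}, {"b"}, annotation).set_index("term")
        assert out.loc["T1", "flag"] == "infinite"
        assert np.isinf(out.loc["T1", "log_ratio"])

    def test_empty_group_rejected(self):
        annotation = hp.AnnotationTable(gene_terms={"a": {"T1"}})
        with pytest.raises(ValueError):
            hp.term_frequency_logratio(set(), {"a"}, annotation)


class TestNoisyRecovery:
    def test_direction_recall_at_noise(self, default_genome, default_expression):
        """At log2 noise sd 0.3, direction recall for truly biased pairs >= 90%."""
        expr, truth = default_expression
        calls = hp.call_bias_table(expr, default_genome.pairs,
                                   default_genome.truth.gene_subgenome)
        merged = calls.merge(truth.table, on=["pair_id", "timepoint"],
                             suffixes=("_called", "_true"))
        biased = merged[merged["category"] == "biased"]
        recall = (biased["direction_called"] == biased["direction_true"]).mean()
        assert recall >= 0.90
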