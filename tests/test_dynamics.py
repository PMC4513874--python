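"""Per-timepoint enrichment, asymmetry, coherence and seed-effect stats,
each checked against exhaustive brute-force oracles on small inputs."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mirdyn.dynamics import (coherence_analysis, discrimination_auc_by_time,
                             gsea_enrichment_score, seed_enrichment_by_time,
                             seed_region_effect, set_enrichment_by_time,
                             tf_mir_ratio, tf_target_split_response,
                             updown_asymmetry)
from mirdyn.targets import MIR9_SEQUENCE, SeedSpec
from conftest import toy_fc


def binom_tail_ge(k, n, p):
    return sum(math.comb(n, j) * p ** j * (1 - p) ** (n - j)
               for j in range(k, n + 1))


def hypergeom_tail_ge(k, N, K, n):
    def pmf(j):
        return (math.comb(K, j) * math.comb(N - K, n - j)
                / math.comb(N, n))
    return sum(pmf(j) for j in range(k, min(K, n) + 1))


class TestSeedEnrichment:
    def test_binomial_tail_matches_brute_force(self, default_dataset):
        # the per-time p-value is an exact one-sided binomial tail
        p_scipy = stats.binomtest(10, 20, 0.35,
                                  alternative="greater").pvalue
        assert p_scipy == pytest.approx(binom_tail_ge(10, 20, 0.35),
                                        rel=1e-12)

    def test_most_significant_timepoint_is_planted_peak(
            self, default_dataset):
        res = seed_enrichment_by_time(default_dataset.fc,
                                      default_dataset.annotations)
        best = res.loc[res["p_value"].idxmin(), "time"]
        assert best == 4.0

    def test_enrichment_fraction_near_planted(self, default_dataset):
        res = seed_enrichment_by_time(default_dataset.fc,
                                      default_dataset.annotations)
        at4 = res[np.isclose(res["time"], 4.0)].iloc[0]
        assert at4["fraction"] == pytest.approx(0.58, abs=0.12)
        assert at4["p_value"] < 1e-4


class TestDiscriminationAuc:
    def test_perfect_separation_gives_one(self):
        vals = np.zeros((3, 17))
        vals[:, 2] = [2.0, 3.0, 1.0]
        fc = toy_fc(vals)
        res = discrimination_auc_by_time(fc, {"g0", "g1"}, {"g2"})
        assert res["auc"][2] == 1.0

    def test_argmax_at_planted_peak(self, default_dataset, default_sets):
        res = discrimination_auc_by_time(default_dataset.fc,
                                         default_sets.direct,
                                         default_sets.indirect)
        assert res.loc[res["auc"].idxmax(), "time"] == 4.0

    def test_missing_gene_rejected(self):
        fc = toy_fc(np.zeros((2, 17)))
        with pytest.raises(ValueError, match="missing"):
            discrimination_auc_by_time(fc, {"g0"}, {"nope"})


class TestGsea:
    def test_top_ranked_set_maximally_enriched(self):
        rng = np.random.default_rng(0)
        vals = np.sort(rng.normal(0, 1, (100, 1)), axis=0)[::-1]
        fc = toy_fc(vals, times=(4.0,))
        top = {f"g{i}" for i in range(20)}
        res = set_enrichment_by_time(fc, {"top": top}, n_perm=199,
                                     rng_seed=0)
        assert res["p_value"].iloc[0] <= 1 / 200 + 1e-12

    def test_evenly_interleaved_set_scores_near_zero(self):
        # a set spread uniformly through the ranking tracks the miss
        # line, so the running sum stays near zero by symmetry
        vals = np.linspace(1, -1, 100)
        member = np.zeros(100, bool)
        member[::5] = True
        es = gsea_enrichment_score(vals, member, weight=0.0, signed=True)
        assert abs(es) < 0.1

    def test_null_pvalues_approximately_uniform(self):
        rng = np.random.default_rng(1)
        fc = toy_fc(rng.normal(0, 1, (150, 1)), times=(4.0,))
        pvals = []
        for rep in range(120):
            members = set(rng.choice([f"g{i}" for i in range(150)], 15,
                                     replace=False))
            res = set_enrichment_by_time(fc, {"s": members}, n_perm=99,
                                         rng_seed=rep)
            pvals.append(res["p_value"].iloc[0])
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01

    def test_improper_set_rejected(self):
        with pytest.raises(ValueError, match="proper subset"):
            gsea_enrichment_score(np.ones(5), np.ones(5, bool))


class TestTfMirRatio:
    @staticmethod
    def enr(rows):
        return pd.DataFrame(rows, columns=["set", "time", "p_value"])

    def test_no_tf_with_mir_hits_gives_zero(self):
        e = self.enr([("tf1", 4.0, 0.5), ("m1", 4.0, 1e-6),
                      ("m2", 4.0, 1e-5)])
        res = tf_mir_ratio(e, {"tf1"}, {"m1", "m2"})
        assert res["ratio"].iloc[0] == 0.0 and res["defined"].iloc[0]

    def test_equal_counts_give_one(self):
        e = self.enr([(s, 4.0, 1e-6) for s in
                      ("tf1", "tf2", "tf3", "m1", "m2", "m3")])
        res = tf_mir_ratio(e, {"tf1", "tf2", "tf3"}, {"m1", "m2", "m3"})
        assert res["ratio"].iloc[0] == 1.0

    def test_zero_mir_count_undefined(self):
        e = self.enr([("tf1", 4.0, 1e-6), ("tf2", 4.0, 1e-6),
                      ("m1", 4.0, 0.5)])
        res = tf_mir_ratio(e, {"tf1", "tf2"}, {"m1"})
        assert not res["defined"].iloc[0]
        assert np.isnan(res["ratio"].iloc[0])


class TestUpdownAsymmetry:
    def test_extreme_asymmetry_significant(self):
        # the (1303 up, 17 down) configuration: boundary-binomial p is
        # far below any floor
        n = 1320
        p = stats.binom.sf(1303 - 1, n, 0.6)
        assert p < 1e-15

    def test_balanced_counts_nonsignificant(self):
        # the (489 up, 560 down) configuration
        p = stats.binom.cdf(489, 1049, 0.4)
        assert p > 0.5

    def test_implementation_reproduces_both_regimes(self):
        vals = np.zeros((1320 + 1049, 2))
        vals[:1303, 0] = 1.0
        vals[1303:1320, 0] = -1.0
        vals[1320:1320 + 489, 1] = 1.0
        vals[1320 + 489:, 1] = -1.0
        fc = toy_fc(vals, times=(4.0, 32.0))
        res = updown_asymmetry(fc, threshold=1.5, delta=0.10)
        p4 = res[np.isclose(res["time"], 4.0)]["p_value"].iloc[0]
        p32 = res[np.isclose(res["time"], 32.0)]["p_value"].iloc[0]
        assert p4 < 1e-15 and p32 > 0.5
        assert res[np.isclose(res["time"], 4.0)]["up_fraction"].iloc[0] \
            == pytest.approx(1303 / 1320)

    def test_no_responders_gives_missing(self):
        res = updown_asymmetry(toy_fc(np.zeros((3, 2)),
                                      times=(4.0, 32.0)))
        assert res["p_value"].isna().all()


class TestCoherence:
    def test_fully_coherent_toy(self):
        vals = np.zeros((4, 2))
        vals[:, 0] = [1.0, 1.0, 0.0, 0.0]
        vals[:, 1] = [0.5, 0.6, 0.0, 0.0]
        fc = toy_fc(vals, times=(4.0, 32.0))
        res = coherence_analysis(fc)
        assert res.coherent_fraction == 1.0

    def test_fisher_p_matches_exhaustive_hypergeometric(self):
        # table (10, 5; 3, 82): P(X >= 10) drawing 15 from 95 with 13
        table = np.array([[10, 5], [3, 82]])
        _, p = stats.fisher_exact(table, alternative="greater")
        want = hypergeom_tail_ge(10, 100, 13, 15)
        assert p == pytest.approx(want, rel=1e-10)

    def test_synthetic_defaults_highly_coherent(self, default_dataset):
        res = coherence_analysis(default_dataset.fc)
        assert res.coherent_fraction > 0.9

    def test_sign_table_sorted_by_first_response(self, default_dataset):
        res = coherence_analysis(default_dataset.fc)
        col = res.sign_table.iloc[:, 0].to_numpy()
        assert (np.diff(col) <= 0).all()

    def test_degenerate_margins_flagged(self):
        vals = np.zeros((3, 2))
        vals[:, 0] = [1.0, 1.0, 1.0]
        vals[:, 1] = [0.5, 0.5, 0.5]
        res = coherence_analysis(toy_fc(vals, times=(4.0, 32.0)))
        assert res.fisher_p == 1.0 and "degenerate" in res.note


class TestTfTargetSplit:
    def test_identical_distributions_give_zero_difference(self):
        rng = np.random.default_rng(0)
        vals = np.tile(rng.normal(1.0, 0.01, 17), (10, 1))
        fc = toy_fc(vals)
        df, diff = tf_target_split_response(
            fc, {f"g{i}" for i in range(5)},
            {f"g{i}" for i in range(5, 10)})
        assert abs(diff) < 0.02

    def test_planted_32h_bump_maximizes_difference_there(self):
        t = np.array([2., 4., 8., 16., 32., 64.])
        bump = np.exp(-0.5 * ((t - 32) / 6) ** 2)
        rows = [1.0 * bump for _ in range(6)] + [0.6 + 0 * t
                                                 for _ in range(6)]
        fc = toy_fc(np.array(rows), times=t)
        df, diff = tf_target_split_response(
            fc, {f"g{i}" for i in range(6)},
            {f"g{i}" for i in range(6, 12)}, query_time=32.0)
        a = df[df["set"] == "mir_tf_targets"].set_index("time")["mean_fc"]
        b = df[df["set"] == "other_tf_targets"].set_index("time")["mean_fc"]
        gap = a - b
        assert gap.idxmax() == 32.0

    def test_se_is_sd_over_sqrt_n(self):
        vals = np.zeros((4, 2))
        vals[:3, 0] = [1.0, 2.0, 3.0]
        vals[3, 0] = 1.0
        fc = toy_fc(vals, times=(4.0, 32.0))
        df, _ = tf_target_split_response(fc, {"g0", "g1", "g2"}, {"g3"},
                                         responder_threshold=1.01,
                                         query_time=4.0)
        row = df[(df["set"] == "mir_tf_targets")
                 & np.isclose(df["time"], 4.0)].iloc[0]
        assert row["se"] == pytest.approx(np.std([1, 2, 3], ddof=1)
                                          / np.sqrt(3))


class TestSeedRegionEffect:
    def test_ks_identical_samples_zero(self):
        assert stats.ks_2samp([1, 2, 3], [1, 2, 3]).statistic == 0

    def test_ks_disjoint_samples_one_with_exact_p(self):
        res = stats.ks_2samp([0.1, 0.2], [0.8, 0.9], method="exact")
        assert res.statistic == 1.0
        # exact p: of C(4,2)=6 orderings, only the observed split has D=1
        assert res.pvalue == pytest.approx(2 / 6)

    @staticmethod
    def _coupled_dataset(seed, rng_seed=0):
        """Responders whose seed carriers respond more strongly."""
        from mirdyn.targets import annotate_sequences
        rng = np.random.default_rng(rng_seed)
        bases = np.frombuffer(b"ACGT", dtype="S1")
        genes = [f"g{i}" for i in range(200)]
        utr, cds = {}, {}
        fc = {}
        for i, g in enumerate(genes):
            u = "".join(np.char.decode(bases[rng.integers(0, 4, 600)]))
            c = "".join(np.char.decode(bases[rng.integers(0, 4, 900)]))
            if i < 60:  # carriers: plant a UTR site, stronger response
                pos = int(rng.integers(0, 600 - 7))
                u = u[:pos] + seed.seed7 + u[pos + 7:]
                fc[g] = rng.normal(0.85, 0.08)
            else:
                fc[g] = rng.normal(0.65, 0.05)
            utr[g], cds[g] = u, c
        ann = annotate_sequences(utr, cds, seed)
        return pd.Series(fc), ann

    def test_absent_seed_gives_zero_removal_delta(self):
        seed = SeedSpec(MIR9_SEQUENCE)
        fcs, ann = self._coupled_dataset(seed)
        # scrub every sequence of the seed: removal cannot change the mean
        clean_utr = {g: s.replace(seed.seed7, "A" * 7)
                     for g, s in ann.utr_sequences.items()}
        clean_cds = {g: s.replace(seed.seed7, "A" * 7)
                     for g, s in ann.cds_sequences.items()}
        from mirdyn.targets import annotate_sequences
        clean = annotate_sequences(clean_utr, clean_cds, seed)
        res = seed_region_effect(fcs, clean, seed, n_shuffles=0,
                                 rng_seed=0)
        deltas = res.removal.set_index("region")["delta"]
        assert np.abs(deltas).max() < 1e-12

    def test_planted_seed_removal_exceeds_shuffled_controls(self):
        seed = SeedSpec(MIR9_SEQUENCE)
        fcs, ann = self._coupled_dataset(seed)
        res = seed_region_effect(fcs, ann, seed, n_shuffles=20,
                                 rng_seed=0)
        row = res.removal.set_index("region").loc["utr3"]
        assert row["delta"] > row["control_mean"] + 2 * row["control_sd"]
        ks = res.ks_results.set_index("group")
        assert ks.loc["utr_only", "p_value"] < 0.05

    def test_default_dataset_carriers_shifted_up_at_peak(
            self, default_dataset):
        # carrier enrichment among responders shifts the carrier FC
        # distribution upward at the planted 4 h peak
        res = seed_region_effect(default_dataset.fc["t4"],
                                 default_dataset.annotations,
                                 SeedSpec(MIR9_SEQUENCE),
                                 n_shuffles=5, rng_seed=0)
        ks = res.ks_results.set_index("group")
        assert (ks["p_value"].dropna() < 0.05).any()
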