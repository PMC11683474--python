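"""Peptide-protein correlation, signed-rank test and distance decay."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pepatlas import correlation as corr


def frame(rows, ids, tissues=None):
    tissues = tissues or [f"t{i}" for i in range(len(rows[0]))]
    return pd.DataFrame(rows, index=ids, columns=tissues, dtype=float)


def pairing(pep_ids, partner_ids, distances=None):
    d = {"peptide_id": pep_ids, "partner_id": partner_ids}
    if distances is not None:
        d["genomic_distance"] = distances
    return pd.DataFrame(d)


class TestTissuewiseSpearman:
    def test_identical_profiles_rho_one(self):
        pep = frame([[1, 2, 3], [4, 5, 6], [7, 8, 9]], ["p1", "p2", "p3"])
        table = corr.tissuewise_spearman(pep, pep.copy(),
                                         pairing(pep.index, pep.index))
        assert np.allclose(table["spearman_rho"].to_numpy(), 1.0)

    def test_reversed_ranks_rho_minus_one(self):
        pep = frame([[1, 0, 0], [2, 0, 0], [3, 0, 0]], ["p1", "p2", "p3"])
        prot = frame([[3, 0, 0], [2, 0, 0], [1, 0, 0]], ["q1", "q2", "q3"])
        table = corr.tissuewise_spearman(pep, prot,
                                         pairing(pep.index, prot.index))
        assert table.iloc[0]["spearman_rho"] == pytest.approx(-1.0)
        # tissues with < 3 detected pairs are undefined
        assert np.isnan(table.iloc[1]["spearman_rho"])

    def test_matches_scipy_with_ties(self, rng):
        n = 40
        pep = frame(np.exp(rng.integers(1, 5, size=(n, 4))),
                    [f"p{i}" for i in range(n)])
        prot = frame(np.exp(rng.integers(1, 5, size=(n, 4))),
                     [f"q{i}" for i in range(n)])
        table = corr.tissuewise_spearman(pep, prot,
                                         pairing(pep.index, prot.index))
        lp, lq = np.log2(pep + 1), np.log2(prot + 1)
        for _, row in table.iterrows():
            t = row["tissue"]
            expected = stats.spearmanr(lp[t], lq[t]).statistic
            assert row["spearman_rho"] == pytest.approx(expected, abs=1e-9)


class TestPairwisePearson:
    def test_identical_rows_r_one(self):
        pep = frame([[1, 2, 3, 4]], ["p1"])
        table = corr.pairwise_pearson(pep, pep.copy(), pairing(["p1"], ["p1"]))
        assert table.iloc[0]["pearson_r"] == pytest.approx(1.0)

    def test_symmetry_under_exchange(self, rng):
        pep = frame(np.exp(rng.random((5, 6))), [f"p{i}" for i in range(5)])
        prot = frame(np.exp(rng.random((5, 6))), [f"q{i}" for i in range(5)])
        a = corr.pairwise_pearson(pep, prot, pairing(pep.index, prot.index))
        b = corr.pairwise_pearson(prot, pep, pairing(prot.index, pep.index))
        assert np.allclose(a["pearson_r"], b["pearson_r"])

    def test_sparse_rows_excluded_and_counted(self):
        pep = frame([[1, 2, 3, 4], [1, 0, 0, 0]], ["p1", "p2"])
        prot = frame([[1, 2, 3, 4], [2, 3, 4, 5]], ["q1", "q2"])
        table = corr.pairwise_pearson(pep, prot,
                                      pairing(["p1", "p2"], ["q1", "q2"]))
        assert len(table) == 1
        assert table.attrs["n_excluded"] + len(table) == table.attrs["n_total"]

    def test_null_tail_matches_analytic_fraction(self, rng):
        """Independent profiles: P(r > 0.7) follows the Pearson null at n=13."""
        n_pairs, n_t = 4000, 13
        pep = frame(np.exp(rng.standard_normal((n_pairs, n_t))),
                    [f"p{i}" for i in range(n_pairs)])
        prot = frame(np.exp(rng.standard_normal((n_pairs, n_t))),
                     [f"q{i}" for i in range(n_pairs)])
        table = corr.pairwise_pearson(pep, prot, pairing(pep.index, prot.index))
        observed = (table["pearson_r"] > 0.70).mean()
        r0 = 0.70
        t0 = r0 * np.sqrt((n_t - 2) / (1 - r0 ** 2))
        expected = stats.t.sf(t0, df=n_t - 2)
        assert observed == pytest.approx(expected, abs=3 * np.sqrt(
            expected * (1 - expected) / n_pairs) + 1e-3)


class TestNeighborPairing:
    GENES = pd.DataFrame({"chrom": ["chr1", "chr1"], "start": [10_000, 30_000]},
                         index=["gA", "gB"])

    def test_nearest_non_source_gene(self):
        pep = pd.DataFrame({"chrom": ["chr1"], "start": [11_000]}, index=["p1"])
        out = corr.neighbor_pairing(pep, self.GENES, {"p1": "gA"})
        assert out.iloc[0]["partner_id"] == "gB"
        assert out.iloc[0]["genomic_distance"] == 19_000

    def test_equidistant_tie_smaller_gene_id(self):
        genes = pd.DataFrame({"chrom": ["chr1"] * 3,
                              "start": [0, 10_000, 20_000]},
                             index=["gC", "gS", "gA"])
        pep = pd.DataFrame({"chrom": ["chr1"], "start": [10_000]}, index=["p1"])
        out = corr.neighbor_pairing(pep, genes, {"p1": "gS"})
        assert out.iloc[0]["partner_id"] == "gA"  # tie 10 kb each; gA < gC

    def test_single_gene_chromosome_excluded(self):
        pep = pd.DataFrame({"chrom": ["chr1"], "start": [11_000]}, index=["p1"])
        genes = self.GENES.iloc[:1]
        out = corr.neighbor_pairing(pep, genes, {"p1": "gA"})
        assert len(out) == 0

    def test_matches_exhaustive_search(self, rng):
        genes = pd.DataFrame({
            "chrom": rng.choice(["chr1", "chr2"], size=30),
            "start": rng.integers(0, 1_000_000, size=30)},
            index=[f"g{i:02d}" for i in range(30)])
        pep = pd.DataFrame({
            "chrom": rng.choice(["chr1", "chr2"], size=50),
            "start": rng.integers(0, 1_000_000, size=50)},
            index=[f"p{i:02d}" for i in range(50)])
        src = {p: f"g{i % 30:02d}" for i, p in enumerate(pep.index)}
        out = corr.neighbor_pairing(pep, genes, src).set_index("peptide_id")
        for pid, prow in pep.iterrows():
            cands = [
                (abs(int(prow["start"]) - int(grow["start"])), gid)
                for gid, grow in genes.iterrows()
                if grow["chrom"] == prow["chrom"] and gid != src[pid]]
            if not cands:
                assert pid not in out.index
                continue
            best = min(cands)
            assert out.at[pid, "partner_id"] == best[1]
            assert out.at[pid, "genomic_distance"] == best[0]


class TestSignedRank:
    def test_identical_samples_p_one(self):
        x = np.arange(10, dtype=float)
        assert corr.signed_rank_test(x, x) == 1.0

    def test_six_positive_differences_exact(self):
        x = np.array([5, 6, 7, 8, 9, 10], dtype=float)
        y = np.array([1, 2, 3, 4, 5, 6], dtype=float)
        assert corr.signed_rank_test(x, y) == pytest.approx(2 * (1 / 2 ** 6))

    def test_matches_scipy_exact_mode(self, rng):
        for _ in range(60):
            n = int(rng.integers(6, 20))
            x = rng.standard_normal(n)
            y = x + rng.standard_normal(n) * 0.8 + 0.3
            mine = corr.signed_rank_test(x, y)
            # tie-free draws: scipy's exact two-sided null is the oracle
            oracle = stats.wilcoxon(x, y, mode="exact").pvalue
            assert mine == pytest.approx(oracle, rel=1e-9)

    def test_large_n_approximation_close_to_scipy(self, rng):
        x = rng.standard_normal(200)
        y = x + rng.standard_normal(200) * 0.5 + 0.1
        mine = corr.signed_rank_test(x, y)
        oracle = stats.wilcoxon(x, y, correction=True, mode="approx").pvalue
        assert mine == pytest.approx(oracle, rel=0.1)


class TestHighCorrelationSet:
    def test_all_zero_pairs_empty(self):
        pairs = pd.DataFrame({"peptide_id": ["p1"], "partner_id": ["q1"],
                              "pearson_r": [0.0]})
        subset, enr = corr.high_correlation_set(pairs)
        assert len(subset) == 0 and len(enr) == 0

    def test_threshold_is_strict(self):
        pairs = pd.DataFrame({"peptide_id": ["p1", "p2"],
                              "partner_id": ["q1", "q2"],
                              "pearson_r": [0.70, 0.700001]})
        subset, _ = corr.high_correlation_set(pairs, r_min=0.70)
        assert list(subset["peptide_id"]) == ["p2"]

    def test_planted_term_top_enriched(self):
        rs = [0.9] * 10 + [0.1] * 30
        pairs = pd.DataFrame({
            "peptide_id": [f"p{i}" for i in range(40)],
            "partner_id": [f"g{i}" for i in range(40)],
            "pearson_r": rs})
        term_map = {"T": {f"g{i}" for i in range(10)},
                    "U": {f"g{i}" for i in range(10, 40)}}
        _, enr = corr.high_correlation_set(
            pairs, term_map=term_map, universe={f"g{i}" for i in range(40)})
        assert enr.iloc[0]["term"] == "T"


class TestDistanceBinned:
    def test_single_bin_mean_equals_overall(self):
        pairs = pd.DataFrame({"genomic_distance": [10, 20, 30],
                              "pearson_r": [0.1, 0.2, 0.6]})
        out = corr.distance_binned_correlation(pairs)
        assert out.iloc[0]["mean_r"] == pytest.approx(0.3)
        assert out.iloc[0]["n_pairs"] == 3

    def test_half_open_bin_convention(self):
        pairs = pd.DataFrame({"genomic_distance": [50_000], "pearson_r": [0.5]})
        out = corr.distance_binned_correlation(pairs)
        assert out.iloc[1]["n_pairs"] == 1  # exactly 50 kb -> second bin
        assert out.iloc[0]["n_pairs"] == 0

    def test_planted_decay_strictly_decreasing(self):
        from pepatlas import synthetic as syn

        atlas = syn.generate_atlas(syn.decay_benchmark_config(seed=0))
        idx = atlas.peptides.index
        pos = pd.DataFrame(
            {"chrom": [atlas.truth.genomic_start[p][0] for p in idx],
             "start": [atlas.truth.genomic_start[p][1] for p in idx]},
            index=idx)
        pp = corr.adjacent_peptide_pairing(pos)
        pairs = corr.pairwise_pearson(atlas.abundance, atlas.abundance, pp)
        out = corr.distance_binned_correlation(pairs)
        means = out["mean_r"].to_numpy()[:4]
        assert (np.diff(means) < 0).all()

    def test_decay_rank_correlation_over_seeds(self):
        """Bin index anti-correlates with bin mean r, seed averaged."""
        from pepatlas import synthetic as syn

        rhos = []
        for seed in range(8):
            atlas = syn.generate_atlas(syn.decay_benchmark_config(seed=seed))
            idx = atlas.peptides.index
            pos = pd.DataFrame(
                {"chrom": [atlas.truth.genomic_start[p][0] for p in idx],
                 "start": [atlas.truth.genomic_start[p][1] for p in idx]},
                index=idx)
            pp = corr.adjacent_peptide_pairing(pos)
            pairs = corr.pairwise_pearson(atlas.abundance, atlas.abundance, pp)
            means = corr.distance_binned_correlation(pairs)["mean_r"][:4]
            rhos.append(stats.spearmanr(np.arange(4), means).statistic)
        assert np.mean(rhos) <= -0.9
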