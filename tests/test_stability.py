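import numpy as np
import pytest

from refstab import (
    bestkeeper_ranking,
    bestkeeper_stats,
    delta_ct_stability,
    genorm_m_values,
    genorm_pairwise_variation,
    genorm_ranking,
    normfinder_stability,
    to_relative_quantity,
)
from refstab.ct_data import CtValidationError
from refstab.stability import BestKeeperStats, QuantityMatrix

import oracles
from conftest import as_quantity, make_ct, random_ct


def make_q(values, genes=None, samples=None, eff=2.0) -> QuantityMatrix:
    arr = np.asarray(values, dtype=float)
    genes = genes or [f"g{i + 1}" for i in range(arr.shape[0])]
    samples = samples or [f"s{i + 1}" for i in range(arr.shape[1])]
    return QuantityMatrix(list(genes), list(samples), arr, {g: eff for g in genes})


class TestRelativeQuantity:
    def test_doubling_per_cycle(self):
        m = make_ct([[20.0, 21.0, 22.0]])
        q = to_relative_quantity(m, 2.0)
        np.testing.assert_allclose(q.q[0], [1.0, 0.5, 0.25])

    def test_constant_gene_all_ones(self):
        q = to_relative_quantity(make_ct(np.full((1, 4), 23.0)))
        np.testing.assert_allclose(q.q, 1.0)

    def test_measured_efficiency(self):
        m = make_ct([[20.0, 21.0]])
        q = to_relative_quantity(m, 1.93)
        assert q.q[0, 1] == pytest.approx(1.0 / 1.93)

    def test_per_gene_max_is_one(self):
        rng = np.random.default_rng(0)
        q = to_relative_quantity(random_ct(rng, 5, 9), {"g1": 1.9, "g2": 2.1})
        np.testing.assert_allclose(q.q.max(axis=1), 1.0)

    def test_efficiency_below_one_rejected(self):
        with pytest.raises(CtValidationError, match="> 1"):
            to_relative_quantity(make_ct([[20.0, 21.0]]), 0.9)

    def test_missing_cell_rejected(self):
        with pytest.raises(CtValidationError, match="missing"):
            to_relative_quantity(make_ct([[20.0, np.nan]]))


class TestDeltaCt:
    def test_constant_offset_pair_is_perfectly_stable(self):
        base = np.array([20.0, 21.0, 19.5, 22.0])
        m = make_ct(np.vstack([base, base + 3.0]))
        t = delta_ct_stability(m)
        assert t.values["g1"] == pytest.approx(0.0)
        assert t.values["g2"] == pytest.approx(0.0)

    def test_per_sample_shift_cancels(self):
        rng = np.random.default_rng(1)
        m = random_ct(rng, 4, 6)
        shift = rng.normal(0, 2, 6)
        m2 = make_ct(m.values2d() + shift[None, :])
        t1, t2 = delta_ct_stability(m), delta_ct_stability(m2)
        for g in m.genes:
            assert t1.values[g] == pytest.approx(t2.values[g], abs=1e-12)

    def test_matches_pair_enumeration_oracle(self):
        rng = np.random.default_rng(2)
        m = random_ct(rng, 4, 6)
        t = delta_ct_stability(m)
        expected = oracles.delta_ct_oracle(m.values2d().tolist())
        np.testing.assert_allclose(list(t.values.values()), expected, rtol=1e-12)

    def test_needs_two_genes(self):
        with pytest.raises(CtValidationError, match="2 genes"):
            delta_ct_stability(make_ct([[20.0, 21.0]]))


class TestGenormM:
    def test_two_genes_share_log_ratio_sd(self):
        rng = np.random.default_rng(3)
        q = as_quantity(random_ct(rng, 2, 8))
        m = genorm_m_values(q)
        sd = np.std(np.log2(q.q[0] / q.q[1]), ddof=1)
        assert m["g1"] == pytest.approx(sd)
        assert m["g2"] == pytest.approx(sd)

    def test_proportional_genes_zero_pair_variation(self):
        rng = np.random.default_rng(4)
        row = rng.uniform(0.1, 1.0, 6)
        q = make_q(np.vstack([row, 0.5 * row, rng.uniform(0.1, 1, 6)]))
        m = genorm_m_values(q)
        # g1 and g2 have a constant ratio; their M values differ only through g3
        a = np.log2(q.q)
        v13 = np.std(a[0] - a[2], ddof=1)
        v23 = np.std(a[1] - a[2], ddof=1)
        assert m["g1"] == pytest.approx(v13 / 2)
        assert m["g2"] == pytest.approx(v23 / 2)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(5)
        q = as_quantity(random_ct(rng, 5, 8))
        m = genorm_m_values(q)
        expected = oracles.genorm_m_oracle(q.q.tolist())
        np.testing.assert_allclose(list(m.values()), expected, rtol=1e-12)


class TestGenormRanking:
    def test_final_pair_shares_rank_one_third_gets_three(self):
        rng = np.random.default_rng(6)
        q = as_quantity(random_ct(rng, 6, 10))
        t = genorm_ranking(q)
        ranks = sorted(t.ranks.values())
        assert ranks == [1, 1, 3, 4, 5, 6]
        pair = [g for g, r in t.ranks.items() if r == 1]
        assert t.values[pair[0]] == pytest.approx(t.values[pair[1]])

    def test_noisy_gene_eliminated_first(self):
        rng = np.random.default_rng(7)
        profile = rng.uniform(0.2, 1.0, 8)
        rows = [profile, 0.7 * profile, 0.4 * profile]
        noisy = profile * 2 ** rng.normal(0, 1.0, 8)
        q = make_q(np.vstack(rows + [noisy / noisy.max()]))
        t = genorm_ranking(q)
        assert t.ranks["g4"] == 4  # eliminated first, strictly largest M

    def test_elimination_order_matches_stepwise_oracle(self):
        rng = np.random.default_rng(8)
        q = as_quantity(random_ct(rng, 6, 9))
        t = genorm_ranking(q)
        oracle_order = oracles.genorm_elimination_oracle(q.q.tolist(), q.genes)
        # oracle lists first-removed first; ranks decrease G, G-1, ..., 3
        for pos, gene in enumerate(oracle_order):
            assert t.ranks[gene] == len(q.genes) - pos

    def test_reported_value_is_elimination_step_m(self):
        rng = np.random.default_rng(9)
        q = as_quantity(random_ct(rng, 5, 8))
        t = genorm_ranking(q)
        first_out = [g for g, r in t.ranks.items() if r == 5][0]
        assert t.values[first_out] == pytest.approx(
            genorm_m_values(q)[first_out]
        )

    def test_requires_three_genes(self):
        rng = np.random.default_rng(10)
        with pytest.raises(CtValidationError, match="genorm_m_values"):
            genorm_ranking(as_quantity(random_ct(rng, 2, 5)))


class TestPairwiseVariation:
    def test_proportional_extra_gene_gives_zero_v(self):
        rng = np.random.default_rng(11)
        rows = [rng.uniform(0.1, 1.0, 8) for _ in range(3)]
        # gene 4 proportional to the geometric mean of the first three
        nf = np.exp(np.mean(np.log(np.vstack(rows)), axis=0))
        q = make_q(np.vstack(rows + [nf / nf.max()]))
        v = genorm_pairwise_variation(q, 3, order=q.genes)
        assert v["V3/4"] == pytest.approx(0.0, abs=1e-12)

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(12)
        q = as_quantity(random_ct(rng, 5, 9))
        order = list(q.genes)
        v = genorm_pairwise_variation(q, 4, order=order)
        logq = np.log2(q.q)
        for n in range(2, 5):
            expected = np.std(
                logq[:n].mean(axis=0) - logq[: n + 1].mean(axis=0), ddof=1
            )
            assert v[f"V{n}/{n + 1}"] == pytest.approx(expected, rel=1e-12)

    def test_sample_permutation_invariant(self):
        rng = np.random.default_rng(13)
        q = as_quantity(random_ct(rng, 5, 9))
        perm = rng.permutation(9)
        qp = make_q(q.q[:, perm], genes=q.genes)
        v1 = genorm_pairwise_variation(q, 3, order=q.genes)
        v2 = genorm_pairwise_variation(qp, 3, order=q.genes)
        np.testing.assert_allclose(v1.values, v2.values)

    def test_max_n_bound(self):
        rng = np.random.default_rng(14)
        q = as_quantity(random_ct(rng, 4, 6))
        with pytest.raises(CtValidationError, match="max_n"):
            genorm_pairwise_variation(q, 4)


class TestNormFinder:
    def test_pure_sample_effect_gives_zero_svs(self):
        load = np.array([1.0, 0.5, 0.25, 0.8, 0.3])
        q = make_q(np.vstack([load, load * 0.5, load * 0.1, load * 0.9]))
        t = normfinder_stability(q)
        assert all(v == pytest.approx(0.0, abs=1e-9) for v in t.values.values())

    def test_per_sample_shift_cancels(self):
        rng = np.random.default_rng(15)
        q = as_quantity(random_ct(rng, 5, 10))
        scale = 2 ** rng.normal(0, 1, 10)
        q2 = make_q(q.q * scale[None, :], genes=q.genes)
        t1, t2 = normfinder_stability(q), normfinder_stability(q2)
        for g in q.genes:
            assert t1.values[g] == pytest.approx(t2.values[g], abs=1e-10)

    def test_matches_decomposition_oracle_ungrouped(self):
        rng = np.random.default_rng(16)
        q = as_quantity(random_ct(rng, 5, 10))
        t = normfinder_stability(q)
        expected = oracles.normfinder_oracle(q.q.tolist())
        np.testing.assert_allclose(list(t.values.values()), expected, rtol=1e-10)

    def test_matches_decomposition_oracle_grouped(self):
        rng = np.random.default_rng(17)
        q = as_quantity(random_ct(rng, 5, 10))
        labels = ["a"] * 5 + ["b"] * 5
        groups = dict(zip(q.samples, labels))
        t = normfinder_stability(q, groups)
        expected = oracles.normfinder_grouped_oracle(q.q.tolist(), labels)
        np.testing.assert_allclose(list(t.values.values()), expected, rtol=1e-10)

    def test_grouped_detects_tissue_biased_gene(self):
        rng = np.random.default_rng(18)
        S = 12
        labels = ["a"] * 6 + ["b"] * 6
        base = rng.normal(0, 0.05, (4, S))
        base[0, 6:] += 3.0  # gene 1 jumps 3 cycles in group b
        q = make_q(2.0 ** (base - base.max(axis=1, keepdims=True)))
        t = normfinder_stability(q, dict(zip(q.samples, labels)))
        assert t.ranks["g1"] == 4

    def test_singleton_group_rejected(self):
        rng = np.random.default_rng(19)
        q = as_quantity(random_ct(rng, 3, 3))
        groups = {"s1": "a", "s2": "a", "s3": "b"}
        with pytest.raises(CtValidationError, match="fewer than 2"):
            normfinder_stability(q, groups)

    def test_requires_three_genes(self):
        rng = np.random.default_rng(20)
        with pytest.raises(CtValidationError, match="3 genes"):
            normfinder_stability(as_quantity(random_ct(rng, 2, 5)))


class TestBestKeeper:
    def test_constant_gene_degenerate_correlation(self):
        vals = np.vstack([np.full(5, 20.0), np.linspace(19, 23, 5)])
        with pytest.warns(UserWarning, match="zero variance"):
            stats = bestkeeper_stats(make_ct(vals))
        row = stats.per_gene.loc["g1"]
        assert row["sd_ct"] == 0.0 and row["cv_pct"] == 0.0
        assert np.isnan(row["r_vs_index"])

    def test_shift_changes_cv_not_sd(self):
        rng = np.random.default_rng(21)
        m = random_ct(rng, 3, 8)
        shifted = m.values2d().copy()
        shifted[0] += 5.0
        s1 = bestkeeper_stats(m).per_gene
        s2 = bestkeeper_stats(make_ct(shifted)).per_gene
        assert s2.loc["g1", "sd_ct"] == pytest.approx(s1.loc["g1", "sd_ct"])
        assert s2.loc["g1", "cv_pct"] < s1.loc["g1", "cv_pct"]
        assert s2.loc["g1", "geo_mean_ct"] > s1.loc["g1", "geo_mean_ct"]

    def test_matches_per_formula_oracle(self):
        rng = np.random.default_rng(22)
        m = random_ct(rng, 6, 8)
        stats = bestkeeper_stats(m)
        expected = oracles.bestkeeper_oracle(m.values2d().tolist())
        for col in ("sd_ct", "cv_pct", "geo_mean_ct", "r_vs_index"):
            np.testing.assert_allclose(
                stats.per_gene[col].to_numpy(), expected[col], rtol=1e-10
            )
        np.testing.assert_allclose(stats.index.to_numpy(), expected["index"], rtol=1e-12)

    def test_ranking_by_sd(self):
        import pandas as pd

        per_gene = pd.DataFrame(
            {"sd_ct": [0.22, 0.41, 0.50], "cv_pct": [1.0, 2.0, 3.0],
             "geo_mean_ct": [20, 20, 20], "r_vs_index": [0.9, 0.8, 0.7]},
            index=pd.Index(["a", "b", "c"], name="gene"),
        )
        t = bestkeeper_ranking(BestKeeperStats("all", per_gene, pd.Series(dtype=float)))
        assert t.ranks == {"a": 1, "b": 2, "c": 3}

    def test_equal_sds_tie_competition(self):
        import pandas as pd

        per_gene = pd.DataFrame(
            {"sd_ct": [0.3, 0.3, 0.5], "cv_pct": [1, 2, 3],
             "geo_mean_ct": [20, 20, 20], "r_vs_index": [0.9, 0.8, 0.7]},
            index=pd.Index(["a", "b", "c"], name="gene"),
        )
        t = bestkeeper_ranking(BestKeeperStats("all", per_gene, pd.Series(dtype=float)))
        assert sorted(t.ranks.values()) == [1, 1, 3]

    def test_sd_and_cv_criteria_can_disagree(self):
        # equal SD, unequal mean: CV ranks the high-Ct gene better
        a = np.array([20.0, 21.0, 20.0, 21.0])
        stats = bestkeeper_stats(make_ct(np.vstack([a, a + 10.0])))
        by_sd = bestkeeper_ranking(stats, by="sd")
        by_cv = bestkeeper_ranking(stats, by="cv")
        assert sorted(by_sd.ranks.values()) == [1, 1]  # tie on SD
        assert by_cv.ranks["g2"] == 1 and by_cv.ranks["g1"] == 2


class TestCrossMethod:
    def test_genorm_and_delta_ct_coincide_at_efficiency_two(self):
        """With E=2 the log2-ratio SD equals the delta-Ct SD, so per-gene
        mean pair dispersions are identical."""
        rng = np.random.default_rng(23)
        m = random_ct(rng, 5, 9)
        t_delta = delta_ct_stability(m)
        m_vals = genorm_m_values(to_relative_quantity(m, 2.0))
        for g in m.genes:
            assert m_vals[g] == pytest.approx(t_delta.values[g], rel=1e-10)

    def test_all_methods_zero_on_proportional_noise_free_genes(self):
        profile = np.array([20.0, 21.0, 19.0, 22.0, 20.5])
        ct = np.vstack([profile + d for d in (0.0, 1.0, 2.5, -0.5)])
        m = make_ct(ct)
        q = to_relative_quantity(m, 2.0)
        assert all(v == pytest.approx(0.0, abs=1e-10)
                   for v in delta_ct_stability(m).values.values())
        assert all(v == pytest.approx(0.0, abs=1e-10)
                   for v in genorm_m_values(q).values())
        assert all(v == pytest.approx(0.0, abs=1e-9)
                   for v in normfinder_stability(q).values.values())
        # BestKeeper sees the shared profile variation: SDs equal, nonzero
        sds = bestkeeper_stats(m).per_gene["sd_ct"]
        assert (sds > 0).all() and sds.nunique() == 1

    def test_log_base_choice_preserves_ranking(self):
        rng = np.random.default_rng(24)
        q = as_quantity(random_ct(rng, 5, 8))
        m2 = genorm_m_values(q)
        # geNorm in natural log = log2 values scaled by ln(2): same order
        a = np.log(q.q)
        m_e = {}
        for j, g in enumerate(q.genes):
            m_e[g] = np.mean(
                [np.std(a[j] - a[k], ddof=1) for k in range(5) if k != j]
            )
        order2 = sorted(q.genes, key=m2.get)
        order_e = sorted(q.genes, key=m_e.get)
        assert order2 == order_e
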