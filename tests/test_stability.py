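"""Five stability algorithms, oracle equivalence, and consensus ranking."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from refstab import (
    bestkeeper,
    consensus_rank,
    delta_cq_m,
    delta_cq_stability,
    genorm,
    normfinder,
)
from refstab.stability import QuantityMatrix, StabilityThresholds


def _qm(values: np.ndarray, groups=None, genes=None):
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = [f"s{j}" for j in range(values.shape[1])]
    if groups is None:
        half = values.shape[1] // 2
        groups = ["A"] * half + ["B"] * (values.shape[1] - half)
    info = pd.DataFrame(
        {
            "donor_id": samples,
            "cell_type": "NV",
            "activated": False,
            "timepoint_h": 2.0,
            "subgroup": groups,
        },
        index=samples,
    )
    vals = pd.DataFrame(values, index=genes, columns=samples)
    # normalize per gene so max = 1 (valid relative quantities)
    vals = vals.div(vals.max(axis=1), axis=0)
    return QuantityMatrix(values=vals, sample_info=info, efficiencies={g: 2.0 for g in genes})


def _random_quantities(rng, g, n):
    cq = rng.normal(20, 1.0, size=(g, n))
    return 2.0 ** (cq.min(axis=1, keepdims=True) - cq)


# --------------------------------------------------------------------------
# geNorm
# --------------------------------------------------------------------------


class TestGeNorm:
    def test_proportional_pair_wins_with_zero_pair_m(self):
        rng = np.random.default_rng(0)
        base = rng.uniform(0.1, 1.0, 20)
        vals = np.vstack([base, 0.5 * base, rng.uniform(0.05, 1.0, 20)])
        res = genorm(_qm(vals))
        assert set(res.final_pair) == {"g0", "g1"}
        assert res.final_pair_m == pytest.approx(0.0, abs=1e-12)

    def test_scale_invariance_of_m_values(self):
        rng = np.random.default_rng(1)
        vals = _random_quantities(rng, 5, 15)
        r1 = genorm(_qm(vals))
        scaled = vals.copy()
        scaled[2] *= 10  # _qm re-normalizes; log-ratios are scale-free anyway
        r2 = genorm(_qm(scaled))
        for g in r1.m_values:
            assert r1.m_values[g] == pytest.approx(r2.m_values[g], abs=1e-10)
        assert r1.exclusion_order == r2.exclusion_order

    def test_m_values_match_brute_force_oracle(self):
        # direct double loop over gene pairs, independent of the implementation
        for seed in range(50):
            rng = np.random.default_rng(seed)
            vals = _random_quantities(rng, 5, 20)
            q = _qm(vals)
            res = genorm(q)
            logq = np.log2(q.values.to_numpy())
            for i, g in enumerate(q.genes):
                sds = [
                    np.std(logq[i] - logq[k], ddof=1)
                    for k in range(5)
                    if k != i
                ]
                assert res.m_values[g] == pytest.approx(np.mean(sds), abs=1e-10)

    def test_final_pair_shares_final_m(self):
        rng = np.random.default_rng(3)
        res = genorm(_qm(_random_quantities(rng, 6, 12)))
        assert res.stepwise_m[-1][res.final_pair[0]] == res.stepwise_m[-1][res.final_pair[1]]

    def test_v_series_and_optimal_n(self):
        rng = np.random.default_rng(4)
        q = _qm(_random_quantities(rng, 6, 12))
        res = genorm(q)
        assert sorted(res.v_series) == [2, 3, 4, 5]
        # oracle for V(2,3) using the stability order implied by the result
        order = [g for g in [*res.final_pair, *res.exclusion_order[::-1]]]
        logq = np.log2(q.values.to_numpy())
        idx = {g: i for i, g in enumerate(q.genes)}
        nf2 = logq[[idx[g] for g in order[:2]]].mean(axis=0)
        nf3 = logq[[idx[g] for g in order[:3]]].mean(axis=0)
        assert res.v_series[2] == pytest.approx(np.std(nf2 - nf3, ddof=1), abs=1e-12)

    def test_optimal_n_threshold_selection(self):
        # two tightly proportional genes + looser ones: V(2,3) below 0.15
        rng = np.random.default_rng(5)
        n = 24
        base = rng.uniform(0.1, 1.0, n)
        noise = lambda s: np.exp(rng.normal(0, s, n))
        vals = np.vstack([base, base * noise(0.02), base * noise(0.25),
                          base * noise(0.35), rng.uniform(0.05, 1.0, n)])
        res = genorm(_qm(vals))
        assert res.v_series[2] < 0.15
        assert res.optimal_n == 2

    def test_fewer_than_three_genes_rejected(self):
        rng = np.random.default_rng(6)
        with pytest.raises(ValueError, match=">= 3"):
            genorm(_qm(_random_quantities(rng, 2, 10)))


# --------------------------------------------------------------------------
# NormFinder
# --------------------------------------------------------------------------


class TestNormFinder:
    def test_identical_genes_all_minimal_and_equal(self):
        rng = np.random.default_rng(0)
        profile = rng.uniform(0.1, 1.0, 16)
        vals = np.vstack([profile, 0.7 * profile, 0.4 * profile, 0.2 * profile])
        res = normfinder(_qm(vals))
        sv = list(res.stability_values.values())
        assert np.allclose(sv, sv[0], atol=1e-12)
        assert np.allclose(sv, 0.0, atol=1e-12)

    def test_intra_group_variance_matches_anova_oracle(self):
        # oracle: solve the moment equations of the sample-centered model
        # directly from naive variances (k genes couple through centering)
        rng = np.random.default_rng(42)
        vals = _random_quantities(rng, 5, 20)
        q = _qm(vals)
        res = normfinder(q)
        y = np.log2(q.values.to_numpy())
        z = y - y.mean(axis=0)
        k = 5
        for gi, lab in enumerate(res.groups):
            cols = np.asarray(q.subgroups()) == lab
            s2 = np.array([np.var(z[i, cols], ddof=1) for i in range(k)])
            oracle = np.clip((s2 - s2.mean() / (k - 1)) * k / (k - 2), 0, None)
            got = res.intra_group_variances[lab].to_numpy()
            assert np.allclose(got, oracle, atol=1e-10)

    def test_planted_group_shift_gene_is_least_stable(self):
        hits = 0
        n_seeds = 100
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            n = 20  # 10 per group
            cq = rng.normal(20, 0.3, size=(5, n))
            cq[4, n // 2:] += 1.5  # planted inter-group shift in gene 5
            vals = 2.0 ** (cq.min(axis=1, keepdims=True) - cq)
            res = normfinder(_qm(vals))
            worst = max(res.stability_values, key=res.stability_values.get)
            hits += worst == "g4"
        assert hits >= 95

    def test_group_with_single_sample_rejected(self):
        rng = np.random.default_rng(1)
        vals = _random_quantities(rng, 3, 5)
        with pytest.raises(ValueError, match="< 2 samples"):
            normfinder(_qm(vals, groups=["A", "A", "A", "A", "B"]))

    def test_best_pair_reported_with_value(self):
        rng = np.random.default_rng(2)
        res = normfinder(_qm(_random_quantities(rng, 5, 20)))
        assert len(res.best_pair) == 2
        assert res.best_pair_value >= 0
        assert res.best_gene == min(res.stability_values, key=res.stability_values.get)


# --------------------------------------------------------------------------
# BestKeeper
# --------------------------------------------------------------------------


def _cq_frame(rng, g=6, n=15, genes=None):
    genes = genes or [f"g{i}" for i in range(g)]
    return pd.DataFrame(rng.normal(20, 1, size=(len(genes), n)), index=genes,
                        columns=[f"s{j}" for j in range(n)])


class TestBestKeeper:
    def test_single_gene_index_self_correlates(self):
        rng = np.random.default_rng(0)
        cq = _cq_frame(rng, g=3)
        res = bestkeeper(cq, include_in_index=["g0"])
        assert np.allclose(res.index.to_numpy(), cq.loc["g0"].to_numpy())
        assert res.correlations["g0"] == pytest.approx(1.0)

    def test_constant_gene_sd_zero_most_stable(self):
        rng = np.random.default_rng(1)
        cq = _cq_frame(rng, g=3)
        cq.loc["g0"] = 20.0
        res = bestkeeper(cq)
        assert res.sd_values["g0"] == 0.0
        assert res.ranks()["g0"] == 1.0
        assert np.isnan(res.correlations["g0"])  # zero variance: r undefined

    def test_sd_and_correlations_match_brute_force(self):
        for seed in range(50):
            rng = np.random.default_rng(seed)
            cq = _cq_frame(rng, g=6, n=15)
            res = bestkeeper(cq)
            arr = cq.to_numpy()
            index = np.exp(np.log(arr).mean(axis=0))
            for i, g in enumerate(cq.index):
                assert res.sd_values[g] == pytest.approx(np.std(arr[i], ddof=1), abs=1e-10)
                r = np.corrcoef(arr[i], index)[0, 1]
                assert res.correlations[g] == pytest.approx(r, abs=1e-10)

    def test_sd_above_one_flagged_unstable(self):
        rng = np.random.default_rng(2)
        cq = _cq_frame(rng, g=3)
        cq.loc["g0"] = rng.normal(20, 1.2, cq.shape[1]) * 1.4  # inflate SD well past 1
        res = bestkeeper(cq)
        assert "g0" in res.unstable_genes

    def test_excluded_gene_removed_from_index_and_correlations(self):
        rng = np.random.default_rng(3)
        cq = _cq_frame(rng, g=4)
        res = bestkeeper(cq, exclude_from_correlation=["g3"])
        assert "g3" not in res.correlations
        others = np.exp(np.log(cq.drop(index="g3").to_numpy()).mean(axis=0))
        assert np.allclose(res.index.to_numpy(), others)

    def test_divergent_expression_level_gets_advisory_flag(self):
        rng = np.random.default_rng(4)
        cq = _cq_frame(rng, g=4)
        cq.loc["g0"] -= 14.0  # far below the panel mean, like an rRNA
        res = bestkeeper(cq)
        assert "g0" in res.advisory_heterogeneous


# --------------------------------------------------------------------------
# deltaCq and deltaCq*M
# --------------------------------------------------------------------------


class TestDeltaCq:
    def test_constant_offset_pair_has_zero_sd(self):
        rng = np.random.default_rng(0)
        a = rng.normal(20, 1, 10)
        cq = pd.DataFrame([a, a + 3.0, rng.normal(25, 1, 10)], index=["g0", "g1", "g2"])
        res = delta_cq_stability(cq)
        assert res.pair_sd.loc["g0", "g1"] == pytest.approx(0.0, abs=1e-12)
        assert res.pair_sd.equals(res.pair_sd.T)

    def test_shift_invariance(self):
        rng = np.random.default_rng(1)
        cq = _cq_frame(rng, g=4, n=8)
        r1 = delta_cq_stability(cq)
        shifted = cq.copy()
        shifted.loc["g2"] += 5.0
        r2 = delta_cq_stability(shifted)
        for g in cq.index:
            assert r1.mean_sd[g] == pytest.approx(r2.mean_sd[g], abs=1e-12)

    def test_hand_matrix_enumerated_oracle(self):
        cq = pd.DataFrame(
            [[20.0, 21.0, 19.5, 20.5],
             [22.0, 22.5, 21.0, 23.0],
             [18.0, 19.5, 18.5, 18.0]],
            index=["a", "b", "c"],
        )
        res = delta_cq_stability(cq)
        sd = lambda x: np.std(x, ddof=1)
        ab = sd(cq.loc["a"] - cq.loc["b"])
        ac = sd(cq.loc["a"] - cq.loc["c"])
        bc = sd(cq.loc["b"] - cq.loc["c"])
        assert res.mean_sd["a"] == pytest.approx((ab + ac) / 2, abs=1e-12)
        assert res.mean_sd["b"] == pytest.approx((ab + bc) / 2, abs=1e-12)
        assert res.mean_sd["c"] == pytest.approx((ac + bc) / 2, abs=1e-12)


class TestDeltaCqM:
    def _cq_groups(self):
        cq = pd.DataFrame(
            [[20.0, 20.0, 21.0, 21.0],  # group means differ by 1
             [22.0, 22.0, 22.0, 22.0]],  # equal group means
            index=["a", "b"],
        )
        return cq, ["A", "A", "B", "B"]

    def test_equal_group_means_give_zero(self):
        cq, groups = self._cq_groups()
        res = delta_cq_m(cq, groups, {"a": 0.5, "b": 0.5})
        assert res.per_comparison[("A", "B")]["b"] == pytest.approx(0.0)

    def test_zero_m_gives_zero_regardless_of_difference(self):
        cq, groups = self._cq_groups()
        res = delta_cq_m(cq, groups, {"a": 0.0, "b": 0.5})
        assert res.per_comparison[("A", "B")]["a"] == pytest.approx(0.0)

    def test_arithmetic(self):
        cq = pd.DataFrame([[20.0, 20.0, 20.4, 20.4]], index=["a"])
        res = delta_cq_m(cq, ["A", "A", "B", "B"], {"a": 0.5})
        assert res.per_comparison[("A", "B")]["a"] == pytest.approx(0.2)

    def test_empty_group_comparison_rejected(self):
        cq, groups = self._cq_groups()
        with pytest.raises(ValueError, match="empty group"):
            delta_cq_m(cq, groups, {"a": 0.5, "b": 0.5}, comparisons=[("A", "C")])

    def test_comprehensive_rank_is_gm_of_per_comparison_ranks(self):
        rng = np.random.default_rng(5)
        cq = _cq_frame(rng, g=4, n=12)
        groups = ["A"] * 4 + ["B"] * 4 + ["C"] * 4
        m = {g: 0.3 + i * 0.1 for i, g in enumerate(cq.index)}
        res = delta_cq_m(cq, groups, m)
        for g in cq.index:
            ranks = [res.per_comparison_ranks[c][g] for c in res.comparisons_used]
            assert res.comprehensive_gm[g] == pytest.approx(
                np.exp(np.mean(np.log(ranks))), abs=1e-12
            )


# --------------------------------------------------------------------------
# consensus
# --------------------------------------------------------------------------


class TestConsensus:
    def test_unanimous_methods_preserve_order(self):
        ranks = {m: {"a": 1, "b": 2, "c": 3} for m in ("m1", "m2", "m3")}
        res = consensus_rank(ranks)
        assert res.final_order == ["a", "b", "c"]
        assert res.ties == []

    def test_seven_gene_panel_known_ranks(self):
        # rank tuples of a real seven-gene panel across the five methods:
        # the consensus must put the ribosomal RNA first and IPO8 second
        per_gene = {
            "18S rRNA": (1, 2, 1, 3, 1),
            "IPO8": (2, 1, 3, 1, 3),
            "RPLP0": (3, 5, 5, 6, 2),
            "UBE2D2": (4, 3, 2, 4, 5),
            "SDHA": (5, 4, 4, 2, 4),
            "B2M": (6, 6, 6, 5, 7),
            "CASC3": (7, 7, 7, 7, 6),
        }
        methods = ["normfinder", "delta_cq", "bestkeeper", "genorm", "delta_cq_m"]
        ranks = {m: {g: per_gene[g][i] for g in per_gene} for i, m in enumerate(methods)}
        res = consensus_rank(ranks)
        assert res.final_order[0] == "18S rRNA"
        assert res.final_order[1] == "IPO8"
        gm = res.geo_mean_rank
        assert gm["18S rRNA"] == pytest.approx(6 ** 0.2, abs=1e-12)
        assert gm["IPO8"] == pytest.approx(18 ** 0.2, abs=1e-12)

    def test_symmetric_tie_reported_and_broken_deterministically(self):
        ranks = {"m1": {"a": 1, "b": 2}, "m2": {"a": 2, "b": 1}}
        res = consensus_rank(ranks)
        assert ("a", "b") in res.ties
        assert res.final_order == ["a", "b"]  # lexicographic tie-break

    def test_mismatched_gene_sets_listed(self):
        ranks = {"m1": {"a": 1, "b": 2}, "m2": {"a": 1, "c": 2}}
        with pytest.raises(ValueError, match="difference.*'b'"):
            consensus_rank(ranks)


# --------------------------------------------------------------------------
# cross-method invariances
# --------------------------------------------------------------------------


def test_sample_permutation_invariance_of_all_scores():
    rng = np.random.default_rng(11)
    vals = _random_quantities(rng, 5, 16)
    groups = (["A"] * 8 + ["B"] * 8)
    perm = rng.permutation(16)
    q1 = _qm(vals, groups=groups)
    q2 = _qm(vals[:, perm], groups=[groups[p] for p in perm])
    for g, a, b in zip(q1.genes, genorm(q1).m_values.values(), genorm(q2).m_values.values()):
        assert a == pytest.approx(b, abs=1e-10)
    nf1, nf2 = normfinder(q1), normfinder(q2)
    for g in q1.genes:
        assert nf1.stability_values[g] == pytest.approx(nf2.stability_values[g], abs=1e-10)
    cq = pd.DataFrame(rng.normal(20, 1, (4, 12)), index=list("wxyz"))
    cqp = cq.iloc[:, rng.permutation(12)]
    d1, d2 = delta_cq_stability(cq), delta_cq_stability(cqp)
    for g in cq.index:
        assert d1.mean_sd[g] == pytest.approx(d2.mean_sd[g], abs=1e-10)
    b1, b2 = bestkeeper(cq), bestkeeper(cqp)
    for g in cq.index:
        assert b1.sd_values[g] == pytest.approx(b2.sd_values[g], abs=1e-10)


def test_gene_order_does_not_affect_scores():
    rng = np.random.default_rng(12)
    vals = _random_quantities(rng, 5, 14)
    genes = [f"g{i}" for i in range(5)]
    q1 = _qm(vals, genes=genes)
    order = [3, 1, 4, 0, 2]
    q2 = _qm(vals[order], genes=[genes[i] for i in order])
    m1, m2 = genorm(q1).m_values, genorm(q2).m_values
    for g in genes:
        assert m1[g] == pytest.approx(m2[g], abs=1e-10)
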