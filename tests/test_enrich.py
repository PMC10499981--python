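"""Single-sample enrichment scoring and derived scores."""

import numpy as np
import pandas as pd
import pytest

from ucbranch.enrich import (
    DdrScore,
    EnrichmentParams,
    GeneSetCollection,
    GeneSetSkipped,
    ddr_score,
    read_gmt,
    regulon_activity,
    score_matrix,
    ssgsea_es,
    ssgsea_nes,
    write_gmt,
)
from ucbranch.quant import AbundanceMatrix
from ucbranch.stats import spearman, wilcoxon_rank_sum


def oracle_es(profile: pd.Series, gene_set, weight=0.75, rank_norm=True):
    """Brute-force running-sum oracle (naive loop, distinct values only)."""
    items = sorted(profile.items(), key=lambda kv: -kv[1])
    n = len(items)
    if rank_norm:
        r = {name: n - i for i, (name, _) in enumerate(items)}
    else:
        r = dict(items)
    members = set(gene_set)
    total_w = sum(abs(r[name]) ** weight for name, _ in items if name in members)
    n_set = len(members & set(profile.index))
    running = 0.0
    area = 0.0
    for name, _ in items:
        if name in members:
            running += abs(r[name]) ** weight / total_w
        else:
            running -= 1.0 / (n - n_set)
        area += running
    return area / n


def _profile(rng, n=40):
    return pd.Series(rng.normal(size=n), index=[f"g{i}" for i in range(n)])


class TestEs:
    def test_top_vs_bottom_monotonicity(self):
        rng = np.random.default_rng(20)
        prof = pd.Series(np.arange(10, 0, -1, dtype=float),
                         index=[f"g{i}" for i in range(10)])
        params = EnrichmentParams(min_overlap=2, seed=1)
        top = ssgsea_es(prof, ["g0", "g1"], params)
        bottom = ssgsea_es(prof, ["g8", "g9"], params)
        assert top > 0 > bottom

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(21)
        params = EnrichmentParams(min_overlap=2, seed=3)
        for _ in range(50):
            prof = _profile(rng)
            gene_set = list(rng.choice(prof.index, size=6, replace=False))
            assert ssgsea_es(prof, gene_set, params) == pytest.approx(
                oracle_es(prof, gene_set), abs=1e-12
            )

    def test_min_overlap_skip(self):
        rng = np.random.default_rng(22)
        prof = _profile(rng)
        with pytest.raises(GeneSetSkipped, match="min.overlap"):
            ssgsea_es(prof, [f"g{i}" for i in range(4)], EnrichmentParams())

    def test_complement_symmetry_at_weight_zero(self):
        rng = np.random.default_rng(23)
        prof = _profile(rng, n=30)
        params = EnrichmentParams(weight=0.0, min_overlap=2, seed=5)
        members = [f"g{i}" for i in range(0, 30, 3)]
        complement = [g for g in prof.index if g not in members]
        es = ssgsea_es(prof, members, params)
        es_c = ssgsea_es(prof, complement, params)
        assert es_c == pytest.approx(-es, abs=1e-12)

    def test_rank_invariance_to_monotone_transform(self):
        rng = np.random.default_rng(24)
        prof = _profile(rng)
        params = EnrichmentParams(min_overlap=2, seed=7)
        gene_set = list(prof.index[:6])
        assert ssgsea_es(np.exp(prof), gene_set, params) == pytest.approx(
            ssgsea_es(prof, gene_set, params), abs=1e-12
        )


class TestNes:
    def test_seed_determinism(self):
        rng = np.random.default_rng(25)
        prof = _profile(rng)
        params = EnrichmentParams(min_overlap=2, n_permutations=200, seed=9)
        gene_set = list(prof.index[5:11])
        assert ssgsea_nes(prof, gene_set, params) == ssgsea_nes(prof, gene_set, params)

    def test_top_k_set_exceeds_null(self):
        prof = pd.Series(np.arange(50, 0, -1, dtype=float),
                         index=[f"g{i}" for i in range(50)])
        params = EnrichmentParams(min_overlap=2, n_permutations=300, seed=11)
        nes = ssgsea_nes(prof, [f"g{i}" for i in range(6)], params)
        assert nes > 1.0

    def test_null_mean_near_zero_unweighted(self):
        # the running sum is symmetric (hence the NES null centered) only
        # at weight 0: positive rank weights bias ES of random sets upward,
        # a known property of weighted single-sample enrichment
        rng = np.random.default_rng(26)
        params = EnrichmentParams(weight=0.0, min_overlap=2,
                                  n_permutations=100, seed=13)
        values = []
        for _ in range(400):
            prof = _profile(rng)
            gene_set = list(rng.choice(prof.index, size=6, replace=False))
            values.append(ssgsea_nes(prof, gene_set, params))
        assert abs(np.mean(values)) < 0.1


class TestScoreMatrix:
    def _matrix(self, rng, n_samples=8, n_features=30):
        values = pd.DataFrame(
            rng.normal(size=(n_samples, n_features)),
            index=[f"s{i}" for i in range(n_samples)],
            columns=[f"g{i}" for i in range(n_features)],
        )
        return AbundanceMatrix(values=values, scale="log2FOT",
                               mask=values.isna())

    def test_shift_and_order_invariance(self):
        rng = np.random.default_rng(27)
        mat = self._matrix(rng)
        sets = GeneSetCollection({"S": [f"g{i}" for i in range(6)]})
        params = EnrichmentParams(min_overlap=2, n_permutations=50, seed=15)
        base, _ = score_matrix(mat, sets, params)
        shifted = AbundanceMatrix(values=mat.values + 5.0, scale="log2FOT")
        out_shift, _ = score_matrix(shifted, sets, params)
        assert np.allclose(base.to_numpy(), out_shift.to_numpy())
        permuted = AbundanceMatrix(
            values=mat.values[list(reversed(mat.values.columns))], scale="log2FOT"
        )
        out_perm, _ = score_matrix(permuted, sets, params)
        assert np.allclose(base.to_numpy(), out_perm.to_numpy())

    def test_detects_injected_pathway_effect(self):
        rng = np.random.default_rng(28)
        n = 30
        values = pd.DataFrame(
            rng.normal(size=(n, 40)),
            index=[f"s{i}" for i in range(n)],
            columns=[f"g{i}" for i in range(40)],
        )
        members = [f"g{i}" for i in range(8)]
        values.loc[values.index[: n // 2], members] += 2.0
        mat = AbundanceMatrix(values=values, scale="log2FOT")
        params = EnrichmentParams(min_overlap=5, n_permutations=100, seed=17)
        scores, _ = score_matrix(mat, GeneSetCollection({"PW": members}), params)
        a = scores["PW"].iloc[: n // 2].to_numpy()
        b = scores["PW"].iloc[n // 2 :].to_numpy()
        assert wilcoxon_rank_sum(a, b).p_value < 0.01


class TestDdrScore:
    def _mat(self, data):
        values = pd.DataFrame(data, index=["s1", "s2", "s3"])
        return AbundanceMatrix(values=values, scale="log2FOT")

    def test_hand_standardization(self):
        mat = self._mat({"m1": [1.0, 2.0, 3.0], "m2": [10.0, 20.0, 30.0]})
        res = ddr_score(mat, ["m1", "m2"])
        assert np.allclose(res.scores, [-1.0, 0.0, 1.0])

    def test_symmetric_cancellation(self):
        mat = self._mat({"m1": [1.0, 2.0, 3.0], "m2": [3.0, 2.0, 1.0]})
        res = ddr_score(mat, ["m1", "m2"])
        assert np.allclose(res.scores, 0.0)

    def test_rescaling_invariance(self):
        mat1 = self._mat({"m1": [1.0, 2.0, 3.0], "m2": [5.0, 9.0, 6.0]})
        mat2 = self._mat({"m1": [1.0, 2.0, 3.0], "m2": [500.0, 900.0, 600.0]})
        assert np.allclose(
            ddr_score(mat1, ["m1", "m2"]).scores, ddr_score(mat2, ["m1", "m2"]).scores
        )

    def test_column_standardization_invariants(self):
        rng = np.random.default_rng(29)
        values = pd.DataFrame(rng.normal(size=(12, 5)),
                              index=[f"s{i}" for i in range(12)],
                              columns=[f"m{i}" for i in range(5)])
        mat = AbundanceMatrix(values=values, scale="log2FOT")
        markers = list(values.columns)
        z = (values - values.mean()) / values.std(ddof=1)
        assert np.allclose(z.mean(), 0.0, atol=1e-12)
        assert np.allclose(z.std(ddof=1), 1.0)
        assert np.allclose(ddr_score(mat, markers).scores, z.mean(axis=1))

    def test_no_marker_error(self):
        mat = self._mat({"m1": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError):
            ddr_score(mat, ["absent"])


class TestRegulon:
    def test_min_size_skip_and_positive_activity(self):
        rng = np.random.default_rng(30)
        values = pd.DataFrame(
            rng.normal(size=(4, 40)),
            index=[f"s{i}" for i in range(4)],
            columns=[f"g{i}" for i in range(40)],
        )
        targets = [f"g{i}" for i in range(10)]
        values[targets] += 3.0  # all targets top-ranked
        mat = AbundanceMatrix(values=values, scale="log2FOT")
        regs = GeneSetCollection({"SMALL": targets[:9], "AP1": targets})
        params = EnrichmentParams(output="ES", seed=19)
        scores, skipped = regulon_activity(mat, regs, params=params)
        assert skipped == {"SMALL": "min_size"}
        assert (scores["AP1"] > 0).all()

    def test_repressor_negatively_correlated_with_activity(self, small_bundle,
                                                           small_protein_matrix):
        """Emulates repressor-regulon coupling: activity tracks -repressor."""
        truth = small_bundle.truth
        regs = GeneSetCollection({truth.regulon_name:
                                  small_bundle.gene_sets.sets[truth.regulon_name]})
        params = EnrichmentParams(output="ES", seed=21)
        scores, _ = regulon_activity(small_protein_matrix, regs, params=params)
        repressor = small_protein_matrix.values[truth.repressor_id]
        res = spearman(repressor.to_numpy(), scores[truth.regulon_name].to_numpy())
        assert res.effect < 0
        assert res.p_value < 0.05


def test_gmt_round_trip(tmp_path):
    sets = GeneSetCollection({"A": ["g1", "g2", "g3"], "B": ["g4"]})
    path = tmp_path / "sets.gmt"
    write_gmt(sets, path)
    back = read_gmt(path)
    assert back.sets == sets.sets
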