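"""Quantification chain: digestion, iBAQ, FOT, RT model, MBR, imputation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ucbranch.quant import (
    FOT_FLOOR,
    FOT_SCALE,
    AbundanceMatrix,
    compute_ibaq,
    count_observable_peptides,
    digest_tryptic,
    filter_and_impute,
    fit_rt_model,
    fot_matrix,
    ibaq_matrix,
    match_between_runs,
    normalize_fot,
    read_matrix_tsv,
    write_matrix_tsv,
)


def oracle_digest(seq):
    """Independent digestion oracle: explicit cleavage-site scan."""
    sites = [
        i + 1
        for i in range(len(seq) - 1)
        if seq[i] in "KR" and seq[i + 1] != "P"
    ]
    bounds = [0, *sites, len(seq)]
    return [seq[a:b] for a, b in zip(bounds[:-1], bounds[1:]) if b > a]


class TestDigestion:
    @pytest.mark.parametrize(
        "seq,expected",
        [
            ("MAAAAAAKGGGGGGGRCCCCCCC", 3),
            ("AKRK", 0),  # all fragments shorter than 7
            ("KPAAAAAAK", 1),  # no cleavage before P
        ],
    )
    def test_examples(self, seq, expected):
        assert count_observable_peptides(seq) == expected

    def test_illegal_character_names_position(self):
        with pytest.raises(ValueError, match="position 3"):
            count_observable_peptides("ACDZAAA")

    def test_matches_oracle_on_random_sequences(self):
        rng = np.random.default_rng(11)
        aas = list("ACDEFGHIKLMNPQRSTVWY")
        for _ in range(1000):
            seq = "".join(rng.choice(aas, size=rng.integers(1, 80)))
            frags = oracle_digest(seq)
            assert digest_tryptic(seq) == frags
            assert count_observable_peptides(seq) == sum(
                7 <= len(f) <= 30 for f in frags
            )


class TestIbaq:
    @pytest.mark.parametrize(
        "intensities,n_obs,expected",
        [([10, 20, 30], 3, 20.0), ([5], 1, 5.0), ([1e6, 2e6], 4, 7.5e5)],
    )
    def test_arithmetic(self, intensities, n_obs, expected):
        assert compute_ibaq(intensities, n_obs) == pytest.approx(expected)

    def test_zero_observable_flagged(self):
        with pytest.raises(ValueError):
            compute_ibaq([10.0], 0)

    def test_matrix_excludes_unnormalizable_protein(self):
        ev = pd.DataFrame(
            {
                "run_id": ["r1", "r1"],
                "peptide": ["AAAAAAA", "CCCCCCC"],
                "protein": ["P1", "P2"],
                "intensity": [10.0, 20.0],
                "rt": [1.0, 2.0],
            }
        )
        with pytest.warns(UserWarning):
            ibaq, excluded = ibaq_matrix(ev, {"P1": 2, "P2": 0})
        assert excluded == ["P2"]
        assert ibaq.loc["r1", "P1"] == pytest.approx(5.0)


class TestFot:
    def test_proportionality(self):
        fot = normalize_fot(pd.Series({"a": 2.0, "b": 3.0, "c": 5.0}))
        assert np.allclose(fot, [2e4, 3e4, 5e4])

    def test_single_protein(self):
        assert normalize_fot(pd.Series({"a": 42.0}))["a"] == pytest.approx(FOT_SCALE)

    def test_floor_applied_after_normalization(self):
        fot = normalize_fot(pd.Series({"tiny": 1.0, "huge": 1e12}))
        assert fot["tiny"] == FOT_FLOOR

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            normalize_fot(pd.Series({"a": 0.0, "b": 0.0}))

    def test_conservation_and_scale_equivariance(self):
        rng = np.random.default_rng(12)
        v = pd.Series(rng.uniform(0.1, 100, size=50))
        fot = v / v.sum() * FOT_SCALE  # pre-floor
        assert fot.sum() == pytest.approx(FOT_SCALE, rel=1e-6)
        assert np.allclose(normalize_fot(v), normalize_fot(v * 37.5))


class TestRtModel:
    def test_exact_linear(self):
        model = fit_rt_model([(1, 2), (2, 4), (3, 6), (4, 8), (5, 10), (6, 12)])
        assert model.degree == 1
        assert model.predict(2.5) == pytest.approx(5.0)
        assert model.r_squared == pytest.approx(1.0)

    def test_quadratic_selected(self):
        pairs = [(x, x**2) for x in range(1, 7)]
        model = fit_rt_model(pairs)
        assert model.degree == 2
        assert model.predict(2.5) == pytest.approx(6.25)

    def test_identity_coefficients(self):
        model = fit_rt_model([(x, x) for x in range(1, 7)])
        assert model.degree == 1
        assert model.coefficients[0] == pytest.approx(1.0)
        assert model.coefficients[1] == pytest.approx(0.0, abs=1e-12)

    def test_insufficient_anchors(self):
        with pytest.raises(ValueError, match="insufficient"):
            fit_rt_model([(1, 1), (2, 2), (3, 3)])

    def test_degenerate_reference(self):
        with pytest.raises(ValueError, match="degenerate"):
            fit_rt_model([(1, y) for y in range(6)])


def _evidence(run, rows):
    return pd.DataFrame(
        [
            {"run_id": run, "peptide": p, "protein": prot, "intensity": i, "rt": rt,
             "observed": True}
            for p, prot, i, rt in rows
        ]
    )


class TestMatchBetweenRuns:
    def _runs(self):
        shared = [(f"PEP{i}AAAK", "P1", 100.0, float(i)) for i in range(1, 8)]
        ref = _evidence("ref", shared + [("HIDDENPEPK", "P2", 50.0, 4.5)])
        tgt = _evidence("tgt", [(p, prot, i, rt * 2.0) for p, prot, i, rt in shared])
        return ref, tgt

    def test_transfer_at_predicted_rt(self):
        ref, tgt = self._runs()
        xics = pd.DataFrame({"peptide": ["HIDDENPEPK"], "rt": [9.0], "intensity": [77.0]})
        out = match_between_runs(ref, tgt, xics, rt_tolerance=0.5)
        row = out[out["peptide"] == "HIDDENPEPK"].iloc[0]
        assert row["intensity"] == 77.0
        assert not row["observed"]

    def test_no_xic_within_tolerance(self):
        ref, tgt = self._runs()
        xics = pd.DataFrame({"peptide": ["HIDDENPEPK"], "rt": [15.0], "intensity": [77.0]})
        out = match_between_runs(ref, tgt, xics, rt_tolerance=0.5)
        assert "HIDDENPEPK" not in set(out["peptide"])

    def test_full_recall_with_exact_map(self):
        # every transferable peptide has an XIC exactly at the mapped RT
        shared = [(f"SHARED{i}K", "P1", 10.0, float(i)) for i in range(1, 9)]
        hidden = [(f"HIDDEN{i}K", f"H{i}", 5.0 * i, 2.0 + i) for i in range(1, 6)]
        ref = _evidence("ref", shared + hidden)
        tgt = _evidence("tgt", [(p, prot, i, 3 * rt + 1) for p, prot, i, rt in shared])
        xics = pd.DataFrame(
            {"peptide": [h[0] for h in hidden], "rt": [3 * h[3] + 1 for h in hidden],
             "intensity": [h[2] for h in hidden]}
        )
        out = match_between_runs(ref, tgt, xics, rt_tolerance=0.01)
        transferred = set(out.loc[~out["observed"], "peptide"])
        assert transferred == {h[0] for h in hidden}


class TestFilterImpute:
    def test_detection_threshold_strict(self):
        samples = [f"s{i}" for i in range(10)]
        values = pd.DataFrame(
            {"at30": [10.0] * 3 + [np.nan] * 7, "at40": [10.0] * 4 + [np.nan] * 6},
            index=samples,
        )
        mat = AbundanceMatrix(values=values, scale="FOT")
        out = filter_and_impute(mat)
        assert list(out.features) == ["at40"]

    def test_imputed_value_and_mask(self):
        values = pd.DataFrame(
            {"f": [10.0, 20.0, np.nan]}, index=["s1", "s2", "s3"]
        )
        out = filter_and_impute(AbundanceMatrix(values=values, scale="FOT"))
        assert out.values.loc["s3", "f"] == pytest.approx(np.log2(1e-5))
        assert bool(out.mask.loc["s3", "f"]) is True
        assert out.values.loc["s1", "f"] == pytest.approx(np.log2(10.0))

    def test_idempotent_on_own_output(self):
        rng = np.random.default_rng(13)
        values = pd.DataFrame(rng.uniform(1, 100, (6, 8)))
        values[values < 20] = np.nan
        out1 = filter_and_impute(AbundanceMatrix(values=values, scale="FOT"))
        back = AbundanceMatrix(values=np.power(2.0, out1.values), scale="FOT")
        out2 = filter_and_impute(back)
        assert np.allclose(out1.values, out2.values)


class TestMatrixRoundTrip:
    def test_scale_header_round_trip(self, tmp_path):
        values = pd.DataFrame(
            [[1.0, 2.0], [3.0, np.nan]], index=["s1", "s2"], columns=["f1", "f2"]
        )
        mat = AbundanceMatrix(values=values, scale="FOT")
        path = tmp_path / "m.tsv"
        write_matrix_tsv(mat, path, mask_path=tmp_path / "mask.tsv")
        back = read_matrix_tsv(path, mask_path=tmp_path / "mask.tsv")
        assert back.scale == "FOT"
        pd.testing.assert_frame_equal(back.values, values, check_names=False)
        assert bool(back.mask.loc["s2", "f2"]) is True


def test_run_fot_rows_sum_to_scale(small_bundle):
    """Conservation on generated evidence: every run's pre-floor FOT sums to 1E5."""
    from ucbranch.quant import count_observable_peptides as cop

    n_obs = {p: cop(s) for p, s in small_bundle.sequences.items()}
    ibaq, _ = ibaq_matrix(small_bundle.peptides, n_obs)
    fot = fot_matrix(ibaq)
    sums = fot.values.sum(axis=1, skipna=True)
    assert np.allclose(sums, FOT_SCALE, rtol=1e-6)
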