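import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from vlamy.disorder import window_provider
from vlamy.features import (
    FINAL7,
    FeatureConfig,
    aromaticity,
    category_fraction,
    extract_features,
    extract_matrix,
    region_average,
    symmetric_charge,
)
from vlamy.io import segment
from vlamy.scales import STANDARD_AA, PropertyScale, get_scale

from conftest import make_record

CONSTANT = PropertyScale("CONST25", {aa: 2.5 for aa in STANDARD_AA})
AV01 = PropertyScale("AV01", {aa: (1.0 if aa == "V" else 0.0) for aa in STANDARD_AA})

seqs = st.text(alphabet=STANDARD_AA, min_size=1, max_size=60)


class TestRegionAverage:
    @pytest.mark.parametrize(
        "seq,scale,expected",
        [
            ("WYKLM", CONSTANT, 2.5),
            ("AV", AV01, 0.5),
            ("AAV", AV01, 1 / 3),
        ],
    )
    def test_arithmetic(self, seq, scale, expected):
        assert region_average(seq, scale) == pytest.approx(expected)

    def test_empty_region_and_missing_residue(self):
        with pytest.raises(ValueError, match="empty"):
            region_average("", CONSTANT)
        with pytest.raises(KeyError, match="missing from scale"):
            region_average("AB", AV01)

    @given(seq=seqs, a=st.floats(-3, 3), b=st.floats(-3, 3))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_affine_equivariance(self, seq, a, b):
        scale = get_scale("HNC")
        shifted = PropertyScale(
            "AFFINE", {aa: a * scale.values[aa] + b for aa in STANDARD_AA}
        )
        assert region_average(seq, shifted) == pytest.approx(
            a * region_average(seq, scale) + b, abs=1e-9
        )

    @given(seq=seqs, seed=st.integers(0, 2**16))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_permutation_invariance(self, seq, seed):
        rng = np.random.default_rng(seed)
        shuffled = "".join(rng.permutation(list(seq)))
        scale = get_scale("BULH740101")
        assert region_average(shuffled, scale) == pytest.approx(region_average(seq, scale))


class TestCategoryFraction:
    @pytest.mark.parametrize(
        "seq,category,expected",
        [
            ("DERKP", "gatekeeper", 1.0),
            ("DAKA", "gatekeeper", 0.5),
            ("AGILMPV", "nonpolar", 1.0),
            ("FWY", "aromatic", 1.0),
        ],
    )
    def test_fractions(self, seq, category, expected):
        assert category_fraction(seq, category) == pytest.approx(expected)

    def test_empty_seq_rejected(self):
        with pytest.raises(ValueError):
            category_fraction("", "gatekeeper")


class TestPageStyleFeatures:
    def test_aromaticity_pure(self):
        assert aromaticity("FWY") == 1.0

    @pytest.mark.parametrize(
        "seq,expected",
        [("KRDE", 0.0), ("KKKK", 1.0), ("KKDA", 1 / 16)],
    )
    def test_symmetric_charge(self, seq, expected):
        assert symmetric_charge(seq) == pytest.approx(expected)


class TestExtractFeatures:
    def test_toy_record_against_residue_sum_oracle(self, toy_record):
        """Brute-force per-residue summation reproduces every feature."""
        provider = window_provider()
        vec = extract_features(toy_record, provider)
        hnc, ct, tfe = get_scale("HNC"), get_scale("CHAM830107"), get_scale("BULH740101")
        beta = get_scale("CHOP780202")
        cdr = segment(toy_record, "CDR_all")
        fr = segment(toy_record, "FR_all")
        vl = toy_record.sequence

        def mean_of(seq, scale):
            total = 0.0
            for residue in seq:
                total += scale.values[residue]
            return total / len(seq)

        assert vec["f_hyd_cdr"] == pytest.approx(mean_of(cdr, hnc))
        assert vec["f_ct_cdr"] == pytest.approx(mean_of(cdr, ct))
        assert vec["f_tfe_fr"] == pytest.approx(mean_of(fr, tfe))
        assert vec["f_beta_vl"] == pytest.approx(mean_of(vl, beta))
        assert vec["f_gk_fr"] == pytest.approx(
            sum(c in "DERKP" for c in fr) / len(fr)
        )
        assert vec["f_np_vl"] == pytest.approx(
            sum(c in "AGILMPV" for c in vl) / len(vl)
        )
        assert vec["f_dis_vl"] == pytest.approx(
            float(np.mean(provider(toy_record).scores))
        )

    def test_constant_scales_give_constant_means(self):
        record = make_record(cdr1="DERKP", cdr2="DEK", cdr3="DERKPDER")
        vec = extract_features(record)
        assert 0.0 <= vec["f_gk_fr"] <= 1.0
        all_gk = make_record(
            fr1="DEKR" * 5, fr2="DEKR" * 4, fr3="DEKR" * 9, fr4="DEKR" * 3
        )
        assert extract_features(all_gk)["f_gk_fr"] == 1.0

    def test_pooling_identity(self, planted_records):
        """Length-weighted CDR/FR means recombine to the V_L mean."""
        scale = get_scale("HNC")
        for rec in planted_records[:20]:
            cdr, fr = segment(rec, "CDR_all"), segment(rec, "FR_all")
            combined = (
                len(cdr) * region_average(cdr, scale)
                + len(fr) * region_average(fr, scale)
            ) / len(rec)
            assert combined == pytest.approx(region_average(rec.sequence, scale))

    def test_mean_of_means_differs_when_loops_unequal(self, toy_record):
        pooled = extract_features(toy_record, config=FeatureConfig(cdr_pooling="pooled"))
        momean = extract_features(
            toy_record, config=FeatureConfig(cdr_pooling="mean_of_means")
        )
        assert pooled["f_hyd_cdr"] != pytest.approx(momean["f_hyd_cdr"])
        assert pooled["f_gk_fr"] == momean["f_gk_fr"]  # FR features unaffected


class TestExtractMatrix:
    def test_final7_shape_and_order(self, planted_records, planted_matrix):
        assert planted_matrix.features.shape == (len(planted_records), 7)
        assert planted_matrix.feature_names == list(FINAL7)
        assert list(planted_matrix.features.index) == [r.id for r in planted_records]

    def test_column_matches_rowwise_fraction(self, planted_records, planted_matrix):
        for rec in planted_records[:15]:
            assert planted_matrix.features.loc[rec.id, "f_np_vl"] == pytest.approx(
                category_fraction(rec.sequence, "nonpolar")
            )

    def test_extended_panel_finite_and_superset(self, planted_records):
        matrix = extract_matrix(planted_records[:5], config=FeatureConfig(panel="extended"))
        assert set(FINAL7) <= set(matrix.feature_names)
        assert np.isfinite(matrix.X).all()
        # every bundled scale appears once per region set
        assert {"HNC_VL", "HNC_CDR_all", "HNC_FR_all"} <= set(matrix.feature_names)

    def test_fractions_within_unit_interval(self, planted_matrix):
        for col in ("f_gk_fr", "f_np_vl"):
            assert planted_matrix.features[col].between(0, 1).all()
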