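import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pepal.constants import AA_INDEX, ALPHABET, CTD_GROUPS
from pepal.featurize import (
    ALL_VIEWS,
    VIEW_DIMS,
    EncoderConfig,
    FeatureView,
    build_views,
    encode_aac,
    encode_ctd,
    encode_dp,
    encode_dpc,
    encode_dr,
    encode_ksctriad,
    encode_onehot,
    encode_ppct,
    encode_pseaac,
    preprocess_filter,
    standardize_views,
)
from pepal.io import LabelMatrix, PeptideRecord
from ._oracles import oracle_ppct


def _encode(name, record, profiles):
    return build_views([record], profiles, view_names=[name]).pop().matrix[0]


class TestDimensionContracts:
    @pytest.mark.parametrize("name", ALL_VIEWS)
    def test_table_dimensions(self, name, tiny_dataset):
        records, _, profiles = tiny_dataset
        vec = _encode(name, records[0], profiles)
        assert vec.shape == (VIEW_DIMS[name],)
        assert np.isfinite(vec).all()

    def test_all_nine_views_together(self, tiny_dataset):
        records, _, profiles = tiny_dataset
        views = build_views(records[:5], profiles)
        assert [v.dim for v in views] == [VIEW_DIMS[v.name] for v in views]
        assert {v.name for v in views} == set(ALL_VIEWS)

    def test_feature_view_rejects_wrong_dim(self):
        with pytest.raises(ValueError):
            FeatureView(name="AAC", matrix=np.zeros((3, 21)))


class TestPreprocessFilter:
    def _dataset(self):
        seqs = {
            "ok1": "MKWVAR",
            "short": "MKWVA",            # 5-mer
            "long": "A" * 201,            # 201-mer
            "amb": "MKXWVA",              # contains X
            "nolabel": "MKWVARGG",        # all-zero label row
            "ok2": "GGGGGGG",
        }
        records = [PeptideRecord(k, v) for k, v in seqs.items()]
        values = np.ones((len(records), 2), dtype=int)
        values[4] = 0
        return records, LabelMatrix(["A", "B"], values)

    def test_rules_and_report(self):
        records, labels = self._dataset()
        kept, kept_labels, report = preprocess_filter(records, labels)
        assert [r.id for r in kept] == ["ok1", "ok2"]
        assert kept_labels.n_samples == 2
        assert (report.too_short, report.too_long, report.nonstandard,
                report.no_label) == (1, 1, 1, 1)
        assert report.n_kept == 2

    def test_empty_output_is_legal(self):
        records = [PeptideRecord("x", "MKX")]
        labels = LabelMatrix(["A"], np.array([[1]]))
        kept, _, report = preprocess_filter(records, labels)
        assert kept == [] and report.n_kept == 0

    def test_rows_with_no_positive_label_removed(self):
        records = [PeptideRecord("x", "MKWVAR")]
        labels = LabelMatrix(["A"], np.array([[0]]))
        kept, _, report = preprocess_filter(records, labels)
        assert kept == [] and report.no_label == 1


class TestCompositionEncoders:
    def test_aac_homopolymer(self):
        v = encode_aac("AAAAAA")
        assert v[AA_INDEX["A"]] == 1.0 and v.sum() == 1.0 and v.shape == (20,)

    def test_dpc_hand_counted(self):
        # ARARAR: 5 adjacent pairs, AR x3 and RA x2
        v = encode_dpc("ARARAR")
        assert v[AA_INDEX["A"] * 20 + AA_INDEX["R"]] == pytest.approx(0.6)
        assert v[AA_INDEX["R"] * 20 + AA_INDEX["A"]] == pytest.approx(0.4)
        assert np.count_nonzero(v) == 2

    @pytest.mark.parametrize("seq", ["MKWVAR", "ACDEFGHIKLMNPQRSTVWY", "GG" * 50])
    def test_aac_dpc_sum_to_one(self, seq):
        assert encode_aac(seq).sum() == pytest.approx(1.0, abs=1e-9)
        assert encode_dpc(seq).sum() == pytest.approx(1.0, abs=1e-9)

    def test_ksctriad_normalized_and_counts_gaps(self):
        v = encode_ksctriad("AAAAAAAA")  # class of A is 0 -> all mass at index 0
        assert v.shape == (343,)
        assert v[0] == pytest.approx(1.0)
        assert v.sum() == pytest.approx(1.0)

    def test_ksctriad_short_sequence_all_zero_is_legal(self):
        # length 6, max gap 3 needs 2*4+1 = 9 positions for k=3; k<=1 contribute
        v = encode_ksctriad("MKWVAR")
        assert v.sum() == pytest.approx(1.0)


class TestPhyschemEncoders:
    def test_ctd_single_class_composition(self):
        v = encode_ctd("AAAAAA")
        for gi, (name, groups) in enumerate(CTD_GROUPS.items()):
            block = v[gi * 21 : (gi + 1) * 21]
            cls = next(i for i, g in enumerate(groups) if "A" in g)
            comp = block[:3]
            assert comp[cls] == 1.0 and comp.sum() == 1.0
            assert np.all(block[3:6] == 0.0)  # no transitions

    def test_ctd_distribution_positions_scale_free(self):
        v = encode_ctd("AAAAAAAAAA")
        for gi, (name, groups) in enumerate(CTD_GROUPS.items()):
            block = v[gi * 21 : (gi + 1) * 21]
            cls = next(i for i, g in enumerate(groups) if "A" in g)
            dist = block[6 + cls * 5 : 6 + cls * 5 + 5]
            assert np.allclose(dist, [0.1, 0.3, 0.5, 0.8, 1.0])

    def test_pseaac_homopolymer_reduces_to_aac(self):
        # identical residues: all squared property differences vanish
        v = encode_pseaac("AAAAAA", lam=5)
        assert v.shape == (25,)
        assert np.all(v[20:] == 0.0)
        assert v[AA_INDEX["A"]] == pytest.approx(1.0)

    def test_pseaac_sums_to_one(self):
        v = encode_pseaac("MKWVARGGA")
        assert v.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(v[20:] > 0)

    def test_pseaac_requires_length_above_lambda(self):
        with pytest.raises(ValueError):
            encode_pseaac("MKWVA", lam=5)


class TestDistanceEncoders:
    def test_dr_hand_counted(self):
        v = encode_dr("ARARAR")
        a, r = AA_INDEX["A"], AA_INDEX["R"]
        d1 = v[20:420]
        assert d1[a * 20 + r] == pytest.approx(0.6)
        assert d1[r * 20 + a] == pytest.approx(0.4)
        d2 = v[420:820]
        assert d2[a * 20 + a] == pytest.approx(0.5)
        assert d2[r * 20 + r] == pytest.approx(0.5)
        d3 = v[820:1220]
        assert d3[a * 20 + r] == pytest.approx(2 / 3)
        assert d3[r * 20 + a] == pytest.approx(1 / 3)

    def test_dr_homopolymer_blocks_sum_to_one(self):
        v = encode_dr("AAAAAA")
        for start in (20, 420, 820):
            block = v[start : start + 400]
            assert block.sum() == pytest.approx(1.0, abs=1e-9)
            assert block[0] == pytest.approx(1.0)  # all mass on (A, A)

    def test_dp_dimension_and_block_sums(self):
        v = encode_dp("MKWVARGG")
        assert v.shape == (602,)
        assert v[:14].sum() == pytest.approx(1.0, abs=1e-9)
        for b in range(3):
            assert v[14 + b * 196 : 14 + (b + 1) * 196].sum() == pytest.approx(
                1.0, abs=1e-9
            )


class TestOnehot:
    def test_six_mer_padding(self):
        v = encode_onehot(PeptideRecord("x", "MKWVAR"))
        m = v.reshape(200, 21)
        assert v.sum() == 200
        assert m[:6, 20].sum() == 0 and m[6:, 20].sum() == 194
        assert m[0, AA_INDEX["M"]] == 1.0

    def test_full_length_has_no_padding(self):
        v = encode_onehot(PeptideRecord("x", "A" * 200))
        m = v.reshape(200, 21)
        assert m[:, 20].sum() == 0 and v.sum() == 200

    def test_too_long_rejected(self):
        with pytest.raises(ValueError):
            encode_onehot(PeptideRecord("x", "A" * 201))


class TestPpct:
    def test_matches_bruteforce_double_loop(self, rng):
        from pepal.io import ProfilePair

        L = 10
        pssm = rng.normal(size=(20, L)) * 3
        psfm = rng.random((20, L))
        psfm /= psfm.sum(axis=0, keepdims=True)
        pair = ProfilePair(pssm=pssm, psfm=psfm)
        rec = PeptideRecord("x", "MKWVARMKWV")
        got = encode_ppct(rec, pair)
        want = oracle_ppct(pssm, psfm)
        assert np.allclose(got, want, atol=1e-12)

    def test_short_sequence_zero_lags(self, tiny_dataset):
        from pepal.io import ProfilePair

        rec = PeptideRecord("x", "MKWVAR")  # length 6 > max lag 5: all lags valid
        pssm = np.zeros((20, 6))
        psfm = np.full((20, 6), 0.05)
        got = encode_ppct(rec, ProfilePair(pssm=pssm, psfm=psfm))
        # logistic(0) = 0.5 everywhere -> every defined entry is 0.5 * 0.05
        assert np.allclose(got[got != 0], 0.025)

    def test_misaligned_profiles_rejected(self, tiny_dataset):
        records, _, profiles = tiny_dataset
        a, b = records[0], records[1]
        if len(a) != len(b):
            with pytest.raises(ValueError):
                encode_ppct(a, profiles[b.id])


class TestInvariantProperties:
    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_encoders_finite_on_random_sequences(self, seed):
        rng = np.random.default_rng(seed)
        L = int(rng.integers(6, 201))
        seq = "".join(rng.choice(list(ALPHABET), size=L))
        rec = PeptideRecord("x", seq)
        for fn in (encode_aac, encode_dpc, encode_ctd, encode_dr, encode_dp,
                   encode_ksctriad):
            assert np.isfinite(fn(seq)).all()
        assert np.isfinite(encode_pseaac(seq)).all()
        assert np.isfinite(encode_onehot(rec)).all()

    def test_aac_shuffle_invariant_others_not(self, rng):
        seq = "ACDEFGHIKLMNPQRSTVWY"
        shuffled = "".join(rng.permutation(list(seq)))
        assert np.array_equal(encode_aac(seq), encode_aac(shuffled))
        rec, srec = PeptideRecord("a", seq), PeptideRecord("b", shuffled)
        for fn in (encode_dpc, encode_dr, encode_dp, encode_ksctriad):
            assert not np.array_equal(fn(seq), fn(shuffled))
        assert not np.array_equal(encode_onehot(rec), encode_onehot(srec))

    def test_determinism_bit_identical(self, tiny_dataset):
        records, _, profiles = tiny_dataset
        for name in ALL_VIEWS:
            a = _encode(name, records[0], profiles)
            b = _encode(name, records[0], profiles)
            assert np.array_equal(a, b)

    def test_nonstandard_residue_is_encoding_error(self):
        with pytest.raises(ValueError):
            encode_aac("MKXWVA")


class TestBuildViews:
    def test_single_view_shape(self, tiny_dataset):
        records, _, _ = tiny_dataset
        views = build_views(records[:10], view_names=["AAC"])
        assert len(views) == 1 and views[0].matrix.shape == (10, 20)

    def test_three_view_committee_configuration(self, tiny_dataset):
        records, _, _ = tiny_dataset
        views = build_views(records[:5], view_names=["DP", "KSCTriad", "PseAAC"])
        assert [v.dim for v in views] == [602, 343, 25]

    def test_ppct_without_profiles_rejected(self, tiny_dataset):
        records, _, _ = tiny_dataset
        with pytest.raises(ValueError):
            build_views(records[:3], profiles=None, view_names=["PPCT"])

    def test_standardization_fit_on_labeled_rows_only(self, tiny_dataset):
        records, _, _ = tiny_dataset
        views = build_views(records, view_names=["AAC"])
        fit_idx = np.arange(10)
        std = standardize_views(views, fit_idx)
        sub = std[0].matrix[fit_idx]
        sd = views[0].matrix[fit_idx].std(axis=0)
        assert np.allclose(sub.mean(axis=0), 0.0, atol=1e-12)
        assert np.allclose(sub.std(axis=0)[sd > 1e-12], 1.0)
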