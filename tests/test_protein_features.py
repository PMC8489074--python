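import numpy as np
import pytest

from lpiboost.features import protein as pf
from lpiboost.features import _tables as T

from conftest import AA, random_aa


class TestKmerComposition:
    def test_dimensions(self, rng):
        seq = random_aa(rng, 40)
        assert pf.kmer_composition(seq, 1).size == 20
        assert pf.kmer_composition(seq, 2).size == 400
        assert pf.kmer_composition(seq, 3).size == 8000

    def test_homopolymer_monomer(self):
        vec = pf.kmer_composition("AAAA", 1)
        assert vec[0] == 1.0 and vec[1:].sum() == 0.0

    def test_acde_dipeptides(self):
        vec = pf.kmer_composition("ACDE", 2)
        idx = {a + b: 20 * AA.index(a) + AA.index(b)
               for a in AA for b in AA}
        for m in ("AC", "CD", "DE"):
            assert vec[idx[m]] == pytest.approx(1 / 3)
        assert vec.sum() == pytest.approx(1.0)

    def test_window_count_oracle(self, rng):
        seq = random_aa(rng, 60)
        vec = pf.kmer_composition(seq, 2)
        expected = np.zeros(400)
        for i in range(len(seq) - 1):
            expected[20 * AA.index(seq[i]) + AA.index(seq[i + 1])] += 1
        np.testing.assert_allclose(vec, expected / (len(seq) - 1))

    def test_aac_permutation_invariant_dipeptide_not(self, rng):
        seq, perm = "ACDEFGHIKLMNPQRSTVWYAC" * 2, None
        perm = "".join(rng.permutation(list(seq)))
        np.testing.assert_allclose(pf.kmer_composition(seq, 1),
                                   pf.kmer_composition(perm, 1))
        # witness pair: same composition, different adjacency
        a, b = "AACD" * 10, "ACAD" * 10
        np.testing.assert_allclose(pf.kmer_composition(a, 1),
                                   pf.kmer_composition(b, 1))
        assert not np.allclose(pf.kmer_composition(a, 2),
                               pf.kmer_composition(b, 2))


class TestAutocorrelation:
    @pytest.mark.parametrize("kind", ["normalized_moreau_broto", "moran",
                                      "geary"])
    def test_dimension_240(self, rng, kind):
        assert pf.autocorrelation(random_aa(rng, 50), kind).size == 240

    def test_homopolymer_moran_all_zero(self):
        assert (pf.autocorrelation("A" * 50, "moran") == 0).all()
        assert (pf.autocorrelation("A" * 50, "geary") == 0).all()

    def test_too_short_errors(self):
        with pytest.raises(ValueError, match="nlag"):
            pf.autocorrelation("ACDE", "moran")

    def test_geary_double_loop_oracle(self, rng):
        """Geary statistic equals the direct double-loop formula."""
        seq = random_aa(rng, 100)
        vec = pf.autocorrelation(seq, "geary", nlag=30)
        scales = list(T.AUTOCORRELATION_SCALES.values())
        n = len(seq)
        for s in (0, 3, 7):
            p = T.scale_vector(scales[s])[[AA.index(c) for c in seq]]
            denom = ((p - p.mean()) ** 2).sum() / (n - 1)
            for d in (1, 15, 30):
                num = sum((p[i] - p[i + d]) ** 2
                          for i in range(n - d)) / (2 * (n - d))
                assert vec[30 * s + d - 1] == pytest.approx(num / denom)

    def test_moran_brute_oracle(self, rng):
        seq = random_aa(rng, 80)
        vec = pf.autocorrelation(seq, "moran", nlag=30)
        p = T.scale_vector(T.HYDROPHOBICITY)[[AA.index(c) for c in seq]]
        n, d = len(seq), 5
        pbar = p.mean()
        num = sum((p[i] - pbar) * (p[i + d] - pbar)
                  for i in range(n - d)) / (n - d)
        denom = ((p - pbar) ** 2).sum() / n
        assert vec[d - 1] == pytest.approx(num / denom)


class TestCTD:
    def test_dimensions(self, rng):
        vec = pf.ctd(random_aa(rng, 60))
        assert vec.size == 147  # 21 + 21 + 105

    def test_single_class_sequence(self):
        # "AG" both fall in the neutral hydrophobicity class
        vec = pf.ctd("AGAGAG")
        comp_hydro = vec[:3]
        assert comp_hydro[1] == pytest.approx(1.0)  # neutral class
        trans_hydro = vec[21:24]
        assert (trans_hydro == 0).all()

    def test_distribution_position_scan_oracle(self, rng):
        seq = random_aa(rng, 40)
        vec = pf.ctd(seq)
        dist = vec[42:]
        groups = list(T.CTD_GROUPS.values())
        for gi in (0, 4):  # hydrophobicity, charge
            for cls in range(3):
                pos = [i + 1 for i, c in enumerate(seq)
                       if c in groups[gi][cls]]
                got = dist[15 * gi + 5 * cls:15 * gi + 5 * cls + 5]
                if not pos:
                    assert (got == 0).all()
                    continue
                expected = [pos[0]]
                for q in (0.25, 0.5, 0.75, 1.0):
                    k = max(1, int(np.ceil(q * len(pos))))
                    expected.append(pos[k - 1])
                np.testing.assert_allclose(
                    got, np.array(expected) / len(seq))

    def test_composition_block_sums(self, rng):
        vec = pf.ctd(random_aa(rng, 50))
        for g in range(7):
            assert vec[3 * g:3 * g + 3].sum() == pytest.approx(1.0)


class TestConjointTriad:
    def test_dimension_and_sum(self, rng):
        vec = pf.conjoint_triad(random_aa(rng, 60))
        assert vec.size == 343
        assert vec.sum() == pytest.approx(1.0)

    def test_homopolymer_single_cell(self):
        vec = pf.conjoint_triad("AAAAA")
        assert vec[0] == pytest.approx(1.0)
        assert np.count_nonzero(vec) == 1

    def test_enumeration_oracle(self, rng):
        seq = random_aa(rng, 60)
        cls = {a: k for k, grp in enumerate(T.CONJOINT_CLASSES)
               for a in grp}
        expected = np.zeros(343)
        for i in range(len(seq) - 2):
            idx = 49 * cls[seq[i]] + 7 * cls[seq[i + 1]] + cls[seq[i + 2]]
            expected[idx] += 1
        np.testing.assert_allclose(pf.conjoint_triad(seq),
                                   expected / (len(seq) - 2))


class TestSequenceOrder:
    def test_dimensions(self, rng):
        socn, qso = pf.sequence_order(random_aa(rng, 80))
        assert socn.size == 60 and qso.size == 100

    def test_socn_brute_oracle(self, rng):
        seq = random_aa(rng, 80)
        socn, _ = pf.sequence_order(seq)
        dist = T.physicochemical_distance_matrix()
        codes = [AA.index(c) for c in seq]
        for lag in (1, 10, 30):
            tau = sum(dist[codes[i], codes[i + lag]] ** 2
                      for i in range(len(seq) - lag))
            assert socn[lag - 1] == pytest.approx(tau)

    def test_qso_composition_block_sums_to_one_as_weight_vanishes(self, rng):
        seq = random_aa(rng, 60)
        _, qso = pf.sequence_order(seq, weight=1e-12)
        assert qso[:20].sum() == pytest.approx(1.0, abs=1e-6)

    def test_too_short_errors(self):
        with pytest.raises(ValueError, match="maxlag"):
            pf.sequence_order("ACDEFGHIKL")


class TestPseAAC:
    @pytest.mark.parametrize("variant", ["classic", "amphiphilic"])
    def test_dimension_and_unit_sum(self, rng, variant):
        vec = pf.pseaac(random_aa(rng, 100), variant)
        assert vec.size == 50
        assert vec.sum() == pytest.approx(1.0)

    def test_weight_zero_reduces_to_composition(self, rng):
        seq = random_aa(rng, 80)
        vec = pf.pseaac(seq, "classic", weight=0.0)
        aac = pf.kmer_composition(seq, 1)
        np.testing.assert_allclose(vec[:20], aac, atol=1e-12)
        assert (vec[20:] == 0).all()

    def test_classic_correlation_factor_oracle(self, rng):
        seq = random_aa(rng, 100)
        vec = pf.pseaac(seq, "classic", weight=0.05)
        codes = [AA.index(c) for c in seq]
        scales = [T.scale_vector(s) for s in
                  (T.HYDROPHOBICITY, T.HYDROPHILICITY, T.SIDE_CHAIN_MASS)]
        n = len(seq)
        theta = []
        for d in range(1, 31):
            acc = [np.mean([(s[codes[i]] - s[codes[i + d]]) ** 2
                            for s in scales]) for i in range(n - d)]
            theta.append(np.mean(acc))
        freqs = np.bincount(codes, minlength=20) / n
        denom = freqs.sum() + 0.05 * np.sum(theta)
        np.testing.assert_allclose(vec[20:], 0.05 * np.array(theta) / denom)

    def test_sequence_shorter_than_lambda_errors(self):
        with pytest.raises(ValueError, match="lambda"):
            pf.pseaac("ACDEFGHIKL", "classic")


class TestFullDescriptor:
    def test_length_and_determinism(self, rng):
        seq = random_aa(rng, 120)
        d1, d2 = pf.protein_descriptor(seq), pf.protein_descriptor(seq)
        assert d1.values.size == 9890
        np.testing.assert_array_equal(d1.values, d2.values)
        assert np.isfinite(d1.values).all()

    def test_block_offsets_partition_descriptor(self, rng):
        d = pf.protein_descriptor(random_aa(rng, 60))
        end = 0
        for off, length in d.blocks.values():
            assert off == end
            end = off + length
        assert end == 9890
        assert [l for _, l in d.blocks.values()] == \
               [20, 400, 8000, 240, 240, 240, 21, 21, 105, 343, 60, 100,
                50, 50]

    def test_frequency_blocks_sum_to_one(self, rng):
        d = pf.protein_descriptor(random_aa(rng, 90))
        for name in ("aac", "dipeptide", "tripeptide", "conjoint_triad",
                     "pseaac", "apseaac"):
            assert d.block(name).sum() == pytest.approx(1.0, abs=1e-9), name

    def test_too_short_names_binding_constraint(self):
        with pytest.raises(ValueError, match="30-lag"):
            pf.protein_descriptor("ACDEFGHIKLMNPQRSTVWY")

    def test_feature_names_align(self):
        assert len(pf.feature_names()) == 9890
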