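import math

import numpy as np
import pytest
from Bio.SeqUtils.ProtParam import ProteinAnalysis
from scipy.optimize import brentq

from orfvec.classic_features import (CTD_NAMES, ClassicFeatureExtractor,
                                     ctd_features, fickett_score, gc_content,
                                     gravy, instability_index,
                                     isoelectric_point, net_charge,
                                     orf_basic_features,
                                     _FICKETT_TABLES, _FICKETT_THRESHOLDS)
from orfvec.hexamer import HexamerTable, build_hexamer_table, hexamer_score
from orfvec.seqio_orf import find_longest_orf

from conftest import random_dna

AA20 = "ACDEFGHIKLMNPQRSTVWY"


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def naive_hexamer_table(coding, noncoding):
    def count(seqs):
        c = {}
        for s in seqs:
            for i in range(0, len(s) - 5, 3):
                h = s[i:i + 6]
                if "N" not in h:
                    c[h] = c.get(h, 0) + 1
        total = sum(c.values())
        return {h: v / total for h, v in c.items()} if total else {}
    return count(coding), count(noncoding)


def naive_hexamer_score(orf_nt, cfreq, nfreq):
    ratios = []
    for i in range(0, len(orf_nt) - 5, 3):
        h = orf_nt[i:i + 6]
        if "N" in h:
            continue
        c, n = cfreq.get(h, 0.0), nfreq.get(h, 0.0)
        if c == 0 and n == 0:
            ratios.append(0.0)
        elif c == 0:
            ratios.append(-1.0)
        elif n == 0:
            ratios.append(1.0)
        else:
            ratios.append(math.log(c / n))
    return sum(ratios) / len(ratios) if ratios else 0.0


def naive_fickett(seq):
    def grab(param, kind, base):
        for t, p in zip(_FICKETT_THRESHOLDS[kind],
                        _FICKETT_TABLES[f"{kind}_prob"][base]):
            if param >= t:
                return p
        return _FICKETT_TABLES[f"{kind}_prob"][base][-1]
    total = 0.0
    for base in "ACGT":
        by_pos = [sum(1 for i in range(off, len(seq), 3) if seq[i] == base)
                  for off in range(3)]
        pos_param = max(by_pos) / (min(by_pos) + 1)
        cont_param = seq.count(base) / len(seq)
        total += grab(pos_param, "position", base) \
            * _FICKETT_TABLES["position_weight"][base]
        total += grab(cont_param, "content", base) \
            * _FICKETT_TABLES["content_weight"][base]
    return total


def naive_ctd(seq):
    n = len(seq)
    out = [seq.count(b) / n for b in "ACGT"]
    from itertools import combinations
    for a, b in combinations("ACGT", 2):
        t = sum(1 for x, y in zip(seq, seq[1:])
                if (x, y) in ((a, b), (b, a)))
        out.append(t / max(n - 1, 1))
    for b in "ACGT":
        pos = [i + 1 for i, ch in enumerate(seq) if ch == b]
        if not pos:
            out += [0.0] * 5
            continue
        for q in (0.0, 0.25, 0.5, 0.75, 1.0):
            out.append(pos[max(1, math.ceil(q * len(pos))) - 1] / n)
    return np.array(out)


# ---------------------------------------------------------------------------
# hexamer table and score
# ---------------------------------------------------------------------------

class TestHexamer:
    def test_inframe_counting_by_hand(self):
        t = build_hexamer_table(["ATGGCAGCATAA"], ["ACGTACGTACGT"])
        for h in ("ATGGCA", "GCAGCA", "GCATAA"):
            assert t.coding_freq(h) == pytest.approx(1 / 3)
        assert t.coding.sum() == pytest.approx(1.0)
        assert t.noncoding.sum() == pytest.approx(1.0)

    def test_short_sequence_contributes_nothing(self):
        t = build_hexamer_table(["ATGAAATAG", "ACGTA"], ["ACGTACGTA"])
        # the 5-nt sequence adds no counts: same as without it
        t2 = build_hexamer_table(["ATGAAATAG"], ["ACGTACGTA"])
        assert np.array_equal(t.coding, t2.coding)

    def test_equal_tables_score_zero(self, rng):
        seqs = [random_dna(rng, 120) for _ in range(5)]
        t = build_hexamer_table(seqs, seqs)
        assert t.score("ATG" + random_dna(rng, 60)) == pytest.approx(0.0)

    def test_score_below_hexamer_length_is_zero(self, rng):
        t = build_hexamer_table([random_dna(rng, 60)], [random_dna(rng, 60)])
        assert t.score("ATGCC") == 0.0

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError):
            build_hexamer_table([], [])

    def test_matches_naive_oracle(self, rng):
        coding = [random_dna(rng, int(rng.integers(30, 300)))
                  for _ in range(20)]
        noncoding = [random_dna(rng, int(rng.integers(30, 300)))
                     for _ in range(20)]
        t = build_hexamer_table(coding, noncoding)
        cfreq, nfreq = naive_hexamer_table(coding, noncoding)
        for _ in range(50):
            orf = random_dna(rng, int(rng.integers(6, 200)))
            assert t.score(orf) == pytest.approx(
                naive_hexamer_score(orf, cfreq, nfreq), abs=1e-12)

    def test_n_hexamers_skipped(self):
        t = build_hexamer_table(["ATGGCAGCATAA"], ["ACGTACGTACGT"])
        assert t.score("ATGNCAGCATAA") == pytest.approx(
            t.log_ratios[_hex_code("GCATAA")] / 1)

    def test_tsv_roundtrip(self, tmp_path, rng):
        t = build_hexamer_table([random_dna(rng, 200)], [random_dna(rng, 200)])
        t.to_tsv(tmp_path / "hex.tsv")
        t2 = HexamerTable.from_tsv(tmp_path / "hex.tsv")
        np.testing.assert_allclose(t.coding, t2.coding, rtol=1e-9)
        np.testing.assert_allclose(t.noncoding, t2.noncoding, rtol=1e-9)


def _hex_code(h):
    return sum("ACGT".index(c) * 4 ** (5 - i) for i, c in enumerate(h))


# ---------------------------------------------------------------------------
# Fickett / CTD / GC
# ---------------------------------------------------------------------------

class TestNucleotideFeatures:
    def test_fickett_matches_independent_implementation(self, rng):
        fixed = "ATGGCATGGCA" * 6
        assert fickett_score(fixed) == pytest.approx(naive_fickett(fixed))
        for _ in range(100):
            seq = random_dna(rng, int(rng.integers(20, 500)))
            assert fickett_score(seq) == pytest.approx(naive_fickett(seq))

    def test_fickett_bounds_from_tables(self, rng):
        lo = sum(min(_FICKETT_TABLES[f"{k}_prob"][b])
                 * _FICKETT_TABLES[f"{k}_weight"][b]
                 for k in ("position", "content") for b in "ACGT")
        hi = sum(max(_FICKETT_TABLES[f"{k}_prob"][b])
                 * _FICKETT_TABLES[f"{k}_weight"][b]
                 for k in ("position", "content") for b in "ACGT")
        for _ in range(50):
            s = fickett_score(random_dna(rng, 100))
            assert lo <= s <= hi

    def test_ctd_homopolymer_by_hand(self):
        v = ctd_features("AAAAAAAAAA")
        np.testing.assert_allclose(v[:4], [1, 0, 0, 0])
        np.testing.assert_allclose(v[4:10], 0)
        np.testing.assert_allclose(v[10:15], [0.1, 0.3, 0.5, 0.8, 1.0])
        np.testing.assert_allclose(v[15:], 0)

    def test_ctd_matches_naive_oracle(self, rng):
        for _ in range(100):
            seq = random_dna(rng, int(rng.integers(2, 300)), bases="ACGTN")
            np.testing.assert_allclose(ctd_features(seq), naive_ctd(seq),
                                       atol=1e-12)

    def test_ctd_composition_sums_to_one_without_n(self, rng):
        seq = random_dna(rng, 100)
        assert ctd_features(seq)[:4].sum() == pytest.approx(1.0)

    @pytest.mark.parametrize("seq,expected", [
        ("GGCC", 1.0), ("ATAT", 0.0), ("GCAT", 0.5), ("GCNN", 0.5)])
    def test_gc_content(self, seq, expected):
        assert gc_content(seq) == expected


# ---------------------------------------------------------------------------
# protein features
# ---------------------------------------------------------------------------

class TestProteinFeatures:
    def test_gravy_single_and_pair(self):
        assert gravy("A") == pytest.approx(1.8)
        assert gravy("AV") == pytest.approx(3.0)
        assert gravy("AX") == pytest.approx(gravy("A"))

    def test_gravy_matches_biopython(self, rng):
        for _ in range(30):
            prot = "".join(rng.choice(list(AA20), size=40))
            assert gravy(prot) == pytest.approx(
                ProteinAnalysis(prot).gravy(), abs=1e-9)

    def test_gravy_empty_defined_zero(self):
        assert gravy("") == 0.0
        assert gravy("XX") == 0.0

    def test_instability_gg_from_table(self):
        from Bio.SeqUtils.ProtParamData import DIWV
        assert instability_index("GG") == pytest.approx(5 * DIWV["G"]["G"])

    def test_instability_matches_biopython(self, rng):
        for _ in range(30):
            prot = "".join(rng.choice(list(AA20), size=50))
            assert instability_index(prot) == pytest.approx(
                ProteinAnalysis(prot).instability_index(), abs=1e-6)

    def test_isoelectric_point_root_contract(self, rng):
        for _ in range(20):
            prot = "".join(rng.choice(list(AA20), size=int(rng.integers(1, 60))))
            ph = isoelectric_point(prot)
            assert 0 <= ph <= 14
            assert abs(net_charge(prot, ph)) < 1e-4

    def test_basic_exceeds_acidic(self):
        assert isoelectric_point("RRRR") > isoelectric_point("DDDD")

    def test_pi_matches_independent_root_finder(self):
        for prot in ("G", "MKKR", "DDEEC", "ACDEFGHIKLMNPQRSTVWY"):
            ref = brentq(lambda ph: net_charge(prot, ph), 0, 14, xtol=1e-10)
            # the production solver stops at |charge| < 1e-4, which on a
            # flat titration curve can sit a few hundredths of a pH unit
            # from the exact root
            assert isoelectric_point(prot) == pytest.approx(ref, abs=0.05)


# ---------------------------------------------------------------------------
# ORF features and extractor
# ---------------------------------------------------------------------------

class TestOrfFeaturesAndExtractor:
    def test_orf_basic_features(self):
        orf = find_longest_orf("ATGAAATAG")
        length, cov, integ = orf_basic_features(orf, 20)
        assert (length, cov, integ) == (9, 0.45, 1.0)

    def test_fallback_orf_has_negative_integrity(self):
        orf = find_longest_orf("CCCCCCCC")
        assert orf_basic_features(orf, 8)[2] == -1.0

    def test_full_coverage(self):
        orf = find_longest_orf("ATGAAATAG")
        assert orf_basic_features(orf, 9)[1] == 1.0

    def test_zero_transcript_length_rejected(self):
        orf = find_longest_orf("ATGAAATAG")
        with pytest.raises(ValueError):
            orf_basic_features(orf, 0)

    def test_default_extractor_emits_10_features(self, rng):
        X = [random_dna(rng, 200) for _ in range(6)]
        y = ["coding"] * 3 + ["noncoding"] * 3
        ext = ClassicFeatureExtractor().fit(X, y)
        M = ext.transform(X)
        assert M.shape == (6, 10)
        assert len(ext.feature_names_) == 10

    def test_ctd_extractor_emits_40_features(self, rng):
        X = [random_dna(rng, 200) for _ in range(6)]
        y = ["coding"] * 3 + ["noncoding"] * 3
        ext = ClassicFeatureExtractor(
            groups=("orf", "protein", "rna", "ctd")).fit(X, y)
        assert ext.transform(X).shape == (6, 40)
        assert ext.feature_names_[-30:] == CTD_NAMES

    def test_features_are_pure(self, rng):
        X = [random_dna(rng, 150) for _ in range(4)]
        y = ["coding", "coding", "noncoding", "noncoding"]
        ext = ClassicFeatureExtractor().fit(X, y)
        np.testing.assert_array_equal(ext.transform(X), ext.transform(X))
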