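"""Compositional statistics against brute-force oracles and printed formulas."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ifncomp.composition import (
    AMINO_ACIDS,
    DINUCLEOTIDES,
    FEATURE_NAMES,
    UndefinedCompositionError,
    codon_amino_features,
    count_dinucleotides,
    cpg_frequency,
    cpg_frequency_normalised,
    dinucleotide_bias,
    dinucleotide_fold_change,
    dinucleotide_proportion,
    expected_cpg,
    feature_table,
    feature_vector,
    valid_dinucleotide_positions,
)
from ifncomp.sequence_io import GeneRecord
from ifncomp.synthetic import generate_cds, generate_sequence

from conftest import random_sequence


# --------------------------------------------------------------------------
# independent brute-force oracles


def oracle_dinuc_counts(seq):
    counts = {xy: 0 for xy in DINUCLEOTIDES}
    for i in range(len(seq) - 1):
        pair = seq[i:i + 2]
        if "N" not in pair:
            counts[pair] += 1
    return counts


def oracle_props(seq):
    valid = [b for b in seq if b != "N"]
    return {b: valid.count(b) / len(valid) for b in "ACGT"}


class TestDinucleotideCounts:
    def test_direct_enumeration(self):
        counts = count_dinucleotides("ACGTACGT")
        nonzero = {k: v for k, v in counts.items() if v}
        assert nonzero == {"AC": 2, "CG": 2, "GT": 2, "TA": 1}

    def test_homopolymer(self):
        counts = count_dinucleotides("AAAA")
        assert counts["AA"] == 3 and sum(counts.values()) == 3

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            count_dinucleotides("A")

    def test_matches_sliding_window_oracle(self, rng):
        for _ in range(200):
            seq = random_sequence(rng, 200, "ACGTN")
            assert count_dinucleotides(seq) == oracle_dinuc_counts(seq)

    def test_n_positions_excluded_from_counts_and_denominator(self):
        seq = "ACNGT"
        counts = count_dinucleotides(seq)
        assert sum(counts.values()) == 2  # AC and GT only
        assert valid_dinucleotide_positions(seq) == 2

    def test_proportions_sum_to_one_without_n(self, rng):
        seq = random_sequence(rng, 500)
        total = sum(dinucleotide_proportion(seq, xy) for xy in DINUCLEOTIDES)
        assert total == pytest.approx(1.0)


class TestCpgMetrics:
    @pytest.mark.parametrize(
        "seq, expected",
        [("ACGT", 1 / 3), ("AAAA", 0.0), ("CCGG", 1 / 3), ("CGCG", 2 / 3)],
    )
    def test_cpg_frequency_formula(self, seq, expected):
        assert cpg_frequency(seq) == pytest.approx(expected)

    def test_cpg_frequency_times_length_is_cg_count(self, rng):
        for _ in range(100):
            seq = random_sequence(rng, int(rng.integers(2, 400)))
            count = cpg_frequency(seq) * (len(seq) - 1)
            assert count == pytest.approx(oracle_dinuc_counts(seq)["CG"])

    def test_normalised_cpg_examples(self):
        assert cpg_frequency_normalised("ACGT") == pytest.approx(16 / 3)
        with pytest.raises(UndefinedCompositionError):
            cpg_frequency_normalised("AATT")

    def test_normalised_equals_observed_over_expected(self, rng):
        for _ in range(100):
            seq = random_sequence(rng, 300)
            props = oracle_props(seq)
            if props["C"] == 0 or props["G"] == 0:
                continue
            expected = cpg_frequency(seq) / (props["C"] * props["G"])
            assert cpg_frequency_normalised(seq) == pytest.approx(expected, rel=1e-12)

    def test_law_of_large_numbers_iid_uniform(self):
        rng = np.random.default_rng(777)
        seq = "".join(rng.choice(list("ACGT"), size=10_000))
        assert cpg_frequency_normalised(seq) == pytest.approx(1.0, abs=0.1)

    @pytest.mark.parametrize(
        "seq, expected",
        [("ACGT", 0.25 * 0.25 * 3), ("CCGG", 0.5 * 0.5 * 3)],
    )
    def test_expected_cpg_formula(self, seq, expected):
        assert expected_cpg(seq) == pytest.approx(expected)

    def test_expected_cpg_matches_recomputation(self, rng):
        for _ in range(100):
            seq = random_sequence(rng, 250)
            props = oracle_props(seq)
            assert expected_cpg(seq) == pytest.approx(
                props["C"] * props["G"] * (len(seq) - 1)
            )


class TestDinucleotideBias:
    def test_cg_bias_equals_normalised_cpg_without_n(self):
        seq = "ACGTACGTAACC"
        assert dinucleotide_bias(seq, "CG") == pytest.approx(
            cpg_frequency_normalised(seq)
        )

    def test_homopolymer_bias_is_one(self):
        assert dinucleotide_bias("AAAA", "AA") == pytest.approx(1.0)

    def test_absent_base_rejected(self):
        with pytest.raises(UndefinedCompositionError):
            dinucleotide_bias("AATT", "CG")

    def test_all_sixteen_match_naive_recomputation(self, rng):
        for _ in range(50):
            seq = random_sequence(rng, 300)
            counts = oracle_dinuc_counts(seq)
            props = oracle_props(seq)
            for xy in DINUCLEOTIDES:
                if props[xy[0]] == 0 or props[xy[1]] == 0:
                    continue
                naive = (counts[xy] / (len(seq) - 1)) / (props[xy[0]] * props[xy[1]])
                assert dinucleotide_bias(seq, xy) == pytest.approx(naive, rel=1e-12)

    @pytest.mark.parametrize("target", [0.4, 1.0, 1.6])
    def test_markov_sequence_converges_to_designed_odds(self, target):
        seq = generate_sequence(10_000, target, seed=99)
        assert dinucleotide_bias(seq, "CG") == pytest.approx(target, abs=0.05)


class TestCodonAminoFeatures:
    def test_amino_acid_proportions_direct_count(self):
        feats = codon_amino_features("ATGATGTGA")
        assert feats["aa:M"] == pytest.approx(2 / 3)
        assert feats["aa:*"] == pytest.approx(1 / 3)
        others = [feats[f"aa:{aa}"] for aa in AMINO_ACIDS if aa not in "M*"]
        assert all(v == 0 for v in others)

    def test_bridge_positions_manual_enumeration(self):
        # codons ATG|CCG|TGA: bridges are GC (pos 3->4) and GT (pos 6->7)
        cds = "ATGCCGTGA"
        feats = codon_amino_features(cds)
        pos1 = [cds[0], cds[3], cds[6]]  # A, C, T
        pos3 = [cds[2], cds[5], cds[8]]  # G, G, A
        f3_g = pos3.count("G") / 3
        f1_c = pos1.count("C") / 3
        f1_t = pos1.count("T") / 3
        assert feats["bridge:GC"] == pytest.approx((1 / 2) / (f3_g * f1_c))
        assert feats["bridge:GT"] == pytest.approx((1 / 2) / (f3_g * f1_t))
        zero_bridges = [
            feats[f"bridge:{xy}"] for xy in DINUCLEOTIDES if xy not in ("GC", "GT")
        ]
        assert all(v == 0 for v in zero_bridges)

    def test_rscu_style_codon_bias_hand_enumeration(self):
        # Leu family (6 codons): 2x CTG and 1x CTA observed
        cds = "ATG" + "CTG" * 2 + "CTA" + "TGA"
        feats = codon_amino_features(cds)
        assert feats["codon:CTG"] == pytest.approx(2 / (3 / 6))
        assert feats["codon:CTA"] == pytest.approx(1 / (3 / 6))
        assert feats["codon:CTT"] == 0.0
        # Ala family unobserved: all four codons 0
        assert all(feats[f"codon:GC{b}"] == 0.0 for b in "ACGT")

    def test_length_not_multiple_of_three_rejected(self):
        with pytest.raises(ValueError):
            codon_amino_features("ATGCC")


class TestFeatureVector:
    def test_exactly_185_features(self, small_gene_set):
        vec = feature_vector(small_gene_set["records"][0])
        assert vec.shape == (185,)
        assert len(FEATURE_NAMES) == 185

    def test_deterministic(self, small_gene_set):
        rec = small_gene_set["records"][0]
        assert np.array_equal(feature_vector(rec), feature_vector(rec))

    def test_all_entries_finite(self, small_features):
        X, _ = small_features
        assert np.isfinite(X.to_numpy()).all()

    def test_whole_sequence_entries_match_standalone_operations(self, small_gene_set):
        rec = small_gene_set["records"][0]
        vec = dict(zip(FEATURE_NAMES, feature_vector(rec)))
        assert vec["cdna:CG-bias"] == pytest.approx(dinucleotide_bias(rec.cdna, "CG"))
        assert vec["cds:CG-bias"] == pytest.approx(dinucleotide_bias(rec.cds, "CG"))
        assert vec["cdna:GC"] == pytest.approx(
            oracle_props(rec.cdna)["G"] + oracle_props(rec.cdna)["C"]
        )

    def test_missing_cds_rejected(self):
        rec = GeneRecord("G1", "ACGTACGT")
        with pytest.raises(ValueError, match="CDS"):
            feature_vector(rec)

    def test_invariant_to_case_and_line_wrapping(self, tmp_path, small_gene_set):
        from ifncomp.sequence_io import read_gene_records

        rec = small_gene_set["records"][0]
        plain = tmp_path / "plain"
        wrapped = tmp_path / "wrapped"
        for d, transform in ((plain, lambda s: s), (wrapped, None)):
            d.mkdir()
        (plain / "c.fa").write_text(f">T1 gene:G\n{rec.cdna}\n")
        (plain / "o.fa").write_text(f">T1 gene:G\n{rec.cds}\n")
        wrap = "\n".join(rec.cdna.lower()[i:i + 60] for i in range(0, len(rec.cdna), 60))
        wrap_cds = "\n".join(rec.cds.lower()[i:i + 60] for i in range(0, len(rec.cds), 60))
        (wrapped / "c.fa").write_text(f">T1 gene:G\n{wrap}\n")
        (wrapped / "o.fa").write_text(f">T1 gene:G\n{wrap_cds}\n")
        (a,) = read_gene_records(plain / "c.fa", plain / "o.fa")
        (b,) = read_gene_records(wrapped / "c.fa", wrapped / "o.fa")
        assert np.array_equal(feature_vector(a), feature_vector(b))


@settings(max_examples=60, deadline=None, derandomize=True)
@given(st.text(alphabet="ACGT", min_size=2, max_size=120))
def test_count_dinucleotides_property_matches_oracle(seq):
    assert count_dinucleotides(seq) == oracle_dinuc_counts(seq)


class TestDinucleotideFoldChange:
    def test_identical_groups_give_unity(self, small_gene_set):
        group = small_gene_set["records"][:10]
        fc = dinucleotide_fold_change(group, group)
        for xy in DINUCLEOTIDES:
            assert fc[xy] == pytest.approx(1.0)

    def test_reciprocal_symmetry(self, small_gene_set):
        a = small_gene_set["records"][:10]
        b = small_gene_set["records"][10:20]
        ab = dinucleotide_fold_change(a, b)
        ba = dinucleotide_fold_change(b, a)
        for xy in DINUCLEOTIDES:
            assert ab[xy] * ba[xy] == pytest.approx(1.0)

    def test_doubled_cpg_group_shows_twofold_change(self):
        # same base composition, CG odds 0.5 vs 1.0 -> CG fold change ~2
        low = [generate_sequence(20_000, 0.5, seed=s) for s in range(8)]
        high = [generate_sequence(20_000, 1.0, seed=100 + s) for s in range(8)]
        fc = dinucleotide_fold_change(high, low)
        assert fc["CG"] == pytest.approx(2.0, rel=0.15)
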