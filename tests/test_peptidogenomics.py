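"""Three-frame translation, matching, genomic mapping and peptide summaries."""

import numpy as np
import pytest
from Bio.Seq import Seq

from pepatlas.peptidogenomics import (
    GeneModel,
    PeptideMatch,
    TranslatedFrames,
    deduplicate,
    map_to_genome,
    match_peptides,
    molecular_weight,
    resolve_frame_class,
    start_codon_of,
    translate_three_frames,
    tss_distance,
)

CODON_TABLE = {  # independent minimal codon oracle, built from Biopython once
    str(Seq(a + b + c)): str(Seq(a + b + c).translate())
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
}


def naive_translate(seq: str, frame: int) -> str:
    out = []
    for i in range(frame, len(seq) - 2, 3):
        codon = seq[i : i + 3]
        out.append("X" if "N" in codon else CODON_TABLE[codon])
    return "".join(out)


class TestTranslation:
    def test_hand_examples(self):
        tf = translate_three_frames("ATGGCCTGA")
        assert (tf.frame0, tf.frame1, tf.frame2) == ("MA*", "WP", "GL")
        tf = translate_three_frames("ATG")
        assert (tf.frame0, tf.frame1, tf.frame2) == ("M", "", "")

    def test_matches_codon_by_codon_oracle_on_random_sequences(self, rng):
        for _ in range(100):
            n = int(rng.integers(3, 300))
            seq = "".join(rng.choice(list("ACGTN"), size=n, p=[0.24] * 4 + [0.04]))
            tf = translate_three_frames(seq)
            for f in range(3):
                assert tf.frame(f) == naive_translate(seq, f)

    def test_invalid_nucleotide_names_gene(self):
        with pytest.raises(ValueError, match="geneX"):
            translate_three_frames("ATGQ", gene_id="geneX")


class TestMatching:
    def test_single_frame_matches(self):
        tf = translate_three_frames("ATGGCCTGA", "g1")
        m = match_peptides({"p1": "MA"}, [tf])
        assert [(x.gene_id, x.frame, x.aa_offset) for x in m] == [("g1", 0, 0)]
        m = match_peptides({"p2": "WP"}, [tf])
        assert [(x.frame, x.aa_offset) for x in m] == [(1, 0)]

    def test_equals_bruteforce_on_random_input(self, rng):
        aas = list("ACDEFGHIKLMNPQRSTVWY")
        frames = []
        for g in range(50):
            prot = "".join(rng.choice(aas + ["*"], size=int(rng.integers(20, 80)),
                                      p=[0.0485] * 20 + [0.03]))
            frames.append(TranslatedFrames(f"g{g:02d}", prot, prot[::-1], prot[1:]))
        peptides = {}
        for p in range(100):
            src = frames[rng.integers(0, 50)].frame(int(rng.integers(0, 3)))
            L = int(rng.integers(2, 6))
            if len(src) <= L:
                continue
            start = int(rng.integers(0, len(src) - L))
            cand = src[start : start + L]
            if "*" not in cand and "X" not in cand:
                peptides[f"p{p:03d}"] = cand
        got = {(m.peptide_id, m.gene_id, m.frame, m.aa_offset)
               for m in match_peptides(peptides, frames)}
        expected = set()
        for pid, pat in peptides.items():
            for tf in frames:
                for f in range(3):
                    text = tf.frame(f)
                    start = text.find(pat)
                    while start != -1:
                        expected.add((pid, tf.gene_id, f, start))
                        start = text.find(pat, start + 1)
        assert got == expected

    def test_empty_peptide_rejected(self):
        tf = translate_three_frames("ATGGCC", "g1")
        with pytest.raises(ValueError):
            match_peptides({"p": ""}, [tf])


class TestFrameClass:
    def test_in_frame_priority(self):
        ms = [PeptideMatch("p", "gB", 1, 0), PeptideMatch("p", "gA", 0, 3)]
        assert resolve_frame_class(ms) == ("in_frame", "gA")

    def test_only_alternative_frames(self):
        ms = [PeptideMatch("p", "gC", 2, 1), PeptideMatch("p", "gB", 1, 0)]
        assert resolve_frame_class(ms) == ("out_of_frame", "gB")

    def test_frame_partition_is_exhaustive(self, identified_records):
        mapped = [r for r in identified_records if r.frame_class != "unmapped"]
        assert all(r.frame_class in ("in_frame", "out_of_frame") for r in mapped)
        n_in = sum(r.frame_class == "in_frame" for r in mapped)
        n_out = sum(r.frame_class == "out_of_frame" for r in mapped)
        assert n_in + n_out == len(mapped)


def make_gene(chrom, strand, segments, genome):
    spliced = "".join(genome[s:e] for s, e in segments)
    if strand == "-":
        spliced = str(Seq(spliced).reverse_complement())
    return GeneModel("g1", chrom, strand, tuple(segments), spliced)


class TestGenomicMapping:
    def test_plus_strand_single_exon(self):
        genome = "ATGGCCAAATGA"
        model = make_gene("chr1", "+", [(0, 12)], genome)
        m = PeptideMatch("p", "g1", 0, 0)
        chrom, strand, blocks = map_to_genome(m, model, 2)
        assert (chrom, strand, blocks) == ("chr1", "+", [(0, 6)])

    def test_minus_strand_single_exon(self):
        # genomic TCATTTGGCCAT reverse-complements to CDS ATGGCCAAATGA
        genome = "TCATTTGGCCAT"
        model = make_gene("chr1", "-", [(0, 12)], genome)
        assert model.cds_sequence == "ATGGCCAAATGA"
        m = PeptideMatch("p", "g1", 0, 0)
        _c, strand, blocks = map_to_genome(m, model, 2)
        assert strand == "-"
        # first two codons occupy the 3'-most six genomic bases
        assert blocks == [(6, 12)]
        # reverse-complementing the blocks reproduces the peptide codons
        sub = "".join(genome[s:e] for s, e in blocks)
        assert str(Seq(sub).reverse_complement()) == "ATGGCC"

    def test_codon_split_across_junction(self):
        # exon1 = 4 nt so codon 2 spans the junction
        genome = "ATGG" + "NNN" + "CCAAATGA"
        model = make_gene("chr1", "+", [(0, 4), (7, 15)], genome)
        m = PeptideMatch("p", "g1", 0, 0)
        _c, _s, blocks = map_to_genome(m, model, 3)
        assert blocks == [(0, 4), (7, 12)]
        assert sum(e - s for s, e in blocks) == 9

    def test_offset_beyond_cds_rejected(self):
        model = make_gene("chr1", "+", [(0, 12)], "ATGGCCAAATGA")
        with pytest.raises(ValueError):
            map_to_genome(PeptideMatch("p", "g1", 0, 3), model, 2)

    def test_roundtrip_translation_of_mapped_blocks(self, default_atlas,
                                                    identified_records):
        """Translating the mapped genomic blocks reproduces the peptide."""
        genome = default_atlas.genome
        checked = 0
        for rec in identified_records[:300]:
            if rec.frame_class != "in_frame" or not rec.genomic_blocks:
                continue
            nt = "".join(genome[rec.chrom][s:e] for s, e in rec.genomic_blocks)
            if rec.strand == "-":
                nt = str(Seq(nt).reverse_complement())
            assert str(Seq(nt).translate()) == rec.sequence
            checked += 1
        assert checked > 50


class TestStartCodon:
    def test_n_terminal_peptide_is_aug(self):
        model = make_gene("chr1", "+", [(0, 12)], "ATGGCCAAATGA")
        codon, klass = start_codon_of(PeptideMatch("p", "g1", 0, 0), model)
        assert (codon, klass) == ("ATG", "AUG")

    def test_internal_codon_non_aug(self):
        model = make_gene("chr1", "+", [(0, 12)], "ATGGCCAAATGA")
        codon, klass = start_codon_of(PeptideMatch("p", "g1", 0, 1), model)
        assert (codon, klass) == ("GCC", "non-AUG")

    def test_aug_fraction_equals_met_start_fraction(self, identified_records):
        """A peptide's start codon is ATG exactly when its first residue is M."""
        mapped = [r for r in identified_records if r.start_codon_class]
        assert all(
            (r.start_codon_class == "AUG") == (r.sequence[0] == "M") for r in mapped)
        planted_aug = [r for r in identified_records if r.sequence[0] == "M"]
        assert len(planted_aug) > 0

    def test_tss_distance_zero_at_protein_start(self):
        model = make_gene("chr1", "+", [(0, 12)], "ATGGCCAAATGA")
        assert tss_distance(PeptideMatch("p", "g1", 0, 0), model, 2) == 0
        assert tss_distance(PeptideMatch("p", "g1", 0, 1), model, 2) == 3

    def test_tss_distance_minus_strand(self):
        genome = "TCATTTGGCCAT"
        model = make_gene("chr1", "-", [(0, 12)], genome)
        # CDS start is the 3'-most genomic base (position 11)
        assert tss_distance(PeptideMatch("p", "g1", 0, 0), model, 2) == 0
        assert tss_distance(PeptideMatch("p", "g1", 0, 1), model, 1) == 3


class TestDeduplicate:
    def test_merges_by_sequence(self):
        table = [("a", "MA", {"t1"}), ("b", "MA", {"t2"}), ("c", "WP", {"t1"})]
        records = deduplicate(table)
        assert len(records) == 2
        ma = next(r for r in records if r.sequence == "MA")
        assert ma.detected_tissues == {"t1", "t2"}

    def test_count_matches_set_size_oracle(self, rng):
        seqs = ["".join(rng.choice(list("ACDE"), size=3)) for _ in range(200)]
        table = [(f"p{i}", s, set()) for i, s in enumerate(seqs)]
        assert len(deduplicate(table)) == len({s.upper() for s in seqs})

    def test_abundance_reducer_max(self):
        table = [("a", "MA", {"t1"}), ("b", "ma", {"t2"})]
        records = deduplicate(table, {"a": {"t1": 5.0}, "b": {"t1": 9.0, "t2": 1.0}})
        rec = records[0]
        assert rec.abundances == {"t1": 9.0, "t2": 1.0}


class TestMolecularWeight:
    @pytest.mark.parametrize(
        "seq,expected",
        [("G", 75.0672), ("GG", 132.1191)],
    )
    def test_glycine_examples(self, seq, expected):
        assert molecular_weight(seq) == pytest.approx(expected, abs=0.01)

    def test_agrees_with_pyteomics_average_mass(self):
        mass = pytest.importorskip("pyteomics.mass")
        for seq in ["LQESLGGNAKLAM", "MA", "WWWW", "ACDEFGHIKLMNPQRSTVWY"]:
            oracle = mass.calculate_mass(sequence=seq, average=True)
            assert molecular_weight(seq) == pytest.approx(oracle, abs=0.2)

    def test_unknown_residue(self):
        with pytest.raises(ValueError):
            molecular_weight("GB")
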