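"""Peptidogenomic mapping of endogenous peptides onto canonical CDSs.

Endogenous peptides (2-100 aa, detected directly by MS rather than by
tryptic digestion) are located in coding space by exact matching against
the three-frame translation of every canonical coding sequence.  Frame 0
is the annotated reading frame; frames 1 and 2 are the two alternative
frames of the same CDS.  A peptide with at least one frame-0 match is
*in-frame*, otherwise *out-of-frame*.  Matches are lifted back to genomic
coordinates through the spliced CDS segments, and the CDS-level codon
covering the peptide's first residue decides its AUG / non-AUG start.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

from Bio.Seq import Seq

__all__ = [
    "GeneModel",
    "TranslatedFrames",
    "PeptideMatch",
    "PeptideRecord",
    "AhoCorasick",
    "translate_three_frames",
    "match_peptides",
    "resolve_frame_class",
    "map_to_genome",
    "start_codon_of",
    "tss_distance",
    "deduplicate",
    "molecular_weight",
]

NUCLEOTIDES = set("ACGTN")
AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")

#: Average residue masses in daltons (monomer mass minus one water).
AVERAGE_RESIDUE_MASS = {
    "G": 57.0519, "A": 71.0788, "S": 87.0782, "P": 97.1167, "V": 99.1326,
    "T": 101.1051, "C": 103.1388, "L": 113.1594, "I": 113.1594,
    "N": 114.1038, "D": 115.0886, "Q": 128.1307, "K": 128.1741,
    "E": 129.1155, "M": 131.1926, "H": 137.1411, "F": 147.1766,
    "R": 156.1875, "Y": 163.1760, "W": 186.2132,
}
WATER_MASS = 18.0153


@dataclass(frozen=True)
class GeneModel:
    """A gene's chromosome, strand and ordered CDS segments.

    ``cds_segments`` are 0-based half-open genomic intervals sorted by
    genomic start; ``cds_sequence`` is the spliced, strand-corrected
    nucleotide sequence read 5'->3'.
    """

    gene_id: str
    chrom: str
    strand: str
    cds_segments: tuple[tuple[int, int], ...]
    cds_sequence: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")
        prev_end = -1
        for start, end in self.cds_segments:
            if end <= start:
                raise ValueError(f"{self.gene_id}: empty CDS segment {start}-{end}")
            if start < prev_end:
                raise ValueError(f"{self.gene_id}: CDS segments overlap or are unsorted")
            prev_end = end
        seg_len = sum(e - s for s, e in self.cds_segments)
        if seg_len != len(self.cds_sequence):
            raise ValueError(
                f"{self.gene_id}: CDS segments span {seg_len} nt but sequence has "
                f"{len(self.cds_sequence)}"
            )
        if len(self.cds_sequence) < 3:
            raise ValueError(f"{self.gene_id}: CDS shorter than one codon")

    @property
    def frame_preserved(self) -> bool:
        """True when the spliced CDS length is a whole number of codons."""
        return len(self.cds_sequence) % 3 == 0

    @property
    def cds_start_genomic(self) -> int:
        """Genomic coordinate of the first CDS base (strand-aware).

        For a minus-strand gene this is the 3'-most genomic position, i.e.
        ``end - 1`` of the last segment.
        """
        if self.strand == "+":
            return self.cds_segments[0][0]
        return self.cds_segments[-1][1] - 1


@dataclass(frozen=True)
class TranslatedFrames:
    gene_id: str
    frame0: str
    frame1: str
    frame2: str

    def frame(self, f: int) -> str:
        return (self.frame0, self.frame1, self.frame2)[f]


@dataclass(frozen=True)
class PeptideMatch:
    peptide_id: str
    gene_id: str
    frame: int
    aa_offset: int
    frame_class: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "frame_class", "in_frame" if self.frame == 0 else "out_of_frame"
        )


@dataclass
class PeptideRecord:
    """One nonredundant peptide with its resolved mapping."""

    peptide_id: str
    sequence: str
    matches: list[PeptideMatch] = field(default_factory=list)
    primary_gene: str | None = None
    frame_class: str = "unmapped"
    detected_tissues: set[str] = field(default_factory=set)
    abundances: dict[str, float] = field(default_factory=dict)
    # filled in once the primary match is lifted to the genome
    chrom: str | None = None
    strand: str | None = None
    genomic_blocks: tuple[tuple[int, int], ...] = ()
    start_codon: str | None = None
    start_codon_class: str | None = None
    tss_distance_bp: int | None = None

    @property
    def genomic_start(self) -> int | None:
        return self.genomic_blocks[0][0] if self.genomic_blocks else None

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def mol_weight(self) -> float:
        return molecular_weight(self.sequence)


def translate_three_frames(cds_sequence: str, gene_id: str = "?") -> TranslatedFrames:
    """Translate a CDS in all three forward frames.

    Standard codon table; stop codons become ``*``; any codon containing
    ``N`` becomes ``X``; trailing 1-2 nt of a frame are dropped.
    """
    seq = cds_sequence.upper()
    bad = set(seq) - NUCLEOTIDES
    if bad:
        raise ValueError(f"gene {gene_id}: invalid nucleotide(s) {sorted(bad)}")
    has_n = "N" in seq
    frames = []
    for f in range(3):
        sub = seq[f : f + 3 * ((len(seq) - f) // 3)]
        if not sub:
            frames.append("")
            continue
        aa = str(Seq(sub).translate())
        if has_n:
            # any codon containing N is reported as X, even when the
            # ambiguity would not change the encoded amino acid
            aa = "".join(
                "X" if "N" in sub[3 * i : 3 * i + 3] else ch
                for i, ch in enumerate(aa)
            )
        frames.append(aa)
    return TranslatedFrames(gene_id, *frames)


class AhoCorasick:
    """Multi-pattern exact string matching in time linear in text length.

    Classic automaton over the amino-acid alphabet: a trie of the patterns
    plus failure links, so one pass over each translated frame reports
    every occurrence of every peptide.
    """

    def __init__(self, patterns: dict[str, str]):
        # goto is a list of dicts: state -> {char: state}
        self.goto: list[dict[str, int]] = [{}]
        self.out: list[list[str]] = [[]]
        self.fail: list[int] = [0]
        for pat_id, pat in patterns.items():
            if not pat:
                raise ValueError(f"empty pattern for id {pat_id!r}")
            self._insert(pat_id, pat)
        self.pattern_len = {pid: len(p) for pid, p in patterns.items()}
        self._build_failure_links()

    def _insert(self, pat_id: str, pat: str) -> None:
        state = 0
        for ch in pat:
            nxt = self.goto[state].get(ch)
            if nxt is None:
                nxt = len(self.goto)
                self.goto.append({})
                self.out.append([])
                self.fail.append(0)
                self.goto[state][ch] = nxt
            state = nxt
        self.out[state].append(pat_id)

    def _build_failure_links(self) -> None:
        queue: deque[int] = deque()
        for child in self.goto[0].values():
            self.fail[child] = 0
            queue.append(child)
        while queue:
            state = queue.popleft()
            for ch, child in self.goto[state].items():
                queue.append(child)
                f = self.fail[state]
                while f and ch not in self.goto[f]:
                    f = self.fail[f]
                self.fail[child] = self.goto[f].get(ch, 0)
                if self.fail[child] == child:
                    self.fail[child] = 0
                self.out[child] = self.out[child] + self.out[self.fail[child]]

    def iter_matches(self, text: str):
        """Yield ``(pattern_id, start_offset)`` for every occurrence in text."""
        state = 0
        for i, ch in enumerate(text):
            while state and ch not in self.goto[state]:
                state = self.fail[state]
            state = self.goto[state].get(ch, 0)
            for pat_id in self.out[state]:
                yield pat_id, i - self.pattern_len[pat_id] + 1


def match_peptides(
    peptides: dict[str, str], frames: list[TranslatedFrames]
) -> list[PeptideMatch]:
    """Exact substring occurrences of every peptide in every translated frame.

    Peptide sequences are pure amino-acid strings, so a reported match can
    never span a stop (``*``) or ambiguous (``X``) position.  Search uses an
    Aho-Corasick automaton: one pass per frame string regardless of how
    many peptides are queried.
    """
    if not peptides:
        raise ValueError("peptide set is empty")
    for pid, seq in peptides.items():
        if not seq:
            raise ValueError(f"peptide {pid!r} has empty sequence")
        bad = set(seq.upper()) - AMINO_ACIDS
        if bad:
            raise ValueError(f"peptide {pid!r}: invalid residue(s) {sorted(bad)}")
    automaton = AhoCorasick({pid: seq.upper() for pid, seq in peptides.items()})
    matches: list[PeptideMatch] = []
    for tf in frames:
        for f in range(3):
            text = tf.frame(f)
            for pid, off in automaton.iter_matches(text):
                matches.append(PeptideMatch(pid, tf.gene_id, f, off))
    matches.sort(key=lambda m: (m.peptide_id, m.gene_id, m.frame, m.aa_offset))
    return matches


def resolve_frame_class(matches: list[PeptideMatch]) -> tuple[str, str]:
    """Frame class and primary source gene for one peptide's matches.

    In-frame takes priority: one frame-0 match anywhere makes the peptide
    in-frame.  The primary gene is the lexicographically smallest gene id
    among the matches of the winning priority class, which makes unique-gene
    counting deterministic for multi-gene peptides.
    """
    if not matches:
        raise ValueError("resolve_frame_class requires at least one match")
    frame0 = [m for m in matches if m.frame == 0]
    if frame0:
        return "in_frame", min(m.gene_id for m in frame0)
    return "out_of_frame", min(m.gene_id for m in matches)


def map_to_genome(match: PeptideMatch, model: GeneModel, peptide_length: int):
    """Genomic blocks covered by a matched peptide.

    The amino-acid offset and frame give a spliced-CDS nucleotide interval,
    which is pushed through the gene's CDS segments (strand aware).  Returns
    ``(chrom, strand, blocks)`` with blocks as 0-based half-open genomic
    intervals sorted by genomic start; block lengths always sum to three
    times the peptide length.
    """
    nt_start = match.frame + 3 * match.aa_offset
    nt_end = nt_start + 3 * peptide_length
    if nt_end > len(model.cds_sequence):
        raise ValueError(
            f"match {match.peptide_id}@{model.gene_id}: CDS offset "
            f"{nt_end} beyond CDS length {len(model.cds_sequence)}"
        )
    blocks: list[tuple[int, int]] = []
    if model.strand == "+":
        pos = 0  # spliced position at segment starts
        for seg_start, seg_end in model.cds_segments:
            seg_len = seg_end - seg_start
            lo = max(nt_start, pos)
            hi = min(nt_end, pos + seg_len)
            if lo < hi:
                blocks.append((seg_start + (lo - pos), seg_start + (hi - pos)))
            pos += seg_len
    else:
        pos = 0
        for seg_start, seg_end in reversed(model.cds_segments):
            seg_len = seg_end - seg_start
            lo = max(nt_start, pos)
            hi = min(nt_end, pos + seg_len)
            if lo < hi:
                # spliced position p in this segment sits at genomic seg_end-1-(p-pos)
                g_hi = seg_end - (lo - pos)
                g_lo = seg_end - (hi - pos)
                blocks.append((g_lo, g_hi))
            pos += seg_len
        blocks.sort()
    assert sum(e - s for s, e in blocks) == 3 * peptide_length
    return model.chrom, model.strand, blocks


def start_codon_of(match: PeptideMatch, model: GeneModel) -> tuple[str, str]:
    """CDS-level codon covering the peptide's first residue.

    Returns ``(codon, klass)`` with klass ``"AUG"`` iff the codon is ATG.
    """
    nt_start = match.frame + 3 * match.aa_offset
    codon = model.cds_sequence[nt_start : nt_start + 3].upper()
    if len(codon) < 3:
        raise ValueError(f"{match.peptide_id}@{model.gene_id}: truncated start codon")
    return codon, ("AUG" if codon == "ATG" else "non-AUG")


def tss_distance(match: PeptideMatch, model: GeneModel, peptide_length: int) -> int:
    """Genomic distance from the peptide's 5'-most mapped base to the CDS start.

    The canonical translation start site is the first base of the first
    codon of the annotated CDS; on the minus strand that is the 3'-most
    genomic coordinate of the model.
    """
    chrom, strand, blocks = map_to_genome(match, model, peptide_length)
    if strand == "+":
        five_prime = blocks[0][0]
    else:
        five_prime = blocks[-1][1] - 1
    return abs(five_prime - model.cds_start_genomic)


def deduplicate(
    peptide_table: list[tuple[str, str, set[str]]],
    abundances: dict[str, dict[str, float]] | None = None,
    reducer=max,
) -> list[PeptideRecord]:
    """Collapse a raw identification table to nonredundant peptides.

    ``peptide_table`` rows are ``(peptide_id, sequence, detected_tissues)``.
    Redundancy is exact case-folded sequence identity; tissue detection
    flags are OR-merged and abundances (if given, keyed by peptide_id then
    tissue) are merged by ``reducer`` (default max).  The merged record
    keeps the first-seen peptide id.
    """
    by_seq: dict[str, PeptideRecord] = {}
    merged_abund: dict[str, dict[str, float]] = {}
    for pid, seq, tissues in peptide_table:
        key = seq.upper()
        rec = by_seq.get(key)
        if rec is None:
            rec = PeptideRecord(peptide_id=pid, sequence=key)
            by_seq[key] = rec
            merged_abund[rec.peptide_id] = {}
        rec.detected_tissues |= set(tissues)
        if abundances is not None:
            for tissue, value in abundances.get(pid, {}).items():
                cur = merged_abund[rec.peptide_id]
                cur[tissue] = reducer([cur[tissue], value]) if tissue in cur else value
    records = list(by_seq.values())
    if abundances is not None:
        for rec in records:
            rec.abundances = merged_abund[rec.peptide_id]
    return records


def molecular_weight(sequence: str) -> float:
    """Average molecular weight of a peptide in daltons.

    Sum of average residue masses plus one water (18.0153 Da).  Average
    rather than monoisotopic masses, matching the reporting convention of
    label-free peptide atlases.
    """
    total = WATER_MASS
    for ch in sequence.upper():
        try:
            total += AVERAGE_RESIDUE_MASS[ch]
        except KeyError:
            raise ValueError(f"unknown amino acid {ch!r} in {sequence!r}") from None
    return total
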