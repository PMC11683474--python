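"""Miniature maize-like atlas generator with planted ground truth.

Every downstream stage of the pipeline (frame classification, tissue
specificity, genomic landscape, coexpression modules, peptide-protein
correlation) is exercised against data whose true structure is known:

* a multi-chromosome genome carrying spliced protein-coding gene models,
  with gene density doubled in the terminal fraction of each chromosome
  (so telomere-proximity and peptide-rich-region analyses have a planted
  signal);
* a nonredundant peptide set drawn from the three-frame translations of
  those genes with a controlled in-frame fraction and a length mix in
  which most peptides are shorter than 23 aa;
* a tissue abundance matrix with planted tissue-specific / tissue-enhanced
  / mixed rows, latent coexpression modules, and a genomically
  distance-decaying co-abundance field;
* a matched one-row-per-gene protein matrix whose peptide-source-protein
  Pearson correlations are planted at configurable levels.

Abundances follow a log-normal model (base abundance times tissue-effect
multipliers), mimicking the right-skew of label-free MS intensities.
Zero encodes "not detected".
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .peptidogenomics import GeneModel, translate_three_frames

logger = logging.getLogger(__name__)

__all__ = [
    "SyntheticConfig",
    "SyntheticTruth",
    "SyntheticAtlas",
    "MAIZE_TISSUES",
    "PHASE_MAP",
    "generate_genome",
    "generate_peptides",
    "generate_abundance",
    "generate_atlas",
    "default_config",
    "module_benchmark_config",
    "decay_benchmark_config",
    "pair_benchmark_config",
]

#: The 13 profiled tissues, vegetative then reproductive phase.
MAIZE_TISSUES = (
    "IND", "JLB3", "ML8", "PR5D", "SR7D", "VM19D",
    "Tas", "GP", "SiU", "FS", "EP", "En8DAP", "Em20DAP",
)
PHASE_MAP = {t: ("vegetative" if i < 6 else "reproductive")
             for i, t in enumerate(MAIZE_TISSUES)}

# Back-translation table: one entry per amino acid, all synonymous codons.
_CODONS = {
    "A": ["GCT", "GCC", "GCA", "GCG"], "C": ["TGT", "TGC"],
    "D": ["GAT", "GAC"], "E": ["GAA", "GAG"], "F": ["TTT", "TTC"],
    "G": ["GGT", "GGC", "GGA", "GGG"], "H": ["CAT", "CAC"],
    "I": ["ATT", "ATC", "ATA"], "K": ["AAA", "AAG"],
    "L": ["TTA", "TTG", "CTT", "CTC", "CTA", "CTG"], "M": ["ATG"],
    "N": ["AAT", "AAC"], "P": ["CCT", "CCC", "CCA", "CCG"],
    "Q": ["CAA", "CAG"], "R": ["CGT", "CGC", "CGA", "CGG", "AGA", "AGG"],
    "S": ["TCT", "TCC", "TCA", "TCG", "AGT", "AGC"],
    "T": ["ACT", "ACC", "ACA", "ACG"], "V": ["GTT", "GTC", "GTA", "GTG"],
    "W": ["TGG"], "Y": ["TAT", "TAC"],
}
_AA = sorted(_CODONS)
_STOPS = ["TAA", "TAG", "TGA"]
_COMP = bytes.maketrans(b"ACGT", b"TGCA")


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator parameters; the seed fully determines every output."""

    n_chromosomes: int = 10
    chrom_length_bp: int = 5_000_000
    n_genes: int = 400
    n_peptides: int = 2_000
    n_tissues: int = 13
    in_frame_fraction: float = 0.91
    specificity_mix: tuple[float, float, float] = (0.35, 0.35, 0.30)
    n_modules: int = 6
    pair_correlation_levels: tuple[float, ...] = (-0.2, 0.0, 0.2, 0.45, 0.7)
    seed: int = 0
    # peptide composition
    short_fraction: float = 0.94     # P(length < 23 aa)
    min_peptide_aa: int = 8          # MS rarely identifies shorter peptides
    max_peptide_aa: int = 60
    aug_fraction: float = 0.0243     # peptides planted at the protein N-terminus
    # abundance model (natural-log scale)
    base_log_abundance: float = 10.0
    base_log_sd: float = 1.0
    effect_fold: float = 8.0         # tissue-effect size for specific/enhanced rows
    noise_sd: float = 0.2
    specific_detect_prob: float = 0.3
    module_amplitude: float = 0.5
    spatial_amplitude: float = 0.3
    spatial_length_bp: float = 100_000.0
    protein_log_sd: float = 0.8
    # genome layout
    terminal_fraction: float = 0.10
    terminal_density_multiplier: float = 2.0
    min_protein_aa: int = 80
    max_protein_aa: int = 300

    def __post_init__(self) -> None:
        for name in ("n_chromosomes", "chrom_length_bp", "n_tissues"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("n_genes", "n_peptides"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("in_frame_fraction", "short_fraction", "aug_fraction",
                     "specific_detect_prob", "terminal_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if any(p < 0 or p > 1 for p in self.specificity_mix):
            raise ValueError("specificity_mix proportions must be in [0, 1]")
        if abs(sum(self.specificity_mix) - 1.0) > 1e-9:
            raise ValueError("specificity_mix must sum to 1")
        for r in self.pair_correlation_levels:
            if not -1.0 < r < 1.0:
                raise ValueError(f"planted pair correlation {r} outside (-1, 1)")

    @property
    def tissues(self) -> tuple[str, ...]:
        if self.n_tissues == len(MAIZE_TISSUES):
            return MAIZE_TISSUES
        return tuple(f"T{i + 1:02d}" for i in range(self.n_tissues))


@dataclass
class SyntheticTruth:
    """Planted ground truth, the oracle for every recovery test."""

    frame_class: dict[str, str] = field(default_factory=dict)
    source_gene: dict[str, str] = field(default_factory=dict)
    frame: dict[str, int] = field(default_factory=dict)
    aa_offset: dict[str, int] = field(default_factory=dict)
    is_n_terminal: dict[str, bool] = field(default_factory=dict)
    genomic_start: dict[str, tuple[str, int]] = field(default_factory=dict)
    specificity: dict[str, str] = field(default_factory=dict)
    top_tissue: dict[str, str] = field(default_factory=dict)
    module: dict[str, int] = field(default_factory=dict)
    pair_r: dict[str, float] = field(default_factory=dict)  # gene_id -> planted r
    pair_peptide: dict[str, str] = field(default_factory=dict)  # gene_id -> peptide_id
    terminal_zones: dict[str, list[tuple[int, int]]] = field(default_factory=dict)
    density_multiplier: float = 2.0
    skipped: list[str] = field(default_factory=list)


@dataclass
class SyntheticAtlas:
    config: SyntheticConfig
    genome: dict[str, str]
    models: list[GeneModel]
    peptides: pd.DataFrame          # index peptide_id; column 'sequence'
    abundance: pd.DataFrame         # peptides x tissues
    protein_abundance: pd.DataFrame  # genes x tissues
    truth: SyntheticTruth

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.genome.items()}


def _stage_rng(config: SyntheticConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng([stage, config.seed])


def _revcomp_bytes(b: bytes) -> bytes:
    return b.translate(_COMP)[::-1]


def generate_genome(config: SyntheticConfig):
    """Random chromosomes carrying non-overlapping spliced gene models.

    Proteins are drawn first (uniform over the 20 amino acids, so frame-0
    translations never contain an internal stop), back-translated codon by
    codon, split into 1-5 CDS segments separated by short introns, and
    written into the chromosome on a random strand.  Gene start positions
    fall in the terminal ``terminal_fraction`` of either chromosome end
    with ``terminal_density_multiplier`` times the interior density.
    """
    rng = _stage_rng(config, 1)
    truth = SyntheticTruth(density_multiplier=config.terminal_density_multiplier)
    alphabet = np.frombuffer(b"ACGT", dtype=np.uint8)
    chroms: dict[str, bytearray] = {}
    for i in range(config.n_chromosomes):
        arr = alphabet[rng.integers(0, 4, size=config.chrom_length_bp)]
        chroms[f"chr{i + 1}"] = bytearray(arr.tobytes())
    L = config.chrom_length_bp
    t = int(round(config.terminal_fraction * L))
    for name in chroms:
        truth.terminal_zones[name] = [(0, t), (L - t, L)]

    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    models: list[GeneModel] = []
    m = config.terminal_density_multiplier
    # probability that a gene start falls in the two terminal zones
    p_term = (2 * config.terminal_fraction * m) / (
        2 * config.terminal_fraction * m + (1 - 2 * config.terminal_fraction)
    )
    chrom_names = sorted(chroms, key=lambda c: int(c[3:]))
    for g in range(config.n_genes):
        gene_id = f"G{g + 1:04d}"
        plen = int(rng.integers(config.min_protein_aa, config.max_protein_aa + 1))
        protein = "M" + "".join(_AA[k] for k in rng.integers(0, 20, size=plen - 1))
        cds = "".join(_CODONS[aa][rng.integers(0, len(_CODONS[aa]))] for aa in protein)
        cds += _STOPS[rng.integers(0, 3)]
        n_segs = int(rng.integers(1, 6))
        cuts = sorted(rng.choice(np.arange(1, len(cds)), size=n_segs - 1, replace=False)) \
            if n_segs > 1 else []
        chunk_bounds = [0, *map(int, cuts), len(cds)]
        chunk_lens = [chunk_bounds[k + 1] - chunk_bounds[k] for k in range(n_segs)]
        introns = [int(rng.integers(60, 500)) for _ in range(n_segs - 1)]
        span = len(cds) + sum(introns)
        placed = False
        for _attempt in range(200):
            chrom = chrom_names[rng.integers(0, config.n_chromosomes)]
            if rng.random() < p_term:
                zone = truth.terminal_zones[chrom][rng.integers(0, 2)]
                start = int(rng.integers(zone[0], max(zone[0] + 1, zone[1] - span)))
            else:
                start = int(rng.integers(t, max(t + 1, L - t - span)))
            end = start + span
            if end > L:
                continue
            if any(s < end and start < e for s, e in occupied[chrom]):
                continue
            occupied[chrom].append((start, end))
            placed = True
            break
        if not placed:
            truth.skipped.append(f"gene {gene_id}: no free placement")
            continue
        segments = []
        pos = start
        for k, clen in enumerate(chunk_lens):
            segments.append((pos, pos + clen))
            pos += clen
            if k < len(introns):
                pos += introns[k]
        strand = "+" if rng.random() < 0.5 else "-"
        seg_tuple = tuple(segments)
        if strand == "+":
            genomic_nt = cds.encode()
        else:
            genomic_nt = _revcomp_bytes(cds.encode())
        off = 0
        buf = chroms[chrom]
        for s, e in seg_tuple:
            buf[s:e] = genomic_nt[off : off + (e - s)]
            off += e - s
        models.append(GeneModel(gene_id, chrom, strand, seg_tuple, cds))
    genome = {c: bytes(b).decode() for c, b in chroms.items()}
    models.sort(key=lambda mdl: mdl.gene_id)
    return genome, models, truth


def _sample_length(rng: np.random.Generator, config: SyntheticConfig) -> int:
    if rng.random() < config.short_fraction:
        return int(rng.integers(config.min_peptide_aa, 23))
    return int(rng.integers(23, config.max_peptide_aa + 1))


def _clean_runs(text: str, min_len: int) -> list[tuple[int, int]]:
    """Maximal [start, end) runs free of '*' and 'X' of length >= min_len."""
    runs, start = [], 0
    for i, ch in enumerate(text + "*"):
        if ch in "*X":
            if i - start >= min_len:
                runs.append((start, i))
            start = i + 1
    return runs


def generate_peptides(models: list[GeneModel], config: SyntheticConfig,
                      truth: SyntheticTruth) -> pd.DataFrame:
    """Draw a nonredundant peptide set from the translated gene models.

    Each peptide is a substring of its source gene's frame-0 translation
    (in-frame) or of a frame-1/2 translation (out-of-frame), with the
    planted in-frame fraction; a small planted fraction starts at the
    protein N-terminus so the AUG start-codon share is controlled.  A draw
    whose requested length fits no stop-free window is retried and, if it
    keeps failing, skipped and logged rather than ever emitting an invalid
    peptide.
    """
    rng = _stage_rng(config, 2)
    if config.n_peptides and not models:
        raise ValueError("cannot generate peptides without gene models")
    frames = {m.gene_id: translate_three_frames(m.cds_sequence, m.gene_id)
              for m in models}
    proteins = {g: tf.frame0.rstrip("*") for g, tf in frames.items()}
    by_gene = {m.gene_id: m for m in models}
    gene_ids = sorted(by_gene)
    seen: set[str] = set()
    rows = []
    p_in_rest = 0.0
    if config.aug_fraction < 1.0:
        p_in_rest = max(
            0.0, min(1.0, (config.in_frame_fraction - config.aug_fraction)
                     / (1.0 - config.aug_fraction)))
    for i in range(config.n_peptides):
        pid = f"P{i + 1:05d}"
        emitted = False
        for _attempt in range(60):
            gene = gene_ids[rng.integers(0, len(gene_ids))]
            n_term = rng.random() < config.aug_fraction
            in_frame = True if n_term else rng.random() < p_in_rest
            length = _sample_length(rng, config)
            if in_frame:
                frame_no = 0
                text = proteins[gene]
                if length > len(text):
                    continue
                offset = 0 if n_term else int(rng.integers(0, len(text) - length + 1))
                seq = text[offset : offset + length]
            else:
                frame_no = int(rng.integers(1, 3))
                text = frames[gene].frame(frame_no)
                runs = _clean_runs(text, length)
                if not runs:
                    continue
                run = runs[rng.integers(0, len(runs))]
                offset = int(rng.integers(run[0], run[1] - length + 1))
                seq = text[offset : offset + length]
            if seq in seen:
                continue
            seen.add(seq)
            model = by_gene[gene]
            nt_start = frame_no + 3 * offset
            # genomic coordinate of the 5'-most base, strand aware
            if model.strand == "+":
                pos, remaining = None, nt_start
                for s, e in model.cds_segments:
                    if remaining < e - s:
                        pos = s + remaining
                        break
                    remaining -= e - s
                gstart = pos if pos is not None else model.cds_segments[-1][1] - 1
            else:
                remaining = nt_start
                pos = None
                for s, e in reversed(model.cds_segments):
                    if remaining < e - s:
                        pos = e - 1 - remaining
                        break
                    remaining -= e - s
                gstart = pos if pos is not None else model.cds_segments[0][0]
            rows.append({"peptide_id": pid, "sequence": seq})
            truth.frame_class[pid] = "in_frame" if in_frame else "out_of_frame"
            truth.source_gene[pid] = gene
            truth.frame[pid] = frame_no
            truth.aa_offset[pid] = offset
            truth.is_n_terminal[pid] = bool(n_term)
            truth.genomic_start[pid] = (model.chrom, int(gstart))
            emitted = True
            break
        if not emitted:
            truth.skipped.append(f"peptide {pid}: no valid draw")
            logger.warning("skipped peptide %s: no valid draw after retries", pid)
    return pd.DataFrame(rows).set_index("peptide_id") if rows else \
        pd.DataFrame(columns=["sequence"]).rename_axis("peptide_id")


def generate_abundance(peptides: pd.DataFrame, truth: SyntheticTruth,
                       config: SyntheticConfig):
    """Planted peptide and protein abundance matrices.

    Log-scale construction (natural log), exponentiated at the end:

    * tissue-specific rows: top tissue at ``effect_fold`` times base, other
      tissues detected with probability ``specific_detect_prob`` at
      ``1 / (2 * effect_fold)`` of the top value (an infinite fold gives
      exactly one detected tissue);
    * tissue-enhanced rows: one secondary tissue at 4x baseline, top tissue
      at ``effect_fold`` times the mean of the others, everything detected;
    * mixed rows: baseline everywhere plus a module latent profile
      (``module_amplitude``) and a chromosome-wise Ornstein-Uhlenbeck
      tissue-profile field (``spatial_amplitude``, correlation length
      ``spatial_length_bp``) that makes co-abundance decay with genomic
      distance;
    * every detected entry gets multiplicative log-normal noise
      (``noise_sd``).

    The protein matrix has one row per gene.  For each gene, one designated
    fully-detected peptide is paired and its protein profile is mixed from
    the standardized peptide profile to hit the planted Pearson r in
    expectation; genes without a planted pair get independent profiles.
    """
    rng = _stage_rng(config, 3)
    tissues = list(config.tissues)
    n_t = config.n_tissues
    pids = list(peptides.index)
    n = len(pids)
    labels = ("tissue_specific", "tissue_enhanced", "mixed")
    if n:
        cat_idx = rng.choice(3, size=n, p=list(config.specificity_mix))
    else:
        cat_idx = np.array([], dtype=int)
    # orthonormalized latent tissue programs (scaled back to unit-variance
    # entries) so distinct planted modules are genuinely distinct
    module_profiles = rng.standard_normal((max(config.n_modules, 1), n_t))
    if module_profiles.shape[0] > 1:
        q = np.linalg.qr(module_profiles.T)[0].T[: module_profiles.shape[0]]
        module_profiles = q * math.sqrt(n_t)
    log_abund = np.full((n, n_t), -np.inf)  # -inf == not detected
    mixed_rows: list[int] = []
    for i, pid in enumerate(pids):
        cat = labels[cat_idx[i]]
        truth.specificity[pid] = cat
        base = config.base_log_abundance + config.base_log_sd * rng.standard_normal()
        top = int(rng.integers(0, n_t))
        truth.top_tissue[pid] = tissues[top]
        if cat == "tissue_specific":
            log_abund[i, top] = base + math.log(config.effect_fold) \
                if math.isfinite(config.effect_fold) else base + 50.0
            if math.isfinite(config.effect_fold):
                for tix in range(n_t):
                    if tix != top and rng.random() < config.specific_detect_prob:
                        log_abund[i, tix] = base - math.log(2.0)
        elif cat == "tissue_enhanced":
            second = int((top + 1 + rng.integers(0, n_t - 1)) % n_t)
            if second == top:
                second = (top + 1) % n_t
            log_abund[i, :] = base
            log_abund[i, second] = base + math.log(4.0)
            mean_others = ((n_t - 2) + 4.0) / (n_t - 1)
            log_abund[i, top] = base + math.log(config.effect_fold * mean_others)
        else:
            log_abund[i, :] = base
            mod = int(rng.integers(0, config.n_modules)) if config.n_modules else 0
            truth.module[pid] = mod
            log_abund[i, :] += config.module_amplitude * module_profiles[mod]
            mixed_rows.append(i)
    # Ornstein-Uhlenbeck tissue-profile field along each chromosome,
    # carried by the broadly detected (mixed) rows.
    if config.spatial_amplitude > 0 and mixed_rows:
        order = sorted(
            mixed_rows,
            key=lambda i: (truth.genomic_start[pids[i]][0],
                           truth.genomic_start[pids[i]][1]),
        )
        prev_chrom, prev_pos, v = None, 0, None
        for i in order:
            chrom, pos = truth.genomic_start[pids[i]]
            if chrom != prev_chrom:
                v = rng.standard_normal(n_t)
            else:
                rho = math.exp(-(pos - prev_pos) / config.spatial_length_bp)
                v = rho * v + math.sqrt(1.0 - rho * rho) * rng.standard_normal(n_t)
            log_abund[i, :] += config.spatial_amplitude * v
            prev_chrom, prev_pos = chrom, pos
    if config.noise_sd > 0 and n:
        noise = config.noise_sd * rng.standard_normal((n, n_t))
        log_abund = np.where(np.isfinite(log_abund), log_abund + noise, log_abund)
    abund = np.where(np.isfinite(log_abund), np.exp(log_abund), 0.0)
    abundance = pd.DataFrame(abund, index=pd.Index(pids, name="peptide_id"),
                             columns=tissues)

    # protein matrix: one row per gene, planted pair correlations
    genes = sorted({truth.source_gene[p] for p in pids})
    levels = config.pair_correlation_levels or (0.0,)
    fully_detected = {pids[i] for i in range(n) if np.all(abund[i] > 0)}
    prot = np.zeros((len(genes), n_t))
    pid_row = {p: i for i, p in enumerate(pids)}
    log2p1 = np.log2(abund + 1.0)
    for gi, gene in enumerate(genes):
        members = [p for p in pids if truth.source_gene[p] == gene]
        designated = next((p for p in members if p in fully_detected), None)
        base_p = config.base_log_abundance + config.base_log_sd * rng.standard_normal()
        e = rng.standard_normal(n_t)
        if designated is not None:
            r = float(levels[gi % len(levels)])
            x = log2p1[pid_row[designated]]
            sd = x.std(ddof=1)
            if sd > 0:
                xs = (x - x.mean()) / sd
                z = r * xs + math.sqrt(1.0 - r * r) * e
                truth.pair_r[gene] = r
                truth.pair_peptide[gene] = designated
            else:
                z = e
        else:
            z = e
        prot[gi] = np.exp(base_p + config.protein_log_sd * z)
    protein = pd.DataFrame(prot, index=pd.Index(genes, name="protein_id"),
                           columns=tissues)
    return abundance, protein


def generate_atlas(config: SyntheticConfig | None = None) -> SyntheticAtlas:
    """Run all three generator stages under one seed."""
    config = config or SyntheticConfig()
    genome, models, truth = generate_genome(config)
    peptides = generate_peptides(models, config, truth)
    abundance, protein = generate_abundance(peptides, truth, config)
    return SyntheticAtlas(config, genome, models, peptides, abundance, protein, truth)


def synthetic_annotation(models: list[GeneModel], config: SyntheticConfig,
                         n_families: int = 10,
                         annotated_fraction: float = 0.15) -> pd.Series:
    """Toy family annotation: a deterministic subset of genes assigned to
    a handful of families (stands in for a TF-family map)."""
    rng = _stage_rng(config, 4)
    families = [f"FAM{i + 1:02d}" for i in range(n_families)]
    genes = sorted(m.gene_id for m in models)
    labels = {}
    for gene in genes:
        if rng.random() < annotated_fraction:
            labels[gene] = families[rng.integers(0, n_families)]
    return pd.Series(labels, name="family")


def default_config(seed: int = 0) -> SyntheticConfig:
    """The full-size study conditions (10 x 5 Mb genome, 2000 peptides)."""
    return SyntheticConfig(seed=seed)


def module_benchmark_config(seed: int = 0) -> SyntheticConfig:
    """Reduced problem size for seed-averaged module-recovery runs."""
    return SyntheticConfig(
        seed=seed, chrom_length_bp=1_000_000, n_genes=200, n_peptides=800,
        spatial_amplitude=0.15,
    )


def decay_benchmark_config(seed: int = 0) -> SyntheticConfig:
    """All-mixed composition isolating the planted distance-decay field."""
    return SyntheticConfig(
        seed=seed, n_peptides=600, specificity_mix=(0.0, 0.0, 1.0),
        n_modules=1, module_amplitude=0.0, spatial_amplitude=0.55,
    )


def pair_benchmark_config(seed: int = 0, r: float = 0.7) -> SyntheticConfig:
    """One planted correlation level, enough genes for >=500 planted pairs."""
    return SyntheticConfig(
        seed=seed, n_genes=700, n_peptides=2_000,
        specificity_mix=(0.0, 0.5, 0.5), pair_correlation_levels=(r,),
        chrom_length_bp=2_000_000,
    )
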