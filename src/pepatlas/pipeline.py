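"""End-to-end orchestration of the atlas analysis.

Ties the stages together: peptide identification against translated gene
models, specificity calls, genomic-landscape statistics, coexpression
modules, and peptide-protein correlation, starting either from files or
from an in-memory synthetic atlas.
"""

from __future__ import annotations

import logging

import pandas as pd

from . import coexpression as cx
from . import correlation as corr
from . import landscape as ls
from . import specificity as sp
from .peptidogenomics import (
    GeneModel,
    PeptideRecord,
    map_to_genome,
    match_peptides,
    resolve_frame_class,
    start_codon_of,
    translate_three_frames,
    tss_distance,
)
from .summary import build_report

logger = logging.getLogger(__name__)

__all__ = ["identify_peptides", "records_to_positions", "run_atlas_analysis"]


def identify_peptides(models: list[GeneModel], peptides: pd.DataFrame,
                      abundance: pd.DataFrame | None = None) -> list[PeptideRecord]:
    """Match peptide sequences against three-frame translations and resolve
    each peptide's frame class, primary gene, genomic placement, start
    codon and TSS distance.

    ``peptides`` is indexed by peptide id with a ``sequence`` column.
    Unmapped peptides keep frame_class "unmapped" and no coordinates.
    """
    frames = [translate_three_frames(m.cds_sequence, m.gene_id) for m in models]
    by_gene = {m.gene_id: m for m in models}
    seqs = {str(pid): str(s) for pid, s in peptides["sequence"].items()}
    matches = match_peptides(seqs, frames) if seqs else []
    by_peptide: dict[str, list] = {}
    for m in matches:
        by_peptide.setdefault(m.peptide_id, []).append(m)
    records = []
    n_unmapped = 0
    for pid, seq in seqs.items():
        rec = PeptideRecord(peptide_id=pid, sequence=seq)
        pm = by_peptide.get(pid)
        if pm:
            rec.matches = pm
            rec.frame_class, rec.primary_gene = resolve_frame_class(pm)
            best_frame = 0 if rec.frame_class == "in_frame" else min(
                m.frame for m in pm if m.gene_id == rec.primary_gene)
            primary = min(
                (m for m in pm
                 if m.gene_id == rec.primary_gene and
                 (m.frame == 0 if rec.frame_class == "in_frame" else m.frame == best_frame)),
                key=lambda m: m.aa_offset)
            model = by_gene[primary.gene_id]
            chrom, strand, blocks = map_to_genome(primary, model, len(seq))
            rec.chrom, rec.strand, rec.genomic_blocks = chrom, strand, tuple(blocks)
            rec.start_codon, rec.start_codon_class = start_codon_of(primary, model)
            rec.tss_distance_bp = tss_distance(primary, model, len(seq))
        else:
            n_unmapped += 1
        if abundance is not None and pid in abundance.index:
            row = abundance.loc[pid]
            rec.abundances = {t: float(v) for t, v in row.items()}
            rec.detected_tissues = {t for t, v in row.items() if v > 0}
        records.append(rec)
    if n_unmapped:
        logger.info("identify_peptides: %d of %d peptides unmapped",
                    n_unmapped, len(seqs))
    return records


def records_to_positions(records: list[PeptideRecord],
                         calls: pd.DataFrame | None = None) -> pd.DataFrame:
    """Mapped peptides as a chrom/start frame (plus category if calls given)."""
    rows = []
    for rec in records:
        if not rec.genomic_blocks:
            continue
        row = {"peptide_id": rec.peptide_id, "chrom": rec.chrom,
               "start": rec.genomic_start}
        if calls is not None and rec.peptide_id in calls.index:
            row["category"] = calls.at[rec.peptide_id, "category"]
        rows.append(row)
    df = pd.DataFrame(rows)
    return df.set_index("peptide_id") if len(df) else df


def run_atlas_analysis(models: list[GeneModel], peptides: pd.DataFrame,
                       abundance: pd.DataFrame, protein: pd.DataFrame,
                       chrom_sizes: dict[str, int],
                       source_gene: dict[str, str] | None = None,
                       min_detected_tissues: int = 6,
                       min_module_size: int = 30) -> dict:
    """Run the full downstream analysis; returns a dict of result tables.

    ``source_gene`` overrides the pairing used for peptide-protein
    correlation (defaults to each peptide's resolved primary gene).
    """
    results: dict = {}
    records = identify_peptides(models, peptides, abundance)
    results["records"] = records
    results["report"] = build_report(records, abundance)

    calls = sp.classify_matrix(abundance)
    results["calls"] = calls
    results["category_summary"] = sp.summarize_categories(abundance, calls)

    positions = records_to_positions(records, calls)
    results["positions"] = positions
    if len(positions):
        results["chromosome_share"] = ls.chromosome_share(positions)
        tracks = ls.window_counts(positions, chrom_sizes)
        results["window_tracks"] = tracks
        results["rich_regions"] = ls.call_rich_regions(tracks)
        dists, frac = ls.adjacent_distances(positions)
        results["adjacent_distances"] = dists
        results["fraction_adjacent_lt_500kb"] = frac
        results["telomere_fraction"] = ls.telomere_fraction(positions, chrom_sizes)
        tssd = pd.Series({rec.peptide_id: rec.tss_distance_bp
                          for rec in records if rec.tss_distance_bp is not None})
        results["fraction_within_2kb_tss"] = ls.tss_proximity(tssd)

    filtered = cx.filter_for_network(abundance, min_detected_tissues)
    st = cx.pick_soft_threshold(filtered)
    network = cx.build_network(filtered, st.chosen)
    assignment = cx.detect_modules(network.tom, network.node_ids, min_module_size)
    eigengenes, var_explained = cx.module_eigengene(
        filtered.loc[network.node_ids], assignment)
    results.update(
        soft_threshold=st, network=network, modules=assignment,
        eigengenes=eigengenes, eigengene_variance=var_explained)
    if len(eigengenes) >= 1:
        r_mat, p_mat = cx.module_tissue_correlation(eigengenes)
        results["module_tissue_r"] = r_mat
        results["module_tissue_p"] = p_mat

    if source_gene is None:
        source_gene = {rec.peptide_id: rec.primary_gene for rec in records
                       if rec.primary_gene is not None}
    pairing = pd.DataFrame(
        [{"peptide_id": p, "partner_id": g} for p, g in sorted(source_gene.items())
         if g in protein.index and p in abundance.index])
    results["tissuewise_spearman"] = corr.tissuewise_spearman(
        abundance, protein, pairing)
    pairs = corr.pairwise_pearson(abundance, protein, pairing)
    results["source_pairs"] = pairs
    high, _ = corr.high_correlation_set(pairs)
    results["high_correlation_pairs"] = high
    if len(positions):
        pp = corr.adjacent_peptide_pairing(positions)
        pp_pairs = corr.pairwise_pearson(abundance, abundance, pp)
        results["peptide_pairs"] = pp_pairs
        if len(pp_pairs):
            results["distance_decay"] = corr.distance_binned_correlation(pp_pairs)
    return results
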