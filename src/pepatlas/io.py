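"""Readers and writers for the formats the pipeline exchanges.

Coordinate conventions: intervals are 0-based half-open internally; GFF3
is 1-based inclusive at the file boundary; BED/bedGraph are 0-based
half-open.  All tabular output is plain TSV, reports are JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .peptidogenomics import GeneModel

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_gene_models",
    "write_gene_models",
    "read_abundance_tsv",
    "write_abundance_tsv",
    "write_bed12",
    "write_bedgraph",
    "read_chrom_sizes",
    "write_chrom_sizes",
    "write_json",
    "read_json",
]


def read_fasta(path: str | Path) -> dict[str, str]:
    """Sequences keyed by record id; wrapped and unwrapped input both accepted."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path: str | Path, width: int = 80) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def _revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def read_gene_models(gff3_path: str | Path, genome: dict[str, str]) -> list[GeneModel]:
    """Assemble spliced gene models from GFF3 CDS features.

    CDS rows are grouped by their ``Parent`` attribute; coordinates are
    converted from 1-based inclusive to 0-based half-open, segments sorted
    by genomic start, and the spliced sequence strand-corrected so it reads
    5'->3'.
    """
    segs: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, tuple[str, str]] = {}
    with open(gff3_path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\r\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"{gff3_path}:{lineno}: expected 9 columns, got {len(fields)}")
            chrom, _src, ftype, start, end, _score, strand, _phase, attrs = fields
            if ftype != "CDS":
                continue
            try:
                start_i, end_i = int(start), int(end)
            except ValueError:
                raise ValueError(f"{gff3_path}:{lineno}: non-integer coordinates") from None
            if end_i < start_i:
                raise ValueError(f"{gff3_path}:{lineno}: end < start")
            attr_map = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            parent = attr_map.get("Parent") or attr_map.get("ID")
            if parent is None:
                raise ValueError(f"{gff3_path}:{lineno}: CDS without Parent attribute")
            segs.setdefault(parent, []).append((start_i - 1, end_i))
            meta[parent] = (chrom, strand)
    models = []
    for gene_id in sorted(segs):
        chrom, strand = meta[gene_id]
        segments = tuple(sorted(segs[gene_id]))
        if chrom not in genome:
            raise ValueError(f"gene {gene_id}: chromosome {chrom!r} not in genome")
        spliced = "".join(genome[chrom][s:e] for s, e in segments)
        if strand == "-":
            spliced = _revcomp(spliced)
        models.append(GeneModel(gene_id, chrom, strand, segments, spliced))
    return models


def write_gene_models(models: list[GeneModel], path: str | Path) -> None:
    """GFF3 export: one gene row plus its CDS rows, 1-based inclusive."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            g_start = m.cds_segments[0][0] + 1
            g_end = m.cds_segments[-1][1]
            fh.write(
                f"{m.chrom}\tpepatlas\tgene\t{g_start}\t{g_end}\t.\t{m.strand}\t.\t"
                f"ID={m.gene_id}\n"
            )
            for s, e in m.cds_segments:
                fh.write(
                    f"{m.chrom}\tpepatlas\tCDS\t{s + 1}\t{e}\t.\t{m.strand}\t0\t"
                    f"Parent={m.gene_id}\n"
                )


def read_abundance_tsv(path: str | Path) -> pd.DataFrame:
    """Rows = peptides/proteins, columns = tissues; first column is the row id."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if (df.to_numpy() < 0).any():
        raise ValueError(f"{path}: negative abundance values")
    return df


def write_abundance_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", lineterminator="\n")


def write_bed12(rows: list[dict], path: str | Path) -> None:
    """BED12 export of spliced peptide placements.

    Each row dict needs chrom, start, end, name, strand and ``blocks`` (a
    list of 0-based half-open genomic intervals inside [start, end)).
    """
    with open(path, "w") as fh:
        for r in rows:
            blocks = sorted(r["blocks"])
            sizes = ",".join(str(e - s) for s, e in blocks)
            starts = ",".join(str(s - r["start"]) for s, _ in blocks)
            fh.write(
                f"{r['chrom']}\t{r['start']}\t{r['end']}\t{r['name']}\t0\t{r['strand']}\t"
                f"{r['start']}\t{r['end']}\t0\t{len(blocks)}\t{sizes},\t{starts},\n"
            )


def read_bed12(path: str | Path) -> list[dict]:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\r\n")
            if not line:
                continue
            f = line.split("\t")
            start, end = int(f[1]), int(f[2])
            if end < start:
                raise ValueError(f"{path}:{lineno}: end < start")
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            offsets = [int(x) for x in f[11].rstrip(",").split(",")]
            blocks = [(start + o, start + o + s) for o, s in zip(offsets, sizes)]
            rows.append(
                {"chrom": f[0], "start": start, "end": end, "name": f[3],
                 "strand": f[5], "blocks": blocks}
            )
    return rows


def write_bedgraph(track_rows: list[tuple[str, int, int, float]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end, value in track_rows:
            fh.write(f"{chrom}\t{start}\t{end}\t{value:g}\n")


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    sizes = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            name, size = line.split("\t")
            sizes[name] = int(size)
    return sizes


def write_chrom_sizes(sizes: dict[str, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, size in sizes.items():
            fh.write(f"{name}\t{size}\n")


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_json(path: str | Path):
    with open(path) as fh:
        return json.load(fh)
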