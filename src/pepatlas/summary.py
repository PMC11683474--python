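"""Atlas-level overview statistics.

Counts and distributions summarizing a nonredundant endogenous-peptide
atlas: per-tissue identified-peptide counts, peptide length and molecular
weight summaries, in-frame versus out-of-frame fractions, AUG versus
non-AUG start-codon shares, and unique source-gene counts.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import asdict, dataclass, field

import pandas as pd

from .peptidogenomics import PeptideRecord, molecular_weight

__all__ = ["AtlasReport", "build_report", "length_mw_summary"]

LENGTH_THRESHOLD_AA = 23
MW_THRESHOLD_DA = 2500.0


@dataclass
class AtlasReport:
    n_nonredundant: int = 0
    n_unique_genes: int = 0
    per_tissue_counts: dict[str, int] = field(default_factory=dict)
    frame_fractions: dict[str, float] = field(default_factory=dict)
    start_codon_fractions: dict[str, float] = field(default_factory=dict)
    length_histogram: dict[int, int] = field(default_factory=dict)
    mean_mw: float = float("nan")
    n_short: int = 0            # length < 23 aa
    n_low_mw: int = 0           # MW < 2500 Da
    n_unmapped: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["length_histogram"] = {str(k): v for k, v in d["length_histogram"].items()}
        return d


def length_mw_summary(records: list[PeptideRecord]):
    """Length histogram, mean molecular weight and sub-threshold counts.

    Thresholds use strict ``<`` (a 23-aa peptide is not "shorter than 23").
    """
    hist = Counter(rec.length for rec in records)
    mws = [molecular_weight(rec.sequence) for rec in records]
    mean_mw = sum(mws) / len(mws) if mws else float("nan")
    n_short = sum(1 for rec in records if rec.length < LENGTH_THRESHOLD_AA)
    n_low_mw = sum(1 for mw in mws if mw < MW_THRESHOLD_DA)
    return dict(sorted(hist.items())), mean_mw, n_short, n_low_mw


def build_report(records: list[PeptideRecord], matrix: pd.DataFrame,
                 min_intensity: float = 0.0) -> AtlasReport:
    """Assemble the atlas report from deduplicated records and abundances.

    "Identified in a tissue" means abundance strictly above
    ``min_intensity`` (default 0, i.e. any nonzero value).  Frame and
    start-codon fractions are computed over mapped peptides only;
    unmapped peptides are tallied separately.
    """
    ids = {rec.peptide_id for rec in records}
    extra = set(matrix.index) - ids
    if extra:
        raise ValueError(
            f"abundance rows without a peptide record (first: {sorted(extra)[:3]})")
    report = AtlasReport(n_nonredundant=len(records))
    mapped = [rec for rec in records if rec.frame_class != "unmapped"]
    report.n_unmapped = len(records) - len(mapped)
    report.n_unique_genes = len({rec.primary_gene for rec in mapped})
    present = [rec.peptide_id for rec in records if rec.peptide_id in matrix.index]
    detected = matrix.loc[present] > min_intensity
    report.per_tissue_counts = {t: int(detected[t].sum()) for t in matrix.columns}
    if mapped:
        n_in = sum(1 for rec in mapped if rec.frame_class == "in_frame")
        report.frame_fractions = {
            "in_frame": n_in / len(mapped),
            "out_of_frame": (len(mapped) - n_in) / len(mapped),
        }
        with_codon = [rec for rec in mapped if getattr(rec, "start_codon_class", None)]
        if with_codon:
            n_aug = sum(1 for rec in with_codon if rec.start_codon_class == "AUG")
            report.start_codon_fractions = {
                "AUG": n_aug / len(with_codon),
                "non-AUG": (len(with_codon) - n_aug) / len(with_codon),
            }
    hist, mean_mw, n_short, n_low = length_mw_summary(records)
    report.length_histogram = hist
    report.mean_mw = mean_mw
    report.n_short = n_short
    report.n_low_mw = n_low
    return report
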