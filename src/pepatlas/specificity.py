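"""Tissue-specificity classification of peptide expression patterns.

Each peptide's abundance row across the tissue panel is placed in exactly
one of three categories, a standard tissue-atlas scheme:

* ``tissue_specific`` — detected in a single tissue, or the top tissue is
  at least ``fold_specific`` times the second-highest;
* ``tissue_enhanced`` — the top tissue is at least ``fold_enhanced`` times
  the mean of the other detected tissues;
* ``mixed`` — everything else.

Both fold thresholds default to 5 and the rules are monotone and
scale-invariant: multiplying a row by a positive constant never changes
its category, and raising ``fold_specific`` can only move peptides out of
the specific class.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "SpecificityCall",
    "classify_specificity",
    "classify_matrix",
    "summarize_categories",
    "phase_profiles",
    "CATEGORIES",
]

CATEGORIES = ("tissue_specific", "tissue_enhanced", "mixed")
UNDETECTED = "undetected"


@dataclass(frozen=True)
class SpecificityCall:
    peptide_id: str
    category: str
    top_tissue: str | None
    fold_over_second: float
    fold_over_background: float


def classify_specificity(
    row: pd.Series,
    fold_specific: float = 5.0,
    fold_enhanced: float = 5.0,
    peptide_id: str = "?",
) -> SpecificityCall:
    """Classify one abundance row (tissues as index, 0 = not detected)."""
    values = row.to_numpy(dtype=float)
    if values.size < 2:
        raise ValueError("specificity needs at least two tissues")
    if (values < 0).any():
        raise ValueError(f"{peptide_id}: negative abundance")
    detected = values > 0
    if not detected.any():
        return SpecificityCall(peptide_id, UNDETECTED, None, np.nan, np.nan)
    top_ix = int(np.argmax(values))  # first tissue on ties
    top = values[top_ix]
    rest = np.delete(values, top_ix)
    second = rest.max()
    others = values[detected & (np.arange(values.size) != top_ix)]
    background = others.mean() if others.size else 0.0
    fold_second = np.inf if second == 0 else top / second
    fold_background = np.inf if background == 0 else top / background
    if detected.sum() == 1 or top >= fold_specific * second:
        cat = "tissue_specific"
    elif top >= fold_enhanced * background:
        cat = "tissue_enhanced"
    else:
        cat = "mixed"
    return SpecificityCall(peptide_id, cat, str(row.index[top_ix]),
                           float(fold_second), float(fold_background))


def classify_matrix(matrix: pd.DataFrame, fold_specific: float = 5.0,
                    fold_enhanced: float = 5.0) -> pd.DataFrame:
    """Classify every row; returns a table indexed by peptide id."""
    calls = [
        classify_specificity(matrix.loc[pid], fold_specific, fold_enhanced, str(pid))
        for pid in matrix.index
    ]
    return pd.DataFrame(
        {
            "category": [c.category for c in calls],
            "top_tissue": [c.top_tissue for c in calls],
            "fold_over_second": [c.fold_over_second for c in calls],
            "fold_over_background": [c.fold_over_background for c in calls],
        },
        index=matrix.index,
    )


def summarize_categories(matrix: pd.DataFrame, calls: pd.DataFrame) -> pd.DataFrame:
    """Per-tissue category tallies plus identified-peptide counts.

    Specific and enhanced peptides are counted in their top tissue; mixed
    peptides are counted in every tissue where they are detected.
    ``identified`` is the number of peptides with nonzero abundance.
    """
    tissues = list(matrix.columns)
    out = pd.DataFrame(0, index=pd.Index(tissues, name="tissue"),
                       columns=[*CATEGORIES, "identified"])
    detected = matrix > 0
    out["identified"] = detected.sum(axis=0).reindex(tissues).to_numpy()
    for pid, row in calls.iterrows():
        cat = row["category"]
        if cat in ("tissue_specific", "tissue_enhanced"):
            out.loc[row["top_tissue"], cat] += 1
        elif cat == "mixed":
            for t in tissues:
                if detected.at[pid, t]:
                    out.loc[t, "mixed"] += 1
    return out


def phase_profiles(matrix: pd.DataFrame, calls: pd.DataFrame,
                   phase_map: dict[str, str]) -> pd.DataFrame:
    """Category-mean trajectories of row-normalized abundance per phase.

    Rows are normalized by their maximum, so every detected row peaks at
    exactly 1; the result is indexed by (category, phase) with the
    phase's tissues, in panel order, as columns.
    """
    missing = [t for t in matrix.columns if t not in phase_map]
    if missing:
        raise ValueError(f"tissues without phase assignment: {missing}")
    row_max = matrix.max(axis=1)
    normed = matrix[row_max > 0].div(row_max[row_max > 0], axis=0)
    calls = calls.loc[normed.index]
    frames = []
    for cat in CATEGORIES:
        members = normed[calls["category"] == cat]
        for phase in sorted(set(phase_map.values())):
            cols = [t for t in matrix.columns if phase_map[t] == phase]
            mean = members[cols].mean(axis=0) if len(members) else \
                pd.Series(np.nan, index=cols)
            frames.append(pd.DataFrame(
                {"category": cat, "phase": phase, "tissue": cols,
                 "mean_normalized_abundance": mean.to_numpy()}))
    return pd.concat(frames, ignore_index=True)
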