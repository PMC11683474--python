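"""Set over-representation tests for annotated peptide families.

Per-tissue over-enrichment of, e.g., transcription-factor-family-derived
peptides: an exact hypergeometric upper-tail test per (family, tissue)
cell with Benjamini-Hochberg correction across the whole grid, plus
clustered, row-normalized family abundance profiles.  The same machinery
doubles as a generic term-enrichment routine given any term -> gene map.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "hypergeom_tail",
    "enrich_by_tissue",
    "enrich_sets",
    "family_profiles",
]


def hypergeom_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n).

    ``k`` successes observed among ``n`` draws from a universe of ``N``
    items of which ``K`` are marked.
    """
    if not (0 <= k <= min(K, n) <= N) or n > N or K > N:
        raise ValueError(f"inconsistent counts k={k} K={K} n={n} N={N}")
    return float(hypergeom.sf(k - 1, N, K, n))


def enrich_by_tissue(detection: pd.DataFrame, annotation: pd.Series) -> pd.DataFrame:
    """Per-tissue family over-representation with BH correction.

    ``detection`` is a boolean peptides x tissues frame; ``annotation``
    maps peptide id -> family label.  The universe is the annotated
    peptide set; one hypergeometric test per (family, tissue), q-values
    from one Benjamini-Hochberg pass over the full table.
    """
    annotation = annotation.dropna()
    universe = [p for p in detection.index if p in annotation.index]
    if not universe:
        raise ValueError("no annotated peptides in the detection table")
    det = detection.loc[universe].astype(bool)
    ann = annotation.loc[universe]
    N = len(universe)
    rows = []
    for family, members in ann.groupby(ann).groups.items():
        K = len(members)
        if K == 0:
            logger.warning("family %s absent from universe; skipped", family)
            continue
        fam_det = det.loc[list(members)]
        for tissue in det.columns:
            n = int(det[tissue].sum())
            k = int(fam_det[tissue].sum())
            rows.append({
                "tissue": tissue, "family": family, "k": k, "K": K, "n": n, "N": N,
                "p_value": hypergeom_tail(k, K, n, N),
            })
    table = pd.DataFrame(rows)
    table["q_value"] = multipletests(table["p_value"], method="fdr_bh")[1]
    return table.sort_values(["p_value", "family", "tissue"]).reset_index(drop=True)


def enrich_sets(hits: set[str], term_map: dict[str, set[str]],
                universe: set[str]) -> pd.DataFrame:
    """Generic term enrichment of a hit set against term -> member maps."""
    rows = []
    N = len(universe)
    hit_set = hits & universe
    for term, members in sorted(term_map.items()):
        members = members & universe
        if not members:
            logger.warning("term %s has no members in universe; skipped", term)
            continue
        k = len(hit_set & members)
        rows.append({
            "term": term, "k": k, "K": len(members), "n": len(hit_set), "N": N,
            "p_value": hypergeom_tail(k, len(members), len(hit_set), N),
        })
    table = pd.DataFrame(rows)
    if len(table):
        table["q_value"] = multipletests(table["p_value"], method="fdr_bh")[1]
        table = table.sort_values(["p_value", "term"]).reset_index(drop=True)
    return table


def family_profiles(matrix: pd.DataFrame, annotation: pd.Series) -> pd.DataFrame:
    """Summed family x tissue abundance, row-normalized and cluster-ordered.

    Member abundances are summed per family and tissue, each row divided
    by its maximum, and rows ordered by average-linkage hierarchical
    clustering on Euclidean distances between normalized profiles.
    """
    annotation = annotation.dropna()
    annotated = [p for p in matrix.index if p in annotation.index]
    if not annotated:
        raise ValueError("no annotated rows in the abundance matrix")
    sums = matrix.loc[annotated].groupby(annotation.loc[annotated]).sum()
    sums.index.name = "family"
    row_max = sums.max(axis=1).replace(0, 1.0)
    normed = sums.div(row_max, axis=0)
    if len(normed) > 2:
        order = leaves_list(linkage(pdist(normed.to_numpy()), method="average"))
        normed = normed.iloc[order]
    return normed
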