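"""Chromosome-level distribution statistics for localized peptides.

Works on peptide placements (chromosome, 0-based start, specificity
category) plus a chromosome-sizes map: per-chromosome shares, fixed-width
window densities with peptide-rich-region calling, adjacent-peptide
start-to-start distances, distance to the canonical translation start,
and telomere-proximity fractions, all optionally stratified by category.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "WindowTrack",
    "RichRegion",
    "chromosome_share",
    "window_counts",
    "call_rich_regions",
    "adjacent_distances",
    "tss_proximity",
    "telomere_fraction",
]

WINDOW_SIZE = 6_000_000


@dataclass(frozen=True)
class WindowTrack:
    chrom: str
    window_size: int
    counts: tuple[int, ...]
    windows: tuple[tuple[int, int], ...]


@dataclass(frozen=True)
class RichRegion:
    chrom: str
    start: int
    end: int
    n_peptides: int
    z_score: float


def _check_positions(positions: pd.DataFrame, chrom_sizes: dict[str, int]) -> None:
    for chrom, grp in positions.groupby("chrom"):
        if chrom not in chrom_sizes:
            raise ValueError(f"unknown chromosome {chrom!r}")
        if (grp["start"] >= chrom_sizes[chrom]).any() or (grp["start"] < 0).any():
            raise ValueError(f"peptide beyond end of {chrom}")


def chromosome_share(positions: pd.DataFrame) -> pd.Series:
    """Percent of localized peptides per chromosome; sums to 100."""
    counts = positions.groupby("chrom").size()
    return (100.0 * counts / counts.sum()).sort_index()


def window_counts(positions: pd.DataFrame, chrom_sizes: dict[str, int],
                  window_size: int = WINDOW_SIZE) -> list[WindowTrack]:
    """Tile each chromosome with half-open windows and count interval starts.

    A peptide belongs to the window containing its start coordinate (a
    start exactly at a boundary falls in the following window); the last,
    possibly partial, window is kept.
    """
    _check_positions(positions, chrom_sizes)
    tracks = []
    for chrom in sorted(chrom_sizes):
        size = chrom_sizes[chrom]
        n_win = max(1, -(-size // window_size))
        windows = tuple(
            (w * window_size, min((w + 1) * window_size, size)) for w in range(n_win)
        )
        counts = np.zeros(n_win, dtype=int)
        starts = positions.loc[positions["chrom"] == chrom, "start"].to_numpy()
        if starts.size:
            np.add.at(counts, starts // window_size, 1)
        tracks.append(WindowTrack(chrom, window_size, tuple(int(c) for c in counts),
                                  windows))
    return tracks


def call_rich_regions(tracks: list[WindowTrack], z_min: float = 2.0) -> list[RichRegion]:
    """Windows whose count exceeds mean + z_min * sd over all windows genome-wide.

    Adjacent rich windows on a chromosome merge into a single region; the
    reported z-score is that of the region's maximal window.
    """
    tracks = sorted(tracks, key=lambda t: t.chrom)  # canonical stats order
    all_counts = np.array([c for t in tracks for c in t.counts], dtype=float)
    if all_counts.size < 2:
        raise ValueError("rich-region calling needs at least two windows")
    mean, sd = all_counts.mean(), all_counts.std(ddof=0)
    if sd == 0:
        return []
    threshold = mean + z_min * sd
    regions: list[RichRegion] = []
    for track in sorted(tracks, key=lambda t: t.chrom):
        run: list[int] = []
        for w, count in enumerate([*track.counts, -1]):
            if count >= threshold and w < len(track.counts):
                run.append(w)
                continue
            if run:
                start = track.windows[run[0]][0]
                end = track.windows[run[-1]][1]
                n = sum(track.counts[x] for x in run)
                zmax = (max(track.counts[x] for x in run) - mean) / sd
                regions.append(RichRegion(track.chrom, start, end, n, float(zmax)))
                run = []
    return regions


def adjacent_distances(positions: pd.DataFrame, cutoff: int = 500_000):
    """Start-to-start gaps between consecutive peptides per chromosome.

    Returns ``(distances, fraction_below_cutoff)``; cross-chromosome pairs
    are never formed.  With a ``category`` column present, peptides are
    first grouped by category (call once per category subset for
    stratified results).
    """
    dists: list[int] = []
    for _, grp in positions.groupby("chrom"):
        starts = np.sort(grp["start"].to_numpy())
        if starts.size >= 2:
            dists.extend(int(d) for d in np.diff(starts))
    if not dists:
        return [], float("nan")
    arr = np.array(dists)
    return dists, float((arr < cutoff).mean())


def tss_proximity(tss_distances: pd.Series, cutoff: int = 2_000) -> float:
    """Fraction of peptides whose 5'-most base lies within ``cutoff`` bp of
    the canonical translation start (distances computed strand-aware by the
    peptidogenomics module)."""
    if tss_distances.empty:
        return float("nan")
    return float((tss_distances <= cutoff).mean())


def telomere_fraction(positions: pd.DataFrame, chrom_sizes: dict[str, int],
                      terminal_fraction: float = 0.10) -> float:
    """Fraction of peptides starting in the terminal portion of either
    chromosome end ("near the telomeres")."""
    _check_positions(positions, chrom_sizes)
    if positions.empty:
        return float("nan")
    near = 0
    for chrom, grp in positions.groupby("chrom"):
        size = chrom_sizes[chrom]
        t = terminal_fraction * size
        starts = grp["start"].to_numpy()
        near += int(((starts < t) | (starts >= size - t)).sum())
    return near / len(positions)
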