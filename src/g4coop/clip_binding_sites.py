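"""Definition of 5-nt binding sites from iCLIP crosslink tracks.

Input is a per-nucleotide crosslink-event track (the crosslink nucleotide is
the position upstream of the truncated-cDNA read start) together with the
significant crosslink positions reported by an upstream peak caller such as
PureCLIP.  Sites are placed iteratively:

1. significant positions no more than 3 nt apart are merged into candidate
   regions, and regions shorter than 2 nt are removed;
2. within each region the position with the most crosslink events is
   extended by 2 nt on both sides into a 5-nt site, then the site plus 4 nt
   of flank is excised and the procedure repeats on the remainders;
3. sites whose center is neither a significant position nor the in-site
   count maximum, and sites covering fewer than 3 positions with crosslink
   events, are removed.

Coordinates are 0-based half-open internally; ``write_bed6`` /
``read_bedgraph`` provide the on-disk BED6/bedGraph surface.  Strands are
processed independently by the caller.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Sequence, Set, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "BindingSite",
    "merge_positions",
    "place_sites",
    "cleanup_sites",
    "call_binding_sites",
    "read_bedgraph",
    "write_bed6",
]

SITE_WIDTH = 5
FLANK_EXCISION = 4  # nt removed on either side of a placed site
MIN_COVERED_POSITIONS = 3


@dataclass(frozen=True)
class BindingSite:
    """A 5-nt binding site; ``center = start + 2``, score = center count."""

    contig: str
    strand: str
    start: int
    end: int
    score: float

    def __post_init__(self) -> None:
        if self.end - self.start != SITE_WIDTH:
            raise ValueError("binding sites are exactly 5 nt wide")

    @property
    def center(self) -> int:
        return self.start + 2


def merge_positions(significant_positions: Sequence[int],
                    max_gap: int = 3) -> List[Tuple[int, int]]:
    """Merge significant positions <= ``max_gap`` nt apart into regions.

    Returns 0-based half-open intervals; regions shorter than 2 nt
    (unmerged singletons) are removed.
    """
    pos = sorted(set(int(p) for p in significant_positions))
    if not pos:
        return []
    regions = []
    start = prev = pos[0]
    for p in pos[1:]:
        if p - prev <= max_gap:
            prev = p
        else:
            regions.append((start, prev + 1))
            start = prev = p
    regions.append((start, prev + 1))
    return [(s, e) for s, e in regions if e - s >= 2]


def place_sites(regions: Iterable[Tuple[int, int]], track: np.ndarray,
                contig: str = ".", strand: str = "+") -> List[BindingSite]:
    """Iteratively place 5-nt sites at crosslink maxima within regions.

    Per region: take the position with the highest count (leftmost on ties),
    extend +-2 nt into a 5-nt site, excise the site plus 4 nt on either side,
    and recurse into the remainders until no position with signal is left.
    Cut-out positions are gone for good: a placement whose 5-nt footprint
    would reuse excised positions, or would leave the track, is discarded
    (its position is still excised so the iteration terminates).  This keeps
    every pair of emitted sites at least 4 nt apart edge-to-edge.
    """
    track = np.asarray(track)
    n = len(track)
    excised = np.zeros(n, dtype=bool)
    sites: List[BindingSite] = []
    for s, e in sorted((int(s), int(e)) for s, e in regions):
        stack = [(max(s, 0), min(e, n))]
        while stack:
            lo, hi = stack.pop()
            if hi <= lo:
                continue
            seg = track[lo:hi]
            p = lo + int(np.argmax(seg))
            if track[p] <= 0:
                continue
            footprint_free = (p - 2 >= 0 and p + 3 <= n
                              and not excised[p - 2:p + 3].any())
            if footprint_free:
                sites.append(BindingSite(contig, strand, p - 2, p + 3,
                                         float(track[p])))
            cut_lo, cut_hi = p - 2 - FLANK_EXCISION, p + 3 + FLANK_EXCISION
            excised[max(cut_lo, 0):min(cut_hi, n)] = True
            if lo < cut_lo:
                stack.append((lo, cut_lo))
            if cut_hi < hi:
                stack.append((cut_hi, hi))
    return sorted(sites, key=lambda st: st.start)


def cleanup_sites(sites: Iterable[BindingSite],
                  significant_positions: Sequence[int],
                  track: np.ndarray,
                  removal: str = "or") -> List[BindingSite]:
    """Final cleanup of placed sites.

    A site is kept when its center is a significant crosslink position or the
    position with the highest count inside the site (``removal="or"``; the
    stricter reading requiring both is available as ``removal="and"``), and
    when at least 3 of its 5 positions carry crosslink events.
    """
    if removal not in ("or", "and"):
        raise ValueError("removal must be 'or' or 'and'")
    sig: Set[int] = set(int(p) for p in significant_positions)
    track = np.asarray(track)
    kept = []
    for site in sites:
        window = track[site.start:site.end]
        covered = int(np.count_nonzero(window))
        is_sig = site.center in sig
        is_max = track[site.center] == window.max()
        ok = (is_sig or is_max) if removal == "or" else (is_sig and is_max)
        if ok and covered >= MIN_COVERED_POSITIONS:
            kept.append(site)
    return kept


def call_binding_sites(track: np.ndarray, significant_positions: Sequence[int],
                       contig: str = ".", strand: str = "+",
                       max_gap: int = 3, removal: str = "or") -> List[BindingSite]:
    """Full pipeline: merge positions, place sites, clean up."""
    regions = merge_positions(significant_positions, max_gap=max_gap)
    sites = place_sites(regions, track, contig=contig, strand=strand)
    return cleanup_sites(sites, significant_positions, track, removal=removal)


def read_bedgraph(path) -> dict:
    """Read a bedGraph file into dense per-contig count arrays."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["contig", "start", "end", "value"])
    out = {}
    for contig, grp in df.groupby("contig", sort=False):
        length = int(grp["end"].max())
        arr = np.zeros(length, dtype=float)
        for _, row in grp.iterrows():
            arr[int(row.start):int(row.end)] = row.value
        out[str(contig)] = arr
    return out


def write_bed6(sites: Iterable[BindingSite], path) -> None:
    """Write binding sites as BED6 (name = contig:center, score = center count)."""
    rows = [(s.contig, s.start, s.end, f"{s.contig}:{s.center}", s.score,
             s.strand) for s in sites]
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)
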