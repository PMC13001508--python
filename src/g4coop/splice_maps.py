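"""Splice maps: positional meta-profiles of crosslink signal at cassette exons.

For each splicing event, windows are opened at the four splice sites of the
cassette-exon triplet (5' splice site of the upstream exon, 3' and 5' splice
sites of the alternative exon, 3' splice site of the downstream exon),
reaching up to 50 nt into the exon and up to 300 nt into the intron.  Raw
crosslink counts in each window are min-max normalized to [0, 1] so a few
heavily crosslinked events cannot dominate, averaged position-wise over all
events of a group, and loess-smoothed.  Control events are sampled so their
PSI distribution matches the regulated group (binding scales with inclusion
level, so unmatched controls would differ in signal for trivial reasons).
Differential binding is assessed in overlapping 10-nt windows (step 1 nt)
with a two-sample Wilcoxon rank-sum test and Benjamini-Hochberg correction
at FDR <= 0.01.

Junction-based PSI helpers quantify exon inclusion from junction read counts
(requiring >= 25 supporting reads), including the variant for an exon whose
skipping produces an NMD-degraded isoform.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.stats.multitest import multipletests

__all__ = [
    "EventCoordinates",
    "MetaProfile",
    "ANCHORS",
    "extract_profiles",
    "aggregate_smooth",
    "sample_matched_controls",
    "window_test",
    "junction_psi",
    "nmd_isoform_psi",
    "ENHANCED_QUANTILES",
    "REPRESSED_QUANTILES",
]

EXON_WINDOW = 50
INTRON_WINDOW = 300
ANCHORS = ("upstream_5ss", "cassette_3ss", "cassette_5ss", "downstream_3ss")
ENHANCED_QUANTILES = (0.0, 0.05, 0.70, 0.80, 1.0)
REPRESSED_QUANTILES = (0.0, 0.10, 0.65, 0.90, 1.0)
FDR_CUTOFF = 0.01


@dataclass(frozen=True)
class EventCoordinates:
    """Cassette-exon event: three ordered exons on one contig/strand.

    Intervals are 0-based half-open genomic coordinates; on the minus strand
    ``upstream`` is the exon with the larger coordinates.
    """

    event_id: str
    contig: str
    strand: str
    upstream: Tuple[int, int]
    cassette: Tuple[int, int]
    downstream: Tuple[int, int]
    psi: float = 0.5
    group: str = "control"

    def __post_init__(self) -> None:
        exons = [self.upstream, self.cassette, self.downstream]
        if self.strand == "-":
            exons = exons[::-1]
        prev_end = -1
        for s, e in exons:
            if not (prev_end <= s < e):
                raise ValueError(f"{self.event_id}: exons must be ordered and "
                                 "non-overlapping in transcript orientation")
            prev_end = e


@dataclass
class MetaProfile:
    anchor: str
    group: str
    positions: np.ndarray        # transcript orientation, exon -> intron axis
    mean: np.ndarray
    smoothed: np.ndarray
    n_events: int


def _minmax(window: np.ndarray) -> np.ndarray:
    """Min-max normalize; all-equal windows (incl. all-zero) map to zeros."""
    finite = np.isfinite(window)
    if not finite.any():
        return window
    lo, hi = np.nanmin(window), np.nanmax(window)
    if hi == lo:
        out = np.where(finite, 0.0, np.nan)
        return out
    return (window - lo) / (hi - lo)


def _anchor_specs(ev: EventCoordinates):
    """Genomic window and feature extents per anchor.

    Yields (anchor, genomic_start, genomic_end, kind, exon_len, intron_len).
    ``kind`` is "donor" (exon precedes intron along the transcript) or
    "acceptor" (intron precedes exon).  Windows are reported in genomic
    coordinates; on the minus strand they are reversed downstream so every
    profile runs 5'->3' along the transcript.
    """
    u, c, d = ev.upstream, ev.cassette, ev.downstream
    if ev.strand == "+":
        up_intron = c[0] - u[1]
        dn_intron = d[0] - c[1]
        yield ("upstream_5ss", u[1] - EXON_WINDOW, u[1] + INTRON_WINDOW,
               "donor", u[1] - u[0], up_intron)
        yield ("cassette_3ss", c[0] - INTRON_WINDOW, c[0] + EXON_WINDOW,
               "acceptor", c[1] - c[0], up_intron)
        yield ("cassette_5ss", c[1] - EXON_WINDOW, c[1] + INTRON_WINDOW,
               "donor", c[1] - c[0], dn_intron)
        yield ("downstream_3ss", d[0] - INTRON_WINDOW, d[0] + EXON_WINDOW,
               "acceptor", d[1] - d[0], dn_intron)
    else:
        up_intron = u[0] - c[1]
        dn_intron = c[0] - d[1]
        yield ("upstream_5ss", u[0] - INTRON_WINDOW, u[0] + EXON_WINDOW,
               "donor", u[1] - u[0], up_intron)
        yield ("cassette_3ss", c[1] - EXON_WINDOW, c[1] + INTRON_WINDOW,
               "acceptor", c[1] - c[0], up_intron)
        yield ("cassette_5ss", c[0] - INTRON_WINDOW, c[0] + EXON_WINDOW,
               "donor", c[1] - c[0], dn_intron)
        yield ("downstream_3ss", d[1] - EXON_WINDOW, d[1] + INTRON_WINDOW,
               "acceptor", d[1] - d[0], dn_intron)


def _feature_mask(kind: str, exon_len: int, intron_len: int) -> np.ndarray:
    """Validity mask on the transcript-oriented window axis.

    Positions beyond a short exon or intron are masked out (the windows reach
    "up to" 50 nt into exons and 300 nt into introns).
    """
    exon_ok = np.zeros(EXON_WINDOW, dtype=bool)
    exon_ok[-min(exon_len, EXON_WINDOW):] = True          # adjacent to the site
    intron_ok = np.zeros(INTRON_WINDOW, dtype=bool)
    intron_ok[:min(intron_len, INTRON_WINDOW)] = True
    if kind == "donor":      # [exon 50][intron 300]
        return np.concatenate([exon_ok, intron_ok])
    return np.concatenate([intron_ok[::-1], exon_ok[::-1]])


def extract_profiles(events: Sequence[EventCoordinates],
                     track: Mapping[Tuple[str, str], np.ndarray]
                     ) -> Dict[str, pd.DataFrame]:
    """Per-event min-max-normalized windows at each of the four anchors.

    ``track`` maps (contig, strand) to a per-nucleotide crosslink-count
    array.  Returns anchor -> DataFrame (events x positions) in transcript
    orientation: donor anchors run exon (50 nt) then intron (300 nt),
    acceptor anchors intron then exon.  Events without a covering track are
    skipped with a warning; positions beyond a short feature or outside the
    track are NaN.
    """
    out: Dict[str, List[Tuple[str, np.ndarray]]] = {a: [] for a in ANCHORS}
    for ev in events:
        key = (ev.contig, ev.strand)
        if key not in track:
            warnings.warn(f"{ev.event_id}: no track for {key}; skipped")
            continue
        arr = np.asarray(track[key], dtype=float)
        for anchor, s, e, kind, exon_len, intron_len in _anchor_specs(ev):
            win = np.full(e - s, np.nan)
            lo, hi = max(s, 0), min(e, len(arr))
            if hi > lo:
                win[lo - s:hi - s] = arr[lo:hi]
            if ev.strand == "-":
                win = win[::-1]
            win[~_feature_mask(kind, exon_len, intron_len)] = np.nan
            out[anchor].append((ev.event_id, _minmax(win)))
    frames = {}
    for anchor, rows in out.items():
        if rows:
            frames[anchor] = pd.DataFrame({eid: w for eid, w in rows}).T
            frames[anchor].index.name = "event_id"
    return frames


def aggregate_smooth(profiles: pd.DataFrame, anchor: str = "",
                     group: str = "", span: float = 0.2) -> MetaProfile:
    """Position-wise mean over events followed by loess smoothing."""
    if len(profiles) < 2:
        raise ValueError("at least 2 events per group are required")
    mean = profiles.to_numpy(dtype=float)
    mean = np.nanmean(mean, axis=0)
    x = np.arange(len(mean), dtype=float)
    ok = np.isfinite(mean)
    smoothed = np.full_like(mean, np.nan)
    if ok.sum() >= 2:
        sm = lowess(mean[ok], x[ok], frac=span, return_sorted=False)
        smoothed[ok] = sm
    return MetaProfile(anchor, group, x, mean, smoothed, len(profiles))


def sample_matched_controls(control_psi: pd.Series, target_psi: Sequence[float],
                            quantiles: Sequence[float] = ENHANCED_QUANTILES,
                            n_per_bin: Optional[int] = None,
                            seed: int = 0) -> pd.Index:
    """PSI-matched control subset.

    The target group's PSI quantiles at ``quantiles`` define four bins;
    ``n_per_bin`` controls are drawn per bin (default: target size / 4,
    rounded up).  Bins with too few controls are sampled with replacement
    and a warning.
    """
    rng = np.random.default_rng(seed)
    target_psi = np.asarray(target_psi, dtype=float)
    edges = np.quantile(target_psi, quantiles)
    if n_per_bin is None:
        n_per_bin = math.ceil(len(target_psi) / (len(edges) - 1))
    chosen: List = []
    for i in range(len(edges) - 1):
        lo, hi = edges[i], edges[i + 1]
        if i == len(edges) - 2:
            mask = (control_psi >= lo) & (control_psi <= hi)
        else:
            mask = (control_psi >= lo) & (control_psi < hi)
        pool = control_psi.index[mask]
        if len(pool) == 0:
            warnings.warn(f"PSI bin [{lo:.3g}, {hi:.3g}] has no controls")
            continue
        replace = len(pool) < n_per_bin
        if replace:
            warnings.warn(f"PSI bin [{lo:.3g}, {hi:.3g}] has only {len(pool)} "
                          f"controls; sampling {n_per_bin} with replacement")
        chosen.extend(rng.choice(pool, size=n_per_bin, replace=replace))
    return pd.Index(chosen)


def window_test(target_profiles: pd.DataFrame, control_profiles: pd.DataFrame,
                width: int = 10, fdr: float = FDR_CUTOFF) -> pd.DataFrame:
    """Sliding 10-nt Wilcoxon rank-sum comparison of normalized signal.

    For every window (step 1 nt) the per-event mean normalized signal is
    compared between target and control events with a two-sample Wilcoxon
    (Mann-Whitney) test; p values are BH-corrected and windows with
    FDR <= 0.01 flagged significant.  Windows in which all values are tied
    get p = 1.
    """
    t = target_profiles.to_numpy(dtype=float)
    c = control_profiles.to_numpy(dtype=float)
    if t.shape[1] != c.shape[1]:
        raise ValueError("profiles must cover identical positions")
    n_win = t.shape[1] - width + 1
    rows = []
    for start in range(n_win):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            tv = np.nanmean(t[:, start:start + width], axis=1)
            cv = np.nanmean(c[:, start:start + width], axis=1)
        tv, cv = tv[np.isfinite(tv)], cv[np.isfinite(cv)]
        if len(tv) == 0 or len(cv) == 0 or np.ptp(np.concatenate([tv, cv])) == 0:
            p = 1.0
        else:
            p = float(stats.mannwhitneyu(tv, cv, alternative="two-sided").pvalue)
        rows.append((start, start + width, p))
    df = pd.DataFrame(rows, columns=["start", "end", "p"])
    df["padj"] = multipletests(df["p"], method="fdr_bh")[1]
    df["significant"] = df["padj"] <= fdr
    return df


def junction_psi(inclusion: float, skipping: float,
                 min_total: int = 25) -> float:
    """Junction-count PSI: inclusion / (inclusion + skipping), or NaN.

    Undefined (NaN) when the summed junction support is below ``min_total``.
    """
    if inclusion < 0 or skipping < 0:
        raise ValueError("junction counts must be non-negative")
    total = inclusion + skipping
    if total < min_total:
        return math.nan
    return inclusion / total


def nmd_isoform_psi(inclusion1: float, inclusion2: float, skipping: float,
                    min_total: int = 25) -> float:
    """PSI of an exon whose skipping yields an NMD isoform.

    (i1 + i2) / (i1 + i2 + 2 * s): the two inclusion junctions both support
    the inclusion isoform, while the single skipping junction is counted
    twice to stay commensurate.
    """
    if min(inclusion1, inclusion2, skipping) < 0:
        raise ValueError("junction counts must be non-negative")
    if inclusion1 + inclusion2 + skipping < min_total:
        return math.nan
    inc = inclusion1 + inclusion2
    return inc / (inc + 2.0 * skipping)
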