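"""rG4 detection from RT-stop profiling of a barcoded 200-nt construct library.

Reverse transcription stalls at stable RNA structure, so an RNA G-quadruplex
(rG4) produces a pileup of read starts immediately 3' of the fold under
quadruplex-stabilizing conditions (KCl) but not under destabilizing ones
(NaCl).  The pipeline, per 200-nt construct:

1. seed detection: positions 19..200 (the 5'-most 18 nt are excluded because
   full-length cDNAs start there) with >= 6 read starts summed over the
   replicates of one condition;
2. 3-nt RT-stop peaks assembled greedily from seeds in descending-signal
   order, kept only when >= 2 of the 3 positions carry read starts;
3. condition merge: identical KCl/NaCl peaks deduplicated, partial overlaps
   re-centered on the maximum combined coverage;
4. construct filters: minimum normalized depth (median-of-ratios size
   factors) and exclusion of constructs whose total counts differ strongly
   between conditions;
5. a negative-binomial Wald test of NaCl vs KCl read starts within each peak;
   peaks with BH-adjusted p < 0.05 and a shrunken log2 fold change < 0
   (signal lost in NaCl) are rG4s;
6. region classification over the four barcoded replicates of a transcript
   region (>= 2 rG4 constructs -> rG4; zero -> non-rG4; otherwise
   inconsistent) and per-construct rG4-propensity scores.

Positions are 1-based 1..200 throughout this module, matching the construct
layout.  Counts are dense arrays of shape (n_replicates, 200) per construct
and condition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "RTstopPeak",
    "RegionClassification",
    "PropensityScores",
    "find_seeds",
    "peaks_from_seeds",
    "merge_condition_peaks",
    "call_rtstop_peaks",
    "size_factors",
    "filter_constructs",
    "nb_wald_test",
    "differential_rg4_test",
    "classify_regions",
    "propensity",
    "run_rtstop_pipeline",
]

CONSTRUCT_LENGTH = 200
FIVE_PRIME_EXCLUSION = 18   # nt excluded from the seed search
SEED_MIN_COUNT = 6
PEAK_WIDTH = 3
MIN_COVERED = 2             # of the 3 peak positions
MIN_NORMALIZED_READS = 100.0
ALPHA = 0.05


@dataclass(frozen=True)
class RTstopPeak:
    """A 3-nt RT-stop peak, 1-based inclusive coordinates, start >= 19."""

    construct_id: str
    start: int
    end: int
    condition: str = ""
    read_starts: float = 0.0

    def __post_init__(self) -> None:
        if self.end - self.start != PEAK_WIDTH - 1:
            raise ValueError("RT-stop peaks are exactly 3 nt wide")
        if self.start < FIVE_PRIME_EXCLUSION + 1:
            raise ValueError("peaks start at position 19 or later")


@dataclass
class RegionClassification:
    region_id: str
    status: str                      # rG4 / non_rG4 / inconsistent
    n_rg4_constructs: int
    n_constructs: int
    representative_construct: Optional[str]


@dataclass
class PropensityScores:
    """Per-construct rG4-propensity summary.

    ``peak_ratios`` maps each peak to (read starts in peak) / (total reads on
    the construct); ``g4_propensity`` sums the ratios of rG4 peaks;
    ``total_construct_ratio`` divides that sum by the number of peaks.
    """

    construct_id: str
    peak_ratios: Dict[Tuple[int, int], float] = field(default_factory=dict)
    representative_peak: Optional[Tuple[int, int]] = None
    g4_propensity: float = 0.0
    total_construct_ratio: float = 0.0


# ---------------------------------------------------------------------------
# peak calling


def _track_count(track: np.ndarray, pos: int) -> float:
    return float(track[pos - 1])


def find_seeds(summed_track: np.ndarray, min_count: int = SEED_MIN_COUNT) -> List[int]:
    """Positions 19..200 with at least ``min_count`` stacked read starts."""
    track = np.asarray(summed_track, dtype=float)
    pos = np.nonzero(track >= min_count)[0] + 1
    return [int(p) for p in pos if p > FIVE_PRIME_EXCLUSION]


def peaks_from_seeds(seeds: Sequence[int], summed_track: np.ndarray,
                     construct_id: str = ".", condition: str = "") -> List[RTstopPeak]:
    """Greedy assembly of non-overlapping 3-nt peaks from seed positions.

    Seeds are processed by descending signal (leftmost on ties); each claims
    a window centered on itself (shifted at the track boundaries so that the
    window stays within positions 19..200).  Windows overlapping an already
    placed peak are skipped, and a window is kept only when at least two of
    its three positions carry read starts.
    """
    track = np.asarray(summed_track, dtype=float)
    n = len(track)
    taken = np.zeros(n + 1, dtype=bool)
    peaks: List[RTstopPeak] = []
    for s in sorted(seeds, key=lambda p: (-_track_count(track, p), p)):
        start = min(max(s - 1, FIVE_PRIME_EXCLUSION + 1), n - PEAK_WIDTH + 1)
        end = start + PEAK_WIDTH - 1
        if taken[start:end + 1].any():
            continue
        window = track[start - 1:end]
        if np.count_nonzero(window) < MIN_COVERED:
            continue
        taken[start:end + 1] = True
        peaks.append(RTstopPeak(construct_id, start, end, condition,
                                float(window.sum())))
    return sorted(peaks, key=lambda p: p.start)


def merge_condition_peaks(peaks_kcl: Sequence[RTstopPeak],
                          peaks_nacl: Sequence[RTstopPeak],
                          combined_track: np.ndarray) -> List[RTstopPeak]:
    """Unify the KCl and NaCl peak sets of one construct.

    Identical peaks are deduplicated.  Partially overlapping peaks are
    replaced by a single 3-nt peak centered on the position of maximum
    combined (KCl + NaCl) coverage within their union.  Disjoint peaks are
    retained as-is.
    """
    track = np.asarray(combined_track, dtype=float)
    n = len(track)
    intervals = sorted({(p.start, p.end) for p in list(peaks_kcl) + list(peaks_nacl)})
    if not intervals:
        return []
    cid = (list(peaks_kcl) + list(peaks_nacl))[0].construct_id

    merged: List[RTstopPeak] = []
    group = [intervals[0]]
    for iv in intervals[1:]:
        if iv[0] <= group[-1][1]:       # overlaps the running group
            group.append(iv)
        else:
            merged.append(_resolve_group(group, track, n, cid))
            group = [iv]
    merged.append(_resolve_group(group, track, n, cid))
    return merged


def _resolve_group(group, track, n, cid) -> RTstopPeak:
    if len(group) == 1:
        s, e = group[0]
    else:
        lo, hi = group[0][0], max(e for _, e in group)
        center = lo + int(np.argmax(track[lo - 1:hi]))
        s = min(max(center - 1, FIVE_PRIME_EXCLUSION + 1), n - PEAK_WIDTH + 1)
        e = s + PEAK_WIDTH - 1
    return RTstopPeak(cid, s, e, "merged", float(track[s - 1:e].sum()))


def call_rtstop_peaks(counts: Mapping[str, np.ndarray],
                      construct_id: str = ".") -> List[RTstopPeak]:
    """Seed -> peak -> condition-merge pipeline for one construct.

    ``counts`` maps condition name ("KCl", "NaCl") to an array of shape
    (n_replicates, 200).
    """
    per_condition = {}
    for cond, mat in counts.items():
        summed = np.asarray(mat, dtype=float).sum(axis=0)
        per_condition[cond] = peaks_from_seeds(find_seeds(summed), summed,
                                               construct_id, cond)
    combined = sum(np.asarray(mat, dtype=float).sum(axis=0)
                   for mat in counts.values())
    conds = list(counts)
    if len(conds) == 1:
        return per_condition[conds[0]]
    return merge_condition_peaks(per_condition[conds[0]],
                                 per_condition[conds[1]], combined)


# ---------------------------------------------------------------------------
# normalization and differential testing


def size_factors(totals: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors (constructs x samples count table)."""
    mat = totals.to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        log_geo = np.log(mat).mean(axis=1)
    ok = np.isfinite(log_geo)
    if not ok.any():
        raise ValueError("no construct with counts in every sample")
    log_ratios = np.log(mat[ok]) - log_geo[ok, None]
    return pd.Series(np.exp(np.median(log_ratios, axis=0)),
                     index=totals.columns, name="size_factor")


def _mom_dispersion(norm: np.ndarray, groups: Sequence[np.ndarray],
                    floor: float = 0.01) -> float:
    """Method-of-moments NB dispersion pooled over condition groups."""
    num = den = 0.0
    for idx in groups:
        sub = norm[idx]
        if len(sub) < 2:
            continue
        m = sub.mean()
        if m <= 0:
            continue
        v = sub.var(ddof=1)
        num += max(v - m, 0.0)
        den += m * m
    if den == 0:
        return floor
    return max(num / den, floor)


def nb_wald_test(counts_a: np.ndarray, counts_b: np.ndarray,
                 sf_a: np.ndarray, sf_b: np.ndarray,
                 dispersion: Optional[float] = None) -> Tuple[float, float, float]:
    """Negative-binomial Wald test of condition b vs condition a.

    Counts are size-factor normalized; the per-unit dispersion defaults to a
    method-of-moments estimate with a floor of 0.01.  Returns
    ``(log2_fold_change, standard_error, p_value)`` with the fold change of b
    relative to a; all-zero input yields ``(nan, nan, nan)``.
    """
    na, nb = np.asarray(counts_a, float) / sf_a, np.asarray(counts_b, float) / sf_b
    if na.sum() == 0 and nb.sum() == 0:
        return (math.nan, math.nan, math.nan)
    if dispersion is None:
        dispersion = _mom_dispersion(np.concatenate([na, nb]),
                                     [np.arange(len(na)),
                                      np.arange(len(na), len(na) + len(nb))])
    eps = 0.5  # pseudocount on the normalized scale stabilizes empty groups
    ma, mb = na.mean() + eps, nb.mean() + eps
    l2fc = math.log2(mb / ma)
    var_log = ((1.0 / ma + dispersion) / len(na)
               + (1.0 / mb + dispersion) / len(nb))
    se = math.sqrt(var_log) / math.log(2.0)
    z = l2fc / se
    p = 2.0 * stats.norm.sf(abs(z))
    return (l2fc, se, p)


def filter_constructs(totals: pd.DataFrame, condition_of: Mapping[str, str],
                      min_normalized: float = MIN_NORMALIZED_READS,
                      literal_lessabs: bool = False) -> pd.Index:
    """Constructs retained for differential testing.

    ``totals`` is a constructs x samples table of total read counts and
    ``condition_of`` maps sample name to condition.  Dropped are constructs
    with mean normalized counts below ``min_normalized`` and constructs whose
    between-condition total-count fold change is strong and significant
    (|L2FC| >= 1, BH-adjusted p < 0.05) -- the high-variability exclusion.
    ``literal_lessabs=True`` instead applies the literal printed rule and
    drops constructs significant under the 'lessAbs' hypothesis
    (|L2FC| < 1), i.e. constructs demonstrated to be stable.
    """
    sf = size_factors(totals)
    norm = totals / sf
    deep = norm.mean(axis=1) >= min_normalized

    samples = list(totals.columns)
    conds = sorted({condition_of[s] for s in samples})
    if len(conds) != 2:
        raise ValueError("exactly two conditions are required")
    a_cols = [s for s in samples if condition_of[s] == conds[0]]
    b_cols = [s for s in samples if condition_of[s] == conds[1]]

    rows = []
    for cid in totals.index:
        l2fc, se, _ = nb_wald_test(totals.loc[cid, a_cols].to_numpy(),
                                   totals.loc[cid, b_cols].to_numpy(),
                                   sf[a_cols].to_numpy(), sf[b_cols].to_numpy())
        if math.isnan(l2fc):
            rows.append((cid, math.nan, 1.0, 1.0))
            continue
        if literal_lessabs:
            # H0: |l2fc| >= 1 against H1: |l2fc| < 1 (composite; conservative
            # p from the boundary closest to the estimate)
            z = (abs(l2fc) - 1.0) / se
            p = stats.norm.cdf(z)
        else:
            # greaterAbs-style: significant when the fold change exceeds 1
            z = (abs(l2fc) - 1.0) / se
            p = stats.norm.sf(z)
        rows.append((cid, l2fc, se, p))
    df = pd.DataFrame(rows, columns=["construct", "l2fc", "se", "p"]).set_index("construct")
    df["padj"] = multipletests(df["p"].fillna(1.0), method="fdr_bh")[1]
    variable = df["padj"] < ALPHA
    keep = deep & ~variable
    return totals.index[keep]


def _shrink_l2fc(l2fc: np.ndarray, se: np.ndarray) -> np.ndarray:
    """Empirical-Bayes shrinkage of fold changes toward zero.

    Normal prior with variance estimated from the cross-peak L2FC spread in
    excess of the sampling noise (adaptive-shrinkage stand-in).
    """
    ok = np.isfinite(l2fc) & np.isfinite(se)
    if ok.sum() < 2:
        return l2fc
    prior_var = max(float(np.var(l2fc[ok]) - np.mean(se[ok] ** 2)), 1e-6)
    out = np.array(l2fc, dtype=float)
    out[ok] = l2fc[ok] * prior_var / (prior_var + se[ok] ** 2)
    return out


def differential_rg4_test(peak_counts: pd.DataFrame,
                          condition_of: Mapping[str, str],
                          sf: Optional[pd.Series] = None,
                          kcl_label: str = "KCl",
                          alpha: float = ALPHA) -> pd.DataFrame:
    """NaCl-vs-KCl differential test on per-peak read-start counts.

    ``peak_counts`` has one row per peak (index: peak identifier) and one
    column per sample.  Returns a frame with ``l2fc`` (NaCl relative to KCl),
    ``l2fc_shrunk``, ``p``, ``padj`` and ``is_rg4`` (padj < alpha and
    shrunken L2FC < 0).  All-zero peaks are not tested.
    """
    samples = list(peak_counts.columns)
    kcl_cols = [s for s in samples if condition_of[s] == kcl_label]
    nacl_cols = [s for s in samples if condition_of[s] != kcl_label]
    if not kcl_cols or not nacl_cols:
        raise ValueError("both conditions must be present")
    if sf is None:
        sf = pd.Series(1.0, index=samples)

    res = []
    for pid in peak_counts.index:
        l2fc, se, p = nb_wald_test(
            peak_counts.loc[pid, kcl_cols].to_numpy(),
            peak_counts.loc[pid, nacl_cols].to_numpy(),
            sf[kcl_cols].to_numpy(), sf[nacl_cols].to_numpy())
        res.append((l2fc, se, p))
    df = pd.DataFrame(res, columns=["l2fc", "se", "p"], index=peak_counts.index)
    df["l2fc_shrunk"] = _shrink_l2fc(df["l2fc"].to_numpy(), df["se"].to_numpy())
    tested = df["p"].notna()
    df["padj"] = np.nan
    if tested.any():
        df.loc[tested, "padj"] = multipletests(df.loc[tested, "p"],
                                               method="fdr_bh")[1]
    df["is_rg4"] = (df["padj"] < alpha) & (df["l2fc_shrunk"] < 0)
    return df


# ---------------------------------------------------------------------------
# region classification and propensity


def classify_regions(construct_flags: pd.DataFrame) -> List[RegionClassification]:
    """Classify 4-barcode regions from per-construct rG4 flags.

    ``construct_flags`` needs columns ``region_id``, ``construct_id``,
    ``is_rg4`` and ``total_reads``.  Two or more rG4 constructs make an rG4
    region; a non-rG4 region may not contain a single rG4 construct; anything
    in between is inconsistent.  The representative construct is the one with
    the highest read count.
    """
    out = []
    for region_id, grp in construct_flags.groupby("region_id", sort=True):
        n_rg4 = int(grp["is_rg4"].sum())
        n = len(grp)
        if n == 0:
            continue
        status = "rG4" if n_rg4 >= 2 else ("non_rG4" if n_rg4 == 0 else "inconsistent")
        rep = grp.loc[grp["total_reads"].idxmax(), "construct_id"]
        out.append(RegionClassification(str(region_id), status, n_rg4, n, rep))
    return out


def propensity(construct_id: str, peaks: Sequence[RTstopPeak],
               rg4_flags: Mapping[Tuple[int, int], bool],
               track: np.ndarray) -> PropensityScores:
    """rG4-propensity scores of one construct.

    Per peak, the ratio of read starts inside the peak over the total reads
    on the construct; the representative peak has the highest ratio.  With no
    peaks all scores are 0; with zero total reads scores are undefined (nan).
    """
    track = np.asarray(track, dtype=float)
    total = float(track.sum())
    scores = PropensityScores(construct_id)
    if not peaks:
        return scores
    if total == 0:
        scores.g4_propensity = math.nan
        scores.total_construct_ratio = math.nan
        return scores
    for p in peaks:
        scores.peak_ratios[(p.start, p.end)] = float(
            track[p.start - 1:p.end].sum()) / total
    scores.representative_peak = max(scores.peak_ratios,
                                     key=lambda k: (scores.peak_ratios[k], -k[0]))
    scores.g4_propensity = sum(r for k, r in scores.peak_ratios.items()
                               if rg4_flags.get(k, False))
    scores.total_construct_ratio = (sum(scores.peak_ratios.values())
                                    / len(scores.peak_ratios))
    return scores


# ---------------------------------------------------------------------------
# end-to-end pipeline


def run_rtstop_pipeline(counts: Mapping[str, Mapping[str, np.ndarray]],
                        manifest: pd.DataFrame,
                        alpha: float = ALPHA) -> Tuple[pd.DataFrame, List[RegionClassification]]:
    """Peak calling, filtering, differential testing and region classification.

    ``counts`` maps construct_id -> condition -> array (n_replicates, 200);
    ``manifest`` needs columns ``construct_id`` and ``region_id``.  Returns
    the per-peak differential table (with construct and region annotations)
    and the region classifications.
    """
    construct_ids = list(counts)
    conditions = sorted({c for cid in construct_ids for c in counts[cid]})
    sample_names, condition_of = [], {}
    for cond in conditions:
        n_rep = np.asarray(counts[construct_ids[0]][cond]).shape[0]
        for r in range(n_rep):
            name = f"{cond}_{r + 1}"
            sample_names.append(name)
            condition_of[name] = cond

    totals = pd.DataFrame(
        {name: [np.asarray(counts[cid][condition_of[name]])[int(name.split("_")[-1]) - 1].sum()
                for cid in construct_ids]
         for name in sample_names},
        index=pd.Index(construct_ids, name="construct_id"))

    retained = filter_constructs(totals, condition_of)
    sf = size_factors(totals)

    peak_rows, peak_index = [], []
    peaks_by_construct: Dict[str, List[RTstopPeak]] = {}
    for cid in retained:
        peaks = call_rtstop_peaks(counts[cid], cid)
        peaks_by_construct[cid] = peaks
        for p in peaks:
            row = []
            for name in sample_names:
                rep = int(name.split("_")[-1]) - 1
                mat = np.asarray(counts[cid][condition_of[name]], dtype=float)
                row.append(mat[rep, p.start - 1:p.end].sum())
            peak_rows.append(row)
            peak_index.append((cid, p.start, p.end))

    if not peak_rows:
        return (pd.DataFrame(columns=["l2fc", "l2fc_shrunk", "p", "padj", "is_rg4"]),
                classify_regions(pd.DataFrame(
                    {"region_id": manifest.set_index("construct_id").loc[list(retained), "region_id"],
                     "construct_id": list(retained),
                     "is_rg4": False,
                     "total_reads": totals.loc[list(retained)].sum(axis=1)})))

    peak_counts = pd.DataFrame(
        peak_rows, columns=sample_names,
        index=pd.MultiIndex.from_tuples(peak_index,
                                        names=["construct_id", "start", "end"]))
    diff = differential_rg4_test(peak_counts, condition_of, sf=sf, alpha=alpha)

    rg4_by_construct = (diff.reset_index().groupby("construct_id")["is_rg4"].any()
                        if len(diff) else pd.Series(dtype=bool))
    region_of = manifest.set_index("construct_id")["region_id"]
    flags = pd.DataFrame({
        "construct_id": list(retained),
        "region_id": [region_of.get(cid) for cid in retained],
        "is_rg4": [bool(rg4_by_construct.get(cid, False)) for cid in retained],
        "total_reads": totals.loc[list(retained)].sum(axis=1).to_numpy(),
    })
    return diff, classify_regions(flags)
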