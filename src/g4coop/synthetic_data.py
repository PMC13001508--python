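"""Seeded generators for every data modality the analysis modules consume.

Each generator emulates one experimental readout of the rG4/HNRNPH study
design, with known ground truth so downstream modules can be tested for
recovery:

* splicing titrations: delta-PSI vs relative HNRNPH level on a 12-point
  log-spaced grid spanning the 46%..176% protein range, generated from
  four-parameter logistic curves with Gaussian noise;
* iCLIP crosslink tracks: Poisson background plus triangular 5-nt peaks, and
  a surrogate for the significant crosslink positions an HMM peak caller
  would report (counts above a high quantile of the background);
* the barcoded in vitro transcription library: 200-nt constructs laid out as
  18-nt T7 promoter + 146-nt insert + 15-nt barcode + 21-nt L3 linker, with
  canonical rG4s planted so the site of interest starts at construct
  position 51, and barcodes pairwise Hamming distance >= 5 without GGG;
* RT-stop read-start matrices: negative-binomial stall pileups immediately
  3' of planted rG4s under KCl+GTP only, plus a 5'-end pileup and uniform
  background in every condition;
* in vitro binding titrations: the equilibrium model's bound fraction plus
  Gaussian noise, suitable for Hill refitting.

All outputs are deterministic functions of ``SimulationConfig.seed``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .dose_response import ll4
from .equilibrium_binding import EnergyParams, bound_fraction

__all__ = [
    "SimulationConfig",
    "T7_PROMOTER",
    "L3_LINKER",
    "gen_titration",
    "gen_crosslink_data",
    "gen_oligo_library",
    "validate_library",
    "gen_rtstop_counts",
    "gen_invitro_binding",
    "write_library_fasta",
]

T7_PROMOTER = "TAATACGACTCACTATAG"          # 18 nt
L3_LINKER = "CTGACTTGAAACGGCATCAGT"         # 21 nt, G-run free
BARCODE_LENGTH = 15
INSERT_LENGTH = 146
FIVE_PRIME_LEN = 18                          # 5'-end pileup footprint
SITE_START = 51                              # 1-based within the construct
CONDITIONS = {("KCl", "GTP"), ("KCl", "7dGTP"),
              ("NaCl", "GTP"), ("NaCl", "7dGTP")}


@dataclass
class SimulationConfig:
    """Knobs of all generators; the defaults are the study conditions."""

    seed: int = 0
    n_events: int = 20
    protein_levels: Optional[Sequence[float]] = None   # default: 12-pt grid
    n_replicates: int = 3
    noise_sd: float = 0.02
    track_length: int = 1000
    site_spec: Sequence[Tuple[int, float]] = field(default_factory=list)
    background_rate: float = 0.5
    significance_quantile: float = 0.999
    n_regions: int = 12
    barcodes_per_region: int = 4
    rg4_fraction: float = 0.5
    stall_intensity: float = 50.0
    five_prime_intensity: float = 10.0
    nb_dispersion: float = 0.1

    def __post_init__(self) -> None:
        for name in ("noise_sd", "background_rate", "stall_intensity",
                     "five_prime_intensity", "nb_dispersion"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.protein_levels is not None:
            if np.any(np.asarray(self.protein_levels, float) <= 0):
                raise ValueError("protein levels must be strictly positive")
        if self.barcodes_per_region < 1:
            raise ValueError("barcodes_per_region must be >= 1")

    def levels(self) -> np.ndarray:
        if self.protein_levels is not None:
            return np.asarray(self.protein_levels, dtype=float)
        return np.logspace(math.log10(0.46), math.log10(1.76), 12)


# ---------------------------------------------------------------------------
# titrations


def gen_titration(config: SimulationConfig,
                  truth: Sequence[Mapping[str, float]]) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Simulated delta-PSI titration series from LL.4 ground-truth curves.

    Each truth entry needs keys ``slope`` (signed), ``min``, ``max``,
    ``ec50`` and optionally ``event_id``.  Observations are
    LL.4(level) + N(0, noise_sd), ``n_replicates`` per level.
    """
    if not truth:
        raise ValueError("truth parameter list must not be empty")
    rng = np.random.default_rng(config.seed)
    levels = config.levels()
    obs_rows, truth_rows = [], []
    for i, t in enumerate(truth):
        event_id = str(t.get("event_id", f"event_{i:04d}"))
        clean = ll4(levels, t["slope"], t["min"], t["max"], t["ec50"])
        for rep in range(config.n_replicates):
            noisy = clean + rng.normal(0.0, config.noise_sd, size=len(levels))
            for lv, dp in zip(levels, noisy):
                obs_rows.append((event_id, rep + 1, lv, float(np.clip(dp, -1, 1))))
        truth_rows.append({"event_id": event_id, **{k: t[k] for k in
                                                    ("slope", "min", "max", "ec50")}})
    obs = pd.DataFrame(obs_rows, columns=["event_id", "replicate", "level",
                                          "delta_psi"])
    return obs, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# crosslink tracks


def gen_crosslink_data(config: SimulationConfig
                       ) -> Tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Poisson crosslink track with planted peaks and a significance surrogate.

    Signal at each planted site follows a triangular kernel of half-width
    2 nt around the site center (matching the 5-nt site geometry); positions
    whose count exceeds the ``significance_quantile`` of the Poisson
    background are flagged as significant, emulating the peak caller's
    significant crosslink positions.
    """
    if config.site_spec and max(p for p, _ in config.site_spec) >= config.track_length:
        raise ValueError("track_length smaller than the largest site position")
    for pos, amp in config.site_spec:
        if amp <= config.background_rate:
            raise ValueError("site amplitudes must exceed the background rate")
    rng = np.random.default_rng(config.seed)
    mean = np.full(config.track_length, float(config.background_rate))
    for pos, amp in config.site_spec:
        for d in range(-2, 3):
            if 0 <= pos + d < config.track_length:
                mean[pos + d] += amp * (1.0 - abs(d) / 3.0)
    counts = rng.poisson(mean).astype(float)
    threshold = stats.poisson.ppf(config.significance_quantile,
                                  max(config.background_rate, 0.0))
    significant = np.nonzero(counts > threshold)[0]
    truth = pd.DataFrame(config.site_spec, columns=["position", "amplitude"])
    return counts, significant, truth


# ---------------------------------------------------------------------------
# oligonucleotide library


def _random_barcodes(n: int, rng: np.random.Generator,
                     min_hamming: int = 5, max_tries: int = 20000) -> List[str]:
    alphabet = np.array(list("ACGT"))
    chosen = np.empty((0, BARCODE_LENGTH), dtype="U1")
    for _ in range(max_tries):
        if len(chosen) == n:
            break
        cand = rng.choice(alphabet, size=BARCODE_LENGTH)
        if "GGG" in "".join(cand):
            continue
        if len(chosen) == 0 or (chosen != cand).sum(axis=1).min() >= min_hamming:
            chosen = np.vstack([chosen, cand])
    if len(chosen) < n:
        raise ValueError(f"could not find {n} barcodes with pairwise Hamming "
                         f">= {min_hamming} and no GGG in {max_tries} tries")
    return ["".join(row) for row in chosen]


def _random_seq_no_grun(length: int, rng: np.random.Generator) -> str:
    """Random sequence without three consecutive Gs."""
    out: List[str] = []
    for _ in range(length):
        letters = "ACGT" if not (len(out) >= 2 and out[-1] == out[-2] == "G") else "ACT"
        out.append(letters[rng.integers(len(letters))])
    return "".join(out)


def _random_rg4(rng: np.random.Generator) -> str:
    """Canonical rG4 (DNA alphabet): four runs of 3 Gs, loops of 1-7 non-G nt."""
    parts = ["GGG"]
    for _ in range(3):
        loop_len = int(rng.integers(1, 8))
        loop = "".join("ACT"[rng.integers(3)] for _ in range(loop_len))
        parts.append(loop + "GGG")
    return "".join(parts)


def gen_oligo_library(config: SimulationConfig
                      ) -> Tuple[Dict[str, str], pd.DataFrame]:
    """Barcoded 200-nt construct library with planted rG4s.

    Each of ``n_regions`` transcript regions appears ``barcodes_per_region``
    times with distinct barcodes; a fraction ``rg4_fraction`` of regions
    carries a canonical rG4 whose first G starts at construct position 51.
    Returns (sequences keyed by construct id, manifest).
    """
    rng = np.random.default_rng(config.seed)
    n_constructs = config.n_regions * config.barcodes_per_region
    barcodes = _random_barcodes(n_constructs, rng)
    n_rg4 = int(round(config.rg4_fraction * config.n_regions))

    seqs: Dict[str, str] = {}
    rows = []
    bc_iter = iter(barcodes)
    for r in range(config.n_regions):
        region_id = f"region_{r:04d}"
        has_rg4 = r < n_rg4
        if has_rg4:
            site = _random_rg4(rng)
            offset = SITE_START - len(T7_PROMOTER) - 1   # 0-based in insert
            left = _random_seq_no_grun(offset, rng)
            right = _random_seq_no_grun(INSERT_LENGTH - offset - len(site), rng)
            insert = left + site + right
            rg4_start, rg4_end = SITE_START, SITE_START + len(site) - 1
        else:
            insert = _random_seq_no_grun(INSERT_LENGTH, rng)
            rg4_start = rg4_end = -1
        for b in range(config.barcodes_per_region):
            cid = f"{region_id}_bc{b + 1}"
            bc = next(bc_iter)
            seqs[cid] = T7_PROMOTER + insert + bc + L3_LINKER
            rows.append((cid, region_id, bc, has_rg4, rg4_start, rg4_end))
    manifest = pd.DataFrame(rows, columns=["construct_id", "region_id",
                                           "barcode", "has_rg4",
                                           "rg4_start", "rg4_end"])
    return seqs, manifest


def validate_library(seqs: Mapping[str, str], manifest: pd.DataFrame) -> None:
    """Re-check layout lengths, barcode constraints and planted rG4 consensus."""
    import re

    rg4_pattern = re.compile(r"GGG(?:[ACT]{1,7}GGG){3}")
    barcodes = manifest.set_index("construct_id")["barcode"]
    for cid, seq in seqs.items():
        if len(seq) != 200:
            raise AssertionError(f"{cid}: construct length {len(seq)} != 200")
        if not seq.startswith(T7_PROMOTER) or not seq.endswith(L3_LINKER):
            raise AssertionError(f"{cid}: promoter/linker layout violated")
        bc = seq[len(T7_PROMOTER) + INSERT_LENGTH:
                 len(T7_PROMOTER) + INSERT_LENGTH + BARCODE_LENGTH]
        if bc != barcodes[cid]:
            raise AssertionError(f"{cid}: barcode does not match the manifest")
        if "GGG" in bc:
            raise AssertionError(f"{cid}: barcode contains a G-run")
    bcs = list(barcodes)
    for i in range(len(bcs)):
        for j in range(i + 1, len(bcs)):
            if sum(a != b for a, b in zip(bcs[i], bcs[j])) < 5:
                raise AssertionError("barcode pair below Hamming distance 5")
    for _, row in manifest.iterrows():
        if row.has_rg4:
            site = seqs[row.construct_id][row.rg4_start - 1:row.rg4_end]
            if row.rg4_start != SITE_START or not rg4_pattern.fullmatch(site):
                raise AssertionError(f"{row.construct_id}: planted rG4 invalid")


def write_library_fasta(seqs: Mapping[str, str], path) -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    records = [SeqRecord(Seq(s), id=cid, description="") for cid, s in seqs.items()]
    SeqIO.write(records, path, "fasta")


# ---------------------------------------------------------------------------
# RT-stop read-start counts


def _nb_draw(rng: np.random.Generator, mean: float, dispersion: float,
             size) -> np.ndarray:
    """Negative binomial with mean/dispersion parameterization (var = m + a m^2)."""
    if mean <= 0:
        return np.zeros(size, dtype=np.int64)
    if dispersion <= 0:
        return rng.poisson(mean, size=size)
    n = 1.0 / dispersion
    p = n / (n + mean)
    return rng.negative_binomial(n, p, size=size)


def gen_rtstop_counts(manifest: pd.DataFrame, config: SimulationConfig,
                      condition: Tuple[str, str]) -> Dict[str, np.ndarray]:
    """Read-start count matrices for one (salt, nucleotide) condition.

    Under KCl+GTP an rG4-bearing construct receives a negative-binomial
    read-start pileup at the position immediately 3' of the planted rG4 (the
    reverse transcriptase walks 3'->5' and stalls at the fold), with a small
    stutter tail one and two nucleotides further 3'.  NaCl or 7dGTP abolish
    the pileup.  A uniform Poisson background and a 5'-end pileup over
    positions 1-18 (full-length cDNAs) are present in every condition.
    Returns construct_id -> (n_replicates, 200) arrays.
    """
    if tuple(condition) not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}; expected one of "
                         f"{sorted(CONDITIONS)}")
    salt, ntp = condition
    # independent, reproducible stream per condition (stable across processes)
    cond_key = sorted(CONDITIONS).index((salt, ntp))
    rng = np.random.default_rng([config.seed, cond_key])
    out: Dict[str, np.ndarray] = {}
    length = 200
    for _, row in manifest.iterrows():
        mat = rng.poisson(config.background_rate,
                          size=(config.n_replicates, length)).astype(np.int64)
        mat[:, :FIVE_PRIME_LEN] += rng.poisson(
            config.five_prime_intensity / FIVE_PRIME_LEN,
            size=(config.n_replicates, FIVE_PRIME_LEN))
        if row.has_rg4 and salt == "KCl" and ntp == "GTP":
            stall = int(row.rg4_end) + 1           # 1-based stall position
            for off, frac in ((0, 0.7), (1, 0.2), (2, 0.1)):
                pos = stall + off
                if pos <= length:
                    mat[:, pos - 1] += _nb_draw(
                        rng, config.stall_intensity * frac,
                        config.nb_dispersion, config.n_replicates)
        out[row.construct_id] = mat
    return out


# ---------------------------------------------------------------------------
# in vitro binding


def gen_invitro_binding(energy_params: EnergyParams,
                        concentrations: Sequence[float],
                        noise_sd: float = 0.0,
                        seed: int = 0) -> pd.DataFrame:
    """Bound-signal table from the equilibrium model plus Gaussian noise."""
    rng = np.random.default_rng(seed)
    conc = np.asarray(concentrations, dtype=float)
    clean = bound_fraction(energy_params, conc)
    signal = clean + rng.normal(0.0, noise_sd, size=conc.shape)
    return pd.DataFrame({"concentration": conc, "signal": signal,
                         "true_fraction": clean})
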