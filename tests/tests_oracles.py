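"""Independent reference implementations used as oracles by the test suite.

These deliberately re-derive results from first principles (explicit
configuration sums, literal rule-by-rule evaluation) and share no code with
the package implementations they check.
"""

import math
from itertools import combinations

import numpy as np

from g4coop.equilibrium_binding import EnergyParams

RT = 1.987e-3 * 298.0


def _explicit_placements(n_sites, max_block):
    """Every set of disjoint contiguous blocks, each block listed explicitly."""
    blocks = [(i, k) for k in range(1, max_block + 1)
              for i in range(n_sites - k + 1)]

    def disjoint(sel):
        used = set()
        for i, k in sel:
            span = set(range(i, i + k))
            if used & span:
                return False
            used |= span
        return True

    out = [()]
    for r in range(1, n_sites + 1):
        for sel in combinations(blocks, r):
            if disjoint(sel):
                out.append(sel)
    return out


def brute_force_bound_fraction(params: EnergyParams, c: float) -> float:
    """Direct sum over explicit binding configurations (n_sites <= 4)."""
    x = c / params.c0
    z_unbound = 1.0 + math.exp(params.g_rG4 / RT)
    z_bound = 0.0
    for placement in _explicit_placements(params.n_sites, params.max_qrrm):
        if not placement:
            continue
        w = 1.0
        for _, k in placement:
            w *= x * math.exp((k * params.g_bind
                               - (k - 1) * params.g_backfold) / RT)
            if params.qrrm_degeneracy:
                w *= math.comb(params.max_qrrm, k)
        z_bound += w
    if params.g_rG4_bind is not None:
        z_bound += x * math.exp((params.g_rG4 + params.g_rG4_bind) / RT)
    return z_bound / (z_bound + z_unbound)


def oracle_call(track, significant, max_gap=3):
    """Step-by-step reference of the binding-site definition rules."""
    track = np.asarray(track)
    sig = sorted(set(int(p) for p in significant))
    # 1. merge positions <= 3 nt apart; drop regions shorter than 2 nt
    regions = []
    for p in sig:
        if regions and p - regions[-1][-1] <= max_gap:
            regions[-1].append(p)
        else:
            regions.append([p])
    regions = [set(range(r[0], r[-1] + 1)) for r in regions
               if r[-1] - r[0] + 1 >= 2]
    # 2. iterative placement; cut-out positions cannot be reused
    sites = []
    excised = set()
    for region in regions:
        remaining = set(region)
        while remaining:
            peak = max(sorted(remaining), key=lambda p: (track[p], -p))
            if track[peak] <= 0:
                break
            footprint = set(range(peak - 2, peak + 3))
            if (peak - 2 >= 0 and peak + 2 < len(track)
                    and not footprint & excised):
                sites.append(peak)
            excised |= set(range(peak - 6, peak + 7))
            remaining -= set(range(peak - 6, peak + 7))
    # 3. cleanup
    out = []
    sig_set = set(sig)
    for center in sorted(sites):
        window = track[center - 2:center + 3]
        if center not in sig_set and track[center] != window.max():
            continue
        if np.count_nonzero(window) < 3:
            continue
        out.append((center - 2, center + 3))
    return out
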