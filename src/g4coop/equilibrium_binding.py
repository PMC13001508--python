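"""Equilibrium statistical-mechanics model of HNRNPH binding to an rG4.

An unfolded RNA G-quadruplex exposes ``n_sites`` single-stranded G-runs
(four for a canonical rG4), each of which can be contacted by one qRRM
domain of an HNRNPH protein.  A protein carries ``max_qrrm`` qRRMs (three
for HNRNPH) and may engage 1..max_qrrm adjacent G-runs; every contact beyond
the first requires a "backfolding" rearrangement of the protein and pays an
entropic penalty.  Three characteristic free energies (all kcal/mol, entered
as positive magnitudes) govern the system:

* ``g_rG4``      -- stabilization of the folded quadruplex versus unfolded RNA,
* ``g_bind``     -- gain per qRRM/G-run contact,
* ``g_backfold`` -- penalty per backfolding event (k contacts cost k-1 events).

With the unfolded, unbound RNA as reference state (weight 1), a state with
``m`` bound proteins making contacts ``(k_1, ..., k_m)`` has statistical weight

    multiplicity * (c / c0)^m * exp[(sum_i k_i * g_bind
                                     - sum_i (k_i - 1) * g_backfold) / RT]

where the multiplicity counts the distinct ordered placements of the
(unlabeled) proteins as contiguous blocks on the linear array of G-runs.
The folded, unbound RNA has weight exp(g_rG4 / RT), and an optional "helper"
state in which one protein binds the still-folded rG4 with energy
``g_rG4_bind`` has weight (c / c0) * exp[(g_rG4 + g_rG4_bind) / RT].

From the partition function the module derives the bound fraction (RNA with
at least one protein), the transition concentration K (half-saturation), the
EC10/EC90 Hill coefficient, a reduced model keeping only the two dominant
double-backfolding states (2^31 and 2^22), and inversions recovering
``g_bind`` from a dissociation constant and ``g_backfold`` from a target K.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import brentq
from scipy.special import logsumexp

__all__ = [
    "GAS_CONSTANT_KCAL",
    "EnergyParams",
    "BindingState",
    "enumerate_states",
    "state_log_weights",
    "state_probabilities",
    "bound_fraction",
    "transition_concentration",
    "model_hill",
    "binding_energy_from_kd",
    "invert_backfold_penalty",
    "reduced_double_backfold",
    "helper_state_effect",
]

#: gas constant in kcal / (mol K)
GAS_CONSTANT_KCAL = 1.987e-3


@dataclass(frozen=True)
class EnergyParams:
    """Free energies and geometry of the rG4/HNRNPH binding model.

    By default statistical weights carry bare placement multiplicities (the
    three qRRMs are treated as fully equivalent).  ``qrrm_degeneracy=True``
    additionally multiplies each protein's weight by the number of ways to
    choose its k engaged qRRMs out of max_qrrm, C(max_qrrm, k); under that
    convention the doubly-backfolded state 2^22 dominates over 2^31 at the
    fitted energies (see docs/methods.md for the convention audit).
    ``contiguous=False`` lets a protein's contacts occupy any subset of
    G-runs instead of a contiguous block.
    """

    g_rG4: float = 23.0
    g_bind: float = 9.2
    g_backfold: float = 0.8
    g_rG4_bind: Optional[float] = None
    temperature: float = 298.0
    n_sites: int = 4
    max_qrrm: int = 3
    c0: float = 1.0
    qrrm_degeneracy: bool = False
    contiguous: bool = True

    def __post_init__(self) -> None:
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        if self.max_qrrm < 1:
            raise ValueError("max_qrrm must be >= 1")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.c0 <= 0:
            raise ValueError("c0 must be positive")

    @property
    def rt(self) -> float:
        return GAS_CONSTANT_KCAL * self.temperature


@dataclass(frozen=True)
class BindingState:
    """One binding mode: m proteins contacting (k_1 >= k_2 >= ...) G-runs.

    The label follows the m^{k1 k2 ...} notation, e.g. "2^31" = two proteins
    binding with 3 and 1 qRRMs.  ``multiplicity`` counts distinct site
    arrangements on the linear G-run array; ``folded`` marks the folded-RNA
    states ("F" unbound, "1^F" helper).
    """

    label: str
    contacts: Tuple[int, ...]
    multiplicity: int
    folded: bool = False

    @property
    def n_proteins(self) -> int:
        return 0 if self.folded and not self.contacts else len(self.contacts)

    @property
    def n_backfolds(self) -> int:
        return sum(k - 1 for k in self.contacts)


def _placements(n_sites: int, max_block: int, contiguous: bool) -> Dict[Tuple[int, ...], int]:
    """Count ordered placements of unlabeled proteins, keyed by contact multiset."""
    counts: Dict[Tuple[int, ...], int] = {}
    if contiguous:
        blocks = [(i, k) for k in range(1, max_block + 1)
                  for i in range(n_sites - k + 1)]

        def rec(next_start: int, sizes: Tuple[int, ...]) -> None:
            counts[tuple(sorted(sizes, reverse=True))] = counts.get(
                tuple(sorted(sizes, reverse=True)), 0) + 1
            for i, k in blocks:
                if i >= next_start:
                    rec(i + k, sizes + (k,))

        rec(0, ())
    else:
        # contacts may occupy arbitrary site subsets; enumerate partitions of
        # every subset of sites into parts of size <= max_block
        from itertools import combinations

        def partitions(sites: Tuple[int, ...]):
            if not sites:
                yield ()
                return
            first, rest = sites[0], sites[1:]
            for k in range(0, min(max_block - 1, len(rest)) + 1):
                for mates in combinations(rest, k):
                    remaining = tuple(s for s in rest if s not in mates)
                    for tail in partitions(remaining):
                        yield ((first,) + mates,) + tail

        all_sites = tuple(range(n_sites))
        for r in range(0, n_sites + 1):
            for subset in combinations(all_sites, r):
                for part in partitions(subset):
                    key = tuple(sorted((len(p) for p in part), reverse=True))
                    counts[key] = counts.get(key, 0) + 1
    return counts


def _label(contacts: Tuple[int, ...]) -> str:
    if not contacts:
        return "0"
    return f"{len(contacts)}^" + "".join(str(k) for k in contacts)


def enumerate_states(params: EnergyParams) -> List[BindingState]:
    """All binding modes of the model, including folded-RNA states.

    Unfolded states cover every assignment of 0..n_sites G-runs to proteins,
    each protein occupying 1..max_qrrm sites (contiguous by default).  The
    folded-unbound state "F" is always present; the helper state "1^F" only
    when ``g_rG4_bind`` is set.
    """
    states = [
        BindingState(_label(contacts), contacts, mult)
        for contacts, mult in sorted(_placements(
            params.n_sites, min(params.max_qrrm, params.n_sites),
            params.contiguous).items())
    ]
    states.append(BindingState("F", (), 1, folded=True))
    if params.g_rG4_bind is not None:
        states.append(BindingState("1^F", (1,), 1, folded=True))
    return states


def state_log_weights(params: EnergyParams, c) -> Dict[str, np.ndarray]:
    """Log statistical weight of every state at concentration(s) ``c`` (mol/l)."""
    c = np.asarray(c, dtype=float)
    if np.any(c < 0):
        raise ValueError("concentration must be non-negative")
    with np.errstate(divide="ignore"):
        logx = np.log(c / params.c0)
    rt = params.rt
    out: Dict[str, np.ndarray] = {}
    for st in enumerate_states(params):
        if st.folded:
            if st.contacts:  # helper 1^F
                lw = logx + (params.g_rG4 + params.g_rG4_bind) / rt
            else:
                lw = np.full_like(c, params.g_rG4 / rt)
        else:
            m = st.n_proteins
            energy = sum(st.contacts) * params.g_bind - st.n_backfolds * params.g_backfold
            log_mult = math.log(st.multiplicity)
            if params.qrrm_degeneracy:
                for k in st.contacts:
                    log_mult += math.log(math.comb(params.max_qrrm, k))
            lw = log_mult + m * logx + energy / rt
            if m == 0:
                lw = np.zeros_like(c)
        out[st.label] = np.broadcast_to(lw, c.shape).astype(float)
    return out


def _bound_unbound_logs(weights: Dict[str, np.ndarray]):
    bound = [lw for lbl, lw in weights.items() if lbl not in ("0", "F")]
    unbound = [weights["0"], weights["F"]]
    return (logsumexp(np.stack(bound), axis=0),
            logsumexp(np.stack(unbound), axis=0))


def bound_fraction(params: EnergyParams, c) -> np.ndarray:
    """Fraction of RNA bound by at least one protein at concentration ``c``.

    The helper state 1^F counts as bound.  Accumulated in log space, so very
    large energies do not overflow.
    """
    scalar = np.isscalar(c)
    weights = state_log_weights(params, np.atleast_1d(np.asarray(c, dtype=float)))
    lb, lu = _bound_unbound_logs(weights)
    frac = 1.0 / (1.0 + np.exp(lu - lb))
    return float(frac[0]) if scalar else frac


def state_probabilities(params: EnergyParams, c) -> Dict[str, np.ndarray]:
    """Equilibrium probability of every binding mode at concentration ``c``."""
    scalar = np.isscalar(c)
    weights = state_log_weights(params, np.atleast_1d(np.asarray(c, dtype=float)))
    lz = logsumexp(np.stack(list(weights.values())), axis=0)
    probs = {lbl: np.exp(lw - lz) for lbl, lw in weights.items()}
    if scalar:
        probs = {lbl: float(p[0]) for lbl, p in probs.items()}
    return probs


_GUARD = (1e-30, 1e10)  # concentration bracket for the half-saturation search


def transition_concentration(params: EnergyParams,
                             _fraction_fn=None) -> float:
    """Concentration K (mol/l) at which the bound fraction crosses 1/2."""
    fn = _fraction_fn or bound_fraction

    def g(log10c: float) -> float:
        return fn(params, 10.0 ** log10c) - 0.5

    lo, hi = math.log10(_GUARD[0]), math.log10(_GUARD[1])
    if g(lo) > 0 or g(hi) < 0:
        raise ValueError("bound fraction does not cross 1/2 inside the guard "
                         f"interval {_GUARD}")
    return 10.0 ** brentq(g, lo, hi, xtol=1e-10, rtol=8.9e-16)


def model_hill(params: EnergyParams, decades: float = 6.0,
               n_points: int = 121, _fraction_fn=None) -> float:
    """EC10/EC90 Hill coefficient of the model's binding curve.

    Evaluated on a log-spaced concentration grid of ``decades`` decades
    centered on the transition concentration.
    """
    from .dose_response import hill_coefficient_ec

    fn = _fraction_fn or bound_fraction
    k = transition_concentration(params, _fraction_fn=fn)
    grid = np.logspace(math.log10(k) - decades / 2,
                       math.log10(k) + decades / 2, n_points)
    return hill_coefficient_ec(grid, fn(params, grid))


def binding_energy_from_kd(kd: float, temperature: float = 298.0,
                           c0: float = 1.0) -> float:
    """Per-contact binding energy from a molecular dissociation constant.

    g_bind = -RT ln(K_d / c0); K_d = 0.2e-6 mol/l at 298 K gives 9.2 kcal/mol.
    """
    if kd <= 0:
        raise ValueError("kd must be positive")
    return -GAS_CONSTANT_KCAL * temperature * math.log(kd / c0)


def invert_backfold_penalty(g_rG4: float, g_bind: float, k_target: float,
                            params: Optional[EnergyParams] = None,
                            bracket: Tuple[float, float] = (-10.0, 20.0),
                            rtol: float = 1e-6) -> float:
    """Backfolding penalty at which the transition concentration equals ``k_target``.

    Root-found by bisection over ``bracket`` (kcal/mol); the transition
    concentration is monotone non-decreasing in the penalty.  On failure the
    error carries a diagnostic scan of K over the bracket.
    """
    base = params or EnergyParams()
    base = replace(base, g_rG4=g_rG4, g_bind=g_bind, g_rG4_bind=None)

    def g(p: float) -> float:
        return math.log(transition_concentration(replace(base, g_backfold=p))
                        / k_target)

    lo, hi = bracket
    glo, ghi = g(lo), g(hi)
    if glo * ghi > 0:
        scan = {p: transition_concentration(replace(base, g_backfold=p))
                for p in np.linspace(lo, hi, 7)}
        raise ValueError(
            f"no backfold penalty in {bracket} gives K = {k_target:g} mol/l; "
            f"K over the bracket: {scan}")
    return brentq(g, lo, hi, rtol=rtol, xtol=1e-12)


#: contact multisets of the two dominant double-backfolding states
_REDUCED_CONTACTS = {(3, 1), (2, 2)}


def reduced_double_backfold(params: EnergyParams, c) -> np.ndarray:
    """Bound fraction of the reduced model keeping only states 2^31 and 2^22.

    The two double-backfolding modes fill all four G-runs with two proteins;
    together with the unbound and folded states they reproduce the full
    four-site model closely for backfolding penalties below ~7 kcal/mol.
    """
    if params.n_sites != 4 or params.max_qrrm < 3:
        raise ValueError("reduced model is defined for n_sites=4, max_qrrm>=3")
    scalar = np.isscalar(c)
    weights = state_log_weights(replace(params, g_rG4_bind=None),
                                np.atleast_1d(np.asarray(c, dtype=float)))
    keep_bound = [lw for lbl, lw in weights.items()
                  if lbl in (_label(k) for k in _REDUCED_CONTACTS)]
    lb = logsumexp(np.stack(keep_bound), axis=0)
    lu = logsumexp(np.stack([weights["0"], weights["F"]]), axis=0)
    frac = 1.0 / (1.0 + np.exp(lu - lb))
    return float(frac[0]) if scalar else frac


def reduced_hill(params: EnergyParams, **kw) -> float:
    """EC10/EC90 Hill coefficient of the reduced double-backfolding model."""
    def fn(p, c):
        return reduced_double_backfold(p, c)

    return model_hill(params, _fraction_fn=fn, **kw)


def helper_state_effect(params: EnergyParams,
                        g_rG4_bind_grid: Sequence[float]) -> List[Tuple[float, float]]:
    """Hill coefficient with the folded-rG4 helper state 1^F across energies.

    Weak helper binding (g_rG4_bind well below g_bind) leaves the Hill
    coefficient unchanged; once binding to the folded rG4 becomes comparable
    to binding the unfolded G-runs it dominates and cooperativity collapses
    toward n_H = 1.
    """
    out = []
    for g in g_rG4_bind_grid:
        out.append((float(g), model_hill(replace(params, g_rG4_bind=float(g)))))
    return out
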