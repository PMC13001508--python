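"""Partition-function model: enumeration oracle, limits, inversions."""

import math
from dataclasses import replace
from itertools import combinations

import numpy as np
import pytest

from g4coop.equilibrium_binding import (
    EnergyParams,
    binding_energy_from_kd,
    bound_fraction,
    enumerate_states,
    helper_state_effect,
    invert_backfold_penalty,
    model_hill,
    reduced_double_backfold,
    reduced_hill,
    state_probabilities,
    transition_concentration,
)

from tests_oracles import brute_force_bound_fraction

RT = 1.987e-3 * 298.0


@pytest.mark.parametrize("n_sites,max_qrrm", [(1, 1), (2, 2), (3, 3), (4, 3), (4, 1)])
@pytest.mark.parametrize("g_backfold", [0.0, 0.8, 3.0])
def test_partition_function_matches_brute_force(n_sites, max_qrrm, g_backfold):
    """Enumerated partition sum equals the explicit configuration sum."""
    params = EnergyParams(g_rG4=8.0, g_bind=5.0, g_backfold=g_backfold,
                          n_sites=n_sites, max_qrrm=max_qrrm)
    for c in np.logspace(-8, 0, 9):
        assert bound_fraction(params, c) == pytest.approx(
            brute_force_bound_fraction(params, c), rel=1e-12)


def test_brute_force_with_helper_state():
    params = EnergyParams(g_rG4=8.0, g_bind=5.0, g_backfold=0.5, g_rG4_bind=3.0)
    for c in np.logspace(-7, -1, 7):
        assert bound_fraction(params, c) == pytest.approx(
            brute_force_bound_fraction(params, c), rel=1e-12)


# ---------------------------------------------------------------------------
# state enumeration


def test_enumeration_contains_named_double_backfold_modes():
    """The 4-site model contains 2^22 (one arrangement) and 2^31 (two)."""
    states = {s.label: s for s in enumerate_states(EnergyParams())}
    assert states["2^22"].multiplicity == 1
    assert states["2^31"].multiplicity == 2
    assert states["2^31"].n_backfolds == 2 and states["2^22"].n_backfolds == 2


def test_enumeration_single_site():
    labels = {s.label for s in enumerate_states(
        EnergyParams(n_sites=1, max_qrrm=1))}
    assert labels == {"0", "1^1", "F"}


def test_no_backfolding_restriction_yields_single_contact_states():
    states = enumerate_states(EnergyParams(max_qrrm=1))
    assert all(set(s.contacts) <= {1} for s in states if not s.folded)
    assert max(s.n_proteins for s in states) == 4


def test_helper_state_present_only_when_configured():
    base = {s.label for s in enumerate_states(EnergyParams())}
    with_helper = {s.label for s in enumerate_states(
        EnergyParams(g_rG4_bind=4.0))}
    assert "1^F" not in base and "1^F" in with_helper


# ---------------------------------------------------------------------------
# bound fraction and derived quantities


def test_probabilities_sum_to_one_and_fraction_monotone():
    params = EnergyParams()
    grid = np.logspace(-9, -2, 40)
    probs = state_probabilities(params, grid)
    total = np.sum(np.stack(list(probs.values())), axis=0)
    assert np.allclose(total, 1.0, atol=1e-12)
    frac = bound_fraction(params, grid)
    assert np.all((frac >= 0) & (frac <= 1))
    assert np.all(np.diff(frac) >= -1e-12)
    assert frac[0] < 1e-3 and frac[-1] > 0.999


def test_single_site_equals_langmuir_isotherm():
    """n_sites = 1 reduces exactly to c / (c + K_d)."""
    params = EnergyParams(g_rG4=-50.0, g_bind=9.2, g_backfold=0.0,
                          n_sites=1, max_qrrm=1)
    kd = math.exp(-9.2 / RT)
    c = np.logspace(-10, -3, 60)
    assert np.abs(bound_fraction(params, c) - c / (c + kd)).max() <= 1e-12
    assert transition_concentration(params) == pytest.approx(kd, rel=1e-9)


def test_dominant_states_at_fitted_energies():
    """At the fitted energies the double-backfolding states carry the bound
    ensemble; under the qRRM-combination degeneracy convention 2^22 dominates
    over 2^31 (with bare placement multiplicities their order flips)."""
    params = EnergyParams(g_rG4=23.0, g_bind=9.2, g_backfold=0.8,
                          qrrm_degeneracy=True)
    probs = state_probabilities(params, transition_concentration(params))
    bound = {lbl: p for lbl, p in probs.items() if lbl not in ("0", "F")}
    ranked = sorted(bound, key=bound.get, reverse=True)
    assert ranked[:2] == ["2^22", "2^31"]
    bare = EnergyParams(g_rG4=23.0, g_bind=9.2, g_backfold=0.8)
    probs_bare = state_probabilities(bare, transition_concentration(bare))
    top2 = sorted((p for lbl, p in probs_bare.items() if lbl not in ("0", "F")),
                  reverse=True)[:2]
    assert sum(top2) == pytest.approx(
        sum(p for lbl, p in probs_bare.items() if lbl not in ("0", "F")),
        abs=0.01)  # the two double-backfolding modes carry ~all bound weight


def test_transition_monotone_in_backfold_penalty():
    ks = [transition_concentration(EnergyParams(g_rG4=23.0, g_bind=9.2,
                                                g_backfold=p))
          for p in (0.0, 1.0, 3.0, 6.0)]
    assert all(a <= b * (1 + 1e-12) for a, b in zip(ks, ks[1:]))


def test_binding_energy_from_kd():
    assert binding_energy_from_kd(0.2e-6) == pytest.approx(9.2, abs=0.1)
    assert binding_energy_from_kd(1.0) == 0.0
    assert binding_energy_from_kd(math.exp(-1.0)) == pytest.approx(RT, rel=1e-12)


def test_invert_backfold_penalty_round_trip():
    params = EnergyParams(g_rG4=23.0, g_bind=9.2, g_backfold=1.7)
    k = transition_concentration(params)
    assert invert_backfold_penalty(23.0, 9.2, k) == pytest.approx(1.7, abs=1e-5)


def test_invert_backfold_penalty_monotone_in_target():
    p_small = invert_backfold_penalty(23.0, 9.2, 1e-6)
    p_large = invert_backfold_penalty(23.0, 9.2, 1e-4)
    assert p_large > p_small


def test_invert_backfold_penalty_no_root_is_diagnosed():
    with pytest.raises(ValueError, match="no backfold penalty"):
        invert_backfold_penalty(5.0, 2.0, 1e-20, bracket=(0.0, 1.0))


def test_reduced_model_close_to_full_at_zero_penalty():
    """With no penalty the two double-backfolding states carry the model."""
    params = EnergyParams(g_rG4=23.0, g_bind=9.2, g_backfold=0.0)
    c = np.logspace(-10, 0, 300)
    diff = np.abs(reduced_double_backfold(params, c) - bound_fraction(params, c))
    assert diff.max() < 0.05


def test_reduced_model_loses_validity_at_high_penalty():
    """g_backfold >> 7: full model's n_H rises toward 4, reduced stays at 2."""
    params = EnergyParams(g_rG4=23.0, g_bind=9.2, g_backfold=12.0)
    assert model_hill(params) > 3.5
    assert reduced_hill(params) == pytest.approx(2.0, abs=0.1)


def test_reduced_model_saturates():
    params = EnergyParams(g_rG4=23.0, g_bind=9.2, g_backfold=0.8)
    assert reduced_double_backfold(params, 1e6) > 0.9999


def test_helper_state_effect_thresholds():
    """Weak helper binding leaves n_H unchanged; strong binding destroys it."""
    base = EnergyParams(g_rG4=23.0, g_bind=9.2, g_backfold=0.8)
    n_base = model_hill(base)
    table = dict(helper_state_effect(base, [0.0, 3.9, 9.2]))
    assert abs(table[0.0] - n_base) < 0.1
    assert abs(table[3.9] - n_base) < 0.1
    assert table[9.2] < 1.2  # comparable binding to folded rG4: cooperativity lost


def test_helper_weight_vanishes_at_very_negative_energy():
    base = EnergyParams(g_rG4=23.0, g_bind=9.2, g_backfold=0.8)
    with_helper = replace(base, g_rG4_bind=-200.0)
    c = np.logspace(-8, -3, 30)
    assert np.allclose(bound_fraction(base, c), bound_fraction(with_helper, c),
                       rtol=1e-12)


def test_negative_concentration_rejected():
    with pytest.raises(ValueError):
        bound_fraction(EnergyParams(), -1e-6)
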