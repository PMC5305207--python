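"""Unit and property tests for the equilibrium-thermodynamics core."""

import math

import pytest
from hypothesis import assume, given
from hypothesis import strategies as st

from revpot import (
    ElectroneutralCycleError,
    GradientSet,
    MissingSpeciesError,
    SpeciesTerm,
    TransportCycle,
    cycle_free_energy,
    equilibrium_substrate_ratio,
    flux_direction,
    nernst_potential,
    net_charge_per_cycle,
    reversal_potential,
    reversal_potential_divalent_substrate,
    reversal_potential_neutral_substrate,
    static_head_ion_gradient,
)
from revpot.scenarios import eaat3_cycle, vcindy_cycle, vcindy_screen_gradients


# ---------------------------------------------------------------- strategies

ratios = st.floats(min_value=1e-3, max_value=1e3, allow_nan=False)
stoichs = st.integers(min_value=-3, max_value=3).filter(lambda v: v != 0)
valences = st.integers(min_value=-2, max_value=2)


@st.composite
def random_cycles(draw):
    n_ions = draw(st.integers(min_value=1, max_value=3))
    terms = [
        SpeciesTerm(f"ion{i}", valence=draw(valences.filter(lambda z: z != 0)),
                    stoichiometry=draw(stoichs), role="coupling_ion")
        for i in range(n_ions)
    ]
    terms.append(
        SpeciesTerm("sub", valence=draw(valences), stoichiometry=draw(stoichs),
                    role="substrate")
    )
    return TransportCycle(terms=tuple(terms))


@st.composite
def cycle_and_gradients(draw):
    cycle = draw(random_cycles())
    grads = GradientSet.from_ratios(
        {name: draw(ratios) for name in cycle.species_names}
    )
    return cycle, grads


# ----------------------------------------------------------------- net charge

def test_net_charge_examples(vcindy_cycle):
    assert net_charge_per_cycle(vcindy_cycle) == 1
    assert net_charge_per_cycle(eaat3_cycle()) == 2


def test_neutral_substrate_cycle_net_charge_comes_from_sodium():
    cyc = TransportCycle.sodium_coupled(1, 1, substrate_valence=0, substrate_name="G")
    assert net_charge_per_cycle(cyc) == 1


def test_electroneutral_two_to_one_cycle():
    cyc = TransportCycle.sodium_coupled(2, 1, substrate_valence=-2)
    assert net_charge_per_cycle(cyc) == 0
    assert not cyc.is_electrogenic


# ----------------------------------------------------------- cycle free energy

def test_free_energy_zero_without_gradients_or_voltage(vcindy_cycle):
    grads = GradientSet.from_ratios({"Na+": 1.0, "succinate": 1.0})
    assert cycle_free_energy(vcindy_cycle, grads, 0.0) == pytest.approx(0.0)


def test_free_energy_vanishes_at_reversal_potential(vcindy_cycle, screen_gradients):
    e = reversal_potential(vcindy_cycle, screen_gradients)
    assert cycle_free_energy(vcindy_cycle, screen_gradients, e) == pytest.approx(0.0, abs=1e-9)


def test_free_energy_positive_above_reversal(vcindy_cycle, screen_gradients):
    g = cycle_free_energy(vcindy_cycle, screen_gradients, 84.0)
    assert g == pytest.approx(84.0 - 48.37, abs=0.01)


def test_free_energy_missing_species_names_it(vcindy_cycle):
    grads = GradientSet.from_ratios({"Na+": 0.25})
    with pytest.raises(MissingSpeciesError, match="succinate"):
        cycle_free_energy(vcindy_cycle, grads, 0.0)


# --------------------------------------------------------- reversal potential

def test_screening_gradients_reverse_at_48_mV(vcindy_cycle, screen_gradients):
    e = reversal_potential(vcindy_cycle, screen_gradients)
    assert e == pytest.approx(48.37, abs=0.01)
    assert round(e) == 48


def test_no_gradients_means_zero_reversal(vcindy_cycle):
    grads = GradientSet.from_ratios({"Na+": 1.0, "succinate": 1.0})
    assert reversal_potential(vcindy_cycle, grads) == pytest.approx(0.0)


def test_neutral_substrate_chemical_terms_can_cancel():
    cyc = TransportCycle.sodium_coupled(1, 1, substrate_valence=0, substrate_name="G")
    grads = GradientSet.from_ratios({"Na+": 0.1, "G": 10.0})
    assert reversal_potential(cyc, grads) == pytest.approx(0.0, abs=1e-12)


def test_electroneutral_cycle_raises(vcindy_cycle):
    cyc = TransportCycle.sodium_coupled(2, 1, substrate_valence=-2)
    grads = GradientSet.from_ratios({"Na+": 0.25, "S": 10.0})
    with pytest.raises(ElectroneutralCycleError):
        reversal_potential(cyc, grads)


@pytest.mark.parametrize(
    "n, m, na_ratio, s_ratio, expected",
    [
        (3, 1, 0.25, 10.0, 48.37),
        (1, 1, 1.0, 1.0, 0.0),
        (1, 1, 4.0, 0.1, -23.88),
    ],
)
def test_divalent_substrate_closed_form(n, m, na_ratio, s_ratio, expected):
    assert reversal_potential_divalent_substrate(n, m, na_ratio, s_ratio) == pytest.approx(expected, abs=0.01)


def test_divalent_substrate_electroneutral_raises():
    with pytest.raises(ElectroneutralCycleError):
        reversal_potential_divalent_substrate(2, 1, 0.25, 10.0)


@pytest.mark.parametrize(
    "n, m, na_ratio, g_ratio, expected",
    [
        (1, 1, 1.0, 1.0, 0.0),
        (1, 1, 0.1, 10.0, 0.0),
        (2, 1, 1.0, 100.0, -60.0),
    ],
)
def test_neutral_substrate_closed_form(n, m, na_ratio, g_ratio, expected):
    assert reversal_potential_neutral_substrate(n, m, na_ratio, g_ratio) == pytest.approx(
        expected, abs=1e-9
    )


# ------------------------------------------------------------ Nernst potential

@pytest.mark.parametrize(
    "valence, ratio, expected",
    [(1, 1.0, 0.0), (1, 0.1, 60.0), (2, 10.0, -30.0), (-1, 10.0, 60.0)],
)
def test_nernst_closed_form(valence, ratio, expected):
    assert nernst_potential(valence, ratio) == pytest.approx(expected)


def test_nernst_neutral_species_raises():
    with pytest.raises(ValueError):
        nernst_potential(0, 1.0)


# -------------------------------------------------- equilibrium substrate ratio

def test_equilibrium_ratio_trivial(vcindy_cycle):
    grads = GradientSet.from_ratios({"Na+": 1.0})
    assert equilibrium_substrate_ratio(vcindy_cycle, grads, 0.0) == pytest.approx(1.0)


def test_triple_coupling_cubes_the_ion_gradient(vcindy_cycle):
    """A 1:1000 inward Na+ gradient lets a 3:1 cycle accumulate substrate
    1000^3-fold at zero voltage; conversely a 10-fold accumulation only
    needs a 10^(1/3)-fold inward ion gradient (exponent m/n, not n/m)."""
    grads = GradientSet.from_ratios({"Na+": 0.001})
    assert equilibrium_substrate_ratio(vcindy_cycle, grads, 0.0) == pytest.approx(1e9)
    grads2 = GradientSet.from_ratios({"Na+": 10.0 ** (-1.0 / 3.0)})
    assert equilibrium_substrate_ratio(vcindy_cycle, grads2, 0.0) == pytest.approx(10.0)


def test_equilibrium_ratio_with_voltage():
    cyc = TransportCycle.sodium_coupled(3, 1, substrate_valence=-1, substrate_name="A-")
    grads = GradientSet.from_ratios({"Na+": 0.1})
    assert equilibrium_substrate_ratio(cyc, grads, -60.0) == pytest.approx(1e5, rel=1e-9)


def test_glutamate_transporter_accumulates_millionfold():
    """Multi-ion coupling at physiological gradients concentrates glutamate
    by more than a million-fold."""
    from revpot.scenarios import mammalian_ion_gradients

    ratio = equilibrium_substrate_ratio(eaat3_cycle(), mammalian_ion_gradients(), -70.0)
    assert 1e6 < ratio < 1e7


# ------------------------------------------------------------------ static head

@pytest.mark.parametrize(
    "n_over_m, s_ratio, expected",
    [(3, 10.0, 1e-3), (1, 1.0, 1.0), (2, 5.0, 0.04)],
)
def test_static_head_closed_form(n_over_m, s_ratio, expected):
    assert static_head_ion_gradient(n_over_m, s_ratio) == pytest.approx(expected)


# --------------------------------------------------------------- flux direction

@pytest.mark.parametrize(
    "voltage, expected",
    [(12.0, "influx"), (48.37079843903322, "equilibrium"), (84.0, "efflux")],
)
def test_flux_direction_bracket(vcindy_cycle, screen_gradients, voltage, expected):
    assert flux_direction(vcindy_cycle, screen_gradients, voltage) == expected


# -------------------------------------------------------------------- properties

@given(cycle_and_gradients())
def test_free_energy_is_zero_at_reversal_potential(cg):
    """Oracle property: E_rev is by definition the root of the per-cycle
    free energy."""
    cycle, grads = cg
    assume(cycle.is_electrogenic)
    e = reversal_potential(cycle, grads)
    assert abs(cycle_free_energy(cycle, grads, e)) < 1e-9


@given(st.integers(1, 4), st.integers(1, 3), ratios, ratios)
def test_general_formula_reduces_to_divalent_closed_form(n, m, na_ratio, s_ratio):
    assume(abs(n / m - 2) > 1e-9)
    cyc = TransportCycle.sodium_coupled(n, m, substrate_valence=-2)
    grads = GradientSet.from_ratios({"Na+": na_ratio, "S": s_ratio})
    assert reversal_potential(cyc, grads) == pytest.approx(
        reversal_potential_divalent_substrate(n, m, na_ratio, s_ratio), rel=1e-12, abs=1e-9
    )


@given(st.integers(1, 4), st.integers(1, 3), ratios, ratios)
def test_general_formula_reduces_to_neutral_substrate_form(n, m, na_ratio, g_ratio):
    cyc = TransportCycle.sodium_coupled(n, m, substrate_valence=0, substrate_name="G")
    grads = GradientSet.from_ratios({"Na+": na_ratio, "G": g_ratio})
    assert reversal_potential(cyc, grads) == pytest.approx(
        reversal_potential_neutral_substrate(n, m, na_ratio, g_ratio),
        rel=1e-12, abs=1e-9,
    )


@given(cycle_and_gradients())
def test_swapping_sides_negates_reversal_potential(cg):
    cycle, grads = cg
    assume(cycle.is_electrogenic)
    e = reversal_potential(cycle, grads)
    assert reversal_potential(cycle, grads.flipped()) == pytest.approx(-e, abs=1e-9)


@given(cycle_and_gradients(), st.floats(1e-3, 1e3))
def test_scaling_one_species_on_both_sides_changes_nothing(cg, factor):
    cycle, grads = cg
    assume(cycle.is_electrogenic)
    e = reversal_potential(cycle, grads)
    scaled = grads.scaled(cycle.terms[0].name, factor)
    assert reversal_potential(cycle, scaled) == pytest.approx(e, abs=1e-9)


@given(cycle_and_gradients(), st.floats(-200, 200))
def test_flux_ordering_around_reversal_potential(cg, offset):
    """For a positively charged cycle, voltages below E_rev drive influx and
    voltages above drive efflux (and mirrored for negative net charge)."""
    cycle, grads = cg
    assume(cycle.is_electrogenic)
    assume(abs(offset) > 1e-3)
    e = reversal_potential(cycle, grads)
    direction = flux_direction(cycle, grads, e + offset)
    if cycle.net_charge > 0:
        assert direction == ("efflux" if offset > 0 else "influx")
    else:
        assert direction == ("influx" if offset > 0 else "efflux")


@given(st.integers(1, 3), ratios, ratios)
def test_electroneutral_candidates_always_raise(m, na_ratio, s_ratio):
    with pytest.raises(ElectroneutralCycleError):
        reversal_potential_divalent_substrate(2 * m, m, na_ratio, s_ratio)


# ------------------------------------------------------------------- validation

def test_species_term_rejects_zero_stoichiometry():
    with pytest.raises(ValueError):
        SpeciesTerm("Na+", valence=1, stoichiometry=0)


def test_gradient_set_rejects_nonpositive_concentrations():
    with pytest.raises(ValueError):
        GradientSet({"Na+": (0.0, 1.0)})


def test_cycle_requires_substrate_and_ion():
    with pytest.raises(ValueError):
        TransportCycle(terms=(SpeciesTerm("Na+", 1, 1, role="coupling_ion"),))
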