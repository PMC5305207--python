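"""Equilibrium thermodynamics of ion-coupled membrane transport.

A secondary active transporter couples the downhill movement of one or more
ions to the uphill movement of its substrate with a fixed stoichiometry.  If
the net charge moved per transport cycle is nonzero the cycle is
*electrogenic* and there exists a unique membrane voltage -- the reversal
(equilibrium) potential ``E_rev`` -- at which the electrical driving force
exactly balances the chemical gradients and no net flux occurs.  For a cycle
with species terms :math:`(\\nu_i, z_i)` (signed stoichiometry and valence)
and in/out concentration ratios :math:`r_i = c_{in,i}/c_{out,i}`,

.. math::

    E_{rev} = -\\frac{s}{Q} \\sum_i \\nu_i \\log_{10} r_i,
    \\qquad Q = \\sum_i \\nu_i z_i,

with ``s`` the Nernst slope in mV per decade (60 mV by convention here) and
``Q`` the net charge per cycle.  For the canonical sodium-coupled symporter
moving ``n`` Na⁺ with ``m`` divalent anionic substrate molecules this reduces
to ``E_rev = -60/(n/m - 2) * ((n/m) log10 r_Na + log10 r_S)``; an ``n/m``
ratio of 2 makes the cycle electroneutral and the voltage undefined.

Sign convention: the membrane potential is ``dPsi = Psi_in - Psi_out`` with
the outside taken as ground.  An "inwardly directed" gradient means a higher
concentration outside (``r < 1``).  Ideal solutions are assumed throughout
(activities equal concentrations).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping

__all__ = [
    "SLOPE_MV_PER_DECADE",
    "EQUILIBRIUM_TOLERANCE_MV",
    "ElectroneutralCycleError",
    "MissingSpeciesError",
    "SpeciesTerm",
    "TransportCycle",
    "GradientSet",
    "net_charge_per_cycle",
    "cycle_free_energy",
    "reversal_potential",
    "reversal_potential_divalent_substrate",
    "reversal_potential_neutral_substrate",
    "nernst_potential",
    "equilibrium_substrate_ratio",
    "static_head_ion_gradient",
    "flux_direction",
]

#: Nernst slope RT*ln(10)/F, rounded to the conventional 60 mV/decade.
#: All voltages in this package are on this scale; temperature is not a
#: parameter.
SLOPE_MV_PER_DECADE: float = 60.0

#: |G| below this (mV-equivalents) counts as equilibrium in flux_direction.
EQUILIBRIUM_TOLERANCE_MV: float = 1e-6

Role = Literal["coupling_ion", "substrate"]
FluxDirection = Literal["influx", "efflux", "equilibrium"]


class ElectroneutralCycleError(ValueError):
    """Raised when a reversal potential is requested for a cycle with zero
    net charge per cycle (e.g. n/m = 2 for a divalent substrate): the
    equilibrium voltage is undefined because voltage does no net work on an
    electroneutral cycle."""


class MissingSpeciesError(KeyError):
    """A cycle species has no concentration entry in the gradient set."""

    def __init__(self, name: str):
        super().__init__(name)
        self.name = name

    def __str__(self) -> str:  # KeyError would show the repr only
        return f"no concentrations given for species {self.name!r}"


@dataclass(frozen=True)
class SpeciesTerm:
    """One chemical species participating in a transport cycle.

    Parameters
    ----------
    name : str
        Species label, unique within a cycle (e.g. ``"Na+"``, ``"succinate"``).
    valence : int
        Integer charge ``z`` (0 is allowed for a neutral substrate such as
        galactose).
    stoichiometry : float
        Signed copies moved per cycle, ``nu``.  Positive terms move in the
        same direction as the substrate (cotransport); negative terms are
        counter-transported (antiport).
    role : {"coupling_ion", "substrate"}
    """

    name: str
    valence: int
    stoichiometry: float
    role: Role = "coupling_ion"

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("species name must be nonempty")
        if self.stoichiometry == 0:
            raise ValueError(f"stoichiometry of {self.name!r} must be nonzero")
        if self.valence != int(self.valence):
            raise ValueError(f"valence of {self.name!r} must be an integer")
        if self.role not in ("coupling_ion", "substrate"):
            raise ValueError(f"unknown role {self.role!r}")


@dataclass(frozen=True)
class TransportCycle:
    """A fixed-stoichiometry transport reaction.

    Holds the ordered species terms of one cycle, e.g. the sodium/succinate
    symporter ``3 Na+(out) + 1 succinate2-(out) <=> 3 Na+(in) + 1
    succinate2-(in)``.  The derived net charge per cycle ``Q = sum(nu_i z_i)``
    decides whether the cycle is electrogenic.
    """

    terms: tuple[SpeciesTerm, ...]
    label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "terms", tuple(self.terms))
        names = [t.name for t in self.terms]
        if len(set(names)) != len(names):
            raise ValueError("species names within a cycle must be unique")
        if not any(t.role == "substrate" for t in self.terms):
            raise ValueError("cycle needs at least one substrate term")
        if not any(t.role == "coupling_ion" for t in self.terms):
            raise ValueError("cycle needs at least one coupling-ion term")

    @property
    def net_charge(self) -> float:
        """Net charge moved inward per cycle, ``Q = sum(nu_i * z_i)``."""
        return float(sum(t.stoichiometry * t.valence for t in self.terms))

    @property
    def is_electrogenic(self) -> bool:
        return abs(self.net_charge) > 1e-12

    @property
    def species_names(self) -> tuple[str, ...]:
        return tuple(t.name for t in self.terms)

    @property
    def substrate_terms(self) -> tuple[SpeciesTerm, ...]:
        return tuple(t for t in self.terms if t.role == "substrate")

    @property
    def coupling_terms(self) -> tuple[SpeciesTerm, ...]:
        return tuple(t for t in self.terms if t.role == "coupling_ion")

    @classmethod
    def sodium_coupled(
        cls,
        n: float,
        m: float = 1,
        substrate_valence: int = -2,
        substrate_name: str = "S",
        label: str = "",
    ) -> "TransportCycle":
        """Build the canonical ``n Na+ : m substrate`` symport cycle."""
        return cls(
            terms=(
                SpeciesTerm("Na+", valence=1, stoichiometry=n, role="coupling_ion"),
                SpeciesTerm(
                    substrate_name,
                    valence=substrate_valence,
                    stoichiometry=m,
                    role="substrate",
                ),
            ),
            label=label or f"{n:g}:{m:g} Na+:{substrate_name}",
        )


@dataclass(frozen=True)
class GradientSet:
    """Inside/outside concentrations per species, in mol/L.

    ``concentrations`` maps species name to ``(c_in, c_out)``; both must be
    strictly positive.  Only ratios enter the thermodynamics, but absolute
    values matter downstream (tracer counts, vesicle occupancy), so they are
    stored as concentrations rather than ratios.
    """

    concentrations: Mapping[str, tuple[float, float]]

    def __post_init__(self) -> None:
        frozen = {}
        for name, pair in dict(self.concentrations).items():
            c_in, c_out = float(pair[0]), float(pair[1])
            if not (c_in > 0 and c_out > 0):
                raise ValueError(
                    f"concentrations of {name!r} must be strictly positive, "
                    f"got c_in={c_in!r}, c_out={c_out!r}"
                )
            frozen[name] = (c_in, c_out)
        object.__setattr__(self, "concentrations", frozen)

    @classmethod
    def from_ratios(cls, ratios: Mapping[str, float], c_out: float = 1.0) -> "GradientSet":
        """Gradient set with the given in/out ratios and unit outside
        concentration (useful when only ratios matter)."""
        return cls({name: (r * c_out, c_out) for name, r in ratios.items()})

    def __contains__(self, name: str) -> bool:
        return name in self.concentrations

    def inside(self, name: str) -> float:
        return self._pair(name)[0]

    def outside(self, name: str) -> float:
        return self._pair(name)[1]

    def ratio(self, name: str) -> float:
        """In/out concentration ratio ``r = c_in / c_out``."""
        c_in, c_out = self._pair(name)
        return c_in / c_out

    def _pair(self, name: str) -> tuple[float, float]:
        try:
            return self.concentrations[name]
        except KeyError:
            raise MissingSpeciesError(name) from None

    def flipped(self) -> "GradientSet":
        """Swap every inside with its outside concentration."""
        return GradientSet({k: (o, i) for k, (i, o) in self.concentrations.items()})

    def with_species(self, name: str, c_in: float, c_out: float) -> "GradientSet":
        merged = dict(self.concentrations)
        merged[name] = (c_in, c_out)
        return GradientSet(merged)

    def scaled(self, name: str, factor: float) -> "GradientSet":
        """Multiply both sides of one species by a positive factor."""
        if factor <= 0:
            raise ValueError("scale factor must be positive")
        c_in, c_out = self._pair(name)
        return self.with_species(name, c_in * factor, c_out * factor)


def net_charge_per_cycle(cycle: TransportCycle) -> float:
    """Net charge moved inward per transport cycle, ``Q = sum(nu_i z_i)``.

    ``Q = 0`` identifies an electroneutral cycle (no reversal potential).
    """
    return cycle.net_charge


def cycle_free_energy(
    cycle: TransportCycle,
    gradients: GradientSet,
    voltage_mv: float,
    slope: float = SLOPE_MV_PER_DECADE,
) -> float:
    """Free energy of one inward transport cycle, in mV-equivalents.

    ``G = slope * sum(nu_i log10 r_i) + Q * V``.  Negative G means the
    inward cycle is spontaneous (influx), positive means efflux, zero is
    equilibrium.  Dividing by ``slope`` recovers dimensionless
    ``dG/(RT ln 10)``.
    """
    chem = sum(t.stoichiometry * math.log10(gradients.ratio(t.name)) for t in cycle.terms)
    return slope * chem + cycle.net_charge * voltage_mv


def reversal_potential(cycle: TransportCycle, gradients: GradientSet) -> float:
    """Reversal potential of an electrogenic cycle, in mV.

    The unique voltage at which :func:`cycle_free_energy` vanishes:
    ``E_rev = -slope * sum(nu_i log10 r_i) / Q``.

    Raises
    ------
    ElectroneutralCycleError
        If the cycle's net charge per cycle is zero.
    MissingSpeciesError
        If a cycle species has no gradient entry.
    """
    q = cycle.net_charge
    if abs(q) < 1e-12:
        raise ElectroneutralCycleError(
            f"cycle {cycle.label or cycle.species_names} is electroneutral "
            "(net charge per cycle is zero); the reversal potential is undefined"
        )
    chem = sum(t.stoichiometry * math.log10(gradients.ratio(t.name)) for t in cycle.terms)
    return -SLOPE_MV_PER_DECADE * chem / q


def reversal_potential_divalent_substrate(
    n: float, m: float, na_ratio: float, s_ratio: float
) -> float:
    """Reversal potential of an ``n Na+ : m S^2-`` symporter, in mV.

    ``E_rev = -60/(n/m - 2) * ((n/m) log10 r_Na + log10 r_S)`` where the
    ratios are in/out.  Equivalent to :func:`reversal_potential` on the
    two-term cycle with ``z_S = -2``.

    Raises
    ------
    ElectroneutralCycleError
        If ``n/m == 2`` (the cycle moves no net charge).
    """
    if n <= 0 or m <= 0:
        raise ValueError("stoichiometries must be positive")
    if na_ratio <= 0 or s_ratio <= 0:
        raise ValueError("concentration ratios must be positive")
    ratio = n / m
    if abs(ratio - 2.0) < 1e-12:
        raise ElectroneutralCycleError(
            "n/m = 2 makes the cycle electroneutral; the reversal potential "
            "is undefined"
        )
    return (
        -SLOPE_MV_PER_DECADE
        / (ratio - 2.0)
        * (ratio * math.log10(na_ratio) + math.log10(s_ratio))
    )


def reversal_potential_neutral_substrate(
    n: float, m: float, na_ratio: float, g_ratio: float
) -> float:
    """Reversal potential of an ``n Na+ : m G`` symporter with a *neutral*
    substrate G (e.g. a sugar), in mV.

    ``E_rev = -60 * ((m/n) log10 r_G + log10 r_Na)``.  With ``z_G = 0`` all
    net charge comes from Na+, so the cycle is always electrogenic.
    """
    if n <= 0 or m <= 0:
        raise ValueError("stoichiometries must be positive")
    if na_ratio <= 0 or g_ratio <= 0:
        raise ValueError("concentration ratios must be positive")
    return -SLOPE_MV_PER_DECADE * ((m / n) * math.log10(g_ratio) + math.log10(na_ratio))


def nernst_potential(valence: int, ratio_in_out: float) -> float:
    """Nernst equilibrium potential for one permeant ion, in mV.

    ``E = -(slope / z) * log10(c_in / c_out)``, same sign convention as the
    membrane potential (inside minus outside).  This is the voltage a
    valinomycin/K+ "chemical patch clamp" imposes given a K+ gradient.
    """
    if valence == 0:
        raise ValueError("Nernst potential is undefined for a neutral species")
    if ratio_in_out <= 0:
        raise ValueError("concentration ratio must be positive")
    return -(SLOPE_MV_PER_DECADE / valence) * math.log10(ratio_in_out)


def equilibrium_substrate_ratio(
    cycle: TransportCycle,
    ion_gradients: GradientSet,
    voltage_mv: float,
    substrate_name: str | None = None,
) -> float:
    """Substrate in/out ratio at which the cycle is at equilibrium.

    Solves ``cycle_free_energy = 0`` for the substrate term with every other
    species ratio and the voltage held fixed:

    ``log10 r_S = (-Q V / slope - sum_ions nu_i log10 r_i) / nu_S``.

    This is the maximal accumulation (or the static-head condition when the
    result is evaluated at zero voltage).  For strongly coupled cycles the
    ratio can be astronomically large -- e.g. glutamate transporters
    concentrate their substrate more than a million-fold.
    """
    subs = cycle.substrate_terms
    if substrate_name is None:
        if len(subs) != 1:
            raise ValueError("substrate_name required when cycle has several substrates")
        sub = subs[0]
    else:
        matches = [t for t in cycle.terms if t.name == substrate_name]
        if not matches:
            raise MissingSpeciesError(substrate_name)
        sub = matches[0]
    if sub.stoichiometry == 0:  # unreachable given SpeciesTerm invariant
        raise ValueError("substrate stoichiometry must be nonzero")
    others = sum(
        t.stoichiometry * math.log10(ion_gradients.ratio(t.name))
        for t in cycle.terms
        if t.name != sub.name
    )
    log_r = (
        -cycle.net_charge * voltage_mv / SLOPE_MV_PER_DECADE - others
    ) / sub.stoichiometry
    return 10.0 ** log_r


def static_head_ion_gradient(n_over_m: float, substrate_ratio_in_out: float) -> float:
    """Conventional static-head design relation, ``(1 / r_S) ** (n/m)``.

    The power-law rule of thumb quoted for static-head experiments: for
    n/m = 3 it maps a 10:1 substrate gradient to a 1:1000 ion gradient,
    illustrating why balancing gradients at zero voltage is considered
    impractical for multi-ion transporters.  Note that the *exact*
    zero-flux condition (``sum nu_i log r_i = 0``) solves to the inverse
    exponent, ``r_ion = (1/r_S) ** (m/n)``; use
    :func:`equilibrium_substrate_ratio` for the thermodynamically exact
    balance.
    """
    if n_over_m <= 0 or substrate_ratio_in_out <= 0:
        raise ValueError("inputs must be positive")
    return (1.0 / substrate_ratio_in_out) ** n_over_m


def flux_direction(
    cycle: TransportCycle,
    gradients: GradientSet,
    voltage_mv: float,
    tolerance: float = EQUILIBRIUM_TOLERANCE_MV,
) -> FluxDirection:
    """Direction of net substrate flux at the given clamped voltage.

    Maps the sign of :func:`cycle_free_energy` to ``"influx"`` (negative),
    ``"efflux"`` (positive) or ``"equilibrium"`` (within ``tolerance``).
    Below the reversal potential a positively charged cycle runs inward;
    above it the voltage overpowers the chemical gradients and flux reverses.
    """
    g = cycle_free_energy(cycle, gradients, voltage_mv)
    if abs(g) < tolerance:
        return "equilibrium"
    return "influx" if g < 0 else "efflux"
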