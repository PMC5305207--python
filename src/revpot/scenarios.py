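"""Ready-made transport cycles and experiment scenarios.

These encode the two benchmark systems of the reversal-potential method:
VcINDY, the Vibrio cholerae Na+/succinate2- symporter (3:1), and vSGLT, the
V. parahaemolyticus Na+/galactose symporter (1:1), plus the mammalian
glutamate transporter EAAT3 as a multi-ion example.
"""

from __future__ import annotations

from .simulate import KineticParams, VesiclePopulation
from .thermo import GradientSet, SpeciesTerm, TransportCycle

__all__ = [
    "vcindy_cycle",
    "vcindy_screen_gradients",
    "vcindy_screen_voltages",
    "vcindy_candidates",
    "vsglt_cycle",
    "eaat3_cycle",
    "mammalian_ion_gradients",
    "default_population",
    "default_params",
]


def vcindy_cycle(n: float = 3, m: float = 1) -> TransportCycle:
    """``n`` Na+ : ``m`` succinate2- symport cycle (VcINDY is 3:1)."""
    return TransportCycle.sodium_coupled(
        n, m, substrate_valence=-2, substrate_name="succinate",
        label=f"VcINDY {n:g}:{m:g}",
    )


def vcindy_screen_gradients(
    na_in: float = 50e-3,
    na_out: float = 200e-3,
    s_in: float = 1e-6,
    s_out: float = 0.1e-6,
) -> GradientSet:
    """The pilot screening gradients: a 1:4 inwardly directed Na+ gradient
    and a 10:1 outwardly directed succinate gradient (1 uM tracer inside).

    Under these a 3:1 cycle reverses at +48 mV; 1:1 at +24 mV; 4:1 at
    +42 mV.
    """
    return GradientSet({"Na+": (na_in, na_out), "succinate": (s_in, s_out)})


def vcindy_screen_voltages() -> tuple[float, float, float]:
    """Clamp voltages bracketing the 3:1 reversal potential: influx at
    +12 mV, equilibrium near +48 mV, efflux at +84 mV."""
    return (12.0, 48.0, 84.0)


def vcindy_candidates() -> list[tuple[int, int]]:
    """Candidate n:1 stoichiometries screened for VcINDY (2:1 is
    electroneutral for a divalent substrate and is kept to show the flag)."""
    return [(1, 1), (2, 1), (3, 1), (4, 1)]


def vsglt_cycle(n: float = 1, m: float = 1) -> TransportCycle:
    """``n`` Na+ : ``m`` galactose symport cycle (vSGLT is 1:1; galactose is
    neutral, so every n is electrogenic)."""
    return TransportCycle.sodium_coupled(
        n, m, substrate_valence=0, substrate_name="galactose",
        label=f"vSGLT {n:g}:{m:g}",
    )


def eaat3_cycle() -> TransportCycle:
    """Glutamate transporter cycle: cotransport of 3 Na+ and 1 H+,
    counter-transport of 1 K+, with monovalent anionic glutamate.  Net
    charge per cycle is +2."""
    return TransportCycle(
        terms=(
            SpeciesTerm("Na+", valence=1, stoichiometry=3, role="coupling_ion"),
            SpeciesTerm("H+", valence=1, stoichiometry=1, role="coupling_ion"),
            SpeciesTerm("K+", valence=1, stoichiometry=-1, role="coupling_ion"),
            SpeciesTerm("glutamate", valence=-1, stoichiometry=1, role="substrate"),
        ),
        label="EAAT3 3Na+/1H+/1K+(counter):glutamate-",
    )


def mammalian_ion_gradients() -> GradientSet:
    """Textbook mammalian ion gradients (mol/L): Na+ 12 in / 145 out,
    K+ 140 in / 4 out, pH 7.2 in / 7.4 out."""
    return GradientSet(
        {
            "Na+": (12e-3, 145e-3),
            "K+": (140e-3, 4e-3),
            "H+": (10 ** -7.2, 10 ** -7.4),
        }
    )


def default_population() -> VesiclePopulation:
    """400 nm extruded vesicles, ~1e10 per filtered sample."""
    return VesiclePopulation(diameter_nm=400.0, vesicle_count=1e10)


def default_params(seed: int = 0, **overrides) -> KineticParams:
    """Default tritium-tracer kinetics (60 Ci/mmol, 30% counting
    efficiency, 5% baseline jitter, no leak)."""
    return KineticParams(seed=seed, **overrides)
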