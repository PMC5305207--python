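"""Forward and inverse design of reversal-potential experiments.

Given a set of candidate coupling stoichiometries, the design problem is to
pick ion and substrate gradients whose predicted reversal potentials are far
enough apart to be told apart with a valinomycin/K+ voltage clamp, and then
to write down the K+ compositions that impose each test voltage and the
choline chloride filler that keeps every buffer iso-osmotic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

from .thermo import (
    SLOPE_MV_PER_DECADE,
    ElectroneutralCycleError,
    GradientSet,
    MissingSpeciesError,
    TransportCycle,
    nernst_potential,
    reversal_potential,
)

__all__ = [
    "CandidatePrediction",
    "SeparabilityReport",
    "BufferSpec",
    "ClampSpec",
    "candidate_cycle",
    "predict_candidate_potentials",
    "check_separability",
    "solve_gradients_for_targets",
    "potassium_for_voltage",
    "balance_osmolarity",
]

#: Default minimum spacing (mV) between candidate predictions that a crude
#: K+/valinomycin clamp can still resolve.
DEFAULT_MIN_SEPARATION_MV: float = 15.0


@dataclass(frozen=True)
class CandidatePrediction:
    """A candidate ``n:m`` ion:substrate stoichiometry and its predicted
    reversal potential under a gradient set.  ``e_rev`` is None when the
    candidate cycle is electroneutral (no reversal potential exists)."""

    n: int
    m: int
    e_rev: float | None

    @property
    def electroneutral(self) -> bool:
        return self.e_rev is None

    @property
    def label(self) -> str:
        return f"{self.n}:{self.m}"


def candidate_cycle(
    n: float,
    m: float,
    substrate_valence: int = -2,
    ion_name: str = "Na+",
    substrate_name: str = "S",
) -> TransportCycle:
    """Two-term symport cycle for one candidate stoichiometry."""
    from .thermo import SpeciesTerm

    return TransportCycle(
        terms=(
            SpeciesTerm(ion_name, valence=1, stoichiometry=n, role="coupling_ion"),
            SpeciesTerm(
                substrate_name,
                valence=substrate_valence,
                stoichiometry=m,
                role="substrate",
            ),
        ),
        label=f"{n:g}:{m:g}",
    )


def _coerce_gradients(
    gradients, ion_name: str, substrate_name: str
) -> tuple[GradientSet, str]:
    """Normalize the gradients argument; returns (gradient set, substrate name).

    When a GradientSet is given without a species literally named
    ``substrate_name``, the substrate is taken to be the single species other
    than the coupling ion."""
    if isinstance(gradients, GradientSet):
        if substrate_name in gradients:
            return gradients, substrate_name
        others = [n for n in gradients.concentrations if n != ion_name]
        if ion_name in gradients and len(others) == 1:
            return gradients, others[0]
        raise MissingSpeciesError(substrate_name)
    na_ratio, s_ratio = gradients
    return (
        GradientSet.from_ratios({ion_name: na_ratio, substrate_name: s_ratio}),
        substrate_name,
    )


def predict_candidate_potentials(
    candidates,
    gradients,
    substrate_valence: int = -2,
    ion_name: str = "Na+",
    substrate_name: str = "S",
) -> list[CandidatePrediction]:
    """Predicted reversal potential for each candidate ``(n, m)``.

    ``gradients`` is either a :class:`~revpot.thermo.GradientSet` containing
    the ion and substrate species, or a plain ``(na_ratio, s_ratio)`` pair of
    in/out ratios.  Electroneutral candidates are flagged (``e_rev=None``),
    not dropped: the experiment itself cannot probe them, which is a finding.
    """
    if not candidates:
        raise ValueError("candidate list must be nonempty")
    grads, substrate_name = _coerce_gradients(gradients, ion_name, substrate_name)
    out = []
    for n, m in candidates:
        cyc = candidate_cycle(n, m, substrate_valence, ion_name, substrate_name)
        try:
            e = reversal_potential(cyc, grads)
        except ElectroneutralCycleError:
            e = None
        out.append(CandidatePrediction(n=n, m=m, e_rev=e))
    return out


@dataclass(frozen=True)
class SeparabilityReport:
    passed: bool
    min_gap_mv: float
    closest_pair: tuple[CandidatePrediction, CandidatePrediction] | None

    def __bool__(self) -> bool:
        return self.passed


def check_separability(
    predictions,
    min_separation_mv: float = DEFAULT_MIN_SEPARATION_MV,
) -> SeparabilityReport:
    """Can the clamp resolve every pair of electrogenic predictions?

    Fails iff some pair of electrogenic candidates predicts reversal
    potentials closer than ``min_separation_mv``; reports the closest pair.
    A single electrogenic candidate trivially passes.
    """
    electro = [p for p in predictions if not p.electroneutral]
    if not electro:
        raise ValueError("need at least one electrogenic prediction")
    best_gap = math.inf
    best_pair = None
    for i in range(len(electro)):
        for j in range(i + 1, len(electro)):
            gap = abs(electro[i].e_rev - electro[j].e_rev)
            if gap < best_gap:
                best_gap = gap
                best_pair = (electro[i], electro[j])
    if best_pair is None:
        return SeparabilityReport(True, math.inf, None)
    return SeparabilityReport(best_gap >= min_separation_mv, best_gap, best_pair)


def solve_gradients_for_targets(
    candidate_a: tuple[float, float],
    target_a_mv: float,
    candidate_b: tuple[float, float],
    target_b_mv: float,
    substrate_valence: int = -2,
) -> tuple[float, float]:
    """Ion and substrate ratios that place two candidates at chosen voltages.

    Inverse design: find ``(na_ratio, s_ratio)`` such that candidate A's
    cycle reverses at ``target_a_mv`` and candidate B's at ``target_b_mv``.
    In log space each condition is linear, ``n_i a + m_i b = -E_i Q_i / s``
    with ``a = log10 na_ratio``, ``b = log10 s_ratio`` and
    ``Q_i = n_i + z_S m_i``, so the design reduces to a 2x2 linear solve.

    Raises
    ------
    ValueError
        If either candidate is electroneutral or the two candidate rows are
        proportional (singular system).
    """
    rows = []
    rhs = []
    for (n, m), target in ((candidate_a, target_a_mv), (candidate_b, target_b_mv)):
        q = n + substrate_valence * m
        if abs(q) < 1e-12:
            raise ElectroneutralCycleError(
                f"candidate {n:g}:{m:g} is electroneutral; it cannot anchor a "
                "reversal-potential target"
            )
        rows.append((n, m))
        rhs.append(-target * q / SLOPE_MV_PER_DECADE)
    (n1, m1), (n2, m2) = rows
    det = n1 * m2 - n2 * m1
    scale = max(abs(n1 * m2), abs(n2 * m1), 1.0)
    if abs(det) < 1e-12 * scale:
        raise ValueError(
            "candidate pair gives a singular design (proportional stoichiometry "
            "rows); the two targets cannot be set independently"
        )
    a = (rhs[0] * m2 - rhs[1] * m1) / det
    b = (n1 * rhs[1] - n2 * rhs[0]) / det
    return 10.0 ** a, 10.0 ** b


def potassium_for_voltage(k_in_mm: float, target_mv: float) -> float:
    """External K+ (mM) that clamps the membrane at ``target_mv`` via
    valinomycin, given the internal K+.

    Valinomycin makes the membrane K+-selective, pinning the voltage at the
    potassium Nernst potential; solving ``E_K = target`` gives
    ``k_out = k_in * 10**(target / 60)``.
    """
    if k_in_mm <= 0:
        raise ValueError("internal K+ must be positive")
    return k_in_mm * 10.0 ** (target_mv / SLOPE_MV_PER_DECADE)


@dataclass(frozen=True)
class ClampSpec:
    """A K+/valinomycin voltage-clamp composition."""

    k_in_mm: float
    k_out_mm: float
    valinomycin: bool = True

    def __post_init__(self) -> None:
        if self.valinomycin and not (self.k_in_mm > 0 and self.k_out_mm > 0):
            raise ValueError("K+ concentrations must be positive under valinomycin")

    @property
    def target_voltage_mv(self) -> float:
        return nernst_potential(+1, self.k_in_mm / self.k_out_mm)

    @classmethod
    def for_voltage(cls, k_in_mm: float, target_mv: float) -> "ClampSpec":
        return cls(k_in_mm=k_in_mm, k_out_mm=potassium_for_voltage(k_in_mm, target_mv))


@dataclass
class BufferSpec:
    """A flux-assay buffer: salts (mM) over a fixed 20 mM Tris/HEPES pH 7.5
    background, osmotically padded with choline chloride filler.

    Osmolarity is counted ideally (van 't Hoff): each salt contributes
    ``concentration * particles`` with 2 particles per monovalent salt by
    default; divalent salts can override via ``particles_per_salt``.
    """

    salts: dict[str, float]
    particles_per_salt: dict[str, float] = field(default_factory=dict)
    filler_mm: float = 0.0  # choline chloride, 2 particles
    background_mm: float = 20.0  # Tris/HEPES pH 7.5, counted once
    label: str = ""

    def __post_init__(self) -> None:
        for salt, conc in self.salts.items():
            if conc < 0:
                raise ValueError(f"negative concentration for {salt!r}")
        if self.filler_mm < 0:
            raise ValueError("filler concentration cannot be negative")

    def particles(self, salt: str) -> float:
        return self.particles_per_salt.get(salt, 2.0)

    def osmolarity_mosm(self, include_background: bool = True) -> float:
        total = sum(conc * self.particles(salt) for salt, conc in self.salts.items())
        total += 2.0 * self.filler_mm
        if include_background:
            total += self.background_mm
        return total


def balance_osmolarity(reference: BufferSpec, adjustable: BufferSpec) -> BufferSpec:
    """Return ``adjustable`` with choline-Cl filler matching ``reference``'s
    osmolarity.  Raises if the adjustable buffer is already hyperosmotic
    (filler cannot be negative)."""
    deficit = reference.osmolarity_mosm() - adjustable.osmolarity_mosm(
        include_background=True
    )
    # ignore the adjustable buffer's existing filler: it is ours to set
    deficit += 2.0 * adjustable.filler_mm
    if deficit < -1e-9:
        raise ValueError(
            "adjustable buffer is hyperosmotic relative to the reference "
            f"({-deficit:.3g} mOsm over); cannot add negative filler"
        )
    return replace(adjustable, filler_mm=max(deficit, 0.0) / 2.0)
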