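"""Inference of coupling stoichiometry from flux time courses.

The analysis mirrors how a reversal-potential experiment is read out:

1.  classify the direction of net flux at each clamped voltage from the
    slope of internalized counts versus time (OLS slope, two-sided t-test);
2.  locate the reversal potential, either at a voltage showing no
    significant flux that is bracketed by influx below and efflux above, or
    by interpolating the sign change of the voltage--dCPM curve (the
    flux-assay analog of an I--V relation);
3.  exclude every candidate stoichiometry whose predicted reversal
    potential coincides with a voltage where flux *was* observed, and assign
    the surviving candidate whose prediction is nearest the estimate.

:class:`StoichiometryModel` packages these steps behind a statsmodels-like
``Model.fit() -> Results`` interface; the individual steps remain available
as functions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .design import CandidatePrediction, predict_candidate_potentials
from .simulate import FluxTimeCourse

__all__ = [
    "DeltaCPM",
    "FluxCall",
    "InferenceResult",
    "StoichiometryModel",
    "IndeterminateEquilibriumError",
    "delta_cpm",
    "normalize_by_early_timepoint",
    "classify_flux",
    "estimate_reversal_potential",
    "assign_stoichiometry",
]

#: Default significance level for the flux slope test.
DEFAULT_ALPHA = 0.05
#: Default assignment tolerance (mV): smaller than the minimal candidate
#: separation a crude K+/valinomycin clamp resolves, larger than clamp
#: rounding.
DEFAULT_TOLERANCE_MV = 10.0
#: Analysis window cap (s) applied when a late-onset leak is expected.
LEAK_SAFE_WINDOW_S = 30.0


class IndeterminateEquilibriumError(RuntimeError):
    """Raised when the tested voltages do not bracket the reversal
    potential (flux in only one direction everywhere): the system was never
    at equilibrium, so no reversal potential can be located."""


@dataclass(frozen=True)
class DeltaCPM:
    """Initial-minus-later internalized counts for one course.

    Positive values mean net efflux (counts were lost), negative values net
    influx -- the sign convention of a voltage--dCPM plot.
    """

    voltage_mv: float
    per_replicate: np.ndarray
    initial_time: float
    eval_time: float

    @property
    def mean(self) -> float:
        return float(np.mean(self.per_replicate))

    @property
    def sem(self) -> float:
        n = len(self.per_replicate)
        if n < 2:
            return 0.0
        return float(np.std(self.per_replicate, ddof=1) / math.sqrt(n))


@dataclass(frozen=True)
class FluxCall:
    """Direction call at one voltage from the CPM-vs-time slope."""

    voltage_mv: float
    direction: str  # "influx" | "efflux" | "none"
    slope_cpm_per_s: float
    slope_se: float
    p_value: float
    ci: tuple[float, float]
    window: tuple[float, float]


def delta_cpm(
    course: FluxTimeCourse,
    initial_time: float = 0.0,
    eval_time: float = 60.0,
) -> DeltaCPM:
    """Per-replicate dCPM = CPM(initial) - CPM(eval), with mean and SEM.

    Raises a ``ValueError`` naming the missing timepoint if either time is
    absent from the course.
    """
    try:
        c0 = course.at(initial_time)
    except KeyError:
        raise ValueError(f"initial timepoint {initial_time} s missing from course") from None
    try:
        c1 = course.at(eval_time)
    except KeyError:
        raise ValueError(f"evaluation timepoint {eval_time} s missing from course") from None
    return DeltaCPM(
        voltage_mv=course.voltage_mv,
        per_replicate=c0 - c1,
        initial_time=initial_time,
        eval_time=eval_time,
    )


def normalize_by_early_timepoint(
    course: FluxTimeCourse, t_norm: float = 5.0, mode: str = "divide"
) -> FluxTimeCourse:
    """Normalize a course by its early-timepoint replicate mean.

    Rescales every CPM value by the mean CPM at ``t_norm`` so that courses
    with scattered t = 0 loading become comparable (the value at ``t_norm``
    becomes 1.0).  ``mode="subtract"`` offsets instead of scaling.
    """
    try:
        ref = float(np.mean(course.at(t_norm)))
    except KeyError:
        raise ValueError(f"normalization timepoint {t_norm} s missing from course") from None
    if mode == "divide":
        if ref <= 0:
            raise ValueError(
                f"mean CPM at {t_norm} s is {ref:g}; cannot divide-normalize"
            )
        new = course.cpm / ref
    elif mode == "subtract":
        new = course.cpm - ref
        new = np.clip(new - new.min(), 0, None) if new.min() < 0 else new
    else:
        raise ValueError(f"unknown normalization mode {mode!r}")
    meta = dict(course.metadata)
    meta["normalized_by"] = {"t_s": t_norm, "mode": mode, "reference_cpm": ref}
    return FluxTimeCourse(
        voltage_mv=course.voltage_mv,
        timepoints=course.timepoints,
        cpm=new,
        metadata=meta,
    )


def classify_flux(
    course: FluxTimeCourse,
    alpha: float = DEFAULT_ALPHA,
    window: tuple[float, float] | None = None,
) -> FluxCall:
    """Call flux direction at one voltage from the pooled OLS slope.

    Regresses CPM on time over all replicates within ``window`` (default:
    the full course) and tests the slope against zero (two-sided, level
    ``alpha``).  A significantly positive slope is influx (internal counts
    rising), negative is efflux, non-significant is ``"none"`` -- the
    confidence interval on the slope contains zero exactly when the call is
    ``"none"``.
    """
    t = course.timepoints
    lo, hi = window if window is not None else (t[0], t[-1])
    mask = (t >= lo) & (t <= hi)
    times = t[mask]
    if len(times) < 3:
        raise ValueError(
            f"need at least 3 timepoints in window [{lo}, {hi}] s, have {len(times)}"
        )
    if course.n_replicates < 2:
        raise ValueError("need at least 2 replicates to classify flux")
    y = course.cpm[mask]
    x = np.repeat(times, y.shape[1])
    res = stats.linregress(x, y.ravel())
    df = x.size - 2
    tcrit = stats.t.ppf(1 - alpha / 2, df)
    ci = (res.slope - tcrit * res.stderr, res.slope + tcrit * res.stderr)
    if res.pvalue < alpha:
        direction = "influx" if res.slope > 0 else "efflux"
    else:
        direction = "none"
    return FluxCall(
        voltage_mv=course.voltage_mv,
        direction=direction,
        slope_cpm_per_s=float(res.slope),
        slope_se=float(res.stderr),
        p_value=float(res.pvalue),
        ci=(float(ci[0]), float(ci[1])),
        window=(float(lo), float(hi)),
    )


def estimate_reversal_potential(
    calls: list[FluxCall],
    delta_cpm_by_voltage: dict[float, float] | None = None,
) -> tuple[float, tuple[float, float]]:
    """Locate the reversal potential from per-voltage flux calls.

    Preferred reading: a no-flux call bracketed by influx at a lower voltage
    and efflux at a higher one -- the point estimate is that voltage and the
    bracket the nearest flanking flux voltages.  Failing that, the sign
    change of mean dCPM (or, if unavailable, of the fitted slopes, negated)
    between adjacent voltages is interpolated linearly.

    Raises
    ------
    IndeterminateEquilibriumError
        If all significant calls go the same way: flux everywhere means the
        system was never at equilibrium at the tested voltages.
    """
    if not calls:
        raise ValueError("no flux calls given")
    calls = sorted(calls, key=lambda c: c.voltage_mv)
    directions = {c.direction for c in calls}
    if not ({"influx", "efflux"} <= directions):
        raise IndeterminateEquilibriumError(
            "flux calls do not bracket the reversal potential (need both "
            "influx and efflux); the system must not be at equilibrium at "
            "any tested voltage"
        )
    influx_vs = [c.voltage_mv for c in calls if c.direction == "influx"]
    efflux_vs = [c.voltage_mv for c in calls if c.direction == "efflux"]
    for c in calls:
        if c.direction != "none":
            continue
        below = [v for v in influx_vs if v < c.voltage_mv]
        above = [v for v in efflux_vs if v > c.voltage_mv]
        if below and above:
            return c.voltage_mv, (max(below), min(above))
    # no bracketed no-flux voltage: interpolate the zero crossing
    if delta_cpm_by_voltage:
        xs = sorted(delta_cpm_by_voltage)
        ys = [delta_cpm_by_voltage[v] for v in xs]  # dCPM: negative = influx
    else:
        xs = [c.voltage_mv for c in calls]
        ys = [-c.slope_cpm_per_s for c in calls]  # same sign convention as dCPM
    for (x0, y0), (x1, y1) in zip(zip(xs, ys), zip(xs[1:], ys[1:])):
        if y0 < 0 <= y1 or y0 <= 0 < y1:
            frac = 0.5 if y1 == y0 else -y0 / (y1 - y0)
            return x0 + frac * (x1 - x0), (x0, x1)
    raise IndeterminateEquilibriumError(
        "no sign change found in the voltage-dCPM curve; cannot interpolate "
        "a reversal potential"
    )


def assign_stoichiometry(
    predictions: list[CandidatePrediction],
    calls: list[FluxCall],
    e_rev_estimate: float,
    tolerance_mv: float = DEFAULT_TOLERANCE_MV,
    bracket: tuple[float, float] | None = None,
    delta_table: pd.DataFrame | None = None,
) -> "InferenceResult":
    """Exclude refuted candidates and assign the surviving stoichiometry.

    A candidate is excluded when significant flux was called within
    ``tolerance_mv`` of its predicted reversal potential *and* the flux
    direction is inconsistent with the candidate: influx at a voltage V
    places the true reversal potential above V, so it refutes candidates
    predicting ``E_rev <= V``; efflux refutes ``E_rev >= V``.  (Flux at the
    predicted equilibrium itself is inconsistent by definition.)  The
    direction condition keeps a marginal detection of the residual flux
    just next to the true equilibrium voltage from refuting the true
    candidate.  Among survivors the candidate nearest ``e_rev_estimate`` is
    assigned if it falls within ``tolerance_mv`` (and inside the bracketing
    interval, when one is given); otherwise the result is unassigned, which
    is a valid outcome.
    """
    if not predictions:
        raise ValueError("prediction list must be nonempty")
    excluded: list[tuple[int, int, str]] = []
    survivors: list[CandidatePrediction] = []
    flux_calls = [c for c in calls if c.direction != "none"]

    def refutes(call: FluxCall, e_rev: float) -> bool:
        if abs(call.voltage_mv - e_rev) > tolerance_mv:
            return False
        if call.direction == "influx":  # implies true E_rev > V
            return e_rev <= call.voltage_mv
        return e_rev >= call.voltage_mv  # efflux implies true E_rev < V

    for pred in predictions:
        if pred.electroneutral:
            continue  # cannot be probed by this experiment; neither excluded nor assigned
        hit = next((c for c in flux_calls if refutes(c, pred.e_rev)), None)
        if hit is not None:
            excluded.append(
                (
                    pred.n,
                    pred.m,
                    f"{hit.direction} observed at {hit.voltage_mv:+.0f} mV, "
                    f"within {tolerance_mv:g} mV of the predicted "
                    f"{pred.e_rev:+.1f} mV equilibrium",
                )
            )
        else:
            survivors.append(pred)
    assigned = None
    if survivors:
        best = min(survivors, key=lambda p: abs(p.e_rev - e_rev_estimate))
        ok = abs(best.e_rev - e_rev_estimate) <= tolerance_mv
        if ok and bracket is not None:
            lo, hi = min(bracket), max(bracket)
            ok = (lo - tolerance_mv) <= best.e_rev <= (hi + tolerance_mv)
        if ok:
            assigned = (best.n, best.m)
    return InferenceResult(
        calls=sorted(calls, key=lambda c: c.voltage_mv),
        e_rev_estimate=float(e_rev_estimate),
        bracket=bracket,
        predictions=list(predictions),
        assigned=assigned,
        excluded=excluded,
        tolerance_mv=tolerance_mv,
        delta_table=delta_table,
    )


@dataclass
class InferenceResult:
    """Fitted outcome of a reversal-potential experiment.

    Carries the per-voltage flux calls, the reversal-potential estimate with
    its bracketing interval, the candidate predictions, the assigned
    stoichiometry (or None) and the refuted candidates with reasons.
    """

    calls: list[FluxCall]
    e_rev_estimate: float
    bracket: tuple[float, float] | None
    predictions: list[CandidatePrediction]
    assigned: tuple[int, int] | None
    excluded: list[tuple[int, int, str]]
    tolerance_mv: float = DEFAULT_TOLERANCE_MV
    delta_table: pd.DataFrame | None = None

    def summary(self) -> str:
        lines = ["Reversal-potential stoichiometry inference", "=" * 44]
        lines.append(f"{'voltage (mV)':>12}  {'direction':>9}  {'slope (CPM/s)':>14}  {'p':>8}")
        for c in self.calls:
            lines.append(
                f"{c.voltage_mv:>+12.0f}  {c.direction:>9}  "
                f"{c.slope_cpm_per_s:>+14.2f}  {c.p_value:>8.3g}"
            )
        lines.append("-" * 44)
        if self.bracket is not None:
            lines.append(
                f"E_rev estimate: {self.e_rev_estimate:+.1f} mV "
                f"(bracket {self.bracket[0]:+.0f} .. {self.bracket[1]:+.0f} mV)"
            )
        else:
            lines.append(f"E_rev estimate: {self.e_rev_estimate:+.1f} mV")
        lines.append("candidate predictions:")
        for p in self.predictions:
            tag = "electroneutral" if p.electroneutral else f"{p.e_rev:+.1f} mV"
            mark = ""
            if self.assigned == (p.n, p.m):
                mark = "  <- assigned"
            elif any(e[:2] == (p.n, p.m) for e in self.excluded):
                mark = "  (excluded)"
            lines.append(f"  {p.label:>5}  {tag}{mark}")
        if self.assigned is not None:
            lines.append(
                f"assigned stoichiometry: {self.assigned[0]}:{self.assigned[1]} "
                "(ion:substrate)"
            )
        else:
            lines.append("assigned stoichiometry: unassigned")
        for n, m, reason in self.excluded:
            lines.append(f"  excluded {n}:{m} -- {reason}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "e_rev_estimate_mv": self.e_rev_estimate,
            "bracket_mv": list(self.bracket) if self.bracket is not None else None,
            "assigned": list(self.assigned) if self.assigned is not None else None,
            "tolerance_mv": self.tolerance_mv,
            "calls": [
                {
                    "voltage_mv": c.voltage_mv,
                    "direction": c.direction,
                    "slope_cpm_per_s": c.slope_cpm_per_s,
                    "slope_se": c.slope_se,
                    "p_value": c.p_value,
                    "ci": list(c.ci),
                    "window_s": list(c.window),
                }
                for c in self.calls
            ],
            "predictions": [
                {"n": p.n, "m": p.m, "e_rev_mv": p.e_rev} for p in self.predictions
            ],
            "excluded": [
                {"n": n, "m": m, "reason": reason} for n, m, reason in self.excluded
            ],
        }


class StoichiometryModel:
    """Reversal-potential stoichiometry model over flux time courses.

    Parameters
    ----------
    courses : list of FluxTimeCourse
        One course per clamped voltage.
    predictions : list of CandidatePrediction
        Candidate stoichiometries with their predicted reversal potentials
        (see :func:`revpot.design.predict_candidate_potentials`).
    alpha : significance level of the per-voltage slope test.
    window : (lo, hi) seconds to restrict the slope fit, or None.
    leak_expected : when True and no window is given, the fit window is
        capped at 30 s so a late-onset leak cannot masquerade as efflux.
    tolerance_mv : assignment/exclusion tolerance.
    normalize_t : when set, every course is divided by its replicate-mean
        CPM at this time before analysis (handles scattered t = 0 loading).
    initial_time, eval_time : timepoints for the dCPM table; ``eval_time``
        defaults to 60 s, falling back to the last timepoint within the
        analysis window.

    Examples
    --------
    >>> model = StoichiometryModel.from_gradients(courses, [(1, 1), (2, 1), (3, 1), (4, 1)],
    ...                                           gradients, substrate_valence=-2)
    >>> result = model.fit()
    >>> result.assigned
    (3, 1)
    """

    def __init__(
        self,
        courses: list[FluxTimeCourse],
        predictions: list[CandidatePrediction],
        *,
        alpha: float = DEFAULT_ALPHA,
        window: tuple[float, float] | None = None,
        leak_expected: bool = False,
        tolerance_mv: float = DEFAULT_TOLERANCE_MV,
        normalize_t: float | None = None,
        initial_time: float | None = None,
        eval_time: float | None = None,
    ):
        if not courses:
            raise ValueError("need at least one flux time course")
        self.courses = list(courses)
        self.predictions = list(predictions)
        self.alpha = alpha
        self.leak_expected = leak_expected
        if window is None:
            # Slopes are fitted over post-dilution timepoints only: the t = 0
            # point is a separately collected batch baseline whose loading
            # scatter would otherwise dominate the regression variance.  It
            # still anchors the reported dCPM table.
            positive = [t for c in courses for t in c.timepoints if t > 0]
            lo = min(positive) if positive else min(c.timepoints[0] for c in courses)
            if normalize_t is not None:
                lo = max(lo, normalize_t)
            hi = LEAK_SAFE_WINDOW_S if leak_expected else max(
                c.timepoints[-1] for c in courses
            )
            window = (lo, hi)
        self.window = window
        self.tolerance_mv = tolerance_mv
        self.normalize_t = normalize_t
        self.initial_time = initial_time
        self.eval_time = eval_time

    @classmethod
    def from_gradients(
        cls,
        courses: list[FluxTimeCourse],
        candidates,
        gradients,
        substrate_valence: int = -2,
        **options,
    ) -> "StoichiometryModel":
        """Build the model from candidate ``(n, m)`` pairs and the imposed
        gradients rather than precomputed predictions."""
        preds = predict_candidate_potentials(
            candidates, gradients, substrate_valence=substrate_valence
        )
        return cls(courses, preds, **options)

    def _prepared_courses(self) -> list[FluxTimeCourse]:
        if self.normalize_t is None:
            return self.courses
        return [normalize_by_early_timepoint(c, self.normalize_t) for c in self.courses]

    def _delta_times(self, course: FluxTimeCourse) -> tuple[float, float] | None:
        t = course.timepoints
        lo = self.initial_time if self.initial_time is not None else float(t[0])
        hi = self.eval_time
        if hi is None:
            cap = self.window[1] if self.window is not None else math.inf
            candidates = t[(t <= min(60.0, cap)) & (t > lo)]
            hi = float(candidates[-1]) if candidates.size else None
        if hi is None:
            return None
        return lo, hi

    def fit(self) -> InferenceResult:
        """Run the full analysis and return an :class:`InferenceResult`."""
        courses = self._prepared_courses()
        calls = [classify_flux(c, alpha=self.alpha, window=self.window) for c in courses]
        rows = []
        dcpm_by_v: dict[float, float] = {}
        for c in courses:
            times = self._delta_times(c)
            if times is None:
                continue
            try:
                d = delta_cpm(c, *times)
            except ValueError:
                continue
            rows.append(
                {
                    "voltage_mV": d.voltage_mv,
                    "delta_cpm_mean": d.mean,
                    "delta_cpm_sem": d.sem,
                    "initial_time_s": d.initial_time,
                    "eval_time_s": d.eval_time,
                }
            )
            dcpm_by_v[d.voltage_mv] = d.mean
        table = (
            pd.DataFrame(rows).sort_values("voltage_mV").reset_index(drop=True)
            if rows
            else None
        )
        # The dCPM table is reported (the I--V analog) but the fallback
        # interpolation uses the fitted slopes: a shared, scattered t = 0
        # baseline offsets every dCPM by the same amount while leaving
        # slopes untouched.
        estimate, bracket = estimate_reversal_potential(calls)
        return assign_stoichiometry(
            self.predictions,
            calls,
            estimate,
            tolerance_mv=self.tolerance_mv,
            bracket=bracket,
            delta_table=table,
        )
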