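"""Minimal plotting helpers (voltage--dCPM curve and time courses)."""

from __future__ import annotations

import numpy as np


def voltage_delta_cpm_plot(delta_table, predictions=None, ax=None):
    """Plot mean dCPM +/- SEM against clamp voltage, the flux-assay analog
    of a current--voltage relation.  Candidate reversal potentials can be
    overlaid as dashed verticals."""
    import matplotlib
    if ax is None:
        matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    ax.errorbar(
        delta_table["voltage_mV"],
        delta_table["delta_cpm_mean"],
        yerr=delta_table["delta_cpm_sem"],
        fmt="o-",
        capsize=3,
    )
    ax.axhline(0.0, color="grey", lw=0.8)
    if predictions is not None:
        for p in predictions:
            if p.e_rev is not None:
                ax.axvline(p.e_rev, ls="--", lw=0.8, color="tab:red")
                ax.annotate(p.label, (p.e_rev, ax.get_ylim()[1]), fontsize=8)
    ax.set_xlabel("membrane potential (mV)")
    ax.set_ylabel(r"$\Delta$CPM (initial $-$ later)")
    return ax


def time_course_plot(courses, ax=None):
    """Overlay replicate-mean CPM time courses, one line per voltage."""
    import matplotlib
    if ax is None:
        matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    for course in courses:
        mean = course.mean()
        sem = course.sem()
        ax.errorbar(
            course.timepoints, mean, yerr=sem, fmt="o-", capsize=3,
            label=f"{course.voltage_mv:+.0f} mV",
        )
    ax.set_xlabel("time (s)")
    ax.set_ylabel("internalized counts (CPM)")
    ax.legend(frameon=False, fontsize=8)
    return ax
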