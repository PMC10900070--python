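"""Optional figures: threshold-power-vs-concentration curves and wall DVHs."""

from __future__ import annotations

import numpy as np

from .planning import DoseVolumeHistogram, TreatmentPlan


def plot_concentration_curve(plan: TreatmentPlan, ax=None):
    """Threshold optical power as a function of Intralipid concentration."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    conc = [p.concentration_pct for p in plan.curve]
    power = [p.threshold_power_mw for p in plan.curve]
    ax.plot(conc, power, "o-")
    if plan.feasible:
        ax.plot([plan.concentration_pct], [plan.power_mw], "r*", markersize=12,
                label=f"optimum {plan.concentration_pct:.3g}% / {plan.power_mw:.0f} mW")
        ax.legend()
    ax.set_xlabel("Intralipid concentration (%)")
    ax.set_ylabel("Threshold optical power (mW)")
    return ax


def plot_dvh(dvh: DoseVolumeHistogram, power_mw: float, ax=None,
             thresholds: np.ndarray | None = None):
    """Cumulative wall coverage versus fluence rate at a delivered power."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    if thresholds is None:
        top = max(1.0, float(dvh.values[-1]) * power_mw)
        thresholds = np.geomspace(max(1e-3, top * 1e-4), top, 200)
    ax.semilogx(thresholds, 100 * dvh.curve(power_mw, thresholds))
    ax.set_xlabel("Fluence rate (mW cm$^{-2}$)")
    ax.set_ylabel("Abscess wall coverage (%)")
    ax.set_ylim(0, 100)
    return ax
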