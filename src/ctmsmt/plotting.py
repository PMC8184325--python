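"""Matplotlib helpers for traces, strength-duration curves and sensitivity sweeps."""

from __future__ import annotations

import numpy as np


def _axes(ax):
    if ax is not None:
        return ax
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    _, ax = plt.subplots()
    return ax


def plot_trace(trace, ax=None):
    """Membrane potential vs time, with the spike instant marked."""
    ax = _axes(ax)
    ax.plot(trace.times / 1000.0, trace.V_m, lw=0.8)
    if trace.spiked:
        ax.axvline(trace.spike_time / 1000.0, color="r", ls="--", lw=0.8)
    ax.set_xlabel("time (ms)")
    ax.set_ylabel("V_m (mV)")
    return ax

def plot_strength_duration(curve_df, ax=None):
    """Threshold intensity (%MSO) vs major-phase width (us), log-x."""
    ax = _axes(ax)
    ax.plot(curve_df["width_us"], curve_df["mt_pct_mso"], "o-")
    ax.set_xscale("log")
    ax.set_xlabel("major-phase width (us)")
    ax.set_ylabel("threshold (%MSO)")
    return ax


def plot_sensitivity(curve, ax=None):
    """Normalized threshold vs the swept parameter value."""
    ax = _axes(ax)
    ok = np.isfinite(curve.normalized)
    ax.plot(curve.grid[ok], curve.normalized[ok], "o-")
    ax.set_xlabel(curve.parameter)
    ax.set_ylabel("normalized threshold")
    ax.set_title(f"reference: {curve.reference_mt:.2f} %MSO")
    return ax
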