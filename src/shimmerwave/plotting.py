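"""Polar and time-course plots mirroring the standard figures."""

from __future__ import annotations

import numpy as np

from .neighborhood import SECTOR_CENTRE_DEG


def plot_linearity_polar(rel_n_fb, ax=None):
    """Polar histogram of normalized trigger-direction rates per dir_WAV."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(subplot_kw={"projection": "polar"})
    # image y points down; flip for a conventional polar display
    for dir_wav, row in rel_n_fb.iterrows():
        angles = np.deg2rad([-SECTOR_CENTRE_DEG[int(s)] for s in row.index])
        vals = row.to_numpy(float)
        angles = np.append(angles, angles[0])
        vals = np.append(vals, vals[0])
        ax.plot(angles, vals, label=f"dir_WAV={int(dir_wav)}")
    ax.set_ylim(0, 1.05)
    ax.legend(loc="lower left", fontsize="small")
    return ax


def plot_continuity_profile(result, ax=None):
    """rel_n_Nh against the angular deviation from the trigger sector."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for c_ws, row in result.rel_n_nh.iterrows():
        ax.plot(row.index, row.to_numpy(float), marker="o", label=f"c_ws={c_ws}")
    ax.set_xlabel("Δα from trigger sector (deg)")
    ax.set_ylabel("rel_n_Nh")
    ax.legend(fontsize="small")
    return ax


def plot_ensembles(ensembles, ax=None):
    """Mean +- SE focus (solid) and trigger-neighbour (dashed) curves."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for c_ws, curves in sorted(ensembles.items()):
        fb = curves["fb"]
        (line,) = ax.plot(fb.t_ms, fb.mean, label=f"fb c_ws={c_ws}")
        ax.fill_between(fb.t_ms, fb.mean - fb.se, fb.mean + fb.se, alpha=0.2,
                        color=line.get_color())
        if "nb" in curves:
            nb = curves["nb"]
            ax.plot(nb.t_ms, nb.mean, "--", color=line.get_color())
    ax.axvline(0.0, color="red", lw=0.8)
    ax.set_xlabel("time relative to t0 (ms)")
    ax.set_ylabel("rel_xymov")
    ax.legend(fontsize="small")
    return ax
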