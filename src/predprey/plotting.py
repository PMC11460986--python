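"""Log-log scaling figure: total/tiger/leopard biomass against prey biomass
with the fitted power law, CCA margin lines, single-species regressions and
the shaded competition gaps."""

from __future__ import annotations

from typing import Mapping, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .cca import Margins
from .data_model import ParkYearBiomass
from .power_law import PowerLawFit


def plot_biomass_scaling(
    records: Sequence[ParkYearBiomass],
    fits: Mapping[str, PowerLawFit],
    margin: Margins | None = None,
):
    """Return a matplotlib Figure in the style of the study's joint figure.

    Circles: total predator biomass; 'T'/'L' markers: tiger and leopard.
    Solid black: total-predator power law (coincident with the CCA prey
    relation); solid red/blue: tiger and leopard margins; dashed: the
    single-species regressions; shading: the competition gap.
    """
    joint = [r for r in records if not r.leopard_missing]
    fig, ax = plt.subplots(figsize=(7, 5))
    x = np.array([r.x for r in joint])
    if joint:
        ax.scatter(x, [r.predator_total for r in joint], facecolors="none",
                   edgecolors="k", label="total predator")
        for r in joint:
            ax.text(r.x, r.T, "T", color="red", ha="center", va="center", fontsize=8)
            if r.L > 0:
                ax.text(r.x, r.L, "L", color="blue", ha="center", va="center", fontsize=8)
    xs = np.geomspace(min(r.x for r in records), max(r.x for r in records), 100)
    lxs = np.log10(xs)
    styles = {"total": ("k-", "total regression"),
              "tiger": ("r--", "tiger-only regression"),
              "leopard": ("b--", "leopard-only regression")}
    for name, fit in fits.items():
        style, lab = styles.get(name, ("g-", name))
        ax.plot(xs, 10.0 ** fit.predict_log(lxs), style, label=f"{lab} (k={fit.k_mean:.2f})")
    if margin is not None:
        mt = margin.predict_tiger_biomass(xs)
        ml = margin.predict_leopard_biomass(xs)
        ax.plot(xs, mt, "r-", label=f"tiger margin (k={margin.tiger_slope:.2f})")
        ax.plot(xs, ml, "b-", label=f"leopard margin (k={margin.leopard_slope:.2f})")
        if "tiger" in fits:
            ax.fill_between(xs, 10.0 ** fits["tiger"].predict_log(lxs), mt,
                            color="red", alpha=0.15)
        if "leopard" in fits:
            ax.fill_between(xs, 10.0 ** fits["leopard"].predict_log(lxs), ml,
                            color="blue", alpha=0.15)
    ax.set_xscale("log")
    ax.set_yscale("log")
    ax.set_xlabel("prey biomass density (kg/km$^2$)")
    ax.set_ylabel("predator biomass density (kg/km$^2$)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    return fig
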