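"""Plot helpers: QC overlays and model-evaluation figures (matplotlib)."""
from __future__ import annotations

import numpy as np


def _ax(ax=None):
    if ax is None:
        import matplotlib.pyplot as plt

        _, ax = plt.subplots()
    return ax


def plot_tiling_overlay(image, squares, ax=None):
    """Radiograph with the FA squares drawn on top (QC view)."""
    ax = _ax(ax)
    ax.imshow(getattr(image, "pixels", image), cmap="gray", vmin=0, vmax=255)
    for sq in squares:
        half = sq.side_mm / 2.0 / image.spacing
        corners = [
            sq.center + half * (st * sq.tangent + sn * sq.normal)
            for st, sn in ((-1, -1), (1, -1), (1, 1), (-1, 1), (-1, -1))
        ]
        corners = np.asarray(corners)
        ax.plot(corners[:, 1], corners[:, 0], lw=0.8, color="yellow")
    ax.set_axis_off()
    return ax


def plot_cv_curve(curve, lambda_star=None, ax=None):
    """Cross-validated deviance against the penalty (selection plot)."""
    ax = _ax(ax)
    ax.errorbar(np.log(curve["lambda"]), curve["mean_deviance"],
                yerr=curve["se_deviance"], fmt="o-", ms=3, lw=1)
    if lambda_star is not None:
        ax.axvline(np.log(lambda_star), ls="--", color="red")
    ax.set_xlabel(r"log $\lambda$")
    ax.set_ylabel("CV partial-likelihood deviance")
    return ax


def plot_km_groups(groups: dict, ax=None):
    """Kaplan-Meier curves per risk group; ``groups`` maps label -> (t, e)."""
    from lifelines import KaplanMeierFitter

    ax = _ax(ax)
    for label, (time, event) in groups.items():
        KaplanMeierFitter(label=label).fit(time, event).plot_survival_function(ax=ax)
    ax.set_xlabel("months since initial radiograph")
    ax.set_ylabel("fraction not yet healed")
    return ax


def plot_calibration(curve, ax=None):
    """Observed vs predicted risk per bin, with the ideal y = x line."""
    ax = _ax(ax)
    ax.plot([0, 1], [0, 1], ls="--", color="gray", lw=1)
    ax.plot(curve["predicted"], curve["observed"], "o-")
    ax.set_xlabel("predicted risk")
    ax.set_ylabel("observed risk (KM)")
    ax.set_xlim(0, 1)
    ax.set_ylim(0, 1)
    return ax


def plot_decision_curve(nb, ax=None):
    """Net benefit of the model vs treat-all / treat-none policies."""
    ax = _ax(ax)
    ax.plot(nb.thresholds, nb.nb_model, label="model")
    ax.plot(nb.thresholds, nb.nb_all, label="treat all", color="brown")
    ax.plot(nb.thresholds, nb.nb_none, label="treat none", color="red")
    ax.set_xlabel("threshold probability")
    ax.set_ylabel("net benefit")
    ax.set_ylim(bottom=max(-0.2, float(np.min(nb.nb_model)) - 0.05))
    ax.legend()
    return ax
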