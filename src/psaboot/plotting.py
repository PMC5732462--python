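"""Quick-look plots: cost-effectiveness plane and CEACs.

Thin matplotlib helpers over :class:`~psaboot.psa.PSACloud`,
:class:`~psaboot.psa.Ellipse` and :class:`~psaboot.psa.CEACCurve`. They
return the axes so callers can compose/annotate further.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")  # headless by default; callers may switch backends first

import matplotlib.pyplot as plt  # noqa: E402

from .psa import CEACCurve, Ellipse, PSACloud, confidence_ellipse  # noqa: E402

__all__ = ["plot_plane", "plot_ceac"]


def plot_plane(clouds: dict[str, PSACloud], level: float = 0.95, ax=None,
               scatter: bool = True):
    """Incremental cost-effectiveness plane with one confidence ellipse per
    labelled cloud (e.g. {'fixed': ..., 'bootstrap': ...})."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 5))
    for label, cloud in clouds.items():
        ell: Ellipse = confidence_ellipse(cloud, level=level)
        if scatter:
            ax.scatter(cloud.d_effect, cloud.d_cost, s=4, alpha=0.25, label=None)
        b = ell.boundary()
        ax.plot(b[:, 0], b[:, 1], label=f"{label} ({int(level*100)}% ellipse)")
        ax.plot(*ell.center, marker="o", ms=5, color=ax.lines[-1].get_color())
    ax.axhline(0.0, color="k", lw=0.5)
    ax.axvline(0.0, color="k", lw=0.5)
    ax.set_xlabel("incremental effect (QALYs)")
    ax.set_ylabel("incremental cost")
    ax.legend(frameon=False)
    return ax


def plot_ceac(curves: dict[str, CEACCurve], ax=None):
    """CEACs (mean with optional percentile band) per labelled curve."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    for label, c in curves.items():
        line, = ax.plot(c.lambdas, c.probabilities, label=label)
        if c.lower is not None:
            ax.plot(c.lambdas, c.lower, ls="--", lw=0.8, color=line.get_color())
            ax.plot(c.lambdas, c.upper, ls="--", lw=0.8, color=line.get_color())
    ax.set_ylim(-0.02, 1.02)
    ax.set_xlabel("willingness to pay per QALY")
    ax.set_ylabel("probability cost-effective")
    ax.legend(frameon=False)
    return ax
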