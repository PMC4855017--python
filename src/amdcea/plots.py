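"""Optional matplotlib figures: cost-effectiveness plane and CEAC.

Matplotlib is imported lazily so the core pipeline has no plotting
dependency; install the ``plot`` extra to use these helpers.
"""

from __future__ import annotations

from amdcea.sensitivity import CEACCurve, PSAResult
from amdcea.states import Strategy


def _plt():
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    return plt


def plot_ce_plane(psa: PSAResult, path, reference: Strategy = Strategy.USUAL_CARE,
                  wtp: float | None = None) -> None:
    """Scatter of incremental cost vs incremental QALYs against the reference.

    With ``wtp`` given, the threshold is drawn as a line through the origin
    with slope WTP ($/QALY).
    """
    plt = _plt()
    df = psa.ce_plane(reference)
    fig, ax = plt.subplots(figsize=(6, 5))
    for strategy, grp in df.groupby("strategy"):
        ax.scatter(grp["d_qaly"], grp["d_cost"], s=6, alpha=0.5, label=strategy)
    if wtp is not None:
        lo, hi = ax.get_xlim()
        ax.axline((0, 0), slope=wtp, color="grey", linestyle=":",
                  label=f"WTP ${wtp:,.0f}/QALY")
        ax.set_xlim(lo, hi)
    ax.axhline(0, color="black", lw=0.5)
    ax.axvline(0, color="black", lw=0.5)
    ax.set_xlabel(f"Incremental QALYs vs {reference.value}")
    ax.set_ylabel(f"Incremental cost ($) vs {reference.value}")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_ceac(curve: CEACCurve, path, thresholds: tuple[float, ...] = ()) -> None:
    """Acceptability curves; vertical dotted lines mark WTP thresholds."""
    plt = _plt()
    fig, ax = plt.subplots(figsize=(6, 4.5))
    for j, strategy in enumerate(curve.strategies):
        ax.plot(curve.wtp, curve.probability[:, j], label=strategy.value)
    for t in thresholds:
        ax.axvline(t, color="grey", linestyle=":")
    ax.set_xlabel("Willingness to pay ($/QALY)")
    ax.set_ylabel("Probability cost-effective")
    ax.set_ylim(-0.02, 1.02)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
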