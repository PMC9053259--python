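"""Optional plots (requires matplotlib, installed via the ``plot`` extra)."""

from __future__ import annotations

from pathlib import Path

import pandas as pd


def plot_sweep_curve(
    curve: pd.DataFrame,
    clinician_rate: float,
    random_rate: float,
    path: str | Path,
    title: str | None = None,
) -> Path:
    """Coverage vs. percent of broad-spectrum budget narrowed."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.2))
    ax.plot(curve["percent_narrowed"], 100 * curve["coverage"], color="tab:blue",
            label="personalized antibiogram")
    ax.axhline(100 * clinician_rate, color="black", ls="--", label="clinician")
    ax.axhline(100 * random_rate, color="gray", ls=":", label="random")
    ax.set_xlabel("% of broad-spectrum prescriptions narrowed")
    ax.set_ylabel("coverage rate (%)")
    if title:
        ax.set_title(title, fontsize=9)
    ax.legend(fontsize=7, frameon=False)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def plot_null_distribution(
    quantiles: dict[str, float], observed: float, path: str | Path
) -> Path:
    """Summary sketch of a null coverage distribution vs. the observed rate."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 2.4))
    qs = {k: v for k, v in quantiles.items() if k.startswith("q")}
    ax.boxplot(
        [[qs["q0.025"], qs["q0.25"], qs["q0.5"], qs["q0.75"], qs["q0.975"]]],
        vert=False, widths=0.5,
    )
    ax.axvline(observed, color="tab:red", label="observed")
    ax.set_yticks([])
    ax.set_xlabel("null coverage rate")
    ax.legend(fontsize=7, frameon=False)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
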