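"""Small plotting helpers for the report bundle (SVG, timestamp-free)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import pandas as pd

__all__ = ["plot_exclusion_by_age", "plot_crude_rates", "save_deterministic"]


def save_deterministic(fig, path) -> None:
    """Save a figure as SVG without embedded timestamps or random ids."""
    with matplotlib.rc_context({"svg.hashsalt": "washout"}):
        fig.savefig(path, format="svg", metadata={"Date": None})
    plt.close(fig)


def plot_exclusion_by_age(selectivity: pd.DataFrame):
    """Excluded proportion per 5-year age bin, one line per lookback x sex."""
    fig, ax = plt.subplots(figsize=(8, 4.5))
    for (k, sex), sub in selectivity.groupby(["lookback_years", "sex"]):
        sub = sub.sort_values("stratum")
        ax.plot(
            sub["stratum"], 100 * sub["proportion_excluded"],
            marker="o", label=f"CON{k}, {sex}",
        )
    ax.set_xlabel("age bin")
    ax.set_ylabel("% of base population excluded")
    ax.legend(fontsize=8)
    ax.tick_params(axis="x", rotation=60)
    fig.tight_layout()
    return fig


def plot_crude_rates(crude: pd.DataFrame, disease: str):
    """Crude rate per 10,000 PY by subpopulation, grouped by sex."""
    fig, ax = plt.subplots(figsize=(6, 4))
    order = ["BASE"] + sorted(
        [s for s in crude["subpopulation"].unique() if s != "BASE"]
    )
    for sex, sub in crude.groupby("sex"):
        sub = sub.set_index("subpopulation").reindex(order)
        ax.plot(order, sub["rate_per_10k"], marker="s", label=sex)
    ax.set_ylabel(f"crude {disease} rate per 10,000 PY")
    ax.set_xlabel("subpopulation (lookback)")
    ax.legend()
    fig.tight_layout()
    return fig
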