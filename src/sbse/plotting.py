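"""Summary and composite plots of scan results.

Two idioms: the single-query summary plot (central match/non-match
triangle with the optimal-division path, flanked by the per-division
score trace on top and the per-step trace on the right, both on the same
score scale), and the composite plot overlaying the per-step score trace
of every motif in a k-mer library with the designated query and the top
scorer highlighted.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .engine import CompositeResult, ScanResult
from .seedcore import MatchVector

FORMATS = ("png", "svg", "pdf")

# deterministic SVG ids so repeated renders are byte-identical
matplotlib.rcParams["svg.hashsalt"] = "sbse"


@dataclass
class PlotConfig:
    path: str | Path = "sbse_plot.png"
    query_color: str = "red"
    top_color: str = "turquoise"
    match_color: str = "green"
    nonmatch_color: str = "lightsteelblue"
    base_color: str = "0.7"
    dpi: int = 120

    def __post_init__(self) -> None:
        fmt = Path(self.path).suffix.lstrip(".").lower()
        if fmt not in FORMATS:
            raise ValueError(f"unsupported format {fmt!r}; use one of {FORMATS}")


def _no_signal(result: ScanResult) -> bool:
    prior = result.metadata.get("prior", 0.5)
    base = result.metadata.get("log_base", np.e)
    baseline = -np.log(1.0 - prior) / np.log(base)
    return result.max_score <= baseline + 1e-12


def render_summary_plot(result: ScanResult, D: MatchVector | np.ndarray,
                        config: PlotConfig) -> Path:
    """Render the three-panel summary plot for a single-query scan.

    Central panel: ranks on x, processing steps on y (top to bottom);
    columns colored by match status once their observation has been
    consumed, with a black tick at the running optimal division.  Top
    panel: final score per division with a dashed guide at i*.  Right
    panel: best score per step with a dashed guide at the optimal step;
    both side panels share the score axis.
    """
    bits = np.asarray(D.bits if isinstance(D, MatchVector) else D)
    n = len(bits)
    n_steps = len(result.step_trace)
    order = result.metadata.get("order")
    spans = result.metadata.get("spans")

    fig = plt.figure(figsize=(8, 8))
    gs = fig.add_gridspec(2, 2, width_ratios=[4, 1], height_ratios=[1, 4],
                          hspace=0.08, wspace=0.08)
    ax_u = fig.add_subplot(gs[0, 0])
    ax_c = fig.add_subplot(gs[1, 0], sharex=ax_u)
    ax_r = fig.add_subplot(gs[1, 1])

    # central triangle: rows = steps, processed columns colored
    img = np.zeros((n_steps, n), dtype=np.uint8)
    for j in range(n_steps):
        if spans is not None:
            lo, hi = spans[result.metadata["order_bins"][j]]
            cols = np.arange(lo - 1, hi)
        else:
            cols = np.array([order[j] - 1]) if order is not None else np.array([j])
        if j > 0:
            img[j] = img[j - 1]
        img[j, cols] = np.where(bits[cols] > 0, 1, 2)
    cmap = matplotlib.colors.ListedColormap(
        ["white", config.match_color, config.nonmatch_color])
    ax_c.imshow(img, aspect="auto", interpolation="nearest", cmap=cmap,
                vmin=0, vmax=2, extent=(0.5, n + 0.5, n_steps + 0.5, 0.5))
    for j in range(n_steps):
        boundary = result.division_ranks[result.division_path[j]]
        ax_c.plot([boundary + 0.5] * 2, [j + 0.5, j + 1.5], color="black", lw=1.5)
    ax_c.set_xlabel("rank (most up- to most down-regulated)")
    ax_c.set_ylabel("processing step")

    ax_u.plot(result.division_ranks + 0.5, result.final_trace, color="black")
    ax_u.set_ylabel("enrichment score")
    ax_u.tick_params(labelbottom=False)

    steps = np.arange(1, n_steps + 1)
    ax_r.plot(result.step_trace, steps, color="black")
    ax_r.set_ylim(n_steps + 0.5, 0.5)
    ax_r.set_xlabel("enrichment score")
    score_lim = max(result.final_trace.max(), result.step_trace.max()) * 1.05
    ax_u.set_ylim(0, score_lim)
    ax_r.set_xlim(0, score_lim)

    if not _no_signal(result):
        ax_u.axvline(result.i_star + 0.5, color="blue", ls="--", lw=0.8, alpha=0.6)
        ax_c.axvline(result.i_star + 0.5, color="blue", ls="--", lw=0.8, alpha=0.6)
        ax_r.axhline(result.j_star_step, color="blue", ls="--", lw=0.8, alpha=0.6)

    fig.savefig(config.path, dpi=config.dpi)
    plt.close(fig)
    return Path(config.path)


def render_composite_plot(composite: CompositeResult, config: PlotConfig,
                          query: str | None = None) -> Path:
    """Overlay every motif's per-step score trace; highlight the designated
    query and the top scorer.  The y-axis is scaled to the observed score
    range."""
    traces = composite.step_traces
    n_mot, n_steps = traces.shape
    steps = np.arange(1, n_steps + 1)
    fig, ax = plt.subplots(figsize=(8, 5))
    ax.plot(steps, traces.T, color=config.base_color, lw=0.4)
    top_idx = int(np.argmax(composite.table["max_score"].to_numpy()))
    top_motif = composite.table["motif"].iloc[top_idx]
    if query is not None and query == top_motif:
        ax.plot(steps, traces[top_idx], color=config.query_color, lw=1.5,
                label=f"{query} (query = top scorer)")
    else:
        ax.plot(steps, traces[top_idx], color=config.top_color, lw=1.5,
                label=f"{top_motif} (top scorer)")
        if query is not None:
            from .seedcore import motif_to_code

            ax.plot(steps, traces[motif_to_code(query)], color=config.query_color,
                    lw=1.5, label=f"{query} (query)")
    ax.set_xlabel("bin (processing step)")
    ax.set_ylabel("enrichment score")
    ax.set_ylim(0, float(traces.max()) * 1.05 or 1.0)
    ax.legend(loc="upper center", frameon=False)
    fig.savefig(config.path, dpi=config.dpi)
    plt.close(fig)
    return Path(config.path)
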