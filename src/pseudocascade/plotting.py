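"""Cascade heatmaps, switch-point confidence-interval glyphs, and enrichment
dot plots.

Figures never re-sort: rows follow the cascade order they are given, and
every figure writes a machine-readable sidecar TSV (row order, color limits,
CI coordinates) so content can be asserted without image diffing.  SVG output
is byte-deterministic for identical inputs.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .cascade import CascadeResult

__all__ = [
    "plot_cascade_heatmap",
    "plot_multisample_heatmap",
    "plot_enrichment_dots",
]

_CMAP = "RdBu_r"


def _deterministic_style():
    plt.rcParams["svg.hashsalt"] = "pseudocascade"


def _save(fig, out, fmt: str):
    _deterministic_style()
    out = Path(out)
    if out.suffix.lower() != f".{fmt}":
        out = out.with_suffix(f".{fmt}")
    fig.savefig(out, format=fmt, metadata={"Date": None} if fmt in ("svg", "pdf") else None)
    plt.close(fig)
    return out


def _color_limit(values: np.ndarray, cap: float = 3.0) -> float:
    return float(min(np.abs(values).max(), cap)) if values.size else 1.0


def _write_sidecar(out: Path, rows: list, vlim: float, cis=None):
    side = out.with_suffix(out.suffix + ".sidecar.tsv")
    with open(side, "w") as fh:
        fh.write(f"# vmin\t{-vlim:.6g}\n# vmax\t{vlim:.6g}\n")
        if cis:
            for gene, frac, lo, hi in cis:
                fh.write(f"# ci\t{gene}\t{frac:.6g}\t{lo:.6g}\t{hi:.6g}\n")
        fh.write("row\tgene\n")
        for i, g in enumerate(rows, start=1):
            fh.write(f"{i}\t{g}\n")
    return side


def plot_cascade_heatmap(
    scaled: pd.DataFrame,
    cascade: CascadeResult,
    markers=None,
    out="cascade_heatmap",
    fmt: str = "png",
    cap: float = 3.0,
):
    """Heatmap of scaled fitted trajectories, rows in cascade order.

    Horizontal separators mark pattern-group boundaries; genes listed in
    ``markers`` are labelled on the row axis.  The diverging color scale is
    symmetric about 0 with limits at +/- min(max|value|, cap).
    """
    missing = [g for g in cascade.genes if g not in scaled.index]
    if missing:
        raise ValueError(f"scaled matrix is missing cascade genes: {missing[:5]}")
    markers = list(markers or [])
    kept_markers = [m for m in markers if m in cascade.ranks]
    for m in markers:
        if m not in cascade.ranks:
            warnings.warn(f"marker {m!r} is not in the cascade; label skipped")
    mat = scaled.loc[cascade.genes].to_numpy()
    vlim = _color_limit(mat, cap)
    fig, ax = plt.subplots(figsize=(8, max(3, 0.02 * len(cascade.genes) + 2)))
    ax.imshow(
        np.clip(mat, -vlim, vlim),
        aspect="auto",
        cmap=_CMAP,
        vmin=-vlim,
        vmax=vlim,
        interpolation="nearest",
    )
    for b in cascade.group_boundaries():
        ax.axhline(b - 0.5, color="black", lw=0.6)
    if kept_markers:
        pos = [cascade.ranks[m] - 1 for m in kept_markers]
        ax.set_yticks(pos)
        ax.set_yticklabels(kept_markers, fontsize=6)
    else:
        ax.set_yticks([])
    ax.set_xlabel("pseudotime (ordered cells)")
    ax.set_ylabel("genes (cascade order)")
    path = _save(fig, out, fmt)
    _write_sidecar(path, cascade.genes, vlim)
    return path


def plot_multisample_heatmap(
    consensus: CascadeResult,
    per_sample_scaled: dict,
    cis,
    out="multisample_heatmap",
    fmt: str = "png",
    cap: float = 3.0,
):
    """One heatmap panel per sample, all sharing the consensus row order;
    grey glyphs span each switch point's confidence interval on the
    pseudotime-fraction axis."""
    samples = sorted(per_sample_scaled)
    for s in samples:
        missing = [g for g in consensus.genes if g not in per_sample_scaled[s].index]
        if missing:
            raise ValueError(f"sample {s!r} lacks consistent genes: {missing[:5]}")
    mats = {s: per_sample_scaled[s].loc[consensus.genes].to_numpy() for s in samples}
    vlim = _color_limit(np.concatenate([m.ravel() for m in mats.values()]), cap)
    fig, axes = plt.subplots(
        1, len(samples), figsize=(4 * len(samples), max(3, 0.02 * len(consensus) + 2)),
        squeeze=False,
    )
    ci_rows = []
    by_gene: dict[str, list] = {}
    for ci in cis:
        by_gene.setdefault(ci.gene_id, []).append(ci)
    for ax, s in zip(axes[0], samples):
        n_cells = mats[s].shape[1]
        ax.imshow(
            np.clip(mats[s], -vlim, vlim),
            aspect="auto",
            cmap=_CMAP,
            vmin=-vlim,
            vmax=vlim,
            interpolation="nearest",
        )
        for row, g in enumerate(consensus.genes):
            for ci in by_gene.get(g, []):
                x0, x1 = ci.lower * (n_cells - 1), ci.upper * (n_cells - 1)
                if ci.upper > ci.lower:
                    ax.plot([x0, x1], [row, row], color="grey", lw=1.2, alpha=0.8)
                ax.plot(
                    [ci.mean_fraction * (n_cells - 1)], [row],
                    marker=".", color="grey", ms=2,
                )
        ax.set_title(s)
        ax.set_yticks([])
        ax.set_xlabel("pseudotime (ordered cells)")
    for g in consensus.genes:
        for ci in by_gene.get(g, []):
            ci_rows.append((g, ci.mean_fraction, ci.lower, ci.upper))
    path = _save(fig, out, fmt)
    _write_sidecar(path, consensus.genes, vlim, cis=ci_rows)
    return path


def plot_enrichment_dots(data, out="enrichment_dots", fmt: str = "png"):
    """Dot plot of enrichment results.

    ``data`` is either a list of EnrichmentRow (per-pattern plot: x =
    GeneRatio) or a TemporalEnrichmentResult (x = window, dot color =
    q-value, size proportional to GeneRatio).  Terms are ordered by their
    maximum GeneRatio.
    """
    from .enrichment import TemporalEnrichmentResult

    if isinstance(data, TemporalEnrichmentResult):
        if not data.display_terms:
            warnings.warn("empty temporal enrichment display set; no figure written")
            return None
        ratio, qval = data.ratio, data.qvalue
        fig, ax = plt.subplots(figsize=(1.0 * len(ratio.columns) + 4, 0.35 * len(ratio) + 2))
        for yi, term in enumerate(ratio.index):
            for xi, col in enumerate(ratio.columns):
                r = ratio.loc[term, col]
                if r > 0:
                    ax.scatter(
                        [xi], [yi], s=30 + 300 * r,
                        c=[qval.loc[term, col]], cmap="viridis_r", vmin=0, vmax=0.05,
                    )
        ax.set_yticks(range(len(ratio.index)))
        ax.set_yticklabels(ratio.index, fontsize=7)
        ax.set_xticks(range(len(ratio.columns)))
        ax.set_xticklabels(ratio.columns, rotation=45, ha="right", fontsize=7)
        ax.set_xlabel("gene rank window (cascade order)")
        ax.invert_yaxis()
        path = _save(fig, out, fmt)
        _write_sidecar(path, list(ratio.index), 1.0)
        return path
    rows = list(data)
    if not rows:
        warnings.warn("empty enrichment result; no figure written")
        return None
    rows = sorted(rows, key=lambda r: r.gene_ratio)
    fig, ax = plt.subplots(figsize=(6, 0.35 * len(rows) + 2))
    y = np.arange(len(rows))
    ax.scatter(
        [r.gene_ratio for r in rows], y,
        s=[20 + 15 * r.count for r in rows],
        c=[r.qvalue for r in rows], cmap="viridis_r",
    )
    ax.set_yticks(y)
    ax.set_yticklabels([r.term_name for r in rows], fontsize=7)
    ax.set_xlabel("GeneRatio")
    path = _save(fig, out, fmt)
    _write_sidecar(path, [r.term_id for r in reversed(rows)], 1.0)
    return path
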