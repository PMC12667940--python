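"""Model/Results interface over the cascade pipeline.

``CascadeAnalysis`` is constructed from an expression matrix and a cell
ordering (plus an optional cell-to-sample assignment); ``fit()`` runs the
full analysis — per-gene spline fits and temporal tests, BH filtering,
scaling, switch-point detection, pattern classification, cascade ordering
and, with multiple samples, cross-sample harmonization — and returns a
``CascadeResults`` object carrying the estimates, diagnostics, a summary
table, and plotting/enrichment methods.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from . import plotting
from .cascade import (
    CascadeResult,
    SampleAnalysis,
    analyze_multisample,
    classify_pattern,
    detect_switch_points,
    order_genes,
)
from .enrichment import pattern_enrichment, temporal_enrichment
from .io import (
    CellOrdering,
    ExpressionMatrix,
    SampleAssignment,
    align_matrix_to_ordering,
    write_results_table,
)
from .trajectory import fit_all_genes

logger = logging.getLogger(__name__)

__all__ = ["CascadeAnalysis", "CascadeResults"]


class CascadeAnalysis:
    """Cascade analysis model for one ordered expression matrix.

    Parameters
    ----------
    expr
        Genes x cells normalized expression.
    ordering
        Ordered cell identifiers with pseudotime values; cells of ``expr``
        absent from the ordering are dropped.
    samples
        Optional cell -> sample-label assignment.  With two or more samples
        each sample is analyzed independently and the results harmonized.
    min_cells_per_sample
        Lower bound on per-sample cell counts (multi-sample mode).
    """

    def __init__(
        self,
        expr: ExpressionMatrix,
        ordering: CellOrdering,
        samples: SampleAssignment | None = None,
        min_cells_per_sample: int = 10,
    ):
        self.expr = align_matrix_to_ordering(expr, ordering)
        self.ordering = ordering
        self.samples = samples
        if samples is not None:
            samples.validate_against(ordering, min_cells=min_cells_per_sample)
        self._per_sample_data = self._split_samples()

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, ordering=None, samples=None, **kwargs):
        """Build from a genes x cells DataFrame.

        ``ordering`` may be a list of cell IDs (rank pseudotime), a mapping /
        Series cell -> pseudotime, or None (column order, rank pseudotime).
        ``samples`` may be a mapping / Series cell -> sample label.
        """
        expr = ExpressionMatrix.from_dataframe(df)
        if ordering is None:
            o = CellOrdering.from_ranks(df.columns)
        elif isinstance(ordering, CellOrdering):
            o = ordering
        elif isinstance(ordering, (pd.Series, dict)):
            s = pd.Series(ordering).sort_values(kind="stable")
            o = CellOrdering(tuple(map(str, s.index)), s.to_numpy(dtype=float))
        else:
            o = CellOrdering.from_ranks(ordering)
        if samples is not None and not isinstance(samples, SampleAssignment):
            samples = SampleAssignment(dict(pd.Series(samples).astype(str)))
        return cls(expr, o, samples=samples, **kwargs)

    @classmethod
    def from_samples(cls, matrices: dict, orderings: dict, **kwargs):
        """Build from per-sample matrices and orderings (same genes each).

        Cells are concatenated sample by sample with rank pseudotime; the
        per-sample analyses use each sample's own ordering, so the
        concatenation order does not affect results.
        """
        names = sorted(matrices)
        genes = matrices[names[0]].gene_ids
        for s in names:
            if matrices[s].gene_ids != genes:
                raise ValueError("all samples must share the same genes")
        values = np.concatenate([matrices[s].values for s in names], axis=1)
        cells, mapping = [], {}
        for s in names:
            ids = list(orderings[s].cell_ids)
            cells.extend(ids)
            mapping.update({c: s for c in ids})
        expr = ExpressionMatrix(genes, tuple(cells), values)
        ordering = CellOrdering.from_ranks(cells)
        return cls(expr, ordering, samples=SampleAssignment(mapping), **kwargs)

    def _split_samples(self):
        if self.samples is None or len(self.samples.samples) < 2:
            return {None: (self.expr, self.ordering)}
        out = {}
        for s in self.samples.samples:
            mask = [self.samples.mapping[c] == s for c in self.ordering.cell_ids]
            cells = [c for c, m in zip(self.ordering.cell_ids, mask) if m]
            times = self.ordering.pseudotime[np.asarray(mask)]
            o = CellOrdering(tuple(cells), times)
            out[s] = (align_matrix_to_ordering(self.expr, o), o)
        return out

    @property
    def n_samples(self) -> int:
        return len(self._per_sample_data)

    def fit(self, spline_df: int = 3, alpha: float = 0.05) -> "CascadeResults":
        """Run the full cascade analysis and return the results object."""
        per_sample: dict[str, SampleAnalysis] = {}
        for s, (m, o) in self._per_sample_data.items():
            fits = fit_all_genes(m, o, df=spline_df, alpha=alpha)
            switches, patterns = {}, {}
            for f in fits:
                if f.retained:
                    sw = detect_switch_points(f.scaled, gene_id=f.gene_id)
                    switches[f.gene_id] = sw
                    patterns[f.gene_id] = classify_pattern(f.scaled, sw)
            per_sample[s] = SampleAnalysis(
                fits={f.gene_id: f for f in fits}, switches=switches, patterns=patterns
            )
        if len(per_sample) == 1:
            sa = next(iter(per_sample.values()))
            cascade = order_genes(sa.patterns, sa.switches)
            return CascadeResults(
                self, per_sample, cascade, alpha=alpha, spline_df=spline_df
            )
        consistent, cis, consensus = analyze_multisample(per_sample)
        return CascadeResults(
            self,
            per_sample,
            consensus,
            alpha=alpha,
            spline_df=spline_df,
            consistent_genes=consistent,
            switch_cis=cis,
        )


class CascadeResults:
    """Results of a fitted cascade analysis.

    Attributes
    ----------
    cascade : CascadeResult
        Ordered genes with ranks, patterns and switch points (the consensus
        cascade in multi-sample mode).
    per_sample : dict
        Sample -> per-sample fits/switches/patterns (key ``None`` for a
        single sample).
    consistent_genes, switch_cis
        Multi-sample mode only: genes with identical patterns in all
        samples, and mean +/- 2 SE intervals for each switch point.
    """

    def __init__(
        self,
        model: CascadeAnalysis,
        per_sample: dict,
        cascade: CascadeResult,
        alpha: float,
        spline_df: int,
        consistent_genes=None,
        switch_cis=None,
    ):
        self.model = model
        self.per_sample = per_sample
        self.cascade = cascade
        self.alpha = alpha
        self.spline_df = spline_df
        self.consistent_genes = consistent_genes
        self.switch_cis = switch_cis

    @property
    def is_multisample(self) -> bool:
        return self.consistent_genes is not None

    @property
    def n_retained(self) -> int:
        return len(self.cascade)

    def _single(self) -> SampleAnalysis:
        if self.is_multisample:
            raise ValueError("per-gene fits are per sample in multi-sample mode")
        return next(iter(self.per_sample.values()))

    @property
    def gene_table(self) -> pd.DataFrame:
        """Per-gene results in cascade order (retained genes)."""
        rows = []
        for g in self.cascade.genes:
            sw = self.cascade.switches[g]
            pat = self.cascade.patterns[g]
            row = {
                "gene": g,
                "pattern": pat.label,
                "sign_string": pat.sign_string,
                "n_switch_points": len(sw.fractions),
                "first_switch_fraction": sw.first_fraction
                if sw.fractions
                else np.nan,
                "cascade_rank": self.cascade.ranks[g],
            }
            if sw.indices:
                row["first_switch_index"] = sw.indices[0]
            if not self.is_multisample:
                fit = self._single().fits[g]
                row["pvalue"] = fit.pvalue
                row["qvalue"] = fit.qvalue
            rows.append(row)
        return pd.DataFrame(rows)

    def scaled_matrix(self, sample=None) -> pd.DataFrame:
        """Scaled fitted trajectories (cascade genes x ordered cells)."""
        key = sample if self.is_multisample else None
        sa = self.per_sample[key]
        genes = [g for g in self.cascade.genes if g in sa.fits and sa.fits[g].retained]
        cells = list(self.model._per_sample_data[key][1].cell_ids)
        return pd.DataFrame(
            np.vstack([sa.fits[g].scaled for g in genes]) if genes else np.empty((0, len(cells))),
            index=genes,
            columns=cells,
        )

    def ci_table(self) -> pd.DataFrame:
        if not self.is_multisample:
            raise ValueError("switch-point CIs exist only in multi-sample mode")
        return pd.DataFrame(
            [
                {
                    "gene": ci.gene_id,
                    "switch_ordinal": ci.ordinal,
                    "mean_fraction": ci.mean_fraction,
                    "se": ci.se,
                    "lower": ci.lower,
                    "upper": ci.upper,
                }
                for ci in self.switch_cis
            ]
        )

    def summary(self) -> str:
        """Human-readable summary of the fitted cascade."""
        lines = ["Pseudotime cascade analysis", "=" * 28]
        n_genes = len(self.model.expr.gene_ids)
        n_cells = len(self.model.ordering)
        lines.append(f"genes: {n_genes}    cells: {n_cells}")
        lines.append(f"spline df: {self.spline_df}    alpha (BH): {self.alpha}")
        if self.is_multisample:
            lines.append(
                f"samples: {len(self.per_sample)}    "
                f"consistent genes: {len(self.consistent_genes)}"
            )
        retained = len(self.cascade)
        lines.append(f"genes in cascade: {retained} / {n_genes}")
        counts: dict[str, int] = {}
        for g in self.cascade.genes:
            lbl = self.cascade.patterns[g].label
            counts[lbl] = counts.get(lbl, 0) + 1
        lines.append("pattern counts:")
        for lbl in counts:
            lines.append(f"  {lbl:<12} {counts[lbl]}")
        return "\n".join(lines)

    # ---- downstream analyses -------------------------------------------

    def pattern_enrichment(self, ann, top_k: int = 10):
        return pattern_enrichment(self.cascade, ann, top_k=top_k)

    def temporal_enrichment(self, ann, pattern="increasing", **kwargs):
        return temporal_enrichment(self.cascade, ann, pattern=pattern, **kwargs)

    # ---- output ---------------------------------------------------------

    def write_table(self, path) -> None:
        if self.is_multisample:
            first = sorted(k for k in self.per_sample)[0]
            fits = self.per_sample[first].fits
        else:
            fits = self._single().fits
        write_results_table(self.cascade, fits, path)

    def plot_heatmap(self, markers=None, out="cascade_heatmap", fmt="png", cap=3.0):
        sample = sorted(self.per_sample)[0] if self.is_multisample else None
        return plotting.plot_cascade_heatmap(
            self.scaled_matrix(sample), self.cascade, markers=markers, out=out,
            fmt=fmt, cap=cap,
        )

    def plot_multisample_heatmap(self, out="multisample_heatmap", fmt="png", cap=3.0):
        if not self.is_multisample:
            raise ValueError("multi-sample heatmap requires multi-sample results")
        scaled = {s: self.scaled_matrix(s) for s in self.per_sample}
        return plotting.plot_multisample_heatmap(
            self.cascade, scaled, self.switch_cis, out=out, fmt=fmt, cap=cap
        )
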