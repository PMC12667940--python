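"""Gene-set over-representation along the cascade.

Two analyses: per-pattern enrichment (one query per temporal-pattern group)
and temporal enrichment (sliding windows over one pattern group's cascade
order, localizing terms to trajectory stages).

Note the GeneRatio convention used throughout: Count divided by the number of
*background* genes annotated to the term (term coverage), not Count divided
by the query size as in most over-representation tools.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .cascade import CascadeResult
from .io import TermAnnotation
from .trajectory import adjust_pvalues

__all__ = [
    "EnrichmentRow",
    "WindowSpec",
    "TemporalEnrichmentResult",
    "hypergeometric_test",
    "pattern_enrichment",
    "temporal_enrichment",
    "enrichment_frame",
]


@dataclass(frozen=True)
class EnrichmentRow:
    term_id: str
    term_name: str
    count: int
    gene_ratio: float  # count / (background genes annotated to the term)
    pvalue: float
    qvalue: float
    member_genes: tuple


@dataclass(frozen=True)
class WindowSpec:
    """Half-open rank intervals (1-based start, exclusive end) over one
    pattern group's cascade order."""

    window_size: int
    step: int
    windows: tuple  # of (start_rank, end_rank)

    @classmethod
    def partition(cls, n_genes: int, n_windows: int, overlap: int = 0) -> "WindowSpec":
        if n_windows < 1:
            raise ValueError("n_windows must be >= 1")
        if n_windows > n_genes:
            raise ValueError(
                f"n_windows={n_windows} exceeds the group size ({n_genes}); "
                "use fewer windows"
            )
        size = math.ceil(n_genes / n_windows)
        return cls.sliding(n_genes, size, size - overlap)

    @classmethod
    def sliding(cls, n_genes: int, size: int, step: int) -> "WindowSpec":
        if size < 1 or step < 1:
            raise ValueError("window size and step must be >= 1")
        if step > size:
            raise ValueError("step larger than the window size leaves gaps")
        wins = []
        start = 1
        while True:
            wins.append((start, min(start + size, n_genes + 1)))
            if start + size > n_genes:
                break
            start += step
        return cls(size, step, tuple(wins))


def hypergeometric_test(query, background, term_members):
    """Upper-tail hypergeometric over-representation test.

    Population = background, successes = term members within the background,
    draws = query.  Returns ``(count, gene_ratio, pvalue)`` with gene_ratio =
    count over the number of background genes annotated to the term.
    """
    query = frozenset(query)
    background = frozenset(background)
    term_members = frozenset(term_members)
    if not query <= background:
        raise ValueError("query must be a subset of the background")
    in_bg = term_members & background
    if not in_bg:
        raise ValueError("term has no members in the background")
    count = len(query & in_bg)
    pvalue = float(hypergeom.sf(count - 1, len(background), len(in_bg), len(query)))
    return count, count / len(in_bg), min(pvalue, 1.0)


def _test_terms(query, background, ann: TermAnnotation) -> list[EnrichmentRow]:
    """Hypergeometric test of every term with background overlap; BH across
    the tested terms."""
    rows = []
    for term_id in sorted(ann.terms):
        name, members = ann.terms[term_id]
        in_bg = frozenset(members) & background
        if not in_bg:
            continue
        count, ratio, p = hypergeometric_test(query, background, members)
        rows.append((term_id, name, count, ratio, p, tuple(sorted(query & in_bg))))
    if not rows:
        return []
    qvals = adjust_pvalues([r[4] for r in rows])
    return [
        EnrichmentRow(tid, name, count, ratio, p, float(q), genes)
        for (tid, name, count, ratio, p, genes), q in zip(rows, qvals)
    ]


def _top_by_ratio(rows: list[EnrichmentRow], top_k: int) -> list[EnrichmentRow]:
    return sorted(rows, key=lambda r: (-r.gene_ratio, r.pvalue, r.term_id))[:top_k]


def pattern_enrichment(
    cascade: CascadeResult, ann: TermAnnotation, top_k: int = 10
) -> dict:
    """Per temporal pattern: top ``top_k`` terms by GeneRatio.

    Background = all cascade (significance-retained) genes that appear in the
    annotation universe; the query is each pattern group's annotated genes.
    """
    if not cascade.genes:
        raise ValueError("cascade is empty")
    background = frozenset(cascade.genes) & ann.universe
    out: dict[str, list[EnrichmentRow]] = {}
    labels = []
    for g in cascade.genes:
        lbl = cascade.patterns[g].label
        if lbl not in labels:
            labels.append(lbl)
    for lbl in labels:
        query = frozenset(cascade.pattern_group(lbl)) & background
        if len(query) < 2:
            warnings.warn(f"pattern {lbl!r} has fewer than 2 annotated genes; skipped")
            out[lbl] = []
            continue
        out[lbl] = _top_by_ratio(_test_terms(query, background, ann), top_k)
    return out


@dataclass
class TemporalEnrichmentResult:
    """Sliding-window enrichment over one pattern group.

    ``ratio`` and ``qvalue`` are term x window DataFrames over the display
    set (the union across windows of each window's top terms by GeneRatio
    that pass the q-value cut); ``per_window`` keeps every tested row.
    """

    spec: WindowSpec
    per_window: list  # of (window, list[EnrichmentRow])
    display_terms: list
    ratio: pd.DataFrame
    qvalue: pd.DataFrame


def temporal_enrichment(
    cascade: CascadeResult,
    ann: TermAnnotation,
    pattern: str = "increasing",
    n_windows: int = 10,
    top_k: int = 5,
    q_cut: float = 0.05,
    window_overlap: int = 0,
    background: frozenset | None = None,
) -> TemporalEnrichmentResult:
    """Enrichment within sliding (by default non-overlapping) windows of one
    pattern group's cascade order; terms localized to trajectory stages."""
    group = cascade.pattern_group(pattern)
    if not group:
        raise ValueError(f"no genes with pattern {pattern!r} in the cascade")
    spec = WindowSpec.partition(len(group), n_windows, overlap=window_overlap)
    if background is None:
        background = frozenset(cascade.genes) & ann.universe
    per_window = []
    display: set[str] = set()
    for start, end in spec.windows:
        query = frozenset(group[start - 1 : end - 1]) & background
        rows = _test_terms(query, background, ann) if query else []
        per_window.append(((start, end), rows))
        for r in _top_by_ratio(rows, top_k):
            if r.qvalue < q_cut:
                display.add(r.term_id)
    display_terms = sorted(
        display,
        key=lambda t: -max(
            (r.gene_ratio for _, rows in per_window for r in rows if r.term_id == t),
            default=0.0,
        ),
    )
    cols = [f"{s}-{e - 1}" for s, e in spec.windows]
    ratio = pd.DataFrame(0.0, index=display_terms, columns=cols)
    qval = pd.DataFrame(1.0, index=display_terms, columns=cols)
    for ((_, _), rows), col in zip(per_window, cols):
        for r in rows:
            if r.term_id in display:
                ratio.loc[r.term_id, col] = r.gene_ratio
                qval.loc[r.term_id, col] = r.qvalue
    return TemporalEnrichmentResult(spec, per_window, display_terms, ratio, qval)


def enrichment_frame(rows: list[EnrichmentRow]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "term_id": r.term_id,
                "term_name": r.term_name,
                "count": r.count,
                "gene_ratio": r.gene_ratio,
                "pvalue": r.pvalue,
                "qvalue": r.qvalue,
                "member_genes": ",".join(r.member_genes),
            }
            for r in rows
        ],
        columns=[
            "term_id",
            "term_name",
            "count",
            "gene_ratio",
            "pvalue",
            "qvalue",
            "member_genes",
        ],
    )
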