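"""Switch-point detection, temporal-pattern classification, cascade ordering,
and multi-sample harmonization.

A switch point of gene j is an index i (1-based, i in 1..N-1) where the
scaled fitted trajectory changes sign between consecutive ordered cells:
x_ij * x_{i+1,j} < 0.  Runs of exact zeros are collapsed: if the nonzero
neighbours flanking a zero-run have opposite signs, one switch is recorded at
the last index before the run, preserving "crosses zero" semantics under
floating-point exactness.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "SwitchPointSet",
    "TemporalPattern",
    "CascadeResult",
    "SwitchPointCI",
    "detect_switch_points",
    "classify_pattern",
    "order_genes",
    "analyze_multisample",
    "alternative_orderings",
]

_LABELS = {"-+": "increasing", "+-": "decreasing", "-+-": "up_down", "+-+": "down_up"}


@dataclass(frozen=True)
class SwitchPointSet:
    """Switch points of one gene: 1-based indices and fractions i/N.

    ``indices`` is ``None`` for consensus (multi-sample) sets, where positions
    exist only on the fraction scale.
    """

    gene_id: str
    indices: tuple | None
    fractions: tuple

    def __post_init__(self):
        if self.indices is not None and len(self.indices) != len(self.fractions):
            raise ValueError("indices and fractions must have equal length")
        if self.indices is not None and list(self.indices) != sorted(set(self.indices)):
            raise ValueError("indices must be strictly increasing")
        if list(self.fractions) != sorted(self.fractions):
            raise ValueError("fractions must be non-decreasing")

    @property
    def first_fraction(self) -> float:
        return self.fractions[0] if self.fractions else float("inf")


@dataclass(frozen=True)
class TemporalPattern:
    """Alternating sign string of the trajectory's constant-sign segments."""

    sign_string: str
    complexity: int
    label: str

    @classmethod
    def from_signs(cls, sign_string: str) -> "TemporalPattern":
        k = len(sign_string) - 1
        label = _LABELS.get(sign_string, f"complex({k})")
        return cls(sign_string, k, label)


@dataclass(frozen=True)
class SwitchPointCI:
    """Mean +/- 2 SE confidence interval for one switch point across samples."""

    gene_id: str
    ordinal: int
    mean_fraction: float
    se: float
    lower: float
    upper: float


@dataclass
class CascadeResult:
    """The cascade: genes ordered by pattern complexity, then first switch."""

    genes: list
    ranks: dict
    patterns: dict
    switches: dict

    def __len__(self) -> int:
        return len(self.genes)

    def pattern_group(self, label: str) -> list:
        """Genes with the given pattern label, in cascade order."""
        return [g for g in self.genes if self.patterns[g].label == label]

    def group_boundaries(self) -> list:
        """Row indices (0-based) where the pattern label changes."""
        out = []
        for i in range(1, len(self.genes)):
            if self.patterns[self.genes[i]].label != self.patterns[self.genes[i - 1]].label:
                out.append(i)
        return out


def detect_switch_points(scaled: np.ndarray, gene_id: str = "") -> SwitchPointSet:
    """All 1-based indices i with scaled[i] * scaled[i+1] < 0, with the
    zero-run collapse rule for exact zeros; fractions are i/N."""
    x = np.asarray(scaled, dtype=float)
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 values to detect switch points")
    nz = np.flatnonzero(x)
    indices = []
    for a, b in zip(nz[:-1], nz[1:]):
        if x[a] * x[b] < 0:
            indices.append(int(a) + 1)  # 1-based: last nonzero before the crossing
    fractions = tuple(i / n for i in indices)
    return SwitchPointSet(gene_id, tuple(indices), fractions)


def classify_pattern(scaled: np.ndarray, s: SwitchPointSet) -> TemporalPattern:
    """Sign string of the segments delimited by the switch points.

    Each segment's sign is taken from its entry of largest absolute value,
    which is robust to entries numerically near zero at segment boundaries.
    """
    x = np.asarray(scaled, dtype=float)
    bounds = [0] + [i for i in s.indices] + [x.size]
    signs = []
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        seg = x[lo:hi]
        signs.append("+" if seg[np.argmax(np.abs(seg))] > 0 else "-")
    sign_string = "".join(signs)
    if len(sign_string) == 1 and not s.indices:
        if np.all(x == 0):
            warnings.warn(f"all-zero scaled trajectory for {s.gene_id!r}")
        else:
            warnings.warn(
                f"no switch point found on a scaled trajectory ({s.gene_id!r}); "
                "labelling complex(0)"
            )
        return TemporalPattern(sign_string, 0, "complex(0)")
    for a, b in zip(sign_string[:-1], sign_string[1:]):
        if a == b:  # pragma: no cover - cannot happen for sets from detect_switch_points
            raise ValueError("segment signs do not alternate")
    return TemporalPattern.from_signs(sign_string)


_SIGN_KEY = {"-": 0, "+": 1}


def _order_key(gene, pattern: TemporalPattern, sw: SwitchPointSet):
    # complexity ascending; '-' before '+' lexicographically; first switch
    # position ascending; gene id as the final tie-break
    return (
        pattern.complexity,
        tuple(_SIGN_KEY[c] for c in pattern.sign_string),
        sw.first_fraction,
        gene,
    )


def order_genes(patterns: dict, switches: dict) -> CascadeResult:
    """Order genes into the cascade and assign ranks 1..G."""
    if set(patterns) != set(switches):
        raise ValueError("patterns and switches must cover the same genes")
    genes = sorted(patterns, key=lambda g: _order_key(g, patterns[g], switches[g]))
    ranks = {g: r for r, g in enumerate(genes, start=1)}
    return CascadeResult(genes, ranks, dict(patterns), dict(switches))


@dataclass(frozen=True)
class SampleAnalysis:
    """Per-sample analysis products consumed by analyze_multisample."""

    fits: dict  # gene -> GeneFit
    switches: dict  # gene -> SwitchPointSet (retained genes only)
    patterns: dict  # gene -> TemporalPattern (retained genes only)


def analyze_multisample(per_sample: dict):
    """Harmonize independently analyzed samples.

    A gene is consistent iff it is retained in every sample and its sign
    string is identical in every sample.  Switch positions are compared on the
    fraction scale (i/N per sample); each switch ordinal gets a mean +/- 2
    standard-error confidence interval across samples.  The consensus cascade
    orders genes by mean first-switch fraction within pattern groups.

    Returns ``(consistent_genes, cis, consensus)``.
    """
    if len(per_sample) < 2:
        raise ValueError("multi-sample analysis requires at least 2 samples")
    sample_names = sorted(per_sample)
    retained_sets = []
    for s in sample_names:
        retained = set(per_sample[s].patterns)
        if not retained:
            warnings.warn(f"sample {s!r} retained zero genes")
        retained_sets.append(retained)
    shared = set.intersection(*retained_sets) if retained_sets else set()
    consistent = {
        g
        for g in shared
        if len({per_sample[s].patterns[g].sign_string for s in sample_names}) == 1
    }
    n_s = len(sample_names)
    cis: list[SwitchPointCI] = []
    cons_switches: dict[str, SwitchPointSet] = {}
    cons_patterns: dict[str, TemporalPattern] = {}
    for g in sorted(consistent):
        pat = per_sample[sample_names[0]].patterns[g]
        cons_patterns[g] = pat
        mean_fracs = []
        for k in range(pat.complexity):
            fracs = np.array(
                [per_sample[s].switches[g].fractions[k] for s in sample_names]
            )
            mean = float(fracs.mean())
            se = float(fracs.std(ddof=1) / np.sqrt(n_s)) if n_s > 1 else 0.0
            cis.append(
                SwitchPointCI(
                    g,
                    k + 1,
                    mean,
                    se,
                    max(0.0, mean - 2 * se),
                    min(1.0, mean + 2 * se),
                )
            )
            mean_fracs.append(mean)
        cons_switches[g] = SwitchPointSet(g, None, tuple(mean_fracs))
    consensus = order_genes(cons_patterns, cons_switches)
    return consistent, cis, consensus


def alternative_orderings(
    scaled, gene_ids, method: str = "hierarchical", k: int = 4, seed: int = 1
) -> list:
    """Gene orders from generic clustering, for contrast with the cascade.

    ``hierarchical``: complete-linkage on Euclidean distances of the scaled
    trajectories, dendrogram leaf order.  ``kmeans``: clusters concatenated by
    the first zero crossing of their centroid, genes within a cluster sorted
    by identifier.
    """
    X = np.asarray(scaled, dtype=float)
    gene_ids = list(gene_ids)
    if X.shape[0] != len(gene_ids):
        raise ValueError("scaled matrix rows must match gene_ids")
    if method == "hierarchical":
        from scipy.cluster.hierarchy import leaves_list, linkage

        Z = linkage(X, method="complete", metric="euclidean")
        return [gene_ids[i] for i in leaves_list(Z)]
    if method == "kmeans":
        if k > len(gene_ids):
            raise ValueError(f"k={k} exceeds the number of genes ({len(gene_ids)})")
        from sklearn.cluster import KMeans

        km = KMeans(n_clusters=k, random_state=seed, n_init=10).fit(X)
        labels, centroids = km.labels_, km.cluster_centers_

        def first_cross(c):
            sign = np.sign(c)
            nz = np.flatnonzero(sign)
            for a, b in zip(nz[:-1], nz[1:]):
                if sign[a] != sign[b]:
                    return int(a) + 1
            return c.size + 1

        cluster_order = sorted(range(k), key=lambda c: (first_cross(centroids[c]), c))
        out = []
        for c in cluster_order:
            out.extend(sorted(g for g, lbl in zip(gene_ids, labels) if lbl == c))
        return out
    raise ValueError(f"unknown ordering method: {method}")
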