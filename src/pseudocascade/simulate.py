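"""Synthetic expression datasets with planted temporal patterns.

The generator emulates the statistical structure the cascade analysis
assumes: smooth per-gene trajectories on normalized expression that cross
their own mean at pattern-specific locations, plus Gaussian measurement
noise.  Monotone genes are sigmoids whose centre is calibrated (by bisection)
so that the mean-centred noiseless signal crosses zero exactly at the planted
fraction t*; bump genes are (inverted) Gaussian bumps with two crossings.
Ground truth records, per gene and sample, the planted pattern and the exact
crossing fractions of the noiseless centred signal, which is sufficient to
score retention, pattern labels, switch localization and enrichment without
re-reading generator internals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import CellOrdering, ExpressionMatrix, SampleAssignment, TermAnnotation

__all__ = [
    "SimulationConfig",
    "SimulatedDataset",
    "simulate_dataset",
    "simulate_annotation",
    "write_gmt",
]

_PATTERNS = ("increasing", "decreasing", "up_down", "down_up", "null")


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic cascade.

    Defaults match the reference simulation used throughout the tests: 300
    cells, 150/150/100/100 patterned genes plus 100 nulls, unit amplitude,
    noise sd 0.3, sigmoid width 0.1 of the trajectory span.
    """

    n_cells: int = 300
    n_samples: int = 1
    n_increasing: int = 150
    n_decreasing: int = 150
    n_up_down: int = 100
    n_down_up: int = 100
    n_null: int = 100
    n_mismatch: int = 0  # pattern flips across samples (multi-sample only)
    amplitude: float = 1.0
    noise_sd: float = 0.3
    sigmoid_width: float = 0.05  # fraction of the trajectory span
    bump_sd: float = 0.12
    switch_fraction_range: tuple = (0.2, 0.8)
    bump_center_range: tuple = (0.35, 0.65)
    jitter_sd: float = 0.0  # cross-sample sd of the planted fraction
    planted_fractions: dict | None = None  # pattern -> explicit per-gene t*
    seed: int = 1

    def __post_init__(self):
        for name in ("n_cells", "n_samples"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in (
            "n_increasing",
            "n_decreasing",
            "n_up_down",
            "n_down_up",
            "n_null",
            "n_mismatch",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        lo, hi = self.switch_fraction_range
        if not (0 < lo < hi < 1):
            raise ValueError("switch_fraction_range must lie inside (0, 1)")
        lo, hi = self.bump_center_range
        if not (0 < lo < hi < 1):
            raise ValueError("bump_center_range must lie inside (0, 1)")
        if self.planted_fractions:
            for pat, fr in self.planted_fractions.items():
                if pat not in _PATTERNS[:4]:
                    raise ValueError(f"unknown pattern {pat!r} in planted_fractions")
                if any(not 0 < f < 1 for f in fr):
                    raise ValueError("planted fractions must lie in (0, 1)")


@dataclass
class SimulatedDataset:
    matrices: dict  # sample -> ExpressionMatrix
    orderings: dict  # sample -> CellOrdering
    assignment: SampleAssignment | None
    truth: pd.DataFrame  # gene, sample, pattern, fractions (";"-joined)


def _centered_crossings(signal: np.ndarray, t: np.ndarray) -> list:
    """Fractions where the mean-centred signal changes sign on the cell grid."""
    x = signal - signal.mean()
    sign = np.sign(x)
    nz = np.flatnonzero(sign)
    out = []
    n = x.size
    for a, b in zip(nz[:-1], nz[1:]):
        if sign[a] != sign[b]:
            out.append((a + 1) / n)
    return out


def _feasible_band(t: np.ndarray, width: float) -> tuple:
    """Range of crossing fractions a mean-centred sigmoid of this width can
    realise on the observed span (plus a one-cell safety margin)."""
    n = t.size

    def crossing(c):
        s = 1.0 / (1.0 + np.exp(-(t - c) / width))
        x = s - s.mean()
        idx = np.flatnonzero(np.diff(np.sign(x)))
        return (idx[0] + 1) / n if idx.size else (1.0 if x[0] < 0 else 0.0)

    return crossing(1e-3) + 1.0 / n, crossing(1.0 - 1e-3) - 1.0 / n


def _sigmoid_signal(t: np.ndarray, t_star: float, width: float, amplitude: float) -> np.ndarray:
    """Rising sigmoid whose centred version crosses zero at fraction t*.

    The raw sigmoid centre c is found by bisection: centring shifts the
    crossing away from c by about width*log((1-c)/c), so c != t* in general.
    """

    n = t.size

    def crossing(c):
        s = 1.0 / (1.0 + np.exp(-(t - c) / width))
        x = s - s.mean()
        # first sign change, on the same (i+1)/N scale the detector reports
        idx = np.flatnonzero(np.diff(np.sign(x)))
        return (idx[0] + 1) / n if idx.size else (1.0 if x[0] < 0 else 0.0)

    lo, hi = 1e-3, 1.0 - 1e-3
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if crossing(mid) < t_star:
            lo = mid
        else:
            hi = mid
    c = 0.5 * (lo + hi)
    if abs(crossing(c) - t_star) > 2.0 / n:
        raise ValueError(
            f"switch fraction {t_star:.3f} is unreachable for a sigmoid of "
            f"width {width}: the mean-centred crossing is confined to a "
            "central band; use a narrower sigmoid or a more central fraction"
        )
    return amplitude / (1.0 + np.exp(-(t - c) / width))


def _bump_signal(t: np.ndarray, center: float, sd: float, amplitude: float) -> np.ndarray:
    return amplitude * np.exp(-0.5 * ((t - center) / sd) ** 2)


def _gene_rng(seed: int, gene_index: int, sample_index: int) -> np.random.Generator:
    return np.random.default_rng([seed, gene_index, sample_index])


def simulate_dataset(cfg: SimulationConfig) -> SimulatedDataset:
    """Generate per-sample expression matrices, orderings, and ground truth."""
    counts = [
        ("increasing", cfg.n_increasing),
        ("decreasing", cfg.n_decreasing),
        ("up_down", cfg.n_up_down),
        ("down_up", cfg.n_down_up),
        ("null", cfg.n_null),
        ("mismatch", cfg.n_mismatch),
    ]
    if cfg.n_mismatch and cfg.n_samples < 2:
        raise ValueError("mismatch genes require at least 2 samples")
    genes, gene_pattern = [], {}
    for pat, n in counts:
        for i in range(n):
            g = f"{pat}_{i + 1:04d}"
            genes.append(g)
            gene_pattern[g] = pat
    if not genes:
        raise ValueError("configuration generates zero genes")

    master = np.random.default_rng([cfg.seed, 915001])
    lo, hi = cfg.switch_fraction_range
    base_fraction: dict[str, float] = {}
    for pat in ("increasing", "decreasing", "mismatch"):
        fr = None if cfg.planted_fractions is None else cfg.planted_fractions.get(pat)
        names = [g for g in genes if gene_pattern[g] == pat]
        if fr is not None:
            if len(fr) != len(names):
                raise ValueError(f"planted_fractions[{pat!r}] has wrong length")
            for g, f in zip(names, fr):
                base_fraction[g] = float(f)
        else:
            for g in names:
                base_fraction[g] = float(master.uniform(lo, hi))
    clo, chi = cfg.bump_center_range
    for pat in ("up_down", "down_up"):
        names = [g for g in genes if gene_pattern[g] == pat]
        for g in names:
            base_fraction[g] = float(master.uniform(clo, chi))  # bump centre

    t = (np.arange(cfg.n_cells) + 0.5) / cfg.n_cells  # normalized pseudotime
    matrices, orderings = {}, {}
    truth_rows = []
    assignment_map: dict[str, str] = {}
    samples = [f"s{j + 1}" for j in range(cfg.n_samples)]
    for sj, sample in enumerate(samples):
        values = np.empty((len(genes), cfg.n_cells))
        cells = [f"{sample}_c{i + 1:05d}" for i in range(cfg.n_cells)]
        for c in cells:
            assignment_map[c] = sample
        for gi, g in enumerate(genes):
            pat = gene_pattern[g]
            rng = _gene_rng(cfg.seed, gi, sj)
            eff_pat = pat
            if pat == "mismatch":
                eff_pat = "increasing" if sj == 0 else "decreasing"
            frac = base_fraction.get(g)
            if frac is not None and cfg.jitter_sd > 0:
                if eff_pat in ("increasing", "decreasing"):
                    jlo, jhi = _feasible_band(t, cfg.sigmoid_width)
                else:
                    jlo, jhi = 0.02, 0.98
                for _ in range(100):
                    cand = frac + rng.normal(0.0, cfg.jitter_sd)
                    if jlo < cand < jhi:
                        frac = cand
                        break
                else:
                    raise ValueError(
                        "could not jitter the planted fraction into the feasible band"
                    )
            if eff_pat == "increasing":
                signal = _sigmoid_signal(t, frac, cfg.sigmoid_width, cfg.amplitude)
            elif eff_pat == "decreasing":
                signal = cfg.amplitude - _sigmoid_signal(
                    t, frac, cfg.sigmoid_width, cfg.amplitude
                )
            elif eff_pat == "up_down":
                signal = _bump_signal(t, frac, cfg.bump_sd, cfg.amplitude)
            elif eff_pat == "down_up":
                signal = cfg.amplitude - _bump_signal(t, frac, cfg.bump_sd, cfg.amplitude)
            else:  # null
                signal = np.full(cfg.n_cells, rng.uniform(0, cfg.amplitude))
            crossings = [] if eff_pat == "null" else _centered_crossings(signal, t)
            if eff_pat in ("up_down", "down_up") and len(crossings) != 2:
                raise ValueError(
                    f"bump gene {g} has {len(crossings)} crossings; "
                    "bump centre/sd place crossings outside (0, 1)"
                )
            values[gi] = signal + rng.normal(0.0, cfg.noise_sd, cfg.n_cells)
            truth_rows.append(
                {
                    "gene": g,
                    "sample": sample,
                    "pattern": pat,
                    "sample_pattern": eff_pat,
                    "fractions": ";".join(f"{f:.8f}" for f in crossings),
                }
            )
        matrices[sample] = ExpressionMatrix(tuple(genes), tuple(cells), values)
        orderings[sample] = CellOrdering.from_ranks(cells)
    assignment = SampleAssignment(assignment_map) if cfg.n_samples > 1 else None
    truth = pd.DataFrame(truth_rows)
    return SimulatedDataset(matrices, orderings, assignment, truth)


def first_fractions(truth: pd.DataFrame, sample: str | None = None) -> dict:
    """gene -> planted first-crossing fraction (NaN for null genes)."""
    df = truth if sample is None else truth[truth["sample"] == sample]
    out = {}
    for _, row in df.iterrows():
        fr = row["fractions"]
        out[row["gene"]] = float(fr.split(";")[0]) if fr else float("nan")
    return out


def simulate_annotation(
    cfg: SimulationConfig,
    truth: pd.DataFrame,
    n_background_terms: int = 40,
    term_size_range: tuple = (8, 15),
    planted: list | None = None,
    purity: float = 0.8,
) -> TermAnnotation:
    """Random gene-set annotation with optional planted enriched terms.

    ``planted`` entries are ``(term_id, pattern, fraction_window, size)``:
    at least ``purity`` of the members come from genes of that pattern whose
    planted first-crossing fraction falls in ``fraction_window`` (a (lo, hi)
    tuple, or None for the whole pattern); the rest are drawn uniformly.
    """
    rng = np.random.default_rng([cfg.seed, 915002])
    first_sample = truth["sample"].iloc[0]
    df = truth[truth["sample"] == first_sample]
    all_genes = df["gene"].tolist()
    fracs = first_fractions(truth, first_sample)
    terms: dict[str, tuple[str, frozenset]] = {}
    lo_sz, hi_sz = term_size_range
    if hi_sz > len(all_genes):
        raise ValueError("term size exceeds the number of available genes")
    for pl in planted or []:
        term_id, pattern, window, size = pl
        if size < 1:
            raise ValueError(f"planted term {term_id!r} has size 0")
        pool = [g for g in all_genes if g.startswith(pattern)]
        if window is not None:
            wlo, whi = window
            pool = [g for g in pool if wlo <= fracs[g] < whi]
        n_core = min(len(pool), int(np.ceil(purity * size)))
        if n_core == 0:
            raise ValueError(f"planted term {term_id!r}: empty gene pool")
        core = list(rng.choice(pool, size=n_core, replace=False))
        rest_pool = [g for g in all_genes if g not in core]
        n_rest = min(size - n_core, len(rest_pool))
        rest = list(rng.choice(rest_pool, size=n_rest, replace=False)) if n_rest else []
        terms[term_id] = (term_id, frozenset(core + rest))
    for i in range(n_background_terms):
        size = int(rng.integers(lo_sz, hi_sz + 1))
        members = rng.choice(all_genes, size=size, replace=False)
        tid = f"BG{i + 1:04d}"
        terms[tid] = (tid, frozenset(members))
    return TermAnnotation(terms)


def write_gmt(ann: TermAnnotation, path) -> None:
    with open(path, "w") as fh:
        for term_id in sorted(ann.terms):
            name, members = ann.terms[term_id]
            fh.write("\t".join([term_id, name] + sorted(members)) + "\n")
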