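import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from pseudocascade import (
    classify_pattern,
    detect_switch_points,
    order_genes,
    analyze_multisample,
    alternative_orderings,
)
from pseudocascade.cascade import (
    SampleAnalysis,
    SwitchPointSet,
    TemporalPattern,
)
from pseudocascade.trajectory import GeneFit, scale_fitted
from .conftest import brute_force_switches


class TestDetectSwitchPoints:
    def test_single_crossing_example(self):
        s = detect_switch_points(np.array([-1.2, -0.3, 0.4, 1.1]))
        assert s.indices == (2,)
        assert s.fractions == (0.5,)

    def test_no_crossing(self):
        assert detect_switch_points(np.array([0.5, 0.7, 0.9])).indices == ()

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            detect_switch_points(np.array([1.0]))

    def test_exact_zero_run_collapsed_to_one_switch(self):
        # -1, 0, 0, +1: neighbours flanking the zero run have opposite signs;
        # one switch at the last index before the run (1-based index 1)
        s = detect_switch_points(np.array([-1.0, 0.0, 0.0, 1.0]))
        assert s.indices == (1,)

    def test_zero_touch_without_crossing_is_no_switch(self):
        s = detect_switch_points(np.array([-1.0, 0.0, -1.0, -2.0]))
        assert s.indices == ()

    @settings(max_examples=200, derandomize=True)
    @given(
        hnp.arrays(
            np.float64,
            st.integers(2, 120),
            elements=st.floats(-5, 5, allow_nan=False).filter(lambda v: v != 0),
        )
    )
    def test_matches_brute_force_scan(self, x):
        assert list(detect_switch_points(x).indices) == brute_force_switches(x)


class TestClassifyPattern:
    def _pattern(self, x):
        x = np.asarray(x, dtype=float)
        return classify_pattern(x, detect_switch_points(x))

    def test_rising_curve_is_increasing(self):
        p = self._pattern(np.linspace(-1.5, 1.5, 20))
        assert p.sign_string == "-+"
        assert p.label == "increasing"
        assert p.complexity == 1

    def test_falling_curve_is_decreasing(self):
        assert self._pattern(np.linspace(1.5, -1.5, 20)).label == "decreasing"

    def test_bump_is_up_down(self):
        t = np.linspace(0, 1, 50)
        x = scale_fitted(np.exp(-0.5 * ((t - 0.5) / 0.15) ** 2))
        p = self._pattern(x)
        assert p.sign_string == "-+-"
        assert p.label == "up_down"

    def test_inverted_bump_is_down_up(self):
        t = np.linspace(0, 1, 50)
        x = scale_fitted(-np.exp(-0.5 * ((t - 0.5) / 0.15) ** 2))
        assert self._pattern(x).label == "down_up"

    def test_many_switches_labelled_complex(self):
        x = scale_fitted(np.sin(np.linspace(0, 6 * np.pi, 200)))
        p = self._pattern(x)
        assert p.complexity > 4
        assert p.label == f"complex({p.complexity})"

    def test_no_switch_warns_complex_zero(self):
        with pytest.warns(UserWarning):
            p = classify_pattern(np.array([0.5, 0.7]), SwitchPointSet("g", (), ()))
        assert p.label == "complex(0)"

    @settings(max_examples=100, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_negation_symmetry(self, seed):
        # negating a trajectory swaps increasing<->decreasing and
        # up_down<->down_up but keeps the switch indices
        rng = np.random.default_rng(seed)
        t = np.linspace(0, 1, 80)
        kind = rng.integers(0, 2)
        if kind == 0:
            x = scale_fitted(1 / (1 + np.exp(-(t - rng.uniform(0.3, 0.7)) / 0.08)))
        else:
            x = scale_fitted(np.exp(-0.5 * ((t - rng.uniform(0.4, 0.6)) / 0.15) ** 2))
        s_pos = detect_switch_points(x)
        s_neg = detect_switch_points(-x)
        assert s_pos.indices == s_neg.indices
        swap = {
            "increasing": "decreasing",
            "decreasing": "increasing",
            "up_down": "down_up",
            "down_up": "up_down",
        }
        lbl_pos = classify_pattern(x, s_pos).label
        lbl_neg = classify_pattern(-x, s_neg).label
        assert lbl_neg == swap.get(lbl_pos, lbl_pos)


def _sw(gene, indices, n=100):
    return SwitchPointSet(gene, tuple(indices), tuple(i / n for i in indices))


class TestOrderGenes:
    def test_forced_order_example(self):
        patterns = {
            "A": TemporalPattern.from_signs("-+"),
            "B": TemporalPattern.from_signs("+-"),
            "C": TemporalPattern.from_signs("-+"),
        }
        switches = {"A": _sw("A", [10]), "B": _sw("B", [5]), "C": _sw("C", [3])}
        res = order_genes(patterns, switches)
        assert res.genes == ["C", "A", "B"]
        assert res.ranks == {"C": 1, "A": 2, "B": 3}

    def test_tie_broken_by_gene_id(self):
        patterns = {g: TemporalPattern.from_signs("-+") for g in ("g2", "g1")}
        switches = {g: _sw(g, [7]) for g in ("g2", "g1")}
        assert order_genes(patterns, switches).genes == ["g1", "g2"]

    def test_monotonic_before_nonmonotonic_and_sign_order(self):
        patterns = {
            "ud": TemporalPattern.from_signs("-+-"),
            "du": TemporalPattern.from_signs("+-+"),
            "inc": TemporalPattern.from_signs("-+"),
            "dec": TemporalPattern.from_signs("+-"),
        }
        switches = {g: _sw(g, [50, 70][: patterns[g].complexity]) for g in patterns}
        assert order_genes(patterns, switches).genes == ["inc", "dec", "ud", "du"]

    def test_empty_input_is_valid(self):
        res = order_genes({}, {})
        assert res.genes == [] and res.ranks == {}

    def test_random_genes_rank_bijection_and_group_monotonicity(self):
        rng = np.random.default_rng(12)
        patterns, switches = {}, {}
        signs = ["-+", "+-", "-+-", "+-+"]
        for i in range(500):
            g = f"g{i:03d}"
            s = signs[rng.integers(0, 4)]
            patterns[g] = TemporalPattern.from_signs(s)
            k = len(s) - 1
            idx = sorted(rng.choice(np.arange(1, 100), size=k, replace=False))
            switches[g] = _sw(g, idx)
        res = order_genes(patterns, switches)
        assert sorted(res.ranks.values()) == list(range(1, 501))
        # oracle: a brute-force stable sort by the documented key
        key = lambda g: (
            patterns[g].complexity,
            patterns[g].sign_string.replace("-", "0").replace("+", "1"),
            switches[g].fractions[0],
            g,
        )
        assert res.genes == sorted(patterns, key=key)
        comp = [patterns[g].complexity for g in res.genes]
        assert comp == sorted(comp)
        for s in signs:
            firsts = [
                switches[g].indices[0]
                for g in res.genes
                if patterns[g].sign_string == s
            ]
            assert firsts == sorted(firsts)


def _sample_analysis(fracs_by_gene, sign="-+", n=100):
    sw, pat, fits = {}, {}, {}
    for g, fr in fracs_by_gene.items():
        idx = tuple(max(1, round(f * n)) for f in fr)
        sw[g] = SwitchPointSet(g, idx, tuple(fr))
        pat[g] = TemporalPattern.from_signs(sign if isinstance(sign, str) else sign[g])
        fits[g] = GeneFit(g, np.zeros(2), 0.0, 0.0, retained=True)
    return SampleAnalysis(fits, sw, pat)


class TestAnalyzeMultisample:
    def test_ci_example_mean_and_se(self):
        per_sample = {
            f"s{i}": _sample_analysis({"g": [f]}) for i, f in enumerate([0.4, 0.5, 0.6])
        }
        consistent, cis, consensus = analyze_multisample(per_sample)
        assert consistent == {"g"}
        ci = cis[0]
        assert ci.mean_fraction == pytest.approx(0.5)
        assert ci.se == pytest.approx(0.1 / np.sqrt(3), abs=1e-6)
        assert ci.lower == pytest.approx(0.5 - 2 * 0.1 / np.sqrt(3), abs=1e-4)
        assert ci.upper == pytest.approx(0.5 + 2 * 0.1 / np.sqrt(3), abs=1e-4)

    def test_pattern_mismatch_excluded(self):
        per_sample = {
            "s1": _sample_analysis({"g": [0.5]}, sign="-+"),
            "s2": _sample_analysis({"g": [0.5]}, sign="+-"),
        }
        consistent, cis, consensus = analyze_multisample(per_sample)
        assert consistent == set()
        assert len(consensus) == 0

    def test_identical_fractions_give_degenerate_ci(self):
        per_sample = {f"s{i}": _sample_analysis({"g": [0.3]}) for i in range(3)}
        _, cis, _ = analyze_multisample(per_sample)
        assert cis[0].se == 0.0
        assert cis[0].lower == cis[0].upper == pytest.approx(0.3)

    def test_consensus_ordered_by_mean_first_fraction(self):
        per_sample = {
            "s1": _sample_analysis({"early": [0.2], "late": [0.7]}),
            "s2": _sample_analysis({"early": [0.3], "late": [0.8]}),
        }
        _, _, consensus = analyze_multisample(per_sample)
        assert consensus.genes == ["early", "late"]

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError, match="2 samples"):
            analyze_multisample({"s1": _sample_analysis({"g": [0.5]})})

    def test_empty_sample_warns(self):
        per_sample = {
            "s1": _sample_analysis({"g": [0.5]}),
            "s2": _sample_analysis({}),
        }
        with pytest.warns(UserWarning, match="zero genes"):
            consistent, _, _ = analyze_multisample(per_sample)
        assert consistent == set()


@pytest.fixture(scope="module")
def scaled():
    rng = np.random.default_rng(6)
    t = np.linspace(0, 1, 60)
    rows, genes = [], []
    for i in range(12):
        c = rng.uniform(0.3, 0.7)
        rows.append(scale_fitted(1 / (1 + np.exp(-(t - c) / 0.1))))
        genes.append(f"g{i:02d}")
    rows.append(rows[0].copy())
    genes.append("twin")
    return np.vstack(rows), genes


class TestAlternativeOrderings:
    def test_identical_trajectories_adjacent_in_hierarchical(self, scaled):
        X, genes = scaled
        order = alternative_orderings(X, genes, method="hierarchical")
        assert abs(order.index("g00") - order.index("twin")) == 1

    def test_kmeans_k1_is_gene_id_order(self, scaled):
        X, genes = scaled
        assert alternative_orderings(X, genes, method="kmeans", k=1) == sorted(genes)

    def test_kmeans_deterministic_given_seed(self, scaled):
        X, genes = scaled
        a = alternative_orderings(X, genes, method="kmeans", k=3, seed=4)
        b = alternative_orderings(X, genes, method="kmeans", k=3, seed=4)
        assert a == b

    def test_k_too_large_rejected(self, scaled):
        X, genes = scaled
        with pytest.raises(ValueError, match="exceeds"):
            alternative_orderings(X, genes, method="kmeans", k=99)
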