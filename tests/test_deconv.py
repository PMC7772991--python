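"""Deconvolution solver, presence classification and explanations."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from abdeconv.crossreact import CrossReactivityMatrix, build_graph
from abdeconv.deconv import (
    DeconvolutionModel,
    classify,
    deconvolve,
    explain,
)


def matrix2(g12=0.0, g21=0.0, names=("ab1", "ab2")):
    G = np.eye(2)
    G[0, 1] = g12
    G[1, 0] = g21
    return CrossReactivityMatrix(tuple(names), G)


def gaussian_elimination(A, b):
    """Brute-force solve with partial pivoting; the independent oracle."""
    A = np.array(A, dtype=float)
    b = np.array(b, dtype=float)
    n = len(b)
    for col in range(n):
        piv = col + int(np.argmax(np.abs(A[col:, col])))
        if piv != col:
            A[[col, piv]] = A[[piv, col]]
            b[[col, piv]] = b[[piv, col]]
        for row in range(col + 1, n):
            f = A[row, col] / A[col, col]
            A[row, col:] -= f * A[col, col:]
            b[row] -= f * b[col]
    x = np.zeros(n)
    for row in range(n - 1, -1, -1):
        x[row] = (b[row] - A[row, row + 1:] @ x[row + 1:]) / A[row, row]
    return x


def random_sparse_matrix(rng, n=16, n_links=28):
    """Random well-conditioned unit-diagonal matrix with ~n_links entries."""
    while True:
        G = np.eye(n)
        off = [(i, j) for i in range(n) for j in range(n) if i != j]
        picks = rng.choice(len(off), size=n_links, replace=False)
        for p in picks:
            i, j = off[p]
            G[i, j] = rng.uniform(0.05, 0.6)
        if np.linalg.cond(G) < 1e6:
            return CrossReactivityMatrix(tuple(f"a{i}" for i in range(n)), G)


class TestDeconvolve:
    def test_identity_returns_input(self):
        m = CrossReactivityMatrix(("a", "b", "c"), np.eye(3))
        F = np.array([5.0, 0.0, 7.0])
        f_prime, info = deconvolve(m, F)
        assert np.allclose(f_prime, F)
        assert info["residual"] < 1e-12

    def test_two_by_two_elimination(self):
        f_prime, _ = deconvolve(matrix2(g12=0.5), [10.0, 4.0])
        assert np.allclose(f_prime, [8.0, 4.0])

    def test_negative_deconvoluted_signal(self):
        # observed signal smaller than the cross-reaction prediction
        f_prime, _ = deconvolve(matrix2(g12=0.8), [0.5, 10.0])
        assert np.allclose(f_prime, [-7.5, 10.0])

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError, match="shape"):
            deconvolve(matrix2(), [1.0, 2.0, 3.0])

    def test_solver_matches_gaussian_elimination(self, rng):
        for _ in range(50):
            m = random_sparse_matrix(rng)
            F = rng.uniform(0, 5000, m.n)
            f_prime, info = deconvolve(m, F)
            expected = gaussian_elimination(m.G, F)
            denom = max(np.max(np.abs(expected)), 1.0)
            assert np.max(np.abs(f_prime - expected)) / denom < 1e-8
            assert info["residual"] / max(np.linalg.norm(F), 1e-30) < 1e-8

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        a=st.floats(min_value=1e-3, max_value=1e3),
        f1=st.floats(min_value=0, max_value=1e4),
        f2=st.floats(min_value=0, max_value=1e4),
    )
    def test_linearity_in_f(self, a, f1, f2):
        m = matrix2(g12=0.5, g21=0.3)
        F = np.array([f1, f2])
        fp1, _ = deconvolve(m, F)
        fp2, _ = deconvolve(m, a * F)
        assert np.allclose(fp2, a * fp1, rtol=1e-9, atol=1e-9)

    def test_singular_matrix_min_norm_with_warning(self):
        # duplicate columns: G is singular, but a report must still come out
        G = np.eye(3)
        G[0, 1] = 1.0
        G[1, 0] = 1.0
        m = CrossReactivityMatrix(("a", "b", "c"), G)
        F = np.array([2.0, 2.0, 1.0])
        with pytest.warns(RuntimeWarning, match="ill-conditioned"):
            f_prime, info = deconvolve(m, F)
        assert info["ill_conditioned"]
        assert np.allclose(m.G @ f_prime, F)  # consistent system: exact lstsq


class TestClassify:
    def test_in_array_explanation_case(self):
        """Bright spot fully explained by an in-array cross-reactor."""
        m = matrix2(g12=0.5)
        graph = build_graph(m)
        F = np.array([5.0, 10.0])
        f_prime, _ = deconvolve(m, F)
        assert np.allclose(f_prime, [0.0, 10.0])
        report = classify(m, graph, F, f_prime, B=1.0)
        ab1, ab2 = report.calls
        assert (ab1.ab_type, ab1.presence) == ("B", "II.a")
        assert [e[0] for e in ab1.explanation] == ["ab2"]
        assert ab1.explanation[0][1] == pytest.approx(5.0)
        assert (ab2.ab_type, ab2.presence) == ("A", "III")

    def test_off_array_relative_case(self):
        """Signal without the expected forward cross-reaction: II.b."""
        m = matrix2(g12=0.8)
        graph = build_graph(m)
        F = np.array([0.5, 10.0])
        f_prime, _ = deconvolve(m, F)
        report = classify(m, graph, F, f_prime, B=1.0)
        ab1, ab2 = report.calls
        assert ab1.presence == "I"
        assert (ab2.ab_type, ab2.presence) == ("A", "II.b")

    def test_all_zero_signals_are_type_i(self):
        m = matrix2(g12=0.5, g21=0.2)
        graph = build_graph(m)
        F = np.zeros(2)
        f_prime, _ = deconvolve(m, F)
        report = classify(m, graph, F, f_prime, B=1.0)
        assert all(c.presence == "I" for c in report.calls)

    def test_b_type_never_gets_iib(self, rng):
        for _ in range(50):
            m = random_sparse_matrix(rng, n=6, n_links=8)
            graph = build_graph(m)
            F = rng.uniform(0, 1000, m.n)
            f_prime, _ = deconvolve(m, F)
            report = classify(m, graph, F, f_prime, B=10.0)
            for c in report.calls:
                assert c.presence in {"I", "II.a", "II.b", "III"}
                if c.ab_type == "B":
                    assert c.presence != "II.b"

    def test_small_expected_signal_cannot_fail_consistency(self):
        # out-link expected signal below theta_pos is not testable
        m = matrix2(g21=0.1)  # link ab1 -> ab2, weight 0.1
        graph = build_graph(m)
        F = np.array([100.0, 10.0])
        f_prime, _ = deconvolve(m, F)
        report = classify(m, graph, F, f_prime, B=10.0)
        # expected signal on ab2 = 0.1 * ~99 < theta_pos = 25 -> vacuous pass
        assert report.call("ab1").presence == "III"

    def test_node_set_mismatch_errors(self):
        m = matrix2()
        other = build_graph(matrix2(names=("x", "y")))
        with pytest.raises(ValueError, match="nodes"):
            classify(m, other, np.zeros(2), np.zeros(2), B=1.0)


def expected_code(f_high, fp_high, ab_type, consistent):
    if not f_high:
        return "I"
    if not fp_high:
        return "II.a"
    if ab_type == "B":
        return "III"
    return "III" if consistent else "II.b"


class TestDecisionTable:
    @pytest.mark.parametrize("f_high", [False, True])
    @pytest.mark.parametrize("fp_high", [False, True])
    @pytest.mark.parametrize("ab_type", ["A", "B"])
    @pytest.mark.parametrize("consistent", [False, True])
    def test_every_combination_has_exactly_one_code(
        self, f_high, fp_high, ab_type, consistent
    ):
        """Exhaustive enumeration of the classification decision tree.

        Node X is probed with every combination of observed-signal level,
        deconvoluted-signal level, node type and out-neighbour consistency;
        each combination must yield exactly the tree's code.
        """
        B, mult = 10.0, 2.5  # theta_pos 25, theta_dec 12.5
        if ab_type == "A":
            # X has one out-link X -> Y of weight 0.8
            G = np.array([[1.0, 0.0], [0.8, 1.0]])
        else:
            # only an in-link Y -> X: X stays B-type
            G = np.array([[1.0, 0.5], [0.0, 1.0]])
        m = CrossReactivityMatrix(("X", "Y"), G)
        graph = build_graph(m)
        f_x = 100.0 if f_high else 20.0
        fp_x = 50.0 if fp_high else 5.0
        # expected signal on Y = 0.8 * 50 = 40 > theta_pos when fp is high
        f_y = 100.0 if consistent else 5.0
        fp_y = 5.0
        report = classify(m, graph, np.array([f_x, f_y]), np.array([fp_x, fp_y]), B=B)
        assert report.call("X").presence == expected_code(
            f_high, fp_high, ab_type, consistent
        )


class TestExplain:
    def test_identity_single_self_contribution(self):
        m = CrossReactivityMatrix(("a", "b"), np.eye(2))
        model = DeconvolutionModel(m)
        res = model.fit(np.array([30.0, 40.0]), background=1.0)
        assert res.explain("a") == [("a", 30.0)]

    def test_contributions_sum_to_observed(self, rng):
        m = random_sparse_matrix(rng, n=8, n_links=12)
        model = DeconvolutionModel(m)
        F = rng.uniform(0, 2000, m.n)
        res = model.fit(F, background=50.0)
        for i, code in enumerate(m.antibody_order):
            contribs = res.explain(code)
            assert sum(v for _, v in contribs) == pytest.approx(F[i], abs=1e-6)
            values = [v for _, v in contribs]
            assert values == sorted(values, reverse=True)

    def test_unknown_antibody_errors(self):
        m = matrix2()
        model = DeconvolutionModel(m)
        res = model.fit(np.array([1.0, 1.0]), background=1.0)
        with pytest.raises(KeyError):
            res.explain("nope")


class TestModelResults:
    def test_summary_and_frame(self):
        m = matrix2(g12=0.5)
        res = DeconvolutionModel(m).fit(np.array([10.0, 4.0]), background=1.0)
        text = res.summary()
        assert "residual" in text and "ab1" in text
        frame = res.to_frame()
        assert frame.loc["ab1", "F_prime"] == pytest.approx(8.0)
        assert set(frame.columns) >= {
            "F", "F_prime", "ab_type", "presence_code", "top_explainer", "residual",
        }

    def test_json_round_trip(self, tmp_path):
        import json

        m = matrix2(g12=0.5)
        res = DeconvolutionModel(m).fit(np.array([10.0, 4.0]), background=1.0)
        path = tmp_path / "report.json"
        res.report.to_json(path)
        payload = json.loads(path.read_text())
        assert payload["antibodies"][0]["code"] == "ab1"
        assert payload["antibodies"][0]["F_prime"] == pytest.approx(8.0)
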