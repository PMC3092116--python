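import numpy as np
import pandas as pd
import pytest

from gbmpipe.annotation import ExonTranscriptIncidence, build_incidence
from gbmpipe.expression import (
    differential_expression,
    fold_change,
    gene_level_from_exons,
    per_sample_fold_change,
    select_dets,
    solve_transcripts,
    solve_transcripts_matrix,
)

from conftest import make_models


def normal_equations(a, e):
    """Independent least-squares oracle: t = (A'A)^-1 A'e."""
    return np.linalg.solve(a.T @ a, a.T @ e)


def incidence(gene, exons, matrix):
    n = np.asarray(matrix, dtype=float).shape[1]
    return ExonTranscriptIncidence(gene, exons, [f"T{k}" for k in range(n)], np.asarray(matrix, float))


@pytest.mark.parametrize(
    "matrix, e, expected_t, expected_resid",
    [
        ([[1.0], [1.0]], [3.0, 5.0], [4.0], np.sqrt(2.0)),  # oracle: (A'A)^-1 A'e = 4
        ([[1.0, 0.0], [0.0, 1.0]], [2.0, 7.0], [2.0, 7.0], 0.0),  # identity system
        ([[1, 0], [1, 1], [0, 1]], [2.0, 5.0, 3.0], [2.0, 3.0], 0.0),  # exact shared-exon fit
    ],
)
def test_solve_transcripts_examples(matrix, e, expected_t, expected_resid):
    sol = solve_transcripts(incidence("G", [f"e{i}" for i in range(len(e))], matrix), e)
    np.testing.assert_allclose(sol.values, expected_t, atol=1e-10)
    assert sol.residual_norm == pytest.approx(expected_resid, abs=1e-10)
    assert not sol.rank_deficient


def test_solver_matches_normal_equations_on_random_systems(rng):
    for _ in range(50):
        m = int(rng.integers(2, 9))
        n = int(rng.integers(1, min(m, 4) + 1))
        a = (rng.random((m, n)) < 0.5).astype(float)
        a[:n, :n] = np.eye(n)  # identity block forces full column rank
        a[a.sum(axis=1) == 0, 0] = 1.0  # every exon belongs to >= 1 transcript
        e = rng.normal(size=m) * 10
        sol = solve_transcripts(incidence("G", [f"e{i}" for i in range(a.shape[0])], a), e)
        np.testing.assert_allclose(sol.values, normal_equations(a, e), atol=1e-8)


def test_rank_deficient_system_flagged_minimum_norm():
    # duplicated transcript columns: infinitely many solutions, min-norm picked
    a = [[1.0, 1.0], [1.0, 1.0]]
    sol = solve_transcripts(incidence("G", ["e0", "e1"], a), [4.0, 4.0])
    assert sol.rank_deficient
    np.testing.assert_allclose(sol.values, [2.0, 2.0], atol=1e-10)


def test_solve_dimension_mismatch():
    with pytest.raises(ValueError, match="does not match"):
        solve_transcripts(incidence("G", ["e0", "e1"], [[1.0], [1.0]]), [1.0, 2.0, 3.0])


def test_solver_consistent_under_row_permutation(rng):
    models = make_models({"G1": {"T1": ["a", "b", "c"], "T2": ["b", "d"]}})
    shuffled = models.sample(frac=1.0, random_state=9)
    e = pd.DataFrame({"s1": [5.0, 9.0, 4.0, 3.0]}, index=["a", "b", "c", "d"])
    t1 = solve_transcripts_matrix(build_incidence(models)["G1"], e)
    t2 = solve_transcripts_matrix(build_incidence(shuffled)["G1"], e)
    pd.testing.assert_frame_equal(t1, t2)


@pytest.mark.parametrize(
    "exon_values, expected",
    [([5.0], 5.0), ([1.0, 2.0, 9.0], 2.0), ([1.0, 3.0], 2.0)],
)
def test_gene_level_median(exon_values, expected):
    exons = [f"e{i}" for i in range(len(exon_values))]
    mat = pd.DataFrame({"s1": exon_values}, index=exons)
    out = gene_level_from_exons(mat, pd.Series("G1", index=exons))
    assert out.loc["G1", "s1"] == expected


@pytest.mark.parametrize(
    "tumor, control, expected",
    [([6.0], [3.0], 2.0), ([4.0, 4.0], [4.0, 4.0], 1.0), ([1.0, 2.0], [4.0, 4.0], 0.375)],
)
def test_fold_change(tumor, control, expected):
    assert fold_change(tumor, control) == pytest.approx(expected)


def test_fold_change_undefined_for_nonpositive_control():
    assert np.isnan(fold_change([1.0], [0.0]))


@pytest.mark.parametrize("value, mean, expected", [(8.0, 4.0, 2.0), (4.0, 4.0, 1.0), (1.0, 4.0, 0.25)])
def test_per_sample_fold_change(value, mean, expected):
    assert per_sample_fold_change(value, mean) == pytest.approx(expected)


def _roles(n_tumor, n_control):
    ids = [f"T{i}" for i in range(n_tumor)] + [f"C{i}" for i in range(n_control)]
    return pd.Index(ids), pd.Series(["tumor"] * n_tumor + ["control"] * n_control, index=ids)


def bh_adjust(p):
    """Independent step-up oracle for Benjamini-Hochberg."""
    p = np.asarray(p, float)
    order = np.argsort(p)
    m = len(p)
    adj = np.empty(m)
    prev = 1.0
    for rank_from_top, idx in enumerate(order[::-1]):
        rank = m - rank_from_top
        prev = min(prev, p[idx] * m / rank)
        adj[idx] = prev
    return adj


def test_differential_expression_matches_hand_bh(rng):
    ids, roles = _roles(6, 6)
    mat = pd.DataFrame(rng.normal(100, 10, size=(20, 12)), columns=ids)
    mat.iloc[:3, :6] *= 3  # a few real effects to spread the p-values
    rec = differential_expression(mat, roles)
    np.testing.assert_allclose(rec["adj_p"], bh_adjust(rec["p"]), atol=1e-12)
    assert (rec["adj_p"] >= rec["p"] - 1e-15).all()
    assert rec["adj_p"].between(0, 1).all()


def test_differential_expression_null_case(rng):
    ids, roles = _roles(40, 40)
    mat = pd.DataFrame(rng.normal(100, 10, size=(50, 80)), columns=ids)
    rec = differential_expression(mat, roles)
    assert rec["adj_p"].median() > 0.5
    assert np.allclose(rec["fc"], 1.0, atol=0.15)


def test_zero_variance_features_flagged_missing():
    ids, roles = _roles(3, 3)
    mat = pd.DataFrame([[5.0] * 6, [1, 2, 3, 4, 5, 6]], index=["flat", "ok"], columns=ids)
    rec = differential_expression(mat, roles)
    assert np.isnan(rec.loc["flat", "p"]) and np.isnan(rec.loc["flat", "adj_p"])
    assert np.isfinite(rec.loc["ok", "p"])


@pytest.mark.parametrize(
    "fc, adj_p, selected",
    [
        (2.5, 0.03, True),  # overexpression passing both gates
        (0.4, 0.01, True),  # underexpression side of the symmetric gate
        (1.5, 0.001, False),  # fails the fold-change gate
        (2.5, 0.05, False),  # adjusted P not strictly below 0.05
        (2.0, 0.01, False),  # fold change not strictly above 2
    ],
)
def test_det_selection_gates(fc, adj_p, selected):
    rec = pd.DataFrame({"fc": [fc], "t": [0.0], "p": [adj_p / 2], "adj_p": [adj_p]}, index=["f"])
    assert ("f" in select_dets(rec)) is selected
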