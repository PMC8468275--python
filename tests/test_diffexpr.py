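import numpy as np
import pandas as pd
import pytest

from cernapipe.diffexpr import (
    DEFAULT_THRESHOLDS,
    DEThresholds,
    ExpressionMatrix,
    call_de,
    compute_cpm,
    filter_detected,
    quantile_normalize,
    read_de_table,
    relative_expression_ddct,
    run_de,
    test_differential as run_t_test,
    write_de_table,
)

from conftest import de_frame, intensity_matrix
from oracles import welch_p


# --------------------------------------------------------------- construction


def test_matrix_validation():
    with pytest.raises(ValueError, match="group label"):
        ExpressionMatrix(
            values=pd.DataFrame(np.ones((2, 4)),
                                columns=["a", "b", "c", "d"]),
            groups=pd.Series(["WT", "WT", "XX", "XX"],
                             index=["a", "b", "c", "d"]),
            platform="intensity",
        )
    with pytest.raises(ValueError, match=">= 2 samples"):
        ExpressionMatrix(
            pd.DataFrame(np.ones((2, 3)), columns=["WT_1", "WT_2", "KO_1"]),
            pd.Series(["WT", "WT", "KO"], index=["WT_1", "WT_2", "KO_1"]),
            platform="intensity",
        )
    with pytest.raises(ValueError, match="nonnegative integers"):
        ExpressionMatrix(
            pd.DataFrame(np.full((1, 4), 1.5), columns=["WT_1", "WT_2", "KO_1", "KO_2"]),
            pd.Series(["WT", "WT", "KO", "KO"],
                      index=["WT_1", "WT_2", "KO_1", "KO_2"]),
            platform="counts",
        )


def test_matrix_tsv_roundtrip(tmp_path):
    mat = intensity_matrix(np.arange(1.0, 13.0).reshape(2, 6))
    path = tmp_path / "m.tsv"
    mat.to_tsv(path, header_comment="hdr")
    assert open(path).readline().startswith("# hdr")
    back = ExpressionMatrix.from_tsv(path, "intensity")
    # the writer labels the index column "feature"; values must round-trip
    pd.testing.assert_frame_equal(back.values, mat.values, check_names=False)
    assert list(back.groups) == list(mat.groups)


# ------------------------------------------------------- quantile normalization


def test_quantile_normalize_hand_example():
    # no ties: each column becomes the rank means, reordered by rank
    vals = np.array([[2.0, 9.0, 2.0, 9.0], [4.0, 1.0, 4.0, 1.0], [6.0, 5.0, 6.0, 5.0]])
    cols = ["WT_1", "WT_2", "KO_1", "KO_2"]
    mat = ExpressionMatrix(
        pd.DataFrame(vals, columns=cols, index=["a", "b", "c"]),
        pd.Series(["WT", "WT", "KO", "KO"], index=cols),
        platform="intensity",
    )
    qn = quantile_normalize(mat).values.to_numpy()
    rank_means = np.sort(vals, axis=0).mean(axis=1)  # [1.5, 4.5, 7.5] per rank
    assert np.allclose(np.sort(qn, axis=0), np.tile(rank_means, (4, 1)).T)
    # column 0 was already sorted: it becomes the rank means directly
    assert np.allclose(qn[:, 0], rank_means)
    # column 1 order 9,1,5 -> ranks 2,0,1
    assert np.allclose(qn[:, 1], rank_means[[2, 0, 1]])


def test_quantile_normalize_identical_columns_and_idempotence(rng):
    vals = 2.0 ** rng.uniform(2, 12, size=(50, 6))
    mat = intensity_matrix(vals)
    qn = quantile_normalize(mat)
    arrs = qn.values.to_numpy()
    for j in range(1, 6):
        assert np.allclose(np.sort(arrs[:, 0]), np.sort(arrs[:, j]))
    qn2 = quantile_normalize(qn)
    assert np.allclose(qn.values.to_numpy(), qn2.values.to_numpy())


def test_quantile_normalize_ties_get_mean_of_spanned_ranks():
    vals = np.array([[1.0, 1.0, 1.0, 1.0],
                     [1.0, 2.0, 2.0, 2.0],
                     [3.0, 3.0, 3.0, 3.0]])
    cols = ["WT_1", "WT_2", "KO_1", "KO_2"]
    mat = ExpressionMatrix(
        pd.DataFrame(vals, columns=cols, index=["a", "b", "c"]),
        pd.Series(["WT", "WT", "KO", "KO"], index=cols),
        platform="intensity",
    )
    qn = quantile_normalize(mat).values.to_numpy()
    rank_means = np.sort(vals, axis=0).mean(axis=1)
    # column 0 ties at ranks 0 and 1: both rows get their mean
    tied = 0.5 * (rank_means[0] + rank_means[1])
    assert np.allclose(qn[:, 0], [tied, tied, rank_means[2]])


# ------------------------------------------------------------ filtering / CPM


def test_filter_detected():
    flags = np.array([["P", "P", "P", "A", "A", "A"],
                      ["P", "M", "A", "A", "A", "A"],
                      ["M", "M", "M", "M", "M", "M"]])
    mat = intensity_matrix(np.ones((3, 6)), flags=flags)
    kept = filter_detected(mat, min_detected=3)
    assert list(kept.values.index) == ["f0", "f2"]
    kept2 = filter_detected(mat, min_detected=2)
    assert list(kept2.values.index) == ["f0", "f1", "f2"]
    with pytest.raises(ValueError):
        filter_detected(intensity_matrix(np.ones((3, 6))), min_detected=3)


def test_compute_cpm_columns_sum_to_1e6(rng):
    counts = rng.integers(0, 1000, size=(20, 6)).astype(float)
    counts[0] += 1  # guard against an all-zero column
    cols = [f"WT_{i}" for i in range(1, 4)] + [f"KO_{i}" for i in range(1, 4)]
    mat = ExpressionMatrix(
        pd.DataFrame(counts, columns=cols, index=[f"m{i}" for i in range(20)]),
        pd.Series(["WT"] * 3 + ["KO"] * 3, index=cols),
        platform="counts",
    )
    cpm = compute_cpm(mat)
    assert np.allclose(cpm.values.sum(axis=0), 1e6)


# ----------------------------------------------------------------- statistics


def test_welch_matches_textbook_formula(rng):
    vals = 2.0 ** rng.normal(8, 1, size=(50, 6))
    mat = intensity_matrix(vals)
    res = run_t_test(mat, var_equal=False)
    logs = np.log2(vals)
    for i in range(50):
        expected = welch_p(logs[i, :3], logs[i, 3:])
        assert res.loc[i, "p"] == pytest.approx(expected, rel=1e-9)


def test_pooled_t_matches_textbook_formula(rng):
    from scipy.stats import t as t_dist

    vals = 2.0 ** rng.normal(8, 1, size=(30, 6))
    mat = intensity_matrix(vals)
    res = run_t_test(mat, var_equal=True)
    logs = np.log2(vals)
    for i in range(30):
        a, b = logs[i, :3], logs[i, 3:]
        sp2 = (a.var(ddof=1) * 2 + b.var(ddof=1) * 2) / 4
        t = (b.mean() - a.mean()) / np.sqrt(sp2 * (1 / 3 + 1 / 3))
        expected = 2 * t_dist.sf(abs(t), 4)
        assert res.loc[i, "p"] == pytest.approx(expected, rel=1e-9)


def test_fold_change_is_ratio_of_linear_means():
    vals = np.array([[10.0, 10.0, 10.0, 25.0, 25.0, 25.0]])
    res = run_t_test(intensity_matrix(vals))
    assert res.loc[0, "FC"] == pytest.approx(2.5)
    assert res.loc[0, "log2FC"] == pytest.approx(np.log2(2.5))


def test_degenerate_rows():
    vals = np.array([[4.0] * 6,                      # constant, equal means
                     [4.0, 4.0, 4.0, 8.0, 8.0, 8.0]])  # constant, unequal
    res = run_t_test(intensity_matrix(vals))
    assert res.loc[0, "p"] == 1.0
    assert res.loc[1, "p"] == 0.0


def _bh_oracle(p: np.ndarray) -> np.ndarray:
    """Textbook Benjamini-Hochberg step-up adjustment."""
    n = len(p)
    order = np.argsort(p)
    adj = np.empty(n)
    running = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * n / rank)
        adj[i] = running
    return adj


def test_bh_fdr_matches_hand_computation(rng):
    # hand example: p = .01,.02,.03,.04 -> all adjusted to 0.04
    assert np.allclose(_bh_oracle(np.array([0.01, 0.02, 0.03, 0.04])), 0.04)
    # the FDR column of test_differential is BH of its p column
    vals = 2.0 ** rng.normal(8, 1, size=(40, 6))
    res = run_t_test(intensity_matrix(vals))
    assert np.allclose(res["FDR"], _bh_oracle(res["p"].to_numpy()))


# -------------------------------------------------------------------- calling


def test_call_de_strict_boundaries_mrna():
    thr = DEFAULT_THRESHOLDS["mRNA"]
    rows = [(1.25, 1e-9), (1.2500001, 1e-9), (0.75, 1e-9), (0.7499999, 1e-9),
            (2.0, 0.05), (2.0, 0.0499999), (1.0, 1e-9)]
    out = call_de(de_frame(rows), thr)
    assert list(out["call"]) == ["none", "up", "none", "down", "none", "up", "none"]


def test_call_de_strict_boundaries_mirna():
    thr = DEFAULT_THRESHOLDS["miRNA"]
    rows = [(1.75, 1e-9), (1.7500001, 1e-9), (0.55, 1e-9), (0.5499999, 1e-9)]
    out = call_de(de_frame(rows), thr)
    assert list(out["call"]) == ["none", "up", "none", "down"]


def test_threshold_validation():
    with pytest.raises(ValueError):
        DEThresholds(up_fc=0.9, down_fc=0.5)
    with pytest.raises(ValueError):
        DEThresholds(up_fc=1.5, down_fc=0.5, alpha=1.5)


# ---------------------------------------------------------------- run_de, qPCR


def test_run_de_intensity_recipe_filters_and_calls(rng):
    n = 40
    vals = 2.0 ** rng.normal(8, 0.05, size=(n, 6))
    vals[0, 3:] *= 4.0   # strong up feature
    flags = np.full((n, 6), "P")
    flags[1] = "A"       # undetected feature dropped
    res = run_de(intensity_matrix(vals, flags=flags), "mRNA")
    assert len(res) == n - 1
    assert "f1" not in set(res["feature"])
    assert res.loc[res["feature"] == "f0", "call"].item() == "up"


def test_run_de_counts_recipe(rng):
    n = 30
    counts = rng.poisson(500, size=(n, 6)).astype(float) + 1
    counts[2, 3:] *= 8
    cols = [f"WT_{i}" for i in range(1, 4)] + [f"KO_{i}" for i in range(1, 4)]
    mat = ExpressionMatrix(
        pd.DataFrame(counts, columns=cols, index=[f"m{i}" for i in range(n)]),
        pd.Series(["WT"] * 3 + ["KO"] * 3, index=cols),
        platform="counts",
    )
    res = run_de(mat, "miRNA")
    assert res.loc[res["feature"] == "m2", "call"].item() == "up"


def test_relative_expression_ddct():
    assert relative_expression_ddct(25.0, 22.0) == pytest.approx(2.0 ** -3)
    assert relative_expression_ddct(20.0, 22.0) == pytest.approx(4.0)
    with pytest.raises(ValueError):
        relative_expression_ddct(float("nan"), 22.0)


def test_de_table_roundtrip(tmp_path):
    out = call_de(de_frame([(2.0, 0.001), (0.5, 0.2)]), DEFAULT_THRESHOLDS["mRNA"])
    path = tmp_path / "de.tsv"
    write_de_table(out, path, header_comment="x")
    back = read_de_table(path)
    assert list(back["call"]) == ["up", "none"]
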