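"""Differential expression for two-group (WT vs KO) designs.

The module covers three analytes with their platform idiosyncrasies:

* mRNA and circRNA arrays: positive intensities with per-cell
  Present/Marginal/Absent detection flags, quantile-normalized, then
  detection-filtered (P or M in >= ``min_detected`` samples).
* miRNA counts: library-size normalized to CPM, a prior count added
  before the log transform.

Testing is a per-feature two-sample t test on log2 values (pooled
variance by default, Welch optional), BH-adjusted FDR, and threshold
calling on the *linear* fold change KO/WT with strict inequalities.
Default cutoffs: mRNA/circRNA up FC > 1.25, down FC < 0.75; miRNA
up FC > 1.75, down FC < 0.55; alpha = 0.05 on the raw p value (FDR is
reported, not used for calling).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

PRIOR_COUNT = 0.5  # added to CPM before log2

Analyte = Literal["mRNA", "circRNA", "miRNA"]


@dataclass(frozen=True)
class DEThresholds:
    """Linear fold-change and p-value cutoffs for one analyte."""

    up_fc: float
    down_fc: float
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not self.down_fc < 1.0 < self.up_fc:
            raise ValueError("need down_fc < 1 < up_fc")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")


DEFAULT_THRESHOLDS: dict[str, DEThresholds] = {
    "mRNA": DEThresholds(up_fc=1.25, down_fc=0.75),
    "circRNA": DEThresholds(up_fc=1.25, down_fc=0.75),
    "miRNA": DEThresholds(up_fc=1.75, down_fc=0.55),
}


@dataclass
class ExpressionMatrix:
    """Features x samples with group labels, platform, optional flags.

    ``values`` is a DataFrame (index = feature ids, columns = sample ids);
    ``groups`` maps sample id -> 'WT' or 'KO'; ``flags`` (intensity
    platform only) is a same-shaped DataFrame over {'P','M','A'}.
    """

    values: pd.DataFrame
    groups: pd.Series
    platform: Literal["intensity", "counts"]
    flags: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.groups = pd.Series(self.groups).reindex(self.values.columns)
        if self.groups.isna().any():
            raise ValueError("every sample column needs a group label")
        bad = set(self.groups.unique()) - {"WT", "KO"}
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)}")
        counts = self.groups.value_counts()
        if (counts < 2).any() or len(counts) < 2:
            raise ValueError("need >= 2 samples in each of WT and KO")
        vals = self.values.to_numpy()
        if not np.isfinite(vals).all():
            raise ValueError("expression values must be finite")
        if self.platform == "counts":
            if (vals < 0).any() or not np.allclose(vals, np.round(vals)):
                raise ValueError("counts platform requires nonnegative integers")
        if self.flags is not None:
            if self.flags.shape != self.values.shape:
                raise ValueError("flags must match the value matrix shape")
            bad_flags = set(np.unique(self.flags.to_numpy())) - {"P", "M", "A"}
            if bad_flags:
                raise ValueError(f"unknown detection flags: {sorted(bad_flags)}")

    def samples(self, group: str) -> list[str]:
        return list(self.groups.index[self.groups == group])

    # ------------------------------------------------------------------ I/O

    def to_tsv(self, path: str | Path, header_comment: str | None = None) -> None:
        with open(path, "w") as fh:
            if header_comment:
                fh.write(f"# {header_comment}\n")
            self.values.rename_axis("feature").to_csv(fh, sep="\t")

    @classmethod
    def from_tsv(
        cls,
        path: str | Path,
        platform: Literal["intensity", "counts"],
        groups: pd.Series | None = None,
        flags_path: str | Path | None = None,
    ) -> "ExpressionMatrix":
        """Load a matrix TSV (first column = feature id).

        When ``groups`` is omitted, sample names must start with their
        group label, e.g. ``WT_1 .. KO_3``.
        """
        values = pd.read_csv(path, sep="\t", index_col=0, comment="#")
        if groups is None:
            groups = pd.Series(
                [c.split("_")[0] for c in values.columns], index=values.columns
            )
        flags = None
        if flags_path is not None:
            flags = pd.read_csv(flags_path, sep="\t", index_col=0, comment="#")
            flags = flags.loc[values.index, values.columns]
        return cls(values=values, groups=groups, platform=platform, flags=flags)


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample column onto the per-rank cross-sample means.

    After normalization every column holds the identical multiset of
    values; ties within a column receive the mean of the rank means they
    span, which makes the transform idempotent.
    """
    if matrix.platform != "intensity":
        raise ValueError("quantile normalization applies to intensity data")
    vals = matrix.values.to_numpy(dtype=float)
    if (vals <= 0).any():
        raise ValueError("quantile normalization requires positive intensities")
    sorted_cols = np.sort(vals, axis=0)
    rank_means = sorted_cols.mean(axis=1)
    out = np.empty_like(vals)
    for j in range(vals.shape[1]):
        # average ranks handle ties; interpolate between rank means
        ranks = stats.rankdata(vals[:, j], method="average") - 1.0
        lo = np.floor(ranks).astype(int)
        hi = np.ceil(ranks).astype(int)
        out[:, j] = 0.5 * (rank_means[lo] + rank_means[hi])
    values = pd.DataFrame(out, index=matrix.values.index, columns=matrix.values.columns)
    return ExpressionMatrix(values, matrix.groups, matrix.platform, matrix.flags)


def filter_detected(matrix: ExpressionMatrix, min_detected: int = 3) -> ExpressionMatrix:
    """Keep features flagged Present or Marginal in >= ``min_detected`` samples."""
    if matrix.flags is None:
        raise ValueError("detection filtering requires flags")
    if min_detected > matrix.values.shape[1]:
        raise ValueError("min_detected exceeds the number of samples")
    n_pm = (matrix.flags.isin(["P", "M"])).sum(axis=1)
    keep = n_pm >= min_detected
    return ExpressionMatrix(
        matrix.values.loc[keep],
        matrix.groups,
        matrix.platform,
        matrix.flags.loc[keep],
    )


def compute_cpm(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Counts per million: count / library size * 1e6, per sample."""
    if matrix.platform != "counts":
        raise ValueError("CPM applies to count data")
    libsizes = matrix.values.sum(axis=0)
    if (libsizes == 0).any():
        raise ValueError("zero library size")
    cpm = matrix.values / libsizes * 1e6
    return ExpressionMatrix(cpm, matrix.groups, platform="intensity", flags=None)


def _two_sample_t(
    log_wt: np.ndarray, log_ko: np.ndarray, var_equal: bool
) -> np.ndarray:
    """Vectorized two-sided two-sample t on rows; degenerate-variance rows
    get p=1 when the group means agree and p=0 when they differ."""
    import warnings

    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        _, p = stats.ttest_ind(log_ko, log_wt, axis=1, equal_var=var_equal)
    p = np.asarray(p, dtype=float)
    degenerate = ~np.isfinite(p)
    if degenerate.any():
        same = np.isclose(log_ko[degenerate].mean(axis=1), log_wt[degenerate].mean(axis=1))
        p[degenerate] = np.where(same, 1.0, 0.0)
    return p


def test_differential(
    matrix: ExpressionMatrix, var_equal: bool = True
) -> pd.DataFrame:
    """Per-feature two-group test on log2 values.

    Intensity input is assumed normalized (quantile or CPM); count input
    is converted to CPM here.  Fold change is the ratio of *linear*
    group means KO/WT; the t test runs on log2 values (log2(CPM+0.5)
    for count-derived data).  Returns a DataFrame with columns
    feature, mean_WT, mean_KO, FC, log2FC, p, FDR, call (call = 'none'
    until :func:`call_de`).
    """
    if matrix.platform == "counts":
        matrix = compute_cpm(matrix)
        prior = PRIOR_COUNT
    else:
        prior = 0.0
    wt = matrix.values[matrix.samples("WT")].to_numpy(dtype=float)
    ko = matrix.values[matrix.samples("KO")].to_numpy(dtype=float)
    mean_wt = wt.mean(axis=1)
    mean_ko = ko.mean(axis=1)
    if (mean_wt <= 0).any():
        raise ValueError("nonpositive WT group mean; cannot form fold change")
    fc = mean_ko / mean_wt
    p = _two_sample_t(np.log2(wt + prior), np.log2(ko + prior), var_equal)
    fdr = multipletests(p, method="fdr_bh")[1]
    with np.errstate(divide="ignore"):
        log2fc = np.log2(fc)
    return pd.DataFrame(
        {
            "feature": matrix.values.index,
            "mean_WT": mean_wt,
            "mean_KO": mean_ko,
            "FC": fc,
            "log2FC": log2fc,
            "p": p,
            "FDR": fdr,
            "call": "none",
        }
    ).reset_index(drop=True)


def call_de(results: pd.DataFrame, thresholds: DEThresholds) -> pd.DataFrame:
    """Apply strict FC/p cutoffs: up if FC > up_fc and p < alpha, down if
    FC < down_fc and p < alpha, else none."""
    out = results.copy()
    sig = out["p"] < thresholds.alpha
    out["call"] = "none"
    out.loc[sig & (out["FC"] > thresholds.up_fc), "call"] = "up"
    out.loc[sig & (out["FC"] < thresholds.down_fc), "call"] = "down"
    return out


def run_de(
    matrix: ExpressionMatrix,
    analyte: Analyte,
    thresholds: DEThresholds | None = None,
    min_detected: int = 3,
    var_equal: bool = True,
) -> pd.DataFrame:
    """The per-analyte DE recipe: normalize, filter, test, call.

    Intensity analytes are quantile-normalized and detection-filtered
    (when flags are present); count analytes go through CPM.
    """
    thresholds = thresholds or DEFAULT_THRESHOLDS[analyte]
    if matrix.platform == "intensity":
        if matrix.flags is not None:
            matrix = filter_detected(matrix, min_detected=min_detected)
        matrix = quantile_normalize(matrix)
    results = test_differential(matrix, var_equal=var_equal)
    return call_de(results, thresholds)


def relative_expression_ddct(ct_target: float, ct_reference: float) -> float:
    """Comparative 2^(-dCt) relative expression for one qPCR sample."""
    if not (np.isfinite(ct_target) and np.isfinite(ct_reference)):
        raise ValueError("Ct values must be finite")
    return float(2.0 ** -(ct_target - ct_reference))


def write_de_table(results: pd.DataFrame, path: str | Path,
                   header_comment: str | None = None) -> None:
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        results.to_csv(fh, sep="\t", index=False, float_format="%.10g")


def read_de_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
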