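"""Statistical comparisons: per-gene Wilcoxon tests, marker detection with
detection-fraction and log-fold-change filters, gene-set signature scores,
and Welch t-tests on per-replicate fractions or per-cell ratios.

Conventions follow common single-cell practice: two-sided Wilcoxon rank-sum
(Mann-Whitney U) for per-gene group comparisons — exact enumeration when
both groups are small and tie-free, normal approximation with tie and
continuity correction otherwise; natural-log fold changes with pseudocount 1
on mean normalized expression; Bonferroni as the default multiple-testing
correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import anndata as ad
import numpy as np
import pandas as pd
from scipy import stats as sps

_EXACT_MAX_N = 8


def _values(expr: ad.AnnData | pd.DataFrame | np.ndarray) -> pd.DataFrame:
    if isinstance(expr, ad.AnnData):
        return pd.DataFrame(
            np.asarray(expr.X, dtype=float),
            index=expr.obs_names,
            columns=expr.var_names,
        )
    if isinstance(expr, pd.DataFrame):
        return expr
    arr = np.asarray(expr, dtype=float)
    return pd.DataFrame(arr)


def _mwu_single(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    if np.ptp(np.concatenate([a, b])) == 0:
        return len(a) * len(b) / 2.0, 1.0  # all values tied
    has_ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    if max(len(a), len(b)) <= _EXACT_MAX_N and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def wilcoxon_gene_test(
    expr: ad.AnnData | pd.DataFrame | np.ndarray,
    cells_a: Sequence[str] | np.ndarray,
    cells_b: Sequence[str] | np.ndarray,
) -> pd.DataFrame:
    """Two-sided Wilcoxon rank-sum test per gene between two cell groups.

    ``cells_a`` / ``cells_b`` are disjoint cell identifiers (or boolean /
    integer indexers).  Returns a DataFrame with the Mann-Whitney U
    statistic of group A and the two-sided p-value per gene.  Genes with
    identical values in all cells get U = n_a * n_b / 2 and p = 1.
    """
    values = _values(expr)

    def take(idx):
        idx = list(idx)
        if idx and isinstance(idx[0], (str, np.str_)):
            return values.loc[idx]
        arr = np.asarray(idx)
        return values.loc[arr] if arr.dtype == bool else values.iloc[arr]

    A, B = take(cells_a), take(cells_b)
    overlap = set(A.index) & set(B.index)
    if overlap:
        raise ValueError(f"groups overlap: {sorted(overlap)[:5]}")
    if A.empty or B.empty:
        raise ValueError("both groups must be non-empty")

    a_arr, b_arr = A.to_numpy(), B.to_numpy()
    n_a, n_b = len(A), len(B)
    if max(n_a, n_b) <= _EXACT_MAX_N:
        rows = [_mwu_single(a_arr[:, j], b_arr[:, j])
                for j in range(values.shape[1])]
        stat, pval = map(np.array, zip(*rows))
    else:
        with np.errstate(invalid="ignore", divide="ignore"):
            res = sps.mannwhitneyu(
                a_arr, b_arr, alternative="two-sided",
                method="asymptotic", axis=0,
            )
        stat = np.asarray(res.statistic, dtype=float)
        pval = np.asarray(res.pvalue, dtype=float)
        constant = np.ptp(np.vstack([a_arr, b_arr]), axis=0) == 0
        stat[constant] = n_a * n_b / 2.0
        pval[constant] = 1.0
    return pd.DataFrame({"statistic": stat, "pvalue": pval},
                        index=values.columns)


def find_markers(
    expr: ad.AnnData | pd.DataFrame,
    labels: Sequence[str] | pd.Series,
    only_pos: bool = True,
    min_pct: float = 0.25,
    logfc_threshold: float = 0.25,
    correction: str = "bonferroni",
) -> dict[str, pd.DataFrame]:
    """One-vs-rest marker genes per label with detection and logFC filters.

    For each label, genes are tested only when detected (value > 0) in at
    least ``min_pct`` of cells in the label or in the rest, and when the
    natural-log fold change of mean normalized expression (pseudocount 1)
    clears ``logfc_threshold`` (positive only when ``only_pos``).  Surviving
    genes get a two-sided Wilcoxon p and a Bonferroni-adjusted p over the
    genes tested for that label.  Labels with fewer than 3 cells are skipped
    with a warning.
    """
    if correction not in ("bonferroni", "bh"):
        raise ValueError("correction must be 'bonferroni' or 'bh'")
    values = _values(expr)
    labels = pd.Series(list(labels), index=values.index)
    if labels.nunique() < 2:
        raise ValueError("need at least 2 distinct labels")

    # mean normalized expression, back-transformed from log1p values
    norm = np.expm1(values)
    out: dict[str, pd.DataFrame] = {}
    for label in labels.unique():
        in_grp = labels == label
        if in_grp.sum() < 3:
            warnings.warn(f"label {label!r} has <3 cells; skipped", stacklevel=2)
            continue
        A, B = values.loc[in_grp.values], values.loc[~in_grp.values]
        pct_a = (A > 0).mean(axis=0)
        pct_b = (B > 0).mean(axis=0)
        logfc = np.log(
            (norm.loc[in_grp.values].mean(axis=0) + 1)
            / (norm.loc[~in_grp.values].mean(axis=0) + 1)
        )
        tested = (pct_a >= min_pct) | (pct_b >= min_pct)
        if only_pos:
            tested &= logfc >= logfc_threshold
        else:
            tested &= logfc.abs() >= logfc_threshold
        genes = values.columns[tested]
        if len(genes) == 0:
            out[label] = pd.DataFrame(
                columns=["logfc", "pct_1", "pct_2", "pvalue", "pvalue_adj"]
            )
            continue
        res = wilcoxon_gene_test(values[genes], A.index, B.index)
        if correction == "bonferroni":
            padj = np.minimum(res["pvalue"] * len(genes), 1.0)
        else:
            padj = sps.false_discovery_control(res["pvalue"], method="bh")
        table = pd.DataFrame({
            "logfc": logfc[genes],
            "pct_1": pct_a[genes],
            "pct_2": pct_b[genes],
            "pvalue": res["pvalue"],
            "pvalue_adj": padj,
        }).sort_values("pvalue")
        out[label] = table
    return out


def signature_score(
    expr: ad.AnnData | pd.DataFrame, geneset: Iterable[str]
) -> pd.Series:
    """Per-cell mean normalized expression over a gene set.

    The same estimator as the phase scores; duplicate genes in the input
    list are ignored, genes absent from the matrix are dropped, and an
    empty intersection raises :class:`ValueError`.
    """
    values = _values(expr)
    genes = [g for g in dict.fromkeys(geneset) if g in values.columns]
    if not genes:
        raise ValueError("no gene of the signature is present in the matrix")
    return values[genes].mean(axis=1).rename("signature_score")


@dataclass(frozen=True)
class WelchResult:
    statistic: float
    df: float
    pvalue: float
    pvalue_adj: float


def welch_fraction_test(
    records_a: Sequence[float],
    records_b: Sequence[float],
    bonferroni_m: int = 1,
) -> WelchResult:
    """Two-sided Welch t-test on per-replicate fractions or per-cell ratios.

    Uses the Welch-Satterthwaite degrees of freedom; the adjusted p-value is
    ``min(1, bonferroni_m * p)``.  Both groups need at least 2 observations.
    Degenerate zero-variance groups with equal means return t = 0, p = 1.
    """
    a = np.asarray(records_a, dtype=float)
    b = np.asarray(records_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 replicates")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    sa, sb = va / len(a), vb / len(b)
    se2 = sa + sb
    if se2 == 0:
        t = 0.0 if a.mean() == b.mean() else np.inf * np.sign(a.mean() - b.mean())
        p = 1.0 if t == 0 else 0.0
        df = float(len(a) + len(b) - 2)
    else:
        t = float((a.mean() - b.mean()) / np.sqrt(se2))
        df = float(se2 ** 2 / (sa ** 2 / (len(a) - 1) + sb ** 2 / (len(b) - 1)))
        p = float(2 * sps.t.sf(abs(t), df))
    return WelchResult(t, df, p, min(1.0, bonferroni_m * p))
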