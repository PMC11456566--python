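"""Lightweight differential expression and group-mean summaries.

Counts are normalized by median-of-ratios size factors (per-sample median,
over genes expressed in every sample, of the count over the gene's
geometric mean).  Differential expression is tested per gene on
log2(normalized + 1): Welch's two-sample t-test between groups, or a paired
t-test across patient-matched samples.  Genes are called differentially
expressed at |log2FC| >= 1 and unadjusted p < 0.01; a Benjamini-Hochberg
column is reported for transparency but does not enter the call.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .matrix import CountMatrix

__all__ = [
    "DEGThresholds",
    "NormalizationError",
    "DEError",
    "normalize_median_of_ratios",
    "de_test",
    "call_degs",
    "group_mean_table",
    "count_directional",
]


class NormalizationError(ValueError):
    pass


class DEError(ValueError):
    pass


@dataclass(frozen=True)
class DEGThresholds:
    """DEG call thresholds: |log2FC| >= min_abs_log2fc and p < max_p."""

    min_abs_log2fc: float = 1.0
    max_p: float = 0.01

    def __post_init__(self) -> None:
        if self.min_abs_log2fc < 0:
            raise DEError("min_abs_log2fc must be >= 0")
        if not 0.0 < self.max_p <= 1.0:
            raise DEError("max_p must be in (0, 1]")


def normalize_median_of_ratios(
    counts: pd.DataFrame | CountMatrix,
) -> tuple[pd.Series, pd.DataFrame]:
    """Median-of-ratios size factors and the normalized matrix.

    For genes with non-zero counts in every sample, each sample's factor is
    the median of count / geometric-mean-across-samples; normalized values
    are counts divided by the sample's factor.  Rescaling one sample's
    library by c multiplies its factor by c relative to every other
    sample's; normalized values are invariant up to a single global
    constant (the per-gene geometric-mean reference moves by c^(1/n)),
    which cancels in any between-sample contrast.

    Returns
    -------
    (size_factors, normalized) — a per-sample Series and a float DataFrame
    of the same shape as ``counts``.
    """
    if isinstance(counts, CountMatrix):
        counts = counts.counts
    if counts.shape[1] < 2:
        raise NormalizationError("normalization requires at least 2 samples")
    x = counts.to_numpy(dtype=float)
    all_expressed = (x > 0).all(axis=1)
    if not all_expressed.any():
        raise NormalizationError(
            "no gene has non-zero counts in every sample; consider adding a "
            "pseudocount before normalization"
        )
    ref = x[all_expressed]
    log_geo_mean = np.log(ref).mean(axis=1, keepdims=True)
    ratios = np.exp(np.log(ref) - log_geo_mean)
    factors = np.median(ratios, axis=0)
    size_factors = pd.Series(factors, index=counts.columns, name="size_factor")
    normalized = counts.astype(float) / size_factors
    return size_factors, normalized


def _welch(xa: np.ndarray, xb: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized Welch t-test per row; zero-variance-in-both rows get p=1."""
    na, nb = xa.shape[1], xb.shape[1]
    ma, mb = xa.mean(axis=1), xb.mean(axis=1)
    va, vb = xa.var(axis=1, ddof=1), xb.var(axis=1, ddof=1)
    denom2 = va / na + vb / nb
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (ma - mb) / np.sqrt(denom2)
        df = denom2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
        p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.where(denom2 == 0.0, 1.0, p)
    return np.where(np.isfinite(t), t, 0.0), p


def _paired_t(d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized paired t-test on per-row difference matrices."""
    n = d.shape[1]
    md = d.mean(axis=1)
    sd = d.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = md / (sd / np.sqrt(n))
        p = 2.0 * stats.t.sf(np.abs(t), n - 1)
    p = np.where(sd == 0.0, 1.0, p)
    return np.where(np.isfinite(t), t, 0.0), p


def de_test(
    normalized: pd.DataFrame,
    group_a: Sequence[str],
    group_b: Sequence[str],
    paired: bool = False,
    patients: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Per-gene differential expression of group A over group B.

    log2FC is the difference of mean log2(normalized + 1) (A minus B); the
    p-value comes from Welch's t-test on the same transformed values, or
    from a paired t-test when ``paired`` is set (``patients`` then maps
    sample id to patient id and every patient must appear in both groups).
    Genes with zero variance in both groups get p = 1.

    Returns a DataFrame indexed by gene with columns ``log2fc``,
    ``p_value``, ``padj`` (Benjamini-Hochberg), ``mean_a``, ``mean_b``.
    """
    group_a, group_b = list(group_a), list(group_b)
    if set(group_a) & set(group_b):
        raise DEError(f"groups overlap: {sorted(set(group_a) & set(group_b))}")
    if len(group_a) < 2 or len(group_b) < 2:
        raise DEError("each group needs at least 2 samples")
    missing = (set(group_a) | set(group_b)) - set(normalized.columns)
    if missing:
        raise DEError(f"samples not in matrix: {sorted(missing)}")
    log_expr = np.log2(normalized + 1.0)
    xa = log_expr[group_a].to_numpy()
    xb = log_expr[group_b].to_numpy()
    if paired:
        if patients is None:
            raise DEError("paired mode requires a sample -> patient mapping")
        pat_a = {patients[s]: s for s in group_a}
        pat_b = {patients[s]: s for s in group_b}
        if len(pat_a) != len(group_a) or len(pat_b) != len(group_b):
            raise DEError("paired mode requires one sample per patient per group")
        if set(pat_a) != set(pat_b):
            raise DEError(
                "paired mode requires matched patients; unmatched: "
                f"{sorted(set(pat_a) ^ set(pat_b))}"
            )
        order = sorted(pat_a)
        xa = log_expr[[pat_a[p] for p in order]].to_numpy()
        xb = log_expr[[pat_b[p] for p in order]].to_numpy()
        t, p = _paired_t(xa - xb)
    else:
        t, p = _welch(xa, xb)
    log2fc = xa.mean(axis=1) - xb.mean(axis=1)
    padj = multipletests(p, method="fdr_bh")[1]
    return pd.DataFrame(
        {
            "log2fc": log2fc,
            "p_value": p,
            "padj": padj,
            "mean_a": normalized[group_a].mean(axis=1).to_numpy(),
            "mean_b": normalized[group_b].mean(axis=1).to_numpy(),
        },
        index=normalized.index.rename("gene"),
    )


def call_degs(
    results: pd.DataFrame, thresholds: DEGThresholds = DEGThresholds()
) -> tuple[list[str], list[str]]:
    """Split DE results into up- and down-regulated gene lists.

    Up: log2FC >= min_abs_log2fc and p < max_p; down: log2FC <=
    -min_abs_log2fc and p < max_p.  Both lists sorted by p, then gene id.
    """
    sig = results[results["p_value"] < thresholds.max_p]
    up = sig[sig["log2fc"] >= thresholds.min_abs_log2fc]
    down = sig[sig["log2fc"] <= -thresholds.min_abs_log2fc]

    def _ordered(frame: pd.DataFrame) -> list[str]:
        return list(frame.reset_index().sort_values(["p_value", "gene"])["gene"])

    return _ordered(up), _ordered(down)


def group_mean_table(
    expr: pd.DataFrame, groups: Mapping[str, Sequence[str]]
) -> pd.DataFrame:
    """Arithmetic mean expression per gene per named group.

    ``groups`` maps the output column name to the sample ids it averages;
    column order follows the mapping order.
    """
    table = {}
    for name, samples in groups.items():
        samples = list(samples)
        if not samples:
            raise DEError(f"group {name!r} is empty")
        missing = set(samples) - set(expr.columns)
        if missing:
            raise DEError(f"group {name!r} references unknown samples: {sorted(missing)}")
        table[name] = expr[samples].mean(axis=1)
    return pd.DataFrame(table, index=expr.index)


def count_directional(
    table: pd.DataFrame,
    left: Sequence[str],
    right: Sequence[str],
    direction: str,
) -> tuple[int, pd.Series]:
    """Count genes whose left-column mean compares strictly to the right.

    Left and right column sets are averaged with equal weight per column;
    a gene is called when mean(left) ``direction`` mean(right) holds
    strictly (ties are never called).  Returns the count and the per-gene
    boolean Series.
    """
    if direction not in ("<", ">"):
        raise DEError(f"direction must be '<' or '>', got {direction!r}")
    for col in (*left, *right):
        if col not in table.columns:
            raise DEError(f"unknown column {col!r}")
    lmean = table[list(left)].mean(axis=1)
    rmean = table[list(right)].mean(axis=1)
    calls = lmean < rmean if direction == "<" else lmean > rmean
    return int(calls.sum()), calls
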