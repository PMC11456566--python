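"""Responder / non-responder gene signatures and the delta-score classifier.

The classifier works in four steps:

1. derive *unique* signatures from two DEG sets (responder-vs-control and
   non-responder-vs-control): genes found in both contrasts are dropped, so
   each signature contains only the genes specific to its arm;
2. score every sample against each signature — each signature gene is
   z-standardized across the cohort and the score is the mean z-value over
   the signature's genes (zero-variance genes contribute 0);
3. classify by the difference score delta = NR-score - R-score: samples at
   or above the cohort median of delta are NR-like, the rest R-like;
4. optionally stratify each class by a within-class median split of its own
   signature score (>= median -> "high").

Standardization and medians are always computed within the cohort being
classified, so signatures transfer to an independent cohort without any
quantity carried over from the derivation cohort.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "GeneSignature",
    "ScoringPolicy",
    "SignatureError",
    "derive_unique_signatures",
    "score_samples",
    "score_cohort",
    "classify_delta",
    "stratify_within_class",
    "transfer_signatures",
]

SCORE_COLUMNS = ("r_score", "nr_score", "delta", "label", "stratum")


class SignatureError(ValueError):
    pass


@dataclass(frozen=True)
class GeneSignature:
    """A named gene set with its derivation provenance."""

    name: str
    genes: tuple[str, ...]
    provenance: str = "external"  # "R_unique", "NR_unique" or "external"
    source_contrast: str = ""

    def __post_init__(self) -> None:
        if not self.genes:
            raise SignatureError(f"signature {self.name!r} has no genes")
        if len(set(self.genes)) != len(self.genes):
            raise SignatureError(f"signature {self.name!r} has duplicate genes")

    def __len__(self) -> int:
        return len(self.genes)


@dataclass(frozen=True)
class ScoringPolicy:
    """Scoring and tie-break rules.

    ``min_gene_coverage`` is the fraction of signature genes that must be
    present in the expression matrix; gene symbols are matched
    case-insensitively after trimming when ``case_insensitive`` is set.
    Ties at the median go to NR-like (classification) and to "high"
    (stratification).
    """

    standardization: str = "cohort_zscore"
    min_gene_coverage: float = 0.5
    case_insensitive: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.min_gene_coverage <= 1.0:
            raise SignatureError("min_gene_coverage must be in (0, 1]")
        if self.standardization != "cohort_zscore":
            raise SignatureError(
                f"unknown standardization {self.standardization!r}"
            )


def derive_unique_signatures(
    deg_r_vs_control: Iterable[str],
    deg_nr_vs_control: Iterable[str],
) -> tuple[GeneSignature, GeneSignature]:
    """Arm-specific signatures by set difference of two DEG sets.

    Genes differentially expressed in both arms versus control carry no
    information about response and are excluded from both signatures.
    """
    set_r = list(dict.fromkeys(deg_r_vs_control))
    set_nr = list(dict.fromkeys(deg_nr_vs_control))
    if not set_r or not set_nr:
        raise SignatureError("both DEG sets must be non-empty")
    shared = set(set_r) & set(set_nr)
    r_unique = [g for g in set_r if g not in shared]
    nr_unique = [g for g in set_nr if g not in shared]
    if not r_unique or not nr_unique:
        raise SignatureError(
            "a unique signature is empty after removing shared genes; "
            "the classifier is undefined"
        )
    logger.info(
        "unique signatures: R=%d, NR=%d (%d shared genes removed)",
        len(r_unique), len(nr_unique), len(shared),
    )
    return (
        GeneSignature("R_unique", tuple(r_unique), "R_unique", "R vs control"),
        GeneSignature("NR_unique", tuple(nr_unique), "NR_unique", "NR vs control"),
    )


def _match_genes(
    expr_index: pd.Index, signature: GeneSignature, policy: ScoringPolicy
) -> list[str]:
    """Expression-matrix row labels matched by the signature's genes."""
    if policy.case_insensitive:
        lookup: dict[str, str] = {}
        for label in expr_index:
            lookup.setdefault(str(label).strip().casefold(), label)
        return [
            lookup[k]
            for g in signature.genes
            if (k := g.strip().casefold()) in lookup
        ]
    present = set(expr_index)
    return [g for g in signature.genes if g in present]


def score_samples(
    expr: pd.DataFrame, signature: GeneSignature, policy: ScoringPolicy = ScoringPolicy()
) -> pd.Series:
    """Mean cohort z-score of the signature's genes, per sample.

    Each present signature gene is standardized to mean 0 / sd 1 across the
    cohort (zero-sd genes contribute 0); the score averages these z-values.
    Scores are invariant to per-gene affine rescaling of the expression
    values, so raw, normalized or log-scale matrices give identical output.
    """
    if expr.shape[1] < 3:
        raise SignatureError("scoring requires at least 3 samples")
    matched = _match_genes(expr.index, signature, policy)
    coverage = len(matched) / len(signature)
    if coverage < policy.min_gene_coverage:
        missing = sorted(set(signature.genes) - set(matched))
        raise SignatureError(
            f"signature {signature.name!r} coverage {coverage:.2f} below "
            f"{policy.min_gene_coverage:.2f}; missing genes: {missing[:10]}"
            + ("..." if len(missing) > 10 else "")
        )
    if coverage < 1.0:
        logger.info(
            "signature %s: %d/%d genes present in matrix",
            signature.name, len(matched), len(signature),
        )
    x = expr.loc[matched].to_numpy(dtype=float)
    mean = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (x - mean) / sd
    z = np.where(sd == 0.0, 0.0, z)
    return pd.Series(z.mean(axis=0), index=expr.columns, name=signature.name)


def score_cohort(
    expr: pd.DataFrame,
    r_signature: GeneSignature,
    nr_signature: GeneSignature,
    policy: ScoringPolicy = ScoringPolicy(),
) -> pd.DataFrame:
    """Score every sample against both signatures.

    Returns a DataFrame indexed by sample id with columns ``r_score``,
    ``nr_score``, ``delta`` (= nr_score - r_score), ``label`` and
    ``stratum`` (both initially unset).
    """
    r = score_samples(expr, r_signature, policy)
    nr = score_samples(expr, nr_signature, policy)
    scores = pd.DataFrame(
        {
            "r_score": r,
            "nr_score": nr,
            "delta": nr - r,
            "label": pd.Series(pd.NA, index=expr.columns, dtype="string"),
            "stratum": pd.Series(pd.NA, index=expr.columns, dtype="string"),
        }
    )
    scores.index.name = "sample_id"
    return scores


def classify_delta(scores: pd.DataFrame) -> pd.DataFrame:
    """Median-split classification on the delta score.

    Samples with delta >= median(delta) over the cohort are labeled
    ``NR_like``, the rest ``R_like``.  Returns a copy with the label
    column filled.
    """
    if len(scores) < 2:
        raise SignatureError("classification requires at least 2 samples")
    out = scores.copy()
    med = float(np.median(out["delta"].to_numpy(dtype=float)))
    out["label"] = np.where(out["delta"] >= med, "NR_like", "R_like")
    out["label"] = out["label"].astype("string")
    n_nr = int((out["label"] == "NR_like").sum())
    logger.info("median split: %d NR-like, %d R-like", n_nr, len(out) - n_nr)
    return out


def stratify_within_class(scores: pd.DataFrame) -> pd.DataFrame:
    """High/low stratification within each labeled class.

    NR-like samples are split at the within-class median of their NR score,
    R-like samples at the median of their R score; scores at or above the
    median are "high".  A class with a single member cannot be split.
    """
    if scores["label"].isna().any():
        raise SignatureError("stratification requires labeled samples")
    out = scores.copy()
    out["stratum"] = out["stratum"].astype("string")
    for label, score_col in (("NR_like", "nr_score"), ("R_like", "r_score")):
        mask = out["label"] == label
        n = int(mask.sum())
        if n == 0:
            continue
        if n == 1:
            raise SignatureError(f"class {label!r} has a single member; cannot stratify")
        vals = out.loc[mask, score_col].to_numpy(dtype=float)
        med = float(np.median(vals))
        out.loc[mask, "stratum"] = np.where(vals >= med, "high", "low")
    out["stratum"] = out["stratum"].astype("string")
    return out


def transfer_signatures(
    r_signature: GeneSignature,
    nr_signature: GeneSignature,
    expr_cohort_b: pd.DataFrame,
    policy: ScoringPolicy = ScoringPolicy(),
    stratify: bool = True,
) -> pd.DataFrame:
    """Apply signatures derived elsewhere to an independent cohort.

    Scoring standardization and the classification median are computed
    entirely within cohort B; only the gene lists transfer.
    """
    scores = score_cohort(expr_cohort_b, r_signature, nr_signature, policy)
    labeled = classify_delta(scores)
    if stratify:
        labeled = stratify_within_class(labeled)
    return labeled
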