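"""Gene-by-sample count matrix with sample metadata.

The cohort container used throughout the pipeline: an integer count matrix
(genes in rows, samples in columns) plus a per-sample metadata table holding
the patient id, the sample group (``control`` / ``pre`` / ``post``) and the
response labels (blast response and hematological response, each one of
``R`` / ``NR`` / ``NA``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

GROUPS = ("control", "pre", "post")
RESPONSES = ("R", "NR", "NA")

META_COLUMNS = ("patient_id", "group", "blast_response", "hem_response")


class MatrixError(ValueError):
    """Raised for an inconsistent or malformed count matrix."""


@dataclass
class CountMatrix:
    """Raw counts (genes x samples) and aligned sample metadata.

    Parameters
    ----------
    counts
        DataFrame with unique gene symbols as the index and unique sample
        ids as columns; values are non-negative integers.
    sample_meta
        DataFrame indexed by sample id with at least the columns
        ``patient_id``, ``group``, ``blast_response``, ``hem_response``.
    """

    counts: pd.DataFrame
    sample_meta: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            dupes = self.counts.index[self.counts.index.duplicated()].unique()
            raise MatrixError(f"duplicate gene ids: {list(dupes[:5])}")
        if self.counts.columns.has_duplicates:
            dupes = self.counts.columns[self.counts.columns.duplicated()].unique()
            raise MatrixError(f"duplicate sample ids: {list(dupes[:5])}")
        vals = self.counts.to_numpy()
        if vals.size and vals.min() < 0:
            raise MatrixError("counts must be non-negative")
        missing = set(self.counts.columns) - set(self.sample_meta.index)
        if missing:
            raise MatrixError(f"samples missing from metadata: {sorted(missing)[:5]}")
        for col in META_COLUMNS:
            if col not in self.sample_meta.columns:
                raise MatrixError(f"metadata lacks required column {col!r}")
        bad = set(self.sample_meta["group"]) - set(GROUPS)
        if bad:
            raise MatrixError(f"unknown sample groups: {sorted(bad)}")
        # keep metadata aligned to, and restricted to, the count columns
        self.sample_meta = self.sample_meta.loc[list(self.counts.columns)]

    # -- convenience -------------------------------------------------------

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def samples_where(self, **criteria: str) -> list[str]:
        """Sample ids whose metadata matches every keyword criterion.

        ``cm.samples_where(group="pre", blast_response="R")`` returns the
        pre-treatment samples of blast responders.
        """
        mask = np.ones(len(self.sample_meta), dtype=bool)
        for col, value in criteria.items():
            if col not in self.sample_meta.columns:
                raise MatrixError(f"unknown metadata column {col!r}")
            mask &= (self.sample_meta[col] == value).to_numpy()
        return list(self.sample_meta.index[mask])

    def subset_samples(self, sample_ids: list[str]) -> "CountMatrix":
        return CountMatrix(
            counts=self.counts[sample_ids].copy(),
            sample_meta=self.sample_meta.loc[sample_ids].copy(),
        )
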