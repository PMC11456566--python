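"""File formats and provenance.

Readers and writers for the pipeline's on-disk formats: count matrices as
TSV (genes in rows) or MatrixMarket MTX with gene/sample side files, sample
metadata TSV, the variant table TSV, survival CSV, GMT gene-set files,
score/label TSV, a minimal VCF reader, and the bundled 56-gene B-cell
development panel of published group-mean expression values.

Every table written here starts with ``#``-prefixed header comments that
record the package version, the seed and a config hash; all readers skip
``#`` lines.  A :class:`RunManifest` captures the provenance of a full
pipeline run.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from . import __version__
from .matrix import CountMatrix, MatrixError
from .signatures import GeneSignature
from .synthetic import SurvivalRecord
from .variants import VariantCall, VariantError

VARIANT_COLUMNS = (
    "patient_id", "gene", "change", "ref", "alt",
    "variant_class", "timepoint", "compartment", "vaf_pct",
)


class ParseError(ValueError):
    pass


# ---------------------------------------------------------------------------
# provenance headers
# ---------------------------------------------------------------------------


def config_hash(config: object) -> str:
    """Short stable hash of any JSON-serializable configuration object."""
    payload = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def _header_lines(seed: int | None, cfg_hash: str | None) -> str:
    parts = [f"azasig={__version__}"]
    if seed is not None:
        parts.append(f"seed={seed}")
    if cfg_hash is not None:
        parts.append(f"config={cfg_hash}")
    return "# " + " ".join(parts) + "\n"


def _write_table(
    frame: pd.DataFrame,
    path: Path,
    sep: str,
    index: bool,
    seed: int | None,
    cfg_hash: str | None,
) -> None:
    with open(path, "w") as fh:
        fh.write(_header_lines(seed, cfg_hash))
        # %.17g keeps float64 values exact across a write/read round-trip
        frame.to_csv(fh, sep=sep, index=index, float_format="%.17g")


# ---------------------------------------------------------------------------
# count matrices
# ---------------------------------------------------------------------------


def write_counts_tsv(
    cm: CountMatrix, path: str | Path, seed: int | None = None, cfg_hash: str | None = None
) -> None:
    """Write counts as TSV (genes in rows) plus a ``.meta.tsv`` sidecar."""
    path = Path(path)
    _write_table(cm.counts.rename_axis("gene"), path, "\t", True, seed, cfg_hash)
    meta_path = path.with_suffix(".meta.tsv")
    _write_table(cm.sample_meta.rename_axis("sample_id"), meta_path, "\t", True, seed, cfg_hash)


def write_counts_mtx(
    cm: CountMatrix, path: str | Path, seed: int | None = None, cfg_hash: str | None = None
) -> None:
    """Write counts as MatrixMarket with gene/sample/metadata side files."""
    path = Path(path)
    spio.mmwrite(str(path), sparse.csr_matrix(cm.counts.to_numpy()))
    path.with_suffix(".genes.txt").write_text("\n".join(cm.gene_ids) + "\n")
    path.with_suffix(".samples.txt").write_text("\n".join(cm.sample_ids) + "\n")
    _write_table(
        cm.sample_meta.rename_axis("sample_id"),
        path.with_suffix(".meta.tsv"), "\t", True, seed, cfg_hash,
    )


def read_counts(path: str | Path, meta_path: str | Path | None = None) -> CountMatrix:
    """Load a count matrix from TSV or MTX (decided by the extension).

    The metadata TSV defaults to the ``.meta.tsv`` sidecar next to the
    matrix file.
    """
    path = Path(path)
    if meta_path is None:
        meta_path = path.with_suffix(".meta.tsv")
    meta = read_table(meta_path, sep="\t", na_filter=False).set_index("sample_id")
    if path.suffix == ".mtx":
        mat = spio.mmread(str(path))
        genes = path.with_suffix(".genes.txt").read_text().splitlines()
        samples = path.with_suffix(".samples.txt").read_text().splitlines()
        dense = np.asarray(mat.todense() if sparse.issparse(mat) else mat)
        if dense.shape != (len(genes), len(samples)):
            raise ParseError(
                f"{path}: matrix is {dense.shape} but side files list "
                f"{len(genes)} genes x {len(samples)} samples"
            )
        counts = pd.DataFrame(dense, index=genes, columns=samples)
    else:
        counts = read_table(path, sep="\t").set_index("gene")
        counts.index.name = None
    if (counts.to_numpy() < 0).any():
        raise ParseError(f"{path}: negative counts")
    try:
        return CountMatrix(counts=counts, sample_meta=meta)
    except MatrixError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def read_table(path: str | Path, sep: str = "\t", na_filter: bool = True) -> pd.DataFrame:
    """Read a delimited table, skipping ``#`` header comments.

    ``na_filter=False`` preserves literal "NA" strings (response labels)
    and empty fields instead of converting them to NaN.
    """
    try:
        return pd.read_csv(
            path, sep=sep, comment="#", float_precision="round_trip", na_filter=na_filter
        )
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ParseError(f"{path}: {exc}") from exc


# ---------------------------------------------------------------------------
# variant tables
# ---------------------------------------------------------------------------


def write_variants_tsv(
    calls: Sequence[VariantCall],
    path: str | Path,
    seed: int | None = None,
    cfg_hash: str | None = None,
) -> None:
    frame = pd.DataFrame(
        [
            (c.patient_id, c.gene, c.change, c.ref_base, c.alt_base,
             c.variant_class, c.timepoint, c.compartment, c.vaf_pct)
            for c in calls
        ],
        columns=VARIANT_COLUMNS,
    )
    _write_table(frame, Path(path), "\t", False, seed, cfg_hash)


def read_variants_tsv(path: str | Path) -> list[VariantCall]:
    frame = read_table(path, sep="\t", na_filter=False)
    missing = set(VARIANT_COLUMNS) - set(frame.columns)
    if missing:
        raise ParseError(f"{path}: missing variant columns {sorted(missing)}")
    calls = []
    for i, row in enumerate(frame.itertuples(index=False), start=2):
        try:
            calls.append(
                VariantCall(
                    patient_id=str(row.patient_id),
                    gene=str(row.gene),
                    change=str(row.change),
                    ref_base="" if pd.isna(row.ref) else str(row.ref),
                    alt_base="" if pd.isna(row.alt) else str(row.alt),
                    variant_class=str(row.variant_class),
                    timepoint=str(row.timepoint),
                    compartment=str(row.compartment),
                    vaf_pct=float(row.vaf_pct),
                )
            )
        except (VariantError, ValueError) as exc:
            raise ParseError(f"{path}: line {i}: {exc}") from exc
    return calls


def read_vcf_minimal(path: str | Path, default_patient: str = "NA") -> list[VariantCall]:
    """Minimal VCF ingestion: CHROM/POS/REF/ALT plus an AF field.

    The allele fraction is taken from INFO ``AF=`` or, failing that, from
    the first sample's FORMAT ``AF`` entry, and converted to a VAF
    percentage.  Sites without an AF are skipped.  Timepoint and
    compartment default to pre/CD34 (a VCF carries neither).
    """
    calls = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("#") or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 8:
                raise ParseError(f"{path}: line {lineno}: fewer than 8 VCF columns")
            chrom, pos, _id, ref, alt, _qual, _filter, info = fields[:8]
            af = None
            for entry in info.split(";"):
                if entry.startswith("AF="):
                    af = float(entry[3:].split(",")[0])
            if af is None and len(fields) >= 10:
                keys = fields[8].split(":")
                vals = fields[9].split(":")
                fmt = dict(zip(keys, vals))
                if "AF" in fmt:
                    af = float(fmt["AF"].split(",")[0])
            if af is None:
                continue
            alt0 = alt.split(",")[0]
            is_snv = len(ref) == 1 and len(alt0) == 1 and ref != alt0
            calls.append(
                VariantCall(
                    patient_id=default_patient,
                    gene=chrom,
                    change=f"{chrom}:{pos}{ref}>{alt0}",
                    ref_base=ref if is_snv else "",
                    alt_base=alt0 if is_snv else "",
                    variant_class="SNV" if is_snv else "indel",
                    timepoint="pre",
                    compartment="CD34",
                    vaf_pct=af * 100.0,
                )
            )
    return calls


# ---------------------------------------------------------------------------
# survival, signatures, scores
# ---------------------------------------------------------------------------


def write_survival_csv(
    records: Sequence[SurvivalRecord],
    path: str | Path,
    seed: int | None = None,
    cfg_hash: str | None = None,
) -> None:
    frame = pd.DataFrame(
        [(r.sample_id, r.time, r.event) for r in records],
        columns=["sample_id", "time", "event"],
    )
    _write_table(frame, Path(path), ",", False, seed, cfg_hash)


def read_survival_csv(path: str | Path) -> list[SurvivalRecord]:
    frame = read_table(path, sep=",")
    for col in ("sample_id", "time", "event"):
        if col not in frame.columns:
            raise ParseError(f"{path}: missing column {col!r}")
    return [
        SurvivalRecord(sample_id=str(r.sample_id), time=float(r.time), event=int(r.event))
        for r in frame.itertuples(index=False)
    ]


def write_gmt(signatures: Iterable[GeneSignature], path: str | Path) -> None:
    """Write gene sets in GMT format (name, description, member genes)."""
    with open(path, "w") as fh:
        for sig in signatures:
            desc = sig.source_contrast or sig.provenance
            fh.write("\t".join([sig.name, desc, *sig.genes]) + "\n")


def read_gmt(path: str | Path) -> list[GeneSignature]:
    signatures = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}: line {lineno}: GMT needs name, description, >=1 gene")
            name, desc, *genes = fields
            provenance = name if name in ("R_unique", "NR_unique") else "external"
            signatures.append(
                GeneSignature(
                    name=name,
                    genes=tuple(dict.fromkeys(g for g in genes if g)),
                    provenance=provenance,
                    source_contrast=desc,
                )
            )
    return signatures


def write_scores_tsv(
    scores: pd.DataFrame, path: str | Path, seed: int | None = None, cfg_hash: str | None = None
) -> None:
    _write_table(scores.rename_axis("sample_id"), Path(path), "\t", True, seed, cfg_hash)


def read_scores_tsv(path: str | Path) -> pd.DataFrame:
    return read_table(path, sep="\t").set_index("sample_id")


# ---------------------------------------------------------------------------
# bundled fixture: B-cell development panel group means
# ---------------------------------------------------------------------------


def load_bcell_panel() -> pd.DataFrame:
    """Published group-mean expression of 56 B-cell development genes.

    Columns: healthy controls, and blast responder (BL-R) / non-responder
    (BL-NR) patients before and after azacytidine.  Indexed by gene symbol.
    """
    ref = resources.files("azasig.data").joinpath("bcell_panel_means.tsv")
    with ref.open("r") as fh:
        table = pd.read_csv(fh, sep="\t", comment="#").set_index("gene")
    return table


# ---------------------------------------------------------------------------
# run manifest
# ---------------------------------------------------------------------------


@dataclass
class RunManifest:
    """Provenance of one pipeline run.

    Identical inputs and config reproduce identical stage outputs; the
    manifest records the version, seed, config hash, input checksums and
    per-stage row/gene counts so that claim is checkable.  Timestamps are
    informational and excluded from equality comparisons.
    """

    version: str = __version__
    seed: int | None = None
    config_hash: str | None = None
    input_checksums: dict[str, str] = field(default_factory=dict)
    stage_counts: dict[str, dict[str, int]] = field(default_factory=dict)
    timestamp: str = field(default_factory=lambda: time.strftime("%Y-%m-%dT%H:%M:%S"))

    def add_input(self, name: str, path: str | Path) -> None:
        digest = hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]
        self.input_checksums[name] = digest

    def add_stage(self, stage: str, **counts: int) -> None:
        self.stage_counts[stage] = dict(counts)

    def comparable(self) -> dict:
        out = self.to_dict()
        out.pop("timestamp")
        return out

    def to_dict(self) -> dict:
        return {
            "version": self.version,
            "seed": self.seed,
            "config_hash": self.config_hash,
            "input_checksums": dict(self.input_checksums),
            "stage_counts": {k: dict(v) for k, v in self.stage_counts.items()},
            "timestamp": self.timestamp,
        }

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def read(cls, path: str | Path) -> "RunManifest":
        data = json.loads(Path(path).read_text())
        return cls(**data)
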