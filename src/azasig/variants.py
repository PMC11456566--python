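"""Paired variant-allele-frequency (VAF) dynamics under azacytidine therapy.

Somatic mutations are tracked as VAF percentages in CD34+ cells (and bulk
bone-marrow mononuclear cells, BMMC) before and after treatment.  This module
implements the targeted-panel filtering rule (a 5% VAF cutoff with a paired
rescue: a sub-threshold call is kept when the same mutation clears the cutoff
at the other timepoint), pre/post pairing, the five-way dynamics
classification (acquired / increased / stable / decreased / lost), the
transition-transversion substitution spectrum, the CD34-vs-BMMC VAF
correlation, and per-patient mutation-burden summaries.
"""

from __future__ import annotations

import enum
from collections import Counter, defaultdict
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")
BASES = frozenset("ACGT")

DEFAULT_VAF_CUTOFF_PCT = 5.0
DEFAULT_REL_CHANGE_MIN = 0.25


class VariantError(ValueError):
    """Raised for malformed variant records or invalid parameters."""


class Dynamics(str, enum.Enum):
    """Clonal trajectory of one mutation between the pre and post samples."""

    ACQUIRED = "ACQUIRED"
    INCREASED = "INCREASED"
    STABLE = "STABLE"
    DECREASED = "DECREASED"
    LOST = "LOST"


@dataclass(frozen=True)
class VariantCall:
    """One mutation observed in one compartment at one timepoint."""

    patient_id: str
    gene: str
    change: str
    ref_base: str
    alt_base: str
    variant_class: str  # "SNV", "indel" or "other"
    timepoint: str  # "pre" or "post"
    compartment: str  # "CD34" or "BMMC"
    vaf_pct: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.vaf_pct <= 100.0:
            raise VariantError(
                f"VAF must be a percentage in [0, 100], got {self.vaf_pct}"
            )
        if self.timepoint not in ("pre", "post"):
            raise VariantError(f"unknown timepoint {self.timepoint!r}")
        if self.variant_class == "SNV":
            if self.ref_base not in BASES or self.alt_base not in BASES:
                raise VariantError(
                    f"SNV bases must be A/C/G/T, got {self.ref_base!r}>{self.alt_base!r}"
                )
            if self.ref_base == self.alt_base:
                raise VariantError("SNV requires ref_base != alt_base")

    @property
    def key(self) -> tuple[str, str, str, str]:
        """Identity of the mutation within a compartment."""
        return (self.patient_id, self.gene, self.change, self.compartment)


@dataclass
class PairedVariant:
    """One mutation with its VAF at both timepoints (either may be absent)."""

    patient_id: str
    gene: str
    change: str
    ref_base: str
    alt_base: str
    variant_class: str
    compartment: str
    pre_vaf_pct: float | None = None
    post_vaf_pct: float | None = None
    dynamics: Dynamics | None = None

    def __post_init__(self) -> None:
        if self.pre_vaf_pct is None and self.post_vaf_pct is None:
            raise VariantError("paired variant needs at least one timepoint VAF")

    @property
    def substitution(self) -> str | None:
        """``"C>T"``-style label for SNVs, ``None`` otherwise."""
        if self.variant_class != "SNV":
            return None
        return f"{self.ref_base}>{self.alt_base}"


@dataclass
class SpectrumSummary:
    """Substitution spectrum of the pre-treatment mutation set.

    Proportions are computed over all mutations present before treatment:
    SNVs are split into transitions and transversions, everything else
    (indels and other events) counts as "other".  ``per_substitution`` maps
    each SNV substitution type to its dynamics-category counts, and
    ``unchanged_by_class`` gives the fraction of transitions (resp.
    transversions) whose VAF did not change (dynamics STABLE).
    """

    n_total: int
    prop_transition: float
    prop_transversion: float
    prop_other: float
    per_substitution: dict[str, dict[str, int]] = field(default_factory=dict)
    unchanged_by_class: dict[str, float] = field(default_factory=dict)


def filter_by_vaf(
    calls: Sequence[VariantCall],
    cutoff_pct: float = DEFAULT_VAF_CUTOFF_PCT,
    paired_rescue: bool = True,
) -> list[VariantCall]:
    """Apply the panel VAF cutoff with the paired rescue rule.

    A call is retained iff its VAF is at or above ``cutoff_pct``, or
    ``paired_rescue`` is on and the same mutation (same patient, gene,
    protein change and compartment) clears the cutoff at the other
    timepoint.  This keeps a small emerging clone whose post-treatment VAF
    is high (possible clonal expansion) and a collapsing clone whose
    pre-treatment VAF was high.  Output order is stable.
    """
    if not 0.0 < cutoff_pct <= 100.0:
        raise VariantError(f"cutoff_pct must be in (0, 100], got {cutoff_pct}")
    passing: set[tuple] = set()
    for call in calls:
        if call.vaf_pct >= cutoff_pct:
            passing.add(call.key)
    kept = []
    for call in calls:
        if call.vaf_pct >= cutoff_pct:
            kept.append(call)
        elif paired_rescue and call.key in passing:
            kept.append(call)
    return kept


def pair_variants(calls: Sequence[VariantCall]) -> list[PairedVariant]:
    """Group calls from one compartment into pre/post pairs.

    Calls are grouped by (patient, gene, change); a missing timepoint is
    recorded as absent.  Duplicate (patient, gene, change, timepoint)
    entries and mixed compartments are data-integrity errors.
    """
    compartments = {c.compartment for c in calls}
    if len(compartments) > 1:
        raise VariantError(
            f"pair_variants expects calls from one compartment, got {sorted(compartments)}"
        )
    by_key: dict[tuple, dict[str, VariantCall]] = defaultdict(dict)
    order: list[tuple] = []
    for call in calls:
        slot = by_key[call.key]
        if call.timepoint in slot:
            raise VariantError(
                "duplicate variant call for "
                f"(patient={call.patient_id}, gene={call.gene}, "
                f"change={call.change}, timepoint={call.timepoint})"
            )
        if not slot:
            order.append(call.key)
        slot[call.timepoint] = call
    paired = []
    for key in order:
        slot = by_key[key]
        proto = slot.get("pre") or slot["post"]
        paired.append(
            PairedVariant(
                patient_id=proto.patient_id,
                gene=proto.gene,
                change=proto.change,
                ref_base=proto.ref_base,
                alt_base=proto.alt_base,
                variant_class=proto.variant_class,
                compartment=proto.compartment,
                pre_vaf_pct=slot["pre"].vaf_pct if "pre" in slot else None,
                post_vaf_pct=slot["post"].vaf_pct if "post" in slot else None,
            )
        )
    return paired


def classify_dynamics(
    pre_vaf: float | None,
    post_vaf: float | None,
    rel_change_min: float = DEFAULT_REL_CHANGE_MIN,
) -> Dynamics:
    """Classify a pre/post VAF pair into one of five dynamics categories.

    Absence (a ``None`` VAF, i.e. below detection) defines ACQUIRED and
    LOST; among mutations present at both timepoints, a relative change of
    less than ``rel_change_min`` of the pre-treatment VAF is STABLE, larger
    changes are INCREASED or DECREASED by sign.
    """
    if rel_change_min <= 0:
        raise VariantError(f"rel_change_min must be > 0, got {rel_change_min}")
    if pre_vaf is None and post_vaf is None:
        raise VariantError("cannot classify dynamics with both VAFs absent")
    if pre_vaf is None:
        return Dynamics.ACQUIRED
    if post_vaf is None:
        return Dynamics.LOST
    if pre_vaf == 0.0:
        # present-but-zero pre VAF: treat any positive post as an increase
        return Dynamics.STABLE if post_vaf == 0.0 else Dynamics.INCREASED
    rel = (post_vaf - pre_vaf) / pre_vaf
    if abs(rel) < rel_change_min:
        return Dynamics.STABLE
    return Dynamics.INCREASED if rel > 0 else Dynamics.DECREASED


def assign_dynamics(
    paired: Iterable[PairedVariant],
    rel_change_min: float = DEFAULT_REL_CHANGE_MIN,
) -> list[PairedVariant]:
    """Return copies of ``paired`` with the dynamics field filled in."""
    return [
        replace(pv, dynamics=classify_dynamics(pv.pre_vaf_pct, pv.post_vaf_pct, rel_change_min))
        for pv in paired
    ]


def classify_substitution(ref_base: str, alt_base: str) -> str:
    """Label a single-nucleotide substitution as transition or transversion.

    Purine<->purine (A<->G) and pyrimidine<->pyrimidine (C<->T) changes are
    transitions; purine<->pyrimidine changes are transversions.
    """
    if ref_base not in BASES or alt_base not in BASES:
        raise VariantError(f"bases must be A/C/G/T, got {ref_base!r}, {alt_base!r}")
    if ref_base == alt_base:
        raise VariantError("ref and alt base must differ")
    same_class = (ref_base in PURINES) == (alt_base in PURINES)
    return "transition" if same_class else "transversion"


def spectrum_summary(
    paired: Sequence[PairedVariant],
    rel_change_min: float = DEFAULT_REL_CHANGE_MIN,
) -> SpectrumSummary:
    """Summarize the substitution spectrum of the pre-treatment mutations.

    Headline proportions (transition / transversion / other) are taken over
    the mutation set present before therapy.  Dynamics counts per
    substitution type and the unchanged-VAF fraction per class (STABLE as
    "no change") describe how each substitution class responds to therapy.
    """
    if not paired:
        raise VariantError("spectrum_summary requires a non-empty variant list")
    paired = assign_dynamics(paired, rel_change_min)
    pre_set = [pv for pv in paired if pv.pre_vaf_pct is not None]
    if not pre_set:
        raise VariantError("no pre-treatment mutations in input")
    n_total = len(pre_set)
    n_ti = n_tv = n_other = 0
    per_sub: dict[str, Counter] = defaultdict(Counter)
    by_class: dict[str, Counter] = {"transition": Counter(), "transversion": Counter()}
    for pv in pre_set:
        sub = pv.substitution
        if sub is None:
            n_other += 1
            continue
        klass = classify_substitution(pv.ref_base, pv.alt_base)
        if klass == "transition":
            n_ti += 1
        else:
            n_tv += 1
        per_sub[sub][pv.dynamics.value] += 1
        by_class[klass][pv.dynamics.value] += 1
    unchanged = {}
    for klass, counter in by_class.items():
        total = sum(counter.values())
        if total:
            unchanged[klass] = counter[Dynamics.STABLE.value] / total
    return SpectrumSummary(
        n_total=n_total,
        prop_transition=n_ti / n_total,
        prop_transversion=n_tv / n_total,
        prop_other=n_other / n_total,
        per_substitution={s: dict(c) for s, c in sorted(per_sub.items())},
        unchanged_by_class=unchanged,
    )


def compartment_correlation(
    bmmc_vaf_pct: Sequence[float], cd34_vaf_pct: Sequence[float]
) -> float:
    """Pearson correlation between BMMC and CD34+ VAFs of matched mutations."""
    x = np.asarray(bmmc_vaf_pct, dtype=float)
    y = np.asarray(cd34_vaf_pct, dtype=float)
    if x.shape != y.shape:
        raise VariantError("BMMC and CD34 VAF vectors must have equal length")
    if x.size < 3:
        raise VariantError("correlation requires at least 3 VAF pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise VariantError("correlation undefined for a constant VAF vector")
    return float(stats.pearsonr(x, y).statistic)


def cohort_mutation_summary(
    paired: Sequence[PairedVariant],
    patient_roster: Sequence[str],
    rel_change_min: float = DEFAULT_REL_CHANGE_MIN,
) -> dict:
    """Per-patient mutation burden and VAF-reduction summary.

    Every patient on the roster contributes to the median and range even
    with zero mutations.  A patient "shows a VAF reduction" when at least
    one of their mutations is DECREASED or LOST.
    """
    if not patient_roster:
        raise VariantError("patient roster must be non-empty")
    roster = list(dict.fromkeys(patient_roster))
    paired = assign_dynamics(paired, rel_change_min)
    per_patient: dict[str, list[PairedVariant]] = {p: [] for p in roster}
    for pv in paired:
        if pv.patient_id not in per_patient:
            raise VariantError(f"variant patient {pv.patient_id!r} not on roster")
        per_patient[pv.patient_id].append(pv)
    counts = np.array([len(v) for v in per_patient.values()])
    reduced = [
        p
        for p, muts in per_patient.items()
        if any(pv.dynamics in (Dynamics.DECREASED, Dynamics.LOST) for pv in muts)
    ]
    n_with = int((counts > 0).sum())
    return {
        "n_mutations_total": int(counts.sum()),
        "median_per_patient": float(np.median(counts)),
        "range": (int(counts.min()), int(counts.max())),
        "n_patients": len(roster),
        "n_patients_with_mutations": n_with,
        "n_patients_with_any_vaf_reduction": len(reduced),
        "frac_patients_with_any_vaf_reduction": (
            len(reduced) / n_with if n_with else 0.0
        ),
    }
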