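"""Seeded synthetic cohorts with known ground truth.

Three generators emulate the data structures of a paired pre-/post-
azacytidine MDS study so every downstream stage can be scored by parameter
recovery without access to deposited data:

* an expression cohort — negative-binomial counts for healthy controls and
  paired pre/post patient samples, with responder-specific and
  non-responder-specific differentially expressed genes planted at a known
  log2 fold change;
* a variant table — per-mutation VAF trajectories with a planted dynamics
  category for each mutation, an SNV transition/transversion mix, and BMMC
  VAFs coupled to CD34+ VAFs at a target Pearson correlation;
* a validation cohort — expression plus survival records in which the
  hazard depends log-linearly on a latent "non-responder burden" that also
  up-shifts the non-responder signature genes.

Counts follow NB(mu, phi) with variance mu + phi * mu^2 (phi = 0 reduces to
Poisson); gene baselines are log-normal.  Every generator is fully
deterministic given its config (which carries the seed).
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .matrix import CountMatrix
from .variants import VariantCall, classify_substitution

__all__ = [
    "SimConfig",
    "VariantSimConfig",
    "SurvivalSimConfig",
    "SurvivalRecord",
    "ConfigError",
    "generate_expression_cohort",
    "generate_variant_table",
    "generate_validation_cohort",
]


class ConfigError(ValueError):
    """Raised for an invalid simulation configuration."""


# Recurrently mutated myeloid-neoplasm genes used to label simulated variants.
MYELOID_GENES = (
    "TP53", "DNMT3A", "TET2", "ASXL1", "SRSF2", "SF3B1", "RUNX1", "NRAS",
    "KRAS", "BCOR", "EZH2", "STAG2", "U2AF1", "IDH1", "IDH2", "CBL",
    "ZRSF2", "ETV6", "MTOR", "JAK2", "NPM1", "PHF6", "GATA2", "WT1",
)

TRANSITIONS = (("A", "G"), ("G", "A"), ("C", "T"), ("T", "C"))
TRANSVERSIONS = (
    ("A", "C"), ("C", "A"), ("A", "T"), ("T", "A"),
    ("G", "C"), ("C", "G"), ("G", "T"), ("T", "G"),
)
# C>T dominates the transition spectrum in hypomethylating-agent cohorts
# (deamination of 5-methylcytosine); weights reflect that skew.
TRANSITION_WEIGHTS = (0.15, 0.15, 0.50, 0.20)

DYNAMICS_CATEGORIES = ("acquired", "increased", "stable", "decreased", "lost")


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, phi: float) -> np.ndarray:
    """NB(mu, phi) with variance mu + phi mu^2; Poisson when phi == 0."""
    mu = np.asarray(mu, dtype=float)
    if phi == 0.0:
        return rng.poisson(mu)
    size = 1.0 / phi
    p = size / (size + mu)
    return rng.negative_binomial(size, p)


# ---------------------------------------------------------------------------
# expression cohort
# ---------------------------------------------------------------------------


@dataclass
class SimConfig:
    """Configuration of the synthetic paired expression cohort.

    Defaults mirror a fourteen-patient cohort with five blast responders,
    seven blast non-responders and two patients of undetermined response,
    plus age-matched healthy controls.  ``planted_log2fc`` is the magnitude
    of the responder-/non-responder-specific expression shifts (random sign
    per gene); ``nb_dispersion`` is phi in var = mu + phi mu^2.
    """

    n_controls: int = 6
    n_patients: int = 14
    n_undetermined: int = 2
    n_genes: int = 2000
    frac_R: float = 5.0 / 12.0
    frac_hem_R: float = 8.0 / 12.0
    n_sig_R: int = 100
    n_sig_NR: int = 100
    planted_log2fc: float = 2.0
    n_treatment_genes: int = 100
    treatment_log2fc: float = 1.0
    nb_dispersion: float = 0.1
    baseline_log_mean: float = 4.0
    baseline_log_sd: float = 1.0
    patient_log2_sd: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_controls, self.n_patients, self.n_genes) < 1:
            raise ConfigError("n_controls, n_patients and n_genes must be >= 1")
        if self.n_undetermined < 0 or self.n_undetermined >= self.n_patients:
            raise ConfigError("n_undetermined must be in [0, n_patients)")
        if not 0.0 < self.frac_R < 1.0:
            raise ConfigError("frac_R must be in (0, 1)")
        if self.planted_log2fc < 0:
            raise ConfigError("planted_log2fc must be >= 0")
        if self.nb_dispersion < 0:
            raise ConfigError("nb_dispersion must be >= 0")
        if self.n_sig_R < 0 or self.n_sig_NR < 0:
            raise ConfigError("signature gene counts must be >= 0")
        if self.n_sig_R + self.n_sig_NR + self.n_treatment_genes > self.n_genes:
            raise ConfigError("planted gene sets exceed n_genes")


@dataclass
class ExpressionTruth:
    """Ground truth of a simulated expression cohort."""

    planted_r: dict[str, int]  # gene -> +1 / -1 (sign of log2FC in R patients)
    planted_nr: dict[str, int]
    treatment_genes: dict[str, float]  # gene -> log2 shift applied post-AZA
    patient_labels: dict[str, str]  # patient -> blast response R/NR/NA
    hem_labels: dict[str, str]
    planted_log2fc: float

    def to_dict(self) -> dict:
        return {
            "planted_r": self.planted_r,
            "planted_nr": self.planted_nr,
            "treatment_genes": self.treatment_genes,
            "patient_labels": self.patient_labels,
            "hem_labels": self.hem_labels,
            "planted_log2fc": self.planted_log2fc,
        }


def generate_expression_cohort(cfg: SimConfig) -> tuple[CountMatrix, ExpressionTruth]:
    """Simulate controls plus paired pre/post patient samples.

    Gene baselines are drawn log-normally; each patient gets a mild
    per-gene log-normal offset shared by their pre and post samples (the
    paired design).  Responder-specific genes are shifted by
    ``+-planted_log2fc`` in responder patients only, non-responder-specific
    genes in non-responders only; a common treatment shift is applied to a
    third, disjoint gene set in every post sample.
    """
    rng = np.random.default_rng(cfg.seed)
    genes = [f"G{i:05d}" for i in range(cfg.n_genes)]
    log_mu0 = rng.normal(cfg.baseline_log_mean, cfg.baseline_log_sd, cfg.n_genes)
    mu0 = np.exp(log_mu0)

    perm = rng.permutation(cfg.n_genes)
    idx_r = perm[: cfg.n_sig_R]
    idx_nr = perm[cfg.n_sig_R : cfg.n_sig_R + cfg.n_sig_NR]
    idx_tr = perm[
        cfg.n_sig_R + cfg.n_sig_NR : cfg.n_sig_R + cfg.n_sig_NR + cfg.n_treatment_genes
    ]
    sign_r = rng.choice([-1, 1], size=len(idx_r))
    sign_nr = rng.choice([-1, 1], size=len(idx_nr))
    sign_tr = rng.choice([-1, 1], size=len(idx_tr))

    n_det = cfg.n_patients - cfg.n_undetermined
    n_r = int(round(cfg.frac_R * n_det))
    blast = ["R"] * n_r + ["NR"] * (n_det - n_r) + ["NA"] * cfg.n_undetermined
    n_hem_r = int(round(cfg.frac_hem_R * n_det))
    hem = ["R"] * n_hem_r + ["NR"] * (n_det - n_hem_r) + ["NA"] * cfg.n_undetermined
    rng.shuffle(hem)
    patients = [f"P{i + 1:02d}" for i in range(cfg.n_patients)]

    columns: dict[str, np.ndarray] = {}
    meta_rows = []
    for i in range(cfg.n_controls):
        sid = f"C{i + 1:02d}"
        columns[sid] = _nb_draw(rng, mu0, cfg.nb_dispersion)
        meta_rows.append((sid, sid, "control", "NA", "NA"))

    log2_r = np.zeros(cfg.n_genes)
    log2_r[idx_r] = sign_r * cfg.planted_log2fc
    log2_nr = np.zeros(cfg.n_genes)
    log2_nr[idx_nr] = sign_nr * cfg.planted_log2fc
    log2_treat = np.zeros(cfg.n_genes)
    log2_treat[idx_tr] = sign_tr * cfg.treatment_log2fc

    for pid, bl, hm in zip(patients, blast, hem):
        patient_shift = rng.normal(0.0, cfg.patient_log2_sd, cfg.n_genes)
        planted = log2_r if bl == "R" else log2_nr if bl == "NR" else 0.0
        mu_pre = mu0 * np.exp2(patient_shift + planted)
        mu_post = mu_pre * np.exp2(log2_treat)
        sid_pre, sid_post = f"{pid}_pre", f"{pid}_post"
        columns[sid_pre] = _nb_draw(rng, mu_pre, cfg.nb_dispersion)
        columns[sid_post] = _nb_draw(rng, mu_post, cfg.nb_dispersion)
        meta_rows.append((sid_pre, pid, "pre", bl, hm))
        meta_rows.append((sid_post, pid, "post", bl, hm))

    counts = pd.DataFrame(columns, index=genes)
    meta = pd.DataFrame(
        meta_rows,
        columns=["sample_id", "patient_id", "group", "blast_response", "hem_response"],
    ).set_index("sample_id")
    truth = ExpressionTruth(
        planted_r={genes[i]: int(s) for i, s in zip(idx_r, sign_r)},
        planted_nr={genes[i]: int(s) for i, s in zip(idx_nr, sign_nr)},
        treatment_genes={
            genes[i]: float(s * cfg.treatment_log2fc) for i, s in zip(idx_tr, sign_tr)
        },
        patient_labels=dict(zip(patients, blast)),
        hem_labels=dict(zip(patients, hem)),
        planted_log2fc=cfg.planted_log2fc,
    )
    return CountMatrix(counts=counts, sample_meta=meta), truth


# ---------------------------------------------------------------------------
# variant table
# ---------------------------------------------------------------------------


@dataclass
class VariantSimConfig:
    """Configuration of the synthetic paired variant table.

    Defaults target a twelve-patient cohort with 0-9 mutations per patient,
    an overall substitution spectrum of roughly 48% transitions / 35%
    transversions / 17% non-SNV events (``snv_fraction`` times
    ``ti_fraction`` resolves the split), and a BMMC-vs-CD34+ VAF
    correlation of 0.73.  ``dynamics_mix`` gives the probability of each
    planted trajectory category.
    """

    n_patients: int = 12
    mutations_per_patient: tuple[int, int] = (0, 9)
    snv_fraction: float = 0.833
    ti_fraction: float = 0.575
    dynamics_mix: dict[str, float] = field(
        default_factory=lambda: {
            "acquired": 0.08,
            "increased": 0.12,
            "stable": 0.30,
            "decreased": 0.35,
            "lost": 0.15,
        }
    )
    compartment_rho: float = 0.73
    bmmc_logit_shift: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ConfigError("n_patients must be >= 1")
        lo, hi = self.mutations_per_patient
        if lo < 0 or hi < lo:
            raise ConfigError("mutations_per_patient must be a valid (lo, hi) range")
        if not 0.0 <= self.ti_fraction <= 1.0:
            raise ConfigError("ti_fraction must be in [0, 1]")
        if not 0.0 <= self.snv_fraction <= 1.0:
            raise ConfigError("snv_fraction must be in [0, 1]")
        if set(self.dynamics_mix) - set(DYNAMICS_CATEGORIES):
            raise ConfigError(f"unknown dynamics categories in mix: {self.dynamics_mix}")
        if abs(sum(self.dynamics_mix.values()) - 1.0) > 1e-9:
            raise ConfigError("dynamics_mix probabilities must sum to 1")
        if not -1.0 <= self.compartment_rho <= 1.0:
            raise ConfigError("compartment_rho must be in [-1, 1]")


@dataclass
class VariantTruth:
    """Ground truth of a simulated variant table."""

    dynamics: dict[tuple[str, str, str], str]  # (patient, gene, change) -> category
    is_transition: dict[tuple[str, str, str], bool | None]
    mutations_per_patient: dict[str, int]
    logit_noise_sd: float


def _solve_logit_noise_sd(
    vafs: np.ndarray, rho: float, rng: np.random.Generator, n_rep: int = 200
) -> float:
    """Noise scale on logit-VAF that induces Pearson correlation ``rho``.

    Uses common random numbers: the induced correlation is estimated on
    ``n_rep`` noise replicates of the observed VAF vector and the scale is
    found by bisection (the induced correlation decreases monotonically in
    the noise scale).
    """
    if not 0.0 < rho <= 1.0:
        raise ConfigError(
            "additive logit noise can only induce correlations in (0, 1], "
            f"got compartment_rho={rho}"
        )
    if rho >= 0.999:
        return 0.0
    v = np.tile(vafs / 100.0, n_rep)
    z = rng.standard_normal(v.size)
    lo_v = logit(np.clip(v, 1e-4, 1 - 1e-4))

    def induced(sd: float) -> float:
        noisy = expit(lo_v + sd * z) * 100.0
        return float(np.corrcoef(noisy, v)[0, 1])

    lo, hi = 1e-4, 10.0
    if induced(hi) > rho:
        return hi
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if induced(mid) > rho:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _realize_vafs(rng: np.random.Generator, category: str) -> tuple[float | None, float | None]:
    """Draw a (pre, post) VAF pair consistent with a dynamics category.

    Relative changes keep a margin around the 25% stability band so the
    classifier recovers the planted category exactly.
    """
    if category == "acquired":
        return None, float(rng.uniform(5.0, 40.0))
    if category == "lost":
        return float(rng.uniform(5.0, 60.0)), None
    pre = float(rng.uniform(5.0, 45.0))
    if category == "stable":
        post = pre * float(rng.uniform(0.88, 1.12))
    elif category == "increased":
        post = pre * float(rng.uniform(1.5, 2.5))
    else:  # decreased
        post = pre * float(rng.uniform(0.2, 0.6))
    return pre, float(min(post, 95.0))


def generate_variant_table(
    cfg: VariantSimConfig,
) -> tuple[list[VariantCall], VariantTruth]:
    """Simulate a paired variant table over CD34+ and BMMC compartments.

    Each mutation carries a true dynamics category realized in its CD34+
    pre/post VAFs; SNV ref/alt bases are drawn to match ``ti_fraction``;
    the BMMC VAF of every observation is the CD34+ VAF perturbed on the
    logit scale, with the noise size solved numerically so the sample
    correlation targets ``compartment_rho``.
    """
    rng = np.random.default_rng(cfg.seed)
    lo, hi = cfg.mutations_per_patient
    categories = list(cfg.dynamics_mix)
    probs = np.array([cfg.dynamics_mix[c] for c in categories])

    muts = []  # (patient, gene, change, ref, alt, vclass, category, pre, post)
    truth_dyn: dict[tuple[str, str, str], str] = {}
    truth_ti: dict[tuple[str, str, str], bool | None] = {}
    per_patient: dict[str, int] = {}
    for i in range(cfg.n_patients):
        pid = f"P{i + 1:02d}"
        n_mut = int(rng.integers(lo, hi + 1))
        per_patient[pid] = n_mut
        seen = set()
        for _ in range(n_mut):
            while True:
                gene = str(rng.choice(MYELOID_GENES))
                pos = int(rng.integers(1, 800))
                aa = rng.choice(list(string.ascii_uppercase), size=2)
                change = f"p.{aa[0]}{pos}{aa[1]}"
                if (gene, change) not in seen:
                    seen.add((gene, change))
                    break
            is_snv = bool(rng.random() < cfg.snv_fraction)
            if is_snv:
                if rng.random() < cfg.ti_fraction:
                    k = rng.choice(len(TRANSITIONS), p=np.array(TRANSITION_WEIGHTS))
                    ref, alt = TRANSITIONS[k]
                else:
                    ref, alt = TRANSVERSIONS[rng.integers(len(TRANSVERSIONS))]
                vclass = "SNV"
            else:
                ref = alt = ""
                vclass = "indel" if rng.random() < 0.7 else "other"
            category = categories[rng.choice(len(categories), p=probs)]
            pre, post = _realize_vafs(rng, category)
            muts.append((pid, gene, change, ref, alt, vclass, category, pre, post))
            key = (pid, gene, change)
            truth_dyn[key] = category
            truth_ti[key] = (
                classify_substitution(ref, alt) == "transition" if is_snv else None
            )

    cd34 = np.array(
        [v for *_, pre, post in muts for v in (pre, post) if v is not None]
    )
    sd = _solve_logit_noise_sd(cd34, cfg.compartment_rho, np.random.default_rng(cfg.seed + 1))

    calls: list[VariantCall] = []
    for pid, gene, change, ref, alt, vclass, _cat, pre, post in muts:
        for tp, vaf in (("pre", pre), ("post", post)):
            if vaf is None:
                continue
            frac = np.clip(vaf / 100.0, 1e-4, 1 - 1e-4)
            noisy = expit(
                logit(frac) + cfg.bmmc_logit_shift + sd * rng.standard_normal()
            )
            for comp, v in (("CD34", vaf), ("BMMC", float(noisy * 100.0))):
                calls.append(
                    VariantCall(
                        patient_id=pid,
                        gene=gene,
                        change=change,
                        ref_base=ref,
                        alt_base=alt,
                        variant_class=vclass,
                        timepoint=tp,
                        compartment=comp,
                        vaf_pct=v,
                    )
                )
    truth = VariantTruth(
        dynamics=truth_dyn,
        is_transition=truth_ti,
        mutations_per_patient=per_patient,
        logit_noise_sd=sd,
    )
    return calls, truth


# ---------------------------------------------------------------------------
# validation cohort (expression + survival)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SurvivalRecord:
    """Follow-up of one sample: duration, event indicator and group label."""

    sample_id: str
    time: float
    event: int
    group: str | None = None

    def __post_init__(self) -> None:
        if self.time <= 0:
            raise ConfigError(f"survival time must be > 0, got {self.time}")
        if self.event not in (0, 1):
            raise ConfigError(f"event must be 0 or 1, got {self.event}")


@dataclass
class SurvivalSimConfig:
    """Configuration of the synthetic validation cohort.

    Each sample receives a latent standard-normal non-responder burden
    ``b``; the non-responder signature genes are up-shifted by
    ``burden_log2fc * b`` and event times are exponential with hazard
    ``baseline_rate * exp(hazard_beta * b)``, with independent exponential
    censoring at ``censor_rate``.
    """

    n_samples: int = 180
    hazard_beta: float = 1.0
    baseline_rate: float = 0.02
    censor_rate: float = 0.01
    burden_log2fc: float = 1.0
    n_extra_genes: int = 1000
    nb_dispersion: float = 0.1
    baseline_log_mean: float = 4.0
    baseline_log_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 2:
            raise ConfigError("n_samples must be >= 2")
        if self.baseline_rate <= 0:
            raise ConfigError("baseline_rate must be > 0")
        if self.censor_rate < 0:
            raise ConfigError("censor_rate must be >= 0")


@dataclass
class ValidationTruth:
    """Ground truth of a simulated validation cohort."""

    burden: dict[str, float]  # sample -> latent non-responder burden b
    nr_genes: list[str]
    r_genes: list[str]


def generate_validation_cohort(
    cfg: SurvivalSimConfig,
    r_genes: Sequence[str],
    nr_genes: Sequence[str],
) -> tuple[CountMatrix, list[SurvivalRecord], ValidationTruth]:
    """Simulate an independent diagnostic cohort with survival follow-up.

    The gene universe is the union of the two signatures plus background
    genes.  Only the non-responder signature genes respond to the latent
    burden; the responder signature genes behave as background, so the
    difference score isolates the planted axis.
    """
    r_genes = list(dict.fromkeys(r_genes))
    nr_genes = list(dict.fromkeys(nr_genes))
    if not r_genes or not nr_genes:
        raise ConfigError("both signatures must be non-empty")
    rng = np.random.default_rng(cfg.seed)
    extra = [f"BG{i:05d}" for i in range(cfg.n_extra_genes)]
    genes = list(dict.fromkeys([*r_genes, *nr_genes, *extra]))
    n_genes = len(genes)
    mu0 = np.exp(rng.normal(cfg.baseline_log_mean, cfg.baseline_log_sd, n_genes))
    nr_mask = np.isin(genes, nr_genes)

    burden = rng.standard_normal(cfg.n_samples)
    sample_ids = [f"V{i + 1:03d}" for i in range(cfg.n_samples)]
    columns = {}
    for sid, b in zip(sample_ids, burden):
        mu = mu0 * np.where(nr_mask, np.exp2(cfg.burden_log2fc * b), 1.0)
        columns[sid] = _nb_draw(rng, mu, cfg.nb_dispersion)
    counts = pd.DataFrame(columns, index=genes)
    meta = pd.DataFrame(
        {
            "patient_id": sample_ids,
            "group": "pre",
            "blast_response": "NA",
            "hem_response": "NA",
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )

    hazards = cfg.baseline_rate * np.exp(cfg.hazard_beta * burden)
    t_event = rng.exponential(1.0 / hazards)
    if cfg.censor_rate > 0:
        t_censor = rng.exponential(1.0 / cfg.censor_rate, cfg.n_samples)
    else:
        t_censor = np.full(cfg.n_samples, np.inf)
    time = np.minimum(t_event, t_censor)
    event = (t_event <= t_censor).astype(int)
    # exponential draws are almost surely positive; guard exact zeros anyway
    time = np.maximum(time, 1e-9)
    records = [
        SurvivalRecord(sample_id=sid, time=float(t), event=int(e))
        for sid, t, e in zip(sample_ids, time, event)
    ]
    truth = ValidationTruth(
        burden=dict(zip(sample_ids, burden.astype(float))),
        nr_genes=nr_genes,
        r_genes=r_genes,
    )
    return CountMatrix(counts=counts, sample_meta=meta), records, truth
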