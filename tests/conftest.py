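"""Shared fixtures: small synthetic cohorts with known ground truth."""

import pytest

from azasig.diffexpr import call_degs, de_test, normalize_median_of_ratios
from azasig.signatures import derive_unique_signatures
from azasig.synthetic import SimConfig, generate_expression_cohort

# cohort sized for signal recovery: 20 controls, 20 R + 20 NR patients
RECOVERY_CONFIG = dict(
    n_controls=20,
    n_patients=44,
    n_undetermined=4,
    frac_R=0.5,
    n_genes=2000,
    n_sig_R=100,
    n_sig_NR=100,
    planted_log2fc=2.0,
    nb_dispersion=0.1,
)


@pytest.fixture(scope="session")
def recovery_cohort():
    """One seeded cohort at recovery scale, with its truth record."""
    cm, truth = generate_expression_cohort(SimConfig(seed=11, **RECOVERY_CONFIG))
    return cm, truth


@pytest.fixture(scope="session")
def derived_signatures(recovery_cohort):
    """R/NR unique signatures derived end-to-end from the recovery cohort."""
    cm, truth = recovery_cohort
    _, norm = normalize_median_of_ratios(cm)
    controls = cm.samples_where(group="control")
    deg_sets = []
    for resp in ("R", "NR"):
        res = de_test(norm, cm.samples_where(group="pre", blast_response=resp), controls)
        up, down = call_degs(res)
        deg_sets.append([*up, *down])
    r_sig, nr_sig = derive_unique_signatures(*deg_sets)
    return r_sig, nr_sig
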