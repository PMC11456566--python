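"""VAF filtering, pairing, dynamics classification and spectrum summaries."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from azasig.variants import (
    Dynamics,
    PairedVariant,
    VariantCall,
    VariantError,
    assign_dynamics,
    classify_dynamics,
    classify_substitution,
    cohort_mutation_summary,
    compartment_correlation,
    filter_by_vaf,
    pair_variants,
    spectrum_summary,
)


def _call(patient="P01", gene="TP53", change="p.R175H", vaf=10.0, timepoint="pre",
          ref="C", alt="T", vclass="SNV", compartment="CD34"):
    return VariantCall(
        patient_id=patient, gene=gene, change=change, ref_base=ref, alt_base=alt,
        variant_class=vclass, timepoint=timepoint, compartment=compartment, vaf_pct=vaf,
    )


class TestFilterByVaf:
    def test_low_pre_rescued_by_expanding_post_clone(self):
        # an emerging clone: 1.27% pre rescued by 15.29% post
        calls = [
            _call(gene="NRAS", change="p.G12D", vaf=1.27, timepoint="pre"),
            _call(gene="NRAS", change="p.G12D", vaf=15.29, timepoint="post"),
        ]
        assert filter_by_vaf(calls, cutoff_pct=5.0, paired_rescue=True) == calls

    def test_low_post_rescued_by_collapsing_pre_clone(self):
        # a collapsing clone: 87.48% pre rescues the 3.98% post observation
        calls = [
            _call(vaf=87.48, timepoint="pre"),
            _call(vaf=3.98, timepoint="post"),
        ]
        assert filter_by_vaf(calls, cutoff_pct=5.0, paired_rescue=True) == calls

    def test_cutoff_boundary_is_inclusive(self):
        lone_low = [_call(vaf=4.99)]
        lone_at = [_call(vaf=5.00)]
        assert filter_by_vaf(lone_low, cutoff_pct=5.0, paired_rescue=True) == []
        assert filter_by_vaf(lone_at, cutoff_pct=5.0, paired_rescue=True) == lone_at

    def test_rescue_off_drops_subthreshold_calls(self):
        calls = [
            _call(vaf=87.48, timepoint="pre"),
            _call(vaf=3.98, timepoint="post"),
        ]
        assert filter_by_vaf(calls, cutoff_pct=5.0, paired_rescue=False) == calls[:1]

    def test_other_compartment_does_not_rescue(self):
        calls = [
            _call(vaf=50.0, timepoint="pre", compartment="BMMC"),
            _call(vaf=3.0, timepoint="post", compartment="CD34"),
        ]
        assert filter_by_vaf(calls, cutoff_pct=5.0, paired_rescue=True) == calls[:1]

    def test_idempotent(self):
        calls = [
            _call(vaf=87.48, timepoint="pre"),
            _call(vaf=3.98, timepoint="post"),
            _call(gene="BCOR", change="p.Q110X", vaf=2.0),
        ]
        once = filter_by_vaf(calls)
        assert filter_by_vaf(once) == once

    def test_invalid_cutoff_rejected(self):
        with pytest.raises(VariantError):
            filter_by_vaf([_call()], cutoff_pct=0.0)

    def test_negative_vaf_rejected_at_construction(self):
        with pytest.raises(VariantError):
            _call(vaf=-1.0)


class TestPairVariants:
    def test_pre_only_call_gives_absent_post(self):
        (pv,) = pair_variants([_call(timepoint="pre", vaf=12.0)])
        assert pv.pre_vaf_pct == 12.0 and pv.post_vaf_pct is None

    def test_pre_and_post_merge_into_one_pair(self):
        pairs = pair_variants([_call(vaf=10, timepoint="pre"), _call(vaf=20, timepoint="post")])
        assert len(pairs) == 1
        assert (pairs[0].pre_vaf_pct, pairs[0].post_vaf_pct) == (10, 20)

    def test_duplicate_timepoint_names_offending_key(self):
        with pytest.raises(VariantError, match="TP53"):
            pair_variants([_call(vaf=10), _call(vaf=11)])

    def test_mixed_compartments_rejected(self):
        with pytest.raises(VariantError, match="compartment"):
            pair_variants([_call(), _call(change="p.X1Y", compartment="BMMC")])


class TestClassifyDynamics:
    @pytest.mark.parametrize(
        "pre,post,expected",
        [
            (87.48, 3.98, Dynamics.DECREASED),  # collapsing TP53-like clone
            (1.27, 15.29, Dynamics.INCREASED),  # expanding NRAS-like clone
            (10.0, 10.0, Dynamics.STABLE),
            (None, 7.2, Dynamics.ACQUIRED),
            (7.2, None, Dynamics.LOST),
            (10.0, 12.0, Dynamics.STABLE),  # +20% < 25% band
            (10.0, 12.5, Dynamics.INCREASED),  # band boundary is exclusive
            (10.0, 7.5, Dynamics.DECREASED),
        ],
    )
    def test_examples(self, pre, post, expected):
        assert classify_dynamics(pre, post) is expected

    def test_both_absent_is_an_error(self):
        with pytest.raises(VariantError):
            classify_dynamics(None, None)

    @given(
        pre=st.one_of(st.none(), st.floats(0.01, 100)),
        post=st.one_of(st.none(), st.floats(0.01, 100)),
    )
    @settings(max_examples=200, deadline=None)
    def test_exhaustive_and_exclusive(self, pre, post):
        """Every valid VAF pair maps to exactly one of the five categories."""
        if pre is None and post is None:
            return
        assert classify_dynamics(pre, post) in list(Dynamics)


class TestSubstitution:
    @pytest.mark.parametrize(
        "ref,alt,expected",
        [
            ("C", "T", "transition"),
            ("A", "G", "transition"),
            ("G", "A", "transition"),
            ("T", "C", "transition"),
            ("C", "A", "transversion"),
            ("A", "T", "transversion"),
            ("G", "C", "transversion"),
        ],
    )
    def test_classification(self, ref, alt, expected):
        assert classify_substitution(ref, alt) == expected

    def test_invalid_base_rejected(self):
        with pytest.raises(VariantError):
            classify_substitution("C", "N")
        with pytest.raises(VariantError):
            classify_substitution("C", "C")


def _paired(gene, ref, alt, pre, post, vclass="SNV", patient="P01", change=None):
    return PairedVariant(
        patient_id=patient, gene=gene, change=change or f"p.{gene}",
        ref_base=ref, alt_base=alt, variant_class=vclass, compartment="CD34",
        pre_vaf_pct=pre, post_vaf_pct=post,
    )


class TestSpectrumSummary:
    def test_all_transitions(self):
        paired = [_paired(f"G{i}", "C", "T", 10, 20, change=f"p.X{i}") for i in range(5)]
        summary = spectrum_summary(paired)
        assert summary.prop_transition == 1.0
        assert summary.prop_transversion == 0.0

    def test_known_mix_is_exact(self):
        # 6 transitions, 3 transversions, 1 indel among pre-treatment mutations
        paired = (
            [_paired(f"T{i}", "C", "T", 10, 10, change=f"p.A{i}") for i in range(6)]
            + [_paired(f"V{i}", "C", "A", 10, 50, change=f"p.B{i}") for i in range(3)]
            + [_paired("IND", "", "", 10, 10, vclass="indel")]
        )
        summary = spectrum_summary(paired)
        assert summary.n_total == 10
        assert summary.prop_transition == pytest.approx(0.6)
        assert summary.prop_transversion == pytest.approx(0.3)
        assert summary.prop_other == pytest.approx(0.1)
        # all 6 transitions stable, all 3 transversions increased
        assert summary.unchanged_by_class["transition"] == pytest.approx(1.0)
        assert summary.unchanged_by_class["transversion"] == pytest.approx(0.0)

    def test_proportions_sum_to_one_and_counts_recover_total(self):
        paired = (
            [_paired(f"T{i}", "C", "T", 10, 30, change=f"p.A{i}") for i in range(4)]
            + [_paired(f"V{i}", "G", "T", 20, 5, change=f"p.B{i}") for i in range(3)]
            + [_paired("IND", "", "", 15, 15, vclass="indel")]
        )
        s = spectrum_summary(paired)
        assert s.prop_transition + s.prop_transversion + s.prop_other == pytest.approx(1.0)
        n_snv = sum(sum(c.values()) for c in s.per_substitution.values())
        assert n_snv + round(s.prop_other * s.n_total) == s.n_total

    def test_empty_input_is_an_error(self):
        with pytest.raises(VariantError):
            spectrum_summary([])

    def test_acquired_mutations_excluded_from_pre_spectrum(self):
        paired = [
            _paired("A", "C", "T", 10, 20),
            _paired("B", "C", "A", None, 20, change="p.B1"),
        ]
        assert spectrum_summary(paired).n_total == 1


class TestCompartmentCorrelation:
    def test_identical_vectors(self):
        assert compartment_correlation([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)

    def test_perfect_anti_order(self):
        assert compartment_correlation([1, 2, 3], [2, 1, 0]) == pytest.approx(-1.0)

    def test_matches_product_moment_formula(self):
        rng = np.random.default_rng(42)
        x = rng.uniform(0, 100, 200)
        y = 0.7 * x + rng.normal(0, 10, 200)
        # independent brute-force covariance-formula oracle
        xm, ym = x.mean(), y.mean()
        expected = float(
            ((x - xm) * (y - ym)).sum()
            / np.sqrt(((x - xm) ** 2).sum() * ((y - ym) ** 2).sum())
        )
        assert compartment_correlation(x, y) == pytest.approx(expected, abs=1e-12)

    def test_constant_vector_is_an_error(self):
        with pytest.raises(VariantError):
            compartment_correlation([1, 1, 1], [1, 2, 3])

    def test_too_few_pairs(self):
        with pytest.raises(VariantError):
            compartment_correlation([1, 2], [2, 1])


class TestCohortSummary:
    def test_patient_without_mutations_counts_toward_median(self):
        summary = cohort_mutation_summary([], ["P01"])
        assert summary["n_mutations_total"] == 0
        assert summary["median_per_patient"] == 0

    def test_reduction_means_decreased_or_lost(self):
        paired = [
            _paired("TP53", "C", "T", 80, 4, patient="P01"),   # decreased
            _paired("BCOR", "C", "A", 10, 10, patient="P02"),  # stable
            _paired("TET2", "G", "A", 12, None, patient="P03", change="p.T1"),  # lost
        ]
        s = cohort_mutation_summary(paired, ["P01", "P02", "P03", "P04"])
        assert s["n_mutations_total"] == 3
        assert s["n_patients_with_mutations"] == 3
        assert s["n_patients_with_any_vaf_reduction"] == 2
        assert s["frac_patients_with_any_vaf_reduction"] == pytest.approx(2 / 3)
        assert s["range"] == (0, 1)

    def test_empty_roster_is_an_error(self):
        with pytest.raises(VariantError):
            cohort_mutation_summary([], [])

    def test_unknown_patient_rejected(self):
        with pytest.raises(VariantError):
            cohort_mutation_summary([_paired("TP53", "C", "T", 10, 10)], ["P99"])


class TestSyntheticRecovery:
    def test_pair_count_and_dynamics_match_truth(self):
        from azasig.synthetic import VariantSimConfig, generate_variant_table

        calls, truth = generate_variant_table(VariantSimConfig(seed=4, n_patients=12))
        cd34 = [c for c in calls if c.compartment == "CD34"]
        paired = assign_dynamics(pair_variants(cd34))
        assert len(paired) == sum(truth.mutations_per_patient.values())
        for pv in paired:
            key = (pv.patient_id, pv.gene, pv.change)
            assert pv.dynamics.value.lower() == truth.dynamics[key]
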