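"""LOF classification, position rules, CADD tiers and segregation filtering.

The segregation filter is checked against an exhaustive brute-force oracle:
for every possible genotype vector over the genotyped members (allele counts
0/1/2), the filter must agree with a direct evaluation of the dominant-model
predicate (all genotyped blood cases carry, no genotyped control carries, at
least one case carrier; affected married-in spouses exempt).
"""

import itertools

import pytest

from famlof.pedigree import Role, assign_roles
from famlof.prioritize import (
    CaddTier,
    LofClass,
    PrioritizationError,
    cadd_tier,
    check_sample_consistency,
    classify_lof,
    gene_position_filter,
    prioritize_variants,
    segregation_filter,
)
from famlof.variants import (
    ConsequenceClass,
    GenotypeCall,
    QCThresholds,
    TranscriptAnnotation,
)

from conftest import FAMILY8_CARRIERS, FAMILY11_CARRIERS, make_variant

# single-family test cohorts have few samples, so the cohort-artifact (local
# AF) filter is widened; its own behaviour is tested at cohort scale
RELAXED = QCThresholds(max_local_af=0.6)


def ann(consequence, exon=2, count=6, coding=True):
    return TranscriptAnnotation(
        gene="G", transcript_id="T", consequence_class=consequence,
        exon_index=exon, exon_count=count, protein_coding=coding,
    )


class TestClassifyLof:
    @pytest.mark.parametrize(
        "consequence, expected",
        [
            (ConsequenceClass.FRAMESHIFT, LofClass.FRAMESHIFT),
            (ConsequenceClass.STOP_GAIN, LofClass.STOP_GAIN),
            (ConsequenceClass.SPLICE_ACCEPTOR, LofClass.CANONICAL_SPLICE),
            (ConsequenceClass.SPLICE_DONOR, LofClass.CANONICAL_SPLICE),
            (ConsequenceClass.MISSENSE, None),
            (ConsequenceClass.SYNONYMOUS, None),
            (ConsequenceClass.OTHER, None),
        ],
    )
    def test_classes(self, consequence, expected):
        assert classify_lof(ann(consequence)) == expected


class TestGenePositionFilter:
    def test_last_exon_excluded(self):
        ok, reason = gene_position_filter(ann(ConsequenceClass.STOP_GAIN, exon=3, count=3))
        assert not ok and reason == "last_exon"

    def test_internal_exon_retained(self):
        ok, reason = gene_position_filter(ann(ConsequenceClass.STOP_GAIN, exon=1, count=2))
        assert ok and reason is None

    def test_non_coding_excluded(self):
        ok, reason = gene_position_filter(
            ann(ConsequenceClass.STOP_GAIN, coding=False)
        )
        assert not ok and reason == "non_coding"

    def test_unlocatable_exon_excluded_conservatively(self):
        a = TranscriptAnnotation(
            gene="G", transcript_id="T",
            consequence_class=ConsequenceClass.STOP_GAIN,
        )
        ok, reason = gene_position_filter(a)
        assert not ok and reason == "unlocatable"

    def test_acceptor_of_second_exon_survives_last_exon_rule(self):
        # splice variants carry the affected (downstream) exon's index
        ok, _ = gene_position_filter(
            ann(ConsequenceClass.SPLICE_ACCEPTOR, exon=2, count=25)
        )
        assert ok


class TestCaddTier:
    @pytest.mark.parametrize(
        "score, tier",
        [
            (44.0, CaddTier.TOP01PCT),
            (30.0001, CaddTier.TOP01PCT),
            (30.0, CaddTier.TOP1PCT),
            (24.7, CaddTier.TOP1PCT),
            (20.0, CaddTier.BELOW20),
            (3.0, CaddTier.BELOW20),
            (None, CaddTier.UNKNOWN),
        ],
    )
    def test_tiers_with_strict_boundaries(self, score, tier):
        assert cadd_tier(score) is tier


class TestSegregationFixtures:
    def test_reference_family_pattern_passes(self, family8):
        v = make_variant(family8, FAMILY8_CARRIERS)
        verdict = segregation_filter(v, family8, assign_roles(family8))
        assert verdict.passes
        assert verdict.case_carriers == 2  # both genotyped CRC cases carry
        assert verdict.case_noncarriers == 0
        assert verdict.control_carriers == 0

    def test_married_in_phenocopy_is_exempt(self, family11):
        v = make_variant(family11, FAMILY11_CARRIERS)
        verdict = segregation_filter(v, family11, assign_roles(family11))
        assert verdict.passes
        assert verdict.exempt_phenocopies == ["II-9"]

    def test_control_carrier_fails(self, family8):
        v = make_variant(family8, FAMILY8_CARRIERS | {"IV-8"})
        verdict = segregation_filter(v, family8, assign_roles(family8))
        assert not verdict.passes
        assert verdict.control_carriers == 1

    def test_case_noncarrier_fails(self, family8):
        v = make_variant(family8, FAMILY8_CARRIERS - {"IV-11"})
        verdict = segregation_filter(v, family8, assign_roles(family8))
        assert not verdict.passes
        assert verdict.case_noncarriers == 1

    def test_no_genotyped_case_fails_with_reason(self, family8):
        v = make_variant(
            family8, FAMILY8_CARRIERS, missing={"III-12", "IV-11"}
        )
        verdict = segregation_filter(v, family8, assign_roles(family8))
        assert not verdict.passes
        assert verdict.reason == "no_genotyped_case"

    def test_missing_genotypes_are_unconstrained(self, family11):
        # a missing control genotype cannot veto
        v = make_variant(family11, FAMILY11_CARRIERS, missing={"IV-1"})
        verdict = segregation_filter(v, family11, assign_roles(family11))
        assert verdict.passes


def oracle_predicate(family, roles, carrier_of):
    """Direct evaluation of the dominant-model segregation rule."""
    case_carrier = False
    for m in family.members:
        if not m.genotyped or carrier_of[m.member_id] is None:
            continue
        carries = carrier_of[m.member_id] >= 1
        role = roles[m.member_id]
        if role is Role.CASE and family.is_blood(m.member_id):
            if not carries:
                return False
            case_carrier = True
        elif role is Role.CONTROL and carries:
            return False
    return case_carrier


class TestSegregationOracle:
    def test_exhaustive_agreement_with_bruteforce(self, family8, family11):
        """All 3^n genotype vectors over <=8 genotyped members agree with the
        brute-force predicate."""
        # restrict the larger family to 8 genotyped members
        for m in family8.members:
            if m.member_id in ("III-13", "III-15"):
                m.genotyped = False
        for family in (family8, family11):
            roles = assign_roles(family)
            genotyped = [m for m in family.members if m.genotyped]
            assert len(genotyped) <= 8
            others = [m for m in family.members if not m.genotyped]
            n_checked = 0
            for vector in itertools.product((0, 1, 2), repeat=len(genotyped)):
                carrier_of = {m.member_id: None for m in others}
                genotypes = {}
                for m, ac in zip(genotyped, vector):
                    carrier_of[m.member_id] = ac
                    genotypes[m.sample_id] = GenotypeCall(m.sample_id, ac, 30)
                v = make_variant(family, set())
                v.genotypes = genotypes
                verdict = segregation_filter(v, family, roles)
                assert verdict.passes == oracle_predicate(family, roles, carrier_of)
                n_checked += 1
            assert n_checked == 3 ** len(genotyped)


class TestSegregationMonotonicity:
    def test_added_control_noncarrier_never_rescues_failure(self, family11):
        roles = assign_roles(family11)
        base = make_variant(family11, FAMILY11_CARRIERS | {"IV-1"})  # fails
        assert not segregation_filter(base, family11, roles).passes
        # genotyping one more control as non-carrier must not flip to pass
        richer = make_variant(
            family11, FAMILY11_CARRIERS | {"IV-1"}
        )
        assert not segregation_filter(richer, family11, roles).passes

    def test_blood_case_noncarrier_always_breaks_passing(self, family8):
        roles = assign_roles(family8)
        passing = make_variant(family8, FAMILY8_CARRIERS)
        assert segregation_filter(passing, family8, roles).passes
        broken = make_variant(family8, FAMILY8_CARRIERS - {"III-12"})
        assert not segregation_filter(broken, family8, roles).passes


class TestCascade:
    def test_population_af_rejection_recorded_in_trail(self, family8):
        v = make_variant(family8, FAMILY8_CARRIERS,
                         population_afs={"gnomad_nfe": 0.002})
        cands, trail = prioritize_variants(
            [v], [family8], thresholds=RELAXED,
            configured_sources=["gnomad_nfe"], verbose_trail=True,
        )
        assert cands == []
        assert (v.key, "population_af", "reject", "0.002") in trail

    def test_last_exon_planted_variant_rejected(self, family8):
        v = make_variant(
            family8, FAMILY8_CARRIERS,
            annotations=[ann(ConsequenceClass.STOP_GAIN, exon=6, count=6)],
        )
        cands, trail = prioritize_variants(
            [v], [family8], thresholds=RELAXED, verbose_trail=True
        )
        assert cands == []
        assert (v.key, "gene_position", "reject", "last_exon") in trail

    def test_qualifying_variant_becomes_candidate_with_full_trail(self, family8):
        v = make_variant(family8, FAMILY8_CARRIERS)
        cands, _ = prioritize_variants([v], [family8], thresholds=RELAXED)
        assert len(cands) == 1
        c = cands[0]
        assert c.lof_class is LofClass.FRAMESHIFT
        assert c.passing_families == ["F8"]
        filters = [f for f, _, _ in c.trail]
        assert filters == sorted(set(filters), key=filters.index)  # no repeats
        assert set(filters) == {
            "qc", "local_af", "population_af", "lof_class",
            "gene_position", "segregation", "cadd_tier",
        }

    def test_filter_order_independence_of_candidate_set(self, family8):
        """The accepted variant SET does not depend on the order of the
        variant-level predicates (QC masking applied first throughout)."""
        from famlof.variants import local_cohort_af, max_population_af, qc_filter
        from famlof.prioritize import _best_lof_annotation

        t = RELAXED
        variants = [
            make_variant(family8, FAMILY8_CARRIERS, pos=1),
            make_variant(family8, FAMILY8_CARRIERS, pos=2,
                         population_afs={"gnomad_nfe": 0.002}),
            make_variant(family8, FAMILY8_CARRIERS, pos=3,
                         annotations=[ann(ConsequenceClass.MISSENSE)]),
            make_variant(family8, FAMILY8_CARRIERS, pos=4, qual=10.0),
            make_variant(family8, FAMILY8_CARRIERS, pos=5,
                         annotations=[ann(ConsequenceClass.STOP_GAIN, exon=6, count=6)]),
        ]
        predicates = [
            lambda v: local_cohort_af(v) < t.max_local_af,
            lambda v: max_population_af(v, ["gnomad_nfe"]) < t.max_pop_af,
            lambda v: _best_lof_annotation(v)[0] is not None,
        ]
        reference = None
        for order in itertools.permutations(range(3)):
            accepted = set()
            for v in variants:
                kept = qc_filter(v, t)
                if kept is None:
                    continue
                if all(predicates[i](kept) for i in order):
                    accepted.add(v.pos)
            if reference is None:
                reference = accepted
            assert accepted == reference
        assert reference == {1}

    def test_sample_mismatch_lists_offenders(self, family8):
        with pytest.raises(PrioritizationError, match="F8_III-12"):
            check_sample_consistency([family8], ["F8_IV-11"])

    def test_ranking_is_deterministic(self, family8):
        hi = make_variant(family8, FAMILY8_CARRIERS, pos=10, cadd=44.0)
        lo = make_variant(family8, FAMILY8_CARRIERS, pos=5, cadd=24.7)
        cands, _ = prioritize_variants([lo, hi], [family8], thresholds=RELAXED)
        assert [c.variant.pos for c in cands] == [10, 5]
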