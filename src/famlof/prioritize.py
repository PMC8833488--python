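"""Dominant-model variant prioritization.

The core procedure: per-variant QC and frequency filters, restriction to
loss-of-function classes (stop gain, frameshift, canonical splice), exclusion
of last-exon and non-coding-transcript hits (truncations in a final exon
typically escape nonsense-mediated decay), per-family segregation under an
autosomal-dominant model, and CADD deleteriousness tiering.  Every variant
accumulates an ordered filter trail so rejections are auditable.

Segregation (dominant model): every genotyped blood-relative case must carry
at least one alt allele, no genotyped control may carry it, and at least one
case carrier must exist.  Possible carriers and uninformative members are
unconstrained, as are missing genotypes.  Affected married-in spouses
(phenocopies) are exempt from the carrier requirement and recorded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Optional, Sequence

from .pedigree import Family, Role, assign_roles
from .variants import (
    AnnotatedVariant,
    AnnotationFieldSpec,
    ConsequenceClass,
    DEFAULT_FIELD_SPEC,
    QCThresholds,
    TranscriptAnnotation,
    local_cohort_af,
    max_population_af,
    qc_filter,
    read_annotated_vcf,
)


class LofClass(str, Enum):
    STOP_GAIN = "stop_gain"
    FRAMESHIFT = "frameshift"
    CANONICAL_SPLICE = "canonical_splice"


class CaddTier(str, Enum):
    BELOW20 = "below20"
    TOP1PCT = "top1pct"  # CADD PHRED > 20
    TOP01PCT = "top0.1pct"  # CADD PHRED > 30
    UNKNOWN = "unknown"


_TIER_RANK = {
    CaddTier.TOP01PCT: 3,
    CaddTier.TOP1PCT: 2,
    CaddTier.BELOW20: 1,
    CaddTier.UNKNOWN: 0,
}


@dataclass
class SegregationVerdict:
    family_id: str
    passes: bool
    case_carriers: int
    case_noncarriers: int
    control_carriers: int
    exempt_phenocopies: list[str] = field(default_factory=list)
    reason: Optional[str] = None


@dataclass
class CandidateVariant:
    variant: AnnotatedVariant
    lof_class: LofClass
    verdicts: list[SegregationVerdict]
    cadd_tier: CaddTier
    trail: list[tuple[str, str, str]] = field(default_factory=list)

    @property
    def passing_families(self) -> list[str]:
        return [v.family_id for v in self.verdicts]


def classify_lof(annotation: TranscriptAnnotation) -> Optional[LofClass]:
    """Map a transcript consequence onto a loss-of-function class, or None."""
    cc = annotation.consequence_class
    if cc is ConsequenceClass.STOP_GAIN:
        return LofClass.STOP_GAIN
    if cc is ConsequenceClass.FRAMESHIFT:
        return LofClass.FRAMESHIFT
    if cc in (ConsequenceClass.SPLICE_ACCEPTOR, ConsequenceClass.SPLICE_DONOR):
        return LofClass.CANONICAL_SPLICE
    return None


def gene_position_filter(
    annotation: TranscriptAnnotation,
) -> tuple[bool, Optional[str]]:
    """Exclude last-exon and non-coding-transcript hits.

    Returns ``(retained, reason)``.  Splice-site variants are expected to
    carry the downstream (affected) exon's index, so a canonical acceptor of
    exon 2 survives the last-exon rule.  Exonic consequences without a
    locatable exon are excluded conservatively.
    """
    if not annotation.protein_coding:
        return False, "non_coding"
    if annotation.exon_index is None or annotation.exon_count is None:
        return False, "unlocatable"
    if annotation.exon_index == annotation.exon_count:
        return False, "last_exon"
    return True, None


def cadd_tier(cadd_phred: Optional[float]) -> CaddTier:
    """CADD PHRED > 20 -> top 1%; > 30 -> top 0.1%; boundaries are strict."""
    if cadd_phred is None:
        return CaddTier.UNKNOWN
    if cadd_phred > 30:
        return CaddTier.TOP01PCT
    if cadd_phred > 20:
        return CaddTier.TOP1PCT
    return CaddTier.BELOW20


def segregation_filter(
    variant: AnnotatedVariant, family: Family, roles: dict[str, Role]
) -> SegregationVerdict:
    """Evaluate dominant-model segregation of one variant in one family."""
    case_carriers = case_noncarriers = control_carriers = 0
    exempt: list[str] = []
    any_genotyped_case = False
    for member in family.members:
        role = roles.get(member.member_id)
        if role is None:
            continue
        call = variant.genotypes.get(member.sample_id)
        if not member.genotyped or call is None or call.is_missing:
            continue
        if role is Role.CASE:
            any_genotyped_case = True
            if not family.is_blood(member.member_id):
                exempt.append(member.member_id)
                continue
            if call.is_carrier:
                case_carriers += 1
            else:
                case_noncarriers += 1
        elif role is Role.CONTROL:
            if call.is_carrier:
                control_carriers += 1
    if not any_genotyped_case:
        return SegregationVerdict(
            family_id=family.family_id,
            passes=False,
            case_carriers=0,
            case_noncarriers=0,
            control_carriers=control_carriers,
            exempt_phenocopies=exempt,
            reason="no_genotyped_case",
        )
    passes = case_noncarriers == 0 and control_carriers == 0 and case_carriers >= 1
    return SegregationVerdict(
        family_id=family.family_id,
        passes=passes,
        case_carriers=case_carriers,
        case_noncarriers=case_noncarriers,
        control_carriers=control_carriers,
        exempt_phenocopies=exempt,
    )


def _best_lof_annotation(
    variant: AnnotatedVariant,
) -> tuple[Optional[LofClass], Optional[str]]:
    """Most-damaging-transcript logic: retained if ANY protein-coding
    transcript annotation passes both the LOF and the position rule."""
    saw_lof = False
    reasons: list[str] = []
    for ann in variant.annotations:
        lof = classify_lof(ann)
        if lof is None:
            continue
        saw_lof = True
        retained, reason = gene_position_filter(ann)
        if retained:
            return lof, None
        reasons.append(reason or "excluded")
    if not saw_lof:
        return None, "not_lof"
    return None, ",".join(sorted(set(reasons)))


class PrioritizationError(ValueError):
    pass


def check_sample_consistency(
    families: Sequence[Family], vcf_samples: Iterable[str]
) -> None:
    """Every genotyped pedigree member must be a VCF sample."""
    vcf = set(vcf_samples)
    missing = [
        m.sample_id
        for fam in families
        for m in fam.members
        if m.genotyped and m.sample_id not in vcf
    ]
    if missing:
        raise PrioritizationError(
            "genotyped pedigree members absent from VCF: " + ", ".join(sorted(missing))
        )


def prioritize_variants(
    variants: Iterable[AnnotatedVariant],
    families: Sequence[Family],
    thresholds: QCThresholds = QCThresholds(),
    af_sources: Optional[Sequence[str]] = None,
    configured_sources: Optional[Iterable[str]] = None,
    verbose_trail: bool = False,
) -> tuple[list[CandidateVariant], list[tuple[str, str, str, str]]]:
    """Run the filter cascade over an in-memory variant stream.

    Returns the ranked candidate list and a flat trail of
    ``(variant_key, filter, verdict, value)`` rows; with ``verbose_trail``
    the trail also covers rejected variants.
    """
    roles_by_family = {f.family_id: assign_roles(f) for f in families}
    candidates: list[CandidateVariant] = []
    trail_rows: list[tuple[str, str, str, str]] = []

    def note(key: str, filt: str, verdict: str, value: str, keep: list) -> None:
        row = (key, filt, verdict, value)
        keep.append(row[1:])
        if verbose_trail or verdict != "reject":
            trail_rows.append(row)

    for variant in variants:
        local_trail: list[tuple[str, str, str]] = []
        key = variant.key
        kept = qc_filter(variant, thresholds)
        if kept is None:
            note(key, "qc", "reject", f"qual={variant.qual}", local_trail)
            continue
        note(key, "qc", "pass", f"qual={variant.qual}", local_trail)
        variant = kept

        local_af = local_cohort_af(variant)
        if not local_af < thresholds.max_local_af:
            note(key, "local_af", "reject", f"{local_af:.4f}", local_trail)
            continue
        note(key, "local_af", "pass", f"{local_af:.4f}", local_trail)

        sources = list(af_sources) if af_sources is not None else sorted(
            set(configured_sources or variant.population_afs)
        )
        pop_af = max_population_af(variant, sources, configured=configured_sources)
        if not pop_af < thresholds.max_pop_af:
            note(key, "population_af", "reject", f"{pop_af:.6g}", local_trail)
            continue
        note(key, "population_af", "pass", f"{pop_af:.6g}", local_trail)

        lof, reason = _best_lof_annotation(variant)
        if lof is None:
            filt = "lof_class" if reason == "not_lof" else "gene_position"
            note(key, filt, "reject", reason or "", local_trail)
            continue
        note(key, "lof_class", "pass", lof.value, local_trail)
        note(key, "gene_position", "pass", "retained", local_trail)

        verdicts = []
        for fam in families:
            v = segregation_filter(variant, fam, roles_by_family[fam.family_id])
            if v.passes:
                verdicts.append(v)
        if not verdicts:
            note(key, "segregation", "reject", "no_passing_family", local_trail)
            continue
        note(
            key,
            "segregation",
            "pass",
            ",".join(v.family_id for v in verdicts),
            local_trail,
        )
        tier = cadd_tier(variant.cadd_phred)
        note(key, "cadd_tier", "pass", tier.value, local_trail)
        candidates.append(
            CandidateVariant(
                variant=variant,
                lof_class=lof,
                verdicts=verdicts,
                cadd_tier=tier,
                trail=local_trail,
            )
        )

    def _chrom_order(c: str):
        c = c.removeprefix("chr")
        return (0, int(c)) if c.isdigit() else (1, c)

    candidates.sort(
        key=lambda c: (
            -_TIER_RANK[c.cadd_tier],
            -len(c.verdicts),
            _chrom_order(c.variant.chrom),
            c.variant.pos,
        )
    )
    return candidates, trail_rows


def run_prioritization(
    vcf_path: str,
    families: Sequence[Family],
    thresholds: QCThresholds = QCThresholds(),
    field_spec: AnnotationFieldSpec = DEFAULT_FIELD_SPEC,
    af_sources: Optional[Sequence[str]] = None,
    verbose_trail: bool = False,
) -> tuple[list[CandidateVariant], list[tuple[str, str, str, str]]]:
    """End-to-end cascade over an annotated multi-sample VCF."""
    variants = list(read_annotated_vcf(vcf_path, field_spec))
    if variants:
        check_sample_consistency(families, variants[0].genotypes.keys())
    return prioritize_variants(
        variants,
        families,
        thresholds=thresholds,
        af_sources=af_sources,
        configured_sources=field_spec.af_keys.keys(),
        verbose_trail=verbose_trail,
    )
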