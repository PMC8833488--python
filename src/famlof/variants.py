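"""Annotated multi-sample VCF records and record/sample-level filters.

The pipeline consumes VCFs that already carry per-transcript functional
annotation in an INFO field (VEP- or ANNOVAR-style); annotation is never
regenerated here.  The field layout is configuration
(:class:`AnnotationFieldSpec`), not code, so the same pipeline runs on
different annotation encodings.

Filters implemented here mirror the upstream WGS QC of the study design:
variant QUAL strictly > 20; per-sample depth >= 5 reads (genotypes below are
masked missing); population allele frequency strictly < 0.1%; local-cohort
carrier frequency strictly < 5% (technical-artifact removal).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Iterator, Optional, Sequence

import pysam


class VcfConfigError(ValueError):
    """The VCF lacks a declared field or a requested source is unknown."""


class ConsequenceClass(str, Enum):
    STOP_GAIN = "stop_gain"
    FRAMESHIFT = "frameshift"
    SPLICE_ACCEPTOR = "splice_acceptor"
    SPLICE_DONOR = "splice_donor"
    MISSENSE = "missense"
    SYNONYMOUS = "synonymous"
    OTHER = "other"


#: Sequence-ontology style terms mapped onto the coarse classes above.
SO_TERM_MAP = {
    "stop_gained": ConsequenceClass.STOP_GAIN,
    "stop_gain": ConsequenceClass.STOP_GAIN,
    "stopgain": ConsequenceClass.STOP_GAIN,
    "frameshift_variant": ConsequenceClass.FRAMESHIFT,
    "frameshift": ConsequenceClass.FRAMESHIFT,
    "splice_acceptor_variant": ConsequenceClass.SPLICE_ACCEPTOR,
    "splice_acceptor": ConsequenceClass.SPLICE_ACCEPTOR,
    "splice_donor_variant": ConsequenceClass.SPLICE_DONOR,
    "splice_donor": ConsequenceClass.SPLICE_DONOR,
    "missense_variant": ConsequenceClass.MISSENSE,
    "missense": ConsequenceClass.MISSENSE,
    "synonymous_variant": ConsequenceClass.SYNONYMOUS,
    "synonymous": ConsequenceClass.SYNONYMOUS,
}

MISSING = None  # allele_count sentinel


@dataclass(frozen=True)
class GenotypeCall:
    sample_id: str
    allele_count: Optional[int]  # 0, 1, 2 or None (missing)
    depth: Optional[int] = None  # reads; None = unreported

    def __post_init__(self) -> None:
        if self.depth is not None and self.depth < 0:
            raise ValueError("negative depth")
        if self.allele_count not in (None, 0, 1, 2):
            raise ValueError(f"bad allele_count {self.allele_count!r}")

    @property
    def is_carrier(self) -> bool:
        """Dominant model: any alt allele makes a carrier."""
        return self.allele_count is not None and self.allele_count >= 1

    @property
    def is_missing(self) -> bool:
        return self.allele_count is None


@dataclass(frozen=True)
class TranscriptAnnotation:
    gene: str
    transcript_id: str
    consequence_class: ConsequenceClass
    exon_index: Optional[int] = None  # 1-based; splice variants carry the
    exon_count: Optional[int] = None  # downstream (affected) exon's index
    protein_coding: bool = True

    def __post_init__(self) -> None:
        if (
            self.exon_index is not None
            and self.exon_count is not None
            and self.exon_index > self.exon_count
        ):
            raise ValueError("exon_index beyond exon_count")


@dataclass
class AnnotatedVariant:
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    qual: Optional[float]
    annotations: list[TranscriptAnnotation] = field(default_factory=list)
    population_afs: dict[str, float] = field(default_factory=dict)
    cadd_phred: Optional[float] = None
    genotypes: dict[str, GenotypeCall] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError("ref == alt")
        for src, af in self.population_afs.items():
            if not (0.0 <= af <= 1.0):
                raise ValueError(f"population AF {src}={af} outside [0,1]")

    @property
    def key(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}>{self.alt}"


@dataclass(frozen=True)
class QCThresholds:
    """Boundary semantics: QUAL strictly >, depth >=, AFs strictly <."""

    min_qual: float = 20.0
    min_depth: int = 5
    max_pop_af: float = 0.001
    max_local_af: float = 0.05

    def __post_init__(self) -> None:
        if self.min_depth < 0 or not (0 <= self.max_pop_af <= 1) or not (
            0 <= self.max_local_af <= 1
        ):
            raise ValueError("thresholds out of range")


@dataclass(frozen=True)
class AnnotationFieldSpec:
    """Where per-transcript annotation and frequencies live in the VCF.

    ``info_key`` holds comma-separated transcript entries, each a
    ``subfield_sep``-joined record whose layout is ``fields`` (recognised
    names: ``allele``, ``gene``, ``transcript``, ``consequence``, ``exon``
    [``index/count``], ``biotype``).  ``af_keys`` maps a source name (as used
    in :func:`max_population_af`) to the INFO key carrying its allele
    fraction; ``cadd_key`` names the CADD PHRED INFO field.
    """

    info_key: str = "ANN"
    fields: tuple[str, ...] = ("allele", "gene", "transcript", "consequence", "exon", "biotype")
    subfield_sep: str = "|"
    af_keys: dict[str, str] = field(default_factory=dict)
    cadd_key: Optional[str] = "CADD"

    def __post_init__(self) -> None:
        for name in ("gene", "transcript", "consequence"):
            if name not in self.fields:
                raise VcfConfigError(f"annotation field spec lacks {name!r}")


DEFAULT_FIELD_SPEC = AnnotationFieldSpec(
    af_keys={"gnomad_nfe": "AF_GNOMAD_NFE", "thousand_genomes": "AF_1000G"},
)


def _parse_annotation_entry(
    entry: str, spec: AnnotationFieldSpec, alt: str
) -> Optional[TranscriptAnnotation]:
    parts = entry.split(spec.subfield_sep)
    if len(parts) < len(spec.fields):
        parts += [""] * (len(spec.fields) - len(parts))
    rec = dict(zip(spec.fields, parts))
    if "allele" in rec and rec["allele"] and rec["allele"] != alt:
        return None
    term = rec.get("consequence", "").strip()
    cls = SO_TERM_MAP.get(term, ConsequenceClass.OTHER)
    exon_index = exon_count = None
    exon = rec.get("exon", "").strip()
    if exon and exon != ".":
        try:
            idx_s, _, cnt_s = exon.partition("/")
            exon_index = int(idx_s)
            exon_count = int(cnt_s) if cnt_s else None
        except ValueError:
            exon_index = exon_count = None
    biotype = rec.get("biotype", "protein_coding").strip() or "protein_coding"
    return TranscriptAnnotation(
        gene=rec.get("gene", "").strip(),
        transcript_id=rec.get("transcript", "").strip(),
        consequence_class=cls,
        exon_index=exon_index,
        exon_count=exon_count,
        protein_coding=(biotype == "protein_coding"),
    )


def _info_scalar(rec: "pysam.VariantRecord", key: str, alt_index: int):
    if key not in rec.info:
        return None
    val = rec.info[key]
    if isinstance(val, tuple):
        # Number=A fields: one value per ALT
        if alt_index < len(val):
            val = val[alt_index]
        else:
            val = val[0]
    return val


def read_annotated_vcf(
    path: str, field_spec: AnnotationFieldSpec = DEFAULT_FIELD_SPEC
) -> Iterator[AnnotatedVariant]:
    """Stream AnnotatedVariants from a VCF, one per ALT allele.

    Multi-allelic records are decomposed: the per-sample allele count for a
    given ALT counts only that allele's index in the genotype.  Annotation
    entries carrying an ``allele`` subfield are matched to their ALT;
    entries without one are attached to every ALT of the record.
    """
    with pysam.VariantFile(path) as vcf:
        if field_spec.info_key not in vcf.header.info:
            raise VcfConfigError(
                f"INFO field {field_spec.info_key!r} not declared in VCF header"
            )
        samples = list(vcf.header.samples)
        for rec in vcf:
            if field_spec.info_key not in rec.info:
                raise VcfConfigError(
                    f"{rec.chrom}:{rec.pos}: missing INFO/{field_spec.info_key}"
                )
            raw = rec.info[field_spec.info_key]
            entries = list(raw) if isinstance(raw, tuple) else [raw]
            alts = rec.alts or ()
            for alt_index, alt in enumerate(alts):
                anns = [
                    a
                    for e in entries
                    if (a := _parse_annotation_entry(str(e), field_spec, alt))
                    is not None
                ]
                afs: dict[str, float] = {}
                for source, key in field_spec.af_keys.items():
                    val = _info_scalar(rec, key, alt_index)
                    if val is not None:
                        afs[source] = float(val)
                cadd = None
                if field_spec.cadd_key:
                    val = _info_scalar(rec, field_spec.cadd_key, alt_index)
                    if val is not None:
                        cadd = float(val)
                genotypes: dict[str, GenotypeCall] = {}
                allele_number = alt_index + 1
                for s in samples:
                    sdata = rec.samples[s]
                    gt = sdata.get("GT")
                    dp = sdata.get("DP")
                    if gt is None or all(a is None for a in gt):
                        ac: Optional[int] = None
                    else:
                        ac = sum(1 for a in gt if a == allele_number)
                    genotypes[s] = GenotypeCall(
                        sample_id=s,
                        allele_count=ac,
                        depth=None if dp is None else int(dp),
                    )
                yield AnnotatedVariant(
                    chrom=str(rec.chrom),
                    pos=int(rec.pos),
                    ref=str(rec.ref),
                    alt=str(alt),
                    qual=None if rec.qual is None else float(rec.qual),
                    annotations=anns,
                    population_afs=afs,
                    cadd_phred=cadd,
                    genotypes=genotypes,
                )


def qc_filter(
    variant: AnnotatedVariant, thresholds: QCThresholds = QCThresholds()
) -> Optional[AnnotatedVariant]:
    """Record/sample QC. Returns the (possibly masked) variant, or None.

    Rejected outright when QUAL <= min_qual (missing QUAL counts as 0).
    Genotypes with reported depth below min_depth are masked missing; a
    variant whose genotypes are all missing after masking is rejected.
    Idempotent.
    """
    qual = variant.qual if variant.qual is not None else 0.0
    if not qual > thresholds.min_qual:
        return None
    masked = {}
    for sid, call in variant.genotypes.items():
        if (
            call.depth is not None
            and call.depth < thresholds.min_depth
            and not call.is_missing
        ):
            call = replace(call, allele_count=None)
        masked[sid] = call
    if masked and all(c.is_missing for c in masked.values()):
        return None
    return replace(variant, genotypes=masked)


def max_population_af(
    variant: AnnotatedVariant,
    sources: Sequence[str],
    configured: Optional[Iterable[str]] = None,
) -> float:
    """Maximum allele fraction over the requested sources (0 = novel).

    ``configured`` is the universe of known source names (from the
    annotation field spec); asking for a source outside it is a
    configuration error, while a configured source simply absent on this
    variant contributes 0.
    """
    known = set(configured) if configured is not None else None
    out = 0.0
    for src in sources:
        if known is not None and src not in known:
            raise VcfConfigError(f"unknown population AF source {src!r}")
        out = max(out, variant.population_afs.get(src, 0.0))
    return out


def local_cohort_af(variant: AnnotatedVariant) -> float:
    """Fraction of genotyped samples cohort-wide carrying >=1 alt allele."""
    genotyped = [c for c in variant.genotypes.values() if not c.is_missing]
    if not genotyped:
        raise ValueError(f"{variant.key}: no genotyped samples")
    carriers = sum(1 for c in genotyped if c.is_carrier)
    return carriers / len(genotyped)
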