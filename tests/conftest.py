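"""Shared fixtures: reference-pattern family pedigrees and VCF builders.

The two fixture families encode the canonical segregation patterns the
filter must honour: a family where every genotyped case carries the variant
and every genotyped unaffected relative does not (F8), and a family with an
affected married-in spouse who does not carry the variant and must be
exempted as a phenocopy (F11).
"""

from __future__ import annotations

import io

import pytest
from hypothesis import HealthCheck, settings

from famlof.pedigree import Family, parse_pedigree
from famlof.variants import (
    AnnotatedVariant,
    ConsequenceClass,
    GenotypeCall,
    TranscriptAnnotation,
)

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


FAMILY8_PED = """\
F8\tI-1\t0\t0\t1\t.\t0\t95
F8\tI-2\t0\t0\t2\t.\t0\t93
F8\tII-1\tI-1\tI-2\t1\t.\t0\t74
F8\tII-2\t0\t0\t2\t.\t0\t72
F8\tII-3\tI-1\tI-2\t2\tother_cancer:abdominal cavity:60\t0\t76
F8\tII-5\tI-1\tI-2\t2\tCRC:colorectal:67\t0\t78
F8\tII-6\t0\t0\t1\t.\t0\t79
F8\tIII-3\tII-1\tII-2\t1\tpolyps:colon:50\t1\t55
F8\tIII-5\tII-1\tII-2\t2\tother_cancer:abdominal cavity:58\t0\t60
F8\tIII-7\tII-1\tII-2\t1\tunaffected:colonoscopy_negative:\t1\t68
F8\tIII-4\t0\t0\t2\t.\t0\t54
F8\tIII-8\t0\t0\t2\t.\t0\t66
F8\tIII-9\tII-5\tII-6\t2\tCRC:colon:55;other_cancer:ovarian:56\t0\t58
F8\tIII-10\t0\t0\t1\t.\t0\t59
F8\tIII-12\tII-5\tII-6\t1\tCRC:colorectal:42\t1\t50
F8\tIII-13\tII-5\tII-6\t2\tpolyps:colon:61\t1\t64
F8\tIII-15\tII-5\tII-6\t2\tpolyps:colon:56\t1\t62
F8\tIV-4\tIII-3\tIII-4\t1\tpolyps:colon:44\t1\t46
F8\tIV-6\tIII-3\tIII-4\t1\tpolyps:colon:47\t1\t48
F8\tIV-8\tIII-7\tIII-8\t1\tunaffected:colonoscopy_negative:\t1\t46
F8\tIV-9\tIII-7\tIII-8\t1\tunaffected:colonoscopy_negative:\t1\t44
F8\tIV-11\tIII-9\tIII-10\t2\tCRC:colorectal:45\t1\t47
"""

#: members of F8 who truly carry the planted variant
FAMILY8_CARRIERS = {"III-12", "IV-11", "III-3", "IV-4", "IV-6"}

FAMILY11_PED = """\
F11\tI-1\t0\t0\t1\t.\t0\t96
F11\tI-2\t0\t0\t2\t.\t0\t94
F11\tII-4\tI-1\tI-2\t2\t.\t0\t80
F11\tII-5\t0\t0\t1\t.\t0\t82
F11\tII-6\tI-1\tI-2\t1\t.\t0\t77
F11\tII-7\t0\t0\t2\t.\t0\t75
F11\tII-8\tI-1\tI-2\t1\tCRC:colorectal:69\t1\t74
F11\tII-9\t0\t0\t2\tCRC:colorectal:66\t1\t72
F11\tIII-1\tII-4\tII-5\t2\tother_cancer:breast:73;unaffected:colonoscopy_negative_74:\t1\t75
F11\tIII-2\t0\t0\t1\t.\t0\t76
F11\tIII-3\tII-4\tII-5\t1\tCRC:colorectal:40\t0\t49
F11\tIII-5\tII-4\tII-5\t2\tCRC:colorectal:52\t1\t56
F11\tIII-7\tII-6\tII-7\t1\tCRC:colorectal:60\t0\t63
F11\tIII-8\tII-8\tII-9\t2\tpolyps:colon:45\t1\t48
F11\tIV-1\tIII-1\tIII-2\t1\tunaffected:colonoscopy_negative:\t1\t50
F11\tIV-2\tIII-1\tIII-2\t1\tunaffected:colonoscopy_negative:\t1\t48
"""

FAMILY11_CARRIERS = {"II-8", "III-5", "III-8"}


def family_from_ped(text: str) -> Family:
    families = parse_pedigree(io.StringIO(text))
    assert len(families) == 1
    return families[0]


@pytest.fixture
def family8() -> Family:
    return family_from_ped(FAMILY8_PED)


@pytest.fixture
def family11() -> Family:
    return family_from_ped(FAMILY11_PED)


def make_variant(
    family: Family,
    carriers: set[str],
    chrom: str = "16",
    pos: int = 100,
    qual: float = 500.0,
    depth: int = 30,
    annotations: list[TranscriptAnnotation] | None = None,
    population_afs: dict[str, float] | None = None,
    cadd: float | None = 30.0,
    missing: set[str] = frozenset(),
) -> AnnotatedVariant:
    """A single-family variant whose carriers are the given member IDs."""
    genotypes = {}
    for m in family.members:
        if not m.genotyped:
            continue
        ac: int | None = 1 if m.member_id in carriers else 0
        if m.member_id in missing:
            ac = None
        genotypes[m.sample_id] = GenotypeCall(m.sample_id, ac, depth)
    return AnnotatedVariant(
        chrom=chrom,
        pos=pos,
        ref="CA",
        alt="C",
        qual=qual,
        annotations=annotations
        or [
            TranscriptAnnotation(
                gene="GENE",
                transcript_id="TX1",
                consequence_class=ConsequenceClass.FRAMESHIFT,
                exon_index=2,
                exon_count=6,
            )
        ],
        population_afs=population_afs or {},
        cadd_phred=cadd,
        genotypes=genotypes,
    )
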