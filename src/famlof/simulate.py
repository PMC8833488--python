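"""Synthetic dominant-model CRC cohorts for offline testing of the pipeline.

Emulates the statistical structure the analysis assumes: multi-generation
families with strong autosomal-dominant CRC aggregation (>= 3 confirmed
cases per family), one planted heterozygous loss-of-function variant per
family that is absent from population databases, background variation with
population allele frequencies, occasional technical artifacts, phenocopies
in married-in spouses, and incomplete genotyping.  Output is an extended
PED, a multi-sample annotated VCF, a gene-model table and a CDS FASTA, plus
a ground-truth record for recovery checks.

All randomness flows from the config seed; a given config reproduces its
output byte for byte.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .pedigree import EventKind, Family, Individual, PhenotypeEvent, Sex
from .prioritize import LofClass

_ROMAN = ["I", "II", "III", "IV", "V", "VI"]
_CODONS = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"]
_STOPS = {"TAA", "TAG", "TGA"}
_SENSE_CODONS = [c for c in _CODONS if c not in _STOPS]


class SimulationError(RuntimeError):
    pass


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the generator.

    Defaults follow the emulated study design: 15 families, three
    pathologically confirmed CRC cases required per family, dominant
    transmission, polyps common among carriers, a background adenoma
    (polyp) rate near the ~18% detected by population colonoscopy
    screening, and rare CRC phenocopies among married-in spouses.
    """

    n_families: int = 15
    generations: int = 3
    mean_sibship: float = 3.0
    penetrance_by_70: float = 0.8
    polyp_prob_carrier: float = 0.5
    polyp_prob_noncarrier: float = 0.18
    sporadic_crc_rate: float = 0.02
    phenocopy_rate_married_in: float = 0.05
    other_cancer_rate: float = 0.05
    screening_prob: float = 0.8
    min_crc_cases: int = 3
    n_background_variants: int = 200
    background_af_beta: tuple[float, float] = (0.2, 50.0)
    genotyping_missing_rate: float = 0.3
    genotype_error_rate: float = 0.0
    max_planted_carrier_fraction: float = 0.04
    seed: int = 0

    def __post_init__(self) -> None:
        fracs = (
            self.penetrance_by_70,
            self.polyp_prob_carrier,
            self.polyp_prob_noncarrier,
            self.sporadic_crc_rate,
            self.phenocopy_rate_married_in,
            self.other_cancer_rate,
            self.screening_prob,
            self.genotyping_missing_rate,
            self.genotype_error_rate,
        )
        if any(not 0 <= f <= 1 for f in fracs):
            raise ValueError("all rate parameters must lie in [0,1]")
        if self.n_families < 1 or self.generations < 2 or self.mean_sibship <= 0:
            raise ValueError("invalid cohort geometry")


@dataclass
class FamilyTruth:
    carriers: set[str] = field(default_factory=set)
    phenocopies: set[str] = field(default_factory=set)  # married-in CRC
    variant_key: Optional[str] = None
    gene: Optional[str] = None
    lof_class: Optional[str] = None
    cds_edit: Optional[dict] = None


@dataclass
class SimTruth:
    per_family: dict[str, FamilyTruth] = field(default_factory=dict)


@dataclass
class SyntheticCohort:
    config: SimConfig
    families: list[Family]
    truth: SimTruth
    ped_text: str = ""
    vcf_text: str = ""
    gene_models_text: str = ""
    cds_fasta_text: str = ""


# ---------------------------------------------------------------------------
# family simulation

def _simulate_family_once(
    cfg: SimConfig, family_id: str, rng: np.random.Generator
) -> tuple[Family, FamilyTruth]:
    members: list[Individual] = []
    truth = FamilyTruth()
    counters = [0] * (cfg.generations + 1)

    def new_id(gen: int) -> str:
        counters[gen] += 1
        return f"{_ROMAN[gen - 1]}-{counters[gen]}"

    base_age = int(rng.integers(86, 95))
    spacing = int(rng.integers(26, 31))

    def age_for(gen: int) -> int:
        jitter = int(rng.integers(-4, 5))
        return max(18, base_age - spacing * (gen - 1) + jitter)

    def add_member(gen: int, father: Optional[str], mother: Optional[str],
                   sex: Sex, carrier: bool, married_in: bool) -> Individual:
        ind = Individual(
            member_id=new_id(gen),
            family_id=family_id,
            father_id=father,
            mother_id=mother,
            sex=sex,
            current_age=age_for(gen),
        )
        members.append(ind)
        if carrier:
            truth.carriers.add(ind.member_id)
        ind._married_in = married_in  # type: ignore[attr-defined]
        return ind

    # founder couple; the variant enters through the male founder
    founder = add_member(1, None, None, Sex.MALE, carrier=True, married_in=False)
    spouse0 = add_member(1, None, None, Sex.FEMALE, carrier=False, married_in=False)
    couples = [(founder, spouse0)]
    for gen in range(2, cfg.generations + 1):
        next_couples = []
        for father, mother in couples:
            n_children = max(1, int(rng.poisson(cfg.mean_sibship)))
            parent_carrier = (
                father.member_id in truth.carriers
                or mother.member_id in truth.carriers
            )
            for _ in range(n_children):
                sex = Sex.MALE if rng.random() < 0.5 else Sex.FEMALE
                carrier = bool(parent_carrier and rng.random() < 0.5)
                child = add_member(
                    gen, father.member_id, mother.member_id, sex, carrier, False
                )
                if gen < cfg.generations and rng.random() < 0.85:
                    partner_sex = Sex.FEMALE if sex is Sex.MALE else Sex.MALE
                    partner = add_member(
                        gen, None, None, partner_sex, carrier=False, married_in=True
                    )
                    if partner_sex is Sex.FEMALE:
                        next_couples.append((child, partner))
                    else:
                        next_couples.append((partner, child))
        couples = next_couples

    # phenotype events
    for ind in members:
        carrier = ind.member_id in truth.carriers
        married_in = getattr(ind, "_married_in", False)
        age = ind.current_age or 0
        events: list[PhenotypeEvent] = []
        crc_rate = (
            cfg.penetrance_by_70
            if carrier
            else (cfg.phenocopy_rate_married_in if married_in else cfg.sporadic_crc_rate)
        )
        destined = rng.random() < crc_rate
        onset = int(rng.integers(40, 71)) if carrier else int(rng.integers(45, 76))
        if destined and age >= onset:
            events.append(
                PhenotypeEvent(EventKind.CRC, "colorectal", onset)
            )
            if married_in:
                truth.phenocopies.add(ind.member_id)
        if not events and age >= 40:
            p_polyp = cfg.polyp_prob_carrier if carrier else cfg.polyp_prob_noncarrier
            if rng.random() < p_polyp:
                polyp_age = int(rng.integers(40, min(age, 70) + 1))
                events.append(PhenotypeEvent(EventKind.POLYPS, "colon", polyp_age))
        if not events and age >= 50 and rng.random() < cfg.other_cancer_rate:
            site = ["breast", "prostate", "abdominal cavity"][int(rng.integers(0, 3))]
            o_age = int(rng.integers(50, age + 1))
            events.append(PhenotypeEvent(EventKind.OTHER_CANCER, site, o_age))
            if rng.random() < 0.5 and not carrier:
                events.append(PhenotypeEvent(EventKind.UNAFFECTED, "colonoscopy_negative"))
        # unaffected carriers never receive a clean-screen record: they fall
        # to uninformative, mirroring the study families in which no
        # screened-negative member carried the causal variant
        if not events and not carrier and age >= 45:
            if rng.random() < cfg.screening_prob:
                events.append(PhenotypeEvent(EventKind.UNAFFECTED, "colonoscopy_negative"))
        ind.events = events

    # genotyping availability: founders predate the study; later members are
    # available at 1 - missing rate; the two youngest-generation CRC cases
    # are always sequenced (index cases)
    for ind in members:
        gen1 = ind.father_id is None and ind.mother_id is None and not getattr(
            ind, "_married_in", False
        ) and ind.member_id.startswith("I-")
        if gen1:
            ind.genotyped = False
        else:
            ind.genotyped = bool(rng.random() >= cfg.genotyping_missing_rate)
    blood_cases_late = [
        m
        for m in members
        if m.has_event(EventKind.CRC)
        and m.member_id in truth.carriers
        and not m.member_id.startswith("I-")
    ]
    for m in blood_cases_late[:2]:
        m.genotyped = True

    fam = Family(family_id=family_id, members=members)
    n_cases = sum(
        1 for m in members if m.has_event(EventKind.CRC) and fam.is_blood(m.member_id)
    )
    need_genotyped = min(2, cfg.min_crc_cases)
    if n_cases < cfg.min_crc_cases or len(blood_cases_late) < need_genotyped:
        raise SimulationError("not enough CRC cases")
    return fam, truth


def simulate_family(
    cfg: SimConfig, seed: int, family_id: str = "FAM1", max_retries: int = 500
) -> tuple[Family, FamilyTruth]:
    """Simulate one family; rejection-sample until >= min_crc_cases blood
    CRC cases (two of them genotyped index cases) are present."""
    rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF]))
    for _ in range(max_retries):
        try:
            return _simulate_family_once(cfg, family_id, rng)
        except SimulationError:
            continue
    raise SimulationError(
        f"could not produce a family with {cfg.min_crc_cases} CRC cases in "
        f"{max_retries} attempts; penetrance/geometry too restrictive"
    )


# ---------------------------------------------------------------------------
# cohort-level variant simulation

_CONSEQ_CHOICES = [
    ("missense", 0.45),
    ("synonymous", 0.30),
    ("other", 0.07),
    ("stop_gained", 0.06),
    ("frameshift_variant", 0.05),
    ("splice_acceptor_variant", 0.04),
    ("splice_donor_variant", 0.03),
]
_LOF_TERMS = {"stop_gained", "frameshift_variant", "splice_acceptor_variant",
              "splice_donor_variant"}
_PLANT_CYCLE = [
    ("stop_gained", LofClass.STOP_GAIN),
    ("frameshift_variant", LofClass.FRAMESHIFT),
    ("splice_acceptor_variant", LofClass.CANONICAL_SPLICE),
]


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    """ATG-initiated open reading frame with stops guaranteed in both
    shifted frames within the final 60 nt, so a frameshift introduced
    anywhere upstream of that tail truncates the protein downstream."""
    for _ in range(200):
        body = "".join(
            _SENSE_CODONS[int(i)]
            for i in rng.integers(0, len(_SENSE_CODONS), n_codons - 2)
        )
        cds = "ATG" + body + "TAA"
        tail = len(cds) - 60
        shifted_ok = all(
            any(
                cds[i : i + 3] in _STOPS
                for i in range(shift, len(cds) - 2, 3)
                if i >= tail
            )
            for shift in (1, 2)
        )
        if shifted_ok:
            return cds
    raise SimulationError("failed to build a CDS with shifted-frame stops")


def _chrom_of(i: int) -> str:
    return str((i % 22) + 1)


def simulate_cohort(cfg: SimConfig) -> SyntheticCohort:
    """Simulate families, planted LOF variants and background variation."""
    master = np.random.SeedSequence(cfg.seed & 0x7FFFFFFF)
    fam_seeds, var_seed = master.spawn(2)
    rng = np.random.default_rng(var_seed)

    families: list[Family] = []
    truth = SimTruth()
    for i in range(cfg.n_families):
        fam_id = f"FAM{i + 1:02d}"
        fam_rng = np.random.default_rng(fam_seeds.spawn(1)[0])
        for attempt in range(500):
            try:
                fam, ftruth = _simulate_family_once(cfg, fam_id, fam_rng)
                break
            except SimulationError:
                continue
        else:
            raise SimulationError(f"family {fam_id}: rejection sampling exhausted")
        families.append(fam)
        truth.per_family[fam_id] = ftruth

    # --- gene models + CDS per family (planted genes) ------------------
    gene_rows: list[str] = []
    fasta_chunks: list[str] = []
    planted_meta: list[dict] = []
    for i, fam in enumerate(families):
        gene = f"SYNG{i + 1:02d}"
        transcript = f"SYNT{i + 1:04d}"
        chrom = _chrom_of(i)
        exon_count = int(rng.integers(4, 9))
        n_codons = int(rng.integers(80, 201))
        cds = _random_cds(rng, n_codons)
        cds_len = len(cds)
        # split CDS across exons, every exon at least 12 nt
        for _ in range(200):
            cuts = sorted(
                int(c) for c in rng.integers(12, cds_len - 12, exon_count - 1)
            )
            bounds = [0, *cuts, cds_len]
            if all(b - a >= 12 for a, b in zip(bounds, bounds[1:])):
                break
        else:
            raise SimulationError("could not partition CDS into exons")
        gene_start = 1_000_000 * (i + 1)
        gpos = gene_start
        exon_spans = []
        for e in range(exon_count):
            e_len = bounds[e + 1] - bounds[e]
            exon_spans.append((gpos, gpos + e_len - 1, bounds[e] + 1, bounds[e + 1]))
            gpos += e_len + 500  # 500 nt introns
        for e, (gs, ge, cs, ce) in enumerate(exon_spans, start=1):
            gene_rows.append(
                "\t".join(
                    [gene, transcript, chrom, "+", "protein_coding",
                     str(e), str(exon_count), str(gs), str(ge), str(cs), str(ce)]
                )
            )
        fasta_chunks.append(f">{transcript} gene={gene}\n")
        for k in range(0, cds_len, 60):
            fasta_chunks.append(cds[k : k + 60] + "\n")

        term, lof_class = _PLANT_CYCLE[i % len(_PLANT_CYCLE)]
        exon_index = int(rng.integers(1, exon_count))  # never the last exon
        if term == "frameshift_variant":
            # keep the edit upstream of the guaranteed shifted-stop tail
            usable = [
                e
                for e in range(1, exon_count)
                if exon_spans[e - 1][2] + 3 <= min(exon_spans[e - 1][3], cds_len - 70)
            ]
            exon_index = usable[int(rng.integers(0, len(usable)))]
        gs, ge, cs, ce = exon_spans[exon_index - 1]
        cds_edit = None
        if term == "frameshift_variant":
            hi = min(ce, cds_len - 70)
            cds_pos = int(rng.integers(cs + 3, hi + 1))
            pos = gs + (cds_pos - cs)
            ref, alt = "CA", "C"
            cds_edit = {"kind": "del", "cds_start": cds_pos, "cds_end": cds_pos}
        elif term == "stop_gained":
            cds_pos = int(rng.integers(cs + 3, ce + 1))
            pos = gs + (cds_pos - cs)
            ref, alt = "C", "T"
        else:  # splice acceptor: intronic -1 of this exon's start
            pos = gs - 1
            ref, alt = "G", "T"
        planted_meta.append(
            {
                "family": fam.family_id,
                "gene": gene,
                "transcript": transcript,
                "chrom": chrom,
                "pos": pos,
                "ref": ref,
                "alt": alt,
                "term": term,
                "lof_class": lof_class,
                "exon_index": exon_index,
                "exon_count": exon_count,
                "cadd": float(np.round(rng.uniform(24.7, 44.0), 1)),
                "cds_edit": cds_edit,
            }
        )

    # --- genotyping guard: keep each planted variant's carrier fraction
    # structurally below the artifact band (limited sample availability) ----
    def genotyped_samples() -> list[Individual]:
        return [m for f in families for m in f.members if m.genotyped]

    for fam in families:
        ftruth = truth.per_family[fam.family_id]
        while True:
            total = len(genotyped_samples())
            cap = max(2, int(cfg.max_planted_carrier_fraction * total))
            gcarr = [
                m
                for m in fam.members
                if m.genotyped and m.member_id in ftruth.carriers
            ]
            if len(gcarr) <= cap:
                break
            trimmable = [m for m in gcarr if not m.has_event(EventKind.CRC)]
            if not trimmable:
                break
            trimmable[-1].genotyped = False

    samples = [m.sample_id for f in families for m in f.members if m.genotyped]
    sample_index = {s: j for j, s in enumerate(samples)}
    n_samples = len(samples)

    # --- assemble VCF records ------------------------------------------
    records: list[tuple[tuple, str]] = []

    def geno_fields(carrier_mask, depths) -> list[str]:
        cols = []
        for j in range(n_samples):
            dp = int(depths[j])
            if dp < 0:
                cols.append("./.:0")
                continue
            gt = "0/1" if carrier_mask[j] else "0/0"
            cols.append(f"{gt}:{dp}")
        return cols

    err = cfg.genotype_error_rate

    for meta in planted_meta:
        fam_id = meta["family"]
        ftruth = truth.per_family[fam_id]
        carrier_mask = np.zeros(n_samples, dtype=bool)
        for f in families:
            for m in f.members:
                if not m.genotyped:
                    continue
                if f.family_id == fam_id and m.member_id in ftruth.carriers:
                    carrier_mask[sample_index[m.sample_id]] = True
        if err > 0:
            flips = rng.random(n_samples) < err
            carrier_mask = carrier_mask ^ flips
        depths = rng.poisson(35, n_samples) + 5
        qual = float(np.round(rng.uniform(200, 900), 1))
        ann = "|".join(
            [
                meta["alt"],
                meta["gene"],
                meta["transcript"],
                meta["term"],
                f"{meta['exon_index']}/{meta['exon_count']}",
                "protein_coding",
            ]
        )
        info = f"ANN={ann};CADD={meta['cadd']:.1f}"
        line = "\t".join(
            [
                meta["chrom"],
                str(meta["pos"]),
                ".",
                meta["ref"],
                meta["alt"],
                f"{qual:.1f}",
                "PASS",
                info,
                "GT:DP",
                *geno_fields(carrier_mask, depths),
            ]
        )
        records.append(((int(meta["chrom"]), meta["pos"]), line))
        key = f"{meta['chrom']}:{meta['pos']}:{meta['ref']}>{meta['alt']}"
        ftruth.variant_key = key
        ftruth.gene = meta["gene"]
        ftruth.lof_class = meta["lof_class"].value
        ftruth.cds_edit = meta["cds_edit"]

    conseq_terms = [t for t, _ in _CONSEQ_CHOICES]
    conseq_probs = np.array([p for _, p in _CONSEQ_CHOICES])
    conseq_probs = conseq_probs / conseq_probs.sum()
    a_beta, b_beta = cfg.background_af_beta
    for j in range(cfg.n_background_variants):
        chrom = _chrom_of(int(rng.integers(0, 22)))
        pos = int(rng.integers(5_000_000, 50_000_000))
        ref = "ACGT"[int(rng.integers(0, 4))]
        term = conseq_terms[int(rng.choice(len(conseq_terms), p=conseq_probs))]
        if term == "frameshift_variant":
            ref, alt = ref + "T", ref
        else:
            alt = "ACGT"[int(rng.integers(0, 4))]
            if alt == ref:
                alt = "A" if ref != "A" else "G"
        novel = rng.random() < 0.05
        af = 0.0 if novel else float(np.clip(rng.beta(a_beta, b_beta), 1e-5, 0.5))
        artifact = rng.random() < 0.08
        carrier_p = float(rng.uniform(0.06, 0.30)) if artifact else min(0.5, 2 * af)
        if novel and not artifact:
            carrier_p = 0.01
        carrier_mask = rng.random(n_samples) < carrier_p
        if err > 0:
            carrier_mask = carrier_mask ^ (rng.random(n_samples) < err)
        depths = rng.poisson(35, n_samples) + 5
        low_dp = rng.random(n_samples) < 0.02
        depths = np.where(low_dp, rng.integers(0, 5, n_samples), depths)
        qual = float(np.round(rng.uniform(30, 1000), 1))
        if rng.random() < 0.03:
            qual = float(np.round(rng.uniform(1, 20), 1))
        exon_count = int(rng.integers(2, 9))
        exon_index = int(rng.integers(1, exon_count + 1))
        biotype = "protein_coding" if rng.random() < 0.92 else "retained_intron"
        gene = f"BGG{j + 1:04d}"
        ann = "|".join(
            [alt, gene, f"BGT{j + 1:04d}", term,
             f"{exon_index}/{exon_count}", biotype]
        )
        if term in _LOF_TERMS:
            cadd = float(np.round(rng.uniform(15, 45), 1))
        else:
            cadd = float(np.round(rng.uniform(0, 35), 1))
        info_parts = [f"ANN={ann}"]
        if af > 0:
            af2 = float(np.clip(af * rng.uniform(0.5, 1.5), 0.0, 1.0))
            info_parts.append(f"AF_GNOMAD_NFE={af:.6g}")
            info_parts.append(f"AF_1000G={af2:.6g}")
        info_parts.append(f"CADD={cadd:.1f}")
        gene_rows.append(
            "\t".join(
                [gene, f"BGT{j + 1:04d}", chrom, "+", biotype, str(exon_index),
                 str(exon_count), str(pos), str(pos), ".", "."]
            )
        )
        line = "\t".join(
            [
                chrom, str(pos), ".", ref, alt, f"{qual:.1f}", "PASS",
                ";".join(info_parts), "GT:DP",
                *geno_fields(carrier_mask, depths),
            ]
        )
        records.append(((int(chrom), pos), line))

    records.sort(key=lambda r: r[0])

    contigs = sorted({line.split("\t", 1)[0] for _, line in records}, key=int)
    header = [
        "##fileformat=VCFv4.2",
        "##source=famlof-simulate",
        *[f"##contig=<ID={c}>" for c in contigs],
        '##INFO=<ID=ANN,Number=.,Type=String,Description="Transcript annotation: '
        'allele|gene|transcript|consequence|exon/count|biotype">',
        '##INFO=<ID=AF_GNOMAD_NFE,Number=A,Type=Float,Description="Simulated gnomAD NFE AF">',
        '##INFO=<ID=AF_1000G,Number=A,Type=Float,Description="Simulated 1000G AF">',
        '##INFO=<ID=CADD,Number=A,Type=Float,Description="Simulated CADD PHRED">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples),
    ]
    vcf_text = "\n".join(header + [line for _, line in records]) + "\n"

    from io import StringIO

    from .pedigree import write_pedigree

    buf = StringIO()
    write_pedigree(families, buf)

    gene_header = (
        "gene\ttranscript\tchrom\tstrand\tbiotype\texon_index\texon_count"
        "\tgenomic_start\tgenomic_end\tcds_start\tcds_end"
    )
    return SyntheticCohort(
        config=cfg,
        families=families,
        truth=truth,
        ped_text=buf.getvalue(),
        vcf_text=vcf_text,
        gene_models_text="\n".join([gene_header, *gene_rows]) + "\n",
        cds_fasta_text="".join(fasta_chunks),
    )


# ---------------------------------------------------------------------------
# fixture bundle

_BUNDLE_FILES = {
    "cohort.ped": "ped_text",
    "cohort.vcf": "vcf_text",
    "gene_models.tsv": "gene_models_text",
    "cds.fa": "cds_fasta_text",
}


def _truth_json(truth: SimTruth) -> str:
    out = {}
    for fam_id, t in truth.per_family.items():
        out[fam_id] = {
            "carriers": sorted(t.carriers),
            "phenocopies": sorted(t.phenocopies),
            "variant_key": t.variant_key,
            "gene": t.gene,
            "lof_class": t.lof_class,
            "cds_edit": t.cds_edit,
        }
    return json.dumps(out, indent=1, sort_keys=True)


def write_fixture_bundle(cohort: SyntheticCohort, directory: str | Path) -> dict:
    """Write the cohort as standard-format files plus a manifest.

    The manifest records the seed, the full config and a sha256 per file so
    a bundle can be validated and regenerated exactly.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    texts = {name: getattr(cohort, attr) for name, attr in _BUNDLE_FILES.items()}
    texts["truth.json"] = _truth_json(cohort.truth) + "\n"
    hashes = {}
    for name, text in texts.items():
        (directory / name).write_text(text)
        hashes[name] = hashlib.sha256(text.encode()).hexdigest()
    cfg = asdict(cohort.config)
    cfg["background_af_beta"] = list(cfg["background_af_beta"])
    manifest = {"seed": cohort.config.seed, "config": cfg, "files": hashes}
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=1) + "\n")
    return manifest


def validate_bundle(directory: str | Path) -> dict:
    """Check every file in a bundle against its manifest hash."""
    directory = Path(directory)
    try:
        manifest = json.loads((directory / "manifest.json").read_text())
        files = manifest["files"]
    except (OSError, json.JSONDecodeError, KeyError) as exc:
        raise ValueError(f"corrupted or missing manifest in {directory}: {exc}") from exc
    for name, digest in files.items():
        path = directory / name
        if not path.exists():
            raise ValueError(f"bundle file {name} missing")
        actual = hashlib.sha256(path.read_bytes()).hexdigest()
        if actual != digest:
            raise ValueError(f"bundle file {name} does not match its manifest hash")
    return manifest
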