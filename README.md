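# famlof

Pedigree-aware prioritization of rare **loss-of-function (LOF) germline
variants** in families with autosomal-dominant cancer aggregation, written
for familial colorectal cancer (CRC) cohorts: multi-generation families with
three or more confirmed CRC cases, sequenced members, and relatives whose
phenotype (polyps, young age, clean colonoscopy) places them between
"affected" and "unaffected".

The package is aimed at statistical-genetics and cancer-genomics analysts
who have an annotated multi-sample VCF and extended pedigrees and want a
reproducible, auditable version of the classic familial filtering recipe —
plus a synthetic cohort generator so the whole pipeline can be exercised and
validated without access-controlled patient data.

## What it computes

**Role assignment.** Each family member gets exactly one role: members with
CRC are *cases*; members with colonic polyps, and offspring of a case who
have not yet reached the age of the family's youngest CRC diagnosis, are
*possible carriers*; members with an explicit negative observation (clean
colonoscopy) are *controls*; everyone else is *uninformative*. Non-CRC
cancers do not make a case.

**Variant filter cascade.** For every ALT allele:
QUAL > 20 → per-sample depth ≥ 5 (else the genotype is masked missing) →
cohort-wide carrier fraction < 5 % (technical-artifact removal) → population
allele frequency < 0.1 % across the configured sources → LOF class (stop
gain, frameshift, canonical ±1/±2 splice) → not in the last exon and not on
a non-coding transcript (last-exon truncations typically escape
nonsense-mediated decay) → **dominant-model segregation** per family:

* every genotyped blood-relative case carries ≥ 1 alt allele,
* no genotyped control carries it,
* at least one case carrier exists,
* affected married-in spouses are phenocopies: exempt and recorded.

Candidates are tiered by CADD PHRED (> 20 = top 1 %, > 30 = top 0.1 %) and
every variant keeps an ordered filter trail.

**Molecular consequence.** A maximum-entropy 3′ splice-site model scores
23-mer acceptor windows (20 intronic nt with the obligate AG, 3 exonic nt)
as `MES = log2 P_maxent(seq) / P_bgd(seq)`, combined from nine marginal
tables by inclusion–exclusion; a scanner ranks de novo acceptors around a
damaged canonical site, and the implied transcript edit (loss of the first
*k* exonic nucleotides) is translated into an HGVS protein call such as
`p.Ser9Leufs*17` — the new reading frame terminating at codon *N*, counting
the first changed residue as 1.

**Association.** For a variant screened in a case–control cohort, the
carrier odds ratio `OR = ad/bc` with the Woolf (log-normal) interval
`exp( ln OR ± z·√(1/a + 1/b + 1/c + 1/d) )`.

## Worked example

Screen counts of 5 carriers among 1705 familial CRC cases versus 2 among
1674 elderly controls:

```console
$ famlof associate --table 5,2,1700,1672
odds_ratio      2.46
ci_0.95 0.48    12.69
```

The carrier odds are 2.46-fold higher in cases, but with single-digit
carrier counts the 95 % interval (0.48–12.69) spans 1: suggestive, not
significant on its own.

An end-to-end synthetic run — simulate 15 dominant CRC families with one
planted LOF variant each plus 200 background variants, prioritize, and call
protein consequences:

```console
$ famlof run-all --seed 1 --n-families 15 --background-variants 200 --out demo
INFO famlof: stage simulate: 15 families
INFO famlof: stage prioritize: 15 candidates
INFO famlof: stage consequence: wrote demo/consequences.tsv

$ head -4 demo/candidates.tsv
variant_key     gene    lof_class       cadd_phred      cadd_tier       passing_families        case_carriers
1:1002159:C>T   SYNG01  stop_gain       32.5    top0.1pct       FAM01   2
2:2001169:CA>C  SYNG02  frameshift      36.7    top0.1pct       FAM02   2
3:3001094:G>T   SYNG03  canonical_splice        38.7    top0.1pct       FAM03   4

$ head -3 demo/consequences.tsv
family  gene    variant_key     hgvs_p  category        stop_offset
FAM02   SYNG02  2:2001169:CA>C  p.Ser57Thrfs*12 frameshift      12
FAM05   SYNG05  5:5000655:CA>C  p.Val53Serfs*39 frameshift      39
```

All 15 planted variants — and nothing else — survive the cascade, each
segregating in exactly its own family; planted frameshifts translate to
premature truncations (`fs*N`). `demo/trail.tsv` records the per-variant
filter verdicts and `demo/run_manifest.json` the seed and output hashes
(identical seed ⇒ byte-identical outputs).

## Layout

| module | contents |
|---|---|
| `famlof.pedigree` | extended-PED I/O, blood-lineage derivation, role assignment |
| `famlof.variants` | annotated-VCF reading (pysam), QC and frequency filters |
| `famlof.prioritize` | LOF classes, position rules, segregation, CADD tiers, cascade |
| `famlof.splice` | maximum-entropy acceptor model, scoring, de novo scanning |
| `famlof.protein` | transcript edits, translation, HGVS frameshift calls |
| `famlof.association` | 2×2 carrier tables, odds ratio, Woolf interval |
| `famlof.simulate` | dominant-model cohort generator with ground truth |
| `famlof.cli` | `famlof simulate / prioritize / consequence / associate / run-all` |

See `docs/methods.md` for the model assumptions, parameter defaults and
known limitations.
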