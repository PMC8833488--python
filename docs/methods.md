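# Methods

## Study design being modelled

The pipeline operationalizes the classic familial rare-variant recipe for
autosomal-dominant colorectal cancer (CRC): in each multi-case family,
retain rare loss-of-function (LOF) variants that are carried by every
affected blood relative with a usable genotype and by no screened unaffected
relative, then characterize the molecular consequence of the survivors and
test recurrent ones in a case–control screen. Every stage is deterministic
given its inputs, and every variant carries an ordered filter trail so a
rejection can be traced to a single rule and value.

## Role assignment

Roles are assigned per family in a fixed precedence order: CRC diagnosis →
`case`; colonic polyps → `possible_carrier`; offspring of a CRC case whose
current age is below the family's youngest CRC onset → `possible_carrier`;
explicit negative observation (an `unaffected` event, e.g. clean
colonoscopy) → `control`; otherwise `uninformative`. Design choices where
practice varies:

* **Non-CRC cancers** (breast, prostate, abdominal-cavity, ovarian) never
  create a case for the CRC segregation model. With a clean colonoscopy the
  member is a control; without one, uninformative.
* **Unobserved members are never controls.** A member with no events and no
  recorded observation contributes nothing; treating silence as health would
  manufacture spurious segregation failures.
* **Blood lineage.** Cases with recorded parents, plus all their ancestors,
  anchor the lineage; the set is then closed under descent. A parentless
  individual whose only link is a partnership (a married-in spouse) is not
  blood — so an affected spouse is a phenocopy, exempt from the carrier
  requirement and reported as such rather than silently ignored.

## Filter cascade

Boundary semantics are fixed and strict where the convention leaves room:
QUAL strictly > 20; depth ≥ 5 (genotypes below are masked missing, and a
fully-masked record is dropped); population allele frequency strictly
< 0.1 % (a variant absent from every configured source counts as 0, i.e.
novel); cohort-wide carrier fraction strictly < 5 %. The local (cohort)
filter counts **carriers over genotyped samples**, not alleles — under a
dominant model a homozygote is still one carrier. LOF classes are stop gain,
frameshift, and canonical ±1/±2 splice site. The last-exon/non-coding
exclusion models escape from nonsense-mediated decay; splice variants
inherit the affected (downstream) exon's index, so an acceptor variant of
exon 2 is never mistaken for a last-exon hit, and an exonic consequence with
no locatable exon is excluded conservatively. A variant qualifies if **any**
protein-coding transcript annotation passes both rules (most-damaging
transcript); this is permissive by intent and configurable upstream via the
annotation field spec. Ties in the candidate ranking are broken by CADD tier,
then number of passing families, then genomic coordinate, making output
order deterministic.

Segregation requires at least one genotyped case; missing genotypes are
unconstrained (absence of evidence), as are possible carriers and
uninformative members. The filter is evaluated on all genotyped members,
whether sequenced or confirmed by targeted genotyping.

## Splice model

The 3′ (acceptor) model scores a 23-mer: intronic positions 1–20 ending in
the obligate AG (positions 19–20), exonic positions 21–23. The score is

    MES = log2 [ P_cons(pos 19) P_cons(pos 20) / P_bgd(pos 19) P_bgd(pos 20) ]
        + log2 P_maxent(21 non-AG positions) − log2 P_bgd(21 non-AG positions)

with `P_maxent` combined from nine marginal tables by inclusion–exclusion:
7-mer marginals over blocks {1–7}, {8–14}, {15–21}, {5–11}, {12–18} in the
numerator and their pairwise overlaps {5–7}, {8–11}, {12–14}, {15–18} in the
denominator. The loader reads the distributed table layout (one probability
per row, row index = lexicographic k-mer rank, A<C<G<T) and validates that
every table normalizes to 1 within 1e-6. A uniform model scores every window
exactly 0, which the tests exploit as a closed-form oracle. The de novo
scanner only proposes windows satisfying the obligate AG; the damaged
canonical window can still be scored directly. Supported splice outcomes are
limited to a downstream de novo acceptor within the exon (deletion of the
first *k* exonic nucleotides, in CDS coordinates); upstream or intronic
alternatives (exon skipping, intron retention) raise an explicit
unsupported-outcome error rather than a guess.

The published model tables are a ~1.3 MB external distribution and are not
bundled; tests that reproduce published scores read them from
`tests/data/reference/` when present.

## Protein consequence

Both alleles are translated (Biopython), and the first codon whose amino
acid differs anchors the call. Frameshifts report `p.<Wt><pos><Mut>fs*N`
with *N* counting the new-frame termination codon from the first changed
residue (= 1); a first changed codon that is itself a stop is a nonsense
call; in-frame edits produce del/ins notation, preferring the clean
deletion/insertion reading (so removing the codon before a stop is
`p.Xdel`, not nonsense); a shifted frame that never reaches a stop is
flagged `no_stop`. A CDS that does not start with ATG triggers a warning
but is processed. HGVS 3′-most normalization of repeated residues is not
applied; calls are anchored at the first differing residue.

## Association

Carrier counts form the 2×2 table; the odds ratio is `ad/bc` and the Woolf
interval `exp(ln OR ± z·√(Σ 1/cell))` with the z-quantile computed from the
normal distribution, not hard-coded. Zero cells raise a hard error by
default; the Haldane–Anscombe +0.5 correction is strictly opt-in, because a
silent correction can mask data problems. Null coverage of the 95 % interval
is verified by simulation in the acceptance suite (~95 % over 10,000
binomial replicates at 200 samples per arm, carrier probability 0.1).

## Synthetic cohort generator

The generator emulates the structure the analysis assumes rather than any
particular dataset: `n_families` (default 15) three-generation pedigrees,
founder couple with the variant entering through one founder, heterozygous
transmission with probability 1/2 per meiosis, and rejection sampling until
a family has ≥ 3 blood CRC cases of which ≥ 2 (outside the founder
generation, who predate sample collection) are genotyped index cases.

Default parameters, chosen once as field-plausible values: carrier CRC
penetrance by age 70 = 0.8 with onset uniform on 40–70 (dominant families
ascertained for strong aggregation); polyp probability 0.5 for carriers
versus 0.18 for non-carriers (population colonoscopy screening detects
adenomas in roughly a fifth of screenees); sporadic CRC rate 0.02; CRC
phenocopy rate among married-in spouses 0.05 (onset 45–75); colonoscopy
screening probability 0.8 for unaffected adults; genotyping missingness
0.3; 200 background variants with allele frequencies from Beta(0.2, 50)
(heavily rare-skewed), 8 % simulated artifacts with inflated cohort carrier
rates, 3 % low-QUAL and 2 % low-depth genotypes; planted-variant CADD
uniform on 24.7–44. All randomness flows from the config seed and output is
byte-for-byte reproducible; bundles carry a manifest with per-file hashes.

Two deliberate idealizations, without which the generator could not supply
ground truth for recovery checks:

* **Unaffected carriers are never screened-negative.** A carrier with no
  CRC and no polyps receives no `unaffected` event and therefore falls to
  uninformative. In reality a penetrance-0.8 dominant cohort would contain
  screened healthy carriers, and the segregation filter would (correctly,
  per its definition) reject the causal variant in those families; the
  emulated study design reports exactly the families where that did not
  happen.
* **Family-private carrier fractions stay below the artifact band.** When a
  planted variant's genotyped carriers would exceed ~4 % of the cohort's
  genotyped samples, non-case carriers are marked ungenotyped (sample
  unavailability). Without this, small cohorts would feed family-private
  variants into the 5 % technical-artifact filter, which exists to catch
  pipeline artifacts, not real private variants.

What passing tests therefore show: the cascade implements its stated rules
exactly (proved exhaustively against a brute-force predicate), recovers
planted variants perfectly under the stated noiseless conditions, and
degrades under genotype error (quantified in the acceptance run at a 2 %
error rate). What they do not show: performance on real WGS data with
calling artifacts, annotation disagreements between transcript sets,
pedigree errors, or population structure — none of which the generator
models (no linkage disequilibrium, recombination, or demography either).

## Problem sizes and numerical choices

The default validation runs use 15 families (~350 members, ~150 genotyped
samples) with 200 background variants, 3ⁿ exhaustive genotype enumeration up
to n = 8, 1,000 random CDS/deletion pairs for the translation oracle, and
10,000 replicates for interval coverage — sizes at which every check is
exact or tightly estimated while the whole suite runs in seconds. Model
tables are validated to a normalization tolerance of 1e-6; splice scores are
deterministic and reproducible to better than 1e-9 across submodel
evaluation orders.

## Known limitations

Recessive, compound-heterozygous and X-linked models are out of scope, as
are statistical linkage (LOD), kinship estimation, CNV handling, and exact
(Fisher-type) association intervals. The 5′ donor maximum-entropy model is
not implemented; donor-site variants are classified by annotation only. The
annotation field spec consumes VEP- or ANNOVAR-style INFO encodings but the
package never generates annotation itself.
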