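# Methods

## Setting

*NUDT15* loss-of-function variants determine tolerated 6-mercaptopurine dose.
The panel covered here holds four coding variants on the cDNA —
c.36_37insGGAGTC (rs869320766), c.52G>A (rs186364861), c.101G>C
(rs766023281) and c.415C>T (rs116855232, p.Arg139Cys) — combining into six
star alleles: \*1 (none), \*2 (insertion + c.415C>T in cis), \*3 (c.415C>T),
\*5 (c.52G>A), \*6 (insertion), \*7 (c.101G>C). \*4 is not defined in this
catalog. Allele definitions and functional statuses (\*2, \*3 nonfunctional;
\*5, \*6, \*7 uncertain; \*1 normal) live in `src/nudtphase/data/*.tsv` and
can be extended without code changes. Metabolizer classification follows the
CPIC-style rules: two nonfunctional alleles → poor; uncertain +
nonfunctional → potential intermediate; nonfunctional + normal →
intermediate; two normal → normal; anything involving an unknown allele, or
combinations the guidelines do not name (e.g. normal + uncertain), →
indeterminate.

The central inference is cis/trans resolution: a sample heterozygous for
both the insertion and c.415C>T is either \*1/\*2 or \*3/\*6, with very
different dosing consequences. A single cDNA amplicon sequenced with 300-bp
paired ends and ~562-bp inserts puts all four panel sites on one fragment,
so each read pair is a direct haplotype observation.

## Reference

The real transcript (NM_018283) is not redistributed. `surrogate_reference()`
builds a deterministic synthetic amplicon with the real CDS length (495 bp),
30-bp UTR flanks, ATG at CDS 1–3, the catalog reference bases at every panel
site, and fixed non-repetitive context at CDS 31–42 so the 6-bp insertion has
a unique, non-shiftable placement. Any user-supplied FASTA passes the same
panel validation (each substitution's reference base must be present;
violations name the position and expected base). Real references work
identically as long as the CDS offset within the record is given.

## Simulator

Per fragment: source haplotype Bernoulli(1/2); insert length ~
Normal(562, 60) rounded, clipped to the amplicon; start uniform over the
amplicon; mate 1 reads the 5' end forward, mate 2 the 3' end
reverse-complemented; read-through past short inserts is clipped to the
insert. Sequencing noise is i.i.d. base substitution at `per_base_error`
(default 0; the cohort experiments use 0.003, a MiSeq-scale rate). Base
qualities are constant and consistent with the error rate
(Q = −10·log10(p), capped at 40), which keeps trimming behavior
predictable. PCR template switching is modelled by `chimera_rate`: with that
probability mate 2 is drawn from the other haplotype over the same
reference window — the realistic mechanism that degrades cis/trans calls —
and defaults to 0.

Numerical notes:

- Fragment windows are drawn in *reference* coordinates and materialized per
  haplotype through a coordinate map, so windows spanning the c.36_37
  junction gain 6 bp on insertion-bearing alleles; the recorded truth insert
  length is the physical (allele-space) length.
- The nominal 562-bp insert mean exceeds the default 555-bp amplicon
  (495-bp CDS + 30-bp flanks), so inserts are truncated at the amplicon and
  the realized mean sits below the nominal. This mirrors an amplicon fully
  tiled by the fragment distribution; the insert-mean recovery test uses
  wide flanks where truncation is negligible.
- Defaults of 2,000 pairs/sample and sd 60 bp are engineering choices:
  MiSeq amplicon runs yield far more, and only relative pattern fractions
  matter to the caller.
- Indel sequencing errors, per-cycle quality decay and barcode
  demultiplexing are not modelled. Consequently, passing tests demonstrate
  correctness of the phasing logic under substitution noise and template
  switching, not robustness to instrument-specific artifacts.

## Trimming

The 4-base sliding window rule with mean-quality threshold 20: scanning
5'→3', the first window (truncated windows at the read end use the mean of
the remaining bases) whose mean quality falls below the threshold sets the
cut; the cut then advances past leading bases of that window that
individually clear the threshold (the failing mean is caused by bases
further in); the procedure iterates to a fixed point, making trimming
idempotent by construction. Reads shorter than `min_length` (default 36 bp,
a common choice; the amplicon context makes the exact value uncritical)
are dropped, and a pair with either mate dropped is discarded entirely — a
lone mate cannot phase across the insert. Adapter removal is a pass-through
hook only: amplicon reads are primer-defined.

## Alignment and observation extraction

A generic gapped aligner can place the 6-bp insertion in several equivalent
gap positions near c.36_37. Instead, each mate is aligned glocally (read
fully consumed, reference local) against **two explicit candidate
templates** — the plain reference and the reference with GGAGTC inserted
between CDS 36 and 37. The optimal edit path per candidate comes from
edlib's infix mode; paths are rescored with affine gap penalties (match +2,
mismatch −4, gap open −10, gap extend −1/base) and the candidate with the
higher summed pair score wins. Ties choose the no-insertion candidate and
mark the fragment ambiguous. For substitution-only reads against explicit
candidates the edit-optimal path is also the affine-optimal path, so the
choice is exact and deterministic. Both orientations are attempted (the
expected orientation first; the reverse complement only when the fit is
poor), supporting real FASTQ with varying mate orientation. Fragments whose
best candidate still leaves more than 30% of bases as edits are flagged
unmapped and excluded with a logged count.

Per-site observations: substitution sites report the aligned base as
REF/ALT/OTHER with its quality; observations below a Q13 floor become
MISSING rather than fabricating haplotypes; overlapping mates that disagree
at a site yield OTHER. The insertion site is called ALT only from a mate
whose alignment spans the junction with at least two matched bases on each
side (CDS 35–36 and 37–38) and covers the inserted hexamer (≥5 of 6 bases
matching); a mate spanning the same junction on the no-insertion candidate
yields REF; anything else — including reads merely ending inside the
insertion — is MISSING.

SAM round trip: internal alignments can be exported as SAM against the
plain reference (insertion-candidate columns become a 6-bp I operation;
leading/trailing I runs are soft-clipped as SAM requires). The import path
accepts any SAM and re-derives observations purely from a CIGAR walk; a
candidate I operation is accepted as the panel insertion when it has the
catalog length, left-aligns to the c.36_37 anchor, and matches GGAGTC with
at most one mismatch. No aligner flags or tags are trusted.

## Phasing and diplotype calling

Fragment vectors over the four panel sites are aggregated: vectors with any
OTHER are excluded from support but counted for QC; complete vectors (all
four sites observed) are counted by pattern; partial vectors are tallied
separately. Patterns with support ≥ `min_support` (default 10 fragments)
**and** ≥ `min_fraction` (default 5%) of informative complete fragments are
credible. Exactly two credible patterns → the two haplotypes; exactly one,
with residual noise below `min_fraction` and partial patterns not
contradicting it → homozygous call; more than two → the top two by support
with an `excess_haplotypes` flag (ties broken lexicographically on the
pattern tuple for reproducibility). Partial vectors compatible with exactly
one credible pattern reinforce its support but never found a haplotype.
Zero informative fragments raises a low-depth error; zero credible patterns
(or a contradicted homozygote, guarding allele dropout) raises an ambiguous
error; the cohort pipeline records these per sample and continues.

The defaults separate sequencing error from real alleles at amplicon
depths: with ~0.3%/base error, a specific erroneous complete pattern occurs
at well under 1% of fragments, far below the 5% credibility fraction, while
true haplotypes sit near 50%. Called haplotypes map to star alleles by
exact variant-set lookup; unmatched sets surface as `unknown` with the
observed set attached, so novel haplotypes survive reporting. An optional
external unphased genotype can be checked against the call
(`genotype_mismatch` flag), guarding the SAM import path.

## Trio inference

A genotype with k heterozygous variants admits 2^(k−1) unordered diplotypes
(all 2-colorings of the het variants; homozygous variants sit on both
haplotypes). `mendelian_phase` keeps a child diplotype only if one haplotype
can come from some diplotype consistent with the mother and the other from
the father, and reports parent diplotypes compatible with the surviving
calls — which pins a parent down when transmission is forced (e.g. a
homozygous \*2/\*2 father must transmit \*2, forcing c.101G>C onto the
maternal haplotype and inferring a triple-het mother as \*2/\*7). An empty
intersection is reported as Mendelian inconsistency, never repaired: the
panel variants are inherited germline alleles, and de novo events at these
sites are not modelled.

## Dose statistics

Groups: heterozygous (\*1/x) versus homozygous-or-compound (two variant
alleles); \*1/\*1 and unknown-containing diplotypes are excluded and listed.
The Mann–Whitney U statistic uses mid-ranks (ties averaged). For pooled
n ≤ 25 the two-sided p-value is exact: the permutation distribution of the
rank sum over all C(n_a+n_b, n_a) assignments is computed by a counting
recursion over doubled ranks (doubling makes mid-ranks integral), and
p = min(1, 2·min(tail)). Above the cutoff — including the study-scale 35 vs
5 comparison — a normal approximation with tie-corrected variance and
continuity correction is used, and the method is recorded in the result.
The cutoff at 25 keeps the exact path checkable against literal enumeration
while exercising the approximation at study scale.

Individual doses for the heterozygous group are not published — only the
summary (median 12.5, range 5.0–42.5 mg/m²/day) — so
`synthetic_het_doses()` generates a clearly-labelled synthetic stand-in
pinning exactly those order statistics; the published individual values for
the homozygous/compound patients (1, 2.2, 4.3, 2.5, 6.7 mg/m²/day) are used
directly in tests. No numeric p-value is claimed for the study comparison
because none is printed; the test's correctness is established by the
enumeration oracle and a 10,000-simulation null calibration (rejection rate
at α = 0.05 within 0.01, i.e. Monte-Carlo error plus a small allowance for
the approximation's discreteness).

## Problem sizes used in the checks

The cohort experiment simulates 37 samples at 2,000 pairs each (0.3%
error); the exhaustive diplotype sweep runs all 21 unordered allele pairs
at 60 error-free pairs each (exact recovery needs only that complete
patterns clear the support floor); oracle equivalence checks use ≥1,000
random reads (trimming) and pooled n ≤ 10 (Mann–Whitney enumeration).

## Known limitations

- The two-candidate design is specific to a panel with a single known
  insertion; a second indel would require more candidates.
- Count-and-threshold calling has no genotype likelihoods; extreme allele
  imbalance (beyond what `min_fraction` tolerates) surfaces as an ambiguous
  error rather than a probabilistic call.
- The simulator's error model is substitution-only with flat qualities;
  homopolymer and indel artifacts of real instruments are out of scope.
- Unphased-genotype trio input assumes accurate parental genotypes;
  genotyping error manifests as Mendelian inconsistency.
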