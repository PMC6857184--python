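# Methods

## Problem setting

A rare dominant disease mutation is observed in a nuclear family. The
question is which ancestral chromosome — which *founder haplotype* — the
mutation arose on, and whether that background matches the one reported in
other populations. The data are (i) family genotypes over a short ordered
panel of markers around the gene, (ii) a phased reference cohort over the
same markers, and (iii) published founder haplotypes to compare against.
The packaged default panel holds 16 markers around *SOD1* (15 SNPs and one
CA-repeat microsatellite, ordered as assayed, spanning *SOD1* to *SCAF4*
on chromosome 21); the mutation site is rs121912442 (p.A5V, c.14C>T,
mutant allele T).

Marker order is taken from the panel definition file, not from genomic
coordinates: every computation here is order-based over the fixed panel,
and positions are optional metadata. Microsatellite alleles are integer
repeat counts (fragment analysis reports a length, not a sequence).

## Pedigree-constrained phasing

Model: one nuclear family (two founders, ≥1 offspring), zero recombination
across the panel within the family — the region is a few hundred kb
transmitted in a single generation, so each offspring receives one intact
haplotype from each parent. Phasing is an exact constraint search:

* For each *transmission vector* (which of each parent's two haplotypes
  each genotyped offspring received — 4 possibilities per offspring), the
  markers decouple. Each marker is solved independently by unifying the
  four parental allele slots against the parental genotypes (when typed)
  and every offspring genotype; a genotype is an unordered pair, so both
  orderings are branched over.
* The solutions under one transmission vector are the cross product of the
  per-marker assignments; the full solution set is the union over feasible
  transmission vectors, deduplicated up to swapping a parent's two
  haplotypes (which relabels transmissions but changes nothing observable).

The search keeps this factored form. With both parents ungenotyped the
number of explicit solutions grows as the product of per-marker ambiguity
counts and can be astronomically large; forced positions, the carrier
background and the family haplotype set are read directly off the factored
representation. Expanding the explicit list is lazy and capped
(default 10^6 configurations, raising an error that advises marker
subsetting) — the cap governs materialization, not the search itself.

Degenerate inputs: a genotype missing at a marker imposes no constraint
there; ungenotyped individuals impose none anywhere; a fully homozygous
offspring forces its own haplotype pair. Mendelian violations are reported
with the offending marker and trio; families whose per-marker constraints
are individually satisfiable but jointly require a recombinant offspring
are rejected (zero-recombination is an assumption, not a fit).

Obligate carrier status is an input annotation (the affected deceased
father; the married-in mother as obligate non-carrier), never inferred from
affection status. Annotations discard assignments they visibly contradict;
a MISSING slot cannot falsify an annotation.

### Carrier background and identifiability

`carrier_background` collects, over all phase solutions, every founder
haplotype that carries the mutant allele and reaches all named carriers,
and reports each position that takes the same allele in every such
placement; positions the solutions disagree on are MISSING. Forced
positions are therefore always correct (the true solution is among those
enumerated), but *completeness* is data-dependent: with both parents
ungenotyped, a marker at which the carrier offspring are all heterozygous
and the maternal slots are not pinned by the other siblings is genuinely
ambiguous, and whole-haplotype swaps between an ungenotyped father and
mother can also be consistent. The published family resolved completely
because the proband was homozygous at every non-mutation site. Genotyping
either parent removes the ambiguity (verified in the test suite: with both
parents typed, recovery of the implanted background and of the true
transmission vector is exact in every replicate).

## Haplotype spectra and rank naming

Haplotypes of a phased reference VCF are matched to the panel by marker ID
(fallback chromosome+position); panel markers absent from the source are
dropped panel-wide so all haplotypes stay aligned — mirroring the move from
the 16 assay markers to the 14 SNPs available in reference data (the
mutation site and the microsatellite are absent from reference panels; the
`pop14` preset selects those 14 SNPs). Unphased genotypes are an error:
statistical phasing of unrelated samples is out of scope, the reference
panel is assumed pre-phased.

A spectrum counts distinct haplotypes exactly (frequencies kept as
rationals internally, displayed to 3 decimals) and names them "1", "2", …
by descending frequency, ties broken by the lexicographic allele string so
output is deterministic. Family haplotypes are labelled by the rank of
their projection onto the spectrum panel; when several family haplotypes
share a rank the mutation-bearing one is suffixed "V", its wild-type
counterpart "A", and any further duplicate (e.g. differing only at the
microsatellite, invisible to the 14-SNP spectrum) gets "*" — yielding the
1A / 1V / n / 1A* annotation style. Super-population groupings follow the
1000 Genomes phase-3 code lists; the spelling "GWC" is accepted and mapped
to GWD with a warning.

Compatibility of a genotype with a reference haplotype is per-marker: one
genotype allele must equal the reference allele (MISSING matches
anything); the leftover alleles form the complement. With a mutation
constraint, the carrier background must additionally equal the reference
at all co-observed sites. Mismatch counting between haplotypes skips sites
MISSING in either; published unresolved-phase entries like "C/G" are
ambiguous sets that match when they intersect (policy "lenient", default)
or never (policy "strict"). The mismatch report always satisfies
compared + skipped = panel length. Founder-background comparisons include
the mutation site by default (both backgrounds carry the mutant allele by
construction, so it never adds a mismatch); any marker can be excluded
explicitly.

## Linkage disequilibrium

With major-allele frequencies p_A, p_B and joint frequency p_AB:
D = p_AB − p_A·p_B; r² = D²/(p_A(1−p_A)p_B(1−p_B)); D′ = |D|/D_max with
D_max = min(p_A(1−p_B), (1−p_A)p_B) for D > 0 and
min(p_A p_B, (1−p_A)(1−p_B)) for D < 0. The major allele is defined per
sample set (frequency ≥ 0.5, ties lexicographic); the sign of D depends on
that labelling, so only r² and D′ are reported by default. Monomorphic
markers get D = r² = D′ = 0 by convention (or an error in strict mode);
haplotypes MISSING at either marker of a pair are dropped for that pair.

Blocks are maximal contiguous runs of ≥2 markers in which *every*
within-run pair meets the metric threshold, found by a greedy
leftmost-maximal scan (deterministic, disjoint, ordered by start). The
default metric is D′ at 0.90: block definitions in the literature vary and
the source analysis names no algorithm or threshold, so the setting is
configurable and the tests use planted ground truth rather than a
published block boundary.

## Synthetic study conditions

The generator emulates the study's data shapes end to end and is fully
deterministic per seed (the seed is recorded in the VCF/popmap/truth
headers):

* **Reference cohort.** Two haplotypes per sample drawn i.i.d. from a
  per-population spectrum. The default Iberian-like spectrum has 8
  haplotypes at frequencies (0.45, 0.20, 0.12, 0.08, 0.06, 0.04, 0.03,
  0.02) — stand-in values, since the source figure prints bars, not
  numbers — over a cohort of 102 diploid samples. Haplotype pools are
  built from the wild-type Iberian background by flipping observed
  biallelic sites (the second pool member is the North American-founder
  background, which differs at 9 of the co-typed SNPs); sites monomorphic
  in the published table are never varied.
* **Worldwide cohort.** Five super-population spectra over a shared
  21-haplotype pool, at 1000-Genomes-phase-3-like cohort sizes (2,499
  samples). The generating frequencies of the European- and
  American-founder backgrounds are the published population values
  (EUR 0.298/0.062, EAS 0.306/0.385, AFR 0.037/0.045); the remaining mass
  is spread over population-private haplotypes (invented, plausible).
* **Family.** Two parents and 4 genotyped offspring; the mutant allele is
  implanted at rs121912442 on the rank-1 paternal haplotype; exactly 2
  offspring inherit it (the observed segregation); parents are ungenotyped
  by default (they were deceased in the study). Genotypes are returned
  phase-stripped; the truth record keeps haplotypes, transmissions,
  carriers and the implanted background. A genotyping-error knob exists
  only to exercise the Mendelian-inconsistency error paths.

What the generator does **not** emulate: linkage-disequilibrium decay with
distance (spectrum draws are exchangeable across samples), mutation or
genotyping error (off by default), recombination within the panel,
relatedness inside the reference cohort, and within-super-population
heterogeneity (populations of a super-population share one spectrum).
Passing tests therefore show correctness of the inference machinery under
the stated sampling model, not robustness to those real-data features.

Because parents are ungenotyped in the default family design, exact
recovery of the full implanted background is *not* guaranteed (see the
identifiability note above): across seeded replicates every recovered
position is correct, and recovery is complete in roughly 6 of 10 replicates
— exactly the replicates in which classification against the generating
spectrum is unique. With genotyped parents both are exact in all
replicates. The acceptance script reports the measured rates rather than
asserting them away.

## Problem sizes and numerics

The test suite and `scripts/acceptance.py` run at the study's own scales —
panels of 14–16 markers, cohorts of 102 (single-population) and 2,499
(worldwide) samples, families of 4 offspring, 200 seeded replicates for
recovery/calibration rates and 500 random families for the
phasing-vs-oracle check — chosen to match the analyses being reproduced
while keeping a full run in the minutes range on one CPU. Frequencies are
exact rationals until display; LD uses double precision with closed-form
expressions only; all randomness flows from explicit seeds through
numpy's Generator.
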