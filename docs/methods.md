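# Methods

This note documents the models behind `arcsim`, the choices made where the
design was genuinely open, and what the synthetic data can and cannot show.

## Fusion rules

A colony genotype is an unordered pair of ARC haplotypes, each carrying one
allele symbol per marker plus one allele at each of *alr1* and *alr2*.
Fusibility between two colonies is classified per locus: a locus is
"shared" if any of the four pairwise haplotype comparisons finds an
identical allele symbol there. Sharing at both alr loci gives fusion, at
neither gives rejection, at exactly one gives transitory fusion subtyped by
the shared locus.

Two points were open and were decided as follows.

* **Cis vs trans sharing.** The published rules are phrased in terms of
  shared haplotypes and shared alleles without fixing whether the shared
  alr1 and alr2 alleles must sit on one chromosome. We evaluate sharing
  per locus over all four haplotype pairings (trans counts), because
  congenic-style transitory fusion arises precisely from recombinant
  haplotypes whose alr alleles have mixed provenance. With intact founder
  haplotypes the two readings coincide.
* **Allele identity.** Exact symbol equality. Wild-type alleles that are
  sequence-similar to an inbred allele ("f-like") behave differently in
  assays and are therefore distinct symbols unless the user aliases them.

The unlinked modifier locus is stored on the genotype (copy number 0–2) but
deliberately ignored by the classifier, which implements the null model;
the modifier's phenotypic effect lives only in the simulated assay.

## Meiosis model

Gametes are drawn under the no-interference model: the haplotype donating
the first marker is chosen fairly, then an independent crossover indicator
fires in each inter-marker interval with probability equal to the inverse
map function of the interval's distance. *alr1* co-segregates with the
first marker and *alr2* with the last — the two loci bracket the marker
panel — so recombinant gametes can carry discordant alr alleles. The
modifier locus is unlinked: each parent transmits a modifier allele with
probability copies/2, independently of the ARC.

Map functions: Haldane (`d = −50·ln(1−2r)`, default, matching the
no-interference simulator) and Kosambi (partial interference), forward and
inverse, with round-trip accuracy better than 1e−10. Recombination
fractions of 0.5 or more have unbounded distance and are reported as such.

## Pedigree presets and the synthetic data

Raw genotype tables for the published crosses are not deposited, so the
simulator emulates their structure: testcross-type progeny genotyped at the
panel 194m6–18m1–28m6–174m4, two genotype classes per marker segregating
1:1, recombination between adjacent markers, optional missing calls,
optional modifier column.

Four presets mirror the published designs:

* **congenic-fr** — inbred ARC-f/f × congenic ARC-f/r, one mapping
  population of 590, total 194–174 distance 1.6 cM.
* **OQ6D** — wild c/d × inbred f/f, F1s backcrossed to the inbred line
  giving four analysis populations (AP110, AP111 at 295 from the f/d F1;
  AP105 at 285 and LB132 at 70 from the f/c F1), population sizes matching
  the published segregation table totals.
* **LH06-082** — wild a/b × inbred r/r, then an F2 sib incross (n = 44,
  so ~11 ARC-r/r homozygotes arise at the Mendelian 1/4).
* **LH06-003** — wild i/r2 × inbred f/f, F2 incross plus two terminal
  backcross-style populations in 25% wild background.

Numbers the sources do not state, chosen once as realistic for this system:
the per-interval split of the total 194–174 distance (40% / 20% / 40%,
reflecting the markers' relative physical spacing with the middle markers
close together); wild-haplotype totals of 30.5 cM (d) and 19.8 cM (c),
the extremes of the published wild range, with the c value also used for
the two presets whose map lengths could not be measured; F1 nursery sizes
(24) large enough that the genotypes needed for the next cross are
essentially always present.

Determinism: every population draws from an RNG sub-stream derived from
(seed, CRC32 of the node id), so identical seeds give byte-identical
outputs and adding a node does not perturb the others.

What the synthetic data do **not** emulate: genotyping error, systematic
missingness, segregation distortion, crossover interference, sex
differences in recombination, and family structure beyond the pedigree
graph. Passing tests therefore validate the estimators under the stated
model, not robustness to these real-data features.

## Segregation testing

Plain chi-square goodness of fit against 1:1, one degree of freedom, **no
Yates continuity correction** — recomputation against the published
segregation table shows the printed values are uncorrected (266:225 gives
3.42; the corrected statistic would be 3.26). Larval and colony samples of
one cross are pooled by summing class counts; missing calls drop out of
both classes. Markers sharing a numeric prefix are reported separately in
segregation output (as the published table does) even though mapping
collapses them.

## Linkage mapping

Recombinants are scored against the informative parent's phase, which is
taken from pedigree founders; the homozygous tester's allele is removed
from each progeny call to recover the transmitted allele. A
coupling-phase inference fallback (`infer_testcross_parents`) serves the
CLI when founders are not supplied; it cannot see repulsion phase.

Markers with a common numeric prefix (e.g. 194m6, 194c17) are closely
linked relative to the ARC and are collapsed to one locus for mapping; an
individual whose same-prefix markers disagree is an intra-group
recombinant, set missing at that locus and counted in a diagnostics log.

The multipoint likelihood of a marker order is the complete-data sum over
adjacent intervals of `R·log₁₀(r̂) + (N−R)·log₁₀(1−r̂)` with per-interval
MLEs, intervals scored on pairwise-complete individuals. This is simpler
than an EM over missing data and equivalent when data are complete; with
heavy missingness the two can diverge. Orders are enumerated exhaustively
(≤ 8 markers), reversal-equivalent orders are identical, the best order is
normalized to relative log-likelihood 0, and odds against any other order
are `10^|Δ|` reported exactly (a Δ of −1.74 is odds of 10^1.74 ≈ 55:1;
rounding to a headline "50:1" is left to the reader). With zero
recombinants all orders tie and are reported as ties.

Across-cross map-length comparison uses the G-statistic decomposition for
replicated binomial counts: each cross's recombinant count is tested
against the pooled recombination fraction, `G_het = Σᵢ Gᵢ(r̂ᵢ vs r̂_pooled)`
on k−1 df, and `G_total = G_pooled + G_het` holds exactly (`G_pooled`
tests the pooled fraction against 0.5). `G_het` equals the 2×k G-test of
independence on the recombinant/parental contingency table, which is the
testable contract (verified against an independent implementation). The
0·ln 0 = 0 convention handles boundary counts; all-zero recombinants give
G_het = 0, p = 1.

## Modifier detection power

Detection is all-or-nothing: any single assayed homozygote departing from
the fusion phenotype is a positive. The miss probability of a design is
the product of per-individual non-carriage probabilities, and the smallest
adequate design size is the exact integer `min n : (1−c)ⁿ < α` (for
α = 0.05, c = 0.5 this is n = 5, since 0.5⁵ = 0.03125 < 0.05 — sometimes
loosely quoted as "more than 5").

Two founder models are provided because the published arithmetic uses
both, and they differ for F2 incrosses:

* **genome_fraction** — carriage probability equals the wild-background
  genome fraction directly: 0.5 for backcross and F2-incross progeny, 0.25
  for terminal populations. Miss probability of n F2 progeny: (0.5)ⁿ.
* **carrier_transmission** — an explicitly heterozygous single-copy
  carrier founder with Mendelian transmission: an F2-incross progeny
  misses the allele with probability (3/4) per transmission opportunity,
  so a composite design with n F2 and m terminal homozygotes misses with
  (0.75)^(2n+m), and per-individual F2 carriage is 1 − (3/4)² = 0.4375.

Neither parameterization is declared "correct"; designs are explicit
per-individual carriage lists so both are expressible without
special-casing. Codominant and incompletely dominant modifiers are treated
as detectable from one copy (the 0.5-per-individual arithmetic implies
single-copy detectability); recessive modifiers are outside the detection
model, as the breeding designs cannot expose them.

`empirical_power` validates the analytic product by Monte Carlo on the
design level (carriage → expression → all-or-nothing detection). The
full-pipeline route — pedigree simulation, homozygote retrieval, simulated
assays — is exercised in the tests; note that under carrier_transmission
the per-pedigree outcomes are correlated through the founder and F1
carrier states (with probability 1/4 neither F2 parent inherits the
allele), so pipeline detection frequencies sit below the independent-model
product. The analytic formulas describe the independent-sampling design
abstraction, not that correlated pedigree.

## Numerical and interface choices

* Genotype calls are unordered pairs normalized lexicographically
  (`f/d` ≡ `d/f`); missing is `-`; tables are TSV, UTF-8, Unix newlines.
* Segregation reports print χ² to 2–4 significant figures and P to 2;
  distances print to 0.1 cM; relative log-likelihoods to 2 decimals.
* Chi-square with both counts zero, a heterogeneity test with fewer than
  two crosses, an empty detection design, and an order search over more
  than 8 markers are errors or flagged degenerate results, not silent
  defaults.
* Problem sizes in the test suite (e.g. 200 replicate experiments of
  n = 600 testcrosses for map-length recovery, 20,000 replicates for the
  power validation, 10⁴ random genotype pairs for classifier properties)
  were chosen to give comfortable Monte-Carlo resolution for the assertions
  they support.

## Known limitations

* No crossover interference; Kosambi distances are offered for conversion
  but the simulator itself is Haldane-consistent.
* The multipoint likelihood is complete-data; it is not an EM and does not
  impute missing genotypes.
* The published wild-type map distances and heterogeneity P values cannot
  be reproduced exactly because the underlying raw genotypes are not
  available; the mapping machinery is instead validated by parameter
  recovery on simulated data at the published map lengths.
* Phase inference from data alone assumes coupling; supply pedigree
  founders for repulsion designs.
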