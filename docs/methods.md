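# Methods

## Setting and model

The package targets germplasm derived from a small number K of strongly
differentiated ancestral taxa (K = 4 by default) genotyped at biallelic
SNPs grouped into short gene fragments (~500 bp amplicons).  Genotypes
are unphased diploid calls, stored as alternate-allele dosage (0/1/2,
−1 missing).  Interspecific admixture is modelled at fragment
granularity: a hybrid or introgressed genome is a mosaic of
whole-fragment haplotypes, each descending from one ancestral taxon.

## Diagnostic-marker statistic

For marker *m* and focal taxon *i* with per-taxon alternate-allele
frequencies `p_u`:

* rest pool: `p_rest = mean(p_u, u ≠ i)` — unweighted over the non-focal
  taxa, i.e. each taxon contributes equally regardless of its sample
  size;
* total pool: `p_tot = (p_i + p_rest)/2`;
* `G_ST(i,m) = (He_tot − (He_i + He_rest)/2)/He_tot` with
  `He(p) = 1 − p² − (1−p)² = 2p(1−p)`.

He is concave, so by Jensen's inequality `He_tot ≥ (He_i + He_rest)/2`
and the statistic lies in [0, 1] for every frequency input (property-
tested over 10⁵ random draws, and checked to 1e−12 against a literal
term-by-term evaluation on the full 11⁴ grid).  Two analytic anchors fix
the weighting convention: a fixed difference (p_i = 1, others 0) gives
exactly 1, and a heterozygous single-accession taxon (p_i = 0.5, others
0) gives exactly 1/3.  An equal-weight *four*-population total would
violate the second anchor (it can go negative), which is why the
two-subpopulation form with equal Ti/T−i weights is used.

Monomorphic markers (He_tot = 0) are assigned G_ST = 0 with a flag
rather than left undefined, keeping result tables rectangular; flagged
markers never enter panels.

**Classification** (one class per marker, exhaustive and exclusive):

| class | rule (defaults) |
|---|---|
| DIAGNOSTIC | max G_ST > 0.9 (strict) |
| TAXON_SPECIFIC_POLYMORPHISM | max G_ST ≤ 0.5, variant allele segregating in exactly one taxon, the others fixed for the shared allele |
| ND | max G_ST ≤ 0.5 otherwise |
| PARTIAL | 0.5 < max G_ST ≤ 0.9 |

Both thresholds are configurable; the specific-polymorphism bound is
taken inclusive (≤ 0.5).  G_ST inside this statistic uses the
uncorrected `1 − Σp²`; *reported* expected heterozygosity elsewhere uses
the unbiased small-sample factor `2n/(2n−1)`.

**Panel QC.**  Diagnostic and taxon-specific markers form the per-taxon
panel; a marker is discarded when its diagnostic allele is also observed
at frequency ≥ `qc_threshold` (default 0.1) in a second taxon — the
shared-polymorphism failure mode of externally selected candidates.
**Assay proximity filter:** candidates with another SNP or indel within
`window_bp` (default 50, the flanking-probe context of competitive
allele-specific PCR assays) on either side are rejected, symmetrically.

## Supporting statistics

* Allele frequencies per group: alternate gene copies over non-missing
  gene copies; undefined (flagged) when no call.
* Ho = heterozygous fraction of non-missing calls; He_unbiased as above;
  Fw = 1 − Ho/He_unbiased by default (0 at Hardy–Weinberg), with the
  single-population Weir–Cockerham variance-components f (1 − c/(b+c))
  available via `fw_estimator="wc"` since the historical software's
  exact estimator is not documented.
* F_ST: the Weir–Cockerham variance-components estimator (a, b, c);
  multilocus θ = Σa/Σ(a+b+c).  Populations with fewer than two called
  diploids at a marker are excluded there; markers with fewer than two
  usable populations are NaN.
* Simple-matching dissimilarity: per locus, similarity = shared allele
  copies/2 = 1 − |dosage₁ − dosage₂|/2; pairwise mean over loci called
  in both accessions.
* Group reports (Na, MD%, polymorphic loci, Ho, He, Fw, NSG) and
  cross-platform genotype concordance (discrepant / compared call pairs,
  missing excluded, per-marker ranking).
* Multilocus-genotype identity treats missing as a wildcard (greedy
  merge in input order, consensus accumulates); strict identity is
  available via a flag.  Aggregated statistics report mean ± standard
  error over markers with defined values.

## Introgression screen

The manual workflow this automates combines an ordination of accessions
per fragment with per-accession fragment heterozygosity: interspecific
fragments appear between taxon clusters with Ho far above the
within-taxon scale.  The automated decision rule flags a *reference*
accession × fragment when

1. fragment Ho ≥ `het_threshold` (default **0.1**), and
2. the accession is heterozygous at ≥ `min_differential_hets`
   (default **2**) markers of that fragment whose frequency difference
   between its own taxon and some other taxon is ≥ `differential_delta`
   (default **0.9**); the donor is the taxon maximising that count.

Design choices behind the defaults:

* The own-taxon frequency in rule 2 is computed **leave-one-out**
  (excluding the evaluated accession).  Otherwise several introgressed
  accessions jointly drag their taxon's provisional frequency away from
  fixation (4 heterozygous of 11 references moves a fixed difference
  from 1.0 to 0.82) and the near-fixed contrast test defeats itself.
* `differential_delta = 0.9` restricts the evidence to near-fixed
  contrasts, which pure accessions essentially cannot be heterozygous
  for; this carries the precision of the rule.
* `min_differential_hets = 2` guards against a single genotyping error
  mimicking evidence.
* `het_threshold = 0.1` is ~5× the within-taxon fragment-Ho scale of
  strongly differentiated taxa (a few percent) while not exceeding the
  smallest signal rule 2 can certify — two divergent sites on a typical
  18-marker fragment.  A higher cutoff (e.g. 0.3) silently discards true
  donor-heterozygous fragments whose realized divergence is small.
* Flags apply at accession × fragment granularity only, never whole
  accessions; TEST-role accessions are never flagged.
* One flag/mask pass by default (a single re-estimation); `passes`
  permits iterating to a fixed point.  Masking is strictly subtractive:
  every call used after masking was present before.
* A principal-coordinates ordination (classical double-centering of the
  simple-matching dissimilarities) is emitted alongside for visual
  audit, matching the manual use; it plays no part in the decision rule.

After masking, taxon frequencies and G_ST are re-estimated; markers that
masking leaves without callable genes in some taxon are dropped from the
post panel and logged.

## Admixture profiling

For taxon *t* with panel markers called in accession *a*: FHom/FHet/FAbs
are the fractions of markers where *a* carries 2/1/0 copies of the
diagnostic allele (missing calls leave the denominator, so the three
fractions always sum to 1).  The contribution estimate

    s_t = (2·FHom_t + FHet_t)/2,    c_t = s_t / Σ_u s_u

normalises by per-taxon panel size first, so unequal panels cannot bias
toward the best-covered taxon.  The estimator is deterministic and
model-free; it replaces Bayesian population-structure inference in this
package (a deliberate non-goal), and is unbiased for the true genome
fraction when panel markers are fixed differences.  Taxon-specific
polymorphism markers dilute each taxon's share by a similar factor, so
the normalised c is nearly unaffected; simulated pedigrees across genome
fractions {0, 1/8, 1/4, 1/2, 3/4, 1} recover the realized fraction with
mean absolute error well under 0.05 at ≥20 markers per taxon.

Ordination of accessions uses PCA of the centered dosage matrix
(missing imputed to marker means, SVD); hybrids project between their
parental clusters.  Axis signs for PCA and PCoA are fixed so each axis's
first nonzero loading is positive, making outputs reproducible.

## Synthetic-data generator

Defaults mirror the reference study design: taxa sampled 11/9/5/1
(one taxon intentionally a single accession, the hardest frequency
estimate), 57 fragments of 500 bp over nine chromosomes, 18 SNPs per
fragment, 2% missing calls.

Marker classes and default fractions: per-taxon fixed differences
(0.075 × 4 = 0.30), two-vs-two fixed splits (0.40), per-taxon private
polymorphisms (0.06 × 4 = 0.24, folded-Beta(0.5, 3) minor frequencies),
soft shared polymorphisms in ≥2 taxa (0.03), monomorphic (0.03).  The
split class represents the pair-differential markers that dominate real
interspecific divergence while being diagnostic for no single taxon
(their taxon-vs-rest G_ST is exactly 0.5); with these fractions a
haplotype pair drawn from two different taxa differs at ≈45% of markers,
so injected donor-heterozygous fragments show Ho near one half while
pure accessions stay at a few percent — the contrast the screen relies
on.  Because fixed-difference frequencies are exactly 0/1 and
private/shared minor frequencies are folded below 0.5, the planted
diagnostic set is recoverable with precision = recall = 1 whenever every
taxon has ≳5 reference accessions and no introgression; with a
single-accession taxon, rare private variants can masquerade as fixed
differences, exactly as in real sparse sampling.

Reference genotypes are two independent Bernoulli(p) haplotypes
(Hardy–Weinberg, linkage equilibrium).  Crosses transmit one whole
fragment per gamete with free recombination between fragments and none
within; each haplotype carries a per-fragment taxon-origin label, so
every simulated individual has an exact, realized per-taxon genome
fraction in the truth table.  Introgression replaces one haplotype of a
target reference over a random fragment subset with a fresh donor
haplotype.  A single seed drives per-stage spawned RNG streams; identical
configurations reproduce byte-identical output files.

What the generator does **not** emulate: genotyping error, linkage
disequilibrium within taxa, intra-fragment recombination, coalescent
frequency spectra (frequencies are specified, not evolved), ascertainment
bias beyond the class fractions, and cytoplasmic markers.  Passing tests
therefore demonstrate correctness of the statistics and the decision
rules under the stated model, not robustness to genotyping error or to
weakly differentiated taxa.

## Numerical and format conventions

* Positions: VCF/marker tables 1-based; fragment intervals (BED) 0-based
  half-open; conversion happens once at load.
* Genotype TSV dialects: two-letter calls, IUPAC heterozygote letters,
  slash-separated; missing as `./.`, `NN`, `NA`, `-` or empty.  When no
  marker metadata accompanies a TSV, ref is the alphabetically first
  observed allele.
* All result tables are TSV, UTF-8, `NA` for missing, floats written
  with full round-trip precision (%.17g), via write-then-rename so
  readers never see partial files.
* G_ST is clipped to [0, 1] against floating-point underflow of the
  analytic bound; PCoA discards negative eigenvalues (non-Euclidean
  inputs) from retained axes.

## Known limitations

* The flagging rule needs ≥2 near-fixed differential markers per
  fragment; fragments carrying fewer are undetectable in principle from
  frequency contrast alone (the simulator's fragment size makes this
  rare but not impossible).
* Contribution estimates assume the panel's diagnostic alleles are
  (nearly) absent outside their taxon; heavy shared polymorphism
  violates this and is only partly caught by panel QC.
* The dissimilarity/ordination tooling is O(n² · markers) in accessions
  and meant for germplasm-collection scale (hundreds), not biobank
  scale.
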