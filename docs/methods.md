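# Methods

`pedflow` implements the statistical workflow used to dissect the genomic
constitution of a crop breeding pedigree from resequencing-derived SNPs:
group diversity and LD scans, selective-sweep detection between a wild and a
domesticated panel, sliding-window identity-by-descent (IBD) detection with
origin tracing through the recorded pedigree, and candidate-SNP association.
Because the package is exercised end-to-end on synthetic data, this note
describes both the analytical procedures and the generative model whose
planted truth the tests recover.

## Coordinate and data model

All coordinates are 1-based inclusive internally (`D02:2204597-2360776`
denotes 156,180 bp); conversion to 0-based half-open happens only at BED
export. Chromosome names are accepted in both the `A1` and `A01` dialect and
normalized to the zero-padded form; the sub-genome (A or D) of allotetraploid
cotton is read off the name prefix. Genotypes are alternate-allele dosages
0/1/2 with −1 for missing; phased data adds a 2n × S haplotype matrix whose
row pairs belong to one accession.

The pedigree is a DAG of accessions with roles (exotic founder, backbone,
elite, hybrid) and at most two recorded parents per node. Crosses that
historically involved three or more contributors are modeled with unnamed
intermediate nodes so the two-parent invariant holds. The packaged fixture
encodes the Ekangmian 9 breeding pedigree with 26 sequenced accessions
(the published description counts 27 pedigree accessions but sequences 26)
plus four intermediates.

## Synthetic data generator

The generator emulates the statistical structure of the study panel rather
than its sequence content.

**Founder/wild haplotypes.** Site positions are uniform without replacement;
alternate-allele frequencies follow a neutral site-frequency spectrum
(P(count i) ∝ 1/i over the panel's haplotype count), under which the
expected per-site heterozygosity of an n-haplotype sample is
(n−1)/(n·Σ_{i<n} 1/i). The default SNP density is solved from this closed
form so that the wild panel's 100 kb windowed π lands at 1.32 × 10⁻³, the
published wild Upland cotton level; with the default 31 wild accessions this
gives ≈ 6.3 SNPs/kb. An optional block-mosaic mode copies founder
haplotypes from a small ancestral pool in exponentially distributed blocks,
inducing background LD when a test needs it.

**Domestication bottleneck.** Pedigree founder lines are drawn at the same
site frequencies, except that a fraction 1 − (0.37/1.32) ≈ 0.72 of sites is
fixed within the pedigree founder pool (the ratio of the published pedigree
and wild diversities). Pedigree-group π then emerges near 0.3 × 10⁻³ — close
to, and deliberately not tuned to, the published 0.37 × 10⁻³, since the
descent structure of the pedigree removes additional diversity.

**Transmission.** Crossover counts per meiosis are Poisson(length_Mb ×
cM/Mb ÷ 100) with uniform breakpoints. Breeding lines are modeled as
*inbred*: founders are doubled haplotypes, and each cross is resolved by
drawing one gamete per recorded parent and then one recombinant of that
union, doubled to a homozygous line (single-seed descent). This matters:
the SNP-identity-ratio IBD rule compares diploid genotype codes and can only
attain ≥ 99 % identity between near-homozygous lines, which real pedigree
cultivars are. Setting `fix_lines=False` keeps the heterozygous F1 union
instead (useful for transmission-model tests, not for IBD detection). The
default toy genome has two 2 Mb chromosomes standing in for ~100 Mb cotton
chromosomes, so the per-Mb recombination rate is scaled up (75 cM/Mb) to
preserve a realistic ~1.5 crossovers per chromosome per meiosis; scan-scale
tests use longer chromosomes with correspondingly lower rates.

`SimTruth` records, per accession, the exact parental origin of every genome
interval (a tiling), the crossover breakpoints, planted sweep intervals and
QTL effects. Because descent is positional, the segments a descendant owes
to any ancestor are obtained by recursively intersecting tilings; this is
the oracle for all IBD acceptance tests. All randomness derives from one
seed through named child streams (sites, founders, meiosis, sweep,
phenotype, missingness), so enlarging one stage does not perturb another.

**Sweeps and phenotypes.** `plant_sweep_region` replaces each haplotype in a
region by a designated swept haplotype with probability = intensity; the
expected residual diversity is the exact pair count m(2k+m−1)/(n(n−1)) given
k swept of n haplotypes, which the tests use as the oracle. Phenotypes are
additive QTL effects plus Gaussian noise scaled to a requested heritability;
environment replicates share the genetic value.

What the generator does **not** emulate: real allele-frequency spectra under
selection, segmental patterns of fixation, mutation on the pedigree,
genotyping error beyond i.i.d. missingness (2 % default), and residual
heterozygosity of nominally inbred lines. Passing tests therefore
demonstrate correctness of the procedures under the stated model, not
robustness to every property of real resequencing data.

## Diversity, LD and trees

* **π** — per site, c_ref·c_alt/C(n,2) over non-missing allele calls; window
  value is the per-site sum divided by window length (100 kb windows, 20 kb
  step by default, anchored at position 1; terminal windows are normalized
  by the base pairs they actually cover).
* **SNP density / zero-diversity segments** — polymorphic sites per bp in
  non-overlapping 100 kb bins; maximal runs of zero-SNP bins ≥ 100 kb are
  reported as conserved segments. Overlapping bins are rejected (the merge
  would be ambiguous).
* **Fst** — Weir–Cockerham variance components per site, window estimate as
  the ratio of sums Σa/Σ(a+b+c); sites with undefined components are
  skipped, all-missing windows flagged NaN.
* **LD** — phased r² from haplotype frequencies (D²/ p_A p_a p_B p_b), with a
  genotype-correlation fallback for unphased input; all intra-chromosomal
  pairs within 1 Mb, decay curve as mean r² per 10 kb distance bin.
* **Distance / NJ** — allele-sharing distance 1 − mean(1 − |g_i − g_j|/2)
  over jointly called sites; Saitou–Nei neighbour joining with the Q
  criterion, ties broken by lowest index pair, negative branch lengths
  clamped to zero with the deficit moved to the sibling (path lengths
  between the joined pair preserved). Authored in-package to pin down these
  tie/clamping rules; tests cross-check topologies against scikit-bio's
  independent implementation.

## Sweep scan

Candidate sweep windows are the top 5 % of log₁₀(π_wild/π_pedigree) across
aligned windows; the threshold is the empirical 95th percentile of finite
ratios, ties flagged inclusively. Windows with π_ped = 0 < π_wild are +∞ and
always flagged; windows with both zero carry no signal and are excluded.
Confirmation is by XP-EHH: EHH around a core site is the probability that
two random haplotypes are identical at every marker between the core and x
(EHH(0) ≡ 1 by convention); iHH is the trapezoidal integral over physical
distance, both directions summed, truncated when EHH < 0.05, at the
chromosome end, or beyond a 2 Mb integration radius — the radius is needed
because highly related panels (a pedigree group contains near-clones) can
hold EHH above the cutoff indefinitely. The per-site score ln(iHH_ped /
iHH_wild) is standardized genome-wide; a window's score is its maximum
standardized site score (mean available), and the top 5 % of windows is
flagged. Confirmed sweeps are windows flagged by both scans, merged into
segments bridging gaps up to one window step.

iHH for all sites is computed via a survival-function identity: EHH at
marker core±k equals the fraction of haplotype pairs whose first mismatch
beyond the core lies past k, so precomputing each pair's next/previous
mismatch index reduces every core site to a histogram lookup. A test asserts
bit-level agreement with direct per-site curve integration.

## IBD detection and genome-flow tracing

Windows span 200 SNPs with a 20-SNP step (never crossing a chromosome); a
chromosome with fewer sites than one window yields a single truncated window
when it has at least one step's worth of sites. For a descendant/parent
pair, the identity ratio is the fraction of jointly called sites with equal
genotype codes; a window qualifies at ratio ≥ 0.99 with at least 100
compared sites (half the window — guards truncated or missing-heavy
windows). An allele-level matching variant is available behind a flag.

Windows where any two designated founder lines are themselves ≥ 99 %
identical are masked as uninformative: where candidate sources are mutually
IBD-indistinguishable, origin cannot be attributed. The mask cutoff mirrors
the IBD threshold so "uninformative" means exactly "sources
indistinguishable at the detection resolution".

Qualifying unmasked windows with overlapping or abutting site spans merge
into runs; segment coordinates span the first to last SNP of the run (so
reported lengths depend on SNP density at the edges). Overlaying per-parent
segments splits the genome into elementary regions attributed to exactly one
parent (unique) or several (shared). Contributions are unique bp per
ancestor over the assembled genome, with shared bp reported separately and
the remainder labelled unknown; they sum to 100 % by construction.

Tracing modes: *direct* compares the target against each ancestor
independently (used for constitution plots); *chained* credits a region only
when a qualifying segment covers it at every parent–child link along some
pedigree path (stable inheritance); chained coverage is provably a subset of
direct coverage on the same data, and a test asserts it. Common IBD across
descendants is the base-pair intersection of their segment sets, keeping
fragments ≥ 10 kb.

## Association and trait statistics

Kinship is the VanRaden genomic relationship (centered dosage cross-product
over Σ2p(1−p), mean-imputed missing, fixed sites excluded). Population
structure uses the top genotype principal components (default 3; sign fixed
by the largest-magnitude loading). The marker model is the one-variance-
component mixed model y = μ + PCβ + xα + u + e with u ~ N(0, σ²_g K); the
variance ratio is estimated once under the null by maximum likelihood on the
eigenrotated data and reused per marker (P3D), each marker then tested by
GLS with a Wald t-test; with K = I and no PCs this reduces exactly to OLS
regression, which a test asserts to 10⁻⁶. Per-marker re-estimation is
available behind a flag. No multiple-testing correction is applied by
default (the use case is a handful of candidate non-synonymous SNPs);
Bonferroni is a one-liner away.

Group comparisons use an F test of variance equality at 0.05 to choose the
pooled versus Welch two-sample t-test, two-sided, with stars at 0.05/0.01.
Yield traits derive from sample weights: lint % = 100·lint/seed-cotton, lint
index = lint per 100 seeds, seed index = weight of 100 seeds; the identity
lint % = 100·LI/(LI+SI) holds exactly and is property-tested.

## SNP effect annotation

Each site receives exactly one region class — exon (within CDS), intron,
upstream/downstream (within a 2 kb flank, configurable; strand-aware), or
intergenic — with gene bodies taking priority over any other gene's flank.
Coding effects translate the reference and alternate codons under the
standard genetic code: stop_gained/stop_lost when stop status changes,
otherwise synonymous iff the amino acids match. dN/dS is the raw count ratio
(nonsynonymous + stop_gained + stop_lost)/synonymous — the panel-level class
count comparison, not a per-site Nei–Gojobori normalization — and
stop-gained/lost sites are additionally reported as large-effect SNPs.

## Problem sizes and numerical choices

Scan-level tests run at deliberately reduced scale chosen to keep each
statistic well-resolved: 10 Mb chromosomes with 10,000 SNPs for IBD recovery
(window ≈ 0.2 Mb against ≈ 2–3 Mb transmitted segments), a 20 Mb chromosome
at the panel's empirical density of ~90 SNPs per 100 kb for sweep recovery,
and n = 258 accessions for association power (the size of the published
association panel). Empirical quantile thresholds use inclusive ties;
merged-interval arithmetic is exact integer bp; EHH truncation and the 2 Mb
integration radius are stated above. Degenerate inputs (monomorphic markers,
all-missing pairs, empty feature sets, single-parent selfing) are handled
explicitly and tested.

## Known limitations

* The IBD rule is deterministic ratio thresholding, not a probabilistic
  (HMM/likelihood) IBD model; there is no inference of unrecorded parentage.
* Independent-site founders understate background LD; XP-EHH behaviour on
  real data with strong LD will differ quantitatively (the planted-sweep
  contrast remains valid).
* The inbred-line transmission model ignores residual heterozygosity, so
  heterozygous descendants of recorded crosses are not generated under the
  default settings.
* Unphased LD falls back to genotype correlation; no phasing or imputation
  is provided.
* Headline counts of the motivating study (segment counts, sweep counts,
  traceable percentages) are data-dependent and are not reproduction
  targets at synthetic scale; the pipeline's correctness is instead
  established against planted ground truth.
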