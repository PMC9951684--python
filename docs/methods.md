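# Methods

This note records the statistical definitions, model assumptions, numerical
choices and known limitations behind `consroh`. Everything quantitative
below is recomputed by the test suite or by `scripts/acceptance.py`; no
number here is asserted from memory.

## Genotype container and file dialects

All stages operate on a samples × markers dosage matrix over
{0, 1, 2, −1(missing)} counting copies of the *alternate* allele, with a
1-based physical marker map sorted by (chromosome, position) and a breed
label per sample. Because PED files do not name a reference allele, the
alternate allele is pinned as the lexicographically larger allele observed
at the marker; the binary reader applies the same rule to the two BIM
alleles, so both dialects decode identically. One consequence: a marker at
which only the reference allele is observed reads back with dosage 2
rather than 0 — the two encodings are statistically indistinguishable in
PED, and every statistic in the package is invariant to the relabeling
x → 2 − x. Binary files use the standard 2-bit SNP-major coding
(00 hom-A1, 01 missing, 10 het, 11 hom-A2, little-endian within a byte).

QC runs in a fixed order — duplicate (chromosome, position) markers →
non-autosomal markers → individual call rate ≥ 0.95 → SNP call rate ≥ 0.99
— with inclusive thresholds and call rates computed on the axes surviving
the previous stage. The order is pinned because it changes retained
counts. LD pruning slides a 50-SNP window in steps of 5; while any
retained pair in the window has r² > 0.2, the lower-MAF member of the
worst pair is removed (ties: the later map position). Monomorphic markers
have r² defined as 0 and are never pruned. r² is always the squared
Pearson correlation of dosage vectors over pairwise-complete samples
(composite LD, no phasing).

## Diversity partitions

With molecular coancestry per locus f = (x_i x_j + (2−x_i)(2−x_j))/4
averaged over loci called in both individuals (self-coancestry is the same
formula at i = j and equals (1 + homozygosity)/2), let f̄_bb′ be the mean
coancestry between breeds b, b′, the within-breed mean taken over the full
submatrix *including* the diagonal. Then

- HS = 1 − (1/B) Σ_b f̄_bb
- DG = (1/B²) Σ_bb′ [(f̄_bb + f̄_b′b′)/2 − f̄_bb′]
- HT = 1 − (1/B²) Σ_bb′ f̄_bb′

and HT = HS + DG holds algebraically — the code asserts it at 1e-10 and
the tests at 1e-12. Including the diagonal in the within-breed mean is
what makes the identity exact; breed weights are equal (1/B) throughout.
The between-breed component D_bb′ converges to the frequency-based Nei
minimum distance (mean (p_b − p_b′)² over loci) at O(1/n) in the breed
sizes; both are exposed.

Allelic diversity uses rarefied richness: at each locus the rarefaction
size g is the smallest per-breed called-allele count (floored at 2), and a
breed's richness is Σ_alleles [1 − C(2N−N_a, g)/C(2N, g)]. AS is the mean
of richness − 1 over breeds and loci. For DA, an allele is "present after
rarefaction" when its expected rarefied copy number g·N_a/2N exceeds 0.5;
DA is the mean over ordered breed pairs of the per-locus count of alleles
present in the first breed and absent in the second, and AT = AS + DA by
construction. Loci uncallable in any breed at size g are dropped
everywhere and counted. A pooled-richness diagnostic field lets users
compare rarefaction conventions.

Per-breed indices: fii and dii average over ordered pairs of *distinct*
individuals (d_ij = (s_i + s_j)/2 − f_ij), si over the diagonal, and
Gi = dii/(dii + (1 − si)) — the between-individual share of within-breed
diversity, with the decomposition (1 − si) + dii. Under this definition
duplicating every individual shifts fii/dii at O(1/n) (the copy-pairs are
new ordered pairs); only si is exactly exchangeable.

## Conservation priority

Leave-one-out contributions recompute both partitions on each reduced
breed set; percentages are relative to the full-panel value, so positive
means diversity is lost on removal. The decomposition
ΔHT% = ΔHS%·(HS/HT) + ΔDG%·(DG/HT) is exact and tested.

The synthetic pool objective treats the pool as defined by its breed
proportions w = c/N: H(c) = mean over loci of 2p(1−p) at
p = Σ_b w_b p_b, times the finite-pool factor N/(N−1) (the expected
heterozygosity of an N-individual random-mating pool); K(c) = mean over
loci of the expected number of alleles present in 2N pooled gametes,
1−(1−p)^2N + 1−p^2N. Both are concave in w, so the optimizer — simulated
annealing over integer compositions (geometric cooling, best of 10
restarts, proposal moves of up to N/50 units) followed by single-unit
hill climbing, with all pure-breed and uniform compositions always
examined — terminates at the global integer optimum; on 2-breed instances
it matches exhaustive search exactly (tested to N = 200). A flat
landscape (all breeds sharing one frequency vector) short-circuits to the
uniform composition with a warning flag. Loci with a missing frequency in
any breed are excluded from the objective and counted.

## ROH detection

Detection is a direct interval scan, not a sliding-window heuristic, so
every constraint is exact: per individual and chromosome the marker
sequence is split at inter-SNP gaps > 1 Mb; a *feasible* interval contains
at most 1 heterozygous and 2 missing calls; intervals are selected
greedily, longest in bp first (ties: leftmost), each selection excluding
overlaps; selected intervals then pass the minimum-length (1 Mb),
minimum-SNP (100) and density (≥ 0.01 SNP/kb) filters. The implementation
selects iteratively the longest feasible window (a monotone two-pointer
computed with cumulative het/missing counts) over the remaining free
regions, stopping once the best candidate is shorter than the length
filter; this is provably identical to ranking *all* feasible subintervals
by length and picking greedily, which the tests verify against a
brute-force enumerator on random instances. Two consequences worth
knowing: segment boundaries sit on SNP positions, and a stricter
het/missing budget can *split* one long run into two shorter segments —
so segment counts are not monotone in the budgets, while the three
post-selection filters are exactly subset-monotone.

Summaries report per breed SROH (total Mb), NROH (count) and MNROH ± SD
(population SD by default; sample SD by option). Panel aggregation
reports both MNROH conventions (unweighted mean of per-breed means, and
total SROH / total NROH), which differ whenever breeds contribute unequal
segment counts. Incidence is the fraction of all individuals whose ROH
cover each SNP; islands are maximal runs of consecutive SNPs with
incidence strictly > 0.30 (no merging across dips), discarding runs
shorter than 50 SNPs (configurable; counted). The published islands
contain 343–671 SNPs, so the 50-SNP floor only suppresses speckle.

## Annotation overlap

Annotation tables are BED-like 0-based half-open records (gene or QTL,
with a trait class). Islands, which are 1-based inclusive SNP coordinates,
are converted to half-open before querying an interval tree per
chromosome; a record counts when the intersection is ≥ 1 bp (configurable),
once per island. Trait-class percentages are tallied over the distinct QTL
records hit, routed through a user class map with unmapped labels falling
to "other", rounded to 2 decimals.

## LD decay and Ne

Pair distances are binned with narrow bins (500 kb) below a 2000 kb
breakpoint and wide bins (1100 kb) above it; bin units are configurable
and recorded. Ne per bin inverts Sved's relation E[r²] = 1/(1 + 4Ne·c)
after subtracting the 1/n sampling floor: c is the bin midpoint converted
at 3 cM/Mb (the chicken genome-wide average: a ~1100 Mb genome with a
2600–3800 cM map), t = 1/(2c) generations, and bins that are empty or at
the sampling floor are reported with a skip reason rather than an
estimate. The round-trip is exact by construction and tested at
Ne ∈ {50, 500, 5000}. This is a deliberately simple, closed-form stand-in
for genetic-algorithm LD-fitting tools: it produces the same qualitative
object (an Ne-per-generation-bin trajectory) while remaining
desk-verifiable; it inherits Sved's assumptions (equilibrium drift-
recombination balance, no admixture or migration) and reports no
confidence intervals.

## Synthetic data generator

The generator is the package's ground truth and emulates a 157-bird,
eight-breed SNP-array panel on a scaled genome (6 autosomes, 240 Mb, 20k
SNPs in the analysis scripts; sizes are configurable and the tests use
smaller ones). Its components:

- **Divergence**: Balding–Nichols — breed frequency ~ Beta with mean p
  (ancestral, uniform on [0.05, 0.95]) and variance F·p(1−p). Expected
  Nei distance between breeds with parameters F_a, F_b is
  (F_a + F_b)·E[p(1−p)] = 0.365·F at F_a = F_b = F, which the recovery
  tests verify within ±15% at 50k SNPs (breed size 200, where the
  O(1/2n) sampling inflation of D̂ is ~1% of the F = 0.05 signal).
- **Autozygosity**: a two-state alternating-exponential mosaic along the
  genetic map (constant 3 cM/Mb), stationary autozygous fraction = the
  target F_ROH, mean autozygous tract 100/(2g) cM with g = 8 generations
  (≈ 2.1 Mb). Tract genotypes are homozygous with the doubled allele drawn
  from the breed frequency; elsewhere Hardy–Weinberg. Exponential tracts
  are memoryless, so starting chromosomes at a segment boundary is the
  stationary process. At g = 8 about 11% of autozygous mass lies in
  sub-1 Mb tracts invisible to detection at the 1 Mb minimum; recovery is
  measured on 24 individuals × 240 Mb at 1 SNP/5 kb, where that intrinsic
  loss (~0.03 absolute at F_ROH = 0.3) dominates the per-individual mosaic
  noise (SD ≈ 0.05 at that genome length) and the ±0.05 recovery band
  holds.
- **Sweeps**: optional regions where each individual independently carries
  an autozygous tract with a given probability — the mechanism that
  produces population-shared ROH islands. The default panel carries five
  such regions with sharing 0.35–0.70, matching a study system in which
  five islands were found with up to ~70% sharing. Without them the >30%
  incidence rule essentially never fires on mosaic ROH alone.
- **Founder-haplotype copying mode** (optional, off by default): K founder
  haplotypes per breed and chromosome, individuals copy two paths whose
  founder index switches at exponential (mean 10 cM) intervals. This
  creates within-breed LD that decays with genetic distance and scales
  like 1/K, so smaller founder pools emulate stronger drift; the monotone
  r²/Ne ordering checks use K ∈ {5, 15, 40}. The default model draws loci
  independently, so it has *no* within-breed LD: LD curves on default
  panels sit at the 1/n sampling floor, which the analysis scripts show as
  a negative control. Passing tests on synthetic data therefore say
  nothing about haplotype-structure effects in real arrays (e.g. PLINK's
  window heuristics interacting with real LD).
- **Missingness** is i.i.d. per call (default 0.005); there is no
  genotyping-batch structure, genotype-error model, sex chromosome or
  pedigree.

Determinism: identical config + seed gives bit-identical datasets; the
pipeline fans one global seed into per-stage seeds via SeedSequence
spawning in a fixed stage order, so toggling a stage never shifts another
stage's randomness.

## Numerical choices and degenerate inputs

- Coancestry/Nei averages are pairwise-complete per locus; a pair (or
  breed pair) sharing no called locus is an error naming the pair.
- A breed with one individual is allowed in the gene-diversity partition
  (its within mean is the self-coancestry); per-breed indices require ≥ 2.
- Gi, MNROH and bin means report NaN markers rather than dividing by zero.
- Rarefaction ratios are computed in log space (gammaln) to avoid
  overflow; impossible absences (n − N_a < g) get presence probability 1.
- The annealing temperature is scaled to the objective magnitude
  (2% of |H| initial), cooling 0.995/step; exactness comes from the
  greedy polish, not the schedule.
- TSV outputs carry a header with version, seed and a config hash that
  excludes the output directory, so identical analyses hash identically.

## Problem sizes

Defaults used by the analysis scripts and acceptance script: 20k SNPs /
240 Mb for the panel stages; 48k SNPs / 240 Mb / 24 individuals for
F_ROH recovery; 50k SNPs / 2 × 200 individuals for divergence recovery;
200 random ≤ 200-SNP instances for the detection oracle; 2-breed pools to
N = 200 for optimizer exactness. These sizes were chosen so each quantity
is dominated by the method under test rather than sampling noise while
the full suite runs in minutes on one CPU.
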