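# Methods

## Data model

All nuclear analyses operate on a `SiteMatrix`: biallelic sites ×
samples, one haploid call per cell (0/1/missing), sorted by
(chromosome, position), 1-based fully-closed coordinates.  Pseudo-haploid
calls emulate sampling a single sequencing read per site, the standard
representation for low-coverage ancient genomes; consequently every
frequency in the package is a *derived-allele frequency among non-missing
haploid calls*, each sample contributing exactly one allele.  The same
convention defines MAF for filtering.  Missing genotype tokens `0 0` and
`N N` in transposed-PLINK input are treated identically; discordant
non-missing token pairs are corrupt input and abort with the site and
sample named.  Sites with more than two observed alleles are rejected at
read time with a logged warning — multi-allelic handling upstream of the
caller output cannot be reconstructed from the files, so rejection is the
only safe behaviour.

Polarization recodes calls so code 0 is the outgroup (ancestral) allele;
sites whose ancestral state is unknown or matches neither allele are
dropped and counted.  CpG flags are carried as input annotations: a
helper can derive them from a reference (site + next base, or previous
base + site, equal to CG), but the flag is data, not inference.  Site
filters apply in a fixed order — whitelist, CpG, transversion,
minimum-called, MAF — each logging its drop count, so filter provenance
is reconstructible from the log.

Resampling blocks are contiguous 5 Mb windows by default:
`block = floor((pos − 1) / 5e6)` within each chromosome, densified so
only non-empty blocks carry indices.  Five megabases comfortably exceeds
the scale of linkage disequilibrium in goat-like genomes, making block
resampling a valid correction for the non-independence of neighbouring
sites.

## D and extended D

Classic D uses frequency-weighted pattern counts,
`nABBA += (1−p₁)p₂p₃` and `nBABA += p₁(1−p₂)p₃` per site, which reduce to
0/1 pattern counts for single genomes.  Sites with any of the three
H-sets entirely missing contribute nothing.  The default uncertainty for
classic D is a weighted delete-one-block jackknife (Busing-style, block
weights equal to the block's pattern-count total) — the common choice for
D statistics; D_ex defaults to a block bootstrap with 1000 replicates.
Both estimators are available for both statistics.  Bootstrap replicate
*b* draws blocks with a generator seeded `seed + b`, so results are
reproducible and independent of replicate execution order.  Blocks with
zero informative weight are excluded from resampling rather than
resampled as structural zeros; a zero SE yields an undefined (NaN) Z with
a warning rather than an infinite score.

D_ex ascertainment retains a site when (a) H3 carries the derived allele
— for an H3 *group* the default demands all non-missing calls derived,
the conservative reading of "derived in" a population, with an
any-derived toggle; (b) every conditioning group and the root outgroup
group has at least one non-missing call ("covered at least once" — an
uncovered group cannot certify absence); and (c) the derived allele is at
frequency 0 in all conditioning groups (strict mode), or at frequency 0
in the root group and within (low, high] — default (0, 0.10] — in at
least one conditioning group (window mode).  Whether window mode should
also cap the remaining groups is genuinely ambiguous; the default
constrains only the qualifying group, and an all-groups-≤high toggle is
provided.  H1/H2 contributions are frequency-weighted per site.  This
choice avoids the coverage-driven bias of raw observation counts (deeper
samples would otherwise dominate a group) and reduces exactly to 0/1
counts for single genomes.

Disentangling restricts window-mode retained sites to those where the
target carries the derived allele, then counts each conditioning
individual's derived calls.  Two denominators are emitted — the number of
shared-variant sites (default) and the total sharing observations summed
over individuals — because either normalization is defensible; the
per-site proportion is more interpretable per individual, the
per-observation one sums to 1 across a heatmap row.  The proportions
remain sensitive to per-individual coverage, which is why the raw counts
and non-missing denominators are always reported alongside.

## IBS, neighbour joining, supports, MDS

IBS distance is the mismatch proportion over co-called sites, per-pair
deletion (a pair is compared wherever both are called, regardless of
other samples).  Pairs with zero co-called sites are undefined; a matrix
containing such pairs is rejected before tree building with the pairs
listed.  Neighbour joining follows the canonical Saitou–Nei algorithm: Q
minimization, ties broken deterministically by the lowest index pair in
current matrix order, standard branch-length updates, final three-taxon
trifurcation.  Negative branch lengths — a normal NJ artefact on noisy
matrices — are clamped to zero with a warning.  Trees are scikit-bio
`TreeNode`s, so newick serialization, rooting on an outgroup, and
bipartition operations use standard machinery; an independent cross-check
against `ape::nj()` in R runs in the test suite.

Node supports come from a region pseudo-bootstrap: each replicate samples
a fixed number (default 50) of distinct 5 Mb blocks without replacement,
recomputes IBS and NJ on their sites, and each internal edge of the
all-sites base tree receives the percentage of replicate trees containing
its bipartition.  Supports are computed on unrooted bipartitions, so the
rooting choice cannot alter them.  Classical MDS is Torgerson scaling
(double-centred squared distances, top-k eigenpairs, eigenvector ×
√eigenvalue); axis signs are fixed by making each axis's
largest-magnitude loading positive, and negative eigenvalues among the
top k (non-Euclidean input) warn and contribute zero.  Outgroup-distance
QC flags samples whose distance to the designated outgroup exceeds their
group peers' mean ± 3 sd — inflated outgroup distance is the signature of
per-sample error in this data type.

## mtDNA differences

Pairwise differences on aligned consensus sequences skip any column where
either sequence is N; alignment gaps are treated as missing by default
(toggle available), since consensus callers emit N for uncovered sites
and gap columns are alignment artefacts.  Group summaries are means of
*raw difference counts* over all unordered within-group pairs — not
per-site rates — matching how such numbers are conventionally quoted;
the compared-site count is reported per pair so rates can be derived.
Label exclusions (e.g. a low-coverage consensus called with relaxed
depth) are applied before pairing.

## Synthetic data

The generator is a Balding–Nichols drift cascade, not a coalescent: per
site, a root derived-allele frequency is drawn Uniform(0.05, 0.95), then
each branch of the population tree draws the child frequency from
Beta(p(1−F)/F, (1−p)(1−F)/F) with branch-specific drift F (F = 0 copies
the parent; fixation is absorbing).  A ghost lineage is just another
leaf; admixture replaces the target population's frequency with
(1−α)·local + α·ghost, genome-wide or within one region.  Observation
noise mirrors pseudo-haploid calling: one Bernoulli(frequency) allele per
sample per site, flipped with the per-call error rate, masked at one
minus the call rate.  Sites carry random ts/tv identity (transition
fraction 2/3, the genomic norm) and CpG flags; matrices are emitted in
random A/B allele orientation so polarization is genuinely exercised.
All randomness flows from the single scenario seed; outputs are
byte-reproducible.

What this emulates: drift-induced population structure, lineage-private
variation, admixture, missingness and call error.  What it does not:
linkage disequilibrium within blocks (sites are independent given the
frequencies), reference bias, post-mortem damage profiles, and
coalescent site-frequency-spectrum shape.  Passing tests therefore
validate the *statistics* — their formulas, calibration and resampling —
under a clean generative model, not robustness to every artefact of real
ancient-DNA data.  A coalescent backend (e.g. msprime) could be slotted
in behind the same interface without changing any consumer.

Preset scenarios define the package's reference study conditions:

* `null_panmictic` — one population, 16 samples carved into H1/H2/H3,
  two conditioning groups and a root group; 5 × 10⁵ sites over ten 100 Mb
  chromosomes (200 five-megabase blocks), call rate 0.9, error 10⁻³.
  Every test statistic has expectation 0 here; the preset measures false
  positive rates.
* `tur_like_ghost` — root outgroup population (drift 0.3), a wild clade
  containing a strongly drifted ghost lineage (F = 0.35) sister to a
  two-population pair, and an ingroup clade (bezoar-like + two domestic
  populations), with α = 0.1 ghost ancestry flowing into one domestic
  population; 10⁶ sites, 200 blocks.  The heavy ghost drift models a
  long-isolated Pleistocene lineage and gives the ascertainment a strong
  supply of lineage-private derived alleles; one ghost sample serves as
  H3 while five others are held out so the ghost population itself can be
  added to the conditioning set (the specificity control).  Problem sizes
  are chosen so one replicate simulates and analyses in a few seconds,
  standing in for a whole-genome dataset at desk scale.
* `introgressed_block` — same topology with α = 0.8 confined to the
  first 5 Mb of one chromosome, emulating a near-fixed introgressed
  haplotype; used to validate region-restricted IBS source assignment.

The mtDNA simulator drops Poisson-distributed Jukes–Cantor substitutions
along a supplied tree (multiple hits allowed) from a uniform-random root
sequence and N-masks each leaf independently, emulating patchy consensus
coverage.  The acceptance script's mtDNA scenario contrasts a tight
matriline (pairwise distance 10⁻⁴ substitutions/site) with a diverse
clade (4 × 10⁻³) on a 16.5 kb genome — the two regimes a within- versus
between-haplogroup comparison produces.

## Numerical and design notes

* Jackknife: weighted delete-one formula; with equal block weights it
  reduces to the textbook delete-one jackknife (verified in tests against
  the bootstrap).
* Bootstrap SE uses the sample standard deviation (ddof = 1) of replicate
  statistics; replicates with zero resampled counts are dropped.
* Undefined statistics are errors or NaN-with-warning, never silent
  zeros: zero informative sites raise, zero SE yields NaN Z, zero shared
  sites yield a NaN attribution row.
* Determinism: simulation, bootstrap and pseudo-bootstrap are pure
  functions of their seeds; the pipeline manifest records sha256
  checksums so identical config + seed reproduces identical files.
* The `run` pipeline validates its whole config (unknown keys rejected)
  before any computation; exit codes distinguish validation (2) from
  runtime (1) failures.

## Known limitations

* No linkage within simulated blocks: pseudo-bootstrap support values on
  simulated data are optimistic relative to real genomes with long-range
  LD.
* Frequency-weighted group D assumes samples within a group are
  exchangeable; structured groups would need per-sample tests.
* The IBS matrix is dense in memory (fine for hundreds of samples, not
  for biobank scale).
* mtDNA group means are raw counts and therefore depend on alignment
  length and coverage; they are comparable only within one alignment.
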