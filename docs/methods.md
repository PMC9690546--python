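# Methods notes

## The problem

A closed studbook breed is a genetic cluster with a fuzzy edge. Two
practical decisions recur: whether a candidate animal falls inside the
cluster, and which registered members sit near its edge. `breedgate`
scores both with simple, auditable statistics computed from genome-wide
SNP genotypes, anchored by two individuals: the *central animal* (the
reference-population member with the maximal summed IBS similarity to
everyone else) at score 0, and a designated *outgroup* (the single
closest animal of the nearest related breed) at score 1. Scores are not
probabilities; they are standardized positions on the axis running from
the breed's core to its border.

## Scoring models and assumptions

**IBS-central.** Pairwise IBS over pairwise-complete loci:
`(n_IBS2 + 0.5 n_IBS1) / n_complete`, PLINK's distance convention.
Sums include every animal currently in the matrix (candidates and the
outgroup too); a strict RP-only summing mode is available
(`rp_only_sums=True`). The published delta `IBS_sum − IBS_max_of_sums`
is nonpositive; we store its magnitude so scores are nonnegative and the
printed 0-to-1 orientation holds. Scores above 1 are possible for
animals less similar to the population than the outgroup and are
deliberately not clamped. Ties for the central animal are broken by
earliest matrix order and logged. Insertion of a new animal adds one
row/column; existing pairwise values are carried over bitwise unchanged
(they are constants of a pair), and all sums and scores are rebuilt.

**PCA-distance.** Classical principal coordinates of the IBS
*similarity* matrix: double-center, eigendecompose, keep the top k
eigenvalues (k = 3 by default — the visual analyses this mirrors plot
components 1–3), coordinates = eigenvectors × √eigenvalue so Euclidean
distances respect the similarity structure (a raw-eigenvector mode
exists; the original analysis suite's scaling convention is not
documented, so ours is a declared choice). Negative eigenvalues are
clipped to zero. The reference point is the component-wise median over
RP members only (even-sized RP: midpoint of the two middle values);
candidates never move it. There is no out-of-sample projection — every
assignment step re-embeds the current animal set, so all coordinates and
scores legitimately change step to step.

**Assignment comparator.** Per biallelic marker with `x` copies of the
candidate-carried allele among `n` reference alleles, the posterior
predictive under a uniform Dirichlet prior (K = 2) is the Pólya urn:
first copy `(x + 1/2)/(n + 1)`, second copy `(x' + 1/2 + [same])/(n + 2)`,
heterozygotes doubled. The three genotype probabilities sum to 1 for any
count table (tested). The Monte-Carlo null draws genotypes from the
*observed* RP allele frequencies (not the posterior), matching the
classic exclusion-simulation practice; the inclusion probability is the
add-one rank `(1 + #{sim ≤ candidate})/(n_sim + 1)`, which cannot return
an exact 0 or 1 at finite `n_sim` — printed exact zeros in comparable
software are an artifact of its unreported simulation count, so they are
not a target here. Candidates already inside the RP are scored
leave-one-out (their own alleles removed from the counts). Within one
dilution/protocol column all candidates share one simulated null (common
random numbers), so ranks are comparable across candidates. Simulated
genotypes are complete; a candidate with missing calls is compared on
its covered loci only — at the simulation sizes used here the bias is
negligible and the synthetic experiments have no missingness.

## Marker panel construction

Per-marker Fst is the frequency-based Wright/Nei two-group form,
`(H_T − H_S)/H_T` with `H_S = (2p_a(1−p_a) + 2p_b(1−p_b))/2`. The screen
contrasts the focal breed against all non-excluded breeds pooled (a
per-breed-minimum mode exists behind a flag); ties at the threshold are
retained (≥). LD pruning is greedy in map order within chromosomes:
a marker is dropped if its squared Pearson correlation of dosages
(composite/genotypic LD, phase-free) with any already-kept marker on the
same chromosome reaches the threshold. No window is applied by default
because post-screen panels are small; a window flag exists for large
inputs. Undefined LD (monomorphic among complete pairs) is treated as
unlinked and logged. Comparisons are deliberately *within chromosome*:
breed-informative markers are mutually correlated genome-wide through
population structure itself, and pruning on that signal would empty the
panel rather than remove physical linkage.

Merging two datasets intersects marker ids, harmonizes swapped allele
order by flipping dosage (`g → 2 − g`), rejects incompatible allele
sets (strand flips are not guessed — the use case is two chip versions
of one assay), and then drops markers whose combined call rate is not
strictly above 0.95.

## Artificial admixture

Mosaic genomes are assembled over the *serial order* of panel markers
(sorted by chromosome, then position, numbered across chromosome ends):
an ordered schedule of (source, block length) pairs fills the genome,
e.g. 24 sources × 38 markers + one 12-marker remainder on a 924-marker
panel. Dilution series replace `⌊f·L + 0.5⌋` markers of a target with
one donor's calls (half-up rounding makes the 10 % grid exact), in
38-marker blocks, either as a leading prefix or — the default — spaced
evenly across the panel, since real backcross admixture is genome-wide.
Appended genomes carry breed label `ADMIX` so they can never silently
enter reference statistics.

## The synthetic study world

`synth_breeds.simulate_breeds` is a Balding–Nichols generator: per
marker an ancestral frequency is uniform on (0.05, 0.5); each breed's
frequency is Beta-distributed with mean p and variance F·p(1−p);
genotypes are binomial(2). No LD, no families, no selection — LD-pruning
tests plant explicit duplicated/flipped markers instead.

`paper_like_fixture` reproduces the *operating regime* of the study
design end to end, not just its sample counts:

- 70-member focal breed and five 10-member distant breeds, all at
  F = 0.25 from the common ancestor — the strong differentiation typical
  of closed dog breeds;
- a 6-member sister breed founded as a 70/30 frequency mixture of the
  focal breed's realised frequencies and one distant breed, plus
  F = 0.03 of subsequent drift. A sister breed emulated by pure small
  drift is statistically invisible at individual level (its members land
  *inside* the focal score distribution and cannot anchor the border);
  founding by crossbreeding is both the actual history of the system
  this models and what produces the observed geometry — sister breed
  adjacent to, but outside, the focal cloud;
- panel selection is run *inside* the fixture: a 100k-marker pool is
  reduced by the package's own Fst ≥ 0.4 screen + LD pruning to a
  ~800-marker informative panel (the study scale: 924 from 145k). All
  scoring happens on informative panels in this design; random markers
  do not reproduce its behaviour;
- the outgroup is the sister-breed member with the highest mean IBS to
  the focal cohort, on the panel;
- four focal members are rewritten as 20–40 % mosaics with sister-breed
  donors at randomly placed 38-marker blocks, standing in for the
  genetically peripheral purebreds every real breed contains.

What passing tests on this fixture show: the scores separate planted
admixture from ordinary purebred variation (planted animals rank top-4
of 70 under both scores across seeds), the anchors are exact, dilution
drives both scores up and inclusion probability down. What they do not
show: behaviour under real LD, family structure, genotyping artifacts,
or multi-source historic admixture.

## Expanding-RP protocol

The RP seeds with the first 30 candidates; each step admits a batch of 2
and re-evaluates everyone from scratch. For the score methods each table
column holds the post-admission single-shot evaluation at that RP
composition (a new member's first score appears in the column whose RP
contains it, matching the published table layout); for the comparator
method the batch is evaluated *before* admission — a member cannot be
ranked against a null fitted to counts containing itself, and the
controls are re-scored each step. Controls (outgroup + admixed
artificials) are scored in every column and never join the RP or move
the median/central animal. Thresholds (0.6 for PCA-distance, 0.4 for
IBS-central by default) only annotate output; nothing is auto-excluded.
30 + 40 candidates at batch 2 give 20 steps and 21 columns. Step
numbering is contiguous (a published variant of this table skips a step
number; we do not reproduce the skip).

Polar export writes (radius = score, angle = golden-angle by score rank,
color band per 0.2-wide intervals with the outgroup its own band) —
angles are presentation only and deterministic.

## Numerical conventions and degenerate inputs

- IBS similarity is computed numerator-first (`(n − 0.5·Σ|Δg|)/n`), which
  is bitwise identical to a per-locus counter; the matrix build uses
  three integer-valued matmuls rather than a pair loop.
- A pair with zero complete loci, an outgroup whose IBS sum equals the
  central animal's, or an outgroup sitting exactly on the RP median are
  explicit errors, never silent NaNs.
- An all-equal similarity matrix embeds to all-zero coordinates and is
  flagged degenerate.
- Component signs are fixed (largest-magnitude entry positive) so
  embeddings are reproducible; scores are sign- and order-invariant by
  construction.
- Genotypes are stored as int8 allele-B dosages with −1 for missing;
  PED/MAP files written by the package carry the two alleles as extra
  MAP columns so round trips are exact. Standard 4-column MAP files are
  accepted, with alleles inferred from the PED body.

## Known limitations

- The Balding–Nichols world mixes ancestry linearly, so a diluted copy
  of a peripheral animal approaches the outgroup's radius from inside
  (0.97–1.00 at 90 % dilution) but does not overshoot it; the over-the-
  border excursions reported on real data arise from structure (LD,
  family relationships, multi-source ancestry) this generator
  deliberately omits.
- Fst uses sample allele frequencies without small-sample moment
  corrections; at n = 50 per group the upward bias is ≈ 1/(2n), visible
  in the undifferentiated-limit test.
- No VCF import, no phasing, no haplotype-based LD, no kinship/IBD — out
  of scope by design.
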