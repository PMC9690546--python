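# breedgate

SNP-based scoring of the genetic boundary of a breed: given genome-wide
genotypes of a reference population (RP) of registered purebreds, one
designated *outgroup* animal from the closest related breed, and a stream
of candidate animals, `breedgate` answers the question registries actually
ask — *does this animal belong inside the breed, and how far from its core
does it sit?*

It was built for the dog-breed setting (a closed studbook breed, a sister
breed created by historical crossbreeding, and a panel of unrelated
breeds), but nothing in it is species-specific.

## Methods

Three complementary assignment statistics are implemented, all operating
on diploid biallelic SNP dosages:

- **IBS-central** — compute the pairwise identity-by-state matrix
  (IBS = (n_IBS2 + ½·n_IBS1)/n loci compared). Each animal is
  characterised by the sum of its row, `IBS_sum`; the RP member with the
  maximal sum (`IBS_max_of_sums`) is the *central animal*, the breed's
  most representative genome. Scores are the normalised shortfall

      score_i = (IBS_max_of_sums − IBS_sum_i) / (IBS_max_of_sums − IBS_sum_outgroup)

  so the central animal scores exactly 0 and the outgroup exactly 1.
  Pairwise values are constants of a pair, so inserting a new animal only
  adds one row/column — but every sum, and possibly the identity of the
  central animal, changes.

- **PCA-distance** — classical principal-coordinate embedding of the IBS
  matrix (double-centering + eigendecomposition, coordinates scaled by
  √eigenvalue, k = 3 components by default). The reference point is the
  component-wise *median* of the RP members; each animal's Euclidean
  distance to it is divided by the outgroup's distance, anchoring the
  breed border at 1. The embedding is recomputed at every assignment
  step — coordinates legitimately shift as the RP grows.

- **Rannala–Mountain / Paetkau comparator** — the classic Bayesian
  assignment computation: per marker, the candidate's two allele copies
  are drawn from the Pólya-urn posterior of the RP allele counts under a
  uniform prior, and the multilocus log-likelihood is ranked within a
  Monte-Carlo null of genotypes simulated from the observed RP allele
  frequencies, yielding an inclusion probability in (0, 1).

Around these sit the supporting stages of the full workflow: PED/MAP and
TSV genotype I/O with call-rate-filtered dataset merging; construction of
breed-informative marker panels (per-marker Wright/Nei Fst screen at
≥ 0.4 against the pooled other breeds, then greedy composite-LD pruning
at r² ≥ 0.5 within chromosomes); artificial admixed genomes (block
mosaics over the marker serial order and donor-dilution series on a 10 %
grid); a Balding–Nichols multi-breed simulator so the entire pipeline is
testable without access-restricted real genotypes; and the expanding-RP
assignment protocol with TSV and polar "dotted ball" exports.

## Worked example

```python
from breedgate.synth_breeds import paper_like_fixture
from breedgate.ibs_central import pairwise_ibs, central_scores
from breedgate.pca_distance import reassess_with_candidates

# study-shaped synthetic data: 70-member focal breed, a 6-member sister
# breed (one of which is the outgroup), 5 distant breeds, and four focal
# members planted as 20-40% admixture mosaics
ds, focal, outgroup = paper_like_fixture(seed=1)

rp = ds.breed_members(focal)
ibs = pairwise_ibs(ds, rp + [outgroup])
tab = central_scores(ibs, rp, outgroup)
```

which prints, via the inspection snippet in the docstrings:

```
panel: 790 markers, 126 animals; outgroup: HWV4
central animal: HSV61  (score 0.000)
outgroup score: 1.000
  most divergent: HSV35  IBS-central 0.516
  most divergent: HSV24  IBS-central 0.350
  most divergent: HSV44  IBS-central 0.345
  most divergent: HSV36  IBS-central 0.300
PCA-distance of HSV35: 0.689
```

The four highest-scoring animals are exactly the four planted mosaics:
ordinary purebreds score ≈ 0–0.3, admixed animals push toward the
outgroup anchor at 1. The same pipeline is scriptable from the shell:

```
breedgate simulate --seed 1 --out-prefix data/sim
breedgate select-markers --ped raw.ped --map raw.map --focal-breed HSV \
    --exclude-breed HWV --fst-min 0.4 --ld-max 0.5 --out-prefix data/panel
breedgate protocol --ped data/panel.ped --map data/panel.map \
    --rp-breed HSV --outgroup HWV4 --method pca_distance --out table.tsv
breedgate polar --table table.tsv --column 70 --out polar.tsv
```

## Layout

```
src/breedgate/
  io_genotypes.py     PED/MAP + TSV I/O, merge, subset, call rates
  marker_selection.py Fst screen + composite-LD pruning
  admix_sim.py        block mosaics, dilution series
  ibs_central.py      IBS matrix, central scores, insertion updates
  pca_distance.py     principal-coordinate embedding + distance scores
  assignment_rm.py    Rannala-Mountain likelihood, Paetkau inclusion
  synth_breeds.py     Balding-Nichols simulator, study-shaped fixture
  cli_report.py       expanding-RP protocol, polar export, CLI
docs/methods.md       modelling notes, conventions, limitations
```
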