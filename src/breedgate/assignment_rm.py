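"""Bayesian population-assignment comparator: genotype likelihood and
Monte-Carlo inclusion probability.

This reimplements the classic assignment computation the field runs
through GeneClass2: a candidate's multilocus genotype likelihood under
the Rannala–Mountain Bayesian model of the reference population's
allele frequencies, and the Paetkau-style exclusion simulation that
turns the likelihood into an inclusion probability.

Per biallelic marker the model draws the candidate's two allele copies
from the Dirichlet (here Beta, K = 2) posterior of the reference
allele frequencies under a uniform prior — a Pólya urn.  With ``x``
copies of an allele among ``n`` reference alleles:

    P(first copy is that allele)            = (x + 1/2) / (n + 1)
    P(second copy, given the first)         = (x' + 1/2 + [same]) / (n + 2)

with heterozygotes doubled for the two orderings.  The three genotype
probabilities sum to one for any count table.

The inclusion probability is the rank of the candidate's log-likelihood
within ``n_sim`` genotypes simulated from the observed reference allele
frequencies: near 0 means exclusion (almost every simulated purebred
fits better), near 1 a central fit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from breedgate.io_genotypes import MISSING, GenotypeDataset


@dataclass
class AlleleCountTable:
    """Reference allele-B counts and total non-missing allele counts."""

    marker_ids: list[str]
    count_b: np.ndarray
    total: np.ndarray

    def __post_init__(self) -> None:
        self.count_b = np.asarray(self.count_b, dtype=np.int64)
        self.total = np.asarray(self.total, dtype=np.int64)
        if ((self.count_b < 0) | (self.count_b > self.total)).any():
            raise ValueError("allele counts must satisfy 0 <= count_b <= total")

    @classmethod
    def from_dataset(
        cls,
        ds: GenotypeDataset,
        rp_ids: Sequence[str],
        leave_out: str | None = None,
    ) -> "AlleleCountTable":
        """Tally reference alleles, optionally removing one member's own
        alleles (leave-one-out for candidates already inside the RP)."""
        ids = [s for s in rp_ids if s != leave_out]
        if not ids:
            raise ValueError("reference population is empty after leave-one-out")
        calls = ds.calls[[ds.sample_index(s) for s in ids]]
        present = calls != MISSING
        return cls(
            marker_ids=list(ds.marker_ids),
            count_b=np.where(present, calls, 0).sum(axis=0),
            total=2 * present.sum(axis=0),
        )


@dataclass(frozen=True)
class InclusionResult:
    candidate_id: str
    log_likelihood: float
    inclusion_probability: float
    n_sim: int
    seed: int


def genotype_log_probs(counts: AlleleCountTable) -> np.ndarray:
    """Per-marker log-probabilities of dosages 0, 1, 2 — shape (L, 3).

    Pólya-urn posterior predictive with a uniform (1/2, 1/2) prior over
    the two alleles; rows always sum to one in probability.
    """
    x = counts.count_b.astype(float)
    n = counts.total.astype(float)
    x_a = n - x
    p0 = (x_a + 0.5) / (n + 1) * (x_a + 1.5) / (n + 2)
    p2 = (x + 0.5) / (n + 1) * (x + 1.5) / (n + 2)
    p1 = 2.0 * (x + 0.5) / (n + 1) * (x_a + 0.5) / (n + 2)
    return np.log(np.column_stack([p0, p1, p2]))


def rm_genotype_loglik(candidate_calls: np.ndarray, counts: AlleleCountTable) -> float:
    """Rannala–Mountain log-likelihood of one multilocus genotype.

    Missing candidate calls contribute nothing (an all-missing genotype
    has log-likelihood 0, the empty product).
    """
    candidate_calls = np.asarray(candidate_calls)
    if candidate_calls.shape[0] != len(counts.marker_ids):
        raise ValueError("candidate call vector length does not match the count table")
    logp = genotype_log_probs(counts)
    ok = candidate_calls != MISSING
    if not ok.any():
        return 0.0
    return float(logp[np.flatnonzero(ok), candidate_calls[ok].astype(np.intp)].sum())


def simulate_purebred_logliks(
    counts: AlleleCountTable, n_sim: int, rng: np.random.Generator
) -> np.ndarray:
    """Log-likelihoods of ``n_sim`` genotypes drawn from the observed
    reference allele frequencies (the Paetkau resampling null).

    Markers with no reference data (total = 0) are skipped, mirroring a
    candidate that cannot be scored there.
    """
    informative = counts.total > 0
    x = counts.count_b[informative].astype(float)
    n = counts.total[informative].astype(float)
    freq = x / n
    logp = genotype_log_probs(counts)[informative]
    dosages = rng.binomial(2, freq, size=(n_sim, freq.size))
    return logp[np.arange(freq.size), dosages].sum(axis=1)


def paetkau_inclusion(
    candidate_id: str,
    ds: GenotypeDataset,
    rp_ids: Sequence[str],
    n_sim: int = 10_000,
    seed: int = 0,
) -> InclusionResult:
    """Monte-Carlo inclusion probability of one candidate against an RP.

    If the candidate is itself a reference-population member its own
    alleles are removed from the counts first (leave-one-out).  The
    probability is the add-one rank estimator
    ``(1 + #{simulated <= candidate}) / (n_sim + 1)``, which never
    returns an exact 0 or 1 at finite ``n_sim``.
    """
    if n_sim < 1:
        raise ValueError("n_sim must be >= 1")
    counts = AlleleCountTable.from_dataset(
        ds, rp_ids, leave_out=candidate_id if candidate_id in rp_ids else None
    )
    cand = ds.calls_for(candidate_id)
    informative = counts.total > 0
    masked = cand.copy()
    masked[~informative] = MISSING
    loglik = rm_genotype_loglik(masked, counts)
    rng = np.random.default_rng(seed)
    sims = simulate_purebred_logliks(counts, n_sim, rng)
    rank = int((sims <= loglik).sum())
    return InclusionResult(
        candidate_id=candidate_id,
        log_likelihood=loglik,
        inclusion_probability=(1 + rank) / (n_sim + 1),
        n_sim=n_sim,
        seed=seed,
    )
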