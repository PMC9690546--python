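"""Pairwise identity-by-state similarity and the IBS-central score.

The IBS-central method characterises each animal by the sum of its
pairwise IBS similarities to everyone else in the matrix (``ibs_sum``).
The reference-population member with the maximal sum is the *central
animal* — the genome most similar to all others, the breed's most
representative individual.  Scores are the shortfall from that maximum,
normalised so the central animal sits at 0 and the designated outgroup
(the closest animal of the nearest related breed, marking the breed
boundary) sits at 1:

    score_i = (IBS_max_of_sums - IBS_sum_i) / (IBS_max_of_sums - IBS_sum_outgroup)

Pairwise IBS values are constants of a pair: inserting a new animal
adds one row/column and changes every ``ibs_sum``, but never an
existing pairwise value, so the matrix is grown incrementally.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from breedgate.io_genotypes import MISSING, GenotypeDataset

logger = logging.getLogger(__name__)


@dataclass
class IbsMatrix:
    """Symmetric matrix of pairwise IBS similarities in [0, 1]."""

    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.sample_ids)
        if self.values.shape != (n, n):
            raise ValueError(f"matrix shape {self.values.shape} != ({n}, {n})")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("IBS matrix is not symmetric")
        if (self.values < -1e-12).any() or (self.values > 1 + 1e-12).any():
            raise ValueError("IBS values outside [0, 1]")

    def index(self, sample_id: str) -> int:
        try:
            return self.sample_ids.index(sample_id)
        except ValueError:
            raise KeyError(f"sample {sample_id!r} not in IBS matrix") from None

    def ibs_sums(self) -> np.ndarray:
        """Row sums over the off-diagonal (each animal vs all others)."""
        return self.values.sum(axis=1) - np.diag(self.values)

    def write_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("sample_id\t" + "\t".join(self.sample_ids) + "\n")
            for sid, row in zip(self.sample_ids, self.values):
                fh.write(sid + "\t" + "\t".join(f"{v:.10f}" for v in row) + "\n")


@dataclass
class CentralScoreTable:
    """Per-sample IBS sums and the 0-to-1 normalised central scores."""

    sample_ids: list[str]
    ibs_sum: np.ndarray
    score: np.ndarray
    central_id: str
    outgroup_id: str

    def score_of(self, sample_id: str) -> float:
        return float(self.score[self.sample_ids.index(sample_id)])


def _pair_ibs(row_a: np.ndarray, row_b: np.ndarray) -> float:
    ok = (row_a != MISSING) & (row_b != MISSING)
    n = int(ok.sum())
    if n == 0:
        return np.nan
    diff = np.abs(row_a[ok].astype(np.int16) - row_b[ok].astype(np.int16))
    n_ibs2 = int((diff == 0).sum())
    n_ibs1 = int((diff == 1).sum())
    return (n_ibs2 + 0.5 * n_ibs1) / n


def pairwise_ibs(ds: GenotypeDataset, sample_ids: Sequence[str] | None = None) -> IbsMatrix:
    """Genome-wide pairwise IBS over pairwise-complete markers.

    For a pair of diploid dosage vectors the per-locus state is IBS2
    (identical genotypes), IBS1 (one shared allele, dosage difference
    of 1) or IBS0 (opposite homozygotes); the genome-wide similarity is
    ``(n_IBS2 + 0.5 n_IBS1) / n_complete`` — the fraction of alleles
    shared, matching PLINK's ``--distance ibs`` convention.  A pair
    with no complete marker is an error naming the pair.
    """
    ids = list(sample_ids) if sample_ids is not None else ds.sample_ids
    if len(ids) < 2:
        raise ValueError("need at least 2 samples for a pairwise IBS matrix")
    idx = [ds.sample_index(s) for s in ids]
    calls = ds.calls[idx]
    n = len(ids)

    # vectorised over marker axis: one pass per pair is fine at panel scale,
    # but the dosage trick below does all pairs with three matmuls.
    present = (calls != MISSING)
    g = np.where(present, calls, 0).astype(np.float64)
    p = present.astype(np.float64)
    n_complete = p @ p.T
    if (n_complete[~np.eye(n, dtype=bool)] == 0).any():
        i, j = np.argwhere((n_complete == 0) & ~np.eye(n, dtype=bool))[0]
        raise ValueError(f"pair ({ids[i]}, {ids[j]}) shares no non-missing marker")
    # sum over complete loci of |g_i - g_j| via sum over dosage levels
    absdiff = np.zeros((n, n))
    for level in (0, 1, 2):
        ind = (np.where(present, calls, -9) == level).astype(np.float64)
        gd = np.abs(g - level) * p
        absdiff += ind @ gd.T
    # numerator n_IBS2 + 0.5 n_IBS1 = n_complete - 0.5 * sum|g_i - g_j|;
    # both sides are exact half-integers, so this division is bitwise
    # identical to a per-locus counter
    values = (n_complete - 0.5 * absdiff) / n_complete
    values = np.maximum(values, values.T)
    np.fill_diagonal(values, 1.0)
    return IbsMatrix(sample_ids=ids, values=values)


def central_scores(
    ibs: IbsMatrix,
    rp_ids: Sequence[str],
    outgroup_id: str,
    rp_only_sums: bool = False,
) -> CentralScoreTable:
    """Normalised IBS-central scores for every animal in the matrix.

    By default ``ibs_sum`` is taken over *all* animals in the matrix
    (reference population, co-evaluated candidates and the outgroup
    together — the outgroup earns its anchor by having the smallest sum
    inside the same matrix); ``rp_only_sums=True`` restricts the summed
    columns to reference-population members instead.  The central
    animal is the argmax restricted to ``rp_ids``.  Scores are anchored
    at 0 for the central animal and 1 for the outgroup; an animal even
    less similar to the population than the outgroup scores above 1
    (scores are not clamped).  Ties at the maximal sum are broken by
    earliest matrix order and logged.
    """
    if outgroup_id in rp_ids:
        raise ValueError(f"outgroup {outgroup_id!r} must not be a reference-population member")
    rp_idx = [ibs.index(s) for s in rp_ids]
    out_idx = ibs.index(outgroup_id)
    if rp_only_sums:
        in_rp = np.zeros(len(ibs.sample_ids), dtype=bool)
        in_rp[rp_idx] = True
        sums = ibs.values[:, in_rp].sum(axis=1)
        sums[in_rp] -= np.diag(ibs.values)[in_rp]  # exclude self-similarity
    else:
        sums = ibs.ibs_sums()
    rp_sums = sums[rp_idx]
    best = int(np.argmax(rp_sums))  # argmax takes the first on ties
    if int((rp_sums == rp_sums[best]).sum()) > 1:
        logger.info("tie for central animal; keeping earliest in order: %s", rp_ids[best])
    central_idx = rp_idx[best]
    max_of_sums = sums[central_idx]
    denom = max_of_sums - sums[out_idx]
    if denom <= 0:
        raise ValueError(
            "degenerate normalisation: outgroup IBS sum "
            f"({sums[out_idx]:.6f}) is not below the central animal's ({max_of_sums:.6f})"
        )
    score = (max_of_sums - sums) / denom
    return CentralScoreTable(
        sample_ids=list(ibs.sample_ids),
        ibs_sum=sums,
        score=score,
        central_id=ibs.sample_ids[central_idx],
        outgroup_id=outgroup_id,
    )


def insert_and_rescore(
    ibs: IbsMatrix,
    ds: GenotypeDataset,
    new_id: str,
    rp_ids: Sequence[str],
    outgroup_id: str,
) -> tuple[IbsMatrix, CentralScoreTable]:
    """Grow the matrix by one animal and recompute sums and scores.

    Only the new animal's pairwise values are computed; every existing
    pairwise value is carried over bitwise unchanged.  All ``ibs_sum``
    values change, so the full score table is rebuilt — which can move
    the identity of the central animal.
    """
    if new_id in ibs.sample_ids:
        raise ValueError(f"sample {new_id!r} already in the matrix")
    new_calls = ds.calls_for(new_id)
    n = len(ibs.sample_ids)
    grown = np.empty((n + 1, n + 1))
    grown[:n, :n] = ibs.values
    for i, sid in enumerate(ibs.sample_ids):
        v = _pair_ibs(new_calls, ds.calls_for(sid))
        if np.isnan(v):
            raise ValueError(f"pair ({new_id}, {sid}) shares no non-missing marker")
        grown[n, i] = grown[i, n] = v
    grown[n, n] = 1.0
    new_ibs = IbsMatrix(sample_ids=ibs.sample_ids + [new_id], values=grown)
    return new_ibs, central_scores(new_ibs, rp_ids, outgroup_id)


def write_score_table(
    table: CentralScoreTable, ds: GenotypeDataset, path: str
) -> None:
    """TSV export: sample, breed, ibs_sum, score and anchor flags."""
    breed = dict(ds.samples)
    with open(path, "w") as fh:
        fh.write("sample_id\tbreed\tibs_sum\tscore\tis_central\tis_outgroup\n")
        for sid, s, sc in zip(table.sample_ids, table.ibs_sum, table.score):
            fh.write(
                f"{sid}\t{breed.get(sid, 'NA')}\t{s:.6f}\t{sc:.6f}"
                f"\t{int(sid == table.central_id)}\t{int(sid == table.outgroup_id)}\n"
            )
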