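"""Principal-coordinate embedding of IBS matrices and the PCA-distance score.

Animals are positioned in a low-dimensional space by classical
multidimensional scaling of the pairwise IBS similarity matrix: the
matrix is double-centered (row, column and grand mean removed), the
centered matrix is eigendecomposed, and coordinates are the leading
eigenvectors scaled by the square roots of their eigenvalues.  In that
space the reference point is the component-wise *median* of the
reference-population members, and an animal's standardized score is its
Euclidean distance to that median divided by the outgroup's distance —
so the outgroup always scores exactly 1 and marks the breed border,
while an animal can exceed 1 by lying beyond it.

Because the embedding is recomputed from the actual set of animals,
coordinates (and therefore all scores) legitimately shift at every
assignment step; there is no out-of-sample projection by design.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from breedgate.io_genotypes import GenotypeDataset
from breedgate.ibs_central import IbsMatrix, pairwise_ibs


@dataclass
class Embedding:
    """Per-animal coordinates from the centered-IBS eigendecomposition."""

    sample_ids: list[str]
    coordinates: np.ndarray  # (n_samples, k), columns ordered by eigenvalue
    eigenvalues: np.ndarray  # length k, nonincreasing
    degenerate: bool = False

    def coords_of(self, sample_id: str) -> np.ndarray:
        return self.coordinates[self.sample_ids.index(sample_id)]

    def write_tsv(self, path: str, breeds: dict[str, str] | None = None) -> None:
        k = self.coordinates.shape[1]
        with open(path, "w") as fh:
            fh.write("#eigenvalues\t" + "\t".join(f"{v:.10g}" for v in self.eigenvalues) + "\n")
            fh.write("sample_id\tbreed\t" + "\t".join(f"c{i + 1}" for i in range(k)) + "\n")
            for sid, row in zip(self.sample_ids, self.coordinates):
                b = breeds.get(sid, "NA") if breeds else "NA"
                fh.write(sid + "\t" + b + "\t" + "\t".join(f"{v:.10f}" for v in row) + "\n")


@dataclass
class DistanceScoreTable:
    """Distances to the RP median and outgroup-normalized scores."""

    sample_ids: list[str]
    distance: np.ndarray
    score: np.ndarray
    rp_median: np.ndarray
    outgroup_id: str

    def score_of(self, sample_id: str) -> float:
        return float(self.score[self.sample_ids.index(sample_id)])


def embed_ibs(ibs: IbsMatrix, k: int = 3, scale_by_eigenvalues: bool = True) -> Embedding:
    """Classical principal-coordinate embedding of an IBS matrix.

    Keeps the top ``k`` eigenvalues of the double-centered similarity;
    negative eigenvalues (possible for a non-Euclidean similarity) are
    clipped to zero so the corresponding coordinates vanish.  Component
    signs are fixed so each column's largest-magnitude entry is
    positive.  ``scale_by_eigenvalues=False`` returns raw unit
    eigenvectors instead of the distance-preserving sqrt-eigenvalue
    scaling.  An all-equal matrix yields all-zero coordinates and is
    flagged ``degenerate``.
    """
    n = len(ibs.sample_ids)
    if not 1 <= k <= n - 1:
        raise ValueError(f"k must be in [1, n-1] = [1, {n - 1}], got {k}")
    s = ibs.values
    j = np.eye(n) - np.ones((n, n)) / n
    b = j @ s @ j
    b = 0.5 * (b + b.T)
    w, v = np.linalg.eigh(b)
    order = np.argsort(w)[::-1][:k]
    w, v = w[order], v[:, order]
    degenerate = bool(np.all(np.abs(w) < 1e-12))
    w_pos = np.clip(w, 0.0, None)
    coords = v * np.sqrt(w_pos) if scale_by_eigenvalues else v.copy()
    for col in range(coords.shape[1]):
        i = np.argmax(np.abs(coords[:, col]))
        if coords[i, col] < 0:
            coords[:, col] = -coords[:, col]
    return Embedding(
        sample_ids=list(ibs.sample_ids),
        coordinates=coords,
        eigenvalues=w,
        degenerate=degenerate,
    )


def distance_scores(
    emb: Embedding, rp_ids: Sequence[str], outgroup_id: str
) -> DistanceScoreTable:
    """Standardized distances to the reference-population median.

    The reference point is the component-wise median over ``rp_ids``
    only (an even-sized population uses the midpoint of the two middle
    values); every animal's Euclidean distance to it is divided by the
    outgroup's distance.
    """
    if outgroup_id in rp_ids:
        raise ValueError(f"outgroup {outgroup_id!r} must not be a reference-population member")
    idx = {s: i for i, s in enumerate(emb.sample_ids)}
    missing = [s for s in (*rp_ids, outgroup_id) if s not in idx]
    if missing:
        raise KeyError(f"not embedded: {missing}")
    rp_median = np.median(emb.coordinates[[idx[s] for s in rp_ids]], axis=0)
    dist = np.linalg.norm(emb.coordinates - rp_median, axis=1)
    d_out = dist[idx[outgroup_id]]
    if d_out == 0:
        raise ValueError("degenerate normalisation: outgroup sits exactly at the RP median")
    return DistanceScoreTable(
        sample_ids=list(emb.sample_ids),
        distance=dist,
        score=dist / d_out,
        rp_median=rp_median,
        outgroup_id=outgroup_id,
    )


def reassess_with_candidates(
    ds: GenotypeDataset,
    rp_ids: Sequence[str],
    outgroup_id: str,
    candidate_ids: Sequence[str] = (),
    k: int = 3,
) -> DistanceScoreTable:
    """Full re-embedding pipeline for one assignment step.

    Builds the IBS matrix over reference population, outgroup and
    candidates, embeds it, and scores everyone against the median of
    the reference population alone.  Candidates influence the embedding
    (coordinates shift whenever the animal set changes) but never the
    reference point.
    """
    overlap = set(candidate_ids) & set(rp_ids)
    if overlap:
        raise ValueError(f"candidates already in the reference population: {sorted(overlap)}")
    ids = [*rp_ids, outgroup_id, *candidate_ids]
    ibs = pairwise_ibs(ds, ids)
    emb = embed_ibs(ibs, k=k)
    return distance_scores(emb, rp_ids, outgroup_id)
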