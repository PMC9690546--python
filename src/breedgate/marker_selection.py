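"""Breed-informative SNP panel construction.

Two filters applied in sequence build the panel:

1. **Fst screen** — each marker is scored with a two-group fixation
   index contrasting the focal breed against the pooled remaining
   breeds; markers with Fst below the threshold are dropped.
2. **Composite-LD pruning** — surviving markers are scanned in map
   order per chromosome and any marker whose genotypic (composite)
   r-squared with an already-kept marker on the same chromosome reaches
   the LD threshold is dropped.

The Fst estimator is the frequency-based Wright/Nei two-group form:
with sample allele frequencies ``p_a`` and ``p_b``,
``p_bar = (p_a + p_b)/2``, ``H_T = 2 p_bar (1 - p_bar)``,
``H_S = (2 p_a (1-p_a) + 2 p_b (1-p_b)) / 2`` and
``Fst = (H_T - H_S) / H_T`` — the same marker-level statistic commercial
SNP suites report for a two-population contrast.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from breedgate.io_genotypes import MISSING, GenotypeDataset, subset

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MarkerStats:
    """Per-marker screening result; ``fst`` is ``nan`` when not scorable."""

    marker_id: str
    fst: float
    retained: bool


def _check_groups(ds: GenotypeDataset, group_a: Sequence[str], group_b: Sequence[str]) -> tuple[list[int], list[int]]:
    if not group_a or not group_b:
        raise ValueError("both groups must be non-empty")
    overlap = set(group_a) & set(group_b)
    if overlap:
        raise ValueError(f"groups overlap: {sorted(overlap)}")
    return [ds.sample_index(s) for s in group_a], [ds.sample_index(s) for s in group_b]


def two_group_fst(p_a: float, p_b: float) -> float:
    """Wright/Nei Fst from two allele frequencies; ``nan`` if H_T = 0."""
    p_bar = 0.5 * (p_a + p_b)
    h_t = 2.0 * p_bar * (1.0 - p_bar)
    if h_t == 0.0:
        return math.nan
    h_s = p_a * (1.0 - p_a) + p_b * (1.0 - p_b)
    return (h_t - h_s) / h_t


def _group_freqs(ds: GenotypeDataset, idx: Sequence[int]) -> np.ndarray:
    """Allele-B frequency per marker within one sample group (nan: no calls)."""
    calls = ds.calls[list(idx)]
    present = calls != MISSING
    total = 2.0 * present.sum(axis=0)
    count = np.where(present, calls, 0).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(total > 0, count / total, np.nan)


def per_marker_fst(
    ds: GenotypeDataset,
    group_a: Sequence[str],
    group_b: Sequence[str],
    fst_min: float | None = None,
) -> list[MarkerStats]:
    """Score every marker with the two-group Fst between two sample sets.

    Markers where either group has no calls, or where both groups are
    fixed for the same allele (total heterozygosity zero), are reported
    with ``fst = nan`` and never retained.  When ``fst_min`` is given
    the ``retained`` flag reflects ``fst >= fst_min``; otherwise every
    scorable marker is flagged retained.
    """
    idx_a, idx_b = _check_groups(ds, group_a, group_b)
    p_a, p_b = _group_freqs(ds, idx_a), _group_freqs(ds, idx_b)
    p_bar = 0.5 * (p_a + p_b)
    h_t = 2.0 * p_bar * (1.0 - p_bar)
    h_s = p_a * (1.0 - p_a) + p_b * (1.0 - p_b)
    with np.errstate(divide="ignore", invalid="ignore"):
        fst = np.where(h_t > 0, (h_t - h_s) / h_t, np.nan)
    out: list[MarkerStats] = []
    for m, f in zip(ds.markers, fst):
        f = float(f)
        keep = (not math.isnan(f)) and (fst_min is None or f >= fst_min)
        out.append(MarkerStats(m.marker_id, f, keep))
    return out


def composite_ld_r2(ds: GenotypeDataset, marker_i: str, marker_j: str) -> float:
    """Squared composite-genotypic correlation between two markers.

    The composite measure is the squared Pearson correlation of the two
    dosage vectors over pairwise-complete samples — the standard
    phase-free LD statistic for unphased diploid data.  Returns ``nan``
    (an "undefined LD" signal) when fewer than two complete pairs exist
    or either marker is monomorphic among them.
    """
    ji = ds.marker_ids.index(marker_i) if marker_i in ds.marker_ids else None
    jj = ds.marker_ids.index(marker_j) if marker_j in ds.marker_ids else None
    if ji is None or jj is None:
        raise KeyError(f"unknown marker id: {marker_i if ji is None else marker_j!r}")
    x, y = ds.calls[:, ji].astype(float), ds.calls[:, jj].astype(float)
    ok = (ds.calls[:, ji] != MISSING) & (ds.calls[:, jj] != MISSING)
    return _r2(x[ok], y[ok])


def _r2(x: np.ndarray, y: np.ndarray) -> float:
    if x.size < 2:
        return math.nan
    vx, vy = x.var(), y.var()
    if vx == 0.0 or vy == 0.0:
        return math.nan
    cov = ((x - x.mean()) * (y - y.mean())).mean()
    return float(cov * cov / (vx * vy))


def ld_prune(
    ds: GenotypeDataset,
    marker_ids: Sequence[str],
    ld_max: float = 0.5,
    window: int | None = None,
) -> list[str]:
    """Greedy map-order LD pruning within chromosomes.

    Scans ``marker_ids`` in dataset (map) order; a marker is dropped
    when its composite r-squared with any already-kept marker on the
    same chromosome is ``>= ld_max``.  ``window`` optionally limits the
    comparison to the last ``window`` kept markers (panels after an Fst
    screen are small, so the default compares chromosome-wide).
    Pairs with undefined LD are treated as unlinked and logged.
    """
    pos = {m: j for j, m in enumerate(ds.marker_ids)}
    ordered = sorted(marker_ids, key=lambda m: pos[m])
    kept: list[str] = []
    kept_by_chrom: dict[str, list[int]] = {}
    for mid in ordered:
        j = pos[mid]
        chrom = ds.markers[j].chromosome
        prior = kept_by_chrom.get(chrom, [])
        if window is not None:
            prior = prior[-window:]
        linked = False
        for k in prior:
            x, y = ds.calls[:, j].astype(float), ds.calls[:, k].astype(float)
            ok = (ds.calls[:, j] != MISSING) & (ds.calls[:, k] != MISSING)
            r2 = _r2(x[ok], y[ok])
            if math.isnan(r2):
                logger.debug("undefined LD for pair (%s, %s); treated as unlinked", mid, ds.marker_ids[k])
                continue
            if r2 >= ld_max:
                linked = True
                break
        if not linked:
            kept.append(mid)
            kept_by_chrom.setdefault(chrom, []).append(j)
    return kept


def select_informative(
    ds: GenotypeDataset,
    focal_breed: str,
    excluded_breeds: Sequence[str] = (),
    fst_min: float = 0.4,
    ld_max: float = 0.5,
    per_breed_minimum: bool = False,
) -> GenotypeDataset:
    """Build the breed-informative panel for a focal breed.

    The contrast group pools every breed other than ``focal_breed`` and
    ``excluded_breeds`` (the study design excludes a near-duplicate
    breed from the contrast).  With ``per_breed_minimum=True`` the
    screen instead requires the minimum focal-vs-single-breed Fst to
    clear the threshold.  Raises ``ValueError`` when no marker survives.
    """
    focal = ds.breed_members(focal_breed)
    if not focal:
        raise ValueError(f"focal breed {focal_breed!r} has no members")
    skip = {focal_breed, *excluded_breeds}
    others = [s for s, b in ds.samples if b not in skip]
    if not others:
        raise ValueError("contrast group is empty after exclusions")

    if per_breed_minimum:
        contrast_breeds = sorted({b for _, b in ds.samples if b not in skip})
        fst_mat = np.full((len(contrast_breeds), ds.n_markers), np.nan)
        for bi, breed in enumerate(contrast_breeds):
            stats = per_marker_fst(ds, focal, ds.breed_members(breed))
            fst_mat[bi] = [s.fst for s in stats]
        per_marker = np.nanmin(fst_mat, axis=0)
        with np.errstate(invalid="ignore"):
            screened = [
                m for m, f in zip(ds.marker_ids, per_marker) if not math.isnan(f) and f >= fst_min
            ]
    else:
        stats = per_marker_fst(ds, focal, others, fst_min=fst_min)
        screened = [s.marker_id for s in stats if s.retained]

    n_screen = len(screened)
    panel = ld_prune(ds, screened, ld_max=ld_max) if screened else []
    if not panel:
        raise ValueError(
            f"no marker survives the filters (Fst >= {fst_min}: {n_screen} markers; "
            f"after LD pruning at r2 >= {ld_max}: 0)"
        )
    logger.info("panel: %d markers passed Fst >= %s, %d after LD pruning", n_screen, fst_min, len(panel))
    return subset(ds, marker_ids=panel)


def write_marker_stats(
    ds: GenotypeDataset, stats: Sequence[MarkerStats], path: str
) -> None:
    """TSV export of the screening table (id, map location, fst, retained)."""
    info = {m.marker_id: m for m in ds.markers}
    with open(path, "w") as fh:
        fh.write("marker_id\tchromosome\tposition_bp\tfst\tretained\n")
        for s in stats:
            m = info[s.marker_id]
            fst = "NA" if math.isnan(s.fst) else f"{s.fst:.6f}"
            fh.write(f"{s.marker_id}\t{m.chromosome}\t{m.position_bp}\t{fst}\t{int(s.retained)}\n")
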