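"""Artificial admixed genotypes: block mosaics and dilution series.

Two constructions calibrate the assignment methods:

* a **block mosaic** assembles an artificial genome by walking the
  marker panel in serial order (markers sorted by chromosome and
  position, numbered 1..L across chromosome boundaries) and copying
  consecutive blocks from different source animals — e.g. 24 sources
  contributing 38 markers each plus a 12-marker remainder on a
  924-marker panel;
* a **dilution series** takes one target animal and replaces a growing
  fraction of its genome with a single donor's calls, in fixed-length
  blocks, producing one hybrid per requested fraction.

Blocks are defined on marker serial positions, not base pairs, so a
block may span the end of one chromosome and the start of the next.
Appended animals carry the breed label ``ADMIX`` so they can never
slip into reference-population statistics unnoticed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from breedgate.io_genotypes import GenotypeDataset

ADMIX_BREED = "ADMIX"

DEFAULT_FRACTIONS = tuple(round(0.1 * i, 1) for i in range(10))  # 0.0 .. 0.9


@dataclass(frozen=True)
class MosaicSchedule:
    """Ordered (source sample, block length) pairs covering a panel."""

    blocks: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        for src, n in self.blocks:
            if n < 1:
                raise ValueError(f"block for {src!r} has non-positive length {n}")

    @property
    def total_markers(self) -> int:
        return sum(n for _, n in self.blocks)

    @classmethod
    def even_blocks(cls, sources: Sequence[str], block_len: int, n_markers: int) -> "MosaicSchedule":
        """Equal blocks for all sources but the last, which takes the rest."""
        if block_len * (len(sources) - 1) >= n_markers:
            raise ValueError("block_len too large for the panel")
        blocks = [(s, block_len) for s in sources[:-1]]
        blocks.append((sources[-1], n_markers - block_len * (len(sources) - 1)))
        return cls(tuple(blocks))

    @classmethod
    def read_tsv(cls, path: str | Path) -> "MosaicSchedule":
        blocks = []
        for line in Path(path).read_text().splitlines():
            if not line.strip() or line.startswith(("step", "#")):
                continue
            _, src, n = line.split("\t")
            blocks.append((src, int(n)))
        return cls(tuple(blocks))

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("step\tsource_sample_id\tn_markers\n")
            for i, (src, n) in enumerate(self.blocks, start=1):
                fh.write(f"{i}\t{src}\t{n}\n")


@dataclass(frozen=True)
class DilutionSpec:
    """How to dilute one target genome with one donor genome.

    ``strategy="interleaved"`` (default) spaces the replaced blocks
    evenly across the panel, emulating genome-wide admixture;
    ``"prefix"`` replaces the leading serial positions instead.
    ``block_len`` defaults to 38 markers, the block grain of the mosaic
    construction.
    """

    target_sample_id: str
    donor_sample_id: str
    strategy: str = "interleaved"
    block_len: int = 38

    def __post_init__(self) -> None:
        if self.strategy not in ("prefix", "interleaved"):
            raise ValueError(f"unknown strategy {self.strategy!r}")
        if self.block_len < 1:
            raise ValueError("block_len must be positive")


def build_mosaic(ds: GenotypeDataset, schedule: MosaicSchedule, new_id: str) -> GenotypeDataset:
    """Append one mosaic genome assembled block-wise from the schedule.

    The call at serial position ``k`` (1-based, chromosome-then-position
    order) is copied from the schedule block covering ``k``.  The block
    lengths must sum exactly to the panel size.
    """
    if schedule.total_markers != ds.n_markers:
        raise ValueError(
            f"schedule covers {schedule.total_markers} markers, panel has {ds.n_markers}"
        )
    calls = np.empty(ds.n_markers, dtype=np.int8)
    at = 0
    for src, n in schedule.blocks:
        calls[at : at + n] = ds.calls_for(src)[at : at + n]
        at += n
    return ds.with_sample(new_id, ADMIX_BREED, calls)


def n_replaced(fraction: float, n_markers: int) -> int:
    """Half-up rounding of ``fraction * n_markers`` (exact on the 10% grid)."""
    return int(np.floor(fraction * n_markers + 0.5))


def _donor_positions(n_markers: int, n_donor: int, block_len: int, strategy: str) -> np.ndarray:
    """Serial indices (0-based) whose calls come from the donor."""
    if n_donor == 0:
        return np.empty(0, dtype=np.intp)
    if strategy == "prefix":
        return np.arange(n_donor, dtype=np.intp)
    # interleaved: whole blocks spaced evenly across the serial order,
    # trailing partial block to hit the exact count
    n_blocks = int(np.ceil(n_donor / block_len))
    starts = np.floor(np.linspace(0, n_markers - block_len, n_blocks)).astype(np.intp)
    chosen: list[int] = []
    taken = np.zeros(n_markers, dtype=bool)
    remaining = n_donor
    for s in starts:
        for pos in range(s, min(s + block_len, n_markers)):
            if remaining == 0:
                break
            if not taken[pos]:
                taken[pos] = True
                chosen.append(pos)
                remaining -= 1
    # overlapping blocks can leave a shortfall; fill from the first free slots
    if remaining:
        for pos in range(n_markers):
            if not taken[pos]:
                taken[pos] = True
                chosen.append(pos)
                remaining -= 1
                if remaining == 0:
                    break
    return np.sort(np.array(chosen, dtype=np.intp))


def dilute(
    ds: GenotypeDataset, spec: DilutionSpec, fraction: float, new_id: str
) -> GenotypeDataset:
    """Append one diluted copy of the target at the given donor fraction."""
    if not 0.0 <= fraction <= 1.0:
        raise ValueError(f"fraction must be in [0, 1], got {fraction}")
    target = ds.calls_for(spec.target_sample_id).copy()
    donor = ds.calls_for(spec.donor_sample_id)
    pos = _donor_positions(ds.n_markers, n_replaced(fraction, ds.n_markers), spec.block_len, spec.strategy)
    target[pos] = donor[pos]
    return ds.with_sample(new_id, ADMIX_BREED, target)


def dilution_series(
    ds: GenotypeDataset,
    spec: DilutionSpec,
    fractions: Sequence[float] = DEFAULT_FRACTIONS,
    id_pattern: str = "{target}_d{pct:02d}",
) -> GenotypeDataset:
    """Append one diluted copy of the target per requested fraction.

    Sample ids follow ``id_pattern`` with ``target``, ``donor`` and
    ``pct`` (percent, rounded) fields available.
    """
    out = ds
    for f in fractions:
        sid = id_pattern.format(
            target=spec.target_sample_id, donor=spec.donor_sample_id, pct=round(100 * f)
        )
        out = dilute(out, spec, f, sid)
    return out


def donor_marker_count(ds: GenotypeDataset, new_id: str, target_id: str) -> int:
    """Number of calls in ``new_id`` that differ from the target row."""
    return int((ds.calls_for(new_id) != ds.calls_for(target_id)).sum())
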