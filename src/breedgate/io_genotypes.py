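"""Genotype dataset container and PLINK-text / TSV input-output.

Genotypes are stored as allele-B dosages: each call is the number of
copies of ``allele_b`` carried at a biallelic marker, i.e. an integer in
``{0, 1, 2}``, with :data:`MISSING` (-1) for no-calls.  Dosage coding is
what every downstream computation (IBS similarity, Fst, composite LD,
assignment likelihoods) consumes directly; allele letters only matter at
the file boundary.

Markers are kept sorted by (chromosome, position).  Chromosome labels
are opaque text ordered by a natural-numeric sort, so "2" < "10" and
"chr2" < "chr10"; no species-specific chromosome table is assumed.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

MISSING: int = -1
"""Sentinel dosage for a missing genotype call."""

_NUC = ("A", "C", "G", "T")


class PlinkParseError(ValueError):
    """Raised when a PED or MAP file cannot be parsed; names the line."""


def _natural_key(label: str) -> tuple:
    """Sort key splitting digit runs so 'chr2' orders before 'chr10'."""
    parts = re.split(r"(\d+)", str(label))
    return tuple(int(p) if p.isdigit() else p for p in parts)


@dataclass(frozen=True)
class MarkerInfo:
    """A biallelic SNP: identifier, map location and the two alleles."""

    marker_id: str
    chromosome: str
    position_bp: int
    allele_a: str
    allele_b: str

    def __post_init__(self) -> None:
        if self.position_bp < 0:
            raise ValueError(f"{self.marker_id}: negative position {self.position_bp}")
        if self.allele_a == self.allele_b:
            raise ValueError(f"{self.marker_id}: alleles must differ, got {self.allele_a!r} twice")


@dataclass
class GenotypeDataset:
    """Sample-by-marker matrix of diploid dosage calls with breed labels.

    Parameters
    ----------
    samples
        Ordered ``(sample_id, breed)`` pairs.
    markers
        Ordered :class:`MarkerInfo` records, sorted by (chromosome,
        position); the constructor sorts them (and the call columns)
        if they are not.
    calls
        ``(n_samples, n_markers)`` integer matrix of allele-B dosages,
        values in ``{0, 1, 2}`` or :data:`MISSING`.
    """

    samples: list[tuple[str, str]]
    markers: list[MarkerInfo]
    calls: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.samples), len(self.markers)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.samples)} samples x {len(self.markers)} markers"
            )
        ids = [s for s, _ in self.samples]
        if len(set(ids)) != len(ids):
            dupes = sorted({s for s in ids if ids.count(s) > 1})
            raise ValueError(f"duplicate sample_id(s): {dupes}")
        mids = [m.marker_id for m in self.markers]
        if len(set(mids)) != len(mids):
            dupes = sorted({m for m in mids if mids.count(m) > 1})
            raise ValueError(f"duplicate marker_id(s): {dupes}")
        bad = ~np.isin(self.calls, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError(f"invalid dosage values: {np.unique(self.calls[bad])}")
        order = sorted(
            range(len(self.markers)),
            key=lambda i: (_natural_key(self.markers[i].chromosome), self.markers[i].position_bp),
        )
        if order != list(range(len(self.markers))):
            self.markers = [self.markers[i] for i in order]
            self.calls = self.calls[:, order]

    # -- convenience views -------------------------------------------------

    @property
    def sample_ids(self) -> list[str]:
        return [s for s, _ in self.samples]

    @property
    def breeds(self) -> list[str]:
        return [b for _, b in self.samples]

    @property
    def marker_ids(self) -> list[str]:
        return [m.marker_id for m in self.markers]

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def sample_index(self, sample_id: str) -> int:
        try:
            return self.sample_ids.index(sample_id)
        except ValueError:
            raise KeyError(f"unknown sample_id {sample_id!r}") from None

    def breed_members(self, breed: str) -> list[str]:
        """Sample ids carrying the given breed label, in dataset order."""
        return [s for s, b in self.samples if b == breed]

    def calls_for(self, sample_id: str) -> np.ndarray:
        return self.calls[self.sample_index(sample_id)]

    def with_sample(self, sample_id: str, breed: str, calls: np.ndarray) -> "GenotypeDataset":
        """Return a copy with one extra sample appended."""
        calls = np.asarray(calls, dtype=np.int8).reshape(1, -1)
        return GenotypeDataset(
            samples=self.samples + [(sample_id, breed)],
            markers=list(self.markers),
            calls=np.vstack([self.calls, calls]),
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeDataset):
            return NotImplemented
        return (
            self.samples == other.samples
            and self.markers == other.markers
            and np.array_equal(self.calls, other.calls)
        )


@dataclass(frozen=True)
class CallRateReport:
    """Fraction of non-missing calls per marker and per sample."""

    per_marker_rate: np.ndarray
    per_sample_rate: np.ndarray


def call_rates(ds: GenotypeDataset) -> CallRateReport:
    present = ds.calls != MISSING
    with np.errstate(invalid="ignore"):
        return CallRateReport(
            per_marker_rate=present.mean(axis=0) if ds.n_samples else np.zeros(ds.n_markers),
            per_sample_rate=present.mean(axis=1) if ds.n_markers else np.zeros(ds.n_samples),
        )


# ---------------------------------------------------------------------------
# PLINK text files
#
# PED: FID IID PAT MAT SEX PHENO  a1 a2  a1 a2 ...   (FID carries the breed)
# MAP: CHROM MARKER_ID CM POS [ALLELE_A ALLELE_B]
#
# The two allele columns appended to MAP rows make the dosage coding
# self-describing, so write -> read round-trips exactly.  Standard
# 4-column MAP files are accepted: alleles are then inferred from the
# PED body (lexicographically smaller allele becomes allele_a).
# ---------------------------------------------------------------------------


def read_plink_text(ped_path: str | Path, map_path: str | Path) -> GenotypeDataset:
    """Read a whitespace-delimited PED/MAP pair into a dataset.

    Missing genotypes are the allele pair ``0 0``.  The family-ID column
    of the PED is interpreted as the breed label.
    """
    map_path, ped_path = Path(map_path), Path(ped_path)
    raw_markers: list[tuple[str, str, int, str | None, str | None]] = []
    for lineno, line in enumerate(map_path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        f = line.split()
        if len(f) not in (4, 6):
            raise PlinkParseError(f"{map_path}:{lineno}: expected 4 or 6 columns, got {len(f)}")
        try:
            pos = int(f[3])
        except ValueError:
            raise PlinkParseError(f"{map_path}:{lineno}: bad position {f[3]!r}") from None
        a, b = (f[4], f[5]) if len(f) == 6 else (None, None)
        raw_markers.append((f[1], f[0], pos, a, b))

    n_markers = len(raw_markers)
    samples: list[tuple[str, str]] = []
    allele_rows: list[list[tuple[str, str]]] = []
    for lineno, line in enumerate(ped_path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        f = line.split()
        if len(f) < 6 or (len(f) - 6) % 2:
            raise PlinkParseError(
                f"{ped_path}:{lineno}: expected 6 + 2*n_markers columns, got {len(f)}"
            )
        if (len(f) - 6) // 2 != n_markers:
            raise PlinkParseError(
                f"{ped_path}:{lineno}: {(len(f) - 6) // 2} genotype pairs but "
                f"{n_markers} MAP rows"
            )
        samples.append((f[1], f[0]))
        allele_rows.append([(f[6 + 2 * k], f[7 + 2 * k]) for k in range(n_markers)])

    ids = [s for s, _ in samples]
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate sample_id(s) in {ped_path}")

    markers: list[MarkerInfo] = []
    calls = np.full((len(samples), n_markers), MISSING, dtype=np.int8)
    for j, (mid, chrom, pos, a, b) in enumerate(raw_markers):
        observed = sorted({al for row in allele_rows for al in row[j] if al != "0"})
        if a is None:
            if len(observed) > 2:
                raise PlinkParseError(f"marker {mid}: more than two alleles {observed}")
            if len(observed) == 2:
                a, b = observed
            elif len(observed) == 1:
                a = observed[0]
                b = next(n for n in _NUC if n != a)
            else:
                a, b = "A", "B"
        markers.append(MarkerInfo(mid, chrom, pos, a, b))
        for i, row in enumerate(allele_rows):
            a1, a2 = row[j]
            if a1 == "0" or a2 == "0":
                continue
            if a1 not in (a, b) or a2 not in (a, b):
                raise PlinkParseError(
                    f"marker {mid}, sample {samples[i][0]}: alleles {a1}/{a2} "
                    f"not in ({a},{b})"
                )
            calls[i, j] = (a1 == b) + (a2 == b)
    return GenotypeDataset(samples=samples, markers=markers, calls=calls)


def write_plink_text(ds: GenotypeDataset, ped_path: str | Path, map_path: str | Path) -> None:
    """Write a dataset as a PED/MAP pair readable by :func:`read_plink_text`."""
    with open(map_path, "w") as fh:
        for m in ds.markers:
            fh.write(f"{m.chromosome}\t{m.marker_id}\t0\t{m.position_bp}\t{m.allele_a}\t{m.allele_b}\n")
    coding = [
        {0: (m.allele_a, m.allele_a), 1: (m.allele_a, m.allele_b), 2: (m.allele_b, m.allele_b), MISSING: ("0", "0")}
        for m in ds.markers
    ]
    with open(ped_path, "w") as fh:
        for i, (sid, breed) in enumerate(ds.samples):
            fields = [breed, sid, "0", "0", "0", "-9"]
            for j in range(ds.n_markers):
                fields.extend(coding[j][int(ds.calls[i, j])])
            fh.write(" ".join(fields) + "\n")


# ---------------------------------------------------------------------------
# TSV genotype matrix (samples x markers)
# ---------------------------------------------------------------------------


def write_tsv(ds: GenotypeDataset, path: str | Path) -> None:
    """Tabular export: sample_id, breed, then one dosage column per marker.

    Missing calls are written as ``NA``.  A commented header block keeps
    the marker map so the file reads back losslessly.
    """
    with open(path, "w") as fh:
        for m in ds.markers:
            fh.write(f"#marker\t{m.marker_id}\t{m.chromosome}\t{m.position_bp}\t{m.allele_a}\t{m.allele_b}\n")
        fh.write("sample_id\tbreed\t" + "\t".join(ds.marker_ids) + "\n")
        for i, (sid, breed) in enumerate(ds.samples):
            row = ["NA" if c == MISSING else str(int(c)) for c in ds.calls[i]]
            fh.write(f"{sid}\t{breed}\t" + "\t".join(row) + "\n")


def read_tsv(path: str | Path) -> GenotypeDataset:
    path = Path(path)
    markers: list[MarkerInfo] = []
    samples: list[tuple[str, str]] = []
    rows: list[list[int]] = []
    header: list[str] | None = None
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if line.startswith("#marker\t"):
            _, mid, chrom, pos, a, b = line.split("\t")
            markers.append(MarkerInfo(mid, chrom, int(pos), a, b))
            continue
        f = line.rstrip("\n").split("\t")
        if header is None:
            header = f
            if f[:2] != ["sample_id", "breed"]:
                raise PlinkParseError(f"{path}:{lineno}: bad header")
            continue
        samples.append((f[0], f[1]))
        rows.append([MISSING if v == "NA" else int(v) for v in f[2:]])
    if header is None:
        raise PlinkParseError(f"{path}: empty file")
    by_id = {m.marker_id: m for m in markers}
    ordered = [by_id[mid] for mid in header[2:]]
    return GenotypeDataset(samples=samples, markers=ordered, calls=np.array(rows, dtype=np.int8))


# ---------------------------------------------------------------------------
# Subsetting and merging
# ---------------------------------------------------------------------------


def subset(
    ds: GenotypeDataset,
    sample_ids: Sequence[str] | None = None,
    marker_ids: Sequence[str] | None = None,
) -> GenotypeDataset:
    """Restrict to the requested samples/markers, preserving dataset order.

    ``None`` keeps everything on that axis.  Unknown ids raise ``KeyError``.
    """
    if sample_ids is None:
        s_idx = list(range(ds.n_samples))
    else:
        pos = {s: i for i, s in enumerate(ds.sample_ids)}
        missing = [s for s in sample_ids if s not in pos]
        if missing:
            raise KeyError(f"unknown sample_id(s): {missing}")
        keep = set(sample_ids)
        s_idx = [i for i, s in enumerate(ds.sample_ids) if s in keep]
    if marker_ids is None:
        m_idx = list(range(ds.n_markers))
    else:
        pos = {m: i for i, m in enumerate(ds.marker_ids)}
        missing = [m for m in marker_ids if m not in pos]
        if missing:
            raise KeyError(f"unknown marker_id(s): {missing}")
        keep = set(marker_ids)
        m_idx = [i for i, m in enumerate(ds.marker_ids) if m in keep]
    return GenotypeDataset(
        samples=[ds.samples[i] for i in s_idx],
        markers=[ds.markers[i] for i in m_idx],
        calls=ds.calls[np.ix_(s_idx, m_idx)],
    )


def merge_intersect(
    ds_a: GenotypeDataset, ds_b: GenotypeDataset, min_call_rate: float = 0.95
) -> GenotypeDataset:
    """Merge two datasets on their shared markers with a call-rate filter.

    Keeps only marker_ids present in both datasets.  Allele coding is
    harmonized: when the two datasets list the same two alleles in
    swapped order, dosages from the second dataset are flipped
    (``g -> 2 - g``); incompatible allele sets are an error (strand
    flips are rejected, not guessed).  After joining samples, markers
    whose combined call rate is not strictly above ``min_call_rate``
    are dropped.
    """
    clash = set(ds_a.sample_ids) & set(ds_b.sample_ids)
    if clash:
        raise ValueError(f"sample_id collision between datasets: {sorted(clash)}")
    b_pos = {m: i for i, m in enumerate(ds_b.marker_ids)}
    shared = [m for m in ds_a.marker_ids if m in b_pos]
    if not shared:
        raise ValueError("no shared markers between the two datasets")
    a_pos = {m: i for i, m in enumerate(ds_a.marker_ids)}

    offenders = []
    flip = {}
    for mid in shared:
        ma, mb = ds_a.markers[a_pos[mid]], ds_b.markers[b_pos[mid]]
        if (ma.allele_a, ma.allele_b) == (mb.allele_a, mb.allele_b):
            flip[mid] = False
        elif (ma.allele_a, ma.allele_b) == (mb.allele_b, mb.allele_a):
            flip[mid] = True
        else:
            offenders.append(f"{mid}: ({ma.allele_a},{ma.allele_b}) vs ({mb.allele_a},{mb.allele_b})")
    if offenders:
        raise ValueError("incompatible allele sets for marker(s): " + "; ".join(offenders))

    cols_a = ds_a.calls[:, [a_pos[m] for m in shared]]
    cols_b = ds_b.calls[:, [b_pos[m] for m in shared]].copy()
    flip_mask = np.array([flip[m] for m in shared])
    if flip_mask.any():
        block = cols_b[:, flip_mask]
        block[block != MISSING] = 2 - block[block != MISSING]
        cols_b[:, flip_mask] = block
    calls = np.vstack([cols_a, cols_b])
    rate = (calls != MISSING).mean(axis=0)
    keep = rate > min_call_rate
    merged = GenotypeDataset(
        samples=ds_a.samples + ds_b.samples,
        markers=[ds_a.markers[a_pos[m]] for m, k in zip(shared, keep) if k],
        calls=calls[:, keep],
    )
    return merged
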