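"""Fragments, genomic regions, and V-plot construction.

A V-plot summarizes paired-end fragments around a locus as a 2-D histogram:
genomic position of the fragment midpoint (x, 5-bp bins over a 640-bp
window by default) against fragment length (y, 10-bp bins up to 640 bp).
Nucleosome-protected fragments trace the characteristic "V" around dyads,
while short fragments pile up over nucleosome-free regions.  All
coordinates are 0-based half-open (BED convention); the fragment position
statistic is the midpoint.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import h5py
import numpy as np
import pandas as pd


@dataclass(frozen=True)
class Fragment:
    """One sequenced paired-end insert."""

    chrom: str
    start: int
    end: int

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(
                f"fragment start must be < end, got [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return self.start + self.length // 2


class Fragments:
    """A column-oriented fragment collection (vectorized midpoint/length)."""

    def __init__(self, chrom: np.ndarray, start: np.ndarray, end: np.ndarray):
        self.chrom = np.asarray(chrom, dtype=object)
        self.start = np.asarray(start, dtype=np.int64)
        self.end = np.asarray(end, dtype=np.int64)
        if np.any(self.start >= self.end):
            bad = int(np.argmax(self.start >= self.end))
            raise ValueError(
                f"fragment {bad}: start {self.start[bad]} >= end {self.end[bad]}")

    def __len__(self) -> int:
        return len(self.start)

    def __iter__(self) -> Iterator[Fragment]:
        for c, s, e in zip(self.chrom, self.start, self.end):
            yield Fragment(str(c), int(s), int(e))

    def __getitem__(self, idx) -> "Fragments":
        return Fragments(self.chrom[idx], self.start[idx], self.end[idx])

    @property
    def length(self) -> np.ndarray:
        return self.end - self.start

    @property
    def midpoint(self) -> np.ndarray:
        return self.start + self.length // 2

    @classmethod
    def from_fragments(cls, frags: Iterable[Fragment]) -> "Fragments":
        frags = list(frags)
        return cls(np.array([f.chrom for f in frags], dtype=object),
                   np.array([f.start for f in frags], dtype=np.int64),
                   np.array([f.end for f in frags], dtype=np.int64))

    @classmethod
    def empty(cls) -> "Fragments":
        return cls(np.array([], dtype=object), np.array([], dtype=np.int64),
                   np.array([], dtype=np.int64))

    def to_bed(self, path) -> None:
        opener = gzip.open if str(path).endswith(".gz") else open
        with opener(path, "wt") as fh:
            for c, s, e in zip(self.chrom, self.start, self.end):
                fh.write(f"{c}\t{s}\t{e}\n")


@dataclass(frozen=True)
class GenomicRegion:
    """A fixed-width analysis window; ``center`` is the anchored site."""

    chrom: str
    start: int
    end: int

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError("region start must be < end")

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> int:
        return self.start + self.width // 2

    @classmethod
    def around(cls, chrom: str, center: int, window_bp: int = 640) -> "GenomicRegion":
        """Window of ``window_bp`` anchored so ``center`` is the midpoint."""
        half = window_bp // 2
        return cls(chrom, center - half, center - half + window_bp)


@dataclass(frozen=True)
class VPlotConfig:
    """Binning geometry of the V-plot.

    ``W = window_bp / genomic_bin_bp`` genomic bins along the window and
    ``H = max_fragment_bp / size_bin_bp`` fragment-size bins; defaults give
    the 128 x 64 grid (640-bp window, 5-bp genomic bins, 10-bp size bins).
    """

    window_bp: int = 640
    genomic_bin_bp: int = 5
    size_bin_bp: int = 10
    max_fragment_bp: int = 640

    def __post_init__(self):
        if self.window_bp % self.genomic_bin_bp:
            raise ValueError("window_bp must be divisible by genomic_bin_bp")
        if self.max_fragment_bp % self.size_bin_bp:
            raise ValueError("max_fragment_bp must be divisible by size_bin_bp")

    @property
    def W(self) -> int:
        return self.window_bp // self.genomic_bin_bp

    @property
    def H(self) -> int:
        return self.max_fragment_bp // self.size_bin_bp


@dataclass
class VPlot:
    """Binned V-plot of one region in one sample.

    ``counts`` is the raw W x H histogram; ``density`` normalizes each
    genomic-bin column (the H-vector at fixed genomic bin) to sum to one,
    leaving empty columns at zero.
    """

    region: GenomicRegion
    counts: np.ndarray
    sample_id: int = 0
    density: np.ndarray = field(init=False)
    n_reads: int = field(init=False)

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.float64)
        self.density = normalize_vplot(self.counts)
        self.n_reads = int(self.counts.sum())


def read_fragments(path, format: str | None = None) -> Fragments:
    """Read a BED3+ or BEDPE fragment file (plain or gzip).

    BEDPE rows collapse to the outer span of the two mates:
    ``(chrom1, min(start1, start2), max(end1, end2))``.  ``format`` defaults
    to BEDPE when a row has >= 6 columns with integer mate coordinates,
    else BED.
    """
    opener = gzip.open if str(path).endswith(".gz") else open
    chroms: list[str] = []
    starts: list[int] = []
    ends: list[int] = []
    with opener(path, "rt") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(
                    f"{path}: line {lineno}: expected >= 3 tab-separated "
                    f"columns, got {len(parts)}")
            try:
                s1, e1 = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(
                    f"{path}: line {lineno}: non-integer coordinate") from exc
            fmt = format
            if fmt is None:
                fmt = "BEDPE" if (len(parts) >= 6 and _is_int(parts[4])
                                  and _is_int(parts[5])) else "BED"
            if fmt.upper() == "BEDPE":
                if len(parts) < 6:
                    raise ValueError(
                        f"{path}: line {lineno}: BEDPE needs >= 6 columns")
                try:
                    s2, e2 = int(parts[4]), int(parts[5])
                except ValueError as exc:
                    raise ValueError(
                        f"{path}: line {lineno}: non-integer coordinate") from exc
                start, end = min(s1, s2), max(e1, e2)
            else:
                start, end = s1, e1
            if start >= end:
                raise ValueError(
                    f"{path}: line {lineno}: start {start} >= end {end}")
            chroms.append(parts[0])
            starts.append(start)
            ends.append(end)
    return Fragments(np.array(chroms, dtype=object),
                     np.array(starts, dtype=np.int64),
                     np.array(ends, dtype=np.int64))


def _is_int(s: str) -> bool:
    try:
        int(s)
        return True
    except ValueError:
        return False


def make_vplot(fragments: Fragments, region: GenomicRegion,
               config: VPlotConfig = VPlotConfig(), sample_id: int = 0) -> VPlot:
    """Bin fragments into the region's V-plot.

    A fragment contributes one count when its midpoint lies in
    ``[region.start, region.end)`` and its length is within
    ``[1, max_fragment_bp]``; genomic bin ``i = (midpoint - start) //
    genomic_bin_bp``, size bin ``j = (length - 1) // size_bin_bp``.
    """
    if region.width != config.window_bp:
        raise ValueError(
            f"region width {region.width} != configured window "
            f"{config.window_bp}")
    counts = np.zeros((config.W, config.H), dtype=np.float64)
    if len(fragments):
        mid = fragments.midpoint
        length = fragments.length
        keep = ((fragments.chrom == region.chrom)
                & (mid >= region.start) & (mid < region.end)
                & (length >= 1) & (length <= config.max_fragment_bp))
        if keep.any():
            i = (mid[keep] - region.start) // config.genomic_bin_bp
            j = (length[keep] - 1) // config.size_bin_bp
            np.add.at(counts, (i, j), 1.0)
    return VPlot(region=region, counts=counts, sample_id=sample_id)


def normalize_vplot(counts: np.ndarray) -> np.ndarray:
    """Normalize each genomic-bin column to sum to one; empty columns stay 0."""
    counts = np.asarray(counts, dtype=np.float64)
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    sums = counts.sum(axis=-1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        density = np.where(sums > 0, counts / np.where(sums > 0, sums, 1.0), 0.0)
    return density


def aggregate_vplots(vplots: Sequence[VPlot] | Sequence[np.ndarray],
                     use_counts: bool = False) -> np.ndarray:
    """Elementwise mean matrix across V-plots (densities by default)."""
    if len(vplots) == 0:
        raise ValueError("cannot aggregate an empty collection")
    if isinstance(vplots[0], VPlot):
        mats = [vp.counts if use_counts else vp.density for vp in vplots]
    else:
        mats = [np.asarray(m) for m in vplots]
    shapes = {m.shape for m in mats}
    if len(shapes) != 1:
        raise ValueError(f"inconsistent V-plot shapes: {shapes}")
    return np.mean(mats, axis=0)


def fragment_size_profile(source, config: VPlotConfig = VPlotConfig()) -> np.ndarray:
    """Fragment-size density over the H size bins (sums to one).

    ``source`` may be a :class:`Fragments` collection, a single
    :class:`VPlot`, or a sequence of V-plots; V-plot totals are summed over
    the genomic axis before normalizing.
    """
    if isinstance(source, Fragments):
        length = source.length
        keep = (length >= 1) & (length <= config.max_fragment_bp)
        j = (length[keep] - 1) // config.size_bin_bp
        totals = np.bincount(j, minlength=config.H).astype(np.float64)
    else:
        vplots = [source] if isinstance(source, VPlot) else list(source)
        if len(vplots) == 0:
            raise ValueError("empty input")
        mats = [vp.counts if isinstance(vp, VPlot) else np.asarray(vp)
                for vp in vplots]
        totals = np.sum([m.sum(axis=0) for m in mats], axis=0).astype(np.float64)
    mass = totals.sum()
    if mass <= 0:
        raise ValueError("no fragments in the valid size range")
    return totals / mass


def build_vplot_matrix(fragments: Fragments, regions: Sequence[GenomicRegion],
                       config: VPlotConfig = VPlotConfig()) -> tuple[np.ndarray, np.ndarray]:
    """Counts for many regions at once: ``(n_regions, W, H)`` plus per-region
    read totals.  Fragments are bucketed by midpoint once, so this scales to
    thousands of regions."""
    n = len(regions)
    counts = np.zeros((n, config.W, config.H), dtype=np.float64)
    if len(fragments) == 0:
        return counts, np.zeros(n, dtype=np.int64)
    mid = fragments.midpoint
    length = fragments.length
    ok = (length >= 1) & (length <= config.max_fragment_bp)
    order = np.argsort(mid[ok], kind="stable")
    mid_s = mid[ok][order]
    len_s = length[ok][order]
    chrom_s = fragments.chrom[ok][order]
    for r, region in enumerate(regions):
        lo = np.searchsorted(mid_s, region.start, side="left")
        hi = np.searchsorted(mid_s, region.end, side="left")
        if hi <= lo:
            continue
        sel = slice(lo, hi)
        same = chrom_s[sel] == region.chrom
        i = (mid_s[sel][same] - region.start) // config.genomic_bin_bp
        j = (len_s[sel][same] - 1) // config.size_bin_bp
        np.add.at(counts[r], (i, j), 1.0)
    return counts, counts.sum(axis=(1, 2)).astype(np.int64)


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def save_vplots(path, counts: np.ndarray, regions: Sequence[GenomicRegion],
                sample_ids: Sequence[int], config: VPlotConfig) -> None:
    """Write a stack of V-plots ``(n_regions, S, W, H)`` to an HDF5 container."""
    counts = np.asarray(counts)
    with h5py.File(path, "w") as f:
        f.create_dataset("counts", data=counts, compression="gzip")
        f.create_dataset("density", data=normalize_vplot(counts),
                         compression="gzip")
        f.create_dataset("region_chrom",
                         data=np.array([r.chrom for r in regions], dtype="S32"))
        f.create_dataset("region_start", data=[r.start for r in regions])
        f.create_dataset("region_end", data=[r.end for r in regions])
        f.create_dataset("sample_ids", data=list(sample_ids))
        for k, v in vars(config).items():
            f.attrs[k] = v


def load_vplots(path):
    """Read back a V-plot container; returns (counts, regions, sample_ids, config)."""
    with h5py.File(path, "r") as f:
        counts = f["counts"][...]
        regions = [GenomicRegion(c.decode(), int(s), int(e))
                   for c, s, e in zip(f["region_chrom"][...],
                                      f["region_start"][...],
                                      f["region_end"][...])]
        sample_ids = list(f["sample_ids"][...])
        config = VPlotConfig(**{k: int(f.attrs[k]) for k in
                                ("window_bp", "genomic_bin_bp", "size_bin_bp",
                                 "max_fragment_bp")})
    return counts, regions, sample_ids, config
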