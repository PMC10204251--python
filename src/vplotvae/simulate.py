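"""Synthetic paired-end fragment generator with known chromatin ground truth.

A synthetic contig carries a regularly spaced nucleosome array (dyads every
~200 bp with 10% jitter) interrupted by nucleosome-free regions (NFRs)
carved out at random positions.  Fragments are drawn from a four-class
mixture mirroring the canonical ATAC-seq fragment-size groups:

* NFR reads: lengths < 100 bp, truncated-exponential, midpoints uniform
  inside an NFR interval;
* mono-nucleosome reads: lengths 180-247 bp, centered on a dyad;
* di-nucleosome reads: lengths 315-473 bp, centered between two adjacent
  dyads;
* tri-nucleosome reads: lengths 558-615 bp, centered on the middle of
  three consecutive dyads.

Nucleosomal midpoints get Gaussian positional jitter.  Per-sample mixture
weights and class length parameters emulate batch-specific fragment-size
profiles; the dyad/NFR map is the ground truth used by the benchmarks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .vplots import Fragments

# canonical fragment-size groups (bp)
NFR_RANGE = (20, 100)
MONO_RANGE = (180, 247)
DI_RANGE = (315, 473)
TRI_RANGE = (558, 615)


@dataclass
class ChromatinTruth:
    """Ground-truth chromatin map of one synthetic contig."""

    chrom: str
    length: int
    dyads: np.ndarray          # sorted dyad positions (bp)
    nfr_intervals: np.ndarray  # (n, 2) 0-based half-open

    def __post_init__(self):
        self.dyads = np.asarray(self.dyads, dtype=np.int64)
        self.nfr_intervals = np.asarray(self.nfr_intervals,
                                        dtype=np.int64).reshape(-1, 2)
        if np.any((self.dyads < 0) | (self.dyads >= self.length)):
            raise ValueError("dyads must lie inside the contig")

    @property
    def nfr_centers(self) -> np.ndarray:
        if len(self.nfr_intervals) == 0:
            return np.array([], dtype=np.int64)
        return (self.nfr_intervals[:, 0] + self.nfr_intervals[:, 1]) // 2


@dataclass
class BatchProfile:
    """Sample-specific fragment-class mixture and length distributions.

    ``weights`` orders the classes (NFR, mono, di, tri).  ``nfr_scale`` is
    the exponential scale of NFR lengths (truncated to 20-100 bp); the
    nucleosomal classes are Gaussians truncated to their canonical ranges.
    ``jitter_sd`` is the positional noise of nucleosomal midpoints.
    """

    sample_id: int = 0
    weights: tuple[float, float, float, float] = (0.45, 0.35, 0.15, 0.05)
    nfr_scale: float = 40.0
    mono_mean: float = 200.0
    mono_sd: float = 15.0
    di_mean: float = 394.0
    di_sd: float = 30.0
    tri_mean: float = 586.0
    tri_sd: float = 12.0
    jitter_sd: float = 20.0

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if w.min() < 0 or abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("class weights must be non-negative and sum to 1")


def simulate_chromatin_map(contig_length: int = 200_000,
                           mean_spacing_bp: int = 200,
                           n_nfr: int = 100,
                           nfr_len_bp: int = 300,
                           seed: int = 0,
                           chrom: str = "chrS") -> ChromatinTruth:
    """Place a jittered nucleosome array, then carve disjoint NFR intervals.

    Dyad spacings are Normal(mean_spacing, 0.1 * mean_spacing); dyads whose
    147-bp core would overlap a carved NFR are removed.
    """
    if contig_length < 10 * mean_spacing_bp:
        raise ValueError("contig too short for the requested spacing")
    rng = np.random.default_rng(seed)
    n_est = int(contig_length / mean_spacing_bp * 1.3) + 10
    gaps = rng.normal(mean_spacing_bp, 0.1 * mean_spacing_bp, size=n_est)
    gaps = np.clip(gaps, 0.25 * mean_spacing_bp, None)
    dyads = np.cumsum(gaps) + mean_spacing_bp / 2
    dyads = dyads[dyads < contig_length - mean_spacing_bp / 2].astype(np.int64)

    intervals: list[tuple[int, int]] = []
    margin = 50  # keep carved NFRs apart
    tries = 0
    while len(intervals) < n_nfr:
        tries += 1
        if tries > 200 * max(1, n_nfr):
            raise RuntimeError(
                f"could not place {n_nfr} disjoint NFR intervals of "
                f"{nfr_len_bp} bp on a {contig_length} bp contig")
        s = int(rng.integers(0, contig_length - nfr_len_bp))
        e = s + nfr_len_bp
        if all(e + margin <= a or b + margin <= s for a, b in intervals):
            intervals.append((s, e))
    intervals.sort()
    ivl = np.asarray(intervals, dtype=np.int64).reshape(-1, 2)

    # nucleosome cores (dyad +/- 73 bp) must not touch an NFR interval
    keep = np.ones(len(dyads), dtype=bool)
    for s, e in ivl:
        keep &= (dyads + 73 < s) | (dyads - 73 >= e)
    return ChromatinTruth(chrom=chrom, length=contig_length,
                          dyads=dyads[keep], nfr_intervals=ivl)


def _truncated(rng: np.random.Generator, sampler, lo: float, hi: float,
               n: int) -> np.ndarray:
    """Rejection-sample ``n`` values from ``sampler`` inside [lo, hi]."""
    out = np.empty(0)
    while len(out) < n:
        draw = sampler(rng, max(64, 2 * (n - len(out))))
        out = np.concatenate([out, draw[(draw >= lo) & (draw <= hi)]])
    return out[:n]


def simulate_fragments(truth: ChromatinTruth, profile: BatchProfile,
                       n_fragments: int, seed: int = 0) -> Fragments:
    """Draw fragments from the class mixture given the chromatin map."""
    if n_fragments < 1:
        raise ValueError("n_fragments must be >= 1")
    w = np.asarray(profile.weights, dtype=float)
    if len(truth.dyads) == 0 and w[1:].sum() > 0:
        raise ValueError("truth has no dyads but nucleosomal weight > 0")
    if len(truth.nfr_intervals) == 0 and w[0] > 0:
        raise ValueError("truth has no NFR intervals but NFR weight > 0")
    rng = np.random.default_rng(seed)
    classes = rng.choice(4, size=n_fragments, p=w)
    lengths = np.empty(n_fragments, dtype=np.int64)
    centers = np.empty(n_fragments, dtype=np.float64)

    dyads = truth.dyads
    # di/tri anchors: midpoints of runs of adjacent dyads; skip runs broken
    # by a carved NFR (gap much larger than the nominal spacing)
    def _run_anchors(k: int) -> np.ndarray:
        if len(dyads) < k:
            return dyads.astype(float)
        span = dyads[k - 1:] - dyads[:len(dyads) - k + 1]
        ok = span < 2.0 * 200 * (k - 1)
        anchors = (dyads[k - 1:] + dyads[:len(dyads) - k + 1]) / 2.0
        return anchors[ok] if ok.any() else dyads.astype(float)

    anchors = {1: dyads.astype(float), 2: _run_anchors(2), 3: _run_anchors(3)}

    for ci, (lo, hi) in enumerate((NFR_RANGE, MONO_RANGE, DI_RANGE, TRI_RANGE)):
        m = classes == ci
        k = int(m.sum())
        if k == 0:
            continue
        if ci == 0:
            # NFR reads are strictly shorter than 100 bp
            lengths[m] = np.round(_truncated(
                rng, lambda r, n: r.exponential(profile.nfr_scale, n) + lo,
                lo, hi - 1, k)).astype(np.int64)
            ivl = truth.nfr_intervals
            pick = rng.integers(0, len(ivl), size=k)
            centers[m] = (ivl[pick, 0]
                          + rng.random(k) * (ivl[pick, 1] - ivl[pick, 0] - 1))
        else:
            mean, sd = ((profile.mono_mean, profile.mono_sd),
                        (profile.di_mean, profile.di_sd),
                        (profile.tri_mean, profile.tri_sd))[ci - 1]
            lengths[m] = np.round(_truncated(
                rng, lambda r, n: r.normal(mean, sd, n), lo, hi, k)).astype(np.int64)
            anc = anchors[ci]
            pick = rng.integers(0, len(anc), size=k)
            centers[m] = anc[pick]
            if profile.jitter_sd > 0:
                centers[m] = centers[m] + rng.normal(0, profile.jitter_sd, k)

    start = np.round(centers).astype(np.int64) - lengths // 2
    end = start + lengths
    inside = (start >= 0) & (end <= truth.length)
    chrom = np.full(int(inside.sum()), truth.chrom, dtype=object)
    return Fragments(chrom, start[inside], end[inside])


def convert_nfr_to_nor(truth: ChromatinTruth, fraction: float = 0.5,
                       seed: int = 0) -> tuple[ChromatinTruth, np.ndarray]:
    """Turn a fraction of NFR intervals into nucleosome-occupied territory.

    Selected intervals receive a dyad at their center and leave the NFR
    list.  Returns the modified truth and the original-index mask of the
    converted intervals (the changed-site ground truth for benchmarking).
    """
    rng = np.random.default_rng(seed)
    n = len(truth.nfr_intervals)
    n_conv = int(round(fraction * n))
    converted = np.zeros(n, dtype=bool)
    converted[rng.choice(n, size=n_conv, replace=False)] = True
    new_dyads = truth.nfr_centers[converted]
    dyads = np.sort(np.concatenate([truth.dyads, new_dyads]))
    return ChromatinTruth(chrom=truth.chrom, length=truth.length,
                          dyads=dyads,
                          nfr_intervals=truth.nfr_intervals[~converted]), converted


def write_truth(truth: ChromatinTruth, dyad_path, nfr_path) -> None:
    """Write dyads (1-bp point intervals) and NFR intervals as BED."""
    with open(dyad_path, "w") as fh:
        fh.write("# dyad positions (0-based, point intervals)\n")
        for d in truth.dyads:
            fh.write(f"{truth.chrom}\t{d}\t{d + 1}\n")
    with open(nfr_path, "w") as fh:
        fh.write("# nucleosome-free intervals (0-based half-open)\n")
        for s, e in truth.nfr_intervals:
            fh.write(f"{truth.chrom}\t{s}\t{e}\n")


def read_truth(dyad_path, nfr_path, chrom: str, length: int) -> ChromatinTruth:
    """Round-trip reader for :func:`write_truth` output."""
    def _read(path):
        rows = []
        with open(path) as fh:
            for line in fh:
                if line.startswith("#") or not line.strip():
                    continue
                c, s, e = line.split("\t")[:3]
                rows.append((int(s), int(e)))
        return rows
    dyads = np.array([s for s, _ in _read(dyad_path)], dtype=np.int64)
    nfr = np.array(_read(nfr_path), dtype=np.int64).reshape(-1, 2)
    return ChromatinTruth(chrom=chrom, length=length, dyads=dyads,
                          nfr_intervals=nfr)


def default_batch_panel(n_samples: int = 3) -> list[BatchProfile]:
    """Samples with deliberately distinct fragment-size mixtures, emulating
    library-preparation batch effects."""
    panel = [
        BatchProfile(sample_id=0, weights=(0.55, 0.30, 0.11, 0.04),
                     nfr_scale=30.0, mono_mean=192.0, mono_sd=8.0),
        BatchProfile(sample_id=1, weights=(0.45, 0.35, 0.15, 0.05),
                     nfr_scale=40.0, mono_mean=205.0, mono_sd=15.0),
        BatchProfile(sample_id=2, weights=(0.32, 0.42, 0.19, 0.07),
                     nfr_scale=55.0, mono_mean=220.0, mono_sd=18.0),
        BatchProfile(sample_id=3, weights=(0.50, 0.28, 0.16, 0.06),
                     nfr_scale=35.0, mono_mean=198.0, mono_sd=12.0),
    ]
    if n_samples > len(panel):
        raise ValueError(f"panel defines at most {len(panel)} samples")
    return panel[:n_samples]
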