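"""Benchmark experiments with known ground truth.

Three designs, each run end-to-end on simulator output:

* **Shift detection** — two independent down-samples of one fragment pool
  are true negatives (identical V-plots in expectation); a 3'-shifted copy
  of the second down-sample is the true positive against the first.  One
  model is trained jointly over the three samples and regions are ranked
  by the differential V-plot p-value.
* **Nucleosome recovery** — windows centered on true dyads (NOR) and NFR
  centers are ranked by the central nucleosome score of the batch-free
  estimated V-plot, at several down-sampling fractions.
* **Nucleosome change** — condition B converts a fraction of NFR sites to
  nucleosome-occupied; sites are ranked by the differential nucleosome
  score delta between the two conditions.

All rankings are scored by ROC AUC (Mann-Whitney form, ties counted 1/2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from . import cvae as cv
from . import difftest as dt
from . import simulate as sim
from .vplots import Fragments, GenomicRegion, VPlotConfig, build_vplot_matrix, \
    normalize_vplot


@dataclass
class BenchmarkSpec:
    """Knobs of one benchmark run."""

    task: str = "shift_differential"
    fraction: float = 0.1
    fractions: tuple[float, ...] = (0.01, 0.1, 1.0)
    shift_bp: int = 50
    n_regions: int = 500
    min_reads: int = 5
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.fraction <= 1:
            raise ValueError("fraction must be in (0, 1]")
        if self.shift_bp < 0:
            raise ValueError("shift_bp must be >= 0")


def downsample_fragments(fragments: Fragments, fraction: float,
                         seed: int = 0) -> Fragments:
    """Sample exactly ``round(fraction * n)`` fragments without replacement."""
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    n = len(fragments)
    k = int(round(fraction * n))
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(n, size=k, replace=False))
    return fragments[idx]


def shift_fragments(fragments: Fragments, shift_bp: int,
                    contig_length: int | None = None) -> Fragments:
    """Translate every fragment by +shift_bp (length preserved); fragments
    running off the contig end are dropped when the length is known."""
    if shift_bp < 0:
        raise ValueError("shift_bp must be >= 0")
    start = fragments.start + shift_bp
    end = fragments.end + shift_bp
    if contig_length is not None:
        keep = end <= contig_length
        return Fragments(fragments.chrom[keep], start[keep], end[keep])
    return Fragments(fragments.chrom, start, end)


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """ROC AUC as the Mann-Whitney probability (ties count 1/2).

    ``labels`` are binary; higher scores should indicate the positive class.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels).astype(bool)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = rankdata(scores)
    return float((ranks[labels].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def tile_regions(truth: sim.ChromatinTruth, window_bp: int = 640,
                 step_bp: int = 320) -> list[GenomicRegion]:
    """Fixed-width windows tiled across the contig."""
    starts = np.arange(0, truth.length - window_bp + 1, step_bp)
    return [GenomicRegion(truth.chrom, int(s), int(s + window_bp))
            for s in starts]


def _stack_for_samples(sample_frags: list[Fragments],
                       regions: list[GenomicRegion],
                       vcfg: VPlotConfig, min_reads: int = 0):
    """Build a density stack (n, S, W, H); drop regions below the read floor
    in any sample.  Returns (stack, kept regions)."""
    counts = []
    for frags in sample_frags:
        c, _ = build_vplot_matrix(frags, regions, vcfg)
        counts.append(c)
    counts = np.stack(counts, axis=1)  # (n, S, W, H)
    n_reads = counts.sum(axis=(2, 3))
    keep = (n_reads >= min_reads).all(axis=1)
    counts = counts[keep]
    stack = cv.VPlotStack(x=normalize_vplot(counts),
                          region_ids=np.nonzero(keep)[0],
                          n_reads=n_reads[keep].astype(np.int64))
    return stack, [r for r, k in zip(regions, keep) if k]


def run_task1_shift_benchmark(fragments: Fragments, truth: sim.ChromatinTruth,
                              spec: BenchmarkSpec,
                              model_config: cv.ModelConfig | None = None,
                              vcfg: VPlotConfig = VPlotConfig(),
                              shifts: tuple[int, ...] | None = None):
    """Differential V-plot detection under the down-sample/shift design.

    Two independent down-samples (datasets #1 and #2) provide the true-same
    comparison; each 3'-shifted copy of dataset #2 provides a true-different
    comparison.  One model is trained jointly over all datasets.  Returns
    ``(aucs, table)`` where ``aucs`` maps shift size to the AUC of ranking
    true-different above true-same comparisons by ``-log10 p``.
    """
    if shifts is None:
        shifts = (spec.shift_bp,)
    rng = np.random.default_rng(spec.seed)
    seeds = rng.integers(0, 2 ** 31 - 1, size=2)
    ds1 = downsample_fragments(fragments, spec.fraction, seed=int(seeds[0]))
    ds2 = downsample_fragments(fragments, spec.fraction, seed=int(seeds[1]))
    samples = [ds1, ds2] + [shift_fragments(ds2, s, contig_length=truth.length)
                            for s in shifts]
    regions = tile_regions(truth, vcfg.window_bp)
    if spec.n_regions and len(regions) > spec.n_regions:
        pick = np.sort(rng.choice(len(regions), size=spec.n_regions,
                                  replace=False))
        regions = [regions[i] for i in pick]
    stack, regions = _stack_for_samples(samples, regions, vcfg,
                                        min_reads=spec.min_reads)
    if stack.n_regions < 50:
        raise ValueError(
            f"only {stack.n_regions} regions pass the read filter (>=50 needed)")
    if model_config is None:
        model_config = cv.ModelConfig(S=len(samples),
                                      seed=int(rng.integers(2 ** 31 - 1)))
    model, _ = cv.train(stack, model_config)
    post = cv.encode(stack, model)
    _, p_same = dt.posterior_pair_test(post, 0, 1)
    p_same = np.atleast_1d(p_same)
    aucs: dict[int, float] = {}
    rows = [pd.DataFrame({
        "chrom": [r.chrom for r in regions],
        "start": [r.start for r in regions],
        "end": [r.end for r in regions],
        "comparison": "ds1_vs_ds2", "shift_bp": 0, "p": p_same, "label": 0})]
    for si, shift in enumerate(shifts):
        _, p_diff = dt.posterior_pair_test(post, 0, 2 + si)
        p_diff = np.atleast_1d(p_diff)
        scores = -np.log10(np.concatenate([p_same, p_diff]) + 1e-300)
        labels = np.concatenate([np.zeros(len(p_same)), np.ones(len(p_diff))])
        aucs[shift] = roc_auc(scores, labels)
        rows.append(pd.DataFrame({
            "chrom": [r.chrom for r in regions],
            "start": [r.start for r in regions],
            "end": [r.end for r in regions],
            "comparison": f"ds1_vs_shift{shift}", "shift_bp": shift,
            "p": p_diff, "label": 1}))
    return aucs, pd.concat(rows, ignore_index=True)


def _nucleosome_scores(sample_frags: list[Fragments],
                       regions: list[GenomicRegion],
                       model_config: cv.ModelConfig,
                       vcfg: VPlotConfig, scfg: dt.ScoreConfig):
    """Train jointly over the samples; return per-sample Nuc scores on the
    batch-free estimated V-plots plus the trained model and stack."""
    counts = []
    for frags in sample_frags:
        c, _ = build_vplot_matrix(frags, regions, vcfg)
        counts.append(c)
    counts = np.stack(counts, axis=1)
    stack = cv.VPlotStack(x=normalize_vplot(counts),
                          n_reads=counts.sum(axis=(2, 3)).astype(np.int64))
    model, _ = cv.train(stack, model_config)
    xhat = cv.batch_free_vplot(stack, model)  # (n, S, W, H)
    nuc = np.stack([dt.central_nucleosome_score(xhat[:, s], scfg, vcfg)
                    for s in range(len(sample_frags))], axis=1)
    return nuc, model, stack


def run_task2_nucleosome_recovery(truth: sim.ChromatinTruth,
                                  fragments: Fragments,
                                  spec: BenchmarkSpec,
                                  model_config: cv.ModelConfig | None = None,
                                  n_seeds: int = 3,
                                  n_per_class: int = 250,
                                  vcfg: VPlotConfig = VPlotConfig(),
                                  scfg: dt.ScoreConfig = dt.ScoreConfig()):
    """Rank NOR vs NFR centers by the central nucleosome score.

    For each down-sampling fraction, ``n_seeds`` independent down-samples
    are stacked as samples of one model; the reported AUC is the mean over
    those replicates.  Returns ``{fraction: auc}``.
    """
    rng = np.random.default_rng(spec.seed)
    nor = truth.dyads
    nfr = truth.nfr_centers
    if len(nor) < 20 or len(nfr) < 20:
        raise ValueError("need >= 20 truth centers per class")
    half = vcfg.window_bp // 2
    nor = nor[(nor >= half) & (nor + half <= truth.length)]
    nfr = nfr[(nfr >= half) & (nfr + half <= truth.length)]
    nor = nor[np.sort(rng.choice(len(nor), size=min(n_per_class, len(nor)),
                                 replace=False))]
    nfr = nfr[np.sort(rng.choice(len(nfr), size=min(n_per_class, len(nfr)),
                                 replace=False))]
    centers = np.concatenate([nor, nfr])
    labels = np.concatenate([np.ones(len(nor)), np.zeros(len(nfr))])
    regions = [GenomicRegion.around(truth.chrom, int(c), vcfg.window_bp)
               for c in centers]
    out: dict[float, float] = {}
    for fraction in spec.fractions:
        seeds = rng.integers(0, 2 ** 31 - 1, size=n_seeds)
        frags = [downsample_fragments(fragments, fraction, seed=int(s))
                 for s in seeds]
        mc = model_config
        if mc is None:
            mc = cv.ModelConfig(S=n_seeds, seed=int(rng.integers(2 ** 31 - 1)))
        nuc, _, _ = _nucleosome_scores(frags, regions, mc, vcfg, scfg)
        out[fraction] = float(np.mean([roc_auc(nuc[:, s], labels)
                                       for s in range(n_seeds)]))
    return out, labels


def run_task3_nucleosome_change(truth_a: sim.ChromatinTruth,
                                truth_b: sim.ChromatinTruth,
                                changed: np.ndarray,
                                fragments_a: Fragments,
                                fragments_b: Fragments,
                                spec: BenchmarkSpec,
                                model_config: cv.ModelConfig | None = None,
                                vcfg: VPlotConfig = VPlotConfig(),
                                scfg: dt.ScoreConfig = dt.ScoreConfig()):
    """Detect NFR -> NOR conversions between two conditions.

    Regions are the NFR centers of condition A; ``changed`` marks the ones
    converted in condition B.  Sites are ranked by delta = log Nuc_B -
    log Nuc_A on batch-free estimated V-plots.  Returns
    ``(auc, delta, labels)``.
    """
    rng = np.random.default_rng(spec.seed)
    centers = truth_a.nfr_centers
    half = vcfg.window_bp // 2
    ok = (centers >= half) & (centers + half <= truth_a.length)
    centers, changed = centers[ok], np.asarray(changed, bool)[ok]
    if changed.sum() < 20 or (~changed).sum() < 20:
        raise ValueError("need >= 20 changed and unchanged sites")
    regions = [GenomicRegion.around(truth_a.chrom, int(c), vcfg.window_bp)
               for c in centers]
    frac = spec.fraction
    seeds = rng.integers(0, 2 ** 31 - 1, size=2)
    fa = downsample_fragments(fragments_a, frac, seed=int(seeds[0]))
    fb = downsample_fragments(fragments_b, frac, seed=int(seeds[1]))
    mc = model_config
    if mc is None:
        mc = cv.ModelConfig(S=2, seed=int(rng.integers(2 ** 31 - 1)))
    nuc, _, _ = _nucleosome_scores([fa, fb], regions, mc, vcfg, scfg)
    delta = dt.differential_nucleosome_score(nuc[:, 0], nuc[:, 1])
    return roc_auc(delta, changed), delta, changed


# ---------------------------------------------------------------------------
# standard end-to-end experiments
#
# These bundle the simulator conditions each benchmark is quoted under:
# fragment density ~1 per bp of contig, 10% down-samples, 640-bp windows.
# Problem sizes are desk-scale (hundreds of regions, 10-20 epochs).
# ---------------------------------------------------------------------------

def standard_shift_experiment(seed: int = 0, shifts: tuple[int, ...] = (50,),
                              fraction: float = 0.1, n_regions: int = 550,
                              contig_length: int = 200_000, n_nfr: int = 100,
                              epochs: int = 20) -> dict:
    """Down-sample/shift differential detection on a fresh simulation.

    Returns a dict with the per-shift AUCs, the null-comparison p-values,
    and the null label AUC (ds1-vs-ds2 ranked against itself split in half).
    """
    rng = np.random.default_rng(seed)
    truth = sim.simulate_chromatin_map(contig_length=contig_length,
                                       n_nfr=n_nfr,
                                       seed=int(rng.integers(2 ** 31 - 1)))
    pool = sim.simulate_fragments(truth, sim.BatchProfile(), contig_length,
                                  seed=int(rng.integers(2 ** 31 - 1)))
    spec = BenchmarkSpec(task="shift_differential", fraction=fraction,
                         shift_bp=shifts[0], n_regions=n_regions, min_reads=5,
                         seed=int(rng.integers(2 ** 31 - 1)))
    mc = cv.ModelConfig(S=2 + len(shifts), epochs=epochs, batch_size=64,
                        warmup_steps=20, seed=int(rng.integers(2 ** 31 - 1)))
    aucs, table = run_task1_shift_benchmark(pool, truth, spec,
                                            model_config=mc, shifts=shifts)
    p_null = table.loc[table.comparison == "ds1_vs_ds2", "p"].to_numpy()
    # chance-level control: the null p-values carry no true signal, so an
    # arbitrary half/half labelling must score ~0.5
    half = len(p_null) // 2
    null_auc = roc_auc(-np.log10(p_null + 1e-300),
                       np.r_[np.zeros(half), np.ones(len(p_null) - half)])
    return {"aucs": aucs, "table": table, "null_pvalues": p_null,
            "null_auc": null_auc, "n_regions": len(p_null)}


def standard_recovery_experiment(seed: int = 0,
                                 fractions: tuple[float, ...] = (0.01, 0.1, 1.0),
                                 contig_length: int = 600_000,
                                 n_nfr: int = 250, n_per_class: int = 250,
                                 epochs: int = 15, n_seeds: int = 3) -> dict:
    """Nucleosome recovery from sparse coverage; AUC per down-sample fraction."""
    rng = np.random.default_rng(seed)
    truth = sim.simulate_chromatin_map(contig_length=contig_length,
                                       n_nfr=n_nfr,
                                       seed=int(rng.integers(2 ** 31 - 1)))
    pool = sim.simulate_fragments(truth, sim.BatchProfile(), contig_length,
                                  seed=int(rng.integers(2 ** 31 - 1)))
    spec = BenchmarkSpec(task="nucleosome_recovery", fractions=fractions,
                         seed=int(rng.integers(2 ** 31 - 1)))
    mc = cv.ModelConfig(S=n_seeds, epochs=epochs, batch_size=64,
                        warmup_steps=20, seed=int(rng.integers(2 ** 31 - 1)))
    aucs, labels = run_task2_nucleosome_recovery(
        truth, pool, spec, model_config=mc, n_seeds=n_seeds,
        n_per_class=n_per_class)
    return {"aucs": aucs, "n_per_class": int(labels.sum())}


def standard_change_experiment(seed: int = 0, convert_fraction: float = 0.5,
                               fraction: float = 0.1,
                               contig_length: int = 600_000, n_nfr: int = 250,
                               epochs: int = 20) -> dict:
    """NFR -> NOR conversion detection between two simulated conditions."""
    rng = np.random.default_rng(seed)
    truth_a = sim.simulate_chromatin_map(contig_length=contig_length,
                                         n_nfr=n_nfr,
                                         seed=int(rng.integers(2 ** 31 - 1)))
    pool_a = sim.simulate_fragments(truth_a, sim.BatchProfile(), contig_length,
                                    seed=int(rng.integers(2 ** 31 - 1)))
    truth_b, changed = sim.convert_nfr_to_nor(
        truth_a, convert_fraction, seed=int(rng.integers(2 ** 31 - 1)))
    pool_b = sim.simulate_fragments(truth_b, sim.BatchProfile(), contig_length,
                                    seed=int(rng.integers(2 ** 31 - 1)))
    spec = BenchmarkSpec(task="nucleosome_change", fraction=fraction,
                         seed=int(rng.integers(2 ** 31 - 1)))
    mc = cv.ModelConfig(S=2, epochs=epochs, batch_size=64, warmup_steps=20,
                        seed=int(rng.integers(2 ** 31 - 1)))
    auc, delta, labels = run_task3_nucleosome_change(
        truth_a, truth_b, changed, pool_a, pool_b, spec, model_config=mc)
    return {"auc": auc, "delta": delta, "labels": labels,
            "median_delta_changed": float(np.median(delta[labels])),
            "n_pairs": len(delta)}


def standard_batch_experiment(seed: int = 0, n_samples: int = 3,
                              n_fragments: int = 100_000,
                              contig_length: int = 200_000, n_nfr: int = 100,
                              n_regions: int = 300, epochs: int = 15) -> dict:
    """Batch correction: samples with distinct fragment-size mixtures.

    Measures the mean pairwise L1 distance between per-sample aggregated
    fragment-size profiles before and after batch-free re-estimation.
    """
    rng = np.random.default_rng(seed)
    truth = sim.simulate_chromatin_map(contig_length=contig_length,
                                       n_nfr=n_nfr,
                                       seed=int(rng.integers(2 ** 31 - 1)))
    panel = sim.default_batch_panel(n_samples)
    samples = [sim.simulate_fragments(truth, prof, n_fragments,
                                      seed=int(rng.integers(2 ** 31 - 1)))
               for prof in panel]
    regions = tile_regions(truth, 640)[:n_regions]
    stack, _ = _stack_for_samples(samples, regions, VPlotConfig(), min_reads=5)
    mc = cv.ModelConfig(S=n_samples, epochs=epochs, batch_size=64,
                        warmup_steps=20, seed=int(rng.integers(2 ** 31 - 1)))
    model, _ = cv.train(stack, mc)
    raw, corrected = batch_correction_distance(stack, model)
    return {"raw_l1": raw, "corrected_l1": corrected,
            "ratio": corrected / raw, "n_regions": stack.n_regions}


def batch_correction_distance(stack: cv.VPlotStack, model: cv.CVAE):
    """Mean pairwise L1 distance between per-sample aggregated fragment-size
    profiles, before (raw densities) and after (batch-free estimates).

    Profiles average the V-plot along the genomic axis and normalize to
    sum one.  Returns ``(raw_distance, corrected_distance)``.
    """
    xhat = cv.batch_free_vplot(stack, model)

    def profiles(x):
        # x: (n, S, W, H) -> (S, H)
        p = x.sum(axis=(0, 2))
        return p / p.sum(axis=1, keepdims=True)

    def mean_l1(p):
        s = p.shape[0]
        d = [np.abs(p[i] - p[j]).sum() for i in range(s) for j in range(i + 1, s)]
        return float(np.mean(d))

    return mean_l1(profiles(stack.x)), mean_l1(profiles(xhat))
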