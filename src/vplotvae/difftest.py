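"""Statistical layer on top of the latent representation.

Differential accessibility between two samples at a region is tested with
the standardized squared latent distance

    Q = sum_k (z_ak - z_bk)^2 / (sigma_ak^2 + sigma_bk^2)

which is chi-square with K degrees of freedom under the null of identical
V-plots.  Nucleosome occupancy is scored on estimated V-plots: the central
NFR weight w (mass of short fragments near the window center), the central
nucleosome score Nuc = 1 - w, and the differential score
delta = log Nuc_j - log Nuc_i (positive = chromatin closing, negative =
opening).  A site is called more accessible in sample j when the
BH-adjusted p-value is < 0.05 and delta < -0.2, less accessible for
delta > 0.2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .cvae import LatentPosterior
from .vplots import VPlotConfig

MORE_ACCESSIBLE = "more_accessible"
LESS_ACCESSIBLE = "less_accessible"
UNCHANGED = "unchanged"


@dataclass(frozen=True)
class ScoreConfig:
    """Geometry and normalization of the nucleosome scores.

    Central genomic bins are those whose bin centers lie within
    ``central_halfwidth_bp`` of the window center (20 bins at defaults);
    NFR fragment-size bins cover lengths up to ``nfr_max_bp`` (15 bins).
    ``normalization='column_fraction'`` averages the per-column NFR mass so
    the score spans [0, 1]; ``'literal_paper'`` divides by N*M instead,
    which differs only by the constant factor M and therefore ranks regions
    identically.
    """

    central_halfwidth_bp: int = 50
    nfr_max_bp: int = 150
    nuc_floor: float = 1e-3
    normalization: str = "column_fraction"

    def __post_init__(self):
        if self.normalization not in ("column_fraction", "literal_paper"):
            raise ValueError(f"unknown normalization {self.normalization!r}")
        if not 0 < self.nuc_floor < 0.1:
            raise ValueError("nuc_floor must be in (0, 0.1)")

    def central_bins(self, vcfg: VPlotConfig) -> np.ndarray:
        """Indices of genomic bins whose centers are within the half-width."""
        centers = (np.arange(vcfg.W) + 0.5) * vcfg.genomic_bin_bp - vcfg.window_bp / 2
        idx = np.nonzero(np.abs(centers) <= self.central_halfwidth_bp)[0]
        if len(idx) == 0:
            raise ValueError("window too narrow: no central genomic bins")
        return idx

    def nfr_bins(self, vcfg: VPlotConfig) -> np.ndarray:
        """Indices of fragment-size bins entirely below ``nfr_max_bp``."""
        # bin j covers lengths (j*size_bin, (j+1)*size_bin]
        upper = (np.arange(vcfg.H) + 1) * vcfg.size_bin_bp
        idx = np.nonzero(upper <= self.nfr_max_bp)[0]
        if len(idx) == 0:
            raise ValueError("no NFR fragment-size bins below nfr_max_bp")
        return idx


def differential_vplot_test(mean_a: np.ndarray, std_a: np.ndarray,
                            mean_b: np.ndarray, std_b: np.ndarray):
    """Q statistic and chi-square p-value for one or many regions.

    Inputs are ``(K,)`` or ``(n, K)`` posterior means and standard
    deviations of the two samples; returns scalars or length-n arrays.
    """
    mean_a, std_a = np.atleast_2d(mean_a), np.atleast_2d(std_a)
    mean_b, std_b = np.atleast_2d(mean_b), np.atleast_2d(std_b)
    if np.any(std_a <= 0) or np.any(std_b <= 0):
        raise ValueError("posterior std must be strictly positive")
    if mean_a.shape != mean_b.shape:
        raise ValueError("posterior shapes differ between samples")
    k = mean_a.shape[1]
    q = ((mean_a - mean_b) ** 2 / (std_a ** 2 + std_b ** 2)).sum(axis=1)
    p = stats.chi2.sf(q, df=k)
    if q.size == 1:
        return float(q[0]), float(p[0])
    return q, p


def posterior_pair_test(post: LatentPosterior, sample_a: int, sample_b: int):
    """Convenience wrapper: test sample_a vs sample_b for every region."""
    ma, sa = post.sample_slice(sample_a)
    mb, sb = post.sample_slice(sample_b)
    return differential_vplot_test(ma, sa, mb, sb)


def adjust_pvalues(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p, dtype=np.float64)
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def central_nfr_score(xhat: np.ndarray, cfg: ScoreConfig = ScoreConfig(),
                      vcfg: VPlotConfig = VPlotConfig()) -> np.ndarray | float:
    """Central NFR weight of estimated V-plot(s) ``(W, H)`` or ``(n, W, H)``."""
    xhat = np.asarray(xhat, dtype=np.float64)
    single = xhat.ndim == 2
    if single:
        xhat = xhat[None]
    ci = cfg.central_bins(vcfg)
    fj = cfg.nfr_bins(vcfg)
    mass = xhat[:, ci[:, None], fj[None, :]].sum(axis=(1, 2))
    n = len(ci)
    if cfg.normalization == "column_fraction":
        w = mass / n
    else:
        w = mass / (n * len(fj))
    return float(w[0]) if single else w


def central_nucleosome_score(xhat: np.ndarray, cfg: ScoreConfig = ScoreConfig(),
                             vcfg: VPlotConfig = VPlotConfig()):
    """Central nucleosome score Nuc = 1 - w, floored at ``nuc_floor``."""
    w = central_nfr_score(xhat, cfg, vcfg)
    return np.clip(1.0 - np.asarray(w), cfg.nuc_floor, 1.0) if np.ndim(w) \
        else float(np.clip(1.0 - w, cfg.nuc_floor, 1.0))


def differential_nucleosome_score(nuc_i, nuc_j):
    """delta = ln(Nuc_j) - ln(Nuc_i); positive when chromatin closes."""
    nuc_i, nuc_j = np.asarray(nuc_i, float), np.asarray(nuc_j, float)
    if np.any(nuc_i <= 0) or np.any(nuc_j <= 0) or np.any(nuc_i > 1) or np.any(nuc_j > 1):
        raise ValueError("nucleosome scores must lie in (0, 1]")
    delta = np.log(nuc_j) - np.log(nuc_i)
    return float(delta) if delta.ndim == 0 else delta


def designate_differential_tfbs(results: pd.DataFrame, p_cut: float = 0.05,
                                delta_cut: float = 0.2) -> pd.DataFrame:
    """Label each site by the accessibility-change rule.

    ``more_accessible`` (in sample j vs i): adjusted p < ``p_cut`` and
    delta < -``delta_cut``; ``less_accessible``: adjusted p < ``p_cut`` and
    delta > ``delta_cut``; otherwise ``unchanged``.
    """
    for col in ("p_adj", "delta"):
        if col not in results:
            raise ValueError(f"results table lacks required column {col!r}")
    out = results.copy()
    sig = out["p_adj"] < p_cut
    label = np.full(len(out), UNCHANGED, dtype=object)
    label[sig & (out["delta"] < -delta_cut)] = MORE_ACCESSIBLE
    label[sig & (out["delta"] > delta_cut)] = LESS_ACCESSIBLE
    out["label"] = label
    return out


def differential_table(post: LatentPosterior, xhat_a: np.ndarray,
                       xhat_b: np.ndarray, sample_a: int, sample_b: int,
                       regions=None, cfg: ScoreConfig = ScoreConfig(),
                       vcfg: VPlotConfig = VPlotConfig(),
                       p_cut: float = 0.05, delta_cut: float = 0.2) -> pd.DataFrame:
    """Full per-region differential result: Q, p, BH-adjusted p, nucleosome
    scores of both samples, delta, and the accessibility label."""
    q, p = posterior_pair_test(post, sample_a, sample_b)
    q, p = np.atleast_1d(q), np.atleast_1d(p)
    nuc_a = np.atleast_1d(central_nucleosome_score(xhat_a, cfg, vcfg))
    nuc_b = np.atleast_1d(central_nucleosome_score(xhat_b, cfg, vcfg))
    df = pd.DataFrame({
        "Q": q,
        "p": p,
        "p_adj": adjust_pvalues(p),
        "nuc_a": nuc_a,
        "nuc_b": nuc_b,
        "delta": differential_nucleosome_score(nuc_a, nuc_b),
    })
    if regions is not None:
        df.insert(0, "chrom", [r.chrom for r in regions])
        df.insert(1, "start", [r.start for r in regions])
        df.insert(2, "end", [r.end for r in regions])
    return designate_differential_tfbs(df, p_cut=p_cut, delta_cut=delta_cut)
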