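"""Diversity, inbreeding, LD-decay and effective-size summaries.

Distances use the 1 cM = 1 Mb convention throughout, so physical-distance
bins (0.1 Mb wide, 0-1 Mb by default) map directly onto the genetic map.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd

from . import _kernels
from .pedigree import Pedigree
from .relationship import inbreeding
from .simulate import ObservedGenotypes


def pedigree_inbreeding(ped: Pedigree, generations=None,
                        F: np.ndarray | None = None) -> float:
    """Mean pedigree inbreeding coefficient (Meuwissen-Luo), optionally
    restricted to a set of generations."""
    if F is None:
        F = inbreeding(ped)
    if generations is None:
        return float(F.mean())
    sel = np.isin(ped.generation, np.asarray(generations))
    if not np.any(sel):
        raise ValueError("no animals in the requested generations")
    return float(F[sel].mean())


def observed_heterozygosity(obs: ObservedGenotypes | np.ndarray) -> float:
    """Fraction of non-missing genotype calls that are heterozygous,
    averaged over individuals."""
    dosage = obs.dosage if isinstance(obs, ObservedGenotypes) else np.asarray(obs)
    nonmiss = (dosage >= 0).sum(axis=1)
    if np.any(nonmiss == 0):
        raise ValueError("individual with no non-missing calls")
    het = (dosage == 1).sum(axis=1)
    return float((het / nonmiss).mean())


def genomic_inbreeding_fhom(obs: ObservedGenotypes | np.ndarray,
                            freqs: np.ndarray | None = None) -> float:
    """Method-of-moments genomic inbreeding from excess homozygosity.

    Per individual, F = (O_hom - E_hom) / (L - E_hom) with
    E_hom = sum_j (1 - 2 p_j (1 - p_j)) over that individual's
    non-missing loci; the sample mean is returned.  Negative values mean
    heterozygote excess.
    """
    dosage = obs.dosage if isinstance(obs, ObservedGenotypes) else np.asarray(obs)
    if freqs is None:
        masked = np.ma.masked_less(dosage, 0)
        freqs = np.asarray(masked.mean(axis=0)) / 2.0
    het_j = 2.0 * freqs * (1.0 - freqs)
    if np.all(het_j == 0.0):
        raise ValueError("all loci monomorphic")
    nm = dosage >= 0
    L = nm.sum(axis=1).astype(np.float64)
    e_hom = nm @ (1.0 - het_j)
    o_hom = ((dosage == 0) | (dosage == 2)).sum(axis=1).astype(np.float64)
    denom = L - e_hom
    if np.any(denom == 0.0):
        raise ValueError("zero expected heterozygosity for some individual")
    return float(((o_hom - e_hom) / denom).mean())


@dataclass
class LDTable:
    """Binned pairwise r2 by inter-marker distance."""

    table: pd.DataFrame   # bin_lo, bin_hi, n_pairs, mean_r2, sd_r2

    def __getitem__(self, i: int) -> pd.Series:
        return self.table.iloc[i]


def _pair_list(chrom: np.ndarray, pos: np.ndarray, max_dist: float):
    """Same-chromosome locus pairs with 0 <= distance < max_dist."""
    pi, pj = [], []
    for c in np.unique(chrom):
        idx = np.where(chrom == c)[0]
        p = pos[idx]
        hi = np.searchsorted(p, p + max_dist, side="left")
        for k in range(len(idx)):
            if hi[k] > k + 1:
                pj.append(idx[k + 1:hi[k]])
                pi.append(np.full(hi[k] - k - 1, idx[k]))
    if not pi:
        return (np.empty(0, np.int64),) * 2
    return np.concatenate(pi).astype(np.int64), np.concatenate(pj).astype(np.int64)


def ld_r2_decay(haps: np.ndarray, chrom: np.ndarray, pos_cm: np.ndarray,
                max_dist: float = 1.0, bin_width: float = 0.1) -> LDTable:
    """Haplotype-based r2 decay for same-chromosome pairs within
    ``max_dist`` (cM = Mb), binned in half-open [lo, hi) distance bins.

    ``haps`` is a (n_haplotypes, n_loci) 0/1 matrix (phase known, e.g.
    simulator output).  Pairs involving a monomorphic locus are skipped.
    """
    haps = np.ascontiguousarray(haps, dtype=np.int8)
    pi, pj = _pair_list(np.asarray(chrom), np.asarray(pos_cm, dtype=float), max_dist)
    r2 = np.empty(len(pi))
    _kernels.ld_r2_kernel(haps, pi, pj, r2)
    dist = np.abs(pos_cm[pj] - pos_cm[pi])
    ok = np.isfinite(r2)
    edges = np.arange(0.0, max_dist + bin_width / 2, bin_width)
    which = np.digitize(dist[ok], edges) - 1
    rows = []
    for b in range(len(edges) - 1):
        sel = which == b
        vals = r2[ok][sel]
        rows.append({
            "bin_lo": edges[b], "bin_hi": edges[b + 1],
            "n_pairs": int(sel.sum()),
            "mean_r2": float(vals.mean()) if vals.size else np.nan,
            "sd_r2": float(vals.std(ddof=1)) if vals.size > 1 else np.nan,
        })
    return LDTable(pd.DataFrame(rows))


def genotype_r2_decay(dosage: np.ndarray, chrom: np.ndarray, pos_cm: np.ndarray,
                      max_dist: float = 1.0, bin_width: float = 0.1) -> LDTable:
    """Composite-LD fallback for unphased external data: squared Pearson
    correlation of dosages.  Missing calls are mean-imputed."""
    d = np.asarray(dosage, dtype=np.float64)
    miss = d < 0
    if np.any(miss):
        col = np.where(miss, np.nan, d)
        mean = np.nanmean(col, axis=0)
        d = np.where(miss, np.broadcast_to(mean, d.shape), d)
    # reuse the haplotype kernel on centred dosages via plain correlation
    pi, pj = _pair_list(np.asarray(chrom), np.asarray(pos_cm, dtype=float), max_dist)
    dc = d - d.mean(axis=0)
    var = (dc ** 2).sum(axis=0)
    num = np.einsum("ki,ki->i", dc[:, pi], dc[:, pj])
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = num ** 2 / (var[pi] * var[pj])
    r2[(var[pi] == 0) | (var[pj] == 0)] = np.nan
    dist = np.abs(pos_cm[pj] - pos_cm[pi])
    ok = np.isfinite(r2)
    edges = np.arange(0.0, max_dist + bin_width / 2, bin_width)
    which = np.digitize(dist[ok], edges) - 1
    rows = []
    for b in range(len(edges) - 1):
        sel = which == b
        vals = r2[ok][sel]
        rows.append({
            "bin_lo": edges[b], "bin_hi": edges[b + 1],
            "n_pairs": int(sel.sum()),
            "mean_r2": float(vals.mean()) if vals.size else np.nan,
            "sd_r2": float(vals.std(ddof=1)) if vals.size > 1 else np.nan,
        })
    return LDTable(pd.DataFrame(rows))


def estimate_ne(ld: LDTable, sample_size: int, phased: bool = True,
                sample_correction: bool = True):
    """LD-based effective population size.

    Per bin with recombination fraction c (Haldane, from the cM midpoint)

        Ne_bin = (1 / r2_adj - 1) / (4 c),

    where r2_adj subtracts the finite-sample expectation 1/(2 n) for
    phased data (1/n unphased).  The summary is the pair-count-weighted
    harmonic mean over bins with a positive, sub-unity adjusted r2.

    Returns (ne_hat, per_bin) where per_bin holds one Ne per usable bin.
    """
    t = ld.table
    mid_cm = (t["bin_lo"] + t["bin_hi"]).to_numpy() / 2.0
    c = 0.5 * (1.0 - np.exp(-2.0 * mid_cm / 100.0))
    corr = (1.0 / (2 * sample_size) if phased else 1.0 / sample_size) \
        if sample_correction else 0.0
    r2_adj = t["mean_r2"].to_numpy() - corr
    w = t["n_pairs"].to_numpy().astype(float)
    ne_bin = np.full(len(t), np.nan)
    usable = np.isfinite(r2_adj) & (r2_adj > 0.0) & (c > 0.0)
    ne_bin[usable] = (1.0 / r2_adj[usable] - 1.0) / (4.0 * c[usable])
    pos = usable & (ne_bin > 0.0)
    if not np.any(pos):
        raise ValueError("no usable bins (adjusted r2 outside (0, 1))")
    if np.any(usable & ~pos):
        warnings.warn("bins with adjusted r2 >= 1 excluded from the Ne summary")
    ne_hat = float(w[pos].sum() / (w[pos] / ne_bin[pos]).sum())
    return ne_hat, ne_bin


def ne_from_delta_f(f_by_generation: np.ndarray) -> float:
    """Alternative Ne from the rate of inbreeding: Ne = 1 / (2 dF), with
    dF the per-generation slope of mean inbreeding."""
    f = np.asarray(f_by_generation, dtype=float)
    if len(f) < 2:
        raise ValueError("need inbreeding at >= 2 generations")
    slope = np.polyfit(np.arange(len(f)), f, 1)[0]
    if slope <= 0.0:
        raise ValueError("non-increasing inbreeding: dF-based Ne undefined")
    return float(1.0 / (2.0 * slope))


@dataclass
class DiversityStats:
    f_ped: float
    f_hom: float
    ho: float
    ne_hat: float
    scope: tuple[int, ...]
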