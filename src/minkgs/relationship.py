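"""Pedigree, genomic and blended relationship matrices.

Implements the numerator relationship matrix A (tabular method), its
sparse inverse (Henderson's rules with inbreeding from the
Meuwissen-Luo algorithm), the genotyped block A22 (dense tabular for
small pedigrees, Colleau's indirect method for large ones), the
VanRaden genomic relationship matrix

    G = (M - P)(M - P)' / (2 * sum_j p_j (1 - p_j)),

and the single-step blended inverse

    H^-1 = A^-1 + [[0, 0], [0, G*^-1 - A22^-1]]

restricted to the genotyped block, with G* = (1 - beta) G + beta A22.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg as sla
import scipy.sparse as sp

from . import _kernels
from .pedigree import Pedigree
from .simulate import ObservedGenotypes

_COLLEAU_THRESHOLD = 2000  # above this, A22 uses the indirect method


def inbreeding(ped: Pedigree, f_init: np.ndarray | None = None) -> np.ndarray:
    """Per-individual inbreeding coefficients (Meuwissen-Luo).

    ``f_init`` allows incremental extension: coefficients of the first
    ``len(f_init)`` animals are taken as given.
    """
    F = np.zeros(ped.n)
    start = 0
    if f_init is not None:
        start = len(f_init)
        F[:start] = f_init
    _kernels.meuwissen_luo(ped.sire, ped.dam, F, start)
    return F


def mendelian_variance(ped: Pedigree, F: np.ndarray) -> np.ndarray:
    """Within-family (Mendelian sampling) variance coefficients d_i."""
    s, d = ped.sire, ped.dam
    Fs = np.where(s >= 0, F[np.maximum(s, 0)], 0.0)
    Fd = np.where(d >= 0, F[np.maximum(d, 0)], 0.0)
    both = (s >= 0) & (d >= 0)
    one = (s >= 0) ^ (d >= 0)
    out = np.ones(ped.n)
    out[both] = 0.5 - 0.25 * (Fs[both] + Fd[both])
    out[one] = 0.75 - 0.25 * (Fs[one] + Fd[one])
    return out


def a_matrix(ped: Pedigree) -> np.ndarray:
    """Dense A by the tabular method (small pedigrees / test oracle)."""
    return _kernels.tabular_a(ped.sire, ped.dam)


def a_inverse(ped: Pedigree, F: np.ndarray | None = None) -> sp.csr_matrix:
    """Sparse A^-1 by Henderson's rules accounting for inbreeding."""
    if F is None:
        F = inbreeding(ped)
    alpha = 1.0 / mendelian_variance(ped, F)
    n = ped.n
    i = np.arange(n)
    s, d = ped.sire, ped.dam
    rows = [i]
    cols = [i]
    vals = [alpha]
    for par in (s, d):
        k = par >= 0
        rows += [i[k], par[k], par[k]]
        cols += [par[k], i[k], par[k]]
        vals += [-0.5 * alpha[k], -0.5 * alpha[k], 0.25 * alpha[k]]
    both = (s >= 0) & (d >= 0)
    rows += [s[both], d[both]]
    cols += [d[both], s[both]]
    vals += [0.25 * alpha[both], 0.25 * alpha[both]]
    m = sp.coo_matrix((np.concatenate(vals),
                       (np.concatenate(rows), np.concatenate(cols))),
                      shape=(n, n))
    return m.tocsr()


def a22(ped: Pedigree, genotyped: np.ndarray,
        F: np.ndarray | None = None) -> np.ndarray:
    """Dense relationship block among ``genotyped`` pedigree rows."""
    genotyped = np.asarray(genotyped, dtype=np.int64)
    if ped.n <= _COLLEAU_THRESHOLD:
        return a_matrix(ped)[np.ix_(genotyped, genotyped)]
    if F is None:
        F = inbreeding(ped)
    D = mendelian_variance(ped, F)
    return _kernels.a22_colleau(ped.sire, ped.dam, D, genotyped)


@dataclass
class PedigreeMatrixSet:
    """A^-1, inbreeding, and the genotyped-block pieces used by ssGBLUP."""

    a_inv: sp.csr_matrix
    F: np.ndarray
    genotyped: np.ndarray | None = None
    a22: np.ndarray | None = None


def build_pedigree_matrices(ped: Pedigree,
                            genotyped: np.ndarray | None = None) -> PedigreeMatrixSet:
    ped.validate()
    F = inbreeding(ped)
    ainv = a_inverse(ped, F)
    blk = a22(ped, genotyped, F) if genotyped is not None else None
    return PedigreeMatrixSet(a_inv=ainv, F=F, genotyped=genotyped, a22=blk)


def vanraden_g(obs: ObservedGenotypes | np.ndarray,
               freqs: np.ndarray | None = None) -> np.ndarray:
    """VanRaden genomic relationship matrix from dosages.

    Missing dosages (coded -1) are mean-imputed to 2 p_j.  Allele
    frequencies default to the observed frequencies of the genotyped set
    itself (centering then makes the column sums of M - P zero).
    """
    if isinstance(obs, ObservedGenotypes):
        dosage = obs.dosage
    else:
        dosage = np.asarray(obs)
    if freqs is None:
        masked = np.ma.masked_less(dosage, 0)
        freqs = np.asarray(masked.mean(axis=0)) / 2.0
    p = np.asarray(freqs, dtype=np.float64)
    het = p * (1.0 - p)
    denom = 2.0 * float(het.sum())
    if denom <= 0.0:
        raise ValueError("all markers monomorphic: VanRaden denominator is zero")
    Z = dosage.astype(np.float64)
    miss = dosage < 0
    if np.any(miss):
        Z[miss] = np.broadcast_to(2.0 * p, Z.shape)[miss]
    Z -= 2.0 * p
    return (Z @ Z.T) / denom


def blend_g(G: np.ndarray, A22_: np.ndarray, beta: float = 0.05) -> np.ndarray:
    """G* = (1 - beta) G + beta A22 (restores full rank of G)."""
    if not 0.0 <= beta <= 1.0:
        raise ValueError("beta must lie in [0, 1]")
    return (1.0 - beta) * G + beta * A22_


def invert_g_with_blending(G: np.ndarray, A22_: np.ndarray,
                           beta: float = 0.05) -> np.ndarray:
    """Inverse of the blended genomic matrix G*."""
    Gstar = blend_g(G, A22_, beta)
    try:
        c, low = sla.cho_factor(Gstar, check_finite=False)
    except sla.LinAlgError as e:
        raise ValueError("blended genomic matrix is numerically singular") from e
    inv = sla.cho_solve((c, low), np.eye(Gstar.shape[0]), check_finite=False)
    return 0.5 * (inv + inv.T)


@dataclass
class BlendedInverse:
    """H^-1 = A^-1 plus a dense correction on the genotyped block.

    ``delta`` holds G*^-1 - A22^-1 for rows/cols ``genotyped``.
    """

    a_inv: sp.csr_matrix
    genotyped: np.ndarray
    delta: np.ndarray

    @property
    def n(self) -> int:
        return self.a_inv.shape[0]

    def matvec(self, x: np.ndarray) -> np.ndarray:
        y = self.a_inv @ x
        y[self.genotyped] += self.delta @ x[self.genotyped]
        return y

    def diagonal(self) -> np.ndarray:
        d = np.asarray(self.a_inv.diagonal()).copy()
        d[self.genotyped] += np.diagonal(self.delta)
        return d

    def to_dense(self) -> np.ndarray:
        H = self.a_inv.toarray()
        H[np.ix_(self.genotyped, self.genotyped)] += self.delta
        return H


def h_inverse(a_inv: sp.csr_matrix, a22_block: np.ndarray, g_inv: np.ndarray,
              genotyped: np.ndarray) -> BlendedInverse:
    """Assemble the single-step blended inverse from its pieces."""
    genotyped = np.asarray(genotyped, dtype=np.int64)
    m = len(genotyped)
    if a22_block.shape != (m, m) or g_inv.shape != (m, m):
        raise ValueError("genotyped-block shapes do not match the index set")
    a22_inv = sla.inv(a22_block, check_finite=False)
    a22_inv = 0.5 * (a22_inv + a22_inv.T)
    return BlendedInverse(a_inv=a_inv, genotyped=genotyped,
                          delta=g_inv - a22_inv)
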