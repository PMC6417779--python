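"""Numba kernels: meiosis, breeding values, pedigree algebra, pairwise LD.

All kernels are deterministic given their inputs; every source of randomness
is drawn outside with a seeded numpy Generator and passed in as arrays.
"""

import numpy as np
from numba import njit


@njit(cache=False, inline="always")
def _seg_copy(dst8, dst64, src8, src64, a, b):
    # byte-copy the unaligned edges, word-copy the aligned middle
    a8 = min(b, (a + 7) & ~7)
    for k in range(a, a8):
        dst8[k] = src8[k]
    b8 = b & ~7
    for w in range(a8 >> 3, b8 >> 3):
        dst64[w] = src64[w]
    for k in range(max(b8, a8), b):
        dst8[k] = src8[k]


@njit(cache=False)
def gametes_kernel(out8, out64, haps8, haps64, parent_idx, start_hap,
                   xo_counts, xo_offsets, xo_pos, chrom_bounds, locus_pos_m):
    # out8: (n_gam, L) int8 aliasing out64: (n_gam, L//8) int64
    # haps8: (n_ind, 2, L) int8 aliasing haps64 likewise
    # start_hap: (n_gam, C) uint8, xo_counts/xo_offsets: (n_gam, C) int64
    # xo_pos: flat crossover positions (Morgans, within chromosome)
    n_gam = out8.shape[0]
    n_chrom = chrom_bounds.shape[0]
    for g in range(n_gam):
        p = parent_idx[g]
        d8 = out8[g]
        d64 = out64[g]
        for c in range(n_chrom):
            lo = chrom_bounds[c, 0]
            hi = chrom_bounds[c, 1]
            h = start_hap[g, c]
            k = xo_counts[g, c]
            off = xo_offsets[g, c]
            # insertion-sort the (small) crossover position slice
            for a in range(off + 1, off + k):
                key = xo_pos[a]
                b = a - 1
                while b >= off and xo_pos[b] > key:
                    xo_pos[b + 1] = xo_pos[b]
                    b -= 1
                xo_pos[b + 1] = key
            cur = lo
            for e in range(k):
                x = xo_pos[off + e]
                cut = lo + np.searchsorted(locus_pos_m[lo:hi], x)
                if cut > cur:
                    _seg_copy(d8, d64, haps8[p, h], haps64[p, h], cur, cut)
                    cur = cut
                h = 1 - h
            if hi > cur:
                _seg_copy(d8, d64, haps8[p, h], haps64[p, h], cur, hi)


@njit(cache=False)
def tbv_kernel(haps, qtl_loci, effects, out):
    # out[i] = sum_q effects[q, maternal allele] + effects[q, paternal allele]
    n = haps.shape[0]
    nq = qtl_loci.shape[0]
    for i in range(n):
        t = 0.0
        for q in range(nq):
            l = qtl_loci[q]
            t += effects[q, haps[i, 0, l]] + effects[q, haps[i, 1, l]]
        out[i] = t


@njit(cache=False)
def meuwissen_luo(sire, dam, F, start):
    """Fill F[start:] given valid F[:start]; parents precede offspring."""
    n = sire.shape[0]
    L = np.zeros(n)
    inanc = np.zeros(n, np.uint8)
    for i in range(start, n):
        s = sire[i]
        d = dam[i]
        if s < 0 or d < 0:
            F[i] = 0.0
            continue
        L[i] = 1.0
        inanc[i] = 1
        acc = 0.0
        for j in range(i, -1, -1):
            if inanc[j] == 1:
                lj = L[j]
                sj = sire[j]
                dj = dam[j]
                if sj >= 0:
                    L[sj] += 0.5 * lj
                    inanc[sj] = 1
                if dj >= 0:
                    L[dj] += 0.5 * lj
                    inanc[dj] = 1
                # mendelian sampling variance of j from parental inbreeding
                if sj >= 0 and dj >= 0:
                    dd = 0.5 - 0.25 * (F[sj] + F[dj])
                elif sj >= 0:
                    dd = 0.75 - 0.25 * F[sj]
                elif dj >= 0:
                    dd = 0.75 - 0.25 * F[dj]
                else:
                    dd = 1.0
                acc += lj * lj * dd
                L[j] = 0.0
                inanc[j] = 0
        F[i] = acc - 1.0


@njit(cache=False)
def tabular_a(sire, dam):
    n = sire.shape[0]
    A = np.zeros((n, n))
    for i in range(n):
        s = sire[i]
        d = dam[i]
        for j in range(i):
            aij = 0.0
            if s >= 0:
                aij += 0.5 * A[j, s]
            if d >= 0:
                aij += 0.5 * A[j, d]
            A[i, j] = aij
            A[j, i] = aij
        aii = 1.0
        if s >= 0 and d >= 0:
            aii += 0.5 * A[s, d]
        A[i, i] = aii
    return A


@njit(cache=False)
def a22_colleau(sire, dam, D, gidx):
    """A22 by the indirect method: columns of A = (I-P)^-1 D (I-P)^-T e_j."""
    n = sire.shape[0]
    m = gidx.shape[0]
    out = np.empty((m, m))
    w = np.zeros(n)
    v = np.zeros(n)
    for col in range(m):
        j = gidx[col]
        w[j] = 1.0
        for i in range(j, -1, -1):
            wi = w[i]
            if wi != 0.0:
                s = sire[i]
                d = dam[i]
                if s >= 0:
                    w[s] += 0.5 * wi
                if d >= 0:
                    w[d] += 0.5 * wi
        for i in range(n):
            t = D[i] * w[i]
            s = sire[i]
            d = dam[i]
            if s >= 0:
                t += 0.5 * v[s]
            if d >= 0:
                t += 0.5 * v[d]
            v[i] = t
        for r in range(m):
            out[r, col] = v[gidx[r]]
        w[: j + 1] = 0.0
        v[:] = 0.0
    # exact symmetry up to fp noise
    for a in range(m):
        for b in range(a):
            s2 = 0.5 * (out[a, b] + out[b, a])
            out[a, b] = s2
            out[b, a] = s2
    return out


@njit(cache=False)
def ld_r2_kernel(h, pi, pj, r2):
    """r2 per locus pair from 0/1 haplotype matrix h (n_hap, m).

    Monomorphic members yield nan (pair skipped downstream).
    """
    n = h.shape[0]
    m = h.shape[1]
    s = np.zeros(m)
    for l in range(m):
        t = 0
        for k in range(n):
            t += h[k, l]
        s[l] = t
    for p in range(pi.shape[0]):
        a = pi[p]
        b = pj[p]
        sa = s[a]
        sb = s[b]
        va = n * sa - sa * sa
        vb = n * sb - sb * sb
        if va <= 0.0 or vb <= 0.0:
            r2[p] = np.nan
            continue
        c = 0
        for k in range(n):
            c += h[k, a] * h[k, b]
        d = n * c - sa * sb
        r2[p] = (d * d) / (va * vb)
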