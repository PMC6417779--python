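"""Animal-model solvers: BLUP, multi-step GBLUP, single-step GBLUP.

All three fit the single-trait model

    y = 1 mu + Z a + e,    a ~ N(0, K sigma_a^2),  e ~ N(0, I sigma_e^2)

with known variance components (sigma_a^2 = h2, sigma_e^2 = 1 - h2 on a
phenotypic variance of 1) and differ only in the relationship kernel K:
the pedigree matrix A for BLUP, the VanRaden genomic matrix G for
GBLUP, and the blended matrix H for single-step GBLUP.  BLUP and
ssGBLUP solve Henderson's mixed-model equations

    [ 1'1   1'Z          ] [mu]   [1'y]
    [ Z'1   Z'Z + la K^-1] [a ] = [Z'y],   la = sigma_e^2 / sigma_a^2;

GBLUP uses the algebraically identical variance-component form
(sigma_a^2 G V^-1 residuals) which avoids inverting G at every
training-set size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg as sla
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .relationship import BlendedInverse

_DENSE_LIMIT = 3000     # ssGBLUP systems up to this size are solved directly
_CG_TOL = 1e-10


@dataclass
class EvaluationResult:
    mu_hat: float
    ebv: np.ndarray
    iterations: int = 0
    residual: float = 0.0

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.ebv)) or not np.isfinite(self.mu_hat):
            raise ValueError("non-finite solution")


def _lambda(h2: float) -> float:
    if not 0.0 < h2 < 1.0:
        raise ValueError("h2 must lie strictly between 0 and 1")
    return (1.0 - h2) / h2


def _record_arrays(n: int, record_idx: np.ndarray, y: np.ndarray):
    record_idx = np.asarray(record_idx, dtype=np.int64)
    y = np.asarray(y, dtype=np.float64)
    if len(record_idx) == 0:
        raise ValueError("no phenotype records: system is singular")
    if record_idx.max() >= n:
        raise ValueError("record index outside the evaluated population")
    counts = np.bincount(record_idx, minlength=n).astype(np.float64)
    zty = np.bincount(record_idx, weights=y, minlength=n)
    return record_idx, y, counts, zty


def solve_blup(n: int, record_idx: np.ndarray, y: np.ndarray,
               a_inv: sp.spmatrix, h2: float) -> EvaluationResult:
    """Pedigree BLUP via sparse Henderson MME (direct factorization).

    Animals without records (including masked prediction animals) obtain
    EBVs through their relationships.
    """
    record_idx, y, counts, zty = _record_arrays(n, record_idx, y)
    lam = _lambda(h2)
    C22 = sp.diags(counts) + lam * a_inv
    z = counts  # 1'Z per animal (record count)
    top = sp.hstack([sp.csr_matrix([[float(len(y))]]), sp.csr_matrix(z[None, :])])
    bottom = sp.hstack([sp.csr_matrix(z[:, None]), C22])
    C = sp.vstack([top, bottom]).tocsc()
    rhs = np.concatenate([[y.sum()], zty])
    if n <= _DENSE_LIMIT:
        sol = spla.spsolve(C, rhs)
        it = 0
    else:
        # SPD system: Jacobi-preconditioned conjugate gradients avoids the
        # heavy fill-in of a direct factorization at this size
        diag = C.diagonal()
        diag[diag <= 0] = 1.0
        M = spla.LinearOperator(C.shape, matvec=lambda x: x / diag)
        sol, info = spla.cg(C, rhs, rtol=_CG_TOL, atol=0.0, maxiter=20000, M=M)
        it = max(int(info), 0)
    resid = float(np.linalg.norm(C @ sol - rhs) / max(1.0, np.linalg.norm(rhs)))
    if resid > 1e-6:
        raise RuntimeError(f"mixed-model solve failed (resid={resid:.2e})")
    return EvaluationResult(mu_hat=float(sol[0]), ebv=sol[1:], iterations=it,
                            residual=resid)


def solve_gblup(G_star: np.ndarray, record_mask: np.ndarray, y: np.ndarray,
                h2: float) -> EvaluationResult:
    """Multi-step GBLUP over the genotyped set.

    ``G_star`` covers all genotyped animals (training and prediction);
    ``record_mask`` flags the training animals, ``y`` their phenotypes in
    the same order.  Returns direct genomic values for every animal in
    ``G_star``; prediction animals carry no records and are predicted
    through their genomic relationships.
    """
    record_mask = np.asarray(record_mask, dtype=bool)
    y = np.asarray(y, dtype=np.float64)
    if record_mask.sum() != len(y):
        raise ValueError("record mask and phenotype vector disagree")
    if record_mask.sum() == 0:
        raise ValueError("no phenotype records: system is singular")
    sg2 = h2
    se2 = 1.0 - h2
    T = np.where(record_mask)[0]
    V = sg2 * G_star[np.ix_(T, T)] + se2 * np.eye(len(T))
    c, low = sla.cho_factor(V, check_finite=False)
    vi_y = sla.cho_solve((c, low), y, check_finite=False)
    vi_1 = sla.cho_solve((c, low), np.ones(len(T)), check_finite=False)
    mu = float(vi_y.sum() / vi_1.sum())
    vi_r = vi_y - mu * vi_1
    ebv = sg2 * (G_star[:, T] @ vi_r)
    return EvaluationResult(mu_hat=mu, ebv=ebv)


def solve_ssgblup(n: int, record_idx: np.ndarray, y: np.ndarray,
                  h_inv: BlendedInverse, h2: float) -> EvaluationResult:
    """Single-step GBLUP: BLUP's MME with A^-1 replaced by H^-1.

    Small systems are assembled densely and solved directly; large ones
    use Jacobi-preconditioned conjugate gradients on an implicit
    operator (sparse A^-1 plus the dense genotyped-block correction).
    """
    record_idx, y, counts, zty = _record_arrays(n, record_idx, y)
    lam = _lambda(h2)
    rhs = np.concatenate([[y.sum()], zty])
    if n <= _DENSE_LIMIT:
        C = np.zeros((n + 1, n + 1))
        C[0, 0] = float(len(y))
        C[0, 1:] = counts
        C[1:, 0] = counts
        C[1:, 1:] = lam * h_inv.to_dense()
        C[1:, 1:][np.diag_indices(n)] += counts
        sol = np.linalg.solve(C, rhs)
        resid = float(np.linalg.norm(C @ sol - rhs) / np.linalg.norm(rhs))
        return EvaluationResult(mu_hat=float(sol[0]), ebv=sol[1:], residual=resid)

    def matvec(x: np.ndarray) -> np.ndarray:
        out = np.empty_like(x)
        out[0] = len(y) * x[0] + counts @ x[1:]
        out[1:] = counts * x[0] + counts * x[1:] + lam * h_inv.matvec(x[1:])
        return out

    op = spla.LinearOperator((n + 1, n + 1), matvec=matvec)
    diag = np.concatenate([[float(len(y))], counts + lam * h_inv.diagonal()])
    diag[diag <= 0] = 1.0
    M = spla.LinearOperator((n + 1, n + 1), matvec=lambda x: x / diag)
    sol, info = spla.cg(op, rhs, rtol=_CG_TOL, atol=0.0, maxiter=20000, M=M)
    resid = float(np.linalg.norm(matvec(sol) - rhs) / np.linalg.norm(rhs))
    if info != 0 and resid > 1e-6:
        raise RuntimeError(f"conjugate gradients failed to converge (resid={resid:.2e})")
    return EvaluationResult(mu_hat=float(sol[0]), ebv=sol[1:],
                            iterations=int(info) if info > 0 else 0,
                            residual=resid)


def solve_gblup_pseudophenotypes(*args, **kwargs):
    """Multi-step GBLUP on deregressed pseudo-phenotypes.

    Not implemented: the variant shipped here regresses raw training
    phenotypes (see :func:`solve_gblup`), which is the displayed model
    this package follows; a deregression front-end may be added later.
    """
    raise NotImplementedError(
        "deregressed pseudo-phenotype GBLUP is not implemented; "
        "use solve_gblup on raw training phenotypes")


def accuracy(tbv: np.ndarray, ebv: np.ndarray) -> float:
    """Pearson correlation between true and estimated breeding values."""
    tbv = np.asarray(tbv, dtype=np.float64)
    ebv = np.asarray(ebv, dtype=np.float64)
    if len(tbv) < 3 or len(tbv) != len(ebv):
        raise ValueError("need >= 3 paired values")
    if np.std(tbv) == 0.0 or np.std(ebv) == 0.0:
        raise ValueError("zero variance in TBV or EBV")
    return float(np.corrcoef(tbv, ebv)[0, 1])


def bias(tbv: np.ndarray, ebv: np.ndarray) -> float:
    """OLS slope of TBV on EBV: 1 = unbiased, < 1 = inflated predictions."""
    tbv = np.asarray(tbv, dtype=np.float64)
    ebv = np.asarray(ebv, dtype=np.float64)
    v = np.var(ebv)
    if v == 0.0:
        raise ValueError("zero EBV variance")
    return float(np.cov(ebv, tbv, bias=True)[0, 1] / v)
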