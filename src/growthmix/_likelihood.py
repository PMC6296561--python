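"""Internal marginal-likelihood machinery shared by the LME and GMM fitters.

Subjects are grouped by identical observation schedules: within a group
the random-effect design Z and hence the marginal covariance
V = Z G Z' + sigma^2 I are shared, so balanced designs cost one small
covariance factorization per variance evaluation.

Variance parameters use a log-Cholesky parameterization
theta = (lower-triangular Cholesky of G with log diagonal, log sigma),
which keeps G positive semi-definite and sigma^2 positive by
construction.  Gradients with respect to theta are analytic.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve

from .basis import DesignInfo, MeanModelSpec, RandomEffectsSpec
from .data import LongitudinalDataset

LOG2PI = np.log(2.0 * np.pi)


@dataclass
class Block:
    times: np.ndarray      # (n_i,)
    ids: list[str]
    idx: np.ndarray        # (m,) global subject indices
    Y: np.ndarray          # (m, n_i)
    X: np.ndarray          # (m, n_i, p)
    Z: np.ndarray          # (n_i, q)


@dataclass
class BlockDesign:
    info: DesignInfo
    blocks: list[Block]
    subject_ids: list[str]

    @property
    def p(self) -> int:
        return self.blocks[0].X.shape[2]

    @property
    def q(self) -> int:
        return self.blocks[0].Z.shape[1]

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def n_obs(self) -> int:
        return sum(b.Y.size for b in self.blocks)

    @classmethod
    def build(
        cls,
        dataset: LongitudinalDataset,
        mean_spec: MeanModelSpec,
        re_spec: RandomEffectsSpec,
        force_zero_G: bool = False,
    ) -> "BlockDesign":
        info = DesignInfo.from_dataset(mean_spec, dataset, re_spec)
        order = {sid: i for i, sid in enumerate(dataset.subject_ids)}
        blocks = []
        for times, ids, Y, X, Z in info.subject_designs(dataset):
            if force_zero_G:
                Z = np.zeros((len(times), 0))
            blocks.append(Block(times, ids, np.array([order[s] for s in ids]), Y, X, Z))
        return cls(info, blocks, dataset.subject_ids)


# -- variance parameterization ---------------------------------------

def n_theta(q: int) -> int:
    return q * (q + 1) // 2 + 1


def tril_indices(q: int) -> list[tuple[int, int]]:
    return [(a, b) for a in range(q) for b in range(a + 1)]


def chol_from_theta(theta: np.ndarray, q: int) -> np.ndarray:
    L = np.zeros((q, q))
    for j, (a, b) in enumerate(tril_indices(q)):
        L[a, b] = np.exp(theta[j]) if a == b else theta[j]
    return L


def theta_from_G_sigma(G: np.ndarray, sigma2: float) -> np.ndarray:
    q = G.shape[0]
    if q:
        L = np.linalg.cholesky(G + 1e-12 * np.eye(q))
    theta = []
    for a, b in tril_indices(q):
        theta.append(np.log(max(L[a, a], 1e-8)) if a == b else L[a, b])
    theta.append(0.5 * np.log(sigma2))
    return np.asarray(theta)


def G_sigma_from_theta(theta: np.ndarray, q: int) -> tuple[np.ndarray, float]:
    L = chol_from_theta(theta, q)
    return L @ L.T, float(np.exp(2.0 * theta[-1]))


@dataclass
class VarTerms:
    """Per-block factorized marginal covariance pieces."""

    Vinv: list[np.ndarray]
    logdet: list[float]
    S: list[np.ndarray]       # Z' Vinv Z, for theta-gradients
    VinvZ: list[np.ndarray]


def variance_terms(theta: np.ndarray, design: BlockDesign) -> VarTerms:
    q = design.q
    G, sigma2 = G_sigma_from_theta(theta, q)
    Vinv, logdet, S, VinvZ = [], [], [], []
    for blk in design.blocks:
        ni = len(blk.times)
        V = sigma2 * np.eye(ni)
        if q:
            V = V + blk.Z @ G @ blk.Z.T
        try:
            c, low = cho_factor(V, lower=True)
        except np.linalg.LinAlgError:
            # extreme variance ratios can defeat the factorization even
            # though V is PD by construction; retry with relative jitter
            V = V + (1e-10 * np.trace(V) / ni) * np.eye(ni)
            c, low = cho_factor(V, lower=True)
        Vi = cho_solve((c, low), np.eye(ni))
        Vinv.append(Vi)
        logdet.append(2.0 * float(np.sum(np.log(np.diag(c)))))
        vz = Vi @ blk.Z if q else np.zeros((ni, 0))
        VinvZ.append(vz)
        S.append(blk.Z.T @ vz if q else np.zeros((0, 0)))
    return VarTerms(Vinv, logdet, S, VinvZ)


# -- Gaussian class log-densities and GLS ------------------------------

def class_logdens(design: BlockDesign, vt: VarTerms, betas: np.ndarray) -> np.ndarray:
    """log N(y_i; X_i beta_k, V_i) for every subject i and class k.

    ``betas`` has shape (K, p); returns (n_subjects, K).
    """
    K = betas.shape[0]
    out = np.empty((design.n_subjects, K))
    for blk, Vi, ld in zip(design.blocks, vt.Vinv, vt.logdet):
        ni = len(blk.times)
        mu = np.einsum("mip,kp->kmi", blk.X, betas)
        r = blk.Y[None, :, :] - mu                      # (K, m, ni)
        quad = np.einsum("kmi,ij,kmj->km", r, Vi, r)
        out[blk.idx, :] = (-0.5 * (ni * LOG2PI + ld + quad)).T
    return out


def weighted_gls(design: BlockDesign, vt: VarTerms, tau: np.ndarray) -> np.ndarray:
    """Responsibility-weighted GLS estimates, one beta per class.

    ``tau`` is (n_subjects, K); columns of ones give plain GLS.
    """
    K = tau.shape[1]
    p = design.p
    A = np.zeros((K, p, p))
    b = np.zeros((K, p))
    for blk, Vi in zip(design.blocks, vt.Vinv):
        XtVi = np.einsum("mip,ij->mpj", blk.X, Vi)
        XtViX = np.einsum("mpj,mjq->mpq", XtVi, blk.X)
        XtViY = np.einsum("mpj,mj->mp", XtVi, blk.Y)
        w = tau[blk.idx, :]                              # (m, K)
        A += np.einsum("mk,mpq->kpq", w, XtViX)
        b += np.einsum("mk,mp->kp", w, XtViY)
        del XtVi
    betas = np.empty((K, p))
    for k in range(K):
        betas[k] = np.linalg.solve(A[k], b[k])
    return betas


def gls_information(design: BlockDesign, vt: VarTerms) -> np.ndarray:
    """sum_i X_i' Vinv X_i — the GLS information for the fixed effects."""
    p = design.p
    A = np.zeros((p, p))
    for blk, Vi in zip(design.blocks, vt.Vinv):
        A += np.einsum("mip,ij,mjq->pq", blk.X, Vi, blk.X)
    return A


def _theta_grad_pieces(design: BlockDesign, vt: VarTerms, betas: np.ndarray,
                       tau: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """Gradient of sum_ik tau_ik log N(y_i; X_i beta_k, V_i) w.r.t. theta.

    Uses dV/dtheta_j = Z (dL L' + L dL') Z' so traces and quadratic forms
    reduce to the q x q matrices S = Z'VinvZ and u = Z'Vinv r.
    """
    q = design.q
    L = chol_from_theta(theta, q)
    sigma2 = float(np.exp(2.0 * theta[-1]))
    idx = tril_indices(q)
    nth = n_theta(q)
    grad = np.zeros(nth)
    for blk, Vi, S, VinvZ in zip(design.blocks, vt.Vinv, vt.S, vt.VinvZ):
        mu = np.einsum("mip,kp->kmi", blk.X, betas)
        r = blk.Y[None, :, :] - mu                       # (K, m, ni)
        w = tau[blk.idx, :].T                            # (K, m)
        w_tot = float(w.sum())
        Vr = np.einsum("ij,kmj->kmi", Vi, r)             # Vinv r
        if q:
            u = np.einsum("iq,kmi->kmq", VinvZ, r)       # Z'Vinv r
            # weighted sum of u u' over subjects/classes
            U = np.einsum("km,kma,kmb->ab", w, u, u)
        # log sigma component
        trace_part = w_tot * float(np.trace(Vi))
        quad_part = float(np.einsum("km,kmi,kmi->", w, Vr, Vr))
        grad[-1] += -0.5 * 2.0 * sigma2 * (trace_part - quad_part)
        for j, (a, b) in enumerate(idx):
            dL = np.zeros((q, q))
            dL[a, b] = L[a, a] if a == b else 1.0
            dG = dL @ L.T + L @ dL.T
            tr = w_tot * float(np.sum(S * dG))
            qd = float(np.sum(U * dG))
            grad[j] += -0.5 * (tr - qd)
    return grad


def q_variance(theta: np.ndarray, design: BlockDesign, betas: np.ndarray,
               tau: np.ndarray) -> float:
    vt = variance_terms(theta, design)
    A = class_logdens(design, vt, betas)
    return float(np.sum(tau * A))


def q_variance_neg_grad(theta: np.ndarray, design: BlockDesign, betas: np.ndarray,
                        tau: np.ndarray) -> tuple[float, np.ndarray]:
    vt = variance_terms(theta, design)
    A = class_logdens(design, vt, betas)
    val = float(np.sum(tau * A))
    grad = _theta_grad_pieces(design, vt, betas, tau, theta)
    return -val, -grad


def profiled_nll_grad(theta: np.ndarray, design: BlockDesign):
    """Negative profiled (beta concentrated out by GLS) ML log-likelihood
    and its gradient; the envelope theorem makes the gradient the partial
    theta-derivative evaluated at the GLS beta."""
    vt = variance_terms(theta, design)
    ones = np.ones((design.n_subjects, 1))
    beta = weighted_gls(design, vt, ones)
    ll = float(np.sum(class_logdens(design, vt, beta)))
    grad = _theta_grad_pieces(design, vt, beta, ones, theta)
    return -ll, -grad, beta


def theta_bounds(q: int) -> list[tuple[float, float]]:
    bounds = []
    for a, b in tril_indices(q):
        bounds.append((-10.0, 6.0) if a == b else (-200.0, 200.0))
    bounds.append((-10.0, 6.0))
    return bounds
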