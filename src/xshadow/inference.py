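"""Exact posterior inference and EM parameter learning.

With the direction variables H fixed, each gene submodel is a tree
(D -> F_m -> G_{m,n} -> y_{m,n}), so sum-product message passing gives
exact marginals in O(M * N).  Every message is kept in log space and
collapsed with log-sum-exp: a gene may have thousands of connected genes
and linear-space products would underflow immediately.

:func:`enumerate_posteriors` is an independent brute-force oracle that
sums the exponentiated joint over every latent assignment; it exists to
cross-check the message-passing code on small instances and refuses
anything larger.

:func:`em_fit` pools expected counts across all submodels: the thetas are
shared across mutated genes within one analysis, which is what lets weak
per-gene evidence borrow strength across the cohort.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .errors import EnumerationSizeError, XshadowError
from .model import (
    DOWN,
    UP,
    GeneSubmodel,
    ModelParameters,
    Posteriors,
    effective_g_cpd,
)

logger = logging.getLogger(__name__)

def _leaf_log_tables(sub: GeneSubmodel, params: ModelParameters):
    """Per-neighbour leaf CPDs in log space: (N, 2, 3) over (F, G)."""
    if sub.h is None:
        raise XshadowError("fix H on the submodel before inference")
    tables = np.empty((sub.N, 2, 3))
    for n in range(sub.N):
        f0, f1 = effective_g_cpd(params, float(sub.weights[n]), int(sub.h[n]))
        tables[n, 0] = f0
        tables[n, 1] = f1
    return np.log(tables)


def infer_posteriors(sub: GeneSubmodel, params: ModelParameters) -> Posteriors:
    """Exact marginals P(D), P(F_m), P(G_{m,n}) by sum-product on the tree.

    Each leaf is collapsed first (sum over G of P(G|F,H) p(y|G) for both F
    values), per-patient evidence is combined across neighbours, and the
    patient messages are aggregated into D's posterior.  Missing leaves
    contribute nothing.  If no patient has any observed neighbour, the
    prior marginals are returned with a warning.
    """
    M, N = sub.M, sub.N
    log_t = _leaf_log_tables(sub, params)  # (N, 2, 3)
    obs = sub.observed
    log_em = np.where(obs[:, :, None], np.nan_to_num(sub.log_emission, nan=0.0), 0.0)

    # collapse each leaf: l[m, n, f] = log sum_k P(G=k|F=f) p(y|G=k)
    leaf = logsumexp(log_t.transpose(1, 0, 2)[None, :, :, :] + log_em[:, None, :, :], axis=3)
    leaf = np.where(obs[:, None, :], leaf, 0.0)  # (M, 2, N)
    if not obs.any():
        warnings.warn(f"gene {sub.gene}: no observed neighbour expression; returning priors")
    a = leaf.sum(axis=2)  # (M, 2): log evidence per patient given F
    log_pf = np.log(
        np.array(
            [
                [1.0 - params.theta_f_d0, params.theta_f_d0],
                [1.0 - params.theta_f_d1, params.theta_f_d1],
            ]
        )
    )  # (d, f)
    # s[m, d] = log sum_f P(F=f|D=d) exp(a[m, f])
    s = logsumexp(log_pf[None, :, :] + a[:, None, :], axis=2)  # (M, 2)
    log_prior_d = np.log(np.array([1.0 - params.theta_d, params.theta_d]))
    log_post_d = log_prior_d + s.sum(axis=0)  # (2,)
    log_z = logsumexp(log_post_d)
    p_d = float(np.exp(log_post_d[1] - log_z))

    # joint P(F_m = f, D = d | Y): swap patient m's message for its f-specific term
    rest = s.sum(axis=0)[None, :] - s  # (M, 2): sum over the other patients
    log_joint_fd = log_prior_d[None, :, None] + rest[:, :, None] + log_pf[None, :, :] + a[:, None, :]
    log_joint_fd -= log_z
    joint_fd = np.exp(log_joint_fd)  # (M, 2, 2) over (d, f)
    p_f = joint_fd[:, :, 1].sum(axis=1)  # (M,)

    # leaf posteriors: P(G|F=f, y) then mix over P(F|Y)
    with np.errstate(invalid="ignore"):
        cond = log_t.transpose(1, 0, 2)[None, :, :, :] + log_em[:, None, :, :]  # (M, 2, N, 3)
        cond = cond - logsumexp(cond, axis=3, keepdims=True)
    r = np.exp(cond)  # (M, 2, N, 3): P(G=k | F=f, y_{m,n})
    pf_both = np.stack([1.0 - p_f, p_f], axis=1)  # (M, 2)
    p_g = np.einsum("mf,mfnk->mnk", pf_both, r)
    # unobserved leaves: posterior over G is the CPD mixed over F
    if not obs.all():
        prior_g = np.einsum("mf,fnk->mnk", pf_both, np.exp(log_t).transpose(1, 0, 2))
        p_g = np.where(obs[:, :, None], p_g, prior_g)
    return Posteriors(p_d=p_d, p_f=p_f, p_g=p_g, log_marginal=float(log_z))


def _estep_counts(sub: GeneSubmodel, params: ModelParameters):
    """Posteriors plus the expected counts the M-step pools.

    Returns (post, counts) where counts holds
      ed:    P(D=1|Y)
      f_d:   (2, 2) expected counts of (D=d, F=f) summed over patients
      g0:    (3,) expected counts for the null G table
      g1:    (2, 3) expected counts for the dysregulated tables by H,
             with each leaf's F=1 mass split between the real-edge table
             and the null table by the convex-mixture responsibility.
    """
    M, N = sub.M, sub.N
    log_t = _leaf_log_tables(sub, params)
    obs = sub.observed
    log_em = np.where(obs[:, :, None], np.nan_to_num(sub.log_emission, nan=0.0), 0.0)
    leaf = logsumexp(log_t.transpose(1, 0, 2)[None, :, :, :] + log_em[:, None, :, :], axis=3)
    leaf = np.where(obs[:, None, :], leaf, 0.0)
    a = leaf.sum(axis=2)
    log_pf = np.log(
        np.array(
            [
                [1.0 - params.theta_f_d0, params.theta_f_d0],
                [1.0 - params.theta_f_d1, params.theta_f_d1],
            ]
        )
    )
    s = logsumexp(log_pf[None, :, :] + a[:, None, :], axis=2)
    log_prior_d = np.log(np.array([1.0 - params.theta_d, params.theta_d]))
    log_post_d = log_prior_d + s.sum(axis=0)
    log_z = logsumexp(log_post_d)
    rest = s.sum(axis=0)[None, :] - s
    log_joint_fd = log_prior_d[None, :, None] + rest[:, :, None] + log_pf[None, :, :] + a[:, None, :]
    joint_fd = np.exp(log_joint_fd - log_z)  # (M, d, f)
    p_f = joint_fd[:, :, 1].sum(axis=1)
    p_d = float(np.exp(log_post_d[1] - log_z))

    with np.errstate(invalid="ignore"):
        cond = log_t.transpose(1, 0, 2)[None, :, :, :] + log_em[:, None, :, :]
        cond = cond - logsumexp(cond, axis=3, keepdims=True)
    r = np.exp(cond)  # (M, 2, N, 3)
    pf_both = np.stack([1.0 - p_f, p_f], axis=1)
    p_g = np.einsum("mf,mfnk->mnk", pf_both, r)
    if not obs.all():
        prior_g = np.einsum("mf,fnk->mnk", pf_both, np.exp(log_t).transpose(1, 0, 2))
        p_g = np.where(obs[:, :, None], p_g, prior_g)
    post = Posteriors(p_d=p_d, p_f=p_f, p_g=p_g, log_marginal=float(log_z))

    # expected counts over observed leaves only
    om = obs.astype(float)
    # P(G=k, F=f | Y) per leaf = P(F=f|Y) * r[m, f, n, k]
    eg = r * pf_both[:, :, None, None] * om[:, None, :, None]  # (M, 2, N, 3)
    g0 = eg[:, 0, :, :].sum(axis=(0, 1))  # F=0 leaves feed the null table
    # split F=1 leaves between the real-edge and null tables
    g1 = np.zeros((2, 3))
    for n in range(sub.N):
        h = int(sub.h[n])
        w = float(sub.weights[n])
        real = w * params.g_table(h)
        null = (1.0 - w) * params.theta_g_f0
        tau = real / (real + null)  # responsibility of the real edge per G state
        contrib = eg[:, 1, n, :].sum(axis=0)
        g1[h] += contrib * tau
        g0 += contrib * (1.0 - tau)
    # non-mutated patients are known-F=0 observations of the null
    # regulation distribution; their responsibilities anchor the null table
    # and stop the F channel from absorbing the cohort's expression tails
    null_ll = 0.0
    if sub.null_log_emission is not None and len(sub.null_log_emission):
        logp0 = np.log(params.theta_g_f0)[None, :] + sub.null_log_emission
        norm0 = logsumexp(logp0, axis=1)
        g0 = g0 + np.exp(logp0 - norm0[:, None]).sum(axis=0)
        null_ll = float(norm0.sum())
    f_d = joint_fd.sum(axis=0)  # (d, f)
    counts = {"ed": p_d, "f_d": f_d, "g0": g0, "g1": g1, "m": M, "null_ll": null_ll}
    return post, counts


def enumerate_posteriors(sub: GeneSubmodel, params: ModelParameters) -> Posteriors:
    """Brute-force marginals by summing over every latent assignment.

    Explicitly evaluates the joint for all 2 * 2^M * 3^(M*N) assignments
    (vectorised over the G block) and accumulates with log-sum-exp.
    Guarded to M * N <= 12.
    """
    M, N = sub.M, sub.N
    if M * N > 12:
        raise EnumerationSizeError(f"enumeration refused for M*N = {M * N} > 12")
    log_t = _leaf_log_tables(sub, params)  # (N, 2, 3)
    obs = sub.observed
    log_em = np.where(obs[:, :, None], np.nan_to_num(sub.log_emission, nan=0.0), 0.0)
    L = M * N
    g_all = np.array(list(itertools.product(range(3), repeat=L)), dtype=int)  # (A, L)
    A = g_all.shape[0]
    leaf_idx = np.arange(L)
    log_z_terms = []
    states = []  # (d, f tuple) per block
    block_logps = []  # (A,) arrays
    for d in (0, 1):
        lp_d = np.log(params.theta_d if d else 1.0 - params.theta_d)
        pf1 = params.theta_f_d1 if d else params.theta_f_d0
        for f in itertools.product((0, 1), repeat=M):
            lp_f = sum(np.log(pf1) if fi else np.log(1.0 - pf1) for fi in f)
            # per-leaf 3-vector contributions under this (d, f); unobserved
            # leaves carry the bare CPD so their G sum contributes factor 1
            c = np.empty((L, 3))
            for m in range(M):
                for n in range(N):
                    li = m * N + n
                    if obs[m, n]:
                        c[li] = log_t[n, f[m]] + log_em[m, n]
                    else:
                        c[li] = log_t[n, f[m]]
            lp_g = c[leaf_idx[None, :], g_all].sum(axis=1)  # (A,)
            block = lp_d + lp_f + lp_g
            block_logps.append(block)
            states.append((d, f))
            log_z_terms.append(logsumexp(block))
    log_z = logsumexp(np.array(log_z_terms))
    # marginals
    p_d = 0.0
    p_f = np.zeros(M)
    p_g = np.zeros((M, N, 3))
    for (d, f), block in zip(states, block_logps):
        w_block = np.exp(block - log_z)  # (A,)
        tot = w_block.sum()
        if d == 1:
            p_d += tot
        for m in range(M):
            if f[m] == 1:
                p_f[m] += tot
            for n in range(N):
                li = m * N + n
                for k in range(3):
                    p_g[m, n, k] += w_block[g_all[:, li] == k].sum()
    return Posteriors(p_d=float(p_d), p_f=p_f, p_g=p_g, log_marginal=float(log_z))


@dataclass
class EMTrace:
    """EM fitting record.

    ``loglik`` is the total log marginal likelihood per iteration;
    ``objective`` adds the log Dirichlet/Beta smoothing prior implied by
    the M-step pseudo-counts.  The objective is the quantity this MAP-EM
    provably never decreases; the raw likelihood tracks it to within the
    (weak) prior's pull and can drift by a hair on very small cohorts.
    """

    loglik: np.ndarray
    objective: np.ndarray
    n_iter: int
    converged: bool
    params: ModelParameters
    scored_genes: list[str] = field(default_factory=list)

    def write_tsv(self, path):
        import pandas as pd

        pd.DataFrame(
            {
                "iteration": np.arange(len(self.loglik)),
                "loglik": self.loglik,
                "objective": self.objective,
            }
        ).to_csv(path, sep="\t", index=False)


_PSEUDO = 0.5  # Dirichlet-style smoothing on every expected count


def _log_prior(params: ModelParameters) -> float:
    """Log of the smoothing prior matching the M-step pseudo-counts.

    Beta(1.5, 1.5) on each Bernoulli parameter, Dirichlet(1.5, 1.5, 1.5)
    on each G table (normalising constants dropped).
    """
    lp = 0.0
    for v in (params.theta_d, params.theta_f_d0, params.theta_f_d1):
        lp += _PSEUDO * (np.log(v) + np.log1p(-v))
    for tab in (params.theta_g_f0, params.theta_g_f1_up, params.theta_g_f1_down):
        lp += _PSEUDO * float(np.log(tab).sum())
    return lp


def _mstep(counts: list[dict], params: ModelParameters) -> ModelParameters:
    n_genes = len(counts)
    ed = sum(c["ed"] for c in counts)
    theta_d = (ed + _PSEUDO) / (n_genes + 2 * _PSEUDO)
    f_d = sum(c["f_d"] for c in counts)  # (d, f)
    theta_f_d0 = (f_d[0, 1] + _PSEUDO) / (f_d[0].sum() + 2 * _PSEUDO)
    theta_f_d1 = (f_d[1, 1] + _PSEUDO) / (f_d[1].sum() + 2 * _PSEUDO)
    g0 = sum(c["g0"] for c in counts) + _PSEUDO
    g1 = sum(c["g1"] for c in counts) + _PSEUDO  # (2, 3)
    theta_g_f0 = g0 / g0.sum()
    theta_g_f1_down = g1[0] / g1[0].sum()
    theta_g_f1_up = g1[1] / g1[1].sum()
    # identifiability: D=1 is the state with the higher P(F=1).  Swapping
    # the D labels (with theta_d -> 1 - theta_d) is an exact symmetry of
    # the model, so this never changes the likelihood.
    if theta_f_d1 < theta_f_d0:
        theta_f_d0, theta_f_d1 = theta_f_d1, theta_f_d0
        theta_d = 1.0 - theta_d
    # the H=up table should be the one skewed towards upregulation; compare
    # up-vs-down asymmetry rather than raw up-mass so near-ties don't flip
    asym_up = theta_g_f1_up[UP] - theta_g_f1_up[DOWN]
    asym_down = theta_g_f1_down[UP] - theta_g_f1_down[DOWN]
    if asym_up < asym_down:
        theta_g_f1_up, theta_g_f1_down = theta_g_f1_down, theta_g_f1_up
    eps = 1e-9
    return ModelParameters(
        theta_d=float(np.clip(theta_d, eps, 1 - eps)),
        theta_f_d0=float(np.clip(theta_f_d0, eps, 1 - eps)),
        theta_f_d1=float(np.clip(max(theta_f_d1, theta_f_d0), eps, 1 - eps)),
        theta_g_f0=theta_g_f0,
        theta_g_f1_up=theta_g_f1_up,
        theta_g_f1_down=theta_g_f1_down,
    )


def em_fit(
    subs: list[GeneSubmodel],
    init: ModelParameters | None = None,
    max_iter: int = 100,
    tol: float = 1e-5,
    min_mutations: int = 2,
) -> EMTrace:
    """Fit the shared thetas by EM over a collection of gene submodels.

    E-step: exact sum-product inference per submodel; M-step: ratios of
    pooled expected counts with 0.5 pseudo-counts, identifiability
    constraints re-imposed by label swap.  Genes with fewer than
    ``min_mutations`` events contribute no pooling signal and are excluded
    from fitting (they are still scored with the final parameters by the
    caller).  Converges when the relative log-likelihood change drops
    below ``tol``.
    """
    if not subs:
        raise XshadowError("em_fit requires at least one submodel")
    fit_subs = [s for s in subs if s.M >= min_mutations]
    if not fit_subs:
        raise XshadowError(f"no submodel has >= {min_mutations} mutations")
    params = init if init is not None else ModelParameters()
    ll_trace = []
    obj_trace = []
    converged = False
    prev = -np.inf
    for it in range(max_iter):
        all_counts = []
        total_ll = 0.0
        for sub in fit_subs:
            post, counts = _estep_counts(sub, params)
            all_counts.append(counts)
            total_ll += post.log_marginal + counts["null_ll"]
        objective = total_ll + _log_prior(params)
        ll_trace.append(total_ll)
        obj_trace.append(objective)
        new_params = _mstep(all_counts, params)
        if np.isfinite(prev) and (objective - prev) < tol * max(abs(objective), 1.0):
            converged = True
            params = new_params
            break
        params = new_params
        prev = objective
    return EMTrace(
        loglik=np.asarray(ll_trace),
        objective=np.asarray(obj_trace),
        n_iter=len(ll_trace),
        converged=converged,
        params=params,
        scored_genes=[s.gene for s in fit_subs],
    )
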