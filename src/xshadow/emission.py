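"""Per-gene three-component Student's-t emission mixtures.

The observed expression of a gene across a cohort is modelled as a mixture
of three location-scale Student's-t components representing downregulated,
neutral and upregulated states.  The fitted component densities serve as
the emission terms p(y | G) of the hierarchical model, and the mixture
responsibilities give the off-line regulation posteriors used to orient
each neighbour (direction variable H).

Fitting is hierarchical.  A single Student's t is fitted to the column as
the no-dysregulation reference, and an *anchored* three-component EM — the
down/up locations are kept at least :data:`SEPARATION_FLOOR` neutral
scales away from the neutral location — is fitted alongside.  The mixture
is kept only when it beats the single component by its BIC margin;
otherwise the column collapses to a neutral-dominant mixture whose flank
components sit at the canonical +/- 2 sigma offsets with nominal weight.
The anchoring and the BIC gate exist for the same reason: an unconstrained
mixture happily carves a unimodal expression distribution into three
overlapping pieces, which would label perfectly ordinary patients as
dysregulated.

Two routes are provided: :func:`fit_t_mixture` (reference per-gene EM, nu
re-estimated by bounded continuous 1-D optimisation each M-step) and
:func:`fit_t_mixtures` (batched across genes, nu selected from a fixed
grid so the step stays vectorised).  Both are monotone in the
observed-data log-likelihood.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import gammaln, logsumexp

from .errors import DegenerateDataError

G_STATES = ("down", "neutral", "up")

_NU_MIN, _NU_MAX = 2.0, 100.0
_SCALE_FLOOR = 1e-3
#: candidate degrees of freedom for the batched fitter
NU_GRID = np.array([2.0, 3.0, 5.0, 8.0, 12.0, 20.0, 35.0, 60.0, 100.0])
#: minimum distance of the down/up locations from the neutral location, in
#: units of the neutral component's scale
SEPARATION_FLOOR = 1.5
#: flank offset (in neutral scales) and flank weight of a collapsed column
_COLLAPSED_OFFSET = 2.0
_COLLAPSED_WEIGHT = 0.01
#: free parameters added by the mixture over the single t (2 weights,
#: 2 locations, 2 scales, 2 dfs) — the BIC gate's complexity term
_EXTRA_PARAMS = 8


def t_log_density(y, loc, scale, df):
    """Log density of the location-scale Student's t at ``y``.

    log t(y; mu, sigma, nu) with scale sigma > 0 and degrees of freedom
    nu > 0.  As nu grows the density approaches the Gaussian of the same
    location and scale.
    """
    loc = np.asarray(loc, dtype=float)
    scale = np.asarray(scale, dtype=float)
    df = np.asarray(df, dtype=float)
    if np.any(scale <= 0):
        raise ValueError("scale must be positive")
    if np.any(df <= 0):
        raise ValueError("degrees of freedom must be positive")
    y = np.asarray(y, dtype=float)
    z = (y - loc) / scale
    return (
        gammaln((df + 1.0) / 2.0)
        - gammaln(df / 2.0)
        - 0.5 * np.log(df * np.pi)
        - np.log(scale)
        - (df + 1.0) / 2.0 * np.log1p(z * z / df)
    )


@dataclass
class TMixture:
    """Three-component t mixture ordered down / neutral / up by location."""

    weights: np.ndarray
    locations: np.ndarray
    scales: np.ndarray
    dfs: np.ndarray
    loglik_trace: Optional[np.ndarray] = field(default=None, repr=False, compare=False)
    collapsed: bool = field(default=False, compare=False)

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        self.locations = np.asarray(self.locations, dtype=float)
        self.scales = np.asarray(self.scales, dtype=float)
        self.dfs = np.asarray(self.dfs, dtype=float)
        for arr in (self.weights, self.locations, self.scales, self.dfs):
            if arr.shape != (3,):
                raise ValueError("TMixture parameters must have shape (3,)")
        if abs(self.weights.sum() - 1.0) > 1e-9:
            raise ValueError("mixture weights must sum to 1")
        if not (self.locations[0] <= self.locations[1] <= self.locations[2]):
            raise ValueError("component locations must be ordered down <= neutral <= up")
        if np.any(self.scales <= 0):
            raise ValueError("scales must be positive")
        if np.any(self.dfs < 2.0) or np.any(self.dfs > 1e6):
            raise ValueError("degrees of freedom must lie in [2, 1e6]")

    def component_log_density(self, y) -> np.ndarray:
        """log p(y | G=k) for each component; shape y.shape + (3,)."""
        y = np.asarray(y, dtype=float)
        return t_log_density(y[..., None], self.locations, self.scales, self.dfs)

    def log_density(self, y) -> np.ndarray:
        """Log of the mixture density at y."""
        with np.errstate(divide="ignore"):
            logw = np.log(self.weights)
        return logsumexp(logw + self.component_log_density(y), axis=-1)


def posterior_G(mix: TMixture, y) -> np.ndarray:
    """Mixture responsibilities P(G = k | y), the off-line regulation posterior.

    Returns an array of shape ``y.shape + (3,)`` summing to 1 over the last
    axis (down, neutral, up).
    """
    with np.errstate(divide="ignore"):
        logw = np.log(mix.weights)
    logp = logw + mix.component_log_density(y)
    logp -= logsumexp(logp, axis=-1, keepdims=True)
    return np.exp(logp)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


def _robust_scale(values: np.ndarray) -> float:
    med = np.median(values)
    s = 1.4826 * np.median(np.abs(values - med))
    if s < _SCALE_FLOOR:
        s = max(values.std(), _SCALE_FLOOR)
    return float(s)


def _init_params(values: np.ndarray):
    """Deterministic init: percentile locations, robust scale, semantic weights."""
    mu = np.percentile(values, [10.0, 50.0, 90.0]).astype(float)
    rs = _robust_scale(values)
    sep = SEPARATION_FLOOR * rs
    mu[0] = min(mu[0], mu[1] - sep)
    mu[2] = max(mu[2], mu[1] + sep)
    sigma = np.full(3, rs)
    w = np.array([0.15, 0.7, 0.15])
    nu = np.full(3, 10.0)
    return w, mu, sigma, nu


def _q_nu(nu, r_k, z2_k):
    """Expected complete-data log-likelihood in nu for one component."""
    return np.sum(
        r_k
        * (
            gammaln((nu + 1.0) / 2.0)
            - gammaln(nu / 2.0)
            - 0.5 * np.log(nu)
            - (nu + 1.0) / 2.0 * np.log1p(z2_k / nu)
        )
    )


def _fit_single_t(values: np.ndarray, max_iter: int = 200, tol: float = 1e-8):
    """Robust single Student's-t fit (EM on the latent scale weights)."""
    y = values
    mu = float(np.median(y))
    sigma = _robust_scale(y)
    nu = 10.0
    trace = []
    prev = -np.inf
    for _ in range(max_iter):
        ll = float(t_log_density(y, mu, sigma, nu).sum())
        trace.append(ll)
        z2 = ((y - mu) / sigma) ** 2
        u = (nu + 1.0) / (nu + z2)
        mu = float((u * y).sum() / u.sum())
        sigma = max(float(np.sqrt((u * (y - mu) ** 2).sum() / y.size)), _SCALE_FLOOR)
        z2n = ((y - mu) / sigma) ** 2
        res = minimize_scalar(
            lambda v: -_q_nu(v, np.ones_like(y), z2n),
            bounds=(_NU_MIN, _NU_MAX),
            method="bounded",
            options={"xatol": 0.05},
        )
        nu = float(res.x)
        if np.isfinite(prev) and ll - prev < tol * max(abs(ll), 1.0):
            break
        prev = ll
    return mu, sigma, nu, np.asarray(trace)


def _collapsed_mixture(mu0, sigma0, nu0, trace) -> TMixture:
    """Neutral-dominant mixture for a column without clear mixture modes.

    The neutral component is the single-t bulk fit; the down/up components
    sit at the canonical +/- 2 sigma offsets with nominal weight, so tail
    expression values still register as possible dysregulation while the
    bulk stays firmly neutral.
    """
    off = _COLLAPSED_OFFSET * sigma0
    e = _COLLAPSED_WEIGHT
    return TMixture(
        weights=np.array([e, 1.0 - 2 * e, e]),
        locations=np.array([mu0 - off, mu0, mu0 + off]),
        scales=np.array([sigma0, sigma0, sigma0]),
        dfs=np.array([nu0, nu0, nu0]),
        loglik_trace=trace,
        collapsed=True,
    )


def fit_t_mixture(
    values,
    max_iter: int = 500,
    tol: float = 1e-6,
    min_obs: int = 30,
) -> TMixture:
    """Fit the down/neutral/up Student's-t mixture of one gene's expression.

    A single t (bulk model) and the anchored three-component EM are both
    fitted; the mixture is returned only if its BIC beats the single
    component's, otherwise the collapsed neutral-dominant mixture is
    returned.  EM initialisation is deterministic (locations at the
    10th/50th/90th percentiles pushed out to the separation floor, robust
    MAD scale, weights (0.15, 0.7, 0.15)); each M-step re-estimates nu by
    bounded optimisation over [2, 100]; components are relabelled by
    location on exit.

    Fewer than ``min_obs`` observations: falls back to a single neutral
    component with weights (0, 1, 0) and warns.  A constant vector raises
    :class:`DegenerateDataError`.
    """
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if values.size and np.ptp(values) == 0:
        raise DegenerateDataError("all expression values identical")
    if values.size < min_obs:
        warnings.warn(
            f"only {values.size} observations; falling back to a single neutral component",
            stacklevel=2,
        )
        loc = float(values.mean()) if values.size else 0.0
        sd = max(float(values.std()) if values.size else 1.0, _SCALE_FLOOR)
        return TMixture(
            weights=np.array([0.0, 1.0, 0.0]),
            locations=np.array([loc, loc, loc]),
            scales=np.array([sd, sd, sd]),
            dfs=np.array([10.0, 10.0, 10.0]),
            collapsed=True,
        )
    mu0, sigma0, nu0, trace1 = _fit_single_t(values)
    w, mu, sigma, nu = _init_params(values)
    mix = _em_t_mixture(values, w, mu, sigma, nu, max_iter, tol)
    gain = mix.loglik_trace[-1] - trace1[-1]
    if gain <= 0.5 * _EXTRA_PARAMS * np.log(values.size):
        return _collapsed_mixture(mu0, sigma0, nu0, trace1)
    return mix


def _em_t_mixture(values, w, mu, sigma, nu, max_iter, tol) -> TMixture:
    y = values[:, None]  # (n, 1) against (3,) parameter rows
    trace = []
    prev = -np.inf
    for _ in range(max_iter):
        logp = np.where(w > 0, np.log(np.maximum(w, 1e-300)), -np.inf) + t_log_density(
            y, mu, sigma, nu
        )
        norm = logsumexp(logp, axis=1)
        ll = float(norm.sum())
        trace.append(ll)
        r = np.exp(logp - norm[:, None])  # responsibilities (n, 3)
        z2 = ((y - mu) / sigma) ** 2
        u = (nu + 1.0) / (nu + z2)  # latent precision weights
        rk = r.sum(axis=0)
        ru = r * u
        mu = (ru * y).sum(axis=0) / np.maximum(ru.sum(axis=0), 1e-300)
        # anchored M-step: clamp flank locations to the separation floor
        # (Q is quadratic in mu given the latent weights, so the boundary
        # is the constrained argmax)
        sep = SEPARATION_FLOOR * sigma[1]
        mu[0] = min(mu[0], mu[1] - sep)
        mu[2] = max(mu[2], mu[1] + sep)
        var = (ru * (y - mu) ** 2).sum(axis=0) / np.maximum(rk, 1e-300)
        sigma = np.maximum(np.sqrt(var), _SCALE_FLOOR)
        w = rk / rk.sum()
        z2_new = ((y - mu) / sigma) ** 2
        for k in range(3):
            if rk[k] < 1e-8:
                continue
            res = minimize_scalar(
                lambda v, k=k: -_q_nu(v, r[:, k], z2_new[:, k]),
                bounds=(_NU_MIN, _NU_MAX),
                method="bounded",
                options={"xatol": 0.05},
            )
            nu[k] = float(res.x)
        if ll - prev < tol * max(abs(ll), 1.0) and np.isfinite(prev):
            break
        prev = ll
    order = np.argsort(mu, kind="stable")
    return TMixture(
        weights=w[order],
        locations=mu[order],
        scales=sigma[order],
        dfs=nu[order],
        loglik_trace=np.asarray(trace),
    )


# ---------------------------------------------------------------------------
# batched fitting
# ---------------------------------------------------------------------------


def _batch_single_t(Yt: np.ndarray, max_iter: int = 100, tol: float = 1e-8):
    """Vectorised single-t fits per row of ``Yt`` (C columns x n points)."""
    C, n = Yt.shape
    mu = np.median(Yt, axis=1)
    sigma = np.maximum(1.4826 * np.median(np.abs(Yt - mu[:, None]), axis=1), _SCALE_FLOOR)
    nu = np.full(C, 10.0)
    prev = np.full(C, -np.inf)
    ll = prev
    for it in range(max_iter):
        ll = t_log_density(Yt, mu[:, None], sigma[:, None], nu[:, None]).sum(axis=1)
        z2 = ((Yt - mu[:, None]) / sigma[:, None]) ** 2
        u = (nu[:, None] + 1.0) / (nu[:, None] + z2)
        mu = (u * Yt).sum(axis=1) / u.sum(axis=1)
        sigma = np.maximum(
            np.sqrt((u * (Yt - mu[:, None]) ** 2).sum(axis=1) / n), _SCALE_FLOOR
        )
        if it % 3 == 0:
            z2n = ((Yt - mu[:, None]) / sigma[:, None]) ** 2
            q = np.stack(
                [t_log_density(Yt, mu[:, None], sigma[:, None], v).sum(axis=1) for v in NU_GRID]
            )
            nu = NU_GRID[np.argmax(q, axis=0)]
        if np.all(ll - prev < tol * np.maximum(np.abs(ll), 1.0)):
            break
        prev = ll
    ll = t_log_density(Yt, mu[:, None], sigma[:, None], nu[:, None]).sum(axis=1)
    return mu, sigma, nu, ll


def fit_t_mixtures(matrix: np.ndarray, max_iter: int = 200, tol: float = 1e-5) -> list[TMixture]:
    """Fit one emission mixture per column of ``matrix`` (patients x genes).

    Vectorised version of :func:`fit_t_mixture` for cohort-scale runs:
    same anchoring and BIC gate, with nu selected from :data:`NU_GRID`.
    Columns with missing values or fewer than 30 finite observations take
    the scalar path.
    """
    matrix = np.asarray(matrix, dtype=float)
    n_obs = np.isfinite(matrix).sum(axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        spread = np.nanmax(matrix, axis=0) > np.nanmin(matrix, axis=0)
    full = (n_obs == matrix.shape[0]) & spread
    out: list[Optional[TMixture]] = [None] * matrix.shape[1]

    for j in np.where(~full)[0]:
        col = matrix[:, j]
        col = col[np.isfinite(col)]
        if col.size and np.ptp(col) == 0:
            raise DegenerateDataError(f"column {j} is constant")
        out[j] = fit_t_mixture(col)

    cols = np.where(full)[0]
    if cols.size == 0:
        return out  # type: ignore[return-value]
    Y = matrix[:, cols]  # (n, C)
    n, C = Y.shape
    Yt2 = Y.T  # (C, n)
    mu0, sigma0, nu0, ll1 = _batch_single_t(Yt2)

    inits = [_init_params(Y[:, c]) for c in range(C)]
    w = np.stack([i[0] for i in inits])  # (C, 3)
    mu = np.stack([i[1] for i in inits])
    sigma = np.stack([i[2] for i in inits])
    nu = np.stack([i[3] for i in inits])
    ll_final = np.full(C, -np.inf)
    active = np.arange(C)  # converged columns are compacted out of the batch
    Yt = Y.T[:, :, None]  # (C, n, 1)
    Ya = Yt
    prev = np.full(C, -np.inf)
    nu_const = gammaln((NU_GRID + 1.0) / 2.0) - gammaln(NU_GRID / 2.0) - 0.5 * np.log(NU_GRID)
    for it in range(max_iter):
        wa, mua, siga, nua = w[active], mu[active], sigma[active], nu[active]
        logp = np.log(np.maximum(wa, 1e-300))[:, None, :] + t_log_density(
            Ya, mua[:, None, :], siga[:, None, :], nua[:, None, :]
        )
        mx = logp.max(axis=2)
        norm = mx + np.log(np.exp(logp - mx[:, :, None]).sum(axis=2))
        ll = norm.sum(axis=1)
        r = np.exp(logp - norm[:, :, None])  # (A, n, 3)
        z2 = ((Ya - mua[:, None, :]) / siga[:, None, :]) ** 2
        u = (nua[:, None, :] + 1.0) / (nua[:, None, :] + z2)
        rk = r.sum(axis=1)  # (A, 3)
        ru = r * u
        mu_new = (ru * Ya).sum(axis=1) / np.maximum(ru.sum(axis=1), 1e-300)
        sep = SEPARATION_FLOOR * siga[:, 1]
        mu_new[:, 0] = np.minimum(mu_new[:, 0], mu_new[:, 1] - sep)
        mu_new[:, 2] = np.maximum(mu_new[:, 2], mu_new[:, 1] + sep)
        var = (ru * (Ya - mu_new[:, None, :]) ** 2).sum(axis=1) / np.maximum(rk, 1e-300)
        sig_new = np.maximum(np.sqrt(var), _SCALE_FLOOR)
        w[active] = rk / rk.sum(axis=1, keepdims=True)
        mu[active] = mu_new
        sigma[active] = sig_new
        if it % 3 == 0:
            # nu-step on the grid: Q(nu) per (column, component, candidate)
            z2n = ((Ya - mu_new[:, None, :]) / sig_new[:, None, :]) ** 2  # (A, n, 3)
            q = np.empty((len(NU_GRID), len(active), 3))
            for gi, v in enumerate(NU_GRID):
                q[gi] = (r * (-(v + 1.0) / 2.0 * np.log1p(z2n / v))).sum(axis=1) + rk * nu_const[gi]
            nu[active] = NU_GRID[np.argmax(q, axis=0)]
        ll_final[active] = ll
        done = ll - prev[active] < tol * np.maximum(np.abs(ll), 1.0)
        prev[active] = ll
        if done.any():
            still = ~done
            active = active[still]
            if active.size == 0:
                break
            Ya = Ya[still]

    penalty = 0.5 * _EXTRA_PARAMS * np.log(n)
    ll = ll_final
    keep = (ll - ll1) > penalty
    for idx, c in enumerate(cols):
        if keep[idx]:
            order = np.argsort(mu[idx], kind="stable")
            out[c] = TMixture(
                weights=w[idx, order],
                locations=mu[idx, order],
                scales=sigma[idx, order],
                dfs=nu[idx, order],
            )
        else:
            out[c] = _collapsed_mixture(mu0[idx], sigma0[idx], nu0[idx], None)
    return out  # type: ignore[return-value]
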