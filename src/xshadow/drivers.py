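"""Binomial-mixture generalisation of the 20/20 driver-gene rule.

Tumour suppressors accumulate loss-of-function mutations spread across the
gene; oncogenes accumulate recurrent (hotspot) missense mutations or
in-frame indels at the same codon.  Instead of a fixed 20% rule, the
fraction of class-specific mutations per gene is modelled as a mixture of
two binomials — a high-rate driver component and a low-rate background
component — and each gene receives the posterior probability of the
high-rate component: P(TSG) from loss-of-function counts, P(OCG) from
hotspot counts.  A threshold of 0.2 on the posterior calls the label.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import binom

from .errors import DegenerateDataError, MixtureUnfitError
from .io import LOF_CLASSES, MutationTable

HOTSPOT_CLASSES = frozenset({"missense", "inframe_indel"})


def count_mutation_classes(mut: MutationTable) -> pd.DataFrame:
    """Per-gene totals N_g, loss-of-function count and hotspot count.

    Loss-of-function = nonsense (incl. stop-gain) + frameshift indel +
    splice site.  Hotspot = missense or in-frame indel whose codon position
    recurs (>= 2 events of the same class at the same codon within the
    gene); events without a position never count as recurrent.
    """
    df = mut.records
    if df.empty:
        raise DegenerateDataError("empty mutation table")
    rows = []
    for gene, grp in df.groupby("gene", sort=True):
        n_total = len(grp)
        n_loss = int(grp["mut_class"].isin(LOF_CLASSES).sum())
        n_rec = 0
        hot = grp[grp["mut_class"].isin(HOTSPOT_CLASSES) & grp["position"].notna()]
        for (_, _pos), sub in hot.groupby(["mut_class", "position"]):
            if len(sub) >= 2:
                n_rec += len(sub)
        rows.append((gene, n_total, n_loss, n_rec))
    return pd.DataFrame(rows, columns=["gene", "n_total", "n_loss", "n_rec"]).set_index("gene")


@dataclass
class BinomialMixture:
    """Two-component binomial mixture with ordered success rates p1 > p2."""

    weights: np.ndarray  # (2,)
    rates: np.ndarray  # (2,), rates[0] > rates[1]
    loglik_trace: Optional[np.ndarray] = field(default=None, repr=False, compare=False)
    separated: bool = True

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        self.rates = np.asarray(self.rates, dtype=float)
        if abs(self.weights.sum() - 1.0) > 1e-9:
            raise ValueError("mixture weights must sum to 1")
        if not (0.0 < self.rates[1] <= self.rates[0] < 1.0):
            raise ValueError("rates must satisfy 0 < p2 <= p1 < 1")


_PSEUDO = 0.5


def fit_binomial_mixture(
    counts, totals, max_iter: int = 500, tol: float = 1e-8, min_genes: int = 50
) -> BinomialMixture:
    """EM fit of the two-component binomial mixture over (n_g, N_g) pairs.

    Initialised at p = (0.3, 0.02), omega = (0.1, 0.9); every expected
    count is smoothed with a 0.5 pseudo-count.  Components are ordered
    p1 > p2 on exit; a fit where the rates collapse together is flagged
    ``separated=False``.
    """
    n = np.asarray(counts, dtype=float)
    N = np.asarray(totals, dtype=float)
    if n.shape != N.shape or n.ndim != 1:
        raise ValueError("counts and totals must be 1-D and aligned")
    if np.any(n < 0) or np.any(n > N):
        raise ValueError("need 0 <= n_g <= N_g")
    keep = N >= 1
    n, N = n[keep], N[keep]
    if n.size < min_genes:
        raise MixtureUnfitError(f"need >= {min_genes} genes with N_g >= 1, got {n.size}")
    if np.all(n == 0):
        raise DegenerateDataError("all class-specific counts are zero")
    p = np.array([0.3, 0.02])
    w = np.array([0.1, 0.9])
    trace = []
    prev = -np.inf
    for _ in range(max_iter):
        logp = np.log(w)[None, :] + binom.logpmf(n[:, None], N[:, None], p[None, :])
        norm = logsumexp(logp, axis=1)
        ll = float(norm.sum())
        trace.append(ll)
        r = np.exp(logp - norm[:, None])
        rk = r.sum(axis=0)
        w = (rk + _PSEUDO) / (n.size + 2 * _PSEUDO)
        w = w / w.sum()
        p = ((r * n[:, None]).sum(axis=0) + _PSEUDO) / ((r * N[:, None]).sum(axis=0) + 2 * _PSEUDO)
        p = np.clip(p, 1e-9, 1 - 1e-9)
        if np.isfinite(prev) and ll - prev < tol * max(abs(ll), 1.0):
            break
        prev = ll
    order = np.argsort(-p, kind="stable")
    p, w = p[order], w[order]
    separated = (p[0] - p[1]) > 0.01 and w[0] > 1e-4
    return BinomialMixture(weights=w, rates=p, loglik_trace=np.asarray(trace), separated=separated)


def posterior_driver_class(count, total, mix: BinomialMixture):
    """Posterior that a gene's counts come from the high-rate component.

    P = w1 Binom(n; N, p1) / [w1 Binom(n; N, p1) + w2 Binom(n; N, p2)].
    N = 0 returns the prior weight w1 with a warning-free fallback.
    """
    n = np.asarray(count, dtype=float)
    N = np.asarray(total, dtype=float)
    if np.any(n < 0) or np.any(n > N):
        raise ValueError("need 0 <= n <= N")
    logp = np.log(mix.weights) + binom.logpmf(n[..., None], np.maximum(N[..., None], 1), mix.rates)
    post = np.exp(logp[..., 0] - logsumexp(logp, axis=-1))
    post = np.where(N == 0, mix.weights[0], post)
    return post if post.ndim else float(post)


def classify_drivers(posteriors, threshold: float = 0.2):
    """Boolean driver labels at the (inclusive) posterior threshold."""
    post = np.asarray(posteriors, dtype=float)
    if np.any((post < 0) | (post > 1)):
        raise ValueError("posteriors must lie in [0, 1]")
    return post >= threshold


def annotate_drivers(mut: MutationTable, threshold: float = 0.2, min_genes: int = 50) -> pd.DataFrame:
    """Full driver annotation: counts, both mixtures, posteriors and labels.

    Fits the TSG mixture on loss-of-function counts and the OCG mixture on
    hotspot counts over the same gene universe, independently.
    """
    counts = count_mutation_classes(mut)
    out = counts.copy()
    for label, col in (("tsg", "n_loss"), ("ocg", "n_rec")):
        try:
            mix = fit_binomial_mixture(counts[col], counts["n_total"], min_genes=min_genes)
            out[f"p_{label}"] = posterior_driver_class(
                counts[col].to_numpy(), counts["n_total"].to_numpy(), mix
            )
        except DegenerateDataError:
            out[f"p_{label}"] = 0.0
    out["is_tsg"] = classify_drivers(out["p_tsg"], threshold)
    out["is_ocg"] = classify_drivers(out["p_ocg"], threshold)
    return out
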