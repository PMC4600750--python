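"""Post-inference statistics.

* Hartigan's dip statistic and a Monte-Carlo unimodality test, used to ask
  whether the per-patient P(F) values of a gene split into distinct
  responder/non-responder groups.
* Threshold-based patient stratification around P(F) >= 0.5.
* A binomial exact test for recurrent dysregulation of the same connected
  gene across tumour types.
* Hypermutator flagging by the extreme Tukey fence Q3 + 4.5 * IQR.

The dip statistic is computed from scratch with the greatest-convex-
minorant / least-concave-majorant algorithm: the dip is half the largest
gap between the empirical CDF and the closest unimodal CDF, located by
iteratively narrowing the modal interval.  P-values are Monte-Carlo,
calibrated against uniform samples of the same size (the null least
favourable for unimodality); the null tables are cached per sample size.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.stats import binom
from statsmodels.stats.multitest import multipletests

from .errors import SampleSizeError

# ---------------------------------------------------------------------------
# Hartigan's dip
# ---------------------------------------------------------------------------


def _gcm(cdf: np.ndarray, xs: np.ndarray):
    """Greatest convex minorant of the points (xs, cdf); returns fitted
    values at every x plus the indices where the minorant touches."""
    fit = [cdf[0]]
    touch = [0]
    pos = 0
    while pos < len(cdf) - 1:
        dx = xs[pos + 1 :] - xs[pos]
        slopes = (cdf[pos + 1 :] - cdf[pos]) / dx
        j = int(np.argmin(slopes))
        m = slopes[j]
        fit.extend(cdf[pos] + dx[: j + 1] * m)
        pos = pos + j + 1
        touch.append(pos)
    return np.asarray(fit), np.asarray(touch, dtype=int)


def _lcm(cdf: np.ndarray, xs: np.ndarray):
    """Least concave majorant via the GCM of the reflected points."""
    fit, touch = _gcm(1.0 - cdf[::-1], xs[-1] - xs[::-1])
    return 1.0 - fit[::-1], (len(cdf) - 1 - touch)[::-1]


def dip_statistic(values) -> float:
    """Hartigan's dip: sup-distance from the empirical CDF to the closest
    unimodal CDF.

    Ties are collapsed into weights.  Equally spaced distinct values give
    the minimum possible dip 1/(2n); two well-separated point masses of
    equal size approach the maximum 1/4.
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 2:
        return 0.0
    xs, counts = np.unique(x, return_counts=True)
    if xs.size == 1:
        return 0.0
    hist = counts / counts.sum()
    cdf = np.cumsum(hist)

    work_x = xs
    work_cdf = cdf
    work_hist = hist
    D = 0.0
    left_fit = []  # frozen GCM fit outside the modal window
    right_fit = []
    full_cdf = cdf
    while True:
        # GCM is fitted to the lower-left step corners, LCM to the upper ones
        gcm_fit, gcm_touch = _gcm(work_cdf - work_hist, work_x)
        lcm_fit, lcm_touch = _lcm(work_cdf, work_x)

        gaps_at_gcm = lcm_fit[gcm_touch] - gcm_fit[gcm_touch]
        gaps_at_lcm = lcm_fit[lcm_touch] - gcm_fit[lcm_touch]
        d_left = gaps_at_gcm.max()
        d_right = gaps_at_lcm.max()
        if d_right > d_left:
            xr = lcm_touch[gaps_at_lcm == d_right][-1]
            xl = gcm_touch[gcm_touch <= xr][-1]
            d = d_right
        else:
            xl = gcm_touch[gaps_at_gcm == d_left][0]
            xr = lcm_touch[lcm_touch >= xl][0]
            d = d_left

        if d <= D or xr == 0 or xl == len(work_cdf) - 1:
            break
        # largest deviation of the empirical CDF from the unimodal fit in
        # the parts being frozen out of the modal window
        left_dev = np.abs(gcm_fit[: xl + 1] - (work_cdf - work_hist)[: xl + 1]).max()
        left_dev = max(
            left_dev, np.abs(gcm_fit[: xl + 1] - work_cdf[: xl + 1]).max()
        )
        right_dev = np.abs(lcm_fit[xr:] - work_cdf[xr:]).max()
        right_dev = max(right_dev, np.abs(lcm_fit[xr:] - (work_cdf - work_hist)[xr:]).max())
        D = max(D, left_dev, right_dev)
        if xl == 0 and xr == len(work_cdf) - 1:
            break
        work_x = work_x[xl : xr + 1]
        work_cdf = work_cdf[xl : xr + 1]
        work_hist = work_hist[xl : xr + 1]
    return max(D, d) / 2.0


@lru_cache(maxsize=64)
def _null_dips(n: int, n_draws: int, seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    return np.array([dip_statistic(rng.random(n)) for _ in range(n_draws)])


def dip_test(values, n_draws: int = 2000, seed: int = 0):
    """Dip statistic with a Monte-Carlo p-value against the uniform null.

    The p-value is the fraction of ``n_draws`` uniform(0,1) samples of the
    same size whose dip is at least as large as the observed one (with the
    +1 continuity adjustment).  Null tables are cached per (n, n_draws,
    seed).  Requires n >= 4.
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 4:
        raise SampleSizeError(f"dip test needs >= 4 values, got {x.size}")
    d = dip_statistic(x)
    null = _null_dips(int(x.size), int(n_draws), int(seed))
    p = (1.0 + np.sum(null >= d)) / (1.0 + n_draws)
    return d, float(p)


# ---------------------------------------------------------------------------
# stratification
# ---------------------------------------------------------------------------


@dataclass
class StratificationResult:
    """Threshold split of mutated patients by P(F), with a bimodality test."""

    gene: str
    dip: float
    dip_pvalue: float
    high_patients: list[str]
    low_patients: list[str]


def stratify_patients(
    pf, patients=None, threshold: float = 0.5, gene: str = "", n_draws: int = 2000, seed: int = 0
) -> StratificationResult:
    """Split patients into high (P(F) >= threshold) and low groups.

    Also runs the dip test on the P(F) values; a small p-value indicates a
    bimodal split into clear responder/non-responder subgroups.
    """
    pf = np.asarray(pf, dtype=float)
    if np.any((pf < 0) | (pf > 1)):
        raise ValueError("P(F) values must lie in [0, 1]")
    if patients is None:
        patients = [str(i) for i in range(pf.size)]
    if pf.size >= 4:
        d, p = dip_test(pf, n_draws=n_draws, seed=seed)
    else:
        d, p = dip_statistic(pf), float("nan")
    hi = pf >= threshold
    return StratificationResult(
        gene=gene,
        dip=d,
        dip_pvalue=p,
        high_patients=[patients[i] for i in np.where(hi)[0]],
        low_patients=[patients[i] for i in np.where(~hi)[0]],
    )


# ---------------------------------------------------------------------------
# cross-tumour recurrence
# ---------------------------------------------------------------------------


def recurrence_test(counts: pd.DataFrame, totals: pd.DataFrame) -> pd.DataFrame:
    """Binomial exact test of recurrent dysregulation across tumour types.

    ``counts``/``totals`` are neighbours x tumour-type tables: counts of
    patients where the connected gene is dysregulated (P(G) >= 0.5) with a
    high-probability mutation (P(F) >= 0.5), and the numbers of mutated
    patients tested.  The background rate p-hat is the pooled MLE
    sum(counts)/sum(totals); per neighbour the upper binomial tail
    P(X >= k | n, p-hat) is computed on the pooled k, n and BH-adjusted.
    Run separately for up- and downregulation counts.
    """
    if not counts.index.equals(totals.index) or not counts.columns.equals(totals.columns):
        raise ValueError("counts and totals must share neighbours and tumour types")
    c = counts.to_numpy(dtype=float)
    t = totals.to_numpy(dtype=float)
    if np.any(c > t):
        raise ValueError("counts cannot exceed totals")
    grand_total = t.sum()
    if grand_total == 0:
        raise SampleSizeError("no trials in the recurrence test")
    p_hat = c.sum() / grand_total
    k = c.sum(axis=1)
    n = t.sum(axis=1)
    rows = []
    for i, neigh in enumerate(counts.index):
        if n[i] == 0:
            rows.append((neigh, 0.0, 0.0, np.nan))
            continue
        pv = float(binom.sf(k[i] - 1, int(n[i]), p_hat))
        rows.append((neigh, k[i], n[i], pv))
    out = pd.DataFrame(rows, columns=["neighbour", "k", "n", "p"]).set_index("neighbour")
    ok = out["p"].notna()
    q = np.full(len(out), np.nan)
    if ok.any():
        q[ok.to_numpy()] = multipletests(out.loc[ok, "p"], method="fdr_bh")[1]
    out["q"] = q
    out["p_hat"] = p_hat
    return out


# ---------------------------------------------------------------------------
# hypermutators
# ---------------------------------------------------------------------------


def flag_hypermutators(mutation_counts, multiplier: float = 4.5):
    """Flag tumours whose mutation burden exceeds Q3 + multiplier * IQR.

    Quartiles use linear interpolation; the comparison is strict (a count
    exactly at the fence is not flagged).  Requires >= 4 patients.
    """
    counts = np.asarray(mutation_counts, dtype=float)
    if counts.size < 4:
        raise SampleSizeError(f"need >= 4 patients, got {counts.size}")
    q1, q3 = np.percentile(counts, [25.0, 75.0])
    fence = q3 + multiplier * (q3 - q1)
    return counts > fence
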