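"""Preprocessing: expressed-gene filtering, copy-number cis-effect removal,
and influence-graph conditioning.

These three procedures run before model fitting.  Genes that are not
expressed in the tumour type are removed (mutations there are unlikely to
be pathogenic); in trans mode the cis dosage effect of copy-number change
on each gene's own expression is regressed out by a Gaussian process so
the remaining variation can be attributed to trans-acting mutations; and
the generic influence graph is specialised to the cohort by keeping
confident edges and promoting differentially expressed neighbours.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import RBF, ConstantKernel, WhiteKernel
from sklearn.mixture import GaussianMixture
from statsmodels.stats.multitest import multipletests

from .errors import MixtureUnfitError, SampleSizeError
from .io import ExpressionMatrix, InfluenceGraph, MutationTable

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# expressed-gene filter
# ---------------------------------------------------------------------------


@dataclass
class ExpressedGeneCall:
    """Per-gene expression call from the two-Gaussian 90th-percentile model."""

    gene: str
    percentile90: float
    posterior_high: float
    is_expressed: bool
    outlier_flag: str  # none | high | low


def detect_expressed_genes(
    expr: ExpressionMatrix, posterior_threshold: float = 0.8
) -> pd.DataFrame:
    """Call each gene highly/lowly expressed in the tumour type.

    The 90th percentile of each gene's log2 expression across patients
    summarises its overall expression (robust to genes deleted in a
    minority of tumours).  Tukey-fence outliers are removed, a
    two-component Gaussian mixture is fitted to the remaining percentiles,
    and each gene receives the posterior of the higher-mean component.
    High outliers get posterior 1, low outliers 0.  A gene is expressed if
    its posterior is >= ``posterior_threshold``.

    Returns a DataFrame indexed by gene with columns percentile90,
    posterior_high, is_expressed, outlier_flag.
    """
    vals = expr.values
    genes = expr.genes
    if len(genes) < 50:
        raise MixtureUnfitError(f"need >= 50 genes to fit the expression mixture, got {len(genes)}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        p90 = np.nanpercentile(vals, 90.0, axis=0)
    if np.ptp(p90[np.isfinite(p90)]) == 0:
        raise MixtureUnfitError("all 90th-percentile values identical")
    q1, q3 = np.percentile(p90, [25.0, 75.0])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    flag = np.where(p90 > hi_fence, "high", np.where(p90 < lo_fence, "low", "none"))
    inliers = p90[flag == "none"]
    if inliers.size < 10 or np.ptp(inliers) == 0:
        raise MixtureUnfitError("too few inlier genes for the expression mixture")
    gm = GaussianMixture(n_components=2, n_init=3, random_state=0)
    gm.fit(inliers[:, None])
    gm1 = GaussianMixture(n_components=1, random_state=0).fit(inliers[:, None])
    posterior = np.empty_like(p90)
    if gm.bic(inliers[:, None]) >= gm1.bic(inliers[:, None]):
        # no evidence of a lowly-expressed class: the filter is inert and
        # every non-low-outlier gene counts as expressed
        logger.info("90th-percentile distribution is unimodal; expression filter inert")
        posterior[flag == "none"] = 1.0
    else:
        hi_comp = int(np.argmax(gm.means_.ravel()))
        posterior[flag == "none"] = gm.predict_proba(inliers[:, None])[:, hi_comp]
    posterior[flag == "high"] = 1.0
    posterior[flag == "low"] = 0.0
    return pd.DataFrame(
        {
            "percentile90": p90,
            "posterior_high": posterior,
            "is_expressed": posterior >= posterior_threshold,
            "outlier_flag": flag,
        },
        index=pd.Index(genes, name="gene"),
    )


# ---------------------------------------------------------------------------
# copy-number cis-effect compensation
# ---------------------------------------------------------------------------


@dataclass
class GPHyperparams:
    """Squared-exponential kernel hyperparameters of the dosage regression."""

    lengthscale: float
    signal_var: float
    noise_var: float
    log_marginal: float

    def __post_init__(self):
        if min(self.lengthscale, self.signal_var, self.noise_var) <= 0:
            raise ValueError("GP hyperparameters must be strictly positive")


def compensate_cnv_cis(y, x) -> tuple[np.ndarray, Optional[GPHyperparams]]:
    """Regress expression on copy number and return trans residuals.

    Fits y_i = f(x_i) + eps with a GP prior on f using the squared
    exponential kernel cov(x_i, x_j) = s^2 exp(-(x_i-x_j)^2 / (2 l^2))
    plus observation noise.  Hyperparameters maximise the log marginal
    likelihood (gradient-based, restarts from l in {0.5, 1, 2} x SD(x));
    residuals are y minus the posterior mean at the observed x.

    A constant copy-number vector degenerates gracefully: residuals are
    the centred expression and the hyperparameters are ``None``.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if y.shape != x.shape or y.ndim != 1:
        raise ValueError("y and x must be 1-D vectors of equal length")
    ok = np.isfinite(y) & np.isfinite(x)
    if ok.sum() < 10:
        raise SampleSizeError(f"need >= 10 paired observations, got {int(ok.sum())}")
    yv, xv = y[ok], x[ok]
    if np.ptp(xv) == 0:
        res = np.full_like(y, np.nan)
        res[ok] = yv - yv.mean()
        return res, None
    y_mean = yv.mean()
    yc = yv - y_mean
    sd_x = xv.std()
    var_y = max(yc.var(), 1e-6)
    best = None
    for factor in (0.5, 1.0, 2.0):
        kernel = ConstantKernel(var_y, (1e-6 * var_y, 1e3 * var_y)) * RBF(
            factor * sd_x, (1e-3 * sd_x, 1e3 * sd_x)
        ) + WhiteKernel(0.5 * var_y, (1e-8 * var_y, 1e2 * var_y))
        gpr = GaussianProcessRegressor(kernel=kernel, optimizer="fmin_l_bfgs_b", normalize_y=False)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            gpr.fit(xv[:, None], yc)
        lml = gpr.log_marginal_likelihood_value_
        if best is None or lml > best[0]:
            best = (lml, gpr)
    lml, gpr = best
    k = gpr.kernel_
    hyper = GPHyperparams(
        lengthscale=float(k.k1.k2.length_scale),
        signal_var=float(k.k1.k1.constant_value),
        noise_var=float(k.k2.noise_level),
        log_marginal=float(lml),
    )
    res = np.full_like(y, np.nan)
    res[ok] = yv - (gpr.predict(xv[:, None]) + y_mean)
    return res, hyper


def compensate_matrix(
    expr: ExpressionMatrix, cn_frame: pd.DataFrame, min_obs: int = 10
) -> ExpressionMatrix:
    """Apply :func:`compensate_cnv_cis` to every gene present in both matrices."""
    out = expr.frame.copy()
    shared = [g for g in expr.genes if g in cn_frame.columns]
    for gene in shared:
        y = expr.frame[gene].to_numpy(dtype=float)
        x = cn_frame.reindex(expr.frame.index)[gene].to_numpy(dtype=float)
        if np.isfinite(y).sum() < min_obs or np.isfinite(x).sum() < min_obs:
            continue
        try:
            res, _ = compensate_cnv_cis(y, x)
        except SampleSizeError:
            continue
        out[gene] = res
    return ExpressionMatrix(out)


# ---------------------------------------------------------------------------
# influence-graph conditioning
# ---------------------------------------------------------------------------


def condition_influence_graph(
    graph: InfluenceGraph,
    expr: ExpressionMatrix,
    mut: MutationTable,
    weight_floor: float = 0.4,
    alpha: float = 0.05,
    min_mutated: int = 3,
    expressed: Optional[Sequence[str]] = None,
) -> dict[str, pd.DataFrame]:
    """Specialise the influence graph to the cohort, per mutated gene.

    Edges below ``weight_floor`` are dropped.  For each mutated gene with
    at least ``min_mutated`` mutated patients, every remaining neighbour
    is tested for differential expression between mutated and non-mutated
    patients (Welch two-sample t-test, BH adjustment at ``alpha``).  If
    any neighbour passes, the neighbour set shrinks to the passers with
    weight 1; otherwise the original weighted neighbour set is kept.  When
    ``expressed`` is given, non-expressed genes are removed both as
    mutated genes and as neighbours.

    Returns a mapping mutated gene -> DataFrame(neighbour, weight).
    """
    expressed_set = set(expressed) if expressed is not None else None
    patients = expr.patients
    mutated_by_gene = mut.modeled().records.groupby("gene")["patient"].apply(list)
    out: dict[str, pd.DataFrame] = {}
    for gene, mut_patients in mutated_by_gene.items():
        if expressed_set is not None and gene not in expressed_set:
            continue
        neigh = graph.neighbours(gene, min_weight=weight_floor)
        if expressed_set is not None:
            neigh = [(n, w) for n, w in neigh if n in expressed_set]
        neigh = [(n, w) for n, w in neigh if n in expr.frame.columns]
        if not neigh:
            logger.info("gene %s: no usable neighbours in the graph", gene)
            out[gene] = pd.DataFrame(columns=["neighbour", "weight"])
            continue
        mut_set = set(mut_patients) & set(patients)
        base = pd.DataFrame(neigh, columns=["neighbour", "weight"])
        if len(mut_set) < min_mutated or len(patients) - len(mut_set) < min_mutated:
            out[gene] = base
            continue
        in_mask = expr.frame.index.isin(mut_set)
        pvals = []
        for n, _ in neigh:
            col = expr.frame[n].to_numpy(dtype=float)
            a = col[in_mask]
            b = col[~in_mask]
            a, b = a[np.isfinite(a)], b[np.isfinite(b)]
            if a.size < min_mutated or b.size < min_mutated or (np.ptp(col[np.isfinite(col)]) == 0):
                pvals.append(1.0)
                continue
            pvals.append(float(stats.ttest_ind(a, b, equal_var=False).pvalue))
        reject, _, _, _ = multipletests(pvals, alpha=alpha, method="fdr_bh")
        if reject.any():
            kept = base[reject].copy()
            kept["weight"] = 1.0
            out[gene] = kept.reset_index(drop=True)
        else:
            out[gene] = base
    return out


def combine_cohort_tests(
    pvalue_tables: Mapping[str, pd.DataFrame], fdr: float = 0.05
) -> pd.DataFrame:
    """Fisher-combine per-cohort DE p-values for (gene, neighbour) pairs.

    ``pvalue_tables`` maps cohort name -> DataFrame(gene, neighbour, p).
    Pairs significant after BH at ``fdr`` on the combined p-value can be
    promoted to weight 1 even in cohorts where they did not pass alone.
    """
    stacked = pd.concat(
        [t.assign(cohort=name) for name, t in pvalue_tables.items()], ignore_index=True
    )
    rows = []
    for (gene, neigh), grp in stacked.groupby(["gene", "neighbour"]):
        stat, p = stats.combine_pvalues(grp["p"].clip(1e-300, 1.0), method="fisher")
        rows.append((gene, neigh, p))
    out = pd.DataFrame(rows, columns=["gene", "neighbour", "p_combined"])
    reject, qvals, _, _ = multipletests(out["p_combined"], alpha=fdr, method="fdr_bh")
    out["q_combined"] = qvals
    out["significant"] = reject
    return out
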