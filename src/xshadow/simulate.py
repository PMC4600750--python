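"""Generative simulator, permutation schemes, and AUROC/FDR evaluation.

The simulator performs ancestral sampling from the model itself: per gene
D ~ Bernoulli, per mutation F | D, per neighbour a uniform direction H,
per leaf G | F, H, and finally expression Y | G from a three-component
Student's-t mixture whose adjacent locations sit ``delta`` component-SDs
apart.  Patients not carrying the mutation draw Y from the null mixture.
The result comes packaged as the same domain containers real data use, so
the full preprocessing + fitting + inference stack can be benchmarked
end to end against the known ground truth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .emission import fit_t_mixtures
from .errors import UndefinedAUCError, XshadowError
from .inference import EMTrace, em_fit, infer_posteriors
from .io import ExpressionMatrix, InfluenceGraph, MutationTable
from .model import GeneSubmodel, ModelParameters, Posteriors, estimate_h

logger = logging.getLogger(__name__)


@dataclass
class SimulationHyperparams:
    """Study conditions for one simulated cohort.

    ``delta`` is the distance between adjacent emission component
    locations in units of the within-component SD (for a t with nu > 2,
    SD = scale * sqrt(nu / (nu - 2))).  ``theta`` holds the generative
    CPDs; ``fraction_d1`` plays the role of the D prior.  ``cohort_size``
    patients are simulated per dataset with ``m_patients`` of them mutated
    in each gene.  ``phenocopy_fraction`` of non-mutated patients can be
    flipped to mutated-like expression to emulate epigenetically silenced
    phenocopies (default off).
    """

    n_genes: int = 200
    fraction_d1: float = 0.5
    m_patients: int = 30
    n_neighbours: int = 20
    delta: float = 1.5
    theta: ModelParameters = field(
        default_factory=lambda: ModelParameters(
            theta_d=0.5,
            theta_f_d0=0.10,
            theta_f_d1=0.85,
            theta_g_f0=np.array([0.05, 0.90, 0.05]),
            theta_g_f1_up=np.array([0.05, 0.45, 0.50]),
            theta_g_f1_down=np.array([0.50, 0.45, 0.05]),
        )
    )
    cohort_size: int = 200
    nu: float = 5.0
    scale: float = 1.0
    edge_weight: float = 1.0
    phenocopy_fraction: float = 0.0
    #: unregulated expressed genes added to the matrix (not connected to any
    #: mutated gene); they emulate the bulk of a real transcriptome and are
    #: what a random network draw mostly lands on
    n_background_genes: int = 0
    rng_seed: int = 0

    def __post_init__(self):
        if min(self.n_genes, self.m_patients, self.n_neighbours, self.cohort_size) < 1:
            raise ValueError("all counts must be >= 1")
        if self.delta < 0:
            raise ValueError("delta must be >= 0")
        if self.m_patients > self.cohort_size:
            raise ValueError("more mutated patients than cohort patients")


@dataclass
class SimTruth:
    """Ground-truth latent assignments of a simulated dataset."""

    genes: list[str]
    d: np.ndarray  # (n_genes,)
    f: dict[str, np.ndarray]  # gene -> (M,)
    g: dict[str, np.ndarray]  # gene -> (M, N)
    h: dict[str, np.ndarray]  # gene -> (N,)
    mutated_patients: dict[str, list[str]]
    neighbours: dict[str, list[str]]
    baselines: dict[str, np.ndarray] = field(default_factory=dict)  # gene -> (N,)


def _component_sd(nu: float, scale: float) -> float:
    if nu <= 2:
        return scale
    return scale * float(np.sqrt(nu / (nu - 2.0)))


def simulate_dataset(h: SimulationHyperparams):
    """Ancestral sampling of a full cohort; deterministic given the seed.

    Returns (MutationTable, ExpressionMatrix, InfluenceGraph, SimTruth).
    Every simulated gene owns a disjoint set of ``n_neighbours`` connected
    genes (weights ``edge_weight``) and ``m_patients`` mutated patients
    drawn from the shared cohort; mutation count is exactly
    n_genes * m_patients.
    """
    rng = np.random.default_rng(h.rng_seed)
    patients = [f"P{i:04d}" for i in range(h.cohort_size)]
    genes = [f"G{j:04d}" for j in range(h.n_genes)]
    th = h.theta
    sd = _component_sd(h.nu, h.scale)
    offsets = np.array([-h.delta * sd, 0.0, h.delta * sd])

    d_true = (rng.random(h.n_genes) < h.fraction_d1).astype(int)
    f_true: dict[str, np.ndarray] = {}
    g_true: dict[str, np.ndarray] = {}
    h_true: dict[str, np.ndarray] = {}
    mut_patients: dict[str, list[str]] = {}
    neighbours: dict[str, list[str]] = {}
    baselines: dict[str, np.ndarray] = {}
    mut_rows = []
    expr_cols: dict[str, np.ndarray] = {}
    edges = []

    for j, gene in enumerate(genes):
        neigh = [f"{gene}.N{k:03d}" for k in range(h.n_neighbours)]
        neighbours[gene] = neigh
        edges.extend((gene, nb, h.edge_weight) for nb in neigh)
        idx = rng.choice(h.cohort_size, size=h.m_patients, replace=False)
        idx.sort()
        mut_patients[gene] = [patients[i] for i in idx]
        mut_rows.extend((patients[i], gene, "missense", np.nan) for i in idx)
        hn = rng.integers(0, 2, size=h.n_neighbours)
        h_true[gene] = hn
        pf1 = th.theta_f_d1 if d_true[j] else th.theta_f_d0
        f = (rng.random(h.m_patients) < pf1).astype(int)
        f_true[gene] = f
        # sample G for every (patient, neighbour); non-mutated patients and
        # F=0 mutations use the null table
        g = np.empty((h.cohort_size, h.n_neighbours), dtype=int)
        null_g = rng.choice(3, size=(h.cohort_size, h.n_neighbours), p=th.theta_g_f0)
        g[:] = null_g
        for mi, i in enumerate(idx):
            if f[mi] == 1:
                for k in range(h.n_neighbours):
                    table = th.g_table(int(hn[k]))
                    g[i, k] = rng.choice(3, p=table)
        if h.phenocopy_fraction > 0:
            non_mut = np.setdiff1d(np.arange(h.cohort_size), idx)
            n_flip = int(round(h.phenocopy_fraction * non_mut.size))
            if n_flip:
                flip = rng.choice(non_mut, size=n_flip, replace=False)
                for i in flip:
                    for k in range(h.n_neighbours):
                        g[i, k] = rng.choice(3, p=th.g_table(int(hn[k])))
        g_true[gene] = g[idx, :]
        baseline = rng.uniform(6.0, 10.0, size=h.n_neighbours)
        baselines[gene] = baseline
        t_noise = rng.standard_t(h.nu, size=(h.cohort_size, h.n_neighbours)) * h.scale
        y = baseline[None, :] + offsets[g] + t_noise
        for k, nb in enumerate(neigh):
            expr_cols[nb] = y[:, k]
        # the mutated gene's own (trans-neutral) expression
        expr_cols[gene] = rng.uniform(6.0, 10.0) + rng.standard_t(h.nu, size=h.cohort_size) * h.scale

    for b in range(h.n_background_genes):
        g_bg = rng.choice(3, size=h.cohort_size, p=th.theta_g_f0)
        y_bg = (
            rng.uniform(6.0, 10.0)
            + offsets[g_bg]
            + rng.standard_t(h.nu, size=h.cohort_size) * h.scale
        )
        expr_cols[f"BG{b:04d}"] = y_bg

    mut = MutationTable(pd.DataFrame(mut_rows, columns=["patient", "gene", "mut_class", "position"]))
    expr = ExpressionMatrix(pd.DataFrame(expr_cols, index=pd.Index(patients, name="patient")))
    graph = InfluenceGraph(edges)
    truth = SimTruth(
        genes=genes,
        d=d_true,
        f=f_true,
        g=g_true,
        h=h_true,
        mutated_patients=mut_patients,
        neighbours=neighbours,
        baselines=baselines,
    )
    return mut, expr, graph, truth


def submodels_with_true_emissions(
    expr: ExpressionMatrix, truth: SimTruth, hyper: SimulationHyperparams, fix_h: bool = True
) -> list[GeneSubmodel]:
    """Build gene submodels using the simulator's own emission components.

    Bypasses mixture fitting: each neighbour's emission densities are the
    generative t components (baseline + delta offsets).  Useful when a test
    targets the inference/EM layer in isolation.  ``fix_h`` installs the
    true directions; otherwise H is estimated from the off-line posteriors.
    """
    from .emission import TMixture

    sd = _component_sd(hyper.nu, hyper.scale)
    offs = np.array([-hyper.delta * sd, 0.0, hyper.delta * sd])
    nu = max(hyper.nu, 2.0)
    subs = []
    for gi, gene in enumerate(truth.genes):
        neigh = truth.neighbours[gene]
        pats = truth.mutated_patients[gene]
        y = expr.frame.loc[pats, neigh].to_numpy(dtype=float)
        mixtures = [
            TMixture(
                weights=hyper.theta.theta_g_f0,
                locations=truth.baselines[gene][k] + offs,
                scales=np.full(3, hyper.scale),
                dfs=np.full(3, nu),
            )
            for k in range(len(neigh))
        ]
        sub = GeneSubmodel.build(
            gene=gene,
            patients=pats,
            neighbours=neigh,
            weights=np.full(len(neigh), hyper.edge_weight),
            y=y,
            mixtures=mixtures,
        )
        sub.h = truth.h[gene].astype(int) if fix_h else estimate_h(sub)
        subs.append(sub)
    return subs


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------


def evaluate_auc(posteriors: dict[str, Posteriors], truth: SimTruth):
    """Rank-based AUROC of P(D) against true D and pooled P(F) against true F."""
    genes = [g for g in truth.genes if g in posteriors]
    d_scores = np.array([posteriors[g].p_d for g in genes])
    d_labels = np.array([truth.d[truth.genes.index(g)] for g in genes])
    f_scores = np.concatenate([posteriors[g].p_f for g in genes])
    f_labels = np.concatenate([truth.f[g] for g in genes])
    for lab in (d_labels, f_labels):
        if len(np.unique(lab)) < 2:
            raise UndefinedAUCError("AUROC undefined with a single-class truth")
    return float(roc_auc_score(d_labels, d_scores)), float(roc_auc_score(f_labels, f_scores))


def auroc(scores, labels) -> float:
    """Plain rank-based AUROC with midrank ties."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise UndefinedAUCError("AUROC undefined with a single-class truth")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


# ---------------------------------------------------------------------------
# permutation schemes
# ---------------------------------------------------------------------------

PERMUTATION_SCHEMES = ("sample", "gene", "network", "all")


def permute(
    mut: MutationTable,
    graph: Optional[InfluenceGraph],
    scheme: str,
    seed: int,
    universe=None,
):
    """Scheme-specific null shuffle; the expression matrix is never touched.

    sample   switch patient names within the mutation table
    gene     switch gene names within the mutation table
    network  redraw each mutated gene's neighbours uniformly from the gene
             universe (``universe`` if given, e.g. all expressed genes, else
             the graph's nodes), preserving neighbour-set sizes and weights
    all      sample + gene + network combined
    """
    if scheme not in PERMUTATION_SCHEMES:
        raise ValueError(f"unknown permutation scheme: {scheme!r}")
    rng = np.random.default_rng(seed)
    new_mut, new_graph = mut, graph
    if scheme in ("sample", "all"):
        pats = sorted(new_mut.records["patient"].unique())
        mapping = dict(zip(pats, rng.permutation(pats)))
        df = new_mut.records.copy()
        df["patient"] = df["patient"].map(mapping)
        new_mut = MutationTable(df.reset_index(drop=True))
    if scheme in ("gene", "all"):
        gs = sorted(new_mut.records["gene"].unique())
        mapping = dict(zip(gs, rng.permutation(gs)))
        df = new_mut.records.copy()
        df["gene"] = df["gene"].map(mapping)
        new_mut = MutationTable(df.reset_index(drop=True))
    if scheme in ("network", "all"):
        if graph is None:
            raise XshadowError("network permutation requires a graph")
        mutated = set(new_mut.records["gene"])
        # draw from the non-mutated universe so no redraw inflates another
        # mutated gene's own neighbour set; keep the original edge weights
        pool = set(universe) if universe is not None else set(graph.nodes())
        universe = np.array(sorted(pool - mutated))
        edges = []
        for gene in sorted(mutated):
            old = graph.neighbours(gene)
            if not old:
                continue
            drawn = rng.choice(universe, size=len(old), replace=False)
            for (_, w), nb in zip(old, drawn):
                edges.append((gene, str(nb), w))
        new_graph = InfluenceGraph(edges)
    return new_mut, new_graph


def estimate_permutation_fdr(real_calls: int, permuted_calls) -> float:
    """Permutation FDR: mean permuted call count over the real call count.

    Clipped to [0, 1]; zero real calls are guarded to 1 in the denominator.
    """
    permuted_calls = np.asarray(permuted_calls, dtype=float)
    if real_calls < 0 or np.any(permuted_calls < 0):
        raise ValueError("call counts must be non-negative")
    fdr = permuted_calls.mean() / max(real_calls, 1)
    return float(np.clip(fdr, 0.0, 1.0))


# ---------------------------------------------------------------------------
# end-to-end benchmark
# ---------------------------------------------------------------------------


def fit_and_score(
    mut: MutationTable,
    expr: ExpressionMatrix,
    graph: InfluenceGraph,
    weight_floor: float = 0.0,
    em_max_iter: int = 100,
    em_tol: float = 1e-5,
    init: Optional[ModelParameters] = None,
    params: Optional[ModelParameters] = None,
) -> tuple[dict[str, Posteriors], EMTrace]:
    """Full trans-mode fit on in-memory containers: emissions -> H -> EM -> score.

    Fits per-neighbour t mixtures on the whole cohort, builds one submodel
    per mutated gene from the graph's neighbour sets, estimates H, runs EM
    across genes and returns the final per-gene posteriors.

    Passing ``params`` skips EM and scores with the given parameters — the
    protocol for permutation nulls, where the scoring function learned on
    the real data must be held fixed while the inputs are shuffled.
    """
    genes = sorted(set(mut.modeled().records["gene"]))
    cols: list[str] = []
    per_gene_neigh: dict[str, list[tuple[str, float]]] = {}
    for gene in genes:
        neigh = [(n, w) for n, w in graph.neighbours(gene, min_weight=weight_floor) if n in expr.frame.columns]
        if neigh:
            per_gene_neigh[gene] = neigh
            cols.extend(n for n, _ in neigh)
    cols = sorted(set(cols))
    col_idx = {c: i for i, c in enumerate(cols)}
    matrix = expr.frame[cols].to_numpy(dtype=float)
    mixtures = fit_t_mixtures(matrix)
    # per-column component log densities over the whole cohort; each gene's
    # non-mutated patients serve as known-null observations during EM
    dens = np.full((matrix.shape[0], len(cols), 3), np.nan)
    for i, mix in enumerate(mixtures):
        colv = matrix[:, i]
        ok = np.isfinite(colv)
        dens[ok, i, :] = mix.component_log_density(colv[ok])
    patient_index = {p: i for i, p in enumerate(expr.frame.index)}
    subs = []
    for gene in genes:
        if gene not in per_gene_neigh:
            continue
        neigh = per_gene_neigh[gene]
        pats = [p for p in mut.patients_of(gene) if p in expr.frame.index]
        if not pats:
            continue
        classes = mut.records.set_index(["gene", "patient"])["mut_class"]
        y = expr.frame.loc[pats, [n for n, _ in neigh]].to_numpy(dtype=float)
        sub = GeneSubmodel.build(
            gene=gene,
            patients=pats,
            neighbours=[n for n, _ in neigh],
            weights=[w for _, w in neigh],
            y=y,
            mixtures=[mixtures[col_idx[n]] for n, _ in neigh],
            mut_classes=[classes.loc[(gene, p)] for p in pats],
        )
        sub.h = estimate_h(sub)
        null_rows = np.setdiff1d(
            np.arange(matrix.shape[0]), [patient_index[p] for p in pats]
        )
        block = dens[np.ix_(null_rows, [col_idx[n] for n, _ in neigh])].reshape(-1, 3)
        sub.null_log_emission = block[np.isfinite(block[:, 0])]
        subs.append(sub)
    if not subs:
        raise XshadowError("no scorable gene submodels")
    if params is not None:
        trace = EMTrace(
            loglik=np.array([]),
            objective=np.array([]),
            n_iter=0,
            converged=True,
            params=params,
            scored_genes=[s.gene for s in subs],
        )
    else:
        trace = em_fit(subs, init=init, max_iter=em_max_iter, tol=em_tol)
    posteriors = {sub.gene: infer_posteriors(sub, trace.params) for sub in subs}
    return posteriors, trace


def run_simulation_benchmark(
    hyper: SimulationHyperparams,
    n_replicates: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate, fit and score ``n_replicates`` cohorts; AUROC per replicate.

    Returns a DataFrame with columns replicate, seed, auc_d, auc_f.
    """
    rows = []
    for rep in range(n_replicates):
        rep_seed = (seed + 1000003 * rep) % (2**31 - 1)
        h = replace(hyper, rng_seed=rep_seed)
        mut, expr, graph, truth = simulate_dataset(h)
        posteriors, _ = fit_and_score(mut, expr, graph)
        auc_d, auc_f = evaluate_auc(posteriors, truth)
        logger.info("replicate %d: auc_d=%.4f auc_f=%.4f", rep, auc_d, auc_f)
        rows.append((rep, rep_seed, auc_d, auc_f))
    return pd.DataFrame(rows, columns=["replicate", "seed", "auc_d", "auc_f"])
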