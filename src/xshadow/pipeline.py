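"""End-to-end orchestration: preprocess -> condition graph -> fit -> score ->
annotate -> report.

``run_pipeline`` wires the modules together for a cis or trans analysis and
records everything needed to reproduce the run in a :class:`RunManifest`.
A single seed fans out deterministically to per-stage child seeds so
partial re-runs stay reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .drivers import annotate_drivers
from .errors import MixtureUnfitError, PipelineError, XshadowError
from .inference import em_fit, infer_posteriors
from .io import (
    ExpressionMatrix,
    InfluenceGraph,
    MutationTable,
    align_cohort,
    read_copy_number,
    read_expression,
    read_influence_graph,
    read_mutations,
    write_posteriors,
)
from .model import GeneResult, GeneSubmodel, estimate_h
from .posthoc import flag_hypermutators, stratify_patients
from .preprocess import compensate_matrix, condition_influence_graph, detect_expressed_genes
from .simulate import fit_and_score

logger = logging.getLogger(__name__)


@dataclass
class AnalysisConfig:
    """User-facing knobs of one analysis run."""

    mode: str = "cis"  # cis | trans
    p_d_threshold: float = 0.8
    p_f_threshold: float = 0.5
    weight_floor: float = 0.4
    em_max_iter: int = 100
    em_tol: float = 1e-5
    rng_seed: int = 0
    include_silent: bool = False
    expressed_filter: bool = True
    driver_threshold: float = 0.2

    def __post_init__(self):
        if self.mode not in ("cis", "trans"):
            raise ValueError("mode must be 'cis' or 'trans'")
        for name in ("p_d_threshold", "p_f_threshold"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name} must lie in (0, 1)")
        if self.em_tol <= 0:
            raise ValueError("em_tol must be positive")

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path):
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


@dataclass
class RunManifest:
    """Reproducibility record of one pipeline run."""

    config: dict
    seed: int
    version: str
    input_checksums: dict[str, str]
    timings: dict[str, float] = field(default_factory=dict)
    outputs: dict[str, str] = field(default_factory=dict)
    n_patients: int = 0
    n_genes_scored: int = 0

    def write(self, path):
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)

    @classmethod
    def read(cls, path) -> "RunManifest":
        with open(path) as fh:
            return cls(**json.load(fh))


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def child_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the global seed."""
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2**31 - 1)


def run_pipeline(
    config: AnalysisConfig,
    mutations_path,
    expression_path,
    out_dir,
    cnv_path=None,
    cnv_calls_path=None,
    graph_path=None,
) -> RunManifest:
    """Execute a full cis or trans analysis from TSV inputs to report TSVs.

    Stages: align -> expressed-gene filter -> (trans) copy-number cis
    compensation -> (trans) graph conditioning / (cis) self-graph ->
    emission fits + H estimation -> EM -> posterior inference -> threshold
    calls -> driver annotation -> stratification and hypermutator reports.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    timings: dict[str, float] = {}
    checksums = {}
    for name, p in (
        ("mutations", mutations_path),
        ("expression", expression_path),
        ("cnv", cnv_path),
        ("cnv_calls", cnv_calls_path),
        ("graph", graph_path),
    ):
        if p is not None:
            checksums[name] = _sha256(p)

    def stage(name):
        timings[name] = time.time() - t0

    try:
        mut = read_mutations(mutations_path)
        expr = read_expression(expression_path)
        cn = read_copy_number(cnv_path, cnv_calls_path) if cnv_path else None
        graph = read_influence_graph(graph_path) if graph_path else None
    except XshadowError as e:
        raise PipelineError("load", str(e)) from e
    if config.mode == "trans" and (graph is None or graph.number_of_edges() == 0):
        raise PipelineError("graph_conditioning", "trans mode requires a non-empty influence graph")

    try:
        mut, expr, cn = align_cohort(mut, expr, cn)
    except XshadowError as e:
        raise PipelineError("align", str(e)) from e
    if not config.include_silent:
        mut_model = mut.modeled()
    else:
        df = mut.records.copy()
        df["modeled"] = True
        mut_model = MutationTable(df)
    stage("align")

    expressed = None
    if config.expressed_filter:
        try:
            calls = detect_expressed_genes(expr)
            expressed = set(calls.index[calls["is_expressed"]])
            calls.to_csv(out_dir / "expressed_genes.tsv", sep="\t")
        except MixtureUnfitError as e:
            logger.warning("expressed-gene filter disabled: %s", e)
    stage("expressed_filter")

    if config.mode == "trans" and cn is not None:
        try:
            expr = compensate_matrix(expr, cn.frame)
        except XshadowError as e:
            raise PipelineError("cnv_compensation", str(e)) from e
    stage("cnv_compensation")

    try:
        if config.mode == "trans":
            neigh_lists = condition_influence_graph(
                graph,
                expr,
                mut_model,
                weight_floor=config.weight_floor,
                expressed=sorted(expressed) if expressed is not None else None,
            )
            edges = [
                (g, r["neighbour"], r["weight"])
                for g, table in neigh_lists.items()
                for _, r in table.iterrows()
            ]
            if not edges:
                raise PipelineError("graph_conditioning", "conditioning left no usable edges")
            work_graph = InfluenceGraph(edges)
        else:
            genes = sorted(set(mut_model.records["gene"]))
            if expressed is not None:
                genes = [g for g in genes if g in expressed]
            genes = [g for g in genes if g in expr.frame.columns]
            if not genes:
                raise PipelineError("graph_conditioning", "no mutated gene has expression data")
            # cis: each mutated gene connects only to itself; networkx cannot
            # hold self-loops in our container, so submodels are built directly
            work_graph = None
    except PipelineError:
        raise
    except XshadowError as e:
        raise PipelineError("graph_conditioning", str(e)) from e
    stage("graph_conditioning")

    try:
        if config.mode == "trans":
            posteriors, trace = fit_and_score(
                mut_model,
                expr,
                work_graph,
                em_max_iter=config.em_max_iter,
                em_tol=config.em_tol,
            )
            neighbours_of = {g: [n for n, _ in work_graph.neighbours(g)] for g in posteriors}
        else:
            posteriors, trace, neighbours_of = _fit_cis(mut_model, expr, genes, config)
    except XshadowError as e:
        raise PipelineError("model_fit", str(e)) from e
    stage("model_fit")

    classes = mut_model.records.set_index(["gene", "patient"])["mut_class"]
    results = {}
    gene_rows = []
    for gene, post in posteriors.items():
        pats = [p for p in mut_model.patients_of(gene) if p in expr.frame.index]
        res = GeneResult(
            gene=gene,
            patients=pats,
            mut_classes=[classes.loc[(gene, p)] for p in pats],
            neighbours=neighbours_of[gene],
            posteriors=post,
        )
        results[gene] = res
        gene_rows.append((gene, post.p_d, post.p_d >= config.p_d_threshold))
    posterior_paths = write_posteriors(results, out_dir)
    calls_df = pd.DataFrame(gene_rows, columns=["gene", "p_d", "called"]).sort_values(
        "p_d", ascending=False
    )
    calls_df.to_csv(out_dir / "gene_calls.tsv", sep="\t", index=False)
    trace.write_tsv(out_dir / "em_trace.tsv")
    trace.params.write_tsv(out_dir / "parameters.tsv")
    stage("score")

    try:
        drivers = annotate_drivers(mut, threshold=config.driver_threshold)
        drivers.to_csv(out_dir / "driver_annotation.tsv", sep="\t")
    except XshadowError as e:
        logger.warning("driver annotation skipped: %s", e)
    stage("driver_annotation")

    strat_rows = []
    seed = child_seed(config.rng_seed, "dip")
    for gene, res in results.items():
        if res.posteriors.p_f.size >= 4:
            s = stratify_patients(
                res.posteriors.p_f,
                patients=res.patients,
                threshold=config.p_f_threshold,
                gene=gene,
                seed=seed,
            )
            strat_rows.append(
                (gene, s.dip, s.dip_pvalue, len(s.high_patients), len(s.low_patients))
            )
    pd.DataFrame(
        strat_rows, columns=["gene", "dip", "dip_pvalue", "n_high", "n_low"]
    ).to_csv(out_dir / "stratification.tsv", sep="\t", index=False)
    burden = mut.records.groupby("patient").size()
    if len(burden) >= 4:
        hyper = flag_hypermutators(burden.to_numpy())
        pd.DataFrame({"patient": burden.index, "n_mutations": burden.to_numpy(), "hypermutator": hyper}).to_csv(
            out_dir / "hypermutators.tsv", sep="\t", index=False
        )
    stage("posthoc")

    manifest = RunManifest(
        config=asdict(config),
        seed=config.rng_seed,
        version=__version__,
        input_checksums=checksums,
        timings=timings,
        outputs={k: str(v) for k, v in posterior_paths.items()}
        | {"gene_calls": str(out_dir / "gene_calls.tsv")},
        n_patients=len(expr.patients),
        n_genes_scored=len(results),
    )
    manifest.write(out_dir / "manifest.json")
    return manifest


def _fit_cis(mut_model: MutationTable, expr: ExpressionMatrix, genes, config: AnalysisConfig):
    """Cis mode: each mutated gene's only neighbour is itself (weight 1)."""
    from .emission import fit_t_mixtures

    matrix = expr.frame[genes].to_numpy(dtype=float)
    mixtures = fit_t_mixtures(matrix)
    classes = mut_model.records.set_index(["gene", "patient"])["mut_class"]
    subs = []
    for i, gene in enumerate(genes):
        pats = [p for p in mut_model.patients_of(gene) if p in expr.frame.index]
        if not pats:
            continue
        y = expr.frame.loc[pats, [gene]].to_numpy(dtype=float)
        sub = GeneSubmodel.build(
            gene=gene,
            patients=pats,
            neighbours=[gene],
            weights=[1.0],
            y=y,
            mixtures=[mixtures[i]],
            mut_classes=[classes.loc[(gene, p)] for p in pats],
        )
        sub.h = estimate_h(sub)
        null_mask = ~expr.frame.index.isin(pats)
        colv = matrix[null_mask, i]
        colv = colv[np.isfinite(colv)]
        sub.null_log_emission = mixtures[i].component_log_density(colv)
        subs.append(sub)
    if not subs:
        raise XshadowError("no scorable cis submodels")
    trace = em_fit(subs, max_iter=config.em_max_iter, tol=config.em_tol)
    posteriors = {s.gene: infer_posteriors(s, trace.params) for s in subs}
    neighbours_of = {s.gene: [s.gene] for s in subs}
    return posteriors, trace, neighbours_of
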