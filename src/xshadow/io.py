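"""Domain containers and TSV readers/writers.

Four inputs drive an analysis: a somatic mutation table, a patients x genes
log2 expression matrix, an optional copy-number matrix, and a weighted
gene-gene influence graph.  All files are tab-separated UTF-8 with a header
row; matrices carry patient ids in the first column and gene ids in the
header.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .errors import CohortError, EmptyTableError, FormatError, XshadowError

logger = logging.getLogger(__name__)

#: Closed set of somatic mutation class labels.
MUTATION_CLASSES = frozenset(
    {
        "missense",
        "nonsense",
        "frameshift_indel",
        "inframe_indel",
        "splice_site",
        "synonymous",
        "noncoding",
        "stop_gain",
        "hlamp",
        "hdel",
        "complex",
    }
)

#: Classes excluded from expression-impact modelling by default: silent and
#: non-coding events are not expected to perturb the transcriptome.
NONFUNCTIONAL_CLASSES = frozenset({"synonymous", "noncoding"})

#: Loss-of-function classes (protein-truncating).
LOF_CLASSES = frozenset({"nonsense", "stop_gain", "frameshift_indel", "splice_site"})

#: MAF-lite Variant_Classification -> internal class label.
MAF_CLASS_MAP = {
    "Missense_Mutation": "missense",
    "Nonsense_Mutation": "nonsense",
    "Nonstop_Mutation": "nonsense",
    "Frame_Shift_Del": "frameshift_indel",
    "Frame_Shift_Ins": "frameshift_indel",
    "In_Frame_Del": "inframe_indel",
    "In_Frame_Ins": "inframe_indel",
    "Splice_Site": "splice_site",
    "Splice_Region": "splice_site",
    "Silent": "synonymous",
    "Translation_Start_Site": "noncoding",
    "5'UTR": "noncoding",
    "3'UTR": "noncoding",
    "5'Flank": "noncoding",
    "3'Flank": "noncoding",
    "Intron": "noncoding",
    "IGR": "noncoding",
    "RNA": "noncoding",
    "lincRNA": "noncoding",
}

_MUT_COLUMNS = ["patient", "gene", "mut_class", "position"]


@dataclass
class MutationTable:
    """Collapsed per-(patient, gene) somatic mutation events.

    Each (patient, gene) pair appears at most once; a pair observed with
    more than one raw event is collapsed into a single record of class
    ``complex`` with the codon position dropped.  The ``modeled`` column
    flags records whose class participates in expression-impact modelling
    (synonymous/noncoding events are retained but flagged out by default).
    """

    records: pd.DataFrame

    def __post_init__(self):
        df = self.records
        missing = [c for c in ("patient", "gene", "mut_class") if c not in df.columns]
        if missing:
            raise FormatError(f"mutation table missing column(s): {missing}")
        if "position" not in df.columns:
            df = df.assign(position=np.nan)
        bad = set(df["mut_class"]) - MUTATION_CLASSES
        if bad:
            raise FormatError(f"unknown mutation class(es): {sorted(bad)}")
        if (df["patient"].astype(str).str.len() == 0).any() or (
            df["gene"].astype(str).str.len() == 0
        ).any():
            raise FormatError("empty patient or gene id in mutation table")
        if df.duplicated(subset=["patient", "gene"]).any():
            raise FormatError(
                "MutationTable requires collapsed records; use from_events()"
            )
        if "modeled" not in df.columns:
            df = df.assign(modeled=~df["mut_class"].isin(NONFUNCTIONAL_CLASSES))
        self.records = df[_MUT_COLUMNS + ["modeled"]].reset_index(drop=True)

    # -- constructors -------------------------------------------------------

    @classmethod
    def from_events(cls, events: pd.DataFrame) -> "MutationTable":
        """Collapse raw events so each (patient, gene) is one record.

        A pair with multiple raw events becomes one ``complex`` record
        (position dropped), mirroring how a gene harbouring several kinds
        of mutation in the same tumour is labelled.
        """
        if events.empty:
            raise EmptyTableError("no mutation events")
        ev = events.copy()
        if "position" not in ev.columns:
            ev["position"] = np.nan
        rows = []
        for (patient, gene), grp in ev.groupby(["patient", "gene"], sort=True):
            if len(grp) == 1:
                r = grp.iloc[0]
                rows.append((patient, gene, r["mut_class"], r["position"]))
            else:
                rows.append((patient, gene, "complex", np.nan))
        df = pd.DataFrame(rows, columns=_MUT_COLUMNS)
        return cls(df)

    # -- accessors ----------------------------------------------------------

    @property
    def patients(self) -> list[str]:
        return sorted(self.records["patient"].unique())

    @property
    def genes(self) -> list[str]:
        return sorted(self.records["gene"].unique())

    def modeled(self) -> "MutationTable":
        """Restrict to records participating in modelling."""
        return MutationTable(self.records[self.records["modeled"]].copy())

    def patients_of(self, gene: str) -> list[str]:
        sub = self.records[self.records["gene"] == gene]
        return sub["patient"].tolist()

    def restrict_patients(self, keep: Iterable[str]) -> "MutationTable":
        keep = set(keep)
        df = self.records[self.records["patient"].isin(keep)].copy()
        if df.empty:
            raise EmptyTableError("no mutation records left after restriction")
        return MutationTable(df)

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class ExpressionMatrix:
    """Patients x genes continuous log2 expression; NaN marks missing."""

    frame: pd.DataFrame  # index = patients, columns = genes

    def __post_init__(self):
        f = self.frame
        if f.index.duplicated().any():
            raise FormatError("duplicate patient ids in expression matrix")
        if f.columns.duplicated().any():
            raise FormatError("duplicate gene ids in expression matrix")
        vals = f.to_numpy()
        if vals.dtype.kind not in "fiu":
            raise FormatError("expression matrix must be numeric")
        if np.isinf(vals).any():
            raise FormatError("expression matrix contains infinities")

    @property
    def patients(self) -> list[str]:
        return list(self.frame.index)

    @property
    def genes(self) -> list[str]:
        return list(self.frame.columns)

    @property
    def values(self) -> np.ndarray:
        return self.frame.to_numpy(dtype=float)

    def restrict_patients(self, keep: Sequence[str]) -> "ExpressionMatrix":
        keep = [p for p in self.patients if p in set(keep)]
        return ExpressionMatrix(self.frame.loc[keep])

    def column(self, gene: str) -> pd.Series:
        return self.frame[gene]


@dataclass
class CopyNumberMatrix:
    """Patients x genes log2 copy-number ratios plus optional discrete calls.

    Discrete calls, when present, are from {hdel, neutral, hlamp}
    (homozygous deletion / neutral / amplification to >= 4 copies).
    """

    frame: pd.DataFrame
    calls: Optional[pd.DataFrame] = None

    _CALLS = frozenset({"hdel", "neutral", "hlamp"})

    def __post_init__(self):
        ExpressionMatrix(self.frame)  # reuse shape/uniqueness validation
        if self.calls is not None:
            if not self.calls.index.equals(self.frame.index) or not self.calls.columns.equals(
                self.frame.columns
            ):
                raise FormatError("copy-number calls must match the ratio matrix shape")
            bad = set(np.unique(self.calls.to_numpy().astype(str))) - self._CALLS
            if bad:
                raise FormatError(f"unknown copy-number call(s): {sorted(bad)}")

    @property
    def patients(self) -> list[str]:
        return list(self.frame.index)

    @property
    def genes(self) -> list[str]:
        return list(self.frame.columns)

    def restrict_patients(self, keep: Sequence[str]) -> "CopyNumberMatrix":
        keep = [p for p in self.patients if p in set(keep)]
        calls = self.calls.loc[keep] if self.calls is not None else None
        return CopyNumberMatrix(self.frame.loc[keep], calls)


class InfluenceGraph:
    """Undirected weighted gene-gene association network.

    Edge weights live in [0, 1] and encode prior confidence that the two
    genes are functionally related.  Merging duplicate edges keeps the
    maximum weight; self-loops are dropped.
    """

    def __init__(self, edges: Iterable[tuple[str, str, float]] = ()):
        g = nx.Graph()
        for a, b, w in edges:
            w = float(w)
            if not (0.0 <= w <= 1.0):
                raise FormatError(f"edge weight {w} outside [0, 1] for ({a}, {b})")
            if a == b:
                continue
            if g.has_edge(a, b):
                g[a][b]["weight"] = max(g[a][b]["weight"], w)
            else:
                g.add_edge(a, b, weight=w)
        self._g = g

    @classmethod
    def merge(cls, *graphs: "InfluenceGraph") -> "InfluenceGraph":
        """Merge edge lists, keeping the maximum weight per unordered pair."""
        out = cls()
        for gr in graphs:
            for a, b, w in gr.edges():
                if out._g.has_edge(a, b):
                    out._g[a][b]["weight"] = max(out._g[a][b]["weight"], w)
                else:
                    out._g.add_edge(a, b, weight=w)
        return out

    def edges(self) -> list[tuple[str, str, float]]:
        return [(a, b, d["weight"]) for a, b, d in self._g.edges(data=True)]

    def nodes(self) -> list[str]:
        return list(self._g.nodes)

    def has_gene(self, gene: str) -> bool:
        return gene in self._g

    def neighbours(self, gene: str, min_weight: float = 0.0) -> list[tuple[str, float]]:
        """Neighbours of ``gene`` with weight >= ``min_weight``, sorted by id."""
        if gene not in self._g:
            return []
        out = [
            (n, self._g[gene][n]["weight"])
            for n in self._g.neighbors(gene)
            if self._g[gene][n]["weight"] >= min_weight
        ]
        return sorted(out)

    def number_of_edges(self) -> int:
        return self._g.number_of_edges()

    def __contains__(self, gene: str) -> bool:
        return gene in self._g


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def _read_tsv(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"file not found: {path}")
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, na_values=["", "NA"])
    if df.empty:
        raise EmptyTableError(f"empty table: {path}")
    return df


def read_mutations(path, dialect: str = "tsv") -> MutationTable:
    """Read a mutation table in ``tsv`` or ``maf_lite`` dialect.

    tsv columns: patient, gene, mut_class [, position].
    MAF-lite columns: Tumor_Sample_Barcode, Hugo_Symbol,
    Variant_Classification [, Codon_Position]; classes are mapped through a
    fixed table and unmapped classes raise a format error.
    """
    df = _read_tsv(path)
    if dialect == "tsv":
        required = ["patient", "gene", "mut_class"]
    elif dialect == "maf_lite":
        required = ["Tumor_Sample_Barcode", "Hugo_Symbol", "Variant_Classification"]
    else:
        raise ValueError(f"unknown dialect: {dialect!r}")
    for col in required:
        if col not in df.columns:
            raise FormatError(f"missing required column {col!r} in {path}")
    if dialect == "maf_lite":
        unmapped = set(df["Variant_Classification"]) - set(MAF_CLASS_MAP)
        if unmapped:
            raise FormatError(f"unmapped Variant_Classification value(s): {sorted(unmapped)}")
        events = pd.DataFrame(
            {
                "patient": df["Tumor_Sample_Barcode"],
                "gene": df["Hugo_Symbol"],
                "mut_class": df["Variant_Classification"].map(MAF_CLASS_MAP),
                "position": pd.to_numeric(
                    df.get("Codon_Position", pd.Series(np.nan, index=df.index)),
                    errors="coerce",
                ),
            }
        )
    else:
        events = df[["patient", "gene", "mut_class"]].copy()
        events["position"] = pd.to_numeric(
            df.get("position", pd.Series(np.nan, index=df.index)), errors="coerce"
        )
    return MutationTable.from_events(events)


def read_expression(path) -> ExpressionMatrix:
    """Read a patients x genes TSV matrix (first column = patient id)."""
    df = _read_tsv(path)
    df = df.set_index(df.columns[0])
    df = df.apply(pd.to_numeric, errors="raise")
    return ExpressionMatrix(df)


def read_copy_number(path, calls_path=None) -> CopyNumberMatrix:
    """Read a log2-ratio matrix and, optionally, a discrete-call matrix."""
    frame = read_expression(path).frame
    calls = None
    if calls_path is not None:
        cdf = _read_tsv(calls_path)
        calls = cdf.set_index(cdf.columns[0])
    return CopyNumberMatrix(frame, calls)


def read_influence_graph(path) -> InfluenceGraph:
    """Read an edge-list TSV with columns gene_a, gene_b, weight."""
    df = _read_tsv(path)
    for col in ("gene_a", "gene_b", "weight"):
        if col not in df.columns:
            raise FormatError(f"missing required column {col!r} in {path}")
    weights = pd.to_numeric(df["weight"], errors="raise")
    return InfluenceGraph(zip(df["gene_a"], df["gene_b"], weights))


# ---------------------------------------------------------------------------
# derived encodings and alignment
# ---------------------------------------------------------------------------


def encode_cnv_events(cn: CopyNumberMatrix) -> MutationTable:
    """Encode focal homozygous deletions / high-level amplifications as events.

    Each non-neutral discrete call becomes one (patient, gene) record of
    class ``hdel`` or ``hlamp`` so copy-number catastrophes enter the model
    alongside point mutations.
    """
    if cn.calls is None:
        raise XshadowError("encode_cnv_events requires a discrete call matrix")
    calls = cn.calls
    rows = []
    for patient in calls.index:
        for gene in calls.columns:
            c = calls.at[patient, gene]
            if c in ("hdel", "hlamp"):
                rows.append((patient, gene, c, np.nan))
    if not rows:
        empty = pd.DataFrame(
            {
                "patient": pd.Series(dtype=str),
                "gene": pd.Series(dtype=str),
                "mut_class": pd.Series(dtype=str),
                "position": pd.Series(dtype=float),
            }
        )
        return MutationTable(empty)
    return MutationTable(pd.DataFrame(rows, columns=_MUT_COLUMNS))


def align_cohort(
    mut: MutationTable,
    expr: ExpressionMatrix,
    cn: Optional[CopyNumberMatrix] = None,
):
    """Restrict all inputs to patients present in every provided data type."""
    common = set(mut.patients) & set(expr.patients)
    if cn is not None:
        common &= set(cn.patients)
    if not common:
        raise CohortError("no patients shared by all input data types")
    logger.info("align_cohort: %d common patients", len(common))
    mut2 = mut.restrict_patients(common)
    expr2 = expr.restrict_patients(common)
    cn2 = cn.restrict_patients(common) if cn is not None else None
    return mut2, expr2, cn2


# ---------------------------------------------------------------------------
# posterior output
# ---------------------------------------------------------------------------

_G_STATES = ("down", "neutral", "up")
_FLOAT_FMT = "%.17g"


def write_posteriors(results: Mapping[str, "object"], outdir) -> dict[str, Path]:
    """Write gene-, mutation- and neighbour-level posterior TSVs.

    ``results`` maps gene id -> GeneResult (see :mod:`xshadow.model`).
    Three files are produced: ``genes.tsv`` (gene, p_d), ``mutations.tsv``
    (gene, patient, mut_class, p_f) and ``regulation.tsv``
    (gene, patient, neighbour, p_down, p_neutral, p_up).  Values round-trip
    through :func:`read_posteriors` to 1e-12.
    """
    if not results:
        raise EmptyTableError("no posterior results to write")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    gene_rows, mut_rows, reg_rows = [], [], []
    for gene in sorted(results):
        res = results[gene]
        post = res.posteriors
        gene_rows.append((gene, post.p_d))
        for i, patient in enumerate(res.patients):
            mut_rows.append((gene, patient, res.mut_classes[i], post.p_f[i]))
            for j, neigh in enumerate(res.neighbours):
                reg_rows.append((gene, patient, neigh, *post.p_g[i, j]))
    paths = {}
    frames = {
        "genes": pd.DataFrame(gene_rows, columns=["gene", "p_d"]),
        "mutations": pd.DataFrame(mut_rows, columns=["gene", "patient", "mut_class", "p_f"]),
        "regulation": pd.DataFrame(
            reg_rows, columns=["gene", "patient", "neighbour", "p_down", "p_neutral", "p_up"]
        ),
    }
    for name, frame in frames.items():
        p = outdir / f"{name}.tsv"
        frame.to_csv(p, sep="\t", index=False, float_format=_FLOAT_FMT)
        paths[name] = p
    return paths


def read_posteriors(outdir) -> dict[str, pd.DataFrame]:
    """Read back the three posterior TSVs written by :func:`write_posteriors`."""
    outdir = Path(outdir)
    out = {}
    for name in ("genes", "mutations", "regulation"):
        out[name] = pd.read_csv(outdir / f"{name}.tsv", sep="\t")
    return out
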