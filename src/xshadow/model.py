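"""Hierarchical model structure: latent variables D, F, G, H over observed Y.

For one mutated gene g with M mutated patients and N connected genes the
model factorises as

    P(D) * prod_m P(F_m | D) * prod_{m,n} P(G_{m,n} | F_m, H_n) * p(y_{m,n} | G_{m,n})

where D in {0,1} is the gene-level impact indicator, F_m in {0,1} the
per-mutation impact indicator, G_{m,n} in {down, neutral, up} the latent
regulation state of connected gene n in patient m, and H_n in {down, up}
the fixed direction in which gene n responds when the mutation is
functional.  Fixing H makes the graph a tree, which is what permits exact
sum-product inference (see :mod:`xshadow.inference`).

In cis mode a mutated gene is connected only to itself (N = 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .emission import TMixture, posterior_G
from .errors import XshadowError

#: index codes for the regulation states
DOWN, NEUTRAL, UP = 0, 1, 2
G_STATES = ("down", "neutral", "up")
#: index codes for directions H
H_DOWN, H_UP = 0, 1
H_STATES = ("down", "up")


def _check_simplex(v, name):
    v = np.asarray(v, dtype=float)
    if v.shape != (3,):
        raise ValueError(f"{name} must have 3 entries")
    if np.any(v <= 0) or np.any(v >= 1):
        raise ValueError(f"{name} entries must lie strictly in (0, 1)")
    if abs(v.sum() - 1.0) > 1e-9:
        raise ValueError(f"{name} must sum to 1")
    return v


@dataclass
class ModelParameters:
    """Conditional probability tables (the thetas) shared across genes.

    theta_d            prior P(D = 1)
    theta_f_d0/theta_f_d1   P(F = 1 | D = 0/1)
    theta_g_f0         P(G | F = 0), 3-simplex over (down, neutral, up)
    theta_g_f1_up/_down     P(G | F = 1, H = up/down)
    """

    theta_d: float = 0.5
    theta_f_d0: float = 0.1
    theta_f_d1: float = 0.8
    theta_g_f0: np.ndarray = field(default_factory=lambda: np.array([0.1, 0.8, 0.1]))
    theta_g_f1_up: np.ndarray = field(default_factory=lambda: np.array([0.05, 0.45, 0.5]))
    theta_g_f1_down: np.ndarray = field(default_factory=lambda: np.array([0.5, 0.45, 0.05]))

    def __post_init__(self):
        for name in ("theta_d", "theta_f_d0", "theta_f_d1"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name} must lie strictly in (0, 1)")
        self.theta_g_f0 = _check_simplex(self.theta_g_f0, "theta_g_f0")
        self.theta_g_f1_up = _check_simplex(self.theta_g_f1_up, "theta_g_f1_up")
        self.theta_g_f1_down = _check_simplex(self.theta_g_f1_down, "theta_g_f1_down")
        if self.theta_f_d1 < self.theta_f_d0:
            raise ValueError("identifiability requires theta_f_d1 >= theta_f_d0")

    def g_table(self, h: int) -> np.ndarray:
        """P(G | F = 1, H = h) for h in {H_DOWN, H_UP}."""
        return self.theta_g_f1_up if h == H_UP else self.theta_g_f1_down

    # -- serialisation ------------------------------------------------------

    def to_series(self) -> pd.Series:
        d = {
            "theta_d": self.theta_d,
            "theta_f_d0": self.theta_f_d0,
            "theta_f_d1": self.theta_f_d1,
        }
        for name, vec in (
            ("theta_g_f0", self.theta_g_f0),
            ("theta_g_f1_up", self.theta_g_f1_up),
            ("theta_g_f1_down", self.theta_g_f1_down),
        ):
            for k, state in enumerate(G_STATES):
                d[f"{name}.{state}"] = vec[k]
        return pd.Series(d)

    def write_tsv(self, path):
        self.to_series().rename_axis("parameter").rename("value").to_csv(
            path, sep="\t", float_format="%.17g"
        )

    @classmethod
    def from_series(cls, s: pd.Series) -> "ModelParameters":
        def vec(name):
            return np.array([s[f"{name}.{st}"] for st in G_STATES], dtype=float)

        return cls(
            theta_d=float(s["theta_d"]),
            theta_f_d0=float(s["theta_f_d0"]),
            theta_f_d1=float(s["theta_f_d1"]),
            theta_g_f0=vec("theta_g_f0"),
            theta_g_f1_up=vec("theta_g_f1_up"),
            theta_g_f1_down=vec("theta_g_f1_down"),
        )

    @classmethod
    def read_tsv(cls, path) -> "ModelParameters":
        s = pd.read_csv(path, sep="\t", index_col=0)["value"]
        return cls.from_series(s)


def effective_g_cpd(params: ModelParameters, w: float, h: int):
    """Leaf CPDs P(G | F = 0) and P(G | F = 1) for an edge of weight ``w``.

    The edge weight is the prior confidence that the interaction is real:
    the F = 1 table is the convex mixture w * P(G | F=1, H) +
    (1 - w) * P(G | F=0), so an uninformative edge (w = 0) reduces the
    neighbour to the null distribution and a certain edge (w = 1) applies
    the dysregulated table exactly.
    """
    if not (0.0 <= w <= 1.0):
        raise ValueError(f"edge weight {w} outside [0, 1]")
    f0 = params.theta_g_f0
    f1 = w * params.g_table(h) + (1.0 - w) * f0
    return f0, f1


@dataclass
class Posteriors:
    """Marginal posteriors for one gene submodel."""

    p_d: float
    p_f: np.ndarray  # (M,)
    p_g: np.ndarray  # (M, N, 3)
    log_marginal: float

    def __post_init__(self):
        self.p_f = np.asarray(self.p_f, dtype=float)
        self.p_g = np.asarray(self.p_g, dtype=float)


@dataclass
class GeneSubmodel:
    """One mutated gene's slice of the data.

    ``y`` is the (M patients x N neighbours) expression matrix restricted
    to the mutated patients (NaN = missing); ``log_emission`` holds the
    per-leaf component log densities log p(y | G = k), shape (M, N, 3);
    ``offline_posterior`` the mixture responsibilities P(G = k | y) used to
    estimate H.  In cis mode N = 1 and the single neighbour is the gene
    itself.
    """

    gene: str
    patients: list[str]
    neighbours: list[str]
    weights: np.ndarray  # (N,)
    y: np.ndarray  # (M, N)
    log_emission: np.ndarray  # (M, N, 3)
    offline_posterior: np.ndarray  # (M, N, 3)
    h: Optional[np.ndarray] = None  # (N,) int codes, fixed before inference
    mut_classes: list[str] = field(default_factory=list)
    #: component log densities of the cohort's NON-mutated patients over
    #: this gene's neighbour columns, flattened to (K, 3).  These patients
    #: are known F=0 observations of the null regulation distribution and
    #: anchor the theta_{G|F=0} update during EM.
    null_log_emission: Optional[np.ndarray] = None

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.M < 1 or self.N < 1:
            raise ValueError("a submodel needs at least one patient and one neighbour")
        if self.y.shape != (self.M, self.N):
            raise ValueError("y shape mismatch")
        if self.log_emission.shape != (self.M, self.N, 3):
            raise ValueError("log_emission shape mismatch")
        if np.any((self.weights < 0) | (self.weights > 1)):
            raise ValueError("weights must lie in [0, 1]")
        if not self.mut_classes:
            self.mut_classes = ["missense"] * self.M

    @property
    def M(self) -> int:
        return len(self.patients)

    @property
    def N(self) -> int:
        return len(self.neighbours)

    @property
    def observed(self) -> np.ndarray:
        """Boolean (M, N) mask of non-missing leaves."""
        return np.isfinite(self.y)

    @classmethod
    def build(
        cls,
        gene: str,
        patients: Sequence[str],
        neighbours: Sequence[str],
        weights: Sequence[float],
        y: np.ndarray,
        mixtures: Sequence[TMixture],
        mut_classes: Optional[Sequence[str]] = None,
    ) -> "GeneSubmodel":
        """Assemble a submodel from data and fitted per-neighbour mixtures."""
        y = np.asarray(y, dtype=float)
        M, N = y.shape
        log_em = np.zeros((M, N, 3))
        offline = np.zeros((M, N, 3))
        for n, mix in enumerate(mixtures):
            col = y[:, n]
            ok = np.isfinite(col)
            log_em[ok, n, :] = mix.component_log_density(col[ok])
            offline[ok, n, :] = posterior_G(mix, col[ok])
            offline[~ok, n, :] = np.nan
            log_em[~ok, n, :] = np.nan
        return cls(
            gene=gene,
            patients=list(patients),
            neighbours=list(neighbours),
            weights=np.asarray(weights, dtype=float),
            y=y,
            log_emission=log_em,
            offline_posterior=offline,
            mut_classes=list(mut_classes) if mut_classes is not None else [],
        )


@dataclass
class GeneResult:
    """Posteriors plus the identifiers needed to report them."""

    gene: str
    patients: list[str]
    mut_classes: list[str]
    neighbours: list[str]
    posteriors: Posteriors


def estimate_h(sub: GeneSubmodel) -> np.ndarray:
    """Estimate the response direction H_n of each connected gene.

    For neighbour n the up-score is the mean over mutated patients of the
    off-line posterior P(G = up | y_{m,n}); the down-score analogously.
    H_n = up iff up-score >= down-score (ties break to up).  Missing
    observations are skipped, reducing the average's denominator.
    """
    counts = sub.observed.sum(axis=0)  # observations per neighbour
    sums = np.where(sub.observed[:, :, None], sub.offline_posterior, 0.0).sum(axis=0)
    denom = np.maximum(counts, 1)[:, None]
    score = sums / denom  # (N, 3); all-missing neighbours score 0 -> tie -> up
    return np.where(score[:, UP] >= score[:, DOWN], H_UP, H_DOWN).astype(int)


def joint_log_prob(
    sub: GeneSubmodel,
    params: ModelParameters,
    d: int,
    f: Sequence[int],
    g_states: np.ndarray,
) -> float:
    """Log joint probability of one complete latent assignment and the data.

    ``g_states`` is an (M, N) integer matrix over {DOWN, NEUTRAL, UP};
    missing y leaves contribute nothing.  Requires ``sub.h`` fixed.
    """
    if sub.h is None:
        raise XshadowError("fix H on the submodel before evaluating the joint")
    f = np.asarray(f, dtype=int)
    g_states = np.asarray(g_states, dtype=int)
    if d not in (0, 1) or np.any((f != 0) & (f != 1)):
        raise ValueError("invalid D/F state codes")
    if np.any((g_states < 0) | (g_states > 2)):
        raise ValueError("invalid G state codes")
    if f.shape != (sub.M,) or g_states.shape != (sub.M, sub.N):
        raise ValueError("assignment shape mismatch")
    lp = np.log(params.theta_d if d == 1 else 1.0 - params.theta_d)
    pf1 = params.theta_f_d1 if d == 1 else params.theta_f_d0
    lp += float(np.sum(np.where(f == 1, np.log(pf1), np.log(1.0 - pf1))))
    # leaf CPDs per neighbour
    tables = np.empty((sub.N, 2, 3))
    for n in range(sub.N):
        f0, f1t = effective_g_cpd(params, sub.weights[n], int(sub.h[n]))
        tables[n, 0] = f0
        tables[n, 1] = f1t
    obs = sub.observed
    for m in range(sub.M):
        for n in range(sub.N):
            if not obs[m, n]:
                continue
            k = g_states[m, n]
            lp += np.log(tables[n, f[m], k]) + sub.log_emission[m, n, k]
    return float(lp)
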