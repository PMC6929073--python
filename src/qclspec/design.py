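"""Mixture-design generation for the multianalyte calibration samples.

The calibration set is a 25-run experimental design over four analytes
(glucose, albumin, urea, lactate) dissolved in buffer.  Concentrations are
mapped to *pseudo-components*: each analyte concentration is scaled by its
range so that the scaled values plus a closing diluent (water/buffer)
fraction live on the unit simplex.  A quadratic Scheffe model — the
canonical mixture polynomial with the q linear terms x_i and the
q(q-1)/2 cross terms x_i x_j, no intercept and no pure quadratics — is then
made A-optimal: the design X minimises trace((X^T X)^-1), the average
variance of the model coefficients.

Optimisation uses a simple Fedorov exchange over a simplex-lattice candidate
grid: starting from a random full-rank subset, single design points are
swapped against candidates whenever the swap lowers the A-criterion, so the
criterion descends monotonically; several random restarts guard against
local minima.  The optimiser is deterministic for a given seed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "AnalyteRange",
    "ConcentrationRanges",
    "SampleDesign",
    "scheffe_quadratic_terms",
    "scheffe_model_matrix",
    "simplex_lattice",
    "a_optimal_design",
    "linear_series",
    "TABLE_RANGES",
]


@dataclass(frozen=True)
class AnalyteRange:
    name: str
    min: float  # mg/dL
    max: float  # mg/dL

    def __post_init__(self) -> None:
        if self.min < 0:
            raise ValueError(f"{self.name}: min concentration must be >= 0")
        if not self.max > self.min:
            raise ValueError(f"{self.name}: max must exceed min (degenerate range)")


@dataclass(frozen=True)
class ConcentrationRanges:
    analytes: tuple[AnalyteRange, ...]

    def __post_init__(self) -> None:
        if len(self.analytes) < 1:
            raise ValueError("need at least one analyte")
        names = [a.name for a in self.analytes]
        if len(set(names)) != len(names):
            raise ValueError("analyte names must be unique")

    @property
    def names(self) -> list[str]:
        return [a.name for a in self.analytes]

    @classmethod
    def default(cls) -> "ConcentrationRanges":
        return TABLE_RANGES


#: Study concentration ranges (mg/dL) for the four analytes.
TABLE_RANGES = ConcentrationRanges(
    analytes=(
        AnalyteRange("glucose", 0.0, 800.0),
        AnalyteRange("albumin", 0.0, 6000.0),
        AnalyteRange("urea", 0.0, 200.0),
        AnalyteRange("lactate", 0.0, 90.0),
    )
)


def scheffe_quadratic_terms(n_components: int) -> list[tuple[int, ...]]:
    """Terms of the quadratic Scheffe mixture model for q components.

    Returns index tuples: ``(i,)`` for the q linear terms and ``(i, j)`` for
    the q(q-1)/2 cross terms.  No intercept, no pure quadratics: on the
    simplex those are confounded with the listed terms.
    """
    if n_components < 2:
        raise ValueError("a mixture model needs at least 2 components")
    terms: list[tuple[int, ...]] = [(i,) for i in range(n_components)]
    terms += list(itertools.combinations(range(n_components), 2))
    return terms


def scheffe_model_matrix(fractions: np.ndarray, terms: list[tuple[int, ...]]) -> np.ndarray:
    """Model matrix of the Scheffe terms evaluated at mixture fractions."""
    X = np.asarray(fractions, dtype=float)
    cols = []
    for t in terms:
        col = X[:, t[0]].copy()
        for i in t[1:]:
            col = col * X[:, i]
        cols.append(col)
    return np.column_stack(cols)


def simplex_lattice(n_components: int, degree: int) -> np.ndarray:
    """{q, m} simplex-lattice candidate points: fractions k/m summing to 1."""
    if n_components < 2 or degree < 1:
        raise ValueError("need n_components >= 2 and degree >= 1")
    pts = []
    for comp in itertools.combinations(range(degree + n_components - 1), n_components - 1):
        # stars-and-bars decomposition of `degree` into q non-negative parts
        prev = -1
        parts = []
        for c in comp:
            parts.append(c - prev - 1)
            prev = c
        parts.append(degree + n_components - 2 - prev)
        pts.append([p / degree for p in parts])
    return np.array(pts, dtype=float)


@dataclass
class SampleDesign:
    """Concentration design: N samples by q analytes, with optimality metadata."""

    concentrations: np.ndarray  # (n_samples, n_analytes) in mg/dL
    analyte_names: list[str]
    fractions: np.ndarray  # (n_samples, n_components) pseudo-component simplex points
    model_terms: list[tuple[int, ...]]
    a_criterion: float
    criterion_history: list[float] = field(default_factory=list)

    @property
    def n_samples(self) -> int:
        return self.concentrations.shape[0]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.concentrations, columns=self.analyte_names)
        df.insert(0, "sample_id", np.arange(self.n_samples))
        return df

    def sample_concentrations(self, i: int) -> dict[str, float]:
        return dict(zip(self.analyte_names, self.concentrations[i]))


def _a_criterion(M: np.ndarray) -> float:
    """trace((X'X)^-1), or +inf for a singular information matrix."""
    try:
        Minv = np.linalg.inv(M)
    except np.linalg.LinAlgError:
        return np.inf
    tr = float(np.trace(Minv))
    if not np.isfinite(tr) or tr <= 0:
        return np.inf
    return tr


def _random_full_rank_start(
    Xc: np.ndarray, n: int, rng: np.random.Generator, max_tries: int = 200
) -> np.ndarray | None:
    k = Xc.shape[1]
    for _ in range(max_tries):
        idx = rng.choice(Xc.shape[0], size=n, replace=False)
        if np.linalg.matrix_rank(Xc[idx]) == k:
            return idx
    return None


def a_optimal_design(
    ranges: ConcentrationRanges | None = None,
    n_samples: int = 25,
    candidate_grid_levels: int = 4,
    seed: int = 0,
    n_restarts: int = 10,
    include_diluent: bool = True,
) -> SampleDesign:
    """A-optimal Scheffe-quadratic mixture design over a simplex lattice.

    Each analyte is scaled by its concentration range to a pseudo-component;
    with ``include_diluent`` a closing water/buffer component brings the
    mixture onto the unit simplex.  ``candidate_grid_levels`` is the lattice
    degree m (fractions k/m).  Deterministic for a given seed.

    Raises a singular-design error when ``n_samples`` is below the number of
    Scheffe terms or no full-rank start can be found.
    """
    if ranges is None:
        ranges = ConcentrationRanges.default()
    q = len(ranges.analytes) + (1 if include_diluent else 0)
    terms = scheffe_quadratic_terms(q)
    if n_samples < len(terms):
        raise ValueError(
            f"n_samples={n_samples} is below the {len(terms)} Scheffe terms: "
            "the design is necessarily singular"
        )
    cand = simplex_lattice(q, candidate_grid_levels)
    # canonical candidate order so results do not depend on construction order
    cand = cand[np.lexsort(cand.T[::-1])]
    Xc = scheffe_model_matrix(cand, terms)

    rng = np.random.default_rng(seed)
    best_idx: np.ndarray | None = None
    best_crit = np.inf
    best_history: list[float] = []

    for _ in range(n_restarts):
        idx = _random_full_rank_start(Xc, n_samples, rng)
        if idx is None:
            continue
        idx = list(idx)
        M = Xc[idx].T @ Xc[idx]
        crit = _a_criterion(M)
        history = [crit]
        improved = True
        while improved and np.isfinite(crit):
            improved = False
            best_swap = None
            in_design = set(idx)
            for pos in range(n_samples):
                xi = Xc[idx[pos]]
                M_minus = M - np.outer(xi, xi)
                for j in range(Xc.shape[0]):
                    if j in in_design:
                        continue  # keep design rows unique
                    xj = Xc[j]
                    cnew = _a_criterion(M_minus + np.outer(xj, xj))
                    if cnew < crit - 1e-12:
                        if best_swap is None or cnew < best_swap[0]:
                            best_swap = (cnew, pos, j)
            if best_swap is not None:
                cnew, pos, j = best_swap
                xi = Xc[idx[pos]]
                M = M - np.outer(xi, xi) + np.outer(Xc[j], Xc[j])
                idx[pos] = j
                crit = cnew
                history.append(crit)
                improved = True
        if crit < best_crit:
            best_crit = crit
            best_idx = np.array(idx)
            best_history = history

    if best_idx is None or not np.isfinite(best_crit):
        raise np.linalg.LinAlgError(
            "Fedorov exchange could not reach a full-rank design within the restarts"
        )

    fractions = cand[best_idx]
    n_analytes = len(ranges.analytes)
    conc = np.empty((n_samples, n_analytes))
    for k, a in enumerate(ranges.analytes):
        conc[:, k] = a.min + fractions[:, k] * (a.max - a.min)
    return SampleDesign(
        concentrations=conc,
        analyte_names=ranges.names,
        fractions=fractions,
        model_terms=terms,
        a_criterion=best_crit,
        criterion_history=best_history,
    )


def linear_series(analyte: AnalyteRange, n_samples: int) -> SampleDesign:
    """Evenly spaced single-analyte series (e.g. glucose-in-water characterisation)."""
    if n_samples < 2:
        raise ValueError("need at least 2 samples")
    levels = np.linspace(analyte.min, analyte.max, n_samples)
    conc = levels[:, None]
    frac = (levels - analyte.min) / (analyte.max - analyte.min)
    return SampleDesign(
        concentrations=conc,
        analyte_names=[analyte.name],
        fractions=np.column_stack([frac, 1.0 - frac]),
        model_terms=[(0,), (1,)],
        a_criterion=float("nan"),
    )
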