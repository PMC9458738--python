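"""Selection procedures: direct selection, Smith-Hazel linear indices,
and a weight-free multiplicative index, plus truncation selection.

The Smith-Hazel aggregate uses the classical weights b = P^-1 G a, where
P and G are the phenotypic and genotypic covariance submatrices of the
index traits and a the vector of relative economic values (all 1 by
default).  A direct (single-trait) procedure is the degenerate case,
b = sigma2_g / sigma2_p, i.e. the trait's heritability as a fraction,
which leaves the family ranking identical to ranking on the trait mean.

The multiplicative index is an Elston-style weight-free score: each
trait is oriented so larger is better, shifted just below the candidate
minimum, and the per-trait deviations are multiplied.  It needs no
covariance estimates and is invariant (in ranking) to positive affine
rescaling of any trait.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._util import round_half_up
from .anova import ComponentSet
from .errors import IndexConstructionError, SchemaError, UndefinedStatisticError
from .traits import CANONICAL_TRAITS, TRAIT_DIRECTIONS, canonical_subset

__all__ = [
    "IndexDefinition", "IndexWeights", "SelectionOutcome",
    "standard_procedures", "load_procedures", "smith_hazel_weights",
    "index_scores", "multiplicative_scores", "truncate_select",
    "union_selected",
]

DIRECT = "direct"
SMITH_HAZEL = "smith_hazel"
MULTIPLICATIVE = "multiplicative"

#: Index traits of the "yield and its components" procedure.
YIELD_TRAITS = ("LY/P", "B/P", "BW", "S/B", "SI", "LP%", "LI")


@dataclass(frozen=True)
class IndexDefinition:
    """One selection procedure: a named trait subset with a kind."""

    name: str
    traits: tuple[str, ...]
    kind: str
    weights: Mapping[str, float] | None = None   # economic weights a

    def __post_init__(self) -> None:
        object.__setattr__(self, "traits", canonical_subset(self.traits))
        if not self.traits:
            raise SchemaError("index trait subset may not be empty")
        if self.kind == DIRECT and len(self.traits) != 1:
            raise SchemaError("a direct procedure selects exactly one trait")
        if self.kind not in (DIRECT, SMITH_HAZEL, MULTIPLICATIVE):
            raise SchemaError(f"unknown index kind {self.kind!r}")
        if self.weights is not None:
            extra = set(self.weights) - set(self.traits)
            if extra:
                raise SchemaError(f"weights given for non-index trait(s) {sorted(extra)}")

    def economic_vector(self) -> np.ndarray:
        w = self.weights or {}
        return np.array([float(w.get(t, 1.0)) for t in self.traits])


def standard_procedures(available: Sequence[str] = CANONICAL_TRAITS,
                        weights: Mapping[str, float] | None = None
                        ) -> list[IndexDefinition]:
    """The eight study procedures, restricted to procedures whose trait
    set is fully covered by *available*.

    Ped.1-3: direct selection for lint yield, lint percentage, lint
    index.  I.1: yield and its components.  I.2: boll weight, seeds per
    boll, seed index, fiber length, Pressley index.  I.3: lint
    percentage, lint index, fiber length, uniformity index.  I.4: all
    traits (Smith-Hazel).  I.5: all traits (multiplicative).
    """
    defs = [
        IndexDefinition("Ped.1", ("LY/P",), DIRECT),
        IndexDefinition("Ped.2", ("LP%",), DIRECT),
        IndexDefinition("Ped.3", ("LI",), DIRECT),
        IndexDefinition("I.1", YIELD_TRAITS, SMITH_HAZEL),
        IndexDefinition("I.2", ("BW", "S/B", "SI", "FL", "PI"), SMITH_HAZEL),
        IndexDefinition("I.3", ("LP%", "LI", "FL", "UI%"), SMITH_HAZEL),
        IndexDefinition("I.4", CANONICAL_TRAITS, SMITH_HAZEL),
        IndexDefinition("I.5", CANONICAL_TRAITS, MULTIPLICATIVE),
    ]
    avail = set(available)
    out = []
    for d in defs:
        if set(d.traits) <= avail:
            if weights:
                w = {t: weights[t] for t in d.traits if t in weights}
                d = IndexDefinition(d.name, d.traits, d.kind, w or None)
            out.append(d)
    return out


def load_procedures(path) -> list[IndexDefinition]:
    """Read custom procedure definitions from a YAML/JSON file.

    The file holds a list of mappings with keys ``name``, ``traits``,
    ``kind`` (direct | smith_hazel | multiplicative) and optional
    ``weights`` (trait -> economic weight).
    """
    import yaml
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, list):
        raise SchemaError("procedure file must hold a list of definitions")
    defs = []
    for entry in raw:
        unknown = set(entry) - {"name", "traits", "kind", "weights"}
        if unknown:
            raise SchemaError(f"unknown procedure key(s) {sorted(unknown)}")
        defs.append(IndexDefinition(
            name=str(entry["name"]), traits=tuple(entry["traits"]),
            kind=str(entry["kind"]), weights=entry.get("weights")))
    return defs


@dataclass
class IndexWeights:
    """Fitted coefficients of one linear procedure."""

    definition: IndexDefinition
    traits: tuple[str, ...]
    b: np.ndarray
    P_sub: np.ndarray
    G_sub: np.ndarray
    a: np.ndarray

    @property
    def sigma_index(self) -> float:
        """Phenotypic standard deviation of the index, sqrt(b' P b)."""
        return float(np.sqrt(max(self.b @ self.P_sub @ self.b, 0.0)))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"trait": self.traits, "b": self.b, "a": self.a,
                             "procedure": self.definition.name})


def smith_hazel_weights(components: ComponentSet,
                        definition: IndexDefinition,
                        max_condition: float = 1e12) -> IndexWeights:
    """Solve P_sub b = G_sub a over the procedure's trait subset."""
    if definition.kind not in (SMITH_HAZEL, DIRECT):
        raise IndexConstructionError(
            f"{definition.name}: weights are defined only for linear procedures")
    sub = components.submatrix(definition.traits)
    P, G = sub.P, sub.G
    cond = np.linalg.cond(P)
    if not np.isfinite(cond) or cond > max_condition:
        raise IndexConstructionError(
            f"phenotypic submatrix for traits {list(sub.traits)} is "
            f"ill-conditioned (cond={cond:.3g})")
    a = definition.economic_vector()
    # definition traits were canonicalized, so sub.traits == definition.traits
    b = np.linalg.solve(P, G @ a)
    return IndexWeights(definition=definition, traits=sub.traits,
                        b=b, P_sub=P, G_sub=G, a=a)


def index_scores(weights: IndexWeights,
                 family_means: pd.DataFrame) -> pd.Series:
    """Aggregate score I = sum_j b_j x_ij on raw trait units."""
    missing = [t for t in weights.traits if t not in family_means.columns]
    if missing:
        raise SchemaError(f"family means lack index trait(s) {missing}")
    x = family_means[list(weights.traits)].to_numpy(dtype=float)
    return pd.Series(x @ weights.b, index=family_means.index, name="score")


def multiplicative_scores(family_means: pd.DataFrame,
                          directions: Mapping[str, int] | None = None,
                          traits: Sequence[str] | None = None) -> pd.Series:
    """Weight-free multiplicative score over the candidate families.

    For each trait j, values are oriented (z = d_j * x), and a baseline
    k_j = min(z) - eps_j with eps_j = 0.01 * range(z) (one trait unit
    when the range is zero) keeps every factor strictly positive; the
    score is the product of (z - k_j).  Larger is better.
    """
    if len(family_means) < 2:
        raise UndefinedStatisticError(
            "multiplicative index needs at least two candidate families")
    directions = directions or TRAIT_DIRECTIONS
    if traits is None:
        traits = [c for c in family_means.columns if c in CANONICAL_TRAITS]
    z = family_means[list(traits)].to_numpy(dtype=float).copy()
    d = np.array([directions.get(t, 1) for t in traits], dtype=float)
    z *= d
    rng = z.max(axis=0) - z.min(axis=0)
    eps = np.where(rng > 0, 0.01 * rng, 1.0)
    k = z.min(axis=0) - eps
    return pd.Series((z - k).prod(axis=1), index=family_means.index,
                     name="score")


@dataclass
class SelectionOutcome:
    """Result of truncation selection on one procedure's scores."""

    procedure: str
    scores: pd.Series
    selected: tuple[str, ...]
    intensity: float | None

    @property
    def n_selected(self) -> int:
        return len(self.selected)

    @property
    def achieved_fraction(self) -> float:
        return self.n_selected / len(self.scores)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "procedure": self.procedure,
            "family": self.scores.index,
            "score": self.scores.to_numpy(),
            "selected": [f in set(self.selected) for f in self.scores.index],
        })


def truncate_select(scores: pd.Series, intensity: float | None = None,
                    n_selected: int | None = None,
                    procedure: str = "") -> SelectionOutcome:
    """Select the top families by score.

    Either a selected fraction (``n = max(1, round_half_up(intensity * f))``)
    or an explicit count.  Ties at the cut are broken by original listing
    order (stable, deterministic).
    """
    vals = scores.to_numpy(dtype=float)
    if not np.all(np.isfinite(vals)):
        raise UndefinedStatisticError("scores must be finite")
    f = len(scores)
    if n_selected is None:
        if intensity is None or not (0 < intensity <= 1):
            raise SchemaError("need an intensity in (0, 1] or an explicit count")
        n_selected = max(1, int(round_half_up(intensity * f, 0)))
    if not (1 <= n_selected <= f):
        raise SchemaError(f"cannot select {n_selected} of {f} families")
    order = np.argsort(-vals, kind="stable")
    selected = tuple(scores.index[order[:n_selected]])
    return SelectionOutcome(procedure=procedure, scores=scores,
                            selected=selected, intensity=intensity)


def union_selected(outcomes: Iterable[SelectionOutcome]) -> dict[str, tuple[str, ...]]:
    """Deduplicated union of selections across procedures.

    Returns family id -> tuple of procedure names that selected it, in
    first-selection order (the "Selected by" report column).
    """
    union: dict[str, list[str]] = {}
    for out in outcomes:
        for fam in out.selected:
            union.setdefault(fam, []).append(out.procedure)
    return {fam: tuple(procs) for fam, procs in union.items()}
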