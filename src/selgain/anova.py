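"""Balanced RCBD analysis of variance/covariance and component extraction.

For a balanced randomized complete block trial with f families and r
replicates the plot model is ``y_ij = mu + g_i + rho_j + e_ij``.  The
family mean square (cross-product) has expectation ``sigma_e + r *
sigma_g``, the error mean square expectation ``sigma_e``, so

    sigma_g = (MF - ME) / r,    sigma_e = ME,    sigma_p = sigma_g + sigma_e

with the phenotypic (co)variance defined on the plot-mean expectation
scale (not divided by r).  This is the convention under which broad-sense
heritability equals (GCV/PCV)^2.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (ComponentError, DegreesOfFreedomError, DesignError,
                     UndefinedStatisticError)
from .io_model import RCBD, UNREPLICATED, ParentTable, TrialTable
from .traits import canonical_subset

__all__ = [
    "AnovaResult", "ComponentSet", "rcbd_anova", "anova_matrices",
    "components_from_anova", "estimate_components", "f2_components",
    "F2Variances",
]


@dataclass(frozen=True)
class AnovaResult:
    """Mean squares (i = j) or mean cross-products (i != j) of one trait pair."""

    trait_i: str
    trait_j: str
    MF: float          # family mean square / cross-product
    ME: float          # error mean square / cross-product
    M_rep: float       # replicate mean square (reported, unused downstream)
    f: int
    r: int

    @property
    def df_family(self) -> int:
        return self.f - 1

    @property
    def df_error(self) -> int:
        return (self.r - 1) * (self.f - 1)

    @property
    def is_variance(self) -> bool:
        return self.trait_i == self.trait_j


def _check_rcbd(table: TrialTable) -> None:
    if table.design != RCBD:
        raise DesignError(
            "analysis of variance requires a replicated (rcbd) table")
    if table.n_families < 2 or table.n_replicates < 2:
        raise DegreesOfFreedomError(
            f"need >=2 families and >=2 replicates, got "
            f"f={table.n_families}, r={table.n_replicates}")


def rcbd_anova(table: TrialTable, trait_i: str,
               trait_j: str | None = None) -> AnovaResult:
    """Two-way balanced decomposition for one trait pair.

    The covariance (cross-product) formula is the single code path; the
    variance case is simply ``trait_j == trait_i``.
    """
    _check_rcbd(table)
    if trait_j is None:
        trait_j = trait_i
    for t in (trait_i, trait_j):
        if t not in table.traits:
            raise KeyError(f"trait {t!r} not present in table")
    ya = table.pivot(trait_i)   # (f, r)
    yb = table.pivot(trait_j)
    f, r = ya.shape
    da = ya - ya.mean()
    db = yb - yb.mean()
    sp_total = float((da * db).sum())
    sp_fam = float(r * (da.mean(axis=1) * db.mean(axis=1)).sum())
    sp_rep = float(f * (da.mean(axis=0) * db.mean(axis=0)).sum())
    sp_err = sp_total - sp_fam - sp_rep
    return AnovaResult(trait_i=trait_i, trait_j=trait_j,
                       MF=sp_fam / (f - 1),
                       ME=sp_err / ((f - 1) * (r - 1)),
                       M_rep=sp_rep / (r - 1),
                       f=f, r=r)


def anova_matrices(table: TrialTable):
    """All-pairs mean square/cross-product matrices in one pass.

    Returns ``(MF, ME, M_rep, f, r)`` with k x k arrays in the table's
    trait order.  Equivalent to calling :func:`rcbd_anova` for every
    pair, but vectorized for simulation studies.
    """
    _check_rcbd(table)
    traits = list(table.traits)
    f, r = table.n_families, table.n_replicates
    # (f, r, k) value cube, families/replicates in first-appearance order
    df = table.data
    fam_codes = pd.Categorical(df["family"],
                               categories=table.family_ids).codes
    rep_order = tuple(dict.fromkeys(df["replicate"]))
    rep_codes = pd.Categorical(df["replicate"], categories=rep_order).codes
    cube = np.empty((f, r, len(traits)))
    cube[fam_codes, rep_codes, :] = df[traits].to_numpy()
    gm = cube.mean(axis=(0, 1))
    centered = cube - gm
    flat = centered.reshape(f * r, -1)
    c_total = flat.T @ flat
    fm = centered.mean(axis=1)     # (f, k)
    rm = centered.mean(axis=0)     # (r, k)
    c_fam = r * fm.T @ fm
    c_rep = f * rm.T @ rm
    c_err = c_total - c_fam - c_rep
    MF = c_fam / (f - 1)
    ME = c_err / ((f - 1) * (r - 1))
    MREP = c_rep / (r - 1)
    return MF, ME, MREP, f, r


@dataclass
class ComponentSet:
    """Genotypic (G), error (E) and phenotypic (P = G + E) covariance
    matrices for one generation, with trial dimensions.

    ``G_raw`` keeps the untruncated genotypic matrix for audit when the
    negative-diagonal truncation rule fired.
    """

    generation: str
    traits: tuple[str, ...]
    G: np.ndarray
    E: np.ndarray
    P: np.ndarray
    f: int
    r: int
    G_raw: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.traits = tuple(self.traits)
        k = len(self.traits)
        for name in ("G", "E", "P"):
            m = np.asarray(getattr(self, name), dtype=float)
            if m.shape != (k, k):
                raise ComponentError(f"{name} must be {k}x{k}")
            scale = max(1.0, float(np.abs(m).max()))
            if np.abs(m - m.T).max() > 1e-9 * scale:
                raise ComponentError(f"{name} is not symmetric")
            setattr(self, name, (m + m.T) / 2)
        if np.abs(self.P - (self.G + self.E)).max() > 1e-9 * max(
                1.0, float(np.abs(self.P).max())):
            raise ComponentError("P != G + E")
        if (np.diag(self.G) < 0).any() or (np.diag(self.P) < 0).any():
            raise ComponentError("negative diagonal in G or P")

    # -- element access -----------------------------------------------------
    def _idx(self, trait: str) -> int:
        try:
            return self.traits.index(trait)
        except ValueError:
            raise KeyError(f"trait {trait!r} not in component set")

    def var_g(self, trait: str) -> float:
        return float(self.G[self._idx(trait), self._idx(trait)])

    def var_e(self, trait: str) -> float:
        return float(self.E[self._idx(trait), self._idx(trait)])

    def var_p(self, trait: str) -> float:
        return float(self.P[self._idx(trait), self._idx(trait)])

    def cov_g(self, trait_i: str, trait_j: str) -> float:
        return float(self.G[self._idx(trait_i), self._idx(trait_j)])

    def cov_p(self, trait_i: str, trait_j: str) -> float:
        return float(self.P[self._idx(trait_i), self._idx(trait_j)])

    def submatrix(self, traits) -> "ComponentSet":
        """Component set restricted to *traits* (canonical order)."""
        sub = canonical_subset(traits)
        ix = [self._idx(t) for t in sub]
        sel = np.ix_(ix, ix)
        return ComponentSet(generation=self.generation, traits=sub,
                            G=self.G[sel], E=self.E[sel], P=self.P[sel],
                            f=self.f, r=self.r,
                            G_raw=None if self.G_raw is None
                            else self.G_raw[sel])

    # -- serialization ------------------------------------------------------
    def to_json(self, path=None) -> str:
        payload = {
            "generation": self.generation, "traits": list(self.traits),
            "G": self.G.tolist(), "E": self.E.tolist(), "P": self.P.tolist(),
            "f": self.f, "r": self.r,
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "ComponentSet":
        if isinstance(source, (str, bytes)) and str(source).lstrip().startswith("{"):
            payload = json.loads(source)
        else:
            with open(source, "r", encoding="utf-8") as fh:
                payload = json.load(fh)
        return cls(generation=payload["generation"],
                   traits=tuple(payload["traits"]),
                   G=np.asarray(payload["G"]), E=np.asarray(payload["E"]),
                   P=np.asarray(payload["P"]),
                   f=int(payload["f"]), r=int(payload["r"]))


def _components(MF: np.ndarray, ME: np.ndarray, f: int, r: int,
                traits, generation: str) -> ComponentSet:
    G_raw = (MF - ME) / r
    E = ME.copy()
    G = G_raw.copy()
    neg = np.diag(G) < 0
    if neg.any():
        bad = [t for t, flag in zip(traits, neg) if flag]
        warnings.warn(
            f"negative genotypic variance truncated to 0 for trait(s) {bad}",
            stacklevel=3)
        d = np.diag(G).copy()
        d[neg] = 0.0
        G[np.diag_indices_from(G)] = d
    return ComponentSet(generation=generation, traits=tuple(traits),
                        G=G, E=E, P=G + E, f=f, r=r, G_raw=G_raw)


def components_from_anova(results, generation: str = "") -> ComponentSet:
    """Assemble a ComponentSet from per-pair :class:`AnovaResult` objects.

    One result per unordered trait pair (diagonal included) is required;
    all results must come from the same trial (equal f and r).
    """
    results = list(results)
    if not results:
        raise ComponentError("no anova results supplied")
    f, r = results[0].f, results[0].r
    if any(res.f != f or res.r != r for res in results):
        raise ComponentError("anova results disagree on f or r")
    traits = canonical_subset(
        {res.trait_i for res in results} | {res.trait_j for res in results})
    k = len(traits)
    pos = {t: i for i, t in enumerate(traits)}
    MF = np.full((k, k), np.nan)
    ME = np.full((k, k), np.nan)
    for res in results:
        i, j = pos[res.trait_i], pos[res.trait_j]
        MF[i, j] = MF[j, i] = res.MF
        ME[i, j] = ME[j, i] = res.ME
    if np.isnan(MF).any():
        missing = [(traits[i], traits[j])
                   for i, j in zip(*np.where(np.isnan(MF))) if i <= j]
        raise ComponentError(f"missing anova results for pair(s) {missing}")
    return _components(MF, ME, f, r, traits, generation)


def estimate_components(table: TrialTable) -> ComponentSet:
    """RCBD analysis of a full table: all-pairs ANOVA plus extraction."""
    MF, ME, _, f, r = anova_matrices(table)
    return _components(MF, ME, f, r, table.traits, table.generation)


@dataclass(frozen=True)
class F2Variances:
    """Per-trait phenotypic variances for the F2 heritability formula."""

    vf2: pd.Series
    vp1: pd.Series
    vp2: pd.Series
    parents: tuple[str, str]


def f2_components(f2_plants: TrialTable, parents: ParentTable) -> F2Variances:
    """Individual-plant F2 variance plus parent phenotypic variances.

    VF2 is the sample variance (denominator n-1) of F2 plants per trait;
    VP1/VP2 come from the parent table (given directly, or computed
    identically from parent plant rows).
    """
    if f2_plants.design != UNREPLICATED:
        raise DesignError("F2 variance expects an unreplicated plant table")
    if len(f2_plants.data) < 2:
        raise UndefinedStatisticError("need at least 2 plants for a variance")
    traits = list(f2_plants.traits)
    vf2 = f2_plants.data[traits].var(ddof=1)
    if parents.variances is None:
        raise ComponentError(
            "parent table provides no variances (supply plant rows or var: columns)")
    if len(parents.parents) != 2:
        raise ComponentError("exactly two parents expected")
    p1, p2 = parents.parents
    common = [t for t in traits if t in parents.variances.columns]
    return F2Variances(vf2=vf2[common],
                       vp1=parents.variances.loc[p1, common],
                       vp2=parents.variances.loc[p2, common],
                       parents=(p1, p2))
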