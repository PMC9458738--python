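"""Seeded generator of parents, F2 plants, and F3/F4 RCBD trials.

The generative model is the one the estimation machinery assumes: plot
values ``y_ij = mu + g_i + rho_j + e_ij`` with family effects g drawn
from a multivariate normal with genotypic covariance G_true, plot errors
from E_true, and optional scalar block effects.  A response-to-selection
mechanism (``advance_generation``) transmits a selected family's
genotypic deviation to its offspring family, so predicted and realized
gains can be compared against the breeder's equation on fully known
truth.

The default scenario is calibrated to the reported Giza 86 x Menoufi F3
trial: per-trait genotypic/phenotypic standard deviations are
back-solved from the reported means, GCV and PCV (sigma_g = GCV *
mean/100, sigma_p = PCV * mean/100, sigma_e^2 = sigma_p^2 - sigma_g^2),
off-diagonals follow the reported F3 genotypic/phenotypic correlations,
and the assembled matrices are projected to the nearest positive
semi-definite matrix (the reported genotypic correlations, one of which
exceeds |1| in F4, cannot form a valid covariance matrix verbatim).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import calibration
from .errors import ComponentError, SchemaError
from .io_model import RCBD, UNREPLICATED, ParentTable, TrialTable
from .traits import CANONICAL_TRAITS, COUNT_TRAITS, F2_TRAITS, PERCENT_TRAITS

__all__ = ["Scenario", "default_scenario", "nearest_psd", "simulate_rcbd",
           "simulate_f2", "advance_generation"]


def nearest_psd(M: np.ndarray, tol: float = 0.0) -> np.ndarray:
    """Project a symmetric matrix onto the PSD cone (eigenvalue clipping)."""
    M = (np.asarray(M, float) + np.asarray(M, float).T) / 2
    w, V = np.linalg.eigh(M)
    w = np.clip(w, tol, None)
    out = V @ np.diag(w) @ V.T
    return (out + out.T) / 2


@dataclass
class Scenario:
    """Study conditions for the generator.

    mu maps generation label -> per-trait means (F2 carries the seven
    yield traits only, as in the source trials).  G/E are 11x11
    genotypic and plot-error covariance matrices over the canonical
    trait order.  ``transmission`` is the fraction of a selected
    family's genotypic deviation passed to its offspring family mean
    (1.0 = fully heritable family effects); the remainder appears as
    segregation noise with covariance (1 - transmission^2) * G.
    """

    traits: tuple[str, ...]
    mu: dict[str, pd.Series]
    G: np.ndarray
    E: np.ndarray
    f: int = 76
    r: int = 3
    n_f2: int = 439
    transmission: float = 1.0
    rep_var: float = 0.0
    n_parent_plants: int = 30
    parent_means: pd.DataFrame = field(default_factory=calibration.parent_means)
    seed: int = 0

    def __post_init__(self) -> None:
        self.traits = tuple(self.traits)
        k = len(self.traits)
        self.G = np.asarray(self.G, float)
        self.E = np.asarray(self.E, float)
        for name, m in (("G", self.G), ("E", self.E)):
            if m.shape != (k, k):
                raise ComponentError(f"{name} must be {k}x{k}")
            if np.abs(m - m.T).max() > 1e-9 * max(1.0, np.abs(m).max()):
                raise ComponentError(f"{name} must be symmetric")
            if np.linalg.eigvalsh(m).min() < -1e-8 * max(1.0, np.abs(m).max()):
                raise ComponentError(f"{name} is not positive semi-definite")
        if self.f < 2 or self.r < 2:
            raise SchemaError("need f >= 2 families and r >= 2 replicates")
        if not (0.0 <= self.transmission <= 1.0):
            raise SchemaError("transmission must lie in [0, 1]")
        self.mu = {g: pd.Series(m, dtype=float).rename(None)
                   for g, m in self.mu.items()}
        for s in self.mu.values():
            s.name = None
            s.index.name = None

    # -- helpers ------------------------------------------------------------
    def _index(self, traits) -> np.ndarray:
        pos = {t: i for i, t in enumerate(self.traits)}
        return np.array([pos[t] for t in traits])

    def sub_G(self, traits) -> np.ndarray:
        ix = self._index(traits)
        return self.G[np.ix_(ix, ix)]

    def sub_E(self, traits) -> np.ndarray:
        ix = self._index(traits)
        return self.E[np.ix_(ix, ix)]

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["traits"] = list(self.traits)
        d["mu"] = {g: {t: float(v) for t, v in m.items()}
                   for g, m in self.mu.items()}
        d["G"] = self.G.tolist()
        d["E"] = self.E.tolist()
        d["parent_means"] = {p: {t: float(v) for t, v in row.items()}
                             for p, row in self.parent_means.iterrows()}
        return d

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_dict(cls, d: dict) -> "Scenario":
        d = dict(d)
        d["mu"] = {g: pd.Series(m) for g, m in d["mu"].items()}
        d["G"] = np.asarray(d["G"])
        d["E"] = np.asarray(d["E"])
        d["parent_means"] = pd.DataFrame.from_dict(d["parent_means"],
                                                   orient="index")
        d["traits"] = tuple(d["traits"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "Scenario":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))


def default_scenario(f: int = 76, r: int = 3, n_f2: int = 439,
                     transmission: float = 1.0, seed: int = 0) -> Scenario:
    """Scenario calibrated to the reported F3 trial of Giza 86 x Menoufi."""
    s3 = calibration.generation_summary("F3")
    sigma_g = (s3["gcv"] * s3["mean"] / 100.0).to_numpy()
    sigma_p = (s3["pcv"] * s3["mean"] / 100.0).to_numpy()
    Rg = calibration.f3_genotypic_correlations().to_numpy()
    Rp = calibration.f3_phenotypic_correlations().to_numpy()
    G = nearest_psd(np.outer(sigma_g, sigma_g) * Rg)
    P = np.outer(sigma_p, sigma_p) * Rp
    E = nearest_psd(P - G)
    mu = {
        "F2": calibration.generation_summary("F2")["mean"],
        "F3": s3["mean"],
        "F4": calibration.generation_summary("F4")["mean"],
    }
    return Scenario(traits=CANONICAL_TRAITS, mu=mu, G=G, E=E, f=f, r=r,
                    n_f2=n_f2, transmission=transmission, seed=seed)


# ---------------------------------------------------------------------------
# sampling machinery
# ---------------------------------------------------------------------------

def _mvn_factor(cov: np.ndarray) -> np.ndarray:
    """Square root of a PSD covariance via symmetric eigendecomposition."""
    w, V = np.linalg.eigh((cov + cov.T) / 2)
    return V * np.sqrt(np.clip(w, 0.0, None))


def _draw(rng: np.random.Generator, n: int, cov: np.ndarray) -> np.ndarray:
    A = _mvn_factor(cov)
    return rng.standard_normal((n, cov.shape[0])) @ A.T


def _clip_bounds(values: np.ndarray, traits) -> np.ndarray:
    """Keep Gaussian draws inside trait domains (counts >= 0, percentages
    in (0, 100)).  At the calibrated parameters this touches well under
    0.1% of draws; the moment distortion is negligible."""
    values = values.copy()
    for j, t in enumerate(traits):
        if t in COUNT_TRAITS:
            values[:, j] = np.clip(values[:, j], 0.0, None)
        elif t in PERCENT_TRAITS:
            values[:, j] = np.clip(values[:, j], 1e-6, 100.0 - 1e-6)
    return values


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)


def _family_ids(generation: str, n: int) -> list[str]:
    return [f"{generation}-{i + 1:03d}" for i in range(n)]


def _build_rcbd(mu: pd.Series, g: np.ndarray, scenario: Scenario,
                generation: str, families: list[str],
                rng: np.random.Generator) -> TrialTable:
    traits = list(mu.index)
    f, r = len(families), scenario.r
    errors = _draw(rng, f * r, scenario.sub_E(traits)).reshape(f, r, -1)
    rho = (rng.standard_normal((1, r, 1)) * np.sqrt(scenario.rep_var)
           if scenario.rep_var > 0 else 0.0)
    y = mu.to_numpy()[None, None, :] + g[:, None, :] + rho + errors
    flat = _clip_bounds(y.reshape(f * r, -1), traits)
    df = pd.DataFrame(flat, columns=traits)
    df.insert(0, "replicate", np.tile([f"R{j + 1}" for j in range(r)], f))
    df.insert(0, "family", np.repeat(families, r))
    return TrialTable(generation=generation, design=RCBD, data=df,
                      traits=tuple(traits))


def simulate_rcbd(scenario: Scenario, generation: str = "F3",
                  seed=None) -> tuple[TrialTable, pd.DataFrame]:
    """Replicated trial of f fresh families; returns (table, latent truth).

    The truth frame holds each family's genotypic effect vector, for
    parameter-recovery and response tests.
    """
    rng = _rng(scenario.seed if seed is None else seed)
    mu = scenario.mu[generation]
    traits = list(mu.index)
    g = _draw(rng, scenario.f, scenario.sub_G(traits))
    families = _family_ids(generation, scenario.f)
    table = _build_rcbd(mu, g, scenario, generation, families, rng)
    truth = pd.DataFrame(g, index=families, columns=traits)
    return table, truth


def simulate_f2(scenario: Scenario, seed=None
                ) -> tuple[TrialTable, ParentTable]:
    """Unreplicated F2 plants plus parent plants grown alongside.

    Each F2 plant is mu_F2 + g + e with g ~ MVN(0, G) and e ~ MVN(0, E)
    over the seven yield traits recorded in F2.  Parents are genetically
    uniform (g = 0), so their plant-to-plant spread is purely the error
    covariance; the returned ParentTable carries plant rows, means and
    variances.
    """
    rng = _rng(scenario.seed if seed is None else seed)
    mu = scenario.mu["F2"]
    traits = list(mu.index)
    cov_g = scenario.sub_G(traits)
    cov_e = scenario.sub_E(traits)
    y = mu.to_numpy() + _draw(rng, scenario.n_f2, cov_g) \
        + _draw(rng, scenario.n_f2, cov_e)
    y = _clip_bounds(y, traits)
    df = pd.DataFrame(y, columns=traits)
    df.insert(0, "replicate", "R1")
    df.insert(0, "family", [f"F2-{i + 1:03d}" for i in range(scenario.n_f2)])
    f2 = TrialTable(generation="F2", design=UNREPLICATED, data=df,
                    traits=tuple(traits))

    ptraits = [t for t in scenario.parent_means.columns
               if t in scenario.traits]
    rows = []
    for parent, means in scenario.parent_means.iterrows():
        e = _draw(rng, scenario.n_parent_plants, scenario.sub_E(ptraits))
        vals = _clip_bounds(means[ptraits].to_numpy() + e, ptraits)
        block = pd.DataFrame(vals, columns=ptraits)
        block.insert(0, "parent", parent)
        rows.append(block)
    parents = ParentTable.from_plants(pd.concat(rows, ignore_index=True))
    return f2, parents


def advance_generation(scenario: Scenario, selected, true_effects: pd.DataFrame,
                       generation: str = "F4",
                       seed=None) -> tuple[TrialTable, pd.DataFrame]:
    """Offspring trial of the selected families.

    Each selected family founds one offspring family whose genotypic
    effect is ``transmission * g_parent`` plus segregation noise with
    covariance ``(1 - transmission^2) * G``; offspring keep their
    parent's family id so realized gains can be matched by id.  The new
    trial is generated around the next generation's mean vector.
    """
    selected = list(selected)
    if not selected:
        raise SchemaError("cannot advance an empty selection")
    missing = [s for s in selected if s not in true_effects.index]
    if missing:
        raise SchemaError(f"no recorded effects for selected families {missing}")
    rng = _rng(scenario.seed if seed is None else seed)
    mu = scenario.mu[generation]
    traits = list(mu.index)
    t = scenario.transmission
    g_par = true_effects.loc[selected, traits].to_numpy()
    seg = _draw(rng, len(selected), (1.0 - t ** 2) * scenario.sub_G(traits))
    g_off = t * g_par + seg
    table = _build_rcbd(mu, g_off, scenario, generation, selected, rng)
    truth = pd.DataFrame(g_off, index=selected, columns=traits)
    return table, truth
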