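"""Genetic parameters per generation.

Broad-sense heritability via two estimators (the F2 parent-variance form
and the F3/F4 component-ratio form), phenotypic/genotypic coefficients of
variation, generation means with standard errors, and phenotypic/genotypic
correlation matrices with significance flags.

On the plot-mean component scale used throughout this package the
component-ratio heritability obeys the identity

    h2_b = 100 * (GCV / PCV)**2

exactly, which is the internal-consistency check applied to replicated
generations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._util import round_half_up
from .anova import ComponentSet, F2Variances
from .errors import UndefinedStatisticError
from .io_model import TrialTable

__all__ = [
    "heritability_f2", "heritability_plot", "cv_coefficients",
    "correlations", "generation_summary", "f2_summary",
    "GeneticSummary", "CorrelationMatrix",
]


def heritability_f2(vf2: float, vp1: float, vp2: float,
                    env: str = "sum") -> float:
    """Broad-sense heritability (%) of an F2 from parent variances.

    The environmental variance is taken as VP1 + VP2 (``env='sum'``, the
    convention of the source trial reports) or as the parent average
    (``env='mean'``).  Estimates falling outside [0, 100] are clamped
    with a warning.
    """
    if vf2 <= 0:
        raise UndefinedStatisticError("VF2 must be positive")
    ve = vp1 + vp2 if env == "sum" else (vp1 + vp2) / 2.0
    h2 = 100.0 * (vf2 - ve) / vf2
    if h2 < 0 or h2 > 100:
        warnings.warn(f"F2 heritability {h2:.2f}% clamped to [0, 100]",
                      stacklevel=2)
        h2 = min(max(h2, 0.0), 100.0)
    return h2


def heritability_plot(var_g: float, var_p: float) -> float:
    """Broad-sense heritability (%) as 100 * sigma2_g / sigma2_p."""
    if var_p <= 0:
        raise UndefinedStatisticError("phenotypic variance must be positive")
    if var_g < 0:
        raise UndefinedStatisticError("genotypic variance must be >= 0")
    return 100.0 * var_g / var_p


def cv_coefficients(var_p: float, var_g: float, mean: float) -> tuple[float, float]:
    """(PCV %, GCV %): component standard deviations relative to the mean."""
    if mean <= 0:
        raise UndefinedStatisticError("trait mean must be positive for CVs")
    if var_p < 0 or var_g < 0:
        raise UndefinedStatisticError("variances must be non-negative")
    return (100.0 * np.sqrt(var_p) / mean, 100.0 * np.sqrt(var_g) / mean)


# ---------------------------------------------------------------------------
# correlations
# ---------------------------------------------------------------------------

@dataclass
class CorrelationMatrix:
    """Phenotypic and genotypic correlations with significance flags.

    ``r_p``/``r_g`` are symmetric DataFrames (diagonal 1); undefined
    pairs (zero variance) are NaN.  ``stars_*`` hold '' / '*' / '**' for
    two-sided significance at 0.05 / 0.01.  Genotypic correlations may
    exceed |1| and are never clamped; such pairs are flagged '**'.
    """

    generation: str
    r_p: pd.DataFrame
    r_g: pd.DataFrame
    stars_p: pd.DataFrame
    stars_g: pd.DataFrame
    n: int

    def to_report(self, decimals: int = 3) -> pd.DataFrame:
        """Long-format table: one row per unordered trait pair."""
        rows = []
        traits = list(self.r_p.index)
        for i, ti in enumerate(traits):
            for tj in traits[i + 1:]:
                rows.append({
                    "generation": self.generation,
                    "trait_i": ti, "trait_j": tj,
                    "r_p": round_half_up(self.r_p.loc[ti, tj], decimals),
                    "sig_p": self.stars_p.loc[ti, tj],
                    "r_g": round_half_up(self.r_g.loc[ti, tj], decimals),
                    "sig_g": self.stars_g.loc[ti, tj],
                    "n": self.n,
                })
        return pd.DataFrame(rows)


def _corr_from_cov(M: np.ndarray) -> np.ndarray:
    d = np.sqrt(np.diag(M).clip(min=0))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = M / np.outer(d, d)
    r[(np.outer(d, d) == 0)] = np.nan
    np.fill_diagonal(r, 1.0)
    return r


def _stars(r: np.ndarray, n: int) -> np.ndarray:
    """Two-sided t test, t = r * sqrt((n-2)/(1-r^2)), n-2 df."""
    out = np.full(r.shape, "", dtype=object)
    df = n - 2
    for i in range(r.shape[0]):
        for j in range(r.shape[1]):
            if i == j or not np.isfinite(r[i, j]):
                continue
            rij = r[i, j]
            if abs(rij) >= 1:        # t undefined; beyond any critical value
                out[i, j] = "**"
                continue
            t = abs(rij) * np.sqrt(df / (1 - rij ** 2))
            p = 2 * stats.t.sf(t, df)
            out[i, j] = "**" if p < 0.01 else "*" if p < 0.05 else ""
    return out


def correlations(components: ComponentSet, n: int | None = None) -> CorrelationMatrix:
    """Phenotypic/genotypic correlation matrices from a component set.

    *n* is the sample size for the significance test (defaults to the
    family count of the trial the components came from).
    """
    if len(components.traits) < 2:
        raise UndefinedStatisticError("need at least 2 traits")
    if n is None:
        n = components.f
    if n < 3:
        raise UndefinedStatisticError("need n >= 3 for a significance test")
    traits = list(components.traits)
    rp = _corr_from_cov(components.P)
    rg = _corr_from_cov(components.G)
    return CorrelationMatrix(
        generation=components.generation,
        r_p=pd.DataFrame(rp, index=traits, columns=traits),
        r_g=pd.DataFrame(rg, index=traits, columns=traits),
        stars_p=pd.DataFrame(_stars(rp, n), index=traits, columns=traits),
        stars_g=pd.DataFrame(_stars(rg, n), index=traits, columns=traits),
        n=n)


# ---------------------------------------------------------------------------
# per-generation summaries
# ---------------------------------------------------------------------------

@dataclass
class GeneticSummary:
    """Per-trait mean, SE, PCV, GCV and h2_b for one generation."""

    generation: str
    table: pd.DataFrame   # index: trait; columns: mean, se, pcv, gcv, h2b

    def to_report(self, decimals: int = 2) -> pd.DataFrame:
        df = self.table.copy()
        out = pd.DataFrame({
            "generation": self.generation,
            "trait": df.index,
            "mean_se": [
                f"{round_half_up(m, decimals)} ± {round_half_up(s, decimals)}"
                for m, s in zip(df["mean"], df["se"])],
            "PCV%": [round_half_up(v, decimals) for v in df["pcv"]],
            "GCV%": [round_half_up(v, decimals) for v in df["gcv"]],
            "h2b%": [round_half_up(v, decimals) for v in df["h2b"]],
        })
        return out.reset_index(drop=True)


def generation_summary(components: ComponentSet, table: TrialTable,
                       se_method: str = "family") -> GeneticSummary:
    """Table-1-style summary for a replicated generation.

    Mean = grand mean of plots.  SE = sd of family means / sqrt(f)
    (``se_method='family'``, reflecting between-family dispersion) or
    sqrt(ME / (r f)) (``se_method='anova'``).
    """
    if tuple(table.traits) != tuple(components.traits):
        raise UndefinedStatisticError(
            "components and table disagree on traits")
    means = table.grand_means()
    fam_means = table.family_means()
    f, r = components.f, components.r
    rows = {}
    for t in table.traits:
        if se_method == "family":
            se = float(fam_means[t].std(ddof=1)) / np.sqrt(f)
        elif se_method == "anova":
            se = float(np.sqrt(max(components.var_e(t), 0.0) / (r * f)))
        else:
            raise ValueError("se_method must be 'family' or 'anova'")
        pcv, gcv = cv_coefficients(components.var_p(t), components.var_g(t),
                                   float(means[t]))
        try:
            h2 = heritability_plot(components.var_g(t), components.var_p(t))
        except UndefinedStatisticError:    # degenerate trait: sigma2_p = 0
            h2 = float("nan")
        rows[t] = {"mean": float(means[t]), "se": se,
                   "pcv": pcv, "gcv": gcv, "h2b": h2}
    return GeneticSummary(generation=table.generation,
                          table=pd.DataFrame.from_dict(rows, orient="index"))


def f2_summary(f2_plants: TrialTable, f2vars: F2Variances,
               env: str = "sum") -> GeneticSummary:
    """Summary for the unreplicated F2 nursery.

    PCV uses the individual-plant variance VF2; the genotypic variance is
    VF2 minus the (non-segregating) parent environmental term, clamped at
    zero; h2_b uses the F2 parent-variance formula.
    """
    n = len(f2_plants.data)
    rows = {}
    for t in f2vars.vf2.index:
        col = f2_plants.data[t]
        mean = float(col.mean())
        se = float(col.std(ddof=1)) / np.sqrt(n)
        vf2 = float(f2vars.vf2[t])
        ve = float(f2vars.vp1[t] + f2vars.vp2[t])
        if env == "mean":
            ve /= 2.0
        vg = max(vf2 - ve, 0.0)
        pcv, gcv = cv_coefficients(vf2, vg, mean)
        h2 = heritability_f2(vf2, float(f2vars.vp1[t]), float(f2vars.vp2[t]),
                             env=env)
        rows[t] = {"mean": mean, "se": se, "pcv": pcv, "gcv": gcv, "h2b": h2}
    return GeneticSummary(generation=f2_plants.generation,
                          table=pd.DataFrame.from_dict(rows, orient="index"))
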