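"""Predicted and realized genetic gains, better-parent comparisons, and
the predicted-vs-realized correlation.

Predicted response uses the breeder's-equation machinery: for selection
with achieved standardized differential K = (X_S - mean)/sigma_p, the
response in trait w to selection on criterion i is K * sigma_g(w,i) /
sigma_p(i).  When w = i this reduces to h2 * (X_S - mean), the form in
which per-trait gains of every selection procedure are tabulated (each
procedure's selected group induces an achieved differential in every
trait).  Realized gain is the deviation of a procedure's family-group
mean from the whole-generation mean in the following generation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._util import round_half_up
from .anova import ComponentSet
from .errors import SchemaError, UndefinedStatisticError
from .index import IndexWeights, SelectionOutcome
from .io_model import ParentTable, TrialTable
from .traits import TRAIT_DIRECTIONS

__all__ = [
    "selection_differential", "predicted_gain_direct",
    "direct_gain_from_heritability", "predicted_gain_index",
    "realized_gain", "gain_percent", "better_parent_percent",
    "predicted_realized_correlation", "gain_table",
    "better_parent_report", "GainRecord",
]


# ---------------------------------------------------------------------------
# elementary quantities
# ---------------------------------------------------------------------------

def selection_differential(selected: Sequence[str], family_means: pd.Series,
                           generation_mean: float,
                           sigma_p: float) -> tuple[float, float, float]:
    """(X_S, raw differential, standardized differential K) for one trait.

    X_S is the unweighted mean of the selected families' means; K is the
    achieved differential in phenotypic standard deviations.
    """
    if len(selected) == 0:
        raise SchemaError("selected set may not be empty")
    missing = [s for s in selected if s not in family_means.index]
    if missing:
        raise SchemaError(f"selected families absent from means: {missing}")
    x_s = float(family_means.loc[list(selected)].mean())
    sd_raw = x_s - float(generation_mean)
    if sigma_p <= 0:
        raise UndefinedStatisticError(
            "phenotypic sd must be positive to standardize the differential")
    return x_s, sd_raw, sd_raw / float(sigma_p)


def predicted_gain_direct(K: float, sigma_g_wi: float, sigma_p_i: float) -> float:
    """Response in trait w to selection on trait i: K * sigma_g(w,i) / sigma_p(i).

    With w = i this equals h2_i * (X_S - mean)_i.
    """
    if sigma_p_i <= 0:
        raise UndefinedStatisticError("sigma_p of the selected trait must be > 0")
    return float(K) * float(sigma_g_wi) / float(sigma_p_i)


def direct_gain_from_heritability(h2_percent: float, x_s: float,
                                  mean: float) -> float:
    """Direct response from a reported heritability: h2 * (X_S - mean).

    Convenience wrapper used when only summary statistics (h2, means)
    are available; routes through :func:`predicted_gain_direct` with the
    differential on a unit phenotypic scale.
    """
    sd_raw = float(x_s) - float(mean)
    return predicted_gain_direct(K=sd_raw, sigma_g_wi=h2_percent / 100.0,
                                 sigma_p_i=1.0)


def predicted_gain_index(weights: IndexWeights, sd: float,
                         components: ComponentSet, target: str,
                         mode: str = "standard") -> float:
    """Index-based predicted response in *target*.

    mode='standard' (default): response form ``SD_I * b' g_w / (b' P b)``
    where ``g_w`` is the genotypic covariance vector between the index
    traits and the target, and *sd* is the achieved differential on the
    index scale (index units).  For a single-trait index this reduces
    exactly to :func:`predicted_gain_direct`.

    mode='as_printed': the square-root selection-advance form
    ``SD * (sum_i b_i sigma_g(i,w))**0.5`` with *sd* the standardized
    differential; kept for fidelity to the source tables although it is
    dimensionally anomalous.  A negative bracket yields NaN with a
    warning.
    """
    if target not in components.traits:
        raise SchemaError(f"target trait {target!r} absent from components")
    g_w = np.array([components.cov_g(t, target) for t in weights.traits])
    if mode == "as_printed":
        bracket = float(weights.b @ g_w)
        if bracket < 0:
            warnings.warn("negative bracket in as-printed selection advance; "
                          "returning NaN", stacklevel=2)
            return float("nan")
        return float(sd) * float(np.sqrt(bracket))
    if mode != "standard":
        raise ValueError("mode must be 'standard' or 'as_printed'")
    var_index = float(weights.b @ weights.P_sub @ weights.b)
    if var_index <= 0:
        if np.allclose(weights.b, 0):
            return 0.0
        raise UndefinedStatisticError("index has non-positive variance")
    return float(sd) * float(weights.b @ g_w) / var_index


def realized_gain(procedure_mean: float, generation_mean: float) -> float:
    """Deviation of a procedure's group mean from the generation mean."""
    return float(procedure_mean) - float(generation_mean)


def gain_percent(gain: float, mean: float, decimals: int = 2) -> float:
    """Gain as a percentage of the generation mean.

    The gain is first rounded (half-up) to the report precision, which
    is the convention the source tables' percentage columns follow.
    """
    if mean <= 0:
        raise UndefinedStatisticError("mean must be positive for a gain percent")
    return 100.0 * round_half_up(gain, decimals) / float(mean)


def better_parent_percent(family_mean: float, better_parent: float) -> float:
    """Family mean as a percentage of the better-parent value."""
    if better_parent <= 0:
        raise UndefinedStatisticError("better-parent value must be positive")
    return 100.0 * float(family_mean) / float(better_parent)


def predicted_realized_correlation(predicted: Sequence[float],
                                   realized: Sequence[float]) -> float:
    """Pearson correlation between predicted and realized gains."""
    predicted = np.asarray(predicted, dtype=float)
    realized = np.asarray(realized, dtype=float)
    if predicted.shape != realized.shape:
        raise SchemaError("predicted and realized lists differ in length")
    if len(predicted) < 3:
        raise UndefinedStatisticError("need at least 3 procedures")
    if np.std(predicted) == 0 or np.std(realized) == 0:
        raise UndefinedStatisticError(
            "correlation undefined when either gain list is constant")
    return float(stats.pearsonr(predicted, realized)[0])


# ---------------------------------------------------------------------------
# report engine
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GainRecord:
    """One procedure x trait row of the gains report."""

    procedure: str
    trait: str
    x_s: float                    # selected-group mean, current generation
    sd_raw: float
    k: float
    g_s: float                    # predicted gain, current generation
    g_s_pct: float
    realized: float | None        # next-generation deviation
    realized_pct: float | None
    x_s_next: float | None        # selected-group mean in next generation
    g_s_next: float | None        # predicted gain within next generation
    g_s_next_pct: float | None


def gain_table(outcomes: Mapping[str, SelectionOutcome],
               current_table: TrialTable, current_components: ComponentSet,
               next_table: TrialTable | None = None,
               next_components: ComponentSet | None = None,
               decimals: int = 2) -> pd.DataFrame:
    """Per-procedure, per-trait gains report.

    For every procedure the selected group's achieved differential in
    every trait is converted to a predicted gain h2_w * SD_w.  When the
    following generation's trial is given, families founded by selected
    parents (matched by family id) provide the realized gain and the
    within-next-generation predicted gain.
    """
    fam_means = current_table.family_means()
    grand = current_table.grand_means()
    next_means = next_table.family_means() if next_table is not None else None
    next_grand = next_table.grand_means() if next_table is not None else None

    rows = []
    for name, outcome in outcomes.items():
        for trait in current_table.traits:
            sigma_p = float(np.sqrt(current_components.var_p(trait)))
            x_s, sd_raw, k = selection_differential(
                outcome.selected, fam_means[trait], float(grand[trait]), sigma_p)
            g_s = predicted_gain_direct(
                k, current_components.cov_g(trait, trait), sigma_p)
            rec = {
                "procedure": name, "trait": trait, "x_s": x_s,
                "sd_raw": sd_raw, "k": k, "g_s": g_s,
                "g_s_pct": gain_percent(g_s, float(grand[trait]), decimals),
                "realized": None, "realized_pct": None, "x_s_next": None,
                "g_s_next": None, "g_s_next_pct": None,
            }
            if next_means is not None and trait in next_means.columns:
                offspring = [s for s in outcome.selected
                             if s in next_means.index]
                if offspring:
                    proc_mean = float(next_means.loc[offspring, trait].mean())
                    nmean = float(next_grand[trait])
                    rec["realized"] = realized_gain(proc_mean, nmean)
                    rec["realized_pct"] = gain_percent(
                        rec["realized"], nmean, decimals)
                    sigma_p_n = float(np.sqrt(next_components.var_p(trait)))
                    _, sd_n, k_n = selection_differential(
                        offspring, next_means[trait], nmean, sigma_p_n)
                    rec["x_s_next"] = proc_mean
                    rec["g_s_next"] = predicted_gain_direct(
                        k_n, next_components.cov_g(trait, trait), sigma_p_n)
                    rec["g_s_next_pct"] = gain_percent(
                        rec["g_s_next"], nmean, decimals)
            rows.append(rec)
    return pd.DataFrame(rows)


def better_parent_report(table: TrialTable,
                         selected_by: Mapping[str, Sequence[str]],
                         parents: ParentTable,
                         directions: Mapping[str, int] | None = None,
                         decimals: int = 2) -> pd.DataFrame:
    """Superior-family report: per family and trait, the family mean and
    its percentage of the better parent (direction-aware).

    *selected_by* maps family id -> procedures that selected it (the
    "Selected by" column).
    """
    directions = directions or TRAIT_DIRECTIONS
    fam_means = table.family_means()
    rows = []
    for fam, procs in selected_by.items():
        if fam not in fam_means.index:
            raise SchemaError(f"family {fam!r} absent from trial table")
        for trait in table.traits:
            bp = parents.better_parent(trait, directions)
            mean = float(fam_means.loc[fam, trait])
            rows.append({
                "family": fam,
                "selected_by": ", ".join(procs),
                "trait": trait,
                "mean": mean,
                "better_parent": bp,
                "pct_better_parent": better_parent_percent(mean, bp),
            })
    return pd.DataFrame(rows)
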