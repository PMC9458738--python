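"""End-to-end study emulation: simulate -> estimate -> select -> advance
-> gains.

Mirrors the three-season design of the source experiment: an
unreplicated F2 nursery with both parents, truncation selection among F2
plants, a replicated F3 family trial ranked by eight selection
procedures at 10% intensity, an F4 trial of the union of selected
families, and the gains bookkeeping across F3 -> F4.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .anova import ComponentSet, estimate_components, f2_components
from .errors import UndefinedStatisticError
from .gains import (better_parent_report, gain_percent, gain_table,
                    predicted_realized_correlation)
from .genpar import (CorrelationMatrix, GeneticSummary, correlations,
                     f2_summary, generation_summary)
from .index import (DIRECT, MULTIPLICATIVE, SMITH_HAZEL, IndexDefinition,
                    SelectionOutcome, index_scores, multiplicative_scores,
                    smith_hazel_weights, standard_procedures, truncate_select,
                    union_selected)
from .io_model import AnalysisConfig, ParentTable, TrialTable
from .synthetic import (Scenario, advance_generation, default_scenario,
                        nearest_psd, simulate_f2, simulate_rcbd)

__all__ = ["StudyResult", "run_study", "apply_procedures",
           "f2_index_components", "f2_selection_gains"]


def apply_procedures(table: TrialTable, components: ComponentSet,
                     procedures: list[IndexDefinition],
                     intensity: float = 0.10,
                     n_selected: int | None = None,
                     config: AnalysisConfig | None = None
                     ) -> tuple[dict[str, SelectionOutcome], dict]:
    """Score and truncate every procedure on one trial.

    Returns (procedure name -> SelectionOutcome, name -> IndexWeights
    for the linear procedures).
    """
    config = config or AnalysisConfig()
    fam_means = table.family_means()
    outcomes: dict[str, SelectionOutcome] = {}
    weights: dict = {}
    for proc in procedures:
        if proc.kind in (DIRECT, SMITH_HAZEL):
            w = smith_hazel_weights(components, proc)
            weights[proc.name] = w
            scores = index_scores(w, fam_means)
        elif proc.kind == MULTIPLICATIVE:
            scores = multiplicative_scores(fam_means, config.directions,
                                           traits=proc.traits)
        else:  # pragma: no cover - definitions validate the kind
            raise ValueError(proc.kind)
        outcomes[proc.name] = truncate_select(
            scores, intensity=intensity, n_selected=n_selected,
            procedure=proc.name)
    return outcomes, weights


def f2_index_components(f2_table: TrialTable,
                        parents: ParentTable) -> ComponentSet:
    """Covariance machinery for index selection among F2 plants.

    With no replication the plant covariance cannot be decomposed by
    ANOVA; instead the phenotypic matrix is the F2 plant covariance and
    the environmental matrix is the pooled covariance of the
    (non-segregating, hence purely environmental) parent plants:
    G = P - E_parents, projected to PSD.
    """
    if parents.plants is None:
        raise UndefinedStatisticError(
            "F2 index components need parent plant rows")
    traits = list(f2_table.traits)
    P = np.cov(f2_table.data[traits].to_numpy(), rowvar=False, ddof=1)
    pooled = []
    for parent in parents.parents:
        rows = parents.plants[parents.plants["parent"] == parent]
        pooled.append(np.cov(rows[traits].to_numpy(), rowvar=False, ddof=1))
    E = np.mean(pooled, axis=0)
    G = nearest_psd(P - E)
    return ComponentSet(generation=f2_table.generation,
                        traits=tuple(traits), G=G, E=P - G, P=P,
                        f=len(f2_table.data), r=1)


def f2_selection_gains(f2_table: TrialTable, parents: ParentTable,
                       summary: GeneticSummary, intensity: float = 0.15,
                       n_selected: int | None = None,
                       config: AnalysisConfig | None = None) -> pd.DataFrame:
    """Predicted gains from truncation selection among F2 plants.

    Procedures applicable to the seven F2 traits are scored on
    individual plants; predicted gain per trait is h2_F2 * (X_S - mean)
    with the parent-variance heritability.
    """
    config = config or AnalysisConfig()
    comps = f2_index_components(f2_table, parents)
    procedures = standard_procedures(available=f2_table.traits)
    plant_means = f2_table.data.set_index("family")[list(f2_table.traits)]
    outcomes: dict[str, SelectionOutcome] = {}
    for proc in procedures:
        if proc.kind in (DIRECT, SMITH_HAZEL):
            w = smith_hazel_weights(comps, proc)
            scores = index_scores(w, plant_means)
        else:
            scores = multiplicative_scores(plant_means, config.directions,
                                           traits=proc.traits)
        outcomes[proc.name] = truncate_select(
            scores, intensity=intensity, n_selected=n_selected,
            procedure=proc.name)
    grand = f2_table.grand_means()
    rows = []
    for name, outcome in outcomes.items():
        sel = list(outcome.selected)
        for trait in f2_table.traits:
            x_s = float(plant_means.loc[sel, trait].mean())
            h2 = float(summary.table.loc[trait, "h2b"])
            g_s = h2 / 100.0 * (x_s - float(grand[trait]))
            rows.append({"procedure": name, "trait": trait, "x_s": x_s,
                         "g_s": g_s,
                         "g_s_pct": gain_percent(g_s, float(grand[trait]),
                                                 config.report_decimals)})
    return pd.DataFrame(rows)


@dataclass
class StudyResult:
    """Everything the pipeline produces for one seeded run."""

    scenario: Scenario
    f2_table: TrialTable
    parents: ParentTable
    f2_summary: GeneticSummary
    f2_gains: pd.DataFrame
    f3_table: TrialTable
    f3_truth: pd.DataFrame
    f3_components: ComponentSet
    f3_summary: GeneticSummary
    f3_correlations: CorrelationMatrix
    outcomes: dict[str, SelectionOutcome]
    weights: dict
    selected_by: dict[str, tuple[str, ...]]
    f4_table: TrialTable
    f4_truth: pd.DataFrame
    f4_components: ComponentSet
    f4_summary: GeneticSummary
    gains: pd.DataFrame
    superior_families: pd.DataFrame
    pred_realized_corr: pd.Series = field(default_factory=pd.Series)

    def reports(self) -> dict[str, pd.DataFrame]:
        """Report set consumed by :func:`selgain.io_model.write_report`."""
        selection = pd.concat(
            [o.to_frame() for o in self.outcomes.values()], ignore_index=True)
        corr = self.pred_realized_corr.rename_axis("trait") \
            .reset_index(name="r_predicted_realized")
        return {
            "summary": pd.concat([s.to_report() for s in
                                  (self.f2_summary, self.f3_summary,
                                   self.f4_summary)], ignore_index=True),
            "correlations_f3": self.f3_correlations.to_report(),
            "f2_gains": self.f2_gains,
            "selection": selection,
            "gains": self.gains,
            "superior_families": self.superior_families,
            "pred_realized_corr": corr,
        }


def run_study(scenario: Scenario | None = None, seed: int | None = None,
              config: AnalysisConfig | None = None,
              n_superior: int = 5) -> StudyResult:
    """Run the full emulated experiment under one seed."""
    config = config or AnalysisConfig()
    if scenario is None:
        scenario = default_scenario(seed=config.seed if seed is None else seed)
    root = np.random.default_rng(scenario.seed if seed is None else seed)
    seeds = root.spawn(3)

    # season 1: F2 nursery with parents
    f2_table, parents = simulate_f2(scenario, seed=seeds[0])
    f2vars = f2_components(f2_table, parents)
    f2sum = f2_summary(f2_table, f2vars, env=config.f2_env)
    f2_gains = f2_selection_gains(
        f2_table, parents, f2sum,
        intensity=config.intensities.get("F2", 0.15), config=config)

    # season 2: replicated F3 family trial
    f3_table, f3_truth = simulate_rcbd(scenario, "F3", seed=seeds[1])
    f3_comp = estimate_components(f3_table)
    f3_sum = generation_summary(f3_comp, f3_table, se_method=config.se_method)
    f3_corr = correlations(f3_comp)

    procedures = standard_procedures(available=f3_table.traits,
                                     weights=None)
    outcomes, weights = apply_procedures(
        f3_table, f3_comp, procedures,
        intensity=config.intensities.get("F3", 0.10), config=config)
    selected_by = union_selected(outcomes.values())

    # season 3: F4 trial of the union of selected families
    f4_table, f4_truth = advance_generation(
        scenario, list(selected_by), f3_truth, generation="F4",
        seed=seeds[2])
    f4_comp = estimate_components(f4_table)
    f4_sum = generation_summary(f4_comp, f4_table, se_method=config.se_method)

    gains = gain_table(outcomes, f3_table, f3_comp, f4_table, f4_comp,
                       decimals=config.report_decimals)

    # predicted (F3) vs realized (F4) correlation across procedures
    corr = {}
    for trait in f3_table.traits:
        block = gains[gains["trait"] == trait]
        try:
            corr[trait] = predicted_realized_correlation(
                block["g_s"].to_numpy(), block["realized"].to_numpy())
        except UndefinedStatisticError:
            corr[trait] = float("nan")
    pred_real = pd.Series(corr, name="r_predicted_realized")

    # superior families: most frequently selected, ties by lint yield
    f4_means = f4_table.family_means()
    ranked = sorted(
        selected_by,
        key=lambda fam: (-len(selected_by[fam]), -f4_means.loc[fam, "LY/P"]))
    top = {fam: selected_by[fam] for fam in ranked[:n_superior]}
    superior = better_parent_report(f4_table, top, parents,
                                    directions=config.directions,
                                    decimals=config.report_decimals)

    return StudyResult(scenario=scenario, f2_table=f2_table, parents=parents,
                       f2_summary=f2sum, f2_gains=f2_gains,
                       f3_table=f3_table, f3_truth=f3_truth,
                       f3_components=f3_comp, f3_summary=f3_sum,
                       f3_correlations=f3_corr, outcomes=outcomes,
                       weights=weights, selected_by=selected_by,
                       f4_table=f4_table, f4_truth=f4_truth,
                       f4_components=f4_comp, f4_summary=f4_sum,
                       gains=gains, superior_families=superior,
                       pred_realized_corr=pred_real)
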