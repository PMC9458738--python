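"""Data model and CSV/config I/O for multi-generation breeding trials.

Two table shapes are accepted on read:

* wide  — one row per plot: ``generation, family, replicate, <trait...>``
* long  — one row per plot and trait: ``generation, family, replicate,
  trait, value``

Tables are stored internally in wide form with traits in the canonical
order.  Replicated tables must be balanced randomized complete blocks
(every family exactly once in every replicate); any missing or duplicate
cell is a hard error, because the downstream analysis of variance assumes
balance.
"""

from __future__ import annotations

import dataclasses
import json
import pathlib
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

from ._util import round_frame
from .errors import BalanceError, DesignError, SchemaError
from .traits import (CANONICAL_TRAITS, COUNT_TRAITS, PERCENT_TRAITS,
                     TRAIT_DIRECTIONS, canonical_subset)

ID_COLUMNS = ("generation", "family", "replicate")

RCBD = "rcbd"
UNREPLICATED = "unreplicated"


# ---------------------------------------------------------------------------
# trial tables
# ---------------------------------------------------------------------------

@dataclass
class TrialTable:
    """Plot- or plant-level observations for one generation.

    ``data`` holds one row per plot (or plant, for unreplicated
    nurseries) with ``family`` and ``replicate`` id columns followed by
    one column per trait.  Family and replicate ids are opaque strings
    with no ordering semantics.
    """

    generation: str
    design: str
    data: pd.DataFrame
    traits: tuple[str, ...]

    def __post_init__(self) -> None:
        self.traits = canonical_subset(self.traits)
        cols = ["family", "replicate", *self.traits]
        missing = [c for c in cols if c not in self.data.columns]
        if missing:
            raise SchemaError(f"table is missing column(s): {missing}")
        df = self.data.loc[:, cols].copy()
        df["family"] = df["family"].astype(str)
        df["replicate"] = df["replicate"].astype(str)
        for t in self.traits:
            df[t] = pd.to_numeric(df[t], errors="coerce").astype(float)
        self.data = df.reset_index(drop=True)
        _validate_values(self.data, self.traits)
        if self.design == RCBD:
            _validate_balance(self.data)
        elif self.design == UNREPLICATED:
            if self.data["replicate"].nunique() > 1:
                raise DesignError(
                    "unreplicated table has more than one replicate id")
        else:
            raise SchemaError(f"unknown design {self.design!r}")

    # -- basic structure ----------------------------------------------------
    @property
    def family_ids(self) -> tuple[str, ...]:
        """Family ids in order of first appearance."""
        return tuple(dict.fromkeys(self.data["family"]))

    @property
    def n_families(self) -> int:
        return len(self.family_ids)

    @property
    def n_replicates(self) -> int:
        return self.data["replicate"].nunique()

    # -- summaries ----------------------------------------------------------
    def family_means(self) -> pd.DataFrame:
        """Per-family means over replicates (rows in first-appearance order)."""
        fm = self.data.groupby("family", sort=False)[list(self.traits)].mean()
        return fm.loc[list(self.family_ids)]

    def grand_means(self) -> pd.Series:
        """Per-trait mean over all plots."""
        return self.data[list(self.traits)].mean()

    def pivot(self, trait: str) -> np.ndarray:
        """family x replicate value matrix for one trait (rcbd only)."""
        if self.design != RCBD:
            raise DesignError("pivot requires a replicated (rcbd) table")
        wide = self.data.pivot(index="family", columns="replicate", values=trait)
        return wide.loc[list(self.family_ids)].to_numpy()

    def values_matrix(self) -> np.ndarray:
        """(n_plots, n_traits) array in canonical trait order."""
        return self.data[list(self.traits)].to_numpy()

    def to_frame(self) -> pd.DataFrame:
        out = self.data.copy()
        out.insert(0, "generation", self.generation)
        return out


def _validate_values(df: pd.DataFrame, traits: Iterable[str]) -> None:
    for t in traits:
        col = df[t].to_numpy()
        if not np.all(np.isfinite(col)):
            raise SchemaError(f"trait {t!r} has missing or non-finite values")
        if t in PERCENT_TRAITS and not ((col > 0) & (col < 100)).all():
            raise SchemaError(f"trait {t!r} must lie strictly in (0, 100)")
        if t in COUNT_TRAITS and not (col >= 0).all():
            raise SchemaError(f"count trait {t!r} must be non-negative")


def _validate_balance(df: pd.DataFrame) -> None:
    counts = df.groupby(["family", "replicate"]).size()
    dup = counts[counts > 1]
    if not dup.empty:
        fam, rep = dup.index[0]
        raise BalanceError(
            f"family {fam!r} appears {dup.iloc[0]} times in replicate {rep!r}")
    families = df["family"].unique()
    replicates = df["replicate"].unique()
    if len(families) * len(replicates) != len(df):
        have = set(counts.index)
        for fam in families:
            for rep in replicates:
                if (fam, rep) not in have:
                    raise BalanceError(
                        f"family {fam!r} is missing from replicate {rep!r}")
    if len(replicates) < 2:
        raise DesignError("rcbd table needs at least two replicates")


# ---------------------------------------------------------------------------
# parent tables
# ---------------------------------------------------------------------------

@dataclass
class ParentTable:
    """Per-parent trait means and phenotypic variances.

    Variances may be supplied directly or computed from individual parent
    plant rows grown alongside the segregating material (both parents are
    genetically uniform, so their plant-to-plant variance is environmental).
    """

    means: pd.DataFrame                       # index: parent name
    variances: pd.DataFrame | None = None     # same shape as means
    plants: pd.DataFrame | None = None        # raw plant rows, if any

    def __post_init__(self) -> None:
        self.means = self.means.copy().astype(float)
        order = canonical_subset(self.means.columns)
        self.means = self.means.loc[:, list(order)]
        if self.variances is not None:
            self.variances = self.variances.loc[:, list(order)].astype(float)
            if (self.variances.to_numpy() < 0).any():
                raise SchemaError("parent variances must be non-negative")

    @classmethod
    def from_plants(cls, plants: pd.DataFrame, traits=None) -> "ParentTable":
        """Build means and sample variances (ddof=1) from plant rows.

        *plants* needs a ``parent`` column plus one column per trait.
        """
        if "parent" not in plants.columns:
            raise SchemaError("parent plant table needs a 'parent' column")
        if traits is None:
            traits = [c for c in plants.columns
                      if c != "parent" and c in CANONICAL_TRAITS]
        traits = list(canonical_subset(traits))
        grp = plants.groupby("parent", sort=False)[traits]
        return cls(means=grp.mean(), variances=grp.var(ddof=1), plants=plants)

    @property
    def parents(self) -> tuple[str, ...]:
        return tuple(self.means.index)

    def better_parent(self, trait: str, directions: Mapping[str, int] | None = None) -> float:
        """Better-parent value: larger mean, or smaller for downward traits."""
        d = (directions or TRAIT_DIRECTIONS).get(trait, 1)
        col = self.means[trait]
        return float(col.min() if d < 0 else col.max())


# ---------------------------------------------------------------------------
# analysis configuration
# ---------------------------------------------------------------------------

@dataclass
class AnalysisConfig:
    """Knobs of the analysis pipeline.

    directions       +1 larger-better / -1 smaller-better per trait
                     (default: -1 only for micronaire)
    economic_weights relative economic values a (default all 1, the
                     "equally important" convention)
    intensities      selected fraction per generation (0.15 among F2
                     plants, 0.10 among F3 families by default)
    report_decimals  half-up rounding precision of emitted reports
    f2_env           environmental term of the F2 heritability:
                     'sum' uses VP1+VP2 (the study's printed formula),
                     'mean' the conventional (VP1+VP2)/2
    corr_n           sample size for correlation significance tests:
                     'families' or 'plots'
    se_method        SE of generation means: 'family' (between-family
                     dispersion / sqrt(f)) or 'anova' (sqrt(ME/(r f)))
    gain_mode        index-gain formula: 'standard' response form or the
                     'as_printed' square-root form
    """

    directions: dict[str, int] = field(
        default_factory=lambda: dict(TRAIT_DIRECTIONS))
    economic_weights: dict[str, float] = field(
        default_factory=lambda: {t: 1.0 for t in CANONICAL_TRAITS})
    intensities: dict[str, float] = field(
        default_factory=lambda: {"F2": 0.15, "F3": 0.10})
    report_decimals: int = 2
    seed: int = 0
    f2_env: str = "sum"
    corr_n: str = "families"
    se_method: str = "family"
    gain_mode: str = "standard"

    def __post_init__(self) -> None:
        for gen, p in self.intensities.items():
            if not (0 < p <= 1):
                raise SchemaError(
                    f"selection intensity for {gen} must be in (0, 1], got {p}")
        for t, w in self.economic_weights.items():
            if not np.isfinite(w):
                raise SchemaError(f"economic weight for {t!r} is not finite")
        if self.f2_env not in ("sum", "mean"):
            raise SchemaError("f2_env must be 'sum' or 'mean'")
        if self.gain_mode not in ("standard", "as_printed"):
            raise SchemaError("gain_mode must be 'standard' or 'as_printed'")

    @classmethod
    def from_file(cls, path) -> "AnalysisConfig":
        """Load from YAML or JSON (YAML is a superset of JSON)."""
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise SchemaError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_trial_table(path, config: AnalysisConfig | None = None,
                     design: str | None = None) -> TrialTable:
    """Read a trial CSV (wide or long layout) into a validated TrialTable.

    The generation label is taken from the (constant) ``generation``
    column.  Unless *design* is given it is inferred: a single distinct
    replicate id means an unreplicated nursery, otherwise the table is
    treated (and validated) as a balanced randomized complete block.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    for c in ID_COLUMNS:
        if c not in df.columns:
            raise SchemaError(f"{path}: missing required column {c!r}")
    if df["generation"].nunique() != 1:
        raise SchemaError(f"{path}: 'generation' column must be constant")
    generation = str(df["generation"].iloc[0])

    if "trait" in df.columns and "value" in df.columns:   # long layout
        wide = df.pivot_table(index=["family", "replicate"], columns="trait",
                              values="value", aggfunc="first", sort=False)
        wide = wide.reset_index()
        wide.columns.name = None
        traits = [c for c in wide.columns if c in CANONICAL_TRAITS]
        df = wide
    else:
        traits = [c for c in df.columns if c in CANONICAL_TRAITS]
    if not traits:
        raise SchemaError(f"{path}: no recognizable trait columns")

    if design is None:
        design = UNREPLICATED if df["replicate"].nunique() == 1 else RCBD
    return TrialTable(generation=generation, design=design,
                      data=df, traits=tuple(traits))


def write_trial_table(table: TrialTable, path) -> pathlib.Path:
    """Write a TrialTable as a wide CSV that round-trips at full precision."""
    path = pathlib.Path(path)
    table.to_frame().to_csv(path, index=False)
    return path


def read_parent_table(path) -> ParentTable:
    """Read a parent CSV: one row per parent (means, with optional
    ``var:<trait>`` variance columns) or several rows per parent
    (individual plants, from which means and variances are computed)."""
    df = pd.read_csv(path)
    if "parent" not in df.columns:
        raise SchemaError(f"{path}: missing required column 'parent'")
    df["parent"] = df["parent"].astype(str)
    if df["parent"].duplicated().any():
        return ParentTable.from_plants(df)
    traits = [c for c in df.columns if c in CANONICAL_TRAITS]
    means = df.set_index("parent")[traits]
    var_cols = {c[4:]: c for c in df.columns if c.startswith("var:")}
    variances = None
    if var_cols:
        variances = df.set_index("parent")[list(var_cols.values())]
        variances.columns = list(var_cols.keys())
    return ParentTable(means=means, variances=variances)


def write_parent_table(parents: ParentTable, path) -> pathlib.Path:
    path = pathlib.Path(path)
    if parents.plants is not None:
        parents.plants.to_csv(path, index=False)
    else:
        out = parents.means.copy()
        if parents.variances is not None:
            for t in parents.variances.columns:
                out[f"var:{t}"] = parents.variances[t]
        out.reset_index(names="parent").to_csv(path, index=False)
    return path


def write_report(reports: Mapping[str, pd.DataFrame], outdir,
                 decimals: int = 2) -> list[pathlib.Path]:
    """Write each report as ``<name>.csv`` plus a JSON mirror.

    Float columns are rounded half-up to *decimals* places in both files.
    Returns the list of written paths.
    """
    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[pathlib.Path] = []
    for name, df in reports.items():
        rounded = round_frame(df, decimals)
        csv_path = outdir / f"{name}.csv"
        rounded.to_csv(csv_path, index=False)
        json_path = outdir / f"{name}.json"
        with open(json_path, "w", encoding="utf-8") as fh:
            json.dump(json.loads(rounded.to_json(orient="records")), fh, indent=1)
        written += [csv_path, json_path]
    return written
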