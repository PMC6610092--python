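"""Food-level aggregation of anti-cancer likeness predictions.

A food compound with ensemble ACL above the cutoff (default 0.7, strict
comparison) that survives curation — not a known toxin, not a cancer
promoter, not a normal cellular metabolite such as dCTP — is a
cancer-beating molecule (CBM).  Foods are scored by how many distinct CBMs
they contain, and related to each other through the pairwise Pearson (phi)
correlation of their binary CBM incidence profiles, which is the edge
structure of the food map.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Default cancer-beating-molecule cutoff on the ACL probability (strict >).
CBM_THRESHOLD = 0.7

EXCLUSION_FLAGS = ("toxic", "cancer_promoting", "normal_metabolite")


@dataclass
class FoodCompoundMap:
    """Compound-food membership table with per-compound exclusion flags.

    ``table`` columns: compound_id, food_id, food_name (+ one boolean column
    per exclusion flag).  (compound_id, food_id) pairs are unique.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"compound_id", "food_id"}
        if not required <= set(self.table.columns):
            raise ValueError(f"food map needs columns {sorted(required)}")
        if "food_name" not in self.table.columns:
            self.table = self.table.assign(food_name=self.table["food_id"])
        if self.table.duplicated(["compound_id", "food_id"]).any():
            raise ValueError("duplicate (compound_id, food_id) pairs in food map")
        for flag in EXCLUSION_FLAGS:
            if flag not in self.table.columns:
                self.table[flag] = False

    @property
    def excluded_mask(self) -> pd.Series:
        return self.table[list(EXCLUSION_FLAGS)].any(axis=1)

    def compounds(self) -> list[str]:
        return sorted(self.table["compound_id"].unique())

    def foods(self) -> list[str]:
        return sorted(self.table["food_id"].unique())


def load_food_map(path: str | Path) -> FoodCompoundMap:
    """Read a FooDB-style compound-food TSV (compound_id, food_id[, food_name])."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = ["compound_id", "food_id", "food_name"][: len(df.columns)]
    df.columns = cols + list(df.columns[len(cols):])
    return FoodCompoundMap(df)


def flag_exclusions(
    food_map: FoodCompoundMap,
    toxin_list: Iterable[str] = (),
    cancer_promoting: Iterable[str] = (),
    metabolite_classes: Iterable[str] = (),
    compound_classes: Mapping[str, str] | None = None,
) -> FoodCompoundMap:
    """Flag curated exclusions; flagged compounds stay in the table but are
    excluded from CBM counting.

    ``toxin_list`` / ``cancer_promoting`` are compound ids; a compound is
    flagged ``normal_metabolite`` when its annotated chemical class (from
    ``compound_classes``) is in ``metabolite_classes`` — e.g. dCTP under
    "nucleosides, nucleotides, and analogues".
    """
    df = food_map.table.copy()
    toxins = set(toxin_list)
    promoting = set(cancer_promoting)
    meta_classes = {m.lower() for m in metabolite_classes}
    classes = {k: v.lower() for k, v in (compound_classes or {}).items()}

    df["toxic"] = df["toxic"] | df["compound_id"].isin(toxins)
    df["cancer_promoting"] = df["cancer_promoting"] | df["compound_id"].isin(promoting)
    df["normal_metabolite"] = df["normal_metabolite"] | df["compound_id"].map(
        lambda c: classes.get(c, "") in meta_classes if meta_classes else False
    )
    flagged = df.loc[df[list(EXCLUSION_FLAGS)].any(axis=1), "compound_id"].nunique()
    logger.info("flag_exclusions: %d compounds flagged for exclusion", flagged)
    return FoodCompoundMap(df)


def exclusion_report(food_map: FoodCompoundMap) -> pd.DataFrame:
    """Per-compound exclusion summary (one row per flagged compound)."""
    df = food_map.table
    flagged = df[df[list(EXCLUSION_FLAGS)].any(axis=1)]
    return (
        flagged.groupby("compound_id")[list(EXCLUSION_FLAGS)].any().reset_index()
    )


def _cbm_compounds(
    scores: Mapping[str, float] | pd.Series,
    food_map: FoodCompoundMap,
    threshold: float,
) -> set[str]:
    scores = pd.Series(dict(scores)) if not isinstance(scores, pd.Series) else scores
    excluded = set(food_map.table.loc[food_map.excluded_mask, "compound_id"])
    return {c for c, v in scores.items() if pd.notna(v) and v > threshold and c not in excluded}


def count_cbms(
    scores: Mapping[str, float] | pd.Series,
    food_map: FoodCompoundMap,
    threshold: float = CBM_THRESHOLD,
) -> pd.Series:
    """Per-food count of distinct non-excluded compounds with ACL strictly
    above ``threshold``.  Counts are monotone non-increasing in the cutoff."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must be in [0, 1]")
    cbms = _cbm_compounds(scores, food_map, threshold)
    df = food_map.table
    hits = df[df["compound_id"].isin(cbms)]
    counts = hits.groupby("food_id")["compound_id"].nunique()
    return counts.reindex(food_map.foods(), fill_value=0).astype(int)


def cbm_table(
    scores: Mapping[str, float] | pd.Series,
    food_map: FoodCompoundMap,
    threshold: float = CBM_THRESHOLD,
    compound_classes: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """CBM listing: compound, ACL, chemical class (if provided), foods."""
    scores = pd.Series(dict(scores)) if not isinstance(scores, pd.Series) else scores
    cbms = sorted(_cbm_compounds(scores, food_map, threshold))
    df = food_map.table
    rows = []
    for c in cbms:
        foods = sorted(df.loc[df["compound_id"] == c, "food_name"].unique())
        rows.append((c, float(scores[c]), (compound_classes or {}).get(c, ""), ";".join(foods)))
    return pd.DataFrame(rows, columns=["compound_id", "acl", "chemical_class", "foods"])


@dataclass
class FoodScoreTable:
    """Aggregated food map outputs."""

    compound_acl: pd.Series
    cbm_threshold: float
    cbm_counts: pd.Series
    correlation: pd.DataFrame          # food x food phi matrix
    incidence: pd.DataFrame            # food x CBM binary incidence


def food_correlation_map(
    food_map: FoodCompoundMap,
    scores: Mapping[str, float] | pd.Series,
    threshold: float = CBM_THRESHOLD,
    edge_cutoff: float | None = None,
    weighted: bool = False,
) -> tuple[FoodScoreTable, pd.DataFrame]:
    """Food x food correlation of CBM profiles plus an edge list.

    The incidence matrix is binary by default (CBM present/absent per food);
    ``weighted=True`` uses the ACL value instead.  Foods with zero CBMs are
    excluded from the correlation (logged).  Edges with correlation above
    ``edge_cutoff`` (if given) are emitted as (food_a, food_b, phi).
    """
    scores = pd.Series(dict(scores)) if not isinstance(scores, pd.Series) else scores
    counts = count_cbms(scores, food_map, threshold)
    cbms = sorted(_cbm_compounds(scores, food_map, threshold))
    foods_with = [f for f in food_map.foods() if counts[f] > 0]
    dropped = [f for f in food_map.foods() if counts[f] == 0]
    if dropped:
        logger.info("food_correlation_map: %d foods with zero CBMs excluded", len(dropped))
    if len(foods_with) < 2 or not cbms:
        raise ValueError("need >= 2 foods with >= 1 CBM to build a correlation map")

    df = food_map.table
    inc = pd.DataFrame(0.0, index=foods_with, columns=cbms)
    pairs = df[df["compound_id"].isin(cbms) & df["food_id"].isin(foods_with)]
    for food, comp in zip(pairs["food_id"], pairs["compound_id"]):
        inc.loc[food, comp] = float(scores[comp]) if weighted else 1.0

    mat = inc.to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = np.corrcoef(mat)
    corr = np.nan_to_num(corr, nan=0.0)
    np.fill_diagonal(corr, 1.0)
    corr_df = pd.DataFrame(corr, index=foods_with, columns=foods_with)

    edges = []
    for i, fa in enumerate(foods_with):
        for fb in foods_with[i + 1:]:
            phi = corr_df.loc[fa, fb]
            if edge_cutoff is None or phi > edge_cutoff:
                edges.append((fa, fb, float(phi)))
    edge_df = pd.DataFrame(edges, columns=["food_a", "food_b", "phi"])

    table = FoodScoreTable(
        compound_acl=scores, cbm_threshold=threshold,
        cbm_counts=counts, correlation=corr_df, incidence=inc,
    )
    return table, edge_df


def export_food_map(
    table: FoodScoreTable, edges: pd.DataFrame, out_dir: str | Path
) -> None:
    """Write the food map as node/edge TSVs and GraphML."""
    import networkx as nx

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    nodes = table.cbm_counts.rename("cbm_count").rename_axis("food_id").reset_index()
    nodes.to_csv(out / "food_nodes.tsv", sep="\t", index=False)
    edges.to_csv(out / "food_edges.tsv", sep="\t", index=False)

    g = nx.Graph()
    for _, row in nodes.iterrows():
        g.add_node(row["food_id"], cbm_count=int(row["cbm_count"]))
    for _, row in edges.iterrows():
        g.add_edge(row["food_a"], row["food_b"], phi=float(row["phi"]))
    nx.write_graphml(g, out / "food_map.graphml")
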