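"""Fully synthetic interactomes, compound-target tables, labels and food
maps with known ground truth.

The generator emulates the structure of the real inputs at desk scale:

* a sparse undirected scored interactome with a planted "disease module" —
  a planted-partition graph whose module edges are denser and carry higher
  (but overlapping) confidence scores than the background, so edge
  thresholding has a detectable optimum;
* positive compounds whose 20-30 targets are enriched in the module
  (default 70% of draws), negative compounds with diffuse targets, at the
  ~1:9 positive:negative imbalance of approved anti-cancer vs other drugs;
* unlabeled "food compounds" drawn from a mixture of positive-like and
  negative-like target samplers, assigned to foods with a planted
  CBM-richness ordering.

All randomness flows from a single seed through named substreams, so any
stage can be regenerated independently and bitwise reproducibly.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components

from .food_scoring import FoodCompoundMap
from .interactome import ScoredEdgeList
from .target_profiles import CompoundTargets

logger = logging.getLogger(__name__)

_STAGES = ("interactome", "scores", "tree", "compounds", "food")


@dataclass
class SyntheticSpec:
    """Study conditions for one synthetic dataset.

    Defaults are the reference conditions used throughout the test suite:
    a 500-gene interactome with a 40-gene planted module (edge densities
    0.3 inside vs 0.01 outside), 100 positive and 900 negative compounds
    with 20-30 targets each, positives drawing 70% of targets from the
    module.  Edge and target scores are overlapping normals so the
    confidence-threshold grids genuinely filter.
    """

    n_genes: int = 500
    module_size: int = 40
    module_density: float = 0.3
    background_density: float = 0.01
    n_positive: int = 100
    n_negative: int = 900
    targets_per_compound: tuple[int, int] = (20, 30)
    module_target_fraction: float = 0.7
    module_edge_score: tuple[float, float] = (750.0, 100.0)   # mean, sd
    background_edge_score: tuple[float, float] = (450.0, 150.0)
    target_score: tuple[float, float] = (450.0, 180.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.module_size < self.n_genes:
            raise ValueError("module_size must be smaller than n_genes")
        for d in (self.module_density, self.background_density):
            if not 0.0 < d <= 1.0:
                raise ValueError("densities must be in (0, 1]")
        lo, hi = self.targets_per_compound
        if not 1 <= lo <= hi:
            raise ValueError("targets_per_compound must be an increasing positive range")
        if not 0.0 <= self.module_target_fraction <= 1.0:
            raise ValueError("module_target_fraction must be in [0, 1]")

    def rng(self, stage: str) -> np.random.Generator:
        """Substream generator for one pipeline stage."""
        if stage not in _STAGES:
            raise ValueError(f"unknown stage {stage!r}; one of {_STAGES}")
        return np.random.default_rng(
            np.random.SeedSequence(self.seed, spawn_key=(_STAGES.index(stage),))
        )


@dataclass
class GroundTruth:
    """What the generator planted, for verification against recovered results."""

    module_genes: list[str]
    compound_labels: dict[str, str] = field(default_factory=dict)
    target_sets: dict[str, list[str]] = field(default_factory=dict)
    food_richness: dict[str, float] = field(default_factory=dict)
    food_compound_kind: dict[str, str] = field(default_factory=dict)  # positive_like / negative_like

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")


def _gene_ids(n: int) -> list[str]:
    width = len(str(n - 1))
    return [f"G{i:0{width}d}" for i in range(n)]


def _draw_scores(rng: np.random.Generator, n: int, mean_sd: tuple[float, float]) -> np.ndarray:
    mean, sd = mean_sd
    return np.clip(np.round(rng.normal(mean, sd, size=n)), 1, 999).astype(int)


def generate_interactome(spec: SyntheticSpec) -> tuple[ScoredEdgeList, GroundTruth]:
    """Planted-partition scored edge list.

    Module-internal pairs are linked with ``module_density``, all other
    pairs with ``background_density``.  A random spanning chain over the
    non-module nodes guarantees the background is connected; any residual
    components (possible at extreme densities) are stitched to the largest
    one with single background-scored edges, logged.
    """
    n, m = spec.n_genes, spec.module_size
    genes = _gene_ids(n)
    module = genes[:m]  # ids are arbitrary labels; the first m are the module
    rng = spec.rng("interactome")

    iu, ju = np.triu_indices(n, k=1)
    in_module = (iu < m) & (ju < m)
    p = np.where(in_module, spec.module_density, spec.background_density)
    keep = rng.random(len(iu)) < p
    ei, ej, emod = iu[keep], ju[keep], in_module[keep]

    # spanning chain over non-module nodes keeps the background connected
    tree_rng = spec.rng("tree")
    non_module = np.arange(m, n)
    order = tree_rng.permutation(non_module)
    ti, tj = order[:-1], order[1:]
    ei = np.concatenate([ei, np.minimum(ti, tj)])
    ej = np.concatenate([ej, np.maximum(ti, tj)])
    emod = np.concatenate([emod, np.zeros(len(ti), dtype=bool)])

    # deduplicate pairs (chain edges may coincide with random ones)
    pair_key = ei * n + ej
    _, first = np.unique(pair_key, return_index=True)
    first = np.sort(first)
    ei, ej, emod = ei[first], ej[first], emod[first]

    # stitch residual components (e.g. an isolated module at low densities)
    adj = sp.coo_matrix((np.ones(len(ei)), (ei, ej)), shape=(n, n))
    n_comp, labels = connected_components(adj + adj.T, directed=False)
    if n_comp > 1:
        sizes = np.bincount(labels)
        main = int(np.argmax(sizes))
        extra_i, extra_j = [], []
        for comp in range(n_comp):
            if comp == main:
                continue
            a = int(np.flatnonzero(labels == comp)[0])
            b = int(np.flatnonzero(labels == main)[0])
            extra_i.append(min(a, b))
            extra_j.append(max(a, b))
        logger.info("generate_interactome: stitched %d extra components", n_comp - 1)
        ei = np.concatenate([ei, extra_i])
        ej = np.concatenate([ej, extra_j])
        emod = np.concatenate([emod, np.zeros(len(extra_i), dtype=bool)])

    score_rng = spec.rng("scores")
    scores = np.where(
        emod,
        _draw_scores(score_rng, len(ei), spec.module_edge_score),
        _draw_scores(score_rng, len(ei), spec.background_edge_score),
    )
    df = pd.DataFrame({
        "node_a": [genes[i] for i in ei],
        "node_b": [genes[j] for j in ej],
        "score": scores,
    }).sort_values(["node_a", "node_b"], kind="mergesort").reset_index(drop=True)
    truth = GroundTruth(module_genes=list(module))
    return ScoredEdgeList(df), truth


def generate_compounds(
    spec: SyntheticSpec, truth: GroundTruth
) -> list[CompoundTargets]:
    """Labeled compounds: positives target the planted module, negatives are
    diffuse.  Target draws are without replacement, so the module must be at
    least as large as the biggest module draw."""
    rng = spec.rng("compounds")
    genes = _gene_ids(spec.n_genes)
    module_idx = np.arange(spec.module_size)
    all_idx = np.arange(spec.n_genes)
    non_module_idx = all_idx[spec.module_size:]
    lo, hi = spec.targets_per_compound

    max_module_draw = int(round(spec.module_target_fraction * hi))
    if max_module_draw > spec.module_size:
        raise ValueError(
            f"module too small: up to {max_module_draw} module targets requested "
            f"without replacement from {spec.module_size} module genes"
        )

    compounds: list[CompoundTargets] = []
    n_total = spec.n_positive + spec.n_negative
    width = len(str(n_total - 1))
    for i in range(n_total):
        positive = i < spec.n_positive
        cid = f"{'POS' if positive else 'NEG'}{i:0{width}d}"
        k = int(rng.integers(lo, hi + 1))
        if positive:
            k_mod = int(round(spec.module_target_fraction * k))
            k_mod = min(k_mod, spec.module_size)
            chosen_mod = rng.choice(module_idx, size=k_mod, replace=False)
            chosen_rest = rng.choice(non_module_idx, size=k - k_mod, replace=False)
            idx = np.concatenate([chosen_mod, chosen_rest])
        else:
            idx = rng.choice(all_idx, size=k, replace=False)
        idx = np.sort(idx)
        scores = _draw_scores(rng, k, spec.target_score)
        targets = [(genes[j], int(s)) for j, s in zip(idx, scores)]
        label = "positive" if positive else "negative"
        compounds.append(CompoundTargets(cid, targets, label))
        truth.compound_labels[cid] = label
        truth.target_sets[cid] = [genes[j] for j in idx]
    return compounds


def generate_food_map(
    spec: SyntheticSpec,
    truth: GroundTruth,
    n_foods: int = 10,
    n_food_compounds: int = 100,
    compounds_per_food: int = 12,
    positive_like_fraction: float = 0.3,
) -> tuple[list[CompoundTargets], FoodCompoundMap]:
    """Unlabeled food compounds plus a food membership table.

    A fraction of food compounds is drawn from the positive-like sampler
    (module-enriched targets), the rest from the negative-like sampler.
    Food ``i`` of ``n_foods`` has planted richness ``1 - i/(n_foods-1)``:
    richer foods preferentially receive positive-like compounds, so the
    expected CBM-count ordering of foods is known.
    """
    if n_foods == 0:
        return [], FoodCompoundMap(pd.DataFrame(columns=["compound_id", "food_id", "food_name"]))
    rng = spec.rng("food")
    genes = _gene_ids(spec.n_genes)
    module_idx = np.arange(spec.module_size)
    all_idx = np.arange(spec.n_genes)
    non_module_idx = all_idx[spec.module_size:]
    lo, hi = spec.targets_per_compound

    food_compounds: list[CompoundTargets] = []
    kinds: list[str] = []
    width = len(str(max(n_food_compounds - 1, 1)))
    for i in range(n_food_compounds):
        positive_like = rng.random() < positive_like_fraction
        cid = f"FC{i:0{width}d}"
        k = int(rng.integers(lo, hi + 1))
        if positive_like:
            k_mod = min(int(round(spec.module_target_fraction * k)), spec.module_size)
            idx = np.concatenate([
                rng.choice(module_idx, size=k_mod, replace=False),
                rng.choice(non_module_idx, size=k - k_mod, replace=False),
            ])
        else:
            idx = rng.choice(all_idx, size=k, replace=False)
        idx = np.sort(idx)
        scores = _draw_scores(rng, k, spec.target_score)
        food_compounds.append(CompoundTargets(cid, [(genes[j], int(s)) for j, s in zip(idx, scores)]))
        kind = "positive_like" if positive_like else "negative_like"
        kinds.append(kind)
        truth.food_compound_kind[cid] = kind

    pos_ids = [c.compound_id for c, k in zip(food_compounds, kinds) if k == "positive_like"]
    neg_ids = [c.compound_id for c, k in zip(food_compounds, kinds) if k == "negative_like"]

    rows = []
    for i in range(n_foods):
        richness = 1.0 - (i / max(n_foods - 1, 1))
        food_id = f"FOOD{i:02d}"
        truth.food_richness[food_id] = richness
        n_pos = int(round(richness * compounds_per_food))
        n_pos = min(n_pos, len(pos_ids))
        n_neg = min(compounds_per_food - n_pos, len(neg_ids))
        chosen = list(rng.choice(pos_ids, size=n_pos, replace=False)) if n_pos else []
        chosen += list(rng.choice(neg_ids, size=n_neg, replace=False)) if n_neg else []
        for cid in chosen:
            rows.append((cid, food_id, f"food {i}"))
    table = pd.DataFrame(rows, columns=["compound_id", "food_id", "food_name"])
    return food_compounds, FoodCompoundMap(table)


# ---------------------------------------------------------------------------
# Dataset bundle and TSV emission
# ---------------------------------------------------------------------------

@dataclass
class SyntheticDataset:
    spec: SyntheticSpec
    edges: ScoredEdgeList
    compounds: list[CompoundTargets]
    food_compounds: list[CompoundTargets]
    food_map: FoodCompoundMap
    truth: GroundTruth


def generate_dataset(
    spec: SyntheticSpec, n_foods: int = 10, n_food_compounds: int = 100
) -> SyntheticDataset:
    """Generate every table of one synthetic study."""
    edges, truth = generate_interactome(spec)
    compounds = generate_compounds(spec, truth)
    food_compounds, food_map = generate_food_map(
        spec, truth, n_foods=n_foods, n_food_compounds=n_food_compounds
    )
    return SyntheticDataset(spec, edges, compounds, food_compounds, food_map, truth)


def write_dataset(ds: SyntheticDataset, out_dir: str | Path) -> None:
    """Emit the TSV dialects the readers consume, plus ground-truth JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ds.edges.edges.to_csv(out / "edges.tsv", sep="\t", index=False)

    target_rows = [
        (ct.compound_id, g, s)
        for ct in ds.compounds + ds.food_compounds
        for g, s in ct.targets
    ]
    pd.DataFrame(target_rows, columns=["compound_id", "gene_id", "score"]).to_csv(
        out / "compound_targets.tsv", sep="\t", index=False
    )
    pd.DataFrame(
        [(ct.compound_id, ct.label) for ct in ds.compounds],
        columns=["compound_id", "label"],
    ).to_csv(out / "labels.tsv", sep="\t", index=False)
    ds.food_map.table[["compound_id", "food_id", "food_name"]].to_csv(
        out / "food_map.tsv", sep="\t", index=False
    )
    ds.truth.to_json(out / "ground_truth.json")
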