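"""Per-compound seed vectors from scored compound-gene interaction tables.

A compound's direct protein targets are its "entry points" for the random
walk: the seed distribution puts mass ``1/k`` on each of the ``k`` targets
that map onto the interactome node list and zero elsewhere.  Target tables
are STITCH-style (compound id, gene id, integer score 0-999) and can be
filtered at a confidence threshold before seeding.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .interactome import InteractomeGraph

logger = logging.getLogger(__name__)

#: Canonical confidence-threshold grid for compound-gene interactions.
DRUG_GENE_THRESHOLDS = (0, 100, 200, 325, 400, 500, 600, 700)

Label = Literal["positive", "negative", "unlabeled"]
VALID_LABELS = ("positive", "negative", "unlabeled")


class NoEntryPointsError(ValueError):
    """Compound has no targets mapping onto the interactome."""


@dataclass
class CompoundTargets:
    """Scored targets of one compound plus its training label."""

    compound_id: str
    targets: list[tuple[str, int]]
    label: Label = "unlabeled"

    def __post_init__(self) -> None:
        if self.label not in VALID_LABELS:
            raise ValueError(f"label must be one of {VALID_LABELS}, got {self.label!r}")
        for gene, score in self.targets:
            if not 0 <= score <= 999:
                raise ValueError(f"{self.compound_id}: target score {score} outside [0, 999]")

    @property
    def n_targets(self) -> int:
        return len(self.targets)

    def gene_ids(self) -> list[str]:
        return [g for g, _ in self.targets]


@dataclass
class SeedVector:
    """Uniform start distribution over a compound's mapped entry points."""

    values: np.ndarray
    support: np.ndarray  # indices of the entry points
    compound_id: str = ""

    def __post_init__(self) -> None:
        s = float(self.values.sum())
        if abs(s - 1.0) > 1e-12:
            raise ValueError(f"seed vector must sum to 1, got {s!r}")


def filter_targets(ct: CompoundTargets, threshold: int) -> CompoundTargets:
    """Retain targets with ``score >= threshold``.

    Composable: filtering at t1 then t2 equals filtering at ``max(t1, t2)``.
    A compound left with zero targets is returned empty (and will raise at
    seed-building time).
    """
    if not 0 <= threshold <= 999:
        raise ValueError(f"threshold must be in [0, 999], got {threshold}")
    kept = [(g, s) for g, s in ct.targets if s >= threshold]
    return CompoundTargets(ct.compound_id, kept, ct.label)


def build_seed_vector(ct: CompoundTargets, graph: InteractomeGraph) -> SeedVector:
    """Uniform seed over the compound's targets that exist in the graph.

    Raises
    ------
    NoEntryPointsError
        If none of the compound's targets map onto the graph node list.
    """
    idx = sorted({graph.index[g] for g, _ in ct.targets if g in graph.index})
    if not idx:
        raise NoEntryPointsError(
            f"compound {ct.compound_id!r}: no entry points (0 of {ct.n_targets} targets map onto the graph)"
        )
    values = np.zeros(graph.n_nodes)
    values[idx] = 1.0 / len(idx)
    return SeedVector(values=values, support=np.asarray(idx, dtype=int), compound_id=ct.compound_id)


def log_transform(profile: np.ndarray, epsilon: float = 1e-12) -> np.ndarray:
    """Elementwise ``ln(profile + epsilon)``.

    A monotone, order-preserving map that compresses the very large values
    of isolated non-propagating genes, which otherwise dominate linear
    classifiers trained on propagated profiles.
    """
    profile = np.asarray(profile, dtype=float)
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    if (profile < 0).any():
        raise ValueError("profile must be elementwise nonnegative")
    return np.log(profile + epsilon)


# ---------------------------------------------------------------------------
# Table IO
# ---------------------------------------------------------------------------

def load_compound_targets(
    targets_path: str | Path,
    labels_path: str | Path | None = None,
) -> list[CompoundTargets]:
    """Read a compound-gene TSV (compound_id, gene_id, score) and an optional
    label TSV (compound_id, label).

    Compound ids are matched between the two tables by exact string equality
    (full InChIKey or database id); compounds absent from the label table are
    ``unlabeled``.
    """
    df = pd.read_csv(targets_path, sep="\t", dtype={0: str, 1: str})
    df.columns = ["compound_id", "gene_id", "score"][: len(df.columns)]
    labels: dict[str, str] = {}
    if labels_path is not None:
        ldf = pd.read_csv(labels_path, sep="\t", dtype=str)
        ldf.columns = ["compound_id", "label"][: len(ldf.columns)]
        bad = set(ldf["label"]) - set(VALID_LABELS)
        if bad:
            raise ValueError(f"{labels_path}: unknown labels {sorted(bad)}")
        labels = dict(zip(ldf["compound_id"], ldf["label"]))

    out = []
    for cid, grp in df.groupby("compound_id", sort=True):
        targets = [(g, int(s)) for g, s in zip(grp["gene_id"], grp["score"])]
        out.append(CompoundTargets(str(cid), targets, labels.get(str(cid), "unlabeled")))
    return out


def seed_support_report(
    compounds: Sequence[CompoundTargets], graph: InteractomeGraph
) -> pd.DataFrame:
    """Per-compound mapping report: targets present, mapped, and usability."""
    rows = []
    for ct in compounds:
        mapped = sum(1 for g, _ in ct.targets if g in graph.index)
        rows.append((ct.compound_id, ct.label, ct.n_targets, mapped, mapped > 0))
    rep = pd.DataFrame(rows, columns=["compound_id", "label", "n_targets", "n_mapped", "usable"])
    n_unusable = int((~rep["usable"]).sum())
    if n_unusable:
        logger.warning("%d compounds have no mapped entry points and are excluded", n_unusable)
    return rep
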