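"""Load, identifier-match, threshold and convert scored protein-protein
interaction data into a walkable transition matrix.

The interactome is an undirected graph whose nodes are gene-encoded proteins
and whose edges carry integer confidence scores on the 0-999 scale used by
STRING-style exports.  Edges are dichotomized at a confidence threshold and
the resulting binary adjacency is row-normalised into the transition matrix
``W`` of a random walk: the probability of stepping from node *a* to a
neighbour *b* is ``1 / degree(a)``.

Cross-database protein records are reconciled by amino-acid sequence in three
sequential tiers: exact equality, contiguous containment, and fuzzy alignment
allowing a bounded mismatch fraction.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import edlib
import numpy as np
import pandas as pd
import scipy.sparse as sp

logger = logging.getLogger(__name__)

#: Canonical confidence-threshold grid for gene-gene edges.
GENE_GENE_THRESHOLDS = (400, 600, 700, 800, 850)

#: Score assigned to unscored (experimentally asserted) edges so they survive
#: every threshold in the canonical grid.
UNSCORED_EDGE_SCORE = 999

_AA_LETTERS = frozenset("ACDEFGHIKLMNPQRSTVWYBXZJUO")


class EdgeListError(ValueError):
    """Raised for malformed or empty edge-list input."""


@dataclass
class ProteinRecord:
    """One protein entry from a source database.

    Parameters
    ----------
    record_id
        Non-empty database identifier.
    synonyms
        Alternative names/identifiers.
    sequence
        Amino-acid sequence; may be empty for records that cannot be
        sequence-matched.
    """

    record_id: str
    synonyms: list[str] = field(default_factory=list)
    sequence: str = ""

    def __post_init__(self) -> None:
        if not self.record_id:
            raise ValueError("record_id must be non-empty")
        seq = self.sequence.upper()
        if seq and not set(seq) <= _AA_LETTERS:
            bad = sorted(set(seq) - _AA_LETTERS)
            raise ValueError(f"sequence of {self.record_id!r} contains non amino-acid letters: {bad}")
        self.sequence = seq


@dataclass
class ScoredEdgeList:
    """Undirected scored edges with self-edges removed and duplicates collapsed."""

    edges: pd.DataFrame  # columns: node_a, node_b, score

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def node_ids(self) -> list[str]:
        """All node identifiers, lexicographically sorted."""
        nodes = pd.unique(pd.concat([self.edges["node_a"], self.edges["node_b"]], ignore_index=True))
        return sorted(nodes)


@dataclass
class InteractomeGraph:
    """Dichotomized interactome with its random-walk transition matrix.

    ``nodes`` fixes the (lexicographic) node order shared by ``adjacency``
    and ``transition``.  ``transition`` is row-stochastic; dangling nodes
    (degree zero after thresholding) carry a self-loop so probability mass
    is conserved.
    """

    nodes: list[str]
    adjacency: sp.csr_matrix
    threshold_used: int
    transition: sp.csr_matrix | None = None

    def __post_init__(self) -> None:
        self.index = {n: i for i, n in enumerate(self.nodes)}

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.nnz // 2)

    def degrees(self) -> np.ndarray:
        return np.asarray(self.adjacency.sum(axis=1)).ravel()

    def summary(self) -> dict:
        return {
            "nodes": self.n_nodes,
            "edges": self.n_edges,
            "threshold": self.threshold_used,
            "dangling_nodes": int((self.degrees() == 0).sum()),
        }

    def write_summary(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.summary(), indent=2) + "\n")


def _looks_numeric(value: str) -> bool:
    try:
        float(value)
    except (TypeError, ValueError):
        return False
    return True


def load_edge_list(path: str | Path, score_column: int | str = 2) -> ScoredEdgeList:
    """Read a STRING-style TSV edge list.

    The file must have >= 3 columns (node, node, score).  A header line is
    auto-detected by a non-numeric score cell.  Self-edges are dropped,
    duplicate undirected pairs collapse to their maximum score, and score
    columns on a [0, 1] scale are rescaled to 0-999 with a warning.

    Parameters
    ----------
    path
        TSV file path.
    score_column
        Column holding the confidence score, as an index or header name.

    Returns
    -------
    ScoredEdgeList

    Raises
    ------
    EdgeListError
        On an empty file or a malformed row (message names the line number).
    """
    path = Path(path)
    raw_lines = [ln for ln in path.read_text().splitlines()]
    lines = [(i + 1, ln) for i, ln in enumerate(raw_lines) if ln.strip()]
    if not lines:
        raise EdgeListError(f"{path}: empty edge-list file")

    first_fields = lines[0][1].split("\t")
    if len(first_fields) < 3:
        raise EdgeListError(f"{path}: line 1: expected >= 3 tab-separated columns")

    if isinstance(score_column, str):
        if score_column in first_fields:
            score_idx = first_fields.index(score_column)
        else:
            raise EdgeListError(f"{path}: score column {score_column!r} not found in header")
        has_header = True
    else:
        score_idx = int(score_column)
        has_header = not _looks_numeric(first_fields[score_idx]) if score_idx < len(first_fields) else True

    body = lines[1:] if has_header else lines
    if not body:
        raise EdgeListError(f"{path}: no data rows after header")

    rows: list[tuple[str, str, float]] = []
    n_self = 0
    for lineno, line in body:
        fields = line.split("\t")
        if len(fields) <= max(2, score_idx):
            raise EdgeListError(f"{path}: line {lineno}: expected >= {max(3, score_idx + 1)} columns, got {len(fields)}")
        a, b = fields[0].strip(), fields[1].strip()
        if not a or not b:
            raise EdgeListError(f"{path}: line {lineno}: empty node identifier")
        if not _looks_numeric(fields[score_idx]):
            raise EdgeListError(f"{path}: line {lineno}: non-numeric score {fields[score_idx]!r}")
        if a == b:
            n_self += 1
            continue
        rows.append((a, b, float(fields[score_idx])))

    if not rows:
        df = pd.DataFrame(columns=["node_a", "node_b", "score"])
        logger.info("load_edge_list: %d self-edges dropped, 0 edges kept", n_self)
        return ScoredEdgeList(df)

    df = pd.DataFrame(rows, columns=["node_a", "node_b", "score"])

    # 0-1 dialect tolerance: rescale to the canonical 0-999 integer range.
    if df["score"].max() <= 1.0:
        logger.warning("load_edge_list: scores on [0, 1] scale; rescaling to 0-999")
        df["score"] = df["score"] * 999.0
    df["score"] = df["score"].round().astype(int)
    if (df["score"] < 0).any() or (df["score"] > 999).any():
        bad = df.index[(df["score"] < 0) | (df["score"] > 999)][0]
        raise EdgeListError(f"{path}: score out of [0, 999] range on data row {bad + 1}")

    # canonical undirected orientation, then collapse duplicates keeping max score
    lo = df[["node_a", "node_b"]].min(axis=1)
    hi = df[["node_a", "node_b"]].max(axis=1)
    df["node_a"], df["node_b"] = lo, hi
    n_before = len(df)
    df = (
        df.groupby(["node_a", "node_b"], as_index=False, sort=True)["score"]
        .max()
    )
    n_dupes = n_before - len(df)
    logger.info(
        "load_edge_list: %d edges kept (%d self-edges dropped, %d duplicate pairs collapsed)",
        len(df), n_self, n_dupes,
    )
    return ScoredEdgeList(df.reset_index(drop=True))


def dichotomize(edges: ScoredEdgeList, threshold: int) -> InteractomeGraph:
    """Binary adjacency keeping edges with ``score >= threshold``.

    Nodes whose every edge falls below the threshold are retained as
    dangling nodes so the node list (and matrix indexing) is stable across
    thresholds.
    """
    if not 0 <= threshold <= 999:
        raise ValueError(f"threshold must be in [0, 999], got {threshold}")
    nodes = edges.node_ids()
    index = {n: i for i, n in enumerate(nodes)}
    kept = edges.edges[edges.edges["score"] >= threshold]
    ia = kept["node_a"].map(index).to_numpy()
    ib = kept["node_b"].map(index).to_numpy()
    n = len(nodes)
    data = np.ones(len(kept), dtype=np.float64)
    adj = sp.coo_matrix((data, (ia, ib)), shape=(n, n))
    adj = adj + adj.T
    return InteractomeGraph(nodes=nodes, adjacency=adj.tocsr(), threshold_used=int(threshold))


def build_transition_matrix(graph: InteractomeGraph) -> InteractomeGraph:
    """Fill ``graph.transition`` with the row-stochastic walk matrix.

    ``W[a, b] = 1 / degree(a)`` for each neighbour *b*; a dangling node
    gets ``W[a, a] = 1`` so every row sums to exactly 1.
    """
    deg = graph.degrees()
    dangling = deg == 0
    inv = np.zeros_like(deg)
    inv[~dangling] = 1.0 / deg[~dangling]
    W = sp.diags(inv) @ graph.adjacency
    if dangling.any():
        idx = np.flatnonzero(dangling)
        loops = sp.coo_matrix(
            (np.ones(len(idx)), (idx, idx)), shape=W.shape
        )
        W = W + loops
    graph.transition = W.tocsr()
    return graph


def build_graph(edges: ScoredEdgeList, threshold: int) -> InteractomeGraph:
    """Convenience: dichotomize then build the transition matrix."""
    return build_transition_matrix(dichotomize(edges, threshold))


# ---------------------------------------------------------------------------
# Sequence-based record matching
# ---------------------------------------------------------------------------

def _mismatch_fraction(seq_a: str, seq_b: str) -> float:
    """Best-alignment mismatch count divided by the shorter sequence length.

    The shorter sequence is aligned as an infix of the longer one (gaps at
    either end of the longer sequence are free), which covers both the
    ungapped best-offset case and near-containment with internal edits.
    """
    short, long_ = (seq_a, seq_b) if len(seq_a) <= len(seq_b) else (seq_b, seq_a)
    dist = edlib.align(short, long_, mode="HW", task="distance")["editDistance"]
    return dist / len(short)


def load_protein_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read protein records from a FASTA file (id = first header token)."""
    from Bio import SeqIO

    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        synonyms = rec.description.split()[1:]
        records.append(ProteinRecord(record_id=rec.id, synonyms=synonyms, sequence=str(rec.seq)))
    return records


def match_protein_records(
    left: Sequence[ProteinRecord],
    right: Sequence[ProteinRecord],
    max_mismatch_frac: float = 0.05,
) -> pd.DataFrame:
    """Reconcile two protein record sets by amino-acid sequence.

    Three sequential tiers are applied; a record matched in an earlier tier
    is excluded from later ones:

    1. ``exact`` — identical sequences;
    2. ``substring`` — one sequence a contiguous slice of the other;
    3. ``fuzzy`` — best infix alignment with mismatch fraction (relative to
       the shorter sequence) at most ``max_mismatch_frac``.

    Left records that no tier matches are reported with tier ``unmatched``.

    Returns
    -------
    pandas.DataFrame
        Columns ``left_id, right_id, tier, mismatch_frac``; one row per
        left record, deterministic order.
    """
    for side_name, side in (("left", left), ("right", right)):
        ids = [r.record_id for r in side]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate record_id on {side_name} side: {dupes}")

    left = sorted(left, key=lambda r: r.record_id)
    right_sorted = sorted(right, key=lambda r: r.record_id)
    taken: set[str] = set()
    out: dict[str, tuple[str | None, str, float]] = {}

    # tier 1: exact sequence equality
    by_seq: dict[str, list[ProteinRecord]] = {}
    for r in right_sorted:
        if r.sequence:
            by_seq.setdefault(r.sequence, []).append(r)
    for l in left:
        if not l.sequence:
            continue
        for cand in by_seq.get(l.sequence, []):
            if cand.record_id not in taken:
                taken.add(cand.record_id)
                out[l.record_id] = (cand.record_id, "exact", 0.0)
                break

    # tier 2: contiguous containment
    for l in left:
        if l.record_id in out or not l.sequence:
            continue
        for cand in right_sorted:
            if cand.record_id in taken or not cand.sequence:
                continue
            if l.sequence in cand.sequence or cand.sequence in l.sequence:
                taken.add(cand.record_id)
                out[l.record_id] = (cand.record_id, "substring", 0.0)
                break

    # tier 3: fuzzy alignment, best (lowest) mismatch fraction wins
    for l in left:
        if l.record_id in out or not l.sequence:
            continue
        best: tuple[float, str] | None = None
        for cand in right_sorted:
            if cand.record_id in taken or not cand.sequence:
                continue
            frac = _mismatch_fraction(l.sequence, cand.sequence)
            if frac <= max_mismatch_frac and (best is None or frac < best[0]):
                best = (frac, cand.record_id)
        if best is not None:
            taken.add(best[1])
            out[l.record_id] = (best[1], "fuzzy", best[0])

    rows = []
    for l in left:
        rid, tier, frac = out.get(l.record_id, (None, "unmatched", float("nan")))
        rows.append((l.record_id, rid, tier, frac))
    return pd.DataFrame(rows, columns=["left_id", "right_id", "tier", "mismatch_frac"])
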