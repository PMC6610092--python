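"""Grid search over preprocessing/propagation/classifier settings with
stratified nested cross-validation, top-model selection and ensemble ACL
prediction.

One *grid point* fixes a gene-gene edge threshold, a compound-gene target
threshold, a restart probability ``c``, the log-transform flag and a
classifier kind.  Each point is scored by 10-fold outer / 5-fold inner
nested cross-validation: inner folds pick the classifier hyperparameter by
mean inner F1, outer folds estimate the generalisation F1 of that choice,
and the final model is refit on the full set with the averaged best
hyperparameter.  The best models (F1 above a cutoff, or a top-n) form an
ensemble whose mean calibrated probability is a compound's anti-cancer
likeness (ACL).

Fold assignments, hyperparameter choices and tie-breaks are all functions
of one integer seed, so identical runs are bitwise reproducible.
"""

from __future__ import annotations

import hashlib
import itertools
import json
import logging
import statistics
from dataclasses import dataclass, field, asdict
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .classification import (
    LabeledProfileMatrix,
    TrainedClassifier,
    f_score,
    fit_linear_svm,
    fit_mmc,
    wrap_mmc,
)
from .interactome import (
    GENE_GENE_THRESHOLDS,
    InteractomeGraph,
    ScoredEdgeList,
    build_graph,
)
from .propagation import (
    C_GRID,
    CLOSED_FORM_MAX_NODES,
    PropagationParams,
    propagate_batch,
)
from .target_profiles import (
    DRUG_GENE_THRESHOLDS,
    CompoundTargets,
    NoEntryPointsError,
    build_seed_vector,
    filter_targets,
    log_transform,
)

logger = logging.getLogger(__name__)

ClassifierKind = Literal["linear_svm", "mmc"]

#: Inner-CV hyperparameter grids.
SVM_C_GRID = (0.01, 0.1, 1.0, 10.0, 100.0)
MMC_K_GRID = (1, 2, 3)


@dataclass(frozen=True)
class GridSettings:
    """One point of the model-selection grid."""

    gene_gene_threshold: int
    drug_gene_threshold: int
    c: float
    log_transform: bool
    classifier: ClassifierKind

    def settings_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class ParameterGrid:
    """Cartesian grid of pipeline settings.

    Defaults are the canonical threshold/restart grids; classifier kinds
    default to both linear strategies.
    """

    gene_gene_thresholds: Sequence[int] = GENE_GENE_THRESHOLDS
    drug_gene_thresholds: Sequence[int] = DRUG_GENE_THRESHOLDS
    c_values: Sequence[float] = C_GRID
    log_transform: Sequence[bool] = (True, False)
    classifier_kinds: Sequence[ClassifierKind] = ("linear_svm", "mmc")

    def __post_init__(self) -> None:
        for name in ("gene_gene_thresholds", "drug_gene_thresholds", "c_values",
                     "log_transform", "classifier_kinds"):
            if not list(getattr(self, name)):
                raise ValueError(f"grid list {name} must be non-empty")

    def points(self) -> list[GridSettings]:
        return [
            GridSettings(gg, dg, c, lt, clf)
            for gg, dg, c, lt, clf in itertools.product(
                self.gene_gene_thresholds, self.drug_gene_thresholds,
                self.c_values, self.log_transform, self.classifier_kinds,
            )
        ]

    def __len__(self) -> int:
        return len(self.points())


# ---------------------------------------------------------------------------
# Feature construction with caching
# ---------------------------------------------------------------------------

class PipelineData:
    """Input edge list + compound targets, with graph/profile caches.

    Profiles are cached keyed by (gene-gene threshold, drug-gene threshold,
    c); the log-transform is applied on read, so two grid points differing
    only in the log flag share one propagation.
    """

    def __init__(self, edges: ScoredEdgeList, compounds: Sequence[CompoundTargets]):
        self.edges = edges
        self.compounds = list(compounds)
        self._graphs: dict[int, InteractomeGraph] = {}
        self._profiles: dict[tuple[int, int, float], tuple[list[str], np.ndarray]] = {}

    def graph(self, gene_gene_threshold: int) -> InteractomeGraph:
        if gene_gene_threshold not in self._graphs:
            self._graphs[gene_gene_threshold] = build_graph(self.edges, gene_gene_threshold)
        return self._graphs[gene_gene_threshold]

    def _propagate_compounds(
        self,
        compounds: Sequence[CompoundTargets],
        gene_gene_threshold: int,
        drug_gene_threshold: int,
        c: float,
    ) -> tuple[list[str], np.ndarray]:
        """Propagate every usable compound; returns (usable ids, profile matrix)."""
        graph = self.graph(gene_gene_threshold)
        seeds, usable = [], []
        for ct in compounds:
            ft = filter_targets(ct, drug_gene_threshold)
            try:
                seeds.append(build_seed_vector(ft, graph))
                usable.append(ct.compound_id)
            except NoEntryPointsError:
                continue
        if not seeds:
            return [], np.zeros((0, graph.n_nodes))
        method = "closed_form" if graph.n_nodes <= CLOSED_FORM_MAX_NODES else "iterative"
        batch = propagate_batch(seeds, graph, PropagationParams(c=c), method=method)
        rows, kept = [], []
        for cid, prof in zip(usable, batch.profiles):
            if prof is not None:
                rows.append(prof.values)
                kept.append(cid)
        return kept, np.vstack(rows)

    def profiles(self, settings: GridSettings) -> tuple[list[str], np.ndarray]:
        """Propagated (and optionally log-transformed) profiles of the
        labeled training compounds under one grid point."""
        key = (settings.gene_gene_threshold, settings.drug_gene_threshold, settings.c)
        if key not in self._profiles:
            labeled = [ct for ct in self.compounds if ct.label in ("positive", "negative")]
            self._profiles[key] = self._propagate_compounds(labeled, *key)
        ids, X = self._profiles[key]
        if settings.log_transform:
            X = log_transform(X)
        return ids, X

    def labeled_matrix(self, settings: GridSettings) -> LabeledProfileMatrix:
        ids, X = self.profiles(settings)
        labels = {ct.compound_id: ct.label for ct in self.compounds}
        y = np.array([1 if labels[c] == "positive" else 0 for c in ids], dtype=int)
        graph = self.graph(settings.gene_gene_threshold)
        return LabeledProfileMatrix(X=X, y=y, compound_ids=list(ids), gene_ids=list(graph.nodes))


# ---------------------------------------------------------------------------
# Nested cross-validation
# ---------------------------------------------------------------------------

@dataclass
class ModelRecord:
    """One evaluated grid point: CV scores, fold bookkeeping, final model."""

    settings: GridSettings
    outer_cv_f1: float
    outer_f1_per_fold: list[float]
    per_class_accuracy: dict[str, float]
    best_inner_hyperparams: dict
    trained_final: TrainedClassifier
    fold_log: list[dict]
    n_compounds: int
    oof_probability: np.ndarray | None = None  # out-of-fold ACL per compound


@dataclass
class EnsembleModel:
    """Top models kept for ACL averaging, sorted by outer-CV F1."""

    members: list[ModelRecord]
    selection_rule: dict

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("ensemble must have at least one member")


def _fit_one(
    data: LabeledProfileMatrix, kind: ClassifierKind, hyper: float | int, seed: int
) -> TrainedClassifier:
    if kind == "linear_svm":
        return fit_linear_svm(data, C=float(hyper), seed=seed)
    model = fit_mmc(data, k=int(hyper))
    return wrap_mmc(model, data.n_genes)


def _hyper_grid(kind: ClassifierKind) -> Sequence[float | int]:
    return SVM_C_GRID if kind == "linear_svm" else MMC_K_GRID


def _average_hyper(kind: ClassifierKind, values: list[float | int]) -> float | int:
    if kind == "linear_svm":
        # C lives on a log scale; the geometric mean is the natural average
        return float(np.exp(np.mean(np.log(values))))
    return int(round(statistics.median(values)))


def nested_cross_validate(
    data: LabeledProfileMatrix,
    settings: GridSettings,
    seed: int = 0,
    n_outer: int = 10,
    n_inner: int = 5,
) -> ModelRecord:
    """Stratified nested CV for one grid point.

    Outer folds (stratified, shuffled by ``seed``) estimate the F1 of the
    hyperparameter choice made by the inner folds, which only ever see the
    outer training split.  The final model is refit on all compounds with
    the averaged best hyperparameter.
    """
    y = data.y
    n_pos, n_neg = int((y == 1).sum()), int((y == 0).sum())
    if min(n_pos, n_neg) < n_outer:
        raise ValueError(
            f"need >= {n_outer} samples per class to stratify {n_outer} outer folds; "
            f"got {n_pos} positive / {n_neg} negative"
        )
    kind = settings.classifier
    grid = _hyper_grid(kind)
    outer = StratifiedKFold(n_splits=n_outer, shuffle=True, random_state=seed % (2**31))

    fold_log: list[dict] = []
    outer_f1, best_hypers = [], []
    accs_pos, accs_neg = [], []
    oof = np.full(len(y), np.nan)

    for fold_i, (tr, te) in enumerate(outer.split(data.X, y)):
        inner_seed = (seed * 1009 + fold_i) % (2**31)
        inner = StratifiedKFold(n_splits=n_inner, shuffle=True, random_state=inner_seed)
        X_tr, y_tr = data.X[tr], y[tr]
        inner_log = []
        mean_inner_f1 = {}
        for hyper in grid:
            scores = []
            for itr, ival in inner.split(X_tr, y_tr):
                sub = LabeledProfileMatrix(
                    X_tr[itr], y_tr[itr],
                    [data.compound_ids[i] for i in tr[itr]], data.gene_ids,
                )
                clf = _fit_one(sub, kind, hyper, inner_seed)
                pred = (clf.predict_acl(X_tr[ival]) > 0.5).astype(int)
                scores.append(f_score(y_tr[ival], pred)["f1"])
                if hyper == grid[0]:
                    inner_log.append({
                        "train_index": tr[itr].tolist(),
                        "val_index": tr[ival].tolist(),
                    })
            mean_inner_f1[hyper] = float(np.mean(scores))
        # first grid entry wins ties (deterministic)
        best = max(grid, key=lambda h: mean_inner_f1[h])
        best_hypers.append(best)

        outer_data = LabeledProfileMatrix(
            X_tr, y_tr, [data.compound_ids[i] for i in tr], data.gene_ids
        )
        clf = _fit_one(outer_data, kind, best, inner_seed)
        prob = clf.predict_acl(data.X[te])
        oof[te] = prob
        pred = (prob > 0.5).astype(int)
        metrics = f_score(y[te], pred)
        outer_f1.append(metrics["f1"])
        accs_pos.append(metrics["accuracy_positive"])
        accs_neg.append(metrics["accuracy_negative"])
        fold_log.append({
            "outer_fold": fold_i,
            "train_index": tr.tolist(),
            "test_index": te.tolist(),
            "inner_folds": inner_log,
            "best_hyper": best,
            "inner_mean_f1": {str(k): v for k, v in mean_inner_f1.items()},
        })

    avg_hyper = _average_hyper(kind, best_hypers)
    final = _fit_one(data, kind, avg_hyper, seed % (2**31))
    hyper_name = "C" if kind == "linear_svm" else "k"
    return ModelRecord(
        settings=settings,
        outer_cv_f1=float(np.mean(outer_f1)),
        outer_f1_per_fold=[float(v) for v in outer_f1],
        per_class_accuracy={
            "positive": float(np.nanmean(accs_pos)),
            "negative": float(np.nanmean(accs_neg)),
        },
        best_inner_hyperparams={
            "per_fold": best_hypers, hyper_name: avg_hyper,
        },
        trained_final=final,
        fold_log=fold_log,
        n_compounds=len(y),
        oof_probability=oof,
    )


# ---------------------------------------------------------------------------
# Grid orchestration
# ---------------------------------------------------------------------------

@dataclass
class GridResult:
    records: list[ModelRecord]
    failures: dict[str, str] = field(default_factory=dict)  # settings hash -> reason


def run_grid(
    data: PipelineData, grid: ParameterGrid, seed: int = 0
) -> GridResult:
    """Evaluate every grid point with nested CV; failures are recorded and
    the grid continues.  Propagation results are cached across points that
    share (thresholds, c)."""
    records, failures = [], {}
    for point in grid.points():
        try:
            matrix = data.labeled_matrix(point)
            records.append(nested_cross_validate(matrix, point, seed=seed))
        except Exception as exc:  # noqa: BLE001 — grid contract: record, continue
            failures[point.settings_hash()] = f"{point}: {exc}"
            logger.warning("grid point failed: %s: %s", point, exc)
    return GridResult(records=records, failures=failures)


def results_table(records: Sequence[ModelRecord]) -> pd.DataFrame:
    """Flat results table: one row per grid point per classifier."""
    rows = []
    for r in records:
        s = r.settings
        rows.append({
            "gene_gene_threshold": s.gene_gene_threshold,
            "drug_gene_threshold": s.drug_gene_threshold,
            "c": s.c,
            "log_transform": s.log_transform,
            "classifier": s.classifier,
            "outer_cv_f1": r.outer_cv_f1,
            "accuracy_positive": r.per_class_accuracy["positive"],
            "accuracy_negative": r.per_class_accuracy["negative"],
            "n_compounds": r.n_compounds,
            "settings_hash": s.settings_hash(),
        })
    return pd.DataFrame(rows)


def select_models(
    records: Sequence[ModelRecord],
    min_f1: float | None = 0.84,
    top_n: int | None = None,
) -> EnsembleModel:
    """Keep the best models for the prediction ensemble.

    Default rule: every model with outer-CV F1 >= 0.84.  ``top_n`` keeps the
    n highest-F1 models instead.  Ties are broken by settings hash so the
    selection is deterministic.
    """
    if not records:
        raise ValueError("no model records to select from")
    ordered = sorted(
        records, key=lambda r: (-r.outer_cv_f1, r.settings.settings_hash())
    )
    if top_n is not None:
        members = ordered[:top_n]
        rule = {"top_n": top_n}
    else:
        members = [r for r in ordered if r.outer_cv_f1 >= min_f1]
        rule = {"min_f1": min_f1}
        if not members:
            best = ordered[0].outer_cv_f1
            raise ValueError(
                f"no model reaches F1 >= {min_f1} (best is {best:.3f}); "
                "relax min_f1 or use top_n selection"
            )
    return EnsembleModel(members=members, selection_rule=rule)


def ensemble_predict_acl(
    ensemble: EnsembleModel,
    compounds: Sequence[CompoundTargets],
    data: PipelineData,
) -> pd.DataFrame:
    """Mean calibrated probability across ensemble members.

    Each member scores a compound in its *own* feature space (its graph,
    thresholds, c and log flag).  Members under which the compound has no
    entry points are skipped; a compound unusable under every member gets a
    missing ACL with the reason recorded.

    Returns
    -------
    pandas.DataFrame
        Columns ``compound_id, acl, n_members, sd, reason``.
    """
    per_member: list[dict[str, float]] = []
    for member in ensemble.members:
        s = member.settings
        ids, X = data._propagate_compounds(
            compounds, s.gene_gene_threshold, s.drug_gene_threshold, s.c
        )
        if len(ids) == 0:
            per_member.append({})
            continue
        if s.log_transform:
            X = log_transform(X)
        probs = member.trained_final.predict_acl(X)
        per_member.append(dict(zip(ids, probs)))

    rows = []
    for ct in compounds:
        vals = [m[ct.compound_id] for m in per_member if ct.compound_id in m]
        if vals:
            arr = np.array(vals)
            rows.append((ct.compound_id, float(arr.mean()), len(vals),
                         float(arr.std(ddof=0)), ""))
        else:
            rows.append((ct.compound_id, np.nan, 0, np.nan,
                         "no entry points under any ensemble member"))
    return pd.DataFrame(rows, columns=["compound_id", "acl", "n_members", "sd", "reason"])
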