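"""Stratified 5-fold cross-validation under three screening scenarios.

* ``per_target`` — an independent stratified 5-fold CV inside every single
  target, training one scorer per target per fold (the tailored-model
  scenario);
* ``horizontal`` — one shared fold assignment stratified within every
  target, so each target contributes ligands to both train and test folds
  (the established-target scenario);
* ``vertical`` — whole targets are dealt round-robin into folds, so train
  and test never share a target (the novel-target scenario).

Stratification is per target and per class: within each target the
actives and the inactives are shuffled separately and dealt into the k
folds, so every fold's active fraction matches the target's overall
fraction to within one molecule.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datasets import ScreeningDataset
from .metrics import enrichment_factor, rank_entries, roc_auc
from .model import ModelSpec, TrainedScorer, score, train

logger = logging.getLogger(__name__)

SCHEMES = ("per_target", "horizontal", "vertical")


@dataclass(frozen=True)
class FoldAssignment:
    scheme: str
    k: int
    seed: int
    assignment: dict  # (target_id, molecule_id) -> fold index

    def fold_array(self, dataset: ScreeningDataset) -> np.ndarray:
        keys = zip(dataset.records["target_id"], dataset.records["molecule_id"])
        return np.array([self.assignment[key] for key in keys], dtype=int)


def make_folds(
    dataset: ScreeningDataset,
    scheme: str,
    k: int = 5,
    seed: int = 0,
) -> FoldAssignment:
    """Deterministic stratified fold assignment for a dataset.

    Vertical requires at least k targets.  For the within-target schemes a
    target with fewer than k actives is assigned anyway with a warning
    (some folds then hold no active of that target).
    """
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; expected one of {SCHEMES}")
    if len(dataset) == 0:
        raise ValueError("empty dataset")
    rng = np.random.default_rng(seed)
    rec = dataset.records
    targets = dataset.targets
    assignment: dict = {}

    if scheme == "vertical":
        if len(targets) < k:
            raise ValueError(
                f"vertical split needs at least k={k} targets, got {len(targets)}"
            )
        order = list(rng.permutation(targets))
        fold_of_target = {t: i % k for i, t in enumerate(order)}
        for t, m in zip(rec["target_id"], rec["molecule_id"]):
            assignment[(t, m)] = fold_of_target[t]
    else:
        for t in targets:
            sub = rec[rec["target_id"] == t]
            n_act = int(sub["is_active"].sum())
            if n_act < k:
                logger.warning(
                    "target %s has only %d actives for k=%d folds", t, n_act, k
                )
            for cls in (True, False):
                mols = sub.loc[sub["is_active"] == cls, "molecule_id"].to_numpy()
                mols = rng.permutation(mols)
                offset = int(rng.integers(k))
                for i, m in enumerate(mols):
                    assignment[(t, m)] = (i + offset) % k
    return FoldAssignment(scheme, k, seed, assignment)


@dataclass
class CVResult:
    scheme: str
    k: int
    seed: int
    predictions: pd.DataFrame  # target_id, molecule_id, fold, pk, is_active, y_pred
    fold_metrics: pd.DataFrame  # fold, target_id, ef1, ef01, auc
    summary: dict  # mean ± sd of per-fold means

    def fold_means(self) -> pd.DataFrame:
        """Per-fold metric means over targets (undefined metrics dropped)."""
        return self.fold_metrics.groupby("fold")[["ef1", "ef01", "auc"]].mean()


def _evaluate_fold(sub: pd.DataFrame, fold: int, seed: int) -> list[dict]:
    """Per-target EF1%, EF0.1% and AUC for one fold's predictions."""
    rows = []
    for j, (t, tsub) in enumerate(sub.groupby("target_id", sort=True)):
        ranked = rank_entries(
            tsub["molecule_id"],
            tsub["y_pred"],
            tsub["is_active"],
            pk=tsub["pk"],
            seed=seed * 1000 + fold * 37 + j,
        )
        ef1 = enrichment_factor(ranked, 0.01)
        ef01 = enrichment_factor(ranked, 0.001)
        auc = roc_auc(ranked)
        if ef1 is None:
            logger.warning("fold %d target %s has no actives; EF undefined", fold, t)
        rows.append(
            {"fold": fold, "target_id": t,
             "ef1": np.nan if ef1 is None else ef1,
             "ef01": np.nan if ef01 is None else ef01,
             "auc": np.nan if auc is None else auc}
        )
    return rows


def run_cv(
    dataset: ScreeningDataset,
    scheme: str,
    spec: ModelSpec,
    k: int = 5,
    seed: int = 0,
) -> CVResult:
    """Train/test over the k folds and pool out-of-fold predictions.

    Horizontal and vertical train one scorer per fold on everything
    outside the fold; per_target runs the fold loop independently inside
    every target, one scorer per (target, fold).  Metrics are computed per
    target within each fold, averaged to a fold value, then summarised as
    mean ± sd over folds.
    """
    fa = make_folds(dataset, scheme, k, seed)
    folds = fa.fold_array(dataset)
    y_pred = np.full(len(dataset), np.nan)

    if scheme == "per_target":
        target_arr = dataset.records["target_id"].to_numpy()
        for t in dataset.targets:
            t_mask = target_arr == t
            for f in range(k):
                tr = t_mask & (folds != f)
                te = t_mask & (folds == f)
                if not te.any():
                    continue
                scorer = train(dataset.subset(tr), spec)
                y_pred[te] = score(scorer, dataset.features[te])
    else:
        for f in range(k):
            tr, te = folds != f, folds == f
            if not te.any():
                continue
            scorer = train(dataset.subset(tr), spec)
            y_pred[te] = score(scorer, dataset.features[te])

    predictions = dataset.records[
        ["target_id", "molecule_id", "pk", "is_active"]
    ].copy()
    predictions["fold"] = folds
    predictions["y_pred"] = y_pred

    metric_rows = []
    for f in range(k):
        sub = predictions[predictions["fold"] == f]
        if len(sub):
            metric_rows.extend(_evaluate_fold(sub, f, seed))
    fold_metrics = pd.DataFrame(
        metric_rows, columns=["fold", "target_id", "ef1", "ef01", "auc"]
    )
    per_fold = fold_metrics.groupby("fold")[["ef1", "ef01", "auc"]].mean()
    summary = {}
    for col in ("ef1", "ef01", "auc"):
        vals = per_fold[col].dropna()
        summary[f"{col}_mean"] = float(vals.mean()) if len(vals) else np.nan
        summary[f"{col}_sd"] = float(vals.std(ddof=1)) if len(vals) > 1 else np.nan
    return CVResult(scheme, k, seed, predictions, fold_metrics, summary)
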