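"""Random-forest regression scorer.

The scorer regresses pK on the contact descriptors with a 500-tree forest
(fully grown trees, bootstrap sampling).  The per-split feature count
(mtry) defaults to the published values — 15 for the 36/42-feature v1/v3
descriptors and 100 for the 216-feature v2 — and can instead be selected
on a grid by out-of-bag mean-squared error.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
from sklearn.ensemble import RandomForestRegressor

from .datasets import ScreeningDataset

#: published mtry defaults per descriptor version
DEFAULT_MTRY = {"v1": 15, "v2": 100, "v3": 15}

#: OOB search grids used in "auto" mode (the narrow-descriptor grid caps
#: at the full 36-count block)
DEFAULT_MTRY_GRID = {
    "v1": (5, 10, 15, 25, 36),
    "v2": (25, 50, 100, 150),
    "v3": (5, 10, 15, 25, 36),
}

_SCHEMA_VERSION = 1


class ModelIntegrityError(RuntimeError):
    """Raised when a persisted model fails its integrity checks."""


@dataclass(frozen=True)
class ModelSpec:
    n_trees: int = 500
    mtry: int | str = "auto"
    mtry_grid: tuple[int, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees <= 0:
            raise ValueError("n_trees must be positive")
        if isinstance(self.mtry, str) and self.mtry != "auto":
            raise ValueError("mtry must be a positive integer or 'auto'")
        if isinstance(self.mtry, int) and self.mtry <= 0:
            raise ValueError("mtry must be positive")


def spec_for_version(version: str, *, n_trees: int = 500, seed: int = 0,
                     mtry: int | str | None = None) -> ModelSpec:
    """ModelSpec with the published defaults for a descriptor version."""
    return ModelSpec(
        n_trees=n_trees,
        mtry=DEFAULT_MTRY[version] if mtry is None else mtry,
        mtry_grid=DEFAULT_MTRY_GRID[version],
        seed=seed,
    )


@dataclass
class TrainedScorer:
    model: RandomForestRegressor
    feature_version: str
    feature_names: tuple[str, ...]
    spec: ModelSpec
    metadata: dict


def _resolve_xy(data, features=None):
    if isinstance(data, ScreeningDataset):
        return (
            data.features,
            data.records["pk"].to_numpy(dtype=float),
            data.feature_names,
            data.feature_version,
        )
    X = np.asarray(data, dtype=float)
    y = np.asarray(features, dtype=float)
    return X, y, None, None


def select_mtry(
    X: np.ndarray,
    y: np.ndarray,
    spec: ModelSpec,
    grid: Sequence[int] | None = None,
) -> int:
    """Pick mtry from a grid by minimum out-of-bag MSE (ties → smallest)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    grid = tuple(grid if grid is not None else (spec.mtry_grid or ()))
    if not grid:
        raise ValueError("empty mtry grid")
    n_features = X.shape[1]
    bad = [m for m in grid if m > n_features]
    if bad:
        raise ValueError(f"grid values {bad} exceed the feature count {n_features}")
    best_mtry, best_mse = None, np.inf
    for m in sorted(grid):
        forest = RandomForestRegressor(
            n_estimators=spec.n_trees,
            max_features=m,
            oob_score=True,
            bootstrap=True,
            random_state=spec.seed,
            n_jobs=1,
        ).fit(X, y)
        oob = forest.oob_prediction_
        mse = float(np.mean((oob - y) ** 2))
        if mse < best_mse:
            best_mtry, best_mse = m, mse
    return int(best_mtry)


def train(
    data: ScreeningDataset | np.ndarray,
    spec: ModelSpec,
    y: np.ndarray | None = None,
    *,
    feature_version: str = "v1",
    feature_names: Sequence[str] | None = None,
) -> TrainedScorer:
    """Fit the forest on a dataset (or a raw X, y pair).

    The regression target is pK.  Deterministic given ``spec.seed``.
    """
    X, target, ds_names, ds_version = _resolve_xy(data, y)
    names = tuple(ds_names or feature_names or (f"f{i}" for i in range(X.shape[1])))
    version = ds_version or feature_version
    if len(np.unique(target)) < 2:
        raise ValueError("degenerate labels: at least 2 distinct pK values required")
    if not np.isfinite(X).all():
        raise ValueError("features must be finite")

    mtry = spec.mtry
    if mtry == "auto":
        grid = spec.mtry_grid or DEFAULT_MTRY_GRID.get(version, (5, 10, 15, 25, 36))
        grid = tuple(m for m in grid if m <= X.shape[1]) or (X.shape[1],)
        mtry = select_mtry(X, target, spec, grid)
    if mtry > X.shape[1]:
        raise ValueError(f"mtry {mtry} exceeds feature count {X.shape[1]}")

    forest = RandomForestRegressor(
        n_estimators=spec.n_trees,
        max_features=mtry,
        bootstrap=True,
        random_state=spec.seed,
        n_jobs=1,
    ).fit(X, target)

    is_active = (
        data.records["is_active"].to_numpy()
        if isinstance(data, ScreeningDataset)
        else None
    )
    metadata = {
        "n_records": int(len(target)),
        "n_active": int(is_active.sum()) if is_active is not None else None,
        "n_inactive": int((~is_active).sum()) if is_active is not None else None,
        "mtry": int(mtry),
        "seed": spec.seed,
        "trained_at": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "label_range": (float(target.min()), float(target.max())),
    }
    return TrainedScorer(forest, version, names, replace(spec, mtry=int(mtry)), metadata)


def score(
    scorer: TrainedScorer,
    features: np.ndarray | ScreeningDataset,
    feature_names: Sequence[str] | None = None,
) -> np.ndarray:
    """Predicted pK per record, order-preserving.

    Feature names (when supplied or carried by a dataset) must match the
    training names exactly and in order.
    """
    if isinstance(features, ScreeningDataset):
        feature_names = features.feature_names
        features = features.features
    if feature_names is not None:
        given = tuple(feature_names)
        if given != tuple(scorer.feature_names):
            for i, (a, b) in enumerate(zip(given, scorer.feature_names)):
                if a != b:
                    raise ValueError(
                        f"feature name mismatch at column {i}: got {a!r}, model "
                        f"expects {b!r}"
                    )
            raise ValueError(
                f"feature count mismatch: got {len(given)}, model expects "
                f"{len(scorer.feature_names)}"
            )
    X = np.asarray(features, dtype=float)
    if X.size == 0:
        return np.zeros(0)
    return scorer.model.predict(X)


def save_model(scorer: TrainedScorer, path) -> None:
    """Persist with a schema header and the feature-name list."""
    payload = {
        "schema_version": _SCHEMA_VERSION,
        "feature_version": scorer.feature_version,
        "feature_names": list(scorer.feature_names),
        "spec": scorer.spec,
        "metadata": scorer.metadata,
        "model": scorer.model,
    }
    joblib.dump(payload, path)


def load_model(path, expect_version: str | None = None, *, force: bool = False) -> TrainedScorer:
    """Load a persisted scorer, verifying schema and descriptor version."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.stat().st_size == 0:
        raise ModelIntegrityError(f"model file {path} is empty")
    try:
        payload = joblib.load(path)
    except Exception as exc:
        raise ModelIntegrityError(f"cannot load model file {path}: {exc}") from exc
    if not isinstance(payload, dict) or payload.get("schema_version") != _SCHEMA_VERSION:
        raise ModelIntegrityError(f"model file {path} has an unknown schema")
    version = payload["feature_version"]
    if expect_version is not None and version != expect_version and not force:
        raise ValueError(
            f"model was trained on {version} features but {expect_version} was "
            "requested (pass force=True to override)"
        )
    return TrainedScorer(
        model=payload["model"],
        feature_version=version,
        feature_names=tuple(payload["feature_names"]),
        spec=payload["spec"],
        metadata=payload["metadata"],
    )
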