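"""Synthetic labeled mixed-type tables with controllable class separation.

The generator emulates EHR-style inputs: Gaussian class blobs for the
numeric block, class-conditional categorical columns, an id column, a
discrete target, and uniformly injected missing cells.  Class centroids sit
at the vertices of a regular simplex scaled so every pairwise centroid
distance equals ``separation`` (in units of the unit within-class standard
deviation), giving symmetric multi-class control.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd


class SyntheticDataError(ValueError):
    """Infeasible blob specification."""


@dataclass
class BlobSpec:
    """Parameters of one synthetic labeled table."""

    n_rows: int = 500
    n_numeric: int = 5
    n_classes: int = 2
    separation: float = 1.0
    class_proportions: Optional[Sequence[float]] = None
    n_categorical: int = 0
    categories_per_column: int = 3
    missing_fraction: float = 0.0
    include_id: bool = True
    seed: int = 0

    def proportions(self) -> np.ndarray:
        if self.class_proportions is None:
            return np.full(self.n_classes, 1.0 / self.n_classes)
        p = np.asarray(self.class_proportions, dtype=float)
        if len(p) != self.n_classes or (p < 0).any() or abs(p.sum() - 1) > 1e-9:
            raise SyntheticDataError(
                "class_proportions must be a simplex vector of length n_classes"
            )
        return p


def simplex_centroids(n_classes: int, n_dims: int, separation: float) -> np.ndarray:
    """Centroids with all pairwise distances equal to ``separation``.

    A regular simplex with c vertices needs c-1 dimensions, so
    ``n_dims >= n_classes - 1`` is required; extra dimensions are padded
    with zeros.
    """
    c = int(n_classes)
    if c < 1:
        raise SyntheticDataError("need at least one class")
    if n_dims < c - 1:
        raise SyntheticDataError(
            f"{c} classes need at least {c - 1} numeric dimensions"
        )
    if c == 1:
        return np.zeros((1, n_dims))
    # scaled identity vertices have pairwise distance `separation`;
    # center and rotate into the first c-1 coordinates
    V = np.eye(c) * (float(separation) / np.sqrt(2.0))
    V = V - V.mean(axis=0)
    _, s, vt = np.linalg.svd(V, full_matrices=False)
    coords = V @ vt[: c - 1].T
    out = np.zeros((c, n_dims))
    out[:, : c - 1] = coords
    return out


def generate_table(spec: BlobSpec) -> pd.DataFrame:
    """Draw one table: columns ``id`` (optional), ``num_*``, ``cat_*``, ``target``.

    Numeric features are unit-variance Gaussians around the class centroid;
    categorical features follow class-conditional Dirichlet-drawn category
    distributions (sharper for well-separated specs); missing cells are
    injected uniformly at ``missing_fraction`` into feature columns only,
    never into the id or target.  Fully deterministic given ``spec.seed``.
    """
    if spec.n_rows < spec.n_classes:
        raise SyntheticDataError("n_rows must be >= n_classes")
    if not (0 <= spec.missing_fraction < 1):
        raise SyntheticDataError("missing_fraction must lie in [0, 1)")
    if spec.n_categorical and spec.categories_per_column < 2:
        raise SyntheticDataError("categories_per_column must be >= 2")
    rng = np.random.default_rng(int(spec.seed))
    p = spec.proportions()
    labels = rng.choice(spec.n_classes, size=spec.n_rows, p=p)

    centroids = simplex_centroids(spec.n_classes, spec.n_numeric, spec.separation)
    X = centroids[labels] + rng.standard_normal((spec.n_rows, spec.n_numeric))

    data = {}
    if spec.include_id:
        data["id"] = np.arange(spec.n_rows)
    for j in range(spec.n_numeric):
        data[f"num_{j}"] = X[:, j]

    cats = list(string.ascii_lowercase[: spec.categories_per_column])
    # concentration grows with separation so categorical columns carry the
    # same "how separable" dial as the numeric blobs
    alpha = 1.0 + float(spec.separation)
    for j in range(spec.n_categorical):
        class_dists = rng.dirichlet(np.full(len(cats), 1.0) * 1.0, size=spec.n_classes)
        sharp = class_dists ** alpha
        sharp = sharp / sharp.sum(axis=1, keepdims=True)
        column = np.array(
            [cats[rng.choice(len(cats), p=sharp[l])] for l in labels], dtype=object
        )
        data[f"cat_{j}"] = column
    data["target"] = labels

    df = pd.DataFrame(data)

    if spec.missing_fraction > 0:
        feature_cols = [c for c in df.columns if c not in ("id", "target")]
        mask = rng.random((spec.n_rows, len(feature_cols))) < spec.missing_fraction
        for idx, col in enumerate(feature_cols):
            df.loc[mask[:, idx], col] = np.nan
    return df


def write_fixture_suite(out_dir, seed: int = 0) -> list:
    """Materialize a small suite of CSV fixtures; returns the paths written."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    suite = {
        "blobs.csv": BlobSpec(n_rows=300, separation=6.0, seed=seed),
        "blobs_mixed.csv": BlobSpec(
            n_rows=300,
            separation=6.0,
            n_categorical=2,
            missing_fraction=0.05,
            seed=seed + 1,
        ),
        "blobs_overlapping.csv": BlobSpec(n_rows=300, separation=0.0, seed=seed + 2),
        "blobs_three_class.csv": BlobSpec(
            n_rows=300, n_classes=3, separation=8.0, seed=seed + 3
        ),
    }
    paths = []
    for name, spec in suite.items():
        path = out_dir / name
        generate_table(spec).to_csv(path, index=False)
        paths.append(path)
    return paths
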