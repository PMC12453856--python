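"""Pipeline configuration: loading, default-filling and validation.

A run is driven by a flat JSON object. Every key has a default except
``input_dataframe``; unknown keys raise a warning (not an error) so that
configuration files written for a newer release degrade gracefully.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Any, Optional


class ConfigError(ValueError):
    """Raised when a configuration file or object is invalid."""


class ConfigWarning(UserWarning):
    """Non-fatal configuration issues (unknown keys, soft fallbacks)."""


_SCALINGS = {"standard", "minmax"}
_ENCODINGS = {"one-hot", "label"}
_NAN_ACTIONS = {"drop row", "drop col", "infer"}
_UNKNOWN_ACTIONS = {"infer", "ignore"}
_MANIFOLDS = {"isomap", "tsne", "umap"}
_METHODS = {"knn", "distance", "similarity"}

# the paper-style spaced spellings and underscored variants are both accepted
_NAN_ACTION_ALIASES = {
    "drop_row": "drop row",
    "drop row": "drop row",
    "drop_col": "drop col",
    "drop col": "drop col",
    "infer": "infer",
}


@dataclass
class Config:
    """Resolved configuration for a full pipeline run.

    Field names match the JSON keys one-to-one; defaults are the documented
    defaults of the tool.  ``random_seed`` and ``n_permutations`` govern the
    stochastic stages (t-SNE/UMAP, force-directed layout, permutation test).
    """

    input_dataframe: str
    output_directory: str = "results/"
    preprocessed_filename: Optional[str] = None
    graph_filename: Optional[str] = None
    numeric_columns: Optional[list] = None
    categorical_columns: list = field(default_factory=list)
    target_columns: list = field(default_factory=list)
    ignore_columns: list = field(default_factory=list)
    unknown_column_action: str = "infer"
    numeric_threshold: float = 0.05
    numeric_scaling: str = "standard"
    categorical_encoding: str = "one-hot"
    nan_action: str = "infer"
    nan_threshold: float = 0.5
    verbose: bool = True
    overwrite: bool = False
    manifold_method: Optional[str] = None
    manifold_dimension: Optional[int] = None
    method: str = "knn"
    k: int = 5
    distance_threshold: Optional[float] = None
    similarity_threshold: Optional[float] = None
    neigh_prob_path: str = "neigh_prob.txt"
    degree_distribution_filename: str = "degree.png"
    community_filename: str = "communities.png"
    graph_visualization_filename: str = "graph.png"
    prob_heatmap_filename: str = "neigh_prob_heatmap.png"
    network_metrics_filename: Optional[str] = None
    random_seed: int = 42
    n_permutations: int = 1000

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def _as_name_list(value, key: str) -> list:
    if value is None:
        return []
    if isinstance(value, str):
        return [value]
    if isinstance(value, (list, tuple)):
        return list(value)
    raise ConfigError(f"{key!r} must be a column name or a list of names")


def load_config(path) -> Config:
    """Read a JSON configuration file, fill defaults, and validate.

    Unknown keys warn; a missing ``input_dataframe`` is an error.
    """
    path = Path(path)
    try:
        raw = json.loads(path.read_text())
    except OSError as exc:
        raise ConfigError(f"cannot read configuration file {path}: {exc}") from exc
    except json.JSONDecodeError as exc:
        raise ConfigError(f"configuration file {path} is not valid JSON: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError(f"configuration file {path} must contain a JSON object")
    return config_from_dict(raw)


def config_from_dict(raw: dict) -> Config:
    """Build a validated :class:`Config` from a plain dict of JSON keys."""
    known = {f.name for f in fields(Config)}
    unknown = sorted(set(raw) - known)
    if unknown:
        warnings.warn(
            f"ignoring unknown configuration keys: {', '.join(unknown)}",
            ConfigWarning,
            stacklevel=2,
        )
    data = {k: v for k, v in raw.items() if k in known}
    if "input_dataframe" not in data or data["input_dataframe"] in (None, ""):
        raise ConfigError("configuration is missing the mandatory key 'input_dataframe'")
    cfg = Config(**data)
    return validate_config(cfg)


def validate_config(config: Config) -> Config:
    """Normalize and check every invariant; returns the (mutated) config.

    Enum fields are lowercased, ``nan_action`` spelling variants are
    normalized, and method-conditional requirements (thresholds, manifold
    pairing) are enforced.
    """
    cfg = config

    for key in ("categorical_columns", "target_columns", "ignore_columns"):
        setattr(cfg, key, _as_name_list(getattr(cfg, key), key))
    if cfg.numeric_columns is not None:
        cfg.numeric_columns = _as_name_list(cfg.numeric_columns, "numeric_columns")

    def _enum(key: str, allowed: set, value: str) -> str:
        v = str(value).strip().lower()
        if v not in allowed:
            raise ConfigError(
                f"{key}={value!r} is not valid; choose one of {sorted(allowed)}"
            )
        return v

    cfg.unknown_column_action = _enum(
        "unknown_column_action", _UNKNOWN_ACTIONS, cfg.unknown_column_action
    )
    cfg.numeric_scaling = _enum("numeric_scaling", _SCALINGS, cfg.numeric_scaling)
    cfg.categorical_encoding = _enum(
        "categorical_encoding", _ENCODINGS, cfg.categorical_encoding
    )
    cfg.method = _enum("method", _METHODS, cfg.method)

    nan_action = str(cfg.nan_action).strip().lower()
    if nan_action not in _NAN_ACTION_ALIASES:
        raise ConfigError(
            f"nan_action={cfg.nan_action!r} is not valid; choose one of "
            f"['drop row', 'drop col', 'infer']"
        )
    cfg.nan_action = _NAN_ACTION_ALIASES[nan_action]

    if not (0 < cfg.numeric_threshold <= 1):
        raise ConfigError("numeric_threshold must lie in (0, 1]")
    if not (0 <= cfg.nan_threshold <= 1):
        raise ConfigError("nan_threshold must lie in [0, 1]")

    if cfg.manifold_method is not None:
        cfg.manifold_method = _enum("manifold_method", _MANIFOLDS, cfg.manifold_method)
        if cfg.manifold_dimension is None:
            raise ConfigError("manifold_method requires manifold_dimension")
        if int(cfg.manifold_dimension) < 1:
            raise ConfigError("manifold_dimension must be a positive integer")
        cfg.manifold_dimension = int(cfg.manifold_dimension)
    elif cfg.manifold_dimension is not None:
        raise ConfigError("manifold_dimension requires manifold_method")

    if cfg.method == "knn":
        if int(cfg.k) < 1:
            raise ConfigError("k must be a positive integer for method='knn'")
        cfg.k = int(cfg.k)
    elif cfg.method == "distance":
        if cfg.distance_threshold is None:
            raise ConfigError("method='distance' requires distance_threshold")
        if float(cfg.distance_threshold) <= 0:
            raise ConfigError("distance_threshold must be > 0")
        cfg.distance_threshold = float(cfg.distance_threshold)
    elif cfg.method == "similarity":
        if cfg.similarity_threshold is None:
            raise ConfigError("method='similarity' requires similarity_threshold")
        t = float(cfg.similarity_threshold)
        if not (-1.0 <= t <= 1.0):
            raise ConfigError("similarity_threshold must lie in [-1, 1]")
        cfg.similarity_threshold = t

    if int(cfg.n_permutations) < 1:
        raise ConfigError("n_permutations must be >= 1")
    cfg.n_permutations = int(cfg.n_permutations)
    cfg.random_seed = int(cfg.random_seed)
    cfg.verbose = bool(cfg.verbose)
    cfg.overwrite = bool(cfg.overwrite)

    both = set(cfg.numeric_columns or []) & set(cfg.categorical_columns)
    if both:
        raise ConfigError(
            f"columns declared both numeric and categorical: {sorted(both)}"
        )
    return cfg
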