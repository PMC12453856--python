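"""Mixed-type table preprocessing.

Turns a raw table (numbers, strings, missing cells) into a fully numeric,
scaled feature matrix plus an optional target-label vector and an optional
low-dimensional manifold embedding used later for graph layout.

Pipeline order: column-role resolution -> missing-value handling ->
categorical encoding -> numeric scaling -> optional manifold embedding.
Row identity (the original row index) is preserved end-to-end.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .config import Config, validate_config

__all__ = [
    "read_table",
    "infer_column_roles",
    "handle_missing",
    "encode_categorical",
    "scale_numeric",
    "embed_manifold",
    "preprocess",
    "PreprocessedTable",
    "TablePreprocessor",
    "FormatError",
    "PreprocessingError",
]


class FormatError(ValueError):
    """Unsupported or unreadable input file format."""


class PreprocessingError(ValueError):
    """A preprocessing step produced an unusable result (e.g. empty table)."""


#: markers treated as missing in addition to genuine NaN/None cells
MISSING_MARKERS = {"", "na", "nan", "null"}

_CORE_READERS = {
    ".csv": pd.read_csv,
    ".json": lambda p: pd.read_json(p, orient="records"),
    ".parquet": pd.read_parquet,
}
# optional formats sit behind a capability check so the core pipeline has no
# hard dependency on Excel/HDF5 readers
_OPTIONAL_READERS = {
    ".xlsx": ("openpyxl", pd.read_excel),
    ".xls": ("openpyxl", pd.read_excel),
    ".h5": ("tables", pd.read_hdf),
    ".hdf5": ("tables", pd.read_hdf),
    ".pkl": (None, pd.read_pickle),
    ".pickle": (None, pd.read_pickle),
}


def _normalize_missing(df: pd.DataFrame) -> pd.DataFrame:
    """Map textual missing markers (case-insensitive) to NaN."""
    def fix(col: pd.Series) -> pd.Series:
        if col.dtype == object:
            mask = col.apply(
                lambda v: isinstance(v, str) and v.strip().lower() in MISSING_MARKERS
            )
            if mask.any():
                col = col.mask(mask)
        return col

    return df.apply(fix)


def read_table(path) -> pd.DataFrame:
    """Read a tabular file into a DataFrame, dispatching on the extension.

    CSV, JSON (records orientation) and Parquet are always available;
    Excel, HDF5 and Pickle work when their readers are installed.
    Empty strings and the usual NA markers become missing values.
    """
    path = Path(path)
    ext = path.suffix.lower()
    supported = sorted(set(_CORE_READERS) | set(_OPTIONAL_READERS))
    if ext in _CORE_READERS:
        reader = _CORE_READERS[ext]
    elif ext in _OPTIONAL_READERS:
        dep, reader = _OPTIONAL_READERS[ext]
        if dep is not None:
            try:
                __import__(dep)
            except ImportError as exc:
                raise FormatError(
                    f"reading {ext} files requires the optional dependency {dep!r}"
                ) from exc
    else:
        raise FormatError(
            f"unsupported table format {ext!r}; supported extensions: "
            + ", ".join(supported)
        )
    if not path.exists():
        raise FormatError(f"input table not found: {path}")
    df = reader(path)
    df = df.reset_index(drop=True)
    return _normalize_missing(df)


def _infer_role(column: pd.Series, numeric_threshold: float) -> str:
    """Numeric iff >=95% of non-missing cells parse as numbers and the
    distinct-value ratio exceeds ``numeric_threshold``; else categorical.

    The ratio rule routes low-cardinality integer codes (e.g. 0/1 flags)
    to categorical treatment, which is what a small default threshold is for.
    """
    obs = column.dropna()
    if len(obs) == 0:
        return "categorical"
    parsed = pd.to_numeric(obs, errors="coerce")
    frac_numeric = parsed.notna().mean()
    if frac_numeric < 0.95:
        return "categorical"
    distinct_ratio = parsed.nunique(dropna=True) / len(obs)
    return "numeric" if distinct_ratio > numeric_threshold else "categorical"


def infer_column_roles(table: pd.DataFrame, config: Config) -> dict:
    """Resolve every column to one role in {numeric, categorical, target, ignored}.

    Declared lists win; ``target_columns`` and ``ignore_columns`` override
    numeric/categorical declarations; undeclared columns are inferred or
    ignored according to ``unknown_column_action``.
    """
    declared_numeric = set(config.numeric_columns or [])
    declared_categorical = set(config.categorical_columns)
    targets = set(config.target_columns)
    ignored = set(config.ignore_columns)

    missing = (declared_numeric | declared_categorical | targets | ignored) - set(
        table.columns
    )
    if missing:
        raise PreprocessingError(
            f"declared columns not present in the table: {sorted(missing)}"
        )
    both = declared_numeric & declared_categorical
    if both:
        raise PreprocessingError(
            f"columns declared both numeric and categorical: {sorted(both)}"
        )

    roles = {}
    for col in table.columns:
        if col in ignored:
            roles[col] = "ignored"
        elif col in targets:
            roles[col] = "target"
        elif col in declared_numeric:
            roles[col] = "numeric"
        elif col in declared_categorical:
            roles[col] = "categorical"
        elif config.unknown_column_action == "ignore":
            roles[col] = "ignored"
        else:
            roles[col] = _infer_role(table[col], config.numeric_threshold)
    return roles


def handle_missing(
    table: pd.DataFrame,
    roles: dict,
    nan_action: str = "infer",
    nan_threshold: float = 0.5,
) -> pd.DataFrame:
    """Remove or impute missing values so the result has none.

    - ``drop col``: drop feature columns whose missing ratio exceeds
      ``nan_threshold``.
    - ``drop row``: drop rows with a missing value in any non-ignored column.
    - ``infer``: first drop feature columns above the threshold, then impute
      the rest (numeric -> mean of observed; categorical/target -> most
      frequent observed value, ties broken lexicographically on the string
      representation).

    Target columns are never dropped by the ratio rule; ignored columns are
    left untouched (they are excluded from the feature matrix anyway).
    """
    if not (0 <= nan_threshold <= 1):
        raise PreprocessingError("nan_threshold must lie in [0, 1]")
    df = table.copy()
    feature_cols = [c for c in df.columns if roles.get(c) in ("numeric", "categorical")]
    considered = [c for c in df.columns if roles.get(c) != "ignored"]

    if nan_action == "drop row":
        df = df.dropna(subset=considered)
        if len(df) == 0:
            raise PreprocessingError("empty table after NaN handling")
        return df

    ratios = df[feature_cols].isna().mean()
    to_drop = [c for c in feature_cols if ratios[c] > nan_threshold]
    fully_missing = [
        c for c in feature_cols if c not in to_drop and df[c].isna().all()
    ]
    if fully_missing:
        warnings.warn(
            f"dropping entirely missing column(s): {fully_missing}", UserWarning
        )
        to_drop += fully_missing
    if to_drop:
        df = df.drop(columns=to_drop)

    if nan_action == "drop col":
        # columns under the ratio threshold may still hold missing cells;
        # the contract is a missing-free table, so residual rows go too
        residual = [c for c in df.columns if roles.get(c) != "ignored"]
        before = len(df)
        df = df.dropna(subset=residual)
        if len(df) < before:
            warnings.warn(
                f"'drop col' removed {before - len(df)} row(s) with residual "
                "missing values in kept columns",
                UserWarning,
            )
        if len(df) == 0:
            raise PreprocessingError("empty table after NaN handling")
        return df

    # nan_action == "infer": impute what survives the column drop
    for col in df.columns:
        role = roles.get(col)
        if role == "ignored" or not df[col].isna().any():
            continue
        if role == "numeric":
            fill = pd.to_numeric(df[col], errors="coerce").mean()
        else:  # categorical or target: most frequent, lexicographic tie-break
            counts = df[col].dropna().value_counts()
            top = counts[counts == counts.max()].index
            fill = sorted(top, key=str)[0]
        df[col] = df[col].fillna(fill)
    if len(df) == 0:
        raise PreprocessingError("empty table after NaN handling")
    return df


def encode_categorical(column: pd.Series, method: str = "one-hot") -> pd.DataFrame:
    """Encode one categorical column as numeric columns.

    ``one-hot`` yields one 0/1 indicator per distinct category (so each row
    sums to 1); ``label`` yields a single integer-code column. Categories are
    ordered lexicographically on their string representation in both modes.
    """
    if column.dropna().empty:
        raise PreprocessingError(f"cannot encode empty column {column.name!r}")
    as_str = column.astype(str)
    cats = sorted(as_str.unique())
    name = column.name if column.name is not None else "cat"
    if method == "label":
        codes = as_str.map({c: i for i, c in enumerate(cats)}).astype(float)
        return codes.to_frame(name=name)
    if method == "one-hot":
        data = {
            f"{name}_{c}": (as_str == c).astype(float).to_numpy() for c in cats
        }
        return pd.DataFrame(data, index=column.index)
    raise PreprocessingError(f"unknown categorical encoding {method!r}")


def scale_numeric(matrix: pd.DataFrame, method: str = "standard") -> pd.DataFrame:
    """Scale each numeric column; constant columns become all-zeros (warned).

    ``standard`` centers and divides by the population (n-denominator)
    standard deviation; ``minmax`` maps the observed range onto [0, 1].
    """
    df = matrix.astype(float).copy()
    constant = []
    for col in df.columns:
        x = df[col].to_numpy()
        if method == "standard":
            spread = x.std()  # population sd, ddof=0
            center = x.mean()
        elif method == "minmax":
            spread = x.max() - x.min()
            center = x.min()
        else:
            raise PreprocessingError(f"unknown scaling method {method!r}")
        if spread == 0:
            constant.append(col)
            df[col] = 0.0
        else:
            df[col] = (x - center) / spread
    if constant:
        warnings.warn(
            f"constant numeric column(s) mapped to zeros: {constant}", UserWarning
        )
    return df


def embed_manifold(
    matrix,
    method: str,
    dimension: int,
    seed: int = 42,
    n_neighbors: Optional[int] = None,
) -> np.ndarray:
    """Embed rows into ``dimension`` coordinates with Isomap, t-SNE or UMAP.

    Output preserves row order; identical input and seed give identical
    output. Small-sample cases raise with a hint to shrink the neighborhood
    parameter.
    """
    X = np.asarray(matrix, dtype=float)
    n = X.shape[0]
    m = int(dimension)
    if m < 1:
        raise PreprocessingError("manifold_dimension must be >= 1")
    if n <= m:
        raise PreprocessingError(
            f"need more rows ({n}) than embedding dimensions ({m})"
        )
    if method == "isomap":
        from sklearn.manifold import Isomap

        nn = n_neighbors if n_neighbors is not None else min(5, n - 1)
        if nn >= n:
            raise PreprocessingError(
                f"isomap needs n_neighbors < n rows; try n_neighbors < {n}"
            )
        return np.asarray(Isomap(n_neighbors=nn, n_components=m).fit_transform(X))
    if method == "tsne":
        from sklearn.manifold import TSNE

        perplexity = min(30.0, (n - 1) / 3)
        if perplexity < 1:
            raise PreprocessingError(
                "too few rows for t-SNE; provide at least 4 rows or use isomap"
            )
        tsne = TSNE(
            n_components=m,
            random_state=int(seed),
            perplexity=perplexity,
            init="pca",
            method="exact" if m > 3 else "barnes_hut",
        )
        return np.asarray(tsne.fit_transform(X))
    if method == "umap":
        import umap

        nn = n_neighbors if n_neighbors is not None else min(15, n - 1)
        if nn < 2:
            raise PreprocessingError(
                "too few rows for UMAP; reduce the neighborhood size or add rows"
            )
        reducer = umap.UMAP(
            n_components=m, n_neighbors=nn, random_state=int(seed)
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # umap warns about forced determinism
            return np.asarray(reducer.fit_transform(X), dtype=float)
    raise PreprocessingError(f"unknown manifold method {method!r}")


@dataclass
class PreprocessedTable:
    """Numeric feature matrix + labels + ids + optional embedding.

    ``X`` rows align one-to-one with ``ids`` (original row indices of the
    surviving rows, in input order) and with ``y`` / ``embedding`` rows.
    """

    X: pd.DataFrame
    y: Optional[pd.DataFrame] = None
    ids: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    embedding: Optional[np.ndarray] = None

    @property
    def feature_names(self) -> list:
        return list(self.X.columns)

    @property
    def primary_target(self) -> Optional[pd.Series]:
        """First target column; analysis uses one label set."""
        if self.y is None or self.y.shape[1] == 0:
            return None
        if self.y.shape[1] > 1:
            warnings.warn(
                "multiple target columns given; analysis uses the first "
                f"({self.y.columns[0]!r})",
                UserWarning,
            )
        return self.y.iloc[:, 0]


def preprocess(table: pd.DataFrame, config: Config) -> PreprocessedTable:
    """Run the full preprocessing pipeline under a validated configuration.

    Ignored columns (e.g. a patient id) never reach the feature matrix;
    target columns are stored separately as labels.  When
    ``preprocessed_filename`` is set the result is persisted as CSV with the
    embedding in columns ``manifold_0..manifold_{m-1}``.
    """
    config = validate_config(config)
    roles = infer_column_roles(table, config)
    df = handle_missing(table, roles, config.nan_action, config.nan_threshold)
    roles = {c: roles[c] for c in df.columns}

    numeric_cols = [c for c in df.columns if roles[c] == "numeric"]
    categorical_cols = [c for c in df.columns if roles[c] == "categorical"]
    target_cols = [c for c in df.columns if roles[c] == "target"]

    blocks = []
    if numeric_cols:
        scaled = scale_numeric(
            df[numeric_cols].apply(pd.to_numeric), config.numeric_scaling
        )
        blocks.append(scaled)
    else:
        scaled = pd.DataFrame(index=df.index)
    for col in categorical_cols:
        blocks.append(encode_categorical(df[col], config.categorical_encoding))
    if blocks:
        X = pd.concat(blocks, axis=1)
    else:
        raise PreprocessingError("no feature columns left after preprocessing")

    y = df[target_cols] if target_cols else None
    ids = df.index.to_numpy()

    embedding = None
    if config.manifold_method is not None:
        if scaled.shape[1] == 0:
            raise PreprocessingError(
                "manifold learning requires at least one numeric column"
            )
        embedding = embed_manifold(
            scaled.to_numpy(),
            config.manifold_method,
            config.manifold_dimension,
            seed=config.random_seed,
        )

    pt = PreprocessedTable(X=X, y=y, ids=ids, embedding=embedding)

    if config.preprocessed_filename:
        out = Path(config.output_directory) / config.preprocessed_filename
        out.parent.mkdir(parents=True, exist_ok=True)
        if out.exists() and not config.overwrite:
            raise FileExistsError(
                f"{out} exists; set overwrite=true to replace it"
            )
        dump = X.copy()
        if y is not None:
            for col in y.columns:
                dump[col] = y[col].to_numpy()
        if embedding is not None:
            for j in range(embedding.shape[1]):
                dump[f"manifold_{j}"] = embedding[:, j]
        dump.to_csv(out, index=False)
    return pt


class TablePreprocessor(BaseEstimator, TransformerMixin):
    """Sklearn-style transformer wrapping :func:`preprocess`.

    Parameters mirror the configuration keys that matter for preprocessing;
    ``transform`` returns the numeric feature matrix as a DataFrame, and the
    full :class:`PreprocessedTable` (labels, ids, embedding) is available as
    the fitted attribute ``table_``.
    """

    def __init__(
        self,
        numeric_columns=None,
        categorical_columns=(),
        target_columns=(),
        ignore_columns=(),
        unknown_column_action="infer",
        numeric_threshold=0.05,
        numeric_scaling="standard",
        categorical_encoding="one-hot",
        nan_action="infer",
        nan_threshold=0.5,
        manifold_method=None,
        manifold_dimension=None,
        random_seed=42,
    ):
        self.numeric_columns = numeric_columns
        self.categorical_columns = categorical_columns
        self.target_columns = target_columns
        self.ignore_columns = ignore_columns
        self.unknown_column_action = unknown_column_action
        self.numeric_threshold = numeric_threshold
        self.numeric_scaling = numeric_scaling
        self.categorical_encoding = categorical_encoding
        self.nan_action = nan_action
        self.nan_threshold = nan_threshold
        self.manifold_method = manifold_method
        self.manifold_dimension = manifold_dimension
        self.random_seed = random_seed

    def _config(self) -> Config:
        return validate_config(
            Config(
                input_dataframe="<in-memory>",
                numeric_columns=(
                    list(self.numeric_columns)
                    if self.numeric_columns is not None
                    else None
                ),
                categorical_columns=list(self.categorical_columns),
                target_columns=list(self.target_columns),
                ignore_columns=list(self.ignore_columns),
                unknown_column_action=self.unknown_column_action,
                numeric_threshold=self.numeric_threshold,
                numeric_scaling=self.numeric_scaling,
                categorical_encoding=self.categorical_encoding,
                nan_action=self.nan_action,
                nan_threshold=self.nan_threshold,
                manifold_method=self.manifold_method,
                manifold_dimension=self.manifold_dimension,
                random_seed=self.random_seed,
            )
        )

    def fit(self, X: pd.DataFrame, y=None) -> "TablePreprocessor":
        self.table_ = preprocess(pd.DataFrame(X), self._config())
        self.feature_names_out_ = self.table_.feature_names
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        self.fit(X)
        return self.table_.X
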