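"""Ingest, validate and encode long-format person-by-item response data.

A dataset is one row per (person, item) pair with a binary response and a set
of predictors that live at the person level, the item level, or the
person-by-item level.  Two encodings are produced: a dummy-coded design matrix
with intercept for logistic mixed models, and an integer-coded feature matrix
that keeps one column per nominal predictor for tree ensembles.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import (
    ConsistencyError,
    DataValidationError,
    EmptyFeatureError,
    EncodingError,
    SchemaError,
)

ID_COLUMNS = ("person_id", "item_id", "response")

LEVELS = ("person", "item", "person_by_item")
KINDS = ("continuous", "nominal")


@dataclass(frozen=True)
class Predictor:
    """One predictor in the schema.

    ``categories`` is the closed, ordered category set for nominal predictors;
    ``reference`` is the dummy-coding reference level (defaults to the first
    category in sorted order).
    """

    name: str
    level: str
    kind: str
    categories: tuple = ()
    reference: object = None

    def __post_init__(self):
        if self.level not in LEVELS:
            raise SchemaError(f"unknown level {self.level!r} for predictor {self.name!r}")
        if self.kind not in KINDS:
            raise SchemaError(f"unknown kind {self.kind!r} for predictor {self.name!r}")
        if self.kind == "nominal":
            if len(self.categories) < 2:
                raise SchemaError(f"nominal predictor {self.name!r} needs >=2 categories")
            if len(set(self.categories)) != len(self.categories):
                raise SchemaError(f"duplicate categories for predictor {self.name!r}")
            ref = self.reference
            if ref is None:
                ref = sorted(self.categories, key=str)[0]
                object.__setattr__(self, "reference", ref)
            if ref not in self.categories:
                raise SchemaError(
                    f"reference {ref!r} not among categories of {self.name!r}"
                )


@dataclass(frozen=True)
class PredictorSchema:
    predictors: tuple

    def __post_init__(self):
        names = [p.name for p in self.predictors]
        if len(set(names)) != len(names):
            raise SchemaError("predictor names must be unique")
        if any(n in ID_COLUMNS for n in names):
            raise SchemaError(f"predictor names may not shadow {ID_COLUMNS}")

    @property
    def names(self):
        return [p.name for p in self.predictors]

    def __iter__(self):
        return iter(self.predictors)

    def __getitem__(self, name):
        for p in self.predictors:
            if p.name == name:
                return p
        raise KeyError(name)

    def subset(self, names: Sequence[str]) -> "PredictorSchema":
        keep = [p for p in self.predictors if p.name in set(names)]
        return PredictorSchema(tuple(keep))

    @classmethod
    def from_records(cls, records: Iterable[Mapping]) -> "PredictorSchema":
        preds = []
        for rec in records:
            preds.append(
                Predictor(
                    name=rec["name"],
                    level=rec["level"],
                    kind=rec["kind"],
                    categories=tuple(rec.get("categories", ()) or ()),
                    reference=rec.get("reference"),
                )
            )
        return cls(tuple(preds))

    @classmethod
    def from_file(cls, path) -> "PredictorSchema":
        text = open(path).read()
        data = yaml.safe_load(text) if not str(path).endswith(".json") else json.loads(text)
        if isinstance(data, Mapping) and "predictors" in data:
            data = data["predictors"]
        return cls.from_records(data)

    def to_records(self):
        return [
            {
                "name": p.name,
                "level": p.level,
                "kind": p.kind,
                "categories": list(p.categories),
                "reference": p.reference,
            }
            for p in self.predictors
        ]


@dataclass
class ResponseTable:
    """Validated long-format person-by-item data."""

    df: pd.DataFrame
    schema: PredictorSchema

    @property
    def n_persons(self) -> int:
        return self.df["person_id"].nunique()

    @property
    def n_items(self) -> int:
        return self.df["item_id"].nunique()

    @property
    def y(self) -> np.ndarray:
        return self.df["response"].to_numpy(dtype=int)

    def person_codes(self):
        """Integer codes plus the ordered id list for persons."""
        cat = pd.Categorical(self.df["person_id"])
        return np.asarray(cat.codes), list(cat.categories)

    def item_codes(self):
        cat = pd.Categorical(self.df["item_id"])
        return np.asarray(cat.codes), list(cat.categories)

    def to_csv(self, path):
        self.df.to_csv(path, index=False)


def load_long_table(source, schema: PredictorSchema) -> ResponseTable:
    """Read a long-format table and validate it against ``schema``.

    ``source`` is a CSV path/handle or a DataFrame.  Rows with any missing
    value are removed (listwise deletion); duplicate (person, item) pairs and
    responses outside {0, 1} are rejected; person- and item-level predictors
    are checked for within-cluster constancy.
    """
    if isinstance(source, pd.DataFrame):
        df = source.copy()
    else:
        df = pd.read_csv(source)

    missing_cols = [c for c in ID_COLUMNS if c not in df.columns]
    missing_cols += [n for n in schema.names if n not in df.columns]
    if missing_cols:
        raise SchemaError(f"missing required columns: {missing_cols}")

    df = df[list(ID_COLUMNS) + schema.names]
    df = df.dropna(axis=0, how="any").reset_index(drop=True)
    if len(df) == 0:
        raise DataValidationError("no complete rows after listwise deletion")

    resp = df["response"]
    if not np.isin(resp.to_numpy(), (0, 1)).all():
        bad = sorted(set(resp) - {0, 1})
        raise DataValidationError(f"response values outside {{0,1}}: {bad}")
    df["response"] = resp.astype(int)

    if df.duplicated(subset=["person_id", "item_id"]).any():
        raise DataValidationError("duplicate (person_id, item_id) pairs")

    for pred in schema:
        if pred.level == "person_by_item":
            continue
        key = "person_id" if pred.level == "person" else "item_id"
        nun = df.groupby(key, sort=False)[pred.name].nunique()
        if (nun > 1).any():
            offender = nun[nun > 1].index[0]
            raise ConsistencyError(
                f"{pred.level}-level predictor {pred.name!r} varies within "
                f"{key}={offender!r}"
            )

    for pred in schema:
        if pred.kind == "nominal":
            seen = set(df[pred.name].unique())
            unknown = seen - set(pred.categories)
            if unknown:
                raise EncodingError(
                    f"predictor {pred.name!r} has categories outside the schema: "
                    f"{sorted(map(str, unknown))}"
                )

    return ResponseTable(df=df, schema=schema)


@dataclass
class PreparedData:
    """Preprocessed table plus the state needed to transform new rows."""

    table: ResponseTable
    centers: dict = field(default_factory=dict)
    dropped: list = field(default_factory=list)
    corr_median: float = float("nan")
    corr_iqr: float = float("nan")
    high_corr_pairs: list = field(default_factory=list)

    @property
    def schema(self) -> PredictorSchema:
        return self.table.schema

    def report(self) -> dict:
        return {
            "dropped": list(self.dropped),
            "centers": dict(self.centers),
            "correlation": {
                "median": self.corr_median,
                "iqr": self.corr_iqr,
                "high_pairs": list(self.high_corr_pairs),
            },
        }


def _near_zero_variance(values: pd.Series, freq_ratio: float, unique_frac: float) -> bool:
    counts = values.value_counts()
    if len(counts) < 2:
        return True
    ratio = counts.iloc[0] / counts.iloc[1]
    frac_unique = len(counts) / len(values)
    return ratio > freq_ratio and frac_unique < unique_frac


def correlation_summary(table: ResponseTable, predictors=None):
    """Median/IQR of pairwise Pearson correlations among encoded predictors.

    Nominal predictors enter as their integer category codes; the summary is
    taken over all off-diagonal pairs of the long-format table.
    """
    schema = table.schema
    names = predictors if predictors is not None else schema.names
    cols = {}
    for name in names:
        pred = schema[name]
        if pred.kind == "nominal":
            mapping = {c: k for k, c in enumerate(pred.categories)}
            cols[name] = table.df[name].map(mapping).to_numpy(dtype=float)
        else:
            cols[name] = table.df[name].to_numpy(dtype=float)
    mat = pd.DataFrame(cols)
    keep = [c for c in mat.columns if mat[c].nunique() > 1]
    mat = mat[keep]
    if mat.shape[1] < 2:
        return float("nan"), float("nan"), []
    corr = mat.corr().to_numpy()
    iu = np.triu_indices_from(corr, k=1)
    vals = corr[iu]
    vals = vals[np.isfinite(vals)]
    pairs = [
        (keep[a], keep[b], float(corr[a, b]))
        for a, b in zip(*iu)
        if np.isfinite(corr[a, b]) and abs(corr[a, b]) > 0.99
    ]
    q1, med, q3 = np.percentile(vals, [25, 50, 75])
    return float(med), float(q3 - q1), pairs


def preprocess(
    table: ResponseTable,
    center: bool = True,
    nzv_freq_ratio: float = 19.0,
    nzv_unique_frac: float = 0.10,
) -> PreparedData:
    """Mean-center continuous predictors and screen near-zero-variance ones.

    The near-zero-variance rule drops a predictor when the frequency ratio of
    its most to second-most common value exceeds ``nzv_freq_ratio`` and the
    fraction of unique values is below ``nzv_unique_frac`` (a constant column
    is always dropped).  Centering offsets are stored so held-out rows can be
    transformed with the training means.
    """
    df = table.df.copy()
    dropped = []
    for pred in table.schema:
        col = df[pred.name]
        if col.nunique() <= 1:
            dropped.append({"name": pred.name, "reason": "zero variance"})
        elif _near_zero_variance(col, nzv_freq_ratio, nzv_unique_frac):
            dropped.append({"name": pred.name, "reason": "near-zero variance"})
    dropped_names = {d["name"] for d in dropped}
    kept = [p for p in table.schema if p.name not in dropped_names]
    if not kept:
        raise EmptyFeatureError("all predictors were dropped by the variance screen")
    schema = PredictorSchema(tuple(kept))

    centers = {}
    if center:
        for pred in kept:
            if pred.kind == "continuous":
                mu = float(df[pred.name].mean())
                centers[pred.name] = mu
                df[pred.name] = df[pred.name] - mu

    new_table = ResponseTable(
        df=df[list(ID_COLUMNS) + schema.names].reset_index(drop=True), schema=schema
    )
    med, iqr, pairs = correlation_summary(new_table)
    return PreparedData(
        table=new_table,
        centers=centers,
        dropped=dropped,
        corr_median=med,
        corr_iqr=iqr,
        high_corr_pairs=pairs,
    )


def encode(prepared: PreparedData, mode: str, df: pd.DataFrame | None = None):
    """Encode predictors as a numeric matrix.

    ``mode='eirm'`` returns an intercept column plus one dummy column per
    non-reference category of each nominal predictor and the continuous
    columns as-is.  ``mode='forest'`` returns exactly one column per retained
    predictor, with nominal categories mapped to integer codes.

    ``df`` defaults to the prepared training table; passing new rows applies
    the stored training transform (unknown categories raise
    :class:`EncodingError`).

    Returns ``(X, columns)`` where ``columns`` parallels the matrix columns.
    """
    if mode not in ("eirm", "forest"):
        raise ValueError(f"unknown encoding mode {mode!r}")
    schema = prepared.schema
    if df is None:
        df = prepared.table.df
    else:
        df = df.copy()
        for name, mu in prepared.centers.items():
            if name in df.columns:
                df[name] = df[name] - mu

    cols = []
    names = []
    if mode == "eirm":
        cols.append(np.ones(len(df)))
        names.append("(intercept)")
    for pred in schema:
        values = df[pred.name]
        if pred.kind == "continuous":
            cols.append(values.to_numpy(dtype=float))
            names.append(pred.name)
            continue
        seen = set(values.unique())
        unknown = seen - set(pred.categories)
        if unknown:
            raise EncodingError(
                f"unseen categories {sorted(map(str, unknown))} for {pred.name!r}"
            )
        if mode == "forest":
            mapping = {c: k for k, c in enumerate(pred.categories)}
            cols.append(values.map(mapping).to_numpy(dtype=float))
            names.append(pred.name)
        else:
            # dummies only for categories observed in the training table, so
            # unobserved schema categories cannot produce all-zero columns
            observed = set(prepared.table.df[pred.name].unique())
            for cat in pred.categories:
                if cat == pred.reference or cat not in observed:
                    continue
                cols.append((values == cat).to_numpy(dtype=float))
                names.append(f"{pred.name}[{cat}]")
    X = np.column_stack(cols) if cols else np.empty((len(df), 0))
    return X, names


def drop_collinear(X, names, tol: float = 1e-8):
    """Remove linearly dependent columns via pivoted QR.

    Returns ``(X_kept, names_kept, dropped_names)``; the first (intercept)
    column is always retained.  Used by the analysis pipelines, where small
    item samples can make dummy blocks exactly collinear.
    """
    import scipy.linalg as sla

    X = np.asarray(X, dtype=float)
    if X.shape[1] == 0:
        return X, list(names), []
    _, R, piv = sla.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    thresh = tol * (diag.max() if diag.size else 1.0)
    rank = int(np.sum(diag > thresh))
    keep = sorted(piv[:rank])
    dropped = [names[k] for k in range(X.shape[1]) if k not in set(keep)]
    return X[:, keep], [names[k] for k in keep], dropped
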