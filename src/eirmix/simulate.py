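"""Synthetic person-by-item data generators.

Two data-generating families are provided:

* crossed-random-intercept logistic data whose fixed part is a linear
  predictor over 13 person-level (4 nominal with 2-3 categories, 9 standard
  normal) and 3 nominal item-level predictors, with either a ``simple``
  structure (main effects only) or a ``complex`` structure (main effects plus
  person-by-item interaction terms), coefficients drawn once from
  Uniform(-1, 1) and held fixed across replications;
* tree-structured data whose fixed part is a single explicit decision tree
  over 2 randomly selected item-level and 5 randomly selected person-level
  predictors, mapped onto the logit scale, used to define exact ground-truth
  values for the interpretation suite.

Cross-predictor dependence is induced through a latent Gaussian copula with a
jittered exchangeable correlation matrix, thresholded at equal-probability
cutpoints for nominal predictors.  An accept-reject loop (with adaptive
rescaling of the latent correlation) drives the median of the pairwise
correlations among the 16 encoded predictors in the long-format table to a
target level; the interquartile range is reported but not enforced, since at
fixed correlation it is dominated by sampling noise and therefore scales with
the number of persons.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .data_prep import (
    Predictor,
    PredictorSchema,
    ResponseTable,
    correlation_summary,
    load_long_table,
)
from .errors import GenerationError


@dataclass(frozen=True)
class SimulationSpec:
    n_persons: int = 100
    n_items: int = 10
    structure: str = "simple"  # or "complex"
    sigma2_person: float = 0.7
    sigma2_item: float = 0.7
    n_person_nominal: int = 4
    n_person_continuous: int = 9
    n_item_nominal: int = 3
    coef_range: tuple = (-1.0, 1.0)
    intercept: float = 0.0
    target_median_corr: float = 0.003
    corr_jitter: float = 0.05
    corr_tol: float = 0.05

    def __post_init__(self):
        if self.n_persons < 2 or self.n_items < 2:
            raise ValueError("need at least 2 persons and 2 items")
        if self.sigma2_person < 0 or self.sigma2_item < 0:
            raise ValueError("variances must be nonnegative")
        if self.structure not in ("simple", "complex"):
            raise ValueError("structure must be 'simple' or 'complex'")


def _expit(x):
    return 0.5 * (1.0 + np.tanh(0.5 * x))


def _jittered_exchangeable(dim, rho, jitter, rng):
    """Correlation matrix: exchangeable ``rho`` plus per-pair jitter, made PSD."""
    R = np.full((dim, dim), rho, dtype=float)
    if jitter > 0:
        noise = rng.uniform(-jitter, jitter, size=(dim, dim))
        noise = (noise + noise.T) / 2
        R = R + noise
    np.fill_diagonal(R, 1.0)
    w, V = np.linalg.eigh(R)
    w = np.clip(w, 1e-6, None)
    R = V @ np.diag(w) @ V.T
    d = np.sqrt(np.diag(R))
    return R / np.outer(d, d)


def _draw_block(n_rows, kinds, n_categories, rho, jitter, rng):
    """Latent-copula draw of one table's predictors.

    ``kinds`` is a list of 'continuous'/'nominal'; nominal columns are
    thresholded at equal-probability normal quantiles into ``n_categories``
    labelled levels.
    """
    dim = len(kinds)
    R = _jittered_exchangeable(dim, rho, jitter, rng)
    L = np.linalg.cholesky(R)
    Z = rng.standard_normal((n_rows, dim)) @ L.T
    cols = {}
    for k, kind in enumerate(kinds):
        if kind == "continuous":
            cols[k] = Z[:, k]
        else:
            K = n_categories[k]
            cuts = norm.ppf(np.arange(1, K) / K)
            codes = np.searchsorted(cuts, Z[:, k])
            cols[k] = np.array([f"c{c + 1}" for c in codes], dtype=object)
    return cols


def default_schema(spec: SimulationSpec, rng) -> PredictorSchema:
    """Predictor schema with seeded 2-vs-3 category counts for nominals."""
    preds = []
    for k in range(spec.n_person_continuous):
        preds.append(Predictor(name=f"pc{k + 1}", level="person", kind="continuous"))
    for k in range(spec.n_person_nominal):
        K = int(rng.integers(2, 4))
        cats = tuple(f"c{c + 1}" for c in range(K))
        preds.append(Predictor(name=f"pn{k + 1}", level="person", kind="nominal",
                               categories=cats, reference=cats[0]))
    for k in range(spec.n_item_nominal):
        K = int(rng.integers(2, 4))
        cats = tuple(f"c{c + 1}" for c in range(K))
        preds.append(Predictor(name=f"in{k + 1}", level="item", kind="nominal",
                               categories=cats, reference=cats[0]))
    return PredictorSchema(tuple(preds))


def make_long_frame(person_df: pd.DataFrame, item_df: pd.DataFrame) -> pd.DataFrame:
    """Person-major crossing of the two tables into a long-format frame."""
    p = person_df.loc[person_df.index.repeat(len(item_df))].reset_index(drop=True)
    i = pd.concat([item_df] * len(person_df), ignore_index=True)
    return pd.concat([p, i], axis=1)


def _achieved_median(person_df, item_df, schema):
    long = make_long_frame(person_df, item_df)
    long.insert(0, "response", 0)
    table = ResponseTable(df=long, schema=schema)
    med, iqr, _ = correlation_summary(table)
    return med, iqr


def gen_predictors(spec: SimulationSpec, seed: int, max_attempts: int = 100):
    """Generate person and item predictor tables honouring the correlation target.

    Returns ``(person_df, item_df, schema, info)`` where ``info`` records the
    achieved correlation median/IQR and the latent correlation used.
    """
    ss = np.random.SeedSequence(seed)
    schema_rng = np.random.default_rng(ss.spawn(1)[0])
    schema = default_schema(spec, schema_rng)
    person_preds = [p for p in schema if p.level == "person"]
    item_preds = [p for p in schema if p.level == "item"]
    ncat = {p.name: len(p.categories) for p in schema if p.kind == "nominal"}

    target = spec.target_median_corr
    rho = min(0.9, max(0.0, target * 1.3))
    substreams = ss.spawn(max_attempts + 1)[1:]
    for attempt in range(max_attempts):
        rng = np.random.default_rng(substreams[attempt])
        pcols = _draw_block(
            spec.n_persons,
            [p.kind for p in person_preds],
            {k: ncat.get(p.name, 0) for k, p in enumerate(person_preds)},
            rho, spec.corr_jitter, rng,
        )
        icols = _draw_block(
            spec.n_items,
            [p.kind for p in item_preds],
            {k: ncat.get(p.name, 0) for k, p in enumerate(item_preds)},
            rho, spec.corr_jitter, rng,
        )
        person_df = pd.DataFrame({"person_id": [f"p{j + 1}" for j in range(spec.n_persons)]})
        for k, p in enumerate(person_preds):
            person_df[p.name] = pcols[k]
        item_df = pd.DataFrame({"item_id": [f"i{i + 1}" for i in range(spec.n_items)]})
        for k, p in enumerate(item_preds):
            item_df[p.name] = icols[k]

        med, iqr = _achieved_median(person_df, item_df, schema)
        if abs(med - target) <= spec.corr_tol:
            info = {"achieved_median": med, "achieved_iqr": iqr,
                    "latent_rho": rho, "attempts": attempt + 1}
            return person_df, item_df, schema, info
        # adapt the latent exchangeable correlation toward the target
        rho = float(np.clip(rho + (target - med) * 1.4, 0.0, 0.95))
    raise GenerationError(
        f"could not reach correlation median {target} in {max_attempts} attempts")


def _dummy_terms(df, pred):
    """(column, label) pairs for the non-reference categories of a nominal."""
    out = []
    for cat in pred.categories:
        if cat == pred.reference:
            continue
        out.append(((df[pred.name] == cat).to_numpy(dtype=float),
                    f"{pred.name}[{cat}]"))
    return out


def linear_predictor(person_df, item_df, schema: PredictorSchema,
                     structure: str, seed: int,
                     coef_range=(-1.0, 1.0), intercept: float = 0.0):
    """Fixed-part linear predictor over the person-by-item crossing.

    ``simple``: intercept plus main effects of every predictor (dummy-coded
    nominals), coefficients i.i.d. Uniform over ``coef_range``.  ``complex``
    adds an interaction block: each continuous person predictor crossed with
    the first dummy of the first item predictor, and each person-level dummy
    crossed with the first dummy of the second item predictor.

    Returns ``(eta, coefs)`` with ``eta`` ordered person-major and ``coefs``
    a name->value record (drawn once per call; reuse the record across
    replications by reusing the same seed).
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    long = make_long_frame(person_df, item_df)
    terms = []
    for pred in schema:
        if pred.kind == "continuous":
            terms.append((long[pred.name].to_numpy(dtype=float), pred.name))
        else:
            terms.extend(_dummy_terms(long, pred))
    if structure == "complex":
        item_preds = [p for p in schema if p.level == "item"]
        person_preds = [p for p in schema if p.level == "person"]
        d1_col, d1_name = _dummy_terms(long, item_preds[0])[0]
        d2_col, d2_name = _dummy_terms(long, item_preds[1])[0]
        for pred in person_preds:
            if pred.kind == "continuous":
                terms.append((long[pred.name].to_numpy(dtype=float) * d1_col,
                              f"{pred.name}:{d1_name}"))
            else:
                for col, label in _dummy_terms(long, pred):
                    terms.append((col * d2_col, f"{label}:{d2_name}"))
    lo, hi = coef_range
    betas = rng.uniform(lo, hi, size=len(terms))
    eta = np.full(len(long), float(intercept))
    coefs = {"(intercept)": float(intercept)}
    for (col, label), b in zip(terms, betas):
        eta += b * col
        coefs[label] = float(b)
    return eta, coefs


def _assemble_table(person_df, item_df, schema, y):
    long = make_long_frame(person_df, item_df)
    long.insert(0, "response", y.astype(int))
    long.insert(0, "item_id", long.pop("item_id"))
    long.insert(0, "person_id", long.pop("person_id"))
    return load_long_table(long, schema)


def gen_eirm_dataset(person_df, item_df, schema, eta, sigma2_person,
                     sigma2_item, seed: int) -> ResponseTable:
    """Bernoulli responses from the crossed random-intercept logistic model.

    Random effects are drawn fresh per call (per replication); ``eta`` is the
    fixed part from :func:`linear_predictor`, person-major.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    J, I = len(person_df), len(item_df)
    theta = rng.normal(0.0, math.sqrt(sigma2_person), J) if sigma2_person > 0 else np.zeros(J)
    b = rng.normal(0.0, math.sqrt(sigma2_item), I) if sigma2_item > 0 else np.zeros(I)
    lin = np.asarray(eta) + np.repeat(theta, I) + np.tile(b, J)
    y = (rng.random(J * I) < _expit(lin)).astype(int)
    return _assemble_table(person_df, item_df, schema, y)


# ---------------------------------------------------------------------------
# explicit decision trees as data-generating fixed parts


@dataclass
class TreeNode:
    feature: str
    kind: str  # 'continuous' or 'nominal'
    threshold: float = None       # continuous: go left when x <= threshold
    left_codes: tuple = None      # nominal: integer codes routed left
    left: object = None
    right: object = None

    def to_dict(self):
        return {
            "feature": self.feature, "kind": self.kind,
            "threshold": self.threshold,
            "left_codes": list(self.left_codes) if self.left_codes else None,
            "left": self.left.to_dict(), "right": self.right.to_dict(),
        }


@dataclass
class TreeLeaf:
    prob: float

    def to_dict(self):
        return {"prob": self.prob}


@dataclass
class TrueTree:
    """Explicit binary decision tree over forest-encoded features.

    ``predict`` maps an encoded feature frame (integer codes for nominal
    columns) to leaf probabilities; ``gamma0 + gamma1 * predict(x)`` is the
    fixed part on the logit scale when the tree generates outcomes.
    """

    root: object
    selected: tuple
    gamma0: float = -2.0
    gamma1: float = 4.0
    depth: int = 0

    def predict(self, data) -> np.ndarray:
        df = data if isinstance(data, pd.DataFrame) else pd.DataFrame(data)
        out = np.empty(len(df), dtype=float)
        self._fill(self.root, df, np.arange(len(df)), out)
        return out

    def _fill(self, node, df, idx, out):
        if isinstance(node, TreeLeaf):
            out[idx] = node.prob
            return
        x = df[node.feature].to_numpy()[idx]
        if node.kind == "continuous":
            mask = x <= node.threshold
        else:
            mask = np.isin(x, node.left_codes)
        self._fill(node.left, df, idx[mask], out)
        self._fill(node.right, df, idx[~mask], out)

    def to_dict(self):
        return {"selected": list(self.selected), "gamma0": self.gamma0,
                "gamma1": self.gamma1, "depth": self.depth,
                "root": self.root.to_dict()}

    @classmethod
    def from_dict(cls, d):
        def build(nd):
            if "prob" in nd:
                return TreeLeaf(prob=nd["prob"])
            return TreeNode(
                feature=nd["feature"], kind=nd["kind"],
                threshold=nd["threshold"],
                left_codes=tuple(nd["left_codes"]) if nd["left_codes"] else None,
                left=build(nd["left"]), right=build(nd["right"]),
            )
        return cls(root=build(d["root"]), selected=tuple(d["selected"]),
                   gamma0=d["gamma0"], gamma1=d["gamma1"], depth=d["depth"])


def encode_features(person_df, item_df, schema) -> pd.DataFrame:
    """Forest-style encoded long-format feature frame (one column/predictor)."""
    long = make_long_frame(person_df, item_df)
    out = {}
    for pred in schema:
        if pred.kind == "continuous":
            out[pred.name] = long[pred.name].to_numpy(dtype=float)
        else:
            mapping = {c: k for k, c in enumerate(pred.categories)}
            out[pred.name] = long[pred.name].map(mapping).to_numpy(dtype=float)
    return pd.DataFrame(out)


def gen_true_tree(person_df, item_df, schema: PredictorSchema, seed: int,
                  n_item_select: int = 2, n_person_select: int = 5,
                  depth_range=(3, 5), leaf_range=(0.05, 0.95),
                  gamma0: float = -2.0, gamma1: float = 4.0) -> TrueTree:
    """Grow a random generating tree on randomly selected predictors.

    Internal nodes pick a selected feature uniformly; continuous thresholds
    are uniform over the central 80% of observed values, nominal splits route
    a random nonempty proper subset of categories left.  Splits that leave a
    child empty among the rows reaching the node are resampled, falling back
    to a leaf.  Leaf probabilities are Uniform over ``leaf_range``.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    item_names = [p.name for p in schema if p.level == "item"]
    person_names = [p.name for p in schema if p.level == "person"]
    sel_items = list(rng.choice(item_names, size=n_item_select, replace=False))
    sel_persons = list(rng.choice(person_names, size=n_person_select, replace=False))
    selected = tuple(sel_items + sel_persons)
    feats = encode_features(person_df, item_df, schema)
    n_selected = len(selected)
    lo_d = max(depth_range[0], math.ceil(math.log2(n_selected + 1)))
    depth = int(rng.integers(lo_d, max(depth_range[1], lo_d) + 1))
    # every selected feature must appear in the tree at least once: internal
    # nodes first consume a shuffled queue of the selected features
    pending = list(rng.permutation(np.asarray(selected, dtype=object)))

    def grow(idx, d):
        if d == 0 or len(idx) < 2:
            return TreeLeaf(prob=float(rng.uniform(*leaf_range)))
        for attempt in range(20):
            if pending and attempt < 10:
                name = str(pending[0])
            else:
                name = str(rng.choice(selected))
            pred = schema[name]
            x = feats[name].to_numpy()[idx]
            if pred.kind == "continuous":
                full = feats[name].to_numpy()
                lo, hi = np.quantile(full, [0.1, 0.9])
                thr = float(rng.uniform(lo, hi))
                mask = x <= thr
                node = TreeNode(feature=name, kind="continuous", threshold=thr)
            else:
                K = len(pred.categories)
                size = int(rng.integers(1, K))
                codes = tuple(sorted(rng.choice(K, size=size, replace=False).tolist()))
                mask = np.isin(x, codes)
                node = TreeNode(feature=name, kind="nominal", left_codes=codes)
            if mask.any() and (~mask).any():
                if pending and str(pending[0]) == name:
                    pending.pop(0)
                node.left = grow(idx[mask], d - 1)
                node.right = grow(idx[~mask], d - 1)
                return node
        return TreeLeaf(prob=float(rng.uniform(*leaf_range)))

    root = grow(np.arange(len(feats)), depth)
    if isinstance(root, TreeLeaf):
        raise GenerationError("degenerate tree: root collapsed to a leaf")
    return TrueTree(root=root, selected=selected, gamma0=gamma0,
                    gamma1=gamma1, depth=depth)


def gen_eirmtree_dataset(tree: TrueTree, person_df, item_df, schema,
                         sigma2_person, sigma2_item, seed: int) -> ResponseTable:
    """Bernoulli responses with ``logit p = gamma0 + gamma1 p_tree + theta + b``."""
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    J, I = len(person_df), len(item_df)
    p_tree = tree.predict(encode_features(person_df, item_df, schema))
    theta = rng.normal(0.0, math.sqrt(sigma2_person), J) if sigma2_person > 0 else np.zeros(J)
    b = rng.normal(0.0, math.sqrt(sigma2_item), I) if sigma2_item > 0 else np.zeros(I)
    lin = tree.gamma0 + tree.gamma1 * p_tree + np.repeat(theta, I) + np.tile(b, J)
    y = (rng.random(J * I) < _expit(lin)).astype(int)
    return _assemble_table(person_df, item_df, schema, y)


def tree_importance(tree: TrueTree, feats: pd.DataFrame) -> pd.Series:
    """Impurity-decrease importance of the generating tree itself.

    Node impurity is the Gini index ``2 p(1-p)`` of the mean tree probability
    over the rows reaching the node; each split credits its weighted impurity
    decrease to the split feature.  Features the tree never uses score exactly
    zero.
    """
    probs = tree.predict(feats)
    n = len(feats)
    imp = {name: 0.0 for name in feats.columns}

    def gini(idx):
        if len(idx) == 0:
            return 0.0
        p = probs[idx].mean()
        return 2.0 * p * (1.0 - p)

    def walk(node, idx):
        if isinstance(node, TreeLeaf) or len(idx) == 0:
            return
        x = feats[node.feature].to_numpy()[idx]
        mask = (x <= node.threshold) if node.kind == "continuous" \
            else np.isin(x, node.left_codes)
        li, ri = idx[mask], idx[~mask]
        decrease = (len(idx) * gini(idx) - len(li) * gini(li)
                    - len(ri) * gini(ri)) / n
        imp[node.feature] += max(decrease, 0.0)
        walk(node.left, li)
        walk(node.right, ri)

    walk(tree.root, np.arange(n))
    return pd.Series(imp)


def distill_forest(tree: TrueTree, feats: pd.DataFrame, mtry: int = 4,
                   n_trees: int = 500, seed: int = 0):
    """Noise-free forest surrogate of the generating tree.

    Fits a Gini random forest to the tree's exact leaf probabilities by
    duplicating every row with class labels 1 and 0 weighted by ``p`` and
    ``1 - p``.  Returns ``(predict_fn, importances)``.  Deriving ground-truth
    interpretation values from this surrogate (rather than from the bare
    tree) puts truth and estimate on the same footing: both carry the
    forest's own dialect (smoothing, split-eligibility biases), so agreement
    scores isolate the effect of noise and random effects rather than the
    tree-vs-forest representation gap.
    """
    from sklearn.ensemble import RandomForestClassifier

    X = feats.to_numpy(dtype=float)
    p = tree.predict(feats)
    Xd = np.vstack([X, X])
    yd = np.concatenate([np.ones(len(X)), np.zeros(len(X))])
    wd = np.concatenate([p, 1.0 - p])
    model = RandomForestClassifier(
        n_estimators=n_trees, max_features=min(mtry, X.shape[1]),
        min_samples_leaf=1, criterion="gini", random_state=seed, n_jobs=1,
    ).fit(Xd, yd, sample_weight=wd)
    col1 = list(model.classes_).index(1)

    def predict_fn(df):
        arr = df.to_numpy(dtype=float) if isinstance(df, pd.DataFrame) else np.asarray(df, dtype=float)
        return model.predict_proba(arr)[:, col1]

    return predict_fn, pd.Series(model.feature_importances_, index=feats.columns)


def true_interpretation_values(tree: TrueTree, person_df, item_df, schema,
                               mode: str = "rf", grid_size: int = 15,
                               ale_bins: int = 8, h_sample: int = 100,
                               mtry: int = 4, n_trees: int = 500,
                               seed: int = 0) -> dict:
    """Ground-truth interpretation values for the generating tree.

    ``mode='rf'`` (default) interprets a forest distilled onto the tree's
    exact probabilities (see :func:`distill_forest`); ``mode='tree'``
    interprets the bare tree function itself, in which case features the tree
    never splits on receive an importance of exactly zero and flat curves.
    """
    from .interpret import (accumulated_local_effects, h_statistic,
                            partial_dependence)

    if mode not in ("rf", "tree"):
        raise ValueError("mode must be 'rf' or 'tree'")
    feats = encode_features(person_df, item_df, schema)
    if mode == "tree":
        predict_fn = tree.predict
        importance = tree_importance(tree, feats)
    else:
        predict_fn, importance = distill_forest(tree, feats, mtry=mtry,
                                                n_trees=n_trees, seed=seed)
    out = {"importance": importance, "pd": {}, "ale": {}, "h": {},
           "mode": mode}
    cont = [p.name for p in schema if p.kind == "continuous"]
    for name in feats.columns:
        out["pd"][name] = partial_dependence(predict_fn, feats, name,
                                             grid_size=grid_size)
        if name in cont:
            out["ale"][name] = accumulated_local_effects(predict_fn, feats,
                                                         name, n_bins=ale_bins)
        out["h"][name] = h_statistic(predict_fn, feats, name,
                                     n_sample=min(h_sample, len(feats)),
                                     seed=seed).value
    return out
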