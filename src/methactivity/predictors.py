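"""Component regressors (random forest, elastic net, 1-D CNN), ensemble
combination rules, permutation feature importance, and model-bundle
(de)serialization.

The random forest is a hand-assembled committee of decision trees, each grown
on an 80% subsample drawn WITHOUT replacement (plain random subsampling, not
a bootstrap). The elastic net follows the glmnet parametrization with a fixed
l1/l2 mix of 0.5 and the penalty weight chosen by internal 10-fold CV over a
log-spaced path. The CNN is the numpy implementation in :mod:`.cnn`.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
from scipy.stats import spearmanr
from sklearn.linear_model import ElasticNetCV
from sklearn.model_selection import KFold
from sklearn.tree import DecisionTreeRegressor

from .cnn import Conv1DRegressor
from .features import FeatureTensor
from .io_formats import ExpressionMatrix

__all__ = [
    "TrainedModel",
    "EnsembleModel",
    "subsample_training_pairs",
    "train_random_forest",
    "train_elastic_net",
    "train_cnn",
    "train_ensemble",
    "predict",
    "feature_importance",
    "save_bundle",
    "load_bundle",
]

MODEL_KINDS = ("random_forest", "elastic_net", "cnn")
ENSEMBLE_RULES = ("unweighted", "weighted_correlation", "weighted_accuracy", "stacking")


@dataclass
class TrainedModel:
    """A fitted component regressor plus the feature layout it expects."""

    model_kind: str
    model: object
    feature_order: list[str]
    hyperparams: dict = field(default_factory=dict)
    training_max_log_expr: float | None = None

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.shape[1] != len(self.feature_order):
            raise ValueError(
                f"feature layout mismatch: model expects {len(self.feature_order)} "
                f"columns, got {X.shape[1]}"
            )
        if self.model_kind == "random_forest":
            return self.model.predict(X)
        if self.model_kind == "elastic_net":
            coef, intercept = self.model["coef"], self.model["intercept"]
            return X @ coef + intercept
        if self.model_kind == "cnn":
            return self.model.predict(X)
        raise ValueError(f"unknown model kind {self.model_kind!r}")


@dataclass
class EnsembleModel:
    components: list[TrainedModel]
    rule: str = "unweighted"
    weights: np.ndarray | None = None  # nonnegative, sums to 1 (weighted rules)
    stacker: TrainedModel | None = None
    feature_order: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.rule not in ENSEMBLE_RULES:
            raise ValueError(f"unknown ensemble rule {self.rule!r}")
        if not self.feature_order and self.components:
            self.feature_order = self.components[0].feature_order
        if self.rule.startswith("weighted"):
            if self.weights is None:
                raise ValueError("weighted rules need weights")
            self.weights = np.asarray(self.weights, dtype=float)
            if np.any(self.weights < 0) or not np.isclose(self.weights.sum(), 1.0):
                raise ValueError("weights must be nonnegative and sum to 1")
        if self.rule == "stacking" and self.stacker is None:
            raise ValueError("stacking rule needs a second-layer model")

    def component_outputs(self, X: np.ndarray) -> np.ndarray:
        return np.column_stack([c.predict(X) for c in self.components])

    def predict(self, X: np.ndarray) -> np.ndarray:
        outs = self.component_outputs(X)
        if self.rule == "unweighted":
            return outs.mean(axis=1)
        if self.rule in ("weighted_correlation", "weighted_accuracy"):
            return outs @ self.weights
        return self.stacker.predict(outs)


# ---------------------------------------------------------------------------
# training data
# ---------------------------------------------------------------------------

def subsample_training_pairs(
    tensor: FeatureTensor,
    targets: ExpressionMatrix,
    n: int = 100_000,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Seeded uniform subsample (without replacement) of eligible pairs.

    A pair is eligible when both its gene and cell exist in ``targets`` and
    the target value is finite. Targets are expected on the normalized [0, 1]
    scale. When fewer than ``n`` pairs exist, all are returned in their
    original gene-major order.
    """
    gmap = {g: i for i, g in enumerate(targets.genes)}
    cmap = {c: i for i, c in enumerate(targets.cells)}
    y_all = np.full(len(tensor), np.nan)
    for r in range(len(tensor)):
        g = tensor.gene_ids[tensor.pair_gene_idx[r]]
        c = tensor.cell_ids[tensor.pair_cell_idx[r]]
        if g in gmap and c in cmap:
            y_all[r] = targets.values[gmap[g], cmap[c]]
    eligible = np.nonzero(np.isfinite(y_all))[0]
    if len(eligible) == 0:
        raise ValueError("no (gene, cell) pairs with available expression")
    if len(eligible) > n:
        rng = np.random.default_rng(seed)
        eligible = np.sort(rng.choice(eligible, size=n, replace=False))
    X = tensor.X[eligible]
    return X, y_all[eligible]


# ---------------------------------------------------------------------------
# component learners
# ---------------------------------------------------------------------------

class _SubsampleForest:
    """Regression forest of trees each fit on a without-replacement subsample."""

    def __init__(self, n_trees: int, sample_frac: float, max_features, seed: int):
        self.n_trees = n_trees
        self.sample_frac = sample_frac
        self.max_features = max_features
        self.seed = seed
        self.trees_: list[DecisionTreeRegressor] = []

    def fit(self, X: np.ndarray, y: np.ndarray) -> "_SubsampleForest":
        rng = np.random.default_rng(self.seed)
        n = len(y)
        m = max(1, int(np.ceil(self.sample_frac * n)))
        self.trees_ = []
        for t in range(self.n_trees):
            idx = rng.choice(n, size=m, replace=False)
            tree = DecisionTreeRegressor(
                max_features=self.max_features,
                random_state=int(rng.integers(0, 2**31 - 1)),
            )
            tree.fit(X[idx], y[idx])
            self.trees_.append(tree)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        out = np.zeros(X.shape[0])
        for tree in self.trees_:
            out += tree.predict(X)
        return out / len(self.trees_)


def _default_feature_order(n_cols: int) -> list[str]:
    half = n_cols // 2
    return [f"cpg_{i + 1:02d}" for i in range(half)] + [f"mr_{i + 1:02d}" for i in range(half)]


def train_random_forest(
    X: np.ndarray,
    y: np.ndarray,
    n_trees: int = 500,
    sample_frac: float = 0.8,
    seed: int = 0,
    max_features: float | str = 1 / 3,
    feature_order: Sequence[str] | None = None,
) -> TrainedModel:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if len(np.unique(y)) < 2:
        warnings.warn("constant training target; forest will predict the constant")
    forest = _SubsampleForest(n_trees, sample_frac, max_features, seed).fit(X, y)
    return TrainedModel(
        model_kind="random_forest",
        model=forest,
        feature_order=list(feature_order or _default_feature_order(X.shape[1])),
        hyperparams={"n_trees": n_trees, "sample_frac": sample_frac, "seed": seed},
    )


def train_elastic_net(
    X: np.ndarray,
    y: np.ndarray,
    alpha_mix: float = 0.5,
    n_cv_folds: int = 10,
    seed: int = 0,
    n_lambdas: int = 100,
    lambda_min_ratio: float = 1e-4,
    feature_order: Sequence[str] | None = None,
) -> TrainedModel:
    """Elastic net with internal K-fold CV over a log-spaced penalty path.

    Features are standardized internally; stored coefficients are mapped back
    to the original scale so prediction is a plain affine map.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if len(y) < n_cv_folds:
        raise ValueError(f"need at least {n_cv_folds} samples for {n_cv_folds}-fold CV")
    mu, sd = X.mean(axis=0), X.std(axis=0)
    sd_safe = np.where(sd == 0, 1.0, sd)
    Xs = (X - mu) / sd_safe
    cv = KFold(n_splits=n_cv_folds, shuffle=True, random_state=seed)
    enet = ElasticNetCV(
        l1_ratio=alpha_mix,
        alphas=n_lambdas,  # int -> length of the automatic log-spaced path
        eps=lambda_min_ratio,
        cv=cv,
        max_iter=5000,
        random_state=seed,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        enet.fit(Xs, y)
    coef = enet.coef_ / sd_safe
    intercept = float(enet.intercept_ - np.dot(coef, mu))
    return TrainedModel(
        model_kind="elastic_net",
        model={"coef": coef, "intercept": intercept, "lambda": float(enet.alpha_)},
        feature_order=list(feature_order or _default_feature_order(X.shape[1])),
        hyperparams={"alpha_mix": alpha_mix, "n_cv_folds": n_cv_folds, "seed": seed},
    )


def train_cnn(
    X: np.ndarray,
    y: np.ndarray,
    n_filters: int = 50,
    kernel: int = 5,
    pool: int = 4,
    dropout: float = 0.2,
    patience: int = 10,
    seed: int = 0,
    dense_units: int = 64,
    max_epochs: int = 200,
    feature_order: Sequence[str] | None = None,
) -> TrainedModel:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    seq_len = X.shape[1] // 2
    net = Conv1DRegressor(
        seq_len=seq_len,
        n_channels=2,
        n_filters=n_filters,
        kernel=kernel,
        pool=pool,
        dropout=dropout,
        dense_units=dense_units,
        patience=patience,
        max_epochs=max_epochs,
        seed=seed,
    ).fit(X, y)
    return TrainedModel(
        model_kind="cnn",
        model=net,
        feature_order=list(feature_order or _default_feature_order(X.shape[1])),
        hyperparams={
            "n_filters": n_filters,
            "kernel": kernel,
            "pool": pool,
            "dropout": dropout,
            "patience": patience,
            "dense_units": dense_units,
            "seed": seed,
        },
    )


_TRAINERS = {
    "random_forest": train_random_forest,
    "elastic_net": train_elastic_net,
    "cnn": train_cnn,
}


# ---------------------------------------------------------------------------
# ensembles
# ---------------------------------------------------------------------------

def _train_components(
    X: np.ndarray, y: np.ndarray, seed: int, component_params: dict | None
) -> list[TrainedModel]:
    component_params = component_params or {}
    out = []
    for offset, kind in enumerate(MODEL_KINDS):
        kwargs = dict(component_params.get(kind, {}))
        kwargs.setdefault("seed", seed + offset)
        out.append(_TRAINERS[kind](X, y, **kwargs))
    return out


def train_ensemble(
    X: np.ndarray,
    y: np.ndarray,
    rule: str = "unweighted",
    seed: int = 0,
    cv_folds: int = 5,
    component_params: dict | None = None,
) -> EnsembleModel:
    """Train the three components and combine them under ``rule``.

    Weighted rules derive per-component weights from seeded internal K-fold
    CV on the training data: the median across folds of each component's
    held-out Spearman correlation (``weighted_correlation``) or of
    1 - held-out MSE (``weighted_accuracy``), clipped at 0 and renormalized.
    Stacking trains an elastic net on out-of-fold component predictions.
    """
    if rule not in ENSEMBLE_RULES:
        raise ValueError(f"unknown ensemble rule {rule!r}")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    components = _train_components(X, y, seed, component_params)
    if rule == "unweighted":
        return EnsembleModel(components=components, rule=rule)

    kf = KFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    fold_corr = {kind: [] for kind in MODEL_KINDS}
    fold_acc = {kind: [] for kind in MODEL_KINDS}
    oof = np.zeros((len(y), len(MODEL_KINDS)))
    for fold_i, (tr, te) in enumerate(kf.split(X)):
        fold_components = _train_components(
            X[tr], y[tr], seed + 1000 * (fold_i + 1), component_params
        )
        for j, comp in enumerate(fold_components):
            pred = comp.predict(X[te])
            oof[te, j] = pred
            rho = spearmanr(pred, y[te]).statistic
            fold_corr[MODEL_KINDS[j]].append(0.0 if np.isnan(rho) else float(rho))
            fold_acc[MODEL_KINDS[j]].append(1.0 - float(np.mean((pred - y[te]) ** 2)))

    if rule in ("weighted_correlation", "weighted_accuracy"):
        stats = fold_corr if rule == "weighted_correlation" else fold_acc
        w = np.array([np.median(stats[k]) for k in MODEL_KINDS])
        w = np.clip(w, 0.0, None)
        if w.sum() == 0:
            w = np.ones_like(w)
        w = w / w.sum()
        return EnsembleModel(components=components, rule=rule, weights=w)

    stacker = train_elastic_net(
        oof, y, seed=seed + 7, feature_order=[f"component_{k}" for k in MODEL_KINDS]
    )
    return EnsembleModel(components=components, rule="stacking", stacker=stacker)


def predict(model: TrainedModel | EnsembleModel, X: np.ndarray) -> np.ndarray:
    out = model.predict(np.asarray(X, dtype=float))
    if not np.all(np.isfinite(out)):
        raise FloatingPointError("model produced non-finite predictions")
    return out


# ---------------------------------------------------------------------------
# permutation feature importance
# ---------------------------------------------------------------------------

def feature_importance(
    model: TrainedModel,
    X: np.ndarray,
    y: np.ndarray,
    n_repeats: int = 5,
    seed: int = 0,
) -> np.ndarray:
    """Permutation importance: mean over repeats of (permuted MSE - base MSE)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    rng = np.random.default_rng(seed)
    base_mse = float(np.mean((model.predict(X) - y) ** 2))
    scores = np.zeros(X.shape[1])
    for f in range(X.shape[1]):
        diffs = []
        for _ in range(n_repeats):
            Xp = X.copy()
            Xp[:, f] = Xp[rng.permutation(X.shape[0]), f]
            diffs.append(float(np.mean((model.predict(Xp) - y) ** 2)) - base_mse)
        scores[f] = np.mean(diffs)
    return scores


# ---------------------------------------------------------------------------
# model bundles
# ---------------------------------------------------------------------------

def save_bundle(ensemble: EnsembleModel, path: str | Path, extra_meta: dict | None = None) -> None:
    """Serialize an ensemble to a directory (JSON metadata + parameter files)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    meta = {
        "rule": ensemble.rule,
        "feature_order": ensemble.feature_order,
        "weights": None if ensemble.weights is None else ensemble.weights.tolist(),
        "components": [],
        "has_stacker": ensemble.stacker is not None,
    }
    if extra_meta:
        meta["extra"] = extra_meta

    def dump_component(comp: TrainedModel, stem: str) -> dict:
        entry = {
            "model_kind": comp.model_kind,
            "feature_order": comp.feature_order,
            "hyperparams": comp.hyperparams,
            "training_max_log_expr": comp.training_max_log_expr,
            "file": None,
        }
        if comp.model_kind == "elastic_net":
            entry["file"] = f"{stem}.json"
            with open(path / entry["file"], "w") as fh:
                json.dump(
                    {
                        "coef": list(map(float, comp.model["coef"])),
                        "intercept": comp.model["intercept"],
                        "lambda": comp.model.get("lambda"),
                    },
                    fh,
                )
        elif comp.model_kind == "cnn":
            entry["file"] = f"{stem}.npz"
            np.savez(path / entry["file"], **comp.model.get_weights())
            entry["cnn_config"] = {
                "seq_len": comp.model.seq_len,
                "n_channels": comp.model.n_channels,
                "n_filters": comp.model.n_filters,
                "kernel": comp.model.kernel,
                "pool": comp.model.pool,
                "dropout": comp.model.dropout,
                "dense_units": comp.model.dense_units,
            }
        else:  # random forest: tree objects via joblib
            entry["file"] = f"{stem}.joblib"
            joblib.dump(comp.model, path / entry["file"])
        return entry

    for comp in ensemble.components:
        meta["components"].append(dump_component(comp, comp.model_kind))
    if ensemble.stacker is not None:
        meta["stacker"] = dump_component(ensemble.stacker, "stacker")
    with open(path / "metadata.json", "w") as fh:
        json.dump(meta, fh, indent=2)


def load_bundle(path: str | Path) -> EnsembleModel:
    path = Path(path)
    with open(path / "metadata.json") as fh:
        meta = json.load(fh)

    def load_component(entry: dict) -> TrainedModel:
        kind = entry["model_kind"]
        if kind == "elastic_net":
            with open(path / entry["file"]) as fh:
                data = json.load(fh)
            model = {
                "coef": np.asarray(data["coef"], dtype=float),
                "intercept": float(data["intercept"]),
                "lambda": data.get("lambda"),
            }
        elif kind == "cnn":
            cfg = entry["cnn_config"]
            net = Conv1DRegressor(**cfg)
            with np.load(path / entry["file"]) as npz:
                net.set_weights({k: npz[k] for k in npz.files})
            model = net
        else:
            model = joblib.load(path / entry["file"])
        return TrainedModel(
            model_kind=kind,
            model=model,
            feature_order=entry["feature_order"],
            hyperparams=entry.get("hyperparams", {}),
            training_max_log_expr=entry.get("training_max_log_expr"),
        )

    components = [load_component(e) for e in meta["components"]]
    stacker = load_component(meta["stacker"]) if meta.get("has_stacker") else None
    weights = None if meta["weights"] is None else np.asarray(meta["weights"], dtype=float)
    return EnsembleModel(
        components=components,
        rule=meta["rule"],
        weights=weights,
        stacker=stacker,
        feature_order=meta["feature_order"],
    )
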