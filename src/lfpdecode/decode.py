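"""Decoder training and evaluation.

Threefold cross-validation over contiguous temporal blocks (lagged features
overlap in time, so shuffled splits would leak), the percent coefficient of
determination as the score, the 3-D CNN decoder and the PLS / Lasso linear
baselines, and the fixed electrode-subset groupings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.compose import TransformedTargetRegressor
from sklearn.cross_decomposition import PLSRegression
from sklearn.linear_model import Lasso
from sklearn.model_selection import GridSearchCV, KFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from .cnn import CNN3DRegressor, CNNConfig
from .preprocess import FeatureNormalizer, FeatureTensorSeries
from .session import JOINT_NAMES

__all__ = [
    "CHANNEL_SUBSETS",
    "DecodeResult",
    "r_squared",
    "subset_channels",
    "fit_baseline",
    "fit_fold",
    "train_cnn",
    "crossvalidate",
]


def train_cnn(
    features: "FeatureTensorSeries | np.ndarray",
    target: np.ndarray,
    config: CNNConfig | None = None,
) -> CNN3DRegressor:
    """Train one single-output 3-D CNN on (already normalised) tensors."""
    tensors = getattr(features, "tensors", features)
    return CNN3DRegressor(config).fit(np.asarray(tensors), np.asarray(target))

#: Electrode groupings (1-based electrode numbers).
CHANNEL_SUBSETS: dict[str, tuple[int, ...]] = {
    "lateral": (1, 4, 5, 8),
    "dorsal": (2, 3, 6, 7),
    "left": (3, 4, 7, 8),
    "right": (1, 2, 5, 6),
    "all": (1, 2, 3, 4, 5, 6, 7, 8),
}


def r_squared(y: np.ndarray, y_hat: np.ndarray) -> float:
    """Coefficient of determination in percent.

    ``(1 - sum((y - y_hat)^2) / sum((y - mean(y))^2)) * 100``; may be
    negative.  Raises for a constant measured series (zero total sum of
    squares).
    """
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y.shape != y_hat.shape:
        raise ValueError("series lengths differ")
    if y.size < 2:
        raise ValueError("need at least two samples")
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("measured series is constant; R^2 is undefined")
    ss_res = float(np.sum((y - y_hat) ** 2))
    return (1.0 - ss_res / ss_tot) * 100.0


def subset_channels(features: FeatureTensorSeries, subset: str) -> FeatureTensorSeries:
    """Reduce the channel axis to one of the electrode groupings."""
    if subset not in CHANNEL_SUBSETS:
        raise ValueError(
            f"unknown subset '{subset}'; expected one of {sorted(CHANNEL_SUBSETS)}"
        )
    if subset == "all":
        return features
    idx = [e - 1 for e in CHANNEL_SUBSETS[subset]]
    if max(idx) >= features.n_channels:
        raise ValueError("feature tensor has too few channels for this subset")
    return FeatureTensorSeries(
        tensors=features.tensors[:, idx, :, :],
        times=features.times,
        feature_names=features.feature_names,
    )


def _contiguous_folds(n: int, k: int) -> list[np.ndarray]:
    if n < 2 * k:
        raise ValueError(f"too few samples ({n}) for {k} folds")
    return list(np.array_split(np.arange(n), k))


def fit_baseline(
    X: np.ndarray, y: np.ndarray, method: str, seed: int = 0, inner_folds: int = 3
):
    """Fit a linear baseline on flattened feature vectors.

    Hyperparameters (PLS component count, Lasso penalty) are chosen by an
    inner cross-validation over contiguous splits of the training data only.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.allclose(X.std(axis=0), 0):
        raise ValueError("features are constant; cannot fit a baseline")
    cv = KFold(n_splits=inner_folds, shuffle=False)
    if method == "pls":
        max_comp = min(30, X.shape[1], X.shape[0] - 1)
        grid = {"model__n_components": [c for c in (2, 5, 10, 20, 30) if c <= max_comp]}
        pipe = Pipeline(
            [("scale", StandardScaler()), ("model", PLSRegression(scale=False))]
        )
    elif method == "lasso":
        # alphas are on the standardised-target scale (see below)
        grid = {"model__regressor__alpha": list(np.logspace(-3, -0.5, 6))}
        lasso = TransformedTargetRegressor(
            regressor=Lasso(max_iter=3000, tol=1e-3, random_state=seed),
            transformer=StandardScaler(),
        )
        pipe = Pipeline([("scale", StandardScaler()), ("model", lasso)])
    else:
        raise ValueError(f"unknown baseline '{method}'")
    search = GridSearchCV(pipe, grid, cv=cv, scoring="neg_mean_squared_error", n_jobs=1)
    search.fit(X, y)
    return search.best_estimator_


@dataclass
class DecodeResult:
    """Per-joint, per-fold decoding performance for one decoder/subset."""

    decoder: str
    subset: str
    r2: np.ndarray  # (n_joints, n_folds), percent
    fold_bounds: list[tuple[int, int]]
    seed: int
    joint_names: tuple[str, ...] = JOINT_NAMES

    @property
    def mean_per_joint(self) -> np.ndarray:
        return self.r2.mean(axis=1)

    @property
    def mean(self) -> float:
        return float(self.r2.mean())

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "decoder": self.decoder,
                "subset": self.subset,
                "joint": self.joint_names[j],
                "fold": f,
                "r2": self.r2[j, f],
            }
            for j in range(self.r2.shape[0])
            for f in range(self.r2.shape[1])
        ]
        return pd.DataFrame(rows)


def fit_fold(
    tensors: np.ndarray,
    target: np.ndarray,
    train_idx: np.ndarray,
    decoder: str,
    seed: int = 0,
    cnn_config: CNNConfig | None = None,
):
    """Fit one decoder on one training fold.

    All training artifacts (normalisation statistics, hyperparameters,
    weights) depend on ``tensors[train_idx]`` only.  Returns
    ``(model, normalizer)`` where ``model.predict`` consumes normalised
    tensors (CNN) or normalised flattened vectors (baselines).
    """
    norm = FeatureNormalizer().fit(tensors[train_idx])
    Xtr = norm.transform(tensors[train_idx])
    ytr = target[train_idx]
    if decoder == "cnn":
        cfg = (cnn_config or CNNConfig()).with_seed(seed)
        model = CNN3DRegressor(cfg).fit(Xtr, ytr)
    elif decoder in ("pls", "lasso"):
        model = fit_baseline(Xtr.reshape(len(train_idx), -1), ytr, decoder, seed=seed)
    else:
        raise ValueError(f"unknown decoder '{decoder}'")
    return model, norm


def _predict_fold(model, norm, tensors, test_idx, decoder):
    Xte = norm.transform(tensors[test_idx])
    if decoder == "cnn":
        return model.predict(Xte)
    return np.ravel(model.predict(Xte.reshape(len(test_idx), -1)))


def crossvalidate(
    features: FeatureTensorSeries,
    targets: np.ndarray,
    decoder: str = "cnn",
    k: int = 3,
    seed: int = 0,
    cnn_config: CNNConfig | None = None,
    subset: str = "all",
    joints: list[int] | None = None,
    folds: list[int] | None = None,
) -> DecodeResult:
    """K-fold cross-validation with contiguous temporal folds.

    Parameters
    ----------
    features : FeatureTensorSeries
    targets : ndarray, shape (n_joints, n_times)
    decoder : 'cnn' | 'pls' | 'lasso'
    joints, folds : optional index lists to restrict the evaluation (the
        result array keeps one row per requested joint / fold).
    """
    feats = subset_channels(features, subset)
    tensors = feats.tensors
    targets = np.atleast_2d(np.asarray(targets, dtype=float))
    if targets.shape[1] != tensors.shape[0]:
        raise ValueError("targets are not aligned with the feature tensors")
    fold_idx = _contiguous_folds(tensors.shape[0], k)
    joints = list(range(targets.shape[0])) if joints is None else list(joints)
    folds = list(range(k)) if folds is None else list(folds)
    r2 = np.empty((len(joints), len(folds)))
    for ff, f in enumerate(folds):
        test_idx = fold_idx[f]
        train_idx = np.concatenate([fold_idx[g] for g in range(k) if g != f])
        norm = FeatureNormalizer().fit(tensors[train_idx])
        Xtr = norm.transform(tensors[train_idx])
        Xte = norm.transform(tensors[test_idx])
        if decoder == "cnn":
            cfg = cnn_config or CNNConfig()
            # patch extraction is joint-independent; share it across joints
            proto = CNN3DRegressor(cfg)
            ptr = proto._extract_patches(Xtr.astype(np.float32))
            pte = proto._extract_patches(Xte.astype(np.float32))
            for jj, j in enumerate(joints):
                model = CNN3DRegressor(cfg.with_seed(seed * 1000 + j * 10 + f))
                model.fit(Xtr, targets[j, train_idx], patches=ptr)
                pred = model.predict(Xte, patches=pte)
                r2[jj, ff] = r_squared(targets[j, test_idx], pred)
        else:
            Xtr_flat = Xtr.reshape(len(train_idx), -1)
            Xte_flat = Xte.reshape(len(test_idx), -1)
            for jj, j in enumerate(joints):
                model = fit_baseline(
                    Xtr_flat, targets[j, train_idx], decoder, seed=seed * 1000 + j * 10 + f
                )
                pred = np.ravel(model.predict(Xte_flat))
                r2[jj, ff] = r_squared(targets[j, test_idx], pred)
    joint_names = tuple(JOINT_NAMES[j] for j in joints)
    return DecodeResult(
        decoder=decoder,
        subset=subset,
        r2=r2,
        fold_bounds=[(int(fi[0]), int(fi[-1]) + 1) for fi in fold_idx],
        seed=seed,
        joint_names=joint_names,
    )
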