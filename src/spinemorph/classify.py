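"""Expert consensus labels and SVM classification of spine shapes.

Each spine is labeled independently by several experts as mushroom, thin,
stubby, filopodia or outlier; the consensus label is the modal vote, with
any tie declared an outlier.  For training, outlier and filopodia spines
are dropped, the remaining classes are balanced by seeded undersampling to
the minority count, and classic features are z-scored.  Multiclass SVMs
(one-vs-one) are trained with linear, RBF, histogram-intersection (HIS) or
Laplacian-RBF kernels; HIS and Laplacian are supplied to the solver as
precomputed Gram matrices.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedShuffleSplit
from sklearn.svm import SVC

CLASSES = ("mushroom", "thin", "stubby", "filopodia", "outlier")
KERNELS = ("rbf", "his", "laplacian", "linear")


def build_consensus(labels: pd.DataFrame) -> pd.Series:
    """Modal expert label per spine; ties for the mode become ``outlier``.

    ``labels``: one row per spine (index = spine id), one column per expert.
    """
    if labels.shape[0] == 0 or labels.shape[1] == 0:
        raise ValueError("empty expert label table")
    bad = set(np.unique(labels.values.astype(str))) - set(CLASSES)
    if bad:
        raise ValueError(f"unknown labels: {sorted(bad)}")
    out = {}
    for sid, row in labels.iterrows():
        counts = Counter(row.astype(str))
        top = counts.most_common()
        if len(top) > 1 and top[0][1] == top[1][1]:
            out[sid] = "outlier"
        else:
            out[sid] = top[0][0]
    return pd.Series(out, name="consensus").loc[labels.index]


def expert_agreement(labels: pd.DataFrame) -> dict:
    """Agreement summary: fraction of spines with unanimous votes and the
    fraction with no consensus (tied mode)."""
    consensus = build_consensus(labels)
    unanimous = (labels.nunique(axis=1) == 1).mean()
    tied = 0
    for sid, row in labels.iterrows():
        top = Counter(row.astype(str)).most_common()
        if len(top) > 1 and top[0][1] == top[1][1]:
            tied += 1
    return {
        "unanimous_fraction": float(unanimous),
        "no_consensus_fraction": tied / len(labels),
        "consensus": consensus,
    }


def per_expert_accuracy(labels: pd.DataFrame) -> pd.Series:
    """Fraction of each expert's labels matching the consensus, over spines
    whose consensus is not outlier (the human baseline for the classifier)."""
    consensus = build_consensus(labels)
    keep = consensus != "outlier"
    sub = labels.loc[keep]
    return sub.eq(consensus.loc[keep], axis=0).mean(axis=0)


def prepare_dataset(
    features: pd.DataFrame,
    consensus: pd.Series,
    balance_seed: int = 0,
    classic_columns=None,
    drop=("outlier", "filopodia"),
):
    """Filter, balance and standardize the labeled feature table.

    Outlier and filopodia spines are removed; remaining classes are
    randomly undersampled to the minority-class count (seeded); classic
    feature columns are z-scored with the scaler parameters retained.

    Returns (DataFrame with a ``label`` column, scaler dict with keys
    ``columns``, ``mean``, ``std``).
    """
    common = features.index.intersection(consensus.index)
    if len(common) == 0:
        raise ValueError("feature rows and consensus ids do not align")
    X = features.loc[common].copy()
    y = consensus.loc[common].astype(str)
    keep = ~y.isin(drop)
    X, y = X.loc[keep], y.loc[keep]
    if len(X) == 0:
        raise ValueError("no spines survive outlier/filopodia removal")
    counts = y.value_counts()
    if (counts == 0).any() or len(counts) == 0:
        raise ValueError("a surviving class is empty")
    n_min = int(counts.min())
    rng = np.random.default_rng(balance_seed)
    chosen = []
    for cls in sorted(counts.index):
        ids = y.index[y == cls].to_numpy()
        chosen.extend(rng.choice(ids, size=n_min, replace=False).tolist())
    X, y = X.loc[chosen], y.loc[chosen]

    if classic_columns is None:
        classic_columns = [c for c in X.columns if not str(c).startswith("cldh")]
    mean = X[classic_columns].mean()
    std = X[classic_columns].std(ddof=0).replace(0.0, 1.0)
    X[classic_columns] = (X[classic_columns] - mean) / std
    X["label"] = y
    scaler = {"columns": list(classic_columns), "mean": mean, "std": std}
    return X, scaler


def kernel_eval(name, x, y, params=None):
    """Evaluate a kernel on two vectors (or two stacked matrices).

    rbf(x,y)       = exp(-||x-y||^2 / 2 sigma^2)
    his(x,y)       = sum_i min(x_i, y_i)          (histogram intersection)
    laplacian(x,y) = exp(-gamma ||x-y||_1)
    linear(x,y)    = <x, y>
    """
    params = params or {}
    x = np.atleast_2d(np.asarray(x, dtype=float))
    y = np.atleast_2d(np.asarray(y, dtype=float))
    if x.shape[1] != y.shape[1]:
        raise ValueError("dimension mismatch")
    if name == "rbf":
        sigma = float(params.get("sigma", 1.0))
        if sigma <= 0:
            raise ValueError("sigma must be > 0")
        d2 = ((x[:, None, :] - y[None, :, :]) ** 2).sum(axis=2)
        out = np.exp(-d2 / (2.0 * sigma**2))
    elif name == "his":
        out = np.minimum(x[:, None, :], y[None, :, :]).sum(axis=2)
    elif name == "laplacian":
        gamma = float(params.get("gamma", 1.0))
        if gamma <= 0:
            raise ValueError("gamma must be > 0")
        d1 = np.abs(x[:, None, :] - y[None, :, :]).sum(axis=2)
        out = np.exp(-gamma * d1)
    elif name == "linear":
        out = x @ y.T
    else:
        raise ValueError(f"unknown kernel {name!r}; choose from {KERNELS}")
    if out.size == 1:
        return float(out[0, 0])
    return out


def median_heuristic(X):
    """Default kernel scales: sigma = median pairwise Euclidean distance,
    gamma = 1 / median pairwise L1 distance."""
    X = np.asarray(X, dtype=float)
    n = len(X)
    idx = np.triu_indices(n, k=1)
    d2 = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(axis=2))[idx]
    d1 = np.abs(X[:, None, :] - X[None, :, :]).sum(axis=2)[idx]
    sigma = float(np.median(d2)) or 1.0
    med1 = float(np.median(d1)) or 1.0
    return {"sigma": sigma, "gamma": 1.0 / med1}


@dataclass
class TrainedClassifier:
    """A fitted multiclass SVM plus everything needed to predict.

    HIS/Laplacian kernels keep the training matrix to rebuild the Gram
    block at prediction time.
    """

    kernel: str
    params: dict
    C: float
    svc: SVC
    feature_columns: list
    X_train: np.ndarray = None
    classes_: np.ndarray = None
    scaler: dict = field(default_factory=dict)

    def _matrix(self, X):
        if isinstance(X, pd.DataFrame):
            X = X[self.feature_columns].to_numpy(dtype=float)
        else:
            X = np.asarray(X, dtype=float)
        if X.shape[1] != len(self.feature_columns):
            raise ValueError(
                f"feature dimension {X.shape[1]} != trained {len(self.feature_columns)}"
            )
        return X

    def predict(self, X):
        Xm = self._matrix(X)
        if self.kernel in ("his", "laplacian"):
            gram = kernel_eval(self.kernel, Xm, self.X_train, self.params)
            return self.svc.predict(gram)
        return self.svc.predict(Xm)


def train_svm(data: pd.DataFrame, kernel="linear", params=None, C=1.0):
    """Train a one-vs-one multiclass SVM on a prepared labeled table.

    ``data`` must carry a ``label`` column; every other column is a feature.
    HIS and Laplacian kernels are passed to the solver as precomputed Gram
    matrices.  RBF/Laplacian scales default to the median heuristic.
    """
    if kernel not in KERNELS:
        raise ValueError(f"unknown kernel {kernel!r}")
    if "label" not in data.columns:
        raise ValueError("data must have a 'label' column")
    y = data["label"].to_numpy()
    cols = [c for c in data.columns if c != "label"]
    X = data[cols].to_numpy(dtype=float)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    if counts.min() < 2:
        raise ValueError("need at least 2 samples per class")

    params = dict(params or {})
    if kernel in ("rbf", "laplacian") and not params:
        params = median_heuristic(X)
    if kernel == "rbf":
        sigma = float(params.get("sigma", 1.0))
        svc = SVC(C=C, kernel="rbf", gamma=1.0 / (2.0 * sigma**2),
                  decision_function_shape="ovo")
        svc.fit(X, y)
        X_train = None
    elif kernel == "linear":
        svc = SVC(C=C, kernel="linear", decision_function_shape="ovo")
        svc.fit(X, y)
        X_train = None
    else:
        gram = kernel_eval(kernel, X, X, params)
        if not np.all(np.isfinite(gram)):
            raise ValueError("degenerate kernel matrix")
        svc = SVC(C=C, kernel="precomputed", decision_function_shape="ovo")
        svc.fit(gram, y)
        X_train = X
    return TrainedClassifier(
        kernel=kernel, params=params, C=C, svc=svc, feature_columns=cols,
        X_train=X_train, classes_=classes,
    )


def evaluate_accuracy(model: TrainedClassifier, test: pd.DataFrame) -> float:
    """Fraction of exact label matches on a labeled test table."""
    if len(test) == 0:
        raise ValueError("empty test set")
    y = test["label"].to_numpy()
    pred = model.predict(test)
    return float((pred == y).mean())


def accuracy_sweep(
    data: pd.DataFrame,
    ratios=(0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9),
    n_trials: int = 30,
    kernel="linear",
    params=None,
    C=1.0,
    rng=None,
) -> pd.DataFrame:
    """Mean and SD of test accuracy per training-dataset ratio.

    Per trial the data is split stratified (class shares preserved), the
    SVM trained on the ratio fraction and evaluated on the complement;
    statistics are taken over ``n_trials`` trials per ratio.
    """
    ratios = list(ratios)
    if not ratios or any(not 0.0 < r < 1.0 for r in ratios):
        raise ValueError("ratios must lie strictly in (0, 1)")
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if rng is None:
        rng = np.random.default_rng()
    y = data["label"].to_numpy()
    rows = []
    for r in ratios:
        splitter = StratifiedShuffleSplit(
            n_splits=n_trials, train_size=r,
            random_state=int(rng.integers(0, 2**31 - 1)),
        )
        accs = []
        for tr_idx, te_idx in splitter.split(np.zeros(len(y)), y):
            train, test = data.iloc[tr_idx], data.iloc[te_idx]
            if train["label"].nunique() < 2 or test["label"].nunique() < 1:
                raise ValueError(f"ratio {r} leaves a class empty")
            model = train_svm(train, kernel=kernel, params=params, C=C)
            accs.append(evaluate_accuracy(model, test))
        rows.append({"ratio": r, "mean": float(np.mean(accs)),
                     "sd": float(np.std(accs, ddof=0))})
    return pd.DataFrame(rows).set_index("ratio")


def simulate_expert_votes(
    true_labels: pd.Series, n_experts: int, confusion: pd.DataFrame, rng
) -> pd.DataFrame:
    """Simulate an expert vote table from per-class confusion rates.

    ``confusion``: rows = true class, columns = assigned class, rows sum
    to 1.  Each expert's label is drawn independently from the confusion
    row of the spine's true class.
    """
    conf = confusion.astype(float)
    if not np.allclose(conf.sum(axis=1), 1.0, atol=1e-9) or (conf.values < 0).any():
        raise ValueError("confusion rows must be non-negative and sum to 1")
    out = {}
    cols = list(conf.columns)
    for sid, cls in true_labels.items():
        p = conf.loc[cls].to_numpy()
        out[sid] = rng.choice(cols, size=n_experts, p=p)
    tab = pd.DataFrame.from_dict(out, orient="index")
    tab.columns = [f"expert_{i + 1}" for i in range(n_experts)]
    tab.index.name = "spine_id"
    return tab
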