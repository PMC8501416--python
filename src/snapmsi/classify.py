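"""Seven-way classifier comparison for 9-band reflectance spectra.

Methods: LDA and KNN on the raw 9-band feature vector, PCA-KNN on principal
component scores, spectral angle mapping (SAM) used three ways (argmin angle
"simple-SAM", and the three angles as features for LDA or KNN), and a small
two-layer feedforward neural network (10 sigmoid hidden units, linear
outputs).

Data are split at the image-cube level: 80% of cubes for training, 20% for
testing; for the network, the test cubes are further halved into validation
(used only for early stopping) and test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.neighbors import NearestNeighbors

METHODS = ("lda", "knn", "pca-knn", "sam", "sam-lda", "sam-knn", "nn")


@dataclass
class SplitSpec:
    """Cube-level split protocol: 80/20 train/test, with the test cubes
    halved again into validation and test for the neural network (the larger
    half goes to validation on odd counts)."""

    train_fraction: float = 0.8
    nn_val_fraction_of_test: float = 0.5
    seed: int = 0


@dataclass
class DatasetSplit:
    train: np.ndarray
    test: np.ndarray
    nn_val: np.ndarray
    nn_test: np.ndarray
    seed: int


def split_dataset(cube_ids, spec: SplitSpec | None = None) -> DatasetSplit:
    """Shuffle unique cube ids and split them train/test (and val/test for
    the network).  Unstratified uniform shuffle; all spectra of a cube stay
    on one side of the split."""
    if spec is None:
        spec = SplitSpec()
    ids = np.unique(np.asarray(cube_ids))
    n = len(ids)
    if n < 2:
        raise ValueError("need at least 2 cubes to split")
    rng = np.random.default_rng(spec.seed)
    perm = rng.permutation(n)
    n_train = int(np.floor(spec.train_fraction * n))
    train = ids[perm[:n_train]]
    test = ids[perm[n_train:]]
    n_val = int(np.ceil(spec.nn_val_fraction_of_test * len(test)))
    return DatasetSplit(
        train=np.sort(train),
        test=np.sort(test),
        nn_val=np.sort(test[:n_val]),
        nn_test=np.sort(test[n_val:]),
        seed=spec.seed,
    )


# ---------------------------------------------------------------------------
# spectral angle mapping


def sam_angles(targets: np.ndarray, references: np.ndarray) -> np.ndarray:
    """n-dimensional angles between target spectra and reference spectra.

    ``targets`` is (m, 9) (or a single 9-vector), ``references`` (c, 9).
    Returns (m, c) angles in radians, arccos of the normalized inner
    product; scale-invariant in both arguments.
    """
    T = np.atleast_2d(np.asarray(targets, dtype=float))
    R = np.atleast_2d(np.asarray(references, dtype=float))
    tn = np.linalg.norm(T, axis=1)
    rn = np.linalg.norm(R, axis=1)
    if np.any(tn == 0) or np.any(rn == 0):
        raise ValueError("zero-norm spectrum has no spectral angle")
    cos = (T @ R.T) / np.outer(tn, rn)
    return np.arccos(np.clip(cos, -1.0, 1.0))


def class_mean_references(X: np.ndarray, y: np.ndarray, classes: np.ndarray) -> np.ndarray:
    """SAM reference spectra: the mean training spectrum of each class."""
    return np.stack([X[y == c].mean(axis=0) for c in classes])


# ---------------------------------------------------------------------------
# KNN with a documented deterministic tie-break


class _KNN:
    """Majority vote over the k nearest neighbors (Euclidean).  If the top
    vote count is tied between classes, the label of the single nearest
    neighbor is used — deterministic by construction."""

    def __init__(self, k: int = 3):
        self.k = k

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        if len(X) < self.k:
            raise ValueError(f"need at least k={self.k} training points")
        self._nn = NearestNeighbors(n_neighbors=self.k).fit(X)
        self._y = np.asarray(y)
        self.classes_ = np.unique(self._y)
        return self

    def predict(self, X):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        _, idx = self._nn.kneighbors(X)  # neighbors sorted by distance
        labels = self._y[idx]  # (m, k)
        out = np.empty(len(X), dtype=self._y.dtype)
        for i, row in enumerate(labels):
            vals, counts = np.unique(row, return_counts=True)
            winners = vals[counts == counts.max()]
            out[i] = row[0] if len(winners) > 1 else winners[0]
        return out


# ---------------------------------------------------------------------------
# two-layer feedforward network


class _TwoLayerNet:
    """9 -> 10 sigmoid -> C linear network trained on one-hot targets with
    mean-squared-error loss (full-batch Adam), early-stopped on a held-out
    validation set (patience 6, max 1000 epochs).  The validation set is
    never used for weight updates.  Early stopping only arms after
    ``min_epochs`` so the optimizer's initial transient (during which the
    validation loss oscillates) cannot trigger it; the best-so-far weights
    are tracked from epoch 1 regardless."""

    def __init__(
        self, n_hidden=10, lr=0.05, max_epochs=1000, patience=6, min_epochs=50, seed=0
    ):
        self.n_hidden = n_hidden
        self.lr = lr
        self.max_epochs = max_epochs
        self.patience = patience
        self.min_epochs = min_epochs
        self.seed = seed

    @staticmethod
    def _sigmoid(z):
        return 1.0 / (1.0 + np.exp(-z))

    def _forward(self, X):
        h = self._sigmoid(X @ self.W1 + self.b1)
        return h, h @ self.W2 + self.b2

    def fit(self, X, y, X_val=None, y_val=None):
        X = np.asarray(X, dtype=float)
        self.classes_ = np.unique(np.asarray(y))
        c = len(self.classes_)
        Y = (np.asarray(y)[:, None] == self.classes_[None, :]).astype(float)
        if X_val is None:
            X_val, Y_val = X, Y
        else:
            X_val = np.asarray(X_val, dtype=float)
            Y_val = (np.asarray(y_val)[:, None] == self.classes_[None, :]).astype(float)

        rng = np.random.default_rng(self.seed)
        d = X.shape[1]
        self.W1 = rng.normal(0.0, 1.0 / np.sqrt(d), size=(d, self.n_hidden))
        self.b1 = np.zeros(self.n_hidden)
        self.W2 = rng.normal(0.0, 1.0 / np.sqrt(self.n_hidden), size=(self.n_hidden, c))
        self.b2 = np.zeros(c)

        params = [self.W1, self.b1, self.W2, self.b2]
        m = [np.zeros_like(p) for p in params]
        v = [np.zeros_like(p) for p in params]
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        best_val = np.inf
        best_params = [p.copy() for p in params]
        bad_epochs = 0
        n = len(X)
        for epoch in range(1, self.max_epochs + 1):
            h, out = self._forward(X)
            err = out - Y  # d(MSE)/d(out) up to 2/n
            g_out = 2.0 * err / n
            gW2 = h.T @ g_out
            gb2 = g_out.sum(axis=0)
            g_h = g_out @ self.W2.T * h * (1 - h)
            gW1 = X.T @ g_h
            gb1 = g_h.sum(axis=0)
            for p, g, mi, vi in zip(params, [gW1, gb1, gW2, gb2], m, v):
                mi *= beta1
                mi += (1 - beta1) * g
                vi *= beta2
                vi += (1 - beta2) * g * g
                mhat = mi / (1 - beta1**epoch)
                vhat = vi / (1 - beta2**epoch)
                p -= self.lr * mhat / (np.sqrt(vhat) + eps)
            _, val_out = self._forward(X_val)
            val_mse = float(np.mean((val_out - Y_val) ** 2))
            if val_mse < best_val - 1e-9:
                best_val = val_mse
                best_params = [p.copy() for p in params]
                bad_epochs = 0
            else:
                bad_epochs += 1
                if epoch >= self.min_epochs and bad_epochs > self.patience:
                    break
        self.W1, self.b1, self.W2, self.b2 = best_params
        self.n_epochs_ = epoch
        return self

    def predict(self, X):
        _, out = self._forward(np.atleast_2d(np.asarray(X, dtype=float)))
        return self.classes_[np.argmax(out, axis=1)]


# ---------------------------------------------------------------------------
# unified training / prediction interface


@dataclass
class TrainedClassifier:
    """One fitted method plus its preprocessing state."""

    method: str
    model: object = None
    classes: np.ndarray = None
    k: int | None = None
    pca: PCA | None = None
    n_components: int | None = None
    sam_references: np.ndarray | None = None
    params: dict = field(default_factory=dict)

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != 9:
            raise ValueError("expected 9-band spectra")
        feats = X
        if self.sam_references is not None:
            feats = sam_angles(X, self.sam_references)
        if self.pca is not None:
            feats = self.pca.transform(feats)
        if self.method == "sam":
            return self.classes[np.argmin(feats, axis=1)]
        return self.model.predict(feats)


def _pca_for_variance(X: np.ndarray, var_target: float, n_components: int | None) -> PCA:
    if n_components is None:
        full = PCA(svd_solver="full").fit(X)
        cum = np.cumsum(full.explained_variance_ratio_)
        n_components = int(np.searchsorted(cum, var_target) + 1)
    return PCA(n_components=n_components, svd_solver="full").fit(X)


def train_classifier(
    method: str,
    X: np.ndarray,
    y: np.ndarray,
    k: int = 3,
    pca_var_target: float = 0.99,
    n_components: int | None = None,
    seed: int = 0,
    X_val: np.ndarray | None = None,
    y_val: np.ndarray | None = None,
) -> TrainedClassifier:
    """Fit one of the seven methods on labeled training spectra.

    ``k`` applies to the KNN variants (k in {3, 5, 7} in the comparison);
    PCA-KNN keeps the smallest number of components explaining at least
    ``pca_var_target`` of the training variance unless ``n_components``
    is given.  The network takes an optional validation set for early
    stopping.
    """
    method = method.lower()
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {METHODS}")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes to train")

    clf = TrainedClassifier(method=method, classes=classes)
    feats = X
    if method.startswith("sam"):
        clf.sam_references = class_mean_references(X, y, classes)
        if method == "sam":
            return clf
        feats = sam_angles(X, clf.sam_references)

    if method == "lda" or method == "sam-lda":
        clf.model = LinearDiscriminantAnalysis().fit(feats, y)
    elif method in ("knn", "sam-knn"):
        clf.k = k
        clf.model = _KNN(k=k).fit(feats, y)
    elif method == "pca-knn":
        clf.pca = _pca_for_variance(feats, pca_var_target, n_components)
        clf.n_components = clf.pca.n_components_
        clf.k = k
        clf.model = _KNN(k=k).fit(clf.pca.transform(feats), y)
    elif method == "nn":
        clf.model = _TwoLayerNet(seed=seed).fit(feats, y, X_val, y_val)
    clf.params = {"k": k, "seed": seed}
    return clf


def predict(model: TrainedClassifier, spectra: np.ndarray) -> np.ndarray:
    """Predict class labels for spectra with a fitted classifier."""
    return model.predict(spectra)
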