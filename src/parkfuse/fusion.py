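"""Distribution-level trimodal fusion and the XGBoost classification head.

The three modality cohorts share no subjects, so fused vectors cannot be
formed per subject.  Instead, embeddings are pooled per class within each
modality and "pseudo-subjects" are assembled by drawing one embedding per
modality from the matching class pool (without replacement while a pool
lasts, refilled with replacement afterwards).  Speech embeddings are
PCA-reduced first; fused vectors are standardized, SMOTE-balanced (train
partition only) and classified by gradient-boosted trees.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA
from sklearn.preprocessing import StandardScaler
from xgboost import XGBClassifier

from .errors import ConfigError, LeakageError
from .types import CLASSES, Embedding, FusedVector, class_index

# --------------------------------------------------------------------------
# speech PCA
# --------------------------------------------------------------------------


def _hash(arr: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()[:16]


@dataclass
class FittedPCA:
    pca: PCA
    fit_hash: str  # hash of the training matrix the basis was fitted on

    def transform(self, x: np.ndarray) -> np.ndarray:
        return self.pca.transform(x)


def pca_speech(train_embeddings: np.ndarray, n_components: int | float = 32,
               seed: int = 0) -> tuple[np.ndarray, FittedPCA]:
    """Fit the PCA basis on the *training* speech embeddings only and
    return (reduced training embeddings, fitted basis)."""
    x = np.asarray(train_embeddings, dtype=float)
    if isinstance(n_components, int):
        if n_components > x.shape[1]:
            raise ConfigError(
                f"n_components={n_components} exceeds embedding dim {x.shape[1]}")
        n_components = min(n_components, x.shape[0])
    pca = PCA(n_components=n_components, svd_solver="full", random_state=seed)
    z = pca.fit_transform(x)
    return z, FittedPCA(pca=pca, fit_hash=_hash(x))


# --------------------------------------------------------------------------
# fused dataset assembly
# --------------------------------------------------------------------------


@dataclass
class DescriptorBlock:
    """Per-class, per-modality population mean/SD of the pooled embeddings
    plus the sampling recipe used to assemble pseudo-subjects."""

    means: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)
    sds: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)
    recipe: str = "class-matched sampling without replacement, refill with replacement"
    fit_hashes: dict[str, str] = field(default_factory=dict)


def build_fused_dataset(embeddings: dict[str, list[Embedding]],
                        mode: str = "distribution_level",
                        n_per_class: int | None = None,
                        seed: int = 0) -> tuple[list[FusedVector], DescriptorBlock]:
    """Assemble trimodal fused vectors [v_speech || v_hand || v_gait].

    ``distribution_level``: for each pseudo-subject one embedding per
    modality is drawn from the matching class pool; ``subject_paired``
    joins on shared subject ids (only meaningful when cohorts overlap).
    """
    modalities = ("speech", "handwriting", "gait")
    if set(embeddings) != set(modalities):
        raise ConfigError(f"need embeddings for exactly {modalities}")

    if mode == "subject_paired":
        by_subject: dict[str, dict[str, Embedding]] = {}
        for m in modalities:
            for e in embeddings[m]:
                by_subject.setdefault(e.subject_id, {})[m] = e
        fused = []
        for sid, per_mod in sorted(by_subject.items()):
            if len(per_mod) != 3:
                continue
            vecs = [per_mod[m].vector for m in modalities]
            spans, start = {}, 0
            for m, v in zip(modalities, vecs):
                spans[m] = (start, start + len(v))
                start += len(v)
            fused.append(FusedVector(values=np.concatenate(vecs), spans=spans,
                                     label=per_mod["gait"].label, pseudo_subject=sid))
        return fused, DescriptorBlock()
    if mode != "distribution_level":
        raise ConfigError(f"unknown fusion mode {mode!r}")

    rng = np.random.default_rng(seed)
    pools: dict[tuple[str, str], list[np.ndarray]] = {}
    desc = DescriptorBlock()
    for m in modalities:
        mat = np.stack([e.vector for e in embeddings[m]])
        desc.fit_hashes[m] = _hash(mat)
        for label in CLASSES:
            pool = [e.vector for e in embeddings[m] if e.label == label]
            if not pool:
                raise ConfigError(f"class {label!r} missing from {m} pool")
            pools[(m, label)] = pool
            arr = np.stack(pool)
            desc.means[(m, label)] = arr.mean(axis=0)
            desc.sds[(m, label)] = arr.std(axis=0)  # population SD

    if n_per_class is None:
        n_per_class = min(len(pools[(m, lbl)]) for m in modalities for lbl in CLASSES)

    fused = []
    for label in CLASSES:
        order = {m: list(rng.permutation(len(pools[(m, label)]))) for m in modalities}
        for i in range(n_per_class):
            vecs = []
            for m in modalities:
                pool = pools[(m, label)]
                if order[m]:
                    idx = order[m].pop()
                else:  # pool exhausted: refill with replacement
                    idx = int(rng.integers(len(pool)))
                vecs.append(pool[idx])
            spans, start = {}, 0
            for m, v in zip(modalities, vecs):
                spans[m] = (start, start + len(v))
                start += len(v)
            fused.append(FusedVector(values=np.concatenate(vecs), spans=spans,
                                     label=label, pseudo_subject=f"{label}-{i:04d}"))
    return fused, desc


def fused_matrix(fused: list[FusedVector]) -> tuple[np.ndarray, np.ndarray]:
    x = np.stack([f.values for f in fused])
    y = np.array([class_index(f.label) for f in fused])
    return x, y


# --------------------------------------------------------------------------
# SMOTE (synthetic minority oversampling)
# --------------------------------------------------------------------------


def smote_balance(x: np.ndarray, y: np.ndarray, k: int = 5,
                  seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Equalize class counts by interpolating new minority points on the
    segment between a minority point and one of its k nearest minority
    neighbours (affine coefficient uniform in [0, 1])."""
    classes, counts = np.unique(y, return_counts=True)
    n_target = counts.max()
    rng = np.random.default_rng(seed)
    xs, ys = [x], [y]
    for cls, cnt in zip(classes, counts):
        deficit = n_target - cnt
        if deficit == 0:
            continue
        minority = x[y == cls]
        if cnt < k + 1:
            raise ConfigError(
                f"minority class has {cnt} samples, fewer than k+1={k + 1}; "
                f"use a smaller SMOTE neighbour count k")
        d2 = ((minority[:, None, :] - minority[None, :, :]) ** 2).sum(-1)
        np.fill_diagonal(d2, np.inf)
        nn = np.argsort(d2, axis=1)[:, :k]
        base = rng.integers(0, cnt, deficit)
        nbr = nn[base, rng.integers(0, k, deficit)]
        lam = rng.uniform(0.0, 1.0, deficit)[:, None]
        synth = minority[base] + lam * (minority[nbr] - minority[base])
        xs.append(synth)
        ys.append(np.full(deficit, cls))
    return np.vstack(xs), np.concatenate(ys)


@dataclass
class FusedSplit:
    x_train: np.ndarray
    y_train: np.ndarray
    x_test: np.ndarray
    y_test: np.ndarray
    scaler: StandardScaler
    scaler_fit_hash: str

    def check_no_leakage(self, x_train_raw: np.ndarray) -> None:
        if _hash(x_train_raw) != self.scaler_fit_hash:
            raise LeakageError("standardizer was not fitted on the training partition")


def split_standardize_balance(fused: list[FusedVector], split_ratio: float = 0.7,
                              k_smote: int = 5, seed: int = 0) -> FusedSplit:
    """Stratified train/test split, z-scoring with training statistics only
    ("apply same scaling" to the test partition), then SMOTE on the
    training partition only; post-SMOTE class counts are equal."""
    x, y = fused_matrix(fused)
    if np.unique(y).size < 2:
        raise ConfigError("both classes must be present")
    rng = np.random.default_rng(seed)
    train_idx, test_idx = [], []
    for cls in np.unique(y):
        idx = rng.permutation(np.flatnonzero(y == cls))
        n_train = int(round(split_ratio * idx.size))
        train_idx.extend(idx[:n_train])
        test_idx.extend(idx[n_train:])
    train_idx, test_idx = np.sort(train_idx), np.sort(test_idx)
    x_train_raw, y_train = x[train_idx], y[train_idx]
    scaler = StandardScaler().fit(x_train_raw)
    x_train = scaler.transform(x_train_raw)
    x_test = scaler.transform(x[test_idx])
    x_bal, y_bal = smote_balance(x_train, y_train, k=k_smote, seed=seed)
    return FusedSplit(x_train=x_bal, y_train=y_bal, x_test=x_test, y_test=y[test_idx],
                      scaler=scaler, scaler_fit_hash=_hash(x_train_raw))


# --------------------------------------------------------------------------
# XGBoost head
# --------------------------------------------------------------------------

XGB_DEFAULTS = dict(n_estimators=300, max_depth=4, learning_rate=0.1,
                    reg_lambda=1.0, gamma=0.0)


def tree_regularization(n_leaves: int, leaf_weights: np.ndarray,
                        gamma: float, lam: float) -> float:
    """Per-tree complexity penalty: Omega = gamma*M + (lambda/2)*||w||^2."""
    w = np.asarray(leaf_weights, dtype=float)
    return float(gamma * n_leaves + 0.5 * lam * (w**2).sum())


def train_xgboost(x: np.ndarray, y: np.ndarray, seed: int = 0,
                  **hyperparams) -> XGBClassifier:
    """Gradient-boosted tree head on fused (or unimodal) feature vectors."""
    if np.unique(y).size < 2:
        raise ConfigError("need >= 2 classes")
    params = {**XGB_DEFAULTS, **hyperparams}
    model = XGBClassifier(random_state=seed, n_jobs=1, eval_metric="logloss",
                          tree_method="exact", **params)
    model.fit(x, y)
    return model


def staged_margin(model: XGBClassifier, x: np.ndarray, n_trees: int) -> np.ndarray:
    """Additive-prediction identity probe: margin after the first
    ``n_trees`` boosting rounds (sum of those trees' leaf outputs plus the
    base score)."""
    booster = model.get_booster()
    import xgboost as xgb

    dm = xgb.DMatrix(x)
    return booster.predict(dm, iteration_range=(0, n_trees), output_margin=True)


def tree_leaf_contributions(model: XGBClassifier, x: np.ndarray) -> np.ndarray:
    """Per-tree margin contributions, shape (n_samples, n_trees)."""
    booster = model.get_booster()
    import xgboost as xgb

    dm = xgb.DMatrix(x)
    n = model.n_estimators
    cum = np.stack([booster.predict(dm, iteration_range=(0, i), output_margin=True)
                    for i in range(n + 1)], axis=1)
    return np.diff(cum, axis=1)


def soft_vote(probabilities: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """Average class-probability distributions from the unimodal heads:
    P_c = (1/3) * sum_m P_m(c).  Returns (mean probabilities, argmax)."""
    shapes = {np.asarray(p).shape for p in probabilities}
    if len(shapes) != 1:
        raise ConfigError(f"probability arrays have mismatched shapes: {shapes}")
    p = np.mean([np.asarray(pi, dtype=float) for pi in probabilities], axis=0)
    return p, p.argmax(axis=-1)
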