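"""Dataset splitting, the optimisation loop, hyperparameter search, and the
Random Forest baseline.

Splitting shuffles samples into 0.70 / 0.15 / 0.15 train/val/test fractions
(stratified by label) in batches of 16.  Training uses cross-entropy with an
Adam-style optimiser (decoupled weight decay), early stopping on validation
accuracy, and restores the best-validation-epoch weights.  The search is a
seeded random sampler over the documented space, ranked by validation
accuracy; the test split is evaluated once, after selection.  Models get
randomly generated code names for legibility of leaderboards.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import f1_score

from .features import SampleRecord
from .model import DeepSetsClassifier, ModelConfig, pack_batch, POOLINGS, REGULARIZATIONS

__all__ = [
    "SplitSpec",
    "SearchSpace",
    "TrialResult",
    "split_dataset",
    "train_model",
    "hyperparameter_search",
    "random_forest_baseline",
]

logger = logging.getLogger(__name__)

_ADJECTIVES = (
    "lumpy", "chirpy", "velvet", "brisk", "mellow", "dapper", "rustic", "breezy",
    "plucky", "quirky", "stately", "nimble", "vivid", "earnest", "jolly", "placid",
)
_NOUNS = (
    "kagu", "heron", "plover", "avocet", "bittern", "dunlin", "godwit", "kestrel",
    "merlin", "osprey", "petrel", "sandpiper", "shrike", "tanager", "vireo", "wigeon",
)


@dataclass(frozen=True)
class SplitSpec:
    fractions: tuple[float, float, float] = (0.70, 0.15, 0.15)
    batch_size: int = 16
    seed: int = 0
    stratify_by: str = "label"

    def __post_init__(self):
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


@dataclass(frozen=True)
class SearchSpace:
    latent_dim: tuple[int, int] = (4, 512)
    hidden_dim: tuple[int, int] = (4, 512)
    pooling: tuple[str, ...] = POOLINGS
    dropout_rate: tuple[float, float] = (0.0, 0.5)
    regularization: tuple[str, ...] = REGULARIZATIONS
    learning_rate: tuple[float, float] = (1e-4, 1e-2)   # log scale
    weight_decay: tuple[float, float] = (1e-6, 1e-2)    # log scale

    def sample(self, rng: np.random.Generator) -> dict:
        return {
            "latent_dim": int(rng.integers(self.latent_dim[0], self.latent_dim[1] + 1)),
            "hidden_dim": int(rng.integers(self.hidden_dim[0], self.hidden_dim[1] + 1)),
            "pooling": str(rng.choice(self.pooling)),
            "dropout_rate": float(rng.uniform(*self.dropout_rate)),
            "regularization": str(rng.choice(self.regularization)),
            "learning_rate": float(np.exp(rng.uniform(np.log(self.learning_rate[0]), np.log(self.learning_rate[1])))),
            "weight_decay": float(np.exp(rng.uniform(np.log(self.weight_decay[0]), np.log(self.weight_decay[1])))),
        }


@dataclass
class TrialResult:
    code_name: str
    config: dict
    train_accuracy: float
    val_accuracy: float
    test_accuracy: float
    f1_per_class: tuple[float, float]
    per_subject_accuracy: dict
    model: DeepSetsClassifier | None = None
    failed: bool = False
    n_epochs: int = 0


def split_dataset(n_samples_or_labels, spec: SplitSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Disjoint, covering train/val/test index arrays.

    Accepts either a label array (stratified default) or a sample count.
    Global sizes are ``round(0.7 n) / round(0.15 n) / remainder``.
    """
    if np.isscalar(n_samples_or_labels):
        labels = np.zeros(int(n_samples_or_labels), dtype=int)
    else:
        labels = np.asarray(n_samples_or_labels, dtype=int)
    n = len(labels)
    if n < 7:
        raise ValueError("need at least 7 samples to split")
    n_train = round(spec.fractions[0] * n)
    n_val = round(spec.fractions[1] * n)
    n_test = n - n_train - n_val
    if min(n_train, n_val, n_test) < 1:
        raise ValueError("a split would be empty")

    rng = np.random.default_rng(spec.seed)
    train_idx, val_idx, test_idx = [], [], []
    classes = np.unique(labels)
    remaining_train, remaining_val = n_train, n_val
    for ci, c in enumerate(classes):
        idx = rng.permutation(np.flatnonzero(labels == c))
        if ci == len(classes) - 1:
            t, v = remaining_train, remaining_val
        else:
            t = round(spec.fractions[0] * len(idx))
            v = round(spec.fractions[1] * len(idx))
            t, v = min(t, remaining_train), min(v, remaining_val)
        remaining_train -= t
        remaining_val -= v
        train_idx.extend(idx[:t])
        val_idx.extend(idx[t : t + v])
        test_idx.extend(idx[t + v :])
    return (
        np.sort(np.asarray(train_idx, dtype=int)),
        np.sort(np.asarray(val_idx, dtype=int)),
        np.sort(np.asarray(test_idx, dtype=int)),
    )


class _Adam:
    """Adam with decoupled weight decay."""

    def __init__(self, arrays: dict, lr: float, weight_decay: float):
        self.lr = lr
        self.wd = weight_decay
        self.m = {k: np.zeros_like(v) for k, v in arrays.items()}
        self.v = {k: np.zeros_like(v) for k, v in arrays.items()}
        self.t = 0
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8

    def step(self, arrays: dict, grads: dict):
        self.t += 1
        for k, x in arrays.items():
            g = grads.get(k)
            if g is None:
                continue
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            x -= self.lr * (mhat / (np.sqrt(vhat) + self.eps) + self.wd * x)


def _evaluate(model, samples, idx):
    if len(idx) == 0:
        return float("nan"), np.array([])
    flat, offs = pack_batch([samples[i].features for i in idx])
    logits, _ = model.forward(flat, offs, train=False)
    preds = np.argmax(logits, axis=1)
    labels = np.array([samples[i].label for i in idx])
    return float(np.mean(preds == labels)), preds


def train_model(
    samples: list[SampleRecord],
    config: ModelConfig,
    splits: tuple[np.ndarray, np.ndarray, np.ndarray],
    learning_rate: float = 1e-3,
    weight_decay: float = 1e-5,
    batch_size: int = 16,
    max_epochs: int = 200,
    patience: int = 20,
    seed: int = 0,
    code_name: str | None = None,
) -> TrialResult:
    """Optimise one configuration; restores best-validation weights."""
    train_idx, val_idx, test_idx = splits
    model = DeepSetsClassifier(config)
    opt = _Adam(model.trainable(), learning_rate, weight_decay)
    rng = np.random.default_rng(seed)
    if code_name is None:
        code_name = make_code_name(rng)

    best_val, best_state, best_epoch = -1.0, None, 0
    labels_train = np.array([samples[i].label for i in train_idx])
    epoch = 0
    for epoch in range(1, max_epochs + 1):
        order = rng.permutation(len(train_idx))
        diverged = False
        for lo in range(0, len(order), batch_size):
            batch = [train_idx[i] for i in order[lo : lo + batch_size]]
            flat, offs = pack_batch([samples[i].features for i in batch])
            y = np.array([samples[i].label for i in batch])
            loss, grads, _ = model.loss_and_grads(flat, offs, y, train=True)
            if not np.isfinite(loss):
                diverged = True
                break
            opt.step(model.trainable(), model.gradients_from(grads))
        if diverged:
            logger.warning("trial %s diverged at epoch %d", code_name, epoch)
            return TrialResult(code_name, asdict(config), 0.0, 0.0, 0.0, (0.0, 0.0), {}, None, failed=True)
        val_acc, _ = _evaluate(model, samples, val_idx)
        if val_acc > best_val:
            best_val, best_state, best_epoch = val_acc, model.get_state(), epoch
        elif epoch - best_epoch >= patience:
            break
    if best_state is not None:
        model.set_state(best_state)

    train_acc, _ = _evaluate(model, samples, train_idx)
    val_acc, _ = _evaluate(model, samples, val_idx)
    test_acc, test_preds = _evaluate(model, samples, test_idx)
    test_labels = np.array([samples[i].label for i in test_idx])
    if len(test_labels):
        f1 = f1_score(test_labels, test_preds, labels=[0, 1], average=None, zero_division=0)
        f1_pair = (float(f1[0]), float(f1[1]))
    else:
        f1_pair = (float("nan"), float("nan"))

    # per-subject accuracy over the full dataset
    flat, offs = pack_batch([s.features for s in samples])
    logits, _ = model.forward(flat, offs, train=False)
    preds = np.argmax(logits, axis=1)
    per_subject: dict[str, float] = {}
    for subject in sorted({s.subject_id for s in samples}):
        mask = np.array([s.subject_id == subject for s in samples])
        per_subject[subject] = float(
            np.mean(preds[mask] == np.array([s.label for s in samples])[mask])
        )
    return TrialResult(
        code_name=code_name,
        config=asdict(config),
        train_accuracy=train_acc,
        val_accuracy=val_acc,
        test_accuracy=test_acc,
        f1_per_class=f1_pair,
        per_subject_accuracy=per_subject,
        model=model,
        n_epochs=epoch,
    )


def make_code_name(rng: np.random.Generator) -> str:
    return "-".join(
        (
            str(rng.choice(_ADJECTIVES)).capitalize(),
            str(rng.choice(_ADJECTIVES)).capitalize(),
            str(rng.choice(_NOUNS)).capitalize(),
        )
    )


def hyperparameter_search(
    samples: list[SampleRecord],
    splits,
    space: SearchSpace = SearchSpace(),
    n_trials: int = 25,
    seed: int = 0,
    max_epochs: int = 200,
    patience: int = 20,
    batch_size: int = 16,
) -> list[TrialResult]:
    """Seeded random search maximising validation accuracy.

    Trial i's configuration depends only on (seed, i), so the best validation
    accuracy is non-decreasing in ``n_trials`` for a fixed seed.  Returns all
    trials ranked by validation accuracy (ties broken by trial order).
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    input_dim = samples[0].features.shape[1]
    results = []
    for trial in range(n_trials):
        rng = np.random.default_rng(np.random.SeedSequence([seed, trial]))
        hp = space.sample(rng)
        config = ModelConfig(
            input_dim=input_dim,
            latent_dim=hp["latent_dim"],
            hidden_dim=hp["hidden_dim"],
            pooling=hp["pooling"],
            dropout_rate=hp["dropout_rate"],
            regularization=hp["regularization"],
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        result = train_model(
            samples,
            config,
            splits,
            learning_rate=hp["learning_rate"],
            weight_decay=hp["weight_decay"],
            batch_size=batch_size,
            max_epochs=max_epochs,
            patience=patience,
            seed=int(rng.integers(0, 2**31 - 1)),
            code_name=make_code_name(rng),
        )
        result.config.update(learning_rate=hp["learning_rate"], weight_decay=hp["weight_decay"])
        logger.info(
            "trial %d (%s): val=%.3f test=%.3f", trial, result.code_name, result.val_accuracy, result.test_accuracy
        )
        results.append(result)
    ok = [r for r in results if not r.failed]
    if not ok:
        raise RuntimeError("all search trials failed")
    order = sorted(range(len(results)), key=lambda i: (-results[i].val_accuracy, i))
    return [results[i] for i in order]


def random_forest_baseline(
    samples: list[SampleRecord], seed: int = 0, test_fraction: float = 0.2
) -> dict:
    """Random Forest on set-flattened features with an 80:20 split.

    Sets are flattened to fixed-length vectors via per-column mean, std, min
    and max over atoms.
    """
    x = np.stack(
        [
            np.concatenate(
                [
                    s.features.mean(axis=0),
                    s.features.std(axis=0),
                    s.features.min(axis=0),
                    s.features.max(axis=0),
                ]
            )
            for s in samples
        ]
    )
    y = np.array([s.label for s in samples])
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(y))
    n_test = max(1, round(test_fraction * len(y)))
    test_idx, train_idx = order[:n_test], order[n_test:]
    forest = RandomForestClassifier(n_estimators=100, random_state=seed)
    forest.fit(x[train_idx], y[train_idx])
    preds = forest.predict(x[test_idx])
    acc = float(np.mean(preds == y[test_idx]))
    f1 = f1_score(y[test_idx], preds, labels=[0, 1], average=None, zero_division=0)
    return {"accuracy": acc, "f1_per_class": (float(f1[0]), float(f1[1]))}
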