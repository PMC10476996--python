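"""Training protocol: weighted cross entropy, custom precision early
stopping, plateau learning-rate halving, in-plane augmentation, and
patient-level 5-fold cross-validation producing a fold ensemble.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .backbone import Adam, CompactCNN3D, softmax
from .preprocess import ClassifierSample, PreprocessConfig

logger = logging.getLogger(__name__)

LOSS_EPS = 1e-12


@dataclass(frozen=True)
class TrainConfig:
    """Hyperparameters of the training protocol.

    Defaults mirror the published protocol (learning rate 1e-4, plateau
    halving with patience 15 on validation loss, early stop on the
    custom precision metric); desk-scale runs shrink ``max_epochs`` and
    the early-stop patience.
    """

    vocabulary: tuple[str, ...]
    learning_rate: float = 1e-4
    plateau_factor: float = 0.5
    plateau_patience: int = 15
    early_stop_patience: int = 20  # 60 for the bowel profile, 20 for pelvis
    folds: int = 5
    batch_size: int = 6
    max_epochs: int = 200
    augment_probability: float = 0.4  # 0.5 bowel profile, 0.4 pelvis profile
    rotation_deg: float = 5.0
    translation_px: int = 10
    flip_enabled: bool = False  # True for the bowel profile (no L/R classes)
    other_class: str = "Other"
    seed: int = 0
    backbone: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.folds < 2:
            raise ValueError("need at least 2 folds")
        if not 0.0 <= self.augment_probability <= 1.0:
            raise ValueError("augment probability must lie in [0, 1]")
        if self.other_class not in self.vocabulary:
            raise ValueError(f"vocabulary must contain {self.other_class!r}")

    @property
    def other_index(self) -> int:
        return self.vocabulary.index(self.other_class)


@dataclass
class FoldModel:
    """Best-validation snapshot of one cross-validation fold."""

    model: CompactCNN3D
    fold_index: int
    vocabulary: tuple[str, ...]
    best_epoch: int
    best_cp: float
    history: list[dict] = field(default_factory=list)

    def predict_proba(self, channels: np.ndarray) -> np.ndarray:
        return self.model.predict_proba(channels)


@dataclass
class EnsembleModel:
    """Ordered fold models sharing one vocabulary and preprocess config."""

    folds: list[FoldModel]
    vocabulary: tuple[str, ...]
    preprocess_fingerprint: str

    def save(self, out_dir: Path | str) -> Path:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        meta = {
            "vocabulary": list(self.vocabulary),
            "preprocess_fingerprint": self.preprocess_fingerprint,
            "folds": [
                {"fold_index": f.fold_index, "best_epoch": f.best_epoch,
                 "best_cp": f.best_cp}
                for f in self.folds
            ],
        }
        (out_dir / "ensemble.json").write_text(json.dumps(meta, indent=2))
        for f in self.folds:
            f.model.save(out_dir / f"fold_{f.fold_index}.npz")
            with open(out_dir / f"fold_{f.fold_index}_log.tsv", "w") as fh:
                if f.history:
                    keys = list(f.history[0])
                    fh.write("\t".join(keys) + "\n")
                    for row in f.history:
                        fh.write("\t".join(str(row[k]) for k in keys) + "\n")
        return out_dir

    @classmethod
    def load(cls, in_dir: Path | str) -> "EnsembleModel":
        in_dir = Path(in_dir)
        meta = json.loads((in_dir / "ensemble.json").read_text())
        vocabulary = tuple(meta["vocabulary"])
        folds = [
            FoldModel(
                model=CompactCNN3D.load(in_dir / f"fold_{fm['fold_index']}.npz"),
                fold_index=fm["fold_index"], vocabulary=vocabulary,
                best_epoch=fm["best_epoch"], best_cp=fm["best_cp"],
            )
            for fm in meta["folds"]
        ]
        return cls(folds=folds, vocabulary=vocabulary,
                   preprocess_fingerprint=meta["preprocess_fingerprint"])


def preprocess_fingerprint(config: PreprocessConfig) -> str:
    payload = json.dumps(asdict(config), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


# ---------------------------------------------------------------------------
# loss components
# ---------------------------------------------------------------------------

def balanced_class_weights(label_counts: dict[str, int]) -> dict[str, float]:
    """Inverse-frequency ("balanced") weights: N_total / (K * n_c)."""
    if any(c < 1 for c in label_counts.values()):
        zero = [k for k, c in label_counts.items() if c < 1]
        raise ValueError(f"classes with zero count: {zero}")
    n_total = sum(label_counts.values())
    k = len(label_counts)
    return {c: n_total / (k * n) for c, n in label_counts.items()}


def weighted_cross_entropy(
    probabilities: np.ndarray, true_indices: np.ndarray, weights: np.ndarray
) -> float:
    """Mean of -w_true * log(p_true) over the batch; p clamped at eps."""
    probabilities = np.asarray(probabilities, dtype=np.float64)
    true_indices = np.atleast_1d(true_indices)
    p_true = probabilities[np.arange(len(true_indices)), true_indices]
    if np.any(p_true <= 0):
        logger.warning("zero probability at true class; clamping at %g", LOSS_EPS)
    p_true = np.clip(p_true, LOSS_EPS, None)
    w = np.asarray(weights, dtype=np.float64)[true_indices]
    return float(np.mean(-w * np.log(p_true)))


def custom_precision(per_class_precision: np.ndarray, other_index: int) -> float:
    """Sum of per-class precisions over every class except "Other".

    Classes with no predicted instances contribute precision 0; range is
    [0, n_classes - 1].
    """
    per_class_precision = np.asarray(per_class_precision, dtype=np.float64)
    mask = np.ones(per_class_precision.size, dtype=bool)
    mask[other_index] = False
    return float(per_class_precision[mask].sum())


def _per_class_precision(true_idx: np.ndarray, pred_idx: np.ndarray, n: int) -> np.ndarray:
    precision = np.zeros(n)
    for c in range(n):
        predicted = pred_idx == c
        if predicted.any():
            precision[c] = np.mean(true_idx[predicted] == c)
    return precision


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------

_ROTATION_MAPS: dict[tuple, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}


def _rotation_map(nr: int, nc: int, angle_deg: float):
    """Cached nearest-neighbor source-index map for an in-plane rotation.

    Angles are quantized to 0.5 degrees so the maps can be reused across
    epochs (a desk-scale shortcut; resampling stays nearest neighbor).
    """
    angle_q = round(angle_deg * 2) / 2.0
    key = (nr, nc, angle_q)
    if key not in _ROTATION_MAPS:
        theta = np.deg2rad(angle_q)
        cos_t, sin_t = np.cos(theta), np.sin(theta)
        r0, c0 = (nr - 1) / 2.0, (nc - 1) / 2.0
        rr, cc = np.meshgrid(np.arange(nr) - r0, np.arange(nc) - c0, indexing="ij")
        src_r = np.rint(cos_t * rr + sin_t * cc + r0).astype(np.intp)
        src_c = np.rint(-sin_t * rr + cos_t * cc + c0).astype(np.intp)
        valid = (src_r >= 0) & (src_r < nr) & (src_c >= 0) & (src_c < nc)
        _ROTATION_MAPS[key] = (src_r.clip(0, nr - 1), src_c.clip(0, nc - 1), valid)
    return _ROTATION_MAPS[key]


def augment(
    channels: np.ndarray, config: TrainConfig, rng: np.random.Generator
) -> np.ndarray:
    """In-plane (row/col) augmentation applied identically to all channels.

    Each enabled transform fires independently with the configured
    probability; all resampling is nearest neighbor so the AddMap
    codomain {0, 0.5, 1} survives unchanged.
    """
    out = channels
    p = config.augment_probability
    if config.flip_enabled and rng.random() < p:
        out = out[..., ::-1]  # left-right = col axis
    if config.rotation_deg > 0 and rng.random() < p:
        angle = rng.uniform(-config.rotation_deg, config.rotation_deg)
        src_r, src_c, valid = _rotation_map(out.shape[-2], out.shape[-1], angle)
        out = np.where(valid, out[..., src_r, src_c], 0.0)
    if config.translation_px > 0 and rng.random() < p:
        shift_r = rng.integers(-config.translation_px, config.translation_px + 1)
        shift_c = rng.integers(-config.translation_px, config.translation_px + 1)
        out = _shift2d(out, int(shift_r), int(shift_c))
    return np.ascontiguousarray(out)


def _shift2d(arr: np.ndarray, dr: int, dc: int) -> np.ndarray:
    """Integer in-plane shift with zero fill (exact, no interpolation)."""
    out = np.zeros_like(arr)
    r_lo_src, r_lo_dst = max(-dr, 0), max(dr, 0)
    c_lo_src, c_lo_dst = max(-dc, 0), max(dc, 0)
    nr, nc = arr.shape[-2], arr.shape[-1]
    h = nr - abs(dr)
    w = nc - abs(dc)
    if h > 0 and w > 0:
        out[..., r_lo_dst:r_lo_dst + h, c_lo_dst:c_lo_dst + w] = \
            arr[..., r_lo_src:r_lo_src + h, c_lo_src:c_lo_src + w]
    return out


# ---------------------------------------------------------------------------
# training loops
# ---------------------------------------------------------------------------

def _labels_to_indices(samples, vocabulary) -> np.ndarray:
    index = {c: i for i, c in enumerate(vocabulary)}
    try:
        return np.array([index[s.label] for s in samples], dtype=np.int64)
    except KeyError as exc:
        raise ValueError(f"label {exc} not in vocabulary {vocabulary}") from None


def train_fold(
    train_samples: list[ClassifierSample],
    val_samples: list[ClassifierSample],
    config: TrainConfig,
    fold_index: int = 0,
    seed: int | None = None,
) -> FoldModel:
    """Train one fold; return the snapshot with the highest validation CP."""
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    vocab = tuple(config.vocabulary)
    n_classes = len(vocab)

    y_train = _labels_to_indices(train_samples, vocab)
    y_val = _labels_to_indices(val_samples, vocab)
    counts = {c: int((y_train == i).sum()) for i, c in enumerate(vocab)}
    if any(v == 0 for v in counts.values()):
        missing = [c for c, v in counts.items() if v == 0]
        raise ValueError(
            f"classes {missing} absent from fold {fold_index} training set; "
            "enlarge the cohort"
        )
    weight_map = balanced_class_weights(counts)
    weights = np.array([weight_map[c] for c in vocab], dtype=np.float64)

    model = CompactCNN3D(n_classes=n_classes, seed=seed, **config.backbone)
    optimizer = Adam(model, lr=config.learning_rate)
    x_val = np.stack([s.channels for s in val_samples])

    best = dict(cp=-np.inf, epoch=-1, weights=model.get_weights())
    best_val_loss, plateau_wait, stop_wait = np.inf, 0, 0
    history = []

    for epoch in range(config.max_epochs):
        order = rng.permutation(len(train_samples))
        epoch_loss = 0.0
        for start in range(0, len(order), config.batch_size):
            idx = order[start:start + config.batch_size]
            batch = np.stack([
                augment(train_samples[i].channels, config, rng) for i in idx
            ])
            yb = y_train[idx]
            logits = model.forward_logits(batch, train=True)
            probs = softmax(logits)
            loss = weighted_cross_entropy(probs, yb, weights)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite loss at fold {fold_index} epoch {epoch}"
                )
            onehot = np.zeros_like(probs)
            onehot[np.arange(len(yb)), yb] = 1.0
            dlogits = ((probs - onehot)
                       * weights[yb][:, None] / len(yb)).astype(np.float32)
            model.backward(dlogits)
            optimizer.step()
            epoch_loss += loss * len(yb)
        epoch_loss /= len(order)

        val_probs = model.predict_proba(x_val)
        val_loss = weighted_cross_entropy(val_probs, y_val, weights)
        val_pred = val_probs.argmax(axis=1)
        cp = custom_precision(
            _per_class_precision(y_val, val_pred, n_classes), config.other_index
        )
        val_acc = float(np.mean(val_pred == y_val))
        history.append(dict(epoch=epoch, train_loss=round(epoch_loss, 6),
                            val_loss=round(val_loss, 6), val_cp=round(cp, 6),
                            val_acc=round(val_acc, 6), lr=optimizer.lr))

        if cp > best["cp"]:
            best = dict(cp=cp, epoch=epoch, weights=model.get_weights())
            stop_wait = 0
        else:
            stop_wait += 1
        if val_loss < best_val_loss - 1e-12:
            best_val_loss, plateau_wait = val_loss, 0
        else:
            plateau_wait += 1
            if plateau_wait >= config.plateau_patience:
                optimizer.lr *= config.plateau_factor
                plateau_wait = 0
                logger.info("fold %d: lr halved to %g at epoch %d",
                            fold_index, optimizer.lr, epoch)
        if stop_wait >= config.early_stop_patience:
            logger.info("fold %d: early stop at epoch %d (best CP %.4f @ %d)",
                        fold_index, epoch, best["cp"], best["epoch"])
            break

    model.set_weights(best["weights"])
    return FoldModel(model=model, fold_index=fold_index, vocabulary=vocab,
                     best_epoch=best["epoch"], best_cp=float(best["cp"]),
                     history=history)


def load_cohort_samples(
    cohort_dir, preprocess_config: PreprocessConfig,
    labels: dict[tuple[str, str], str] | None = None,
) -> list[ClassifierSample]:
    """Preprocess every eligible structure of every patient folder.

    ``labels`` maps (patient_id, structure_name) to a class; names not in
    the map (or with no map at all) get no label.  The body structure is
    never emitted as a sample.
    """
    from pathlib import Path

    from . import rtstruct_io
    from .preprocess import assemble_sample

    samples = []
    for pdir in sorted(p for p in Path(cohort_dir).iterdir() if p.is_dir()):
        ct, sset = rtstruct_io.load_patient(pdir)
        body = rtstruct_io.find_body(sset)
        for struct in sset:
            if struct.name == body.name:
                continue
            sample = assemble_sample(
                ct, body, struct, preprocess_config,
                label=(labels or {}).get((pdir.name, struct.name)),
                patient_id=pdir.name,
            )
            if sample is not None:
                samples.append(sample)
    return samples


def assign_folds(patient_ids: list[str], n_folds: int, seed: int) -> dict[str, int]:
    """Deterministic patient-level fold assignment (validation fold id)."""
    unique = sorted(set(patient_ids))
    if len(unique) < n_folds:
        raise ValueError(f"need >= {n_folds} patients, have {len(unique)}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(unique))
    return {unique[j]: int(i % n_folds) for i, j in enumerate(order)}


def train_kfold(
    samples: list[ClassifierSample],
    config: TrainConfig,
    preprocess_config: PreprocessConfig,
) -> EnsembleModel:
    """Patient-level k-fold cross-validation -> fold ensemble.

    Every patient appears in exactly one fold's validation set; per-fold
    class weights come from that fold's training labels.
    """
    fold_of = assign_folds([s.patient_id for s in samples], config.folds, config.seed)
    folds = []
    for fold_index in range(config.folds):
        train = [s for s in samples if fold_of[s.patient_id] != fold_index]
        val = [s for s in samples if fold_of[s.patient_id] == fold_index]
        folds.append(train_fold(train, val, config, fold_index=fold_index,
                                seed=config.seed + fold_index))
    return EnsembleModel(
        folds=folds, vocabulary=tuple(config.vocabulary),
        preprocess_fingerprint=preprocess_fingerprint(preprocess_config),
    )
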