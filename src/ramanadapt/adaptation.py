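"""Pre-training, efficient fine-tuning and test-time adaptation.

Three ways of fitting the spectral classifier to data:

* :func:`pretrain` — supervised training on one or more source cohorts with
  a patient-stratified train/validation/test split (60/20/20 by default),
  early stopping on validation accuracy, and best-weights restoration.
* :func:`finetune_efficient` — supervised adaptation of a pre-trained model
  to a small target cohort that updates only the later half of the network
  (blocks 4-6 and the head by default); the frozen early layers act as a
  fixed feature extractor, which curbs overfitting on ten-patient data and
  roughly halves the trainable parameter count.
* :func:`tta_adapt` — unsupervised test-time adaptation: for every new
  measurement, a few gradient steps minimize the Shannon entropy of the
  model's own prediction, updating only the fully connected head and the
  batch-norm affine parameters.  The model is restored to its pre-adaptation
  checkpoint before the next patient, so patients never influence each
  other's predictions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .cohort import Cohort
from .nn.functional import entropy_grad_logits, softmax, softmax_cross_entropy
from .nn.optim import Adam
from .resnet1d import Resnet1D

__all__ = [
    "TrainConfig",
    "FinetuneConfig",
    "TTAConfig",
    "AdaptationResult",
    "TrainHistory",
    "entropy",
    "pretrain",
    "train_supervised",
    "finetune_efficient",
    "tta_adapt",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TrainConfig:
    """Supervised-training settings: Adam at learning rate 1e-3, at most 25
    epochs, early stopping after 8 epochs without validation-accuracy
    improvement, batch size 32."""

    max_epochs: int = 25
    patience: int = 8
    learning_rate: float = 1e-3
    batch_size: int = 32
    seed: int = 0

    def __post_init__(self) -> None:
        if self.patience > self.max_epochs:
            raise ValueError("patience must be <= max_epochs")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


_DEFAULT_FROZEN = ("stem", "block_1", "block_2", "block_3")
_DEFAULT_TRAINABLE = ("block_4", "block_5", "block_6", "head")


@dataclass(frozen=True)
class FinetuneConfig(TrainConfig):
    """Fine-tuning settings: which parameter groups stay frozen.

    The defaults freeze the first half of the network (stem + blocks 1-3)
    and adapt the last three residual blocks plus the head.
    """

    frozen_groups: tuple[str, ...] = _DEFAULT_FROZEN
    trainable_groups: tuple[str, ...] = _DEFAULT_TRAINABLE
    validation_fraction: float = 0.2

    def __post_init__(self) -> None:
        super().__post_init__()
        overlap = set(self.frozen_groups) & set(self.trainable_groups)
        if overlap:
            raise ValueError(f"groups both frozen and trainable: {sorted(overlap)}")
        if not 0.0 < self.validation_fraction < 1.0:
            raise ValueError("validation_fraction must be in (0, 1)")


@dataclass(frozen=True)
class TTAConfig:
    """Test-time adaptation settings.

    ``n_steps`` entropy-descent steps are taken per measurement on the head
    and batch-norm affine parameters.  By default the batch-norm statistics
    are first replaced by the patient batch's own moments when the patient
    has at least ``min_batch_for_statistics`` spectra (fewer spectra fall
    back to the stored running statistics, which keep single-spectrum
    adaptation well posed), and each measurement adapts afresh from that
    state (``cumulative=False``); letting adaptation accumulate across a
    patient's measurements tends to collapse all of that patient's
    predictions onto one class.  The model is always reset before the next
    patient.
    """

    n_steps: int = 5
    learning_rate: float = 1e-3
    cumulative: bool = False
    use_batch_statistics: bool = True
    min_batch_for_statistics: int = 8

    def __post_init__(self) -> None:
        # n_steps = 0 is allowed as the degenerate "no adaptation" variant,
        # useful as a control in benchmarks.
        if self.n_steps < 0:
            raise ValueError("n_steps must be >= 0")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")


@dataclass
class TrainHistory:
    train_loss: list[float] = field(default_factory=list)
    val_accuracy: list[float] = field(default_factory=list)
    best_epoch: int = -1
    stopped_early: bool = False

    @property
    def n_epochs(self) -> int:
        return len(self.train_loss)


@dataclass
class AdaptationResult:
    """Per-measurement predictions plus the entropy trace of each
    adaptation; ``entropy_trace[i]`` has ``n_steps + 1`` values, the first
    being the pre-adaptation entropy of measurement ``i``."""

    predictions: np.ndarray  # (n_measurements, n_classes)
    entropy_trace: np.ndarray  # (n_measurements, n_steps + 1)
    sample_ids: list[str]


def entropy(probabilities: np.ndarray) -> float | np.ndarray:
    """Shannon entropy in nats of one or many class distributions.

    ``0 * log 0`` is treated as 0.  Rows must be nonnegative and sum to 1
    within 1e-6.
    """
    p = np.asarray(probabilities, dtype=float)
    squeeze = p.ndim == 1
    p = np.atleast_2d(p)
    if np.any(p < -1e-12):
        raise ValueError("probabilities must be nonnegative")
    sums = p.sum(axis=-1)
    if np.any(np.abs(sums - 1.0) > 1e-6):
        raise ValueError(f"probabilities must sum to 1 (got sums {sums})")
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log(p), 0.0)
    h = -terms.sum(axis=-1)
    return float(h[0]) if squeeze else h


# --------------------------------------------------------------------------
# supervised training
# --------------------------------------------------------------------------

def _patient_stratified_split(
    cohort_like: list[tuple[str, int, int]],
    fractions: tuple[float, ...],
    rng: np.random.Generator,
) -> list[list[int]]:
    """Assign whole patients to partitions targeting spectrum-count
    fractions.  ``cohort_like`` rows are (patient_id, spectrum_index, label).
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"split fractions must sum to 1, got {fractions}")
    patients: dict[str, list[int]] = {}
    for pid, idx, _ in cohort_like:
        patients.setdefault(pid, []).append(idx)
    order = list(patients)
    rng.shuffle(order)
    total = len(cohort_like)
    targets = np.cumsum(np.asarray(fractions) * total)
    parts: list[list[int]] = [[] for _ in fractions]
    assigned = 0
    owner: list[int] = []
    for pid in order:
        # Place the patient in the first partition still below its target.
        part = int(np.searchsorted(targets - 1e-9, assigned, side="right"))
        part = min(part, len(parts) - 1)
        parts[part].extend(patients[pid])
        owner.append(part)
        assigned += len(patients[pid])
    # Guarantee every nonzero-fraction partition holds at least one patient
    # (greedy spectrum-count targeting can starve the last partitions when
    # there are few patients): move one patient out of the fullest partition.
    for part, frac in enumerate(fractions):
        if frac > 0 and not parts[part]:
            donor = max(range(len(parts)), key=lambda q: sum(
                1 for o in owner if o == q))
            for k in range(len(order) - 1, -1, -1):
                if owner[k] == donor:
                    moved = patients[order[k]]
                    parts[donor] = [i for i in parts[donor] if i not in set(moved)]
                    parts[part].extend(moved)
                    owner[k] = part
                    break
    return parts


def _check_both_classes(y: np.ndarray, partition: str) -> None:
    if np.unique(y).size < 2:
        raise ValueError(
            f"{partition} partition contains a single class; re-split with a "
            "different seed or provide more patients"
        )


def _accuracy(model: Resnet1D, x: np.ndarray, y: np.ndarray, batch: int = 256) -> float:
    preds = []
    for i in range(0, len(x), batch):
        preds.append(model.predict_proba(x[i : i + batch]).argmax(axis=1))
    return float((np.concatenate(preds) == y).mean())


def train_supervised(
    model: Resnet1D,
    x_train: np.ndarray,
    y_train: np.ndarray,
    x_val: np.ndarray,
    y_val: np.ndarray,
    config: TrainConfig,
    trainable_groups: tuple[str, ...] | None = None,
) -> TrainHistory:
    """Core loop: minibatch Adam on softmax cross-entropy, early stopping on
    validation accuracy, best-validation weights restored on exit.  The model
    is modified in place."""
    rng = np.random.default_rng(config.seed)
    if trainable_groups is None:
        trainable = set(model.parameters())
        needed = None
    else:
        unknown = set(trainable_groups) - set(model.group_order)
        if unknown:
            raise ValueError(
                f"unknown parameter groups {sorted(unknown)}; valid: {model.group_order}"
            )
        trainable = {n for g in trainable_groups for n in model.group_map[g]}
        needed = set(trainable_groups)
    model.trainable_names = trainable
    optimizer = Adam(model.parameters(), lr=config.learning_rate, trainable=trainable)

    history = TrainHistory()
    best_acc = -np.inf
    best_state: dict | None = None
    epochs_without_improvement = 0

    n = len(x_train)
    for epoch in range(config.max_epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            model.zero_grad()
            logits = model.forward(x_train[idx], training=True)
            loss, dlogits = softmax_cross_entropy(logits, y_train[idx])
            model.backward(dlogits, needed_groups=needed)
            optimizer.step(model.gradients())
            losses.append(loss)
        val_acc = _accuracy(model, x_val, y_val)
        history.train_loss.append(float(np.mean(losses)))
        history.val_accuracy.append(val_acc)
        if val_acc > best_acc:
            best_acc = val_acc
            best_state = model.state_dict()
            history.best_epoch = epoch
            epochs_without_improvement = 0
        else:
            epochs_without_improvement += 1
            if epochs_without_improvement >= config.patience:
                history.stopped_early = True
                break
    if best_state is not None:
        model.load_state_dict(best_state)
    return history


def _cohort_xy(cohorts: list[Cohort]) -> tuple[np.ndarray, np.ndarray, list[tuple[str, int, int]]]:
    xs, ys, rows = [], [], []
    i = 0
    for cohort in cohorts:
        labels = cohort.labels()
        xs.append(cohort.intensity_matrix())
        ys.append(labels)
        for s, lab in zip(cohort.spectra, labels):
            # Prefix with the domain so same-named patients in different
            # cohorts are kept apart.
            rows.append((f"{cohort.domain}:{s.patient_id}", i, int(lab)))
            i += 1
    return np.concatenate(xs), np.concatenate(ys), rows


def pretrain(
    model: Resnet1D,
    source_cohorts: list[Cohort],
    config: TrainConfig | None = None,
    split: tuple[float, float, float] = (0.6, 0.2, 0.2),
) -> tuple[Resnet1D, TrainHistory]:
    """Supervised pre-training on source cohorts.

    Patients are assigned whole to the train/validation/test partitions so
    no patient leaks across them.  Returns ``(model, history)``; the test
    partition indices are recorded on the history for downstream use.
    """
    if not source_cohorts or all(len(c) == 0 for c in source_cohorts):
        raise ValueError("source cohorts must be nonempty")
    config = config or TrainConfig()
    x, y, rows = _cohort_xy(source_cohorts)
    rng = np.random.default_rng(config.seed)
    parts = _patient_stratified_split(rows, split, rng)
    tr, va, te = (np.asarray(p, dtype=int) for p in parts)
    _check_both_classes(y[tr], "training")
    _check_both_classes(y[va], "validation")
    history = train_supervised(model, x[tr], y[tr], x[va], y[va], config)
    history.test_indices = te  # type: ignore[attr-defined]
    history.test_accuracy = _accuracy(model, x[te], y[te]) if len(te) else None  # type: ignore[attr-defined]
    return model, history


def finetune_efficient(
    pretrained_model: Resnet1D,
    target_cohort: Cohort,
    config: FinetuneConfig | None = None,
) -> tuple[Resnet1D, TrainHistory]:
    """Adapt a pre-trained model to a small labelled target cohort.

    Only ``config.trainable_groups`` receive updates; the frozen groups are
    bitwise untouched.  A patient-stratified slice of the target training
    data serves as the early-stopping validation set.  Returns a fine-tuned
    copy; the input model is left unmodified.
    """
    config = config or FinetuneConfig()
    model = pretrained_model.copy()
    covered = set(config.frozen_groups) | set(config.trainable_groups)
    missing = set(model.group_order) - covered
    if missing:
        raise ValueError(f"groups neither frozen nor trainable: {sorted(missing)}")
    unknown = covered - set(model.group_order)
    if unknown:
        raise ValueError(
            f"unknown parameter groups {sorted(unknown)}; valid: {model.group_order}"
        )

    x, y, rows = _cohort_xy([target_cohort])
    rng = np.random.default_rng(config.seed)
    vf = config.validation_fraction
    tr, va = (
        np.asarray(p, dtype=int)
        for p in _patient_stratified_split(rows, (1.0 - vf, vf), rng)
    )
    _check_both_classes(y[tr], "training")
    _check_both_classes(y[va], "validation")
    history = train_supervised(
        model, x[tr], y[tr], x[va], y[va], config, trainable_groups=config.trainable_groups
    )
    return model, history


# --------------------------------------------------------------------------
# test-time adaptation
# --------------------------------------------------------------------------

def tta_adapt(
    pretrained_model: Resnet1D,
    measurements: Cohort,
    config: TTAConfig | None = None,
) -> AdaptationResult:
    """Entropy-minimization test-time adaptation for one patient.

    For each measurement, ``config.n_steps`` Adam steps minimize the entropy
    of the model's prediction, updating only the head and every batch-norm
    ``gamma`` / ``beta``; the prediction after the last step is emitted.
    Adaptation is cumulative across the patient's measurements by default.
    On return the model is restored to its pre-adaptation state, so adapting
    one patient can never affect another's predictions.
    """
    config = config or TTAConfig()
    model = pretrained_model
    pids = {s.patient_id for s in measurements}
    if len(pids) > 1:
        raise ValueError(
            f"tta_adapt expects measurements from a single patient, got {sorted(pids)}"
        )
    x = measurements.intensity_matrix()
    if x.shape[1] != model.config.input_length:
        raise ValueError(
            f"measurement length {x.shape[1]} != model input_length "
            f"{model.config.input_length}"
        )

    snapshot = model.state_dict()
    if config.use_batch_statistics and len(x) >= config.min_batch_for_statistics:
        # Replace the stored normalization statistics with the patient
        # batch's own moments (one training-mode forward with momentum 1);
        # the snapshot taken above restores the source statistics after this
        # patient.
        from .nn.layers import BatchNorm1d

        bns = [l for l in model._layers.values() if isinstance(l, BatchNorm1d)]
        old_momenta = [bn.momentum for bn in bns]
        for bn in bns:
            bn.momentum = 1.0
        try:
            model.forward(x, training=True)
        finally:
            for bn, mom in zip(bns, old_momenta):
                bn.momentum = mom

    adapted = set(model.group_map["head"]) | model.batchnorm_param_names()
    model.trainable_names = adapted
    optimizer = Adam(model.parameters(), lr=config.learning_rate, trainable=adapted)

    # Per-measurement resets return to the state *after* any statistics
    # replacement; the outer snapshot still guarantees patient isolation.
    start_state = model.state_dict()
    n_steps = config.n_steps
    predictions = np.zeros((len(x), model.config.n_classes))
    traces = np.zeros((len(x), n_steps + 1))
    try:
        for i in range(len(x)):
            if not config.cumulative:
                model.load_state_dict(start_state)
                optimizer = Adam(model.parameters(), lr=config.learning_rate, trainable=adapted)
            xi = x[i : i + 1]
            for step in range(n_steps):
                model.zero_grad()
                logits = model.forward(xi, training=False)
                h, dlogits = entropy_grad_logits(logits)
                traces[i, step] = h[0]
                model.backward(dlogits, needed_groups=None)
                optimizer.step(model.gradients())
            probs = model.predict_proba(xi)
            predictions[i] = probs[0]
            traces[i, n_steps] = entropy(probs[0])
    finally:
        model.load_state_dict(snapshot)
    return AdaptationResult(
        predictions=predictions,
        entropy_trace=traces,
        sample_ids=[s.sample_id for s in measurements],
    )
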