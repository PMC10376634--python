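"""Two-network co-training engine with class-wise distribution alignment.

Each iteration follows the same fixed order: update each network's labeled
distribution matrix from the labeled batch, update its unlabeled matrix
from the raw unlabeled predictions, align the unlabeled predictions,
build pseudo-labels with the over-expectation filter, then take one SGD
step on the summed supervised and unsupervised losses for both networks.
Pseudo-labels, acceptance masks and alignment weights are detached
statistics, so every gradient reduces to a (masked, weighted) softmax
cross-entropy gradient on the network's own logits.

The public surface is the sklearn-style :class:`CoDASegmenter` estimator;
:func:`train` and :func:`make_model_pair` are thin functional wrappers.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

from .distributions import (
    ClassDistributionMatrix,
    EMAConfig,
    ProbabilityMap,
    align_prediction,
    init_distributions,
    update_labeled_distribution,
    update_unlabeled_distribution,
)
from .losses import LossReport, build_pseudo_labels, oe_loss, supervised_loss
from .metrics import confusion_counts, miou, per_class_iou
from .network import SGDMomentum, TinyUNet

__all__ = [
    "TrainConfig",
    "TrainLog",
    "CoDASegmenter",
    "make_model_pair",
    "train",
    "unsupervised_artifacts",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass(frozen=True)
class TrainConfig:
    """All hyperparameters of one co-training run.

    ``supervised_only`` drops the unsupervised loss entirely and forces the
    alignment and over-expectation switches off; ``static_threshold``
    replaces the dynamic per-class thresholds with one scalar.
    """

    num_classes: int = 4
    alpha: float = 0.999
    epsilon: float = 1e-8
    tau_min: float = 0.05
    lambda_u: float = 1.0
    learning_rate: float = 0.02
    momentum: float = 0.9
    lr_poly_power: float = 0.0  # 0 = constant lr; else lr*(1 - it/Imax)^power
    max_iterations: int = 1000
    labeled_batch_size: int = 4
    unlabeled_batch_size: int = 4
    seed1: int = 1
    seed2: int = 2
    data_seed: int = 0
    width: int = 8
    use_alignment: bool = True
    use_oe: bool = True
    supervised_only: bool = False
    static_threshold: float | None = None
    val_interval: int = 0  # 0 = no periodic validation

    def __post_init__(self) -> None:
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.labeled_batch_size < 1 or self.unlabeled_batch_size < 1:
            raise ValueError("batch sizes must be >= 1")
        if self.supervised_only and (self.use_alignment or self.use_oe):
            object.__setattr__(self, "use_alignment", False)
            object.__setattr__(self, "use_oe", False)

    def ema(self) -> EMAConfig:
        return EMAConfig(alpha=self.alpha, epsilon=self.epsilon, tau_min=self.tau_min)

    def effective_lr(self, iteration: int) -> float:
        if self.lr_poly_power <= 0:
            return self.learning_rate
        return self.learning_rate * (1.0 - (iteration - 1) / self.max_iterations) ** self.lr_poly_power

    def digest(self) -> str:
        return hashlib.sha256(json.dumps(asdict(self), sort_keys=True).encode()).hexdigest()[:16]


@dataclass
class TrainLog:
    """Per-iteration records plus periodic validation results."""

    records: list = field(default_factory=list)

    def append(self, record: dict) -> None:
        if self.records and record["iteration"] <= self.records[-1]["iteration"]:
            raise ValueError("iteration indices must increase")
        self.records.append(record)

    def to_jsonl(self) -> str:
        return "\n".join(json.dumps(r) for r in self.records)

    @classmethod
    def from_jsonl(cls, text: str) -> "TrainLog":
        return cls(records=[json.loads(line) for line in text.splitlines() if line.strip()])


class _CyclicSampler:
    """Wraparound shuffled batch sampler; state fully serialisable."""

    def __init__(self, n: int, seed: int):
        self.n = n
        self.rng = np.random.default_rng(seed)
        self.order = self.rng.permutation(n)
        self.pos = 0

    def next_batch(self, size: int) -> np.ndarray:
        out = []
        while len(out) < size:
            if self.pos >= self.n:
                self.order = self.rng.permutation(self.n)
                self.pos = 0
            take = min(size - len(out), self.n - self.pos)
            out.extend(self.order[self.pos : self.pos + take].tolist())
            self.pos += take
        return np.asarray(out)

    def get_state(self) -> dict:
        return {
            "rng": self.rng.bit_generator.state,
            "order": self.order.tolist(),
            "pos": self.pos,
        }

    def set_state(self, state: dict) -> None:
        self.rng.bit_generator.state = state["rng"]
        self.order = np.asarray(state["order"])
        self.pos = state["pos"]


def make_model_pair(config: TrainConfig) -> tuple[TinyUNet, TinyUNet]:
    """Two networks with identical architecture, different initial weights."""
    if config.seed1 == config.seed2:
        raise ValueError("seed1 and seed2 must differ (co-training needs diverse views)")
    m1 = TinyUNet(config.num_classes, seed=config.seed1, width=config.width)
    m2 = TinyUNet(config.num_classes, seed=config.seed2, width=config.width)
    return m1, m2


def unsupervised_artifacts(
    probs_u: tuple[ProbabilityMap, ProbabilityMap],
    matrices: tuple[dict, dict],
    config: TrainConfig,
) -> dict:
    """Pure unsupervised pipeline stage: alignment then pseudo-labeling.

    Given both models' raw unlabeled probability maps and their own
    ``{"Ml":..., "Mu":...}`` matrix pairs, produce the aligned maps and
    pseudo-label maps each switch setting would generate.  Used by the
    engine each iteration and directly testable for switch isolation.
    """
    ema = config.ema()
    out = {}
    for m in (0, 1):
        raw = probs_u[m]
        Ml, Mu = matrices[m]["Ml"], matrices[m]["Mu"]
        aligned = align_prediction(raw, Ml, Mu, ema) if config.use_alignment else raw.mark_aligned()
        static = None
        if not config.use_oe:
            static = 0.0
        elif config.static_threshold is not None:
            static = config.static_threshold
        pseudo = build_pseudo_labels(aligned, Mu, static_threshold=static, source=f"model{m + 1}")
        out[f"aligned{m + 1}"] = aligned
        out[f"pseudo{m + 1}"] = pseudo
    return out


def _onehot(labels: np.ndarray, k: int) -> np.ndarray:
    return np.eye(k)[labels]


class _TrainerState:
    """Everything that evolves during training; checkpointable."""

    def __init__(self, config: TrainConfig, n_labeled: int, n_unlabeled: int):
        self.config = config
        self.model1, self.model2 = make_model_pair(config)
        self.opt1 = SGDMomentum(self.model1.params, config.learning_rate, config.momentum)
        self.opt2 = SGDMomentum(self.model2.params, config.learning_rate, config.momentum)
        self.matrices = tuple(
            {
                "Ml": init_distributions(config.num_classes, "labeled"),
                "Mu": init_distributions(config.num_classes, "unlabeled"),
            }
            for _ in range(2)
        )
        self.labeled_sampler = _CyclicSampler(n_labeled, config.data_seed)
        self.unlabeled_sampler = _CyclicSampler(max(n_unlabeled, 1), config.data_seed + 1)
        self.iteration = 0
        self.log = TrainLog()


def _to_batch(images: np.ndarray) -> np.ndarray:
    """uint8 (B, H, W) -> float (B, 1, H, W) in [0, 1]."""
    return (np.asarray(images, dtype=np.float64) / 255.0)[:, None]


def _run_training(
    config: TrainConfig,
    labeled: tuple[np.ndarray, np.ndarray],
    unlabeled: np.ndarray | None,
    validation: tuple[np.ndarray, np.ndarray] | None = None,
    artifact_hook=None,
    state: _TrainerState | None = None,
    stop_at: int | None = None,
) -> _TrainerState:
    images_l, masks_l = labeled
    if len(images_l) == 0:
        raise ValueError("labeled set must be nonempty")
    masks_l = np.asarray(masks_l)
    if masks_l.size and (masks_l.min() < 0 or masks_l.max() >= config.num_classes):
        raise ValueError("labeled masks contain classes outside the configured range")
    has_unlabeled = unlabeled is not None and len(unlabeled) > 0
    if not has_unlabeled and not config.supervised_only:
        raise ValueError("semi-supervised training requires unlabeled images")

    K = config.num_classes
    ema = config.ema()
    if state is None:
        state = _TrainerState(config, len(images_l), len(unlabeled) if has_unlabeled else 1)
    models = (state.model1, state.model2)
    opts = (state.opt1, state.opt2)

    stop = config.max_iterations if stop_at is None else min(stop_at, config.max_iterations)
    while state.iteration < stop:
        state.iteration += 1
        it = state.iteration
        lb = state.labeled_sampler.next_batch(config.labeled_batch_size)
        xl = _to_batch(images_l[lb])
        yl = masks_l[lb]
        if has_unlabeled:
            ub = state.unlabeled_sampler.next_batch(config.unlabeled_batch_size)
            xu = _to_batch(unlabeled[ub])

        probs_l, caches_l, probs_u, caches_u = [], [], [], []
        for m, model in enumerate(models):
            p, c = model.forward_probs(xl)
            probs_l.append(ProbabilityMap(p.transpose(0, 2, 3, 1)))
            caches_l.append(c)
            if has_unlabeled and not config.supervised_only:
                p, c = model.forward_probs(xu)
                probs_u.append(ProbabilityMap(p.transpose(0, 2, 3, 1)))
                caches_u.append(c)
            # distribution statistics are maintained in every mode so logs
            # and checkpoints are comparable across ablations
            mats = state.matrices[m]
            mats["Ml"] = update_labeled_distribution(mats["Ml"], probs_l[m], yl, ema)
            if has_unlabeled and not config.supervised_only:
                mats["Mu"] = update_unlabeled_distribution(mats["Mu"], mats["Ml"], probs_u[m], ema)

        ls = supervised_loss(probs_l[0], probs_l[1], yl)
        n_l = yl.size
        grads = []
        for m in range(2):
            dlog = (probs_l[m].values - _onehot(yl, K)) / n_l  # (B, H, W, K)
            grads.append(models[m].backward(dlog.transpose(0, 3, 1, 2), caches_l[m]))

        lu = 0.0
        frac = [0.0, 0.0]
        if not config.supervised_only:
            arts = unsupervised_artifacts(tuple(probs_u), state.matrices, config)
            if artifact_hook is not None:
                artifact_hook(it, {"raw1": probs_u[0], "raw2": probs_u[1], **arts})
            n_u = arts["pseudo1"].labels.size
            for m, other in ((0, 1), (1, 0)):
                # alignment steers pseudo-label generation only; the CE is on
                # the model's own raw prediction (keeps the alignment switch
                # isolated to pseudo-labels/confidences)
                raw_self = probs_u[m]
                pseudo = arts[f"pseudo{other + 1}"]
                lu += oe_loss(raw_self, pseudo)
                frac[other] = pseudo.accepted_fraction
                dlog = (
                    config.lambda_u
                    * pseudo.accept_mask[..., None]
                    * (raw_self.values - _onehot(pseudo.labels, K))
                    / n_u
                )
                g = models[m].backward(dlog.transpose(0, 3, 1, 2), caches_u[m])
                for k in grads[m]:
                    grads[m][k] += g[k]
        elif artifact_hook is not None:
            artifact_hook(it, {})

        lr = config.effective_lr(it)
        for m in range(2):
            opts[m].step(models[m].params, grads[m], lr=lr)

        report = LossReport(
            supervised=ls,
            unsupervised=lu,
            lambda_u=config.lambda_u,
            accepted_fraction_1=frac[0],
            accepted_fraction_2=frac[1],
        )
        record = {
            "iteration": it,
            "loss": json.loads(report.to_json()),
            "ml_diag": [np.diag(state.matrices[m]["Ml"].entries).tolist() for m in range(2)],
            "mu_diag": [np.diag(state.matrices[m]["Mu"].entries).tolist() for m in range(2)],
        }
        if validation is not None and config.val_interval and (
            it % config.val_interval == 0 or it == config.max_iterations
        ):
            record["val_miou"] = _validate(models, validation, K)
        state.log.append(record)
    return state


def _predict_labels(models, images: np.ndarray) -> np.ndarray:
    probs = _ensemble_probs(models, images)
    return np.argmax(probs, axis=-1)


def _ensemble_probs(models, images: np.ndarray) -> np.ndarray:
    x = _to_batch(images)
    return 0.5 * (models[0].predict_probs(x) + models[1].predict_probs(x))


def _validate(models, validation, num_classes: int) -> float:
    images, masks = validation
    pred = _predict_labels(models, images)
    return miou(confusion_counts(pred, np.asarray(masks), num_classes))


# -- checkpointing ----------------------------------------------------------


def save_checkpoint(path: str, state: _TrainerState) -> None:
    """Persist models, optimizers, matrices, samplers and iteration."""
    arrays = {}
    for tag, model in (("m1", state.model1), ("m2", state.model2)):
        for k, v in model.get_state().items():
            arrays[f"{tag}.{k}"] = v
    for tag, opt in (("o1", state.opt1), ("o2", state.opt2)):
        for k, v in opt.get_state().items():
            arrays[f"{tag}.{k}"] = v
    meta = {
        "iteration": state.iteration,
        "config_digest": state.config.digest(),
        "config": asdict(state.config),
        "matrices": [
            {r: state.matrices[m][r].to_json() for r in ("Ml", "Mu")} for m in range(2)
        ],
        "samplers": {
            "labeled": state.labeled_sampler.get_state(),
            "unlabeled": state.unlabeled_sampler.get_state(),
        },
        "log": state.log.records,
    }
    np.savez(path if path.endswith(".npz") else path + ".npz", **arrays)
    with open(_meta_path(path), "w") as fh:
        json.dump(meta, fh)


def _meta_path(path: str) -> str:
    base = path[:-4] if path.endswith(".npz") else path
    return base + ".json"


def load_checkpoint(path: str, n_labeled: int, n_unlabeled: int) -> _TrainerState:
    with open(_meta_path(path)) as fh:
        meta = json.load(fh)
    cfg_dict = meta["config"]
    config = TrainConfig(**cfg_dict)
    state = _TrainerState(config, n_labeled, max(n_unlabeled, 1))
    data = np.load(path if path.endswith(".npz") else path + ".npz")
    for tag, model in (("m1", state.model1), ("m2", state.model2)):
        model.set_state({k: data[f"{tag}.{k}"] for k in model.params})
    for tag, opt in (("o1", state.opt1), ("o2", state.opt2)):
        opt.set_state({k: data[f"{tag}.{k}"] for k in opt.velocity})
    for m in range(2):
        for r in ("Ml", "Mu"):
            state.matrices[m][r] = ClassDistributionMatrix.from_json(meta["matrices"][m][r])
    state.labeled_sampler.set_state(meta["samplers"]["labeled"])
    state.unlabeled_sampler.set_state(meta["samplers"]["unlabeled"])
    state.iteration = meta["iteration"]
    state.log = TrainLog(records=meta["log"])
    return state


# -- public functional interface --------------------------------------------


def train(
    config: TrainConfig,
    labeled: tuple[np.ndarray, np.ndarray],
    unlabeled: np.ndarray | None,
    validation: tuple[np.ndarray, np.ndarray] | None = None,
    artifact_hook=None,
    resume_state: _TrainerState | None = None,
):
    """Run Algorithm-style co-training; returns (model1, model2, log)."""
    state = _run_training(config, labeled, unlabeled, validation, artifact_hook, resume_state)
    return state.model1, state.model2, state.log


class CoDASegmenter(BaseEstimator):
    """Semi-supervised segmentation estimator with co-distribution alignment.

    Follows the sklearn semi-supervised convention: ``fit(X, y)`` takes
    images ``X`` of shape (N, H, W) (uint8 or [0, 1] floats) and masks ``y``
    of shape (N, H, W); images whose mask is entirely ``-1`` are treated as
    unlabeled.  ``predict`` returns the argmax of the two trained networks'
    averaged probabilities.

    Parameters mirror :class:`TrainConfig`; fitted attributes are
    ``models_``, ``matrices_``, ``log_`` and ``n_classes_``.
    """

    def __init__(
        self,
        num_classes: int = 4,
        alpha: float = 0.999,
        epsilon: float = 1e-8,
        tau_min: float = 0.05,
        lambda_u: float = 1.0,
        learning_rate: float = 0.02,
        momentum: float = 0.9,
        lr_poly_power: float = 0.0,
        max_iterations: int = 1000,
        labeled_batch_size: int = 4,
        unlabeled_batch_size: int = 4,
        seed1: int = 1,
        seed2: int = 2,
        data_seed: int = 0,
        width: int = 8,
        use_alignment: bool = True,
        use_oe: bool = True,
        supervised_only: bool = False,
        static_threshold: float | None = None,
        val_interval: int = 0,
    ):
        self.num_classes = num_classes
        self.alpha = alpha
        self.epsilon = epsilon
        self.tau_min = tau_min
        self.lambda_u = lambda_u
        self.learning_rate = learning_rate
        self.momentum = momentum
        self.lr_poly_power = lr_poly_power
        self.max_iterations = max_iterations
        self.labeled_batch_size = labeled_batch_size
        self.unlabeled_batch_size = unlabeled_batch_size
        self.seed1 = seed1
        self.seed2 = seed2
        self.data_seed = data_seed
        self.width = width
        self.use_alignment = use_alignment
        self.use_oe = use_oe
        self.supervised_only = supervised_only
        self.static_threshold = static_threshold
        self.val_interval = val_interval

    def _config(self) -> TrainConfig:
        return TrainConfig(**{k: getattr(self, k) for k in TrainConfig.__dataclass_fields__})

    @staticmethod
    def _as_uint8(X: np.ndarray) -> np.ndarray:
        X = np.asarray(X)
        if X.dtype == np.uint8:
            return X
        return np.round(np.clip(X, 0.0, 1.0) * 255).astype(np.uint8)

    def fit(self, X, y, validation=None, artifact_hook=None):
        X = self._as_uint8(X)
        y = np.asarray(y)
        if X.shape != y.shape:
            raise ValueError("X and y must share shape (N, H, W)")
        is_labeled = np.array([(m >= 0).any() for m in y])
        labeled = (X[is_labeled], y[is_labeled].astype(np.int64))
        unlabeled = X[~is_labeled]
        config = self._config()
        state = _run_training(
            config, labeled, unlabeled if len(unlabeled) else None, validation, artifact_hook
        )
        self.models_ = (state.model1, state.model2)
        self.matrices_ = state.matrices
        self.log_ = state.log
        self.n_classes_ = config.num_classes
        return self

    def predict_proba(self, X) -> np.ndarray:
        self._check_fitted()
        return _ensemble_probs(self.models_, self._as_uint8(X))

    def predict(self, X) -> np.ndarray:
        self._check_fitted()
        return _predict_labels(self.models_, self._as_uint8(X))

    def score(self, X, y) -> float:
        """Mean IoU of the ensemble prediction against masks ``y``."""
        pred = self.predict(X)
        return miou(confusion_counts(pred, np.asarray(y), self.n_classes_))

    def per_class_iou(self, X, y) -> np.ndarray:
        pred = self.predict(X)
        return per_class_iou(confusion_counts(pred, np.asarray(y), self.n_classes_))

    def _check_fitted(self) -> None:
        if not hasattr(self, "models_"):
            raise RuntimeError("estimator is not fitted; call fit first")
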