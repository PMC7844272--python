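"""Training: weighted multi-head loss, ADAM schedule, experiments and ranking.

The loss compares one-hot ground truth ``x`` against the two prediction heads
over an output window of N voxels::

    L = (1/N) sum W . H(x, xhat_3d)  +  (c_2d/N) sum W . H(x, xhat_2d)
        + lambda_2d |Theta_2D|^2 + lambda_3d |Theta_3D|^2
        + lambda_p (|theta_2DP|^2 + |theta_3DP|^2)

where ``H`` is the per-voxel cross entropy ``-log xhat_v(l_v)``, ``W`` the
per-voxel weight volume, ``.`` the elementwise product, and the L2 penalties
run over every variable (biases included) of each parameter subset.  With
``use_multi_loss=False`` the ``xhat_2d`` term is dropped; with
``use_3d_pyramid=False`` the ``xhat_3d`` term is dropped and the ``xhat_2d``
term (still scaled by ``c_2d``) is the sole data term.

Optimization is ADAM at minibatch size 1 with a continuously decaying
learning rate ``lr(step) = lr0 * decay_rate^(step / decay_interval_steps)``
(a staircase variant is flag-selectable).  Each epoch the training volume is
re-augmented, windows are extracted on the spacing grid and presented in
shuffled order.  Evaluation-set MIoU over all 7 classes is computed once per
epoch from stitched full-volume predictions of the network's output head;
instances that fail to reach ``early_stop_miou`` after ``early_stop_epoch``
epochs are halted.  Experiments train several instances differing only in
seed and rank them by best evaluation MIoU for Top-k ensembling.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np

from . import model_zoo
from .augmentation import AugmentConfig, augment_epoch
from .ensemble import predict_volume, segmentation_from_probs
from .metrics import miou
from .model_zoo import HybridNet, ModelConfig, NetworkParams, partition_params
from .nn import Adam
from .nn import autograd as ag
from .volume_io import CLASSES, ORGANELLE_CLASSES, ImageVolume, LabelVolume
from .weight_maps import WeightVolume
from .windowing import WindowSpec, extract_epoch_windows

LOG_PROB_CLAMP = 1e-12


@dataclass
class LossParams:
    lambda_2d: float = 10.0 ** -4.7
    lambda_3d: float = 1e-5
    lambda_p: float = 1e-9
    c_2d: float = 0.33

    def __post_init__(self) -> None:
        if min(self.lambda_2d, self.lambda_3d, self.lambda_p, self.c_2d) < 0:
            raise ValueError("loss parameters must be >= 0")


@dataclass
class TrainConfig:
    epochs: int = 40
    window_spec: WindowSpec = field(default_factory=WindowSpec)
    lr0: float = 1e-3
    beta1: float = 1.0 - 10.0 ** -1.5
    beta2: float = 1.0 - 10.0 ** -2.1
    eps: float = 1e-7
    decay_rate: float = 0.75
    decay_interval_steps: float = 10.0 ** 3.4
    staircase_decay: bool = False
    early_stop_miou: float = 0.3
    early_stop_epoch: int = 10
    augment: AugmentConfig = field(default_factory=AugmentConfig)
    max_steps: int | None = None  # optional cap for scaled-down runs
    stop_at_miou: float | None = None  # optional success-based halt
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")
        if not 0 < self.decay_rate <= 1:
            raise ValueError("decay_rate must be in (0, 1]")


def cross_entropy_map(x: np.ndarray, xhat: np.ndarray) -> np.ndarray:
    """Per-voxel cross entropy -log xhat_v(l_v) between one-hot truth and predictions.

    Both arrays are (7, z, y, x); log-probabilities are clamped at 1e-12.
    """
    x = np.asarray(x, dtype=np.float64)
    xhat = np.asarray(xhat, dtype=np.float64)
    if x.shape != xhat.shape:
        raise ValueError("truth/prediction shapes must match")
    p_true = (x * xhat).sum(axis=0)
    return -np.log(np.maximum(p_true, LOG_PROB_CLAMP))


def one_hot(labels: np.ndarray, n_classes: int = len(CLASSES)) -> np.ndarray:
    out = np.zeros((n_classes,) + labels.shape, dtype=np.float64)
    np.put_along_axis(out, labels[None].astype(np.int64), 1.0, axis=0)
    return out


def total_loss(
    x: np.ndarray,
    xhat_3d: np.ndarray | None,
    xhat_2d: np.ndarray | None,
    weights: np.ndarray,
    params: LossParams,
    net_params: NetworkParams | None = None,
    use_multi_loss: bool = True,
) -> float:
    """The scalar training loss for one output window (reference computation).

    ``xhat_3d=None`` reproduces the No-3D-Pyramid ablation (the 2D term is the
    sole data term); ``use_multi_loss=False`` drops the 2D term.
    """
    if xhat_3d is None and (xhat_2d is None or not use_multi_loss):
        raise ValueError("at least one prediction head is required by the loss")
    n = weights.size
    loss = 0.0
    if xhat_3d is not None:
        loss += float((weights * cross_entropy_map(x, xhat_3d)).sum()) / n
    if xhat_2d is not None and use_multi_loss:
        loss += params.c_2d * float((weights * cross_entropy_map(x, xhat_2d)).sum()) / n
    if net_params is not None:
        for lam, group in (
            (params.lambda_2d, net_params.theta_2d),
            (params.lambda_3d, net_params.theta_3d),
            (params.lambda_p, net_params.theta_2dp),
            (params.lambda_p, net_params.theta_3dp),
        ):
            for p in group:
                loss += lam * float((p.data.astype(np.float64) ** 2).sum())
    return loss


def loss_tensor(
    x2d: ag.Tensor,
    x3d: ag.Tensor | None,
    labels: np.ndarray,
    weights: np.ndarray,
    params: LossParams,
    net_params: NetworkParams,
    use_multi_loss: bool = True,
) -> ag.Tensor:
    """Differentiable version of :func:`total_loss` used by the training loop."""
    n = float(weights.size)
    w32 = weights.astype(np.float32)
    lab = labels.astype(np.int64)
    loss: ag.Tensor | None = None
    if x3d is not None:
        loss = (1.0 / n) * ag.weighted_cross_entropy(x3d, lab, w32, LOG_PROB_CLAMP)
    if use_multi_loss or x3d is None:
        term = (params.c_2d / n) * ag.weighted_cross_entropy(
            x2d, lab, w32, LOG_PROB_CLAMP
        )
        loss = term if loss is None else loss + term
    for lam, group in (
        (params.lambda_2d, net_params.theta_2d),
        (params.lambda_3d, net_params.theta_3d),
        (params.lambda_p, net_params.theta_2dp),
        (params.lambda_p, net_params.theta_3dp),
    ):
        if lam == 0:
            continue
        for p in group:
            loss = loss + lam * ag.sum_squares(p)
    return loss


def lr_schedule(step: int, config: TrainConfig) -> float:
    """Continuous exponential decay (staircase optional)."""
    if step < 0:
        raise ValueError("step must be >= 0")
    exponent = step / config.decay_interval_steps
    if config.staircase_decay:
        exponent = np.floor(exponent)
    return config.lr0 * config.decay_rate ** exponent


@dataclass
class InstanceRecord:
    """One trained instance: seed, per-epoch trace and checkpoints."""

    seed: int
    model_config: ModelConfig
    trace: list[dict] = field(default_factory=list)
    best_miou: float = -np.inf
    best_state: dict | None = None
    final_state: dict | None = None
    best_checkpoint_path: str | None = None
    final_checkpoint_path: str | None = None
    halted_early: bool = False
    steps_taken: int = 0

    def load_best_network(self) -> HybridNet:
        net = HybridNet(self.model_config)
        if self.best_state is not None:
            net.load_state_dict(self.best_state)
        elif self.best_checkpoint_path is not None:
            return model_zoo.load_checkpoint(self.best_checkpoint_path)
        return net


@dataclass
class ExperimentResult:
    """All instances of one experiment, ranked by best evaluation MIoU."""

    instances: list[InstanceRecord]

    def ranking(self) -> list[int]:
        order = np.argsort([-rec.best_miou for rec in self.instances], kind="stable")
        return [int(i) for i in order]

    def ranked_instances(self) -> list[InstanceRecord]:
        return [self.instances[i] for i in self.ranking()]


def _evaluate_network(
    net: HybridNet,
    eval_image: ImageVolume,
    eval_labels: LabelVolume,
    spec: WindowSpec,
) -> tuple[float, float]:
    probs = predict_volume(net, eval_image, spec)
    seg = segmentation_from_probs(probs)
    return (
        miou(eval_labels, seg, CLASSES, probs.valid),
        miou(eval_labels, seg, ORGANELLE_CLASSES, probs.valid),
    )


def train_instance(
    image: ImageVolume,
    labels: LabelVolume,
    weights: WeightVolume,
    eval_data: tuple[ImageVolume, LabelVolume],
    model_config: ModelConfig,
    train_config: TrainConfig,
    loss_params: LossParams | None = None,
    outdir: str | None = None,
    log_fn=None,
) -> InstanceRecord:
    """Train one network instance; fully deterministic given the config seed.

    The instance seed controls variable initialization, per-epoch augmentation
    and window presentation order.  Training volumes must be preprocessed
    (image z-scored, weights built); ``eval_data`` is the held-out
    (image, labels) pair used for the per-epoch MIoU trace.
    """
    if eval_data is None:
        raise ValueError("evaluation data is required for instance ranking")
    loss_params = loss_params or LossParams()
    eval_image, eval_labels = eval_data
    seed = train_config.seed
    cfg = replace(model_config, init_seed=seed)
    net = HybridNet(cfg)
    parts = partition_params(net)
    opt = Adam(
        net.parameters(),
        beta1=train_config.beta1,
        beta2=train_config.beta2,
        eps=train_config.eps,
    )
    record = InstanceRecord(seed=seed, model_config=cfg)
    spec = train_config.window_spec
    epoch_seeds = np.random.SeedSequence(seed).spawn(max(train_config.epochs, 1))
    step = 0
    done = False
    for epoch in range(train_config.epochs):
        rng = np.random.default_rng(epoch_seeds[epoch])
        img, lab, wgt = augment_epoch(
            image.data, labels.data, weights.data, train_config.augment, rng
        )
        windows = extract_epoch_windows(img, lab, wgt, spec, rng)
        losses = []
        for xw, lw, ww in windows:
            opt.zero_grad()
            x2d, x3d = net.forward_tensors(xw[None])
            loss = loss_tensor(
                x2d, x3d, lw, ww, loss_params, parts, cfg.use_multi_loss
            )
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"non-finite loss at step {step} (seed {seed}); aborting"
                )
            loss.backward()
            opt.step(lr_schedule(step, train_config))
            losses.append(float(loss.data))
            step += 1
            if train_config.max_steps is not None and step >= train_config.max_steps:
                done = True
                break
        miou_all, miou_org = _evaluate_network(net, eval_image, eval_labels, spec)
        if miou_all > record.best_miou:
            record.best_miou = miou_all
            record.best_state = net.state_dict()
        entry = {
            "epoch": epoch,
            "step": step,
            "lr": lr_schedule(step, train_config),
            "loss": float(np.mean(losses)) if losses else float("nan"),
            "eval_miou_all": miou_all,
            "eval_miou_org": miou_org,
        }
        record.trace.append(entry)
        if log_fn is not None:
            log_fn(entry)
        if (
            epoch + 1 >= train_config.early_stop_epoch
            and record.best_miou < train_config.early_stop_miou
        ):
            record.halted_early = True
            done = True
        if (
            train_config.stop_at_miou is not None
            and record.best_miou >= train_config.stop_at_miou
        ):
            done = True
        if done:
            break
    record.final_state = net.state_dict()
    record.steps_taken = step
    if record.best_state is None:  # zero-epoch run: initialized network
        record.best_state = record.final_state
    if outdir is not None:
        os.makedirs(outdir, exist_ok=True)
        best = os.path.join(outdir, f"seed{seed}_best.npz")
        final = os.path.join(outdir, f"seed{seed}_final.npz")
        net.load_state_dict(record.best_state)
        model_zoo.save_checkpoint(best, net)
        net.load_state_dict(record.final_state)
        model_zoo.save_checkpoint(final, net)
        record.best_checkpoint_path = best
        record.final_checkpoint_path = final
    return record


def run_experiment(
    seeds: list[int],
    image: ImageVolume,
    labels: LabelVolume,
    weights: WeightVolume,
    eval_data: tuple[ImageVolume, LabelVolume],
    model_config: ModelConfig,
    train_config: TrainConfig,
    loss_params: LossParams | None = None,
    outdir: str | None = None,
    log_fn=None,
) -> ExperimentResult:
    """Train one instance per seed and rank them by best evaluation MIoU."""
    if len(set(seeds)) != len(seeds):
        raise ValueError("instance seeds must be distinct")
    instances = []
    for seed in seeds:
        cfg = replace(train_config, seed=seed)
        instances.append(
            train_instance(
                image,
                labels,
                weights,
                eval_data,
                model_config,
                cfg,
                loss_params,
                outdir=outdir,
                log_fn=log_fn,
            )
        )
    return ExperimentResult(instances)
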