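"""Model/Results interface over the training pipeline.

:class:`DenseSegmentationModel` bundles the preprocessed training and
evaluation volumes with the architecture, loss and optimization
configuration; :meth:`~DenseSegmentationModel.fit` trains one instance per
seed and returns a :class:`SegmentationResults` carrying the ranked
instances, their evaluation traces, and prediction/ensembling/evaluation
methods.

Example
-------
>>> model = DenseSegmentationModel.from_volumes(img, lab, eval_img, eval_lab)
>>> res = model.fit(seeds=[0, 1, 2])
>>> print(res.summary())
>>> seg = res.segment(test_img, top_k=2)
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .ensemble import (
    ClassProbs,
    ensemble_average,
    predict_volume,
    segmentation_from_probs,
    top_k,
)
from .metrics import MetricsReport, evaluate
from .model_zoo import ModelConfig
from .training import (
    ExperimentResult,
    LossParams,
    TrainConfig,
    run_experiment,
)
from .volume_io import ImageVolume, LabelVolume, normalize_zscore
from .weight_maps import EdgeWeightParams, WeightVolume, build_weight_volume


@dataclass
class DenseSegmentationModel:
    """A dense cellular segmentation model bound to training data.

    Volumes passed to :meth:`from_volumes` are z-score normalized and the
    loss weight volume is built from the training labels; the plain
    constructor assumes preprocessed inputs.
    """

    train_image: ImageVolume
    train_labels: LabelVolume
    eval_image: ImageVolume
    eval_labels: LabelVolume
    weights: WeightVolume
    model_config: ModelConfig = field(default_factory=ModelConfig)
    train_config: TrainConfig = field(default_factory=TrainConfig)
    loss_params: LossParams = field(default_factory=LossParams)

    @classmethod
    def from_volumes(
        cls,
        train_image: ImageVolume,
        train_labels: LabelVolume,
        eval_image: ImageVolume,
        eval_labels: LabelVolume,
        weight_params: EdgeWeightParams | None = None,
        **kwargs,
    ) -> "DenseSegmentationModel":
        return cls(
            train_image=normalize_zscore(train_image),
            train_labels=train_labels,
            eval_image=normalize_zscore(eval_image),
            eval_labels=eval_labels,
            weights=build_weight_volume(train_labels, weight_params),
            **kwargs,
        )

    def fit(
        self,
        seeds: list[int] | tuple[int, ...] = (0,),
        outdir: str | None = None,
        log_fn=None,
    ) -> "SegmentationResults":
        """Train one instance per seed; instances differ only in their seed."""
        experiment = run_experiment(
            list(seeds),
            self.train_image,
            self.train_labels,
            self.weights,
            (self.eval_image, self.eval_labels),
            self.model_config,
            self.train_config,
            self.loss_params,
            outdir=outdir,
            log_fn=log_fn,
        )
        return SegmentationResults(model=self, experiment=experiment)


@dataclass
class SegmentationResults:
    """Fitted instances, their evaluation traces, and inference utilities."""

    model: DenseSegmentationModel
    experiment: ExperimentResult

    @property
    def best_miou(self) -> float:
        return self.experiment.ranked_instances()[0].best_miou

    def networks(self, k: int = 1) -> list:
        """The k top-ranked trained networks (best checkpoints)."""
        return top_k(self.experiment, k)

    def predict(self, vol: ImageVolume, k: int = 1) -> ClassProbs:
        """Top-k ensemble class probabilities for a full volume."""
        spec = self.model.train_config.window_spec
        members = [predict_volume(net, vol, spec) for net in self.networks(k)]
        return ensemble_average(members)

    def segment(self, vol: ImageVolume, k: int = 1) -> LabelVolume:
        return segmentation_from_probs(self.predict(vol, k))

    def evaluate(
        self, truth: LabelVolume, vol: ImageVolume, k: int = 1
    ) -> MetricsReport:
        probs = self.predict(vol, k)
        return evaluate(truth, segmentation_from_probs(probs), mask=probs.valid)

    def summary(self) -> str:
        """Plain-text ranking table of the fitted instances."""
        lines = [
            "Dense cellular segmentation -- experiment summary",
            f"instances: {len(self.experiment.instances)}   "
            f"architecture: 2D-3D"
            + (" + 3x3x3" if self.model.model_config.use_333_convs else "")
            + ("" if self.model.model_config.use_3d_pyramid else " (no 3D pyramid)"),
            f"{'rank':>4} {'seed':>6} {'best eval MIoU(all)':>20} "
            f"{'final MIoU(all)':>16} {'epochs':>7} {'halted':>7}",
        ]
        for rank, rec in enumerate(self.experiment.ranked_instances(), 1):
            final = rec.trace[-1]["eval_miou_all"] if rec.trace else float("nan")
            lines.append(
                f"{rank:>4} {rec.seed:>6} {rec.best_miou:>20.4f} "
                f"{final:>16.4f} {len(rec.trace):>7} {str(rec.halted_early):>7}"
            )
        return "\n".join(lines)


def tiny_model_config(**overrides) -> ModelConfig:
    """A small 2-scale, 8-channel configuration for desk-scale experiments."""
    base = dict(encoder_channels=(8, 16), feature_width_out=8, pyramid_channels=8)
    base.update(overrides)
    return ModelConfig(**base)


def tiny_train_config(**overrides) -> TrainConfig:
    """Desk-scale training defaults matched to :func:`tiny_model_config`."""
    from .augmentation import NO_AUGMENT
    from .windowing import WindowSpec

    base = dict(
        epochs=40,
        window_spec=WindowSpec((5, 64, 64), (5, 60, 60), (3, 32, 32)),
        augment=NO_AUGMENT,
        early_stop_miou=0.0,
        early_stop_epoch=10**9,
    )
    base.update(overrides)
    return TrainConfig(**base)
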