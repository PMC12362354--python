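"""End-to-end optimization: epoch expansion, mini-batching, best checkpoint.

Each epoch the training split is expanded by the augmentation policy
(two independently augmented copies of every patch by default, doubling the
data), shuffled, and consumed in mini-batches; both encoders are updated
under the configured contrastive loss. After every epoch the mean loss on a
held-out evaluation split (20% of the reference cohort by default) is
computed in evaluation mode, and the parameters achieving the lowest
evaluation loss over the run are kept as the final model.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import nn
from .encoders import HeclipModel, ImageEncoderConfig, build_model, preprocess_patches
from .objective import AugmentationPolicy, LossConfig, contrastive_loss, expand_epoch
from .types import GeneSelection, PairedCohort, PatchSpotPair

logger = logging.getLogger(__name__)

CHECKPOINT_FORMAT_VERSION = 1


@dataclass
class TrainConfig:
    epochs: int = 15
    batch_size: int = 128
    learning_rate: float = 1e-3
    weight_decay: float = 1e-3
    eval_fraction: float = 0.2
    seed: int = 0
    loss: LossConfig = field(default_factory=LossConfig)
    augmentation: AugmentationPolicy = field(default_factory=AugmentationPolicy)
    encoder: ImageEncoderConfig = field(default_factory=ImageEncoderConfig)

    def __post_init__(self) -> None:
        if not 0.0 < self.eval_fraction < 1.0:
            raise ValueError("eval_fraction must lie in (0, 1)")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


@dataclass
class Checkpoint:
    state: dict[str, np.ndarray]
    config: TrainConfig
    gene_selection: GeneSelection
    best_eval_loss: float
    best_epoch: int
    train_curve: list[float]
    eval_curve: list[float]

    def build_model(self) -> HeclipModel:
        model = build_model(self.gene_selection.size, self.config.encoder, seed=self.config.seed)
        model.load_state_dict(self.state)
        model.set_training(False)
        return model

    def save(self, path: str | Path) -> None:
        manifest = {
            "format_version": CHECKPOINT_FORMAT_VERSION,
            "config": _config_to_dict(self.config),
            "gene_selection": {
                "mode": self.gene_selection.mode,
                "n_requested": self.gene_selection.n_requested,
                "gene_names": self.gene_selection.gene_names,
            },
            "best_eval_loss": self.best_eval_loss,
            "best_epoch": self.best_epoch,
            "train_curve": self.train_curve,
            "eval_curve": self.eval_curve,
        }
        np.savez(path, __manifest__=np.array(json.dumps(manifest)), **self.state)

    @staticmethod
    def load(path: str | Path) -> "Checkpoint":
        with np.load(path, allow_pickle=False) as data:
            manifest = json.loads(str(data["__manifest__"]))
            state = {k: data[k] for k in data.files if k != "__manifest__"}
        if manifest["format_version"] != CHECKPOINT_FORMAT_VERSION:
            raise ValueError(f"unsupported checkpoint format {manifest['format_version']}")
        return Checkpoint(
            state=state,
            config=_config_from_dict(manifest["config"]),
            gene_selection=GeneSelection(**manifest["gene_selection"]),
            best_eval_loss=manifest["best_eval_loss"],
            best_epoch=manifest["best_epoch"],
            train_curve=manifest["train_curve"],
            eval_curve=manifest["eval_curve"],
        )


def _config_to_dict(config: TrainConfig) -> dict:
    d = asdict(config)
    d["augmentation"]["rotations"] = list(config.augmentation.rotations)
    return d


def _config_from_dict(d: dict) -> TrainConfig:
    d = dict(d)
    loss = LossConfig(**d.pop("loss"))
    aug = d.pop("augmentation")
    aug["rotations"] = tuple(aug["rotations"])
    augmentation = AugmentationPolicy(**aug)
    encoder = ImageEncoderConfig(**d.pop("encoder"))
    return TrainConfig(loss=loss, augmentation=augmentation, encoder=encoder, **d)


def split_train_eval(
    cohort: PairedCohort, eval_fraction: float = 0.2, seed: int = 0
) -> tuple[PairedCohort, PairedCohort]:
    """Random disjoint train/eval partition of a cohort.

    ``round((1 - eval_fraction) * n)`` pairs go to training, the remainder
    to evaluation; the draw is reproducible under ``seed`` and each split
    preserves the cohort's original ordering.
    """
    if not 0.0 < eval_fraction < 1.0:
        raise ValueError("eval_fraction must lie in (0, 1)")
    n = len(cohort)
    if n < 2:
        raise ValueError("cohort must contain at least 2 pairs to split")
    n_train = int(round((1.0 - eval_fraction) * n))
    n_train = min(max(n_train, 1), n - 1)
    perm = np.random.default_rng(seed).permutation(n)
    train_idx = np.sort(perm[:n_train])
    eval_idx = np.sort(perm[n_train:])
    return cohort.subset(train_idx.tolist()), cohort.subset(eval_idx.tolist())


def _batch_forward_loss(
    model: HeclipModel, pairs: list[PatchSpotPair], config: TrainConfig, training: bool
):
    patches = preprocess_patches(np.stack([p.patch for p in pairs]))
    expr = np.stack([p.expression for p in pairs]).astype(nn.DTYPE)
    model.set_training(training)
    h_p = model.image_encoder.forward(patches)
    h_s = model.spot_encoder.forward(expr)
    return h_p, h_s


def evaluate_loss(model: HeclipModel, cohort: PairedCohort, config: TrainConfig) -> float:
    """Mean contrastive loss over a cohort in evaluation mode (no dropout,
    no augmentation), batched as in training and weighted by batch size."""
    total, count = 0.0, 0
    for start in range(0, len(cohort), config.batch_size):
        pairs = cohort.pairs[start : start + config.batch_size]
        h_p, h_s = _batch_forward_loss(model, pairs, config, training=False)
        loss = contrastive_loss(h_p, h_s, config.loss, with_grad=False)
        total += loss * len(pairs)
        count += len(pairs)
    return total / count


def train(reference: PairedCohort, config: TrainConfig) -> Checkpoint:
    """Optimize both encoders on the reference cohort; return the checkpoint
    with the lowest held-out evaluation loss."""
    if len(reference) == 0:
        raise ValueError("reference cohort is empty")
    train_split, eval_split = split_train_eval(reference, config.eval_fraction, config.seed)

    batch_size = config.batch_size
    n_expanded = len(train_split) * config.augmentation.copies_per_epoch
    if batch_size > n_expanded:
        logger.warning("batch_size %d > expanded train size %d; clamping", batch_size, n_expanded)
        batch_size = n_expanded

    model = build_model(reference.gene_selection.size, config.encoder, seed=config.seed)
    optimizer = nn.Adam(
        list(model.named_params()),
        lr=config.learning_rate,
        weight_decay=config.weight_decay,
    )
    shuffle_rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 1]))

    train_curve: list[float] = []
    eval_curve: list[float] = []
    best_eval = np.inf
    best_epoch = -1
    best_state = model.state_dict()

    for epoch in range(config.epochs):
        expanded = expand_epoch(train_split, config.augmentation, epoch)
        order = shuffle_rng.permutation(len(expanded))
        epoch_total, epoch_count = 0.0, 0
        for start in range(0, len(expanded), batch_size):
            batch = [expanded[i] for i in order[start : start + batch_size]]
            h_p, h_s = _batch_forward_loss(model, batch, config, training=True)
            loss, (dh_p, dh_s) = contrastive_loss(h_p, h_s, config.loss, with_grad=True)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, batch starting {start}: {loss}; "
                    f"|h_p|max={np.abs(h_p).max():.3g} |h_s|max={np.abs(h_s).max():.3g}"
                )
            optimizer.zero_grad()
            model.image_encoder.backward(dh_p.astype(nn.DTYPE))
            model.spot_encoder.backward(dh_s.astype(nn.DTYPE))
            optimizer.step()
            epoch_total += loss * len(batch)
            epoch_count += len(batch)
        train_loss = epoch_total / epoch_count
        eval_loss = evaluate_loss(model, eval_split, config)
        train_curve.append(train_loss)
        eval_curve.append(eval_loss)
        logger.info(
            "epoch %d/%d: variant=%s tau=%g train_loss=%.5f eval_loss=%.5f",
            epoch + 1, config.epochs, config.loss.variant, config.loss.temperature,
            train_loss, eval_loss,
        )
        if eval_loss < best_eval:
            best_eval = eval_loss
            best_epoch = epoch
            best_state = model.state_dict()

    return Checkpoint(
        state=best_state,
        config=config,
        gene_selection=reference.gene_selection,
        best_eval_loss=float(best_eval),
        best_epoch=best_epoch,
        train_curve=train_curve,
        eval_curve=eval_curve,
    )
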