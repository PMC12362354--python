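"""The desk-scale synthetic recovery study.

A single workflow used both as an executable validation of the whole
pipeline and as the basis for ablation comparisons: generate a clustered
patch-spot cohort, hold one slice out as the query set, train both encoders
on the reference slices, impute the query expression by top-K retrieval,
and score the result against the ground truth and against a permuted-
reference null model that destroys the image-expression link.
"""

from __future__ import annotations

from dataclasses import dataclass

from .data_prep import split_by_slice
from .encoders import ImageEncoderConfig
from .metrics import MetricConfig, MetricsReport, summarize
from .objective import IMAGE_CENTRIC, AugmentationPolicy, LossConfig
from .retrieval import build_reference, impute
from .synthetic import SyntheticConfig, generate_cohort, permuted_reference_baseline
from .training import Checkpoint, TrainConfig, train


@dataclass
class StudyResult:
    checkpoint: Checkpoint
    report: MetricsReport
    baseline_report: MetricsReport
    n_reference: int
    n_query: int

    def headline(self) -> dict[str, float]:
        s, b = self.report, self.baseline_report
        return {
            "hit_at_1": s.hit_at[1],
            "hit_at_2": s.hit_at[2],
            "hit_at_3": s.hit_at[3],
            "baseline_hit_at_1": b.hit_at[1],
            "median_pcc": s.summaries["pcc_median"],
            "baseline_median_pcc": b.summaries["pcc_median"],
            "median_rmse": s.summaries["rmse_median"],
            "median_ssim": s.summaries["ssim_median"],
            "first_epoch_train_loss": self.checkpoint.train_curve[0],
            "final_train_loss": self.checkpoint.train_curve[-1],
            "best_eval_loss": self.checkpoint.best_eval_loss,
        }


def default_synthetic_config(seed: int) -> SyntheticConfig:
    """The study's cohort: 2400 spots over 6 slices (one slice of 400 held
    out as the query, leaving 2000 reference spots), 200 genes, 4 latent
    clusters, 64x64 patches, moderate noise."""
    return SyntheticConfig(
        n_spots=2400,
        n_genes=200,
        n_clusters=4,
        patch_size=64,
        n_slices=6,
        within_cluster_noise_sd=0.3,
        pixel_noise_sd=0.05,
        seed=seed,
    )


def default_train_config(seed: int, epochs: int = 5) -> TrainConfig:
    return TrainConfig(
        epochs=epochs,
        batch_size=128,
        learning_rate=1e-3,
        weight_decay=1e-3,
        eval_fraction=0.2,
        seed=seed,
        loss=LossConfig(variant=IMAGE_CENTRIC, temperature=1.0),
        augmentation=AugmentationPolicy(copies_per_epoch=2, seed=seed),
        encoder=ImageEncoderConfig(backbone="tiny_cnn", d_o=256),
    )


def run_synthetic_recovery(
    seed: int = 0,
    synthetic_config: SyntheticConfig | None = None,
    train_config: TrainConfig | None = None,
    K: int = 50,
    query_slice: str | None = None,
) -> StudyResult:
    """Run the full study under one seed and return trained model + scores."""
    synthetic_config = synthetic_config or default_synthetic_config(seed)
    train_config = train_config or default_train_config((seed * 2 + 1) % (2**31))
    cohort, _labels = generate_cohort(synthetic_config)
    query_slice = query_slice or f"slice{synthetic_config.n_slices - 1}"
    reference, query = split_by_slice(cohort, query_slice)

    checkpoint = train(reference, train_config)
    index = build_reference(checkpoint, reference)
    result = impute(query, index, checkpoint, K=K)
    baseline = permuted_reference_baseline(index, query, checkpoint, K=K, seed=(seed + 17) % (2**31))

    truth = query.expression_array()
    config = MetricConfig()
    return StudyResult(
        checkpoint=checkpoint,
        report=summarize(truth, result.predictions, config),
        baseline_report=summarize(truth, baseline.predictions, config),
        n_reference=len(reference),
        n_query=len(query),
    )
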