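"""Seed-reproducible synthetic patch-spot cohorts.

The generator emulates the statistical structure the imputation task relies
on: a latent tissue cluster drives both a patch's appearance (base color,
stripe texture, blob density — a deterministic visual program per cluster)
and the spot's expression (a cluster-specific mean program on the
normalized-log scale, with the cluster's marker genes elevated). Gaussian
noise is added independently to pixels and to expression; slices optionally
receive per-gene mean shifts to mimic batch effects.

Independent seed streams are used for cluster assignment, expression
programs, expression noise, pixel noise and batch shifts, so perturbing one
source of randomness never alters the draws of another.
"""

from __future__ import annotations

import colorsys
from dataclasses import dataclass

import numpy as np

from .data_prep import normalize_expression
from .retrieval import ImputationResult, ReferenceIndex, impute
from .training import Checkpoint
from .types import HVG, GeneSelection, PairedCohort, PatchSpotPair, SpotRecord

# fixed entropy prefix making visual/expression programs functions of the
# cluster id alone (not of the cohort seed)
_PROGRAM_ENTROPY = 977


@dataclass
class SyntheticConfig:
    n_spots: int = 2400
    n_genes: int = 200
    n_clusters: int = 4
    patch_size: int = 64
    n_slices: int = 6
    within_cluster_noise_sd: float = 0.3
    pixel_noise_sd: float = 0.05
    batch_shift_sd: float = 0.0
    expression_mode: str = "lognormal"  # or "counts"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_clusters > self.n_spots:
            raise ValueError("n_clusters must not exceed n_spots")
        if min(self.within_cluster_noise_sd, self.pixel_noise_sd, self.batch_shift_sd) < 0:
            raise ValueError("noise standard deviations must be >= 0")
        if self.expression_mode not in ("lognormal", "counts"):
            raise ValueError(f"unknown expression_mode {self.expression_mode!r}")
        if self.n_slices < 1 or self.n_spots < self.n_slices:
            raise ValueError("need 1 <= n_slices <= n_spots")


def _cluster_template(cluster: int, patch_size: int) -> np.ndarray:
    """Deterministic visual program for one cluster, float in [0, 1]."""
    rng = np.random.default_rng(np.random.SeedSequence([_PROGRAM_ENTROPY, cluster, patch_size]))
    hue = (0.05 + cluster * 0.618033988749895) % 1.0
    base = np.array(colorsys.hsv_to_rgb(hue, 0.45, 0.85))
    yy, xx = np.mgrid[0:patch_size, 0:patch_size] / patch_size
    theta = cluster * np.pi / 5.0 + 0.3
    freq = 3.0 + 2.0 * cluster
    stripes = 0.10 * np.sin(2 * np.pi * freq * (xx * np.cos(theta) + yy * np.sin(theta)))
    img = base[None, None, :] + stripes[:, :, None]
    n_blobs = 4 + 3 * cluster
    radius = max(2, patch_size // 16)
    centers = rng.uniform(0, patch_size, size=(n_blobs, 2))
    yy_px, xx_px = np.mgrid[0:patch_size, 0:patch_size]
    for cy, cx in centers:
        mask = (yy_px - cy) ** 2 + (xx_px - cx) ** 2 <= radius**2
        img[mask] *= 0.55  # dark nucleus-like blob
    return np.clip(img, 0.0, 1.0)


def _expression_programs(config: SyntheticConfig) -> np.ndarray:
    """Per-cluster mean expression on the log scale, n_clusters x n_genes.

    Each cluster gets a contiguous marker block raised well above the shared
    baseline, with one dominant marker per cluster, so cluster identity is
    recoverable from the expression argmax.
    """
    rng = np.random.default_rng(np.random.SeedSequence([_PROGRAM_ENTROPY, 1]))
    baseline = rng.uniform(0.5, 2.0, size=config.n_genes)
    programs = np.tile(baseline, (config.n_clusters, 1))
    programs += rng.normal(0.0, 0.3, size=programs.shape)  # diffuse cluster character
    block = max(1, config.n_genes // (4 * config.n_clusters))
    for c in range(config.n_clusters):
        lo = (c * block) % config.n_genes
        programs[c, lo : lo + block] += 2.5
        programs[c, lo] += 3.0  # dominant marker
    return np.clip(programs, 0.0, None)


def generate_cohort(config: SyntheticConfig) -> tuple[PairedCohort, np.ndarray]:
    """Generate a paired cohort plus the latent cluster label per spot."""
    root = np.random.SeedSequence(config.seed)
    rng_cluster = np.random.default_rng(np.random.SeedSequence([config.seed, 10]))
    rng_expr = np.random.default_rng(np.random.SeedSequence([config.seed, 12]))
    rng_pixel = np.random.default_rng(np.random.SeedSequence([config.seed, 13]))
    rng_batch = np.random.default_rng(np.random.SeedSequence([config.seed, 14]))
    del root

    labels = rng_cluster.integers(0, config.n_clusters, size=config.n_spots)
    programs = _expression_programs(config)
    templates = [_cluster_template(c, config.patch_size) for c in range(config.n_clusters)]

    log_expr = programs[labels] + rng_expr.normal(
        0.0, config.within_cluster_noise_sd, size=(config.n_spots, config.n_genes)
    )
    slice_ids = [f"slice{i % config.n_slices}" for i in range(config.n_spots)]
    if config.batch_shift_sd > 0:
        shifts = rng_batch.normal(0.0, config.batch_shift_sd, size=(config.n_slices, config.n_genes))
        log_expr = log_expr + shifts[[i % config.n_slices for i in range(config.n_spots)]]
    log_expr = np.clip(log_expr, 0.0, None)

    gene_names = [f"g{j:04d}" for j in range(config.n_genes)]
    spot_names = [f"spot{i:05d}" for i in range(config.n_spots)]
    if config.expression_mode == "counts":
        # exercise the preprocessing path: Poisson counts around the
        # (de-logged) cluster means, then the standard normalize + log1p
        lam = np.expm1(log_expr)
        counts = rng_expr.poisson(lam).astype(np.float64)
        expr_values = normalize_expression(counts, spot_names, gene_names).values
    else:
        expr_values = log_expr

    selection = GeneSelection(mode=HVG, n_requested=config.n_genes, gene_names=gene_names)
    half = config.patch_size // 2
    per_slice_counter: dict[str, int] = {}
    pairs: list[PatchSpotPair] = []
    for i in range(config.n_spots):
        c = int(labels[i])
        img = templates[c]
        if config.pixel_noise_sd > 0:
            img = np.clip(img + rng_pixel.normal(0.0, config.pixel_noise_sd, size=img.shape), 0.0, 1.0)
        patch = np.round(img * 255.0).astype(np.uint8)
        k = per_slice_counter.get(slice_ids[i], 0)
        per_slice_counter[slice_ids[i]] = k + 1
        spot = SpotRecord(
            spot_id=spot_names[i],
            x=half + (k % 64) * config.patch_size,
            y=half + (k // 64) * config.patch_size,
            slice_id=slice_ids[i],
        )
        pairs.append(PatchSpotPair(patch, expr_values[i], spot))
    return PairedCohort(pairs, selection), labels


def permuted_reference_baseline(
    index: ReferenceIndex,
    queries: PairedCohort | np.ndarray,
    checkpoint: Checkpoint,
    K: int = 50,
    seed: int = 0,
    query_embeddings: np.ndarray | None = None,
) -> ImputationResult:
    """Null model: impute against an index whose expression rows were
    randomly permuted relative to the embeddings, destroying the
    image-expression link while preserving the expression marginals."""
    rng = np.random.default_rng(seed)
    perm = rng.permutation(index.n_ref)
    permuted = ReferenceIndex(
        embeddings=index.embeddings,
        expression=index.expression[perm],
        spot_ids=[index.spot_ids[i] for i in perm],
    )
    return impute(queries, permuted, checkpoint, K=K, query_embeddings=query_embeddings)
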