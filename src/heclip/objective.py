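"""Contrastive objectives and the patch-augmentation policy.

The image-centric loss is the asymmetric variant of the CLIP objective:
cross-modal logits (h_s @ h_p^T)/tau are scored against soft targets derived
solely from the image-image similarity matrix, dropping the spot-side term
of the symmetric loss. Concretely::

    logits  = (h_s @ h_p.T) / tau
    targets = row_softmax((h_p @ h_p.T) / tau)
    loss    = mean_k  sum_j -targets.T[k, j] * log_softmax(logits.T[k])[j]

i.e. the soft cross-entropy is taken row-wise on the *transposed* matrices
and averaged. The symmetric variant (the conventional soft-target CLIP loss)
is retained as an ablation baseline.

Both losses return analytic gradients w.r.t. the two embedding blocks so
they can drive the numpy training loop. Target matrices are treated as
constants under differentiation by default (they define the reference
distribution); a flag lets gradients flow through them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .types import PairedCohort, PatchSpotPair

IMAGE_CENTRIC = "image_centric"
SYMMETRIC_CLIP = "symmetric_clip"


@dataclass
class LossConfig:
    temperature: float = 1.0
    variant: str = IMAGE_CENTRIC
    targets_stop_gradient: bool = True

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0")
        if self.variant not in (IMAGE_CENTRIC, SYMMETRIC_CLIP):
            raise ValueError(f"unknown loss variant {self.variant!r}")


@dataclass
class AugmentationPolicy:
    """Expression-preserving geometric ops drawn per (epoch, pair, copy).

    Only flips and quarter-turn rotations are allowed: they keep the pixel
    grid intact (no interpolation) and cannot change what tissue the spot's
    expression was measured on.
    """

    horizontal_flip: bool = True
    vertical_flip: bool = True
    rotations: tuple[int, ...] = (90, 180, 270)
    copies_per_epoch: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.copies_per_epoch < 1:
            raise ValueError("copies_per_epoch must be >= 1")
        bad = set(self.rotations) - {90, 180, 270}
        if bad:
            raise ValueError(f"rotations must be multiples of 90 degrees, got {sorted(bad)}")


def _softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    x = x - x.max(axis=axis, keepdims=True)
    e = np.exp(x)
    return e / e.sum(axis=axis, keepdims=True)


def _log_softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    x = x - x.max(axis=axis, keepdims=True)
    return x - np.log(np.exp(x).sum(axis=axis, keepdims=True))


def _check_pair(h_p: np.ndarray, h_s: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    h_p = np.asarray(h_p, dtype=np.float64)
    h_s = np.asarray(h_s, dtype=np.float64)
    if h_p.ndim != 2 or h_s.ndim != 2 or h_p.shape != h_s.shape:
        raise ValueError(f"embedding blocks must share a (batch, d_o) shape, got {h_p.shape} vs {h_s.shape}")
    if h_p.shape[0] < 1:
        raise ValueError("batch must contain at least one pair")
    return h_p, h_s


def _softmax_backward_rows(dprobs: np.ndarray, probs: np.ndarray) -> np.ndarray:
    """Jacobian-vector product of a row-wise softmax."""
    return probs * (dprobs - (dprobs * probs).sum(axis=-1, keepdims=True))


def image_centric_loss(
    h_p: np.ndarray, h_s: np.ndarray, config: LossConfig | None = None, with_grad: bool = False
):
    """Image-centric contrastive loss; optionally its gradients.

    Returns the scalar loss, or ``(loss, (dh_p, dh_s))`` when ``with_grad``.
    """
    config = config or LossConfig()
    h_p, h_s = _check_pair(h_p, h_s)
    tau = config.temperature
    b = h_p.shape[0]

    logits = (h_s @ h_p.T) / tau
    targets = _softmax((h_p @ h_p.T) / tau, axis=-1)

    L = logits.T  # rows indexed by image, columns by spot
    Tm = targets.T
    lsm = _log_softmax(L, axis=-1)
    loss = float((-Tm * lsm).sum(axis=1).mean())

    if not with_grad:
        return loss

    probs = np.exp(lsm)
    row_mass = Tm.sum(axis=1, keepdims=True)  # columns of a row-softmax need not sum to 1
    dL = (probs * row_mass - Tm) / b
    dlogits = dL.T
    dh_s = dlogits @ h_p / tau
    dh_p = dlogits.T @ h_s / tau
    if not config.targets_stop_gradient:
        dTm = -lsm / b
        dtargets = dTm.T
        dA = _softmax_backward_rows(dtargets, targets)
        dh_p = dh_p + (dA + dA.T) @ h_p / tau
    return loss, (dh_p, dh_s)


def symmetric_clip_loss(
    h_p: np.ndarray, h_s: np.ndarray, config: LossConfig | None = None, with_grad: bool = False
):
    """Conventional bidirectional soft-target CLIP loss (ablation baseline).

    Targets are the row-softmax of the average of the two within-modality
    similarity matrices (a symmetric matrix, so the same target distribution
    serves both directions); the loss is the mean of the spot->image and
    image->spot soft cross-entropies. With h_p == h_s the two directions
    coincide row by row.
    """
    config = config or LossConfig()
    h_p, h_s = _check_pair(h_p, h_s)
    tau = config.temperature
    b = h_p.shape[0]

    logits = (h_s @ h_p.T) / tau
    sim_avg = (h_p @ h_p.T + h_s @ h_s.T) / (2.0 * tau)
    targets = _softmax(sim_avg, axis=-1)

    lsm1 = _log_softmax(logits, axis=-1)
    lsm2 = _log_softmax(logits.T, axis=-1)
    spots_term = (-targets * lsm1).sum(axis=1)
    images_term = (-targets * lsm2).sum(axis=1)
    loss = float(((spots_term + images_term) / 2.0).mean())

    if not with_grad:
        return loss

    probs1 = np.exp(lsm1)
    probs2 = np.exp(lsm2)
    # target rows are distributions (row softmax), mass 1, in both terms
    dlogits = 0.5 / b * (probs1 - targets)
    dlogits += (0.5 / b * (probs2 - targets)).T
    dh_s = dlogits @ h_p / tau
    dh_p = dlogits.T @ h_s / tau
    if not config.targets_stop_gradient:
        dtargets = 0.5 / b * (-lsm1 - lsm2)
        dA = _softmax_backward_rows(dtargets, targets)
        sym = dA + dA.T
        dh_p = dh_p + sym @ h_p / (2.0 * tau)
        dh_s = dh_s + sym @ h_s / (2.0 * tau)
    return loss, (dh_p, dh_s)


def contrastive_loss(
    h_p: np.ndarray, h_s: np.ndarray, config: LossConfig, with_grad: bool = False
):
    """Dispatch on ``config.variant``."""
    fn = image_centric_loss if config.variant == IMAGE_CENTRIC else symmetric_clip_loss
    return fn(h_p, h_s, config, with_grad=with_grad)


def augment_patch(
    patch: np.ndarray, policy: AugmentationPolicy, rng: np.random.Generator
) -> np.ndarray:
    """Apply one randomly drawn composition of the allowed geometric ops."""
    patch = np.asarray(patch)
    rotations = (0,) + tuple(policy.rotations)
    angle = int(rng.choice(rotations))
    if angle in (90, 270) and patch.shape[0] != patch.shape[1]:
        raise ValueError("90/270-degree rotation requires a square patch")
    out = np.rot90(patch, k=angle // 90, axes=(0, 1))
    if policy.horizontal_flip and rng.random() < 0.5:
        out = out[:, ::-1]
    if policy.vertical_flip and rng.random() < 0.5:
        out = out[::-1, :]
    return np.ascontiguousarray(out)


def _draw_rng(policy: AugmentationPolicy, epoch_index: int, pair_index: int, copy_index: int):
    seq = np.random.SeedSequence([int(policy.seed), int(epoch_index), int(pair_index), int(copy_index)])
    return np.random.default_rng(seq)


def expand_epoch(
    cohort: PairedCohort, policy: AugmentationPolicy, epoch_index: int
) -> list[PatchSpotPair]:
    """Per-epoch augmentation doubling: each pair contributes
    ``copies_per_epoch`` independently augmented patches, with the expression
    vector untouched. The draw for (pair, copy) is a pure function of
    (policy seed, epoch index, pair index, copy index)."""
    if len(cohort) == 0:
        raise ValueError("cannot expand an empty cohort")
    out: list[PatchSpotPair] = []
    for i, pair in enumerate(cohort):
        for c in range(policy.copies_per_epoch):
            rng = _draw_rng(policy, epoch_index, i, c)
            out.append(PatchSpotPair(augment_patch(pair.patch, policy, rng), pair.expression, pair.spot))
    return out
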