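"""Core data containers shared across the pipeline.

The unit of both training and retrieval is the patch-spot pair: a square
H&E image crop centered on a spatial-transcriptomics capture spot, together
with that spot's (normalized, log-transformed) expression vector restricted
to a selected gene panel.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np

REFERENCE = "reference"
QUERY = "query"
UNASSIGNED = "unassigned"

HEG = "HEG"
HVG = "HVG"


@dataclass(frozen=True)
class SpotRecord:
    """A spatial capture location on one tissue slice.

    ``x`` is the pixel column and ``y`` the pixel row of the spot center,
    0-based, within the slice's whole-slide image.
    """

    spot_id: str
    x: int
    y: int
    slice_id: str


@dataclass
class ExpressionMatrix:
    """A spots x genes real matrix with row and column names.

    Values are assumed non-negative after library-size normalization and
    log1p transformation (raw counts also fit the container).
    """

    values: np.ndarray
    spot_ids: list[str]
    gene_names: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.spot_ids = list(self.spot_ids)
        self.gene_names = list(self.gene_names)
        if self.values.ndim != 2:
            raise ValueError("expression values must be 2-D (spots x genes)")
        if self.values.shape != (len(self.spot_ids), len(self.gene_names)):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.spot_ids)} spots x {len(self.gene_names)} genes"
            )
        if len(set(self.gene_names)) != len(self.gene_names):
            raise ValueError("duplicate gene names")

    @property
    def n_spots(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def row_index(self) -> dict[str, int]:
        return {s: i for i, s in enumerate(self.spot_ids)}

    def subset_genes(self, gene_names: Sequence[str]) -> "ExpressionMatrix":
        """Restrict columns to ``gene_names``, in the given order."""
        col = {g: j for j, g in enumerate(self.gene_names)}
        missing = [g for g in gene_names if g not in col]
        if missing:
            raise KeyError(f"genes not present: {missing[:5]}{'...' if len(missing) > 5 else ''}")
        idx = [col[g] for g in gene_names]
        return ExpressionMatrix(self.values[:, idx], self.spot_ids, list(gene_names))


@dataclass
class GeneSelection:
    """An ordered gene panel chosen by the HEG or HVG criterion."""

    mode: str
    n_requested: int
    gene_names: list[str]

    def __post_init__(self) -> None:
        if self.mode not in (HEG, HVG):
            raise ValueError(f"mode must be {HEG!r} or {HVG!r}, got {self.mode!r}")
        self.gene_names = list(self.gene_names)

    @property
    def size(self) -> int:
        return len(self.gene_names)


@dataclass
class PatchSpotPair:
    """One aligned (image patch, expression vector, spot) triple."""

    patch: np.ndarray  # patch_size x patch_size x 3, uint8
    expression: np.ndarray  # length d, float
    spot: SpotRecord

    def __post_init__(self) -> None:
        self.patch = np.asarray(self.patch)
        if self.patch.ndim != 3 or self.patch.shape[2] != 3:
            raise ValueError("patch must be H x W x 3")
        self.expression = np.asarray(self.expression, dtype=np.float64).ravel()


@dataclass
class PairedCohort:
    """An ordered, index-addressable collection of patch-spot pairs.

    All pairs share a single gene selection; ``role`` marks whether the
    cohort is searched at inference (reference) or imputed (query).
    """

    pairs: list[PatchSpotPair]
    gene_selection: GeneSelection
    role: str = UNASSIGNED

    def __post_init__(self) -> None:
        if self.role not in (REFERENCE, QUERY, UNASSIGNED):
            raise ValueError(f"invalid role {self.role!r}")
        d = self.gene_selection.size
        for p in self.pairs:
            if p.expression.shape[0] != d:
                raise ValueError(
                    f"pair {p.spot.spot_id}: expression length {p.expression.shape[0]} "
                    f"!= selection size {d}"
                )

    def __len__(self) -> int:
        return len(self.pairs)

    def __getitem__(self, i: int) -> PatchSpotPair:
        return self.pairs[i]

    def __iter__(self) -> Iterator[PatchSpotPair]:
        return iter(self.pairs)

    def patches_array(self) -> np.ndarray:
        """Stack patches to an (n, s, s, 3) uint8 array."""
        return np.stack([p.patch for p in self.pairs]) if self.pairs else np.zeros((0, 0, 0, 3), np.uint8)

    def expression_array(self) -> np.ndarray:
        """Stack expression vectors to an (n, d) float array."""
        if not self.pairs:
            return np.zeros((0, self.gene_selection.size))
        return np.stack([p.expression for p in self.pairs])

    def spot_ids(self) -> list[str]:
        return [p.spot.spot_id for p in self.pairs]

    def slice_ids(self) -> list[str]:
        return sorted({p.spot.slice_id for p in self.pairs})

    def subset(self, indices: Sequence[int], role: str | None = None) -> "PairedCohort":
        return PairedCohort(
            [self.pairs[i] for i in indices],
            self.gene_selection,
            role if role is not None else self.role,
        )


@dataclass
class EmbeddingMatrix:
    """A batch x d_o embedding block produced by one encoder."""

    values: np.ndarray
    modality: str  # "image" | "spot"
    normalized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.modality not in ("image", "spot"):
            raise ValueError(f"invalid modality {self.modality!r}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("embedding contains non-finite entries")
        if self.normalized:
            norms = np.linalg.norm(self.values, axis=1)
            if not np.allclose(norms, 1.0, atol=1e-6):
                raise ValueError("normalized flag set but rows are not unit norm")
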