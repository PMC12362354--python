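"""Cohort construction: patches, normalization, gene panels, slice splits.

Coordinate convention: a spot's (x, y) are 0-based pixel coordinates with
x = column and y = row. The patch for a spot is the axis-aligned square of
side ``patch_size`` covering the half-open window
[c - patch_size/2, c + patch_size/2) on each axis, so a 256-pixel patch at
(x, y) spans columns [x-128, x+128) and rows [y-128, y+128). Spots closer
than patch_size/2 to an image edge get zero-padded patches (logged).
"""

from __future__ import annotations

import logging
import shlex
import subprocess
import tempfile
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .types import (
    HEG,
    HVG,
    QUERY,
    REFERENCE,
    ExpressionMatrix,
    GeneSelection,
    PairedCohort,
    PatchSpotPair,
    SpotRecord,
)

logger = logging.getLogger(__name__)


def extract_patch(image: np.ndarray, spot: SpotRecord, patch_size: int = 256) -> np.ndarray:
    """Crop the square patch centered on the spot, zero-padding at borders."""
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"image must be H x W x 3, got shape {image.shape}")
    if patch_size <= 0 or patch_size % 2 != 0:
        raise ValueError("patch_size must be a positive even integer")
    h, w = image.shape[:2]
    half = patch_size // 2
    r0, r1 = spot.y - half, spot.y + half
    c0, c1 = spot.x - half, spot.x + half
    patch = np.zeros((patch_size, patch_size, 3), dtype=image.dtype)
    sr0, sr1 = max(r0, 0), min(r1, h)
    sc0, sc1 = max(c0, 0), min(c1, w)
    if sr0 < sr1 and sc0 < sc1:
        patch[sr0 - r0 : sr1 - r0, sc0 - c0 : sc1 - c0] = image[sr0:sr1, sc0:sc1]
    if r0 < 0 or c0 < 0 or r1 > h or c1 > w:
        logger.info("spot %s at (%d, %d): patch window clipped, zero-padded", spot.spot_id, spot.x, spot.y)
    return patch


def normalize_expression(
    counts: np.ndarray,
    spot_ids: Sequence[str],
    gene_names: Sequence[str],
    target_sum: float = 1e4,
) -> ExpressionMatrix:
    """Library-size normalize each spot to ``target_sum`` and log1p-transform.

    Uses the Scanpy preprocessing primitives. All-zero spot rows are left
    zero with a warning rather than erroring.
    """
    import anndata as ad
    import scanpy as sc

    counts = np.asarray(counts, dtype=np.float64)
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    row_sums = counts.sum(axis=1)
    n_zero = int((row_sums == 0).sum())
    if n_zero:
        logger.warning("%d spot(s) have all-zero counts; left as zeros", n_zero)
    adata = ad.AnnData(counts.copy())
    sc.pp.normalize_total(adata, target_sum=target_sum)
    sc.pp.log1p(adata)
    return ExpressionMatrix(np.asarray(adata.X, dtype=np.float64), list(spot_ids), list(gene_names))


def _aligned_values(matrices: Sequence[ExpressionMatrix], gene_order: list[str]) -> list[np.ndarray]:
    out = []
    for m in matrices:
        col = {g: j for j, g in enumerate(m.gene_names)}
        idx = [col[g] for g in gene_order]
        out.append(m.values[:, idx])
    return out


def select_genes(matrices: Sequence[ExpressionMatrix], mode: str, n: int = 3500) -> GeneSelection:
    """Choose the gene panel used throughout training and imputation.

    HEG ranks genes by their mean normalized expression pooled over every
    spot of every slice. HVG takes each slice's top-n genes by (population)
    variance, pools those candidate lists, and re-ranks the union by the
    variance computed over all spots pooled. Ties break lexicographically by
    gene name so the panel is deterministic.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if not matrices:
        raise ValueError("at least one expression matrix is required")
    namespace = set(matrices[0].gene_names)
    for m in matrices[1:]:
        if set(m.gene_names) != namespace:
            raise ValueError("matrices do not share a common gene namespace")
    gene_order = sorted(namespace)
    aligned = _aligned_values(matrices, gene_order)
    pooled = np.vstack(aligned)

    if n > len(gene_order):
        logger.warning("requested %d genes but only %d available; using all", n, len(gene_order))
        n = len(gene_order)

    if mode == HEG:
        score = pooled.mean(axis=0)
        ranked = sorted(range(len(gene_order)), key=lambda j: (-score[j], gene_order[j]))
        chosen = ranked[:n]
    elif mode == HVG:
        candidates: set[int] = set()
        for vals in aligned:
            var = vals.var(axis=0)
            top = sorted(range(len(gene_order)), key=lambda j: (-var[j], gene_order[j]))[:n]
            candidates.update(top)
        pooled_var = pooled.var(axis=0)
        ranked = sorted(candidates, key=lambda j: (-pooled_var[j], gene_order[j]))
        chosen = ranked[:n]
    else:
        raise ValueError(f"mode must be {HEG!r} or {HVG!r}, got {mode!r}")
    return GeneSelection(mode=mode, n_requested=n, gene_names=[gene_order[j] for j in chosen])


def build_cohort(
    images: Mapping[str, np.ndarray],
    spots: Sequence[SpotRecord],
    expression: ExpressionMatrix,
    selection: GeneSelection,
    patch_size: int = 256,
    role: str = "unassigned",
) -> PairedCohort:
    """Pair every spot with its patch and panel-restricted expression row.

    ``images`` maps slice_id to that slice's RGB image. Pairing is by
    spot_id, so expression rows may be in any order.
    """
    restricted = expression.subset_genes(selection.gene_names)
    row_of = restricted.row_index()
    missing = [s.spot_id for s in spots if s.spot_id not in row_of]
    if missing:
        raise KeyError(f"spots without expression rows: {missing[:10]}{'...' if len(missing) > 10 else ''}")
    pairs = []
    for spot in spots:
        if spot.slice_id not in images:
            raise KeyError(f"no image for slice {spot.slice_id!r}")
        patch = extract_patch(images[spot.slice_id], spot, patch_size)
        pairs.append(PatchSpotPair(patch, restricted.values[row_of[spot.spot_id]], spot))
    return PairedCohort(pairs, selection, role=role)


def split_by_slice(cohort: PairedCohort, query_slice: str) -> tuple[PairedCohort, PairedCohort]:
    """Hold one slice out as the query set; the rest become the reference."""
    slices = cohort.slice_ids()
    if query_slice not in slices:
        raise ValueError(f"unknown slice {query_slice!r}; available: {slices}")
    if len(slices) < 2:
        raise ValueError("cannot split a single-slice cohort into reference and query")
    ref_idx = [i for i, p in enumerate(cohort) if p.spot.slice_id != query_slice]
    qry_idx = [i for i, p in enumerate(cohort) if p.spot.slice_id == query_slice]
    return cohort.subset(ref_idx, role=REFERENCE), cohort.subset(qry_idx, role=QUERY)


def apply_batch_correction_hook(
    matrix: ExpressionMatrix,
    slice_labels: Sequence[str],
    command: str | None = None,
) -> ExpressionMatrix:
    """Run an external batch-correction tool over the expression matrix.

    Between-slice technical variation is removed by a published external
    tool (e.g. a Harmony wrapper), never re-implemented here. ``command`` is
    a shell-style template with ``{input}``, ``{labels}`` and ``{output}``
    placeholders; the matrix is handed over as a CSV (spot_id index, gene
    columns), labels as a two-column TSV, and the corrected matrix is read
    back from ``{output}``. ``command=None`` disables the hook (identity).
    """
    if len(slice_labels) != matrix.n_spots:
        raise ValueError("slice_labels length must equal the number of spots")
    if not command:
        return matrix
    import pandas as pd

    with tempfile.TemporaryDirectory(prefix="heclip_bc_") as tmp:
        tmp_path = Path(tmp)
        in_csv = tmp_path / "expression.csv"
        labels_tsv = tmp_path / "labels.tsv"
        out_csv = tmp_path / "corrected.csv"
        pd.DataFrame(matrix.values, index=matrix.spot_ids, columns=matrix.gene_names).to_csv(in_csv)
        pd.DataFrame({"spot_id": matrix.spot_ids, "slice_id": list(slice_labels)}).to_csv(
            labels_tsv, sep="\t", index=False
        )
        argv = [
            a.format(input=str(in_csv), labels=str(labels_tsv), output=str(out_csv))
            for a in shlex.split(command)
        ]
        proc = subprocess.run(argv, capture_output=True, text=True)
        if proc.returncode != 0 or not out_csv.exists():
            raise RuntimeError(
                f"batch-correction hook failed (exit {proc.returncode}):\n"
                f"stdout:\n{proc.stdout}\nstderr:\n{proc.stderr}"
            )
        df = pd.read_csv(out_csv, index_col=0)
    values = df.loc[matrix.spot_ids, matrix.gene_names].to_numpy(dtype=np.float64)
    if values.shape != matrix.values.shape:
        raise RuntimeError("hook returned a matrix of unexpected shape")
    return ExpressionMatrix(values, matrix.spot_ids, matrix.gene_names)
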