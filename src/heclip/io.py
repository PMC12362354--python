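"""On-disk formats: cohort cache directories and expression/spot tables."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from PIL import Image

from .types import ExpressionMatrix, GeneSelection, PairedCohort, PatchSpotPair, SpotRecord

COHORT_FORMAT_VERSION = 1


def save_cohort(cohort: PairedCohort, directory: str | Path) -> None:
    """Write the standard cohort cache: patch PNGs named by spot id, an
    expression CSV, a spot TSV and a JSON manifest."""
    directory = Path(directory)
    (directory / "patches").mkdir(parents=True, exist_ok=True)
    for pair in cohort:
        Image.fromarray(pair.patch).save(directory / "patches" / f"{pair.spot.spot_id}.png")
    pd.DataFrame(
        cohort.expression_array(), index=cohort.spot_ids(), columns=cohort.gene_selection.gene_names
    ).to_csv(directory / "expression.csv")
    pd.DataFrame(
        [
            {"spot_id": p.spot.spot_id, "x": p.spot.x, "y": p.spot.y, "slice_id": p.spot.slice_id}
            for p in cohort
        ]
    ).to_csv(directory / "spots.tsv", sep="\t", index=False)
    patch_size = cohort[0].patch.shape[0] if len(cohort) else 0
    manifest = {
        "format_version": COHORT_FORMAT_VERSION,
        "role": cohort.role,
        "patch_size": patch_size,
        "n_pairs": len(cohort),
        "gene_selection": {
            "mode": cohort.gene_selection.mode,
            "n_requested": cohort.gene_selection.n_requested,
            "gene_names": cohort.gene_selection.gene_names,
        },
        "spot_order": cohort.spot_ids(),
    }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))


def load_cohort(directory: str | Path) -> PairedCohort:
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    if manifest["format_version"] != COHORT_FORMAT_VERSION:
        raise ValueError(f"unsupported cohort format {manifest['format_version']}")
    sel = manifest["gene_selection"]
    selection = GeneSelection(sel["mode"], sel["n_requested"], sel["gene_names"])
    expr = pd.read_csv(directory / "expression.csv", index_col=0)
    expr.index = expr.index.astype(str)
    spots = pd.read_csv(directory / "spots.tsv", sep="\t", dtype={"spot_id": str, "slice_id": str})
    spot_rows = {r.spot_id: r for r in spots.itertuples(index=False)}
    pairs = []
    for spot_id in manifest["spot_order"]:
        rec = spot_rows[spot_id]
        patch = np.asarray(Image.open(directory / "patches" / f"{spot_id}.png").convert("RGB"))
        pairs.append(
            PatchSpotPair(
                patch,
                expr.loc[spot_id, selection.gene_names].to_numpy(dtype=np.float64),
                SpotRecord(spot_id, int(rec.x), int(rec.y), str(rec.slice_id)),
            )
        )
    return PairedCohort(pairs, selection, role=manifest["role"])


def load_expression_csv(path: str | Path, sep: str = ",") -> ExpressionMatrix:
    """Dense spots x genes table: header row of gene names, first column
    spot ids."""
    df = pd.read_csv(path, index_col=0, sep=sep)
    return ExpressionMatrix(df.to_numpy(dtype=np.float64), [str(s) for s in df.index], list(df.columns))


def load_expression_mtx(
    mtx_path: str | Path, genes_path: str | Path, barcodes_path: str | Path
) -> ExpressionMatrix:
    """MatrixMarket triplet (spots x genes) with sidecar gene/barcode files."""
    from scipy.io import mmread

    values = np.asarray(mmread(mtx_path).todense(), dtype=np.float64)
    genes = Path(genes_path).read_text().split()
    barcodes = Path(barcodes_path).read_text().split()
    return ExpressionMatrix(values, barcodes, genes)


def load_spot_table(path: str | Path) -> list[SpotRecord]:
    """TSV with columns spot_id, x, y, slice_id."""
    df = pd.read_csv(path, sep="\t", dtype={"spot_id": str, "slice_id": str})
    required = {"spot_id", "x", "y", "slice_id"}
    if not required.issubset(df.columns):
        raise ValueError(f"spot table must have columns {sorted(required)}")
    return [
        SpotRecord(r.spot_id, int(r.x), int(r.y), r.slice_id) for r in df.itertuples(index=False)
    ]


def load_slice_images(directory: str | Path, slice_ids: Sequence[str]) -> dict[str, np.ndarray]:
    """Load one PNG/TIFF whole-slice image per slice id from a directory."""
    directory = Path(directory)
    images = {}
    for sid in slice_ids:
        for ext in (".png", ".tif", ".tiff"):
            p = directory / f"{sid}{ext}"
            if p.exists():
                images[sid] = np.asarray(Image.open(p).convert("RGB"))
                break
        else:
            raise FileNotFoundError(f"no image found for slice {sid!r} under {directory}")
    return images
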