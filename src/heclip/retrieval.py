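"""Top-K retrieval imputation: embed, rank by dot product, average expression.

At inference the frozen image encoder embeds the reference patches once and
each query patch is scored against every reference embedding by dot product
(optionally cosine). The K most similar reference spots are selected and
their expression profiles averaged to impute the query's expression.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .encoders import encode_images
from .training import Checkpoint
from .types import PairedCohort


@dataclass
class ReferenceIndex:
    """Frozen-encoder embeddings of the reference cohort plus its labels."""

    embeddings: np.ndarray  # n_ref x d_o
    expression: np.ndarray  # n_ref x d
    spot_ids: list[str]

    def __post_init__(self) -> None:
        self.embeddings = np.asarray(self.embeddings, dtype=np.float64)
        self.expression = np.asarray(self.expression, dtype=np.float64)
        if not (len(self.spot_ids) == self.embeddings.shape[0] == self.expression.shape[0]):
            raise ValueError("row counts of embeddings, expression and spot_ids must agree")
        if not np.all(np.isfinite(self.embeddings)):
            raise ValueError("reference embeddings contain non-finite entries")

    @property
    def n_ref(self) -> int:
        return self.embeddings.shape[0]


@dataclass
class ImputationResult:
    predictions: np.ndarray  # n_query x d
    topk_indices: np.ndarray  # n_query x K
    topk_scores: np.ndarray  # n_query x K, non-increasing along each row
    K: int


def _embed_patches(checkpoint: Checkpoint, patches: np.ndarray, batch_size: int = 256) -> np.ndarray:
    model = checkpoint.build_model()
    chunks = [
        encode_images(model, patches[i : i + batch_size], training=False).values
        for i in range(0, len(patches), batch_size)
    ]
    return np.vstack(chunks).astype(np.float64)


def build_reference(
    checkpoint: Checkpoint,
    cohort: PairedCohort,
    include_query: PairedCohort | None = None,
) -> ReferenceIndex:
    """Embed every reference patch in evaluation mode (raw patches — no
    augmentation, no dropout) and store the paired expression.

    The reference set is the training cohort. ``include_query`` appends a
    second (query) cohort's pairs to the searchable index as well; this
    reproduces an alternative reference-set composition for comparison, but
    leaks query expression into the index and is off by default.
    """
    if cohort.gene_selection.gene_names != checkpoint.gene_selection.gene_names:
        raise ValueError("cohort gene selection does not match the checkpoint's")
    if len(cohort) == 0:
        raise ValueError("reference cohort is empty")
    cohorts = [cohort] if include_query is None else [cohort, include_query]
    embeddings = np.vstack([_embed_patches(checkpoint, c.patches_array()) for c in cohorts])
    expression = np.vstack([c.expression_array() for c in cohorts])
    spot_ids = [s for c in cohorts for s in c.spot_ids()]
    return ReferenceIndex(embeddings, expression, spot_ids)


def _topk_rows(scores: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    # stable sort on negated scores: ties resolve to the lower reference index
    order = np.argsort(-scores, axis=1, kind="stable")[:, :k]
    picked = np.take_along_axis(scores, order, axis=1)
    return order, picked


def impute(
    queries: PairedCohort | np.ndarray,
    index: ReferenceIndex,
    checkpoint: Checkpoint,
    K: int = 50,
    l2_normalize_scores: bool = False,
    query_embeddings: np.ndarray | None = None,
) -> ImputationResult:
    """Predict each query's expression as the mean of its top-K neighbours.

    ``queries`` is a cohort or an (n, s, s, 3) patch stack; precomputed
    ``query_embeddings`` bypass the encoder. ``l2_normalize_scores`` switches
    the similarity from raw dot product (the default) to cosine.
    """
    if not 1 <= K <= index.n_ref:
        raise ValueError(f"K must lie in [1, {index.n_ref}], got {K}")
    if query_embeddings is None:
        patches = queries.patches_array() if isinstance(queries, PairedCohort) else np.asarray(queries)
        q = _embed_patches(checkpoint, patches)
    else:
        q = np.asarray(query_embeddings, dtype=np.float64)
    r = index.embeddings
    if l2_normalize_scores:
        q = q / np.maximum(np.linalg.norm(q, axis=1, keepdims=True), 1e-12)
        r = r / np.maximum(np.linalg.norm(r, axis=1, keepdims=True), 1e-12)
    scores = q @ r.T
    topk_indices, topk_scores = _topk_rows(scores, K)
    predictions = index.expression[topk_indices].mean(axis=1)
    return ImputationResult(predictions, topk_indices, topk_scores, K)


def self_retrieval_check(
    index: ReferenceIndex, checkpoint: Checkpoint | None = None, l2_normalize_scores: bool = True
) -> dict:
    """Impute each reference spot against its own index at K = 1 and report
    the fraction whose own expression is recovered.

    With cosine scoring every embedding is its own nearest neighbour (up to
    exact duplicates), so on a pairwise-distinct index the fraction is 1.0;
    with raw dot products a larger-norm neighbour can win, which is why
    cosine is the default here.
    """
    if index.n_ref == 0:
        raise ValueError("empty reference index")
    result = impute(
        queries=None,
        index=index,
        checkpoint=checkpoint,
        K=1,
        l2_normalize_scores=l2_normalize_scores,
        query_embeddings=index.embeddings,
    )
    recovered = np.all(
        np.isclose(result.predictions, index.expression, atol=1e-9), axis=1
    )
    return {
        "n": index.n_ref,
        "recovered_fraction": float(recovered.mean()),
        "self_matched_fraction": float((result.topk_indices[:, 0] == np.arange(index.n_ref)).mean()),
    }
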