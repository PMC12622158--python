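"""Convenience wiring of the pipeline stages.

These helpers compose the module-level operations (curate -> embed ->
cluster -> vote -> train -> evaluate) without adding behavior of their own;
each stage remains individually callable.
"""

from __future__ import annotations

import numpy as np

from .clustering import CysCluster, build_clusters, vote_and_propagate
from .consensus import ConsensusCriteria
from .embeddings import EmbeddingProvider, site_embeddings
from .models import LabeledSite
from .records import NEG, POS, CuratedDB

Site = tuple[str, int]


def embed_db_sites(db: CuratedDB, provider: EmbeddingProvider) -> dict[Site, np.ndarray]:
    """Embeddings for every site carrying at least one record."""
    return site_embeddings(provider, db.proteins, db.sites())


def cluster_and_label(
    db: CuratedDB,
    vectors: dict[Site, np.ndarray],
    criteria: ConsensusCriteria,
    threshold: float = 0.90,
) -> tuple[list[CysCluster], dict[Site, str]]:
    """Build similarity clusters and assign consensus labels with propagation."""
    clusters = build_clusters(vectors, threshold)
    labeled = vote_and_propagate(clusters, db, criteria)
    return clusters, labeled


def training_sites(
    clusters: list[CysCluster],
    labeled: dict[Site, str],
    vectors: dict[Site, np.ndarray],
    representatives_only: bool = True,
) -> list[LabeledSite]:
    """Convert labeled clusters into model-ready training examples.

    By default only cluster representatives enter training; set
    ``representatives_only=False`` to use all members (ablation mode).
    """
    out: list[LabeledSite] = []
    for cid, cluster in enumerate(clusters):
        if cluster.label not in (POS, NEG):
            continue
        members = [cluster.representative] if representatives_only else cluster.members
        for site in members:
            if site in labeled:
                out.append(LabeledSite.make(
                    uid=site[0], position=site[1],
                    label=1 if labeled[site] == POS else 0,
                    cluster_id=cid, vector=vectors[site]))
    return out


def site_label_error(labeled: dict[Site, str],
                     truth: dict[Site, int]) -> float:
    """Fraction of labeled sites whose label disagrees with ground truth."""
    common = [s for s in labeled if s in truth]
    if not common:
        return float("nan")
    wrong = sum(1 for s in common
                if (labeled[s] == POS) != bool(truth[s]))
    return wrong / len(common)


__all__ = ["embed_db_sites", "cluster_and_label", "training_sites",
           "site_label_error"]
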