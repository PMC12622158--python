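"""Embedding-similarity clustering of cysteine sites and leakage-safe splits.

Greedy leader clustering with one refinement pass: sites are processed in a
deterministic order (sorted by uid, then position); each joins the first
existing cluster whose representative's cosine similarity meets the
threshold, otherwise it founds a new cluster.  Representatives are then
re-selected as the member with the highest mean similarity to the rest of
the cluster, membership is re-checked once against the refreshed
representatives, and representatives are re-selected a final time.  The
result always partitions the site set.

Cluster labels come from the nS-mR consensus rule applied to the pooled
observed records of all members; unquantified members contribute one default
negative vote each, from a per-site pseudo-source, to the negative tally
only.  Every member — including unquantified ones — inherits the cluster
label, which is how label coverage is extended beyond probe-detected sites.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .consensus import EXCLUDED, ConsensusCriteria, consensus_label
from .records import NEG, CuratedDB, SiteRecord

Site = tuple[str, int]

PARTITIONS = ("train", "validation", "test")


@dataclass
class CysCluster:
    members: list[Site]
    representative: Site
    label: str | None = None
    similarity_threshold: float | None = None

    def __post_init__(self):
        if self.representative not in self.members:
            raise ValueError("representative must be a member")

    @property
    def uids(self) -> set[str]:
        return {uid for uid, _ in self.members}


def _normalize_rows(keys: list[Site], vectors: dict[Site, np.ndarray]) -> np.ndarray:
    mat = np.stack([np.asarray(vectors[k], dtype=float) for k in keys])
    return mat / np.linalg.norm(mat, axis=1, keepdims=True)


def select_representative(members: list[Site], sims: np.ndarray) -> Site:
    """Member with highest mean similarity to the other members.

    ``sims`` is the members' pairwise similarity matrix in member order.
    Singletons return themselves; exact ties break to the lexicographically
    smallest (uid, position).
    """
    if len(members) == 1:
        return members[0]
    n = len(members)
    means = (sims.sum(axis=1) - np.diag(sims)) / (n - 1)
    top = means.max()
    tied = [members[i] for i in range(n) if means[i] >= top - 1e-12]
    return min(tied)


def build_clusters(site_embeddings: dict[Site, np.ndarray],
                   threshold: float) -> list[CysCluster]:
    """Greedy leader clustering of sites at a cosine-similarity threshold."""
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    if not site_embeddings:
        raise ValueError("no sites to cluster")
    keys = sorted(site_embeddings)
    unit = _normalize_rows(keys, site_embeddings)
    index = {k: i for i, k in enumerate(keys)}

    def assign(order: list[Site], reps: list[Site] | None) -> list[list[Site]]:
        """One pass; if reps given they seed the clusters (and stay put)."""
        clusters: list[list[Site]] = [[r] for r in reps] if reps else []
        rep_vecs = [unit[index[r]] for r in reps] if reps else []
        seeded = set(reps) if reps else set()
        for k in order:
            if k in seeded:
                continue
            v = unit[index[k]]
            placed = False
            if rep_vecs:
                sims = np.asarray(rep_vecs) @ v
                # join the first qualifying cluster in creation order
                qualifying = np.flatnonzero(sims >= threshold)
                if qualifying.size:
                    clusters[int(qualifying[0])].append(k)
                    placed = True
            if not placed:
                clusters.append([k])
                rep_vecs.append(v)
        return clusters

    clusters = assign(keys, None)
    reps = [_rep_of(members, unit, index) for members in clusters]
    clusters = [m for m in assign(keys, reps) if m]
    out = []
    for members in clusters:
        members = sorted(members)
        out.append(CysCluster(members=members,
                              representative=_rep_of(members, unit, index),
                              similarity_threshold=threshold))
    return out


def _rep_of(members: list[Site], unit: np.ndarray, index: dict[Site, int]) -> Site:
    sub = unit[[index[m] for m in members]]
    return select_representative(members, sub @ sub.T)


def vote_and_propagate(
    clusters: list[CysCluster],
    db: CuratedDB,
    criteria: ConsensusCriteria,
) -> dict[Site, str]:
    """Label clusters by pooled consensus and propagate to all members.

    Each member's unquantified record becomes one synthetic negative record
    from a pseudo-source unique to that site (so an all-unquantified cluster
    of >= n members can satisfy the neg clause).  Excluded clusters yield no
    labeled sites.  Sets ``cluster.label`` in place and returns the labeled
    site map.
    """
    by_site = db.records_by_site()
    labeled: dict[Site, str] = {}
    for cluster in clusters:
        pooled: list[SiteRecord] = []
        for site in cluster.members:
            for r in by_site.get(site, []):
                if r.observed:
                    pooled.append(r)
                else:
                    pooled.append(SiteRecord(
                        uid=site[0], position=site[1], label=NEG,
                        source_id=f"unq::{site[0]}::{site[1]}",
                        record_id=f"UV:{site[0]}:{site[1]}"))
        cluster.label = consensus_label(pooled, criteria)
        if cluster.label != EXCLUDED:
            for site in cluster.members:
                labeled[site] = cluster.label
    return labeled


@dataclass
class PartitionAssignment:
    assignment: dict[int, str]  # cluster index -> partition name
    fractions: tuple[float, float, float]
    seed: int
    components: list[list[int]] = field(default_factory=list)

    def partition_of(self, cluster_index: int) -> str:
        return self.assignment[cluster_index]


def _uid_components(clusters: list[CysCluster]) -> list[list[int]]:
    """Union-find over shared uids; components listed in deterministic order."""
    parent = list(range(len(clusters)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    by_uid: dict[str, int] = {}
    for i, c in enumerate(clusters):
        for uid in sorted(c.uids):
            if uid in by_uid:
                ri, rj = find(i), find(by_uid[uid])
                if ri != rj:
                    parent[max(ri, rj)] = min(ri, rj)
            else:
                by_uid[uid] = i
    comps: dict[int, list[int]] = {}
    for i in range(len(clusters)):
        comps.setdefault(find(i), []).append(i)
    return [comps[r] for r in sorted(comps)]


def partition_clusters(clusters: list[CysCluster],
                       fractions: tuple[float, float, float],
                       seed: int) -> PartitionAssignment:
    """Assign whole uid-connected cluster components to train/validation/test.

    Components are shuffled deterministically by seed, then placed greedily
    into the partition with the largest remaining site deficit relative to
    its target fraction.  No cluster is ever split and clusters sharing a uid
    always land together.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    comps = _uid_components(clusters)
    sizes = [sum(len(clusters[i].members) for i in comp) for comp in comps]
    total = sum(sizes)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(comps))
    # largest components first within the shuffled order for better balance
    order = sorted(order, key=lambda i: -sizes[i])

    targets = [f * total for f in fractions]
    filled = [0.0, 0.0, 0.0]
    assignment: dict[int, str] = {}
    largest_quota = max(targets)
    for ci in order:
        if sizes[ci] > largest_quota:
            warnings.warn(
                f"uid component of {sizes[ci]} sites exceeds the largest "
                "partition quota; assigned to train", stacklevel=2)
            choice = 0
        else:
            deficits = [(targets[p] - filled[p]) if fractions[p] > 0 else -np.inf
                        for p in range(3)]
            choice = int(np.argmax(deficits))
        for i in comps[ci]:
            assignment[i] = PARTITIONS[choice]
        filled[choice] += sizes[ci]
    return PartitionAssignment(assignment=assignment, fractions=tuple(fractions),
                               seed=seed, components=comps)


def exclude_external_overlap(clusters: list[CysCluster],
                             external_sites: list[Site]) -> list[CysCluster]:
    """Drop clusters touching an external evaluation set.

    A cluster is removed if it contains an external site or shares a uid
    with the external set — both are leakage paths into training material.
    """
    ext = set(external_sites)
    ext_uids = {uid for uid, _ in ext}
    return [c for c in clusters
            if not (set(c.members) & ext) and not (c.uids & ext_uids)]


def check_leakage(clusters: list[CysCluster],
                  assignment: PartitionAssignment) -> list[str]:
    """Return a list of leakage violations (empty when the split is clean)."""
    violations = []
    uid_part: dict[str, str] = {}
    for i, c in enumerate(clusters):
        part = assignment.assignment[i]
        for uid in c.uids:
            if uid in uid_part and uid_part[uid] != part:
                violations.append(f"uid {uid} split across {uid_part[uid]}/{part}")
            uid_part[uid] = part
    return violations


__all__ = [
    "PARTITIONS", "CysCluster", "PartitionAssignment",
    "build_clusters", "select_representative", "vote_and_propagate",
    "partition_clusters", "exclude_external_overlap", "check_leakage",
]
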