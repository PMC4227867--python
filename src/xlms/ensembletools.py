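"""Model-ensemble machinery: superposition, loop-masked RMSD, radius
clustering, and cross-homologue consensus.

Clustering is greedy center-based: the model with the most neighbors
within the radius seeds a cluster, its neighborhood is removed, and the
procedure repeats.  Consensus flags a model as representing a shared
topology only if *every* homologue ensemble contains at least one model
within the RMSD threshold (an existential test per homologue, universal
over homologues).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from xlms.xlinkmap import ScoreRow


class SuperpositionError(ValueError):
    """Mismatched lengths or too few points to superpose."""


@dataclass
class ModelRecord:
    """A Calpha-coordinate model with an RMSD inclusion mask."""

    model_id: str
    ca_coords: np.ndarray  # (n, 3)
    residue_mask: np.ndarray | None = None  # True = included in RMSD
    source_tag: str = ""

    def __post_init__(self):
        self.ca_coords = np.asarray(self.ca_coords, dtype=float)
        if self.residue_mask is None:
            self.residue_mask = np.ones(len(self.ca_coords), dtype=bool)
        self.residue_mask = np.asarray(self.residue_mask, dtype=bool)
        if len(self.residue_mask) != len(self.ca_coords):
            raise ValueError("mask and coordinates differ in length")

    @property
    def masked_coords(self) -> np.ndarray:
        return self.ca_coords[self.residue_mask]


@dataclass
class ClusterResult:
    """Disjoint clusters covering all models; members lie within
    ``radius`` of their center."""

    clusters: list[tuple[str, list[str]]]  # (center_id, member_ids incl. center)
    radius: float


def superpose(a: ModelRecord, b: ModelRecord) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of ``b`` onto ``a`` (Kabsch).

    Uses positions unmasked in *both* records, corresponding by index.
    Returns (rotation, translation, rmsd) with ``R @ b + t ~ a``.
    """
    if len(a.ca_coords) != len(b.ca_coords):
        raise SuperpositionError("models differ in residue count")
    mask = a.residue_mask & b.residue_mask
    P = a.ca_coords[mask]
    Q = b.ca_coords[mask]
    if len(P) < 3:
        raise SuperpositionError("fewer than 3 unmasked positions")
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    P0, Q0 = P - pc, Q - qc
    H = Q0.T @ P0
    U, _S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = pc - R @ qc
    diff = P0 - Q0 @ R.T
    rmsd = float(np.sqrt((diff**2).sum() / len(P)))
    return R, t, rmsd


def rmsd(a: ModelRecord, b: ModelRecord) -> float:
    """Masked RMSD after optimal superposition."""
    return superpose(a, b)[2]


def loop_mask(secondary_structure: str, max_loop: int = 5) -> np.ndarray:
    """Mask excluding long loops: False exactly for residues inside
    maximal runs of ``L`` longer than ``max_loop``; helix (H) and strand
    (E) positions always remain included."""
    labels = list(secondary_structure)
    for lab in labels:
        if lab not in ("H", "E", "L"):
            raise ValueError(f"unknown secondary-structure label {lab!r}")
    mask = np.ones(len(labels), dtype=bool)
    i = 0
    while i < len(labels):
        if labels[i] == "L":
            j = i
            while j < len(labels) and labels[j] == "L":
                j += 1
            if j - i > max_loop:
                mask[i:j] = False
            i = j
        else:
            i += 1
    return mask


def _pairwise_rmsd(models: list[ModelRecord]) -> np.ndarray:
    n = len(models)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = rmsd(models[i], models[j])
    return D


def cluster(models: list[ModelRecord], radius: float) -> ClusterResult:
    """Greedy center-based clustering at a fixed radius.

    Repeatedly promotes the unassigned model with the most unassigned
    neighbors within ``radius`` (ties broken by model id) to cluster
    center and removes its neighborhood.  The result is a partition.
    """
    if radius < 0:
        raise ValueError("radius must be >= 0")
    D = _pairwise_rmsd(models)
    ids = [m.model_id for m in models]
    remaining = set(range(len(models)))
    clusters: list[tuple[str, list[str]]] = []
    while remaining:
        best = None
        for i in sorted(remaining, key=lambda k: ids[k]):
            neighbors = sum(1 for j in remaining if D[i, j] <= radius)
            if best is None or neighbors > best[1]:
                best = (i, neighbors)
        center = best[0]
        members = sorted(
            (j for j in remaining if D[center, j] <= radius), key=lambda k: ids[k]
        )
        clusters.append((ids[center], [ids[j] for j in members]))
        remaining -= set(members)
    return ClusterResult(clusters, radius)


def merge_clusters_by_source(
    result: ClusterResult,
    models: list[ModelRecord],
    scores: list[ScoreRow] | None = None,
) -> ClusterResult:
    """Merge clusters whose best-scoring members share a source tag.

    With no scores the cluster centers' tags are used.  Intended as a
    post-pass after coarse clustering, when several clusters trace back
    to the same originating (centroid) model.
    """
    by_id = {m.model_id: m for m in models}
    score_of = {r.model_id: r.total_score for r in scores} if scores else {}

    def tag_of(cluster_members: list[str], center: str) -> str:
        if score_of:
            best = min(cluster_members, key=lambda m: (score_of.get(m, math.inf), m))
        else:
            best = center
        return by_id[best].source_tag

    merged: dict[str, tuple[str, list[str]]] = {}
    for center, members in result.clusters:
        tag = tag_of(members, center)
        if tag and tag in merged:
            old_center, old_members = merged[tag]
            merged[tag] = (old_center, sorted(old_members + members))
        else:
            merged[tag or f"__{center}"] = (center, members)
    return ClusterResult(list(merged.values()), result.radius)


def consensus(
    query_models: list[ModelRecord],
    homologue_sets: dict[str, list[ModelRecord]],
    threshold: float = 5.0,
) -> dict[str, bool]:
    """Flag query models representing a topology shared by all homologues.

    A model passes only if, for every homologue ensemble, at least one
    member lies within the masked-RMSD ``threshold``.
    """
    if not homologue_sets:
        raise ValueError("need at least one homologue set")
    flags = {}
    for q in query_models:
        flags[q.model_id] = all(
            any(rmsd(q, h) <= threshold for h in hset)
            for hset in homologue_sets.values()
        )
    return flags


def top_fraction(scores: list[ScoreRow], fraction: float = 0.10) -> list[str]:
    """Ids of the best ``ceil(fraction * N)`` models by total score
    (ascending; ties broken by id)."""
    if not (0 < fraction <= 1):
        raise ValueError("fraction must be in (0, 1]")
    k = math.ceil(fraction * len(scores))
    ranked = sorted(scores, key=lambda r: (r.total_score, r.model_id))
    return [r.model_id for r in ranked[:k]]


# ---------------------------------------------------------------------------
# score-table I/O


def read_scores(path) -> list[ScoreRow]:
    df = pd.read_csv(path, sep="\t")
    return [
        ScoreRow(str(r.model_id), float(r.total_score), float(r.constraint_score))
        for r in df.itertuples()
    ]


def write_scores(scores: list[ScoreRow], path) -> None:
    pd.DataFrame([s.__dict__ for s in scores]).to_csv(path, sep="\t", index=False)


def cluster_report(result: ClusterResult) -> pd.DataFrame:
    rows = []
    for k, (center, members) in enumerate(result.clusters):
        for m in members:
            rows.append({"cluster": k, "center_id": center, "model_id": m})
    return pd.DataFrame(rows)
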