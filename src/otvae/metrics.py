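"""Integration-quality metrics computed on a caller-supplied embedding.

The suite covers label-transfer accuracy (ARI / NMI / macro-F1 of a kNN
classifier trained on the reference embedding), cluster separation
(silhouette rescaled to [0, 1]), dataset mixing (batch entropy of local
neighborhoods, normalized so perfect mixing scores 1), and — for paired
datasets — FOSCTTM, the fraction of samples closer than the true match
(0 = perfect correspondence, 0.5 = random).

Metrics never compute an embedding themselves; the conventional choice is a
2-D UMAP (n_neighbors=15, min_dist=0.1) of the latent means, or the latent
means directly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.metrics import adjusted_rand_score, f1_score, silhouette_score
from sklearn.metrics import normalized_mutual_info_score
from sklearn.neighbors import KNeighborsClassifier, NearestNeighbors


@dataclass
class MetricReport:
    ari: float | None = None
    nmi: float | None = None
    f1: float | None = None
    silhouette_scaled: float | None = None
    batch_entropy: float | None = None
    foscttm: float | None = None
    embedding: str = ""
    parameters: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "ari": self.ari, "nmi": self.nmi, "f1": self.f1,
            "silhouette_scaled": self.silhouette_scaled,
            "batch_entropy": self.batch_entropy, "foscttm": self.foscttm,
            "embedding": self.embedding, "parameters": self.parameters,
        }


def knn_transfer_scores(
    ref_embedding: np.ndarray,
    ref_labels,
    query_embedding: np.ndarray,
    query_labels,
    k_neighbors: int = 5,
) -> tuple[float, float, float]:
    """Fit a kNN classifier on the reference, predict the query, and score.

    Returns (ARI, NMI, macro-averaged F1) between true and predicted query
    labels. NMI of a single-class labeling is defined as 0. Disjoint label
    sets raise a warning; scores are computed over the label union.
    """
    ref_labels = np.asarray(ref_labels)
    query_labels = np.asarray(query_labels)
    if len(ref_labels) != len(ref_embedding) or len(query_labels) != len(query_embedding):
        raise ValueError("labels and embeddings disagree in length")
    if not set(ref_labels) & set(query_labels):
        warnings.warn("reference and query label sets are disjoint")
    clf = KNeighborsClassifier(n_neighbors=k_neighbors)
    clf.fit(ref_embedding, ref_labels)
    pred = clf.predict(query_embedding)
    labels_union = sorted(set(query_labels) | set(pred))
    ari = adjusted_rand_score(query_labels, pred)
    if len(set(query_labels)) < 2 or len(set(pred)) < 2:
        nmi = 0.0
    else:
        nmi = normalized_mutual_info_score(query_labels, pred)
    f1 = f1_score(query_labels, pred, labels=labels_union, average="macro",
                  zero_division=0)
    return float(ari), float(nmi), float(f1)


def silhouette_scaled(embedding: np.ndarray, labels) -> float:
    """Mean silhouette (b - a) / max(a, b) rescaled to [0, 1] via (s + 1) / 2."""
    labels = np.asarray(labels)
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("silhouette requires at least 2 labels")
    if counts.min() < 2:
        raise ValueError("every cluster needs at least 2 members")
    s = silhouette_score(embedding, labels)
    return float((s + 1.0) / 2.0)


def batch_entropy(
    embedding: np.ndarray,
    batch_ids,
    common_celltype_mask: np.ndarray | None = None,
    n_probes: int = 100,
    k_neighbors: int = 50,
    rng: np.random.Generator | int | None = 0,
) -> float:
    """Normalized entropy of batch proportions in random local neighborhoods.

    Restricted to cells flagged by ``common_celltype_mask`` (cells whose type
    occurs in more than one batch). For each probe cell, batch proportions
    p_i in its k-NN region are corrected by the global proportions P_i,
    p'_i = (p_i / P_i) / sum(p_i / P_i), and the regional entropy
    E = sum p'_i log p'_i is normalized to -E / log(n_batches), so 1 means
    perfectly mixed and 0 a single-batch region. The probe average is
    returned.
    """
    batch_ids = np.asarray(batch_ids)
    if common_celltype_mask is not None:
        mask = np.asarray(common_celltype_mask, dtype=bool)
        embedding = embedding[mask]
        batch_ids = batch_ids[mask]
    batches = np.unique(batch_ids)
    if len(batches) < 2:
        raise ValueError("batch entropy requires >= 2 batches")
    n = len(batch_ids)
    if n < k_neighbors:
        raise ValueError(f"need at least k_neighbors={k_neighbors} cells, got {n}")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    P = np.array([(batch_ids == b).mean() for b in batches])
    nn = NearestNeighbors(n_neighbors=k_neighbors).fit(embedding)
    probes = rng.choice(n, size=min(n_probes, n), replace=False)
    _, idx = nn.kneighbors(embedding[probes])
    scores = np.empty(len(probes))
    for r, neigh in enumerate(idx):
        p = np.array([(batch_ids[neigh] == b).mean() for b in batches])
        w = p / P
        w = w / w.sum()
        nzw = w[w > 0]
        E = float(np.sum(nzw * np.log(nzw)))
        scores[r] = -E / np.log(len(batches))
    return float(scores.mean())


def foscttm(z_x: np.ndarray, z_y: np.ndarray) -> float:
    """Average fraction of samples closer than the true match.

    Row i of ``z_x`` is paired with row i of ``z_y``. For each cell, counts
    how many cells of the other dataset lie strictly closer (Euclidean) than
    its true match, averaged both ways and over cells.
    """
    z_x = np.asarray(z_x, dtype=np.float64)
    z_y = np.asarray(z_y, dtype=np.float64)
    if z_x.shape[0] != z_y.shape[0]:
        raise ValueError("paired embeddings must have equal numbers of cells")
    n = z_x.shape[0]
    D = cdist(z_x, z_y)
    d_true = np.diag(D)
    s = (D < d_true[None, :]).sum(axis=0)  # cells x_j closer to y_i than x_i
    t = (D < d_true[:, None]).sum(axis=1)  # cells y_j closer to x_i than y_i
    return float((s.sum() / n + t.sum() / n) / (2 * n))


def compute_report(
    embedding_ref: np.ndarray,
    embedding_query: np.ndarray,
    ref_labels=None,
    query_labels=None,
    paired: bool = False,
    k_neighbors: int = 5,
    batch_entropy_kwargs: dict | None = None,
    description: str = "latent means",
) -> MetricReport:
    """Convenience wrapper computing every applicable metric at once."""
    rep = MetricReport(embedding=description,
                       parameters={"k_neighbors": k_neighbors})
    if ref_labels is not None and query_labels is not None:
        rep.ari, rep.nmi, rep.f1 = knn_transfer_scores(
            embedding_ref, ref_labels, embedding_query, query_labels, k_neighbors
        )
        joint = np.vstack([embedding_ref, embedding_query])
        joint_labels = np.concatenate([np.asarray(ref_labels), np.asarray(query_labels)])
        try:
            rep.silhouette_scaled = silhouette_scaled(joint, joint_labels)
        except ValueError:
            pass
        batches = np.array(["ref"] * len(embedding_ref) + ["query"] * len(embedding_query))
        shared = set(ref_labels) & set(query_labels)
        mask = np.isin(joint_labels, sorted(shared))
        kwargs = dict(n_probes=100, k_neighbors=50, rng=0)
        kwargs.update(batch_entropy_kwargs or {})
        try:
            rep.batch_entropy = batch_entropy(joint, batches, mask, **kwargs)
        except ValueError:
            pass
    if paired:
        rep.foscttm = foscttm(embedding_ref, embedding_query)
    return rep
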