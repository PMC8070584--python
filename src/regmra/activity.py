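"""Per-sample regulon activity (two-tailed GSEA), association maps, clustering.

Expression is first converted to per-gene z-scores across the cohort. For
every sample, genes are ranked by z (descending, ties broken by gene id)
and each regulon's positive- and negative-mode target sets are scored with
a weighted Kolmogorov–Smirnov enrichment score (hit increments proportional
to |z|, miss decrements 1/(N - hits)). The two-tailed activity is

    dES = ES(positive targets) - ES(negative targets)  in [-2, 2],

positive when positively regulated targets sit at the top of the ranking
and negatively regulated targets at the bottom (regulon activated), and
negative in the mirrored configuration (regulon repressed). No permutation
renormalization is applied; the raw dES is reported and recorded as such
in the output metadata.

Regulon *association maps* label pairs of regulons agonist or antagonist
according to the fraction of mutually regulated genes whose modes agree,
and hierarchical clustering of the activity matrix (1 - Pearson distance,
average linkage) recovers co-activated regulon groups.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform

from .network import RegulatoryNetwork

logger = logging.getLogger("regmra")

__all__ = [
    "ActivityMatrix",
    "ClusterTree",
    "zscore_transform",
    "enrichment_score",
    "regulon_activity_matrix",
    "association_map",
    "cluster_activity",
]


@dataclass
class ActivityMatrix:
    """Regulon x sample dES scores with their one-tailed components."""

    des: pd.DataFrame
    es_pos: pd.DataFrame
    es_neg: pd.DataFrame
    meta: dict = field(default_factory=dict)


@dataclass
class ClusterTree:
    """Average-linkage merge tree with flat labels at the requested cut."""

    items: list[str]
    linkage_matrix: np.ndarray
    labels: pd.Series  # item -> cluster id (1..k)

    def partition(self) -> list[set[str]]:
        return [
            set(self.labels.index[self.labels == c])
            for c in sorted(self.labels.unique())
        ]


def zscore_transform(expr: pd.DataFrame) -> pd.DataFrame:
    """Per-gene z-scores across the cohort (sample sd, denominator n - 1).

    Genes with zero variance are dropped with a warning; every retained row
    has mean 0 and sd 1.
    """
    if expr.shape[1] < 2:
        raise ValueError("z-score transform needs at least 2 samples")
    values = expr.to_numpy(dtype=float)
    sd = values.std(axis=1, ddof=1)
    keep = sd > 0
    if (~keep).any():
        logger.warning(
            "%d constant gene(s) dropped before z-scoring: %s",
            int((~keep).sum()), expr.index[~keep].tolist()[:10],
        )
    z = (values[keep] - values[keep].mean(axis=1, keepdims=True)) / sd[keep, None]
    return pd.DataFrame(z, index=expr.index[keep], columns=expr.columns)


def _es_from_positions(pos: np.ndarray, weights: np.ndarray, n_genes: int) -> float:
    """Signed extreme of the weighted KS running sum, from hit positions only.

    ``pos`` are sorted 0-based positions of the hits in the ranking and
    ``weights`` the matching non-negative weights. Between hits the running
    sum decreases linearly, so extremes occur immediately after a hit
    (maximum candidates) or immediately before one (minimum candidates).
    """
    n_hits = pos.size
    if n_hits == 0:
        return 0.0
    if n_hits >= n_genes:
        raise ValueError("hit set must be a proper subset of the ranked genes")
    total = weights.sum()
    wn = weights / total if total > 0 else np.full(n_hits, 1.0 / n_hits)
    miss = 1.0 / (n_genes - n_hits)
    j = np.arange(n_hits)
    after = np.cumsum(wn) - (pos - j) * miss
    before = after - wn
    hi = float(after.max())
    lo = float(min(before.min(), 0.0))
    return hi if hi >= -lo else lo


def enrichment_score(ranked: list[str], weights, hits) -> float:
    """ES of ``hits`` in a ranked gene list with per-gene weights.

    ``ranked`` is ordered best-to-worst (z descending) and ``weights`` are
    the matching |z| values. Returns the maximum-magnitude signed running
    deviation in [-1, 1].
    """
    hits = set(hits)
    if not hits:
        raise ValueError("hit set is empty")
    if not hits <= set(ranked):
        raise ValueError("hits must be a subset of the ranked genes")
    weights = np.asarray(weights, dtype=float)
    mask = np.fromiter((g in hits for g in ranked), count=len(ranked), dtype=bool)
    pos = np.nonzero(mask)[0]
    return _es_from_positions(pos, weights[pos], len(ranked))


def regulon_activity_matrix(
    z: pd.DataFrame,
    network: RegulatoryNetwork,
    min_overlap: float = 0.5,
) -> ActivityMatrix:
    """dES per (size-filtered regulon, sample).

    Supports projection onto a cohort the network was not inferred from:
    target sets are intersected with the available genes; regulons losing
    more than half of their targets are flagged, and regulons with no
    overlapping target yield NaN with a warning. An empty positive or
    negative sub-set contributes ES = 0, so one-sided regulons still score.
    """
    # Deterministic ranking: sort rows by gene id so that stable argsort on
    # -z breaks z ties lexicographically.
    z = z.sort_index(kind="stable")
    genes = z.index
    loc = {g: i for i, g in enumerate(genes)}
    values = z.to_numpy(dtype=float)
    absz = np.abs(values)
    n_genes, n_samples = values.shape

    regulons = network.filtered_regulons
    if not regulons:
        raise ValueError("no regulon meets the size cut-off")
    sets: list[tuple[str, np.ndarray, np.ndarray]] = []
    flags: dict[str, float] = {}
    for reg in regulons:
        present = [g for g in reg.targets if g in loc]
        frac = len(present) / reg.size if reg.size else 0.0
        if not present:
            logger.warning("regulon %s has no target in the cohort; NaN activity", reg.tf)
            flags[reg.tf] = 0.0
            sets.append((reg.tf, np.array([], dtype=int), np.array([], dtype=int)))
            continue
        if frac < min_overlap:
            logger.warning(
                "regulon %s retains only %.0f%% of its targets in this cohort",
                reg.tf, 100 * frac,
            )
            flags[reg.tf] = frac
        pos_idx = np.array(sorted(loc[g] for g in reg.positive_targets if g in loc), dtype=int)
        neg_idx = np.array(sorted(loc[g] for g in reg.negative_targets if g in loc), dtype=int)
        sets.append((reg.tf, pos_idx, neg_idx))

    tf_ids = [s[0] for s in sets]
    es_pos = np.zeros((len(sets), n_samples))
    es_neg = np.zeros((len(sets), n_samples))
    for s in range(n_samples):
        order = np.argsort(-values[:, s], kind="stable")
        invpos = np.empty(n_genes, dtype=int)
        invpos[order] = np.arange(n_genes)
        col_abs = absz[:, s]
        for i, (tf, pos_idx, neg_idx) in enumerate(sets):
            if pos_idx.size + neg_idx.size == 0:
                es_pos[i, s] = es_neg[i, s] = np.nan
                continue
            for arr, out in ((pos_idx, es_pos), (neg_idx, es_neg)):
                if arr.size == 0:
                    out[i, s] = 0.0
                    continue
                p = invpos[arr]
                o = np.argsort(p)
                out[i, s] = _es_from_positions(p[o], col_abs[arr][o], n_genes)

    des = es_pos - es_neg
    cols = z.columns
    return ActivityMatrix(
        des=pd.DataFrame(des, index=tf_ids, columns=cols),
        es_pos=pd.DataFrame(es_pos, index=tf_ids, columns=cols),
        es_neg=pd.DataFrame(es_neg, index=tf_ids, columns=cols),
        meta={"score": "dES (raw, unnormalized)", "projection_flags": flags},
    )


def association_map(network: RegulatoryNetwork, min_shared: int = 1) -> pd.DataFrame:
    """Agonist/antagonist labels for every regulon pair sharing targets.

    ``agreement`` is the fraction of mutually regulated genes whose mode
    product is +1; pairs with agreement > 0.5 are agonists, < 0.5
    antagonists, = 0.5 ambiguous. Pairs sharing fewer than ``min_shared``
    targets are omitted.
    """
    regulons = network.filtered_regulons
    if len(regulons) < 2:
        raise ValueError("association map needs at least 2 regulons")
    rows = []
    for i in range(len(regulons)):
        for j in range(i + 1, len(regulons)):
            r1, r2 = regulons[i], regulons[j]
            shared = set(r1.targets) & set(r2.targets)
            if len(shared) < min_shared:
                continue
            agree = sum(
                1 for g in shared if r1.targets[g][0] == r2.targets[g][0]
            ) / len(shared)
            label = (
                "agonist" if agree > 0.5
                else "antagonist" if agree < 0.5
                else "ambiguous"
            )
            rows.append((r1.tf, r2.tf, len(shared), agree, label))
    return pd.DataFrame(
        rows, columns=["tf1", "tf2", "shared", "agreement", "label"]
    )


def cluster_activity(
    activity,
    k: int,
    items: str = "regulons",
) -> ClusterTree:
    """Average-linkage hierarchical clustering of an activity matrix.

    Regulon profiles use the 1 - Pearson correlation distance; sample
    profiles use Euclidean distance. The merge order is deterministic
    (scipy's nearest-neighbour-chain agglomeration with its fixed tie
    ordering).
    """
    des = getattr(activity, "des", activity)
    if items == "samples":
        des = des.T
    elif items != "regulons":
        raise ValueError("items must be 'regulons' or 'samples'")
    names = list(des.index)
    if k > len(names):
        raise ValueError(f"k={k} exceeds the {len(names)} items to cluster")
    if len(names) < 2 or des.shape[1] < 2:
        raise ValueError("clustering needs at least 2 items and 2 observations")

    x = des.to_numpy(dtype=float)
    if items == "regulons":
        corr = np.corrcoef(x)
        dist = squareform(np.clip(1.0 - corr, 0.0, 2.0), checks=False)
    else:
        dist = pdist(x, metric="euclidean")
    z = linkage(dist, method="average")
    labels = pd.Series(fcluster(z, t=k, criterion="maxclust"), index=names)
    return ClusterTree(items=names, linkage_matrix=z, labels=labels)
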