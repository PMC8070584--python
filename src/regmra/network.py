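"""TF-centric transcriptional network inference.

The inference stage mirrors the classic mutual-information (MI) workflow for
reverse-engineering regulatory networks from expression cohorts:

1. ``compute_mi_matrix`` — MI between every regulator (TF) and every other
   gene, estimated on rank-transformed expression with equal-frequency
   binning (plug-in entropy, natural log).
2. ``filter_edges_by_permutation`` — an empirical null built by permuting
   sample labels of the targets, pooled across all (TF, target) pairs, with
   Benjamini–Hochberg control over all tested pairs.
3. ``apply_dpi`` — data-processing-inequality pruning: in every fully
   connected (TF1, TF2, gene) triplet the weakest TF–gene edge is removed
   when it is weaker than both other edges by more than ``dpi_eps``.
4. ``build_regulons`` — signed regulons: mode of action is the sign of the
   Spearman correlation between TF and target; regulons below ``min_size``
   targets are excluded from downstream analyses but kept in the raw listing.

Expression matrices are pandas DataFrames with genes as rows (unique index)
and samples as columns, on a log2 scale.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.special import xlogy
from scipy.stats import false_discovery_control, rankdata

logger = logging.getLogger("regmra")

__all__ = [
    "Regulon",
    "RegulatoryNetwork",
    "equal_frequency_bins",
    "compute_mi_matrix",
    "filter_edges_by_permutation",
    "apply_dpi",
    "build_regulons",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class Regulon:
    """A TF with its inferred target set.

    ``targets`` maps each target gene to ``(mode, weight)`` where mode is
    +1 (activated) or -1 (repressed) and weight is the MI of the edge.
    """

    tf: str
    targets: dict[str, tuple[int, float]]

    def __post_init__(self) -> None:
        if self.tf in self.targets:
            raise ValueError(f"regulon {self.tf} lists itself as a target")

    @property
    def size(self) -> int:
        return len(self.targets)

    def targets_by_mode(self, mode: int) -> set[str]:
        return {g for g, (m, _) in self.targets.items() if m == mode}

    @property
    def positive_targets(self) -> set[str]:
        return self.targets_by_mode(+1)

    @property
    def negative_targets(self) -> set[str]:
        return self.targets_by_mode(-1)


@dataclass
class RegulatoryNetwork:
    """A collection of regulons plus the universe of genes tested.

    ``regulons`` keeps every assembled regulon regardless of size; analyses
    that honour the size cut-off should use :meth:`filtered_regulons`.
    ``params`` records the inference provenance (bins, n_perm, alpha,
    dpi_eps, min_size, seed).
    """

    regulons: list[Regulon]
    universe: list[str]
    min_size: int = 15
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        uni = set(self.universe)
        for reg in self.regulons:
            missing = set(reg.targets) - uni
            if missing:
                raise ValueError(
                    f"regulon {reg.tf} has targets outside the universe: "
                    f"{sorted(missing)[:5]}"
                )

    @property
    def filtered_regulons(self) -> list[Regulon]:
        """Regulons meeting the minimum-size cut-off."""
        return [r for r in self.regulons if r.size >= self.min_size]

    def get(self, tf: str) -> Regulon | None:
        for r in self.regulons:
            if r.tf == tf:
                return r
        return None

    def sizes(self) -> dict[str, int]:
        return {r.tf: r.size for r in self.regulons}

    def to_edge_frame(self) -> pd.DataFrame:
        rows = [
            (r.tf, g, m, w)
            for r in self.regulons
            for g, (m, w) in sorted(r.targets.items())
        ]
        return pd.DataFrame(rows, columns=["tf", "target", "mode", "mi"])


# ---------------------------------------------------------------------------
# MI estimation
# ---------------------------------------------------------------------------

def equal_frequency_bins(values: np.ndarray, n_bins: int) -> np.ndarray:
    """Equal-frequency bin labels from average-tie ranks.

    Values are ranked (ties get the average rank) and rank r in 1..n is
    assigned to bin floor((r - 0.5) * B / n). With no ties and n divisible
    by B every bin holds exactly n/B samples.
    """
    r = rankdata(values, method="average")
    n = len(values)
    b = np.floor((r - 0.5) * n_bins / n).astype(np.int64)
    return np.clip(b, 0, n_bins - 1)


def _bin_matrix(values: np.ndarray, n_bins: int) -> np.ndarray:
    """Row-wise equal-frequency bin labels for a genes x samples array."""
    n = values.shape[1]
    r = rankdata(values, axis=1, method="average")
    b = np.floor((r - 0.5) * n_bins / n).astype(np.int64)
    return np.clip(b, 0, n_bins - 1)


class _MIEngine:
    """Vectorised plug-in MI between a block of TF rows and all gene rows.

    Joint histograms for every (tf, gene) pair are accumulated with a single
    offset ``bincount`` per call. Marginal entropies are invariant under
    sample permutation, so the permutation loop only recomputes the joint
    entropy, via a precomputed k*ln(k) lookup table on integer counts:

        MI = H_row + H_col - H_joint,
        H_joint = ln n - (1/n) * sum_ij c_ij ln c_ij.
    """

    def __init__(self, tf_bins: np.ndarray, gene_bins: np.ndarray, n_bins: int):
        self.B = B = n_bins
        self.T, self.n = tf_bins.shape
        self.G = gene_bins.shape[0]
        self.gene_bins = gene_bins.astype(np.int64)
        self._tf_codes = (tf_bins.astype(np.int64) * B)[:, None, :]
        self._offs = (np.arange(self.T * self.G, dtype=np.int64) * (B * B)).reshape(
            self.T, self.G, 1
        )
        k = np.arange(self.n + 1, dtype=float)
        self._klnk = xlogy(k, k)
        # marginal entropies: fixed under any column permutation
        h = np.empty((2, max(self.T, self.G)))
        for j, bins in enumerate((tf_bins, gene_bins)):
            cnt = np.apply_along_axis(np.bincount, 1, bins, minlength=B)
            h[j, : bins.shape[0]] = np.log(self.n) - self._klnk[cnt].sum(axis=1) / self.n
        self._h_marg = h[0, : self.T, None] + h[1, None, : self.G]

    def mi(self, perm: np.ndarray | None = None) -> np.ndarray:
        """(T, G) MI matrix in nats; targets optionally column-permuted."""
        B = self.B
        gb = self.gene_bins if perm is None else self.gene_bins[:, perm]
        code = self._tf_codes + gb[None, :, :]
        code += self._offs
        cnt = np.bincount(code.ravel(), minlength=self.T * self.G * B * B)
        h_joint = np.log(self.n) - self._klnk[
            cnt.reshape(self.T, self.G, B * B)
        ].sum(axis=2) / self.n
        return np.maximum(self._h_marg - h_joint, 0.0)


def _check_regulators(expr: pd.DataFrame, tf_ids: Sequence[str]) -> list[str]:
    if len(tf_ids) == 0:
        raise ValueError("regulator list is empty")
    present = [t for t in tf_ids if t in expr.index]
    absent = sorted(set(tf_ids) - set(present))
    if absent:
        logger.warning(
            "%d regulators absent from the expression matrix and skipped: %s",
            len(absent), absent[:10],
        )
    if not present:
        raise ValueError("no regulator is present in the expression matrix")
    return present


def _validate_expr(expr: pd.DataFrame, min_samples: int = 4) -> None:
    if expr.index.has_duplicates:
        dup = expr.index[expr.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene ids in expression matrix: {dup[:5]}")
    if expr.isna().to_numpy().any():
        raise ValueError("expression matrix contains missing values")
    if expr.shape[1] < min_samples:
        raise ValueError(f"need at least {min_samples} samples, got {expr.shape[1]}")


def default_bins(n_samples: int) -> int:
    """Default bin count: floor(sqrt(n))."""
    return int(np.floor(np.sqrt(n_samples)))


def compute_mi_matrix(
    expr: pd.DataFrame,
    tf_ids: Sequence[str],
    n_bins: int | None = None,
) -> pd.DataFrame:
    """MI between every regulator and every gene.

    Returns a (TF x gene) DataFrame in nats. Self pairs are NaN. Constant
    genes (zero variance) are flagged in ``result.attrs['constant_genes']``
    and produce MI 0 against everything (all samples share one rank bin).
    """
    _validate_expr(expr)
    n = expr.shape[1]
    B = default_bins(n) if n_bins is None else int(n_bins)
    if B < 2:
        raise ValueError("n_bins must be >= 2")
    if n < 2 * B:
        raise ValueError(f"need at least 2*n_bins={2 * B} samples, got {n}")
    tfs = _check_regulators(expr, tf_ids)

    values = expr.to_numpy(dtype=float)
    constant = expr.index[np.ptp(values, axis=1) == 0].tolist()
    if constant:
        logger.warning("%d constant gene(s) flagged: %s", len(constant), constant[:10])

    bins = _bin_matrix(values, B)
    tf_idx = [expr.index.get_loc(t) for t in tfs]
    engine = _MIEngine(bins[tf_idx], bins, B)
    mi = engine.mi()
    out = pd.DataFrame(mi, index=tfs, columns=expr.index)
    for t, i in zip(tfs, tf_idx):
        out.iloc[out.index.get_loc(t), i] = np.nan  # self pair
    out.attrs["n_bins"] = B
    out.attrs["constant_genes"] = constant
    return out


# ---------------------------------------------------------------------------
# Permutation filtering
# ---------------------------------------------------------------------------

def filter_edges_by_permutation(
    expr: pd.DataFrame,
    tf_ids: Sequence[str],
    mi: pd.DataFrame | None = None,
    n_perm: int = 500,
    alpha: float = 0.05,
    seed: int = 0,
    n_bins: int | None = None,
    adjust: str = "global",
) -> pd.DataFrame:
    """Retain (TF, target) edges that beat a pooled permutation null.

    The null is built by permuting the sample labels of the targets; null MI
    values are pooled across all tested pairs. Empirical p-values use the
    add-one rule p = (1 + #{null >= mi}) / (1 + total null draws). BH is
    applied globally across all tested pairs (``adjust='global'``) or within
    each TF (``adjust='per_tf'``); edges with adjusted p <= alpha survive.

    Returns a DataFrame with columns tf, target, mi, p, p_adj.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    if adjust not in ("global", "per_tf"):
        raise ValueError("adjust must be 'global' or 'per_tf'")
    if mi is None:
        mi = compute_mi_matrix(expr, tf_ids, n_bins=n_bins)
    tfs = list(mi.index)
    genes = list(mi.columns)
    n = expr.shape[1]
    B = mi.attrs.get("n_bins", default_bins(n) if n_bins is None else n_bins)

    values = expr.loc[genes].to_numpy(dtype=float)
    bins = _bin_matrix(values, B)
    tf_idx = [genes.index(t) for t in tfs]
    engine = _MIEngine(bins[tf_idx], bins, B)

    valid = ~np.isnan(mi.to_numpy())
    n_valid = int(valid.sum())
    rng = np.random.default_rng(seed)
    null = np.empty((n_perm, n_valid), dtype=np.float32)
    for i in range(n_perm):
        perm = rng.permutation(n)
        null[i] = engine.mi(perm)[valid]
    null_sorted = np.sort(null, axis=None)
    total = null_sorted.size

    obs = mi.to_numpy()[valid]
    count_ge = total - np.searchsorted(null_sorted, obs.astype(np.float32), side="left")
    p = (1.0 + count_ge) / (1.0 + total)

    ti, gi = np.nonzero(valid)
    edges = pd.DataFrame(
        {
            "tf": np.asarray(tfs, dtype=object)[ti],
            "target": np.asarray(genes, dtype=object)[gi],
            "mi": obs,
            "p": p,
        }
    )
    if adjust == "global":
        edges["p_adj"] = false_discovery_control(edges["p"].to_numpy(), method="bh")
    else:
        edges["p_adj"] = edges.groupby("tf")["p"].transform(
            lambda s: false_discovery_control(s.to_numpy(), method="bh")
        )
    kept = edges[edges["p_adj"] <= alpha].reset_index(drop=True)
    logger.info(
        "permutation filter: %d/%d pairs retained (alpha=%g, n_perm=%d)",
        len(kept), len(edges), alpha, n_perm,
    )
    return kept


# ---------------------------------------------------------------------------
# DPI pruning
# ---------------------------------------------------------------------------

def apply_dpi(edges: pd.DataFrame, dpi_eps: float = 0.0) -> pd.DataFrame:
    """Prune indirect edges with the data-processing inequality.

    For every triplet (TF1, TF2, g) where the TF–TF edge and both TF–g edges
    are present, the TF–g edge with the smallest MI is removed if it is
    smaller than both other edges by more than ``dpi_eps``. TF–TF edges are
    never removed by a triplet they anchor; all removals are evaluated on
    the pre-pruning edge set, so the result is order-independent.
    """
    if edges.empty:
        return edges.copy()
    und: dict[frozenset, float] = {}
    targets_of: dict[str, set[str]] = {}
    for tf, target, m in edges[["tf", "target", "mi"]].itertuples(index=False):
        und[frozenset((tf, target))] = float(m)
        targets_of.setdefault(tf, set()).add(target)

    tf_list = sorted(targets_of)
    removal: set[frozenset] = set()
    for t1, t2 in itertools.combinations(tf_list, 2):
        anchor = und.get(frozenset((t1, t2)))
        if anchor is None:
            continue
        common = (targets_of[t1] & targets_of[t2]) - {t1, t2}
        for g in common:
            m1 = und[frozenset((t1, g))]
            m2 = und[frozenset((t2, g))]
            if m1 <= m2:
                weak, weak_mi, other_mi = (t1, g), m1, m2
            else:
                weak, weak_mi, other_mi = (t2, g), m2, m1
            if weak_mi < anchor - dpi_eps and weak_mi < other_mi - dpi_eps:
                removal.add(frozenset(weak))

    keep = [
        frozenset((tf, tg)) not in removal
        for tf, tg in edges[["tf", "target"]].itertuples(index=False)
    ]
    pruned = edges[keep].reset_index(drop=True)
    logger.info("DPI removed %d edge rows (eps=%g)", len(edges) - len(pruned), dpi_eps)
    return pruned


# ---------------------------------------------------------------------------
# Regulon assembly
# ---------------------------------------------------------------------------

def build_regulons(
    edges: pd.DataFrame,
    expr: pd.DataFrame,
    min_size: int = 15,
    params: dict | None = None,
) -> RegulatoryNetwork:
    """Assemble signed regulons from a filtered edge list.

    Mode of action is the sign of the Spearman correlation between TF and
    target expression; targets with exactly zero (or undefined) correlation
    are dropped with a warning. Every regulon is kept in the network object;
    the ``min_size`` cut governs :meth:`RegulatoryNetwork.filtered_regulons`.
    """
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    ranks = rankdata(expr.to_numpy(dtype=float), axis=1)
    ranks = ranks - ranks.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(ranks, axis=1)
    loc = {g: i for i, g in enumerate(expr.index)}

    regulons: list[Regulon] = []
    dropped = 0
    for tf, grp in edges.groupby("tf", sort=True):
        ti = loc[tf]
        targets: dict[str, tuple[int, float]] = {}
        for target, m in grp[["target", "mi"]].itertuples(index=False):
            if target == tf:
                continue
            gi = loc[target]
            denom = norms[ti] * norms[gi]
            rho = float(ranks[ti] @ ranks[gi] / denom) if denom > 0 else np.nan
            if not np.isfinite(rho) or rho == 0.0:
                dropped += 1
                logger.warning(
                    "target %s dropped from regulon %s (zero/undefined correlation)",
                    target, tf,
                )
                continue
            targets[target] = (1 if rho > 0 else -1, float(m))
        regulons.append(Regulon(tf=tf, targets=targets))
    if dropped:
        logger.warning("%d target(s) dropped for undefined mode of action", dropped)

    net = RegulatoryNetwork(
        regulons=regulons,
        universe=list(expr.index),
        min_size=min_size,
        params=dict(params or {}),
    )
    net.params.setdefault("min_size", min_size)
    return net


def infer_network(
    expr: pd.DataFrame,
    tf_ids: Sequence[str],
    n_bins: int | None = None,
    n_perm: int = 500,
    alpha: float = 0.05,
    dpi_eps: float | None = 0.0,
    min_size: int = 15,
    seed: int = 0,
) -> RegulatoryNetwork:
    """MI -> permutation filter -> (optional) DPI -> signed regulons.

    ``dpi_eps=None`` switches DPI off.
    """
    mi = compute_mi_matrix(expr, tf_ids, n_bins=n_bins)
    edges = filter_edges_by_permutation(
        expr, tf_ids, mi=mi, n_perm=n_perm, alpha=alpha, seed=seed, n_bins=n_bins
    )
    if dpi_eps is not None:
        edges = apply_dpi(edges, dpi_eps=dpi_eps)
    params = {
        "bins": mi.attrs.get("n_bins"),
        "n_perm": n_perm,
        "alpha": alpha,
        "dpi_eps": dpi_eps,
        "min_size": min_size,
        "seed": seed,
    }
    return build_regulons(edges, expr, min_size=min_size, params=params)
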