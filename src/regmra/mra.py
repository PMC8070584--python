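"""Gene signatures, master-regulator analysis and cross-analysis consensus.

A *gene signature* is the set of genes differentially expressed between a
tumor cohort and a putative cell-of-origin cohort (Welch t-test per gene,
BH adjustment, adjusted p <= alpha). *Master-regulator analysis* (MRA) asks,
for every size-filtered regulon, whether the signature is over-represented
among its targets (one-tailed hypergeometric / Fisher test), with BH across
regulons. TFs whose regulons pass are master regulators (MRs); the
*consensus* is the strict intersection of MR sets across networks and
signatures.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import false_discovery_control, hypergeom, ttest_ind

from .network import RegulatoryNetwork

logger = logging.getLogger("regmra")

__all__ = [
    "GeneSignature",
    "EnrichmentResult",
    "MRAResult",
    "ConsensusResult",
    "differential_expression",
    "overrepresentation_test",
    "adjust_pvalues",
    "run_mra",
    "consensus_mrs",
]


@dataclass
class GeneSignature:
    """A differentially expressed gene set with its per-gene statistics.

    ``stats`` (may be None for plain gene-list signatures) is indexed by
    every tested gene with columns effect (mean log2 difference), p, p_adj.
    """

    genes: set[str]
    stats: pd.DataFrame | None = None
    name: str = "signature"

    @property
    def tested(self) -> set[str] | None:
        return None if self.stats is None else set(self.stats.index)

    @classmethod
    def from_gene_list(cls, genes, name: str = "signature") -> "GeneSignature":
        return cls(genes=set(genes), stats=None, name=name)


@dataclass(frozen=True)
class EnrichmentResult:
    """Hypergeometric over-representation of a query set in a reference set."""

    set_id: str
    k: int   # overlap
    K: int   # reference (regulon) size within the universe
    n: int   # query (signature) size within the universe
    N: int   # universe size
    p: float
    p_adj: float = float("nan")


@dataclass
class MRAResult:
    network_id: str
    signature_id: str
    enrichments: list[EnrichmentResult]
    mrs: set[str]
    alpha: float = 0.05

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (e.set_id, e.k, e.K, e.n, e.N, e.p, e.p_adj, e.set_id in self.mrs)
                for e in self.enrichments
            ],
            columns=["tf", "k", "K", "n", "N", "p", "p_adj", "is_mr"],
        )


@dataclass
class ConsensusResult:
    per_analysis: list[set[str]]
    consensus: set[str]


# ---------------------------------------------------------------------------


def differential_expression(
    case: pd.DataFrame,
    origin: pd.DataFrame,
    alpha: float = 0.05,
    name: str = "signature",
) -> GeneSignature:
    """Welch two-sample t-test per gene on log2 expression, BH across genes.

    The signature is the set of genes with adjusted p <= alpha. Genes with
    zero variance in both groups carry no statistical information and are
    excluded with a warning.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if case.shape[1] < 2 or origin.shape[1] < 2:
        raise ValueError("each group needs at least 2 samples")
    shared = case.index.intersection(origin.index)
    if shared.empty:
        raise ValueError("case and origin matrices share no genes")
    a = case.loc[shared].to_numpy(dtype=float)
    b = origin.loc[shared].to_numpy(dtype=float)

    degenerate = (a.var(axis=1) == 0) & (b.var(axis=1) == 0)
    if degenerate.any():
        logger.warning(
            "%d gene(s) with zero variance in both groups excluded from the "
            "signature contrast", int(degenerate.sum()),
        )
    keep = ~degenerate
    genes = shared[keep]
    stat, p = ttest_ind(a[keep], b[keep], axis=1, equal_var=False)
    p = np.where(np.isnan(p), 1.0, p)
    p_adj = false_discovery_control(p, method="bh")
    stats = pd.DataFrame(
        {
            "effect": a[keep].mean(axis=1) - b[keep].mean(axis=1),
            "stat": stat,
            "p": p,
            "p_adj": p_adj,
        },
        index=genes,
    )
    sig = set(genes[p_adj <= alpha])
    logger.info("signature %s: %d/%d genes differentially expressed", name,
                len(sig), len(genes))
    return GeneSignature(genes=sig, stats=stats, name=name)


def overrepresentation_test(
    query: set[str],
    reference: set[str],
    universe: set[str],
    set_id: str = "",
) -> EnrichmentResult:
    """One-tailed hypergeometric enrichment p-value.

    p = sum_{j >= k} C(K, j) C(N-K, n-j) / C(N, n) with k the observed
    overlap, K the reference size, n the query size, N the universe size —
    all counted inside the universe. k = 0 gives p = 1 exactly.
    """
    if not universe:
        raise ValueError("empty universe")
    uni = set(universe)
    q = set(query) & uni
    r = set(reference) & uni
    k = len(q & r)
    K = len(r)
    n = len(q)
    N = len(uni)
    p = float(hypergeom.sf(k - 1, N, K, n))
    p = min(max(p, 0.0), 1.0)
    return EnrichmentResult(set_id=set_id, k=k, K=K, n=n, N=N, p=p)


def adjust_pvalues(p, method: str = "bh") -> np.ndarray:
    """Multiple-testing adjustment: 'bh' (step-up, monotone) or 'bonferroni'."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    method = method.lower()
    if method == "bh":
        return false_discovery_control(p, method="bh")
    if method == "bonferroni":
        return np.minimum(1.0, p * p.size)
    raise ValueError(f"unknown method {method!r}")


def run_mra(
    network: RegulatoryNetwork,
    signature: GeneSignature,
    alpha: float = 0.05,
    network_id: str = "network",
) -> MRAResult:
    """One over-representation test per size-filtered regulon.

    The test universe is the intersection of the network universe with the
    genes tested by the signature (the full network universe for plain
    gene-list signatures); BH is applied across regulons and MRs are the
    TFs with adjusted p <= alpha.
    """
    if not 0 <= alpha < 1:
        raise ValueError("alpha must be in [0, 1)")
    tested = signature.tested
    universe = set(network.universe) if tested is None else set(network.universe) & tested
    if not universe:
        raise ValueError("network universe and signature-tested genes are disjoint")
    regulons = network.filtered_regulons
    if not regulons:
        logger.warning("no regulon meets the size cut-off; MRA result is empty")
        return MRAResult(network_id, signature.name, [], set(), alpha)

    query = signature.genes & universe
    enrichments = [
        overrepresentation_test(query, set(r.targets), universe, set_id=r.tf)
        for r in regulons
    ]
    p_adj = adjust_pvalues([e.p for e in enrichments], method="bh")
    enrichments = [
        EnrichmentResult(e.set_id, e.k, e.K, e.n, e.N, e.p, float(q))
        for e, q in zip(enrichments, p_adj)
    ]
    mrs = {e.set_id for e in enrichments if e.p_adj <= alpha}
    logger.info("MRA %s x %s: %d/%d regulons enriched", network_id,
                signature.name, len(mrs), len(enrichments))
    return MRAResult(network_id, signature.name, enrichments, mrs, alpha)


def consensus_mrs(results: list[MRAResult]) -> ConsensusResult:
    """Strict intersection of MR sets across all supplied analyses."""
    if not results:
        raise ValueError("need at least one MRA result")
    sets = [set(r.mrs) for r in results]
    consensus = set.intersection(*sets)
    return ConsensusResult(per_analysis=sets, consensus=consensus)
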