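"""Probe-wise differential methylation and per-regulon Fisher enrichment.

Beta values (methylated fraction, in [0, 1]) are compared between case and
control groups on the M-value scale, M = log2(beta / (1 - beta)) with beta
clipped away from 0 and 1 — the standard variance-stabilizing transform.
Probes are tested with a Welch t-test and Bonferroni-corrected; a gene is
differentially methylated (DM) when at least one of its probes is. Each
size-filtered regulon is then tested for over-representation of DM genes
(one-tailed Fisher/hypergeometric test, Bonferroni across regulons).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import ttest_ind

from .mra import adjust_pvalues, overrepresentation_test, EnrichmentResult
from .network import RegulatoryNetwork

logger = logging.getLogger("regmra")

__all__ = [
    "BETA_CLIP",
    "RegulonMethylation",
    "m_values",
    "dm_probe_test",
    "dm_genes",
    "regulon_dm_enrichment",
]

BETA_CLIP = 1e-3


@dataclass(frozen=True)
class RegulonMethylation:
    """Enrichment of one regulon for differentially methylated genes."""

    regulon: str
    enrichment: EnrichmentResult
    is_enriched: bool


def m_values(beta: pd.DataFrame, eps: float = BETA_CLIP) -> pd.DataFrame:
    """M = log2(beta / (1 - beta)) with beta clipped to [eps, 1 - eps]."""
    b = beta.to_numpy(dtype=float)
    if (b < 0).any() or (b > 1).any():
        raise ValueError("beta values must lie in [0, 1]")
    b = np.clip(b, eps, 1.0 - eps)
    return pd.DataFrame(np.log2(b / (1.0 - b)), index=beta.index, columns=beta.columns)


def dm_probe_test(
    case: pd.DataFrame,
    control: pd.DataFrame,
    threshold: float = 0.01,
    qc_mask=None,
) -> pd.DataFrame:
    """Welch t-test per probe on M-values, Bonferroni over probes.

    Probes absent from either matrix (or listed in the optional ``qc_mask``
    of failed positions) are skipped with a warning. Returns a DataFrame
    with probe, delta_beta (case - control mean beta), stat, p, p_adj and
    is_dm (p_adj < threshold).
    """
    if case.shape[1] < 2 or control.shape[1] < 2:
        raise ValueError("each group needs at least 2 samples")
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    shared = case.index.intersection(control.index)
    skipped = len(case.index.union(control.index)) - len(shared)
    if skipped:
        logger.warning("%d probe(s) absent from one matrix; skipped", skipped)
    if qc_mask is not None:
        bad = shared.intersection(pd.Index(qc_mask))
        if len(bad):
            logger.warning("%d probe(s) dropped by the QC mask", len(bad))
            shared = shared.difference(bad)
    if shared.empty:
        raise ValueError("no shared probes to test")

    bc, bt = case.loc[shared], control.loc[shared]
    mc, mt = m_values(bc).to_numpy(), m_values(bt).to_numpy()
    stat, p = ttest_ind(mc, mt, axis=1, equal_var=False)
    p = np.where(np.isnan(p), 1.0, p)
    p_adj = adjust_pvalues(p, method="bonferroni")
    out = pd.DataFrame(
        {
            "probe": shared,
            "delta_beta": bc.mean(axis=1).to_numpy() - bt.mean(axis=1).to_numpy(),
            "stat": stat,
            "p": p,
            "p_adj": p_adj,
            "is_dm": p_adj < threshold,
        }
    ).reset_index(drop=True)
    logger.info("%d/%d probes differentially methylated (Bonferroni < %g)",
                int(out["is_dm"].sum()), len(out), threshold)
    return out


def dm_genes(dm: pd.DataFrame, probe_map: pd.Series) -> set[str]:
    """Collapse probe calls to genes: a gene is DM iff >= 1 probe is DM.

    Probes missing from the map are reported and excluded.
    """
    unmapped = dm.loc[~dm["probe"].isin(probe_map.index), "probe"]
    if len(unmapped):
        logger.warning("%d unmapped probe(s) excluded: %s",
                       len(unmapped), unmapped.tolist()[:10])
    hit = dm.loc[dm["is_dm"] & dm["probe"].isin(probe_map.index), "probe"]
    return set(probe_map.loc[hit])


def regulon_dm_enrichment(
    network: RegulatoryNetwork,
    dm_gene_set: set[str],
    probe_map: pd.Series,
    threshold: float = 0.01,
) -> list[RegulonMethylation]:
    """Fisher enrichment of DM genes in every size-filtered regulon.

    The universe is the set of genes covered by the probe map that also
    belong to the network universe; p-values are Bonferroni-adjusted across
    regulons and a regulon is enriched when the adjusted p < threshold.
    """
    universe = set(probe_map) & set(network.universe)
    if not universe:
        raise ValueError("no probe-mapped gene belongs to the network universe")
    regulons = network.filtered_regulons
    if not regulons:
        raise ValueError("no regulon meets the size cut-off")
    raw = [
        overrepresentation_test(
            set(dm_gene_set), set(r.targets), universe, set_id=r.tf
        )
        for r in regulons
    ]
    p_adj = adjust_pvalues([e.p for e in raw], method="bonferroni")
    out = [
        RegulonMethylation(
            regulon=e.set_id,
            enrichment=EnrichmentResult(e.set_id, e.k, e.K, e.n, e.N, e.p, float(q)),
            is_enriched=bool(q < threshold),
        )
        for e, q in zip(raw, p_adj)
    ]
    logger.info("%d/%d regulons enriched for DM genes", sum(r.is_enriched for r in out),
                len(out))
    return out


def enrichment_frame(results: list[RegulonMethylation]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (r.regulon, r.enrichment.k, r.enrichment.K, r.enrichment.n,
             r.enrichment.N, r.enrichment.p, r.enrichment.p_adj, r.is_enriched)
            for r in results
        ],
        columns=["regulon", "k", "K", "n", "N", "p", "p_adj", "enriched"],
    )
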