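"""Configuration-driven orchestration of the full analysis.

The pipeline mirrors the study design it emulates: two tumor cohorts each
yield an independently inferred regulatory network; two case-versus-origin
contrasts yield two gene signatures; the four network x signature MRA runs
are intersected into a consensus MR set; regulon activity is scored per
cohort (and projected onto a third survival cohort using the first
network's regulon structure); activity median-splits drive Kaplan–Meier /
log-rank survival screens; and an independent case/control methylation
contrast feeds per-regulon enrichment of differentially methylated genes,
run once per network.

Because the cohorts are synthetic, the run report also scores the pipeline
against the planted ground truth (edge precision/recall, mode agreement,
consensus identity, activity fidelity, cluster partition, survival
directions, methylation enrichment).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as rio
from .activity import (
    ActivityMatrix,
    association_map,
    cluster_activity,
    regulon_activity_matrix,
    zscore_transform,
)
from .methylation import dm_genes, dm_probe_test, enrichment_frame, regulon_dm_enrichment
from .mra import consensus_mrs, differential_expression, run_mra
from .network import RegulatoryNetwork, infer_network
from .survival import survival_screen
from .synthetic import (
    SyntheticTruth,
    TruthConfig,
    generate_truth,
    simulate_cohort,
    simulate_methylation,
    simulate_origin_cohort,
    simulate_survival,
)

logger = logging.getLogger("regmra")

__all__ = ["PipelineConfig", "run_pipeline", "evaluate_recovery"]


@dataclass(frozen=True)
class PipelineConfig:
    """All study conditions and stage parameters, with reference defaults.

    Thresholds follow the analysis conventions: BH 0.05 for edges, DE and
    MRA; Bonferroni 0.01 for methylation; regulon size cut 15.
    """

    # ground truth
    n_tfs: int = 10
    n_mr: int = 7
    cluster_sizes: tuple[int, int] = (2, 5)
    n_genes: int = 500
    targets_per_regulon: int = 40
    cross_shared_fraction: float = 0.3
    weight_magnitude: float = 2.0
    noise_sd: float = 1.0
    # cohorts
    n_cohort1: int = 120
    n_cohort2: int = 120
    n_survival_cohort: int = 44
    n_case: int = 20
    n_origin: int = 20
    activity_shift: float = 3.0
    activity_coupling: float = 0.6
    # network inference
    n_bins: int | None = None
    n_perm: int = 500
    edge_alpha: float = 0.05
    dpi_eps: float | None = 0.0
    min_size: int = 15
    # signatures / MRA
    de_alpha: float = 0.05
    mra_alpha: float = 0.05
    # activity / association
    min_shared: int = 1
    # survival
    effect_a: float = -1.0
    effect_b: float = 1.0
    baseline_scale: float = 1.0
    censor_rate: float = 0.2
    survival_alpha: float = 0.05
    # methylation
    meth_n_case: int = 15
    meth_n_ctrl: int = 9
    delta_beta: float = 0.4
    probes_per_gene: int = 2
    meth_noise_sd: float = 0.05
    meth_threshold: float = 0.01
    # reproducibility
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "cluster_sizes" in raw:
            raw["cluster_sizes"] = tuple(raw["cluster_sizes"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cluster_sizes"] = list(d["cluster_sizes"])
        return d

    def truth_config(self, seed: int) -> TruthConfig:
        return TruthConfig(
            n_tfs=self.n_tfs,
            n_mr=self.n_mr,
            cluster_sizes=self.cluster_sizes,
            n_genes=self.n_genes,
            targets_per_regulon=self.targets_per_regulon,
            cross_shared_fraction=self.cross_shared_fraction,
            weight_magnitude=self.weight_magnitude,
            noise_sd=self.noise_sd,
            seed=seed,
        )


def _jsonable(x):
    """Recursively coerce numpy scalars so the report serializes cleanly."""
    if isinstance(x, dict):
        return {str(k): _jsonable(v) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_jsonable(v) for v in x]
    if isinstance(x, np.bool_):
        return bool(x)
    if isinstance(x, np.integer):
        return int(x)
    if isinstance(x, np.floating):
        return float(x)
    return x


def _stage_seeds(seed: int, n: int = 16) -> list[int]:
    """Independent sub-seeds below 2^31, derived from one master seed."""
    children = np.random.SeedSequence(seed).spawn(n)
    return [int(c.generate_state(1)[0] >> 1) for c in children]


def evaluate_recovery(
    network: RegulatoryNetwork, truth: SyntheticTruth
) -> dict[str, float]:
    """Per-target precision/recall of the planted MR regulons.

    Predicted pairs are the (TF, target) edges of the inferred regulons of
    planted-MR TFs that meet the size cut; mode agreement is scored over the
    correctly recovered pairs against the planted weight signs.
    """
    truth_pairs = truth.target_pairs()
    mr_set = set(truth.mrs)
    predicted: set[tuple[str, str]] = set()
    mode_hits = 0
    mode_total = 0
    for reg in network.filtered_regulons:
        if reg.tf not in mr_set:
            continue
        for g, (mode, _) in reg.targets.items():
            predicted.add((reg.tf, g))
            if (reg.tf, g) in truth_pairs:
                mode_total += 1
                planted = 1 if truth.regulons[reg.tf][g] > 0 else -1
                mode_hits += int(mode == planted)
    tp = len(predicted & truth_pairs)
    precision = tp / len(predicted) if predicted else 0.0
    recall = tp / len(truth_pairs) if truth_pairs else 0.0
    return {
        "precision": precision,
        "recall": recall,
        "mode_agreement": mode_hits / mode_total if mode_total else float("nan"),
        "n_predicted": float(len(predicted)),
        "n_truth": float(len(truth_pairs)),
    }


def _activity_fidelity(act: ActivityMatrix, cohort, truth) -> dict:
    """Correlation of dES with the planted activities, per MR."""
    corr = {}
    for m in truth.mrs:
        if m in act.des.index:
            a = cohort.activities.loc[m].to_numpy()
            d = act.des.loc[m].to_numpy()
            if np.isfinite(d).all() and d.std() > 0:
                corr[m] = float(np.corrcoef(a, d)[0, 1])
    a_rows = [m for m in truth.cluster_members("A") if m in act.des.index]
    b_rows = [m for m in truth.cluster_members("B") if m in act.des.index]
    ab = float("nan")
    if a_rows and b_rows:
        ab = float(
            np.corrcoef(
                act.des.loc[a_rows].mean(axis=0), act.des.loc[b_rows].mean(axis=0)
            )[0, 1]
        )
    partition_ok = float("nan")
    mr_rows = [m for m in truth.mrs if m in act.des.index]
    if len(mr_rows) == len(truth.mrs):
        tree = cluster_activity(act.des.loc[mr_rows], k=2)
        planted = [set(truth.cluster_members("A")), set(truth.cluster_members("B"))]
        found = tree.partition()
        partition_ok = float(
            found == planted or found == planted[::-1]
        )
    return {
        "activity_truth_correlation": corr,
        "cluster_ab_correlation": ab,
        "cluster_partition_recovered": partition_ok,
    }


SKIPPABLE_STAGES = frozenset({"activity", "association", "survival", "methylation"})


def run_pipeline(config: PipelineConfig, outdir=None, skip=()) -> dict:
    """Execute the full analysis DAG; deterministic for a fixed config.

    Returns the run report (a JSON-serializable dict). When ``outdir`` is
    given, stage outputs are written beneath it in the pipeline's text
    formats and the report lists their relative paths. ``skip`` names tail
    stages to omit (any of ``SKIPPABLE_STAGES``); the simulation, network
    and MRA stages always run because everything downstream consumes them.
    Because every stage is seeded deterministically, "resuming" a run is
    simply rerunning with the same config — results are bit-identical.
    """
    skip = set(skip)
    unknown = skip - SKIPPABLE_STAGES
    if unknown:
        raise ValueError(
            f"cannot skip {sorted(unknown)}; skippable: {sorted(SKIPPABLE_STAGES)}"
        )
    cfg = config
    seeds = _stage_seeds(cfg.seed)
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    report: dict = {
        "config": cfg.to_dict(),
        "config_hash": hashlib.sha256(
            json.dumps(cfg.to_dict(), sort_keys=True).encode()
        ).hexdigest(),
        "stages": {},
    }

    # --- simulate ---------------------------------------------------------
    truth = generate_truth(cfg.truth_config(seeds[0]))
    cohort1 = simulate_cohort(
        truth, cfg.n_cohort1, activity_shift=0.0, seed=seeds[1],
        activity_coupling=cfg.activity_coupling, label="c1",
    )
    cohort2 = simulate_cohort(
        truth, cfg.n_cohort2, activity_shift=0.0, seed=seeds[2],
        activity_coupling=cfg.activity_coupling, label="c2",
    )
    case = simulate_cohort(
        truth, cfg.n_case, activity_shift=cfg.activity_shift, seed=seeds[3],
        activity_coupling=cfg.activity_coupling, label="es",
    )
    origin1 = simulate_origin_cohort(truth, cfg.n_origin, seed=seeds[4], label="msc")
    origin2 = simulate_origin_cohort(truth, cfg.n_origin, seed=seeds[5], label="ncc")
    cohort3 = simulate_cohort(
        truth, cfg.n_survival_cohort, activity_shift=0.0, seed=seeds[6],
        activity_coupling=cfg.activity_coupling, label="c3",
    )
    report["stages"]["simulate"] = {
        "mrs": truth.mrs,
        "clusters": truth.cluster_of,
        "decoys": truth.non_mr_tfs,
        "cohort_sizes": {
            "cohort1": cfg.n_cohort1, "cohort2": cfg.n_cohort2,
            "survival_cohort": cfg.n_survival_cohort,
            "case": cfg.n_case, "origin": cfg.n_origin,
        },
    }

    # --- networks ---------------------------------------------------------
    networks: dict[str, RegulatoryNetwork] = {}
    recovery = {}
    for name, cohort, s in (
        ("network1", cohort1, seeds[7]),
        ("network2", cohort2, seeds[8]),
    ):
        net = infer_network(
            cohort.expression, truth.tf_ids,
            n_bins=cfg.n_bins, n_perm=cfg.n_perm, alpha=cfg.edge_alpha,
            dpi_eps=cfg.dpi_eps, min_size=cfg.min_size, seed=s,
        )
        networks[name] = net
        recovery[name] = evaluate_recovery(net, truth)
    report["stages"]["networks"] = {
        name: {
            "n_regulons_total": len(net.regulons),
            "n_regulons_filtered": len(net.filtered_regulons),
            "sizes": net.sizes(),
            "recovery": recovery[name],
            "params": net.params,
        }
        for name, net in networks.items()
    }

    # --- signatures -------------------------------------------------------
    sig1 = differential_expression(case.expression, origin1.expression,
                                   alpha=cfg.de_alpha, name="sig_msc")
    sig2 = differential_expression(case.expression, origin2.expression,
                                   alpha=cfg.de_alpha, name="sig_ncc")
    report["stages"]["signatures"] = {
        s.name: {"n_genes": len(s.genes)} for s in (sig1, sig2)
    }

    # --- MRA + consensus --------------------------------------------------
    mras = [
        run_mra(networks[n], s, alpha=cfg.mra_alpha, network_id=n)
        for n in ("network1", "network2")
        for s in (sig1, sig2)
    ]
    cons = consensus_mrs(mras)
    report["stages"]["mra"] = {
        f"{m.network_id}|{m.signature_id}": sorted(m.mrs) for m in mras
    }
    report["stages"]["consensus"] = {
        "mrs": sorted(cons.consensus),
        "matches_planted": sorted(cons.consensus) == sorted(truth.mrs),
    }

    # --- activity ---------------------------------------------------------
    if "activity" in skip and "survival" not in skip:
        raise ValueError("the survival stage consumes activity; skip both")
    act1 = act2 = act3 = None
    if "activity" not in skip:
        act1 = regulon_activity_matrix(zscore_transform(cohort1.expression), networks["network1"])
        act2 = regulon_activity_matrix(zscore_transform(cohort2.expression), networks["network2"])
        # cohort 3 is too small for inference; project network 1's regulons
        act3 = regulon_activity_matrix(zscore_transform(cohort3.expression), networks["network1"])
        report["stages"]["activity"] = {
            "cohort1": _activity_fidelity(act1, cohort1, truth),
            "cohort2": _activity_fidelity(act2, cohort2, truth),
            "cohort3_projected": _activity_fidelity(act3, cohort3, truth),
        }
    else:
        report["stages"]["activity"] = "skipped"

    # --- association maps -------------------------------------------------
    assoc = {}
    if "association" not in skip:
        assoc = {
            name: association_map(net, min_shared=cfg.min_shared)
            for name, net in networks.items()
        }
        report["stages"]["association"] = {
            name: {
                "n_pairs": len(df),
                "labels": df["label"].value_counts().to_dict(),
            }
            for name, df in assoc.items()
        }
    else:
        report["stages"]["association"] = "skipped"

    # --- survival ---------------------------------------------------------
    surv_report = {}
    screens = {}
    pairs = () if "survival" in skip else (
        ("cohort2", cohort2, act2, seeds[9]),
        ("cohort3_projected", cohort3, act3, seeds[10]),
    )
    for name, cohort, act, s in pairs:
        records = simulate_survival(
            cohort, truth, effect_a=cfg.effect_a, effect_b=cfg.effect_b,
            baseline_scale=cfg.baseline_scale, censor_rate=cfg.censor_rate, seed=s,
        )
        screen = survival_screen(act, records, alpha=cfg.survival_alpha)
        screens[name] = (records, screen)
        expected = {
            m: ("good" if truth.cluster_of.get(m) == "A" else "bad")
            for m in truth.mrs
        }
        rows = screen.set_index("regulon")
        checked = [m for m in truth.mrs if m in rows.index]
        correct = [m for m in checked if rows.loc[m, "direction"] == expected[m]]
        surv_report[name] = {
            "screen": screen.to_dict(orient="records"),
            "direction_accuracy": len(correct) / len(checked) if checked else float("nan"),
            "significant_fraction": float(
                rows.loc[checked, "significant"].mean()
            ) if checked else float("nan"),
        }
    report["stages"]["survival"] = surv_report if "survival" not in skip else "skipped"

    # --- methylation ------------------------------------------------------
    meth = None
    dm = None
    dm_set = set()
    if "methylation" not in skip:
        meth = simulate_methylation(
            truth, dm_regulons=set(truth.mrs),
            n_case=cfg.meth_n_case, n_ctrl=cfg.meth_n_ctrl,
            delta_beta=cfg.delta_beta, probes_per_gene=cfg.probes_per_gene,
            noise_sd=cfg.meth_noise_sd, seed=seeds[11],
        )
        dm = dm_probe_test(
            meth.beta[meth.case_samples], meth.beta[meth.control_samples],
            threshold=cfg.meth_threshold,
        )
        dm_set = dm_genes(dm, meth.probe_map)
        meth_report = {"n_dm_probes": int(dm["is_dm"].sum()),
                       "n_dm_genes": len(dm_set)}
        for name, net in networks.items():
            res = regulon_dm_enrichment(net, dm_set, meth.probe_map,
                                        threshold=cfg.meth_threshold)
            meth_report[name] = {
                "enriched": sorted(r.regulon for r in res if r.is_enriched),
                "n_tested": len(res),
            }
        report["stages"]["methylation"] = meth_report
    else:
        report["stages"]["methylation"] = "skipped"

    report = _jsonable(report)

    # --- outputs ----------------------------------------------------------
    if out is not None:
        paths = {}
        for label, cohort in (
            ("cohort1", cohort1), ("cohort2", cohort2), ("cohort3", cohort3),
            ("case", case), ("origin1", origin1), ("origin2", origin2),
        ):
            p = f"{label}_expression.tsv"
            rio.write_expression(cohort.expression, out / p)
            paths[label] = p
        rio.write_truth_json(truth, out / "truth.json")
        for name, net in networks.items():
            rio.write_network_edges(net, out / f"{name}_edges.tsv")
            rio.write_gene_sets(
                {r.tf: set(r.targets) for r in net.filtered_regulons},
                out / f"{name}_regulons.gmt",
            )
            rio.write_graphml(net, out / f"{name}.graphml")
            if name in assoc:
                assoc[name].to_csv(out / f"{name}_association.tsv",
                                   sep="\t", index=False)
        for sig in (sig1, sig2):
            rio.write_gene_list(sig.genes, out / f"{sig.name}.txt")
        for name, act in (("cohort1", act1), ("cohort2", act2), ("cohort3", act3)):
            if act is not None:
                act.des.to_csv(out / f"{name}_activity.tsv", sep="\t",
                               index_label="regulon", float_format="%.17g")
        for name, (records, screen) in screens.items():
            rio.write_survival(records, out / f"{name}_survival.csv")
            screen.to_csv(out / f"{name}_survival_screen.tsv", sep="\t", index=False)
        if meth is not None:
            rio.write_beta(meth.beta, out / "methylation_beta.tsv")
            rio.write_probe_map(meth.probe_map, out / "probe_map.tsv")
            dm.to_csv(out / "dm_probes.tsv", sep="\t", index=False)
            rio.write_gene_list(dm_set, out / "dm_genes.txt")
            for name, net in networks.items():
                enrichment_frame(
                    regulon_dm_enrichment(net, dm_set, meth.probe_map,
                                          threshold=cfg.meth_threshold)
                ).to_csv(out / f"{name}_dm_enrichment.tsv", sep="\t", index=False)
        report["outputs"] = paths
        (out / "run_report.json").write_text(
            json.dumps(report, indent=1, sort_keys=True)
        )
    return report
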