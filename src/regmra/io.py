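"""Readers and writers for the pipeline's plain-text formats.

Expression and beta matrices travel as TSV with the gene/probe id in the
first column; survival tables as CSV (sample,time,event); regulons as TSV
edge lists, GMT gene-set files, or GraphML; the planted truth as JSON.
Write-then-read round-trips reproduce objects to full precision.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .network import Regulon, RegulatoryNetwork
from .survival import SurvivalRecord, frame_to_records, records_to_frame

__all__ = [
    "read_expression", "write_expression",
    "read_survival", "write_survival",
    "read_beta", "write_beta",
    "read_probe_map", "write_probe_map",
    "read_gene_sets", "write_gene_sets",
    "read_network_edges", "write_network_edges",
    "write_graphml",
    "read_gene_list", "write_gene_list",
    "write_truth_json",
]

_FLOAT_FMT = "%.17g"


def _check_unique(index: pd.Index, what: str, path) -> None:
    if index.has_duplicates:
        dup = index[index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate {what} ids in {path}: {dup[:5]}")


def read_expression(path) -> pd.DataFrame:
    """Gene x sample log2 TSV; first column holds gene ids."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    _check_unique(df.index, "gene", path)
    if df.isna().to_numpy().any():
        bad = df.index[df.isna().any(axis=1)].tolist()
        raise ValueError(f"NA cells in {path}, e.g. gene(s) {bad[:5]}")
    return df


def write_expression(expr: pd.DataFrame, path) -> None:
    expr.to_csv(path, sep="\t", index_label="gene", float_format=_FLOAT_FMT)


def read_survival(path) -> list[SurvivalRecord]:
    """CSV with header sample,time,event."""
    df = pd.read_csv(path)
    missing = {"sample", "time", "event"} - set(df.columns)
    if missing:
        raise ValueError(f"{path} lacks columns: {sorted(missing)}")
    return frame_to_records(df)


def write_survival(records: list[SurvivalRecord], path) -> None:
    records_to_frame(records).to_csv(path, index=False, float_format=_FLOAT_FMT)


read_beta = read_expression  # probes x samples TSV shares the layout


def write_beta(beta: pd.DataFrame, path) -> None:
    beta.to_csv(path, sep="\t", index_label="probe", float_format=_FLOAT_FMT)


def read_probe_map(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t")
    if list(df.columns[:2]) != ["probe", "gene"]:
        raise ValueError(f"{path} must have columns probe, gene")
    _check_unique(pd.Index(df["probe"]), "probe", path)
    return pd.Series(df["gene"].to_numpy(), index=df["probe"], name="gene")


def write_probe_map(probe_map: pd.Series, path) -> None:
    pd.DataFrame({"probe": probe_map.index, "gene": probe_map.to_numpy()}).to_csv(
        path, sep="\t", index=False
    )


def read_gene_sets(path) -> dict[str, set[str]]:
    """GMT: name <tab> description <tab> member1 <tab> member2 ..."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed GMT line {lineno} in {path}: {line!r}")
            name = parts[0]
            if name in sets:
                raise ValueError(f"duplicate set {name!r} at GMT line {lineno}")
            sets[name] = {g for g in parts[2:] if g}
    return sets


def write_gene_sets(sets: dict[str, set[str]], path, description: str = "regmra") -> None:
    with open(path, "w") as fh:
        for name in sorted(sets):
            members = "\t".join(sorted(sets[name]))
            fh.write(f"{name}\t{description}\t{members}\n")


def write_network_edges(network: RegulatoryNetwork, path) -> None:
    """TSV edge list: tf, target, mi, mode."""
    network.to_edge_frame()[["tf", "target", "mi", "mode"]].to_csv(
        path, sep="\t", index=False, float_format=_FLOAT_FMT
    )


def read_network_edges(path, universe=None, min_size: int = 15) -> RegulatoryNetwork:
    df = pd.read_csv(path, sep="\t")
    missing = {"tf", "target", "mi", "mode"} - set(df.columns)
    if missing:
        raise ValueError(f"{path} lacks columns: {sorted(missing)}")
    regulons = [
        Regulon(
            tf=tf,
            targets={
                t: (int(m), float(w))
                for t, m, w in grp[["target", "mode", "mi"]].itertuples(index=False)
            },
        )
        for tf, grp in df.groupby("tf", sort=True)
    ]
    if universe is None:
        universe = sorted(set(df["tf"]) | set(df["target"]))
    return RegulatoryNetwork(
        regulons=regulons, universe=list(universe), min_size=min_size,
        params={"source": str(path)},
    )


def write_graphml(network: RegulatoryNetwork, path) -> None:
    g = nx.DiGraph()
    for reg in network.regulons:
        g.add_node(reg.tf, kind="tf", regulon_size=reg.size)
        for target, (mode, mi) in reg.targets.items():
            if target not in g:
                g.add_node(target, kind="gene")
            g.add_edge(reg.tf, target, mode=mode, mi=mi)
    nx.write_graphml(g, path)


def read_gene_list(path) -> list[str]:
    """One gene per line; a two-column (gene, direction) TSV is also accepted."""
    genes = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line:
                genes.append(line.split("\t")[0])
    return genes


def write_gene_list(genes, path) -> None:
    with open(path, "w") as fh:
        for g in sorted(genes):
            fh.write(f"{g}\n")


def write_truth_json(truth, path) -> None:
    payload = {
        "config": dataclasses.asdict(truth.config),
        "regulons": {tf: dict(sorted(t.items())) for tf, t in truth.regulons.items()},
        "cluster_of": truth.cluster_of,
        "non_mr_tfs": truth.non_mr_tfs,
        "universe": truth.universe,
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))
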