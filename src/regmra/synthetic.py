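"""Synthetic cohorts with a planted two-cluster master-regulator structure.

The generator plants the statistical structure the downstream analysis is
designed to detect: a small set of master-regulator TFs partitioned into two
clusters (default sizes 2 and 5) that are within-cluster agonists and
between-cluster antagonists. A fraction of each regulon's targets is shared
across clusters and carries opposite regulatory signs on the two sides —
the agonist/antagonist fingerprint.

Expression is linear-Gaussian on the log2 scale:

    x_gs = sum_t w_tg * a_ts + eps,   eps ~ N(0, noise_sd)

where ``a_ts`` are latent per-sample TF activities. Each TF's own expression
is its activity plus noise, so TF–target dependence is visible to MI-based
inference. Cluster antagonism is induced by coupling MR activities to one
shared latent axis with opposite loadings per cluster. Survival times follow
an exponential proportional-hazards model on the mean cluster activities,
and methylation beta values carry a planted case/control shift concentrated
in the regulon targets.

All randomness flows from explicit integer seeds through
``numpy.random.default_rng``; the same seed reproduces every object
bit-identically.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .network import Regulon, RegulatoryNetwork
from .survival import SurvivalRecord

logger = logging.getLogger("regmra")

__all__ = [
    "TruthConfig",
    "SyntheticTruth",
    "CohortSim",
    "MethylationSim",
    "generate_truth",
    "truth_network",
    "simulate_cohort",
    "simulate_origin_cohort",
    "simulate_survival",
    "simulate_methylation",
    "simulate_chain",
]


@dataclass(frozen=True)
class TruthConfig:
    """Ground-truth network configuration.

    Defaults are the package's reference study conditions: 10 TFs of which
    7 are planted master regulators in clusters of 2 and 5, 500 non-TF
    genes, 40 targets per planted regulon with 30% shared across clusters
    (opposite signs), unit regulatory weights and unit residual noise.
    Non-MR TFs receive small decoy regulons below the size-15 cut so the
    size filter and MRA specificity are both exercised.
    """

    n_tfs: int = 10
    n_mr: int = 7
    cluster_sizes: tuple[int, int] = (2, 5)
    n_genes: int = 500
    targets_per_regulon: int = 40
    cross_shared_fraction: float = 0.3
    weight_magnitude: float = 2.0
    noise_sd: float = 1.0
    decoy_targets: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if sum(self.cluster_sizes) != self.n_mr:
            raise ValueError(
                f"cluster_sizes {self.cluster_sizes} must sum to n_mr={self.n_mr}"
            )
        if self.n_mr > self.n_tfs:
            raise ValueError("n_mr cannot exceed n_tfs")
        if self.targets_per_regulon < 15:
            raise ValueError("targets_per_regulon must be >= 15 (size filter)")
        if self.targets_per_regulon > self.n_genes:
            raise ValueError("targets_per_regulon exceeds n_genes")
        if not 0.0 <= self.cross_shared_fraction <= 1.0:
            raise ValueError("cross_shared_fraction must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0 <= self.decoy_targets < 15:
            raise ValueError("decoy regulons must stay below the size-15 cut")
        n_shared = int(round(self.cross_shared_fraction * self.targets_per_regulon))
        need = (
            n_shared
            + self.n_mr * (self.targets_per_regulon - n_shared)
            + (self.n_tfs - self.n_mr) * self.decoy_targets
        )
        if need > self.n_genes:
            raise ValueError(
                f"configuration needs {need} distinct target genes but only "
                f"{self.n_genes} are available"
            )


@dataclass
class SyntheticTruth:
    """Planted regulons and cluster memberships.

    ``regulons`` maps TF -> {target -> signed weight}; ``cluster_of`` maps
    each planted MR to 'A' or 'B'. For any target shared by an MR in cluster
    A and one in cluster B, the planted weights have opposite signs; within
    a cluster shared targets have equal signs.
    """

    config: TruthConfig
    regulons: dict[str, dict[str, float]]
    cluster_of: dict[str, str]
    non_mr_tfs: list[str]
    universe: list[str]

    @property
    def mrs(self) -> list[str]:
        return list(self.cluster_of)

    def cluster_members(self, cluster: str) -> list[str]:
        return [m for m, c in self.cluster_of.items() if c == cluster]

    @property
    def tf_ids(self) -> list[str]:
        return self.mrs + self.non_mr_tfs

    def target_pairs(self) -> set[tuple[str, str]]:
        """(MR, target) pairs of the planted master-regulator regulons."""
        return {(m, g) for m in self.mrs for g in self.regulons[m]}


@dataclass
class CohortSim:
    """A simulated expression cohort with its latent MR activities."""

    expression: pd.DataFrame          # (n_tfs + n_genes) x n_samples
    activities: pd.DataFrame          # n_mr x n_samples latent a_ts
    survival: list[SurvivalRecord] | None
    label: str


@dataclass
class MethylationSim:
    """Simulated beta-value methylation with planted differential genes."""

    beta: pd.DataFrame                # probes x (case + control) samples
    probe_map: pd.Series              # probe -> gene
    dm_truth: set[str]
    case_samples: list[str]
    control_samples: list[str]


# ---------------------------------------------------------------------------
# Truth generation
# ---------------------------------------------------------------------------

def generate_truth(config: TruthConfig) -> SyntheticTruth:
    """Plant the two-cluster agonist/antagonist regulon structure.

    Every MR regulon is the union of one cross-cluster shared target pool
    (size ``round(cross_shared_fraction * targets_per_regulon)``, opposite
    signs between clusters, equal signs within) and a private disjoint
    remainder with random signs. Decoy TFs receive small disjoint regulons.
    """
    rng = np.random.default_rng(config.seed)
    tf_ids = [f"TF{i + 1:02d}" for i in range(config.n_tfs)]
    mrs = tf_ids[: config.n_mr]
    decoys = tf_ids[config.n_mr:]
    n_a = config.cluster_sizes[0]
    cluster_of = {m: ("A" if i < n_a else "B") for i, m in enumerate(mrs)}
    genes = [f"G{i + 1:04d}" for i in range(config.n_genes)]

    tpr = config.targets_per_regulon
    n_shared = int(round(config.cross_shared_fraction * tpr))
    order = rng.permutation(config.n_genes)
    cursor = 0

    shared = [genes[i] for i in order[cursor:cursor + n_shared]]
    cursor += n_shared
    shared_sign_a = rng.choice([-1.0, 1.0], size=n_shared)

    w = config.weight_magnitude
    regulons: dict[str, dict[str, float]] = {}
    for m in mrs:
        sign_flip = 1.0 if cluster_of[m] == "A" else -1.0
        targets = {g: sign_flip * s * w for g, s in zip(shared, shared_sign_a)}
        n_priv = tpr - n_shared
        priv = [genes[i] for i in order[cursor:cursor + n_priv]]
        cursor += n_priv
        priv_signs = rng.choice([-1.0, 1.0], size=n_priv)
        targets.update({g: s * w for g, s in zip(priv, priv_signs)})
        regulons[m] = targets
    for d in decoys:
        priv = [genes[i] for i in order[cursor:cursor + config.decoy_targets]]
        cursor += config.decoy_targets
        signs = rng.choice([-1.0, 1.0], size=config.decoy_targets)
        regulons[d] = {g: s * w for g, s in zip(priv, signs)}

    return SyntheticTruth(
        config=config,
        regulons=regulons,
        cluster_of=cluster_of,
        non_mr_tfs=decoys,
        universe=tf_ids + genes,
    )


def truth_network(truth: SyntheticTruth, min_size: int = 15) -> RegulatoryNetwork:
    """The planted truth expressed as a RegulatoryNetwork (noise-free modes)."""
    regs = [
        Regulon(tf=tf, targets={g: (1 if w > 0 else -1, abs(w)) for g, w in tg.items()})
        for tf, tg in truth.regulons.items()
    ]
    return RegulatoryNetwork(
        regulons=regs,
        universe=list(truth.universe),
        min_size=min_size,
        params={"source": "planted-truth", "min_size": min_size},
    )


# ---------------------------------------------------------------------------
# Expression cohorts
# ---------------------------------------------------------------------------

def _normalise_shift(activity_shift) -> tuple[float, float]:
    """Scalar s means an antagonistic (+s, -s) per-cluster shift."""
    if np.isscalar(activity_shift):
        s = float(activity_shift)
        return (s, -s)
    a, b = activity_shift
    return (float(a), float(b))


def simulate_cohort(
    truth: SyntheticTruth,
    n_samples: int,
    noise_sd: float | None = None,
    activity_shift=0.0,
    seed: int = 0,
    activity_coupling: float = 0.6,
    tf_noise_sd: float = 0.3,
    label: str = "C",
) -> CohortSim:
    """Draw one expression cohort from the planted truth.

    MR activities are standard normal with a per-cluster mean shift and a
    shared latent axis: cluster A loads +coupling on the axis, cluster B
    loads -coupling, producing the antagonistic activity pattern. Decoy TF
    activities are independent. Expression follows the linear model; genes
    targeted by no TF are pure noise. A TF's own transcript reads out its
    activity with a smaller observation noise (``tf_noise_sd``) than the
    residual target noise — the regulator's expression is the proxy the
    inference stage conditions on, so its fidelity is a property of the
    planted model, not of the measurement of its targets.
    """
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    cfg = truth.config
    sd = cfg.noise_sd if noise_sd is None else float(noise_sd)
    if sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if not 0.0 <= activity_coupling < 1.0:
        raise ValueError("activity_coupling must be in [0, 1)")
    if tf_noise_sd < 0:
        raise ValueError("tf_noise_sd must be >= 0")
    shift_a, shift_b = _normalise_shift(activity_shift)

    rng = np.random.default_rng(seed)
    n = n_samples
    mrs = truth.mrs
    axis = rng.standard_normal(n)
    resid = np.sqrt(1.0 - activity_coupling**2)
    act = np.empty((len(mrs), n))
    for i, m in enumerate(mrs):
        if truth.cluster_of[m] == "A":
            act[i] = shift_a + activity_coupling * axis + resid * rng.standard_normal(n)
        else:
            act[i] = shift_b - activity_coupling * axis + resid * rng.standard_normal(n)
    decoy_act = rng.standard_normal((len(truth.non_mr_tfs), n))

    tf_ids = truth.tf_ids
    a_all = np.vstack([act, decoy_act]) if len(truth.non_mr_tfs) else act
    genes = [g for g in truth.universe if g not in set(tf_ids)]
    gene_loc = {g: i for i, g in enumerate(genes)}
    tf_loc = {t: i for i, t in enumerate(tf_ids)}
    weights = np.zeros((len(genes), len(tf_ids)))
    for tf, targets in truth.regulons.items():
        for g, w in targets.items():
            weights[gene_loc[g], tf_loc[tf]] = w

    noise = rng.standard_normal((len(tf_ids) + len(genes), n))
    x_tfs = a_all + tf_noise_sd * noise[: len(tf_ids)]
    x_genes = weights @ a_all + sd * noise[len(tf_ids):]
    samples = [f"{label}S{i + 1:03d}" for i in range(n)]
    expr = pd.DataFrame(
        np.vstack([x_tfs, x_genes]), index=tf_ids + genes, columns=samples
    )
    activities = pd.DataFrame(act, index=mrs, columns=samples)
    return CohortSim(expression=expr, activities=activities, survival=None, label=label)


def simulate_origin_cohort(
    truth: SyntheticTruth,
    n_samples: int,
    noise_sd: float | None = None,
    seed: int = 0,
    label: str = "O",
) -> CohortSim:
    """A putative cell-of-origin cohort: MR activities at baseline zero.

    Differential expression against a shifted case cohort then flags the
    planted targets. Accepts very small groups (n >= 2), matching the
    reference two-versus-three contrast design.
    """
    return simulate_cohort(
        truth, n_samples, noise_sd=noise_sd, activity_shift=0.0, seed=seed, label=label
    )


# ---------------------------------------------------------------------------
# Survival
# ---------------------------------------------------------------------------

def _censor_horizon(hazard: np.ndarray, censor_rate: float) -> float:
    """Horizon tau of U(0, tau) censoring achieving the requested rate.

    For an exponential event time with hazard h and C ~ U(0, tau) the
    censoring probability is (1 - exp(-h tau)) / (h tau); the mean over
    samples is monotone decreasing in tau, so bisection applies.
    """

    def rate(tau: float) -> float:
        x = hazard * tau
        return float(np.mean((1.0 - np.exp(-x)) / x))

    lo, hi = 1e-9, 1.0
    while rate(hi) > censor_rate:
        hi *= 2.0
        if hi > 1e12:
            break
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if rate(mid) > censor_rate:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def simulate_survival(
    cohort: CohortSim,
    truth: SyntheticTruth,
    effect_a: float = -1.0,
    effect_b: float = 1.0,
    baseline_scale: float = 1.0,
    censor_rate: float = 0.2,
    seed: int = 0,
) -> list[SurvivalRecord]:
    """Exponential proportional-hazards survival driven by cluster activity.

    h_s = (1 / baseline_scale) * exp(effect_a * mean_A(s) + effect_b * mean_B(s));
    negative effects are protective. Censoring is independent uniform on
    (0, tau) with tau calibrated so the expected censored fraction equals
    ``censor_rate``.
    """
    if baseline_scale <= 0:
        raise ValueError("baseline_scale must be positive")
    if not 0.0 <= censor_rate < 1.0:
        raise ValueError("censor_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    a_members = truth.cluster_members("A")
    b_members = truth.cluster_members("B")
    mean_a = cohort.activities.loc[a_members].mean(axis=0).to_numpy()
    mean_b = cohort.activities.loc[b_members].mean(axis=0).to_numpy()
    hazard = np.exp(effect_a * mean_a + effect_b * mean_b) / baseline_scale
    times = rng.exponential(1.0 / hazard)
    times = np.maximum(times, 1e-12)
    if censor_rate > 0:
        tau = _censor_horizon(hazard, censor_rate)
        cens = rng.uniform(0.0, tau, size=times.size)
        observed = np.minimum(times, cens)
        event = (times <= cens).astype(int)
    else:
        observed = times
        event = np.ones(times.size, dtype=int)
    records = [
        SurvivalRecord(sample=s, time=float(t), event=int(e))
        for s, t, e in zip(cohort.expression.columns, observed, event)
    ]
    cohort.survival = records
    return records


# ---------------------------------------------------------------------------
# Methylation
# ---------------------------------------------------------------------------

def simulate_methylation(
    truth: SyntheticTruth,
    dm_regulons: set[str] | None = None,
    n_case: int = 15,
    n_ctrl: int = 9,
    delta_beta: float = 0.4,
    probes_per_gene: int = 2,
    noise_sd: float = 0.05,
    seed: int = 0,
) -> MethylationSim:
    """Beta-value methylation with planted case/control differences.

    Probes of genes targeted by ``dm_regulons`` (default: all planted MRs)
    shift by +/- ``delta_beta`` in cases; every other probe shares one
    baseline distribution (uniform 0.2–0.8 plus Gaussian noise). Betas are
    clipped to [0, 1]. The default 15-case / 9-control design follows the
    reference methylation comparison.
    """
    if n_case < 2 or n_ctrl < 2:
        raise ValueError("need at least 2 case and 2 control samples")
    if not 0.0 <= delta_beta < 1.0:
        raise ValueError("delta_beta must be in [0, 1)")
    if probes_per_gene < 1:
        raise ValueError("probes_per_gene must be >= 1")
    if dm_regulons is None:
        dm_regulons = set(truth.mrs)
    unknown = dm_regulons - set(truth.regulons)
    if unknown:
        raise ValueError(f"unknown regulons: {sorted(unknown)}")

    rng = np.random.default_rng(seed)
    genes = list(truth.universe)
    dm_genes: set[str] = set()
    if delta_beta > 0:
        for tf in sorted(dm_regulons):
            dm_genes.update(truth.regulons[tf])

    probes = [f"{g}_p{j + 1}" for g in genes for j in range(probes_per_gene)]
    probe_gene = [g for g in genes for _ in range(probes_per_gene)]
    n_probes = len(probes)
    baseline = rng.uniform(0.2, 0.8, size=n_probes)
    gene_sign = {g: s for g, s in zip(genes, rng.choice([-1.0, 1.0], size=len(genes)))}
    shift = np.array(
        [gene_sign[g] * delta_beta if g in dm_genes else 0.0 for g in probe_gene]
    )

    case = baseline[:, None] + shift[:, None] + rng.normal(0, noise_sd, (n_probes, n_case))
    ctrl = baseline[:, None] + rng.normal(0, noise_sd, (n_probes, n_ctrl))
    case_samples = [f"case{i + 1:02d}" for i in range(n_case)]
    ctrl_samples = [f"ctrl{i + 1:02d}" for i in range(n_ctrl)]
    beta = pd.DataFrame(
        np.clip(np.hstack([case, ctrl]), 0.0, 1.0),
        index=probes,
        columns=case_samples + ctrl_samples,
    )
    return MethylationSim(
        beta=beta,
        probe_map=pd.Series(probe_gene, index=probes, name="gene"),
        dm_truth=dm_genes,
        case_samples=case_samples,
        control_samples=ctrl_samples,
    )


# ---------------------------------------------------------------------------
# Auxiliary constructions for inference soundness checks
# ---------------------------------------------------------------------------

def simulate_chain(
    n_samples: int = 300,
    n_targets: int = 10,
    step_noise_sd: float = 0.3,
    seed: int = 0,
) -> pd.DataFrame:
    """A regulatory chain TF1 -> TF2 -> targets.

    TF2 tracks TF1 with a small per-step noise, and every target tracks TF2
    likewise, so TF1–target dependence is strictly indirect: the weakest MI
    of every (TF1, TF2, target) triplet is always the TF1–target edge, the
    configuration the data-processing inequality is meant to prune.
    """
    rng = np.random.default_rng(seed)
    a = rng.standard_normal(n_samples)
    tf2 = a + step_noise_sd * rng.standard_normal(n_samples)
    rows = {"TF1": a, "TF2": tf2}
    for i in range(n_targets):
        rows[f"G{i + 1:03d}"] = tf2 + step_noise_sd * rng.standard_normal(n_samples)
    return pd.DataFrame(
        rows, index=[f"S{i + 1:03d}" for i in range(n_samples)]
    ).T
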