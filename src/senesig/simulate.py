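"""Synthetic probe-level expression data and a connectivity-style database.

The expression generator emulates an Illumina HT-12-style two-condition
study: one breast-carcinoma line driven into accelerated senescence by
irradiation (condition A) and one by ectopic p21 expression (condition B),
each with its own untreated control arm. A planted shared up/down gene
signature (same sign in both conditions) plus condition-specific DEGs sit
on a log2-additive Gaussian background; multi-probe genes share the gene
effect with probe-level jitter so probe-to-gene collapsing is non-trivial.

The instance generator emulates a cmap-build02-like database: ~10^3
perturbagens with a handful of instances each, stored as full probe
rankings, where a chosen subset of perturbagens is rank-biased toward the
planted signature (up probes near the top, down probes near the bottom).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError, MissingAnnotationError
from .matrix import ExpressionMatrix
from .connectivity import InstanceDatabase

__all__ = ["SimulationConfig", "InstanceDbConfig", "GroundTruth",
           "generate_paired_dataset", "generate_instance_db",
           "write_ground_truth", "read_ground_truth"]


@dataclass
class SimulationConfig:
    """Study-design parameters for the paired expression simulation.

    Defaults mirror the study scale: a shared signature of 378 up / 391
    down genes, condition-specific DEG pools sized so each condition's
    total DEG count lands near 1.5-1.7k genes, |log2FC| 1.5 effects on a
    noise SD of 0.5, 4 arrays per arm, and a fifth of probes undetected
    so ~16k probes survive the detection filter.
    """

    n_genes: int = 10_000
    probes_per_gene: tuple[int, int] = (1, 3)   # inclusive uniform range
    n_samples_per_arm: int = 4
    n_shared_up: int = 378
    n_shared_down: int = 391
    n_specific_A: int = 911
    n_specific_B: int = 754
    effect_log2fc: float = 1.5
    noise_sd: float = 0.5
    detection_fail_rate: float = 0.2
    baseline_mean: float = 8.0
    baseline_sd: float = 1.5
    seed: int = 0

    def validate(self) -> None:
        for f in ("n_genes", "n_samples_per_arm", "n_shared_up", "n_shared_down",
                  "n_specific_A", "n_specific_B"):
            if getattr(self, f) < 0:
                raise ConfigurationError(f"{f} must be non-negative")
        if self.n_samples_per_arm < 2:
            raise ConfigurationError("n_samples_per_arm must be >= 2")
        planted = (self.n_shared_up + self.n_shared_down
                   + self.n_specific_A + self.n_specific_B)
        if planted > self.n_genes:
            raise ConfigurationError(
                f"n_genes: planted gene count {planted} exceeds n_genes {self.n_genes}")
        if self.noise_sd <= 0:
            raise ConfigurationError("noise_sd must be > 0")
        if self.effect_log2fc < 0:
            raise ConfigurationError("effect_log2fc must be >= 0")
        if not (0 <= self.detection_fail_rate < 1):
            raise ConfigurationError("detection_fail_rate must be in [0, 1)")
        lo, hi = self.probes_per_gene
        if not (1 <= lo <= hi):
            raise ConfigurationError("probes_per_gene must satisfy 1 <= min <= max")


@dataclass
class InstanceDbConfig:
    """Parameters for the synthetic ranked-instance database."""

    n_perturbagens: int = 1000
    instances_per_perturbagen: tuple[int, int] = (1, 10)   # inclusive uniform range
    n_probes: int | None = None     # None: use every annotated probe
    n_concordant_perturbagens: int = 20
    concordance_strength: float = 0.8
    mcf7_fraction: float = 0.6      # cell line of non-concordant instances
    seed: int = 0

    def validate(self) -> None:
        if self.n_perturbagens < 1:
            raise ConfigurationError("n_perturbagens must be >= 1")
        if self.n_concordant_perturbagens > self.n_perturbagens:
            raise ConfigurationError(
                "n_concordant_perturbagens must not exceed n_perturbagens")
        if not (0 <= self.concordance_strength <= 1):
            raise ConfigurationError("concordance_strength must be in [0, 1]")
        lo, hi = self.instances_per_perturbagen
        if not (1 <= lo <= hi):
            raise ConfigurationError(
                "instances_per_perturbagen must satisfy 1 <= min <= max")


@dataclass
class GroundTruth:
    """Planted gene sets and concordant perturbagens (the recovery oracle)."""

    shared_up: set = field(default_factory=set)
    shared_down: set = field(default_factory=set)
    specific_A: set = field(default_factory=set)
    specific_B: set = field(default_factory=set)
    concordant_perturbagens: set = field(default_factory=set)

    def __post_init__(self):
        sets = [self.shared_up, self.shared_down, self.specific_A, self.specific_B]
        for i in range(len(sets)):
            for j in range(i + 1, len(sets)):
                if sets[i] & sets[j]:
                    raise ConfigurationError("planted gene sets must be pairwise disjoint")


def generate_paired_dataset(config: SimulationConfig):
    """Simulate the two-condition study.

    Returns ``(matrix_A, matrix_B, annotation, truth)`` where each matrix
    holds the treated and control arms of one condition (samples named
    ``<arm>_ctrl_i`` / ``<arm>_trt_i``), ``annotation`` maps probe ids to
    gene symbols and ``truth`` records the planted sets.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    genes = np.array([f"GENE{i:05d}" for i in range(config.n_genes)])
    lo, hi = config.probes_per_gene
    n_probes_per_gene = rng.integers(lo, hi + 1, size=config.n_genes)
    gene_of_probe = np.repeat(np.arange(config.n_genes), n_probes_per_gene)
    n_probes = len(gene_of_probe)
    probes = np.array([f"PR{i:06d}" for i in range(n_probes)])
    annotation = pd.Series(genes[gene_of_probe], index=pd.Index(probes, name="probe_id"),
                           name="gene_symbol")

    order = rng.permutation(config.n_genes)
    cuts = np.cumsum([config.n_shared_up, config.n_shared_down,
                      config.n_specific_A, config.n_specific_B])
    shared_up = order[:cuts[0]]
    shared_down = order[cuts[0]:cuts[1]]
    spec_A = order[cuts[1]:cuts[2]]
    spec_B = order[cuts[2]:cuts[3]]

    # gene-level signed effects: +/- effect_log2fc, same sign in both
    # conditions for shared genes; the Gaussian jitter is probe-level
    gene_effect_A = np.zeros(config.n_genes)
    gene_effect_B = np.zeros(config.n_genes)
    gene_effect_A[shared_up] = gene_effect_B[shared_up] = config.effect_log2fc
    gene_effect_A[shared_down] = gene_effect_B[shared_down] = -config.effect_log2fc
    gene_effect_A[spec_A] = rng.choice([-1, 1], size=len(spec_A)) * config.effect_log2fc
    gene_effect_B[spec_B] = rng.choice([-1, 1], size=len(spec_B)) * config.effect_log2fc

    baseline = rng.normal(config.baseline_mean, config.baseline_sd, size=n_probes)

    # detection failure is a probe property (an unexpressed transcript fails in
    # every hybridization), drawn once and shared by both conditions; planted
    # genes are expressed by construction, so their probes always detect
    planted_gene = np.zeros(config.n_genes, dtype=bool)
    planted_gene[np.concatenate([shared_up, shared_down, spec_A, spec_B])] = True
    eligible = np.flatnonzero(~planted_gene[gene_of_probe])
    n_fail = min(len(eligible), int(round(config.detection_fail_rate * n_probes)))
    fail_probe = np.zeros(n_probes, dtype=bool)
    if n_fail:
        fail_probe[rng.choice(eligible, size=n_fail, replace=False)] = True

    # probe-level jitter on the planted effect is a probe property (hybridization
    # affinity), drawn once and applied wherever the probe's gene carries an effect
    probe_jitter = rng.normal(0, config.noise_sd / 2, size=n_probes)

    def probe_effects(gene_effect):
        eff = gene_effect[gene_of_probe].copy()
        planted = eff != 0
        eff[planted] += probe_jitter[planted]
        return eff

    def build_arm(arm: str, probe_eff: np.ndarray) -> ExpressionMatrix:
        n = config.n_samples_per_arm
        samples = [f"{arm}_ctrl_{i+1}" for i in range(n)] + \
                  [f"{arm}_trt_{i+1}" for i in range(n)]
        X = baseline[:, None] + rng.normal(0, config.noise_sd, size=(n_probes, 2 * n))
        X[:, n:] += probe_eff[:, None]
        detp = np.where(fail_probe[:, None],
                        rng.uniform(0.05, 1.0, size=(n_probes, 2 * n)),
                        rng.uniform(0.0, 0.05, size=(n_probes, 2 * n)))
        idx = pd.Index(probes, name="probe_id")
        return ExpressionMatrix(pd.DataFrame(X, index=idx, columns=samples),
                                pd.DataFrame(detp, index=idx, columns=samples))

    mat_A = build_arm("A", probe_effects(gene_effect_A))
    mat_B = build_arm("B", probe_effects(gene_effect_B))

    truth = GroundTruth(
        shared_up=set(genes[shared_up]), shared_down=set(genes[shared_down]),
        specific_A=set(genes[spec_A]), specific_B=set(genes[spec_B]))
    return mat_A, mat_B, annotation, truth


def generate_instance_db(config: InstanceDbConfig, truth: GroundTruth,
                         annotation: pd.Series):
    """Simulate a ranked-instance database embedding the planted signature.

    Concordant perturbagens have every instance's ranking biased so that
    probes of planted shared-up genes drift toward rank 1 and shared-down
    probes toward rank n, with magnitude ``concordance_strength``; all
    other instances are uniform random permutations. Returns
    ``(InstanceDatabase, truth)`` with ``truth.concordant_perturbagens``
    filled in.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    annotation = pd.Series(annotation)

    sig_genes = truth.shared_up | truth.shared_down
    missing = sig_genes - set(annotation.to_numpy())
    if missing:
        raise MissingAnnotationError(missing, kind="gene")

    probes = annotation.index.to_numpy()
    is_up = np.isin(annotation.to_numpy(), sorted(truth.shared_up))
    is_down = np.isin(annotation.to_numpy(), sorted(truth.shared_down))
    if config.n_probes is not None:
        n_sig = int(is_up.sum() + is_down.sum())
        if config.n_probes < n_sig:
            raise ConfigurationError(
                f"n_probes: need at least {n_sig} probes to carry the planted signature")
        keep_sig = is_up | is_down
        others = np.flatnonzero(~keep_sig)
        n_fill = config.n_probes - n_sig
        if n_fill <= len(others):
            keep = np.concatenate([np.flatnonzero(keep_sig),
                                   rng.choice(others, size=n_fill, replace=False)])
            keep.sort()
            probes, is_up, is_down = probes[keep], is_up[keep], is_down[keep]
        else:
            extra = np.array([f"XPR{i:06d}" for i in range(n_fill - len(others))])
            probes = np.concatenate([probes, extra])
            is_up = np.concatenate([is_up, np.zeros(len(extra), dtype=bool)])
            is_down = np.concatenate([is_down, np.zeros(len(extra), dtype=bool)])
    n_probes = len(probes)

    names = np.array([f"pert{i:04d}" for i in range(config.n_perturbagens)])
    concordant = set(names[rng.permutation(config.n_perturbagens)
                           [:config.n_concordant_perturbagens]])
    lo, hi = config.instances_per_perturbagen
    counts = rng.integers(lo, hi + 1, size=config.n_perturbagens)

    concentrations = np.array(["100nM", "1uM", "10uM"])
    cell_lines = np.array(["MCF7", "PC3", "HL60"])
    n_instances = int(counts.sum())
    positions = np.empty((n_instances, n_probes), dtype=np.int32)
    meta = []
    c = config.concordance_strength
    i = 0
    for name, k in zip(names, counts):
        for rep in range(k):
            latent = rng.random(n_probes)
            if name in concordant:
                latent[is_up] -= c * (1.0 + rng.random(int(is_up.sum())))
                latent[is_down] += c * (1.0 + rng.random(int(is_down.sum())))
                cell = "MCF7"
            else:
                p_rest = (1.0 - config.mcf7_fraction) / 2
                cell = rng.choice(cell_lines,
                                  p=[config.mcf7_fraction, p_rest, p_rest])
            order = np.argsort(latent, kind="stable")
            positions[i, order] = np.arange(1, n_probes + 1)
            meta.append({"instance_id": f"{name}_i{rep+1}", "perturbagen": name,
                         "concentration": str(rng.choice(concentrations)),
                         "batch": f"batch{int(rng.integers(1, 8))}",
                         "cell_line": str(cell)})
            i += 1

    db = InstanceDatabase(pd.Index(probes, name="probe_id"), positions,
                          pd.DataFrame(meta))
    truth.concordant_perturbagens = concordant
    return db, truth


def write_ground_truth(truth: GroundTruth, path) -> None:
    payload = {k: sorted(v) for k, v in asdict(truth).items()}
    Path(path).write_text(json.dumps(payload, indent=1))


def read_ground_truth(path) -> GroundTruth:
    payload = json.loads(Path(path).read_text())
    return GroundTruth(**{k: set(v) for k, v in payload.items()})
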