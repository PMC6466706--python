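"""End-to-end pipeline: simulate -> normalize -> SAM x2 -> signature -> query.

Composes the stage modules in discovery order, writing every intermediate
as tab-delimited text and a JSON run manifest (config snapshot, per-stage
I/O checksums, row counts and timings) so a run can be audited and
replayed. Identical config + seeds reproduce identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import __version__
from .errors import ConfigurationError, SenesigError
from .matrix import write_matrix, write_annotation
from .preprocess import quantile_normalize, detection_filter
from .sam import sam_two_class, select_delta, deg_table, fold_filter, collapse_probes
from .signature import (intersect_signatures, expand_to_tags, concordance_summary,
                        write_signature, write_tags)
from .connectivity import query
from .simulate import (SimulationConfig, InstanceDbConfig, generate_paired_dataset,
                       generate_instance_db, write_ground_truth)

__all__ = ["RunConfig", "RunManifest", "run_pipeline"]


@dataclass
class RunConfig:
    """All stage parameters of one pipeline run."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    instance_db: InstanceDbConfig = field(default_factory=InstanceDbConfig)
    alpha: float = 0.05                 # detection p-value threshold
    min_detected: int | str = "all"
    fdr: float = 0.01                   # SAM target median FDR
    min_fold: float = 1.5
    n_permutations: int = 1000
    collapse_scale: str = "log2"
    n_draws: int = 10000                # permutation draws for perturbagen p
    positive_only: bool = True
    restrict_cell_line: str | None = "MCF7"
    seed: int = 0
    write_db: bool = False              # rank files can be large; off by default

    def validate(self) -> None:
        if not (0 < self.alpha <= 1):
            raise ConfigurationError(f"alpha must be in (0, 1], got {self.alpha}")
        if not (0 < self.fdr < 1):
            raise ConfigurationError(f"fdr must be in (0, 1), got {self.fdr}")
        if self.min_fold < 1:
            raise ConfigurationError(f"min_fold must be >= 1, got {self.min_fold}")
        if self.n_permutations < 1 or self.n_draws < 1:
            raise ConfigurationError("n_permutations and n_draws must be >= 1")
        if self.collapse_scale not in ("log2", "linear"):
            raise ConfigurationError("collapse_scale must be 'log2' or 'linear'")
        self.simulation.validate()
        self.instance_db.validate()

    @classmethod
    def from_dict(cls, payload: dict) -> "RunConfig":
        payload = dict(payload)
        sim = SimulationConfig(**{k: tuple(v) if isinstance(v, list) else v
                                  for k, v in payload.pop("simulation", {}).items()})
        dbc = InstanceDbConfig(**{k: tuple(v) if isinstance(v, list) else v
                                  for k, v in payload.pop("instance_db", {}).items()})
        return cls(simulation=sim, instance_db=dbc, **payload)


@dataclass
class RunManifest:
    config: dict
    version: str
    stages: list = field(default_factory=list)
    outputs: dict = field(default_factory=dict)
    counts: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, default=str))


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


class _StageRecorder:
    def __init__(self, manifest: RunManifest):
        self.manifest = manifest

    def record(self, name: str, outputs: list[Path], **info):
        self.manifest.stages.append({
            "stage": name,
            "outputs": {p.name: _checksum(p) for p in outputs},
            **info,
        })


def run_pipeline(config: RunConfig, out_dir) -> RunManifest:
    """Execute the full synthetic study and return its manifest.

    Stage order: simulate expression -> quantile normalize -> detection
    filter -> SAM per condition -> fold filter + probe collapse ->
    signature intersection/expansion -> simulate instance database ->
    connectivity query. Any stage failure aborts with the stage name
    recorded in the manifest (written as ``manifest.json`` even on error).
    """
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=dataclasses.asdict(config), version=__version__)
    rec = _StageRecorder(manifest)
    current = "setup"
    try:
        # 1. simulate expression
        current = "simulate_expression"
        t0 = time.perf_counter()
        mat_A, mat_B, annotation, truth = generate_paired_dataset(config.simulation)
        files = []
        for arm, m in (("A", mat_A), ("B", mat_B)):
            vp, dp = out / f"expr_{arm}.tsv", out / f"detection_{arm}.tsv"
            write_matrix(m, vp, dp)
            files += [vp, dp]
        write_annotation(annotation, out / "annotation.tsv")
        files.append(out / "annotation.tsv")
        rec.record(current, files, n_probes=mat_A.n_probes,
                   seconds=round(time.perf_counter() - t0, 3))

        # 2. quantile normalize
        current = "quantile_normalize"
        t0 = time.perf_counter()
        norm = {arm: quantile_normalize(m) for arm, m in (("A", mat_A), ("B", mat_B))}
        files = []
        for arm, m in norm.items():
            p = out / f"norm_{arm}.tsv"
            write_matrix(m, p)
            files.append(p)
        rec.record(current, files, seconds=round(time.perf_counter() - t0, 3))

        # 3. detection filter
        current = "detection_filter"
        t0 = time.perf_counter()
        filt = {arm: detection_filter(m, config.alpha, config.min_detected)
                for arm, m in norm.items()}
        files = []
        for arm, m in filt.items():
            p = out / f"filtered_{arm}.tsv"
            write_matrix(m, p)
            files.append(p)
            manifest.counts[f"detected_probes_{arm}"] = m.n_probes
        rec.record(current, files,
                   n_detected={a: m.n_probes for a, m in filt.items()},
                   seconds=round(time.perf_counter() - t0, 3))

        # 4+5. SAM per condition (with fold filter and collapse per arm)
        degs = {}
        for arm in ("A", "B"):
            current = f"sam_{arm}"
            t0 = time.perf_counter()
            m = filt[arm]
            labels = ["control" if "_ctrl_" in s else "treated" for s in m.sample_ids]
            res = sam_two_class(m, labels, n_permutations=config.n_permutations,
                                seed=config.seed, treatment="treated")
            sel = select_delta(res, config.fdr)
            probe_deg = fold_filter(deg_table(res, sel), config.min_fold)
            p = out / f"deg_probes_{arm}.tsv"
            probe_deg.to_csv(p, sep="\t", index=False)
            manifest.counts[f"deg_probes_{arm}"] = len(probe_deg)
            rec.record(current, [p], delta=sel.delta, est_fdr=sel.fdr,
                       n_called=len(probe_deg),
                       seconds=round(time.perf_counter() - t0, 3))
            degs[arm] = probe_deg

        # 6. collapse probes to genes
        current = "collapse_probes"
        t0 = time.perf_counter()
        files = []
        for arm in ("A", "B"):
            gene_deg = collapse_probes(degs[arm], annotation, scale=config.collapse_scale)
            degs[arm] = gene_deg
            p = out / f"deg_genes_{arm}.tsv"
            gene_deg.to_csv(p, sep="\t", index=False)
            files.append(p)
            manifest.counts[f"deg_genes_{arm}"] = len(gene_deg)
        rec.record(current, files, seconds=round(time.perf_counter() - t0, 3))

        # 7. shared signature + tag expansion
        current = "signature"
        t0 = time.perf_counter()
        sig = intersect_signatures(degs["A"], degs["B"])
        summary = concordance_summary(sig)
        manifest.counts.update({f"signature_{k}": v for k, v in summary.items()})
        write_signature(sig, out / "signature.tsv")
        tags = expand_to_tags(sig, annotation)
        write_tags(tags, out / "up_tags.grp", out / "down_tags.grp")
        write_ground_truth(truth, out / "ground_truth.json")
        rec.record(current, [out / "signature.tsv", out / "up_tags.grp",
                             out / "down_tags.grp"],
                   venn=sig.venn, seconds=round(time.perf_counter() - t0, 3))

        # 8. simulate instance database
        current = "simulate_instances"
        t0 = time.perf_counter()
        db, truth = generate_instance_db(config.instance_db, truth, annotation)
        write_ground_truth(truth, out / "ground_truth.json")
        db.meta.to_csv(out / "instances.tsv", sep="\t", index=False)
        if config.write_db:
            db.to_dir(out / "instance_db")
        rec.record(current, [out / "instances.tsv"], n_instances=db.n_instances,
                   seconds=round(time.perf_counter() - t0, 3))

        # 9. connectivity query
        current = "connectivity_query"
        t0 = time.perf_counter()
        meta_filter = ({"cell_line": config.restrict_cell_line}
                       if config.restrict_cell_line else None)
        report = query(tags, db, metadata_filter=meta_filter,
                       positive_only=config.positive_only,
                       n_draws=config.n_draws, seed=config.seed)
        p = out / "connectivity_report.tsv"
        report.to_csv(p, sep="\t", index=False)
        manifest.counts["report_perturbagens"] = len(report)
        rec.record(current, [p], seconds=round(time.perf_counter() - t0, 3))
        manifest.outputs["report"] = str(p)
    except SenesigError as err:
        manifest.stages.append({"stage": current, "error": str(err)})
        manifest.to_json(out / "manifest.json")
        raise
    manifest.to_json(out / "manifest.json")
    return manifest
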