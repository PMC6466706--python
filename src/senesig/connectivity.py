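"""Rank-based connectivity scoring of query signatures against instances.

One *instance* is a full ranked probe list for one small-molecule
treatment (rank 1 = most up-regulated). A query is a pair of tag lists
(up/down probes). Each tag list receives a signed two-sided
Kolmogorov–Smirnov statistic against an instance's ranking:

    a = max_j [ j/t - V(j)/n ],  b = max_j [ V(j)/n - (j-1)/t ]
    ks = a  if a > b  else  -b

where V(1..t) are the ascending tag ranks. The raw instance score is
ks_up - ks_down when the two statistics disagree in sign and 0
otherwise; raw scores are scaled by the extreme positive/negative raw
score across all instances so the connectivity score lies in [-1, 1].
Per-perturbagen results aggregate instance scores (arithmetic mean, n),
an enrichment KS of the perturbagen's instance positions within the
score-ordered instance list, and a permutation p-value for that
enrichment.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import MissingTagError, ValidationError
from .signature import TagLists

__all__ = ["Instance", "InstanceDatabase", "InstanceScore", "ks_tag_statistic",
           "score_instance", "scale_scores", "aggregate_perturbagen",
           "rank_results", "query"]

META_COLUMNS = ["instance_id", "perturbagen", "concentration", "batch", "cell_line"]


@dataclass
class Instance:
    """One treatment's full probe ranking plus perturbagen metadata."""

    instance_id: str
    perturbagen: str
    concentration: str
    batch: str
    ranking: np.ndarray          # probe ids, position 0 = rank 1 = most up-regulated
    cell_line: str = "MCF7"

    def __post_init__(self):
        self.ranking = np.asarray(self.ranking)
        if len(self.ranking) < 2:
            raise ValidationError("an instance ranking needs at least 2 probes")
        if len(np.unique(self.ranking)) != len(self.ranking):
            raise ValidationError("instance ranking contains duplicate probes")


@dataclass
class InstanceScore:
    instance_id: str
    ks_up: float
    ks_down: float
    raw_score: float
    scaled_score: float = 0.0


class InstanceDatabase:
    """A set of instances stored as a probe-position matrix plus metadata.

    ``positions[i, p]`` is the 1-based rank of probe ``p`` (column order of
    ``probe_ids``) in instance ``i``.
    """

    def __init__(self, probe_ids, positions: np.ndarray, meta: pd.DataFrame):
        self.probe_ids = pd.Index(probe_ids)
        self.positions = np.asarray(positions)
        self.meta = meta.reset_index(drop=True)
        if self.positions.shape != (len(self.meta), len(self.probe_ids)):
            raise ValidationError("positions shape must be (n_instances, n_probes)")
        if self.meta["instance_id"].duplicated().any():
            raise ValidationError("duplicate instance ids")

    @property
    def n_instances(self) -> int:
        return self.positions.shape[0]

    @property
    def n_probes(self) -> int:
        return self.positions.shape[1]

    @classmethod
    def from_instances(cls, instances) -> "InstanceDatabase":
        probe_ids = pd.Index(instances[0].ranking)
        pos = np.empty((len(instances), len(probe_ids)), dtype=np.int32)
        meta = []
        for i, inst in enumerate(instances):
            idx = probe_ids.get_indexer(inst.ranking)
            if (idx < 0).any():
                raise ValidationError("all instances must rank the same probe set")
            pos[i, idx] = np.arange(1, len(probe_ids) + 1)
            meta.append({"instance_id": inst.instance_id,
                         "perturbagen": inst.perturbagen,
                         "concentration": inst.concentration,
                         "batch": inst.batch, "cell_line": inst.cell_line})
        return cls(probe_ids, pos, pd.DataFrame(meta))

    def instance(self, instance_id: str) -> Instance:
        row = self.meta[self.meta["instance_id"] == instance_id]
        if row.empty:
            raise KeyError(instance_id)
        i = row.index[0]
        order = np.argsort(self.positions[i])
        r = row.iloc[0]
        return Instance(instance_id=r["instance_id"], perturbagen=r["perturbagen"],
                        concentration=r["concentration"], batch=r["batch"],
                        ranking=np.asarray(self.probe_ids)[order],
                        cell_line=r.get("cell_line", "MCF7"))

    def subset(self, mask) -> "InstanceDatabase":
        meta = self.meta[mask].reset_index(drop=True)
        return InstanceDatabase(self.probe_ids, self.positions[np.asarray(mask)], meta)

    # ---- text serialization (rank file per instance + manifest) ----

    def to_dir(self, out_dir) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        self.meta[META_COLUMNS].to_csv(out_dir / "instances.tsv", sep="\t", index=False)
        probes = np.asarray(self.probe_ids)
        for i, iid in enumerate(self.meta["instance_id"]):
            order = np.argsort(self.positions[i])
            (out_dir / f"{iid}.rank").write_text("\n".join(probes[order]) + "\n")

    @classmethod
    def from_dir(cls, db_dir) -> "InstanceDatabase":
        db_dir = Path(db_dir)
        meta = pd.read_csv(db_dir / "instances.tsv", sep="\t")
        instances = []
        for _, r in meta.iterrows():
            ranking = (db_dir / f"{r['instance_id']}.rank").read_text().split()
            instances.append(Instance(
                instance_id=str(r["instance_id"]), perturbagen=str(r["perturbagen"]),
                concentration=str(r["concentration"]), batch=str(r["batch"]),
                ranking=np.asarray(ranking),
                cell_line=str(r.get("cell_line", "MCF7"))))
        return cls.from_instances(instances)


def _ks_from_sorted(V: np.ndarray, n: int) -> float:
    t = len(V)
    j = np.arange(1, t + 1)
    a = np.max(j / t - V / n)
    b = np.max(V / n - (j - 1) / t)
    return float(a) if a > b else float(-b)


def ks_tag_statistic(tag_ranks, n_probes: int) -> float:
    """Signed two-sided KS statistic for a tag list at the given ranks.

    Positive values mean the tags crowd the top (up-regulated end) of the
    ranking, negative the bottom.
    """
    V = np.sort(np.asarray(tag_ranks, dtype=float))
    t = len(V)
    if t == 0:
        raise ValidationError("tag list is empty")
    if t >= n_probes:
        raise ValidationError("tag list must be smaller than the ranking")
    if V[0] < 1 or V[-1] > n_probes or len(np.unique(V)) != t:
        raise ValidationError("tag ranks must be distinct integers in [1, n_probes]")
    return _ks_from_sorted(V, n_probes)


def _tag_positions(db: InstanceDatabase, tags, drop_missing: bool) -> np.ndarray:
    idx = db.probe_ids.get_indexer(np.asarray(tags))
    missing = np.asarray(tags)[idx < 0]
    if len(missing):
        if not drop_missing:
            raise MissingTagError(missing)
        idx = idx[idx >= 0]
        if len(idx) == 0:
            raise MissingTagError(missing)
    return db.positions[:, idx]


def score_instance(tags: TagLists, instance: Instance) -> InstanceScore:
    """Raw connectivity score of one instance against a query signature."""
    rank_of = pd.Index(instance.ranking)
    n = len(instance.ranking)
    ups = rank_of.get_indexer(np.asarray(tags.up_tags)) + 1
    downs = rank_of.get_indexer(np.asarray(tags.down_tags)) + 1
    missing = [t for t, r in zip(tags.up_tags, ups) if r == 0] + \
              [t for t, r in zip(tags.down_tags, downs) if r == 0]
    if missing:
        raise MissingTagError(missing)
    ks_up = ks_tag_statistic(ups, n)
    ks_down = ks_tag_statistic(downs, n)
    raw = ks_up - ks_down if np.sign(ks_up) != np.sign(ks_down) else 0.0
    return InstanceScore(instance.instance_id, ks_up, ks_down, raw)


def _score_db(tags: TagLists, db: InstanceDatabase, drop_missing: bool) -> pd.DataFrame:
    """Vectorized raw scoring of every instance in the database."""
    up_pos = np.sort(_tag_positions(db, tags.up_tags, drop_missing), axis=1)
    down_pos = np.sort(_tag_positions(db, tags.down_tags, drop_missing), axis=1)
    n = db.n_probes

    def signed_ks(P: np.ndarray) -> np.ndarray:
        t = P.shape[1]
        j = np.arange(1, t + 1)
        a = (j / t - P / n).max(axis=1)
        b = (P / n - (j - 1) / t).max(axis=1)
        return np.where(a > b, a, -b)

    ks_up = signed_ks(up_pos)
    ks_down = signed_ks(down_pos)
    raw = np.where(np.sign(ks_up) != np.sign(ks_down), ks_up - ks_down, 0.0)
    return pd.DataFrame({"instance_id": db.meta["instance_id"],
                         "ks_up": ks_up, "ks_down": ks_down, "raw_score": raw})


def scale_scores(scores) -> list[InstanceScore] | pd.DataFrame:
    """Scale raw scores into [-1, 1] by the extreme raw score of each sign.

    Positive raws divide by the maximum positive raw, negative raws by the
    magnitude of the most negative raw; a sign with no raw scores divides
    by 1. Accepts and returns either a list of InstanceScore or the
    DataFrame produced by the vectorized scorer.
    """
    if isinstance(scores, pd.DataFrame):
        raw = scores["raw_score"].to_numpy()
        out = scores.copy()
        out["scaled_score"] = _scale_raw(raw)
        return out
    raw = np.array([s.raw_score for s in scores])
    scaled = _scale_raw(raw)
    return [InstanceScore(s.instance_id, s.ks_up, s.ks_down, s.raw_score, sc)
            for s, sc in zip(scores, scaled)]


def _scale_raw(raw: np.ndarray) -> np.ndarray:
    if len(raw) == 0:
        raise ValidationError("no instance scores to scale")
    p = raw[raw > 0].max() if (raw > 0).any() else 1.0
    q = (-raw[raw < 0]).max() if (raw < 0).any() else 1.0
    return np.where(raw > 0, raw / p, np.where(raw < 0, raw / q, 0.0))


def _null_enrichment(n_positions: int, n_instances: int, n_draws: int,
                     rng: np.random.Generator) -> np.ndarray:
    """Null distribution of the enrichment KS for random instance positions."""
    draws = np.empty((n_draws, n_positions), dtype=float)
    for i in range(n_draws):
        draws[i] = rng.choice(n_instances, size=n_positions, replace=False) + 1
    draws.sort(axis=1)
    t = n_positions
    j = np.arange(1, t + 1)
    a = (j / t - draws / n_instances).max(axis=1)
    b = (draws / n_instances - (j - 1) / t).max(axis=1)
    return np.where(a > b, a, -b)


def aggregate_perturbagen(scored: pd.DataFrame, meta: pd.DataFrame,
                          n_draws: int = 10000, seed: int = 0) -> pd.DataFrame:
    """Per-perturbagen mean/n/enrichment/p over scaled instance scores.

    Instances are ordered by scaled score descending (ties broken by
    instance id for determinism); each perturbagen's enrichment is the
    signed KS of its instance positions in that ordering, with a
    permutation p-value (the add-one-corrected tail in the observed
    direction, doubled; floor 2/(n_draws+1)).
    """
    merged = scored.merge(meta[["instance_id", "perturbagen"]], on="instance_id")
    # Ties (e.g. the zero-score block) are ordered by a hash of the instance
    # id: deterministic, but uncorrelated with perturbagen membership, so a
    # perturbagen's instances do not artificially cluster inside a tie block.
    merged["_tie"] = [hashlib.md5(str(i).encode()).hexdigest()
                      for i in merged["instance_id"]]
    merged = merged.sort_values(["scaled_score", "_tie"],
                                ascending=[False, True], kind="stable")
    merged["position"] = np.arange(1, len(merged) + 1)
    N = len(merged)
    null_cache: dict[int, np.ndarray] = {}
    rows = []
    for name, grp in merged.groupby("perturbagen"):
        n = len(grp)
        mean = float(grp["scaled_score"].mean())
        if n >= N:
            enr, p = 0.0, 1.0
        else:
            enr = _ks_from_sorted(np.sort(grp["position"].to_numpy(dtype=float)), N)
            if n not in null_cache:
                rng = np.random.default_rng([seed, n])
                null_cache[n] = _null_enrichment(n, N, n_draws, rng)
            null = null_cache[n]
            # two-sided permutation p: the tail in the observed direction,
            # doubled (add-one corrected); uniform under a null database
            if enr >= 0:
                tail = (1 + int((null >= enr).sum())) / (n_draws + 1)
            else:
                tail = (1 + int((null <= enr).sum())) / (n_draws + 1)
            p = min(1.0, 2.0 * tail)
        rows.append({"name": name, "mean": mean, "n": n,
                     "enrichment": enr, "p_value": p, "specificity": np.nan})
    return pd.DataFrame(rows)


def rank_results(results: pd.DataFrame) -> pd.DataFrame:
    """Order perturbagen results: p ascending, |enrichment| descending, name."""
    out = results.copy()
    out["_abs_enr"] = -out["enrichment"].abs()
    out = out.sort_values(["p_value", "_abs_enr", "name"], kind="stable")
    out = out.drop(columns="_abs_enr").reset_index(drop=True)
    out.insert(0, "rank", np.arange(1, len(out) + 1))
    return out


def query(tags: TagLists, db: InstanceDatabase, metadata_filter: dict | None = None,
          positive_only: bool = False, n_draws: int = 10000, seed: int = 0,
          drop_missing_tags: bool = False) -> pd.DataFrame:
    """Full signature query: score -> scale -> aggregate -> rank.

    ``metadata_filter`` restricts instances by exact metadata match (e.g.
    ``{"cell_line": "MCF7"}``); ``positive_only`` keeps only perturbagens
    with positive enrichment, mirroring a positive-enrichment search.
    """
    if db.n_instances == 0:
        raise ValidationError("instance database is empty")
    if metadata_filter:
        mask = np.ones(db.n_instances, dtype=bool)
        for col, val in metadata_filter.items():
            if col not in db.meta.columns:
                raise ValidationError(f"unknown metadata column {col!r}")
            mask &= (db.meta[col] == val).to_numpy()
        if not mask.any():
            raise ValidationError("metadata filter removed every instance")
        db = db.subset(mask)
    scored = scale_scores(_score_db(tags, db, drop_missing_tags))
    results = aggregate_perturbagen(scored, db.meta, n_draws=n_draws, seed=seed)
    if positive_only:
        results = results[results["enrichment"] > 0]
    return rank_results(results)
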