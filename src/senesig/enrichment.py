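"""Over-representation and upstream-regulator statistics.

Two generic statistics for interpreting a DEG list against user-supplied
knowledge: a one-sided Fisher's exact (hypergeometric tail) test of
overlap with named gene sets, and the simple activation z-score
(consistent - inconsistent targets over sqrt(N)) for a signed
regulator -> target network, with |z| >= 2 declaring a predicted
activated/inhibited state. Both are deliberately knowledge-base-free:
gene sets come from GMT files and networks from three-column TSV.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError

__all__ = ["read_gmt", "write_gmt", "read_network", "fisher_ora", "activation_zscore"]


def read_gmt(path) -> dict[str, set]:
    """Read a GMT file (name, description, members...) into named gene sets."""
    sets: dict[str, set] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValidationError(f"malformed GMT line: {line[:60]!r}")
        name, members = parts[0], {m for m in parts[2:] if m}
        if name in sets:
            raise ValidationError(f"duplicate gene-set name {name!r}")
        if not members:
            raise ValidationError(f"empty gene set {name!r}")
        sets[name] = members
    return sets


def write_gmt(sets: dict[str, set], path, description: str = "na") -> None:
    lines = [f"{name}\t{description}\t" + "\t".join(sorted(members))
             for name, members in sets.items()]
    Path(path).write_text("\n".join(lines) + "\n")


def read_network(path) -> pd.DataFrame:
    """Read a (regulator, target, sign) TSV network."""
    net = pd.read_csv(path, sep="\t")
    net.columns = [c.lower() for c in net.columns]
    return net[["regulator", "target", "sign"]]


def fisher_ora(query, collection: dict[str, set], universe) -> pd.DataFrame:
    """One-sided over-representation test of a query set against gene sets.

    Each set is intersected with the universe before testing; the p-value
    is the hypergeometric upper tail P(X >= overlap) and the ratio is
    overlap / |set ∩ universe|. Benjamini-Hochberg adjustment across sets.
    """
    query, universe = set(query), set(universe)
    if not universe:
        raise ValidationError("universe is empty")
    if not query:
        raise ValidationError("query is empty")
    if not query <= universe:
        raise ValidationError(
            f"{len(query - universe)} query gene(s) absent from the universe")
    M, N = len(universe), len(query)
    rows = []
    for name, members in collection.items():
        inset = members & universe
        K = len(inset)
        k = len(query & inset)
        p = float(hypergeom.sf(k - 1, M, K, N)) if K else 1.0
        rows.append({"set": name, "overlap": k, "set_size": K,
                     "ratio": (k / K) if K else np.nan, "p_value": min(p, 1.0)})
    out = pd.DataFrame(rows)
    if len(out):
        out["adjusted_p"] = multipletests(out["p_value"], method="fdr_bh")[1]
    return out.sort_values("p_value", kind="stable").reset_index(drop=True)


def activation_zscore(deg: pd.DataFrame, network: pd.DataFrame) -> pd.DataFrame:
    """Signed activation z-score per regulator over its DEG targets.

    A target is consistent when the sign of its log2 fold change matches
    the edge's expected sign; z = (consistent - inconsistent)/sqrt(N).
    Regulators with no target in the DEG table are omitted.
    """
    if network.duplicated(["regulator", "target"]).any():
        raise ValidationError("duplicate (regulator, target) edges")
    if not network["sign"].isin([1, -1]).all():
        raise ValidationError("edge signs must be +1 or -1")
    lfc = pd.Series(deg["log2fc"].to_numpy(), index=deg["id"].to_numpy())
    hits = network[network["target"].isin(lfc.index)].copy()
    if hits.empty:
        return pd.DataFrame(columns=["regulator", "n_targets", "z", "predicted_state"])
    hits["consistent"] = np.sign(lfc.loc[hits["target"]].to_numpy()) == hits["sign"]
    rows = []
    for reg, grp in hits.groupby("regulator"):
        n = len(grp)
        n_cons = int(grp["consistent"].sum())
        z = (2 * n_cons - n) / np.sqrt(n)
        state = "activated" if z >= 2 else ("inhibited" if z <= -2 else "indeterminate")
        rows.append({"regulator": reg, "n_targets": n, "z": z, "predicted_state": state})
    return (pd.DataFrame(rows)
            .sort_values("z", ascending=False, kind="stable")
            .reset_index(drop=True))
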