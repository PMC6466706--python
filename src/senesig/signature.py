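"""Shared-signature construction from two gene-level DEG tables.

Genes differentially expressed after both perturbations form the shared
set; those whose fold changes agree in sign are split into the up and
down halves of the candidate senescence signature, discordant genes are
set aside, and the concordant gene symbols are expanded to probe-level
tag lists for rank-based database queries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = ["SharedSignature", "TagLists", "intersect_signatures",
           "expand_to_tags", "concordance_summary", "write_signature",
           "read_signature", "write_tags", "read_tags"]


@dataclass
class SharedSignature:
    """Concordant up/down gene lists with per-condition fold changes.

    ``up``/``down``/``discordant`` are DataFrames with columns
    (gene, log2fc_A, log2fc_B); ``venn`` holds the overlap counts.
    """

    up: pd.DataFrame
    down: pd.DataFrame
    discordant: pd.DataFrame
    venn: dict

    def __post_init__(self):
        if set(self.up["gene"]) & set(self.down["gene"]):
            raise ValidationError("up and down gene sets overlap")
        if self.venn["shared"] != len(self.up) + len(self.down) + len(self.discordant):
            raise ValidationError("venn shared count inconsistent with gene lists")


@dataclass
class TagLists:
    """Probe-level expansion of the signature's up and down halves."""

    up_tags: list
    down_tags: list
    unmapped: list = field(default_factory=list)

    def __post_init__(self):
        if set(self.up_tags) & set(self.down_tags):
            raise ValidationError("up and down tag lists overlap")
        if len(set(self.up_tags)) != len(self.up_tags) or \
           len(set(self.down_tags)) != len(self.down_tags):
            raise ValidationError("tags must be unique within each list")


def _check_gene_table(deg: pd.DataFrame, name: str) -> pd.Series:
    if deg["id"].duplicated().any():
        dups = deg["id"][deg["id"].duplicated()].tolist()
        raise ValidationError(f"duplicate gene ids in {name}: {dups[:5]}")
    return pd.Series(deg["log2fc"].to_numpy(), index=deg["id"].to_numpy())


def intersect_signatures(deg_A: pd.DataFrame, deg_B: pd.DataFrame) -> SharedSignature:
    """Intersect two gene-level DEG tables into a shared signature.

    Shared genes whose log2 fold changes agree in sign in both conditions
    are concordant (up if both positive); sign disagreements are kept as
    discordant. Venn counts record A-only, B-only, shared and
    shared-concordant genes.
    """
    a = _check_gene_table(deg_A, "deg_A")
    b = _check_gene_table(deg_B, "deg_B")
    shared_genes = a.index.intersection(b.index).sort_values()
    table = pd.DataFrame({
        "gene": shared_genes,
        "log2fc_A": a.loc[shared_genes].to_numpy(),
        "log2fc_B": b.loc[shared_genes].to_numpy(),
    })
    both_up = (table["log2fc_A"] > 0) & (table["log2fc_B"] > 0)
    both_down = (table["log2fc_A"] < 0) & (table["log2fc_B"] < 0)
    up = table[both_up].reset_index(drop=True)
    down = table[both_down].reset_index(drop=True)
    disc = table[~both_up & ~both_down].reset_index(drop=True)
    venn = {
        "A_only": int(len(a.index.difference(b.index))),
        "B_only": int(len(b.index.difference(a.index))),
        "shared": int(len(shared_genes)),
        "shared_concordant": int(len(up) + len(down)),
    }
    return SharedSignature(up=up, down=down, discordant=disc, venn=venn)


def expand_to_tags(sig: SharedSignature, platform_annotation: pd.Series) -> TagLists:
    """Expand concordant signature genes to target-platform probe tags.

    Every probe of every up gene enters ``up_tags`` (likewise down);
    genes with no probe on the target platform are recorded in
    ``unmapped``. Discordant genes are excluded entirely.
    """
    ann = pd.Series(platform_annotation)
    gene_to_probes = ann.index.to_series().groupby(ann.to_numpy()).apply(list)
    up_tags, down_tags, unmapped = [], [], []
    for genes, sink in ((sig.up["gene"], up_tags), (sig.down["gene"], down_tags)):
        for g in genes:
            if g in gene_to_probes.index:
                sink.extend(gene_to_probes[g])
            else:
                unmapped.append(g)
    if not up_tags or not down_tags:
        raise ValidationError(
            "signature expansion produced an empty tag list; query impossible")
    return TagLists(up_tags=up_tags, down_tags=down_tags, unmapped=unmapped)


def concordance_summary(sig: SharedSignature) -> dict:
    """Counts and concordant fraction of the shared gene set.

    The fraction is (|up|+|down|)/shared, or None when nothing is shared.
    """
    shared = sig.venn["shared"]
    n_up, n_down, n_disc = len(sig.up), len(sig.down), len(sig.discordant)
    fraction = (n_up + n_down) / shared if shared else None
    return {"n_up": n_up, "n_down": n_down, "n_discordant": n_disc,
            "n_shared": shared, "fraction_concordant": fraction}


def write_signature(sig: SharedSignature, path) -> None:
    rows = []
    for df, direction in ((sig.up, "up"), (sig.down, "down"),
                          (sig.discordant, "discordant")):
        part = df.copy()
        part["direction"] = direction
        rows.append(part)
    pd.concat(rows, ignore_index=True).to_csv(path, sep="\t", index=False)


def read_signature(path) -> SharedSignature:
    table = pd.read_csv(path, sep="\t")
    cols = ["gene", "log2fc_A", "log2fc_B"]
    up = table[table["direction"] == "up"][cols].reset_index(drop=True)
    down = table[table["direction"] == "down"][cols].reset_index(drop=True)
    disc = table[table["direction"] == "discordant"][cols].reset_index(drop=True)
    venn = {"A_only": -1, "B_only": -1, "shared": len(table),
            "shared_concordant": len(up) + len(down)}
    return SharedSignature(up=up, down=down, discordant=disc, venn=venn)


def write_tags(tags: TagLists, up_path, down_path) -> None:
    """Write tag lists as one-probe-per-line grp-style files."""
    Path(up_path).write_text("\n".join(map(str, tags.up_tags)) + "\n")
    Path(down_path).write_text("\n".join(map(str, tags.down_tags)) + "\n")


def read_tags(up_path, down_path) -> TagLists:
    up = [l.strip() for l in Path(up_path).read_text().splitlines() if l.strip()]
    down = [l.strip() for l in Path(down_path).read_text().splitlines() if l.strip()]
    return TagLists(up_tags=up, down_tags=down)
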