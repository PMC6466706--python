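"""Two-class unpaired Significance Analysis of Microarrays (SAM).

Implements the Tusher d-statistic d_i = r_i / (s_i + s0) with the
coefficient-of-variation fudge-factor selection, a balanced
label-permutation null (exhaustive when the number of distinct label
assignments is small), delta-vs-FDR calibration with a pi0 correction,
the linear fold-change filter, and probe-to-gene collapsing by averaging
fold changes across probes of a gene.

A DegTable is a DataFrame with columns ``id``, ``log2fc``, ``direction``
(``up``/``down``) and ``q_value``, one row per probe or gene.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import median_abs_deviation

from .errors import ConfigurationError, MissingAnnotationError, ValidationError
from .matrix import ExpressionMatrix

__all__ = [
    "SamResult",
    "DeltaSelection",
    "sam_two_class",
    "select_delta",
    "deg_table",
    "fold_filter",
    "collapse_probes",
]


@dataclass
class SamResult:
    """Observed and permuted SAM statistics for one two-class comparison."""

    probe_ids: pd.Index
    d: np.ndarray                # observed statistic, probe order
    d_expected: np.ndarray       # mean ordered permuted statistic, ascending rank order
    s: np.ndarray                # per-probe pooled standard error
    s0: float                    # fudge factor
    fold_change: np.ndarray      # linear ratio treated/control (2**log2fc)
    log2fc: np.ndarray           # difference of group means (log2 scale)
    permutation_d: np.ndarray    # (n_probes, n_permutations), each column sorted
    n_permutations: int
    seed: int

    def __post_init__(self):
        if len(self.d) != len(self.probe_ids):
            raise ValidationError("d and probe_ids length mismatch")
        if self.s0 < 0:
            raise ValidationError("s0 must be non-negative")
        if (self.fold_change <= 0).any():
            raise ValidationError("fold changes must be positive")
        if self.permutation_d.shape[1] != self.n_permutations:
            raise ValidationError("permutation_d must have n_permutations columns")


@dataclass
class DeltaSelection:
    """Outcome of the delta-vs-FDR calibration."""

    delta: float
    called: pd.Index             # probe ids called at the selected delta
    fdr: float                   # estimated median FDR at the selected delta
    pi0: float
    q_values: pd.Series          # per-probe q-value (min FDR at which called)
    achieved: bool               # False when no delta met the target
    warning: str | None = None


def _group_stats(X: np.ndarray, treated: np.ndarray):
    """Difference of means and Tusher pooled standard error per probe."""
    a = X[:, treated]
    b = X[:, ~treated]
    n1, n2 = a.shape[1], b.shape[1]
    r = a.mean(axis=1) - b.mean(axis=1)
    ss = ((a - a.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + \
         ((b - b.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    s = np.sqrt((1.0 / n1 + 1.0 / n2) * ss / (n1 + n2 - 2))
    return r, s


def _choose_s0(r: np.ndarray, s: np.ndarray) -> float:
    """Fudge factor by the coefficient-of-variation criterion.

    Candidates are the 0th..100th percentiles (step 5) of s; the winner
    minimizes the CV of the MAD of d computed within moving s-percentile
    windows.
    """
    candidates = np.unique(np.percentile(s, np.arange(0, 101, 5)))
    n_windows = min(100, max(2, len(s) // 10))
    edges = np.quantile(s, np.linspace(0, 1, n_windows + 1))
    window = np.clip(np.searchsorted(edges, s, side="right") - 1, 0, n_windows - 1)
    best, best_cv = candidates[0], np.inf
    for s0c in candidates:
        with np.errstate(divide="ignore", invalid="ignore"):
            d = r / (s + s0c)
        mads = []
        for w in range(n_windows):
            dw = d[window == w]
            dw = dw[np.isfinite(dw)]
            if len(dw) >= 2:
                mads.append(median_abs_deviation(dw, scale="normal"))
        mads = np.asarray(mads)
        if len(mads) < 2 or mads.mean() == 0:
            continue
        cv = mads.std(ddof=1) / mads.mean()
        if cv < best_cv:
            best_cv, best = cv, s0c
    return float(best)


def _distinct_assignments(n: int, k: int, n_permutations: int, rng: np.random.Generator):
    """Distinct size-k treated-group assignments (as boolean masks)."""
    total = math.comb(n, k)
    masks = []
    if total <= n_permutations:
        for combo in itertools.combinations(range(n), k):
            m = np.zeros(n, dtype=bool)
            m[list(combo)] = True
            masks.append(m)
    else:
        seen = set()
        while len(masks) < n_permutations:
            combo = tuple(sorted(rng.choice(n, size=k, replace=False).tolist()))
            if combo in seen:
                continue
            seen.add(combo)
            m = np.zeros(n, dtype=bool)
            m[list(combo)] = True
            masks.append(m)
    return masks


def sam_two_class(matrix: ExpressionMatrix, labels, n_permutations: int = 1000,
                  seed: int = 0, treatment=None, s0: float | None = None) -> SamResult:
    """Two-class unpaired SAM on a complete log2 expression matrix.

    Parameters
    ----------
    labels
        One label per sample column; exactly two distinct values.
    treatment
        The label of the treated group (numerator of the fold change).
        Defaults to the second distinct label in order of appearance.
    s0
        Force the fudge factor instead of estimating it (mainly for tests).
    """
    labels = np.asarray(list(labels))
    if len(labels) != matrix.n_samples:
        raise ValidationError("one label per sample required")
    uniq = list(dict.fromkeys(labels.tolist()))
    if len(uniq) != 2:
        raise ValidationError(f"exactly two groups required, got {len(uniq)}")
    if treatment is None:
        treatment = uniq[1]
    elif treatment not in uniq:
        raise ValidationError(f"treatment label {treatment!r} not among labels")
    treated = labels == treatment
    n_t, n_c = int(treated.sum()), int((~treated).sum())
    if n_t < 2 or n_c < 2:
        raise ValidationError("each group needs at least 2 samples")

    X = matrix.values.to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValidationError("missing values are not supported")

    r, s = _group_stats(X, treated)
    if s0 is None:
        s0 = _choose_s0(r, s)
    d = r / (s + s0)

    rng = np.random.default_rng(seed)
    masks = _distinct_assignments(len(labels), n_t, n_permutations, rng)
    perm = np.empty((len(d), len(masks)))
    for j, mask in enumerate(masks):
        rp, sp = _group_stats(X, mask)
        perm[:, j] = np.sort(rp / (sp + s0))
    d_expected = perm.mean(axis=1)

    return SamResult(
        probe_ids=matrix.probe_ids, d=d, d_expected=d_expected, s=s, s0=float(s0),
        fold_change=np.exp2(r), log2fc=r, permutation_d=perm,
        n_permutations=perm.shape[1], seed=seed,
    )


def _cutoffs(ds: np.ndarray, de: np.ndarray, delta: float):
    """Asymmetric d cutoffs for one delta on the sorted observed statistics."""
    diff = ds - de
    up = (diff >= delta) & (ds > 0)
    down = (-diff >= delta) & (ds < 0)
    cutup = ds[up].min() if up.any() else np.inf
    cutlow = ds[down].max() if down.any() else -np.inf
    return cutup, cutlow


def select_delta(result: SamResult, target_fdr: float, n_grid: int = 200) -> DeltaSelection:
    """Smallest delta whose estimated median FDR meets the target.

    FDR(delta) = pi0 * median over permutations of permuted calls divided
    by observed calls; pi0 is twice the proportion of observed d inside
    the interquartile range of the pooled permuted d, capped at 1. A
    delta with zero observed calls has FDR 0 by convention. Per-probe
    q-values are the minimum FDR over the grid at which the probe is
    called.
    """
    if not (0 < target_fdr < 1):
        raise ConfigurationError(f"target_fdr must be in (0, 1), got {target_fdr}")
    order = np.argsort(result.d, kind="stable")
    ds = result.d[order]
    de = result.d_expected
    perm = result.permutation_d
    pooled_q25, pooled_q75 = np.percentile(perm, [25, 75])
    pi0 = min(1.0, 2.0 * np.mean((result.d >= pooled_q25) & (result.d <= pooled_q75)))

    max_delta = np.abs(ds - de).max()
    grid = np.linspace(0.0, max_delta, n_grid)
    n = len(ds)
    q = np.full(n, 1.0)
    chosen = None
    for delta in grid:
        cutup, cutlow = _cutoffs(ds, de, delta)
        called = (ds >= cutup) | (ds <= cutlow)
        n_called = int(called.sum())
        if n_called == 0:
            fdr = 0.0
        else:
            false = (perm >= cutup).sum(axis=0) + (perm <= cutlow).sum(axis=0)
            fdr = pi0 * float(np.median(false)) / n_called
        q[called] = np.minimum(q[called], max(fdr, 0.0))
        if chosen is None and fdr <= target_fdr:
            chosen = (float(delta), called.copy(), float(fdr))

    q_series = pd.Series(1.0, index=result.probe_ids)
    q_series.iloc[order] = q

    if chosen is None:
        return DeltaSelection(
            delta=float(grid[-1]), called=result.probe_ids[:0], fdr=1.0, pi0=pi0,
            q_values=q_series, achieved=False,
            warning=f"no delta achieved target FDR {target_fdr}; empty call set returned")
    delta, called_sorted, fdr = chosen
    called_ids = result.probe_ids[order][called_sorted]
    return DeltaSelection(delta=delta, called=called_ids, fdr=fdr, pi0=pi0,
                          q_values=q_series, achieved=True)


def deg_table(result: SamResult, selection: DeltaSelection) -> pd.DataFrame:
    """Probe-level DegTable for the called probes."""
    pos = result.probe_ids.get_indexer(selection.called)
    lfc = result.log2fc[pos]
    return pd.DataFrame({
        "id": np.asarray(selection.called),
        "log2fc": lfc,
        "direction": np.where(lfc > 0, "up", "down"),
        "q_value": selection.q_values.loc[selection.called].to_numpy(),
    }).reset_index(drop=True)


def fold_filter(deg: pd.DataFrame, min_fold: float = 1.5) -> pd.DataFrame:
    """Two-sided linear fold-change filter, boundary inclusive."""
    if min_fold < 1:
        raise ConfigurationError(f"min_fold must be >= 1, got {min_fold}")
    thresh = np.log2(min_fold) - 1e-12    # keep exact-boundary folds
    return deg[np.abs(deg["log2fc"]) >= thresh].reset_index(drop=True)


def collapse_probes(deg: pd.DataFrame, annotation: pd.Series,
                    scale: str = "log2") -> pd.DataFrame:
    """Collapse a probe-level DegTable to gene level by averaging.

    The gene fold change is the arithmetic mean of its probes' log2 fold
    changes (``scale="linear"`` averages linear folds instead and re-logs);
    the gene q-value is the minimum over member probes. Genes whose probes
    cancel to exactly zero have no direction and are dropped with a warning.
    """
    if scale not in ("log2", "linear"):
        raise ConfigurationError(f"scale must be 'log2' or 'linear', got {scale!r}")
    annotation = pd.Series(annotation)
    missing = set(deg["id"]) - set(annotation.index)
    if missing:
        raise MissingAnnotationError(missing, kind="probe")
    genes = annotation.loc[deg["id"]].to_numpy()
    work = deg.assign(gene=genes)
    if scale == "log2":
        agg_lfc = work.groupby("gene")["log2fc"].mean()
    else:
        agg_lfc = np.log2(work.assign(fold=np.exp2(work["log2fc"]))
                          .groupby("gene")["fold"].mean())
    agg_q = work.groupby("gene")["q_value"].min()
    out = pd.DataFrame({"id": agg_lfc.index, "log2fc": agg_lfc.to_numpy(),
                        "q_value": agg_q.to_numpy()})
    degenerate = out["log2fc"] == 0
    if degenerate.any():
        warnings.warn(
            f"dropping {int(degenerate.sum())} gene(s) whose probe fold changes "
            "cancel to zero (no direction assignable)")
        out = out[~degenerate]
    out["direction"] = np.where(out["log2fc"] > 0, "up", "down")
    return out[["id", "log2fc", "direction", "q_value"]].reset_index(drop=True)
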