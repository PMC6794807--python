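"""Weighted co-expression modules: soft threshold, TOM, tree-cut modules,
eigengenes and module-trait correlation.

The adjacency is |cor|^beta (unsigned, the classic default) or
((1 + cor)/2)^beta (signed). The topological overlap between transcripts i
and j is

    TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij),

with TOM_ii = 1. Modules come from average-linkage clustering of 1 - TOM
with a static cut; the module eigengene is the first principal component of
the standardised member submatrix, oriented to correlate positively with
the module's mean profile. The hub module maximises min(|r_glucose|,
|r_ttr|), a formalisation of "highest correlation with both traits".

All operations take a log-scale expression frame (transcripts x samples),
e.g. ``ExpressionMatrix.log2p1()``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .data import ValidationError

log = logging.getLogger(__name__)

# WGCNA-style colour labels, assigned in decreasing module-size order
MODULE_COLOURS = (
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan", "midnightblue",
    "lightcyan", "grey60", "lightgreen", "lightyellow", "royalblue", "darkred",
    "darkgreen", "darkturquoise", "darkgrey", "orange", "darkorange", "white",
    "skyblue", "saddlebrown", "steelblue",
)
UNASSIGNED = "grey"


def _drop_constant(expr: pd.DataFrame) -> pd.DataFrame:
    sd = expr.std(axis=1, ddof=1)
    keep = sd > 0
    dropped = int((~keep).sum())
    if dropped:
        log.warning("dropping %d constant-expression transcripts", dropped)
    return expr.loc[keep]


def adjacency(expr: pd.DataFrame, beta: float, kind: str = "unsigned") -> pd.DataFrame:
    """Soft-power adjacency between transcript expression profiles."""
    if beta < 1:
        raise ValidationError("beta must be >= 1")
    if kind not in ("unsigned", "signed"):
        raise ValidationError(f"unknown adjacency kind {kind!r}")
    expr = _drop_constant(expr)
    cor = np.corrcoef(expr.to_numpy())
    if not np.all(np.isfinite(cor)):
        raise ValidationError("non-finite correlations in adjacency")
    cor = np.clip(cor, -1.0, 1.0)
    base = np.abs(cor) if kind == "unsigned" else (1.0 + cor) / 2.0
    adj = base**beta
    np.fill_diagonal(adj, 0.0)
    adj = (adj + adj.T) / 2.0
    return pd.DataFrame(adj, index=expr.index, columns=expr.index)


def _scale_free_r2(k: np.ndarray, nbins: int = 10) -> float:
    """Signed R^2 of the log-log degree-distribution regression."""
    k = k[k > 0]
    if k.size < 2 or np.isclose(k.max(), k.min()):
        return 0.0
    edges = np.linspace(k.min(), k.max(), nbins + 1)
    which = np.clip(np.digitize(k, edges) - 1, 0, nbins - 1)
    dk, p = [], []
    for b in range(nbins):
        m = which == b
        if m.any():
            dk.append(k[m].mean())
            p.append(m.mean())
    dk_arr, p_arr = np.asarray(dk), np.asarray(p)
    keep = (dk_arr > 0) & (p_arr > 0)
    if keep.sum() < 2:
        return 0.0
    res = stats.linregress(np.log10(dk_arr[keep]), np.log10(p_arr[keep]))
    if not np.isfinite(res.rvalue):
        return 0.0
    return float(-np.sign(res.slope) * res.rvalue**2)


@dataclass
class SoftThresholdScan:
    """Per-power scale-free fit and connectivity, plus the chosen power."""

    table: pd.DataFrame  # index: power; columns: scale_free_fit_r2, mean_connectivity
    chosen_beta: int
    used_fallback: bool


def pick_soft_threshold(
    expr: pd.DataFrame,
    candidate_powers=tuple(range(1, 21)),
    r2_target: float = 0.8,
    fallback: int = 10,
    kind: str = "unsigned",
) -> SoftThresholdScan:
    """Choose the smallest power whose scale-free fit reaches ``r2_target``.

    If no candidate reaches the target the configured fallback (default 10,
    the power the study settled on) is returned with ``used_fallback=True``.
    """
    candidate_powers = tuple(int(b) for b in candidate_powers)
    if not candidate_powers or any(b < 1 for b in candidate_powers):
        raise ValidationError("candidate_powers must be positive integers")
    if expr.shape[1] < 4:
        raise ValidationError("need at least 4 samples for a soft-threshold scan")
    expr = _drop_constant(expr)
    cor = np.clip(np.corrcoef(expr.to_numpy()), -1.0, 1.0)
    base = np.abs(cor) if kind == "unsigned" else (1.0 + cor) / 2.0
    np.fill_diagonal(base, 0.0)
    rows = []
    for beta in candidate_powers:
        k = (base**beta).sum(axis=1)
        rows.append((beta, _scale_free_r2(k), float(k.mean())))
    table = pd.DataFrame(
        rows, columns=["power", "scale_free_fit_r2", "mean_connectivity"]
    ).set_index("power")
    hits = table.index[table["scale_free_fit_r2"] >= r2_target]
    if len(hits):
        return SoftThresholdScan(table, int(hits[0]), False)
    log.warning(
        "no candidate power reached scale-free R^2 >= %.2f; falling back to %d",
        r2_target,
        fallback,
    )
    return SoftThresholdScan(table, int(fallback), True)


def topological_overlap(
    expr: pd.DataFrame, beta: float, adjacency_type: str = "unsigned"
) -> pd.DataFrame:
    """Topological overlap matrix of the soft-power co-expression network."""
    adj = adjacency(expr, beta, adjacency_type)
    return tom_from_adjacency(adj)


def tom_from_adjacency(adj: pd.DataFrame) -> pd.DataFrame:
    """TOM from an adjacency with zero diagonal; entries lie in [0, 1]."""
    a = adj.to_numpy(dtype=float)
    if not np.all(np.isfinite(a)):
        raise ValidationError("adjacency has non-finite entries")
    k = a.sum(axis=1)
    shared = a @ a
    denom = np.minimum.outer(k, k) + 1.0 - a
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = (shared + a) / denom
    tom = np.where(denom > 0, tom, 0.0)
    np.fill_diagonal(tom, 1.0)
    tom = np.clip((tom + tom.T) / 2.0, 0.0, 1.0)
    return pd.DataFrame(tom, index=adj.index, columns=adj.columns)


@dataclass
class ModuleAssignment:
    """Transcript -> module colour labels ("grey" = unassigned)."""

    labels: pd.Series

    def members(self, module: str) -> list[str]:
        return list(self.labels.index[self.labels == module])

    @property
    def modules(self) -> list[str]:
        sizes = self.labels[self.labels != UNASSIGNED].value_counts()
        return list(sizes.index)


def detect_modules(
    tom: pd.DataFrame, min_module_size: int = 10, cut_height: float = 0.9
) -> ModuleAssignment:
    """Average-linkage clustering of 1 - TOM with a static cut.

    Clusters smaller than ``min_module_size`` become "grey"; surviving
    clusters are named from the colour list in decreasing size order.
    """
    if tom.empty:
        raise ValidationError("empty TOM")
    if min_module_size < 2:
        raise ValidationError("min_module_size must be >= 2")
    d = 1.0 - tom.to_numpy()
    np.fill_diagonal(d, 0.0)
    z = linkage(squareform(d, checks=False), method="average")
    raw = fcluster(z, t=cut_height, criterion="distance")
    labels = pd.Series(UNASSIGNED, index=tom.index, dtype=object, name="module")
    sizes = pd.Series(raw).value_counts()
    kept = [c for c in sizes.index if sizes[c] >= min_module_size]
    # decreasing size; ties broken by first appearance for determinism
    order = sorted(kept, key=lambda c: (-sizes[c], int(np.argmax(raw == c))))
    for rank, cluster in enumerate(order):
        colour = (
            MODULE_COLOURS[rank]
            if rank < len(MODULE_COLOURS)
            else f"module{rank + 1}"
        )
        labels.iloc[np.flatnonzero(raw == cluster)] = colour
    return ModuleAssignment(labels)


@dataclass
class Eigengenes:
    """Module eigengenes (module x sample) with variance explained."""

    scores: pd.DataFrame
    variance_explained: pd.Series


def module_eigengene(expr: pd.DataFrame, assignment: ModuleAssignment) -> Eigengenes:
    """First principal component of each module's standardised submatrix.

    The sign is fixed so the eigengene correlates positively with the
    module's mean standardised expression profile.
    """
    rows = {}
    varexp = {}
    for module in assignment.modules:
        members = assignment.members(module)
        if len(members) < 2:
            raise ValidationError(f"module {module!r} has fewer than 2 members")
        sub = expr.loc[members].to_numpy(dtype=float)
        sd = sub.std(axis=1, ddof=1)
        if np.any(sd == 0):
            raise ValidationError(f"module {module!r} contains constant transcripts")
        z = (sub - sub.mean(axis=1, keepdims=True)) / sd[:, None]
        u, s, vt = np.linalg.svd(z, full_matrices=False)
        me = vt[0]
        mean_profile = z.mean(axis=0)
        orient = np.dot(me, mean_profile)
        if orient < 0 or (orient == 0 and me[np.argmax(np.abs(me))] < 0):
            me = -me
        rows[module] = me
        varexp[module] = float(s[0] ** 2 / np.sum(s**2))
    scores = pd.DataFrame(rows, index=expr.columns).T
    return Eigengenes(scores, pd.Series(varexp, name="variance_explained"))


@dataclass
class ModuleTraitResult:
    """Pearson r (and p) of each eigengene against each trait."""

    correlations: pd.DataFrame  # MultiIndex columns: (trait, {"r","p"})
    hub_module: str | None


def module_trait_correlation(
    eigengenes: Eigengenes,
    traits: pd.DataFrame,
    hub_rule: str = "min_abs",
) -> ModuleTraitResult:
    """Correlate eigengenes with numeric traits and nominate the hub module.

    hub_rule="min_abs" (default) picks argmax of min_t |r_t| — the module
    most correlated with *both* traits; "mean_abs" uses the mean |r|.
    """
    if hub_rule not in ("min_abs", "mean_abs"):
        raise ValidationError(f"unknown hub rule {hub_rule!r}")
    for trait in traits.columns:
        if traits[trait].std(ddof=1) == 0:
            raise ValidationError(f"trait {trait!r} is constant; correlation undefined")
    aligned = traits.loc[eigengenes.scores.columns]
    data = {}
    for module, me in eigengenes.scores.iterrows():
        for trait in traits.columns:
            r, p = stats.pearsonr(me.to_numpy(), aligned[trait].to_numpy())
            data[(trait, "r")] = data.get((trait, "r"), {})
            data[(trait, "p")] = data.get((trait, "p"), {})
            data[(trait, "r")][module] = float(r)
            data[(trait, "p")][module] = float(p)
    correlations = pd.DataFrame(
        {key: pd.Series(vals) for key, vals in data.items()}
    )
    correlations.columns = pd.MultiIndex.from_tuples(correlations.columns)
    hub = None
    if len(correlations):
        r_abs = correlations.loc[:, pd.IndexSlice[:, "r"]].abs()
        score = r_abs.min(axis=1) if hub_rule == "min_abs" else r_abs.mean(axis=1)
        hub = str(score.sort_values(ascending=False, kind="stable").index[0])
    return ModuleTraitResult(correlations, hub)


def sample_dendrogram(expr: pd.DataFrame) -> np.ndarray:
    """Average-linkage linkage matrix over samples (outlier diagnostic only)."""
    d = 1.0 - np.corrcoef(expr.to_numpy().T)
    np.fill_diagonal(d, 0.0)
    return linkage(squareform(np.clip(d, 0, 2), checks=False), method="average")
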