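"""lncRNA target networks: cis proximity, trans correlation, ceRNA triads.

cis: a lncRNA/mRNA pair is linked when both lie on one chromosome and
their spans overlap or sit within a window (default 10 kb, boundary
inclusive); the relation labels where the mRNA lies relative to the
lncRNA in strand-agnostic genomic order. trans: pairs whose expression
profiles correlate beyond |r| >= 0.95 on log2(FPKM+1). ceRNA: lncRNA and
mRNA sharing seed-complementary sites of one miRNA form a
lncRNA-miRNA-mRNA triad. Hub lncRNAs are ranked by trans-network degree.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .data import ExpressionMatrix, TranscriptAnnotation, ValidationError, LNC_BIOTYPES

log = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
SEED_MATCH_RULES = ("8mer", "7mer-m8", "7mer-A1", "6mer")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class CisPair:
    lncrna_id: str
    mrna_id: str
    relation: str  # upstream | downstream | overlapping (mRNA vs lncRNA)
    gap_bp: int  # 0 when overlapping
    opposite_strand: bool


def cis_pairs(
    annotation: TranscriptAnnotation,
    lncrna_set,
    mrna_set,
    window_bp: int = 10_000,
) -> list[CisPair]:
    """All lncRNA/mRNA pairs within ``window_bp`` on a shared chromosome.

    The gap is measured end-to-start between spans; a gap exactly equal to
    the window is included ("within"). Transcripts without coordinates are
    skipped with a warning.
    """
    if window_bp <= 0:
        raise ValidationError("window_bp must be > 0")
    table = annotation.table

    def rows_for(ids):
        kept = []
        for t in ids:
            if t not in table.index:
                log.warning("skipping %s: no coordinates in annotation", t)
                continue
            kept.append(t)
        return table.loc[kept]

    lnc = rows_for(lncrna_set)
    mrna = rows_for(mrna_set)
    out: list[CisPair] = []
    for lnc_id, lrow in lnc.iterrows():
        same = mrna[mrna["chrom"] == lrow["chrom"]]
        for mrna_id, mrow in same.iterrows():
            if mrna_id == lnc_id:
                continue
            if mrow["start"] <= lrow["end"] and lrow["start"] <= mrow["end"]:
                relation, gap = "overlapping", 0
            elif mrow["end"] < lrow["start"]:
                relation, gap = "upstream", int(lrow["start"] - mrow["end"])
            else:
                relation, gap = "downstream", int(mrow["start"] - lrow["end"])
            if gap > window_bp:
                continue
            out.append(
                CisPair(
                    lnc_id,
                    mrna_id,
                    relation,
                    gap,
                    bool(lrow["strand"] != mrow["strand"]),
                )
            )
    out.sort(key=lambda p: (p.lncrna_id, p.mrna_id))
    return out


@dataclass(frozen=True)
class TransEdge:
    lncrna_id: str
    mrna_id: str
    pearson_r: float

    @property
    def sign(self) -> str:
        return "positive" if self.pearson_r >= 0 else "negative"


def trans_pairs(
    matrix: ExpressionMatrix,
    lncrna_set,
    mrna_set,
    r_threshold: float = 0.95,
    log_scale: bool = True,
) -> list[TransEdge]:
    """lncRNA/mRNA pairs with |Pearson r| >= r_threshold across all samples."""
    if not 0 < r_threshold <= 1:
        raise ValidationError("r_threshold must lie in (0, 1]")
    if matrix.values.shape[1] < 3:
        raise ValidationError("need at least 3 samples for trans correlation")
    expr = matrix.log2p1() if log_scale else matrix.values
    lnc_ids = [t for t in lncrna_set if t in expr.index]
    mrna_ids = [t for t in mrna_set if t in expr.index]
    if not lnc_ids or not mrna_ids:
        return []

    def standardise(ids):
        x = expr.loc[ids].to_numpy(dtype=float)
        sd = x.std(axis=1, ddof=1)
        keep = sd > 0
        for t, ok in zip(ids, keep):
            if not ok:
                log.warning("skipping %s: constant expression profile", t)
        x = x[keep]
        x = (x - x.mean(axis=1, keepdims=True)) / sd[keep][:, None]
        return [t for t, ok in zip(ids, keep) if ok], x

    lnc_ids, zl = standardise(lnc_ids)
    mrna_ids, zm = standardise(mrna_ids)
    if not lnc_ids or not mrna_ids:
        return []
    r = np.clip(zl @ zm.T / (zl.shape[1] - 1), -1.0, 1.0)
    out = [
        TransEdge(lnc_ids[i], mrna_ids[j], float(r[i, j]))
        for i, j in zip(*np.nonzero(np.abs(r) >= r_threshold))
        if lnc_ids[i] != mrna_ids[j]
    ]
    out.sort(key=lambda e: (e.lncrna_id, e.mrna_id))
    return out


@dataclass(frozen=True)
class SeedSite:
    """One seed-complementary site on a target, 1-based start of the 6mer core."""

    mirna_id: str
    target_id: str
    start: int
    match_type: str  # 8mer | 7mer-m8 | 7mer-A1 | 6mer


def _normalise_rna(seq: str, what: str) -> str:
    s = seq.upper().replace("U", "T")
    bad = set(s) - set("ACGT")
    if bad:
        raise ValidationError(f"invalid characters in {what}: {sorted(bad)}")
    return s


def seed_match_sites(
    target_sequence: str,
    mirna_sequence: str,
    rules=SEED_MATCH_RULES,
    *,
    target_id: str = "",
    mirna_id: str = "",
) -> list[SeedSite]:
    """Canonical seed matches of a miRNA on a target written 5'->3'.

    The target is scanned for reverse complements of miRNA positions 2-7
    (the 6mer core); each hit is classified by m8 complementarity (the
    target base 5' of the core pairing miRNA position 8) and by an A
    opposite miRNA position 1 (the target base 3' of the core):
    8mer > 7mer-m8 > 7mer-A1 > 6mer, strongest class per location.
    ``mirna_sequence`` may be a full miRNA (>= 8 nt) or the 7-nt seed
    (positions 2-8). T and U are equivalent on input.
    """
    rules = tuple(rules)
    unknown = set(rules) - set(SEED_MATCH_RULES)
    if unknown:
        raise ValidationError(f"unknown seed-match rules: {sorted(unknown)}")
    target = _normalise_rna(target_sequence, "target sequence")
    mir = _normalise_rna(mirna_sequence, "miRNA sequence")
    if len(mir) == 7:  # seed positions 2-8
        core, m8 = mir[:6], mir[6]
    elif len(mir) >= 8:
        core, m8 = mir[1:7], mir[7]
    else:
        raise ValidationError("miRNA sequence must be a 7-nt seed or >= 8 nt")
    core_rc = _revcomp(core)
    m8_rc = m8.translate(_COMPLEMENT)
    sites: list[SeedSite] = []
    at = target.find(core_rc)
    while at != -1:
        has_m8 = at > 0 and target[at - 1] == m8_rc
        has_a1 = at + 6 < len(target) and target[at + 6] == "A"
        if has_m8 and has_a1:
            match_type = "8mer"
        elif has_m8:
            match_type = "7mer-m8"
        elif has_a1:
            match_type = "7mer-A1"
        else:
            match_type = "6mer"
        if match_type in rules:
            sites.append(SeedSite(mirna_id, target_id, at + 1, match_type))
        at = target.find(core_rc, at + 1)
    return sites


def find_all_sites(
    sequences: dict[str, str],
    mirnas: dict[str, str] | pd.DataFrame,
    rules=SEED_MATCH_RULES,
) -> pd.DataFrame:
    """Seed sites of every miRNA on every sequence, as a tidy table.

    ``mirnas`` is either an id -> sequence dict or a seed table with
    columns (mirna_id, seed_7mer).
    """
    if isinstance(mirnas, pd.DataFrame):
        mirnas = dict(zip(mirnas["mirna_id"], mirnas["seed_7mer"]))
    rows = []
    for target_id in sorted(sequences):
        for mirna_id in sorted(mirnas):
            for site in seed_match_sites(
                sequences[target_id],
                mirnas[mirna_id],
                rules,
                target_id=target_id,
                mirna_id=mirna_id,
            ):
                rows.append((site.mirna_id, site.target_id, site.start, site.match_type))
    return pd.DataFrame(rows, columns=["mirna_id", "target_id", "start", "match_type"])


@dataclass(frozen=True)
class CeRNATriad:
    lncrna_id: str
    mirna_id: str
    mrna_id: str
    lnc_site_count: int
    mrna_site_count: int


def cerna_triads(
    lnc_sites: pd.DataFrame, mrna_sites: pd.DataFrame, min_sites: int = 1
) -> list[CeRNATriad]:
    """Triads (lncRNA, miRNA, mRNA) sharing >= min_sites sites of one miRNA."""
    if min_sites < 1:
        raise ValidationError("min_sites must be >= 1")
    out: list[CeRNATriad] = []
    if lnc_sites.empty or mrna_sites.empty:
        return out
    lnc_counts = lnc_sites.groupby(["mirna_id", "target_id"]).size()
    mrna_counts = mrna_sites.groupby(["mirna_id", "target_id"]).size()
    for mirna_id in sorted(set(lnc_counts.index.get_level_values(0)) & set(mrna_counts.index.get_level_values(0))):
        lncs = lnc_counts[mirna_id]
        mrnas = mrna_counts[mirna_id]
        for lnc_id, n_l in lncs.items():
            if n_l < min_sites:
                continue
            for mrna_id, n_m in mrnas.items():
                if n_m < min_sites or mrna_id == lnc_id:
                    continue
                out.append(CeRNATriad(lnc_id, mirna_id, mrna_id, int(n_l), int(n_m)))
    out.sort(key=lambda t: (t.lncrna_id, t.mirna_id, t.mrna_id))
    return out


def hub_rank(trans_edges: list[TransEdge], top_n: int = 10) -> pd.DataFrame:
    """lncRNAs ranked by trans-network degree (unique mRNA partners).

    Ties are broken lexicographically by id.
    """
    if top_n < 1:
        raise ValidationError("top_n must be >= 1")
    partners: dict[str, set[str]] = {}
    for e in trans_edges:
        partners.setdefault(e.lncrna_id, set()).add(e.mrna_id)
    ranked = sorted(partners.items(), key=lambda kv: (-len(kv[1]), kv[0]))[:top_n]
    return pd.DataFrame(
        [(lnc, len(m)) for lnc, m in ranked], columns=["lncrna_id", "degree"]
    )


def merge_networks(
    cis: list[CisPair],
    trans: list[TransEdge],
    triads: list[CeRNATriad],
    focus_lncrnas,
    annotation: TranscriptAnnotation | None = None,
    de_direction: dict[str, dict[str, str]] | None = None,
) -> nx.MultiGraph:
    """Typed multigraph of all relations incident to the focus lncRNAs.

    ceRNA triads contribute the miRNA bridge node with lncRNA-miRNA and
    miRNA-mRNA edges. Node attributes carry kind (lncRNA/mRNA/miRNA),
    biotype when annotation is given, and per-contrast DE direction when
    ``de_direction`` (contrast -> transcript -> status) is given. A focus
    lncRNA absent from every network stays as an isolated node.
    """
    focus = list(dict.fromkeys(focus_lncrnas))
    if not focus:
        raise ValidationError("focus set must be non-empty")
    g = nx.MultiGraph()

    def add_node(node: str, kind: str) -> None:
        attrs = {"kind": kind}
        if annotation is not None and node in annotation.table.index:
            attrs["biotype"] = annotation.table.at[node, "biotype"]
        if de_direction:
            for contrast, calls in de_direction.items():
                if node in calls:
                    attrs[f"status_{contrast}"] = calls[node]
        g.add_node(node, **attrs)

    for lnc in focus:
        add_node(lnc, "lncRNA")
    focus_set = set(focus)
    touched = set()
    for p in cis:
        if p.lncrna_id in focus_set:
            add_node(p.mrna_id, "mRNA")
            g.add_edge(
                p.lncrna_id,
                p.mrna_id,
                type="cis",
                relation=p.relation,
                gap_bp=p.gap_bp,
                opposite_strand=p.opposite_strand,
            )
            touched.add(p.lncrna_id)
    for e in trans:
        if e.lncrna_id in focus_set:
            add_node(e.mrna_id, "mRNA")
            g.add_edge(
                e.lncrna_id, e.mrna_id, type="trans", pearson_r=e.pearson_r, sign=e.sign
            )
            touched.add(e.lncrna_id)
    for t in triads:
        if t.lncrna_id in focus_set:
            add_node(t.mirna_id, "miRNA")
            add_node(t.mrna_id, "mRNA")
            g.add_edge(
                t.lncrna_id, t.mirna_id, type="ceRNA", site_count=t.lnc_site_count
            )
            g.add_edge(
                t.mirna_id, t.mrna_id, type="ceRNA", site_count=t.mrna_site_count
            )
            touched.add(t.lncrna_id)
    for lnc in focus_set - touched:
        log.warning("focus lncRNA %s absent from all networks; kept isolated", lnc)
    return g


def biotype_split(
    ids, annotation: TranscriptAnnotation
) -> tuple[list[str], list[str]]:
    """Partition transcript ids into (lncRNA-like, coding)."""
    lnc, coding = [], []
    for t in ids:
        bio = annotation.table.at[t, "biotype"]
        (lnc if bio in LNC_BIOTYPES else coding).append(t)
    return lnc, coding
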