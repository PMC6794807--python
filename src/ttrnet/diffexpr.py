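"""Two-group differential expression and the converse-trend (TTR-DEG) filter.

The screening rule follows the study design: per-transcript Student's
t-test plus fold-change filtering, Benjamini-Hochberg FDR across all
transcripts of a contrast jointly, and significance gates
FC >= 2 (or <= 0.5 for down), P <= 0.05, FDR <= 0.05. A transcript whose
fold changes in (HG vs LG) and (HG+TTR vs HG) carry opposite signs is a
TTR-DEG; strict mode additionally requires significance in both contrasts.

Fold changes are ratios of group-mean FPKM with a pseudocount; t-tests run
on log2(FPKM + 1), where the simulated noise is additive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .data import (
    ExpressionMatrix,
    TranscriptAnnotation,
    ValidationError,
    LNC_BIOTYPES,
)


@dataclass(frozen=True)
class Thresholds:
    """Significance gates for one contrast (defaults are the study's)."""

    fc_threshold: float = 2.0
    p_max: float = 0.05
    q_max: float = 0.05
    pseudocount: float = 1.0

    def __post_init__(self) -> None:
        if self.fc_threshold < 1:
            raise ValidationError("fc_threshold must be >= 1")
        if not (0 < self.p_max <= 1 and 0 < self.q_max <= 1):
            raise ValidationError("p_max and q_max must lie in (0, 1]")
        if self.pseudocount < 0:
            raise ValidationError("pseudocount must be >= 0")


def log2_fold_change(test_values, control_values, pseudocount: float = 1.0) -> float:
    """log2((mean(test) + c) / (mean(control) + c)) with pseudocount c."""
    test_values = np.asarray(test_values, dtype=float)
    control_values = np.asarray(control_values, dtype=float)
    if test_values.size == 0 or control_values.size == 0:
        raise ValidationError("both groups must be non-empty")
    mt = test_values.mean() + pseudocount
    mc = control_values.mean() + pseudocount
    if mt == 0 and mc == 0:
        raise ValidationError("undefined ratio: both means are 0 with pseudocount 0")
    if mc == 0 or mt == 0:
        raise ValidationError("zero group mean requires pseudocount > 0")
    return float(np.log2(mt / mc))


def two_group_t_test(group_a, group_b, variant: str = "student") -> tuple[float, float]:
    """Two-sided t-test; the t sign follows mean(a) - mean(b).

    ``variant`` is "student" (pooled variance, the study's named test) or
    "welch". Zero variance with equal means degenerates to (0, 1); zero
    variance with unequal means to (+-inf, 0).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("each group needs at least 2 values")
    if variant not in ("student", "welch"):
        raise ValidationError(f"unknown t-test variant {variant!r}")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return (np.inf if a.mean() > b.mean() else -np.inf), 0.0
    t, p = stats.ttest_ind(a, b, equal_var=(variant == "student"))
    return float(t), float(p)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values, order-preserving."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or p.min() < 0 or p.max() > 1:
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class ContrastResult:
    """Per-transcript statistics for one two-group contrast.

    ``table`` has columns log2fc, fc, t_stat, p_value, q_value, status
    (up / down / ns), indexed by transcript id.
    """

    table: pd.DataFrame
    test_group: str
    control_group: str
    thresholds: Thresholds = field(default_factory=Thresholds)

    @property
    def significant(self) -> pd.Index:
        return self.table.index[self.table["status"] != "ns"]


def run_contrast(
    matrix: ExpressionMatrix,
    test_group: str,
    control_group: str,
    thresholds: Thresholds | None = None,
    variant: str = "student",
) -> ContrastResult:
    """Screen every transcript for differential expression in one contrast.

    BH adjustment runs across all transcripts jointly (coding and lncRNA
    together). Status is up iff fc >= fc_threshold, down iff
    fc <= 1/fc_threshold, in both cases requiring p <= p_max and
    q <= q_max.
    """
    thresholds = thresholds or Thresholds()
    test_samples = matrix.group_samples(test_group)
    ctrl_samples = matrix.group_samples(control_group)
    if len(test_samples) < 2 or len(ctrl_samples) < 2:
        raise ValidationError(
            f"groups {test_group!r}/{control_group!r} need >= 2 samples each"
        )

    fpkm_test = matrix.values[test_samples].to_numpy()
    fpkm_ctrl = matrix.values[ctrl_samples].to_numpy()
    c = thresholds.pseudocount
    log2fc = np.log2((fpkm_test.mean(axis=1) + c) / (fpkm_ctrl.mean(axis=1) + c))

    log_all = matrix.log2p1()
    a = log_all[test_samples].to_numpy()
    b = log_all[ctrl_samples].to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = stats.ttest_ind(a, b, axis=1, equal_var=(variant == "student"))
    # degenerate zero-variance rows
    var0 = (a.var(axis=1, ddof=1) == 0) & (b.var(axis=1, ddof=1) == 0)
    same = var0 & (a.mean(axis=1) == b.mean(axis=1))
    diff = var0 & ~same
    t = np.where(same, 0.0, t)
    p = np.where(same, 1.0, p)
    t = np.where(diff, np.where(a.mean(axis=1) > b.mean(axis=1), np.inf, -np.inf), t)
    p = np.where(diff, 0.0, p)

    q = bh_fdr(p)
    fc = np.exp2(log2fc)
    passes = (p <= thresholds.p_max) & (q <= thresholds.q_max)
    status = np.where(
        passes & (fc >= thresholds.fc_threshold),
        "up",
        np.where(passes & (fc <= 1.0 / thresholds.fc_threshold), "down", "ns"),
    )
    table = pd.DataFrame(
        {
            "log2fc": log2fc,
            "fc": fc,
            "t_stat": t,
            "p_value": p,
            "q_value": q,
            "status": status,
        },
        index=matrix.transcripts,
    )
    return ContrastResult(table, test_group, control_group, thresholds)


def gene_level_calls(
    contrast: ContrastResult,
    annotation: TranscriptAnnotation,
    rule: str = "any_transcript",
) -> pd.DataFrame:
    """Aggregate transcript calls to genes.

    rule="any_transcript": a gene is DE if any transcript is significant
    (default reading of the study's aggregation sentence);
    rule="at_least_two": the literal ">= 2 transcripts" reading. Genes with
    significant transcripts in both directions get direction_conflict=True.
    """
    if rule not in ("any_transcript", "at_least_two"):
        raise ValidationError(f"unknown gene-level rule {rule!r}")
    unmapped = contrast.table.index.difference(annotation.transcripts)
    if len(unmapped):
        raise ValidationError(f"transcript {unmapped[0]!r} missing from annotation")
    genes = annotation.table.loc[contrast.table.index, "gene_id"]
    df = contrast.table.assign(gene_id=genes.to_numpy())
    rows = []
    for gene, sub in df.groupby("gene_id", sort=True):
        n_sig = int((sub["status"] != "ns").sum())
        need = 1 if rule == "any_transcript" else 2
        call = "de" if n_sig >= need else "ns"
        conflict = bool({"up", "down"} <= set(sub["status"]))
        rows.append((gene, call, n_sig, conflict))
    return pd.DataFrame(
        rows, columns=["gene_id", "call", "n_significant_transcripts", "direction_conflict"]
    ).set_index("gene_id")


@dataclass
class TTRDEGSet:
    """Transcripts with converse fold-change trend between the two contrasts.

    ``table`` carries both contrasts' statistics side by side; members are
    split by biotype into mRNA and lncRNA lists when annotation is given.
    """

    table: pd.DataFrame
    mode: str
    mrna_ids: list[str] = field(default_factory=list)
    lncrna_ids: list[str] = field(default_factory=list)

    @property
    def transcripts(self) -> list[str]:
        return list(self.table.index)


def ttr_trend_filter(
    hg_vs_lg: ContrastResult,
    ttr_vs_hg: ContrastResult,
    mode: str = "strict",
    annotation: TranscriptAnnotation | None = None,
) -> TTRDEGSet:
    """Select transcripts whose two contrasts trend in opposite directions.

    Membership requires sign(log2fc1) * sign(log2fc2) < 0; "strict" mode
    (default) also requires significance in both contrasts, "lenient" only
    in the TTR contrast.
    """
    if mode not in ("strict", "lenient"):
        raise ValidationError(f"unknown trend-filter mode {mode!r}")
    t1, t2 = hg_vs_lg.table, ttr_vs_hg.table
    if not t1.index.equals(t2.index):
        raise ValidationError("contrasts cover different transcript universes")
    opposite = np.sign(t1["log2fc"]) * np.sign(t2["log2fc"]) < 0
    sig1 = t1["status"] != "ns"
    sig2 = t2["status"] != "ns"
    member = opposite & sig2 & (sig1 if mode == "strict" else True)
    table = pd.DataFrame(
        {
            "log2fc_hg_vs_lg": t1["log2fc"],
            "p_hg_vs_lg": t1["p_value"],
            "fdr_hg_vs_lg": t1["q_value"],
            "status_hg_vs_lg": t1["status"],
            "log2fc_ttr_vs_hg": t2["log2fc"],
            "p_ttr_vs_hg": t2["p_value"],
            "fdr_ttr_vs_hg": t2["q_value"],
            "status_ttr_vs_hg": t2["status"],
        }
    ).loc[member]
    mrna_ids: list[str] = []
    lncrna_ids: list[str] = []
    if annotation is not None:
        bio = annotation.table["biotype"]
        for t in table.index:
            if t not in bio.index:
                raise ValidationError(f"transcript {t!r} missing from annotation")
            (lncrna_ids if bio[t] in LNC_BIOTYPES else mrna_ids).append(t)
    return TTRDEGSet(table.sort_index(), mode, mrna_ids, lncrna_ids)


def ddct_relative_expression(
    ct_target_test: float,
    ct_ref_test: float,
    ct_target_ctrl: float,
    ct_ref_ctrl: float,
) -> float:
    """Comparative qRT-PCR quantification, fold = 2^(-ddCt)."""
    cts = (ct_target_test, ct_ref_test, ct_target_ctrl, ct_ref_ctrl)
    if not all(np.isfinite(cts)):
        raise ValidationError("all Ct values must be finite")
    ddct = (ct_target_test - ct_ref_test) - (ct_target_ctrl - ct_ref_ctrl)
    return float(2.0 ** (-ddct))


def mean_ratio(group_a_values, group_b_values, decimals: int | None = None) -> float:
    """mean(a) / mean(b), optionally rounded to ``decimals`` places."""
    a = np.asarray(group_a_values, dtype=float)
    b = np.asarray(group_b_values, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("both groups must be non-empty")
    if b.mean() <= 0:
        raise ValidationError("undefined ratio: denominator mean must be > 0")
    ratio = float(a.mean() / b.mean())
    return round(ratio, decimals) if decimals is not None else ratio
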