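"""Synthetic dataset generator with known ground truth.

Emulates the three-arm design of the study system (human retinal
endothelial cells in low glucose, high glucose, and high glucose plus
transthyretin; three RNA-seq replicates per arm) at desk scale:

* log-normal FPKM: log2(FPKM + 1) drawn normal around per-group means and
  back-transformed, so the downstream t-tests and Pearson correlations see
  roughly additive noise;
* planted up/down differentially expressed transcripts at a fixed log2
  effect in each of the two contrasts (HG vs LG and HG+TTR vs HG);
* planted trend-reversal transcripts whose effects in the two contrasts
  have opposite sign (the converse-trend "TTR-DEG" targets);
* planted co-expression modules whose shared latent factor is correlated
  with a binary glucose or TTR trait at a target Pearson r;
* planted cis lncRNA/mRNA neighbours at controlled genomic gaps, including
  one pair exactly at the window boundary, an antisense-overlapping pair,
  and decoys just outside the window;
* planted ceRNA triads whose lncRNA and mRNA sequences each carry an exact
  seed-complement site of the triad's miRNA, with rejection sampling so
  that no other sequence contains any seed match at all.

Every operation derives its RNG deterministically from ``rng_seed``, so a
given config always produces byte-identical files.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, model_validator

from .data import (
    ConfigError,
    ExpressionMatrix,
    GenerationError,
    GroundTruth,
    TranscriptAnnotation,
)

GROUPS = ("LG", "HG", "HG_TTR")

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

# substream indices so that independently callable ops never share draws
_STREAM_EXPRESSION = 1
_STREAM_ANNOTATION = 2
_STREAM_SEQUENCES = 3
_STREAM_PPI = 4


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class SimulationConfig(BaseModel):
    """Parameters of one synthetic dataset.

    Defaults encode the desk-scale study conditions: 400 coding + 50 lncRNA
    transcripts, a 3x3x3 design, 40 up / 40 down planted DE transcripts per
    contrast of which 30 reverse trend between contrasts, a log2 effect of
    2.0 over noise sd 0.25, two 50-member trait-linked modules at target
    |r| = 0.85, a 10 kb cis window and five rejection-sampled ceRNA triads.
    """

    model_config = ConfigDict(extra="forbid", frozen=True)

    n_coding: int = 400
    n_lncrna: int = 50
    n_replicates_per_group: int = 3
    groups: tuple[str, str, str] = GROUPS
    n_de_up: int = 40
    n_de_down: int = 40
    n_trend_reversal: int = 30
    log2fc_effect: float = 2.0
    noise_sd: float = 0.25
    n_modules: int = 2
    module_size: int = 50
    module_trait_cor: float = 0.85
    cis_window_bp: int = 10_000
    n_cis_pairs: int = 8
    n_mirnas: int = 10
    seed_length: int = 7
    n_cerna_triads: int = 5
    rng_seed: int = 0

    @model_validator(mode="after")
    def _check_invariants(self) -> "SimulationConfig":
        counts = {
            "n_coding": self.n_coding,
            "n_lncrna": self.n_lncrna,
            "n_replicates_per_group": self.n_replicates_per_group,
            "n_de_up": self.n_de_up,
            "n_de_down": self.n_de_down,
            "n_trend_reversal": self.n_trend_reversal,
            "n_modules": self.n_modules,
            "module_size": self.module_size,
            "n_cis_pairs": self.n_cis_pairs,
            "n_mirnas": self.n_mirnas,
            "n_cerna_triads": self.n_cerna_triads,
        }
        for name, value in counts.items():
            if value < 0:
                raise ConfigError(f"{name} must be >= 0 (got {value})")
        if self.n_trend_reversal > self.n_de_up + self.n_de_down:
            raise ConfigError("n_trend_reversal must be <= n_de_up + n_de_down")
        if self.module_size * self.n_modules > self.n_coding + self.n_lncrna:
            raise ConfigError("module_size * n_modules must be <= n_coding + n_lncrna")
        if self.noise_sd <= 0:
            raise ConfigError("noise_sd must be > 0")
        if self.log2fc_effect < 0:
            raise ConfigError("log2fc_effect must be >= 0")
        if not 0 <= self.module_trait_cor < 1:
            raise ConfigError("module_trait_cor must be in [0, 1)")
        if self.cis_window_bp <= 0:
            raise ConfigError("cis_window_bp must be > 0")
        if self.seed_length != 7:
            raise ConfigError("seed_length: only the canonical 7-nt seed (positions 2-8) is supported")
        if self.n_cerna_triads > 0 and (
            self.n_cerna_triads > self.n_mirnas
            or self.n_cerna_triads > self.n_lncrna
            or self.n_cerna_triads > self.n_coding
        ):
            raise ConfigError("n_cerna_triads must be <= n_mirnas, n_lncrna and n_coding")
        # DE/module bookkeeping must fit inside the transcript universe
        n_unique_de = 2 * (self.n_de_up + self.n_de_down) - self.n_trend_reversal
        if n_unique_de + self.n_modules * self.module_size > self.n_coding + self.n_lncrna:
            raise ConfigError(
                "planted DE transcripts plus module members exceed the transcript universe"
            )
        return self

    # -- identifier layout ------------------------------------------------

    def transcript_frame(self) -> pd.DataFrame:
        """Deterministic id/biotype/gene layout shared by all generator ops.

        One in ten coding genes carries two transcripts (to exercise
        gene-level aggregation); one in five lncRNAs is flagged as a novel
        assembly-style lncRNA.
        """
        rows: list[tuple[str, str, str]] = []  # (transcript, gene, biotype)
        n_multi = self.n_coding // 10
        gi = 0
        produced = 0
        while produced < self.n_coding:
            gene = f"GENE{gi:04d}"
            rows.append((f"{gene}.t1", gene, "coding"))
            produced += 1
            if gi < n_multi and produced < self.n_coding:
                rows.append((f"{gene}.t2", gene, "coding"))
                produced += 1
            gi += 1
        n_novel = self.n_lncrna // 5
        for i in range(self.n_lncrna):
            gene = f"LNC{i:04d}"
            biotype = "novel_lncRNA" if i < n_novel else "lncRNA"
            rows.append((f"{gene}.t1", gene, biotype))
        frame = pd.DataFrame(rows, columns=["transcript_id", "gene_id", "biotype"])
        return frame.set_index("transcript_id")

    def sample_ids(self) -> list[str]:
        return [f"{g}_{r + 1}" for g in self.groups for r in range(self.n_replicates_per_group)]

    def sample_groups(self) -> pd.Series:
        return pd.Series(
            {s: s.rsplit("_", 1)[0] for s in self.sample_ids()}, name="group"
        )

    def trait_table(self) -> pd.DataFrame:
        """Binary traits over samples: glucose (HG and HG+TTR) and ttr (HG+TTR)."""
        design = self.sample_groups()
        glucose = (design != self.groups[0]).astype(float)
        ttr = (design == self.groups[2]).astype(float)
        return pd.DataFrame({"glucose": glucose, "ttr": ttr})


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([stream, config.rng_seed])


def _planted_assignments(config: SimulationConfig) -> dict[str, object]:
    """Deterministic split of the transcript universe into planted roles."""
    frame = config.transcript_frame()
    ids = list(frame.index)
    rng = _rng(config, _STREAM_EXPRESSION)
    perm = [ids[i] for i in rng.permutation(len(ids))]

    n_r = config.n_trend_reversal
    n_r_up = min(max(math.ceil(n_r / 2), n_r - config.n_de_down), config.n_de_up)
    n_r_down = n_r - n_r_up

    take = 0

    def grab(n: int) -> list[str]:
        nonlocal take
        out = perm[take : take + n]
        take += n
        return out

    rev_up = grab(n_r_up)      # up in HG vs LG, down in HG+TTR vs HG
    rev_down = grab(n_r_down)  # down in HG vs LG, up in HG+TTR vs HG
    c1_up = grab(config.n_de_up - n_r_up)
    c1_down = grab(config.n_de_down - n_r_down)
    c2_up = grab(config.n_de_up - n_r_down)
    c2_down = grab(config.n_de_down - n_r_up)
    modules = {m: grab(config.module_size) for m in range(config.n_modules)}
    return {
        "frame": frame,
        "rng": rng,
        "rev_up": rev_up,
        "rev_down": rev_down,
        "c1_up": c1_up,
        "c1_down": c1_down,
        "c2_up": c2_up,
        "c2_down": c2_down,
        "modules": modules,
    }


def _unit(v: np.ndarray) -> np.ndarray:
    v = v - v.mean()
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise GenerationError("degenerate direction while building module factors")
    return v / n


def _module_factor(
    rng: np.random.Generator,
    trait: np.ndarray,
    rho: float,
    previous: list[np.ndarray],
    all_traits: list[np.ndarray] = (),
) -> np.ndarray:
    """Per-sample latent factor with sample correlation exactly ``rho`` to
    its trait and exactly zero to every previously planted factor.

    Works in the centred unit-vector geometry where Pearson correlation is
    a dot product: the trait direction is orthogonalised against earlier
    factors (rescaling rho accordingly) and completed with a random
    direction orthogonal to everything planted so far. Raises when the
    requested correlation is infeasible given trait collinearity.
    """
    z = _unit(trait.astype(float))
    d = z.copy()
    for f in previous:
        d = d - (d @ f) * f
    nd = np.linalg.norm(d)
    if nd < 1e-9 or rho / nd > 1:
        raise ConfigError(
            "module_trait_cor infeasible: planted factors leave too little of the "
            "trait direction free (lower module_trait_cor or n_modules)"
        )
    d_unit = d / nd
    rho_eff = rho / nd
    trait_units = [_unit(t.astype(float)) for t in all_traits] or [z]
    for _ in range(_MAX_REJECTION_TRIES):
        u = _unit(rng.standard_normal(z.size))
        for v in [d_unit, *trait_units, *previous]:
            u = u - (u @ v) * v
        norm = np.linalg.norm(u)
        if norm > 1e-6:
            u = u / norm
            break
    else:  # pragma: no cover - requires pathological dimensionality
        raise GenerationError("could not draw an orthogonal factor direction")
    f_unit = rho_eff * d_unit + math.sqrt(max(0.0, 1 - rho_eff**2)) * u
    return f_unit


def generate_expression(config: SimulationConfig) -> tuple[ExpressionMatrix, GroundTruth]:
    """Simulate the FPKM matrix and its ground truth.

    Group-mean log2(FPKM+1) values of planted DE transcripts differ by
    exactly +-log2fc_effect before noise; trend-reversal transcripts carry
    opposite-signed effects in the two contrasts. Module members add a
    shared latent factor with loading 3 x noise_sd (within-module
    correlation ~0.9); even-numbered modules track the glucose trait,
    odd-numbered modules the TTR trait.
    """
    parts = _planted_assignments(config)
    frame: pd.DataFrame = parts["frame"]
    rng: np.random.Generator = parts["rng"]
    ids = list(frame.index)
    n = len(ids)
    samples = config.sample_ids()
    design = config.sample_groups()
    idx = {t: i for i, t in enumerate(ids)}

    e = config.log2fc_effect
    delta1 = np.zeros(n)  # HG offset relative to LG
    delta2 = np.zeros(n)  # HG+TTR offset relative to HG
    for t in parts["rev_up"]:
        delta1[idx[t]], delta2[idx[t]] = e, -e
    for t in parts["rev_down"]:
        delta1[idx[t]], delta2[idx[t]] = -e, e
    for t in parts["c1_up"]:
        delta1[idx[t]] = e
    for t in parts["c1_down"]:
        delta1[idx[t]] = -e
    for t in parts["c2_up"]:
        delta2[idx[t]] = e
    for t in parts["c2_down"]:
        delta2[idx[t]] = -e

    baseline = rng.uniform(3.0, 8.0, size=n)
    in_hg = (design.values != config.groups[0]).astype(float)
    in_ttr = (design.values == config.groups[2]).astype(float)

    x = baseline[:, None] + np.outer(delta1, in_hg) + np.outer(delta2, in_ttr)

    traits = config.trait_table()
    loading = 3.0 * config.noise_sd
    module_labels: dict[str, int] = {}
    factor_units: list[np.ndarray] = []
    n_samples = len(samples)
    all_trait_vecs = [traits[c].to_numpy() for c in traits.columns]
    for m, members in parts["modules"].items():
        trait = traits["glucose" if m % 2 == 0 else "ttr"].to_numpy()
        f_unit = _module_factor(
            rng, trait, config.module_trait_cor, factor_units, all_trait_vecs
        )
        factor_units.append(f_unit)
        factor = f_unit * math.sqrt(n_samples - 1)  # per-sample sd 1
        for t in members:
            x[idx[t]] += loading * factor
            module_labels[t] = m

    x = x + rng.normal(0.0, config.noise_sd, size=x.shape)
    fpkm = np.maximum(np.exp2(x) - 1.0, 1e-9)

    matrix = ExpressionMatrix(
        values=pd.DataFrame(fpkm, index=pd.Index(ids, name="transcript_id"), columns=samples),
        design=design,
    )
    truth = GroundTruth(
        de_hg_vs_lg={
            **{t: "up" for t in parts["rev_up"] + parts["c1_up"]},
            **{t: "down" for t in parts["rev_down"] + parts["c1_down"]},
        },
        de_ttr_vs_hg={
            **{t: "down" for t in parts["rev_up"] + parts["c2_down"]},
            **{t: "up" for t in parts["rev_down"] + parts["c2_up"]},
        },
        trend_reversal_set=sorted(parts["rev_up"] + parts["rev_down"]),
        module_labels=module_labels,
    )
    return matrix, truth


def generate_annotation(
    config: SimulationConfig, truth: Optional[GroundTruth] = None
) -> TranscriptAnnotation:
    """Genomic layout with planted cis neighbourhoods.

    Planted lncRNA/mRNA pairs live on private chromosomes: pair 0 is an
    antisense-overlapping arrangement, pair 1 sits exactly at the window
    boundary (gap == cis_window_bp, inclusive by the "within" rule), the
    rest alternate downstream/upstream at random gaps inside the window.
    Half as many decoy pairs are placed just outside the window. All other
    transcripts are spaced 3 windows apart so no accidental pair exists.
    If ``truth`` is given, the planted pairs are recorded on it.
    """
    frame = config.transcript_frame()
    rng = _rng(config, _STREAM_ANNOTATION)
    lnc_ids = list(frame.index[frame["biotype"] != "coding"])
    mrna_ids = list(frame.index[frame["biotype"] == "coding"])

    # pair only single-transcript coding genes so a gene never spans two chromosomes
    mrna_single = [t for t in mrna_ids if f"{frame.at[t, 'gene_id']}.t2" not in frame.index]
    n_pairs = min(config.n_cis_pairs, len(lnc_ids), len(mrna_single))
    n_decoys = min(
        n_pairs // 2 + (1 if n_pairs else 0),
        len(lnc_ids) - n_pairs,
        len(mrna_single) - n_pairs,
    )
    n_decoys = max(n_decoys, 0)

    lnc_pick = [lnc_ids[i] for i in rng.permutation(len(lnc_ids))]
    mrna_pick = [mrna_single[i] for i in rng.permutation(len(mrna_single))]

    rows: dict[str, tuple[str, int, int, str]] = {}  # id -> (chrom, start, end, strand)
    cis_pairs: list[tuple[str, str, str]] = []
    boundary: list[tuple[str, str]] = []
    decoys: list[tuple[str, str]] = []
    w = config.cis_window_bp

    def span_len() -> int:
        return int(rng.integers(300, 601))

    for p in range(n_pairs):
        lnc, mrna = lnc_pick[p], mrna_pick[p]
        chrom = f"chrP{p:02d}"
        l_start = 100_001
        l_end = l_start + span_len() - 1
        if p == 0:
            # antisense overlap (FRMD6-AS2 / FRMD6-like arrangement)
            m_start = l_start + (l_end - l_start) // 2
            m_end = m_start + span_len() - 1
            rows[lnc] = (chrom, l_start, l_end, "-")
            rows[mrna] = (chrom, m_start, m_end, "+")
            cis_pairs.append((lnc, mrna, "overlapping"))
            continue
        strand_l = "+" if rng.random() < 0.5 else "-"
        strand_m = "+" if rng.random() < 0.5 else "-"
        if p == 1:
            gap = w  # boundary case: included by the inclusive "within" rule
        else:
            gap = int(rng.integers(1, w))
        if p % 2 == 1:  # mRNA after the lncRNA in genomic order -> downstream
            m_start = l_end + gap
            m_end = m_start + span_len() - 1
            relation = "downstream"
        else:  # mRNA before the lncRNA -> upstream
            m_end_target = l_start - gap
            m_start = m_end_target - span_len() + 1
            m_end = m_end_target
            relation = "upstream"
        rows[lnc] = (chrom, l_start, l_end, strand_l)
        rows[mrna] = (chrom, m_start, m_end, strand_m)
        cis_pairs.append((lnc, mrna, relation))
        if p == 1:
            boundary.append((lnc, mrna))

    for d in range(n_decoys):
        lnc, mrna = lnc_pick[n_pairs + d], mrna_pick[n_pairs + d]
        chrom = f"chrD{d:02d}"
        l_start = 100_001
        l_end = l_start + span_len() - 1
        gap = w + 1 if d == 0 else w + 1 + int(rng.integers(1, w))
        m_start = l_end + gap
        rows[lnc] = (chrom, l_start, l_end, "+")
        rows[mrna] = (chrom, m_start, m_start + span_len() - 1, "+")
        decoys.append((lnc, mrna))

    # remaining transcripts: 3-window spacing, multi-transcript genes overlap
    spacing = 3 * w
    pos = 1
    chrom_i = 0
    per_chrom = 0
    gene_locus: dict[str, tuple[str, int, int]] = {}
    for t in frame.index:
        if t in rows:
            continue
        gene = frame.at[t, "gene_id"]
        if gene in gene_locus:  # second transcript of a gene: overlapping span
            chrom, g_start, g_end = gene_locus[gene]
            start = g_start + 100
            rows[t] = (chrom, start, start + span_len() - 1, rows[f"{gene}.t1"][3])
            continue
        if per_chrom >= 50:
            chrom_i += 1
            per_chrom = 0
            pos = 1
        chrom = f"chrA{chrom_i:02d}"
        start = pos
        end = start + span_len() - 1
        strand = "+" if rng.random() < 0.5 else "-"
        rows[t] = (chrom, start, end, strand)
        gene_locus[gene] = (chrom, start, end)
        pos = end + spacing
        per_chrom += 1

    table = pd.DataFrame(
        {
            "gene_id": frame["gene_id"],
            "gene_name": frame["gene_id"],
            "biotype": frame["biotype"],
            "chrom": [rows[t][0] for t in frame.index],
            "start": [rows[t][1] for t in frame.index],
            "end": [rows[t][2] for t in frame.index],
            "strand": [rows[t][3] for t in frame.index],
        },
        index=frame.index,
    )
    if truth is not None:
        truth.cis_pairs = cis_pairs
        truth.cis_boundary_pairs = boundary
        truth.cis_decoy_pairs = decoys
    return TranscriptAnnotation(table)


_MAX_REJECTION_TRIES = 1000


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))


def _has_core_match(seq: str, cores_rc: list[str]) -> bool:
    return any(c in seq for c in cores_rc)


def generate_sequences(
    annotation: TranscriptAnnotation,
    config: SimulationConfig,
    truth: Optional[GroundTruth] = None,
) -> tuple[dict[str, str], pd.DataFrame]:
    """Transcript sequences plus the miRNA seed table.

    Background sequences are rejection-sampled to contain no reverse
    complement of any miRNA 6-mer core (positions 2-7), so the only seed
    sites in the dataset are the planted ones. Each planted triad's lncRNA
    and mRNA receive one exact 8mer site (reverse complement of miRNA
    positions 2-8 followed by an A opposite position 1). Sequence length
    equals the annotated genomic span (single-interval transcripts).
    If ``truth`` is given, the planted triads are recorded on it.
    """
    rng = _rng(config, _STREAM_SEQUENCES)

    mirnas: dict[str, str] = {}
    seeds_seen: set[str] = set()
    for i in range(config.n_mirnas):
        for _ in range(_MAX_REJECTION_TRIES):
            seq = _random_seq(rng, 22)
            seed = seq[1:8]
            if seed not in seeds_seen:
                seeds_seen.add(seed)
                mirnas[f"mir{i:03d}"] = seq
                break
        else:  # pragma: no cover
            raise GenerationError("could not draw distinct miRNA seeds; lower n_mirnas")
    mirna_ids = list(mirnas)
    cores_rc = [_revcomp(seq[1:7]) for seq in mirnas.values()]

    lnc_ids = annotation.lncrna_ids()
    mrna_ids = annotation.coding_ids()
    triads: list[tuple[str, str, str]] = []
    site_for: dict[str, str] = {}  # transcript -> 8mer site string to embed
    for k in range(min(config.n_cerna_triads, len(lnc_ids), len(mrna_ids), len(mirna_ids))):
        lnc, mir, mrna = lnc_ids[k], mirna_ids[k], mrna_ids[k]
        site = _revcomp(mirnas[mir][1:8]) + "A"
        triads.append((lnc, mir, mrna))
        site_for[lnc] = site
        site_for[mrna] = site

    sequences: dict[str, str] = {}
    for t in annotation.transcripts:
        length = int(annotation.table.at[t, "end"] - annotation.table.at[t, "start"] + 1)
        planted = site_for.get(t)
        for _ in range(_MAX_REJECTION_TRIES):
            seq = _random_seq(rng, length)
            if planted is not None:
                pos = int(rng.integers(1, length - len(planted)))
                seq = seq[:pos] + planted + seq[pos + len(planted) :]
                # the embedded site must be the only core match anywhere
                if sum(seq.count(c) for c in cores_rc) == 1:
                    break
            elif not _has_core_match(seq, cores_rc):
                break
        else:
            raise GenerationError(
                f"rejection sampling failed for {t!r}; use longer sequences or fewer miRNAs"
            )
        sequences[t] = seq

    seed_table = pd.DataFrame(
        {"mirna_id": mirna_ids, "seed_7mer": [mirnas[m][1:8].replace("T", "U") for m in mirna_ids]}
    )
    if truth is not None:
        truth.planted_triads = triads
    return sequences, seed_table


def generate_ppi(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, list[list[str]]]:
    """Scored interaction edge list with planted dense complexes.

    Three cliques (sizes 6, 5 and 4) over coding gene symbols receive
    confidence scores in (0.6, 0.99); a sparse random background gets
    scores in (0.05, 0.9), so the standard score > 0.4 filter thins it.
    Returns the edge table and the planted clique memberships.
    """
    rng = _rng(config, _STREAM_PPI)
    frame = config.transcript_frame()
    genes = sorted(set(frame.loc[frame["biotype"] == "coding", "gene_id"]))
    clique_sizes = [6, 5, 4]
    need = sum(clique_sizes) + 20
    if len(genes) < need:
        clique_sizes = [s for s in clique_sizes if s <= len(genes) // 3]
    perm = [genes[i] for i in rng.permutation(len(genes))]
    rows: list[tuple[str, str, float]] = []
    cliques: list[list[str]] = []
    at = 0
    for size in clique_sizes:
        members = sorted(perm[at : at + size])
        at += size
        cliques.append(members)
        for i in range(size):
            for j in range(i + 1, size):
                rows.append((members[i], members[j], float(rng.uniform(0.6, 0.99))))
    background = perm[at : at + min(40, len(perm) - at)]
    for _ in range(len(background)):
        a, b = rng.choice(len(background), size=2, replace=False)
        na, nb = sorted((background[a], background[b]))
        rows.append((na, nb, float(rng.uniform(0.05, 0.9))))
    edges = pd.DataFrame(rows, columns=["node_a", "node_b", "score"]).drop_duplicates(
        subset=["node_a", "node_b"]
    )
    return edges.reset_index(drop=True), cliques


@dataclass
class SyntheticDataset:
    """One fully generated dataset with its ground truth."""

    config: SimulationConfig
    matrix: ExpressionMatrix
    annotation: TranscriptAnnotation
    sequences: dict[str, str]
    seed_table: pd.DataFrame
    truth: GroundTruth


def generate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Run all generator stages and return a consistent dataset."""
    matrix, truth = generate_expression(config)
    annotation = generate_annotation(config, truth)
    sequences, seed_table = generate_sequences(annotation, config, truth)
    return SyntheticDataset(config, matrix, annotation, sequences, seed_table, truth)
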