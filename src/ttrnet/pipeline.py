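"""End-to-end orchestration: simulate (optional) -> contrasts -> trend
filter -> modules -> cis/trans/ceRNA networks -> hub ranking -> merged
focus graph, with deterministic tabular outputs and a run manifest.

The manifest records the package version, a hash of the semantic config
and the SHA-256 of every written table; identical configs produce
byte-identical outputs (no timestamps anywhere).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import networkx as nx
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, model_validator

from . import __version__
from . import coexpression as coex
from . import graphs as ga
from . import io as tio
from . import networks as nets
from .data import ConfigError, ExpressionMatrix, GroundTruth, TranscriptAnnotation
from .diffexpr import ContrastResult, Thresholds, gene_level_calls, run_contrast, ttr_trend_filter
from .simulate import SimulationConfig, generate_dataset, generate_ppi

log = logging.getLogger(__name__)


class PipelineConfig(BaseModel):
    """Every stage threshold in one validated, hashable object."""

    model_config = ConfigDict(extra="forbid")

    # inputs: either a simulation config or paths to an on-disk dataset
    simulate: Optional[SimulationConfig] = None
    dataset_dir: Optional[str] = None
    ppi_path: Optional[str] = None
    out_dir: str = "results/pipeline"

    # differential expression
    fc_threshold: float = 2.0
    p_max: float = 0.05
    q_max: float = 0.05
    pseudocount: float = 1.0
    t_test_variant: str = "student"
    gene_rule: str = "any_transcript"
    trend_mode: str = "strict"

    # co-expression
    beta_candidates: tuple[int, ...] = tuple(range(1, 21))
    r2_target: float = 0.8
    beta_fallback: int = 10
    adjacency_type: str = "unsigned"
    cut_height: float = 0.9
    min_module_size: int = 10

    # networks
    cis_window_bp: int = 10_000
    trans_r_threshold: float = 0.95
    seed_rules: tuple[str, ...] = nets.SEED_MATCH_RULES
    min_triad_sites: int = 1
    network_scope: str = "ttr_deg"  # or "all"
    top_n_hubs: int = 10
    focus_lncrnas: Optional[tuple[str, ...]] = None  # default: top 3 hubs

    # graph analysis
    ppi_min_score: float = 0.4
    mcode_node_score_cutoff: float = 0.2
    mcode_haircut: bool = True
    mcode_min_size: int = 3

    rng_seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "PipelineConfig":
        if not (0 < self.p_max <= 1 and 0 < self.q_max <= 1):
            raise ConfigError("p_max and q_max must lie in (0, 1]")
        if self.fc_threshold < 1:
            raise ConfigError("fc_threshold must be >= 1")
        if not 0 < self.trans_r_threshold <= 1:
            raise ConfigError("trans_r_threshold must lie in (0, 1]")
        if not 0 < self.cut_height <= 1:
            raise ConfigError("cut_height must lie in (0, 1]")
        if self.trend_mode not in ("strict", "lenient"):
            raise ConfigError("trend_mode must be strict or lenient")
        if self.network_scope not in ("ttr_deg", "all"):
            raise ConfigError("network_scope must be ttr_deg or all")
        if self.simulate is None and self.dataset_dir is None:
            raise ConfigError("either simulate or dataset_dir must be given")
        return self

    def semantic_hash(self) -> str:
        """Hash of every field that affects results (paths excluded)."""
        payload = self.model_dump(mode="json", exclude={"out_dir", "dataset_dir", "ppi_path"})
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls.model_validate(payload)


@dataclass
class PipelineResult:
    config: PipelineConfig
    matrix: ExpressionMatrix
    annotation: TranscriptAnnotation
    truth: Optional[GroundTruth]
    contrast_hg_vs_lg: ContrastResult
    contrast_ttr_vs_hg: ContrastResult
    ttr_degs: object
    soft_threshold: coex.SoftThresholdScan
    modules: coex.ModuleAssignment
    eigengenes: coex.Eigengenes
    module_traits: coex.ModuleTraitResult
    cis: list
    trans: list
    triads: list
    hub_table: pd.DataFrame
    merged: nx.MultiGraph
    complexes: list = field(default_factory=list)
    manifest: dict = field(default_factory=dict)


def _write_table(df: pd.DataFrame, path: Path, index: bool) -> None:
    tio.round6(df).to_csv(path, sep="\t", index=index)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute every stage and write deterministic outputs to out_dir."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    timers: dict[str, float] = {}

    def stage(name: str):
        log.info("stage %s", name)
        timers[name] = time.perf_counter()
        return name

    def done(name: str) -> None:
        log.info("stage %s finished in %.2fs", name, time.perf_counter() - timers[name])

    # ---- inputs ---------------------------------------------------------
    s = stage("inputs")
    truth: Optional[GroundTruth] = None
    seed_table = pd.DataFrame(columns=["mirna_id", "seed_7mer"])
    sequences: dict[str, str] = {}
    if config.simulate is not None:
        sim_cfg = config.simulate.model_copy(update={"rng_seed": config.rng_seed})
        ds = generate_dataset(sim_cfg)
        matrix, annotation = ds.matrix, ds.annotation
        sequences, seed_table, truth = ds.sequences, ds.seed_table, ds.truth
        tio.write_dataset(matrix, annotation, sequences, seed_table, truth, out_dir / "dataset")
    else:
        matrix, annotation, sequences, seed_table, truth = tio.read_dataset(config.dataset_dir)
    done(s)

    thresholds = Thresholds(
        fc_threshold=config.fc_threshold,
        p_max=config.p_max,
        q_max=config.q_max,
        pseudocount=config.pseudocount,
    )

    # ---- differential expression ---------------------------------------
    s = stage("contrasts")
    groups = (
        config.simulate.groups if config.simulate is not None else tuple(dict.fromkeys(matrix.design))
    )
    lg, hg, ttr = groups
    c1 = run_contrast(matrix, hg, lg, thresholds, config.t_test_variant)
    c2 = run_contrast(matrix, ttr, hg, thresholds, config.t_test_variant)
    genes1 = gene_level_calls(c1, annotation, config.gene_rule)
    genes2 = gene_level_calls(c2, annotation, config.gene_rule)
    ttr_degs = ttr_trend_filter(c1, c2, config.trend_mode, annotation)
    done(s)

    # ---- co-expression ---------------------------------------------------
    s = stage("modules")
    expr = matrix.log2p1()
    scan = coex.pick_soft_threshold(
        expr, config.beta_candidates, config.r2_target, config.beta_fallback, config.adjacency_type
    )
    tom = coex.topological_overlap(expr, scan.chosen_beta, config.adjacency_type)
    modules = coex.detect_modules(tom, config.min_module_size, config.cut_height)
    eigengenes = coex.module_eigengene(expr, modules)
    traits = _default_traits(matrix.design, groups)
    module_traits = coex.module_trait_correlation(eigengenes, traits)
    done(s)

    # ---- lncRNA networks -------------------------------------------------
    s = stage("networks")
    if config.network_scope == "ttr_deg" and (ttr_degs.lncrna_ids or ttr_degs.mrna_ids):
        lnc_ids, mrna_ids = ttr_degs.lncrna_ids, ttr_degs.mrna_ids
    else:
        lnc_ids = annotation.lncrna_ids()
        mrna_ids = annotation.coding_ids()
    cis = nets.cis_pairs(annotation, lnc_ids, mrna_ids, config.cis_window_bp)
    trans = nets.trans_pairs(matrix, lnc_ids, mrna_ids, config.trans_r_threshold)
    lnc_seq = {t: sequences[t] for t in lnc_ids if t in sequences}
    mrna_seq = {t: sequences[t] for t in mrna_ids if t in sequences}
    lnc_sites = nets.find_all_sites(lnc_seq, seed_table, config.seed_rules)
    mrna_sites = nets.find_all_sites(mrna_seq, seed_table, config.seed_rules)
    triads = nets.cerna_triads(lnc_sites, mrna_sites, config.min_triad_sites)
    hub_table = nets.hub_rank(trans, config.top_n_hubs)
    focus = (
        list(config.focus_lncrnas)
        if config.focus_lncrnas
        else list(hub_table["lncrna_id"].head(3))
    )
    if not focus:
        focus = lnc_ids[:1] or annotation.lncrna_ids()[:1]
    de_dir = {
        "hg_vs_lg": dict(c1.table["status"]),
        "ttr_vs_hg": dict(c2.table["status"]),
    }
    merged = (
        nets.merge_networks(cis, trans, triads, focus, annotation, de_dir)
        if focus
        else nx.MultiGraph()
    )
    done(s)

    # ---- dense sub-networks ---------------------------------------------
    s = stage("subnetworks")
    complexes: list[ga.ComplexResult] = []
    if config.ppi_path is not None:
        graph = ga.load_interactions(config.ppi_path, config.ppi_min_score)
    elif config.simulate is not None:
        edges, _ = generate_ppi(sim_cfg)
        ppi_file = out_dir / "ppi_edges.tsv"
        edges.to_csv(ppi_file, sep="\t", index=False, header=False, float_format="%.6f")
        graph = ga.load_interactions(ppi_file, config.ppi_min_score)
    else:
        graph = nx.Graph()
    if graph.number_of_nodes():
        complexes = ga.mcode_complexes(
            graph,
            config.mcode_node_score_cutoff,
            config.mcode_haircut,
            config.mcode_min_size,
        )
    done(s)

    # ---- outputs ---------------------------------------------------------
    s = stage("outputs")
    _write_table(c1.table.rename_axis("transcript_id"), out_dir / "contrast_hg_vs_lg.tsv", True)
    _write_table(c2.table.rename_axis("transcript_id"), out_dir / "contrast_ttr_vs_hg.tsv", True)
    _write_table(genes1, out_dir / "genes_hg_vs_lg.tsv", True)
    _write_table(genes2, out_dir / "genes_ttr_vs_hg.tsv", True)
    _write_table(ttr_degs.table.rename_axis("transcript_id"), out_dir / "ttr_degs.tsv", True)
    _write_table(scan.table, out_dir / "soft_threshold_scan.tsv", True)
    _write_table(
        modules.labels.rename_axis("transcript_id").to_frame(), out_dir / "modules.tsv", True
    )
    _write_table(eigengenes.scores.rename_axis("module"), out_dir / "eigengenes.tsv", True)
    flat = module_traits.correlations.copy()
    flat.columns = [f"{t}_{k}" for t, k in flat.columns]
    _write_table(flat.rename_axis("module"), out_dir / "module_trait.tsv", True)
    _write_table(
        pd.DataFrame(
            [(p.lncrna_id, p.mrna_id, p.relation, p.gap_bp, p.opposite_strand) for p in cis],
            columns=["lncrna_id", "mrna_id", "relation", "gap_bp", "opposite_strand"],
        ),
        out_dir / "cis_pairs.tsv",
        False,
    )
    _write_table(
        pd.DataFrame(
            [(e.lncrna_id, e.mrna_id, e.pearson_r, e.sign) for e in trans],
            columns=["lncrna_id", "mrna_id", "pearson_r", "sign"],
        ),
        out_dir / "trans_pairs.tsv",
        False,
    )
    _write_table(
        pd.DataFrame(
            [
                (t.lncrna_id, t.mirna_id, t.mrna_id, t.lnc_site_count, t.mrna_site_count)
                for t in triads
            ],
            columns=["lncrna_id", "mirna_id", "mrna_id", "lnc_site_count", "mrna_site_count"],
        ),
        out_dir / "cerna_triads.tsv",
        False,
    )
    _write_table(hub_table, out_dir / "hub_lncrnas.tsv", False)
    _write_table(ga.complexes_table(complexes), out_dir / "mcode_complexes.tsv", False)
    sif_edges = sorted(
        (str(a), str(attrs.get("type", "edge")), str(b))
        for a, b, attrs in merged.edges(data=True)
    )
    tio.write_sif(sif_edges, out_dir / "merged_network.sif")
    nx.write_graphml(merged, out_dir / "merged_network.graphml")

    tables = sorted(p for p in out_dir.glob("*.tsv")) + [out_dir / "merged_network.sif"]
    manifest = {
        "package_version": __version__,
        "config_hash": config.semantic_hash(),
        "rng_seed": config.rng_seed,
        "outputs": {p.name: _sha256(p) for p in tables},
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    done(s)

    return PipelineResult(
        config=config,
        matrix=matrix,
        annotation=annotation,
        truth=truth,
        contrast_hg_vs_lg=c1,
        contrast_ttr_vs_hg=c2,
        ttr_degs=ttr_degs,
        soft_threshold=scan,
        modules=modules,
        eigengenes=eigengenes,
        module_traits=module_traits,
        cis=cis,
        trans=trans,
        triads=triads,
        hub_table=hub_table,
        merged=merged,
        complexes=complexes,
        manifest=manifest,
    )


def _default_traits(design: pd.Series, groups: tuple[str, str, str]) -> pd.DataFrame:
    lg, hg, ttr = groups
    return pd.DataFrame(
        {
            "glucose": (design != lg).astype(float),
            "ttr": (design == ttr).astype(float),
        }
    )
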