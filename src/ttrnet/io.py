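"""File round-tripping: expression TSV, design TSV, GTF, FASTA, miRNA seed
table and the ground-truth manifest (JSON).

All tables are tab-separated UTF-8 with a header row; coordinates are
1-based inclusive in every file. Round-trips reproduce objects exactly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import pyranges as pr
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .data import (
    ConsistencyError,
    ExpressionMatrix,
    GroundTruth,
    ParseError,
    TranscriptAnnotation,
    ValidationError,
)


# -- expression -----------------------------------------------------------


def read_expression(expr_path, design_path) -> ExpressionMatrix:
    """Read an FPKM table (first column transcript_id) and a design TSV."""
    values = pd.read_csv(expr_path, sep="\t", index_col=0, float_precision="round_trip")
    values.index.name = "transcript_id"
    design = read_design(design_path)
    return ExpressionMatrix(values, design)


def read_design(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t")
    if list(df.columns[:2]) != ["sample", "group"]:
        raise ParseError(f"{path}: design file needs columns (sample, group)")
    if df["sample"].duplicated().any():
        dup = df.loc[df["sample"].duplicated(), "sample"].iloc[0]
        raise ParseError(f"{path}: duplicate sample id {dup!r}")
    return df.set_index("sample")["group"]


def write_expression(matrix: ExpressionMatrix, expr_path, design_path) -> None:
    # default float repr round-trips exactly through read_csv
    matrix.values.to_csv(expr_path, sep="\t")
    matrix.design.rename_axis("sample").rename("group").reset_index().to_csv(
        design_path, sep="\t", index=False
    )


# -- GTF ------------------------------------------------------------------


def read_gtf(path) -> TranscriptAnnotation:
    """Read transcript features from a GTF into a TranscriptAnnotation.

    A light pre-scan reports start > end (and non-numeric coordinates) with
    the offending line number; parsing proper goes through pyranges.
    """
    path = Path(path)
    n_data_lines = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            n_data_lines += 1
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 8:
                raise ParseError(f"{path}:{lineno}: expected >= 8 GTF columns")
            try:
                start, end = int(fields[3]), int(fields[4])
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-numeric coordinates")
            if start > end:
                raise ParseError(f"{path}:{lineno}: start {start} > end {end}")

    if n_data_lines == 0:
        return TranscriptAnnotation(
            pd.DataFrame(columns=list(TranscriptAnnotation.COLUMNS)).rename_axis(
                "transcript_id"
            )
        )
    df = pr.read_gtf(str(path)).df
    if df.empty or "Feature" not in df:
        return TranscriptAnnotation(
            pd.DataFrame(columns=list(TranscriptAnnotation.COLUMNS)).rename_axis(
                "transcript_id"
            )
        )
    tx = df[df["Feature"] == "transcript"].copy()
    for col in ("transcript_id", "gene_id"):
        if col not in tx or tx[col].isna().any():
            raise ParseError(f"{path}: transcript feature missing {col}")
    if tx["transcript_id"].duplicated().any():
        dup = tx.loc[tx["transcript_id"].duplicated(), "transcript_id"].iloc[0]
        raise ParseError(f"{path}: duplicate transcript_id {dup!r}")
    table = pd.DataFrame(
        {
            "gene_id": tx["gene_id"].to_numpy(),
            "gene_name": tx.get("gene_name", tx["gene_id"]).to_numpy(),
            "biotype": tx.get("transcript_biotype", pd.Series(["coding"] * len(tx))).to_numpy(),
            "chrom": tx["Chromosome"].astype(str).to_numpy(),
            "start": tx["Start"].to_numpy() + 1,  # pyranges is 0-based half-open
            "end": tx["End"].to_numpy(),
            "strand": tx["Strand"].astype(str).to_numpy(),
        },
        index=pd.Index(tx["transcript_id"].to_numpy(), name="transcript_id"),
    )
    return TranscriptAnnotation(table)


def _gtf_attrs(**kv: str) -> str:
    return " ".join(f'{k} "{v}";' for k, v in kv.items())


def write_gtf(annotation: TranscriptAnnotation, path) -> None:
    """Write gene + transcript features with the documented attributes."""
    lines = []
    table = annotation.table
    for gene_id, sub in table.groupby("gene_id", sort=True):
        chrom = sub["chrom"].iloc[0]
        if (sub["chrom"] != chrom).any():
            raise ValidationError(f"gene {gene_id!r} spans multiple chromosomes")
        lines.append(
            "\t".join(
                [
                    chrom,
                    "ttrnet",
                    "gene",
                    str(int(sub["start"].min())),
                    str(int(sub["end"].max())),
                    ".",
                    sub["strand"].iloc[0],
                    ".",
                    _gtf_attrs(gene_id=gene_id, gene_name=sub["gene_name"].iloc[0]),
                ]
            )
        )
        for tid, row in sub.sort_index().iterrows():
            lines.append(
                "\t".join(
                    [
                        row["chrom"],
                        "ttrnet",
                        "transcript",
                        str(int(row["start"])),
                        str(int(row["end"])),
                        ".",
                        row["strand"],
                        ".",
                        _gtf_attrs(
                            gene_id=row["gene_id"],
                            transcript_id=tid,
                            gene_name=row["gene_name"],
                            transcript_biotype=row["biotype"],
                        ),
                    ]
                )
            )
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


# -- FASTA ----------------------------------------------------------------


def read_fasta(path) -> dict[str, str]:
    """Read transcript sequences; duplicate ids and non-nucleotide characters error."""
    sequences: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in sequences:
            raise ParseError(f"{path}: duplicated sequence id {record.id!r}")
        seq = str(record.seq).upper()
        bad = set(seq) - set("ACGTUN")
        if bad:
            raise ParseError(
                f"{path}: non-nucleotide characters in {record.id!r}: {sorted(bad)}"
            )
        sequences[record.id] = seq
    return sequences


def write_fasta(sequences: dict[str, str], path) -> None:
    records = [
        SeqRecord(Seq(sequences[name]), id=name, description="")
        for name in sorted(sequences)
    ]
    SeqIO.write(records, str(path), "fasta")


# -- miRNA seed table -----------------------------------------------------


def read_seed_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if list(df.columns[:2]) != ["mirna_id", "seed_7mer"]:
        raise ParseError(f"{path}: seed table needs columns (mirna_id, seed_7mer)")
    if df["mirna_id"].duplicated().any():
        dup = df.loc[df["mirna_id"].duplicated(), "mirna_id"].iloc[0]
        raise ParseError(f"{path}: duplicate mirna_id {dup!r}")
    for seed in df["seed_7mer"]:
        if len(seed) != 7 or set(seed.upper()) - set("ACGU" "T"):
            raise ParseError(f"{path}: invalid 7-mer seed {seed!r}")
    return df


def write_seed_table(seed_table: pd.DataFrame, path) -> None:
    seed_table.to_csv(path, sep="\t", index=False)


# -- ground truth manifest ------------------------------------------------


def write_truth(truth: GroundTruth, path) -> None:
    payload = {
        "de_hg_vs_lg": truth.de_hg_vs_lg,
        "de_ttr_vs_hg": truth.de_ttr_vs_hg,
        "trend_reversal_set": truth.trend_reversal_set,
        "module_labels": truth.module_labels,
        "cis_pairs": [list(p) for p in truth.cis_pairs],
        "cis_boundary_pairs": [list(p) for p in truth.cis_boundary_pairs],
        "cis_decoy_pairs": [list(p) for p in truth.cis_decoy_pairs],
        "planted_triads": [list(p) for p in truth.planted_triads],
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")


def read_truth(path) -> GroundTruth:
    payload = json.loads(Path(path).read_text())
    return GroundTruth(
        de_hg_vs_lg=payload["de_hg_vs_lg"],
        de_ttr_vs_hg=payload["de_ttr_vs_hg"],
        trend_reversal_set=payload["trend_reversal_set"],
        module_labels=payload["module_labels"],
        cis_pairs=[tuple(p) for p in payload["cis_pairs"]],
        cis_boundary_pairs=[tuple(p) for p in payload["cis_boundary_pairs"]],
        cis_decoy_pairs=[tuple(p) for p in payload["cis_decoy_pairs"]],
        planted_triads=[tuple(p) for p in payload["planted_triads"]],
    )


# -- dataset bundle -------------------------------------------------------

DATASET_FILES = {
    "expression": "expression.tsv",
    "design": "design.tsv",
    "annotation": "annotation.gtf",
    "sequences": "transcripts.fa",
    "seeds": "mirna_seeds.tsv",
    "truth": "ground_truth.json",
}


def write_dataset(
    matrix: ExpressionMatrix,
    annotation: TranscriptAnnotation,
    sequences: dict[str, str],
    seed_table: pd.DataFrame,
    truth: GroundTruth,
    out_dir,
) -> dict[str, Path]:
    """Write the full dataset bundle after cross-checking identifiers."""
    missing = set(matrix.transcripts) - set(annotation.transcripts)
    if missing:
        raise ConsistencyError(
            f"transcripts in matrix missing from annotation: {sorted(missing)[:3]}"
        )
    missing_seq = set(annotation.transcripts) - set(sequences)
    if missing_seq:
        raise ConsistencyError(
            f"annotated transcripts without sequence: {sorted(missing_seq)[:3]}"
        )
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {key: out_dir / name for key, name in DATASET_FILES.items()}
    write_expression(matrix, paths["expression"], paths["design"])
    write_gtf(annotation, paths["annotation"])
    write_fasta(sequences, paths["sequences"])
    write_seed_table(seed_table, paths["seeds"])
    write_truth(truth, paths["truth"])
    return paths


def read_dataset(out_dir):
    """Read a dataset bundle back; returns (matrix, annotation, sequences, seeds, truth)."""
    out_dir = Path(out_dir)
    matrix = read_expression(
        out_dir / DATASET_FILES["expression"], out_dir / DATASET_FILES["design"]
    )
    annotation = read_gtf(out_dir / DATASET_FILES["annotation"])
    sequences = read_fasta(out_dir / DATASET_FILES["sequences"])
    seeds = read_seed_table(out_dir / DATASET_FILES["seeds"])
    truth = read_truth(out_dir / DATASET_FILES["truth"])
    return matrix, annotation, sequences, seeds, truth


# -- network exports ------------------------------------------------------


def write_sif(edges: list[tuple[str, str, str]], path) -> None:
    """SIF export: rows (source, interaction, target)."""
    lines = [f"{a}\t{kind}\t{b}" for a, kind, b in edges]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def round6(df: pd.DataFrame) -> pd.DataFrame:
    """Round float columns for stable text output."""
    out = df.copy()
    for col in out.columns:
        if np.issubdtype(out[col].dtype, np.floating):
            out[col] = out[col].round(6)
    return out
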