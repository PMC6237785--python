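"""Readers and writers for the small text formats used throughout.

Everything is 0-based, half-open internally.  Nick sets are serialized as
BED6 with 1-bp intervals (strand ``+`` = top, ``-`` = bottom); gene tables as
a GFF-like TSV (chrom, start, end, strand, gene_id, rpkm); tiled signal as
bedGraph; configuration as a flat YAML mapping.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .combing import LabelParams
from .fragmentation import FragPhysicsParams
from .synthetic_data import GENE_COLUMNS, Genome, SimConfig

logger = logging.getLogger(__name__)

_STRAND_TO_BED = {"top": "+", "bottom": "-"}
_BED_TO_STRAND = {"+": "top", "-": "bottom"}


class FormatError(ValueError):
    """Malformed input file; message carries the offending line number."""


# ---------------------------------------------------------------------------
# genome
# ---------------------------------------------------------------------------

def write_genome(genome: Genome, path) -> None:
    pd.DataFrame(genome.chromosomes, columns=["chrom", "length"]).to_csv(
        path, sep="\t", index=False
    )


def read_genome(path) -> Genome:
    df = pd.read_csv(path, sep="\t")
    return Genome(tuple((str(r.chrom), int(r.length)) for r in df.itertuples()))


# ---------------------------------------------------------------------------
# BED6 for nick sets and interval sets
# ---------------------------------------------------------------------------

def write_nicks_bed(nicks: pd.DataFrame, path) -> None:
    """Nick positions as 1-bp BED6 intervals."""
    with open(path, "w") as fh:
        for i, row in enumerate(nicks.itertuples(index=False)):
            fh.write(
                f"{row.chrom}\t{row.position}\t{row.position + 1}\t"
                f"nick{i + 1}\t0\t{_STRAND_TO_BED[row.strand]}\n"
            )


def read_nicks_bed(path, genome: Genome | None = None) -> pd.DataFrame:
    intervals = read_bed(path, genome)
    if ((intervals["end"] - intervals["start"]) != 1).any():
        raise FormatError("nick BED must contain 1-bp intervals")
    return pd.DataFrame(
        {
            "chrom": intervals["chrom"],
            "position": intervals["start"],
            "strand": [_BED_TO_STRAND[s] for s in intervals["strand"]],
        }
    )


def write_bed(intervals: pd.DataFrame, path, score_col: str | None = None) -> None:
    """Generic BED6 writer for interval tables (chrom/start/end[/strand])."""
    with open(path, "w") as fh:
        for i, row in intervals.reset_index(drop=True).iterrows():
            strand = row.get("strand", "+")
            if strand in _STRAND_TO_BED:
                strand = _STRAND_TO_BED[strand]
            score = row[score_col] if score_col else 0
            fh.write(
                f"{row['chrom']}\t{int(row['start'])}\t{int(row['end'])}\t"
                f"iv{i + 1}\t{score}\t{strand}\n"
            )


def read_bed(path, genome: Genome | None = None) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"line {lineno}: fewer than 3 BED fields")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise FormatError(f"line {lineno}: non-integer coordinates") from exc
            if start < 0 or start >= end:
                raise FormatError(
                    f"line {lineno}: invalid interval [{start}, {end})"
                )
            chrom = parts[0]
            if genome is not None:
                if chrom not in genome.lengths:
                    raise FormatError(f"line {lineno}: unknown chromosome {chrom!r}")
                if end > genome.lengths[chrom]:
                    raise FormatError(
                        f"line {lineno}: interval end {end} beyond {chrom} "
                        f"length {genome.lengths[chrom]}"
                    )
            name = parts[3] if len(parts) > 3 else "."
            score = float(parts[4]) if len(parts) > 4 and parts[4] != "." else 0.0
            strand = parts[5] if len(parts) > 5 else "+"
            rows.append((chrom, start, end, name, score, strand))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score", "strand"])


# ---------------------------------------------------------------------------
# GFF-like gene TSV
# ---------------------------------------------------------------------------

def write_genes_tsv(genes: pd.DataFrame, path) -> None:
    genes[GENE_COLUMNS].to_csv(path, sep="\t", index=False)


def read_genes_tsv(path, genome: Genome | None = None) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(GENE_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"gene table missing columns: {sorted(missing)}")
    bad = df.index[(df["start"] < 0) | (df["start"] >= df["end"])]
    if len(bad):
        raise FormatError(f"line {bad[0] + 2}: invalid gene interval")
    if (df["rpkm"] < 0).any():
        raise FormatError("negative expression value")
    if genome is not None:
        for _, r in df.iterrows():
            if r["chrom"] not in genome.lengths or r["end"] > genome.lengths[r["chrom"]]:
                raise FormatError(f"gene {r['gene_id']} outside genome")
    return df


# ---------------------------------------------------------------------------
# bedGraph
# ---------------------------------------------------------------------------

def write_bedgraph(signal: pd.DataFrame, path) -> None:
    """Probe signal (chrom/position/value) as 1-bp bedGraph records."""
    with open(path, "w") as fh:
        for row in signal.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.position}\t{row.position + 1}\t{row.value:.6g}\n")


def read_bedgraph(path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "#")):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise FormatError(f"line {lineno}: bedGraph needs 4 fields")
            try:
                rows.append((parts[0], int(parts[1]), float(parts[3])))
            except ValueError as exc:
                raise FormatError(f"line {lineno}: malformed bedGraph record") from exc
    df = pd.DataFrame(rows, columns=["chrom", "position", "value"])
    if not df.empty:
        sorted_df = df.sort_values(["chrom", "position"], ignore_index=True)
        if not df.equals(sorted_df):
            logger.warning("bedGraph %s was unsorted; sorting", path)
            df = sorted_df
    return df


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Everything a pipeline run needs, round-trippable through flat YAML."""

    seed: int = 0
    sim: SimConfig = field(default_factory=SimConfig)
    frag: FragPhysicsParams = field(default_factory=FragPhysicsParams)
    label: LabelParams = field(default_factory=LabelParams)
    n_perm: int = 200
    window: int = 1500
    bin_size: int = 100
    span: float = 0.3
    alpha: float = 0.05
    n_chrom: int = 16
    n_genes: int = 6664
    rdna_units: int = 150
    nicked_unit_fraction: float = 0.1
    plan: tuple = ("digest:SfiI", "s1")

    def to_yaml(self, path) -> None:
        flat = {}
        for prefix, obj in (("sim", self.sim), ("frag", self.frag), ("label", self.label)):
            for k, v in asdict(obj).items():
                flat[f"{prefix}.{k}"] = list(v) if isinstance(v, tuple) else v
        for k in ("seed", "n_perm", "window", "bin_size", "span", "alpha",
                  "n_chrom", "n_genes", "rdna_units", "nicked_unit_fraction"):
            flat[k] = getattr(self, k)
        flat["plan"] = list(self.plan)
        with open(path, "w") as fh:
            yaml.safe_dump(flat, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            flat = yaml.safe_load(fh) or {}
        groups: dict[str, dict] = {"sim": {}, "frag": {}, "label": {}}
        top = {}
        for k, v in flat.items():
            if "." in k:
                prefix, name = k.split(".", 1)
                groups[prefix][name] = tuple(v) if isinstance(v, list) else v
            elif k == "plan":
                top["plan"] = tuple(v)
            else:
                top[k] = v
        return cls(
            sim=SimConfig(**groups["sim"]),
            frag=FragPhysicsParams(**groups["frag"]),
            label=LabelParams(**groups["label"]),
            **top,
        )
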