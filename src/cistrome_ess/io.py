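"""Readers and writers for the plain-text formats the pipeline exchanges.

All stage handoffs are files on disk: BED for intervals (0-based half-open),
TSV with headers for tables, bedGraph-style TSV for signal tracks, YAML for
run configuration.  Every writer has a matching reader that round-trips the
frame exactly (up to dtypes).
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import yaml

from .synthetic_screen import GenomeFixture

SITE_BED_COLUMNS = [
    "chrom",
    "start",
    "end",
    "site_id",
    "score",
    "strand",
    "summit",
    "factor",
    "cell_specificity",
    "selection_class",
    "context",
]


def write_tsv(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)
    return path


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_sites_bed(sites: pd.DataFrame, path: str | Path) -> Path:
    out = sites.copy()
    out["score"] = 0
    out["strand"] = "."
    return write_tsv(out[SITE_BED_COLUMNS], path)


def read_sites_bed(path: str | Path) -> pd.DataFrame:
    df = read_tsv(path)
    return df[
        [
            "site_id",
            "chrom",
            "start",
            "end",
            "summit",
            "factor",
            "cell_specificity",
            "selection_class",
            "context",
        ]
    ]


def write_intervals_bed(df: pd.DataFrame, path: str | Path) -> Path:
    return write_tsv(df, path)


def read_intervals_bed(path: str | Path) -> pd.DataFrame:
    return read_tsv(path)


def write_bedgraph(track: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    track[["chrom", "start", "end", "value"]].to_csv(
        path, sep="\t", index=False, header=False
    )
    return path


def read_bedgraph(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t", names=["chrom", "start", "end", "value"], header=None
    )


def write_fixture(fixture: GenomeFixture, outdir: str | Path) -> dict[str, Path]:
    """Serialise a genome fixture into a directory of text files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "chrom_sizes": outdir / "chrom_sizes.tsv",
        "genes": outdir / "genes.tsv",
        "sites": outdir / "sites.bed",
        "tad_boundaries": outdir / "tad_boundaries.bed",
        "anchors": outdir / "anchors.bed",
        "copy_segments": outdir / "copy_segments.tsv",
    }
    pd.DataFrame(
        {"chrom": list(fixture.chrom_sizes), "size": list(fixture.chrom_sizes.values())}
    ).to_csv(paths["chrom_sizes"], sep="\t", index=False)
    write_tsv(fixture.genes, paths["genes"])
    write_sites_bed(fixture.sites, paths["sites"])
    write_tsv(fixture.tad_boundaries, paths["tad_boundaries"])
    write_tsv(fixture.anchors, paths["anchors"])
    write_tsv(fixture.copy_segments, paths["copy_segments"])
    return paths


def read_fixture(outdir: str | Path) -> GenomeFixture:
    outdir = Path(outdir)
    cs = pd.read_csv(outdir / "chrom_sizes.tsv", sep="\t")
    return GenomeFixture(
        chrom_sizes=dict(zip(cs["chrom"], cs["size"].astype(int))),
        genes=read_tsv(outdir / "genes.tsv"),
        sites=read_sites_bed(outdir / "sites.bed"),
        tad_boundaries=read_tsv(outdir / "tad_boundaries.bed"),
        anchors=read_tsv(outdir / "anchors.bed"),
        copy_segments=read_tsv(outdir / "copy_segments.tsv"),
    )


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} did not parse to a mapping")
    return cfg


def dump_config(cfg: dict, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
    return path


def write_json(obj, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=str)
    return path
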