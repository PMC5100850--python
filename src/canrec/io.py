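"""Readers and writers for the on-disk formats.

Conventions: crossover-call and genetic-map TSVs use 1-based inclusive
coordinates on disk (the linkage-community convention) and 0-based
half-open coordinates in memory; BED is 0-based half-open as the format
mandates; GTF is 1-based inclusive.  All conversions live here.
"""

from __future__ import annotations

import re
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .gmap import GeneticMap

CALL_COLUMNS = ["meiosis_id", "parent_id", "child_id", "parent_sex",
                "chrom", "left_bp", "right_bp", "probability"]


def read_crossover_calls(path, chrom_lengths: dict[str, int] | None = None) -> pd.DataFrame:
    """Read a crossover-call TSV, validating every row.

    File coordinates are 1-based inclusive; returned left_bp/right_bp
    are 0-based half-open.
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in CALL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    left = df["left_bp"].astype(float) - 1.0
    right = df["right_bp"].astype(float)
    bad = np.where(left.values >= right.values)[0]
    if len(bad):
        raise ValueError(f"{path}: left_bp >= right_bp at line {bad[0] + 2}")
    if chrom_lengths is not None:
        unknown = set(df["chrom"]) - set(chrom_lengths)
        if unknown:
            line = int(np.where(df["chrom"].isin(unknown))[0][0]) + 2
            raise ValueError(f"{path}: unknown chromosome at line {line}: {sorted(unknown)}")
    out = df.copy()
    out["left_bp"], out["right_bp"] = left, right
    return out


def write_crossover_calls(calls: pd.DataFrame, path) -> None:
    out = calls.copy()
    out["left_bp"] = out["left_bp"].astype(float).astype(int) + 1
    out["right_bp"] = out["right_bp"].astype(float).astype(int)
    out.to_csv(path, sep="\t", index=False)


def read_spans(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    need = ["duo_id", "chrom", "first_het_bp", "last_het_bp"]
    missing = [c for c in need if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    if (df["first_het_bp"] >= df["last_het_bp"]).any():
        raise ValueError(f"{path}: degenerate informative span")
    return df


def write_spans(spans: pd.DataFrame, path) -> None:
    spans.to_csv(path, sep="\t", index=False)


def read_genetic_map(path, sex: str = "sex-averaged") -> GeneticMap:
    """Genetic-map TSV (chrom, start, end, rate_cM_per_Mb, cum_cM);
    on-disk coordinates 1-based inclusive."""
    df = pd.read_csv(path, sep="\t")
    df["start"] = df["start"].astype(float) - 1.0
    df["end"] = df["end"].astype(float)
    return GeneticMap(df, sex=sex)


def write_genetic_map(gmap: GeneticMap, path) -> None:
    out = gmap.intervals.copy()
    out["start"] = out["start"].astype(int) + 1
    out["end"] = out["end"].astype(int)
    out.to_csv(path, sep="\t", index=False)


def read_bed(path) -> pd.DataFrame:
    """BED3+ reader; returns chrom, start, end (0-based half-open) and
    strand when a 6th column is present."""
    rows = []
    bad = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                bad.append((ln, line))
                continue
            try:
                rec = {"chrom": parts[0], "start": int(parts[1]), "end": int(parts[2])}
            except ValueError:
                bad.append((ln, line))
                continue
            if len(parts) >= 6:
                rec["strand"] = parts[5]
            rows.append(rec)
    if bad:
        raise ValueError(f"{path}: {len(bad)} malformed BED lines; first at line {bad[0][0]}: {bad[0][1]!r}")
    if not rows:
        warnings.warn(f"{path}: empty BED file")
        return pd.DataFrame(columns=["chrom", "start", "end"])
    return pd.DataFrame(rows)


_GTF_ATTR = re.compile(r'(\w+) "([^"]*)"')


def read_gtf_genes(path, protein_coding_only: bool = True,
                   longest_isoform: bool = True) -> pd.DataFrame:
    """Gene/TSS table from a GTF.

    Returns one row per retained transcript: chrom, start, end (0-based
    half-open), strand, gene_id, transcript_id, tss (strand-aware
    transcription start coordinate).  Optionally restricts to
    protein-coding genes and, per gene, the longest isoform.
    """
    rows = []
    bad = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9:
                bad.append((ln, line))
                continue
            if parts[2] != "transcript":
                continue
            attrs = dict(_GTF_ATTR.findall(parts[8]))
            try:
                start, end = int(parts[3]) - 1, int(parts[4])
            except ValueError:
                bad.append((ln, line))
                continue
            rows.append({
                "chrom": parts[0], "start": start, "end": end,
                "strand": parts[6],
                "gene_id": attrs.get("gene_id", ""),
                "transcript_id": attrs.get("transcript_id", ""),
                "biotype": attrs.get("gene_biotype", attrs.get("transcript_biotype", "")),
            })
    if bad:
        raise ValueError(
            f"{path}: {len(bad)} malformed GTF lines; first at line {bad[0][0]}"
        )
    if not rows:
        warnings.warn(f"{path}: no transcript records")
        return pd.DataFrame(
            columns=["chrom", "start", "end", "strand", "gene_id", "transcript_id", "tss"]
        )
    df = pd.DataFrame(rows)
    if protein_coding_only:
        df = df[df["biotype"].isin(["protein_coding", ""])]
    if longest_isoform and len(df):
        df = df.assign(_len=df["end"] - df["start"])
        df = df.sort_values("_len", ascending=False).groupby("gene_id", as_index=False).first()
        df = df.drop(columns="_len")
    df["tss"] = np.where(df["strand"] == "-", df["end"] - 1, df["start"])
    return df.reset_index(drop=True)


def read_features(path, fmt: str = "bed", **kwargs) -> pd.DataFrame:
    if fmt.lower() == "bed":
        return read_bed(path)
    if fmt.lower() == "gtf":
        return read_gtf_genes(path, **kwargs)
    raise ValueError(f"unknown feature format {fmt!r}")


def read_plink_map(path) -> pd.DataFrame:
    """PLINK .map: chrom, marker id, genetic position (cM), bp position."""
    df = pd.read_csv(path, sep=r"\s+", header=None,
                     names=["chrom", "marker_id", "cm", "pos"])
    return df


def read_plink_fam(path) -> pd.DataFrame:
    """PLINK .fam: family, individual, father, mother, sex code, phenotype."""
    df = pd.read_csv(path, sep=r"\s+", header=None,
                     names=["fid", "iid", "father", "mother", "sex", "phenotype"])
    return df


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def save_config(cfg: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)


def write_exclusion_list(ids, path) -> None:
    Path(path).write_text("\n".join(str(i) for i in ids) + ("\n" if len(ids) else ""))
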