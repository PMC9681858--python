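"""Readers and writers for the plain-text formats used throughout the pipeline.

All matrices are TSV with a header row of sample ids and probe ids in the
first column. Genomic coordinates are 1-based inclusive except in BED output,
which follows the 0-based half-open convention.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

MANIFEST_COLUMNS = ["chrom", "pos", "arm", "cross_reactive", "snp_dist_bp", "snp_maf"]
SAMPLE_COLUMNS = ["age_years", "mycn", "inss", "cog_risk", "pfs_years", "event"]


def read_matrix(path: str | Path) -> pd.DataFrame:
    """Read a probes x samples TSV matrix (first column = probe id)."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_matrix(df: pd.DataFrame, path: str | Path, index_label: str = "probe_id") -> None:
    df.to_csv(path, sep="\t", index_label=index_label, float_format="%.6g")


def read_manifest(path: str | Path) -> pd.DataFrame:
    man = pd.read_csv(path, sep="\t", index_col=0, dtype={"chrom": str})
    man["cross_reactive"] = man["cross_reactive"].astype(bool)
    return man


def write_manifest(man: pd.DataFrame, path: str | Path) -> None:
    out = man.copy()
    out["cross_reactive"] = out["cross_reactive"].astype(int)
    out.to_csv(path, sep="\t", index_label="probe_id", float_format="%.4g")


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_sample_sheet(sheet: pd.DataFrame, path: str | Path) -> None:
    sheet.to_csv(path, sep="\t", index_label="sample_id", float_format="%.6g")


def read_gene_annotation(path: str | Path) -> pd.DataFrame:
    """Read a BED-like gene table (chrom, start, end, name; 0-based half-open
    for .bed files, otherwise TSV with 1-based inclusive columns)."""
    path = Path(path)
    if path.suffix == ".bed":
        genes = pd.read_csv(
            path, sep="\t", header=None, usecols=range(4),
            names=["chrom", "start", "end", "gene"], dtype={"chrom": str},
        )
        genes["start"] = genes["start"] + 1  # to 1-based inclusive
    else:
        genes = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    genes["chrom"] = genes["chrom"].str.removeprefix("chr")
    return genes


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_jsonify) + "\n")


def _jsonify(o):
    try:
        return o.item()  # numpy scalars
    except AttributeError:
        if isinstance(o, (set, frozenset)):
            return sorted(o)
        if hasattr(o, "tolist"):
            return o.tolist()
        raise TypeError(f"not JSON serialisable: {type(o)}")
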