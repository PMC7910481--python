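"""Plain-text I/O for the pipeline's tables.

All interchange is TSV (cells, variants, targets, SNPs, clones) plus JSON
for truth/reports; a minimal VCF 4.2 export is provided for passing bulk
calls.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

__all__ = [
    "write_cells_tsv",
    "read_cells_tsv",
    "read_tsv",
    "write_tsv",
    "write_json",
    "export_vcf",
]


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_cells_tsv(depth: pd.DataFrame, alt: pd.DataFrame, path: str | Path) -> None:
    """Write a long-format cells table: cell_id, locus, depth, alt."""
    long = (
        depth.stack()
        .rename("depth")
        .to_frame()
        .join(alt.stack().rename("alt"))
        .reset_index()
    )
    long.columns = ["cell_id", "locus", "depth", "alt"]
    long.to_csv(path, sep="\t", index=False)


def read_cells_tsv(path: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a long-format cells table back into (depth, alt) matrices."""
    long = pd.read_csv(path, sep="\t")
    depth = long.pivot(index="cell_id", columns="locus", values="depth")
    alt = long.pivot(index="cell_id", columns="locus", values="alt")
    return depth.fillna(0).astype(int), alt.fillna(0).astype(int)


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=str)


def export_vcf(calls: pd.DataFrame, path: str | Path) -> None:
    """Export passing bulk calls as minimal VCF 4.2.

    INFO carries the duplex depth/alt counts and the filter reason for
    non-passing records (written with FILTER set accordingly).
    """
    cols = ["chrom", "pos", "ref", "alt", "duplex_depth", "duplex_alt", "status"]
    missing = [c for c in cols if c not in calls.columns]
    if missing:
        raise ValueError(f"calls table missing columns: {missing}")
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=DDP,Number=1,Type=Integer,Description="Duplex consensus depth">\n')
        fh.write('##INFO=<ID=DALT,Number=1,Type=Integer,Description="Duplex consensus alt count">\n')
        fh.write('##INFO=<ID=REASON,Number=1,Type=String,Description="First failing filter rule">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for _, row in calls.iterrows():
            filt = "PASS" if row["status"] == "pass" else (row.get("reason") or row["status"])
            info = f"DDP={int(row['duplex_depth'])};DALT={int(row['duplex_alt'])}"
            if row["status"] != "pass" and row.get("reason"):
                info += f";REASON={row['reason']}"
            fh.write(
                f"{row['chrom']}\t{int(row['pos'])}\t.\t{row['ref']}\t{row['alt']}\t.\t{filt}\t{info}\n"
            )
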