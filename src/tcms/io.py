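"""Readers and writers for the plain-text formats the pipeline consumes.

All tabular formats are TSV with a header row.  Gene sets travel as GMT
(one set per line: name, description, then member genes, tab-separated).
SV tables are BEDPE-like: 0-based half-open input coordinates are converted
to the 1-based inclusive convention used internally.
"""

from __future__ import annotations

import os
from typing import Iterable, Mapping

import pandas as pd

# Canonical clinical-table column names (documented schema).
CLINICAL_COLUMNS = [
    "sample",
    "os_time",
    "os_event",
    "rfs_time",
    "rfs_event",
    "stage",
    "relapse",
    "adjuvant",
    "therapy",
]

MUTATION_COLUMNS = ["sample", "gene", "protein_change", "exon", "variant_class"]
FUSION_COLUMNS = ["sample", "gene_a", "gene_b"]


def read_gmt(path: str | os.PathLike) -> dict[str, list[str]]:
    """Read a GMT file into an ordered mapping set-name -> gene list."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"malformed GMT line (need name, description, >=1 gene): {line!r}"
                )
            name = fields[0]
            if name in sets:
                raise ValueError(f"duplicate gene-set name in GMT: {name!r}")
            genes = [g for g in fields[2:] if g]
            sets[name] = genes
    return sets


def write_gmt(
    sets: Mapping[str, Iterable[str]],
    path: str | os.PathLike,
    descriptions: Mapping[str, str] | None = None,
) -> None:
    """Write gene sets as GMT; description defaults to the set name."""
    with open(path, "w") as fh:
        for name, genes in sets.items():
            desc = (descriptions or {}).get(name, name)
            fh.write("\t".join([name, desc, *genes]) + "\n")


def read_expression_tsv(path: str | os.PathLike) -> pd.DataFrame:
    """Read a genes x samples expression matrix (first column = gene id)."""
    expr = pd.read_csv(path, sep="\t", index_col=0)
    if expr.index.has_duplicates:
        raise ValueError("duplicate gene identifiers in expression matrix")
    return expr


def write_matrix_tsv(df: pd.DataFrame, path: str | os.PathLike, index_label: str = "id") -> None:
    df.to_csv(path, sep="\t", index_label=index_label)


def read_mutations_tsv(path: str | os.PathLike) -> pd.DataFrame:
    """Read a MAF-like mutation table (sample, gene, protein_change, exon, variant_class)."""
    df = pd.read_csv(path, sep="\t", dtype={"protein_change": str})
    missing = [c for c in MUTATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"mutation table missing columns: {missing}")
    df["exon"] = df["exon"].astype("Int64")
    return df


def read_fusions_tsv(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in FUSION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"fusion table missing columns: {missing}")
    return df


def read_cnv_tsv(path: str | os.PathLike) -> pd.DataFrame:
    """Read a gene-level thresholded CNV matrix (genes x samples, integers -2..2)."""
    cnv = pd.read_csv(path, sep="\t", index_col=0)
    vals = cnv.to_numpy()
    if ((vals < -2) | (vals > 2)).any():
        raise ValueError("CNV matrix contains values outside {-2..2}")
    return cnv.astype(int)


def read_clinical_tsv(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_sv_bedpe(path: str | os.PathLike) -> pd.DataFrame:
    """Read a BEDPE-like SV table into the internal 1-based representation.

    Expected columns: chrom1, start1, end1, chrom2, start2, end2, sample, svtype.
    Breakpoints are taken as the start coordinate of each side, converted from
    0-based half-open to 1-based.
    """
    df = pd.read_csv(path, sep="\t")
    needed = ["chrom1", "start1", "chrom2", "start2", "sample", "svtype"]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise ValueError(f"BEDPE table missing columns: {missing}")
    out = pd.DataFrame(
        {
            "sample": df["sample"],
            "svtype": df["svtype"],
            "chrom1": df["chrom1"].astype(str),
            "pos1": df["start1"].astype(int) + 1,
            "chrom2": df["chrom2"].astype(str),
            "pos2": df["start2"].astype(int) + 1,
        }
    )
    return out
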