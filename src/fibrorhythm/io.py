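"""Readers and writers for the plain-text formats the pipeline exchanges.

Counts travel as MatrixMarket triplets plus gene/barcode lists (or dense
TSV), coordinates and partitions as TSV, genomic intervals as BED6, gene
models as GFF3, genomes as FASTA and ground truth as JSON.  Everything round
trips exactly; all tables are written with deterministic ordering so that a
fixed seed yields byte-identical artifacts.
"""

from __future__ import annotations

import json
from typing import Iterable

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

__all__ = [
    "write_counts_mtx",
    "read_counts_mtx",
    "write_embedding",
    "read_embedding",
    "write_partition",
    "read_partition",
    "write_bed6",
    "read_bed6",
    "write_gff3",
    "read_gff3",
    "write_fasta",
    "read_fasta",
]


# ---------------------------------------------------------------------------
# counts
# ---------------------------------------------------------------------------

def write_counts_mtx(adata: ad.AnnData, prefix: str) -> None:
    """Write an AnnData counts matrix as ``<prefix>.mtx`` triplets plus
    ``<prefix>.genes.tsv`` / ``<prefix>.barcodes.tsv`` with cell metadata."""
    x = sp.csr_matrix(adata.X)
    # genes x cells, CellRanger-style orientation
    scipy.io.mmwrite(f"{prefix}.mtx", x.T.tocoo(), field="integer")
    pd.DataFrame({"gene_id": adata.var_names}).to_csv(
        f"{prefix}.genes.tsv", sep="\t", index=False
    )
    obs = adata.obs.copy()
    obs.insert(0, "cell_id", adata.obs_names)
    obs.to_csv(f"{prefix}.barcodes.tsv", sep="\t", index=False)


def read_counts_mtx(prefix: str) -> ad.AnnData:
    x = sp.csr_matrix(scipy.io.mmread(f"{prefix}.mtx").T)
    genes = pd.read_csv(f"{prefix}.genes.tsv", sep="\t")
    obs = pd.read_csv(f"{prefix}.barcodes.tsv", sep="\t")
    obs = obs.set_index("cell_id")
    obs.index = obs.index.astype(str)
    adata = ad.AnnData(X=x, obs=obs, var=pd.DataFrame(index=genes["gene_id"].astype(str)))
    return adata


# ---------------------------------------------------------------------------
# per-cell tables
# ---------------------------------------------------------------------------

def write_embedding(cells: Iterable[str], coords: np.ndarray, path: str) -> None:
    df = pd.DataFrame({"cell_id": list(cells)})
    df["x"] = np.asarray(coords)[:, 0]
    df["y"] = np.asarray(coords)[:, 1]
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_embedding(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"cell_id": str})
    return df.set_index("cell_id")


def write_partition(cells: Iterable[str], labels: Iterable, path: str,
                    column: str = "cluster") -> None:
    pd.DataFrame({"cell_id": list(cells), column: list(labels)}).to_csv(
        path, sep="\t", index=False
    )


def read_partition(path: str) -> pd.Series:
    df = pd.read_csv(path, sep="\t", dtype={"cell_id": str})
    return df.set_index("cell_id").iloc[:, 0]


# ---------------------------------------------------------------------------
# genomic intervals
# ---------------------------------------------------------------------------

def write_bed6(df: pd.DataFrame, path: str) -> None:
    """Write intervals with columns chrom,start,end,name,score,strand as BED6
    (0-based half-open, as in memory)."""
    out = df.copy()
    for col, default in (("name", "."), ("score", 0), ("strand", ".")):
        if col not in out:
            out[col] = default
    out[["chrom", "start", "end", "name", "score", "strand"]].to_csv(
        path, sep="\t", header=False, index=False
    )


def read_bed6(path: str) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", header=None,
        names=["chrom", "start", "end", "name", "score", "strand"],
        dtype={"chrom": str, "name": str, "strand": str},
    )
    return df


# ---------------------------------------------------------------------------
# gene annotation (GFF3)
# ---------------------------------------------------------------------------

def write_gff3(genes: pd.DataFrame, path: str) -> None:
    """Write gene models (columns gene_id, chrom, start, end, strand;
    0-based half-open in memory) as GFF3 gene features (1-based closed)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for row in genes.itertuples(index=False):
            fh.write(
                f"{row.chrom}\tfibrorhythm\tgene\t{row.start + 1}\t{row.end}\t.\t"
                f"{row.strand}\t.\tID={row.gene_id}\n"
            )


def read_gff3(path: str) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if f[2] != "gene":
                continue
            attrs = dict(kv.split("=", 1) for kv in f[8].split(";") if "=" in kv)
            rows.append(
                {
                    "gene_id": attrs.get("ID", f"{f[0]}:{f[3]}"),
                    "chrom": f[0],
                    "start": int(f[3]) - 1,
                    "end": int(f[4]),
                    "strand": f[6],
                }
            )
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand"])


# ---------------------------------------------------------------------------
# sequence
# ---------------------------------------------------------------------------

def write_fasta(seqs: dict, path: str, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name in seqs:
            fh.write(f">{name}\n")
            s = seqs[name]
            for i in range(0, len(s), width):
                fh.write(s[i : i + width] + "\n")


def read_fasta(path: str) -> dict:
    seqs: dict = {}
    name = None
    buf: list = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                if name is not None:
                    seqs[name] = "".join(buf)
                name = line[1:].split()[0]
                buf = []
            else:
                buf.append(line)
    if name is not None:
        seqs[name] = "".join(buf)
    return seqs


def write_json(obj, path: str) -> None:
    """Deterministic JSON dump (sorted keys, fixed float formatting)."""
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serialisable: {type(o)}")
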