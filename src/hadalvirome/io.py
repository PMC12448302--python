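"""Readers and writers for the plain-text interchange formats.

* abundance TSV — rows = vOTU ids, columns = sample ids, values RPKM
* metadata TSV — sample, latitude, longitude, water_depth, layer, trench
* pileup TSV — contig, pos (1-based), ref, nA, nC, nG, nT
* gene-model TSV — contig, gene_id, start, end, strand (1-based inclusive)
* FASTA via Biopython; newick via dendropy; truth files as JSON
"""

from __future__ import annotations

import json
from pathlib import Path

import dendropy
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


def write_abundance(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index_label="vOTU")


def read_abundance(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_metadata(meta: pd.DataFrame, path: str | Path) -> None:
    meta.to_csv(path, sep="\t", index_label="sample")


def read_metadata(path: str | Path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", index_col=0)
    bad = meta[(meta["latitude"].abs() > 90) | (meta["longitude"].abs() > 180)]
    if len(bad):
        raise ValueError(f"invalid coordinates for samples {bad.index.tolist()}")
    return meta


def write_fasta(records: dict, path: str | Path) -> None:
    """Write a {id: sequence} or {(part_id, genome_id): sequence} mapping.

    Tuple keys become ``partID|genomeID`` headers (spacer/tRNA convention).
    """
    out = []
    for key, seq in records.items():
        name = "|".join(key) if isinstance(key, tuple) else str(key)
        out.append(SeqRecord(Seq(seq), id=name, description=""))
    SeqIO.write(out, str(path), "fasta")


def read_fasta(path: str | Path, split_headers: bool = False) -> dict:
    records = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        key = tuple(rec.id.split("|", 1)) if split_headers else rec.id
        records[key] = str(rec.seq).upper()
    return records


def write_tree(tree: dendropy.Tree, path: str | Path) -> None:
    tree.write(path=str(path), schema="newick")


def read_tree(path: str | Path) -> dendropy.Tree:
    return dendropy.Tree.get(path=str(path), schema="newick")


def write_pileup(pileup: pd.DataFrame, path: str | Path) -> None:
    pileup.to_csv(path, sep="\t", index=False)


def read_pileup(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if (df[["nA", "nC", "nG", "nT"]] < 0).any().any():
        raise ValueError("negative pileup counts")
    return df


def write_genes(genes: pd.DataFrame, path: str | Path) -> None:
    genes.to_csv(path, sep="\t", index=False)


def read_genes(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=str) + "\n")


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())
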