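"""Readers and writers for the formats the pipeline touches.

FASTA is read through pyfaidx and written as wrapped plain text; GTF gene
features are read through gffutils (1-based closed coordinates converted to
0-based half-open); BED and count/metadata tables go through pandas; GMT is
the usual tab-separated one-set-per-line format.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from hecpipe.isochores import Isochore, isochores_to_bed

_FASTA_WIDTH = 60


def read_fasta(path: str | Path) -> dict[str, str]:
    """Chromosome name -> sequence, via pyfaidx."""
    from pyfaidx import Fasta

    with Fasta(str(path), as_raw=True) as fasta:
        return {name: str(fasta[name][:]) for name in fasta.keys()}


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), _FASTA_WIDTH):
                fh.write(seq[i : i + _FASTA_WIDTH] + "\n")


def read_gtf_genes(path: str | Path) -> pd.DataFrame:
    """Gene features of a GTF as a frame with 0-based half-open coordinates."""
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique", disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    rows = []
    for feat in db.features_of_type("gene"):
        rows.append(
            {"gene_id": feat.attributes.get("gene_id", [feat.id])[0],
             "chrom": feat.seqid, "start": feat.start - 1, "end": feat.end,
             "strand": feat.strand}
        )
    return pd.DataFrame(rows)


def write_gtf(genes: pd.DataFrame, path: str | Path, source: str = "hecpipe") -> None:
    """Write gene records (0-based half-open in memory) as GTF gene features."""
    with open(path, "w") as fh:
        for row in genes.itertuples(index=False):
            attrs = f'gene_id "{row.gene_id}";'
            fh.write(
                f"{row.chrom}\t{source}\tgene\t{row.start + 1}\t{row.end}\t.\t"
                f"{row.strand}\t.\t{attrs}\n"
            )


def read_bed_genes(path: str | Path) -> pd.DataFrame:
    """BED6 gene records (chrom, start, end, name, score, strand)."""
    frame = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "gene_id", "score", "strand"],
        usecols=range(6),
    )
    return frame[["gene_id", "chrom", "start", "end", "strand"]]


def write_bed_genes(genes: pd.DataFrame, path: str | Path) -> None:
    out = genes.assign(score=0)[["chrom", "start", "end", "gene_id", "score", "strand"]]
    out.to_csv(path, sep="\t", header=False, index=False)


def write_isochore_bed(isochores: Sequence[Isochore], path: str | Path) -> None:
    isochores_to_bed(isochores).to_csv(path, sep="\t", header=False, index=False)


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """GMT gene sets: name <tab> description <tab> member..., one per line."""
    from gseapy import read_gmt as _read_gmt  # lazy: heavy import

    return {name: list(members) for name, members in _read_gmt(str(path)).items()}


def write_gmt(sets: Mapping[str, Sequence[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, "synthetic"] + list(members)) + "\n")


def read_counts(path: str | Path) -> pd.DataFrame:
    """TSV count table: first column gene id, remaining columns samples."""
    frame = pd.read_csv(path, sep="\t", index_col=0)
    frame.index.name = "gene_id"
    return frame


def write_counts(counts: pd.DataFrame, path: str | Path) -> None:
    counts.to_csv(path, sep="\t")


def read_sample_metadata(path: str | Path) -> pd.DataFrame:
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    return pd.read_csv(path, sep=sep)


def write_json(obj: object, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=float)
        fh.write("\n")
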