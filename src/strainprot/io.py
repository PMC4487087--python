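"""Readers and writers for the pipeline's external formats.

All tabular interfaces are UTF-8 tab-separated files with a header row and
``NA`` as the missing-value token. The protein database is a standard
amino-acid FASTA (one record per gene, id = gene_id) plus a gene map TSV
with columns (gene_id, organism_id, contig_id, start, end, strand,
annotations), annotations being semicolon-separated and possibly empty.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from .model import (
    GENE_MAP_COLUMNS,
    PATHWAY_LIST_COLUMNS,
    PSM_COLUMNS,
    READ_COUNT_COLUMNS,
    GeneRecord,
    OrganismBin,
)

NA_TOKEN = "NA"


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a result table (TSV, header, NA token, no index)."""
    df.to_csv(path, sep="\t", index=False, na_rep=NA_TOKEN)


def read_table(path: str | Path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=[NA_TOKEN], keep_default_na=False, **kwargs)


def _require_columns(df: pd.DataFrame, columns: list[str], what: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{what}: missing columns {missing}")


def load_database(
    proteome_fasta: str | Path, gene_map: str | Path
) -> tuple[dict[str, GeneRecord], dict[str, OrganismBin]]:
    """Load the protein FASTA + gene map into GeneRecords and OrganismBins.

    ``protein_count`` and ``genome_length_bp`` are recomputed from the
    records (genome length as the per-contig maximum gene end, summed),
    never trusted from a file.

    Raises on: empty FASTA, duplicate gene ids, FASTA ids absent from the
    gene map (and vice versa), sequences with characters outside the 20
    standard amino acids + X, contigs claimed by two organisms.
    """
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(proteome_fasta), "fasta"):
        if rec.id in seqs:
            raise ValueError(f"duplicate gene_id in FASTA: {rec.id}")
        seqs[rec.id] = str(rec.seq).upper().rstrip("*")
    if not seqs:
        raise ValueError(f"empty proteome: no FASTA records in {proteome_fasta}")

    gmap = read_table(gene_map, dtype={"gene_id": str, "organism_id": str, "contig_id": str})
    _require_columns(gmap, GENE_MAP_COLUMNS[:6], "gene_map")
    if gmap["gene_id"].duplicated().any():
        dup = gmap.loc[gmap["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise ValueError(f"duplicate gene_id in gene map: {dup}")

    map_ids = set(gmap["gene_id"])
    for gid in seqs:
        if gid not in map_ids:
            raise ValueError(f"FASTA id absent from gene map: {gid}")
    for gid in map_ids:
        if gid not in seqs:
            raise ValueError(f"gene map id absent from FASTA: {gid}")

    records: dict[str, GeneRecord] = {}
    contig_owner: dict[str, str] = {}
    for row in gmap.itertuples(index=False):
        terms = frozenset()
        ann = getattr(row, "annotations", None)
        if isinstance(ann, str) and ann:
            terms = frozenset(t for t in ann.split(";") if t)
        rec = GeneRecord(
            gene_id=row.gene_id,
            organism_id=row.organism_id,
            contig_id=row.contig_id,
            start=int(row.start),
            end=int(row.end),
            strand=row.strand,
            aa_sequence=seqs[row.gene_id],
            annotation_terms=terms,
        )
        prev = contig_owner.setdefault(rec.contig_id, rec.organism_id)
        if prev != rec.organism_id:
            raise ValueError(
                f"contig {rec.contig_id} assigned to both {prev} and {rec.organism_id}"
            )
        records[rec.gene_id] = rec

    bins: dict[str, OrganismBin] = {}
    by_org: dict[str, list[GeneRecord]] = {}
    for rec in records.values():
        by_org.setdefault(rec.organism_id, []).append(rec)
    for org, recs in by_org.items():
        contig_len = {}
        for r in recs:
            contig_len[r.contig_id] = max(contig_len.get(r.contig_id, 0), r.end)
        bins[org] = OrganismBin(
            organism_id=org,
            contig_ids=frozenset(contig_len),
            genome_length_bp=int(sum(contig_len.values())),
            protein_count=len(recs),
        )
    return records, bins


def write_database(
    records: dict[str, GeneRecord],
    proteome_fasta: str | Path,
    gene_map: str | Path,
) -> None:
    """Write GeneRecords back out as FASTA + gene map TSV."""
    with open(proteome_fasta, "w") as fh:
        for gid in sorted(records):
            fh.write(f">{gid}\n{records[gid].aa_sequence}\n")
    rows = [
        {
            "gene_id": r.gene_id,
            "organism_id": r.organism_id,
            "contig_id": r.contig_id,
            "start": r.start,
            "end": r.end,
            "strand": r.strand,
            "annotations": ";".join(sorted(r.annotation_terms)),
        }
        for r in sorted(records.values(), key=lambda r: r.gene_id)
    ]
    write_table(pd.DataFrame(rows, columns=GENE_MAP_COLUMNS), gene_map)


def read_psm_table(path: str | Path) -> pd.DataFrame:
    """Read a peptide-spectrum-match table (sample_id, peptide, spectral_count)."""
    df = read_table(path, dtype={"sample_id": str, "peptide": str})
    _require_columns(df, PSM_COLUMNS, "psm table")
    df = df[PSM_COLUMNS].copy()
    df["spectral_count"] = df["spectral_count"].astype(int)
    if (df["spectral_count"] < 1).any():
        raise ValueError("psm table: spectral_count must be >= 1")
    if df.duplicated(["sample_id", "peptide"]).any():
        # one row per (sample, peptide): aggregate duplicates
        df = (
            df.groupby(["sample_id", "peptide"], as_index=False)["spectral_count"].sum()
        )
    return df


def read_read_counts(path: str | Path) -> pd.DataFrame:
    df = read_table(path, dtype={"sample_id": str, "contig_id": str})
    _require_columns(df, READ_COUNT_COLUMNS, "read count table")
    df = df[READ_COUNT_COLUMNS].copy()
    df["read_count"] = df["read_count"].astype(int)
    if (df["read_count"] < 0).any():
        raise ValueError("read count table: read_count must be >= 0")
    return df


def read_pathway_lists(path: str | Path) -> dict[str, frozenset]:
    """Read pathway gene lists (list_name, gene_id) into {name: gene id set}."""
    df = read_table(path, dtype=str)
    _require_columns(df, PATHWAY_LIST_COLUMNS, "pathway list table")
    lists = {
        name: frozenset(sub["gene_id"])
        for name, sub in df.groupby("list_name", sort=True)
    }
    for name, genes in lists.items():
        if not genes:
            raise ValueError(f"pathway list {name} is empty")
    return lists


def write_pathway_lists(lists: dict[str, frozenset], path: str | Path) -> None:
    rows = [
        {"list_name": name, "gene_id": gid}
        for name in sorted(lists)
        for gid in sorted(lists[name])
    ]
    write_table(pd.DataFrame(rows, columns=PATHWAY_LIST_COLUMNS), path)
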