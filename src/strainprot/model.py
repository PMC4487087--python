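"""Shared data model for strain-resolved metaproteomics.

The pipeline operates on a *database* of predicted proteomes from binned
metagenome-assembled genomes: each :class:`GeneRecord` is one protein-coding
gene with its amino-acid sequence, contig coordinates and annotation terms,
and each :class:`OrganismBin` groups the contigs attributed to one organism
or strain (e.g. a major and a minor *Citrobacter* strain at ~99% amino-acid
identity).

Quantitative inputs and outputs are plain :class:`pandas.DataFrame` tables;
the canonical column sets are defined here as module constants so that the
readers/writers, the stage functions and the tests all agree on one schema.

Coordinates are 1-based inclusive (GFF convention) throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

STANDARD_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")
#: residues allowed in database sequences; X marks an ambiguous residue
ALLOWED_AA = STANDARD_AA | {"X"}

#: column schemas for the tabular interfaces (TSV, UTF-8, header, NA token)
PSM_COLUMNS = ["sample_id", "peptide", "spectral_count"]
READ_COUNT_COLUMNS = ["sample_id", "contig_id", "read_count"]
PATHWAY_LIST_COLUMNS = ["list_name", "gene_id"]
GENE_MAP_COLUMNS = [
    "gene_id",
    "organism_id",
    "contig_id",
    "start",
    "end",
    "strand",
    "annotations",
]

UNIQUENESS_CLASSES = (
    "protein_unique",
    "organism_unique",
    "shared_within_strain_pair",
    "shared_across_organisms",
)


@dataclass(frozen=True)
class GeneRecord:
    """One predicted protein-coding gene of one organism bin.

    Parameters
    ----------
    gene_id
        Unique identifier across the whole database.
    organism_id
        Bin the gene belongs to.
    contig_id
        Contig carrying the gene; a contig belongs to exactly one organism.
    start, end
        1-based inclusive nucleotide coordinates on the contig, ``end >= start``.
    strand
        ``+`` or ``-``.
    aa_sequence
        Uppercase amino-acid sequence over the 20 standard residues,
        optionally containing ``X``.
    annotation_terms
        EC numbers, orthology identifiers and free-text terms.
    """

    gene_id: str
    organism_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    aa_sequence: str
    annotation_terms: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise ValueError("gene_id must be non-empty")
        if self.end < self.start or self.start < 1:
            raise ValueError(
                f"gene {self.gene_id}: invalid coordinates "
                f"start={self.start} end={self.end} (1-based inclusive)"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")
        seq = self.aa_sequence
        if not seq:
            raise ValueError(f"gene {self.gene_id}: empty amino-acid sequence")
        if seq != seq.upper() or any(c.isspace() for c in seq):
            raise ValueError(
                f"gene {self.gene_id}: sequence must be uppercase, no whitespace"
            )
        bad = set(seq) - ALLOWED_AA
        if bad:
            raise ValueError(
                f"gene {self.gene_id}: non-amino-acid characters {sorted(bad)}"
            )

    @property
    def length_aa(self) -> int:
        return len(self.aa_sequence)


@dataclass(frozen=True)
class OrganismBin:
    """A set of assembled contigs attributed to one organism/strain."""

    organism_id: str
    contig_ids: frozenset
    genome_length_bp: int
    protein_count: int

    def __post_init__(self) -> None:
        if self.genome_length_bp <= 0:
            raise ValueError(f"bin {self.organism_id}: genome_length_bp must be > 0")
        if self.protein_count <= 0:
            raise ValueError(f"bin {self.organism_id}: protein_count must be > 0")


def contig_to_organism(bins: dict[str, OrganismBin]) -> dict[str, str]:
    """Map each contig id to its owning organism, enforcing exclusivity."""
    mapping: dict[str, str] = {}
    for bin_ in bins.values():
        for contig in bin_.contig_ids:
            if contig in mapping and mapping[contig] != bin_.organism_id:
                raise ValueError(
                    f"contig {contig} claimed by both {mapping[contig]} "
                    f"and {bin_.organism_id}"
                )
            mapping[contig] = bin_.organism_id
    return mapping


def gene_to_organism(records: dict[str, GeneRecord]) -> dict[str, str]:
    return {g.gene_id: g.organism_id for g in records.values()}
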