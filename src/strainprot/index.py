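"""Peptide → protein → organism uniqueness index and PSM assignment.

This is the computational heart of strain-resolved proteomics: every
canonical (I/L-collapsed) tryptic peptide of the database is mapped to the
set of genes and organisms that contain it, and classified as

- ``protein_unique``: occurs in exactly one gene (hence one organism);
- ``organism_unique``: occurs in one organism but more than one gene;
- ``shared_within_strain_pair``: parents span exactly one declared strain
  pair (both members) — informative about the species, not the strain;
- ``shared_across_organisms``: anything broader.

Observed PSMs are then assigned by exact canonical-sequence lookup; shared
peptides keep their full parent sets (no razor/parsimony winner-takes-all),
and quantification decides what to use.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .digestion import Peptide, canonicalize
from .model import ALLOWED_AA, GeneRecord

logger = logging.getLogger(__name__)

ASSIGNED_COLUMNS = [
    "sample_id",
    "canonical_sequence",
    "spectral_count",
    "gene_ids",
    "organism_ids",
    "uniqueness_class",
]


def normalize_strain_pairs(pairs) -> frozenset:
    """Normalize an iterable of organism-id pairs to a set of frozensets."""
    out = set()
    for pair in pairs or ():
        fs = frozenset(pair)
        if len(fs) != 2:
            raise ValueError(f"strain pair must have two distinct members: {pair}")
        out.add(fs)
    return frozenset(out)


def classify_parents(
    gene_ids: frozenset, organism_ids: frozenset, strain_pairs: frozenset
) -> str:
    if len(gene_ids) == 1:
        return "protein_unique"
    if len(organism_ids) == 1:
        return "organism_unique"
    if any(organism_ids <= pair for pair in strain_pairs):
        return "shared_within_strain_pair"
    return "shared_across_organisms"


@dataclass(frozen=True)
class IndexEntry:
    parent_gene_ids: frozenset
    parent_organism_ids: frozenset
    uniqueness_class: str

    @property
    def is_organism_unique(self) -> bool:
        """True when all parents lie in a single organism bin."""
        return len(self.parent_organism_ids) == 1


@dataclass(frozen=True)
class PeptideIndex:
    """Map canonical peptide sequence → parent sets + uniqueness class."""

    entries: dict
    strain_pairs: frozenset
    collapse_IL: bool = True

    def __len__(self) -> int:
        return len(self.entries)

    def lookup(self, peptide: str) -> IndexEntry | None:
        return self.entries.get(canonicalize(peptide, self.collapse_IL))

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "canonical_sequence": seq,
                "gene_ids": ";".join(sorted(e.parent_gene_ids)),
                "organism_ids": ";".join(sorted(e.parent_organism_ids)),
                "uniqueness_class": e.uniqueness_class,
            }
            for seq, e in sorted(self.entries.items())
        ]
        return pd.DataFrame(
            rows,
            columns=["canonical_sequence", "gene_ids", "organism_ids", "uniqueness_class"],
        )


def build_index(
    peptides: list[Peptide],
    records: dict[str, GeneRecord],
    strain_pairs=(),
    collapse_IL: bool = True,
) -> PeptideIndex:
    """Build the uniqueness index from a digested proteome.

    X-containing (non-indexable) peptides are skipped. ``strain_pairs`` are
    declared, not auto-detected — the analyst knows the pair a priori from
    genome curation.
    """
    if not peptides:
        raise ValueError("empty peptide set: digest the proteome first")
    pairs = normalize_strain_pairs(strain_pairs)
    parents: dict[str, set] = {}
    for pep in peptides:
        if not pep.indexable:
            continue
        parents.setdefault(pep.canonical_sequence, set()).add(pep.parent_gene_id)
    entries = {}
    for seq, gene_ids in parents.items():
        gids = frozenset(gene_ids)
        orgs = frozenset(records[g].organism_id for g in gids)
        entries[seq] = IndexEntry(gids, orgs, classify_parents(gids, orgs, pairs))
    return PeptideIndex(entries=entries, strain_pairs=pairs, collapse_IL=collapse_IL)


def assign_psms(
    psm: pd.DataFrame, index: PeptideIndex
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assign observed PSMs to database proteins/organisms.

    Returns ``(assigned, unmatched)``. Every input row lands in exactly one
    of the two frames, so spectral counts are conserved. Rows whose peptide
    contains illegal characters are collected as unmatched with reason
    ``illegal_characters`` rather than aborting the run. A sample with >50%
    unmatched spectra triggers a log warning.
    """
    assigned_rows = []
    unmatched_rows = []
    for row in psm.itertuples(index=False):
        pep = str(row.peptide).upper()
        if set(pep) - ALLOWED_AA:
            unmatched_rows.append(
                {
                    "sample_id": row.sample_id,
                    "peptide": row.peptide,
                    "spectral_count": row.spectral_count,
                    "reason": "illegal_characters",
                }
            )
            continue
        entry = index.lookup(pep)
        if entry is None:
            unmatched_rows.append(
                {
                    "sample_id": row.sample_id,
                    "peptide": row.peptide,
                    "spectral_count": row.spectral_count,
                    "reason": "not_in_index",
                }
            )
            continue
        assigned_rows.append(
            {
                "sample_id": row.sample_id,
                "canonical_sequence": canonicalize(pep, index.collapse_IL),
                "spectral_count": row.spectral_count,
                "gene_ids": ";".join(sorted(entry.parent_gene_ids)),
                "organism_ids": ";".join(sorted(entry.parent_organism_ids)),
                "uniqueness_class": entry.uniqueness_class,
            }
        )
    assigned = pd.DataFrame(assigned_rows, columns=ASSIGNED_COLUMNS)
    unmatched = pd.DataFrame(
        unmatched_rows, columns=["sample_id", "peptide", "spectral_count", "reason"]
    )
    # identical canonical sequences from different raw peptides collapse
    if not assigned.empty:
        assigned = assigned.groupby(
            ["sample_id", "canonical_sequence", "gene_ids", "organism_ids", "uniqueness_class"],
            as_index=False,
        )["spectral_count"].sum()[ASSIGNED_COLUMNS]

    for sample in psm["sample_id"].unique():
        total = int(psm.loc[psm["sample_id"] == sample, "spectral_count"].sum())
        if total == 0:
            continue
        miss = (
            int(unmatched.loc[unmatched["sample_id"] == sample, "spectral_count"].sum())
            if not unmatched.empty
            else 0
        )
        if miss / total > 0.5:
            logger.warning(
                "sample %s: %.0f%% of spectra unmatched against the database",
                sample,
                100 * miss / total,
            )
    return assigned, unmatched


def organism_unique_totals(assigned: pd.DataFrame) -> pd.Series:
    """Per-sample totals of organism-unique spectral counts (QC statistic)."""
    if assigned.empty:
        return pd.Series(dtype=int)
    mask = assigned["uniqueness_class"].isin(["protein_unique", "organism_unique"])
    return assigned[mask].groupby("sample_id")["spectral_count"].sum()
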