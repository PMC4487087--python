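"""In-silico tryptic digestion of predicted proteomes.

Trypsin cleaves C-terminal to lysine (K) or arginine (R) unless the next
residue is proline (P). Because the instrument cannot distinguish the
isobaric residues isoleucine and leucine, peptides are *canonicalized* by
default with I mapped to L, so that downstream uniqueness claims are never
based on an I/L difference.

Missed cleavages: an internal K/R site left uncut produces a longer peptide;
peptides with 0..``max_missed_cleavages`` internal sites are emitted, then a
length filter is applied (positions are recorded before filtering).
"""

from __future__ import annotations

from dataclasses import dataclass

from .model import ALLOWED_AA, GeneRecord


@dataclass(frozen=True)
class DigestParams:
    """Digestion rule parameters.

    Defaults (2 missed cleavages, length 6-50, I/L collapse on) follow common
    search-engine practice for LC-MS/MS; they are decisions, not measurements,
    and are configurable.
    """

    max_missed_cleavages: int = 2
    min_length: int = 6
    max_length: int = 50
    collapse_IL: bool = True

    def __post_init__(self) -> None:
        if self.min_length > self.max_length:
            raise ValueError("min_length must be <= max_length")
        if not (0 <= self.max_missed_cleavages <= 5):
            raise ValueError("max_missed_cleavages must be in 0..5")


#: parameters that disable both the length filter and I/L collapse — useful
#: for oracle checks such as re-concatenating a protein from its fragments
RAW_DIGEST = DigestParams(
    max_missed_cleavages=0, min_length=1, max_length=10**9, collapse_IL=False
)


@dataclass(frozen=True)
class Peptide:
    """A tryptic peptide tied to its parent gene.

    ``start_pos`` is the 1-based position of the peptide's first residue in
    the parent protein. ``indexable`` is False for X-containing peptides,
    which are emitted but excluded from the uniqueness index.
    """

    canonical_sequence: str
    parent_gene_id: str
    start_pos: int
    missed_cleavages: int
    indexable: bool = True


def canonicalize(sequence: str, collapse_IL: bool = True) -> str:
    """Uppercase a peptide string and, if requested, merge I into L."""
    seq = sequence.upper()
    return seq.replace("I", "L") if collapse_IL else seq


def cleavage_fragments(aa_sequence: str) -> list[tuple[int, str]]:
    """Split a protein into minimal tryptic fragments.

    Returns ``(start_pos, fragment)`` pairs, 1-based, in order. Cleavage is
    after K/R except before P.
    """
    sites = [
        i + 1
        for i, c in enumerate(aa_sequence[:-1])
        if c in "KR" and aa_sequence[i + 1] != "P"
    ]
    bounds = [0, *sites, len(aa_sequence)]
    return [
        (bounds[i] + 1, aa_sequence[bounds[i] : bounds[i + 1]])
        for i in range(len(bounds) - 1)
    ]


def digest_protein(
    aa_sequence: str,
    params: DigestParams = DigestParams(),
    gene_id: str = "",
) -> list[Peptide]:
    """Digest one protein sequence into tryptic peptides.

    Emits every run of ``1..max_missed_cleavages+1`` consecutive minimal
    fragments, applies the length filter, and records start positions before
    filtering. Ordered by (start_pos, length).
    """
    if not aa_sequence:
        raise ValueError("cannot digest an empty sequence")
    if aa_sequence != aa_sequence.upper():
        raise ValueError("sequence must be uppercase")
    bad = set(aa_sequence) - ALLOWED_AA
    if bad:
        raise ValueError(f"non-amino-acid characters in sequence: {sorted(bad)}")

    frags = cleavage_fragments(aa_sequence)
    out: list[Peptide] = []
    for i in range(len(frags)):
        start_pos = frags[i][0]
        for m in range(min(params.max_missed_cleavages + 1, len(frags) - i)):
            pep = "".join(f for _, f in frags[i : i + m + 1])
            if not (params.min_length <= len(pep) <= params.max_length):
                continue
            out.append(
                Peptide(
                    canonical_sequence=canonicalize(pep, params.collapse_IL),
                    parent_gene_id=gene_id,
                    start_pos=start_pos,
                    missed_cleavages=m,
                    indexable="X" not in pep,
                )
            )
    out.sort(key=lambda p: (p.start_pos, len(p.canonical_sequence)))
    return out


def digest_proteome(
    records: dict[str, GeneRecord] | list[GeneRecord],
    params: DigestParams = DigestParams(),
) -> list[Peptide]:
    """Digest every protein of a loaded database.

    Deterministic ordering by (gene_id, start_pos, length).
    """
    if isinstance(records, dict):
        records = list(records.values())
    if not records:
        raise ValueError("empty record set: nothing to digest")
    out: list[Peptide] = []
    for rec in sorted(records, key=lambda r: r.gene_id):
        out.extend(digest_protein(rec.aa_sequence, params, gene_id=rec.gene_id))
    return out
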