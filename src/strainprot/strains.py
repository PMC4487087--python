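"""Two-strain comparison: ortholog pairing, strain-unique genes, contig profiles.

For a pair of closely related strains (here ~99% amino-acid identity between
orthologs) the machinery answers three questions:

1. which genes are orthologous between the strains, and how similar are they
   (bidirectional best match under global alignment identity);
2. which genes are unique to one strain, and which of those are actually
   detected in the proteome;
3. how does proteomic coverage (unique spectral counts normalized by protein
   length) track along each strain's contigs, gene by gene.

Candidate ortholog pairs are pre-screened by shared 8-mers before alignment:
at strain-level divergence true orthologs share hundreds of 8-mers while
unrelated proteins essentially never collide, so the screen changes nothing
at these identity levels and keeps the all-vs-all cost linear.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from Bio import Align

from .model import GeneRecord

_KMER = 8
_MAX_CANDIDATES = 5  # alignments attempted per gene, best-screened first

PAIR_COLUMNS = ["gene_a", "gene_b", "aa_identity"]
PROFILE_COLUMNS = [
    "sample_id",
    "gene_id",
    "contig_id",
    "start",
    "normalized_count",
    "strain_unique_flag",
]


@dataclass
class OrthologMap:
    """BBH ortholog pairs between two strains plus each side's unique genes."""

    strain_a: str
    strain_b: str
    pairs: pd.DataFrame  # columns PAIR_COLUMNS
    unique_to_a: frozenset
    unique_to_b: frozenset
    mean_aa_identity: float = field(default=float("nan"))

    def paired_genes(self) -> frozenset:
        return frozenset(self.pairs["gene_a"]) | frozenset(self.pairs["gene_b"])


def _aligner() -> Align.PairwiseAligner:
    # identity scoring: at ~99% identity the substitution matrix is immaterial
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = 0.0
    aligner.open_gap_score = -1.0
    aligner.extend_gap_score = -1.0
    return aligner


def global_identity(seq_a: str, seq_b: str) -> tuple[float, float]:
    """Identity and shorter-sequence coverage of the best global alignment.

    Identity = identical columns / aligned (both non-gap) columns;
    coverage = aligned columns / length of the shorter sequence.
    """
    alignment = _aligner().align(seq_a, seq_b)[0]
    blocks_a, blocks_b = alignment.aligned
    aligned_cols = 0
    matches = 0
    for (a0, a1), (b0, b1) in zip(blocks_a, blocks_b):
        aligned_cols += a1 - a0
        matches += sum(1 for x, y in zip(seq_a[a0:a1], seq_b[b0:b1]) if x == y)
    if aligned_cols == 0:
        return 0.0, 0.0
    return matches / aligned_cols, aligned_cols / min(len(seq_a), len(seq_b))


def _kmers(seq: str) -> set:
    return {seq[i : i + _KMER] for i in range(len(seq) - _KMER + 1)}


def pair_orthologs(
    proteome_a: dict[str, GeneRecord],
    proteome_b: dict[str, GeneRecord],
    min_identity: float = 0.8,
    min_coverage: float = 0.8,
) -> OrthologMap:
    """Bidirectional-best-match ortholog pairing between two strain proteomes.

    A pair is kept when it is mutually best by alignment identity, identity
    >= ``min_identity`` and the alignment covers >= ``min_coverage`` of the
    shorter protein. Unpaired genes form the strain-unique sets. Symmetric:
    swapping the arguments swaps the unique sets and preserves the pairs.
    """
    if not proteome_a or not proteome_b:
        raise ValueError("both strain proteomes must be non-empty")
    strain_a = next(iter(proteome_a.values())).organism_id
    strain_b = next(iter(proteome_b.values())).organism_id

    kmer_index_b: dict[str, set] = {}
    for gid, rec in proteome_b.items():
        for k in _kmers(rec.aa_sequence):
            kmer_index_b.setdefault(k, set()).add(gid)

    # score all screened candidate pairs once (identity is symmetric)
    scored: dict[tuple[str, str], tuple[float, float]] = {}
    for gid_a in sorted(proteome_a):
        seq_a = proteome_a[gid_a].aa_sequence
        shared: dict[str, int] = {}
        for k in _kmers(seq_a):
            for gid_b in kmer_index_b.get(k, ()):
                shared[gid_b] = shared.get(gid_b, 0) + 1
        candidates = sorted(shared, key=lambda g: (-shared[g], g))[:_MAX_CANDIDATES]
        for gid_b in candidates:
            scored[(gid_a, gid_b)] = global_identity(
                seq_a, proteome_b[gid_b].aa_sequence
            )

    def best(side_pairs: dict) -> dict:
        out: dict[str, tuple[str, float]] = {}
        for (ga, gb), (ident, cov) in side_pairs.items():
            if ident < min_identity or cov < min_coverage:
                continue
            cur = out.get(ga)
            # tie-break deterministically on partner id
            if cur is None or ident > cur[1] or (ident == cur[1] and gb < cur[0]):
                out[ga] = (gb, ident)
        return out

    best_a = best(scored)
    best_b = best({(gb, ga): v for (ga, gb), v in scored.items()})

    pair_rows = []
    for ga, (gb, ident) in sorted(best_a.items()):
        if best_b.get(gb, (None,))[0] == ga:
            pair_rows.append({"gene_a": ga, "gene_b": gb, "aa_identity": ident})
    pairs = pd.DataFrame(pair_rows, columns=PAIR_COLUMNS)
    paired_a = set(pairs["gene_a"])
    paired_b = set(pairs["gene_b"])
    mean_identity = float(pairs["aa_identity"].mean()) if len(pairs) else float("nan")
    return OrthologMap(
        strain_a=strain_a,
        strain_b=strain_b,
        pairs=pairs,
        unique_to_a=frozenset(set(proteome_a) - paired_a),
        unique_to_b=frozenset(set(proteome_b) - paired_b),
        mean_aa_identity=mean_identity,
    )


def strain_unique_detection(
    ortho: OrthologMap, detect: pd.DataFrame, kept_samples=None
) -> pd.DataFrame:
    """Count strain-unique genes and how many are detected in >=1 kept sample."""
    if kept_samples is not None:
        detect = detect[detect["sample_id"].isin(kept_samples)]
    detected_genes = set(detect.loc[detect["detected"], "gene_id"])
    rows = []
    for strain, unique in (
        (ortho.strain_a, ortho.unique_to_a),
        (ortho.strain_b, ortho.unique_to_b),
    ):
        rows.append(
            {
                "strain": strain,
                "n_unique_genes": len(unique),
                "n_unique_detected": sum(1 for g in unique if g in detected_genes),
            }
        )
    return pd.DataFrame(rows, columns=["strain", "n_unique_genes", "n_unique_detected"])


def contig_profile(
    detect: pd.DataFrame,
    records: dict[str, GeneRecord],
    ortho: OrthologMap,
    strain: str,
) -> pd.DataFrame:
    """Dense per-sample coverage profile along one strain's contigs.

    normalized_count = unique spectral count / protein length (aa);
    undetected genes appear with 0. Ordered by (contig_id, start). Genes in
    the strain's unique set are flagged (plotted as triangles in the
    figure-style rendering).
    """
    if strain == ortho.strain_a:
        unique = ortho.unique_to_a
    elif strain == ortho.strain_b:
        unique = ortho.unique_to_b
    else:
        raise ValueError(f"strain {strain} is not part of this ortholog map")
    genes = {g: r for g, r in records.items() if r.organism_id == strain}
    counts = {
        (row.sample_id, row.gene_id): float(row.unique_spectral_count)
        for row in detect.itertuples(index=False)
        if row.gene_id in genes
    }
    samples = sorted(detect["sample_id"].unique())
    ordered = sorted(genes.values(), key=lambda r: (r.contig_id, r.start))
    rows = [
        {
            "sample_id": s,
            "gene_id": r.gene_id,
            "contig_id": r.contig_id,
            "start": r.start,
            "normalized_count": counts.get((s, r.gene_id), 0.0) / r.length_aa,
            "strain_unique_flag": r.gene_id in unique,
        }
        for s in samples
        for r in ordered
    ]
    return pd.DataFrame(rows, columns=PROFILE_COLUMNS)
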