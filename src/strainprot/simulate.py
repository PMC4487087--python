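"""Synthetic community generator with full ground truth.

Emulates the structure of a strain-resolved infant-gut metaproteomics study
without any external data: a small community of organism bins in which two
bins are strains of one species (the base proteome plus i.i.d. amino-acid
substitutions at rate rho per site, plus a few entirely novel strain-unique
genes per strain), per-sample *cell abundance* decoupled from *proteomic
activity*, shotgun read counts per contig, and a peptide-spectrum-match
table whose peptides include both strain-shared and strain-unique sequences.

Truth-vector semantics (this is what makes recovery tests meaningful):

- ``abundance_truth[s]`` is the cell-fraction simplex a genome-length-
  normalized read composition estimates, so reads are drawn per contig with
  probability proportional to abundance × contig length (more cells and a
  bigger genome both yield more DNA).
- ``activity_truth[s]`` is the simplex the length- and proteome-size-
  normalized peptide composition estimates, so spectra are drawn per gene
  with probability proportional to activity × per-gene weight × protein
  length (an organism's total signal scales with its activity and its
  proteome size; a protein's signal scales with its length).

Ortholog partners share their base gene's abundance weight: the strains
express the same protein complement with organism-level activity providing
the only systematic difference.

All randomness flows from ``SimParams.seed``; identical parameters give
byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .digestion import DigestParams, digest_protein
from .io import write_database, write_pathway_lists, write_table
from .model import GeneRecord, OrganismBin

AA20 = "ACDEFGHIKLMNPQRSTVWY"
#: uniform residue frequencies; K+R jointly 0.1, so tryptic peptides
#: average ~10 residues — a realistic identifiable-length regime
AA_FREQS = np.full(20, 1 / 20)

_INTERGENIC_BP = 150  # fixed spacer between genes on a contig


@dataclass
class SimParams:
    """The stated synthetic world; defaults are the documented conditions.

    The community has four bins: a strain pair (~``1 - rho`` amino-acid
    identity between orthologs) plus two unrelated organisms. A reads-
    dominant organism with middling proteomic activity (and vice versa)
    builds the abundance/activity decoupling in by default. Sample depths
    mirror a deep spectral-counting study at desk scale.
    """

    seed: int = 0
    n_organisms: int = 4
    genes_per_organism: tuple = (150, 250)
    gene_length_median_aa: int = 300
    gene_length_sigma: float = 0.35
    rho: float = 0.01  # amino-acid substitution rate between the strain pair
    unique_gene_fraction: float = 0.05
    n_samples: int = 6
    reads_per_sample: int = 100_000
    psms_per_sample: int = 20_000
    n_pathway_lists: int = 8
    pathway_list_size: tuple = (10, 40)
    protein_weight_sigma: float = 0.5
    detectable_length: tuple = (7, 30)
    n_contigs_per_organism: int = 2
    #: mean simplex per organism (strainA, strainAii, orgB, orgC); per-sample
    #: vectors are Dirichlet-jittered around these. orgB dominates by reads
    #: while the strain pair dominates activity — the decoupling under study.
    abundance_base: tuple = (0.18, 0.12, 0.55, 0.15)
    activity_base: tuple = (0.30, 0.28, 0.27, 0.15)
    dirichlet_concentration: float = 150.0
    abundance_truth: np.ndarray | None = None
    activity_truth: np.ndarray | None = None
    organism_ids: tuple = ("strainA", "strainAii", "orgB", "orgC")

    def __post_init__(self) -> None:
        if not (0.0 <= self.rho <= 0.2):
            raise ValueError("rho outside [0, 0.2]: not a strain-level divergence")
        if self.n_organisms < 2:
            raise ValueError("need at least 2 organisms")
        if self.n_samples < 1 or self.reads_per_sample < 1 or self.psms_per_sample < 1:
            raise ValueError("counts must be positive")
        if len(self.organism_ids) != self.n_organisms:
            self.organism_ids = tuple(
                list(self.organism_ids[: self.n_organisms])
                + [f"org{i}" for i in range(len(self.organism_ids), self.n_organisms)]
            )


@dataclass
class Truth:
    """Ground truth sufficient to score every downstream estimate."""

    abundance: pd.DataFrame  # sample_id, organism_id, fraction
    activity: pd.DataFrame  # sample_id, organism_id, fraction
    ortholog_pairs: pd.DataFrame  # gene_a (strain A), gene_b (strain Aii)
    strain_unique: pd.DataFrame  # strain, gene_id
    gene_weights: dict = field(default_factory=dict)
    psm_origin: pd.DataFrame | None = None  # sample_id, peptide, gene_id, count


def _truth_vectors(params: SimParams, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    def draw(base):
        base = np.asarray(base[: params.n_organisms], dtype=float)
        base = base / base.sum()
        return rng.dirichlet(base * params.dirichlet_concentration, size=params.n_samples)

    ab = params.abundance_truth
    ac = params.activity_truth
    if ab is None:
        ab = draw(params.abundance_base)
    if ac is None:
        ac = draw(params.activity_base)
    return np.asarray(ab, float), np.asarray(ac, float)


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AA20), size=length, p=AA_FREQS))


def _mutate(seq: str, rho: float, rng: np.random.Generator) -> str:
    if rho == 0:
        return seq
    out = list(seq)
    hits = np.flatnonzero(rng.random(len(seq)) < rho)
    for i in hits:
        choices = [c for c in AA20 if c != out[i]]
        out[i] = choices[rng.integers(len(choices))]
    return "".join(out)


def simulate_database(
    params: SimParams,
) -> tuple[dict[str, GeneRecord], dict[str, OrganismBin], dict[str, frozenset], Truth]:
    """Generate the database, pathway lists and structural ground truth.

    Organisms 0 and 1 are the strain pair: organism 1's shared genes are the
    base proteome with i.i.d. substitutions at rate ``rho``; each strain
    additionally carries ``unique_gene_fraction`` novel random genes with no
    homolog anywhere.
    """
    rng = np.random.default_rng(params.seed)
    orgs = params.organism_ids
    n_genes = rng.integers(
        params.genes_per_organism[0], params.genes_per_organism[1] + 1
    )

    def gene_lengths(n):
        mu = np.log(params.gene_length_median_aa)
        return np.maximum(
            30, np.round(rng.lognormal(mu, params.gene_length_sigma, size=n))
        ).astype(int)

    records: dict[str, GeneRecord] = {}
    pairs = []
    unique_rows = []

    # strain pair (organisms 0 and 1)
    base_lengths = gene_lengths(n_genes)
    base_seqs = [_random_protein(rng, L) for L in base_lengths]
    n_unique = int(round(params.unique_gene_fraction * n_genes))
    strain_genes: dict[str, list[tuple[str, str]]] = {orgs[0]: [], orgs[1]: []}
    for i, seq in enumerate(base_seqs):
        ga = f"{orgs[0]}_g{i+1:04d}"
        gb = f"{orgs[1]}_g{i+1:04d}"
        strain_genes[orgs[0]].append((ga, seq))
        strain_genes[orgs[1]].append((gb, _mutate(seq, params.rho, rng)))
        pairs.append({"gene_a": ga, "gene_b": gb})
    for org in (orgs[0], orgs[1]):
        for j, L in enumerate(gene_lengths(n_unique)):
            gid = f"{org}_u{j+1:04d}"
            strain_genes[org].append((gid, _random_protein(rng, L)))
            unique_rows.append({"strain": org, "gene_id": gid})

    # unrelated organisms
    other_genes: dict[str, list[tuple[str, str]]] = {}
    for org in orgs[2:]:
        m = rng.integers(params.genes_per_organism[0], params.genes_per_organism[1] + 1)
        other_genes[org] = [
            (f"{org}_g{i+1:04d}", _random_protein(rng, L))
            for i, L in enumerate(gene_lengths(m))
        ]

    # lay genes onto contigs with 1-based coordinates; contig ends at the
    # last gene so the gene map fully determines genome length
    all_genes = {**strain_genes, **other_genes}
    for org in orgs:
        genes = all_genes[org]
        per_contig = int(np.ceil(len(genes) / params.n_contigs_per_organism))
        for idx, (gid, seq) in enumerate(genes):
            contig = f"{org}_c{idx // per_contig + 1}"
            records[gid] = GeneRecord(
                gene_id=gid,
                organism_id=org,
                contig_id=contig,
                start=1,
                end=3 * len(seq),
                strand="+" if idx % 2 == 0 else "-",
                aa_sequence=seq,
            )
        # second pass: sequential coordinates per contig
        by_contig: dict[str, list[str]] = {}
        for gid, _ in genes:
            by_contig.setdefault(records[gid].contig_id, []).append(gid)
        for contig, gids in by_contig.items():
            cursor = 1
            for gid in gids:
                rec = records[gid]
                end = cursor + 3 * rec.length_aa - 1
                records[gid] = GeneRecord(
                    gene_id=rec.gene_id,
                    organism_id=rec.organism_id,
                    contig_id=rec.contig_id,
                    start=cursor,
                    end=end,
                    strand=rec.strand,
                    aa_sequence=rec.aa_sequence,
                    annotation_terms=rec.annotation_terms,
                )
                cursor = end + 1 + _INTERGENIC_BP

    bins: dict[str, OrganismBin] = {}
    for org in orgs:
        contig_len: dict[str, int] = {}
        for gid, _ in all_genes[org]:
            r = records[gid]
            contig_len[r.contig_id] = max(contig_len.get(r.contig_id, 0), r.end)
        bins[org] = OrganismBin(
            organism_id=org,
            contig_ids=frozenset(contig_len),
            genome_length_bp=int(sum(contig_len.values())),
            protein_count=len(all_genes[org]),
        )

    # pathway lists: random gene subsets across the whole database
    gene_ids = sorted(records)
    lists: dict[str, frozenset] = {}
    for k in range(params.n_pathway_lists):
        size = int(rng.integers(params.pathway_list_size[0], params.pathway_list_size[1] + 1))
        lists[f"list{k+1:02d}"] = frozenset(
            rng.choice(gene_ids, size=min(size, len(gene_ids)), replace=False)
        )

    # per-gene abundance weights; ortholog partners share the base weight
    weights: dict[str, float] = {}
    for gid in gene_ids:
        weights[gid] = float(rng.lognormal(0.0, params.protein_weight_sigma))
    for row in pairs:
        weights[row["gene_b"]] = weights[row["gene_a"]]

    abundance, activity = _truth_vectors(params, rng)
    samples = [f"S{j+1:02d}" for j in range(params.n_samples)]
    truth = Truth(
        abundance=pd.DataFrame(
            [
                {"sample_id": s, "organism_id": o, "fraction": abundance[j, i]}
                for j, s in enumerate(samples)
                for i, o in enumerate(orgs)
            ]
        ),
        activity=pd.DataFrame(
            [
                {"sample_id": s, "organism_id": o, "fraction": activity[j, i]}
                for j, s in enumerate(samples)
                for i, o in enumerate(orgs)
            ]
        ),
        ortholog_pairs=pd.DataFrame(pairs, columns=["gene_a", "gene_b"]),
        strain_unique=pd.DataFrame(unique_rows, columns=["strain", "gene_id"]),
        gene_weights=weights,
    )
    return records, bins, lists, truth


def simulate_reads(
    records: dict[str, GeneRecord],
    bins: dict[str, OrganismBin],
    truth: Truth,
    params: SimParams,
) -> pd.DataFrame:
    """Multinomial read counts per contig.

    P(contig c of organism o) ∝ abundance_truth(o) × contig_length(c): cells
    × genome size, so that genome-length-normalized composition recovers the
    abundance simplex.
    """
    rng = np.random.default_rng(np.random.SeedSequence([params.seed, 1]))
    contigs = sorted(c for b in bins.values() for c in b.contig_ids)
    contig_len = {}
    owner = {}
    for b in bins.values():
        for c in b.contig_ids:
            owner[c] = b.organism_id
            contig_len[c] = max(
                r.end for r in records.values() if r.contig_id == c
            )
    ab = truth.abundance.pivot(index="sample_id", columns="organism_id", values="fraction")
    rows = []
    for s in ab.index:
        p = np.array([ab.loc[s, owner[c]] * contig_len[c] for c in contigs])
        counts = rng.multinomial(params.reads_per_sample, p / p.sum())
        rows.extend(
            {"sample_id": s, "contig_id": c, "read_count": int(n)}
            for c, n in zip(contigs, counts)
        )
    return pd.DataFrame(rows, columns=["sample_id", "contig_id", "read_count"])


def simulate_psms(
    records: dict[str, GeneRecord],
    truth: Truth,
    params: SimParams,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw a PSM table; returns ``(psm_table, psm_origin_truth)``.

    Spectra are drawn per gene with probability ∝ activity × weight ×
    protein length (genes with no peptide in the detectability window are
    excluded and the simplex renormalized), then uniformly over the gene's
    tryptic peptides within the length window (missed cleavages up to 2).
    The origin table records the generating gene of every count.
    """
    if params.psms_per_sample < 100:
        import warnings

        warnings.warn("psms_per_sample < 100: recovery estimates will be noisy")
    rng = np.random.default_rng(np.random.SeedSequence([params.seed, 2]))
    lo, hi = params.detectable_length
    digest_params = DigestParams(
        max_missed_cleavages=2, min_length=lo, max_length=hi, collapse_IL=False
    )
    peptides_by_gene: dict[str, list[str]] = {}
    for gid in sorted(records):
        peps = [
            p.canonical_sequence
            for p in digest_protein(records[gid].aa_sequence, digest_params, gid)
        ]
        if peps:
            peptides_by_gene[gid] = peps

    genes = sorted(peptides_by_gene)
    act = truth.activity.pivot(index="sample_id", columns="organism_id", values="fraction")
    base_w = np.array(
        [truth.gene_weights[g] * records[g].length_aa for g in genes]
    )
    org_of = np.array([records[g].organism_id for g in genes])

    psm_rows: dict[tuple[str, str], int] = {}
    origin_rows: dict[tuple[str, str, str], int] = {}
    for s in act.index:
        p = base_w * np.array([act.loc[s, o] for o in org_of])
        counts = rng.multinomial(params.psms_per_sample, p / p.sum())
        for g, n in zip(genes, counts):
            if n == 0:
                continue
            peps = peptides_by_gene[g]
            draws = rng.integers(0, len(peps), size=n)
            for i in draws:
                pep = peps[i]
                psm_rows[(s, pep)] = psm_rows.get((s, pep), 0) + 1
                origin_rows[(s, pep, g)] = origin_rows.get((s, pep, g), 0) + 1

    psm = pd.DataFrame(
        [
            {"sample_id": s, "peptide": pep, "spectral_count": n}
            for (s, pep), n in sorted(psm_rows.items())
        ],
        columns=["sample_id", "peptide", "spectral_count"],
    )
    origin = pd.DataFrame(
        [
            {"sample_id": s, "peptide": pep, "gene_id": g, "count": n}
            for (s, pep, g), n in sorted(origin_rows.items())
        ],
        columns=["sample_id", "peptide", "gene_id", "count"],
    )
    return psm, origin


def simulate_all(params: SimParams, out_dir: str | Path | None = None):
    """Generate the complete input set (+ truth); optionally write it out.

    Returns ``(records, bins, lists, truth, psm, reads)``. When ``out_dir``
    is given, writes proteome.faa, gene_map.tsv, psm.tsv, read_counts.tsv,
    pathway_lists.tsv and truth/*.tsv.
    """
    records, bins, lists, truth = simulate_database(params)
    reads = simulate_reads(records, bins, truth, params)
    psm, origin = simulate_psms(records, truth, params)
    truth.psm_origin = origin
    if out_dir is not None:
        out = Path(out_dir)
        (out / "truth").mkdir(parents=True, exist_ok=True)
        write_database(records, out / "proteome.faa", out / "gene_map.tsv")
        write_table(psm, out / "psm.tsv")
        write_table(reads, out / "read_counts.tsv")
        write_pathway_lists(lists, out / "pathway_lists.tsv")
        write_table(truth.abundance, out / "truth" / "abundance.tsv")
        write_table(truth.activity, out / "truth" / "activity.tsv")
        write_table(truth.ortholog_pairs, out / "truth" / "ortholog_pairs.tsv")
        write_table(truth.strain_unique, out / "truth" / "strain_unique.tsv")
        write_table(origin, out / "truth" / "psm_origin.tsv")
    return records, bins, lists, truth, psm, reads
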