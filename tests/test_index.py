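"""Peptide uniqueness index and PSM assignment."""

import numpy as np
import pandas as pd
import pytest

from strainprot.digestion import DigestParams, canonicalize, digest_protein, digest_proteome
from strainprot.index import assign_psms, build_index, classify_parents, normalize_strain_pairs

PAIR = [("CITa", "CITb")]
PARAMS = DigestParams(0, 1, 100, collapse_IL=True)


@pytest.fixture
def tiny_index(tiny_db):
    records, _ = tiny_db
    return build_index(digest_proteome(records, PARAMS), records, PAIR)


def test_uniqueness_classes(tiny_index):
    assert tiny_index.lookup("GGGHHHK").uniqueness_class == "protein_unique"
    assert tiny_index.lookup("CCCDDDK").uniqueness_class == "protein_unique"
    # MK and TAYIAK occur in ser1 and ser2, both SER
    assert tiny_index.lookup("TAYIAK").uniqueness_class == "organism_unique"
    assert tiny_index.lookup("TAYIAK").is_organism_unique
    # identical gene in both strains of the declared pair
    assert tiny_index.lookup("AAAPWWK").uniqueness_class == "shared_within_strain_pair"


def test_undeclared_pair_is_shared_across_organisms(tiny_db):
    records, _ = tiny_db
    index = build_index(digest_proteome(records, PARAMS), records, strain_pairs=())
    assert index.lookup("AAAPWWK").uniqueness_class == "shared_across_organisms"


def test_identical_strain_proteomes_have_no_organism_unique_peptides(tiny_db):
    """Symmetry: a strain pair with identical proteomes yields zero peptides
    unique to either member."""
    records, _ = tiny_db
    pair = {g: r for g, r in records.items() if r.organism_id in ("CITa", "CITb")}
    index = build_index(digest_proteome(pair, PARAMS), pair, PAIR)
    strain_unique = [
        e
        for e in index.entries.values()
        if e.is_organism_unique and e.parent_organism_ids <= {"CITa", "CITb"}
    ]
    # cita2 exists only in CITa, so its peptides are genuinely unique;
    # nothing from the shared gene may be
    assert all(e.parent_gene_ids == {"cita2"} for e in strain_unique)


def test_brute_force_uniqueness_oracle(small_sim):
    """Index classes equal an exhaustive per-protein set comparison."""
    records = small_sim["records"]
    pairs = normalize_strain_pairs([("strainA", "strainAii")])
    params = DigestParams()
    index = build_index(digest_proteome(records, params), records, [("strainA", "strainAii")])

    # oracle: independent parent reconstruction by pairwise set membership
    per_gene = {
        gid: {p.canonical_sequence for p in digest_protein(r.aa_sequence, params, gid) if p.indexable}
        for gid, r in records.items()
    }
    all_peps = set().union(*per_gene.values())
    assert set(index.entries) == all_peps
    for pep in all_peps:
        genes = frozenset(g for g, peps in per_gene.items() if pep in peps)
        orgs = frozenset(records[g].organism_id for g in genes)
        expected = classify_parents(genes, orgs, pairs)
        entry = index.entries[pep]
        assert entry.parent_gene_ids == genes
        assert entry.uniqueness_class == expected


def test_assign_psms_examples(tiny_index, tiny_psm):
    assigned, unmatched = assign_psms(tiny_psm, tiny_index)
    row = assigned[
        (assigned["sample_id"] == "s1") & (assigned["canonical_sequence"] == "TAYLAK")
    ].iloc[0]
    assert row["spectral_count"] == 3
    assert row["organism_ids"] == "SER"
    assert row["uniqueness_class"] == "organism_unique"
    # unmatched peptide is excluded from assignment but reported
    assert unmatched["peptide"].tolist() == ["WWWDDDK"]
    assert unmatched["reason"].tolist() == ["not_in_index"]


def test_assignment_conserves_spectral_counts(tiny_index, tiny_psm):
    assigned, unmatched = assign_psms(tiny_psm, tiny_index)
    total = assigned["spectral_count"].sum() + unmatched["spectral_count"].sum()
    assert total == tiny_psm["spectral_count"].sum()


def test_illegal_peptide_is_row_level_error(tiny_index):
    psm = pd.DataFrame(
        [
            {"sample_id": "s1", "peptide": "GGGHHHK", "spectral_count": 2},
            {"sample_id": "s1", "peptide": "GG*HHK", "spectral_count": 1},
        ]
    )
    assigned, unmatched = assign_psms(psm, tiny_index)
    assert len(assigned) == 1
    assert unmatched["reason"].tolist() == ["illegal_characters"]


def test_assignment_matches_generator_truth(small_sim):
    """Every matched PSM carries its generating organism among its parents."""
    records = small_sim["records"]
    index = build_index(digest_proteome(records), records, [("strainA", "strainAii")])
    assigned, unmatched = assign_psms(small_sim["psm"], index)
    assert unmatched.empty

    origin = small_sim["truth"].psm_origin.copy()
    origin["canonical"] = origin["peptide"].map(canonicalize)
    origin["origin_org"] = origin["gene_id"].map(lambda g: records[g].organism_id)
    parent_orgs = {
        (r.sample_id, r.canonical_sequence): set(r.organism_ids.split(";"))
        for r in assigned.itertuples(index=False)
    }
    for row in origin.itertuples(index=False):
        assert row.origin_org in parent_orgs[(row.sample_id, row.canonical)]


def test_organism_unique_counts_increase_with_divergence():
    """Mean organism-unique peptide count per strain is non-decreasing in the
    substitution rate (reduced-scale version of the divergence sweep)."""
    from strainprot.simulate import SimParams, simulate_database

    means = []
    for rho in (0.0, 0.01, 0.05):
        counts = []
        for seed in range(2):
            params = SimParams(
                seed=seed, rho=rho, unique_gene_fraction=0.0, genes_per_organism=(20, 25)
            )
            records, _, _, _ = simulate_database(params)
            index = build_index(digest_proteome(records), records, [("strainA", "strainAii")])
            for strain in ("strainA", "strainAii"):
                counts.append(
                    sum(
                        1
                        for e in index.entries.values()
                        if e.is_organism_unique and e.parent_organism_ids == {strain}
                    )
                )
        means.append(np.mean(counts))
    assert means[0] == 0.0
    assert means == sorted(means)


def test_build_index_empty_errors(tiny_db):
    records, _ = tiny_db
    with pytest.raises(ValueError):
        build_index([], records)
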