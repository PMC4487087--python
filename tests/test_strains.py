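"""Ortholog pairing, strain-unique gene detection, contig profiles."""

import numpy as np
import pandas as pd
import pytest

from strainprot.model import GeneRecord
from strainprot.strains import (
    OrthologMap,
    contig_profile,
    global_identity,
    pair_orthologs,
    strain_unique_detection,
)


def _proteome(org, seqs):
    records = {}
    start = 1
    for i, seq in enumerate(seqs):
        gid = f"{org}_g{i}"
        records[gid] = GeneRecord(gid, org, f"{org}_c1", start, start + 3 * len(seq) - 1, "+", seq)
        start += 3 * len(seq) + 100
    return records


SEQS = [
    "MKTAYIAKQRGGGHHHKLMNPQRSTVWY" * 3,
    "ACDEFGHIKLMNPQRSTVWYACDEFGHI" * 3,
    "WYACDEFGHMKTAYIAKQRGGGHHHKLM" * 3,
]


def test_identity_of_identical_proteomes():
    a = _proteome("A", SEQS)
    b = _proteome("B", SEQS)
    ortho = pair_orthologs(a, b)
    assert len(ortho.pairs) == 3
    assert (ortho.pairs["aa_identity"] == 1.0).all()
    assert ortho.mean_aa_identity == 1.0
    assert ortho.unique_to_a == frozenset() and ortho.unique_to_b == frozenset()


def test_extra_gene_is_unique():
    a = _proteome("A", SEQS + ["PPPPPPWWWWCCCCDDDDEEEEFFFF"])
    b = _proteome("B", SEQS)
    ortho = pair_orthologs(a, b)
    assert ortho.unique_to_a == frozenset({"A_g3"})
    assert len(ortho.pairs) + len(ortho.unique_to_a) == len(a)
    assert len(ortho.pairs) + len(ortho.unique_to_b) == len(b)


def test_pairing_symmetry(small_sim):
    records = small_sim["records"]
    pa = {g: r for g, r in records.items() if r.organism_id == "strainA"}
    pb = {g: r for g, r in records.items() if r.organism_id == "strainAii"}
    fwd = pair_orthologs(pa, pb)
    rev = pair_orthologs(pb, pa)
    fwd_pairs = set(zip(fwd.pairs["gene_a"], fwd.pairs["gene_b"]))
    rev_pairs = set(zip(rev.pairs["gene_b"], rev.pairs["gene_a"]))
    assert fwd_pairs == rev_pairs
    assert fwd.unique_to_a == rev.unique_to_b
    assert fwd.unique_to_b == rev.unique_to_a


def test_mean_identity_tracks_substitution_rate():
    """At substitution rate 0.01/site the mean pair identity is ~0.99,
    within 3 binomial standard errors."""
    from strainprot.simulate import SimParams, simulate_database

    rho = 0.01
    params = SimParams(seed=5, rho=rho, genes_per_organism=(60, 80))
    records, _, _, truth = simulate_database(params)
    pa = {g: r for g, r in records.items() if r.organism_id == "strainA"}
    pb = {g: r for g, r in records.items() if r.organism_id == "strainAii"}
    ortho = pair_orthologs(pa, pb)
    total_sites = sum(pa[g].length_aa for g in ortho.pairs["gene_a"])
    se = np.sqrt(rho * (1 - rho) / total_sites)
    assert abs(ortho.mean_aa_identity - (1 - rho)) < 3 * se


def test_global_identity_definition():
    ident, cov = global_identity("MKTAYIAK", "MKTAYIAK")
    assert (ident, cov) == (1.0, 1.0)
    ident, cov = global_identity("MKTAYIAK", "MKTAYVAK")
    assert ident == pytest.approx(7 / 8)


def _detect(rows):
    df = pd.DataFrame(rows, columns=["sample_id", "gene_id", "unique_spectral_count"])
    df["detected"] = df["unique_spectral_count"] >= 1
    return df


def _map(a, b, pairs, ua, ub):
    return OrthologMap(
        strain_a=a,
        strain_b=b,
        pairs=pd.DataFrame(pairs, columns=["gene_a", "gene_b", "aa_identity"]),
        unique_to_a=frozenset(ua),
        unique_to_b=frozenset(ub),
    )


def test_strain_unique_detection_counts():
    ortho = _map("A", "B", [], ["A_u1", "A_u2", "A_u3"], [])
    detect = _detect([("s1", "A_u1", 2), ("s1", "A_u2", 0), ("s1", "A_u3", 0)])
    table = strain_unique_detection(ortho, detect).set_index("strain")
    assert table.loc["A", "n_unique_genes"] == 3
    assert table.loc["A", "n_unique_detected"] == 1
    assert table.loc["B", "n_unique_genes"] == 0
    assert table.loc["B", "n_unique_detected"] == 0


def test_contig_profile_dense_ordered(tiny_db):
    records, _ = tiny_db
    ortho = _map("CITa", "CITb", [("cita1", "citb1", 1.0)], ["cita2"], [])
    # cita1 has length 14 aa; SpC 4 on a 200 aa gene would be 0.02 — use
    # the real length here: 4 / 14
    detect = _detect([("s1", "cita1", 4), ("s1", "cita2", 0)])
    profile = contig_profile(detect, records, ortho, "CITa")
    assert profile["gene_id"].tolist() == ["cita1", "cita2"]  # ordered by start
    assert profile.iloc[0]["normalized_count"] == pytest.approx(4 / 14)
    assert profile.iloc[1]["normalized_count"] == 0.0  # dense: undetected kept
    assert bool(profile.iloc[1]["strain_unique_flag"])
    assert not bool(profile.iloc[0]["strain_unique_flag"])


def test_contig_profile_normalization_arithmetic():
    """SpC 4 over a 200-residue protein -> 0.02 per residue."""
    records = {"A_g0": GeneRecord("A_g0", "A", "A_c1", 1, 600, "+", "M" * 200)}
    ortho = _map("A", "B", [], [], [])
    profile = contig_profile(_detect([("s1", "A_g0", 4)]), records, ortho, "A")
    assert profile.iloc[0]["normalized_count"] == pytest.approx(0.02)


def test_contig_profile_unknown_strain():
    ortho = _map("A", "B", [], [], [])
    with pytest.raises(ValueError, match="C"):
        contig_profile(_detect([]), {}, ortho, "C")


def test_paired_profiles_correlate(small_sim):
    """Orthologs share activity weights, so the two strains' per-gene
    profiles correlate positively in most samples."""
    from scipy.stats import spearmanr

    from strainprot.digestion import digest_proteome
    from strainprot.index import assign_psms, build_index
    from strainprot.quantify import detect_proteins

    records = small_sim["records"]
    pa = {g: r for g, r in records.items() if r.organism_id == "strainA"}
    pb = {g: r for g, r in records.items() if r.organism_id == "strainAii"}
    ortho = pair_orthologs(pa, pb)
    index = build_index(digest_proteome(records), records, [("strainA", "strainAii")])
    assigned, _ = assign_psms(small_sim["psm"], index)
    detect = detect_proteins(assigned, records, share_mode="proportional")
    prof_a = contig_profile(detect, records, ortho, "strainA")
    prof_b = contig_profile(detect, records, ortho, "strainAii")
    b_of_a = dict(zip(ortho.pairs["gene_a"], ortho.pairs["gene_b"]))
    positive = 0
    samples = sorted(prof_a["sample_id"].unique())
    for s in samples:
        a_counts = prof_a[prof_a["sample_id"] == s].set_index("gene_id")["normalized_count"]
        b_counts = prof_b[prof_b["sample_id"] == s].set_index("gene_id")["normalized_count"]
        xs = [a_counts[ga] for ga in b_of_a]
        ys = [b_counts[gb] for gb in b_of_a.values()]
        rho, _ = spearmanr(xs, ys)
        positive += rho > 0
    assert positive >= 0.9 * len(samples)
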