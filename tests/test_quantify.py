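"""Detection calls, sample QC, and peptide-based composition."""

import numpy as np
import pandas as pd
import pytest

from strainprot.digestion import DigestParams, digest_proteome
from strainprot.index import assign_psms, build_index
from strainprot.model import GeneRecord, OrganismBin
from strainprot.quantify import (
    detect_proteins,
    peptide_composition,
    proteome_coverage_percent,
    qc_exclude_samples,
    summary_table,
)

PARAMS = DigestParams(0, 1, 100, collapse_IL=True)


def _assigned(tiny_db, tiny_psm):
    records, _ = tiny_db
    index = build_index(digest_proteome(records, PARAMS), records, [("CITa", "CITb")])
    assigned, _ = assign_psms(tiny_psm, index)
    return assigned


def test_detection_calls(tiny_db, tiny_psm):
    records, _ = tiny_db
    detect = detect_proteins(_assigned(tiny_db, tiny_psm), records, detection_min=1)
    d = detect.set_index(["sample_id", "gene_id"])
    # one protein-unique PSM suffices
    assert d.loc[("s1", "ser1"), "detected"]
    assert d.loc[("s1", "ser1"), "unique_spectral_count"] == 5
    assert d.loc[("s1", "cita2"), "unique_spectral_count"] == 2
    # genes hit only by shared peptides are not detected
    assert not d.loc[("s1", "cita1"), "detected"]
    assert not d.loc[("s1", "citb1"), "detected"]
    # the table is dense: every gene appears in every sample
    assert len(detect) == 2 * len(records)


def test_qc_exclusion_boundary():
    """A failed sample at 190 unique spectra is dropped at threshold 500; the
    threshold is a strict less-than."""
    assigned = pd.DataFrame(
        [
            {"sample_id": "low", "canonical_sequence": "AAAAK", "spectral_count": 190,
             "gene_ids": "g1", "organism_ids": "O1", "uniqueness_class": "protein_unique"},
            {"sample_id": "high", "canonical_sequence": "AAAAK", "spectral_count": 4300,
             "gene_ids": "g1", "organism_ids": "O1", "uniqueness_class": "protein_unique"},
        ]
    )
    kept, excluded = qc_exclude_samples(assigned, 500)
    assert (kept, excluded) == (["high"], ["low"])
    kept, excluded = qc_exclude_samples(assigned, 0)
    assert excluded == []
    # totals equal to the threshold are kept
    kept, excluded = qc_exclude_samples(assigned, 190)
    assert kept == ["high", "low"]


def test_qc_all_excluded_is_hard_error():
    assigned = pd.DataFrame(
        [{"sample_id": "s", "canonical_sequence": "AAAAK", "spectral_count": 1,
          "gene_ids": "g1", "organism_ids": "O1", "uniqueness_class": "protein_unique"}]
    )
    with pytest.raises(ValueError, match="threshold"):
        qc_exclude_samples(assigned, 10**6)


def _one_gene_db(spcs_lengths_counts):
    """Build organisms with one or more genes of given lengths."""
    records, bins = {}, {}
    for org, lengths in spcs_lengths_counts.items():
        contig = f"{org}_c1"
        start = 1
        for i, L in enumerate(lengths):
            gid = f"{org}_g{i}"
            records[gid] = GeneRecord(gid, org, contig, start, start + 3 * L - 1, "+", "A" * L)
            start += 3 * L + 10
        bins[org] = OrganismBin(org, frozenset([contig]), start, len(lengths))
    return records, bins


def _detect_frame(rows):
    df = pd.DataFrame(rows, columns=["sample_id", "gene_id", "unique_spectral_count"])
    df["detected"] = df["unique_spectral_count"] >= 1
    return df


def test_composition_length_normalization():
    """Equal counts, lengths 100 vs 200 -> fractions 2/3 and 1/3."""
    records, bins = _one_gene_db({"O1": [100], "O2": [200]})
    detect = _detect_frame([("s1", "O1_g0", 10), ("s1", "O2_g0", 10)])
    comp = peptide_composition(detect, records, bins)
    f = comp.set_index("organism_id")["fraction"]
    assert f["O1"] == pytest.approx(2 / 3)
    assert f["O2"] == pytest.approx(1 / 3)


def test_composition_protein_count_normalization():
    """Same counts and length but protein_count 2 -> activities 0.1 vs 0.025."""
    records, bins = _one_gene_db({"O1": [100], "O2": [100, 400]})
    detect = _detect_frame([("s1", "O1_g0", 10), ("s1", "O2_g0", 5), ("s1", "O2_g1", 0)])
    comp = peptide_composition(detect, records, bins).set_index("organism_id")
    assert comp.loc["O1", "raw_activity"] == pytest.approx(0.1)
    assert comp.loc["O2", "raw_activity"] == pytest.approx(0.025)
    assert comp.loc["O1", "fraction"] == pytest.approx(0.8)
    assert comp.loc["O2", "fraction"] == pytest.approx(0.2)


def test_composition_scale_invariance_and_closure():
    records, bins = _one_gene_db({"O1": [100], "O2": [150], "O3": [220]})
    rows = [("s1", "O1_g0", 7), ("s1", "O2_g0", 13), ("s1", "O3_g0", 2)]
    comp1 = peptide_composition(_detect_frame(rows), records, bins)
    scaled = [(s, g, 5 * c) for s, g, c in rows]
    comp2 = peptide_composition(_detect_frame(scaled), records, bins)
    assert np.allclose(comp1["fraction"], comp2["fraction"])
    assert comp1["fraction"].sum() == pytest.approx(1.0, abs=1e-9)


def test_composition_zero_activity_organism_is_neutral():
    """Adding an organism with zero detected peptides leaves others unchanged."""
    records, bins = _one_gene_db({"O1": [100], "O2": [150]})
    rows = [("s1", "O1_g0", 7), ("s1", "O2_g0", 13)]
    base = peptide_composition(_detect_frame(rows), records, bins)
    records3, bins3 = _one_gene_db({"O1": [100], "O2": [150], "O3": [220]})
    rows3 = rows + [("s1", "O3_g0", 0)]
    with3 = peptide_composition(_detect_frame(rows3), records3, bins3)
    merged = base.merge(with3, on=["sample_id", "organism_id"], suffixes=("_a", "_b"))
    assert np.allclose(merged["fraction_a"], merged["fraction_b"])


def test_composition_zero_sample_is_na():
    records, bins = _one_gene_db({"O1": [100]})
    comp = peptide_composition(_detect_frame([("s1", "O1_g0", 0)]), records, bins)
    assert comp["fraction"].isna().all()


def test_proteome_coverage_percent():
    assert proteome_coverage_percent(1, 4) == pytest.approx(25.0)
    assert proteome_coverage_percent([2, 2], [4, 4]) == pytest.approx(50.0)
    with pytest.raises(ValueError):
        proteome_coverage_percent(1, 0)


def test_summary_table_hand_counts(tiny_db, tiny_psm):
    records, bins = tiny_db
    detect = detect_proteins(_assigned(tiny_db, tiny_psm), records)
    summary = summary_table(detect, records, bins).set_index("statistic")
    # ser1 detected in both samples, cita2 in one; strain genes never
    assert summary.loc["unique_proteins_detected", "SER"] == 1
    assert summary.loc["unique_proteins_detected", "CITa"] == 1
    assert summary.loc["unique_proteins_detected", "CITb"] == 0
    assert summary.loc["genes", "SER"] == 2
    # 5+1 unique SpC for ser1 over two samples
    assert summary.loc["unique_protein_matches", "SER"] == 6
    assert summary.loc["avg_unique_proteins_per_sample", "SER"] == pytest.approx(1.0)
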