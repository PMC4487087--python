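"""Shared fixtures: a tiny hand-built community and a small simulated one."""

import pandas as pd
import pytest

from strainprot.model import GeneRecord, OrganismBin


def _gene(gid, org, contig, start, seq, terms=()):
    return GeneRecord(
        gene_id=gid,
        organism_id=org,
        contig_id=contig,
        start=start,
        end=start + 3 * len(seq) - 1,
        strand="+",
        aa_sequence=seq,
        annotation_terms=frozenset(terms),
    )


@pytest.fixture
def tiny_db():
    """Three organisms, of which CITa/CITb are an identical-ish strain pair.

    Tryptic structure (0 missed cleavages, no length filter):
      ser1: MK | TAYIAK | QR | GGGHHHK
      ser2: MK | TAYIAK | CCCR          (shares MK, TAYIAK with ser1)
      cita1 = citb1: AAAPWWK | TTTTTTR  (strain-pair shared)
      cita2: CCCDDDK | EEEFFFR          (unique to CITa)
    """
    records = {}
    for rec in [
        _gene("ser1", "SER", "SER_c1", 1, "MKTAYIAKQRGGGHHHK", {"EC:1.1.1.1"}),
        _gene("ser2", "SER", "SER_c1", 300, "MKTAYIAKCCCR"),
        _gene("cita1", "CITa", "CITa_c1", 1, "AAAPWWKTTTTTTR", {"K00001"}),
        _gene("cita2", "CITa", "CITa_c1", 200, "CCCDDDKEEEFFFR"),
        _gene("citb1", "CITb", "CITb_c1", 1, "AAAPWWKTTTTTTR"),
    ]:
        records[rec.gene_id] = rec
    by_org = {}
    for r in records.values():
        by_org.setdefault(r.organism_id, []).append(r)
    bins = {
        org: OrganismBin(
            organism_id=org,
            contig_ids=frozenset(r.contig_id for r in recs),
            genome_length_bp=max(r.end for r in recs),
            protein_count=len(recs),
        )
        for org, recs in by_org.items()
    }
    return records, bins


@pytest.fixture
def tiny_psm():
    """PSMs hitting a protein-unique, a strain-shared and a cross-organism peptide."""
    return pd.DataFrame(
        [
            {"sample_id": "s1", "peptide": "GGGHHHK", "spectral_count": 5},
            {"sample_id": "s1", "peptide": "TAYIAK", "spectral_count": 3},
            {"sample_id": "s1", "peptide": "AAAPWWK", "spectral_count": 4},
            {"sample_id": "s1", "peptide": "CCCDDDK", "spectral_count": 2},
            {"sample_id": "s2", "peptide": "GGGHHHK", "spectral_count": 1},
            {"sample_id": "s2", "peptide": "WWWDDDK", "spectral_count": 7},
        ]
    )


@pytest.fixture(scope="session")
def small_sim():
    """A small but complete simulated community (shared across tests)."""
    from strainprot.simulate import SimParams, simulate_all

    params = SimParams(
        seed=11,
        genes_per_organism=(30, 40),
        n_samples=3,
        psms_per_sample=4000,
        reads_per_sample=20000,
    )
    records, bins, lists, truth, psm, reads = simulate_all(params)
    return {
        "params": params,
        "records": records,
        "bins": bins,
        "lists": lists,
        "truth": truth,
        "psm": psm,
        "reads": reads,
    }
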