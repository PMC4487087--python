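"""Compare the two simulated strains: orthologs, unique genes, contig profiles.

Pairs the strain proteomes by bidirectional best match, scores the planted
strain-unique genes against the ortholog map, and writes the per-contig
peptide-coverage profiles to results/strain/.
"""

from pathlib import Path

import pandas as pd

from strainprot.digestion import digest_proteome
from strainprot.index import assign_psms, build_index
from strainprot.io import load_database, read_psm_table, read_table, write_table
from strainprot.quantify import detect_proteins, qc_exclude_samples
from strainprot.strains import contig_profile, pair_orthologs, strain_unique_detection

SIM = Path("results/sim")
OUT = Path("results/strain")
PAIR = ("strainA", "strainAii")


def main() -> None:
    records, bins = load_database(SIM / "proteome.faa", SIM / "gene_map.tsv")
    proteome_a = {g: r for g, r in records.items() if r.organism_id == PAIR[0]}
    proteome_b = {g: r for g, r in records.items() if r.organism_id == PAIR[1]}
    ortho = pair_orthologs(proteome_a, proteome_b)
    print(f"{len(ortho.pairs)} ortholog pairs, mean aa identity {ortho.mean_aa_identity:.4f}")

    truth = read_table(SIM / "truth" / "strain_unique.tsv")
    truth_sets = {s: set(truth.loc[truth["strain"] == s, "gene_id"]) for s in PAIR}
    for strain, pred in ((PAIR[0], ortho.unique_to_a), (PAIR[1], ortho.unique_to_b)):
        tp = len(pred & truth_sets[strain])
        print(f"  {strain}: {len(pred)} predicted unique, {tp} match the planted truth")

    index = build_index(digest_proteome(records), records, [PAIR])
    assigned, _ = assign_psms(read_psm_table(SIM / "psm.tsv"), index)
    kept, _ = qc_exclude_samples(assigned)
    detect = detect_proteins(assigned, records)

    OUT.mkdir(parents=True, exist_ok=True)
    write_table(ortho.pairs, OUT / "orthologs.tsv")
    unique_table = strain_unique_detection(ortho, detect, kept)
    write_table(unique_table, OUT / "strain_unique.tsv")
    print("\nstrain-unique detection (unique counts only):")
    print(unique_table.to_string(index=False))
    for strain in PAIR:
        profile = contig_profile(detect, records, ortho, strain)
        write_table(profile, OUT / f"contig_profile_{strain}.tsv")
    print(f"\nprofiles + tables in {OUT}/")


if __name__ == "__main__":
    main()
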