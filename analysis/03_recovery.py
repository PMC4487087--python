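"""Score the pipeline's estimates against the generator's ground truth.

Compares read-based fractions to the abundance truth and peptide-based
fractions (under each shared-peptide policy) to the activity truth, and
writes results/recovery_summary.tsv. The headline finding: unique-only
counting collapses for a 99%-identical strain pair because ~90% of strain
peptides are shared; proportional distribution of shared counts recovers
the truth.
"""

from pathlib import Path

import pandas as pd

from strainprot.abundance import read_composition
from strainprot.digestion import digest_proteome
from strainprot.index import assign_psms, build_index
from strainprot.io import load_database, read_psm_table, read_read_counts, read_table
from strainprot.quantify import detect_proteins, peptide_composition, qc_exclude_samples

SIM = Path("results/sim")
OUT = Path("results/recovery_summary.tsv")


def main() -> None:
    records, bins = load_database(SIM / "proteome.faa", SIM / "gene_map.tsv")
    psm = read_psm_table(SIM / "psm.tsv")
    reads = read_read_counts(SIM / "read_counts.tsv")
    truth_ab = read_table(SIM / "truth" / "abundance.tsv").pivot(
        index="sample_id", columns="organism_id", values="fraction"
    )
    truth_act = read_table(SIM / "truth" / "activity.tsv").pivot(
        index="sample_id", columns="organism_id", values="fraction"
    )

    rows = []
    est_read = read_composition(reads, bins).pivot(
        index="sample_id", columns="organism_id", values="fraction"
    )
    err = (est_read - truth_ab).abs()
    rows.append({"estimate": "read_fraction", "share_mode": "-",
                 "max_abs_error": err.max().max(), "mean_abs_error": err.mean().mean()})

    index = build_index(digest_proteome(records), records, [("strainA", "strainAii")])
    assigned, _ = assign_psms(psm, index)
    kept, _ = qc_exclude_samples(assigned)
    for mode in ("unique", "fractional", "proportional"):
        detect = detect_proteins(assigned, records, share_mode=mode)
        est = peptide_composition(detect, records, bins, kept).pivot(
            index="sample_id", columns="organism_id", values="fraction"
        )
        err = (est - truth_act.loc[est.index]).abs()
        rows.append({"estimate": "activity_fraction", "share_mode": mode,
                     "max_abs_error": err.max().max(), "mean_abs_error": err.mean().mean()})

    summary = pd.DataFrame(rows).round(4)
    summary.to_csv(OUT, sep="\t", index=False)
    print(summary.to_string(index=False))
    print(f"\nwrote {OUT}")


if __name__ == "__main__":
    main()
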