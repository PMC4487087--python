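"""Read-based community composition and abundance-vs-activity divergence.

Read counts per contig estimate DNA abundance; dividing an organism's summed
counts by its genome length converts DNA share to an (unnormalized) cell
share, which per-sample closure turns into a cell-fraction estimate. The
divergence table joins the read-based and peptide-based compositions and
reports log2(peptide_fraction / read_fraction): an organism can be abundant
but inactive (negative) or rare but highly active (positive).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .model import OrganismBin, contig_to_organism
from .quantify import COMPOSITION_COLUMNS

logger = logging.getLogger(__name__)

#: |log2 ratio| above which a (sample, organism) is flagged discordant.
#: A reporting convenience with no inferential claim attached.
DISCORDANCE_THRESHOLD = 0.5

DIVERGENCE_COLUMNS = [
    "sample_id",
    "organism_id",
    "read_fraction",
    "peptide_fraction",
    "log2_activity_ratio",
    "discordant",
]


def read_composition(
    reads: pd.DataFrame, bins: dict[str, OrganismBin]
) -> pd.DataFrame:
    """Read-based community composition (source tag ``read``).

    raw(o, s) = sum of read counts on o's contigs / genome_length_bp(o);
    fractions closed per sample. Unknown contigs are a hard error.
    """
    owner = contig_to_organism(bins)
    unknown = set(reads["contig_id"]) - set(owner)
    if unknown:
        raise ValueError(f"read counts reference unknown contig: {sorted(unknown)[0]}")
    df = reads.copy()
    df["organism_id"] = df["contig_id"].map(owner)
    per_org = df.groupby(["sample_id", "organism_id"])["read_count"].sum().reset_index()
    rows = []
    for s in sorted(df["sample_id"].unique()):
        sub = per_org[per_org["sample_id"] == s]
        raw = {
            org: float(sub.loc[sub["organism_id"] == org, "read_count"].sum())
            / bins[org].genome_length_bp
            for org in sorted(bins)
        }
        total = sum(raw.values())
        if total <= 0:
            logger.warning("sample %s: zero mapped reads; fractions are NA", s)
        for org in sorted(bins):
            rows.append(
                {
                    "sample_id": s,
                    "organism_id": org,
                    "raw_activity": raw[org],
                    "fraction": raw[org] / total if total > 0 else np.nan,
                    "source": "read",
                }
            )
    return pd.DataFrame(rows, columns=COMPOSITION_COLUMNS)


def divergence(read_comp: pd.DataFrame, pep_comp: pd.DataFrame) -> pd.DataFrame:
    """Join read and peptide compositions and compute log2 activity ratios.

    The ratio is finite only when both fractions are > 0; otherwise NA.
    Organisms present on one side only are kept with the missing side NA
    (with a warning).
    """
    r = read_comp[["sample_id", "organism_id", "fraction"]].rename(
        columns={"fraction": "read_fraction"}
    )
    p = pep_comp[["sample_id", "organism_id", "fraction"]].rename(
        columns={"fraction": "peptide_fraction"}
    )
    merged = r.merge(p, on=["sample_id", "organism_id"], how="outer")
    one_sided = merged["read_fraction"].isna() ^ merged["peptide_fraction"].isna()
    if one_sided.any():
        logger.warning(
            "%d (sample, organism) rows present in only one composition table",
            int(one_sided.sum()),
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.log2(merged["peptide_fraction"] / merged["read_fraction"])
    ok = (merged["read_fraction"] > 0) & (merged["peptide_fraction"] > 0)
    merged["log2_activity_ratio"] = np.where(ok, ratio, np.nan)
    merged["discordant"] = ok & (np.abs(merged["log2_activity_ratio"]) > DISCORDANCE_THRESHOLD)
    merged = merged.sort_values(["sample_id", "organism_id"]).reset_index(drop=True)
    return merged[DIVERGENCE_COLUMNS]
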