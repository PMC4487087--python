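"""Pathway gene-list coverage: metabolic potential and expression-over-potential.

A pathway list is a curated set of gene ids (compiled from EC numbers, KO
identifiers and free-text annotation terms). Two summaries are computed:

- the *potential matrix*: how many of each list's genes each organism
  encodes (what the community could do);
- the *expression-over-potential ratio*: per sample, organism and list, the
  non-redundant count of the list's genes detected by proteomics divided by
  the count of the list's genes in that organism — a value in [0, 1] that
  tracks how much of an encoded capability is actually expressed.

"Feature" means gene: each gene counts once regardless of spectral counts
or how many annotation terms it carries.
"""

from __future__ import annotations

import pandas as pd

from .model import GeneRecord

POTENTIAL_COLUMNS = ["list_name", "organism_id", "n_features"]
RATIO_COLUMNS = ["sample_id", "organism_id", "list_name", "n_detected", "n_total", "ratio"]


def _resolve_lists(
    lists: dict[str, frozenset], records: dict[str, GeneRecord]
) -> None:
    for name in sorted(lists):
        for gid in sorted(lists[name]):
            if gid not in records:
                raise ValueError(f"pathway list {name}: gene {gid} not in database")


def potential_matrix(
    lists: dict[str, frozenset], records: dict[str, GeneRecord]
) -> pd.DataFrame:
    """Count each list's genes per organism; zero rows are kept."""
    _resolve_lists(lists, records)
    organisms = sorted({r.organism_id for r in records.values()})
    rows = []
    for name in sorted(lists):
        by_org = {o: 0 for o in organisms}
        for gid in lists[name]:
            by_org[records[gid].organism_id] += 1
        rows.extend(
            {"list_name": name, "organism_id": o, "n_features": by_org[o]}
            for o in organisms
        )
    return pd.DataFrame(rows, columns=POTENTIAL_COLUMNS)


def expression_potential_ratio(
    lists: dict[str, frozenset],
    detect: pd.DataFrame,
    records: dict[str, GeneRecord],
    samples=None,
    pooled: bool = False,
) -> pd.DataFrame:
    """Expression-over-potential ratios per (sample, organism, list).

    ``n_detected`` counts the list's genes of the organism detected in the
    sample (each gene once); ``ratio = n_detected / n_total``. (list,
    organism) cells with ``n_total == 0`` are omitted. With ``pooled=True``
    a single table is returned where a gene counts as detected if it is
    detected in any kept sample (sample_id ``"pooled"``).
    """
    _resolve_lists(lists, records)
    if samples is None:
        samples = sorted(detect["sample_id"].unique())
    det = detect[detect["sample_id"].isin(samples) & detect["detected"]]
    detected_by_sample = {
        s: set(det.loc[det["sample_id"] == s, "gene_id"]) for s in samples
    }
    if pooled:
        detected_by_sample = {"pooled": set(det["gene_id"])}

    organisms = sorted({r.organism_id for r in records.values()})
    genes_by_org_list = {
        (name, o): [gid for gid in lists[name] if records[gid].organism_id == o]
        for name in sorted(lists)
        for o in organisms
    }
    rows = []
    for s, detected in detected_by_sample.items():
        for name in sorted(lists):
            for o in organisms:
                members = genes_by_org_list[(name, o)]
                if not members:
                    continue
                n_det = sum(1 for g in members if g in detected)
                rows.append(
                    {
                        "sample_id": s,
                        "organism_id": o,
                        "list_name": name,
                        "n_detected": n_det,
                        "n_total": len(members),
                        "ratio": n_det / len(members),
                    }
                )
    return pd.DataFrame(rows, columns=RATIO_COLUMNS)


def plot_ratio_heatmap(ratio: pd.DataFrame, organism_id: str, out_png: str) -> None:
    """Optional helper: heatmap of ratio (lists × samples) for one organism.

    Requires matplotlib; the TSV values are the contract, the figure is a
    convenience.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    sub = ratio[ratio["organism_id"] == organism_id]
    pivot = sub.pivot(index="list_name", columns="sample_id", values="ratio")
    fig, ax = plt.subplots(figsize=(1 + 0.5 * pivot.shape[1], 1 + 0.3 * pivot.shape[0]))
    im = ax.imshow(pivot.to_numpy(), aspect="auto", vmin=0, vmax=1, cmap="viridis")
    ax.set_xticks(range(pivot.shape[1]), pivot.columns, rotation=90)
    ax.set_yticks(range(pivot.shape[0]), pivot.index)
    ax.set_title(f"expression / potential — {organism_id}")
    fig.colorbar(im, ax=ax, label="ratio")
    fig.tight_layout()
    fig.savefig(out_png, dpi=150)
    plt.close(fig)
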