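"""End-to-end pipeline: chain the stage modules from a YAML config.

Config layout (all stages have defaults except the four input paths)::

    inputs:
      proteome_fasta: proteome.faa
      gene_map: gene_map.tsv
      psm_table: psm.tsv
      read_counts: read_counts.tsv
      pathway_lists: pathway_lists.tsv
    digestion: {max_missed_cleavages: 2, min_length: 6, max_length: 50, collapse_IL: true}
    detection: {detection_min: 1, qc_min_unique_spectra: 500}
    normalization: {share_mode: unique}
    strain: {pairs: [[strainA, strainAii]], min_identity: 0.8, min_coverage: 0.8}
    output_dir: results/

Outputs are written only after every stage succeeded, so a failed run leaves
no partial tables; the run log records parameter values and input checksums.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import yaml

from . import abundance as ab
from . import io as sp_io
from . import pathways as pw
from . import quantify as qt
from . import strains as st
from .digestion import DigestParams, digest_proteome
from .index import assign_psms, build_index

OUTPUT_TABLES = [
    "detection.tsv",
    "composition_peptide.tsv",
    "composition_read.tsv",
    "divergence.tsv",
    "potential_matrix.tsv",
    "ratio_table.tsv",
]


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name."""


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        config = yaml.safe_load(fh) or {}
    inputs = config.get("inputs", {})
    for key in ("proteome_fasta", "gene_map", "psm_table", "read_counts", "pathway_lists"):
        if key not in inputs:
            raise ValueError(f"{key} required in config inputs section")
    return config


def _stage(name: str):
    def wrap(fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:  # re-raise with stage context
            raise PipelineError(f"stage {name}: {exc}") from exc

    return wrap


def run_pipeline(config_path: str | Path, out_dir: str | Path | None = None) -> Path:
    """Run all stages and write the result tables; returns the output dir."""
    config = load_config(config_path)
    base = Path(config_path).parent
    inputs = {k: str((base / v)) for k, v in config["inputs"].items()}
    out = Path(out_dir or (base / config.get("output_dir", "results")))

    dig_cfg = config.get("digestion", {})
    det_cfg = config.get("detection", {})
    norm_cfg = config.get("normalization", {})
    strain_cfg = config.get("strain", {})
    params = DigestParams(
        max_missed_cleavages=int(dig_cfg.get("max_missed_cleavages", 2)),
        min_length=int(dig_cfg.get("min_length", 6)),
        max_length=int(dig_cfg.get("max_length", 50)),
        collapse_IL=bool(dig_cfg.get("collapse_IL", True)),
    )
    detection_min = int(det_cfg.get("detection_min", 1))
    qc_min = int(det_cfg.get("qc_min_unique_spectra", 500))
    share_mode = norm_cfg.get("share_mode", "unique")
    pairs = [tuple(p) for p in strain_cfg.get("pairs", [])]

    records, bins = _stage("load_database")(
        sp_io.load_database, inputs["proteome_fasta"], inputs["gene_map"]
    )
    psm = _stage("load_psms")(sp_io.read_psm_table, inputs["psm_table"])
    reads = _stage("load_reads")(sp_io.read_read_counts, inputs["read_counts"])
    lists = _stage("load_pathway_lists")(sp_io.read_pathway_lists, inputs["pathway_lists"])

    peptides = _stage("digestion")(digest_proteome, records, params)
    index = _stage("index")(
        build_index, peptides, records, pairs, params.collapse_IL
    )
    assigned, unmatched = _stage("assignment")(assign_psms, psm, index)
    kept, excluded = _stage("qc")(qt.qc_exclude_samples, assigned, qc_min)
    detect = _stage("detection")(
        qt.detect_proteins, assigned, records, detection_min, share_mode
    )
    pep_comp = _stage("peptide_composition")(
        qt.peptide_composition, detect, records, bins, kept
    )
    read_comp = _stage("read_composition")(ab.read_composition, reads, bins)
    read_comp_kept = read_comp[read_comp["sample_id"].isin(kept)]
    div = _stage("divergence")(ab.divergence, read_comp_kept, pep_comp)
    potential = _stage("potential_matrix")(pw.potential_matrix, lists, records)
    ratios = _stage("ratio_table")(
        pw.expression_potential_ratio, lists, detect, records, kept
    )
    summary = _stage("summary")(qt.summary_table, detect, records, bins, kept)

    strain_outputs = {}
    for pair in pairs:
        a, b = pair
        prot_a = {g: r for g, r in records.items() if r.organism_id == a}
        prot_b = {g: r for g, r in records.items() if r.organism_id == b}
        ortho = _stage("pair_orthologs")(
            st.pair_orthologs,
            prot_a,
            prot_b,
            float(strain_cfg.get("min_identity", 0.8)),
            float(strain_cfg.get("min_coverage", 0.8)),
        )
        tag = f"{a}__{b}"
        strain_outputs[f"orthologs_{tag}.tsv"] = ortho.pairs
        strain_outputs[f"strain_unique_{tag}.tsv"] = _stage("strain_unique")(
            st.strain_unique_detection, ortho, detect, kept
        )
        for strain in pair:
            strain_outputs[f"contig_profile_{strain}.tsv"] = _stage("contig_profile")(
                st.contig_profile, detect, records, ortho, strain
            )

    # all stages succeeded: write everything
    out.mkdir(parents=True, exist_ok=True)
    sp_io.write_table(detect, out / "detection.tsv")
    sp_io.write_table(pep_comp, out / "composition_peptide.tsv")
    sp_io.write_table(read_comp, out / "composition_read.tsv")
    sp_io.write_table(div, out / "divergence.tsv")
    sp_io.write_table(potential, out / "potential_matrix.tsv")
    sp_io.write_table(ratios, out / "ratio_table.tsv")
    sp_io.write_table(summary, out / "summary_table.tsv")
    sp_io.write_table(unmatched, out / "unmatched_psms.tsv")
    for name, table in strain_outputs.items():
        sp_io.write_table(table, out / name)

    log = {
        "inputs": {k: {"path": v, "sha256": _sha256(v)} for k, v in inputs.items()},
        "digestion": {
            "max_missed_cleavages": params.max_missed_cleavages,
            "min_length": params.min_length,
            "max_length": params.max_length,
            "collapse_IL": params.collapse_IL,
        },
        "detection": {"detection_min": detection_min, "qc_min_unique_spectra": qc_min},
        "normalization": {"share_mode": share_mode},
        "strain": {"pairs": [list(p) for p in pairs]},
        "samples": {"kept": kept, "excluded": excluded},
    }
    with open(out / "run_log.yaml", "w") as fh:
        yaml.safe_dump(log, fh, sort_keys=True)
    return out
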