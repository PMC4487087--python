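"""Generate the synthetic strain-resolved community used by the analyses.

Writes the four pipeline inputs plus ground truth to results/sim/. The
community is four organism bins: a strain pair at 99% amino-acid identity
("strainA"/"strainAii", ~5% strain-unique genes each) plus two unrelated
organisms, 6 samples, 1e5 reads and 2e4 PSMs per sample, with cell
abundance (reads) decoupled from proteomic activity (spectra) by design.
"""

from pathlib import Path

from strainprot.simulate import SimParams, simulate_all

OUT = Path("results/sim")


def main() -> None:
    params = SimParams(seed=42)
    records, bins, lists, truth, psm, reads = simulate_all(params, OUT)
    print(f"wrote inputs + truth to {OUT}/")
    print(f"  organisms: {sorted(bins)}")
    print(f"  genes: {len(records)}; pathway lists: {len(lists)}")
    print(f"  PSM rows: {len(psm)} over {params.n_samples} samples")
    print(f"  planted strain-unique genes: {len(truth.strain_unique)}")


if __name__ == "__main__":
    main()
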