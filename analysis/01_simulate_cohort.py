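#!/usr/bin/env python
"""Generate the synthetic study cohort.

Writes 20 sagittal-section phantoms (8 sham, 12 injured; 120x80 pixels at
50 µm) as imzML under scratch/cohort/ and the cohort-level text artifacts —
samples table and ground-truth expectation table — under results/.
"""

from pathlib import Path
import shutil

from lipidmsi.phantom import default_config, generate_cohort

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "cohort"
RESULTS = ROOT / "results"


def main() -> None:
    cfg = default_config()
    datasets, truth = generate_cohort(cfg, master_seed=0, outdir=SCRATCH)
    RESULTS.mkdir(exist_ok=True)
    shutil.copy(SCRATCH / "samples.tsv", RESULTS / "samples.tsv")
    shutil.copy(SCRATCH / "truth_table.tsv", RESULTS / "truth_table.tsv")
    n_lipid = len(cfg.peaks_of_kind("lipid"))
    n_decoy = len(cfg.peaks_of_kind("decoy", "marker"))
    print(f"wrote {len(datasets)} sections to {SCRATCH}")
    print(
        f"panel: {n_lipid} discriminant lipid ions, {n_decoy} decoys/markers, "
        f"{len(cfg.background_mz())} matrix/embedding ions"
    )
    print(f"samples + truth tables copied to {RESULTS}")


if __name__ == "__main__":
    main()
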