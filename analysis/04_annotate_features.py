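#!/usr/bin/env python
"""Exact-mass annotation of the reference panel and lock-mass check.

Annotates the printed experimental m/z values of the discriminant lipid
panel against the bundled lipid table (±0.005 Da) and recomputes the two
instrument lock masses.  Writes results/annotations.tsv.
"""

from pathlib import Path

from lipidmsi.masses import (
    ADDUCTS,
    Formula,
    adduct_mz,
    annotation_report,
    load_lipid_table,
    load_reference_annotations,
)

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"


def main() -> None:
    lipids = load_lipid_table()
    ref = load_reference_annotations()
    report = annotation_report(ref["exp_mz"].tolist(), lipids)
    report["printed_identity"] = ref["name"] + " " + ref["adduct"]
    report["agrees"] = (report["name"] == ref["name"]) & (report["adduct"] == ref["adduct"])
    RESULTS.mkdir(exist_ok=True)
    report.to_csv(RESULTS / "annotations.tsv", sep="\t", index=False)

    pc34 = adduct_mz(Formula.parse("C42H82NO8P"), ADDUCTS["[M+H]+"])
    dan2 = adduct_mz(Formula.parse("C20H18N4"), ADDUCTS["[M]+."])
    print(f"lock masses: PC(34:1) [M+H]+ = {pc34:.6f}, DAN dimer [2M-H2]+. = {dan2:.6f}")
    print(f"{int(report['agrees'].sum())}/{len(report)} panel m/z annotated to the printed identity")
    print(f"max |delta| = {report['delta_da'].abs().max()*1000:.3f} mDa (tolerance 5 mDa)")
    print(f"table -> {RESULTS / 'annotations.tsv'}")


if __name__ == "__main__":
    main()
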