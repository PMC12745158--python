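"""Generate the synthetic study cohort and record its planted ground truth.

Writes the per-sample tissue peak calls, the truth region tables, and the
sample sheet for the default study conditions (one 10-Mb chromosome, four
tissue/CSF samples, 3x protection in 50 of 100 shared regions, 16 differential
marker regions among 200 analysis regions at 8-fold effect, 111-sample graded
cohort). Fragment files are large and deterministic given the seed, so they
are regenerated on demand by the downstream scripts instead of being stored.
"""

from pathlib import Path

import pandas as pd

from cfaccess.genomic_io import write_bed, write_narrowpeak
from cfaccess.synthetic_data import SimConfig, plan_truth, simulate_tissue_peaks

SEED = 7
OUT = Path(__file__).resolve().parent.parent / "results" / "cohort"


def main():
    config = SimConfig()
    truth = plan_truth(config, SEED)
    peaksets, _ = simulate_tissue_peaks(config, SEED, truth=truth)

    OUT.mkdir(parents=True, exist_ok=True)
    for sample, peaks in peaksets.items():
        write_narrowpeak(peaks, OUT / f"{sample}.narrowPeak")
    write_bed(truth.shared_regions, OUT / "truth_shared.bed")
    write_bed(truth.protected_regions, OUT / "truth_protected.bed")
    write_bed(truth.analysis_regions, OUT / "truth_analysis.bed")
    write_bed([r for r, _, _ in truth.differential_regions],
              OUT / "truth_differential.bed")

    rows = (
        [(s, "csf", "", "") for s in config.csf_sample_names()]
        + [(s, "plasma", g, "") for s, g in sorted(truth.subtype_groups.items())]
        + [(s, "plasma", "", g) for s, g in sorted(truth.grade_labels.items())]
    )
    sheet = pd.DataFrame(rows, columns=["sample", "fluid", "subtype", "grade"])
    sheet.to_csv(OUT / "sample_sheet.tsv", sep="\t", index=False)

    print(f"cohort written to {OUT} (seed {SEED})")
    print(f"  tissue samples: {len(peaksets)}, peaks/sample: "
          f"{ {s: len(p) for s, p in peaksets.items()} }")
    print(f"  planted: {len(truth.shared_regions)} shared "
          f"({len(truth.protected_regions)} protected), "
          f"{len(truth.analysis_regions)} analysis regions "
          f"({len(truth.differential_regions)} differential), "
          f"{len(truth.grade_labels)} graded samples")


if __name__ == "__main__":
    main()
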