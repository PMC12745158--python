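"""Call open chromatin regions from CSF cfDNA and test background enrichment.

Runs the Peak-F/Peak/Peak-B caller on the shared tissue regions of the default
synthetic cohort, scores sensitivity and false discovery against the planted
protected regions, and Fisher-tests whether cfDNA support concentrates in
tissue-derived candidates relative to non-peak 500-bp background windows.
"""

import json
from pathlib import Path

from cfaccess.cfdna_access import call_open_regions, make_flanks
from cfaccess.pipeline import (
    _csf_fragments,
    null_open_call_rate,
    open_region_recovery,
    unified_shared_regions,
)
from cfaccess.synthetic_data import SimConfig

SEED = 7
RESULTS = Path(__file__).resolve().parent.parent / "results"


def main():
    config = SimConfig()
    rec = open_region_recovery(config, SEED)

    # per-region call table for the record
    _, truth, _, shared = unified_shared_regions(config, SEED)
    fragments = _csf_fragments(config, truth, SEED)
    flanked = [make_flanks(r, 500, config.sizes) for r in shared]
    summary = call_open_regions(flanked, fragments)
    RESULTS.mkdir(parents=True, exist_ok=True)
    summary.to_frame().to_csv(RESULTS / "open_region_calls.tsv", sep="\t", index=False)

    null_rate = null_open_call_rate(config, seeds=range(200, 220))
    report = {**rec, "null_false_call_rate_20_seeds": null_rate, "seed": SEED}
    with open(RESULTS / "open_region_summary.json", "w") as fh:
        json.dump(report, fh, indent=2)
        fh.write("\n")

    print(f"candidates (shared tissue regions): {rec['n_candidates']}")
    print(f"called open by cfDNA: {rec['n_called']}")
    print(f"sensitivity vs planted protected regions: {rec['sensitivity']:.2f} "
          f"(dominance in all {config.n_tissue_samples} samples is a strict rule "
          f"at ~0.8x coverage; see docs/methods.md)")
    print(f"false discovery proportion: {rec['fdp']:.3f}")
    print(f"pooled signed-rank global p: {rec['global_p']:.3e}")
    print(f"Fisher enrichment vs background windows: odds ratio "
          f"{rec['fisher_odds']:.1f}, p = {rec['fisher_p']:.3e}")
    print(f"null false-call rate (uniform fragments, 20 seeds): {null_rate:.4f}")


if __name__ == "__main__":
    main()
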