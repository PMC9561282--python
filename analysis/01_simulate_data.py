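#!/usr/bin/env python
"""Generate the synthetic study inputs with known ground truth.

Writes the break-site table (BED6 + attribute sidecar), per-condition
library summaries, the DRIP-qPCR and resection Ct plates, and the eleven
proteomic study hit lists under results/data/. Fragment files are large
and reproducible from the seed, so only a per-library summary is kept.
"""

import json
from pathlib import Path

from driploop.simulate import (
    SimConfig,
    make_drip_qpcr_plate,
    make_resection_plate,
    make_study_hit_lists,
    simulate_experiment,
    write_ct_table,
    write_hit_lists,
    write_site_table,
)

import pandas as pd

OUT = Path(__file__).resolve().parents[1] / "results" / "data"


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = SimConfig(seed=17)
    sites, libraries = simulate_experiment(cfg)
    write_site_table(sites, OUT / "break_sites.bed", OUT / "break_sites_attrs.tsv",
                     window_bp=cfg.window_bp)

    summary = {
        "_".join(map(str, key)): {
            "sample_id": lib.sample_id,
            "library_size": lib.library_size,
            "planted_window_fragments": int(lib.site_counts.sum()),
        }
        for key, lib in libraries.items()
    }
    (OUT / "library_summary.json").write_text(json.dumps(summary, indent=1))

    targets = pd.DataFrame({
        "target": ["DSB_HR1", "DSB_HR2", "DSB_NHEJ1", "DSB_NHEJ2", "ACTB_e5"],
        "background": [0.001] * 5,
        "preexisting": [0.010, 0.004, 0.012, 0.006, 0.008],
        "induction": [0.030, 0.020, 0.025, 0.018, 0.0],  # uncut control: none
    })
    write_ct_table(make_drip_qpcr_plate(targets, dilution=0.1, replicates=3,
                                        noise_sd=0.12, seed=cfg.seed),
                   OUT / "drip_qpcr_plate.tsv")

    planted = pd.DataFrame({
        "target": ["site1_200bp", "site1_1kb", "site2_200bp", "site2_1kb"] * 2,
        "condition": ["ctrl"] * 4 + ["kd"] * 4,
        "ssdna_pct": [14.0, 4.5, 11.0, 3.5, 6.0, 1.8, 4.5, 1.2],
    })
    write_ct_table(make_resection_plate(planted, replicates=3, noise_sd=0.08,
                                        seed=cfg.seed),
                   OUT / "resection_plate.tsv")

    lists, truth = make_study_hit_lists(seed=cfg.seed)
    write_hit_lists(lists, OUT / "proteomics")
    (OUT / "proteomics" / "ground_truth.json").write_text(json.dumps(
        {k: sorted(v) if isinstance(v, set) else v for k, v in truth.items()},
        indent=1))

    print(f"wrote synthetic inputs to {OUT}")
    print(f"  {len(sites)} break sites "
          f"({(sites['true_class'] == 'dependent').sum()} dependent / "
          f"{(sites['true_class'] == 'independent').sum()} independent / "
          f"{(sites['true_class'] == 'increased').sum()} increased)")
    print(f"  {len(libraries)} fragment libraries of {cfg.library_size:,} fragments")
    print(f"  {len(lists)} proteomic hit lists; planted core of "
          f"{len(truth['core_set'])} with candidate {truth['candidate']}")


if __name__ == "__main__":
    main()
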