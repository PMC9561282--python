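#!/usr/bin/env python
"""DRIP-qPCR fold changes and the resection ssDNA quantification.

Reads the simulated Ct plates written by 01_simulate_data.py (generating
them if absent), computes percent input and the damaged/undamaged fold
change per locus with its RNase-H control channel, and the per-distance
ssDNA percentages with the control-vs-knockdown paired contrast.
"""

import json
import subprocess
import sys
from pathlib import Path

import pandas as pd

from driploop.qpcr import drip_fold_change, read_ct_table, resection_contrast, \
    resection_ssdna

DATA = Path(__file__).resolve().parents[1] / "results" / "data"
OUT = Path(__file__).resolve().parents[1] / "results"


def main():
    if not (DATA / "drip_qpcr_plate.tsv").exists():
        subprocess.run([sys.executable,
                        str(Path(__file__).parent / "01_simulate_data.py")],
                       check=True)
    drip = read_ct_table(DATA / "drip_qpcr_plate.tsv")
    rows, stats = [], {}
    for target in drip["target"].unique():
        res = drip_fold_change(drip, target, dilution=0.1)
        rows.append((target, res.mean_fc, res.sem_fc, res.test.p, res.rnaseh_mean_fc))
        print(f"{target:10s} FC(+OHT/-OHT) = {res.mean_fc:5.2f} +/- {res.sem_fc:.2f} "
              f"(paired t p={res.test.p:.3f}; RNase-H channel "
              f"{res.rnaseh_mean_fc:.2f})")
    pd.DataFrame(rows, columns=["target", "mean_fc", "sem_fc", "paired_t_p",
                                "rnaseh_fc"]).round(4).to_csv(
        OUT / "drip_qpcr_fold_changes.tsv", sep="\t", index=False)

    resection = read_ct_table(DATA / "resection_plate.tsv")
    rrows = []
    for target in resection["target"].unique():
        for cond in ("ctrl", "kd"):
            out = resection_ssdna(resection, target, {"condition": cond})
            rrows.append((target, cond, out["ssdna_pct"].mean(),
                          out["inconsistent"].any()))
        t = resection_contrast(resection, target,
                               {"condition": "ctrl"}, {"condition": "kd"})
        stats[target] = {"paired_t": t.statistic, "p": t.p}
        print(f"{target:12s} ssDNA ctrl {rrows[-2][2]:5.2f}% vs kd {rrows[-1][2]:5.2f}%"
              f"  paired t p={t.p:.3f}")
    pd.DataFrame(rrows, columns=["target", "condition", "ssdna_pct",
                                 "inconsistent"]).round(3).to_csv(
        OUT / "resection_ssdna.tsv", sep="\t", index=False)
    (OUT / "resection_contrasts.json").write_text(json.dumps(stats, indent=1))


if __name__ == "__main__":
    main()
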