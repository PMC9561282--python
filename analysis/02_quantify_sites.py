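#!/usr/bin/env python
"""Coverage, per-site window quantification and dependence classification.

Re-simulates the default experiment, runs the fragment -> depth ->
per-million -> window-mean -> log2 fold-change chain, classifies every
site by its deviation score and writes the per-site table plus class
counts under results/.
"""

import json
from pathlib import Path

from driploop.pipeline import run_break_pipeline
from driploop.simulate import SimConfig

OUT = Path(__file__).resolve().parents[1] / "results"

COLUMNS = ["site_id", "contig", "cut_pos", "repair_class", "true_class",
           "m_ctrl_on", "m_ctrl_off", "m_kd_on", "m_kd_off",
           "log2fc_ctrl", "log2fc_kd", "delta", "preexisting", "class"]


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    res = run_break_pipeline(SimConfig(seed=17))
    quants = res["quants"]
    quants[COLUMNS].round(4).to_csv(OUT / "site_quantification.tsv",
                                    sep="\t", index=False)
    payload = {"counts": res["counts"],
               "recovery_accuracy": round(res["accuracy"], 4)}
    (OUT / "classification_summary.json").write_text(json.dumps(payload, indent=1))

    print("per-site quantification ->", OUT / "site_quantification.tsv")
    print("class counts:", res["counts"])
    print(f"planted-label recovery: {100 * res['accuracy']:.1f}%")
    mis = quants[quants["class"] != quants["true_class"]]
    if len(mis):
        print(f"{len(mis)} sites misclassified "
              f"(|delta| near the 0.5 threshold): {', '.join(mis['site_id'])}")


if __name__ == "__main__":
    main()
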