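#!/usr/bin/env python
"""Cross-study hit-frequency meta-analysis on the synthetic hit lists.

Frequency-ranks proteins across the eleven studies, extracts candidates
identified in four or more, intersects the three phosphoproteomic
studies, runs the nominated-candidate query (top hybrid interactor with
no annotated repair role) and scans its phospho-peptide for SQ motifs.
"""

import json
import subprocess
import sys
from pathlib import Path

from driploop.proteomics import (
    annotate,
    candidates_at_threshold,
    frequency_table,
    intersect_studies,
    read_hit_lists,
    sq_motif_count,
    top_flagged_candidate,
)

DATA = Path(__file__).resolve().parents[1] / "results" / "data"
OUT = Path(__file__).resolve().parents[1] / "results"


def main():
    manifest = DATA / "proteomics" / "manifest.tsv"
    if not manifest.exists():
        subprocess.run([sys.executable,
                        str(Path(__file__).parent / "01_simulate_data.py")],
                       check=True)
    lists = read_hit_lists(manifest)
    truth = json.loads((DATA / "proteomics" / "ground_truth.json").read_text())

    table = frequency_table(lists)
    table = annotate(table, "hybrid_interactor", set(truth["hybrid_interactors"]))
    table = annotate(table, "known_repair", set(truth["known_repair"]))
    table.to_frame().to_csv(OUT / "protein_frequency.tsv", sep="\t", index=False)
    print("identification-frequency histogram (k studies -> proteins):",
          table.histogram())

    candidates = candidates_at_threshold(table, 4)
    print(f"{len(candidates)} proteins identified in >= 4 of {table.n_studies} studies")
    hit = top_flagged_candidate(table, "hybrid_interactor", "known_repair")
    print(f"top hybrid interactor without annotated repair role: {hit} "
          f"(planted: {truth['candidate']})")

    regions, core = intersect_studies(lists, category="phosphoproteomics")
    print(f"phosphoproteomic 3-way intersection: {len(core)} shared proteins")
    venn = {"+".join(k): v for k, v in regions.items()}
    (OUT / "phospho_venn.json").write_text(json.dumps(
        {"regions": venn, "shared_core_size": len(core)}, indent=1))

    peptide = truth["candidate_peptide"]
    print(f"candidate phospho-peptide {peptide}: "
          f"{sq_motif_count(peptide)} SQ motifs "
          f"({sq_motif_count(peptide, include_tq=True)} with TQ included)")
    summary = {
        "n_candidates_k4": len(candidates),
        "candidate": hit,
        "phospho_shared_core": len(core),
        "candidate_peptide_sq": sq_motif_count(peptide),
    }
    (OUT / "meta_analysis_summary.json").write_text(json.dumps(summary, indent=1))


if __name__ == "__main__":
    main()
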