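"""End-to-end drivers tying simulation, coverage and break analysis together.

These are the entry points the analysis scripts, the test suite and the
acceptance script share: simulate an experiment, turn every library into a
normalised coverage track, quantify the site windows and classify sites.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import breaks, coverage
from .simulate import SimConfig, simulate_experiment

__all__ = ["quantify_libraries", "run_break_pipeline", "classification_accuracy"]

DEFAULT_WINDOW = 2_000
DEFAULT_EPS = 0.1


def quantify_libraries(
    sites: pd.DataFrame,
    libraries: dict,
    window: int = DEFAULT_WINDOW,
    eps: float = DEFAULT_EPS,
    contig_lengths: dict[str, int] | None = None,
    keep_tracks: bool = False,
):
    """Coverage -> per-million normalisation -> per-site window means ->
    fold changes. ``libraries`` is keyed by (sirna, oht, replicate)."""
    signals, tracks = {}, {}
    for key, lib in libraries.items():
        track = coverage.normalize(coverage.depth(lib), lib.library_size)
        signals[key] = breaks.window_signal(track, sites, window, contig_lengths)
        if keep_tracks:
            tracks[key] = track
    quants = breaks.site_fold_changes(sites, signals, eps)
    return (quants, tracks) if keep_tracks else quants


def run_break_pipeline(
    cfg: SimConfig,
    tau: float = 0.5,
    window: int = DEFAULT_WINDOW,
    eps: float = DEFAULT_EPS,
):
    """Simulate the full 2x2 experiment and run the break analysis.

    Returns a dict with the classified site table, class counts, the
    dependent-vs-independent pre-existing-level contrast and the
    per-arm hybrid correlations.
    """
    sites, libraries = simulate_experiment(cfg)
    contig_lengths = dict(cfg.genome)
    quants = quantify_libraries(sites, libraries, window, eps, contig_lengths)
    classified, counts = breaks.classify_sites(quants, tau)
    result = {
        "sites": sites,
        "quants": classified,
        "counts": counts,
        "accuracy": classification_accuracy(classified),
        "correlation": {
            arm: breaks.hybrid_correlation(classified, arm) for arm in ("ctrl", "kd")
        },
    }
    if counts["dependent"] and counts["independent"]:
        result["preexisting_contrast"] = breaks.group_compare(
            classified, "class", "preexisting", direction="less"
        )
    return result


def classification_accuracy(classified: pd.DataFrame) -> float:
    """Fraction of sites whose assigned class matches the planted class."""
    truth = classified["true_class"].to_numpy()
    assigned = classified["class"].to_numpy()
    return float(np.mean(truth == assigned))
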