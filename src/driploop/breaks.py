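"""Break-centric quantification of DNA:RNA-hybrid signal.

Per cut site, the mean normalised DRIP coverage over a window around the
break is summarised into a damaged/undamaged log2 fold change per siRNA
arm; the deviation of the knockdown-arm fold change from the control-arm
fold change classifies each site as knockdown-dependent, -independent or
-increased. Metagene profiles, group contrasts (rank-sum) and the
pre-existing-hybrid correlation analysis complete the picture.

Definitions (per site):

    m_cond         mean normalised depth over [cut - W, cut + W)
    log2FC_arm     mean over replicates of log2((m_on + eps) / (m_off + eps))
    delta          log2FC_kd - log2FC_ctrl
    preexisting    mean over replicates of m_(ctrl, off)
    class          dependent if delta < -tau, increased if delta > +tau,
                   else independent (ties at +/-tau are independent)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .coverage import CoverageTrack
from .stats import TestResult, pearson_test, wilcoxon_one_sided

__all__ = [
    "window_signal",
    "site_fold_changes",
    "classify_sites",
    "metagene",
    "group_compare",
    "hybrid_correlation",
    "GroupResult",
]

ARMS = ("ctrl", "kd")


def window_signal(
    track: CoverageTrack,
    sites: pd.DataFrame,
    half_width: int,
    contig_lengths: dict[str, int] | None = None,
) -> np.ndarray:
    """Mean normalised depth over [cut - W, cut + W) for every site.

    Windows are clipped at contig edges (position 0, and the contig end
    when ``contig_lengths`` is given); the mean divides by the clipped
    width actually used.
    """
    if half_width <= 0:
        raise ValueError("window half-width must be positive")
    out = np.empty(len(sites))
    for i, row in enumerate(sites.itertuples(index=False)):
        lo = max(int(row.cut_pos) - half_width, 0)
        hi = int(row.cut_pos) + half_width
        if contig_lengths is not None:
            hi = min(hi, int(contig_lengths[row.contig]))
        width = hi - lo
        if width <= 0:
            raise ValueError(f"site {row.site_id}: window entirely off-contig")
        out[i] = track.window_sum(row.contig, lo, hi) / width
    return out


def _mean_log2_ratio(on: np.ndarray, off: np.ndarray, eps: float, labels) -> np.ndarray:
    """log2((on + eps)/(off + eps)) per replicate column, averaged across reps."""
    if eps < 0:
        raise ValueError("eps must be non-negative")
    if eps == 0.0:
        zero = np.asarray(off) == 0.0
        if zero.any():
            bad = np.asarray(labels)[zero.any(axis=1) if zero.ndim > 1 else zero]
            raise ZeroDivisionError(
                f"undefined fold change with eps=0 at site(s) {list(bad)[:5]}"
            )
    return np.log2((on + eps) / (off + eps)).mean(axis=1)


def site_fold_changes(
    sites: pd.DataFrame,
    signals: dict[tuple[str, str, int], np.ndarray],
    eps: float = 0.1,
) -> pd.DataFrame:
    """Per-site fold changes and deviation score from the 2x2 condition grid.

    ``signals`` maps (sirna, oht, replicate) — sirna in {"ctrl","kd"},
    oht in {"on","off"} — to per-site mean window signals. Replicates are
    combined as the mean of per-replicate log2 fold changes.
    """
    reps = sorted({k[2] for k in signals})
    for sirna in ARMS:
        for oht in ("on", "off"):
            for rep in reps:
                if (sirna, oht, rep) not in signals:
                    raise KeyError(f"missing condition {(sirna, oht, rep)}")
    labels = sites["site_id"].to_numpy()

    def stack(sirna, oht):
        return np.column_stack([signals[(sirna, oht, r)] for r in reps])

    out = sites.copy()
    for sirna in ARMS:
        on, off = stack(sirna, "on"), stack(sirna, "off")
        out[f"m_{sirna}_on"] = on.mean(axis=1)
        out[f"m_{sirna}_off"] = off.mean(axis=1)
        out[f"log2fc_{sirna}"] = _mean_log2_ratio(on, off, eps, labels)
    out["preexisting"] = stack("ctrl", "off").mean(axis=1)
    out["delta"] = out["log2fc_kd"] - out["log2fc_ctrl"]
    return out


def classify_sites(quants: pd.DataFrame, tau: float = 0.5):
    """Deviation-threshold classification of every site.

    dependent if delta < -tau, increased if delta > +tau, independent
    otherwise (strict inequalities: delta == +/-tau stays independent).
    Returns ``(quants_with_class, counts)``.
    """
    delta = quants["delta"].to_numpy()
    if not np.isfinite(delta).all():
        raise ValueError("non-finite deviation score; use eps > 0")
    cls = np.where(delta < -tau, "dependent",
                   np.where(delta > tau, "increased", "independent"))
    out = quants.copy()
    out["class"] = cls
    counts = {c: int((cls == c).sum()) for c in ("dependent", "independent", "increased")}
    return out, counts


@dataclass(frozen=True)
class MetageneProfile:
    """Binned mean log2 fold change versus distance from the cut site."""

    arm: str
    replicate: int
    bin_centers: np.ndarray
    mean_log2fc: np.ndarray
    n_sites: np.ndarray
    bin_width: int


def metagene(
    tracks: dict[tuple[str, str, int], CoverageTrack],
    sites: pd.DataFrame,
    span: int = 5_000,
    bin_width: int = 100,
    eps: float = 0.1,
    contig_lengths: dict[str, int] | None = None,
) -> list[MetageneProfile]:
    """Cut-site-centred metagene: per bin, the mean over sites of
    log2((+OHT bin mean + eps) / (-OHT bin mean + eps)), one profile per
    siRNA arm per replicate.

    Sites whose span reaches off-contig are excluded from the affected
    bins; ``n_sites`` records per-bin contributions.
    """
    if span % bin_width != 0:
        raise ValueError("span must be a multiple of bin_width")
    offsets = np.arange(-span, span, bin_width)
    centers = offsets + bin_width / 2.0
    reps = sorted({k[2] for k in tracks})
    profiles = []
    for sirna in ARMS:
        for rep in reps:
            t_on = tracks[(sirna, "on", rep)]
            t_off = tracks[(sirna, "off", rep)]
            acc = np.zeros(len(offsets))
            n = np.zeros(len(offsets), dtype=int)
            for row in sites.itertuples(index=False):
                cut = int(row.cut_pos)
                clen = (contig_lengths or {}).get(row.contig)
                for j, off in enumerate(offsets):
                    lo, hi = cut + int(off), cut + int(off) + bin_width
                    if lo < 0 or (clen is not None and hi > clen):
                        continue  # off-contig: site excluded from this bin
                    m_on = t_on.window_sum(row.contig, lo, hi) / bin_width
                    m_off = t_off.window_sum(row.contig, lo, hi) / bin_width
                    acc[j] += np.log2((m_on + eps) / (m_off + eps))
                    n[j] += 1
            with np.errstate(invalid="ignore"):
                mean = np.where(n > 0, acc / np.maximum(n, 1), np.nan)
            profiles.append(MetageneProfile(sirna, rep, centers, mean, n, bin_width))
    return profiles


@dataclass(frozen=True)
class GroupResult:
    """Rank-sum contrast between two site groups on one site-level variable."""

    variable: str
    group_a: str
    group_b: str
    median_a: float
    median_b: float
    n_a: int
    n_b: int
    test: TestResult


_VARIABLES = {"transcription_level", "preexisting", "delta", "log2fc_ctrl", "log2fc_kd"}


def group_compare(
    quants: pd.DataFrame,
    grouping: str,
    variable: str,
    direction: str = "less",
) -> GroupResult:
    """Directional unpaired rank-sum contrast between two site groups.

    grouping: "class" (dependent vs independent), "repair" (HR vs NHEJ)
    or "transcription" (high vs low, split at the median transcription
    level). ``direction`` states the alternative for group A vs group B.
    """
    if variable not in _VARIABLES:
        raise ValueError(f"unknown variable {variable!r}")
    if grouping == "class":
        a = quants.loc[quants["class"] == "dependent", variable]
        b = quants.loc[quants["class"] == "independent", variable]
        names = ("dependent", "independent")
    elif grouping == "repair":
        a = quants.loc[quants["repair_class"] == "HR", variable]
        b = quants.loc[quants["repair_class"] == "NHEJ", variable]
        names = ("HR", "NHEJ")
    elif grouping == "transcription":
        cutoff = quants["transcription_level"].median()
        a = quants.loc[quants["transcription_level"] >= cutoff, variable]
        b = quants.loc[quants["transcription_level"] < cutoff, variable]
        names = ("high_transcription", "low_transcription")
    else:
        raise ValueError(f"unknown grouping {grouping!r}")
    if len(a) == 0 or len(b) == 0:
        raise ValueError(f"empty group in {grouping!r} contrast")
    test = wilcoxon_one_sided(a.to_numpy(), b.to_numpy(), direction)
    return GroupResult(variable, names[0], names[1],
                       float(a.median()), float(b.median()),
                       len(a), len(b), test)


def hybrid_correlation(quants: pd.DataFrame, arm: str) -> TestResult:
    """Pearson correlation of pre-existing hybrid level against the
    damaged/undamaged log2 fold change of one siRNA arm."""
    if arm not in ARMS:
        raise ValueError(f"arm must be one of {ARMS}, got {arm!r}")
    x = quants["preexisting"].to_numpy(dtype=float)
    y = quants[f"log2fc_{arm}"].to_numpy(dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    if keep.sum() < 3:
        raise ValueError("need at least 3 sites with finite values")
    return pearson_test(x[keep], y[keep])
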