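"""qPCR quantification: DRIP percent-input fold changes and the
restriction-digest resection assay.

Both assays start from a long-format Ct table (one row per well) as
written by :mod:`driploop.simulate`:

    target  [condition columns...]  fraction  replicate  ct

Percent input adjusts the input-well Ct for its dilution factor D
(Ct' = Ct_input - log_eff(1/D)) and reports 100 * eff^(Ct' - Ct_IP).
The resection assay quantifies single-stranded DNA from the Ct gap
between restriction-digested and undigested template:
ssDNA% = 100 / (2^(dCt - 1) + 0.5), the standard formula for
enzyme-protection resection assays at AsiSI breaks.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import log

import numpy as np
import pandas as pd

from .stats import TestResult, paired_t

__all__ = [
    "PairingError",
    "read_ct_table",
    "percent_input",
    "drip_fold_change",
    "resection_ssdna",
    "ssdna_percent",
]


class PairingError(ValueError):
    """A well is missing its mate (IP/input or digested/undigested)."""


def read_ct_table(path) -> pd.DataFrame:
    plate = pd.read_csv(path, sep="\t")
    if "ct" not in plate.columns or "replicate" not in plate.columns:
        raise ValueError("Ct table needs 'ct' and 'replicate' columns")
    if not np.isfinite(plate["ct"]).all() or (plate["ct"] <= 0).any():
        raise ValueError("Ct values must be finite and positive")
    return plate


def _select(plate: pd.DataFrame, target: str, condition: dict | None) -> pd.DataFrame:
    sub = plate[plate["target"] == target]
    for key, val in (condition or {}).items():
        sub = sub[sub[key] == val]
    return sub


def _paired_ct(sub: pd.DataFrame, fraction_a: str, fraction_b: str):
    """Replicate-matched Ct values for two fractions of the same wells."""
    a = sub[sub["fraction"] == fraction_a].set_index("replicate")["ct"]
    b = sub[sub["fraction"] == fraction_b].set_index("replicate")["ct"]
    common = a.index.intersection(b.index)
    if len(common) == 0 or len(common) < max(len(a), len(b)):
        raise PairingError(
            f"unpaired wells: {fraction_a} replicates {sorted(a.index)}, "
            f"{fraction_b} replicates {sorted(b.index)}"
        )
    return a.loc[common], b.loc[common]


def percent_input(
    plate: pd.DataFrame,
    target: str,
    condition: dict | None = None,
    dilution: float = 0.1,
    efficiency: float = 2.0,
) -> pd.Series:
    """Per-replicate IP enrichment as a percentage of dilution-adjusted input.

    Ct'_input = Ct_input - log_eff(1/D); %input = 100 * eff^(Ct' - Ct_IP).
    """
    if not 0.0 < dilution <= 1.0:
        raise ValueError("dilution factor D must lie in (0, 1]")
    if efficiency <= 1.0:
        raise ValueError("amplification efficiency must exceed 1")
    sub = _select(plate, target, condition)
    ct_ip, ct_input = _paired_ct(sub, "IP", "input")
    adjusted = ct_input - log(1.0 / dilution) / log(efficiency)
    return 100.0 * efficiency ** (adjusted - ct_ip)


@dataclass(frozen=True)
class DripResult:
    """Damaged/undamaged percent-input fold change at one locus."""

    target: str
    percent_input_on: pd.Series
    percent_input_off: pd.Series
    fold_changes: pd.Series    # per replicate, +OHT / -OHT
    mean_fc: float
    sem_fc: float
    test: TestResult
    rnaseh_mean_fc: float | None = None


def drip_fold_change(
    plate: pd.DataFrame,
    target: str,
    dilution: float = 0.1,
    efficiency: float = 2.0,
) -> DripResult:
    """Mean fold change of damaged (+OHT) over undamaged (-OHT) percent input.

    Fold changes are per biological replicate, aggregated as their
    arithmetic mean with SEM; the paired t-test compares the per-replicate
    +OHT and -OHT percent-input values. RNase-H-treated wells, when
    present, are reported as a separate control channel (expected ~1 when
    the signal is hybrid-derived).
    """
    base = {"rnaseh": False} if "rnaseh" in plate.columns else {}
    pi_on = percent_input(plate, target, {**base, "oht": "on"}, dilution, efficiency)
    pi_off = percent_input(plate, target, {**base, "oht": "off"}, dilution, efficiency)
    common = pi_on.index.intersection(pi_off.index)
    if len(common) < 2:
        raise PairingError("need >= 2 paired +/-OHT replicates")
    pi_on, pi_off = pi_on.loc[common], pi_off.loc[common]
    fc = pi_on / pi_off
    sem = float(fc.std(ddof=1) / np.sqrt(len(fc))) if len(fc) > 1 else float("nan")
    try:
        test = paired_t(pi_on.to_numpy(), pi_off.to_numpy())
    except ValueError:
        # constant non-zero difference (noise-free data): t diverges
        sign = 1.0 if float((pi_on - pi_off).mean()) > 0 else -1.0
        test = TestResult(sign * float("inf"), 0.0, "two-sided",
                          (len(pi_on),), "degenerate")
    rnaseh_fc = None
    if "rnaseh" in plate.columns and bool(plate["rnaseh"].any()):
        r_on = percent_input(plate, target, {"rnaseh": True, "oht": "on"},
                             dilution, efficiency)
        r_off = percent_input(plate, target, {"rnaseh": True, "oht": "off"},
                              dilution, efficiency)
        rnaseh_fc = float((r_on / r_off).mean())
    return DripResult(target, pi_on, pi_off, fc, float(fc.mean()), sem, test, rnaseh_fc)


def ssdna_percent(delta_ct) -> np.ndarray | float:
    """ssDNA% = 100 / (2^(dCt - 1) + 0.5); 100 at dCt=0, -> 0 as dCt grows."""
    return 100.0 / (np.power(2.0, np.asarray(delta_ct, dtype=float) - 1.0) + 0.5)


def resection_ssdna(
    plate: pd.DataFrame,
    target: str,
    condition: dict | None = None,
    inconsistency_tolerance: float = 0.5,
) -> pd.DataFrame:
    """Per-replicate ssDNA percentage at one locus/distance.

    dCt = Ct_digested - Ct_undigested per replicate. A digested well
    amplifying earlier than its undigested mate beyond the tolerance
    (dCt < -0.5) is assay-inconsistent; it is flagged but still reported.
    """
    sub = _select(plate, target, condition)
    ct_dig, ct_undig = _paired_ct(sub, "digested", "undigested")
    dct = (ct_dig - ct_undig).astype(float)
    out = pd.DataFrame({
        "replicate": dct.index,
        "delta_ct": dct.to_numpy(),
        "ssdna_pct": ssdna_percent(dct.to_numpy()),
        "inconsistent": dct.to_numpy() < -inconsistency_tolerance,
    }).reset_index(drop=True)
    return out


def resection_contrast(plate: pd.DataFrame, target: str,
                       condition_a: dict, condition_b: dict) -> TestResult:
    """Paired t-test on per-replicate ssDNA% between two conditions."""
    a = resection_ssdna(plate, target, condition_a).set_index("replicate")["ssdna_pct"]
    b = resection_ssdna(plate, target, condition_b).set_index("replicate")["ssdna_pct"]
    common = a.index.intersection(b.index)
    if len(common) < 2:
        raise PairingError("need >= 2 paired replicates across conditions")
    return paired_t(a.loc[common].to_numpy(), b.loc[common].to_numpy())
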