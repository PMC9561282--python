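"""Synthetic data generation for the whole pipeline.

Everything the downstream analyses consume can be generated here at desk
scale with known ("planted") ground truth: a table of restriction-induced
double-strand-break sites, paired-end DRIP fragment libraries for every
condition (control / knockdown siRNA x +/- cut induction, with or without
RNase-H pre-treatment), qPCR plates for the percent-input and resection
assays, and per-study proteomic hit lists with a planted core repair set.

The generative model for the sequencing libraries:

* each break site carries a pre-existing hybrid level (lognormal, in
  fragments-per-million, CPM), an induction magnitude proportional to that
  level, and a dependence class (dependent / independent / increased);
* the expected hybrid fragment count in a site window is
  ``background_rate + preexisting + [oht] * induction * m`` (CPM, scaled
  by library size), where the multiplier ``m`` is 1 under control siRNA
  and, under knockdown, 0 for dependent sites (``knockdown_effect``),
  1 for independent sites and >1 for increased sites;
* counts are negative binomial (variance mu + alpha mu^2) so biological
  replicates are overdispersed relative to Poisson;
* fragment midpoints fall uniformly in the site window, lengths are
  truncated normal; the remainder of the library is uniform genomic
  background so that the total fragment count equals ``library_size``
  exactly. Site windows receive that same uniform background on top of
  their hybrid signal; ``background_rate`` (default 0) plants *extra*
  site-local background and is only needed to emulate locus-specific
  chromatin background — with the default of 0, an RNase-H library at
  residual 0 is exchangeable with random background windows by
  construction.

Dependent sites have their pre-existing level shifted down on the log
scale (``coupling_shift``), which is what couples knockdown dependence to
hybrid-poor loci and produces the control-arm/knockdown-arm correlation
switch downstream.

Fixed ``seed`` implies byte-identical output everywhere.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .coverage import FragmentLibrary
from .proteomics import StudyHitList

__all__ = [
    "SimConfig",
    "SizingError",
    "make_break_sites",
    "simulate_fragment_library",
    "simulate_rnaseh_library",
    "simulate_experiment",
    "simulate_qpcr_plate",
    "make_drip_qpcr_plate",
    "make_resection_plate",
    "make_study_hit_lists",
    "write_site_table",
    "write_ct_table",
    "write_hit_lists",
]

CLASSES = ("dependent", "independent", "increased")

DEFAULT_GENOME = tuple((f"chr{i}", 500_000_000) for i in range(1, 5))


class SizingError(ValueError):
    """Genome too small to place the requested sites at the required spacing."""


@dataclass
class SimConfig:
    """Parameters of the synthetic DRIP experiment.

    Rates are in fragments per million library fragments (CPM) over the
    full site window [cut - window_bp, cut + window_bp).
    """

    n_sites: int = 99
    genome: Sequence[tuple[str, int]] = DEFAULT_GENOME
    window_bp: int = 2_000            # half-width of the signal window
    background_rate: float = 0.0      # extra site-local background (CPM per window)
    preexisting_log_mean: float = float(np.log(400.0))  # ln CPM
    preexisting_log_sd: float = 0.8
    induction_ratio: float = 4.0      # induction ~ ratio * preexisting
    induction_log_jitter: float = 0.35
    class_counts: tuple[int, int, int] = (40, 51, 8)  # dependent/independent/increased
    knockdown_effect: float = 0.0     # induction multiplier for dependent sites under kd
    increased_effect: float = 2.0     # ... for increased sites under kd
    coupling_shift: float = 1.0       # ln-units subtracted from dependent preexisting
    noise_dispersion: float = 0.005   # NB alpha: var = mu + alpha mu^2
    fragment_length_mean: float = 300.0
    fragment_length_sd: float = 100.0
    fragment_length_min: float = 50.0
    library_size: int = 400_000       # fragments per condition per replicate
    n_replicates: int = 2
    rnaseh_residual: float = 0.0
    repair_counts: tuple[int, int] = (30, 30)  # HR, NHEJ; remainder unassigned
    seed: int = 17

    def __post_init__(self):
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        for name in ("background_rate", "induction_ratio", "noise_dispersion",
                     "knockdown_effect", "increased_effect", "rnaseh_residual",
                     "library_size"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.window_bp <= self.fragment_length_mean:
            raise ValueError("window_bp must exceed the mean fragment length")
        if sum(self.class_counts) <= 0:
            raise ValueError("class_counts must sum to a positive number")

    def rng(self, *stream) -> np.random.Generator:
        """Deterministic child generator for a named stream."""
        words = tuple(
            zlib.crc32(s.encode()) if isinstance(s, str) else int(s) for s in stream
        )
        return np.random.default_rng(np.random.SeedSequence((self.seed,) + words))


def _allocate_counts(total: int, weights: Sequence[float]) -> np.ndarray:
    """Largest-remainder apportionment of ``total`` over ``weights``."""
    w = np.asarray(weights, dtype=float)
    quota = total * w / w.sum()
    counts = np.floor(quota).astype(int)
    remainder = quota - counts
    for i in np.argsort(-remainder)[: total - counts.sum()]:
        counts[i] += 1
    return counts


def make_break_sites(cfg: SimConfig) -> pd.DataFrame:
    """Place break sites and draw their per-site attributes.

    Sites are >= 2*window_bp apart (windows never overlap) and at least
    window_bp away from contig ends. Returns a frame with columns
    contig, cut_pos, site_id, repair_class, transcription_level,
    preexisting_hybrid (CPM), induction (CPM), true_class.
    """
    rng = cfg.rng("sites")
    w = cfg.window_bp
    capacity = sum(max(0, (length - 2 * w) // (2 * w) + 1) for _, length in cfg.genome)
    if capacity < cfg.n_sites:
        raise SizingError(
            f"genome holds at most {capacity} sites at spacing {2 * w} bp, "
            f"requested {cfg.n_sites}"
        )
    contigs = [c for c, _ in cfg.genome]
    lengths = np.array([ln for _, ln in cfg.genome], dtype=float)
    placed: dict[str, list[int]] = {c: [] for c in contigs}
    out_contig, out_pos = [], []
    for _ in range(cfg.n_sites):
        for _attempt in range(10_000):
            ci = rng.choice(len(contigs), p=lengths / lengths.sum())
            contig, clen = contigs[ci], int(lengths[ci])
            if clen < 2 * w:
                continue
            pos = int(rng.integers(w, clen - w))
            if all(abs(pos - q) >= 2 * w for q in placed[contig]):
                placed[contig].append(pos)
                out_contig.append(contig)
                out_pos.append(pos)
                break
        else:
            raise SizingError("could not place sites at the required spacing")

    n = cfg.n_sites
    classes = np.repeat(CLASSES, _allocate_counts(n, cfg.class_counts))
    rng.shuffle(classes)

    log_pre = rng.normal(cfg.preexisting_log_mean, cfg.preexisting_log_sd, size=n)
    log_pre[classes == "dependent"] -= cfg.coupling_shift
    preexisting = np.exp(log_pre)
    induction = cfg.induction_ratio * preexisting * np.exp(
        rng.normal(0.0, cfg.induction_log_jitter, size=n)
    )
    # transcription loosely tracks the pre-existing hybrid level
    transcription = np.sqrt(preexisting) * np.exp(rng.normal(0.0, 0.4, size=n))

    n_hr, n_nhej = cfg.repair_counts
    repair = np.array(["HR"] * n_hr + ["NHEJ"] * n_nhej
                      + ["unassigned"] * max(0, n - n_hr - n_nhej))[:n]
    rng.shuffle(repair)

    sites = pd.DataFrame({
        "contig": out_contig,
        "cut_pos": out_pos,
        "site_id": [f"DSB{i + 1:03d}" for i in range(n)],
        "repair_class": repair,
        "transcription_level": transcription,
        "preexisting_hybrid": preexisting,
        "induction": induction,
        "true_class": classes,
    })
    return sites.sort_values(["contig", "cut_pos"], kind="mergesort").reset_index(drop=True)


def _class_multiplier(true_class: np.ndarray, sirna: str, cfg: SimConfig) -> np.ndarray:
    if sirna == "ctrl":
        return np.ones(len(true_class))
    if sirna != "kd":
        raise ValueError(f"unknown siRNA condition {sirna!r}")
    mult = np.ones(len(true_class))
    mult[true_class == "dependent"] = cfg.knockdown_effect
    mult[true_class == "increased"] = cfg.increased_effect
    return mult


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, alpha: float) -> np.ndarray:
    """Negative binomial with mean mu and variance mu + alpha*mu^2."""
    mu = np.asarray(mu, dtype=float)
    if alpha <= 1e-12:
        return rng.poisson(mu)
    size = 1.0 / alpha
    return rng.negative_binomial(size, size / (size + mu))


def _fragment_lengths(rng, n, cfg) -> np.ndarray:
    """Truncated-normal lengths (>= fragment_length_min) by rejection."""
    out = rng.normal(cfg.fragment_length_mean, cfg.fragment_length_sd, size=n)
    bad = out < cfg.fragment_length_min
    while bad.any():
        out[bad] = rng.normal(cfg.fragment_length_mean, cfg.fragment_length_sd,
                              size=int(bad.sum()))
        bad = out < cfg.fragment_length_min
    return np.rint(out).astype(np.int64)


def simulate_fragment_library(
    sites: pd.DataFrame,
    cfg: SimConfig,
    condition: dict,
    replicate: int = 0,
    _hybrid_scale: float = 1.0,
) -> FragmentLibrary:
    """Draw one condition's fragment library.

    ``condition`` must provide ``sirna`` in {"ctrl", "kd"} and ``oht`` in
    {"on", "off"} (booleans also accepted). Per-site window counts are
    negative binomial around the rate model described in the module
    docstring; the rest of the library is uniform genomic background so
    the total equals ``cfg.library_size`` exactly.
    """
    sirna = condition.get("sirna")
    oht = condition.get("oht")
    if isinstance(oht, str):
        if oht not in ("on", "off"):
            raise ValueError(f"unknown OHT condition {oht!r}")
        oht = oht == "on"
    if sirna not in ("ctrl", "kd"):
        raise ValueError(f"unknown siRNA condition {sirna!r}")

    # RNase-H treatment scales hybrid signal only; it must not perturb the
    # random stream, so residual=1 reproduces the untreated library exactly.
    rng = cfg.rng("library", sirna, "on" if oht else "off", replicate)

    true_class = sites["true_class"].to_numpy()
    mult = _class_multiplier(true_class, sirna, cfg)
    hybrid_cpm = sites["preexisting_hybrid"].to_numpy() + (
        sites["induction"].to_numpy() * mult if oht else 0.0
    )
    rate_cpm = cfg.background_rate + _hybrid_scale * hybrid_cpm
    mu = rate_cpm * cfg.library_size / 1e6
    counts = _nb_draw(rng, mu, cfg.noise_dispersion)

    total_signal = int(counts.sum())
    n_background = cfg.library_size - total_signal
    if n_background < 0:
        raise ValueError(
            f"site signal ({total_signal}) exceeds library_size ({cfg.library_size})"
        )

    contig_names = sorted(c for c, _ in cfg.genome)
    clens = {c: int(ln) for c, ln in cfg.genome}
    code_of = {c: i for i, c in enumerate(contig_names)}
    clen_arr = np.array([clens[c] for c in contig_names], dtype=np.int64)

    # signal fragments: midpoints uniform in the site window
    sig_code = np.repeat(sites["contig"].map(code_of).to_numpy(), counts)
    sig_cut = np.repeat(sites["cut_pos"].to_numpy(), counts)
    mids = sig_cut + rng.integers(-cfg.window_bp, cfg.window_bp, size=total_signal)
    sig_len = _fragment_lengths(rng, total_signal, cfg)
    sig_start = mids - sig_len // 2

    # background fragments: uniform genome-wide
    bg_code = rng.choice(len(contig_names), size=n_background,
                         p=clen_arr / clen_arr.sum())
    bg_len = _fragment_lengths(rng, n_background, cfg)
    bg_start = (rng.random(n_background) * (clen_arr[bg_code] - bg_len)).astype(np.int64)

    code_all = np.concatenate([sig_code, bg_code])
    start_all = np.concatenate([sig_start, bg_start])
    len_all = np.concatenate([sig_len, bg_len])
    # clip into contig bounds without losing length
    start_all = np.clip(start_all, 0, np.maximum(clen_arr[code_all] - len_all, 0))
    end_all = start_all + len_all

    order = np.lexsort((end_all, start_all, code_all))
    frg = pd.DataFrame({
        "contig": pd.Categorical.from_codes(code_all[order], categories=contig_names),
        "start": start_all[order],
        "end": end_all[order],
    })
    label = {"sirna": sirna, "oht": "on" if oht else "off",
             "rnaseh": _hybrid_scale != 1.0, "replicate": replicate}
    sample_id = f"{sirna}_{'OHT' if oht else 'noOHT'}_rep{replicate}" + (
        "_rnaseh" if _hybrid_scale != 1.0 else "")
    return FragmentLibrary(sample_id, frg, condition=label, site_counts=counts)


def simulate_rnaseh_library(sites, cfg, condition, replicate: int = 0,
                            residual: float | None = None) -> FragmentLibrary:
    """RNase-H pre-treated library: hybrid signal scaled by ``residual``.

    residual=0 removes all hybrid-derived signal (background remains);
    residual=1 reproduces the untreated library exactly under the same seed.
    """
    if residual is None:
        residual = cfg.rnaseh_residual
    if residual < 0:
        raise ValueError("residual must be non-negative")
    return simulate_fragment_library(sites, cfg, condition, replicate,
                                     _hybrid_scale=residual)


def simulate_experiment(cfg: SimConfig, rnaseh: bool = False):
    """Sites plus the full 2x2 (siRNA x OHT) x replicate library grid.

    Returns ``(sites, libraries)`` with libraries keyed by
    ``(sirna, oht, replicate)`` where oht is "on"/"off".
    """
    sites = make_break_sites(cfg)
    libraries = {}
    for sirna in ("ctrl", "kd"):
        for oht in ("on", "off"):
            for rep in range(cfg.n_replicates):
                cond = {"sirna": sirna, "oht": oht}
                lib = (simulate_rnaseh_library(sites, cfg, cond, rep)
                       if rnaseh else
                       simulate_fragment_library(sites, cfg, cond, rep))
                libraries[(sirna, oht, rep)] = lib
    return sites, libraries


# ---------------------------------------------------------------------------
# qPCR plates


def simulate_qpcr_plate(
    template_abundances: pd.DataFrame,
    replicates: int = 3,
    noise_sd: float = 0.15,
    efficiency: float = 2.0,
    baseline_ct: float = 30.0,
    seed: int = 17,
) -> pd.DataFrame:
    """Ct table from per-well template abundances.

    ``template_abundances`` carries one row per well type with an
    ``abundance`` column (>0) plus arbitrary label columns; each row is
    replicated and Ct = baseline - log_eff(abundance) + N(0, noise_sd).
    """
    if "abundance" not in template_abundances.columns:
        raise ValueError("template_abundances needs an 'abundance' column")
    ab = template_abundances["abundance"].to_numpy(dtype=float)
    if (ab <= 0).any():
        raise ValueError("abundances must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if efficiency <= 1:
        raise ValueError("amplification efficiency must exceed 1")
    rng = np.random.default_rng(np.random.SeedSequence((seed, 9001)))
    rows = template_abundances.loc[
        np.repeat(template_abundances.index, replicates)
    ].reset_index(drop=True)
    rows["replicate"] = np.tile(np.arange(replicates), len(template_abundances))
    ct0 = baseline_ct - np.log(rows["abundance"].to_numpy()) / np.log(efficiency)
    rows["ct"] = ct0 + rng.normal(0.0, noise_sd, size=len(rows))
    return rows.drop(columns=["abundance"])


def make_drip_qpcr_plate(
    targets: pd.DataFrame,
    dilution: float = 0.1,
    replicates: int = 3,
    noise_sd: float = 0.15,
    rnaseh_residual: float = 0.0,
    seed: int = 17,
    **plate_kwargs,
) -> pd.DataFrame:
    """DRIP-qPCR plate: IP and (diluted) input wells, +/-OHT, +/-RNase-H.

    ``targets`` columns: target, background, preexisting, induction —
    fractions of input material captured in the IP (e.g. 0.01 = 1% input).
    Input wells measure ``dilution`` x total material.
    """
    wells = []
    for row in targets.itertuples(index=False):
        for oht in ("off", "on"):
            for rnaseh in (False, True):
                scale = rnaseh_residual if rnaseh else 1.0
                captured = row.background + scale * (
                    row.preexisting + (row.induction if oht == "on" else 0.0)
                )
                wells.append((row.target, oht, rnaseh, "IP", captured))
                wells.append((row.target, oht, rnaseh, "input", dilution))
    frame = pd.DataFrame(wells, columns=["target", "oht", "rnaseh", "fraction", "abundance"])
    return simulate_qpcr_plate(frame, replicates, noise_sd, seed=seed, **plate_kwargs)


def make_resection_plate(
    planted: pd.DataFrame,
    replicates: int = 3,
    noise_sd: float = 0.1,
    seed: int = 17,
    **plate_kwargs,
) -> pd.DataFrame:
    """Resection-assay plate from planted ssDNA percentages.

    ``planted`` columns: target (site/distance label), condition (e.g.
    siRNA arm), ssdna_pct in (0, 100]. Undigested wells carry unit
    template; digested wells carry 2^(-dCt) where dCt solves the assay
    formula ssDNA% = 100 / (2^(dCt - 1) + 0.5).
    """
    pct = planted["ssdna_pct"].to_numpy(dtype=float)
    if ((pct <= 0) | (pct > 100)).any():
        raise ValueError("planted ssdna_pct must lie in (0, 100]")
    dct = 1.0 + np.log2(100.0 / pct - 0.5)
    wells = []
    for (row, d) in zip(planted.itertuples(index=False), dct):
        wells.append((row.target, row.condition, "undigested", 1.0))
        wells.append((row.target, row.condition, "digested", float(2.0 ** (-d))))
    frame = pd.DataFrame(wells, columns=["target", "condition", "fraction", "abundance"])
    return simulate_qpcr_plate(frame, replicates, noise_sd, seed=seed, **plate_kwargs)


# ---------------------------------------------------------------------------
# proteomic hit lists

AA = "ACDEFGHIKLMNPQRSTVWY"

#: phospho-peptide planted for the nominated candidate: carries exactly two
#: SQ dipeptides, the ATM/ATR consensus.
CANDIDATE_PEPTIDE = "LASQDSEDSQTK"

DEFAULT_CATEGORIES = (
    ["chromatin_association"] * 3 + ["interactome"] * 3
    + ["phosphoproteomics"] * 3 + ["ubiquitylomics"] * 2
)


def make_study_hit_lists(
    n_studies: int = 11,
    categories: Sequence[str] | None = None,
    core_set_size: int = 30,
    n_background: int = 2_000,
    capture_prob_core: float = 0.9,
    capture_prob_background: float = 0.05,
    seed: int = 17,
) -> tuple[list[StudyHitList], dict]:
    """Per-study protein hit lists with a planted core repair set.

    Core proteins are captured by each study with probability
    ``capture_prob_core``; a large background pool is captured with
    ``capture_prob_background``. One core protein is planted as the
    hybrid-interacting, not-yet-annotated repair candidate; the three
    phosphoproteomics studies carry peptides, and the candidate's peptide
    (:data:`CANDIDATE_PEPTIDE`, two SQ motifs) is identical in all of them.

    Returns ``(lists, truth)`` where ``truth`` records the planted sets.
    """
    for p in (capture_prob_core, capture_prob_background):
        if not 0.0 <= p <= 1.0:
            raise ValueError("capture probabilities must lie in [0, 1]")
    if categories is None:
        categories = (DEFAULT_CATEGORIES if n_studies == 11
                      else [DEFAULT_CATEGORIES[i % len(DEFAULT_CATEGORIES)]
                            for i in range(n_studies)])
    if len(categories) != n_studies:
        raise ValueError("need one category per study")
    rng = np.random.default_rng(np.random.SeedSequence((seed, 7001)))

    core = [f"CORE{i + 1:03d}" for i in range(core_set_size)]
    background = [f"PROT{i + 1:04d}" for i in range(n_background)]
    candidate = core[-1] if core else None
    known_repair = set(core[:-1])           # every core protein except the candidate
    hybrid_interactors = ({candidate} if candidate else set()) | set(
        rng.choice(background, size=min(25, n_background), replace=False)
    )

    def random_peptide(size=12):
        return "".join(rng.choice(list(AA), size=size))

    lists = []
    for i in range(n_studies):
        captured = [p for p in core if rng.random() < capture_prob_core]
        captured += [p for p in background if rng.random() < capture_prob_background]
        peptides = None
        if categories[i] == "phosphoproteomics":
            peptides = {p: [CANDIDATE_PEPTIDE] if p == candidate else [random_peptide()]
                        for p in captured}
        lists.append(StudyHitList(
            study_id=f"study{i + 1:02d}",
            category=categories[i],
            proteins=frozenset(captured),
            peptides=peptides,
        ))
    truth = {
        "core_set": set(core),
        "candidate": candidate,
        "candidate_peptide": CANDIDATE_PEPTIDE,
        "known_repair": known_repair,
        "hybrid_interactors": hybrid_interactors,
    }
    return lists, truth


# ---------------------------------------------------------------------------
# writers (plain-text interchange formats)


def write_site_table(sites: pd.DataFrame, bed_path, sidecar_path=None,
                     window_bp: int = 2_000) -> None:
    """BED6 site table (score = transcription level) + attribute sidecar TSV."""
    with open(bed_path, "w") as fh:
        for row in sites.itertuples(index=False):
            fh.write(f"{row.contig}\t{row.cut_pos - window_bp}\t{row.cut_pos + window_bp}"
                     f"\t{row.site_id}\t{row.transcription_level:.4f}\t.\n")
    if sidecar_path is not None:
        sites[["site_id", "repair_class", "preexisting_hybrid", "true_class"]].to_csv(
            sidecar_path, sep="\t", index=False)


def write_ct_table(plate: pd.DataFrame, path) -> None:
    plate.to_csv(path, sep="\t", index=False)


def write_hit_lists(lists: Sequence[StudyHitList], directory) -> str:
    """One TSV per study plus a manifest TSV; returns the manifest path."""
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest_rows = []
    for sl in lists:
        path = directory / f"{sl.study_id}.tsv"
        with open(path, "w") as fh:
            if sl.peptides is None:
                fh.write("protein\n")
                for p in sorted(sl.proteins):
                    fh.write(f"{p}\n")
            else:
                fh.write("protein\tpeptide\n")
                for p in sorted(sl.proteins):
                    for pep in sl.peptides.get(p, [""]):
                        fh.write(f"{p}\t{pep}\n")
        manifest_rows.append((sl.study_id, sl.category, path.name))
    manifest = directory / "manifest.tsv"
    pd.DataFrame(manifest_rows, columns=["study_id", "category", "path"]).to_csv(
        manifest, sep="\t", index=False)
    return str(manifest)
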