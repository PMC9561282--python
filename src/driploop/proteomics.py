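"""Cross-study hit-frequency meta-analysis of proteomic screens.

Given per-study protein hit lists (chromatin association, interactome,
phosphoproteomics, ubiquitylomics screens of the DNA-damage response),
rank proteins by the number of distinct studies identifying them, extract
thresholded candidate sets, intersect selected studies (Venn regions),
overlay annotation flags (e.g. DNA:RNA-hybrid interactors, known repair
factors) and scan phospho-peptides for SQ/TQ motifs, the ATM/ATR
consensus phosphorylation target.

Identifiers are opaque strings, uppercased on ingest; no cross-database
ID mapping is attempted — harmonising identifiers across heterogeneous
studies is the caller's responsibility.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from itertools import combinations
from pathlib import Path

import pandas as pd

__all__ = [
    "StudyHitList",
    "FrequencyTable",
    "read_hit_lists",
    "frequency_table",
    "candidates_at_threshold",
    "intersect_studies",
    "annotate",
    "top_flagged_candidate",
    "sq_motif_count",
]

CATEGORIES = ("chromatin_association", "interactome", "phosphoproteomics", "ubiquitylomics")


@dataclass(frozen=True)
class StudyHitList:
    """One study's protein hits; phospho studies may carry peptides."""

    study_id: str
    category: str
    proteins: frozenset[str]
    peptides: dict[str, list[str]] | None = None

    def __post_init__(self):
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown study category {self.category!r}")
        object.__setattr__(self, "proteins", frozenset(p.upper() for p in self.proteins))
        if self.peptides is not None:
            object.__setattr__(
                self, "peptides", {p.upper(): list(v) for p, v in self.peptides.items()}
            )


@dataclass
class FrequencyTable:
    """protein -> number of distinct studies identifying it, plus flags."""

    counts: dict[str, int]
    n_studies: int
    flags: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self):
        bad = {p: k for p, k in self.counts.items() if not 1 <= k <= self.n_studies}
        if bad:
            raise ValueError(f"counts outside [1, n_studies]: {bad}")

    def histogram(self) -> dict[int, int]:
        """k -> number of proteins identified by exactly k studies."""
        hist: dict[int, int] = {}
        for k in self.counts.values():
            hist[k] = hist.get(k, 0) + 1
        return dict(sorted(hist.items()))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            sorted(self.counts.items(), key=lambda kv: (-kv[1], kv[0])),
            columns=["protein", "n_studies_identified"],
        )
        for name, members in self.flags.items():
            df[name] = df["protein"].isin(members)
        return df


def read_hit_lists(manifest_path) -> list[StudyHitList]:
    """Load study TSVs (columns: protein[, peptide]) via a manifest TSV."""
    manifest = pd.read_csv(manifest_path, sep="\t")
    base = Path(manifest_path).parent
    lists = []
    for row in manifest.itertuples(index=False):
        df = pd.read_csv(base / row.path, sep="\t")
        peptides = None
        if "peptide" in df.columns:
            peptides = {}
            for prot, grp in df.groupby("protein"):
                peps = [p for p in grp["peptide"].astype(str) if p and p != "nan"]
                peptides[str(prot)] = peps
        lists.append(StudyHitList(str(row.study_id), str(row.category),
                                  frozenset(df["protein"].astype(str)), peptides))
    return lists


def frequency_table(lists: list[StudyHitList]) -> FrequencyTable:
    """Count, for each protein, the number of distinct studies identifying it."""
    if not lists:
        raise ValueError("need at least one study")
    ids = [sl.study_id for sl in lists]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate study_id in input")
    counts: dict[str, int] = {}
    for sl in lists:
        for protein in sl.proteins:  # proteins is a set: each study counts once
            counts[protein] = counts.get(protein, 0) + 1
    return FrequencyTable(counts, n_studies=len(lists))


def candidates_at_threshold(table: FrequencyTable, kmin: int) -> list[str]:
    """Proteins identified by >= kmin studies, ordered by k desc then name asc."""
    if not 1 <= kmin <= table.n_studies:
        raise ValueError(f"kmin must lie in [1, {table.n_studies}]")
    hits = [(p, k) for p, k in table.counts.items() if k >= kmin]
    hits.sort(key=lambda pk: (-pk[1], pk[0]))
    return [p for p, _ in hits]


def intersect_studies(lists: list[StudyHitList], category: str | None = None):
    """Exact Venn region counts for 2 or 3 studies plus the core intersection.

    Returns ``(regions, core)``: ``regions`` maps a tuple of study_ids (the
    studies a region belongs to exactly) to the number of proteins falling
    only in those studies; ``core`` is the set shared by all.
    """
    if category is not None:
        lists = [sl for sl in lists if sl.category == category]
    if not 2 <= len(lists) <= 3:
        raise ValueError(f"Venn intersection needs 2 or 3 studies, got {len(lists)}")
    sets = {sl.study_id: sl.proteins for sl in lists}
    ids = list(sets)
    regions: dict[tuple[str, ...], int] = {}
    for r in range(1, len(ids) + 1):
        for members in combinations(ids, r):
            inside = set.intersection(*(set(sets[i]) for i in members))
            outside = set().union(*(sets[i] for i in ids if i not in members))
            regions[members] = len(inside - outside)
    core = set.intersection(*(set(s) for s in sets.values()))
    return regions, core


def annotate(table: FrequencyTable, flag_name: str, flag_set) -> FrequencyTable:
    """Return a copy of the table with ``flag_name`` true for listed proteins."""
    members = {p.upper() for p in flag_set} & set(table.counts)
    flags = dict(table.flags)
    flags[flag_name] = members
    return replace(table, flags=flags)


def top_flagged_candidate(table: FrequencyTable, flag: str,
                          exclude_flag: str | None = None) -> str | None:
    """Most frequently identified protein carrying ``flag`` but not
    ``exclude_flag`` — the query that nominates a novel candidate (a
    hybrid interactor with no annotated repair role)."""
    flagged = table.flags.get(flag, set())
    excluded = table.flags.get(exclude_flag, set()) if exclude_flag else set()
    eligible = [(p, k) for p, k in table.counts.items()
                if p in flagged and p not in excluded]
    if not eligible:
        return None
    eligible.sort(key=lambda pk: (-pk[1], pk[0]))
    return eligible[0][0]


VALID_AA = set("ACDEFGHIKLMNPQRSTVWY")


def sq_motif_count(peptide: str, include_tq: bool = False) -> int:
    """Number of SQ (optionally also TQ) dipeptides in a peptide.

    SQ/TQ are the consensus phosphorylation motifs of the DDR kinases
    ATM and ATR. Case-insensitive; any character outside the 20-letter
    amino-acid alphabet raises a ValueError naming its position.
    """
    pep = peptide.upper()
    for i, ch in enumerate(pep):
        if ch not in VALID_AA:
            raise ValueError(f"illegal amino acid {ch!r} at position {i}")
    first = ("S", "T") if include_tq else ("S",)
    return sum(1 for i in range(len(pep) - 1)
               if pep[i] in first and pep[i + 1] == "Q")
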