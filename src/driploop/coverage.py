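"""Fragment files, per-base depth and library-size normalisation.

This module re-implements the standard DRIP-seq coverage chain: paired
alignments collapsed to fragments (BEDPE -> one interval per pair), a
sweep-line per-base depth, and scaling to fragments-per-million so that
libraries of different sizes are comparable. Coverage is stored as
run-length blocks, so whole-genome tracks of desk-scale simulations stay
light regardless of contig length.

All coordinates are 0-based half-open (BED convention).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FragmentLibrary",
    "CoverageTrack",
    "ParseError",
    "read_fragments",
    "write_fragments",
    "depth",
    "normalize",
    "write_bedgraph",
    "read_bedgraph",
    "read_site_bed",
]


class ParseError(ValueError):
    """Malformed fragment or interval file; carries the offending line number."""


@dataclass
class FragmentLibrary:
    """A sequencing condition's aligned fragments plus its total library size.

    fragments: DataFrame with columns (contig, start, end), 0-based half-open.
    library_size: total fragment count; always equals len(fragments).
    condition: free-form labels (sirna / oht / rnaseh / replicate).
    site_counts: per-site planted window counts (synthetic libraries only).
    """

    sample_id: str
    fragments: pd.DataFrame
    condition: dict = field(default_factory=dict)
    n_skipped: int = 0
    site_counts: np.ndarray | None = None

    @property
    def library_size(self) -> int:
        return len(self.fragments)

    def __post_init__(self):
        frg = self.fragments
        if len(frg) and not (frg["start"] < frg["end"]).all():
            raise ValueError("fragment with start >= end")


@dataclass
class CoverageTrack:
    """Run-length encoded per-base depth.

    blocks: contig -> (bounds, values); ``bounds`` has k+1 breakpoints
    covering [bounds[0], bounds[-1]) and ``values`` the k block depths.
    Zero-depth runs are stored explicitly so the track tiles its extent.
    """

    blocks: dict[str, tuple[np.ndarray, np.ndarray]]
    scale: str = "raw"  # "raw" | "per_million"
    scale_factor: float = 1.0

    def value_at(self, contig: str, pos: int) -> float:
        bounds, values = self.blocks[contig]
        if pos < bounds[0] or pos >= bounds[-1]:
            return 0.0
        i = int(np.searchsorted(bounds, pos, side="right")) - 1
        return float(values[i])

    def window_sum(self, contig: str, start: int, end: int) -> float:
        """Sum of depth over [start, end); positions outside the track are 0."""
        if contig not in self.blocks or end <= start:
            return 0.0
        bounds, values = self.blocks[contig]
        cum = self._cumsums.setdefault(
            contig, np.concatenate([[0.0], np.cumsum(values * np.diff(bounds))])
        )
        start = max(start, int(bounds[0]))
        end = min(end, int(bounds[-1]))
        if end <= start:
            return 0.0
        return float(self._partial(bounds, values, cum, end) - self._partial(bounds, values, cum, start))

    @staticmethod
    def _partial(bounds, values, cum, pos):
        """Integral of the step function over [bounds[0], pos)."""
        i = int(np.searchsorted(bounds, pos, side="right")) - 1
        i = min(max(i, 0), len(values) - 1)
        return cum[i] + values[i] * (pos - bounds[i])

    def __post_init__(self):
        self._cumsums: dict[str, np.ndarray] = {}

    def to_dense(self, contig: str) -> np.ndarray:
        """Expand one contig to a dense per-base vector (tests / tiny contigs)."""
        bounds, values = self.blocks[contig]
        out = np.zeros(int(bounds[-1]), dtype=float)
        for i, v in enumerate(values):
            out[int(bounds[i]) : int(bounds[i + 1])] = v
        return out


# ---------------------------------------------------------------------------
# fragment I/O


def _parse_bed_row(fields, lineno):
    if len(fields) < 3:
        raise ParseError(f"line {lineno}: expected >=3 BED columns, got {len(fields)}")
    try:
        return fields[0], int(fields[1]), int(fields[2])
    except ValueError as exc:
        raise ParseError(f"line {lineno}: non-integer coordinate ({exc})") from None


def _parse_bedpe_row(fields, lineno):
    if len(fields) < 6:
        raise ParseError(f"line {lineno}: expected >=6 BEDPE columns, got {len(fields)}")
    try:
        c1, s1, e1 = fields[0], int(fields[1]), int(fields[2])
        c2, s2, e2 = fields[3], int(fields[4]), int(fields[5])
    except ValueError as exc:
        raise ParseError(f"line {lineno}: non-integer coordinate ({exc})") from None
    if c1 != c2:
        return None  # inter-contig pair: skipped by caller
    return c1, min(s1, s2), max(e1, e2)


def read_fragments(path, fmt: str = "bedpe", sample_id: str | None = None) -> FragmentLibrary:
    """Read a BEDPE or BED3 fragment file into a sorted FragmentLibrary.

    A BEDPE row (c, s1, e1, c, s2, e2) becomes the mate-spanning fragment
    (c, min starts, max ends). Pairs with mates on different contigs are
    skipped with a warning and counted in ``n_skipped``. Malformed lines
    raise :class:`ParseError` naming the line.
    """
    if fmt not in ("bedpe", "bed"):
        raise ValueError(f"unknown format {fmt!r}")
    rows, skipped = [], 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if fmt == "bed":
                rows.append(_parse_bed_row(fields, lineno))
            else:
                parsed = _parse_bedpe_row(fields, lineno)
                if parsed is None:
                    skipped += 1
                else:
                    rows.append(parsed)
    if skipped:
        warnings.warn(f"{path}: skipped {skipped} inter-contig pairs", stacklevel=2)
    frg = pd.DataFrame(rows, columns=["contig", "start", "end"])
    frg = frg.sort_values(["contig", "start", "end"], kind="mergesort").reset_index(drop=True)
    return FragmentLibrary(sample_id or str(path), frg, n_skipped=skipped)


def write_fragments(lib: FragmentLibrary, path, fmt: str = "bed") -> None:
    """Write fragments as BED3 or degenerate BEDPE (both mates = fragment)."""
    frg = lib.fragments
    with open(path, "w") as fh:
        if fmt == "bed":
            for c, s, e in frg.itertuples(index=False):
                fh.write(f"{c}\t{s}\t{e}\n")
        elif fmt == "bedpe":
            for c, s, e in frg.itertuples(index=False):
                fh.write(f"{c}\t{s}\t{e}\t{c}\t{s}\t{e}\n")
        else:
            raise ValueError(f"unknown format {fmt!r}")


def write_library_size(lib: FragmentLibrary, path) -> None:
    with open(path, "w") as fh:
        json.dump({"sample_id": lib.sample_id, "library_size": lib.library_size,
                   "condition": lib.condition}, fh, indent=1)


# ---------------------------------------------------------------------------
# depth and normalisation


def depth(lib: FragmentLibrary) -> CoverageTrack:
    """Per-base raw depth: depth[p] = #{fragments with start <= p < end}.

    Sweep-line over fragment endpoints; O(n log n) in the number of
    fragments, independent of contig length.
    """
    blocks: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for contig, grp in lib.fragments.groupby("contig", sort=True, observed=True):
        starts = grp["start"].to_numpy(dtype=np.int64)
        ends = grp["end"].to_numpy(dtype=np.int64)
        pts = np.concatenate([starts, ends])
        deltas = np.concatenate([np.ones_like(starts), -np.ones_like(ends)])
        order = np.argsort(pts, kind="mergesort")
        pts, deltas = pts[order], deltas[order]
        bounds, first = np.unique(pts, return_index=True)
        csum = np.cumsum(deltas)
        # depth within [bounds[i], bounds[i+1]) = running sum after all events at bounds[i]
        last = np.append(first[1:], len(pts)) - 1
        values = csum[last][:-1].astype(float)
        blocks[str(contig)] = (bounds.astype(np.int64), values)
    return CoverageTrack(blocks, scale="raw", scale_factor=1.0)


def normalize(track: CoverageTrack, library_size: int) -> CoverageTrack:
    """Scale a raw track to fragments-per-million: values * 1e6 / L."""
    if track.scale != "raw":
        raise ValueError("track is already normalized")
    if library_size <= 0:
        raise ValueError("library size must be positive for normalization")
    s = 1e6 / library_size
    blocks = {c: (b.copy(), v * s) for c, (b, v) in track.blocks.items()}
    return CoverageTrack(blocks, scale="per_million", scale_factor=s)


def total_signal(track: CoverageTrack) -> float:
    """Sum of depth over every base of the track (conservation checks)."""
    return float(sum((v * np.diff(b)).sum() for b, v in track.blocks.values()))


# ---------------------------------------------------------------------------
# bedGraph round-trip


def _fmt(v: float) -> str:
    if v == int(v):
        return str(int(v))
    return repr(float(v))  # shortest round-trip decimal


def write_bedgraph(track: CoverageTrack, path) -> None:
    """4-column bedGraph with adjacent equal-value runs merged.

    Zero-depth runs are written too, so ``read_bedgraph(write_bedgraph(x))``
    reproduces the track exactly, including its extent.
    """
    with open(path, "w") as fh:
        for contig in sorted(track.blocks):
            bounds, values = track.blocks[contig]
            prev_end = None
            i = 0
            while i < len(values):
                j = i
                while j + 1 < len(values) and values[j + 1] == values[i]:
                    j += 1
                start, end = int(bounds[i]), int(bounds[j + 1])
                if prev_end is not None and start < prev_end:
                    raise RuntimeError("internal error: overlapping bedGraph intervals")
                fh.write(f"{contig}\t{start}\t{end}\t{_fmt(float(values[i]))}\n")
                prev_end = end
                i = j + 1


def read_bedgraph(path) -> CoverageTrack:
    per_contig: dict[str, list[tuple[int, int, float]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise ParseError(f"line {lineno}: expected 4 bedGraph columns")
            per_contig.setdefault(fields[0], []).append(
                (int(fields[1]), int(fields[2]), float(fields[3]))
            )
    blocks = {}
    for contig, runs in per_contig.items():
        runs.sort()
        bounds = np.array([runs[0][0]] + [r[1] for r in runs], dtype=np.int64)
        values = np.array([r[2] for r in runs], dtype=float)
        blocks[contig] = (bounds, values)
    track = CoverageTrack(blocks)
    track.scale = "per_million" if any(
        float(v) != int(v) for _, vals in blocks.values() for v in vals
    ) else "raw"
    return track


def read_site_bed(path) -> pd.DataFrame:
    """Read a BED6 break-site table (score column = transcription level)."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 6:
                raise ParseError(f"line {lineno}: expected 6 BED columns")
            rows.append((f[0], int(f[1]), int(f[2]), f[3], float(f[4]), f[5]))
    df = pd.DataFrame(rows, columns=["contig", "start", "end", "site_id",
                                     "transcription_level", "strand"])
    df["cut_pos"] = (df["start"] + df["end"]) // 2
    return df
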