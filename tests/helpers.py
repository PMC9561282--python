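"""Shared test utilities: tiny fragment libraries and random instances."""

import numpy as np
import pandas as pd

from driploop.coverage import FragmentLibrary


def make_library(rows, sample_id="test"):
    frg = pd.DataFrame(rows, columns=["contig", "start", "end"])
    frg = frg.sort_values(["contig", "start", "end"], kind="mergesort").reset_index(drop=True)
    return FragmentLibrary(sample_id, frg)


def random_fragments(rng, n, contig="chr1", contig_len=10_000, max_len=500):
    starts = rng.integers(0, contig_len - 1, size=n)
    lengths = rng.integers(1, max_len, size=n)
    ends = np.minimum(starts + lengths, contig_len)
    return [(contig, int(s), int(e)) for s, e in zip(starts, ends)]


def brute_force_depth(rows, contig_len):
    """Naive per-base counting loop — the independent oracle for depth()."""
    out = np.zeros(contig_len)
    for _, s, e in rows:
        out[s:e] += 1
    return out
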