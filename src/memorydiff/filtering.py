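"""Low-support read-count filtering.

Transcripts must exceed one count per million mapped reads (CPM) in at
least three samples to stay in the analysis; both bounds are
parameters. Library sizes are the column sums of the matrix the filter
receives, recomputed after any exclusion-list removal, so CPM always
refers to the currently retained reads.
"""

from __future__ import annotations

from typing import Iterable

import pandas as pd


class FilterError(ValueError):
    pass


def _check_counts(counts: pd.DataFrame) -> None:
    if (counts.to_numpy() < 0).any():
        raise FilterError("count matrix contains negative cells")


def cpm(counts: pd.DataFrame) -> pd.DataFrame:
    """Counts per million: count / library size x 1e6, per column."""
    _check_counts(counts)
    libsize = counts.sum(axis=0)
    if (libsize <= 0).any():
        bad = list(libsize.index[libsize <= 0])
        raise FilterError(f"zero library size for samples: {bad}")
    return counts / libsize * 1e6


def exclude_transcripts(counts: pd.DataFrame, exclude_ids: Iterable[str]) -> pd.DataFrame:
    """Drop an exclusion list (e.g. contaminant transcripts) before
    filtering; downstream CPM uses the reduced column sums."""
    exclude = set(exclude_ids)
    return counts.loc[[t for t in counts.index if t not in exclude]]


def filter_low_support(
    counts: pd.DataFrame,
    cpm_threshold: float = 1.0,
    min_samples: int = 3,
) -> pd.DataFrame:
    """Keep transcripts with CPM strictly above ``cpm_threshold`` in at
    least ``min_samples`` samples; columns are unchanged."""
    keep = (cpm(counts) > cpm_threshold).sum(axis=1) >= min_samples
    return counts.loc[keep]
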