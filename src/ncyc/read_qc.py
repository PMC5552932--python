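"""Length-based read filtering and per-sample summary statistics.

The trimming rule is strict: a read is kept when its length is strictly
greater than ``min_len_exclusive`` (default 100 nt, so the shortest kept
read is 101 nt). The comparison can be relaxed to >= for sensitivity
analysis via ``inclusive=True``.
"""

from __future__ import annotations

from typing import Sequence

from .records import SampleStats, SequenceRead

__all__ = ["filter_by_length", "summarize"]


def filter_by_length(reads: Sequence[SequenceRead],
                     min_len_exclusive: int = 100,
                     inclusive: bool = False) -> list[SequenceRead]:
    """Keep reads longer than the threshold, preserving order."""
    if inclusive:
        return [r for r in reads if len(r.seq) >= min_len_exclusive]
    return [r for r in reads if len(r.seq) > min_len_exclusive]


def summarize(reads: Sequence[SequenceRead], sample_id: str,
              n_reads_raw: int | None = None) -> SampleStats:
    """Exact read count plus mean length (half-even rounded, 2 decimals).

    ``n_reads_raw`` defaults to the number of reads given; pass the pre-QC
    count when summarizing a filtered set. An empty set reports the mean as
    missing (None).
    """
    n = len(reads)
    if n == 0:
        mean = None
    else:
        mean = round(sum(len(r.seq) for r in reads) / n, 2)
    return SampleStats(
        sample_id=sample_id,
        n_reads_raw=n if n_reads_raw is None else n_reads_raw,
        n_reads_kept=n,
        mean_len_kept=mean,
    )
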