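"""Interval arithmetic on a circular genome.

All internal coordinates are 0-based half-open and live in [0, L).  A feature
that wraps past the origin is represented as a *chain* of in-range intervals
(e.g. [950,1000) + [0,50) on a 1000 bp circle); helpers here do the modular
bookkeeping so the rest of the package can treat chains uniformly.
"""

from __future__ import annotations

import numpy as np

Interval = tuple[int, int]


def norm(pos: int, length: int) -> int:
    return pos % length


def split_interval(start: int, end: int, length: int) -> list[Interval]:
    """Normalize a possibly origin-crossing interval to 1 or 2 in-range pieces.

    ``start`` may be any integer; ``end`` must satisfy start < end <= start+length.
    """
    if not start < end <= start + length:
        raise ValueError(f"bad circular interval [{start},{end}) on length {length}")
    s = start % length
    e = s + (end - start)
    if e <= length:
        return [(s, e)]
    return [(s, length), (0, e - length)]


def mark(cov: np.ndarray, start: int, end: int) -> None:
    """Set cov[start:end] = True, wrapping past the origin if needed."""
    for s, e in split_interval(start, end, cov.shape[0]):
        cov[s:e] = True


def add_depth(depth: np.ndarray, start: int, end: int) -> None:
    for s, e in split_interval(start, end, depth.shape[0]):
        depth[s:e] += 1


def gap_between(prev_end: int, next_start: int, length: int) -> int:
    """Length of the genomic gap from prev_end to next_start, going forward
    around the circle (0 means the two intervals are contiguous)."""
    return (next_start - prev_end) % length


def chain_length(chain: list[Interval]) -> int:
    return sum(e - s for s, e in chain)


def smallest_covering_arc(intervals: list[Interval], length: int) -> Interval:
    """Smallest circular arc containing every interval; returned as (start, end)
    with end possibly > length when the arc wraps the origin."""
    if not intervals:
        raise ValueError("no intervals")
    pts = sorted((s % length, s % length + (e - s)) for s, e in intervals)
    # try each interval as the arc start; the best arc starts at some interval
    best = None
    for i, (s0, _) in enumerate(pts):
        end = s0
        for s, e in pts:
            su = s if s >= s0 else s + length
            eu = su + (e - s)
            end = max(end, eu)
        if end - s0 <= length and (best is None or end - s0 < best[1] - best[0]):
            best = (s0, end)
    if best is None:  # intervals cover the whole circle
        best = (0, length)
    return best
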