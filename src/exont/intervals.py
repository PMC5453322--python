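"""Half-open integer interval arithmetic used by the hit store."""

from __future__ import annotations

Interval = tuple[int, int]


def merge(intervals: list[Interval]) -> list[Interval]:
    """Sorted union of half-open intervals; adjacent runs coalesce."""
    out: list[Interval] = []
    for s, e in sorted(intervals):
        if e <= s:
            continue
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def clip(intervals: list[Interval], window: Interval) -> list[Interval]:
    """Intersect each interval with *window*, dropping empties."""
    ws, we = window
    return [(max(s, ws), min(e, we)) for s, e in intervals if max(s, ws) < min(e, we)]


def total_length(intervals: list[Interval]) -> int:
    """Union length; input need not be disjoint."""
    return sum(e - s for s, e in merge(list(intervals)))
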