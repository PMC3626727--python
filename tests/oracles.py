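"""Independent brute-force oracles used by the unit and acceptance tests.

These deliberately avoid the package's own interval logic: episode merging is
iterated pairwise to a fixpoint, and drug coverage is enumerated day by day.
"""

from __future__ import annotations


def fixpoint_merge(event_days: list[int], clean_period: int) -> list[tuple[int, int]]:
    """Merge events into episodes by repeatedly joining any pair of adjacent
    episodes separated by less than ``clean_period`` days, until stable.
    Returns sorted (start_day, end_day) episode boundaries."""
    episodes = [[d, d] for d in sorted(event_days)]
    changed = True
    while changed:
        changed = False
        for i in range(len(episodes) - 1):
            if episodes[i + 1][0] - episodes[i][1] < clean_period:
                episodes[i][1] = max(episodes[i][1], episodes[i + 1][1])
                del episodes[i + 1]
                changed = True
                break
    return [(a, b) for a, b in episodes]


def enumerate_covered_days(fills: list[tuple[int, int]], period_days: int) -> int:
    """Day-by-day union of [start, start+supply) within [0, period_days)."""
    covered = set()
    for start, supply in fills:
        for d in range(start, start + supply):
            if 0 <= d < period_days:
                covered.add(d)
    return len(covered)
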