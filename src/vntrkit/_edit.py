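"""Bit-parallel approximate string matching (Myers' algorithm).

Semi-global ("search") semantics throughout: the pattern must be consumed in
full, both ends of the text are free, costs are unit Levenshtein.  The
pattern is encoded as column bitmasks in arbitrary-precision integers, so
patterns longer than a machine word are handled transparently.

A plain dynamic-programming oracle lives in the test suite and is kept
independent of this module.
"""

from __future__ import annotations

__all__ = [
    "min_edit_distance",
    "end_positions_within",
    "global_edit_distance",
    "min_hamming_distance",
]


def _precompute(pattern: str) -> dict[str, int]:
    peq: dict[str, int] = {}
    for i, ch in enumerate(pattern):
        peq[ch] = peq.get(ch, 0) | (1 << i)
    return peq


def _scan(pattern: str, text: str):
    """Yield (end_exclusive, distance) for every text position.

    ``distance`` is the Levenshtein distance of the best occurrence of
    ``pattern`` ending exactly at ``end_exclusive``.
    """
    m = len(pattern)
    if m == 0:
        raise ValueError("pattern must be non-empty")
    peq = _precompute(pattern)
    mask = (1 << m) - 1
    hib = 1 << (m - 1)
    pv = mask
    mv = 0
    score = m
    for j, ch in enumerate(text):
        eq = peq.get(ch, 0)
        xv = eq | mv
        xh = (((eq & pv) + pv) ^ pv) | eq
        ph = mv | (~(xh | pv) & mask)
        mh = pv & xh
        if ph & hib:
            score += 1
        elif mh & hib:
            score -= 1
        ph = (ph << 1) & mask
        mh = (mh << 1) & mask
        pv = mh | (~(xv | ph) & mask)
        mv = ph & xv
        yield j + 1, score


def min_edit_distance(pattern: str, text: str) -> tuple[int, int]:
    """Best semi-global edit distance of ``pattern`` within ``text``.

    Returns ``(distance, end)`` where ``end`` is the exclusive end position
    of the first best occurrence.  If the text is shorter than the pattern
    the distance still accounts for the missing characters (deletions).
    """
    best = len(pattern)
    best_end = 0
    for end, score in _scan(pattern, text):
        if score < best:
            best, best_end = score, end
    return best, best_end


def end_positions_within(pattern: str, text: str, max_edit: int) -> list[tuple[int, int]]:
    """All ``(end_exclusive, distance)`` with distance <= ``max_edit``."""
    return [(end, s) for end, s in _scan(pattern, text) if s <= max_edit]


def global_edit_distance(a: str, b: str, limit: int | None = None) -> int:
    """Plain end-to-end Levenshtein distance (small inputs only).

    ``limit`` allows early exit: any value > limit may be returned as soon
    as the distance provably exceeds it.
    """
    if len(a) > len(b):
        a, b = b, a
    prev = list(range(len(a) + 1))
    for j, cb in enumerate(b, start=1):
        cur = [j]
        row_min = j
        for i, ca in enumerate(a, start=1):
            d = min(prev[i] + 1, cur[i - 1] + 1, prev[i - 1] + (ca != cb))
            cur.append(d)
            if d < row_min:
                row_min = d
        if limit is not None and row_min > limit:
            return row_min
        prev = cur
    return prev[-1]


def min_hamming_distance(pattern: str, text: str) -> tuple[int, int]:
    """Substitution-only analogue of :func:`min_edit_distance`.

    Slides the pattern over the text (no indels) and returns the minimum
    mismatch count and the exclusive end of the first best placement.
    The pattern must fit inside the text.
    """
    m, n = len(pattern), len(text)
    if m == 0:
        raise ValueError("pattern must be non-empty")
    if m > n:
        return m, 0
    best = m + 1
    best_end = 0
    for off in range(n - m + 1):
        d = sum(1 for x, y in zip(pattern, text[off : off + m]) if x != y)
        if d < best:
            best, best_end = d, off + m
            if d == 0:
                break
    return best, best_end
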