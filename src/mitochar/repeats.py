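"""Exact repeated-motif detection for the A+T-rich control region.

A hit is a substring of length >= min_len occurring at >= 2 positions, reported
once with every copy position, unless every one of its occurrences lies inside
an occurrence of a longer repeated substring (containment suppression, which
also removes non-maximal sub-repeats). Hits whose copies overlap each other
(period smaller than the motif) are canonicalized into tandem arrays: the unit
is the minimal period of the spanned region (padded to min_len when shorter)
and fractional trailing copies are truncated.

Detection is suffix-array based (LCP-interval enumeration of right-maximal
repeats); regions of interest are control regions of a few kb, where this is
instantaneous.
"""

from __future__ import annotations

import math
from dataclasses import dataclass


@dataclass(frozen=True)
class RepeatHit:
    motif: str
    positions: tuple[int, ...]  # 1-based, region-relative, strictly increasing
    tandem: bool  # consecutive copies abut exactly
    identity: float = 1.0  # exact-match detection only

    @property
    def length(self) -> int:
        return len(self.motif)

    @property
    def copy_number(self) -> int:
        return len(self.positions)

    def __post_init__(self):
        if self.copy_number < 2:
            raise ValueError("a repeat needs at least two copies")
        if list(self.positions) != sorted(set(self.positions)):
            raise ValueError("positions must be strictly increasing")


def _suffix_array(s: str) -> list[int]:
    return sorted(range(len(s)), key=lambda i: s[i:])


def _lcp_array(s: str, sa: list[int]) -> list[int]:
    # Kasai's algorithm: lcp[i] = lcp(s[sa[i-1]:], s[sa[i]:]) for i >= 1
    n = len(s)
    rank = [0] * n
    for i, suf in enumerate(sa):
        rank[suf] = i
    lcp = [0] * n
    h = 0
    for i in range(n):
        if rank[i] > 0:
            j = sa[rank[i] - 1]
            while i + h < n and j + h < n and s[i + h] == s[j + h]:
                h += 1
            lcp[rank[i]] = h
            if h:
                h -= 1
        else:
            h = 0
    return lcp


def _lcp_intervals(lcp: list[int], n: int):
    """Yield (depth, left, right) for every branching LCP interval."""
    stack: list[tuple[int, int]] = []  # (depth, left boundary)
    for i in range(1, n):
        left = i - 1
        while stack and lcp[i] < stack[-1][0]:
            depth, l = stack.pop()
            yield depth, l, i - 1
            left = l
        if not stack or lcp[i] > stack[-1][0]:
            stack.append((lcp[i], left))
    while stack:
        depth, l = stack.pop()
        yield depth, l, n - 1


def _minimal_period(s: str) -> int:
    # KMP failure function; minimal p with s[i] == s[i+p] for all valid i
    fail = [0] * len(s)
    k = 0
    for i in range(1, len(s)):
        while k and s[i] != s[k]:
            k = fail[k - 1]
        if s[i] == s[k]:
            k += 1
        fail[i] = k
    return len(s) - fail[-1]


def canonicalize_hit(motif: str, positions: list[int], region: str, min_len: int
                     ) -> list[tuple[str, tuple[int, ...], bool]]:
    """Apply the tandem-array rule to one (motif, 0-based positions) candidate.

    Returns (motif, 0-based positions, tandem) tuples; may split a candidate
    whose occurrences form several overlapping clusters.
    """
    L = len(motif)
    positions = sorted(positions)
    if all(q - p >= L for p, q in zip(positions, positions[1:])):
        tandem = all(q - p == L for p, q in zip(positions, positions[1:]))
        return [(motif, tuple(positions), tandem)]
    # overlapping copies: periodic array(s)
    clusters: list[list[int]] = [[positions[0]]]
    for p in positions[1:]:
        if p - clusters[-1][-1] < L:
            clusters[-1].append(p)
        else:
            clusters.append([p])
    out = []
    leftovers = []  # non-overlapping stray copies
    for cluster in clusters:
        if len(cluster) == 1:
            leftovers.append(cluster[0])
            continue
        span = region[cluster[0]: cluster[-1] + L]
        p = _minimal_period(span)
        unit_len = p if p >= min_len else p * math.ceil(min_len / p)
        copies = len(span) // unit_len
        if copies >= 2:
            out.append((
                span[:unit_len],
                tuple(cluster[0] + i * unit_len for i in range(copies)),
                True,
            ))
        else:
            leftovers.extend(cluster)
    if len(leftovers) >= 2:
        out.append((motif, tuple(leftovers), False))
    return out


def find_repeats(region: str, min_len: int = 9) -> list[RepeatHit]:
    """All maximal exact repeats of length >= min_len in a region.

    Positions in the returned hits are 1-based and region-relative. Hits are
    sorted by first position, then by descending length.
    """
    if min_len < 2:
        raise ValueError("min_len must be >= 2")
    region = region.upper().replace("U", "T")
    n = len(region)
    if n < min_len:
        raise ValueError(f"region ({n} bp) shorter than min_len ({min_len})")

    sa = _suffix_array(region)
    lcp = _lcp_array(region, sa)

    candidates: dict[str, set[int]] = {}
    for depth, l, r in _lcp_intervals(lcp, n):
        if depth < min_len:
            continue
        motif = region[sa[l]: sa[l] + depth]
        candidates.setdefault(motif, set()).update(sa[l: r + 1])

    kept: list[tuple[str, list[int]]] = []  # descending motif length
    for motif in sorted(candidates, key=len, reverse=True):
        positions = sorted(candidates[motif])
        if not _suppressed(motif, positions, kept):
            kept.append((motif, positions))

    hits: dict[tuple[str, tuple[int, ...]], bool] = {}
    for motif, positions in kept:
        for m, pos, tandem in canonicalize_hit(motif, positions, region, min_len):
            hits[(m, pos)] = tandem

    result = [
        RepeatHit(motif=m, positions=tuple(p + 1 for p in pos), tandem=tandem)
        for (m, pos), tandem in hits.items()
    ]
    result.sort(key=lambda h: (h.positions[0], -h.length))
    return result


def _suppressed(motif: str, positions: list[int],
                kept: list[tuple[str, list[int]]]) -> bool:
    """True when every occurrence lies inside an occurrence of a longer kept hit."""
    L = len(motif)
    for p in positions:
        covered = False
        for km, kpos in kept:
            if len(km) <= L:
                continue
            if any(q <= p and p + L <= q + len(km) for q in kpos):
                covered = True
                break
        if not covered:
            return False
    return bool(kept)
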