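"""Independent brute-force oracles, kept deliberately naive.

These recompute the same quantities as the package via a different route:
the Ka/Ks oracle enumerates pathways with plain loops on top of Biopython's
NCBI codon table (the package embeds its own), and the repeat oracle scans
all substrings length by length with a dictionary (the package walks a suffix
array). Tests assert equality between the two routes.
"""

from __future__ import annotations

import itertools
import math

from Bio.Data import CodonTable


def _translator(code_id: int = 5):
    bio = CodonTable.unambiguous_dna_by_id[code_id]
    stops = set(bio.stop_codons)

    def tr(codon: str) -> str:
        return "*" if codon in stops else bio.forward_table[codon]

    return tr


def ng_oracle(seq_a: str, seq_b: str, code_id: int = 5) -> dict:
    """Nei-Gojobori by direct enumeration: sites, pathway-averaged differences, JC."""
    tr = _translator(code_id)
    assert len(seq_a) == len(seq_b) and len(seq_a) % 3 == 0
    S = N = Sd = Nd = 0.0
    codons = 0
    for i in range(0, len(seq_a), 3):
        ca, cb = seq_a[i:i + 3], seq_b[i:i + 3]
        if set(ca + cb) - set("ACGT"):
            continue
        if tr(ca) == "*" or tr(cb) == "*":
            continue
        codons += 1
        for codon in (ca, cb):
            s_c = 0.0
            for pos in range(3):
                syn = nonstop = 0
                for alt in "ACGT":
                    if alt == codon[pos]:
                        continue
                    mutated = codon[:pos] + alt + codon[pos + 1:]
                    if tr(mutated) == "*":
                        continue
                    nonstop += 1
                    if tr(mutated) == tr(codon):
                        syn += 1
                if nonstop:
                    s_c += syn / nonstop
            S += s_c / 2
            N += (3 - s_c) / 2
        diff = [p for p in range(3) if ca[p] != cb[p]]
        paths = []
        for perm in itertools.permutations(diff):
            cur, sd, nd, ok = ca, 0, 0, True
            for p in perm:
                nxt = cur[:p] + cb[p] + cur[p + 1:]
                if tr(nxt) == "*" and nxt != cb:
                    ok = False
                    break
                if tr(nxt) == tr(cur):
                    sd += 1
                else:
                    nd += 1
                cur = nxt
            if ok:
                paths.append((sd, nd))
        if not paths:  # every route blocked by a stop: use all, unweighted
            for perm in itertools.permutations(diff):
                cur, sd, nd = ca, 0, 0
                for p in perm:
                    nxt = cur[:p] + cb[p] + cur[p + 1:]
                    if tr(nxt) == tr(cur):
                        sd += 1
                    else:
                        nd += 1
                    cur = nxt
                paths.append((sd, nd))
        if diff:
            Sd += sum(p[0] for p in paths) / len(paths)
            Nd += sum(p[1] for p in paths) / len(paths)
    pS = Sd / S if S else 0.0
    pN = Nd / N if N else 0.0

    def jc(p):
        assert p < 0.75
        return -0.75 * math.log(1 - 4 * p / 3)

    ks, ka = jc(pS), jc(pN)
    return {
        "ka": ka, "ks": ks, "omega": (ka / ks if ks > 0 else None),
        "N": N, "S": S, "Sd": Sd, "Nd": Nd, "pS": pS, "pN": pN, "codons": codons,
    }


# --- repeats -----------------------------------------------------------------

def _minimal_period_naive(s: str) -> int:
    for p in range(1, len(s) + 1):
        if all(s[i] == s[i + p] for i in range(len(s) - p)):
            return p
    return len(s)


def _canonicalize_naive(motif, positions, region, min_len):
    L = len(motif)
    positions = sorted(positions)
    if all(q - p >= L for p, q in zip(positions, positions[1:])):
        tandem = all(q - p == L for p, q in zip(positions, positions[1:]))
        return [(motif, tuple(positions), tandem)]
    clusters = [[positions[0]]]
    for p in positions[1:]:
        (clusters[-1].append(p) if p - clusters[-1][-1] < L else clusters.append([p]))
    out, leftovers = [], []
    for cluster in clusters:
        if len(cluster) == 1:
            leftovers.append(cluster[0])
            continue
        span = region[cluster[0]: cluster[-1] + L]
        p = _minimal_period_naive(span)
        unit_len = p if p >= min_len else p * math.ceil(min_len / p)
        copies = len(span) // unit_len
        if copies >= 2:
            out.append((span[:unit_len],
                        tuple(cluster[0] + i * unit_len for i in range(copies)), True))
        else:
            leftovers.extend(cluster)
    if len(leftovers) >= 2:
        out.append((motif, tuple(leftovers), False))
    return out


def repeat_oracle(region: str, min_len: int) -> set[tuple[str, tuple[int, ...], bool]]:
    """All repeats by per-length substring scan; positions 1-based like the package."""
    n = len(region)
    reps: dict[str, list[int]] = {}
    length = min_len
    while length <= n:
        seen: dict[str, list[int]] = {}
        for i in range(n - length + 1):
            seen.setdefault(region[i:i + length], []).append(i)
        dups = {m: p for m, p in seen.items() if len(p) >= 2}
        if not dups:
            break
        reps.update(dups)
        length += 1

    kept: list[tuple[str, list[int]]] = []
    for m in sorted(reps, key=len, reverse=True):
        pos, L = reps[m], len(m)
        covered = kept and all(
            any(len(km) > L and any(q <= p and p + L <= q + len(km) for q in kp)
                for km, kp in kept)
            for p in pos
        )
        if not covered:
            kept.append((m, pos))

    hits = set()
    for m, pos in kept:
        for mm, pp, td in _canonicalize_naive(m, pos, region, min_len):
            hits.add((mm, tuple(x + 1 for x in pp), td))
    return hits
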