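"""Nucleotide diversity and Nei-Gojobori Ka/Ks for aligned orthologous CDS.

Nucleotide diversity (pi) is the mean pairwise per-site difference with
pairwise deletion of gaps and ambiguous bases:

    pi = 2 / (n (n - 1)) * sum_{i<j} d_ij / L_ij

Ka/Ks uses the Nei & Gojobori (1986) pathway-counting method. Per codon, the
synonymous site fraction at each position is the number of synonymous one-step
changes divided by the number of one-step changes that do not create a stop
codon (so N + S = 3 * compared codons). Observed differences between a codon
pair are resolved by enumerating all orderings of single-base steps, excluding
pathways that pass through a stop codon and weighting the remaining pathways
equally. Raw proportions pN = Nd/N and pS = Sd/S receive the Jukes-Cantor
correction d = -(3/4) ln(1 - (4/3) p); omega = dN/dS.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from itertools import combinations, permutations

from .genetic_codes import BASES, get_code

GAP_CHARS = set("-.?")
UNAMBIGUOUS = set("ACGT")


class SaturationError(ValueError):
    """Raw difference proportion >= 3/4: Jukes-Cantor correction undefined."""


@dataclass
class OrthologAlignmentSet:
    """Aligned, in-frame, equal-length coding-strand sequences for one gene."""

    gene: str
    taxa: list[str]
    sequences: list[str]

    def __post_init__(self):
        if len(self.taxa) != len(self.sequences):
            raise ValueError("taxa and sequences differ in number")
        if len(self.taxa) < 2:
            raise ValueError("at least two taxa required")
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError("taxa labels must be unique")
        self.sequences = [s.upper().replace("U", "T") for s in self.sequences]
        lengths = {len(s) for s in self.sequences}
        if len(lengths) != 1:
            raise ValueError(f"aligned sequences differ in length: {sorted(lengths)}")
        (length,) = lengths
        if length % 3:
            raise ValueError(f"alignment length {length} not divisible by 3")

    @property
    def length(self) -> int:
        return len(self.sequences[0])


@dataclass
class DivergenceEstimate:
    gene: str
    pi: float
    ka: float
    ks: float
    omega: float | None  # None when ks == 0 (undefined, never infinity)
    N: float
    S: float
    pN: float
    pS: float
    n_pairs: int
    dropped_pairs: int = 0  # pairs with undefined omega excluded from the mean


def nucleotide_diversity(aln: OrthologAlignmentSet) -> float:
    """Mean pairwise difference per site with site-wise pairwise deletion."""
    total = 0.0
    n_pairs = 0
    any_comparable = False
    for a, b in combinations(aln.sequences, 2):
        d = L = 0
        for x, y in zip(a, b):
            if x in UNAMBIGUOUS and y in UNAMBIGUOUS:
                L += 1
                if x != y:
                    d += 1
        n_pairs += 1
        if L:
            any_comparable = True
            total += d / L
    if not any_comparable:
        raise ValueError("no pair shares comparable sites")
    return total / n_pairs


@lru_cache(maxsize=None)
def _syn_site_fraction(codon: str, code_id: int) -> float:
    """Synonymous sites of a codon: sum over positions of syn / non-stop changes."""
    code = get_code(code_id)
    s = 0.0
    for pos in range(3):
        syn = 0
        nonstop = 0
        for b in BASES:
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1:]
            if code.is_stop(alt):
                continue
            nonstop += 1
            if code.synonymous(codon, alt):
                syn += 1
        if nonstop:
            s += syn / nonstop
    return s


@lru_cache(maxsize=None)
def _pathway_differences(c1: str, c2: str, code_id: int) -> tuple[float, float]:
    """(synonymous, nonsynonymous) differences between two codons.

    Averages over all orderings of single-base steps; pathways through stop
    codons are excluded. If every pathway is blocked (possible only for
    multi-step pairs hemmed in by stops), all pathways are used unweighted.
    """
    code = get_code(code_id)
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_pos:
        return 0.0, 0.0

    def walk(order):
        cur = c1
        sd = nd = 0
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if code.is_stop(nxt) and nxt != c2:
                return None
            if code.synonymous(cur, nxt):
                sd += 1
            else:
                nd += 1
            cur = nxt
        return sd, nd

    results = [r for r in (walk(o) for o in permutations(diff_pos)) if r is not None]
    if not results:
        results = []
        for order in permutations(diff_pos):
            cur = c1
            sd = nd = 0
            for pos in order:
                nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
                if code.synonymous(cur, nxt):
                    sd += 1
                else:
                    nd += 1
                cur = nxt
            results.append((sd, nd))
    sd = sum(r[0] for r in results) / len(results)
    nd = sum(r[1] for r in results) / len(results)
    return sd, nd


def jukes_cantor(p: float) -> float:
    """JC69 distance correction; raises SaturationError for p >= 3/4."""
    if p < 0:
        raise ValueError("proportion must be non-negative")
    if p >= 0.75:
        raise SaturationError(
            f"difference proportion {p:.3f} >= 0.75: correction undefined"
        )
    return -0.75 * math.log(1 - 4 * p / 3)


def nei_gojobori(seq_a: str, seq_b: str, code_id: int = 5) -> dict:
    """Pairwise Nei-Gojobori estimates: ka, ks, omega, N, S, pN, pS, Sd, Nd.

    Codons containing gaps or ambiguous bases in either sequence are skipped
    (codon-wise complete deletion). Codons that are stop codons in either
    sequence are likewise skipped.
    """
    a = seq_a.upper().replace("U", "T")
    b = seq_b.upper().replace("U", "T")
    if len(a) != len(b):
        raise ValueError("sequences must be aligned to equal length")
    if len(a) % 3:
        raise ValueError(f"alignment length {len(a)} not divisible by 3")
    code = get_code(code_id)

    S = N = Sd = Nd = 0.0
    codons = 0
    for i in range(0, len(a), 3):
        ca, cb = a[i:i + 3], b[i:i + 3]
        if not (set(ca) <= UNAMBIGUOUS and set(cb) <= UNAMBIGUOUS):
            continue
        if code.is_stop(ca) or code.is_stop(cb):
            continue
        codons += 1
        s = (_syn_site_fraction(ca, code_id) + _syn_site_fraction(cb, code_id)) / 2
        S += s
        N += 3 - s
        sd, nd = _pathway_differences(ca, cb, code_id)
        Sd += sd
        Nd += nd
    if codons == 0:
        raise ValueError("no comparable codons between the two sequences")

    pS = Sd / S if S else 0.0
    pN = Nd / N if N else 0.0
    ks = jukes_cantor(pS)
    ka = jukes_cantor(pN)
    omega = ka / ks if ks > 0 else None
    return {
        "ka": ka, "ks": ks, "omega": omega,
        "N": N, "S": S, "pN": pN, "pS": pS, "Sd": Sd, "Nd": Nd,
        "codons": codons,
    }


def estimate_divergence(aln: OrthologAlignmentSet, code_id: int = 5) -> DivergenceEstimate:
    """Per-gene estimate: pi plus mean pairwise Nei-Gojobori quantities.

    Multi-taxon ka/ks/omega are means over all unordered pairs; pairs with
    undefined omega (ks = 0) are dropped from the omega mean and counted.
    """
    pi = nucleotide_diversity(aln)
    pair_results = [
        nei_gojobori(a, b, code_id)
        for a, b in combinations(aln.sequences, 2)
    ]
    n_pairs = len(pair_results)

    def mean(key):
        return sum(r[key] for r in pair_results) / n_pairs

    omegas = [r["omega"] for r in pair_results if r["omega"] is not None]
    dropped = n_pairs - len(omegas)
    omega = sum(omegas) / len(omegas) if omegas else None
    return DivergenceEstimate(
        gene=aln.gene, pi=pi,
        ka=mean("ka"), ks=mean("ks"), omega=omega,
        N=mean("N"), S=mean("S"), pN=mean("pN"), pS=mean("pS"),
        n_pairs=n_pairs, dropped_pairs=dropped,
    )


def gene_panel(alignments: list[OrthologAlignmentSet], code_id: int = 5):
    """One row per gene: Pi, Ka, Ks, Ka/Ks plus conservation ranks (1 = most conserved)."""
    import pandas as pd

    if not alignments:
        raise ValueError("no alignments supplied")
    rows = []
    for aln in alignments:
        est = estimate_divergence(aln, code_id)
        rows.append({
            "gene": est.gene, "pi": est.pi, "ka": est.ka, "ks": est.ks,
            "ka_ks": est.omega, "N": est.N, "S": est.S,
            "n_pairs": est.n_pairs, "dropped_pairs": est.dropped_pairs,
        })
    df = pd.DataFrame(rows)
    df["rank_pi"] = df["pi"].rank(method="min").astype(int)
    df["rank_ka_ks"] = df["ka_ks"].rank(method="min")
    return df
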