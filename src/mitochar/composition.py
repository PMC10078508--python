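"""Base composition and strand-skew statistics.

AT-skew = (A - T) / (A + T) and GC-skew = (G - C) / (G + C), computed on a
stated strand. Skews are undefined (None) when the denominator is zero. N bases
are counted but excluded from skew denominators and percentage normalization
uses all counted bases including N.
"""

from __future__ import annotations

from dataclasses import dataclass

from .core import (
    CONTROL, PCG, RRNA, TRNA,
    MitogenomeRecord, reverse_complement,
)

GENOME = "genome"
CODON_POS = ("codon_pos_1", "codon_pos_2", "codon_pos_3")
CLASSES = (GENOME, PCG, TRNA, RRNA, CONTROL) + CODON_POS


@dataclass(frozen=True)
class CompositionProfile:
    counts: dict[str, int]  # A, T, G, C, N

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def fraction(self, base: str) -> float:
        """Percentage of this base among all counted bases."""
        return 100.0 * self.counts[base] / self.total

    @property
    def at_content(self) -> float:
        return self.fraction("A") + self.fraction("T")

    @property
    def at_skew(self) -> float | None:
        a, t = self.counts["A"], self.counts["T"]
        return (a - t) / (a + t) if a + t else None

    @property
    def gc_skew(self) -> float | None:
        g, c = self.counts["G"], self.counts["C"]
        return (g - c) / (g + c) if g + c else None

    def merge(self, other: "CompositionProfile") -> "CompositionProfile":
        """Count-weighted merge: the profile of the concatenation."""
        return CompositionProfile(
            {b: self.counts[b] + other.counts[b] for b in "ATGCN"}
        )


def composition_profile(seq: str) -> CompositionProfile:
    """Base counts/fractions and skews of a sequence on the given strand."""
    if not seq:
        raise ValueError("empty sequence")
    seq = seq.upper().replace("U", "T")
    counts = {b: seq.count(b) for b in "ATGCN"}
    if sum(counts.values()) != len(seq):
        bad = sorted(set(seq) - set("ATGCN"))
        raise ValueError(f"sequence contains non-nucleotide characters: {bad}")
    return CompositionProfile(counts)


def skew_from_fractions(a_pct: float, t_pct: float, g_pct: float, c_pct: float
                        ) -> tuple[float | None, float | None]:
    """(AT-skew, GC-skew) from base percentages, as printed in genome tables."""
    if min(a_pct, t_pct, g_pct, c_pct) < 0:
        raise ValueError("fractions must be non-negative")
    at = (a_pct - t_pct) / (a_pct + t_pct) if a_pct + t_pct else None
    gc = (g_pct - c_pct) / (g_pct + c_pct) if g_pct + c_pct else None
    return at, gc


def class_composition(m: MitogenomeRecord, cls: str) -> CompositionProfile:
    """Composition of a gene class, with an explicit strand convention per class.

    genome / control: J strand as stored. PCG and tRNA: sense (coding) strand,
    i.e. N-strand features reverse-complemented before concatenation. rRNA:
    sense strand of the rRNAs (the N strand in the typical insect arrangement),
    which is the strand on which published rRNA compositions are T-rich.
    Codon-position classes use complete codons of the coding strand only.
    """
    if m.sequence is None:
        raise ValueError("sequence required: this record carries coordinates only")
    if cls == GENOME:
        return composition_profile(m.sequence)
    if cls in (PCG, TRNA, RRNA, CONTROL):
        feats = m.by_category(cls)
        if not feats:
            raise ValueError(f"record has no {cls} features")
        if cls == CONTROL:
            parts = [
                m.sequence[f.start - 1: f.stop] if not f.wraps
                else m.sequence[f.start - 1:] + m.sequence[: f.stop]
                for f in feats
            ]
        else:
            parts = [m.extract(f) for f in feats]  # coding/sense strand
        return composition_profile("".join(parts))
    if cls in CODON_POS:
        pos = int(cls[-1]) - 1
        feats = m.by_category(PCG)
        if not feats:
            raise ValueError("record has no PCG features")
        bases = []
        for f in feats:
            cds = m.extract(f)
            n_codons = len(cds) // 3  # complete codons only
            bases.extend(cds[3 * i + pos] for i in range(n_codons))
        return composition_profile("".join(bases))
    raise ValueError(f"unknown composition class {cls!r}; choose from {CLASSES}")


def all_class_profiles(m: MitogenomeRecord) -> dict[str, CompositionProfile]:
    """Profiles for every class present in the record (skipping empty classes)."""
    out: dict[str, CompositionProfile] = {}
    for cls in CLASSES:
        try:
            out[cls] = class_composition(m, cls)
        except ValueError:
            continue
    return out


def profile_reverse_complement(p_seq: str) -> CompositionProfile:
    return composition_profile(reverse_complement(p_seq))
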