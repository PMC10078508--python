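"""Domain types and circular-genome layout arithmetic.

Coordinates are 1-based inclusive on the majority (J) strand, the convention of
published mitogenome annotation tables. Minority (N) strand features are stored
with start < stop in J-strand coordinates and reverse-complemented on sequence
extraction. A feature may wrap the circular origin, in which case ``start`` lies
near the end of the genome and ``stop`` near the beginning (``wraps=True``).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .genetic_codes import get_code

PCG = "PCG"
TRNA = "tRNA"
RRNA = "rRNA"
CONTROL = "control"
CATEGORIES = (PCG, TRNA, RRNA, CONTROL)

# canonical protein-coding gene tokens, alphabetical (the concatenation order)
CANONICAL_PCGS = (
    "atp6", "atp8", "cox1", "cox2", "cox3", "cytb",
    "nad1", "nad2", "nad3", "nad4", "nad4l", "nad5", "nad6",
)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def category_for_name(name: str) -> str:
    """Infer a feature category from a canonical gene token."""
    low = name.lower()
    if low.startswith("trn"):
        return TRNA
    if low.startswith("rrn"):
        return RRNA
    if low in ("d-loop", "dloop", "control", "at-rich", "a+t-rich"):
        return CONTROL
    return PCG


@dataclass(frozen=True)
class GeneFeature:
    """One annotated gene with strand and 1-based inclusive coordinates."""

    name: str
    strand: str  # "J" (majority) or "N" (minority)
    start: int
    stop: int
    category: str = ""
    anticodon: str | None = None
    wraps: bool = False  # feature spans the circular origin

    def __post_init__(self):
        if self.strand not in ("J", "N"):
            raise ValueError(f"{self.name}: strand must be J or N, got {self.strand!r}")
        if self.start < 1:
            raise ValueError(f"{self.name}: start must be >= 1, got {self.start}")
        if not self.wraps and self.stop < self.start:
            raise ValueError(
                f"{self.name}: stop {self.stop} < start {self.start} for a "
                "non-wrapping feature"
            )
        if not self.category:
            object.__setattr__(self, "category", category_for_name(self.name))
        if self.category not in CATEGORIES:
            raise ValueError(f"{self.name}: unknown category {self.category!r}")


def feature_length(f: GeneFeature, genome_length: int) -> int:
    """Feature size in bp on a circular genome of the given length."""
    if f.start > genome_length or f.stop > genome_length:
        raise ValueError(
            f"{f.name}: coordinates ({f.start}, {f.stop}) outside "
            f"[1, {genome_length}]"
        )
    if f.wraps:
        return (genome_length - f.start + 1) + f.stop
    return f.stop - f.start + 1


def intergenic(f_prev: GeneFeature, f_next: GeneFeature, genome_length: int | None = None) -> int:
    """Signed gap between adjacent features: positive = spacer, negative = overlap.

    Both strands share the J-strand coordinate system, so the computation is
    strand-agnostic. Pass ``genome_length`` to evaluate the wrap-around pair
    (last feature, first feature) across the circular origin.
    """
    if genome_length is not None:
        return f_next.start + genome_length - f_prev.stop - 1
    return f_next.start - f_prev.stop - 1


@dataclass
class MitogenomeRecord:
    """A circular mitogenome: sequence (optional), ordered features, metadata."""

    id: str
    length: int
    features: list[GeneFeature]
    sequence: str | None = None
    circular: bool = True

    def __post_init__(self):
        if self.sequence is not None:
            self.sequence = self.sequence.upper().replace("U", "T")
            if len(self.sequence) != self.length:
                raise ValueError(
                    f"sequence length {len(self.sequence)} != declared length {self.length}"
                )
            bad = set(self.sequence) - set("ACGTN")
            if bad:
                raise ValueError(f"sequence contains non-nucleotide characters: {sorted(bad)}")
        for f in self.features:
            if f.stop > self.length or f.start > self.length:
                raise ValueError(
                    f"feature {f.name} ({f.start}, {f.stop}) outside [1, {self.length}]"
                )
        self.features = sorted(self.features, key=lambda f: (f.start, f.stop))

    @property
    def complete(self) -> bool:
        """True for the canonical 37-gene set plus at least one control region."""
        counts = {cat: 0 for cat in CATEGORIES}
        for f in self.features:
            counts[f.category] += 1
        return (
            counts[PCG] == 13
            and counts[TRNA] == 22
            and counts[RRNA] == 2
            and counts[CONTROL] >= 1
        )

    def by_category(self, category: str) -> list[GeneFeature]:
        return [f for f in self.features if f.category == category]

    def get(self, name: str) -> GeneFeature:
        for f in self.features:
            if f.name == name:
                return f
        raise KeyError(name)

    def extract(self, f: GeneFeature) -> str:
        """Feature sequence 5'->3' on its coding strand."""
        if self.sequence is None:
            raise ValueError("sequence required: this record carries coordinates only")
        if f.wraps:
            raw = self.sequence[f.start - 1:] + self.sequence[: f.stop]
        else:
            raw = self.sequence[f.start - 1: f.stop]
        return reverse_complement(raw) if f.strand == "N" else raw


@dataclass
class GapRecord:
    prev: str
    next: str
    value: int  # positive spacer, negative overlap
    rrna_involved: bool


@dataclass
class LayoutReport:
    """Spacer/overlap accounting and strand tallies for a circular record.

    Gaps are always recomputed from coordinates; printed "intergenic" columns in
    annotation tables are display-only and frequently carry sign errors.
    Overlaps that involve an rRNA boundary are split out because rRNA ends are
    annotation-soft; headline statistics use the non-rRNA pairs.
    """

    genome_length: int
    sizes: dict[str, int]
    gaps: list[GapRecord]
    spacer_count: int = 0
    overlap_count: int = 0
    longest_spacer: tuple[str, str, int] | None = None
    longest_overlap: tuple[str, str, int] | None = None
    overlap_count_non_rrna: int = 0
    longest_overlap_non_rrna: tuple[str, str, int] | None = None
    rrna_overlaps: list[GapRecord] = field(default_factory=list)
    strand_tallies: dict[tuple[str, str], int] = field(default_factory=dict)

    @property
    def j_gene_count(self) -> int:
        """Genes on the J strand, excluding the control region."""
        return sum(
            n for (strand, cat), n in self.strand_tallies.items()
            if strand == "J" and cat != CONTROL
        )

    def conservation_residual(self) -> int:
        """Sigma(sizes) + Sigma(signed gaps) - genome length; 0 when the identity holds."""
        return sum(self.sizes.values()) + sum(g.value for g in self.gaps) - self.genome_length


def layout_report(m: MitogenomeRecord) -> LayoutReport:
    """Compute sizes, spacers/overlaps (incl. the wrap-around pair) and strand tallies."""
    feats = m.features
    if not feats:
        raise ValueError("record has no features")
    starts = [f.start for f in feats]
    if starts != sorted(starts):
        raise ValueError("features are not sorted by start position")

    sizes = {f.name: feature_length(f, m.length) for f in feats}

    gaps: list[GapRecord] = []
    for prev, nxt in zip(feats, feats[1:]):
        gaps.append(GapRecord(
            prev.name, nxt.name, intergenic(prev, nxt),
            rrna_involved=(prev.category == RRNA or nxt.category == RRNA),
        ))
    if m.circular and len(feats) > 1:
        prev, nxt = feats[-1], feats[0]
        gaps.append(GapRecord(
            prev.name, nxt.name, intergenic(prev, nxt, genome_length=m.length),
            rrna_involved=(prev.category == RRNA or nxt.category == RRNA),
        ))

    spacers = [g for g in gaps if g.value > 0]
    overlaps = [g for g in gaps if g.value < 0]
    non_rrna_overlaps = [g for g in overlaps if not g.rrna_involved]

    def _extreme(records, key):
        if not records:
            return None
        g = max(records, key=key)
        return (g.prev, g.next, g.value)

    tallies: dict[tuple[str, str], int] = {}
    for f in feats:
        key = (f.strand, f.category)
        tallies[key] = tallies.get(key, 0) + 1

    return LayoutReport(
        genome_length=m.length,
        sizes=sizes,
        gaps=gaps,
        spacer_count=len(spacers),
        overlap_count=len(overlaps),
        longest_spacer=_extreme(spacers, key=lambda g: g.value),
        longest_overlap=_extreme(overlaps, key=lambda g: -g.value),
        overlap_count_non_rrna=len(non_rrna_overlaps),
        longest_overlap_non_rrna=_extreme(non_rrna_overlaps, key=lambda g: -g.value),
        rrna_overlaps=[g for g in overlaps if g.rrna_involved],
        strand_tallies=tallies,
    )


@dataclass(frozen=True)
class CodonEndClassification:
    start_codon: str
    stop_codon: str  # TAA / TAG / "T--" / "TA-"
    complete: bool


class MalformedCdsError(ValueError):
    pass


def classify_ends(cds: str, code_id: int = 5) -> CodonEndClassification:
    """Classify the start codon and (possibly incomplete) stop codon of a CDS.

    The CDS is given 5'->3' on its coding strand. Lengths that are not a
    multiple of 3 must end in T (-> "T--") or TA (-> "TA-"): these truncated
    stops are completed to TAA by post-transcriptional polyadenylation and are
    flagged ``complete=False``.
    """
    cds = cds.upper().replace("U", "T")
    if len(cds) < 4:
        raise MalformedCdsError(f"CDS too short to classify ({len(cds)} bp)")
    code = get_code(code_id)
    start = cds[:3]
    rem = len(cds) % 3
    if rem == 1:
        if cds[-1] != "T":
            raise MalformedCdsError(
                f"CDS length mod 3 == 1 but trailing base is {cds[-1]!r}, not T"
            )
        return CodonEndClassification(start, "T--", complete=False)
    if rem == 2:
        if cds[-2:] != "TA":
            raise MalformedCdsError(
                f"CDS length mod 3 == 2 but trailing bases are {cds[-2:]!r}, not TA"
            )
        return CodonEndClassification(start, "TA-", complete=False)
    last = cds[-3:]
    if not code.is_stop(last):
        raise MalformedCdsError(
            f"in-frame CDS does not end in a stop codon (last triplet {last})"
        )
    return CodonEndClassification(start, last, complete=True)


def normalize_feature(name, strand, start, stop, **kw) -> GeneFeature:
    """Build a GeneFeature from table-style coordinates.

    Published tables print N-strand features with start > stop (the 5' end on
    the minority strand); these are normalized to start < stop in J-strand
    coordinates.
    """
    if strand == "N" and start > stop:
        start, stop = stop, start
    return GeneFeature(name=name, strand=strand, start=start, stop=stop, **kw)
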