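"""Supermatrix construction and partition export for phylogenomic inference.

The pipeline prepares the inputs downstream tree software consumes: per-gene
codon alignments are stripped of terminal stop codons, filtered codon-column by
codon-column on gap/ambiguity content, and concatenated in canonical gene order
with a partition table. A neighbor-joining distance tree is provided as a
sanity check only; real inference (BI/ML) is out of scope.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from io import StringIO
from itertools import combinations

from .core import CANONICAL_PCGS
from .divergence import GAP_CHARS, UNAMBIGUOUS, OrthologAlignmentSet
from .genetic_codes import get_code


class FrameError(ValueError):
    pass


def strip_stops(aln: OrthologAlignmentSet, code_id: int = 5) -> OrthologAlignmentSet:
    """Remove the terminal stop-codon column triplet; reject internal stops.

    The last codon column is removed when every sequence with bases there ends
    in a stop codon. An internal stop in any sequence is a frame error naming
    the taxon and codon position.
    """
    code = get_code(code_id)
    n_codons = aln.length // 3
    for taxon, seq in zip(aln.taxa, aln.sequences):
        for i in range(n_codons - 1):
            codon = seq[3 * i: 3 * i + 3]
            if set(codon) <= UNAMBIGUOUS and code.is_stop(codon):
                raise FrameError(
                    f"internal stop codon {codon} in taxon {taxon!r} "
                    f"at codon {i + 1} of gene {aln.gene}"
                )
    last = [seq[-3:] for seq in aln.sequences]
    informative = [c for c in last if not (set(c) & GAP_CHARS)]
    if informative and all(
        set(c) <= UNAMBIGUOUS and code.is_stop(c) for c in informative
    ):
        return OrthologAlignmentSet(
            gene=aln.gene, taxa=list(aln.taxa),
            sequences=[s[:-3] for s in aln.sequences],
        )
    return OrthologAlignmentSet(
        gene=aln.gene, taxa=list(aln.taxa), sequences=list(aln.sequences)
    )


def filter_columns(aln: OrthologAlignmentSet, max_gap_fraction: float = 0.0
                   ) -> OrthologAlignmentSet:
    """Drop whole codon columns whose gap/ambiguity fraction exceeds the cap.

    A codon column counts a sequence as gapped when any of its three bases is a
    gap or ambiguity character. The strict default (0) removes every column
    with any gap, the honest stand-in for block-based filtering whose published
    parameters are unreported. Frame is preserved (columns leave in triplets).
    """
    if not 0 <= max_gap_fraction <= 1:
        raise ValueError("max_gap_fraction must be in [0, 1]")
    n_seq = len(aln.sequences)
    keep: list[int] = []
    for i in range(0, aln.length, 3):
        n_bad = sum(
            1 for seq in aln.sequences
            if set(seq[i:i + 3]) - UNAMBIGUOUS
        )
        if n_bad / n_seq <= max_gap_fraction:
            keep.append(i)
    return OrthologAlignmentSet(
        gene=aln.gene, taxa=list(aln.taxa),
        sequences=["".join(seq[i:i + 3] for i in keep) for seq in aln.sequences],
    )


@dataclass
class Supermatrix:
    taxa: list[str]
    sequences: list[str]  # one row per taxon, equal lengths
    partitions: list[tuple[str, int, int]]  # (gene, start, end) 1-based inclusive

    def __post_init__(self):
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            raise ValueError("supermatrix rows differ in length")
        # partitions must tile [1, L]
        expected = 1
        for gene, start, end in self.partitions:
            if start != expected or end < start:
                raise ValueError(
                    f"partitions do not tile the matrix: {gene} at ({start}, {end}), "
                    f"expected start {expected}"
                )
            expected = end + 1
        if self.sequences and expected != len(self.sequences[0]) + 1:
            raise ValueError("partitions do not cover the full matrix length")

    @property
    def length(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0


def concatenate(alignments: list[OrthologAlignmentSet],
                taxa: list[str] | None = None) -> Supermatrix:
    """Concatenate per-gene alignments in canonical PCG order.

    Genes not in the canonical list follow it alphabetically. A taxon missing
    from a gene gets an all-gap block, so every row has equal length.
    """
    if not alignments:
        raise ValueError("no alignments supplied")
    order = {g: i for i, g in enumerate(CANONICAL_PCGS)}
    alignments = sorted(
        alignments, key=lambda a: (order.get(a.gene, len(order)), a.gene)
    )
    if taxa is None:
        seen: list[str] = []
        for aln in alignments:
            for t in aln.taxa:
                if t not in seen:
                    seen.append(t)
        taxa = seen
    if len(set(taxa)) != len(taxa):
        raise ValueError("duplicate taxon labels")

    rows = {t: [] for t in taxa}
    partitions = []
    offset = 0
    for aln in alignments:
        lookup = dict(zip(aln.taxa, aln.sequences))
        for t in taxa:
            rows[t].append(lookup.get(t, "-" * aln.length))
        partitions.append((aln.gene, offset + 1, offset + aln.length))
        offset += aln.length
    return Supermatrix(
        taxa=list(taxa),
        sequences=["".join(rows[t]) for t in taxa],
        partitions=partitions,
    )


def raxml_partitions(sm: Supermatrix) -> str:
    return "".join(
        f"DNA, {gene} = {start}-{end}\n" for gene, start, end in sm.partitions
    )


def nexus_sets_block(sm: Supermatrix) -> str:
    lines = ["#NEXUS", "begin sets;"]
    for gene, start, end in sm.partitions:
        lines.append(f"    charset {gene} = {start}-{end};")
    lines.append("end;")
    return "\n".join(lines) + "\n"


def write_phylip(sm: Supermatrix) -> str:
    """Relaxed PHYLIP (names and sequences whitespace-separated)."""
    out = [f"{len(sm.taxa)} {sm.length}"]
    for t, s in zip(sm.taxa, sm.sequences):
        out.append(f"{t}  {s}")
    return "\n".join(out) + "\n"


def write_fasta_matrix(sm: Supermatrix) -> str:
    return "".join(f">{t}\n{s}\n" for t, s in zip(sm.taxa, sm.sequences))


def pairwise_distance(a: str, b: str, model: str = "p-distance") -> float:
    """p-distance or JC distance with site-wise pairwise deletion."""
    d = L = 0
    for x, y in zip(a, b):
        if x in UNAMBIGUOUS and y in UNAMBIGUOUS:
            L += 1
            if x != y:
                d += 1
    if L == 0:
        raise ValueError("no comparable sites")
    p = d / L
    if model == "p-distance":
        return p
    if model == "JC":
        if p >= 0.75:
            raise ValueError(f"p-distance {p:.3f} saturates the JC correction")
        return -0.75 * math.log(1 - 4 * p / 3)
    raise ValueError(f"unknown model {model!r}")


def nj_tree(taxa: list[str], dist: list[list[float]]) -> str:
    """Neighbor-joining tree (Newick) from a full distance matrix.

    Ties break deterministically by taxon-label order (Biopython's NJ is
    deterministic given matrix order; taxa are passed in label order). Negative
    branch lengths are clamped to zero.
    """
    from Bio.Phylo import write as phylo_write
    from Bio.Phylo.TreeConstruction import DistanceMatrix, DistanceTreeConstructor

    if len(taxa) < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    lower = [[dist[i][j] for j in range(i + 1)] for i in range(len(taxa))]
    dm = DistanceMatrix(names=list(taxa), matrix=lower)
    tree = DistanceTreeConstructor().nj(dm)
    for clade in tree.find_clades():
        if clade.branch_length is not None and clade.branch_length < 0:
            clade.branch_length = 0.0
        if clade.name and clade.name.startswith("Inner"):
            clade.name = None  # drop synthetic internal labels
    buf = StringIO()
    phylo_write(tree, buf, "newick")
    return buf.getvalue().strip()


def distance_tree(sm: Supermatrix, model: str = "p-distance") -> str:
    """NJ sanity-check tree from the supermatrix under p-distance or JC."""
    n = len(sm.taxa)
    dist = [[0.0] * n for _ in range(n)]
    for i, j in combinations(range(n), 2):
        d = pairwise_distance(sm.sequences[i], sm.sequences[j], model)
        dist[i][j] = dist[j][i] = d
    return nj_tree(sm.taxa, dist)
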