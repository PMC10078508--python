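"""Codon counting, RSCU, and amino-acid composition for protein-coding gene sets.

RSCU (relative synonymous codon usage) for codon c of amino acid aa:

    RSCU_c = n_c * d_aa / sum(n_c' for c' synonymous with c)

where d_aa is the codon-family degeneracy. Uniform use within a family gives
RSCU = 1 for each member; the family's RSCU values always sum to d_aa.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .genetic_codes import BASES, GeneticCode, get_code

ALL_CODONS = tuple(a + b + c for a in BASES for b in BASES for c in BASES)


def dna_to_rna(codon: str) -> str:
    """Report codons RNA-style (UUA) to match figure conventions."""
    return codon.replace("T", "U")


@dataclass
class CodonUsageTable:
    code: GeneticCode
    counts: dict[str, int]  # DNA-style codons, stops excluded from counting

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def frequency(self, codon: str) -> float:
        """Percent of total counted codons."""
        if self.total == 0:
            raise ValueError("empty codon table")
        return 100.0 * self.counts.get(codon, 0) / self.total


def count_codons(cds_set: list[str] | str, code_id: int = 5) -> CodonUsageTable:
    """Pool codon counts across a set of in-frame coding-strand CDS.

    Only complete codons are counted; stop codons (terminal or otherwise) and
    trailing incomplete codons (truncated T-- / TA- stops) are excluded.
    """
    if isinstance(cds_set, str):
        cds_set = [cds_set]
    code = get_code(code_id)
    counts: dict[str, int] = {}
    any_codon = False
    for cds in cds_set:
        cds = cds.upper().replace("U", "T")
        if len(cds) < 3:
            raise ValueError(f"CDS shorter than one codon ({len(cds)} bp)")
        for i in range(0, len(cds) - len(cds) % 3, 3):
            codon = cds[i:i + 3]
            any_codon = True
            if codon not in ALL_CODONS:  # ambiguous bases
                continue
            if code.is_stop(codon):
                continue
            counts[codon] = counts.get(codon, 0) + 1
    if not any_codon:
        raise ValueError("no complete codons in input")
    return CodonUsageTable(code=code, counts=counts)


def rscu(table: CodonUsageTable) -> dict[str, float | None]:
    """Per-codon RSCU; None for codons of families with zero total occurrences.

    Stop codons are not part of any family and are omitted.
    """
    code = table.code
    families: dict[str, list[str]] = {}
    for codon in ALL_CODONS:
        aa = code.translate(codon)
        if aa == "*":
            continue
        families.setdefault(aa, []).append(codon)
    out: dict[str, float | None] = {}
    for aa, codons in families.items():
        family_total = sum(table.counts.get(c, 0) for c in codons)
        d = len(codons)
        for c in codons:
            if family_total == 0:
                out[c] = None
            else:
                out[c] = table.counts.get(c, 0) * d / family_total
    return out


def amino_acid_usage(table: CodonUsageTable) -> dict[str, float]:
    """Percent of total codons per amino acid (stops already excluded)."""
    if table.total == 0:
        raise ValueError("empty codon table")
    usage: dict[str, float] = {}
    for codon, n in table.counts.items():
        aa = table.code.translate(codon)
        usage[aa] = usage.get(aa, 0.0) + n
    return {aa: 100.0 * n / table.total for aa, n in usage.items()}


def usage_dataframe(table: CodonUsageTable):
    """Tidy per-codon table: codon (RNA-style), aa, count, frequency_pct, RSCU."""
    import pandas as pd

    rscu_map = rscu(table)
    rows = []
    for codon in ALL_CODONS:
        aa = table.code.translate(codon)
        if aa == "*":
            continue
        rows.append({
            "codon": dna_to_rna(codon),
            "aa": aa,
            "count": table.counts.get(codon, 0),
            "frequency_pct": table.frequency(codon),
            "rscu": rscu_map[codon],
        })
    return pd.DataFrame(rows)
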