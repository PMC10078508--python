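"""Genetic code tables for codon-level statistics.

The invertebrate mitochondrial code (NCBI translation table 5) is the default
throughout the package and is embedded verbatim so the core statistics do not
depend on any external table at run time. Any other NCBI table id is resolved
through Biopython.
"""

from __future__ import annotations

from functools import lru_cache

STOP = "*"

BASES = "TCAG"

# NCBI translation table 5 (invertebrate mitochondrial):
# ATA=Met, TGA=Trp, AGA/AGG=Ser; stops are TAA and TAG only.
INVERTEBRATE_MITO: dict[str, str] = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "M", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": STOP, "TAG": STOP,
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "W", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "S", "AGG": "S",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


class GeneticCode:
    """A forward codon->amino-acid map with stop-aware helpers."""

    def __init__(self, code_id: int, table: dict[str, str]):
        if len(table) != 64:
            raise ValueError(f"genetic code table must have 64 codons, got {len(table)}")
        self.id = code_id
        self.table = dict(table)
        self.stop_codons = frozenset(c for c, aa in table.items() if aa == STOP)
        # codon-family degeneracy: number of synonymous codons per amino acid
        self.degeneracy: dict[str, int] = {}
        for aa in table.values():
            if aa != STOP:
                self.degeneracy[aa] = self.degeneracy.get(aa, 0) + 1

    def translate(self, codon: str) -> str:
        """Amino acid for a codon; '*' for stops; 'X' for ambiguous codons."""
        return self.table.get(codon.upper().replace("U", "T"), "X")

    def is_stop(self, codon: str) -> bool:
        return codon.upper().replace("U", "T") in self.stop_codons

    def synonymous(self, codon_a: str, codon_b: str) -> bool:
        return self.translate(codon_a) == self.translate(codon_b)


@lru_cache(maxsize=None)
def get_code(code_id: int = 5) -> GeneticCode:
    """Return the genetic code for an NCBI translation table id (default 5)."""
    if code_id == 5:
        return GeneticCode(5, INVERTEBRATE_MITO)
    from Bio.Data import CodonTable

    try:
        bio = CodonTable.unambiguous_dna_by_id[code_id]
    except KeyError as exc:
        raise ValueError(f"unknown NCBI translation table id: {code_id}") from exc
    table = dict(bio.forward_table)
    for stop in bio.stop_codons:
        table[stop] = STOP
    return GeneticCode(code_id, table)
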