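"""Readers and writers for the formats the pipeline touches.

GenBank and FASTA go through Biopython; the tab-separated feature table mirrors
the layout of published mitogenome annotation tables (name, strand J/N, start,
stop, 1-based inclusive, with N-strand rows allowed to print start > stop).
"""

from __future__ import annotations

import csv
import json
import logging
import math
from importlib import resources
from pathlib import Path

from .core import (
    CONTROL, GeneFeature, MitogenomeRecord, category_for_name, normalize_feature,
)
from .divergence import OrthologAlignmentSet

log = logging.getLogger("mitochar")

# canonical lower-case tokens for the usual aliases found in GenBank records
SYNONYMS = {
    "coi": "cox1", "co1": "cox1", "coxi": "cox1",
    "coii": "cox2", "co2": "cox2", "coxii": "cox2",
    "coiii": "cox3", "co3": "cox3", "coxiii": "cox3",
    "cob": "cytb", "cytochrome b": "cytb", "cyt b": "cytb",
    "nd1": "nad1", "nd2": "nad2", "nd3": "nad3", "nd4": "nad4",
    "nd4l": "nad4l", "nd5": "nad5", "nd6": "nad6",
    "atpase6": "atp6", "atpase8": "atp8", "atp synthase f0 subunit 6": "atp6",
    "atp synthase f0 subunit 8": "atp8",
    "16s": "rrnL", "16s rrna": "rrnL", "l-rrna": "rrnL", "lrrna": "rrnL",
    "large subunit ribosomal rna": "rrnL", "rrnl": "rrnL",
    "12s": "rrnS", "12s rrna": "rrnS", "s-rrna": "rrnS", "srrna": "rrnS",
    "small subunit ribosomal rna": "rrnS", "rrns": "rrnS",
    "d-loop": "d-loop", "dloop": "d-loop", "control region": "d-loop",
    "a+t-rich region": "d-loop", "at-rich region": "d-loop",
}

_KNOWN = {
    *(f"nad{i}" for i in range(1, 7)), "nad4l",
    "cox1", "cox2", "cox3", "cytb", "atp6", "atp8", "rrnL", "rrnS", "d-loop",
}


_AA3 = {
    "ala": "A", "arg": "R", "asn": "N", "asp": "D", "cys": "C", "gln": "Q",
    "glu": "E", "gly": "G", "his": "H", "ile": "I", "leu": "L", "lys": "K",
    "met": "M", "phe": "F", "pro": "P", "ser": "S", "thr": "T", "trp": "W",
    "tyr": "Y", "val": "V",
}


def canonical_name(raw: str) -> str:
    """Map a raw gene label to the canonical token; unknown labels pass through."""
    import re

    key = raw.strip().lower()
    m = re.fullmatch(r"trn([a-z])([12])?", key)
    if m:
        # one-letter amino-acid code with optional L1/L2/S1/S2 disambiguation
        return "trn" + m.group(1).upper() + (m.group(2) or "")
    m = re.fullmatch(r"trna[-_ ]([a-z]{3})\s*(?:\(\w+\))?", key)
    if m and m.group(1) in _AA3:
        return "trn" + _AA3[m.group(1)]
    if key in _KNOWN:
        return "rrnL" if key == "rrnl" else "rrnS" if key == "rrns" else key
    if key in SYNONYMS:
        return SYNONYMS[key]
    log.warning("unknown gene name %r kept as-is", raw)
    return raw.strip()


def _clean_sequence(seq: str) -> str:
    seq = seq.upper().replace("U", "T")
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValueError(f"sequence contains characters outside ACGTN: {sorted(bad)}")
    return seq


def read_fasta(path) -> dict[str, str]:
    from Bio import SeqIO

    out = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        out[rec.id] = _clean_sequence(str(rec.seq))
    if not out:
        raise ValueError(f"no FASTA records in {path}")
    return out


def write_fasta(seqs: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i:i + 70] + "\n")


def read_alignment_fasta(path, gene: str | None = None) -> OrthologAlignmentSet:
    seqs = read_fasta(path)
    gene = gene or Path(str(path)).stem
    return OrthologAlignmentSet(
        gene=gene, taxa=list(seqs), sequences=list(seqs.values())
    )


# --- feature table dialect ---------------------------------------------------

def read_feature_table(table_path, fasta_path=None, record_id: str = "record"
                       ) -> MitogenomeRecord:
    """Read the TSV feature-table dialect, optionally with a genome FASTA.

    Without a FASTA the record is sequence-free (layout/length analyses only)
    and the genome length is inferred from the maximum coordinate.
    """
    rows = []
    with open(table_path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or "name" not in reader.fieldnames:
            raise ValueError(f"{table_path}: missing header row with 'name' column")
        for row in reader:
            rows.append(row)
    if not rows:
        raise ValueError(f"{table_path}: empty feature table")

    features = []
    for row in rows:
        strand = row["strand"].strip()
        if strand not in ("J", "N"):
            raise ValueError(f"{row['name']}: strand token must be J or N, got {strand!r}")
        try:
            start, stop = int(row["start"]), int(row["stop"])
        except ValueError as exc:
            raise ValueError(f"{row['name']}: non-integer coordinates") from exc
        features.append(normalize_feature(
            name=canonical_name(row["name"]), strand=strand, start=start, stop=stop,
        ))

    sequence = None
    if fasta_path is not None:
        seqs = read_fasta(fasta_path)
        sequence = next(iter(seqs.values()))
        length = len(sequence)
    else:
        length = max(max(f.start, f.stop) for f in features)
    return MitogenomeRecord(
        id=record_id, length=length, features=features, sequence=sequence
    )


def write_feature_table(record: MitogenomeRecord, path) -> None:
    """Write the dialect; N-strand rows print 5'-end first (start > stop)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["name", "strand", "start", "stop"])
        for f in record.features:
            if f.strand == "N" and not f.wraps:
                writer.writerow([f.name, f.strand, f.stop, f.start])
            else:
                writer.writerow([f.name, f.strand, f.start, f.stop])


# --- GenBank -----------------------------------------------------------------

_GB_TYPES = {"CDS", "tRNA", "rRNA", "D-loop", "misc_feature"}


def read_genbank(path) -> MitogenomeRecord:
    from Bio import SeqIO

    rec = SeqIO.read(str(path), "genbank")
    length = len(rec.seq)
    features = []
    seen = set()
    for feat in rec.features:
        if feat.type not in _GB_TYPES:
            continue
        quals = feat.qualifiers
        raw = (quals.get("gene") or quals.get("product") or quals.get("note") or [feat.type])[0]
        name = canonical_name(raw)
        if feat.type == "D-loop":
            name = "d-loop"
        if name in seen:
            raise ValueError(f"duplicate canonical gene name {name!r} in {path}")
        seen.add(name)
        strand = "N" if feat.location.strand == -1 else "J"
        parts = feat.location.parts
        if len(parts) > 1 and int(parts[0].end) == length and int(parts[-1].start) == 0:
            # join(a..length, 1..b): wraps the circular origin
            feature = GeneFeature(
                name=name, strand=strand,
                start=int(parts[0].start) + 1, stop=int(parts[-1].end),
                category=_category_from(feat.type, name), wraps=True,
            )
        else:
            feature = normalize_feature(
                name=name, strand=strand,
                start=int(feat.location.start) + 1, stop=int(feat.location.end),
                category=_category_from(feat.type, name),
            )
        features.append(feature)
    return MitogenomeRecord(
        id=rec.id or "record", length=length,
        features=features, sequence=_clean_sequence(str(rec.seq)),
    )


def _category_from(feat_type: str, name: str) -> str:
    if feat_type == "CDS":
        return "PCG"
    if feat_type == "tRNA":
        return "tRNA"
    if feat_type == "rRNA":
        return "rRNA"
    if feat_type == "D-loop":
        return CONTROL
    return category_for_name(name)


def write_genbank(record: MitogenomeRecord, path) -> None:
    from Bio.Seq import Seq
    from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
    from Bio.SeqRecord import SeqRecord
    from Bio import SeqIO

    if record.sequence is None:
        raise ValueError("sequence required to write GenBank")
    seqrec = SeqRecord(
        Seq(record.sequence), id=record.id, name=record.id[:16],
        description="synthetic mitogenome",
        annotations={"molecule_type": "DNA", "topology": "circular"},
    )
    type_for = {"PCG": "CDS", "tRNA": "tRNA", "rRNA": "rRNA", CONTROL: "D-loop"}
    for f in record.features:
        strand = -1 if f.strand == "N" else 1
        if f.wraps:
            loc = CompoundLocation([
                SimpleLocation(f.start - 1, record.length, strand),
                SimpleLocation(0, f.stop, strand),
            ])
        else:
            loc = SimpleLocation(f.start - 1, f.stop, strand)
        seqrec.features.append(SeqFeature(
            loc, type=type_for[f.category], qualifiers={"gene": [f.name]}
        ))
    SeqIO.write(seqrec, str(path), "genbank")


# --- reference architecture (bundled annotation table) -----------------------

def load_reference_rows() -> list[dict]:
    """The bundled drywood-termite mitogenome annotation table, verbatim."""
    text = resources.files("mitochar.data").joinpath(
        "cdomesticus_features.tsv").read_text()
    reader = csv.DictReader(text.splitlines(), delimiter="\t")
    return list(reader)


def load_reference_record() -> MitogenomeRecord:
    """Sequence-free record of the bundled reference architecture."""
    features = [
        normalize_feature(
            name=canonical_name(r["name"]), strand=r["strand"],
            start=int(r["start"]), stop=int(r["stop"]),
        )
        for r in load_reference_rows()
    ]
    length = max(max(f.start, f.stop) for f in features)
    return MitogenomeRecord(
        id="reference", length=length, features=features, sequence=None
    )


# --- tabular/JSON output -----------------------------------------------------

def format_value(v, float_dp: int = 2):
    if v is None:
        return "NA"
    if isinstance(v, float):
        if math.isnan(v):
            return "NA"
        return f"{v:.{float_dp}f}"
    return str(v)


def write_tsv(rows: list[dict], path, float_dp: int = 2) -> None:
    """Deterministic TSV: column order from the first row, NA for missing values."""
    if not rows:
        raise ValueError("no rows to write")
    columns = list(rows[0])
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(columns)
        for row in rows:
            writer.writerow([format_value(row.get(c), float_dp) for c in columns])


def _sanitize(obj):
    """NaN -> null so the JSON stays standard-compliant."""
    if isinstance(obj, float) and math.isnan(obj):
        return None
    if isinstance(obj, dict):
        return {k: _sanitize(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_sanitize(v) for v in obj]
    return obj


def write_json(payload, path) -> None:
    with open(path, "w") as fh:
        json.dump(_sanitize(payload), fh, indent=2, sort_keys=True)
        fh.write("\n")
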