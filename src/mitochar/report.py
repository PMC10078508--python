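"""Orchestration: one call characterizes a genome the way a mitogenome paper does.

The report bundle mirrors the structure of a genome-description results
section: an annotation table with recomputed sizes and intergenic values, a
composition/skew table per gene class, codon usage with RSCU, the
spacer/overlap summary, the control-region repeat report, and (when ortholog
alignments are supplied) a per-gene divergence panel. Stages that need the
nucleotide sequence are skipped with an explicit notice when only a coordinate
table is available. Every number in the tabular outputs is also present in the
machine-readable JSON.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

from . import codons, composition, divergence, formats, repeats
from .core import CONTROL, MitogenomeRecord, feature_length, intergenic, layout_report


@dataclass
class RunConfig:
    genetic_code: int = 5
    rounding: int = 2
    min_repeat_len: int = 9
    seed: int = 0
    out_dir: str | None = None
    inputs: dict = field(default_factory=dict)


def _feature_rows(m: MitogenomeRecord) -> list[dict]:
    rows = []
    feats = m.features
    for i, f in enumerate(feats):
        if i + 1 < len(feats):
            gap = intergenic(f, feats[i + 1])
        elif m.circular and len(feats) > 1:
            gap = intergenic(f, feats[0], genome_length=m.length)
        else:
            gap = None
        rows.append({
            "name": f.name, "category": f.category, "strand": f.strand,
            "start": f.start, "stop": f.stop,
            "size_bp": feature_length(f, m.length),
            "intergenic_bp": gap,
        })
    return rows


def _composition_rows(m: MitogenomeRecord) -> list[dict]:
    rows = []
    for cls, prof in composition.all_class_profiles(m).items():
        rows.append({
            "class": cls,
            "length_bp": prof.total,
            "A_pct": prof.fraction("A"), "T_pct": prof.fraction("T"),
            "G_pct": prof.fraction("G"), "C_pct": prof.fraction("C"),
            "AT_pct": prof.at_content,
            "at_skew": prof.at_skew, "gc_skew": prof.gc_skew,
        })
    return rows


def characterize(m: MitogenomeRecord, alignments=None,
                 config: RunConfig | None = None) -> dict:
    """Full characterization report as a nested dict (the report bundle)."""
    cfg = config or RunConfig()
    report: dict = {"record_id": m.id, "config": asdict(cfg), "skipped": []}

    lay = layout_report(m)
    report["features"] = _feature_rows(m)
    report["layout"] = {
        "genome_length": lay.genome_length,
        "n_features": len(m.features),
        "complete": m.complete,
        "spacer_count": lay.spacer_count,
        "overlap_count": lay.overlap_count,
        "overlap_count_non_rrna": lay.overlap_count_non_rrna,
        "longest_spacer": lay.longest_spacer,
        "longest_overlap": lay.longest_overlap,
        "longest_overlap_non_rrna": lay.longest_overlap_non_rrna,
        "rrna_overlaps": [[g.prev, g.next, g.value] for g in lay.rrna_overlaps],
        "strand_tallies": {f"{s}:{c}": n for (s, c), n in sorted(lay.strand_tallies.items())},
        "j_gene_count": lay.j_gene_count,
        "conservation_residual": lay.conservation_residual(),
    }

    if m.sequence is None:
        report["skipped"].extend([
            {"stage": s, "reason": "sequence required"}
            for s in ("composition", "codon_usage", "repeats")
        ])
    else:
        report["composition"] = _composition_rows(m)

        pcg_feats = m.by_category("PCG")
        if pcg_feats:
            table = codons.count_codons([m.extract(f) for f in pcg_feats],
                                        cfg.genetic_code)
            usage = codons.usage_dataframe(table)
            report["codon_usage"] = {
                "total_codons": table.total,
                "genetic_code": cfg.genetic_code,
                "codons": usage.to_dict(orient="records"),
                "amino_acid_pct": codons.amino_acid_usage(table),
            }
        else:
            report["skipped"].append({"stage": "codon_usage", "reason": "no PCG features"})

        control = m.by_category(CONTROL)
        if control:
            f = control[0]
            region = (m.sequence[f.start - 1:] + m.sequence[:f.stop]) if f.wraps \
                else m.sequence[f.start - 1: f.stop]
            hits = repeats.find_repeats(region, cfg.min_repeat_len)
            report["repeats"] = [
                {"motif": h.motif, "length": h.length, "copy_number": h.copy_number,
                 "positions": list(h.positions), "tandem": h.tandem}
                for h in hits
            ]
        else:
            report["skipped"].append({"stage": "repeats", "reason": "no control region"})

    if alignments:
        panel = divergence.gene_panel(list(alignments), cfg.genetic_code)
        report["divergence"] = panel.to_dict(orient="records")
    else:
        report["skipped"].append({"stage": "divergence", "reason": "no alignments supplied"})

    return report


def validate_report(report: dict) -> None:
    """Structural check against the shipped report schema (required keys only)."""
    import json
    from importlib import resources

    schema = json.loads(resources.files("mitochar.data")
                        .joinpath("report.schema.json").read_text())

    def check(obj, sch, where):
        for key in sch.get("required", []):
            if key not in obj:
                raise ValueError(f"report invalid: missing {where}{key}")
        for key, sub in sch.get("properties", {}).items():
            if key in obj and sub.get("type") == "object":
                check(obj[key], sub, f"{where}{key}.")
            if key in obj and sub.get("type") == "array" and "items" in sub:
                for i, item in enumerate(obj[key]):
                    check(item, sub["items"], f"{where}{key}[{i}].")

    check(report, schema, "")


def write_report_bundle(report: dict, out_dir, float_dp: int = 2) -> list[Path]:
    """Write the bundle: one TSV per tabular section plus the full JSON."""
    validate_report(report)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []

    def tsv(name, rows):
        path = out / f"{name}.tsv"
        formats.write_tsv(rows, path, float_dp)
        written.append(path)

    tsv("features", report["features"])
    if "composition" in report:
        tsv("composition", report["composition"])
    if "codon_usage" in report:
        tsv("codon_usage", report["codon_usage"]["codons"])
    if report.get("repeats"):
        tsv("repeats", [
            {k: (",".join(map(str, v)) if isinstance(v, list) else v)
             for k, v in row.items()}
            for row in report["repeats"]
        ])
    if "divergence" in report:
        tsv("divergence", report["divergence"])
    json_path = out / "report.json"
    formats.write_json(report, json_path)
    written.append(json_path)
    return written
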