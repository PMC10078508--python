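"""Synthetic mitogenomes and diverged ortholog panels.

The genome generator emits a fully specified circular mitogenome following a
real 38-feature annotation architecture (13 PCGs, 22 tRNAs, 2 rRNAs, control
region, both strands, genuine overlaps), with a stated target base composition,
valid ATN/GTG starts, complete or truncated (T--/TA-) stops, no internal stops
under the invertebrate mitochondrial code, and planted control-region repeats.
Every generated parameter is returned as a truth record so downstream
statistics can be checked in a closed loop.

The ortholog simulator is a rejection sampler, not a codon-model matrix
exponential: single-base proposals are accepted with relative probability
omega for nonsynonymous changes and 1 for synonymous ones, stops are rejected,
and realized counts are recorded as truth. That is sufficient (and fully
specifiable) for estimator-recovery tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .core import (
    CONTROL, PCG,
    GeneFeature, MitogenomeRecord, classify_ends, normalize_feature,
    reverse_complement,
)
from .divergence import OrthologAlignmentSet
from .formats import canonical_name, load_reference_rows
from .genetic_codes import get_code
from .repeats import find_repeats

_COMP = {"A": "T", "T": "A", "G": "C", "C": "G"}

# whole-genome base composition of the reference drywood-termite mitogenome (%)
DEFAULT_FRACTIONS = {"A": 41.8, "T": 24.9, "G": 12.3, "C": 21.0}


@dataclass(frozen=True)
class RepeatSpec:
    motif_len: int
    copies: int
    tandem: bool


# an 89-bp motif duplicated with a spacer, plus a 9-bp tandem duplication:
# the repeat structure reported for the reference control region
DEFAULT_REPEATS = (RepeatSpec(89, 2, False), RepeatSpec(9, 2, True))


@dataclass
class GenomeTemplate:
    """Architecture + targets for one synthetic genome; identical seed => identical genome."""

    rows: list[dict] = field(default_factory=load_reference_rows)
    base_fractions: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_FRACTIONS))
    repeats: tuple[RepeatSpec, ...] = DEFAULT_REPEATS
    seed: int = 0
    code_id: int = 5
    id: str = "synthetic"


class TemplateError(ValueError):
    pass


def _parse_features(rows) -> list[GeneFeature]:
    feats = []
    for r in rows:
        feats.append(normalize_feature(
            name=canonical_name(r["name"]), strand=r["strand"],
            start=int(r["start"]), stop=int(r["stop"]),
        ))
    return feats


def _base_probs(fractions) -> tuple[list[str], np.ndarray]:
    bases = ["A", "T", "G", "C"]
    p = np.array([fractions[b] for b in bases], dtype=float)
    return bases, p / p.sum()


def generate_mitogenome(template: GenomeTemplate | None = None
                        ) -> tuple[MitogenomeRecord, dict]:
    """Sample a genome honoring the template; returns (record, truth record)."""
    t = template or GenomeTemplate()
    rng = np.random.default_rng(t.seed)
    code = get_code(t.code_id)
    feats = _parse_features(t.rows)
    length = max(max(f.start, f.stop) for f in feats)
    for f in feats:
        if f.stop > length or f.start > length:
            raise TemplateError(f"{f.name} exceeds genome length {length}")
    seq: list[str | None] = [None] * length
    bases, probs = _base_probs(t.base_fractions)

    def jpos(f: GeneFeature, i: int) -> int:
        """0-based J-strand index of coding-strand position i of a feature."""
        return (f.start - 1 + i) if f.strand == "J" else (f.stop - 1 - i)

    def set_coding(f: GeneFeature, i: int, base: str) -> None:
        p = jpos(f, i)
        jbase = base if f.strand == "J" else _COMP[base]
        if seq[p] is not None and seq[p] != jbase:
            raise TemplateError(
                f"conflicting hard constraints at position {p + 1} "
                f"({f.name}: {jbase} vs existing {seq[p]})"
            )
        seq[p] = jbase

    def get_coding(f: GeneFeature, i: int) -> str | None:
        b = seq[jpos(f, i)]
        if b is None:
            return None
        return b if f.strand == "J" else _COMP[b]

    pcg_rows = [r for r in t.rows if canonical_name(r["name"]) in
                {f.name for f in feats if f.category == PCG}]
    pcgs = {f.name: f for f in feats if f.category == PCG}
    truth_pcgs: dict[str, dict] = {}

    # 1. hard constraints: start and (possibly truncated) stop codons
    for r in pcg_rows:
        name = canonical_name(r["name"])
        f = pcgs[name]
        flen = f.stop - f.start + 1
        start_codon = r.get("start_codon", "ATG")
        stop_codon = r.get("stop_codon", "TAA")
        if start_codon in (None, "", "-"):
            start_codon = "ATG"
        if stop_codon in (None, "", "-"):
            stop_codon = ("TAA", "T--", "TA-")[flen % 3]
        stop_bases = stop_codon.rstrip("-")
        if flen % 3 != len(stop_bases) % 3:
            raise TemplateError(
                f"{name}: stop codon {stop_codon} inconsistent with length {flen} mod 3"
            )
        for i, b in enumerate(start_codon):
            set_coding(f, i, b)
        for i, b in enumerate(stop_bases):
            set_coding(f, flen - len(stop_bases) + i, b)
        truth_pcgs[name] = {
            "start_codon": start_codon,
            "stop_codon": stop_codon,
            "complete": len(stop_bases) == 3,
        }

    # 2. fill PCG codons, rejecting stops given already-fixed bases
    def fill_codon(f: GeneFeature, k: int) -> None:
        idx = [3 * k, 3 * k + 1, 3 * k + 2]
        free = [i for i in idx if get_coding(f, i) is None]
        for _ in range(200):
            for i in free:
                jb = bases[int(rng.choice(4, p=probs))]
                p = jpos(f, i)
                seq[p] = jb
            codon = "".join(get_coding(f, i) for i in idx)
            if not code.is_stop(codon):
                return
            if not free:
                break
        if free:
            raise TemplateError(f"{f.name}: cannot avoid stop at codon {k + 1}")

    for r in pcg_rows:
        f = pcgs[canonical_name(r["name"])]
        flen = f.stop - f.start + 1
        for k in range(flen // 3):
            fill_codon(f, k)
        # trailing truncated-stop bases were hard-assigned in step 1

    # 3. repair: a later gene's frame may have been fixed entirely by an
    # earlier overlapping gene; resample non-hard bases of violating codons
    hard = set()
    for r in pcg_rows:
        name = canonical_name(r["name"])
        f = pcgs[name]
        flen = f.stop - f.start + 1
        n_stop = len(truth_pcgs[name]["stop_codon"].rstrip("-"))
        hard.update(jpos(f, i) for i in range(3))
        hard.update(jpos(f, flen - n_stop + i) for i in range(n_stop))

    def internal_stops(f: GeneFeature) -> list[int]:
        flen = f.stop - f.start + 1
        n_codons = flen // 3
        limit = n_codons - 1 if truth_pcgs[f.name]["complete"] else n_codons
        out = []
        for k in range(limit):
            codon = "".join(get_coding(f, i) for i in (3 * k, 3 * k + 1, 3 * k + 2))
            if code.is_stop(codon):
                out.append(k)
        return out

    for _ in range(20):
        violations = [(f, k) for f in pcgs.values() for k in internal_stops(f)]
        if not violations:
            break
        f, k = violations[0]
        idx = [jpos(f, i) for i in (3 * k, 3 * k + 1, 3 * k + 2)]
        mutable = [p for p in idx if p not in hard]
        if not mutable:
            raise TemplateError(f"{f.name}: unrepairable stop at codon {k + 1}")
        fixed = False
        for combo in np.ndindex(*(4,) * len(mutable)):
            for p, b in zip(mutable, combo):
                seq[p] = bases[b]
            if not any(internal_stops(g) for g in pcgs.values()):
                fixed = True
                break
        if not fixed:
            raise TemplateError(f"{f.name}: unrepairable stop at codon {k + 1}")
    else:
        raise TemplateError("stop-codon repair did not converge")

    # 4. control region with planted repeats
    control = [f for f in feats if f.category == CONTROL]
    truth_repeats = []
    if control:
        cr = control[0]
        cr_len = cr.stop - cr.start + 1
        dloop, truth_repeats = _build_control_region(cr_len, t.repeats, rng, bases, probs)
        for i, b in enumerate(dloop):
            seq[cr.start - 1 + i] = b

    # 5. remaining positions from a composition-balancing pool
    free_idx = [i for i, b in enumerate(seq) if b is None]
    if free_idx:
        target = {b: t.base_fractions[b] / 100.0 * length for b in bases}
        current = {b: 0 for b in bases}
        for b in seq:
            if b is not None:
                current[b] += 1
        need = {b: max(0.0, target[b] - current[b]) for b in bases}
        total_need = sum(need.values()) or 1.0
        quota = {b: need[b] / total_need * len(free_idx) for b in bases}
        pool: list[str] = []
        for b in bases:
            pool.extend(b * int(quota[b]))
        frac_order = sorted(bases, key=lambda b: quota[b] - int(quota[b]), reverse=True)
        i = 0
        while len(pool) < len(free_idx):
            pool.append(frac_order[i % 4])
            i += 1
        rng.shuffle(pool)
        for i, b in zip(free_idx, pool):
            seq[i] = b

    record = MitogenomeRecord(
        id=t.id, length=length, features=feats, sequence="".join(seq)
    )
    truth = {
        "seed": t.seed,
        "length": length,
        "base_fractions": dict(t.base_fractions),
        "code_id": t.code_id,
        "pcgs": truth_pcgs,
        "repeats": truth_repeats,
        "control_span": [control[0].start, control[0].stop] if control else None,
    }
    # closed-loop self-check: every PCG classifies as generated
    for name, info in truth_pcgs.items():
        cls = classify_ends(record.extract(pcgs[name]), t.code_id)
        assert cls.start_codon == info["start_codon"], name
        assert cls.stop_codon == info["stop_codon"], name
    return record, truth


class _RetryBuild(Exception):
    pass


def _build_control_region(cr_len: int, specs, rng, bases, probs,
                          max_tries: int = 60) -> tuple[str, list[dict]]:
    """A+T-rich region whose only repeats >= min_len are the planted ones.

    Background bases are sampled greedily so that every k-mer (k = detection
    min_len) in the region is unique except for the duplications implied by the
    planted copies; any repeated substring >= k would imply a repeated k-mer,
    so the construction is repeat-free by design. A final detector pass
    validates the closed loop.
    """
    planted = sum(s.motif_len * s.copies for s in specs)
    min_len = min([9] + [s.motif_len for s in specs])
    k = min_len
    n_slots = sum(1 if s.tandem else s.copies for s in specs)
    background = cr_len - planted
    if background < 2 * n_slots + 2:
        raise TemplateError(f"control region ({cr_len} bp) too short for the repeat spec")

    def attempt() -> tuple[str, list]:
        chars: list[str] = []
        kmers: set[str] = set()

        def grow(n: int) -> None:
            for _ in range(n):
                order = rng.permutation(4)
                # composition-weighted first pick, then fall through the rest
                first = int(rng.choice(4, p=probs))
                cand_order = [first] + [int(i) for i in order if int(i) != first]
                for bi in cand_order:
                    b = bases[bi]
                    if len(chars) + 1 < k:
                        chars.append(b)
                        break
                    km = "".join(chars[-(k - 1):]) + b
                    if km not in kmers:
                        chars.append(b)
                        kmers.add(km)
                        break
                else:
                    raise _RetryBuild

        def paste_copy(motif: str, skip_prefix_windows: int = 0) -> None:
            """Append a repeat copy verbatim, checking junction k-mers only."""
            start = len(chars)
            chars.extend(motif)
            lo = max(0, start - (k - 1))
            for w in range(lo, len(chars) - k + 1):
                km = "".join(chars[w: w + k])
                if w >= start:
                    continue  # internal to the copy: intentional duplicate
                if w - lo < skip_prefix_windows:
                    continue  # tandem-internal boundary, identical by design
                if km in kmers:
                    raise _RetryBuild
                kmers.add(km)

        cuts = sorted(int(c) for c in rng.choice(
            background - n_slots, size=n_slots, replace=False)) if n_slots else []
        flank_lens = []
        prev = 0
        for c in cuts:
            flank_lens.append(c - prev + 1)  # every flank >= 1 bp
            prev = c + 1
        flank_lens.append(background - sum(flank_lens))

        expected = []
        fi = 0
        for s in specs:
            if s.tandem:
                grow(flank_lens[fi]); fi += 1
                first = len(chars)
                grow(s.motif_len)
                unit = "".join(chars[first:])
                if first > 0 and chars[first - 1] == unit[-1]:
                    raise _RetryBuild  # would shift the array's apparent origin
                boundary_checked = False
                for _c in range(s.copies - 1):
                    paste_copy(unit, skip_prefix_windows=(k - 1) if boundary_checked else 0)
                    boundary_checked = True
                expected.append((s.motif_len, s.copies, True, first + 1))
            else:
                grow(flank_lens[fi]); fi += 1
                first = len(chars)
                grow(s.motif_len)
                motif = "".join(chars[first:])
                for _c in range(s.copies - 1):
                    grow(flank_lens[fi]); fi += 1
                    paste_copy(motif)
                expected.append((s.motif_len, s.copies, False, first + 1))
        grow(flank_lens[fi])
        region = "".join(chars)
        assert len(region) == cr_len
        return region, expected

    for _ in range(max_tries):
        try:
            region, expected = attempt()
        except _RetryBuild:
            continue
        hits = find_repeats(region, min_len=min_len) if cr_len >= min_len else []
        found = sorted((h.length, h.copy_number, h.tandem, h.positions[0]) for h in hits)
        if found == sorted(expected):
            truth = [
                {"length": L, "copies": c, "tandem": td, "first_position": p}
                for (L, c, td, p) in sorted(expected)
            ]
            return region, truth
    raise TemplateError("could not build a control region with exactly the planted repeats")


# --- ortholog simulation -----------------------------------------------------

@dataclass
class DivergenceScenario:
    """Controls for the rejection-sampling ortholog simulator."""

    taxa: int = 6
    omega: float = 0.3
    subs_per_codon: float = 0.3  # accepted substitutions per codon per lineage
    tstv: float = 1.0  # matches the equal-weighting assumption of the estimator
    seed: int = 0

    def __post_init__(self):
        if self.omega <= 0:
            raise ValueError("omega must be > 0")
        if self.taxa < 2:
            raise ValueError("at least two taxa")


_PURINES = {"A", "G"}


def _is_transition(a: str, b: str) -> bool:
    return (a in _PURINES) == (b in _PURINES)


def _evolve(seq: str, n_events: int, omega: float, tstv: float, rng,
            code) -> tuple[str, int, int]:
    """Evolve a stop-free in-frame CDS by accepted single-base substitutions."""
    s = list(seq)
    p_nonsyn = min(1.0, omega)
    p_syn = min(1.0, 1.0 / omega)
    syn = nonsyn = 0
    guard = 0
    while syn + nonsyn < n_events:
        guard += 1
        if guard > 1000 * max(n_events, 1) + 10000:
            raise RuntimeError("substitution sampler failed to progress")
        i = int(rng.integers(len(s)))
        cur = s[i]
        alts = [b for b in "ACGT" if b != cur]
        w = np.array([tstv if _is_transition(cur, b) else 1.0 for b in alts])
        b = alts[int(rng.choice(3, p=w / w.sum()))]
        k = i - i % 3
        old = "".join(s[k:k + 3])
        new = old[: i - k] + b + old[i - k + 1:]
        if code.is_stop(new):
            continue
        synonymous = code.translate(old) == code.translate(new)
        p = p_syn if synonymous else p_nonsyn
        if rng.random() < p:
            s[i] = b
            if synonymous:
                syn += 1
            else:
                nonsyn += 1
    return "".join(s), syn, nonsyn


def simulate_orthologs(cds: str, scenario: DivergenceScenario | None = None
                       ) -> tuple[OrthologAlignmentSet, dict]:
    """Evolve each taxon independently from a root CDS (star phylogeny).

    Returns the gap-free codon alignment plus a truth record with realized
    synonymous/nonsynonymous accepted counts per taxon.
    """
    sc = scenario or DivergenceScenario()
    cds = cds.upper().replace("U", "T")
    if len(cds) % 3:
        raise ValueError("root CDS must be in frame")
    code = get_code(5)
    for i in range(0, len(cds), 3):
        if code.is_stop(cds[i:i + 3]):
            raise ValueError(f"root CDS contains a stop codon at codon {i // 3 + 1}")
    rng = np.random.default_rng(sc.seed)
    n_codons = len(cds) // 3
    n_events = int(round(sc.subs_per_codon * n_codons))
    taxa, seqs, truth_taxa = [], [], {}
    for k in range(sc.taxa):
        label = f"taxon{k + 1}"
        evolved, syn, nonsyn = _evolve(cds, n_events, sc.omega, sc.tstv, rng, code)
        taxa.append(label)
        seqs.append(evolved)
        truth_taxa[label] = {"syn": syn, "nonsyn": nonsyn}
    aln = OrthologAlignmentSet(gene="synthetic", taxa=taxa, sequences=seqs)
    truth = {
        "omega": sc.omega, "subs_per_codon": sc.subs_per_codon,
        "tstv": sc.tstv, "seed": sc.seed, "n_codons": n_codons,
        "events_per_lineage": n_events, "taxa": truth_taxa,
    }
    return aln, truth


def simulate_on_tree(cds: str, tree, scenario: DivergenceScenario | None = None
                     ) -> OrthologAlignmentSet:
    """Evolve a CDS along a nested-tuple tree: leaf ("name", bl), node ([children], bl).

    Branch lengths are accepted substitutions per codon. Used for end-to-end
    supermatrix/NJ smoke tests where a known topology must be recoverable.
    """
    sc = scenario or DivergenceScenario()
    code = get_code(5)
    rng = np.random.default_rng(sc.seed)
    n_codons = len(cds) // 3
    taxa, seqs = [], []

    def walk(node, seq):
        label, bl = node
        n_events = int(round(bl * n_codons))
        evolved, _, _ = _evolve(seq, n_events, sc.omega, sc.tstv, rng, code)
        if isinstance(label, str):
            taxa.append(label)
            seqs.append(evolved)
        else:
            for child in label:
                walk(child, evolved)

    walk(tree, cds.upper().replace("U", "T"))
    return OrthologAlignmentSet(gene="simulated", taxa=taxa, sequences=seqs)


def random_cds(n_codons: int, seed: int = 0, code_id: int = 5) -> str:
    """A stop-free in-frame CDS starting with ATG, codons uniform over non-stops."""
    code = get_code(code_id)
    rng = np.random.default_rng(seed)
    non_stop = sorted(c for c in code.table if code.table[c] != "*")
    codons = ["ATG"] + [
        non_stop[int(rng.integers(len(non_stop)))] for _ in range(n_codons - 1)
    ]
    return "".join(codons)


def random_layout(seed: int = 0, n_features: int | None = None) -> MitogenomeRecord:
    """A random sequence-free circular layout (sizes/gaps/strands) for layout tests.

    Gaps may be negative (pairwise overlaps) but are bounded so feature starts
    stay strictly increasing and no triple overlap arises.
    """
    rng = np.random.default_rng(seed)
    n = n_features or int(rng.integers(5, 40))
    sizes = rng.integers(60, 1600, size=n)
    feats = []
    start = 1
    categories = ["PCG", "tRNA", "rRNA", "control"]
    for i in range(n):
        size = int(sizes[i])
        stop = start + size - 1
        feats.append(GeneFeature(
            name=f"f{i + 1}", strand=("J", "N")[int(rng.integers(2))],
            start=start, stop=stop, category=categories[int(rng.integers(4))],
        ))
        next_size = int(sizes[(i + 1) % n])
        low = 1 - min(size, next_size)
        gap = int(rng.integers(low, 40))
        start = stop + 1 + gap
    trailing = int(rng.integers(0, 60))
    length = feats[-1].stop + trailing
    return MitogenomeRecord(id=f"layout{seed}", length=length, features=feats)
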