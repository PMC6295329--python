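"""Mock mitogenome generator with exact ground truth.

Builds a circular ~16.8 kb genome laid out on the canonical (Type I) gene
order — optionally edited by the rearrangement event operators to produce
Types II–VI or arbitrary novel arrangements — with a control region
assembled from known parts:

    [ ETAS: tandem array of a TAS-bearing unit + pad ]
    [ CCR: background with one CSB-F instance ]
    [ CSB: CSB-1, (TA)n, CSB-2, CSB-3, (CA)n at known offsets ]

Every planted coordinate is recorded in a :class:`TruthRecord`, so each
pipeline stage can be scored against exact truth without any downloads.
Gene bodies are random background at the target base composition with
realistic lengths (ND5 longest, ATP8 shortest among the protein genes);
no codon structure is attempted.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np

from .cr_domains import DEFAULT_MOTIFS
from .formats import GeneFeature, MitoGenome, NucSequence, IUPAC_CODES
from .gene_order import GeneOrder, canonical_type1_order

# realistic spans (bp) for the 38 non-CR features
GENE_LENGTHS: dict[str, int] = {
    "trnF": 70, "rrnS": 950, "trnV": 70, "rrnL": 1500, "trnL(UUR)": 72,
    "ND1": 930, "trnI": 70, "trnQ": 70, "trnM": 70, "ND2": 990, "trnW": 70,
    "trnA": 68, "trnN": 72, "OL": 34, "trnC": 66, "trnY": 66, "COI": 1551,
    "trnS(UCN)": 70, "trnD": 68, "COII": 688, "trnK": 72, "ATP8": 165,
    "ATP6": 675, "COIII": 775, "trnG": 68, "ND3": 339, "trnR": 66,
    "ND4L": 297, "ND4": 1378, "trnH": 68, "trnS(AGY)": 60, "trnL(CUN)": 70,
    "ND5": 1700, "ND6": 516, "trnE": 68, "Cytb": 1120, "trnT": 70, "trnP": 68,
}

#: default H-strand base fractions (A, T, G, C), near the genus average
DEFAULT_COMPOSITION = (0.305, 0.218, 0.155, 0.322)

TAS_OFFSET = 10  # position of the TACAT pentanucleotide inside each repeat unit


@dataclass(frozen=True)
class CRSpec:
    """Control-region recipe; defaults mirror a peguensis-like CR (~1.65 kb)."""

    etas_len: int = 496
    unit_len: int = 75
    copies: int = 6
    divergence: float = 0.05
    indel_prob: float = 0.1        # chance of one 1-3 bp indel per copy
    ccr_len: int = 312
    csb_len: int = 845
    microsats: tuple[tuple[str, int], ...] = (("TA", 6), ("CA", 7))

    def __post_init__(self) -> None:
        if self.copies < 2:
            raise ValueError("copies must be >= 2")
        if not 0 <= self.divergence <= 0.5:
            raise ValueError("divergence must be in [0, 0.5]")
        if self.unit_len < TAS_OFFSET + 5:
            raise ValueError("unit too short to carry a TAS")


@dataclass(frozen=True)
class SyntheticSpec:
    seed: int = 0
    genome_length: int | None = 16800   # target minimum; spacer pads up to it
    order_type: str = "I"
    cr: CRSpec = field(default_factory=CRSpec)
    base_composition: tuple[float, float, float, float] = DEFAULT_COMPOSITION
    events: tuple = ()                  # explicit events for order_type="novel"


@dataclass
class TruthRecord:
    """Planted coordinates consistent with the emitted annotation."""

    genome_length: int = 0
    order_type: str = "I"
    events: list = field(default_factory=list)
    features: list = field(default_factory=list)      # (label, start, end, strand)
    cr_span: tuple[int, int] = (0, 0)
    cr_length: int = 0
    domains: dict = field(default_factory=dict)       # CR-local etas/ccr/csb
    array: dict = field(default_factory=dict)         # start, end, unit, copies
    motifs: dict = field(default_factory=dict)        # name -> [CR-local starts]
    microsats: list = field(default_factory=list)     # (motif, start, count)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1, default=list)


# ---------------------------------------------------------------------------

def _rand_seq(rng: np.random.Generator, n: int, comp) -> str:
    """Background of length n with base counts matching comp exactly (rounded)."""
    bases = np.array(list("ATGC"))
    counts = np.floor(np.asarray(comp) * n).astype(int)
    while counts.sum() < n:
        counts[rng.integers(0, 4)] += 1
    arr = np.repeat(bases, counts)
    rng.shuffle(arr)
    return "".join(arr)


def _instantiate(rng: np.random.Generator, pattern: str) -> str:
    """A literal realization of an IUPAC degenerate pattern."""
    return "".join(sorted(IUPAC_CODES[c])[rng.integers(0, len(IUPAC_CODES[c]))]
                   for c in pattern)


def _mutate_copy(rng: np.random.Generator, unit: str, divergence: float,
                 indel_prob: float) -> str:
    protected = set(range(TAS_OFFSET, TAS_OFFSET + 5))
    out = list(unit)
    for i in range(len(out)):
        if i in protected:
            continue
        if rng.random() < divergence:
            out[i] = "ACGT"[rng.integers(0, 4)]
    if rng.random() < indel_prob:
        size = int(rng.integers(1, 4))
        pos = int(rng.integers(TAS_OFFSET + 5, len(out)))
        if rng.random() < 0.5:
            del out[pos:pos + size]
        else:
            out[pos:pos] = ["ACGT"[rng.integers(0, 4)] for _ in range(size)]
    return "".join(out)


def _build_cr(rng: np.random.Generator, cr: CRSpec, comp) -> tuple[str, TruthRecord]:
    truth = TruthRecord()
    unit = _rand_seq(rng, cr.unit_len, comp)
    unit = unit[:TAS_OFFSET] + "TACAT" + unit[TAS_OFFSET + 5:]
    copies = [_mutate_copy(rng, unit, cr.divergence, cr.indel_prob)
              for _ in range(cr.copies)]
    array = "".join(copies)
    pad = max(0, cr.etas_len - len(array))
    etas = array + _rand_seq(rng, pad, comp)

    tas_starts, off = [], 0
    for c in copies:
        tas_starts.append(off + c.index("TACAT"))
        off += len(c)
    truth.array = {"start": 0, "end": len(array), "unit": unit,
                   "unit_length": cr.unit_len, "copies": cr.copies}
    truth.motifs["TAS"] = tas_starts

    ccr = _rand_seq(rng, cr.ccr_len, comp)
    csbf = _instantiate(rng, DEFAULT_MOTIFS["CSB-F"][0])
    fpos = (cr.ccr_len - len(csbf)) // 2
    ccr = ccr[:fpos] + csbf + ccr[fpos + len(csbf):]
    truth.motifs["CSB-F"] = [len(etas) + fpos]

    # CSB segment: CSB-1 first (so the partition anchor is the domain start),
    # then (TA)n, CSB-2, CSB-3, (CA)n separated by even gaps.
    parts = [("CSB-1", _instantiate(rng, DEFAULT_MOTIFS["CSB-1"][0]))]
    ms = list(cr.microsats)
    if ms:
        parts.append((f"ms:{ms[0][0]}", ms[0][0] * ms[0][1]))
    parts.append(("CSB-2", _instantiate(rng, DEFAULT_MOTIFS["CSB-2"][0])))
    parts.append(("CSB-3", _instantiate(rng, DEFAULT_MOTIFS["CSB-3"][0])))
    for motif, reps in ms[1:]:
        parts.append((f"ms:{motif}", motif * reps))
    planted = sum(len(s) for _, s in parts)
    free = cr.csb_len - planted
    if free < len(parts):
        raise ValueError("infeasible spec: csb_len too small for planted elements")
    gap = free // len(parts)
    sizes = [gap] * len(parts)
    sizes[-1] += free - gap * len(parts)

    seg, pos = [], 0
    base = len(etas) + len(ccr)
    for (name, s), g in zip(parts, sizes):
        if name.startswith("ms:"):
            truth.microsats.append((name[3:], base + pos, len(s) // len(name[3:])))
        else:
            truth.motifs.setdefault(name, []).append(base + pos)
        filler = _rand_seq(rng, g, comp)
        # a G break stops microsatellite runs from extending into the filler
        filler = "G" + filler[1:-1] + "G" if g >= 2 else filler
        seg.append(s)
        seg.append(filler)
        pos += len(s) + g
    csb = "".join(seg)

    seq = etas + ccr + csb
    truth.cr_length = len(seq)
    truth.domains = {"etas": (0, len(etas)), "ccr": (len(etas), len(etas) + len(ccr)),
                     "csb": (len(etas) + len(ccr), len(seq))}
    return seq, truth


# -- gene-order event operators ---------------------------------------------

def _rotate_to(tokens: tuple, label: str) -> tuple:
    i = next(k for k, (l, _) in enumerate(tokens) if l == label)
    return tokens[i:] + tokens[:i]


def apply_deletion(order: GeneOrder, label: str) -> GeneOrder:
    if label not in order.labels():
        raise ValueError(f"{label} not in order")
    return GeneOrder(tuple(t for t in order.tokens if t[0] != label))


def apply_duplication(order: GeneOrder, labels) -> GeneOrder:
    toks = []
    todo = set(labels)
    missing = todo - set(order.labels())
    if missing:
        raise ValueError(f"labels not in order: {sorted(missing)}")
    for t in order.tokens:
        toks.append(t)
        if t[0] in todo:
            toks.append(t)  # in-place tandem duplicate
            todo.discard(t[0])
    return GeneOrder(tuple(toks))


def apply_block_duplication(order: GeneOrder, start_label: str, end_label: str) -> GeneOrder:
    for lbl in (start_label, end_label):
        if lbl not in order.labels():
            raise ValueError(f"{lbl} not in order")
    t = _rotate_to(order.tokens, start_label)
    j = next(k for k, (l, _) in enumerate(t) if l == end_label)
    return GeneOrder(t[: j + 1] + t)


def apply_translocation(order: GeneOrder, label: str, before: str) -> GeneOrder:
    if label not in order.labels() or before not in order.labels():
        raise ValueError("label not in order")
    moved = next(t for t in order.tokens if t[0] == label)
    rest = tuple(t for t in order.tokens if t[0] != label)
    i = next(k for k, (l, _) in enumerate(rest) if l == before)
    return GeneOrder(rest[:i] + (moved,) + rest[i:])


def apply_extra_OL(order: GeneOrder, n: int = 1) -> GeneOrder:
    if "OL" not in order.labels():
        raise ValueError("no OL in order")
    toks = []
    for t in order.tokens:
        toks.append(t)
        if t[0] == "OL":
            toks.extend([t] * n)
    return GeneOrder(tuple(toks))


def apply_event(order: GeneOrder, event: tuple) -> GeneOrder:
    """Dispatch one edit event: (kind, *args); pure, returns an edited copy."""
    kind = event[0]
    if kind == "deletion":
        return apply_deletion(order, event[1])
    if kind == "duplication":
        return apply_duplication(order, event[1])
    if kind == "block_duplication":
        return apply_block_duplication(order, event[1], event[2])
    if kind == "translocation":
        return apply_translocation(order, event[1], event[2])
    if kind == "extra_OL":
        return apply_extra_OL(order, event[1] if len(event) > 1 else 1)
    raise ValueError(f"unknown event kind {kind!r}")


#: the defining event list of each rearrangement type
TYPE_EVENTS: dict[str, tuple] = {
    "I": (),
    "II": (("duplication", ("trnQ", "ND4")),),
    "III": (("extra_OL", 1),),
    "IV": (("translocation", "trnE", "trnP"),),
    "V": (("deletion", "trnE"),),
    "VI": (("block_duplication", "ND5", "trnT"),),
}


def order_for_type(order_type: str, events: tuple = ()) -> GeneOrder:
    order = canonical_type1_order()
    for ev in (events if order_type == "novel" else TYPE_EVENTS[order_type]):
        order = apply_event(order, ev)
    return order


# ---------------------------------------------------------------------------

def build_mock_mitogenome(spec: SyntheticSpec) -> tuple[MitoGenome, TruthRecord]:
    """Deterministically assemble a genome + truth record from a spec."""
    rng = np.random.default_rng(spec.seed)
    comp = spec.base_composition
    order = order_for_type(spec.order_type, spec.events)

    cr_seq, truth = _build_cr(rng, spec.cr, comp)
    truth.order_type = spec.order_type
    truth.events = [list(e) for e in
                    (spec.events if spec.order_type == "novel" else TYPE_EVENTS[spec.order_type])]

    # token lengths; duplicate copies reuse the label's span
    lengths = []
    for lbl, _ in order.tokens:
        lengths.append(len(cr_seq) if lbl == "CR" else GENE_LENGTHS[lbl])
    # genome_length is a target minimum: spacer pads up to it, while genomes
    # enlarged by duplication events simply come out longer
    base_total = sum(lengths)
    pad = max(0, (spec.genome_length or 0) - base_total)

    seqs: dict[int, str] = {}
    first_copy: dict[str, str] = {}
    for i, (lbl, _) in enumerate(order.tokens):
        if lbl == "CR":
            seqs[i] = cr_seq
        elif lbl in first_copy:
            # a duplicate copy: the original with light divergence
            src = list(first_copy[lbl])
            for j in range(len(src)):
                if rng.random() < 0.02:
                    src[j] = "ACGT"[rng.integers(0, 4)]
            seqs[i] = "".join(src)
        else:
            seqs[i] = _rand_seq(rng, lengths[i], comp)
            first_copy[lbl] = seqs[i]

    pieces, feats, pos = [], [], 0
    labels = [l for l, _ in order.tokens]
    pad_before = labels.index("trnP") if pad and "trnP" in labels else None
    for i, (lbl, strand) in enumerate(order.tokens):
        if i == pad_before:
            pieces.append(_rand_seq(rng, pad, comp))  # unannotated spacer
            pos += pad
        pieces.append(seqs[i])
        feats.append(GeneFeature(lbl, pos, pos + len(seqs[i]), strand))
        if lbl == "CR":
            truth.cr_span = (pos, pos + len(seqs[i]))
        pos += len(seqs[i])

    genome = MitoGenome(NucSequence(f"synthetic-{spec.order_type}-{spec.seed}",
                                    "".join(pieces), circular=True),
                        feats, source_id=f"SYN{spec.seed:06d}")
    truth.genome_length = len(genome.sequence)
    truth.features = [(f.label, f.start, f.end, f.strand) for f in genome.features]
    return genome, truth
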