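"""Gene-order linearization and rearrangement typing.

Gecko-lizard mitogenome arrangements fall into six recurrent types relative
to the canonical vertebrate (Type I) order:

* **I**   — canonical order, no events;
* **II**  — duplication of trnQ and ND4;
* **III** — extra copies of the light-strand origin (OL) inside the WANCY
  tRNA cluster (trnW–trnA–trnN–OL–trnC–trnY);
* **IV**  — translocation of trnE from its position next to ND6 to
  immediately 5' of trnP;
* **V**   — deletion of trnE;
* **VI**  — duplication of a contiguous block spanning the ND4-through-trnI
  region.

The classifier works on the circular order (every signature test is
rotation-invariant) and emits the supporting edit events; anything that does
not match exactly one signature is reported as ``novel`` with the raw
content difference, so compound rearrangements are never silently collapsed
onto a single type.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

from .formats import MitoGenome, UNKNOWN

Token = tuple[str, str]  # (vocabulary label, strand H/L)

# Canonical Type I layout: 37 genes + OL + CR, linearized from trnF.
_L_STRAND = {"trnQ", "trnA", "trnN", "trnC", "trnY", "trnS(UCN)", "ND6", "trnE", "trnP"}

_TYPE1_LABELS = [
    "trnF", "rrnS", "trnV", "rrnL", "trnL(UUR)", "ND1", "trnI", "trnQ", "trnM",
    "ND2", "trnW", "trnA", "trnN", "OL", "trnC", "trnY", "COI", "trnS(UCN)",
    "trnD", "COII", "trnK", "ATP8", "ATP6", "COIII", "trnG", "ND3", "trnR",
    "ND4L", "ND4", "trnH", "trnS(AGY)", "trnL(CUN)", "ND5", "ND6", "trnE",
    "Cytb", "trnT", "trnP", "CR",
]

TYPES = ("I", "II", "III", "IV", "V", "VI", "novel")


@dataclass(frozen=True)
class GeneOrder:
    """A rotation-canonicalized circular gene order."""

    tokens: tuple[Token, ...]
    origin: str = "trnF"

    def __post_init__(self) -> None:
        if not self.tokens:
            raise ValueError("empty gene order")
        object.__setattr__(self, "tokens", _canonical_rotation(tuple(self.tokens), self.origin))

    def labels(self) -> tuple[str, ...]:
        return tuple(lbl for lbl, _ in self.tokens)

    def __len__(self) -> int:
        return len(self.tokens)


def _canonical_rotation(tokens: tuple[Token, ...], origin: str) -> tuple[Token, ...]:
    """Rotate so the order starts at ``origin``; among several origin copies
    pick the lexicographically smallest rotation (deterministic and
    rotation-invariant)."""
    starts = [i for i, (lbl, _) in enumerate(tokens) if lbl == origin]
    if not starts:
        return tokens
    best = min(tokens[i:] + tokens[:i] for i in starts)
    return best


def canonical_type1_order() -> GeneOrder:
    """The 39-token canonical (Type I) gene order, trnF first."""
    return GeneOrder(tuple((lbl, "L" if lbl in _L_STRAND else "H")
                           for lbl in _TYPE1_LABELS))


def extract_gene_order(g: MitoGenome) -> GeneOrder:
    """Linearize a genome's features into a GeneOrder anchored at trnF."""
    if not g.features:
        raise ValueError("genome has no features")
    tokens = tuple((f.label, f.strand) for f in sorted(g.features, key=lambda f: f.start))
    if not any(lbl == "trnF" for lbl, _ in tokens):
        warnings.warn("no trnF feature; anchoring gene order on the first feature")
    return GeneOrder(tokens)


@dataclass(frozen=True)
class RearrangementCall:
    type: str
    events: tuple[tuple[str, tuple[str, ...]], ...] = ()
    template_diff: tuple[tuple[str, int], ...] = ()
    flags: tuple[str, ...] = ()


# -- circular sequence helpers ----------------------------------------------

def _circular_equal(a: Sequence[Token], b: Sequence[Token]) -> bool:
    if len(a) != len(b):
        return False
    a, b = tuple(a), tuple(b)
    return a in (b[i:] + b[:i] for i in range(len(b)))  # n <= ~45, fine


def _remove_indices(seq: tuple[Token, ...], idx: set[int]) -> tuple[Token, ...]:
    return tuple(t for i, t in enumerate(seq) if i not in idx)


def _successor(seq: tuple[Token, ...], i: int) -> Token:
    return seq[(i + 1) % len(seq)]


def _type1_span_nd4_trni() -> set[str]:
    """Labels on the circular Type I path from ND4 forward to trnI."""
    i, j = _TYPE1_LABELS.index("ND4"), _TYPE1_LABELS.index("trnI")
    n = len(_TYPE1_LABELS)
    return {_TYPE1_LABELS[k % n] for k in range(i, i + (j - i) % n + 1)}


def classify_rearrangement(order: GeneOrder) -> RearrangementCall:
    """Assign a rearrangement type (I–VI or novel) with supporting events.

    Unknown labels are dropped before matching and reported in ``flags``.
    """
    template = canonical_type1_order().tokens
    flags: list[str] = []
    toks = order.tokens
    if any(lbl == UNKNOWN for lbl, _ in toks):
        flags.append("unknown-labels-ignored")
        toks = tuple(t for t in toks if t[0] != UNKNOWN)
        if not toks:
            raise ValueError("no known labels to classify")

    have = Counter(lbl for lbl, _ in toks)
    want = Counter(lbl for lbl, _ in template)
    extra = have - want
    missing = want - have
    diff = tuple(sorted({**dict(extra), **{k: -v for k, v in missing.items()}}.items()))

    def call(t: str, events, fl=()) -> RearrangementCall:
        return RearrangementCall(t, tuple(events), diff, tuple(flags) + tuple(fl))

    # Type I: identical circular order
    if _circular_equal(toks, template):
        return call("I", [])

    # Type II: exactly one extra trnQ and one extra ND4, removable in place
    if not missing and extra == Counter({"trnQ": 1, "ND4": 1}):
        q_pos = [i for i, (l, _) in enumerate(toks) if l == "trnQ"]
        d_pos = [i for i, (l, _) in enumerate(toks) if l == "ND4"]
        for q in q_pos:
            for d in d_pos:
                if _circular_equal(_remove_indices(toks, {q, d}), template):
                    return call("II", [("duplication", ("trnQ",)), ("duplication", ("ND4",))])

    # Type III: >1 OL, all inside the WANCY cluster between trnN and trnC
    if not missing and set(extra) == {"OL"}:
        n_idx = [i for i, (l, _) in enumerate(toks) if l == "trnN"]
        ok = False
        for i in n_idx:
            j = i
            between = []
            while True:
                j = (j + 1) % len(toks)
                if toks[j][0] == "trnC":
                    ok = all(l == "OL" for l, _ in between) and len(between) >= 2
                    break
                between.append(toks[j])
                if j == i:
                    break
            if ok:
                break
        if ok:
            ol_extra = [i for i, (l, _) in enumerate(toks) if l == "OL"][1:]
            if _circular_equal(_remove_indices(toks, set(ol_extra)), template):
                return call("III", [("extra_OL", ("OL",) * extra["OL"])])

    # Type IV: same content, trnE moved to immediately 5' of trnP
    if not missing and not extra:
        e_idx = [i for i, (l, _) in enumerate(toks) if l == "trnE"]
        t_no_e = tuple(t for t in template if t[0] != "trnE")
        if len(e_idx) == 1 and _circular_equal(_remove_indices(toks, {e_idx[0]}), t_no_e):
            if _successor(toks, e_idx[0])[0] == "trnP":
                return call("IV", [("translocation", ("trnE", "trnP"))])

    # Type V: trnE deleted, everything else canonical
    if not extra and missing == Counter({"trnE": 1}):
        t_no_e = tuple(t for t in template if t[0] != "trnE")
        if _circular_equal(toks, t_no_e):
            return call("V", [("deletion", ("trnE",))])

    # Type VI: one contiguous duplicated block intersecting the ND4..trnI span
    if not missing and extra:
        k = sum(extra.values())
        n = len(toks)
        doubled = toks + toks
        for i in range(n):
            seg = doubled[i:i + k]
            if Counter(l for l, _ in seg) != extra:
                continue
            rest = doubled[i + k:i + n]
            if _circular_equal(rest, template):
                seg_labels = tuple(l for l, _ in seg)
                if set(seg_labels) & _type1_span_nd4_trni():
                    return call("VI", [("duplication", seg_labels)])
                return call("novel", [("duplication", seg_labels)])

    # fall through: report raw content events
    events = [("duplication" if v > 0 else "deletion", (k,) * abs(v))
              for k, v in sorted(extra.items())] + \
             [("deletion", (k,) * v) for k, v in sorted(missing.items())]
    if not events:
        events = [("translocation", tuple(sorted(have)))]
    return call("novel", events)


def type_census(calls: Iterable[RearrangementCall]) -> dict[str, dict[str, float]]:
    """Exact counts and one-decimal percentages per rearrangement type."""
    calls = list(calls)
    if not calls:
        raise ValueError("empty call list")
    counts = Counter(c.type for c in calls)
    total = sum(counts.values())
    return {t: {"count": counts[t], "percent": round(100.0 * counts[t] / total, 1)}
            for t in TYPES if counts[t]}
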