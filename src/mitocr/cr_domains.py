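"""Control-region extraction, degenerate-motif scanning and domain partition.

The vertebrate control region (CR) sits between trnP and trnF and divides
into three domains: the extended termination-associated sequence (ETAS)
domain at the 5' end, the central conserved region (CCR), and the conserved
sequence block (CSB) domain at the 3' end.  Landmarks are short degenerate
consensus motifs: the TAS pentanucleotide TACAT inside the ETAS repeats,
CSB-F in the CCR, and CSB-1/2/3 in the CSB domain.

The partition rule anchors the ETAS/CCR boundary on the 3' end of the last
TAS-bearing tandem-repeat array and the CCR/CSB boundary on the best CSB-1
hit (fewest mismatches, leftmost on ties; CSB-2 as fallback).  The exact
published boundary convention is not recoverable, so the rule is
configurable and the enforced invariant is the exact three-way partition:
len(ETAS) + len(CCR) + len(CSB) = CR length.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .composition import compute_composition
from .formats import IUPAC_CODES, MitoGenome, NucSequence, reverse_complement

#: Degenerate consensus motifs of the gecko CR, with default mismatch budgets.
#: CSB-2/CSB-3 are more conserved than CSB-1, hence the tighter budgets.
DEFAULT_MOTIFS: dict[str, tuple[str, int]] = {
    "TAS":   ("TACAT", 0),
    "CSB-F": ("CHCGRGAAACCAKCRACCCS", 3),
    "CSB-1": ("KTTMATGCTCGAWRGACATAY", 3),
    "CSB-2": ("AAACCCCCCTTACCCCCC", 2),
    "CSB-3": ("CGCCAAACCCCTAAAACG", 2),
}


@dataclass(frozen=True)
class MotifDef:
    name: str
    pattern: str
    max_mismatch: int = 0

    def __post_init__(self) -> None:
        if not self.pattern:
            raise ValueError("empty motif pattern")
        bad = set(self.pattern.upper()) - set(IUPAC_CODES)
        if bad:
            raise ValueError(f"invalid IUPAC codes in pattern: {sorted(bad)}")
        object.__setattr__(self, "pattern", self.pattern.upper())
        if self.max_mismatch < 0:
            raise ValueError("max_mismatch must be >= 0")


def default_motifs() -> list[MotifDef]:
    return [MotifDef(n, p, m) for n, (p, m) in DEFAULT_MOTIFS.items()]


@dataclass(frozen=True)
class MotifHit:
    motif: str
    start: int
    end: int
    mismatches: int
    strand: str = "H"


class PartitionError(ValueError):
    """CR domain partition could not be established."""


@dataclass(frozen=True)
class CRPartition:
    """Machine-readable CR annotation: three domains plus the motif evidence."""

    cr_span: tuple[int, int]            # genome coordinates (end may wrap past L)
    etas: tuple[int, int]               # CR-local
    ccr: tuple[int, int]
    csb: tuple[int, int]
    hits: tuple[MotifHit, ...] = ()
    domain_at_content: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        e, c, s = self.etas, self.ccr, self.csb
        if not (e[0] == 0 and e[1] == c[0] and c[1] == s[0]):
            raise PartitionError(f"domains do not tile the CR: {e} {c} {s}")
        if not (e[0] < e[1] and c[0] < c[1] and s[0] < s[1]):
            raise PartitionError("empty domain in partition")

    @property
    def cr_length(self) -> int:
        return self.csb[1]

    def sizes(self) -> tuple[int, int, int]:
        return (self.etas[1] - self.etas[0], self.ccr[1] - self.ccr[0],
                self.csb[1] - self.csb[0])


def extract_cr(g: MitoGenome) -> tuple[NucSequence, tuple[int, int]]:
    """The H-strand subsequence strictly between end(trnP) and start(trnF).

    Handles a CR that wraps the circular origin.  Raises ``ValueError`` naming
    the missing flank if trnP or trnF is absent.
    """
    for flank in ("trnP", "trnF"):
        if g.get(flank) is None:
            raise ValueError(f"cannot locate CR: genome lacks {flank}")
    n = len(g.sequence)
    start = g.get("trnP").end % n
    end = g.get("trnF").start % n
    seq = g.sequence.slice_circular(start, end)
    if not seq:
        raise ValueError("empty CR between trnP and trnF")
    return NucSequence(f"{g.source_id or g.sequence.id}|CR", seq), (start, start + len(seq))


def _matches(base: str, code: str) -> bool:
    # N in the sequence never counts as a match; it must spend mismatch budget
    return base in IUPAC_CODES.get(code, frozenset())


def iupac_scan(seq: NucSequence | str, motif: MotifDef,
               both_strands: bool = False) -> list[MotifHit]:
    """All windows within Hamming distance ``max_mismatch`` of the pattern.

    A window position matches when the sequence base is in the IUPAC set of
    the pattern code.  Hits are sorted by position then mismatch count; hits
    on the L strand (when ``both_strands``) report H-strand coordinates.
    """
    s = seq.residues if isinstance(seq, NucSequence) else str(seq).upper()
    pat = motif.pattern
    m, n = len(pat), len(s)
    hits: list[MotifHit] = []
    sets = [IUPAC_CODES[c] for c in pat]
    for i in range(n - m + 1):
        mm = 0
        for j in range(m):
            if s[i + j] not in sets[j]:
                mm += 1
                if mm > motif.max_mismatch:
                    break
        else:
            hits.append(MotifHit(motif.name, i, i + m, mm, "H"))
    if both_strands:
        rc = reverse_complement(s)
        for h in iupac_scan(rc, motif):
            hits.append(MotifHit(motif.name, n - h.end, n - h.start, h.mismatches, "L"))
    hits.sort(key=lambda h: (h.start, h.mismatches))
    return hits


def scan_all(cr: NucSequence, motifs: Iterable[MotifDef] | None = None) -> list[MotifHit]:
    hits: list[MotifHit] = []
    for motif in motifs if motifs is not None else default_motifs():
        hits.extend(iupac_scan(cr, motif))
    hits.sort(key=lambda h: (h.start, h.mismatches))
    return hits


def _best_hit(hits: Sequence[MotifHit], name: str) -> MotifHit | None:
    cand = [h for h in hits if h.motif == name]
    return min(cand, key=lambda h: (h.mismatches, h.start)) if cand else None


def partition_cr(cr: NucSequence, arrays: Sequence = (), hits: Sequence[MotifHit] = (),
                 cr_span: tuple[int, int] | None = None,
                 default_etas_fraction: float = 1 / 3) -> CRPartition:
    """Partition a CR into ETAS / CCR / CSB domains.

    ETAS ends at the 3' end of the last tandem array containing a TAS hit
    (fallbacks: last TAS hit in the 5' half, then ``default_etas_fraction``);
    the CSB domain starts at the best CSB-1 hit, falling back to CSB-2.
    """
    n = len(cr)
    tas_hits = [h for h in hits if h.motif == "TAS"]

    e = None
    for arr in sorted(arrays, key=lambda a: a.end):
        if any(arr.start <= h.start and h.end <= arr.end for h in tas_hits):
            e = arr.end
    if e is None:
        in_5p = [h for h in tas_hits if h.end <= n // 2]
        if in_5p:
            e = in_5p[-1].end
    if e is None:
        e = int(round(n * default_etas_fraction))

    anchor = _best_hit(hits, "CSB-1") or _best_hit(hits, "CSB-2")
    if anchor is None:
        raise PartitionError("no CSB-1 or CSB-2 hit; cannot place the CCR/CSB boundary")
    c = anchor.start
    if e >= c:
        raise PartitionError(f"boundary conflict: ETAS end {e} >= CSB start {c}")
    if e <= 0:
        raise PartitionError("empty ETAS domain")

    at = {}
    for name, (a, b) in (("ETAS", (0, e)), ("CCR", (e, c)), ("CSB", (c, n))):
        at[name] = compute_composition(cr.residues[a:b], id=name).at_content
    return CRPartition((cr_span or (0, n)), (0, e), (e, c), (c, n),
                       tuple(hits), at)
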