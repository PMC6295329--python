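"""Tandem-repeat (VNTR) detection and decomposition, microsatellites, stems.

The ETAS domain of the gecko control region carries a tandem array of a
~75-bp unit (the "75-bp box" family; one lineage instead carries a 225-bp
unit that decomposes into three 75-bp sub-units).  The detector here is a
seed-and-extend scheme: candidate periods are seeded from recurring k-mers,
an array is grown while consecutive windows stay above an identity
threshold, and overlapping candidates are merged keeping the one covering
the most sequence.  Identity between copies is edit-distance based (copies
of real VNTR units differ in length, not only in substitutions).
"""

from __future__ import annotations

import re
from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Sequence

import edlib
import numpy as np

from .formats import NucSequence, reverse_complement


def _as_str(seq: NucSequence | str) -> str:
    return seq.residues if isinstance(seq, NucSequence) else str(seq).upper()


def unit_identity(a: str, b: str) -> float:
    """1 − edit_distance(a, b) / max(len(a), len(b)); symmetric, in [0, 1]."""
    a, b = _as_str(a), _as_str(b)
    if not a or not b:
        raise ValueError("empty subsequence")
    if a == b:
        return 1.0
    d = edlib.align(a, b, task="distance")["editDistance"]
    return 1.0 - d / max(len(a), len(b))


@dataclass(frozen=True)
class TandemArray:
    start: int
    end: int
    unit_length: int
    copy_number: int
    units: tuple[str, ...]
    adjacent_identity: tuple[float, ...]
    consensus: str

    @property
    def score(self) -> int:
        return self.copy_number * self.unit_length


@dataclass(frozen=True)
class DecompositionResult:
    unit: str
    base_length: int
    sub_units: tuple[str, ...]
    remainder: str
    pairwise_identity: tuple[tuple[float, ...], ...]
    vs_reference: tuple[float, ...]
    box_like: tuple[bool, ...]


@dataclass(frozen=True)
class MicrosatHit:
    motif: str
    start: int
    end: int
    repeat_count: int


@dataclass(frozen=True)
class StemHit:
    arm_start: int
    arm_length: int
    loop_length: int
    arm_identity: float

    @property
    def end(self) -> int:
        return self.arm_start + 2 * self.arm_length + self.loop_length


def _consensus(units: Sequence[str], unit_length: int) -> str:
    cols = []
    for j in range(unit_length):
        col = Counter(u[j] for u in units if j < len(u) and u[j] in "ACGT")
        cols.append(col.most_common(1)[0][0] if col else "A")
    return "".join(cols)


def _locate(query: str, target: str) -> tuple[int, int, int] | None:
    """Best infix alignment of query in target: (start, end, distance)."""
    if not target or len(target) < len(query) // 2:
        return None
    res = edlib.align(query, target, mode="HW", task="locations")
    if not res["locations"]:
        return None
    s, e = res["locations"][0]
    return s, e + 1, res["editDistance"]


def _extend(s: str, seed: int, p: int, min_identity: float) -> list[int] | None:
    """Grow an array of approximate period ``p`` around ``seed``.

    Steps copy by copy, re-locating each neighbouring copy by infix
    alignment of the current one so indel drift and an imprecise seeded
    period self-correct.  Returns the copy start positions (the last copy
    is assumed one period long).
    """
    n = len(s)
    delta = min(max(2, p // 8), max(1, p - 2))
    if p - delta < 2 or seed + p > n:
        return None
    starts = [seed]
    while True:  # leftward
        j = starts[0]
        q = s[j:j + p]
        lo, hi = max(0, j - p - delta), min(n, j + delta)
        loc = _locate(q, s[lo:hi - 1])  # forbid re-finding q itself
        if loc is None:
            break
        a, b, d = loc
        if 1 - d / max(len(q), b - a) < min_identity or lo + a >= j - p + delta + 1:
            break
        starts.insert(0, lo + a)
    while True:  # rightward
        j = starts[-1]
        q = s[j:j + p]
        lo = j + p - delta
        hi = min(n, j + 2 * p + delta)
        if lo <= j or hi - lo < p // 2:
            break
        loc = _locate(q, s[lo:hi])
        if loc is None:
            break
        a, b, d = loc
        if 1 - d / max(len(q), b - a) < min_identity or lo + a > j + p + delta:
            break
        starts.append(lo + a)
        if starts[-1] + p > n:
            starts.pop()
            break
    return starts


def _is_periodic(unit: str, min_unit: int, min_identity: float) -> bool:
    """True when the unit is itself tandemly periodic at a smaller period.

    Periodicity at shift q is judged positionally (fraction of i with
    unit[i] == unit[i+q]); an edit-distance measure would score every small
    shift of any string highly and is useless here.
    """
    for q in range(min_unit, len(unit) // 2 + 1):
        pairs = list(zip(unit, unit[q:]))
        if sum(a == b for a, b in pairs) / len(pairs) >= min_identity:
            return True
    return False


def _is_primitive(units: Sequence[str], min_unit: int, min_identity: float) -> bool:
    """False when any copy of the array is internally periodic at a smaller
    period (>= min_unit): the array is then a multiple of that period and
    should be reported at the smaller unit, which is seeded independently."""
    return not any(_is_periodic(u, min_unit, min_identity) for u in units)


def _refine(s: str, start: int, end: int, p0: int,
            min_copies: int) -> tuple[int, int, int] | None:
    """Phase-free boundary refinement via the positional match profile.

    For periods near ``p0`` builds M[x] = (s[x] == s[x+p]); inside a tandem
    array of period p this is dense (~1 - 2*divergence), outside it is at the
    random base-coincidence level.  A single dense run fixes the array start
    and copy count exactly, whatever phase the seed had.  Returns
    (array_start, copies, period), or None when the profile is broken (e.g.
    an indel shifts the phase mid-array) and the alignment-stepping estimate
    should stand.
    """
    n = len(s)
    best = None
    for p in range(max(2, p0 - 2), p0 + 3):
        lo, hi = max(0, start - 2 * p), min(n, end + 2 * p)
        if hi - lo < 2 * p:
            continue
        arr = np.frombuffer(s[lo:hi].encode(), np.uint8)
        M = arr[:-p] == arr[p:]
        w = min(p, 20)
        if M.size < w:
            continue
        dens = np.convolve(M, np.ones(w), "valid") / w
        G = dens >= 0.6
        runs: list[tuple[int, int]] = []
        i = 0
        while i < G.size:
            if G[i]:
                j = i
                while j < G.size and G[j]:
                    j += 1
                a, b = i, min(j + w - 1, M.size)
                # snap edges to where the local profile is actually dense
                while b - a > 5 and M[a:a + 5].mean() < 0.6:
                    a += 1
                while b - a > 5 and M[b - 5:b].mean() < 0.6:
                    b -= 1
                while a < b and not M[a]:
                    a += 1
                while b > a and not M[b - 1]:
                    b -= 1
                runs.append((a, b))
                i = j
            else:
                i += 1
        big = [(a, b) for a, b in runs if b - a >= p / 2]
        if len(big) != 1:
            continue  # no run, or an indel split the profile
        a, b = big[0]
        span = b - a
        copies = int(round(span / p)) + 1
        if copies < min_copies:
            continue
        if best is None or span > best[0]:
            best = (span, lo + a, copies, p)
    if best is None:
        return None
    _, array_start, copies, p = best
    if array_start + copies * p > n:
        copies -= 1
    return (array_start, copies, p) if copies >= min_copies else None


def find_tandem_repeats(seq: NucSequence | str, min_unit: int = 10, max_unit: int = 300,
                        min_identity: float = 0.7, min_copies: int = 2,
                        k: int = 8) -> list[TandemArray]:
    """Detect tandem arrays by k-mer seeding and greedy extension.

    Candidate periods come from distances between recurrences of exact
    k-mers; each candidate is extended in both directions while consecutive
    period-length windows keep identity >= ``min_identity``.  Overlapping
    candidates are merged, keeping the representative with the largest
    copy_number x unit_length (ties: smaller unit, then leftmost).
    """
    if min_unit > max_unit:
        raise ValueError("min_unit > max_unit")
    s = _as_str(seq)
    n = len(s)
    if n < 2 * min_unit:
        return []

    def collect_seeds(km: int) -> set[tuple[int, int]]:
        positions: dict[str, list[int]] = defaultdict(list)
        for i in range(n - km + 1):
            positions[s[i:i + km]].append(i)
        found: set[tuple[int, int]] = set()
        for pos in positions.values():
            for ai in range(len(pos) - 1):
                for bi in range(ai + 1, len(pos)):
                    p = pos[bi] - pos[ai]
                    if p > max_unit:
                        break
                    if p >= min_unit:
                        found.add((pos[ai], p))
        return found

    seed_sets = [collect_seeds(k)]

    candidates: list[TandemArray] = []
    tried: set[tuple[int, int]] = set()
    covered: dict[int, list[tuple[int, int]]] = defaultdict(list)
    if k > 6:
        # diverged low-copy arrays can lack any shared k-mer; a shorter-seed
        # pass runs only when the first finds nothing, keeping cost low
        seed_sets.append(None)
    for seeds in seed_sets:
      if seeds is None:
        if candidates:
            break
        seeds = collect_seeds(6)
      for seed, p in sorted(seeds):
        delta = max(2, p // 8)
        if any(a <= seed and seed + p <= b and
               min((seed - a) % p, p - (seed - a) % p) <= delta
               for a, b in covered[p]):
            continue  # same period, same phase: already extended
        starts = _extend(s, seed, p, min_identity)
        if starts is None or len(starts) < min_copies:
            continue
        bounds = starts + [starts[-1] + p]
        p_est = int(np.median(np.diff(bounds)))
        refined = _refine(s, bounds[0], bounds[-1], p_est, min_copies)
        if refined is not None:
            a, copies, rp = refined
            bounds = [a + i * rp for i in range(copies + 1)]
            # an indel shifts the profile phase, so the run may exclude
            # genuine flanking copies: re-step from the refined start with a
            # threshold set between the detection floor and the core copies'
            # own identity — real copies clear it, absorbed flank does not
            ref_adj = [unit_identity(s[bounds[i]:bounds[i + 1]],
                                     s[bounds[i + 1]:bounds[i + 2]])
                       for i in range(copies - 1)]
            if ref_adj:
                thr = max(min_identity, (min_identity + sum(ref_adj) / len(ref_adj)) / 2)
                starts2 = _extend(s, a, rp, thr)
                if starts2 and len(starts2) > copies:
                    bounds = starts2 + [starts2[-1] + rp]
        units = tuple(s[bounds[i]:bounds[i + 1]] for i in range(len(bounds) - 1))
        # trim terminal copies that fall below the identity threshold
        adj = [unit_identity(units[i], units[i + 1]) for i in range(len(units) - 1)]
        while adj and adj[0] < min_identity:
            units, bounds, adj = units[1:], bounds[1:], adj[1:]
        while adj and adj[-1] < min_identity:
            units, bounds, adj = units[:-1], bounds[:-1], adj[:-1]
        if len(units) < min_copies:
            continue
        unit_len = int(np.median([len(u) for u in units]))
        if not min_unit <= unit_len <= max_unit:
            continue
        covered[p].append((bounds[0], bounds[-1]))
        key = (bounds[0], unit_len)
        if key in tried:
            continue
        tried.add(key)
        if not _is_primitive(units, min_unit, min_identity):
            continue  # a multiple of a smaller period; that period is seeded too
        candidates.append(TandemArray(bounds[0], bounds[-1], unit_len, len(units),
                                      units, tuple(adj), _consensus(units, unit_len)))

    # merge overlapping candidates, ranking by the identity each adjacency
    # carries above the random-DNA baseline: a phase-shifted or
    # flank-absorbing rival earns nearly nothing from its junk copies and
    # cannot outrank the clean array on sheer length
    baseline = max(0.0, min_identity - 0.1)

    def rank(a: TandemArray):
        excess = sum(i - baseline for i in a.adjacent_identity)
        return (-a.unit_length * excess, a.unit_length, a.start)

    candidates.sort(key=rank)
    chosen: list[TandemArray] = []
    for cand in candidates:
        if all(cand.end <= c.start or cand.start >= c.end for c in chosen):
            chosen.append(cand)
    chosen.sort(key=lambda a: a.start)
    return chosen


def decompose_unit(unit: str, base_length: int,
                   reference: str | None = None,
                   box_like_threshold: float = 0.65) -> DecompositionResult:
    """Cut a long repeat unit into consecutive base-length sub-units.

    Sub-units plus the remainder reconstruct the unit exactly.  A sub-unit
    whose best identity (to any other sub-unit, or to ``reference`` if given)
    falls below ``box_like_threshold`` is flagged "box-like": recognizably of
    the family but diverged.
    """
    unit = _as_str(unit)
    if base_length <= 0:
        raise ValueError("base_length must be positive")
    if len(unit) < base_length:
        raise ValueError("unit shorter than base_length")
    m = len(unit) // base_length
    subs = tuple(unit[i * base_length:(i + 1) * base_length] for i in range(m))
    remainder = unit[m * base_length:]
    pid = tuple(tuple(unit_identity(a, b) for b in subs) for a in subs)
    vs_ref = tuple(unit_identity(sub, reference) for sub in subs) if reference else ()
    box_like = []
    for i in range(m):
        others = [pid[i][j] for j in range(m) if j != i]
        if vs_ref:
            others.append(vs_ref[i])
        best = max(others) if others else 1.0
        box_like.append(best < box_like_threshold)
    return DecompositionResult(unit, base_length, subs, remainder, pid, vs_ref,
                               tuple(box_like))


def microsat_scan(seq: NucSequence | str, motifs: Sequence[str] = ("TA", "CA"),
                  min_repeats: int = 4) -> list[MicrosatHit]:
    """Maximal perfect microsatellite runs of each motif (default (TA)n, (CA)n).

    Runs are non-extendable by a full motif copy on either side; runs of
    different motifs may overlap and are reported independently.
    """
    s = _as_str(seq)
    hits: list[MicrosatHit] = []
    for motif in motifs:
        m = motif.upper()
        for match in re.finditer(f"(?:{m}){{{min_repeats},}}", s):
            count = (match.end() - match.start()) // len(m)
            hits.append(MicrosatHit(m, match.start(), match.start() + count * len(m), count))
    hits.sort(key=lambda h: (h.start, h.motif))
    return hits


def find_stems(unit: NucSequence | str, min_arm: int = 6, max_loop: int = 30,
               min_arm_identity: float = 0.8, min_loop: int = 3) -> list[StemHit]:
    """All hairpin-capable placements: arms that reverse-complement match.

    Scans every (arm_start, arm_length, loop_length) placement and reports
    those where the fraction of complementary arm positions reaches
    ``min_arm_identity``.  Sorted by arm length descending.
    """
    s = _as_str(unit)
    n = len(s)
    if n < 2 * min_arm + min_loop:
        return []
    hits: list[StemHit] = []
    for arm in range(min_arm, (n - min_loop) // 2 + 1):
        for loop in range(min_loop, max_loop + 1):
            span = 2 * arm + loop
            if span > n:
                break
            for i in range(n - span + 1):
                left = s[i:i + arm]
                right_rc = reverse_complement(s[i + arm + loop:i + span])
                ident = sum(x == y and x in "ACGT" for x, y in zip(left, right_rc)) / arm
                if ident >= min_arm_identity:
                    hits.append(StemHit(i, arm, loop, ident))
    hits.sort(key=lambda h: (-h.arm_length, h.arm_start, h.loop_length))
    return hits
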