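"""Base composition and strand-asymmetry (skew) statistics.

AT-skew = (A − T)/(A + T) and GC-skew = (G − C)/(G + C), tallied on the
heavy strand as given.  A skew is undefined (``None``) when its denominator
is zero.  IUPAC ambiguity codes are counted in ``other`` and excluded from
both percentages of the four bases and the skews.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping

from .formats import NucSequence


@dataclass(frozen=True)
class CompositionStats:
    id: str
    a: int
    t: int
    g: int
    c: int
    other: int

    @property
    def length(self) -> int:
        return self.a + self.t + self.g + self.c + self.other

    @property
    def pct_a(self) -> float:
        return 100.0 * self.a / self.length

    @property
    def pct_t(self) -> float:
        return 100.0 * self.t / self.length

    @property
    def pct_g(self) -> float:
        return 100.0 * self.g / self.length

    @property
    def pct_c(self) -> float:
        return 100.0 * self.c / self.length

    @property
    def at_content(self) -> float:
        return self.pct_a + self.pct_t

    @property
    def gc_content(self) -> float:
        return self.pct_g + self.pct_c

    @property
    def at_skew(self) -> float | None:
        return (self.a - self.t) / (self.a + self.t) if self.a + self.t else None

    @property
    def gc_skew(self) -> float | None:
        return (self.g - self.c) / (self.g + self.c) if self.g + self.c else None


def compute_composition(seq: NucSequence | str, id: str = "") -> CompositionStats:
    """Tally base counts and skews for one sequence (H-strand orientation)."""
    if isinstance(seq, NucSequence):
        residues, sid = seq.residues, seq.id
    else:
        residues, sid = str(seq).upper(), id
    if not residues:
        raise ValueError("empty sequence")
    counts = Counter(residues)
    a, t, g, c = counts["A"], counts["T"], counts["G"], counts["C"]
    other = len(residues) - a - t - g - c
    return CompositionStats(sid or id, a, t, g, c, other)


def stats_from_percentages(pct_a: float, pct_t: float, pct_g: float, pct_c: float,
                           id: str = "", scale: int = 100000) -> CompositionStats:
    """Build stats from printed percentage values (e.g. a published table row).

    Percentages are scaled to integer counts; skews are ratio statistics and
    therefore independent of the scale chosen.
    """
    counts = [round(p * scale) for p in (pct_a, pct_t, pct_g, pct_c)]
    return CompositionStats(id, *counts, other=0)


_METRICS = ("at_content", "gc_content", "at_skew", "gc_skew",
            "pct_a", "pct_t", "pct_g", "pct_c")


def summarize_values(values: Iterable[float]) -> dict[str, float | None]:
    """Mean, sample SD (n−1) and SE = SD/√n of a list of metric values.

    With a single value the dispersion entries are ``None``.  The SE is the
    default display dispersion for cohort tables (a cohort of five A+T%
    values around 52 has SD ~1.4 but SE ~0.6).
    """
    vals = [v for v in values if v is not None]
    if not vals:
        return {"mean": None, "sd": None, "se": None, "n": 0}
    n = len(vals)
    mean = sum(vals) / n
    if n > 1:
        sd = math.sqrt(sum((v - mean) ** 2 for v in vals) / (n - 1))
        se = sd / math.sqrt(n)
    else:
        sd = se = None
    return {"mean": mean, "sd": sd, "se": se, "n": n}


def cohort_summary(stats: Iterable[CompositionStats]) -> dict[str, Mapping[str, float | None]]:
    """Per-metric :func:`summarize_values` over a cohort of sequences.

    Undefined skews are excluded pairwise (per metric).
    """
    stats = list(stats)
    if not stats:
        raise ValueError("empty cohort")
    return {metric: summarize_values(getattr(s, metric) for s in stats)
            for metric in _METRICS}
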