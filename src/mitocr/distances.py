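"""Uncorrected p-distances on aligned sequences and group divergence summaries.

p-distance = proportion of differing sites among comparable sites.  Sites
holding a gap or N are excluded either pairwise (per sequence pair, the
default) or completely (any row).  Group summaries report the mean over
unordered within-group pairs with a site-bootstrap standard error.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from Bio import SeqIO

_VALID = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class Alignment:
    ids: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.rows) < 2:
            raise ValueError("alignment needs at least two rows")
        if len({len(r) for r in self.rows}) != 1:
            raise ValueError("rows differ in length")
        object.__setattr__(self, "rows", tuple(r.upper() for r in self.rows))

    @property
    def length(self) -> int:
        return len(self.rows[0])

    def to_array(self) -> np.ndarray:
        return np.frombuffer("".join(self.rows).encode(), dtype=np.uint8).reshape(
            len(self.rows), self.length)


def read_alignment(path: str | Path) -> Alignment:
    recs = list(SeqIO.parse(str(path), "fasta"))
    return Alignment(tuple(r.id for r in recs), tuple(str(r.seq) for r in recs))


@dataclass(frozen=True)
class DistanceMatrix:
    ids: tuple[str, ...]
    values: np.ndarray  # NaN marks an undefined (no comparable sites) entry

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i, j = self.ids.index(pair[0]), self.ids.index(pair[1])
        return float(self.values[i, j])


def _pdist_from_array(arr: np.ndarray, deletion: str) -> np.ndarray:
    n = arr.shape[0]
    valid = np.isin(arr, _VALID)
    if deletion == "complete":
        keep = valid.all(axis=0)
        arr, valid = arr[:, keep], valid[:, keep]
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            comp = valid[i] & valid[j]
            m = int(comp.sum())
            d[i, j] = d[j, i] = np.nan if m == 0 else (arr[i, comp] != arr[j, comp]).sum() / m
    return d


def p_distance(aln: Alignment, deletion: str = "pairwise") -> DistanceMatrix:
    """Pairwise uncorrected p-distances with pairwise or complete gap deletion."""
    if deletion not in ("pairwise", "complete"):
        raise ValueError("deletion must be 'pairwise' or 'complete'")
    return DistanceMatrix(aln.ids, _pdist_from_array(aln.to_array(), deletion))


def _group_means(d: np.ndarray, idx: Sequence[int]) -> float:
    pairs = [d[i, j] for i, j in combinations(idx, 2)]
    pairs = [p for p in pairs if not np.isnan(p)]
    return float(np.mean(pairs)) if pairs else float("nan")


def divergence_summary(aln: Alignment | DistanceMatrix,
                       groups: Mapping[str, Sequence[str]],
                       deletion: str = "pairwise",
                       bootstrap: int = 500, seed: int = 0) -> dict[str, dict]:
    """Mean within-group p-distance with a site-bootstrap standard error.

    ``groups`` maps a group name to member ids.  Singleton groups yield an
    undefined (None) mean, matching the convention of dashing out groups
    with a single member.  When a precomputed :class:`DistanceMatrix` is
    passed, means are reported without SEs (no site-level data available).
    """
    out: dict[str, dict] = {}
    if isinstance(aln, DistanceMatrix):
        for name, members in groups.items():
            idx = [aln.ids.index(m) for m in members]
            if len(idx) < 2:
                out[name] = {"mean": None, "se": None, "n": len(idx)}
            else:
                out[name] = {"mean": _group_means(aln.values, idx), "se": None, "n": len(idx)}
        return out

    arr = aln.to_array()
    d = _pdist_from_array(arr, deletion)
    rng = np.random.default_rng(seed)
    boot_means: dict[str, list[float]] = {name: [] for name in groups}
    if bootstrap:
        for _ in range(bootstrap):
            cols = rng.integers(0, arr.shape[1], size=arr.shape[1])
            db = _pdist_from_array(arr[:, cols], deletion)
            for name, members in groups.items():
                idx = [aln.ids.index(m) for m in members]
                if len(idx) >= 2:
                    boot_means[name].append(_group_means(db, idx))
    for name, members in groups.items():
        idx = [aln.ids.index(m) for m in members]
        if len(idx) < 2:
            out[name] = {"mean": None, "se": None, "n": len(idx)}
            continue
        se = float(np.std(boot_means[name], ddof=1)) if len(boot_means[name]) > 1 else None
        out[name] = {"mean": _group_means(d, idx), "se": se, "n": len(idx)}
    return out
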