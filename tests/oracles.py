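"""Independent brute-force oracles used to cross-check the implementation."""

from itertools import product

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

COMP = {"A": "T", "T": "A", "G": "C", "C": "G"}


def expand_iupac(pattern: str) -> list[str]:
    """All literal ACGT strings a degenerate pattern denotes."""
    return ["".join(p) for p in product(*(IUPAC[c] for c in pattern))]


def scan_by_expansion(seq: str, pattern: str, max_mismatch: int) -> list[tuple[int, int]]:
    """(start, mismatches) of every window within Hamming distance of any
    literal expansion of the pattern; ambiguous sequence bases never match."""
    literals = expand_iupac(pattern)
    m = len(pattern)
    hits = []
    for i in range(len(seq) - m + 1):
        window = seq[i:i + m]
        best = min(sum(a != b for a, b in zip(window, lit)) for lit in literals)
        if best <= max_mismatch:
            hits.append((i, best))
    return hits


def edit_distance_dp(a: str, b: str) -> int:
    """Textbook quadratic Levenshtein DP."""
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[-1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


def p_distance_recount(rows: list[str], pair: tuple[int, int]) -> float | None:
    """Position-by-position mismatch recount with pairwise gap deletion."""
    i, j = pair
    diffs = comp = 0
    for a, b in zip(rows[i].upper(), rows[j].upper()):
        if a in "ACGT" and b in "ACGT":
            comp += 1
            diffs += a != b
    return diffs / comp if comp else None


def stems_exhaustive(seq: str, min_arm: int, max_loop: int, min_identity: float,
                     min_loop: int = 3) -> set[tuple[int, int, int]]:
    """All (arm_start, arm_length, loop_length) hairpin placements, by direct
    pairing of each left-arm base with its mirror partner."""
    n = len(seq)
    out = set()
    for i in range(n):
        for arm in range(min_arm, n + 1):
            for loop in range(min_loop, max_loop + 1):
                j = i + 2 * arm + loop
                if j > n:
                    break
                good = 0
                for k in range(arm):
                    left = seq[i + k]
                    right = seq[j - 1 - k]
                    if left in COMP and COMP[left] == right:
                        good += 1
                if good / arm >= min_identity:
                    out.add((i, arm, loop))
    return out
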