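"""RNA secondary-structure accessibility around editing sites.

A-to-I editing is read out as an A-to-G change, and inosine base-pairs like
guanosine.  This module quantifies how that single substitution changes local
secondary structure: minimum-free-energy (MFE) pairing, the partition-function
probability that a 7-nt window is entirely unpaired ("7mer accessibility"),
and the log2 edited/unedited accessibility profile around a site.  It also
implements the opposite-nucleotide call used to classify what base faces an
editing site in the MFE structure, control-adenosine selection, and the
distance-windowed correlation between accessibility change at the nearest
miRNA target site and the expression ratio of edited vs unedited individuals.

Folding is delegated to the Vienna RNA package through its scripting
bindings, behind a narrow engine interface (MFE structure + windowed unpaired
probabilities with RNAplfold semantics, parameters u=7, L=300, W=400).  A
base-pair-maximisation engine is provided for pair-table unit testing only;
it has no thermodynamic model and cannot compute accessibilities.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "FoldResult",
    "AccessibilityDelta",
    "ViennaEngine",
    "PairMaxEngine",
    "fold_sequence",
    "fold_window",
    "relative_accessibility",
    "opposite_nucleotide",
    "opposite_base_spectrum",
    "select_control_adenosines",
    "accessibility_expression_correlation",
    "pair_table_from_dotbracket",
]

# Floor applied to unpaired probabilities before taking log ratios, so the
# relative-accessibility profile stays finite even when the engine reports
# numerically zero probabilities in tight helices.
PROB_FLOOR = 1e-8


def pair_table_from_dotbracket(structure: str) -> np.ndarray:
    """0-based pair table for a dot-bracket string; -1 marks unpaired.

    Only round brackets are accepted (no pseudoknots).
    """
    n = len(structure)
    table = np.full(n, -1, dtype=int)
    stack: list[int] = []
    for i, c in enumerate(structure):
        if c == "(":
            stack.append(i)
        elif c == ")":
            if not stack:
                raise ValueError(f"unbalanced ')' at position {i}")
            j = stack.pop()
            table[i], table[j] = j, i
        elif c != ".":
            raise ValueError(f"unexpected character {c!r} in dot-bracket string")
    if stack:
        raise ValueError(f"unbalanced '(' at position {stack[-1]}")
    return table


@dataclass(frozen=True)
class FoldResult:
    """A folded sequence with its MFE structure and 7mer accessibilities.

    ``pair_table`` maps each 0-based position to its partner, -1 if unpaired.
    ``accessibility`` holds, per position, the partition-function probability
    that the 7mer centred there is completely unpaired; NaN where a centred
    7mer does not fit (first/last three positions), or everywhere when the
    engine does not provide accessibilities.
    """

    sequence: str
    structure: str
    pair_table: np.ndarray
    accessibility: np.ndarray
    energy: float = float("nan")

    def __post_init__(self) -> None:
        n = len(self.sequence)
        if len(self.structure) != n or len(self.pair_table) != n:
            raise ValueError("sequence/structure/pair-table lengths disagree")
        if len(self.accessibility) != n:
            raise ValueError("accessibility length disagrees with sequence")
        # involution: partner of partner is self
        paired = np.nonzero(self.pair_table >= 0)[0]
        if not np.array_equal(self.pair_table[self.pair_table[paired]], paired):
            raise ValueError("pair table is not involutive")

    def is_paired(self, i: int) -> bool:
        return bool(self.pair_table[i] >= 0)


class ViennaEngine:
    """Folding engine backed by the Vienna RNA scripting bindings.

    ``u``, ``L`` and ``W`` follow RNAplfold's -u/-L/-W parameters: length of
    the unpaired region, maximum base-pair span, and averaging window.
    """

    def __init__(self, u: int = 7, L: int = 300, W: int = 400) -> None:
        if u < 1 or L < 1 or W < 1:
            raise ValueError("u, L, W must be positive")
        self.u, self.L, self.W = u, L, W

    def mfe(self, sequence: str) -> tuple[str, float]:
        import RNA

        structure, energy = RNA.fold(sequence.upper().replace("T", "U"))
        return structure, energy

    def unpaired_probabilities(self, sequence: str) -> np.ndarray:
        """Probability that the u-mer centred at each position is unpaired."""
        import RNA

        seq = sequence.upper().replace("T", "U")
        n = len(seq)
        half = self.u // 2
        # pfl_fold_up rows are 1-based window *end* positions; up[i][u] is the
        # probability that the u-long region ending at i is unpaired.
        up = RNA.pfl_fold_up(seq, self.u, self.W, self.L)
        probs = np.full(n, np.nan)
        for centre in range(half, n - half):
            end_1based = centre + half + 1
            probs[centre] = up[end_1based][self.u]
        return np.clip(probs, 0.0, 1.0)


class PairMaxEngine:
    """Base-pair maximisation (Nussinov-style) fold, for pair-table tests only.

    No energy model, no accessibility; never used for accessibility analyses.
    """

    _CANON = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}

    def __init__(self, min_loop: int = 3) -> None:
        self.min_loop = min_loop

    def mfe(self, sequence: str) -> tuple[str, float]:
        seq = sequence.upper().replace("T", "U")
        n = len(seq)
        dp = np.zeros((n, n), dtype=int)
        for span in range(self.min_loop + 1, n):
            for i in range(n - span):
                j = i + span
                best = dp[i][j - 1]
                for k in range(i, j - self.min_loop):
                    if (seq[k], seq[j]) in self._CANON:
                        left = dp[i][k - 1] if k > i else 0
                        best = max(best, left + 1 + dp[k + 1][j - 1])
                dp[i][j] = best
        struct = ["."] * n

        def traceback(i: int, j: int) -> None:
            if j - i <= self.min_loop:
                return
            if dp[i][j] == dp[i][j - 1]:
                traceback(i, j - 1)
                return
            for k in range(i, j - self.min_loop):
                if (seq[k], seq[j]) in self._CANON:
                    left = dp[i][k - 1] if k > i else 0
                    if left + 1 + dp[k + 1][j - 1] == dp[i][j]:
                        struct[k], struct[j] = "(", ")"
                        if k > i:
                            traceback(i, k - 1)
                        traceback(k + 1, j - 1)
                        return
            raise AssertionError("traceback failed")

        if n > self.min_loop:
            traceback(0, n - 1)
        return "".join(struct), float(-dp[0][n - 1])

    def unpaired_probabilities(self, sequence: str) -> np.ndarray:
        raise NotImplementedError("PairMaxEngine provides MFE pair tables only")


_DEFAULT_ENGINE: ViennaEngine | None = None


def _engine(engine=None):
    global _DEFAULT_ENGINE
    if engine is not None:
        return engine
    if _DEFAULT_ENGINE is None:
        _DEFAULT_ENGINE = ViennaEngine()
    return _DEFAULT_ENGINE


def fold_sequence(sequence: str, engine=None, with_accessibility: bool = True) -> FoldResult:
    """Fold one sequence: MFE structure plus (optionally) 7mer accessibility."""
    eng = _engine(engine)
    seq = sequence.upper().replace("T", "U")
    structure, energy = eng.mfe(seq)
    table = pair_table_from_dotbracket(structure)
    if with_accessibility:
        acc = eng.unpaired_probabilities(seq)
    else:
        acc = np.full(len(seq), np.nan)
    return FoldResult(seq, structure, table, acc, energy)


def fold_window(
    sequence: str,
    site_pos: int,
    window: int = 1001,
    engine=None,
    with_accessibility: bool = True,
) -> tuple[FoldResult, FoldResult, int]:
    """Fold the unedited and edited (A->G) variants of a window around a site.

    A ``window``-nt stretch centred on ``site_pos`` is extracted (truncated at
    the sequence ends when the site sits near a boundary) and folded twice
    with identical engine settings: once as-is and once with the site's A
    replaced by G.  Returns ``(unedited, edited, window_start)`` where
    ``window_start`` is the 0-based offset of the window in ``sequence``.
    """
    seq = sequence.upper().replace("T", "U")
    if not 0 <= site_pos < len(seq):
        raise ValueError("site position outside sequence")
    if seq[site_pos] != "A":
        raise ValueError(f"base at editing site is {seq[site_pos]!r}, expected 'A'")
    half = window // 2
    start = max(0, site_pos - half)
    end = min(len(seq), site_pos + half + 1)
    sub = seq[start:end]
    pos = site_pos - start
    edited_seq = sub[:pos] + "G" + sub[pos + 1 :]
    unedited = fold_sequence(sub, engine, with_accessibility)
    edited = fold_sequence(edited_seq, engine, with_accessibility)
    return unedited, edited, start


@dataclass(frozen=True)
class AccessibilityDelta:
    """Per-offset log2 (edited / unedited) 7mer accessibility around a site.

    Offset 0 is the editing site; the 7mer is centred at each offset.  Values
    are NaN where a centred 7mer does not fit inside the folding window.
    """

    site_id: str
    offsets: np.ndarray
    log2_ratio: np.ndarray

    def within(self, lo: int, hi: int) -> np.ndarray:
        mask = (self.offsets >= lo) & (self.offsets <= hi)
        return self.log2_ratio[mask]

    def at(self, offset: int) -> float:
        idx = np.nonzero(self.offsets == offset)[0]
        if len(idx) == 0:
            return float("nan")
        return float(self.log2_ratio[idx[0]])


def relative_accessibility(
    unedited: FoldResult, edited: FoldResult, site_pos: int, site_id: str = ""
) -> AccessibilityDelta:
    """log2 accessibility change caused by the A->G substitution, per offset."""
    if len(unedited.sequence) != len(edited.sequence):
        raise ValueError("unedited/edited windows have different lengths")
    diff = [
        i
        for i, (a, b) in enumerate(zip(unedited.sequence, edited.sequence))
        if a != b
    ]
    if diff and diff != [site_pos]:
        raise ValueError("sequences differ away from the editing site")
    n = len(unedited.sequence)
    offsets = np.arange(n) - site_pos
    pu = np.clip(unedited.accessibility, PROB_FLOOR, 1.0)
    pe = np.clip(edited.accessibility, PROB_FLOOR, 1.0)
    ratio = np.log2(pe) - np.log2(pu)
    ratio[np.isnan(unedited.accessibility) | np.isnan(edited.accessibility)] = np.nan
    return AccessibilityDelta(site_id, offsets, ratio)


def opposite_nucleotide(fold: FoldResult, site_pos: int) -> str:
    """Base structurally opposite an editing site in the MFE structure.

    If the site is paired, its partner's base is returned.  If it is unpaired
    but an immediate neighbour is paired, the base adjacent to the neighbour's
    partner (on the far side, per antiparallel geometry) is returned; the 5'
    neighbour is consulted first.  Otherwise (loops, multi-branch bulges) 'N'.
    """
    pt = fold.pair_table
    n = len(pt)
    if not 0 <= site_pos < n:
        raise ValueError("site position outside structure")
    j = pt[site_pos]
    if j >= 0:
        return fold.sequence[j]
    if site_pos - 1 >= 0 and pt[site_pos - 1] >= 0:
        idx = pt[site_pos - 1] - 1
        return fold.sequence[idx] if 0 <= idx < n else "N"
    if site_pos + 1 < n and pt[site_pos + 1] >= 0:
        idx = pt[site_pos + 1] + 1
        return fold.sequence[idx] if 0 <= idx < n else "N"
    return "N"


def opposite_base_spectrum(
    folds_unedited: Sequence[FoldResult],
    folds_edited: Sequence[FoldResult],
    site_positions: Sequence[int],
) -> pd.DataFrame:
    """Frequencies of bases opposite editing sites, unedited vs edited folds.

    Returns a tidy table with one row per (variant, base) plus the fraction
    of sites whose editing position is directly paired in each variant.
    """
    if len(folds_unedited) == 0:
        raise ValueError("no sites supplied")
    if not (len(folds_unedited) == len(folds_edited) == len(site_positions)):
        raise ValueError("fold lists and site positions differ in length")
    rows = []
    for variant, folds in (("unedited", folds_unedited), ("edited", folds_edited)):
        bases = [opposite_nucleotide(f, p) for f, p in zip(folds, site_positions)]
        paired = [f.is_paired(p) for f, p in zip(folds, site_positions)]
        total = len(bases)
        for b in "ACGUN":
            rows.append(
                {
                    "variant": variant,
                    "base": b,
                    "count": bases.count(b),
                    "frequency": bases.count(b) / total,
                    "paired_fraction": sum(paired) / total,
                }
            )
    return pd.DataFrame(rows)


def select_control_adenosines(
    sequences: Mapping[str, str],
    edit_sites: Mapping[str, Sequence[int]],
    dist_range: tuple[int, int] = (300, 500),
    n: int = 100,
    seed: int = 0,
    utr3_intervals: Mapping[str, tuple[int, int]] | None = None,
) -> list[tuple[str, int]]:
    """Sample control A positions at a controlled distance from editing sites.

    Candidates are adenosines that are (1) not editing sites, (2) inside the
    3' UTR (the whole sequence unless ``utr3_intervals`` restricts it), and
    (3) whose distance to the nearest editing site falls in ``dist_range``
    (inclusive).  ``n`` positions are drawn uniformly without replacement.
    """
    lo, hi = dist_range
    if lo < 0 or hi < lo:
        raise ValueError("invalid distance range")
    candidates: list[tuple[str, int]] = []
    for gene, seq in sequences.items():
        sites = sorted(edit_sites.get(gene, []))
        if not sites:
            continue
        start, end = (0, len(seq))
        if utr3_intervals and gene in utr3_intervals:
            start, end = utr3_intervals[gene]
        arr = np.array(sites)
        for pos in range(start, end):
            if seq[pos].upper() not in ("A",):
                continue
            if pos in sites:
                continue
            d = int(np.min(np.abs(arr - pos)))
            if lo <= d <= hi:
                candidates.append((gene, pos))
    if not candidates:
        raise ValueError("no control adenosines satisfy the distance constraints")
    if n > len(candidates):
        raise ValueError(
            f"requested {n} controls but only {len(candidates)} candidates exist"
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(candidates), size=n, replace=False)
    return [candidates[i] for i in sorted(idx)]


def accessibility_expression_correlation(
    per_gene: pd.DataFrame,
    window: int = 10,
    slide: int = 1,
) -> tuple[float, float, pd.DataFrame]:
    """Distance-windowed correlation of accessibility change with expression.

    ``per_gene`` has one row per gene with columns ``distance`` (nt between
    editing site and its closest miRNA target site), ``delta`` (relative 7mer
    accessibility at the target site) and ``log2_ratio`` (log2 expression
    ratio of edited over unedited individuals).  Genes are grouped into
    ``window``-nt sliding distance windows (step ``slide``); the Pearson
    correlation is computed across non-empty window means.

    Returns ``(r, p, window_table)``; ``r`` is NaN (correlation undefined)
    when fewer than 3 non-empty windows exist or the deltas are constant.
    """
    required = {"distance", "delta", "log2_ratio"}
    if not required.issubset(per_gene.columns):
        raise ValueError(f"per_gene must have columns {sorted(required)}")
    df = per_gene.dropna(subset=["distance", "delta", "log2_ratio"])
    rows = []
    if len(df):
        dmin, dmax = int(df["distance"].min()), int(df["distance"].max())
        for start in range(dmin, max(dmin, dmax - window + 1) + 1, slide):
            sel = df[(df["distance"] >= start) & (df["distance"] < start + window)]
            if len(sel) == 0:
                continue
            rows.append(
                {
                    "window_start": start,
                    "n_genes": len(sel),
                    "mean_delta": sel["delta"].mean(),
                    "mean_log2_ratio": sel["log2_ratio"].mean(),
                }
            )
    table = pd.DataFrame(rows)
    if len(table) < 3 or table["mean_delta"].nunique() < 2:
        return float("nan"), float("nan"), table
    r, p = stats.pearsonr(table["mean_delta"], table["mean_log2_ratio"])
    return float(r), float(p), table
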