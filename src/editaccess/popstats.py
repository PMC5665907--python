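"""Population-level editome statistics.

Operates on an :class:`EditingMatrix` — editing levels and read depths for a
set of sites across individuals with population labels.  A site-individual
pair is *testable* when read depth >= 10; levels at untestable cells are
treated as missing throughout.  Implements site prevalence and its
rare/prevalent classification, per-individual mean editing and the
depth-weighted editing index, hypergeometric sharing tests, rank-sum
differential editing with an effect-size floor, the per-site variance in
editing explained by ADAR1/2/3 expression, sequence-context (UAG) enrichment,
paired-nucleotide window profiles, and RPKM.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Collection, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "EditingMatrix",
    "PrevalenceRecord",
    "prevalence",
    "prevalence_table",
    "mean_editing_per_individual",
    "editing_index",
    "overlap_test",
    "rank_sum_test",
    "differential_editing",
    "minimum_detectable_delta",
    "variance_explained",
    "context_enrichment",
    "paired_window_profile",
    "compute_rpkm",
    "population_correlation_contrast",
]

MIN_TESTABLE_DEPTH = 10
EDITED_MIN_ALT = 2
EDITED_MIN_LEVEL = 0.1


@dataclass
class EditingMatrix:
    """Sites x individuals editing levels with depth-aware missingness.

    ``levels``/``depths``/``alts`` share the same index (site ids) and
    columns (individual ids); ``populations`` maps individual id to its
    population label.  Levels are masked to NaN wherever depth < 10.
    """

    levels: pd.DataFrame
    depths: pd.DataFrame
    alts: pd.DataFrame
    populations: pd.Series

    def __post_init__(self) -> None:
        for name, df in (("depths", self.depths), ("alts", self.alts)):
            if not df.index.equals(self.levels.index) or not df.columns.equals(
                self.levels.columns
            ):
                raise ValueError(f"{name} shape disagrees with levels")
        missing = set(self.levels.columns) - set(self.populations.index)
        if missing:
            raise ValueError(f"individuals without population label: {sorted(missing)}")
        self.levels = self.levels.where(self.depths >= MIN_TESTABLE_DEPTH)

    @classmethod
    def from_counts(
        cls, alts: pd.DataFrame, depths: pd.DataFrame, populations: pd.Series
    ) -> "EditingMatrix":
        with np.errstate(divide="ignore", invalid="ignore"):
            levels = alts / depths
        return cls(levels.astype(float), depths, alts, populations)

    @property
    def testable(self) -> pd.DataFrame:
        return self.depths >= MIN_TESTABLE_DEPTH

    @property
    def edited(self) -> pd.DataFrame:
        """Edited calls: testable, >= 2 edited reads and level >= 0.1."""
        return (
            self.testable
            & (self.alts >= EDITED_MIN_ALT)
            & (self.levels >= EDITED_MIN_LEVEL)
        )

    def individuals_of(self, population: str) -> list[str]:
        ids = [i for i in self.levels.columns if self.populations[i] == population]
        if not ids:
            raise ValueError(f"population {population!r} has no individuals")
        return ids


@dataclass(frozen=True)
class PrevalenceRecord:
    site: str
    percent: float
    n_testable: int
    n_edited: int
    category: str  # rare (<=10%), intermediate, prevalent (>90%), untestable


def prevalence(matrix: EditingMatrix, site: str) -> PrevalenceRecord:
    """% of testable individuals in which the site is edited."""
    testable = matrix.testable.loc[site]
    n_testable = int(testable.sum())
    if n_testable == 0:
        return PrevalenceRecord(site, float("nan"), 0, 0, "untestable")
    n_edited = int(matrix.edited.loc[site].sum())
    pct = 100.0 * n_edited / n_testable
    if pct > 90.0:
        cat = "prevalent"
    elif pct <= 10.0:
        cat = "rare"
    else:
        cat = "intermediate"
    return PrevalenceRecord(site, pct, n_testable, n_edited, cat)


def prevalence_table(matrix: EditingMatrix) -> pd.DataFrame:
    recs = [prevalence(matrix, s) for s in matrix.levels.index]
    return pd.DataFrame(
        {
            "site": [r.site for r in recs],
            "percent": [r.percent for r in recs],
            "n_testable": [r.n_testable for r in recs],
            "n_edited": [r.n_edited for r in recs],
            "category": [r.category for r in recs],
        }
    ).set_index("site")


def mean_editing_per_individual(matrix: EditingMatrix, individual: str) -> float:
    """Unweighted mean editing level over the individual's testable sites."""
    levels = matrix.levels[individual].dropna()
    if len(levels) == 0:
        return float("nan")
    return float(levels.mean())


def editing_index(matrix: EditingMatrix, individual: str) -> float:
    """Depth-weighted editing: total edited reads / total reads, testable sites."""
    testable = matrix.testable[individual]
    if not testable.any():
        return float("nan")
    alt = matrix.alts.loc[testable, individual].sum()
    depth = matrix.depths.loc[testable, individual].sum()
    return float(alt / depth)


def overlap_test(
    set_a: Collection, set_b: Collection, background: Collection | int
) -> tuple[int, float]:
    """Overlap of two site sets with an upper-tail hypergeometric p value.

    ``background`` is the universe the sets are drawn from (a collection, or
    its size when containment need not be checked).  p = P(X >= overlap).
    """
    a, b = set(set_a), set(set_b)
    if isinstance(background, int):
        n_bg = background
        if len(a) > n_bg or len(b) > n_bg:
            raise ValueError("set larger than background")
    else:
        bg = set(background)
        if not a <= bg or not b <= bg:
            raise ValueError("sets must be contained in the background")
        n_bg = len(bg)
    overlap = len(a & b)
    # P(X >= k) for X ~ Hypergeom(N=n_bg, K=|A|, n=|B|)
    p = float(stats.hypergeom.sf(overlap - 1, n_bg, len(a), len(b)))
    return overlap, min(1.0, p)


def rank_sum_test(x: Sequence[float], y: Sequence[float], exact_max: int = 8) -> float:
    """Two-sided Wilcoxon rank-sum p value.

    Exact permutation enumeration (midranks for ties) when both group sizes
    are <= ``exact_max``; otherwise the normal approximation with continuity
    and tie correction.  The exact two-sided p counts permutations whose
    rank-sum deviates from its null mean by at least the observed deviation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = len(x), len(y)
    if nx == 0 or ny == 0:
        raise ValueError("both groups must be non-empty")
    if nx <= exact_max and ny <= exact_max:
        pooled = np.concatenate([x, y])
        ranks = stats.rankdata(pooled)
        observed = ranks[:nx].sum()
        mu = nx * (nx + ny + 1) / 2.0
        dev = abs(observed - mu)
        total = 0
        hits = 0
        for combo in itertools.combinations(range(nx + ny), nx):
            total += 1
            if abs(ranks[list(combo)].sum() - mu) >= dev - 1e-9:
                hits += 1
        return hits / total
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(res.pvalue)


@dataclass(frozen=True)
class DifferentialResult:
    p: float
    delta: float
    is_differential: bool
    tested: bool
    reason: str = ""


def differential_editing(
    matrix: EditingMatrix,
    site: str,
    group_a: Sequence[str],
    group_b: Sequence[str],
    p_threshold: float = 0.01,
    delta_threshold: float = 0.067,
    min_group: int = 3,
) -> DifferentialResult:
    """Differential editing between two groups of individuals at one site.

    Two-sided rank-sum p on testable levels plus an effect-size floor: the
    absolute difference in mean editing levels must exceed
    ``delta_threshold`` (one edited read at read coverage 15).
    """
    a = matrix.levels.loc[site, list(group_a)].dropna()
    b = matrix.levels.loc[site, list(group_b)].dropna()
    if len(a) < min_group or len(b) < min_group:
        return DifferentialResult(
            float("nan"), float("nan"), False, False, "insufficient testable individuals"
        )
    delta = abs(a.mean() - b.mean())
    if np.ptp(np.concatenate([a.values, b.values])) == 0:
        return DifferentialResult(1.0, float(delta), False, True, "")
    p = rank_sum_test(a.values, b.values)
    return DifferentialResult(
        float(p), float(delta), bool(p < p_threshold and delta > delta_threshold), True
    )


def minimum_detectable_delta(coverage: int = 15, ndigits: int = 3) -> float:
    """Smallest editing-level difference one edited read can make at a depth.

    At read coverage 15 this is 1/15 = 0.067 (3 decimals), the floor applied
    by :func:`differential_editing`.
    """
    if coverage < 1:
        raise ValueError("coverage must be positive")
    return round(1.0 / coverage, ndigits)


def variance_explained(
    levels: pd.Series,
    adar: pd.DataFrame,
    min_testable: int = 10,
) -> tuple[float | None, str]:
    """R^2 of per-site editing levels regressed on ADAR1/2/3 expression.

    Least-squares fit with intercept, taking the editing level as the
    dependent variable and the three ADAR expression levels as regressors.
    Eligibility: more than ``min_testable`` testable individuals and at least
    two distinct levels.  Returns ``(r2, reason)``; ``r2`` is None with a
    reason when the site is ineligible.
    """
    joined = pd.concat([levels.rename("level"), adar], axis=1).dropna()
    if len(joined) <= min_testable:
        return None, f"needs > {min_testable} testable individuals"
    y = joined["level"].to_numpy()
    if len(np.unique(y)) < 2:
        return None, "fewer than 2 distinct editing levels"
    X = np.column_stack([np.ones(len(joined)), joined.drop(columns="level").to_numpy()])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot
    return float(np.clip(r2, 0.0, 1.0)), ""


def context_enrichment(
    prevalent_contexts: Sequence[str], rare_contexts: Sequence[str]
) -> tuple[pd.DataFrame, float]:
    """±1-nt sequence context comparison between prevalent and rare sites.

    Contexts are 3-mers centred on the edited A.  Returns a per-position
    nucleotide frequency-difference table (prevalent minus rare) and the
    two-sided Fisher exact p for the 2x2 table of UAG vs non-UAG counts.
    """
    if len(prevalent_contexts) == 0 or len(rare_contexts) == 0:
        raise ValueError("both context groups must be non-empty")

    def check(group: Sequence[str], name: str) -> list[str]:
        out = []
        for c in group:
            c = c.upper().replace("T", "U")
            if len(c) != 3 or c[1] != "A":
                raise ValueError(f"{name} context {c!r} is not a 3-mer centred on A")
            out.append(c)
        return out

    prev = check(prevalent_contexts, "prevalent")
    rare = check(rare_contexts, "rare")
    rows = []
    for pos, label in ((0, -1), (1, 0), (2, 1)):
        for base in "ACGU":
            fp = sum(c[pos] == base for c in prev) / len(prev)
            fr = sum(c[pos] == base for c in rare) / len(rare)
            rows.append(
                {"position": label, "base": base, "freq_prevalent": fp,
                 "freq_rare": fr, "difference": fp - fr}
            )
    table = pd.DataFrame(rows)
    uag_prev = sum(c == "UAG" for c in prev)
    uag_rare = sum(c == "UAG" for c in rare)
    _, p = stats.fisher_exact(
        [[uag_prev, len(prev) - uag_prev], [uag_rare, len(rare) - uag_rare]],
        alternative="two-sided",
    )
    return table, float(p)


def paired_window_profile(
    pair_tables: Sequence[np.ndarray],
    site_positions: Sequence[int],
    window: int = 9,
    max_offset: int = 50,
) -> pd.DataFrame:
    """Mean paired-nucleotide count in a sliding window around sites.

    For each offset, a ``window``-nt window (default 9, the footprint of the
    ADAR double-stranded binding region) is centred at site + offset in each
    MFE pair table and the number of paired positions counted.  Windows that
    would extend past a sequence are skipped for that sequence, not
    zero-filled.  Returns offset, mean, SEM and the number of contributing
    sequences.
    """
    if window % 2 != 1:
        raise ValueError("window must be odd so it can be centred")
    half = window // 2
    rows = []
    for offset in range(-max_offset, max_offset + 1):
        counts = []
        for pt, pos in zip(pair_tables, site_positions):
            centre = pos + offset
            if centre - half < 0 or centre + half >= len(pt):
                continue
            counts.append(int(np.sum(pt[centre - half : centre + half + 1] >= 0)))
        if counts:
            arr = np.array(counts, dtype=float)
            sem = arr.std(ddof=1) / np.sqrt(len(arr)) if len(arr) > 1 else 0.0
            rows.append(
                {"offset": offset, "mean_paired": arr.mean(), "sem": sem, "n": len(arr)}
            )
        else:
            rows.append({"offset": offset, "mean_paired": np.nan, "sem": np.nan, "n": 0})
    return pd.DataFrame(rows)


def compute_rpkm(
    counts: np.ndarray | pd.Series,
    gene_lengths: np.ndarray | pd.Series,
    total_mapped: float,
) -> np.ndarray | pd.Series:
    """Reads per kilobase of transcript per million mapped reads."""
    lengths = np.asarray(gene_lengths, dtype=float)
    if np.any(lengths <= 0):
        raise ValueError("gene lengths must be positive")
    if total_mapped <= 0:
        raise ValueError("total mapped reads must be positive")
    return counts * 1.0e9 / (lengths * total_mapped)


def population_correlation_contrast(matrix: EditingMatrix, max_pairs: int = 2000,
                                    seed: int = 0) -> tuple[float, float]:
    """Mean within- vs between-population correlation of editing levels.

    Pearson correlation over sites testable in both individuals of a pair;
    pairs are subsampled when there are more than ``max_pairs`` of a kind.
    Returns ``(intra_mean, inter_mean)``.
    """
    rng = np.random.default_rng(seed)
    ids = list(matrix.levels.columns)
    intra, inter = [], []
    pairs = list(itertools.combinations(ids, 2))
    if len(pairs) > max_pairs:
        idx = rng.choice(len(pairs), size=max_pairs, replace=False)
        pairs = [pairs[i] for i in idx]
    for a, b in pairs:
        sub = matrix.levels[[a, b]].dropna()
        if len(sub) < 3 or sub[a].nunique() < 2 or sub[b].nunique() < 2:
            continue
        r = float(np.corrcoef(sub[a], sub[b])[0, 1])
        if matrix.populations[a] == matrix.populations[b]:
            intra.append(r)
        else:
            inter.append(r)
    return float(np.mean(intra)), float(np.mean(inter))
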