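"""miRNA seed matching, editing-to-target distances, and group contrasts.

Canonical seed-site matching (8mer, 7mer-m8, 7mer-A1) is the internal
stand-in for precomputed target predictions; BED-style target intervals can
also be supplied directly.  On top of the matcher sit the distance analyses
(closest target site per editing site, cumulative editing-vs-distance
profile), the population stratifications that compare miRNA target gene
expression between ADAR1 (or AGO2-and-miRNA) tertiles under covariate
matching, and knockdown-vs-control contrasts with replicate averaging.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .popstats import rank_sum_test

__all__ = [
    "TargetSite",
    "GroupComparison",
    "find_seed_matches",
    "top_expressed_mirnas",
    "nearest_target_distance",
    "editing_vs_distance_profile",
    "assign_tertiles",
    "stratified_comparison",
    "kd_contrast",
]

_COMPLEMENT = str.maketrans("ACGU", "UGCA")
_VALID = set("ACGU")


def _revcomp(rna: str) -> str:
    return rna.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class TargetSite:
    """A predicted miRNA target site in a 3' UTR (half-open interval)."""

    mirna_id: str
    start: int
    end: int
    site_type: str  # 8mer, 7mer-m8, 7mer-A1
    gene_id: str = ""

    def __post_init__(self) -> None:
        expected = {"8mer": 8, "7mer-m8": 7, "7mer-A1": 7}
        if self.site_type not in expected:
            raise ValueError(f"unknown site type {self.site_type!r}")
        if self.end - self.start != expected[self.site_type]:
            raise ValueError("interval length does not match site type")


def find_seed_matches(
    utr_sequence: str, mirna_sequence: str, mirna_id: str = "", gene_id: str = ""
) -> list[TargetSite]:
    """All canonical seed matches of one miRNA in one 3' UTR.

    Site types follow the TargetScan conventions: 7mer-m8 is the reverse
    complement of miRNA nucleotides 2-8; 7mer-A1 is the reverse complement of
    nucleotides 2-7 followed by an A in the UTR; 8mer combines both.  A locus
    matching the 8mer is reported once, as an 8mer.
    """
    utr = utr_sequence.upper().replace("T", "U")
    mirna = mirna_sequence.upper().replace("T", "U")
    if len(mirna) < 8:
        raise ValueError("miRNA must be at least 8 nt")
    if not set(utr) <= _VALID or not set(mirna) <= _VALID:
        raise ValueError("sequences must be RNA (ACGU)")
    m8_heptamer = _revcomp(mirna[1:8])  # pairs miRNA nt 2-8
    hexamer = _revcomp(mirna[1:7])  # pairs miRNA nt 2-7
    sites: list[TargetSite] = []
    claimed: set[int] = set()
    # 8mer: m8 heptamer followed by A (the A across from miRNA nt 1)
    eight = m8_heptamer + "A"
    for i in range(len(utr) - 7):
        if utr[i : i + 8] == eight:
            sites.append(TargetSite(mirna_id, i, i + 8, "8mer", gene_id))
            claimed.update(range(i, i + 8))
    for i in range(len(utr) - 6):
        if utr[i : i + 7] == m8_heptamer and not (set(range(i, i + 7)) & claimed):
            sites.append(TargetSite(mirna_id, i, i + 7, "7mer-m8", gene_id))
    for i in range(len(utr) - 6):
        if (
            utr[i : i + 6] == hexamer
            and utr[i + 6] == "A"
            and utr[i : i + 7] != m8_heptamer
            and not (set(range(i, i + 7)) & claimed)
        ):
            sites.append(TargetSite(mirna_id, i, i + 7, "7mer-A1", gene_id))
    return sorted(sites, key=lambda s: (s.start, s.site_type))


def top_expressed_mirnas(mirna_expression: pd.DataFrame, k: int = 20) -> list[str]:
    """The k most highly expressed miRNAs (mean across individuals)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    means = mirna_expression.mean(axis=1).sort_values(ascending=False)
    return list(means.index[:k])


def nearest_target_distance(
    edit_pos: int, target_sites: Sequence[TargetSite]
) -> tuple[int, TargetSite]:
    """Edge-to-edge distance from an editing site to its closest target site.

    Distance is 0 when the site falls inside the seed interval (the rare
    seed-overlap category).  Equidistant candidates resolve toward the 5'
    (smaller-start) site.
    """
    if not target_sites:
        raise ValueError("no target sites supplied (gene is no-target)")

    def dist(site: TargetSite) -> int:
        if site.start <= edit_pos < site.end:
            return 0
        if edit_pos < site.start:
            return site.start - edit_pos
        return edit_pos - (site.end - 1)

    best = min(target_sites, key=lambda s: (dist(s), s.start))
    return dist(best), best


def editing_vs_distance_profile(
    distances: Sequence[float],
    levels: Sequence[float],
    x_grid: Sequence[float] = tuple(range(25, 1025, 25)),
    close_max: float = 50.0,
    far_range: tuple[float, float] = (500.0, 1000.0),
) -> tuple[pd.DataFrame, float]:
    """Cumulative mean editing level vs distance to the nearest target site.

    For each x on the grid the mean (with SEM) is taken over all sites whose
    distance is <= x; empty cutoffs are reported as missing.  Also returns
    the rank-sum p contrasting close (< ``close_max``) against relatively far
    (``far_range``) sites, NaN when either stratum is empty.
    """
    d = np.asarray(distances, dtype=float)
    lv = np.asarray(levels, dtype=float)
    if len(d) == 0 or len(d) != len(lv):
        raise ValueError("distances and levels must be equal-length, non-empty")
    rows = []
    for x in x_grid:
        sel = lv[d <= x]
        if len(sel) == 0:
            rows.append({"x": x, "mean_level": np.nan, "sem": np.nan, "n": 0})
        else:
            sem = sel.std(ddof=1) / np.sqrt(len(sel)) if len(sel) > 1 else 0.0
            rows.append({"x": x, "mean_level": sel.mean(), "sem": sem, "n": len(sel)})
    close = lv[d < close_max]
    far = lv[(d >= far_range[0]) & (d <= far_range[1])]
    p = rank_sum_test(close, far) if len(close) and len(far) else float("nan")
    return pd.DataFrame(rows), p


def assign_tertiles(values: pd.Series) -> pd.Series:
    """Rank-based tertiles (0 = low, 1 = mid, 2 = high), deterministic ties.

    Ties are broken by the index label so the partition is reproducible;
    group sizes differ by at most one.
    """
    if len(values) < 3:
        raise ValueError("need at least 3 individuals for tertiles")
    order = sorted(values.index, key=lambda i: (values[i], str(i)))
    n = len(order)
    base, extra = divmod(n, 3)
    sizes = [base + (1 if i < extra else 0) for i in range(3)]
    labels = {}
    pos = 0
    for tertile, size in enumerate(sizes):
        for i in order[pos : pos + size]:
            labels[i] = tertile
        pos += size
    return pd.Series(labels, name="tertile").reindex(values.index)


@dataclass
class GroupComparison:
    """High-vs-low tertile contrast of target-gene expression."""

    grouping: str
    feasible: bool
    reason: str
    n_high: int
    n_low: int
    covariate_match_p: dict[str, float]
    log2_fold_change: pd.Series  # per gene, high over low
    control_log2_fold_change: pd.Series  # same contrast, no-editing genes


def stratified_comparison(
    expression: pd.DataFrame,
    profiles: pd.DataFrame,
    grouping: str | Sequence[str],
    covariates: Sequence[str],
    eligible_genes: Sequence[str],
    control_genes: Sequence[str] = (),
    covariate_stratum: int | None = None,
    match_p: float = 0.1,
    min_group: int = 3,
) -> GroupComparison:
    """Compare target-gene expression between grouping-variable tertiles.

    Individuals are split into three equally populated tertiles of the
    grouping variable (for a multi-variable grouping such as AGO2-and-miRNA,
    the product of the variables is used).  The high and low tertiles are
    compared, optionally restricted to individuals in one tertile of the
    first covariate (``covariate_stratum``); every covariate must be
    insignificantly different between the compared groups (rank-sum p >
    ``match_p``), otherwise the comparison is infeasible.  Emits the per-gene
    log2 fold change of mean expression (high over low) for eligible genes
    and for no-editing control genes.
    """
    grouping_vars = [grouping] if isinstance(grouping, str) else list(grouping)
    values = profiles[grouping_vars].prod(axis=1)
    name = "&".join(grouping_vars)
    tertiles = assign_tertiles(values)
    high = set(tertiles.index[tertiles == 2])
    low = set(tertiles.index[tertiles == 0])
    if covariate_stratum is not None and covariates:
        cov_t = assign_tertiles(profiles[covariates[0]])
        keep = set(cov_t.index[cov_t == covariate_stratum])
        high &= keep
        low &= keep
    high_l, low_l = sorted(high), sorted(low)

    def empty() -> pd.Series:
        return pd.Series(dtype=float)

    if len(high_l) < min_group or len(low_l) < min_group:
        return GroupComparison(
            name, False, f"fewer than {min_group} individuals in a group",
            len(high_l), len(low_l), {}, empty(), empty(),
        )
    match_ps = {}
    for cov in covariates:
        p = rank_sum_test(
            profiles.loc[high_l, cov].to_numpy(), profiles.loc[low_l, cov].to_numpy()
        )
        match_ps[cov] = float(p)
    bad = [c for c, p in match_ps.items() if p <= match_p]
    if bad:
        return GroupComparison(
            name, False, f"covariates differ between groups: {bad}",
            len(high_l), len(low_l), match_ps, empty(), empty(),
        )

    def log2fc(gene_list: Sequence[str]) -> pd.Series:
        gene_list = [g for g in gene_list if g in expression.index]
        hi = expression.loc[gene_list, high_l].mean(axis=1)
        lo = expression.loc[gene_list, low_l].mean(axis=1)
        return np.log2(hi / lo)

    return GroupComparison(
        name, True, "", len(high_l), len(low_l), match_ps,
        log2fc(eligible_genes), log2fc(control_genes),
    )


def kd_contrast(
    expression: pd.DataFrame,
    editing_levels: pd.DataFrame,
    kd_replicates: Sequence[str],
    control_replicates: Sequence[str],
    near_target_sites: Sequence[str],
    control_sites: Sequence[str],
) -> dict:
    """Knockdown-vs-control contrast with replicate averaging.

    Expression of each gene is first averaged across the replicates of each
    condition, then the KD/control ratio is formed per gene.  Editing-level
    differences (KD minus control, replicate-averaged) are compared between
    sites near predicted miRNA target sites and the stated control group
    (rank-sum).  ``expression`` and ``editing_levels`` are indexed by gene and
    site respectively, with one column per replicate sample.
    """
    for col in list(kd_replicates) + list(control_replicates):
        if col not in expression.columns or col not in editing_levels.columns:
            raise ValueError(f"missing replicate column {col!r}")
    expr_kd = expression[list(kd_replicates)].mean(axis=1)
    expr_ctrl = expression[list(control_replicates)].mean(axis=1)
    fold_change = expr_kd / expr_ctrl
    ed_kd = editing_levels[list(kd_replicates)].mean(axis=1)
    ed_ctrl = editing_levels[list(control_replicates)].mean(axis=1)
    editing_diff = ed_kd - ed_ctrl
    near = editing_diff.loc[[s for s in near_target_sites if s in editing_diff.index]]
    ctrl = editing_diff.loc[[s for s in control_sites if s in editing_diff.index]]
    if len(near) and len(ctrl) and (near.nunique() > 1 or ctrl.nunique() > 1):
        p = rank_sum_test(near.to_numpy(), ctrl.to_numpy())
    elif len(near) and len(ctrl):
        p = 1.0
    else:
        p = float("nan")
    return {
        "expression_fold_change": fold_change,
        "editing_difference": editing_diff,
        "near_target_diff": near,
        "control_diff": ctrl,
        "contrast_p": float(p),
    }
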