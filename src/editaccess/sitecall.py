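"""Calling and filtering A-to-I editing sites from pileup mismatch tables.

Candidate sites arrive as per-individual pileup summaries (depth, alt count,
base qualities of the alt-supporting reads).  The caller applies a
likelihood-ratio test against a sequencing-error-only model, followed by the
filter cascade used for population editomes: read coverage >= 10, >= 2 edited
reads, editing level >= 0.1, and exclusion of known SNPs, simple repeats,
homopolymer runs longer than 4 nt, and intronic positions within 4 nt of a
splice junction.  Population-level site selection and the genomic-context
priority classification (CDS > 3'UTR > 5'UTR > ncExon > Intron-close >
Intron-deep > Intergenic) live here too.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .popstats import EditingMatrix

__all__ = [
    "MismatchObservation",
    "AnnotationSet",
    "EditingSite",
    "FilterResult",
    "compute_llr",
    "filter_sites",
    "classify_context",
    "select_population_sites",
    "a2g_fraction",
    "FILTER_ORDER",
    "CONTEXT_PRIORITY",
]

# Fixed evaluation order; only the "first failing rule" label depends on it,
# the surviving set does not.
FILTER_ORDER = (
    "coverage",
    "edited_reads",
    "editing_level",
    "llr",
    "snp",
    "simple_repeat",
    "homopolymer",
    "splice_junction",
)

CONTEXT_PRIORITY = (
    "CDS",
    "UTR3",
    "UTR5",
    "ncExon",
    "Intron-close",
    "Intron-deep",
    "Intergenic",
)

INTRON_CLOSE_MAX_DIST = 300  # nt from an exon-intron boundary
SPLICE_MARGIN = 4  # intronic sites within 4 nt of a junction are excluded
HOMOPOLYMER_MAX = 4  # runs longer than this are excluded

_COMPLEMENT = {"A": "U", "C": "G", "G": "C", "U": "A", "T": "A", "N": "N"}


@dataclass(frozen=True)
class MismatchObservation:
    """One site x individual pileup summary."""

    contig: str
    pos0: int
    strand: str
    ref: str
    alt: str
    depth: int
    alt_count: int
    quals: tuple[int, ...] = ()
    read_pos: tuple[int, ...] = ()
    individual: str = ""

    def __post_init__(self) -> None:
        if not 0 <= self.alt_count <= self.depth:
            raise ValueError("alt_count must lie in [0, depth]")
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")
        for b in (self.ref, self.alt):
            if b.upper() not in "ACGTUN":
                raise ValueError(f"invalid base {b!r}")

    @property
    def level(self) -> float:
        return self.alt_count / self.depth if self.depth else float("nan")

    @property
    def testable(self) -> bool:
        return self.depth >= 10

    @property
    def mismatch_type(self) -> str:
        """Strand-resolved mismatch, e.g. 'A-to-G' (genomic T-to-C on the
        minus strand reads as A-to-G on the transcript)."""
        ref, alt = self.ref.upper().replace("T", "U"), self.alt.upper().replace("T", "U")
        if self.strand == "-":
            ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
        ref = ref.replace("U", "T") if ref == "U" else ref
        alt = alt.replace("U", "T") if alt == "U" else alt
        return f"{ref}-to-{alt}"


@dataclass
class AnnotationSet:
    """Labelled half-open genomic intervals used by the filter cascade.

    ``regions`` maps contig -> sorted list of ``(start, end, label)`` with
    labels in {CDS, UTR3, UTR5, ncExon, intron}.  Splice junction positions
    are the exon-intron boundary coordinates.  Any track set to None is
    treated as missing and makes :func:`filter_sites` fail loudly.
    """

    regions: Mapping[str, Sequence[tuple[int, int, str]]] = field(default_factory=dict)
    splice_junctions: Mapping[str, Sequence[int]] | None = None
    snps: Mapping[str, set[int]] | None = None
    simple_repeats: Mapping[str, Sequence[tuple[int, int]]] | None = None
    homopolymers: Mapping[str, Sequence[tuple[int, int]]] | None = None
    strand: Mapping[str, str] = field(default_factory=dict)

    def require(self, *tracks: str) -> None:
        for t in tracks:
            if getattr(self, t) is None:
                raise ValueError(f"annotation track {t!r} is missing")

    def in_track(self, track: str, contig: str, pos: int) -> bool:
        intervals = getattr(self, track)
        if intervals is None:
            raise ValueError(f"annotation track {track!r} is missing")
        for start, end in intervals.get(contig, ()):
            if start <= pos < end:
                return True
        return False

    def is_snp(self, contig: str, pos: int) -> bool:
        if self.snps is None:
            raise ValueError("annotation track 'snps' is missing")
        return pos in self.snps.get(contig, set())

    def region_labels(self, contig: str, pos: int) -> list[str]:
        return [
            label
            for start, end, label in self.regions.get(contig, ())
            if start <= pos < end
        ]

    def intron_boundary_distance(self, contig: str, pos: int) -> int | None:
        """Distance to the nearest exon-intron boundary, if any is annotated."""
        if self.splice_junctions is None:
            return None
        bounds = self.splice_junctions.get(contig, ())
        if not bounds:
            return None
        return int(min(abs(pos - b) for b in bounds))


@dataclass(frozen=True)
class EditingSite:
    site_id: str
    contig: str
    pos0: int
    strand: str
    ref: str
    alt: str
    context: str
    mismatch_type: str
    llr: float
    depth: int
    alt_count: int
    level: float

    @property
    def is_a2g(self) -> bool:
        return self.mismatch_type == "A-to-G"


def _phred_to_prob(quals: Sequence[int]) -> np.ndarray:
    return 10.0 ** (-np.asarray(quals, dtype=float) / 10.0)


def compute_llr(
    obs: MismatchObservation,
    read_end_downweight: bool = False,
    end_margin: int = 6,
    log_base: float = 10.0,
) -> float:
    """Log likelihood ratio of a true variant vs a sequencing-error model.

    Per alt-supporting read i with Phred quality Q_i, the error probability
    is p_i = 10^(-Q_i/10).  Under a variant present at fraction f, an alt
    read is seen with probability f(1-p_i) + (1-f)p_i and a reference read
    with probability (1-f)(1-p) + f p (the mean alt-read error probability
    standing in for the unreported reference-read qualities).  The ratio
    compares the likelihood maximised over f in [0,1] with the errors-only
    model (f = 0), in log10 by default.  Mismatches within ``end_margin`` nt
    of a read end can optionally contribute half weight.
    """
    if obs.depth < 1:
        raise ValueError("depth must be >= 1")
    if obs.alt_count < 1:
        raise ValueError("no alt reads: not an LLR candidate")
    quals = obs.quals if obs.quals else (30,) * obs.alt_count
    if len(quals) != obs.alt_count:
        raise ValueError("need one quality per alt-supporting read")
    p = _phred_to_prob(quals)
    weights = np.ones(len(p))
    if read_end_downweight and obs.read_pos:
        rp = np.asarray(obs.read_pos)
        read_len = max(int(rp.max()) + 1, 100)
        near_end = (rp < end_margin) | (rp >= read_len - end_margin)
        weights[near_end[: len(weights)]] = 0.5
    p_mean = float(p.mean())
    n_ref = obs.depth - obs.alt_count

    def negloglik(f: float) -> float:
        alt_probs = f * (1.0 - p) + (1.0 - f) * p
        ref_prob = (1.0 - f) * (1.0 - p_mean) + f * p_mean
        ll = float(np.sum(weights * np.log(np.clip(alt_probs, 1e-300, 1.0))))
        ll += n_ref * np.log(max(ref_prob, 1e-300))
        return -ll

    res = minimize_scalar(negloglik, bounds=(0.0, 1.0), method="bounded")
    ll_alt = -res.fun
    ll_null = -negloglik(0.0)
    return float((ll_alt - ll_null) / np.log(log_base))


@dataclass(frozen=True)
class FilterResult:
    observation: MismatchObservation
    passed: bool
    llr: float
    first_failure: str | None
    failures: tuple[str, ...]


def _rule_failures(
    obs: MismatchObservation,
    annotations: AnnotationSet,
    llr: float,
    min_depth: int,
    min_alt: int,
    min_level: float,
    min_llr: float,
) -> dict[str, bool]:
    """Evaluate all eight predicates; True means the rule failed."""
    annotations.require("snps", "simple_repeats", "homopolymers")
    in_intron = "intron" in annotations.region_labels(obs.contig, obs.pos0)
    dist = annotations.intron_boundary_distance(obs.contig, obs.pos0)
    near_splice = in_intron and dist is not None and dist <= SPLICE_MARGIN
    return {
        "coverage": obs.depth < min_depth,
        "edited_reads": obs.alt_count < min_alt,
        "editing_level": obs.depth == 0 or obs.level < min_level,
        "llr": llr < min_llr,
        "snp": annotations.is_snp(obs.contig, obs.pos0),
        "simple_repeat": annotations.in_track("simple_repeats", obs.contig, obs.pos0),
        "homopolymer": annotations.in_track("homopolymers", obs.contig, obs.pos0),
        "splice_junction": near_splice,
    }


def filter_sites(
    observations: Iterable[MismatchObservation],
    annotations: AnnotationSet,
    min_depth: int = 10,
    min_alt: int = 2,
    min_level: float = 0.1,
    min_llr: float = 2.0,
    rule_order: Sequence[str] = FILTER_ORDER,
) -> list[FilterResult]:
    """Apply the full filter cascade; every record keeps its failure profile.

    A record survives iff it passes ALL rules.  ``first_failure`` reports the
    first failing rule in ``rule_order``; ``failures`` lists every failing
    rule, so the surviving set is invariant to the order.
    """
    if set(rule_order) != set(FILTER_ORDER):
        raise ValueError("rule_order must be a permutation of the eight rules")
    results = []
    for obs in observations:
        llr = (
            compute_llr(obs)
            if obs.alt_count >= 1 and obs.depth >= 1
            else float("-inf")
        )
        fails = _rule_failures(
            obs, annotations, llr, min_depth, min_alt, min_level, min_llr
        )
        failing = tuple(r for r in rule_order if fails[r])
        results.append(
            FilterResult(obs, len(failing) == 0, llr, failing[0] if failing else None, failing)
        )
    return results


def classify_context(contig: str, pos0: int, annotations: AnnotationSet) -> str:
    """Genomic-context label with the fixed priority rule.

    A site overlapping several region types takes the highest-priority label;
    intronic sites within 300 nt of an exon-intron boundary are Intron-close,
    deeper ones Intron-deep; sites overlapping nothing are Intergenic.
    """
    labels = set(annotations.region_labels(contig, pos0))
    for label in ("CDS", "UTR3", "UTR5", "ncExon"):
        if label in labels:
            return label
    if "intron" in labels:
        dist = annotations.intron_boundary_distance(contig, pos0)
        if dist is not None and dist <= INTRON_CLOSE_MAX_DIST:
            return "Intron-close"
        return "Intron-deep"
    return "Intergenic"


def select_population_sites(
    matrix: EditingMatrix,
    population: str,
    min_edited_individuals: int = 3,
    min_coverage_fraction: float = 0.10,
) -> list[str]:
    """Population-level site selection.

    A site is retained when (1) it is edited (>= 2 edited reads and level
    >= 0.1) in at least ``min_edited_individuals`` individuals of the
    population, and (2) it has read coverage >= 10 in at least
    ``min_coverage_fraction`` of the population's individuals.
    """
    ids = matrix.individuals_of(population)
    edited_counts = matrix.edited[ids].sum(axis=1)
    covered_counts = matrix.testable[ids].sum(axis=1)
    need_covered = min_coverage_fraction * len(ids)
    keep = (edited_counts >= min_edited_individuals) & (covered_counts >= need_covered)
    return [s for s in matrix.levels.index if keep[s]]


def a2g_fraction(sites: Sequence[MismatchObservation] | Sequence[EditingSite]) -> float:
    """Fraction of strand-resolved A-to-G sites among all mismatch sites."""
    sites = list(sites)
    if not sites:
        raise ValueError("no sites supplied")
    types = [
        s.mismatch_type if isinstance(s, (MismatchObservation, EditingSite)) else str(s)
        for s in sites
    ]
    return sum(t == "A-to-G" for t in types) / len(types)


def sites_from_results(
    results: Sequence[FilterResult], annotations: AnnotationSet
) -> list[EditingSite]:
    """Promote surviving filter records to annotated editing sites."""
    out = []
    for res in results:
        if not res.passed:
            continue
        o = res.observation
        out.append(
            EditingSite(
                site_id=f"{o.contig}:{o.pos0}",
                contig=o.contig,
                pos0=o.pos0,
                strand=o.strand,
                ref=o.ref,
                alt=o.alt,
                context=classify_context(o.contig, o.pos0, annotations),
                mismatch_type=o.mismatch_type,
                llr=res.llr,
                depth=o.depth,
                alt_count=o.alt_count,
                level=o.level,
            )
        )
    return out
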