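"""Synthetic populations, hairpin-bearing 3' UTRs, and pileup observations.

The generator emulates the statistical structure the population analyses
assume: per-individual ADAR1/2/3, AGO2 and miRNA expression drawn from
population-specific log-normals; per-site true editing levels linked
logistically to log ADAR1 expression; 3' UTRs carrying a hairpin in which the
editable A faces a C or U on the opposite strand, with a miRNA seed-match
site at a controlled distance; AGO2-miRNA degradation that preferentially
removes unedited transcripts; and binomial read sampling with Phred-scored
sequencing errors.

The degradation model is the core formalism: a transcript pool with true
editing level e, where unedited molecules survive with probability s_u and
edited molecules with s_e, yields

    observed editing = e * s_e / (e * s_e + (1 - e) * s_u)
    relative abundance = e * s_e + (1 - e) * s_u

so that preferential degradation of the unedited copies (s_u < s_e) inflates
observed editing and compresses differences between sites ("buffering").
Survival is linked to structure through s = exp(-k * AGO2 * accessibility):
the more accessible the (unedited) target site and the more AGO2-miRNA
activity, the less of that transcript survives.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .sitecall import AnnotationSet, MismatchObservation

__all__ = [
    "PopulationSimConfig",
    "SyntheticTranscript",
    "DegradationParams",
    "CohortParams",
    "CohortData",
    "MIR24",
    "generate_population",
    "generate_hairpin_utr",
    "apply_degradation",
    "editing_accessibility_profile",
    "survival_from_accessibility",
    "simulate_pileup",
    "generate_annotation_tracks",
    "make_gene_panel",
    "simulate_cohort",
    "revcomp",
    "default_population_config",
]

# hsa-miR-24-3p; its 7mer-m8 seed match (reverse complement of nt 2-8) is
# CUGAGCC, which conveniently carries an A usable for seed-overlap designs.
MIR24 = "UGGCUCAGUUCAGCAGGAACAG"

_COMPLEMENT = str.maketrans("ACGU", "UGCA")


def revcomp(rna: str) -> str:
    return rna.upper().replace("T", "U").translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class PopulationSimConfig:
    """Configuration for drawing per-individual expression profiles.

    ``expression`` maps gene -> population -> (location, scale) of a
    log-normal (location/scale on the log scale).  ``editing_slope`` and
    ``editing_midpoint`` parameterise the logistic link from log ADAR1 to
    true editing; ``degradation_k`` scales AGO2-miRNA degradation.
    """

    populations: Mapping[str, int]
    expression: Mapping[str, Mapping[str, tuple[float, float]]]
    editing_slope: float = 1.2
    editing_midpoint: float = 2.0
    degradation_k: float = 1.0
    error_rate: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.populations:
            raise ValueError("at least one population required")
        for pop, n in self.populations.items():
            if n < 1:
                raise ValueError(f"population {pop!r} needs >= 1 individual")
        for gene, per_pop in self.expression.items():
            for pop, (loc, scale) in per_pop.items():
                if scale <= 0:
                    raise ValueError(
                        f"non-positive scale for {gene!r} in {pop!r}"
                    )
        if not 0.0 <= self.error_rate <= 0.5:
            raise ValueError("error rate must lie in [0, 0.5]")
        if self.degradation_k < 0:
            raise ValueError("degradation scale k must be nonnegative")


def default_population_config(
    n_per_population: int = 100, seed: int = 0, k: float = 1.0
) -> PopulationSimConfig:
    """Two populations with shifted ADAR1 and AGO2 locations.

    Emulates the qualitative picture of population-level editomes: clearly
    different ADAR expression distributions between populations combined
    with broad inter-individual AGO2 and miRNA variation.
    """
    expr = {
        "ADAR1": {"POP1": (2.0, 0.30), "POP2": (2.5, 0.30)},
        "ADAR2": {"POP1": (0.5, 0.30), "POP2": (0.6, 0.30)},
        "ADAR3": {"POP1": (-1.0, 0.50), "POP2": (-0.9, 0.50)},
        "AGO2": {"POP1": (1.5, 0.45), "POP2": (1.5, 0.45)},
        "miR-24": {"POP1": (3.0, 0.40), "POP2": (3.0, 0.40)},
    }
    return PopulationSimConfig(
        populations={"POP1": n_per_population, "POP2": n_per_population},
        expression=expr,
        degradation_k=k,
        seed=seed,
    )


def generate_population(config: PopulationSimConfig) -> pd.DataFrame:
    """Draw one expression profile per individual.

    Returns a data frame indexed by individual id with a ``population``
    column and one column per configured gene.  Deterministic per seed.
    """
    rng = np.random.default_rng(config.seed)
    rows: list[dict] = []
    index: list[str] = []
    for pop in sorted(config.populations):
        n = config.populations[pop]
        draws = {}
        for gene in sorted(config.expression):
            loc, scale = config.expression[gene][pop]
            draws[gene] = rng.lognormal(mean=loc, sigma=scale, size=n)
        for i in range(n):
            index.append(f"{pop}_{i:04d}")
            rows.append({"population": pop, **{g: draws[g][i] for g in draws}})
    return pd.DataFrame(rows, index=pd.Index(index, name="individual"))


@dataclass(frozen=True)
class SyntheticTranscript:
    """A designed 3' UTR with (optionally) an editing site and a target site.

    ``edit_pos`` is the 0-based offset of the editable A; ``target_interval``
    is the half-open miRNA seed-match interval.  Panel genes without editing
    or without a target site leave the respective field as None.
    """

    gene_id: str
    sequence: str
    edit_pos: int | None
    edit_opposite: str | None
    target_interval: tuple[int, int] | None
    mirna_id: str | None
    target_distance: int | None

    def __post_init__(self) -> None:
        if self.edit_pos is not None and self.sequence[self.edit_pos] != "A":
            raise ValueError("base at the editing-site offset must be A")
        if self.target_interval is not None:
            s, e = self.target_interval
            if not (0 <= s < e <= len(self.sequence)):
                raise ValueError("target interval outside sequence bounds")


def _low_structure_flank(n: int, rng: np.random.Generator) -> list[str]:
    # Pyrimidine-biased, G-free: avoids hairpins competing with the designed stem.
    return list(rng.choice(["C", "U", "A"], size=n, p=[0.40, 0.40, 0.20]))


def generate_hairpin_utr(
    length: int = 360,
    stem_len: int = 10,
    edit_opposite: str = "C",
    target_distance: int = 30,
    seed: int = 0,
    gene_id: str = "gene",
    mirna_id: str = "miR-24",
    mirna_sequence: str = MIR24,
    loop: str = "UUCG",
    include_target: bool = True,
    allow_seed_overlap: bool = False,
) -> SyntheticTranscript:
    """Design a 3' UTR with a hairpin-embedded editing site and a seed site.

    The stem is a GC-rich inverted repeat whose 5' arm carries the editable A
    at its midpoint; the 3' arm pairs every stem position except that one,
    which faces ``edit_opposite`` ('C' gives an A.C mismatch that closes to a
    G-C pair upon editing; 'U' gives an A-U pair that becomes a G.U wobble).
    A 7mer-m8 seed match for ``mirna_sequence`` is written into the 5' flank
    at ``target_distance`` nt (edge-to-edge) from the editing site.  Flanking
    sequence is pyrimidine-biased to stay low-structure.
    """
    if stem_len < 4:
        raise ValueError("stem_len must be >= 4")
    if edit_opposite not in ("C", "U"):
        raise ValueError("edit_opposite must be 'C' or 'U'")
    if len(mirna_sequence) < 8:
        raise ValueError("miRNA must be at least 8 nt")
    rng = np.random.default_rng(seed)
    mid = stem_len // 2
    seed_site = revcomp(mirna_sequence[1:8])  # 7mer-m8 match

    overlap_mode = include_target and target_distance == 0
    if overlap_mode and not allow_seed_overlap:
        raise ValueError(
            "editing site inside the seed heptamer; pass allow_seed_overlap=True"
        )
    if include_target and not overlap_mode and target_distance <= mid:
        raise ValueError(
            f"infeasible geometry: target_distance must exceed {mid} "
            "(half stem) so the seed site clears the hairpin"
        )

    flank5_len = max(20, (target_distance if include_target else 0) - mid + 10)
    hairpin_len = 2 * stem_len + len(loop)
    if length < flank5_len + hairpin_len + 20:
        raise ValueError("infeasible geometry: sequence too short for layout")

    # 5' stem arm: GC-rich with the editable A at the midpoint.
    arm1 = list(rng.choice(["G", "C"], size=stem_len))
    arm1[mid] = "A"
    if overlap_mode:
        if seed_site[3] != "A" or mid < 3 or mid + 4 > stem_len:
            raise ValueError(
                "seed-overlap design needs an A at seed position 3 and a "
                "stem long enough to host the heptamer"
            )
        arm1[mid - 3 : mid + 4] = list(seed_site)
    arm2 = [c.translate(_COMPLEMENT) for c in arm1][::-1]
    opp_idx = stem_len - 1 - mid  # faces the editing site in the 3' arm
    arm2[opp_idx] = edit_opposite

    flank5 = _low_structure_flank(flank5_len, rng)
    edit_pos = flank5_len + mid
    target_interval: tuple[int, int] | None = None
    if include_target:
        if overlap_mode:
            target_interval = (flank5_len + mid - 3, flank5_len + mid + 4)
        else:
            t_end = edit_pos - target_distance + 1
            t_start = t_end - 7
            flank5[t_start:t_end] = list(seed_site)
            target_interval = (t_start, t_end)

    used = flank5_len + hairpin_len
    flank3 = _low_structure_flank(length - used, rng)
    sequence = "".join(flank5) + "".join(arm1) + loop + "".join(arm2) + "".join(flank3)
    return SyntheticTranscript(
        gene_id=gene_id,
        sequence=sequence,
        edit_pos=edit_pos,
        edit_opposite=edit_opposite,
        target_interval=target_interval,
        mirna_id=mirna_id if include_target else None,
        target_distance=target_distance if include_target else None,
    )


@dataclass(frozen=True)
class DegradationParams:
    """True editing level and survival probabilities of the two molecule types."""

    e: float
    s_u: float
    s_e: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.e <= 1.0:
            raise ValueError("true editing level must lie in [0, 1]")
        for name, s in (("s_u", self.s_u), ("s_e", self.s_e)):
            if not 0.0 < s <= 1.0:
                raise ValueError(f"{name} must lie in (0, 1]")


def apply_degradation(params: DegradationParams) -> tuple[float, float]:
    """Observed editing level and relative abundance after degradation.

    observed = e*s_e / (e*s_e + (1-e)*s_u); abundance = e*s_e + (1-e)*s_u.
    Whenever edited molecules survive at least as well as unedited ones
    (s_e >= s_u), observed >= e: degradation inflates apparent editing.
    """
    surviving_edited = params.e * params.s_e
    abundance = surviving_edited + (1.0 - params.e) * params.s_u
    observed = surviving_edited / abundance
    return observed, abundance


def editing_accessibility_profile(
    distance: int,
    base_accessibility: float = 0.7,
    delta0: float = 2.5,
    tau: float = 40.0,
) -> tuple[float, float]:
    """Model target-site accessibilities of the unedited and edited variants.

    The structural effect of a single A-to-I edit on 7mer accessibility is
    strongest at the site and decays over tens of nucleotides; the generator
    encodes this as a log2 accessibility change of ``-delta0 * exp(-d/tau)``
    at a target site ``d`` nt away.  Returns ``(acc_unedited, acc_edited)``.
    """
    if distance < 0:
        raise ValueError("distance must be nonnegative")
    if not 0.0 < base_accessibility <= 1.0:
        raise ValueError("base accessibility must lie in (0, 1]")
    delta = -delta0 * math.exp(-distance / tau)
    return base_accessibility, base_accessibility * 2.0**delta


def survival_from_accessibility(
    ago2_activity: float, accessibility: float, k: float
) -> float:
    """Survival probability of a transcript under AGO2-miRNA targeting.

    s = exp(-k * AGO2 activity * target-site accessibility): the simplest
    monotone link keeping survival in (0, 1].  Less accessible (more
    structured) target sites and less AGO2-miRNA activity both increase
    survival.
    """
    if ago2_activity < 0 or k < 0:
        raise ValueError("ago2_activity and k must be nonnegative")
    if not 0.0 < accessibility <= 1.0:
        raise ValueError("accessibility must lie in (0, 1]")
    return math.exp(-k * ago2_activity * accessibility)


def simulate_pileup(
    observed_editing: float,
    depth: int,
    error_rate: float = 1e-3,
    quality: tuple[float, float] = (35.0, 5.0),
    seed: int = 0,
    contig: str = "gene",
    pos0: int = 0,
    strand: str = "+",
    individual: str = "",
) -> MismatchObservation:
    """Binomial sampling of edited reads with Phred-scored sequencing errors.

    Each of ``depth`` reads carries the edited base with probability
    ``observed_editing``; unedited reads are miscalled with probability
    ``error_rate``, the erroneous base uniform over the three alternatives
    (errors landing on G add to the alt count).  Phred qualities follow a
    clipped normal; depth 0 yields an empty, untestable observation.
    """
    if depth < 0:
        raise ValueError("depth must be >= 0")
    if not 0.0 <= observed_editing <= 1.0:
        raise ValueError("observed editing must lie in [0, 1]")
    if depth == 0:
        return MismatchObservation(
            contig, pos0, strand, "A", "G", 0, 0, (), (), individual
        )
    rng = np.random.default_rng(seed)
    edited = int(rng.binomial(depth, observed_editing))
    errors = int(rng.binomial(depth - edited, error_rate))
    err_bases = rng.choice(["C", "G", "U"], size=errors)
    alt = edited + int(np.sum(err_bases == "G"))
    mu, sd = quality
    quals = tuple(
        int(q) for q in np.clip(np.rint(rng.normal(mu, sd, size=alt)), 2, 41)
    )
    read_pos = tuple(int(p) for p in rng.integers(0, 100, size=alt))
    return MismatchObservation(
        contig, pos0, strand, "A", "G", depth, alt, quals, read_pos, individual
    )


def _homopolymer_runs(seq: str, min_run: int = 5) -> list[tuple[int, int]]:
    runs = []
    i = 0
    n = len(seq)
    while i < n:
        j = i
        while j < n and seq[j] == seq[i]:
            j += 1
        if j - i >= min_run:
            runs.append((i, j))
        i = j
    return runs


def generate_annotation_tracks(
    transcripts: Sequence[SyntheticTranscript] | Mapping[str, str],
    snp_density: float = 0.0,
    repeat_spec: Mapping[str, Sequence[tuple[int, int]]] | None = None,
    seed: int = 0,
) -> AnnotationSet:
    """Synthetic stand-ins for the SNP/repeat/homopolymer/junction tracks.

    Each transcript is annotated as one 3' UTR region on the plus strand
    with no splice junctions.  SNP positions are Bernoulli draws at
    ``snp_density`` per position, never placed on a designed editing site;
    homopolymer intervals (runs of more than 4 identical nucleotides) are
    computed from the sequence, not drawn; simple repeats are planted from
    ``repeat_spec``.  Deterministic per seed.
    """
    if not 0.0 <= snp_density <= 1.0:
        raise ValueError("snp_density must lie in [0, 1]")
    if isinstance(transcripts, Mapping):
        seqs = dict(transcripts)
        edit_sites: dict[str, set[int]] = {g: set() for g in seqs}
    else:
        seqs = {t.gene_id: t.sequence for t in transcripts}
        edit_sites = {
            t.gene_id: ({t.edit_pos} if t.edit_pos is not None else set())
            for t in transcripts
        }
    rng = np.random.default_rng(seed)
    regions = {g: [(0, len(s), "UTR3")] for g, s in seqs.items()}
    snps: dict[str, set[int]] = {}
    repeats: dict[str, list[tuple[int, int]]] = {}
    homos: dict[str, list[tuple[int, int]]] = {}
    for g in sorted(seqs):
        s = seqs[g]
        if snp_density > 0:
            hits = np.nonzero(rng.random(len(s)) < snp_density)[0]
            snps[g] = {int(p) for p in hits if p not in edit_sites[g]}
        else:
            snps[g] = set()
        homos[g] = _homopolymer_runs(s)
        planted = list((repeat_spec or {}).get(g, ()))
        for start, end in planted:
            if not (0 <= start < end <= len(s)):
                raise ValueError(
                    f"repeat interval [{start}, {end}) outside {g!r} bounds"
                )
        repeats[g] = planted
    return AnnotationSet(
        regions=regions,
        splice_junctions={g: [] for g in seqs},
        snps=snps,
        simple_repeats=repeats,
        homopolymers=homos,
        strand={g: "+" for g in seqs},
    )


@dataclass(frozen=True)
class CohortParams:
    """Tunables of the end-to-end synthetic cohort.

    The logistic editing link operates on log ADAR1 centred at
    ``editing_midpoint`` with slope ``editing_slope``; ``site_sd`` spreads
    per-site baselines (logit scale) and ``noise_sd`` adds per-cell logit
    noise (within-individual editing variation, a free parameter of the
    model).  ``k`` scales degradation, ``depth_mean`` the sequencing depth.
    """

    editing_slope: float = 1.2
    editing_midpoint: float = 2.25
    site_sd: float = 0.8
    site_mean: float = -1.0
    noise_sd: float = 1.8
    k: float = 1.0
    depth_mean: float = 60.0
    error_rate: float = 1e-3
    expression_noise_sd: float = 0.25


@dataclass
class CohortData:
    """Everything the downstream analyses consume, genes x individuals."""

    profiles: pd.DataFrame
    genes: list[SyntheticTranscript]
    accessibilities: Mapping[str, tuple[float, float]]
    true_levels: pd.DataFrame
    observed_levels: pd.DataFrame
    abundance: pd.DataFrame
    expression: pd.DataFrame
    depths: pd.DataFrame
    alts: pd.DataFrame
    params: CohortParams

    def to_editing_matrix(self) -> "EditingMatrix":
        from .popstats import EditingMatrix

        edited_genes = [g.gene_id for g in self.genes if g.edit_pos is not None]
        return EditingMatrix.from_counts(
            self.alts.loc[edited_genes],
            self.depths.loc[edited_genes],
            self.profiles["population"],
        )


def make_gene_panel(
    n_edited_target: int = 30,
    n_edited_no_target: int = 10,
    n_unedited_target: int = 10,
    distances: Sequence[int] | None = None,
    utr_length: int = 360,
    stem_len: int = 10,
    seed: int = 0,
) -> list[SyntheticTranscript]:
    """The fixed gene panel of the simulation study.

    Three gene classes: edited genes with a miRNA target site at staggered
    distances (alternating A.C and A-U stem designs), edited genes without
    any target site, and unedited genes with a target site.  The panel plays
    the role of the genome: it is generated once per study seed and shared
    across cohort draws.
    """
    rng = np.random.default_rng(seed)
    if distances is None:
        distances = [6 + 3 * i for i in range(n_edited_target)]
    genes: list[SyntheticTranscript] = []
    opposites = ["C", "U"]
    for i in range(n_edited_target):
        genes.append(
            generate_hairpin_utr(
                length=utr_length,
                stem_len=stem_len,
                edit_opposite=opposites[i % 2],
                target_distance=int(distances[i % len(distances)]),
                seed=int(rng.integers(2**31)),
                gene_id=f"geneET{i:03d}",
            )
        )
    for i in range(n_edited_no_target):
        genes.append(
            generate_hairpin_utr(
                length=utr_length,
                stem_len=stem_len,
                edit_opposite=opposites[i % 2],
                target_distance=30,
                seed=int(rng.integers(2**31)),
                gene_id=f"geneEN{i:03d}",
                include_target=False,
            )
        )
    for i in range(n_unedited_target):
        # No editing site: a low-structure UTR carrying only the seed site.
        g_rng = np.random.default_rng(int(rng.integers(2**31)))
        flank = _low_structure_flank(utr_length, g_rng)
        t_start = utr_length // 2
        seed_site = revcomp(MIR24[1:8])
        flank[t_start : t_start + 7] = list(seed_site)
        genes.append(
            SyntheticTranscript(
                gene_id=f"geneUT{i:03d}",
                sequence="".join(flank),
                edit_pos=None,
                edit_opposite=None,
                target_interval=(t_start, t_start + 7),
                mirna_id="miR-24",
                target_distance=None,
            )
        )
    return genes


def simulate_cohort(
    profiles: pd.DataFrame,
    genes: Sequence[SyntheticTranscript],
    accessibilities: Mapping[str, tuple[float, float]],
    params: CohortParams = CohortParams(),
    seed: int = 0,
) -> CohortData:
    """Simulate editing, degradation, expression and read counts for a cohort.

    ``accessibilities`` maps gene id -> (unedited, edited) 7mer accessibility
    at the gene's miRNA target site (from the folding engine); genes without
    a target site are exempt from degradation.  True editing follows the
    logistic ADAR1 link per individual with per-site baselines; observed
    editing and relative abundance follow the closed-form degradation model;
    read depths are Poisson around ``depth_mean`` scaled by abundance, and
    alt counts binomial with sequencing errors folded in.
    """
    rng = np.random.default_rng(seed)
    inds = profiles.index
    n = len(inds)
    log_adar1 = np.log(profiles["ADAR1"].to_numpy())
    ago2 = profiles["AGO2"].to_numpy()
    mirna_cols = [c for c in profiles.columns if c.startswith("miR")]
    mirna = (
        profiles[mirna_cols[0]].to_numpy() if mirna_cols else np.ones(n)
    )
    activity = (ago2 / ago2.mean()) * (mirna / mirna.mean())

    site_rng = np.random.default_rng(seed + 1)
    true = {}
    observed = {}
    abundance = {}
    expression = {}
    depths = {}
    alts = {}
    for gene in genes:
        gid = gene.gene_id
        if gene.edit_pos is not None:
            offset = params.site_mean + params.site_sd * site_rng.standard_normal()
            logit = (
                params.editing_slope * (log_adar1 - params.editing_midpoint)
                + offset
                + params.noise_sd * rng.standard_normal(n)
            )
            e = 1.0 / (1.0 + np.exp(-logit))
        else:
            e = np.zeros(n)
        if gene.target_interval is not None:
            acc_u, acc_e = accessibilities[gid]
            s_u = np.exp(-params.k * activity * acc_u)
            s_e = np.exp(-params.k * activity * acc_e)
        else:
            s_u = np.ones(n)
            s_e = np.ones(n)
        surv_edit = e * s_e
        ab = surv_edit + (1.0 - e) * s_u
        obs = np.where(ab > 0, surv_edit / ab, 0.0)
        base = 50.0
        expr = base * ab * np.exp(params.expression_noise_sd * rng.standard_normal(n))
        depth = rng.poisson(params.depth_mean * ab)
        p_alt = obs * (1.0 - params.error_rate) + (1.0 - obs) * params.error_rate / 3.0
        alt = rng.binomial(depth, p_alt)
        true[gid] = e
        observed[gid] = obs
        abundance[gid] = ab
        expression[gid] = expr
        depths[gid] = depth
        alts[gid] = alt

    def frame(d: dict) -> pd.DataFrame:
        return pd.DataFrame(d, index=inds).T

    return CohortData(
        profiles=profiles,
        genes=list(genes),
        accessibilities=dict(accessibilities),
        true_levels=frame(true),
        observed_levels=frame(observed),
        abundance=frame(abundance),
        expression=frame(expression),
        depths=frame(depths),
        alts=frame(alts),
        params=params,
    )
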