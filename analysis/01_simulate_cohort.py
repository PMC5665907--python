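"""Simulate the study cohort: gene panel, populations, pileups, expression.

Generates the fixed panel of designed 3' UTRs (30 edited genes with a miRNA
target site at staggered distances, 10 edited genes without target sites, 10
unedited genes with target sites), simulates 2 populations x 100 individuals
under the preferential-degradation model, and writes the raw artifacts the
downstream analyses consume.
"""

from pathlib import Path

from editaccess import io as eio
from editaccess.pipeline import build_cohort, cohort_pileup
from editaccess.syndata import generate_annotation_tracks, make_gene_panel

SEED = 1
OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    genes = make_gene_panel(seed=SEED)
    cohort = build_cohort(genes, seed=SEED)

    eio.write_fasta(
        {g.gene_id: g.sequence for g in genes}, OUT / "utrs.fa",
        header_note=f"seed={SEED}",
    )
    eio.write_expression(cohort.expression, OUT / "expression.tsv")
    cohort.profiles.to_csv(OUT / "individual_profiles.tsv", sep="\t")
    observations = cohort_pileup(cohort, seed=SEED + 2)
    eio.write_pileup(observations, OUT / "pileup.tsv")
    tracks = generate_annotation_tracks(genes, snp_density=0.0, seed=SEED)
    rows = [
        {"chrom": g, "start": s, "end": e, "name": "homopolymer"}
        for g, runs in tracks.homopolymers.items()
        for s, e in runs
    ]
    if rows:
        import pandas as pd

        eio.write_bed(pd.DataFrame(rows), OUT / "homopolymers.bed")

    n_edited = sum(g.edit_pos is not None for g in genes)
    print(f"panel: {len(genes)} genes ({n_edited} with editing sites)")
    print(f"cohort: {len(cohort.profiles)} individuals, "
          f"{len(observations)} pileup observations")
    print(f"artifacts written under {OUT}")


if __name__ == "__main__":
    main()
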