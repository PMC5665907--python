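"""Structural consequences of editing on the designed UTRs.

Folds each edited panel gene's 1001-nt window (truncated to the UTR) in its
unedited and edited (A->G) forms, then reports: the relative 7mer
accessibility profile around editing sites, the spectrum of nucleotides
opposite the editing site in MFE structures with the paired fractions, the
paired-nucleotide 9-nt window profile near sites versus control adenosines,
and writes dot-bracket structures.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from editaccess import io as eio
from editaccess.popstats import paired_window_profile
from editaccess.structacc import (
    ViennaEngine,
    fold_window,
    opposite_base_spectrum,
    relative_accessibility,
    select_control_adenosines,
)
from editaccess.syndata import make_gene_panel

SEED = 1
OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    engine = ViennaEngine()
    genes = [g for g in make_gene_panel(seed=SEED) if g.edit_pos is not None]

    folds_u, folds_e, sites, deltas, records = [], [], [], [], []
    for g in genes:
        unedited, edited, start = fold_window(g.sequence, g.edit_pos, 1001, engine)
        pos = g.edit_pos - start
        folds_u.append(unedited)
        folds_e.append(edited)
        sites.append(pos)
        deltas.append(relative_accessibility(unedited, edited, pos, g.gene_id))
        records.append((g.gene_id, unedited.sequence, unedited.structure))
    eio.write_dotbracket(records, OUT / "structures_unedited.db")

    offsets = np.arange(-50, 51)
    profile = pd.DataFrame(
        {"offset": offsets,
         "mean_log2_ratio": [
             np.nanmean([d.at(o) for d in deltas]) for o in offsets
         ]}
    )
    profile.to_csv(OUT / "relative_accessibility_profile.tsv", sep="\t", index=False)
    near = profile.query("-10 <= offset <= 10")["mean_log2_ratio"].mean()
    print(f"mean relative 7mer accessibility within +/-10 nt: {near:+.3f} "
          "(negative = editing closes structure)")

    spectrum = opposite_base_spectrum(folds_u, folds_e, sites)
    spectrum.to_csv(OUT / "opposite_base_spectrum.tsv", sep="\t", index=False)
    pu = spectrum.query("variant=='unedited'")["paired_fraction"].iloc[0]
    pe = spectrum.query("variant=='edited'")["paired_fraction"].iloc[0]
    print(f"editing site paired in MFE structure: unedited {pu:.0%} -> edited {pe:.0%}")

    controls = select_control_adenosines(
        {g.gene_id: g.sequence for g in genes},
        {g.gene_id: [g.edit_pos] for g in genes},
        dist_range=(100, 200), n=30, seed=SEED,
    )
    by_gene = {g.gene_id: (g, fu) for g, fu in zip(genes, folds_u)}
    ctrl_tables = [by_gene[g][1].pair_table for g, _ in controls]
    ctrl_sites = [p for _, p in controls]
    site_prof = paired_window_profile([f.pair_table for f in folds_u], sites,
                                      max_offset=20)
    ctrl_prof = paired_window_profile(ctrl_tables, ctrl_sites, max_offset=20)
    merged = site_prof.merge(ctrl_prof, on="offset", suffixes=("_site", "_control"))
    merged.to_csv(OUT / "paired_window_profile.tsv", sep="\t", index=False)
    print(f"paired nt in 9-nt window at offset 0: "
          f"{site_prof.loc[site_prof.offset == 0, 'mean_paired'].item():.1f} at sites vs "
          f"{ctrl_prof.loc[ctrl_prof.offset == 0, 'mean_paired'].item():.1f} at control A's")


if __name__ == "__main__":
    main()
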