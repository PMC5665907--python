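"""Shared fixtures: folded hairpin sets and small editing matrices."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from editaccess.popstats import EditingMatrix
from editaccess.structacc import ViennaEngine, fold_window
from editaccess.syndata import generate_hairpin_utr


@pytest.fixture(scope="session")
def engine() -> ViennaEngine:
    return ViennaEngine()


@pytest.fixture(scope="session")
def hairpin_fixtures(engine):
    """20 designed hairpin UTRs (A opposite C or U, alternating), folded.

    Yields a list of dicts with the transcript, both fold results, and the
    site position inside the folding window.
    """
    out = []
    for s in range(20):
        opposite = "C" if s % 2 == 0 else "U"
        t = generate_hairpin_utr(
            length=360,
            stem_len=10,
            edit_opposite=opposite,
            target_distance=30,
            seed=s,
            gene_id=f"hp{s:02d}",
        )
        unedited, edited, start = fold_window(t.sequence, t.edit_pos, 1001, engine)
        out.append(
            {
                "transcript": t,
                "unedited": unedited,
                "edited": edited,
                "site": t.edit_pos - start,
            }
        )
    return out


@pytest.fixture()
def small_matrix() -> EditingMatrix:
    """4 sites x 6 individuals across two populations with varied depths."""
    individuals = [f"i{j}" for j in range(6)]
    populations = pd.Series(
        ["A", "A", "A", "B", "B", "B"], index=individuals, name="population"
    )
    depths = pd.DataFrame(
        [
            [20, 20, 20, 20, 20, 20],
            [10, 10, 5, 100, 10, 10],
            [9, 9, 9, 9, 9, 9],
            [50, 50, 50, 50, 50, 50],
        ],
        index=["s1", "s2", "s3", "s4"],
        columns=individuals,
    )
    alts = pd.DataFrame(
        [
            [4, 6, 0, 2, 10, 0],
            [2, 2, 5, 2, 0, 1],
            [3, 3, 3, 3, 3, 3],
            [25, 20, 15, 10, 5, 0],
        ],
        index=depths.index,
        columns=individuals,
    )
    return EditingMatrix.from_counts(alts, depths, populations)
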