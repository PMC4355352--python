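"""Gene-set over-representation and signed activation scoring.

Two generic decision rules on user-supplied gene sets:

* Fisher's exact (hypergeometric tail) over-representation p-value of a
  DEG list against a gene set within an explicit universe;
* an activation z-score for signed regulons: with n overlapping genes of
  which c move in the expected direction and i against it,
  z = (c - i) / sqrt(n), called activated at z >= threshold and inhibited
  at z <= -threshold (default threshold 2).

Evidence is unweighted; the knowledge base (which genes belong to which
regulon, and their expected directions) is entirely the caller's input.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class Regulon:
    """A regulator with signed expected effects on its member genes."""

    regulator_id: str
    members: dict  # gene -> +1 / -1 expected direction
    z_threshold: float = 2.0

    def __post_init__(self):
        if not self.members:
            raise ValueError("regulon members must be non-empty")
        bad = {g: d for g, d in self.members.items() if d not in (1, -1)}
        if bad:
            raise ValueError(f"member directions must be +1/-1: {bad}")


@dataclass(frozen=True)
class EnrichmentResult:
    regulator_id: str
    p_fisher: float | None
    z: float
    call: str  # activated | inhibited | not_significant
    n_overlap: int
    n_consistent: int
    flagged_no_overlap: bool = False


def fisher_enrichment(deg_set, gene_set, universe) -> float:
    """One-sided over-representation p-value of a DEG list in a gene set.

    P(overlap >= observed) under hypergeometric sampling of ``len(deg_set)``
    genes from the universe containing ``len(gene_set)`` marked genes.
    Both sets are intersected with the universe before testing.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("universe must be non-empty")
    deg = set(deg_set) & universe
    gs = set(gene_set) & universe
    k = len(deg & gs)
    # P(X >= k), X ~ Hypergeom(N=len(universe), K=len(gs), n=len(deg))
    return float(stats.hypergeom.sf(k - 1, len(universe), len(gs), len(deg)))


def activation_zscore(
    deg_table: pd.DataFrame,
    regulon: Regulon,
    gene_col: str = "probe_id",
    fc_col: str = "log2fc",
) -> EnrichmentResult:
    """Signed consistency z-score of a regulon against observed changes.

    Overlapping members whose fold-change sign matches their expected
    direction count as consistent. ``z = (consistent - inconsistent) /
    sqrt(overlap)``; a call is made at ``|z| >= z_threshold``. A regulon
    with no overlapping member yields z = 0, not_significant, flagged.
    """
    fc = dict(zip(deg_table[gene_col], deg_table[fc_col]))
    overlap = [g for g in regulon.members if g in fc and fc[g] != 0]
    if not overlap:
        return EnrichmentResult(
            regulator_id=regulon.regulator_id,
            p_fisher=None,
            z=0.0,
            call="not_significant",
            n_overlap=0,
            n_consistent=0,
            flagged_no_overlap=True,
        )
    consistent = sum(1 for g in overlap if math.copysign(1, fc[g]) == regulon.members[g])
    inconsistent = len(overlap) - consistent
    z = (consistent - inconsistent) / math.sqrt(len(overlap))
    if z >= regulon.z_threshold:
        call = "activated"
    elif z <= -regulon.z_threshold:
        call = "inhibited"
    else:
        call = "not_significant"
    return EnrichmentResult(
        regulator_id=regulon.regulator_id,
        p_fisher=None,
        z=z,
        call=call,
        n_overlap=len(overlap),
        n_consistent=consistent,
    )


def score_regulons(
    deg_table: pd.DataFrame,
    regulons: list,
    universe,
    gene_col: str = "probe_id",
    fc_col: str = "log2fc",
) -> pd.DataFrame:
    """Score a panel of regulons: Fisher p on membership plus activation z."""
    deg_genes = set(deg_table[gene_col])
    rows = []
    for reg in regulons:
        res = activation_zscore(deg_table, reg, gene_col=gene_col, fc_col=fc_col)
        p = fisher_enrichment(deg_genes, reg.members.keys(), universe)
        rows.append(
            {
                "regulator_id": reg.regulator_id,
                "p_fisher": p,
                "z": res.z,
                "call": res.call,
                "n_overlap": res.n_overlap,
                "n_consistent": res.n_consistent,
            }
        )
    return pd.DataFrame(rows)
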