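"""Integration of RNA-seq and PRO-seq differential results.

Genes changing at the mRNA level and in engaged-polymerase occupancy
are cross-classified: concordant movement in both assays points at
transcriptional control, movement in only one at post-transcriptional
control.  The module also reports the genome-wide Pearson correlation
of fold changes, intersects the concordantly-up set with the
locus-wide FLAG-enriched genes, and tests user-supplied gene sets for
hypergeometric over-representation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .differential import bh_adjust

__all__ = [
    "ConcordanceResult",
    "pearson_correlation",
    "quadrant_classify",
    "intersect_with_flag",
    "hypergeometric_overrepresentation",
    "overrepresentation_table",
]

QUADRANTS = (
    "both_up",
    "both_down",
    "rna_only_up",
    "rna_only_down",
    "pro_only_up",
    "pro_only_down",
    "discordant",
    "neither",
)


def pearson_correlation(x, y) -> tuple[float, float]:
    """Sample Pearson r of paired fold changes with a two-sided t-reference p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need paired vectors of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


@dataclass
class ConcordanceResult:
    pearson_r: float
    p_r: float
    n_shared: int
    quadrants: dict[str, set[str]] = field(default_factory=dict)
    dropped_genes: set[str] = field(default_factory=set)
    intersection_with_flag: set[str] = field(default_factory=set)


def quadrant_classify(
    rna: pd.DataFrame,
    pro: pd.DataFrame,
) -> ConcordanceResult:
    """Cross-classify genes by joint RNA-seq / PRO-seq differential call.

    The shared gene universe is the intersection of the two tables;
    genes present in only one are recorded in ``dropped_genes``.  The
    eight quadrant buckets partition the shared universe; genes moving
    in opposite directions land in ``discordant`` rather than being
    folded into the one-sided buckets.
    """
    shared = rna.index.intersection(pro.index)
    dropped = set(rna.index.symmetric_difference(pro.index))
    r, p = pearson_correlation(
        rna.loc[shared, "log2fc"].to_numpy(), pro.loc[shared, "log2fc"].to_numpy()
    )
    rc = rna.loc[shared, "call"]
    pc = pro.loc[shared, "call"]
    q: dict[str, set[str]] = {k: set() for k in QUADRANTS}
    for gene in shared:
        a, b = rc[gene], pc[gene]
        if a == "up" and b == "up":
            q["both_up"].add(gene)
        elif a == "down" and b == "down":
            q["both_down"].add(gene)
        elif a == "up" and b == "ns":
            q["rna_only_up"].add(gene)
        elif a == "down" and b == "ns":
            q["rna_only_down"].add(gene)
        elif a == "ns" and b == "up":
            q["pro_only_up"].add(gene)
        elif a == "ns" and b == "down":
            q["pro_only_down"].add(gene)
        elif a == "ns" and b == "ns":
            q["neither"].add(gene)
        else:  # up/down or down/up
            q["discordant"].add(gene)
    return ConcordanceResult(
        pearson_r=r,
        p_r=p,
        n_shared=len(shared),
        quadrants=q,
        dropped_genes=dropped,
    )


def intersect_with_flag(
    both_up: set[str],
    flag_enriched: set[str],
    rna: pd.DataFrame | None = None,
    pro: pd.DataFrame | None = None,
    locus_scores: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Concordantly-up genes that also carry locus-wide FLAG enrichment.

    Returns one annotated row per intersection gene (fold changes and
    locus score when the tables are supplied).
    """
    genes = sorted(both_up & flag_enriched)
    out = pd.DataFrame(index=pd.Index(genes, name="gene_id"))
    if rna is not None:
        out["log2fc_rna"] = rna.loc[genes, "log2fc"]
    if pro is not None:
        out["log2fc_pro"] = pro.loc[genes, "log2fc"]
    if locus_scores is not None:
        out["locus_score"] = locus_scores.loc[genes, "score"]
    return out


def hypergeometric_overrepresentation(
    hit_genes: set[str],
    gene_set: set[str],
    universe: set[str],
) -> tuple[int, float]:
    """Upper-tail hypergeometric p of the observed overlap.

    Probability of drawing at least ``|hit & set|`` members of
    ``gene_set`` when ``|hit_genes|`` genes are drawn from ``universe``
    without replacement.
    """
    if not universe:
        raise ValueError("empty universe")
    if not gene_set <= universe or not hit_genes <= universe:
        raise ValueError("hit genes and gene set must be subsets of the universe")
    N = len(universe)
    K = len(gene_set)
    n = len(hit_genes)
    k = len(hit_genes & gene_set)
    p = float(stats.hypergeom.sf(k - 1, N, K, n))
    return k, min(p, 1.0)


def overrepresentation_table(
    hit_genes: set[str],
    gene_sets: dict[str, set[str]],
    universe: set[str],
) -> pd.DataFrame:
    """Hypergeometric test per gene set with BH adjustment across sets."""
    rows = []
    for name, gs in gene_sets.items():
        k, p = hypergeometric_overrepresentation(hit_genes, gs & universe, universe)
        rows.append((name, len(gs & universe), k, p))
    df = pd.DataFrame(
        rows, columns=["gene_set", "set_size", "overlap", "p"]
    ).set_index("gene_set")
    df["q"] = bh_adjust(df["p"].to_numpy()) if len(df) else []
    return df
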