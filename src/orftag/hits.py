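"""Per-gene enrichment of sorted vs background insertion counts.

For every gene with enough evidence (>= 3 unique insertions in the sorted
sample; the filter is applied *before* multiple-testing correction, shrinking
the tested family), a one-tailed Fisher's exact test (alternative='greater')
compares its insertion count against the merged background on the 2x2 table

    [[n_sorted,     total_sorted - n_sorted],
     [n_background, total_background - n_background]]

where the totals are the assigned unique insertions per sample.  P-values are
Benjamini-Hochberg adjusted; hits require FDR < 0.001 and log2 odds ratio >= 1.

The odds ratio is the sample (unconditional) estimator, with Haldane-Anscombe
0.5 pseudo-counts added to all four cells only when a zero cell would make it
degenerate.

Hits whose *strand-flipped* insertions are also significantly enriched get the
comment "Enriched for reversed integrations": a strand-symmetric pileup can be
a neighbouring antisense hit or an artefact, and deserves caution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "HitCallingConfig",
    "REVERSED_COMMENT",
    "fisher_one_tailed",
    "bh_fdr",
    "call_hits",
    "flag_reversed",
]

REVERSED_COMMENT = "Enriched for reversed integrations"


@dataclass
class HitCallingConfig:
    fdr_threshold: float = 0.001
    log2_or_threshold: float = 1.0
    min_sorted_insertions: int = 3
    pseudo_count: float = 0.5  # odds ratio only, and only on zero cells

    def __post_init__(self):
        if min(self.fdr_threshold, self.log2_or_threshold, self.min_sorted_insertions, self.pseudo_count) <= 0:
            raise ValueError("all hit-calling thresholds must be positive")


def _check_table(n_sorted: int, total_sorted: int, n_background: int, total_background: int) -> None:
    if min(n_sorted, n_background) < 0:
        raise ValueError("negative counts in 2x2 table")
    if total_sorted <= 0 or total_background <= 0:
        raise ValueError("library totals must be positive")
    if n_sorted > total_sorted or n_background > total_background:
        raise ValueError("cell count exceeds its margin total")


def fisher_one_tailed(
    n_sorted: int,
    total_sorted: int,
    n_background: int,
    total_background: int,
    pseudo_count: float = 0.5,
) -> tuple[float, float]:
    """Upper-tail Fisher p and log2 sample odds ratio for one gene.

    p = P(X >= n_sorted) under the central hypergeometric distribution with
    the table's margins fixed.  The odds ratio is
    (a*d)/(b*c) on [[a,b],[c,d]], with ``pseudo_count`` added to all four
    cells iff any cell is zero, then log2-transformed.
    """
    from scipy.stats import hypergeom

    _check_table(n_sorted, total_sorted, n_background, total_background)
    a = n_sorted
    b = total_sorted - n_sorted
    c = n_background
    d = total_background - n_background
    population = total_sorted + total_background
    successes = n_sorted + n_background
    p = float(hypergeom.sf(a - 1, population, successes, total_sorted))
    p = min(p, 1.0)
    if min(a, b, c, d) == 0:
        a, b, c, d = (x + pseudo_count for x in (a, b, c, d))
    log2_or = math.log2((a * d) / (b * c))
    return p, log2_or


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order-preserving."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.empty(0, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    from statsmodels.stats.multitest import multipletests

    return multipletests(p, method="fdr_bh")[1]


def call_hits(
    counts,
    config: HitCallingConfig = HitCallingConfig(),
    total_sorted: Optional[int] = None,
    total_background: Optional[int] = None,
):
    """Hit table from a per-gene count table.

    ``counts`` is a DataFrame with columns gene_id, n_sorted, n_background
    (one row per gene with any assigned insertion).  Totals default to the
    column sums, i.e. all assigned unique insertions per sample.  Genes with
    fewer than ``min_sorted_insertions`` sorted insertions are excluded before
    testing and do not appear in the output.  Output columns mirror the
    published hit tables: counts, totals, log2 odds ratio, p, FDR, hit flag,
    comment; sorted by FDR, then descending log2 OR, then gene_id.
    """
    import pandas as pd

    total_sorted = int(counts["n_sorted"].sum()) if total_sorted is None else total_sorted
    total_background = int(counts["n_background"].sum()) if total_background is None else total_background
    if total_sorted <= 0 or total_background <= 0:
        raise ValueError("zero assigned insertions in sorted or background sample")

    tested = counts[counts["n_sorted"] >= config.min_sorted_insertions].copy()
    if tested.empty:
        return pd.DataFrame(
            columns=[
                "gene_id", "n_sorted", "n_background", "total_sorted", "total_background",
                "log2_odds_ratio", "p_value", "fdr", "is_hit", "comment",
            ]
        )
    p_values = []
    log2_ors = []
    for n_s, n_b in zip(tested["n_sorted"], tested["n_background"]):
        p, lor = fisher_one_tailed(
            int(n_s), total_sorted, int(n_b), total_background, pseudo_count=config.pseudo_count
        )
        p_values.append(p)
        log2_ors.append(lor)
    tested["total_sorted"] = total_sorted
    tested["total_background"] = total_background
    tested["log2_odds_ratio"] = log2_ors
    tested["p_value"] = p_values
    tested["fdr"] = bh_fdr(p_values)
    tested["is_hit"] = (tested["fdr"] < config.fdr_threshold) & (
        tested["log2_odds_ratio"] >= config.log2_or_threshold
    )
    tested["comment"] = ""
    tested = tested.sort_values(
        ["fdr", "log2_odds_ratio", "gene_id"], ascending=[True, False, True]
    ).reset_index(drop=True)
    return tested[
        [
            "gene_id", "n_sorted", "n_background", "total_sorted", "total_background",
            "log2_odds_ratio", "p_value", "fdr", "is_hit", "comment",
        ]
    ]


def flag_reversed(
    hits,
    reversed_counts,
    config: HitCallingConfig = HitCallingConfig(),
):
    """Annotate hits that are also enriched after strand-flipping.

    ``reversed_counts`` is the count table produced from strand-flipped
    assignments of the same sorted and background samples.  The identical
    Fisher/FDR/threshold machinery runs on it; forward hits whose gene also
    qualifies on reversed counts get :data:`REVERSED_COMMENT`, all others an
    empty comment.  Non-hit genes are never flagged.
    """
    out = hits.copy()
    out["comment"] = ""
    if reversed_counts is None or len(reversed_counts) == 0:
        return out
    reversed_hits = call_hits(reversed_counts, config=config)
    flagged = set(reversed_hits.loc[reversed_hits["is_hit"], "gene_id"])
    mask = out["is_hit"] & out["gene_id"].isin(flagged)
    out.loc[mask, "comment"] = REVERSED_COMMENT
    return out
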