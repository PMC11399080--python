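"""Bias and enrichment analyses around screen results.

The workhorse is the *normalized ratio*: for a gene subset (tagged genes, or
screen hits) and a stratification of the reference gene universe,

    ratio(stratum) = (subset genes in stratum / subset total)
                   / (reference genes in stratum / reference total)

1.0 means the subset mirrors the reference in that stratum; the identity
sum_over_strata(reference fraction x ratio) = 1 holds algebraically for any
subset.  Strata used here: shortest-CDS length (<2.5 kb, 2.5-5 kb, >5 kb) and
expression (inactive TPM = 0 plus quartiles of active genes).

A generic one-tailed Fisher over-representation engine handles arbitrary
gene-set files (GO terms, protein domains, curated lists), with the screen's
category filters: categories with fewer than five genes, or fewer than three
matching hits, are dropped before testing; significance at BH-FDR < 0.05.

The Poisson multi-transduction calculator answers how often a cell carries
two or more cassettes when a fraction ``rate`` of cells is transduced:
with the per-cell cassette count ~ Poisson(lambda = rate),
P(>= 2) = 1 - e^(-lambda)(1 + lambda).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Dict, Iterable, Mapping, Optional, Sequence

import numpy as np

from .annotation import AnnotationSet
from .hits import bh_fdr

__all__ = [
    "NormalizedRatioInput",
    "normalized_ratio",
    "cds_length_bias",
    "expression_bias",
    "gene_set_enrichment",
    "multi_transduction_probability",
    "round_percent",
    "CDS_STRATA",
]

# shortest-CDS strata in nt: <2.5 kb, [2.5 kb, 5 kb], >5 kb (middle inclusive)
CDS_STRATA: tuple[tuple[str, int, Optional[int]], ...] = (
    ("<2.5kb", 0, 2500),
    ("2.5-5kb", 2500, 5001),
    (">5kb", 5001, None),
)


@dataclass
class NormalizedRatioInput:
    subset_in_stratum: int
    subset_total: int
    reference_in_stratum: int
    reference_total: int

    def __post_init__(self):
        if self.subset_in_stratum > self.subset_total or self.reference_in_stratum > self.reference_total:
            raise ValueError("stratum counts cannot exceed totals")
        if min(self.subset_in_stratum, self.subset_total, self.reference_in_stratum, self.reference_total) < 0:
            raise ValueError("counts must be non-negative")


def normalized_ratio(inp: NormalizedRatioInput) -> Optional[float]:
    """Subset-vs-reference stratum fraction ratio; None when undefined.

    Undefined (None) for an empty subset or an empty reference stratum; an
    occupied reference stratum with zero subset genes gives 0.0.
    """
    if inp.subset_total == 0 or inp.reference_in_stratum == 0:
        return None
    if inp.reference_total == 0:
        return None
    subset_fraction = inp.subset_in_stratum / inp.subset_total
    reference_fraction = inp.reference_in_stratum / inp.reference_total
    return subset_fraction / reference_fraction


def _strata_ratios(
    subsets: Mapping[str, set],
    reference_by_stratum: Mapping[str, set],
    reference_total: int,
):
    import pandas as pd

    rows = {}
    for stratum, ref_genes in reference_by_stratum.items():
        row = {"n_reference": len(ref_genes)}
        for name, subset in subsets.items():
            ratio = normalized_ratio(
                NormalizedRatioInput(
                    subset_in_stratum=len(subset & ref_genes),
                    subset_total=len(subset),
                    reference_in_stratum=len(ref_genes),
                    reference_total=reference_total,
                )
            )
            row[f"ratio_{name}"] = np.nan if ratio is None else ratio
            row[f"n_{name}"] = len(subset & ref_genes)
        rows[stratum] = row
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "stratum"
    return table


def cds_length_bias(
    tagged: set,
    hit_union: set,
    annotation: AnnotationSet,
    strata: Sequence[tuple[str, int, Optional[int]]] = CDS_STRATA,
):
    """Normalized ratios per shortest-CDS-length stratum.

    Reference: intronic protein-coding genes with a defined shortest CDS
    (genes without CDS are excluded and counted in the ``excluded_no_cds``
    DataFrame attribute).  ``tagged`` and ``hit_union`` are restricted to the
    reference universe.
    """
    reference: dict[str, int] = {}
    excluded = 0
    for gene_id in annotation.intronic_coding_gene_ids():
        cds = annotation.genes[gene_id].shortest_cds_nt
        if cds is None:
            excluded += 1
            continue
        reference[gene_id] = cds
    by_stratum: Dict[str, set] = {}
    for name, lo, hi in strata:
        by_stratum[name] = {
            g for g, cds in reference.items() if cds >= lo and (hi is None or cds < hi)
        }
    universe = set(reference)
    table = _strata_ratios(
        {"tagged": tagged & universe, "hits": hit_union & universe},
        by_stratum,
        reference_total=len(universe),
    )
    table.attrs["excluded_no_cds"] = excluded
    return table


def _active_quartile_bounds(values: np.ndarray) -> list[float]:
    """Nearest-rank quartile boundary values (q25, q50, q75)."""
    x = np.sort(values)
    n = len(x)
    return [x[max(0, math.ceil(k * n / 4) - 1)] for k in (1, 2, 3)]


def expression_bias(
    tagged: set,
    hit_union: set,
    expression: Mapping[str, float],
    annotation: AnnotationSet,
):
    """Normalized ratios per expression class (inactive + active quartiles).

    ``expression`` maps gene_id to mean TPM.  Genes with TPM 0 are the
    inactive class; active genes split into nearest-rank quartiles with
    boundary ties going to the lower class.  Reference universe: intronic
    protein-coding genes present in the expression table (missing genes are
    excluded and counted).
    """
    universe = annotation.intronic_coding_gene_ids()
    covered = {g: float(expression[g]) for g in universe if g in expression}
    excluded = len(universe) - len(covered)

    inactive = {g for g, tpm in covered.items() if tpm == 0.0}
    active = {g: tpm for g, tpm in covered.items() if tpm > 0.0}
    by_class: Dict[str, set] = {"inactive": inactive}
    if active:
        bounds = _active_quartile_bounds(np.array(list(active.values())))
        for i, name in enumerate(["Q1", "Q2", "Q3", "Q4"]):
            lo = bounds[i - 1] if i > 0 else None
            hi = bounds[i] if i < 3 else None
            by_class[name] = {
                g
                for g, tpm in active.items()
                if (lo is None or tpm > lo) and (hi is None or tpm <= hi)
            }
    table = _strata_ratios(
        {"tagged": tagged & set(covered), "hits": hit_union & set(covered)},
        by_class,
        reference_total=len(covered),
    )
    table.attrs["excluded_missing_expression"] = excluded
    return table


def gene_set_enrichment(
    hit_genes: set,
    categories: Mapping[str, set],
    background: set,
    min_category_size: int = 5,
    min_matching_hits: int = 3,
    fdr_threshold: float = 0.05,
    pseudo_count: float = 0.5,
):
    """One-tailed Fisher over-representation of hits in gene categories.

    Categories and hits are intersected with ``background`` (typically all
    intronic protein-coding genes).  Categories with fewer than
    ``min_category_size`` genes, or fewer than ``min_matching_hits`` hit
    members, are dropped before testing; the BH family is the surviving set.
    Returns a DataFrame (category, n_genes, n_hits, odds_ratio, p_value, fdr,
    significant) sorted by FDR.
    """
    import pandas as pd
    from scipy.stats import hypergeom

    if not background:
        raise ValueError("empty background gene universe")
    hits = hit_genes & background
    rows = []
    for category, genes in categories.items():
        genes = genes & background
        k = len(genes & hits)
        if len(genes) < min_category_size or k < min_matching_hits:
            continue
        K, n, N = len(genes), len(hits), len(background)
        p = float(hypergeom.sf(k - 1, N, K, n))
        a, b_, c, d = k, n - k, K - k, N - K - (n - k)
        if min(a, b_, c, d) == 0:
            a, b_, c, d = (x + pseudo_count for x in (a, b_, c, d))
        rows.append(
            {
                "category": category,
                "n_genes": K,
                "n_hits": k,
                "odds_ratio": (a * d) / (b_ * c),
                "p_value": min(p, 1.0),
            }
        )
    if not rows:
        return pd.DataFrame(
            columns=["category", "n_genes", "n_hits", "odds_ratio", "p_value", "fdr", "significant"]
        )
    table = pd.DataFrame(rows)
    table["fdr"] = bh_fdr(table["p_value"].to_numpy())
    table["significant"] = table["fdr"] < fdr_threshold
    return table.sort_values(["fdr", "p_value", "category"]).reset_index(drop=True)


def multi_transduction_probability(rate: float) -> float:
    """P(cell carries >= 2 cassettes) at transduction rate ``rate``.

    The per-cell cassette count is modelled Poisson with lambda equal to the
    measured transduced fraction; P(>=2) = 1 - e^(-lambda)(1 + lambda).  For
    rate >= 1 the lambda interpretation breaks down; a warning is emitted and
    the value still computed.
    """
    if rate < 0:
        raise ValueError("transduction rate cannot be negative")
    if rate >= 1:
        warnings.warn(
            f"transduction rate {rate} >= 1: Poisson-mean interpretation is dubious",
            stacklevel=2,
        )
    return 1.0 - math.exp(-rate) * (1.0 + rate)


def round_percent(fraction: float, ndigits: int = 2) -> float:
    """Fraction -> percentage, rounded half-up (reporting parity)."""
    q = Decimal(1).scaleb(-ndigits)
    return float((Decimal(repr(fraction)) * 100).quantize(q, rounding=ROUND_HALF_UP))
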