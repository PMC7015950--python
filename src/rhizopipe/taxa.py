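"""Rank-level aggregation and taxa-level effect screens.

Aggregates OTU relative abundances to a chosen lineage rank (unassigned
OTUs pooled into an "unassigned" bin, so per-sample totals are
conserved at 100%), tests per-taxon group differences with one-way
ANOVA and pairwise Welch t-tests under Bonferroni correction (with a
compact letter display), computes taxon-taxon Pearson correlations over
samples or genotype means, screens for taxa whose abundance in one
factor level is at least doubled against the average of the other
levels, and maps the Glomeromycetes class from its four constituent
orders (Glomerales, Diversisporales, Archaeosporales, Paraglomerales).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._pairwise import (anova_oneway, compact_letter_display,
                        pairwise_welch_bonferroni)
from .data_model import (RANKS, RelAbundanceMatrix, SampleFrame,
                         TaxonomyTable, ValidationError)

__all__ = ["TaxaMatrix", "aggregate_taxa", "glomeromycetes_mask",
           "group_tests", "taxon_correlation", "fold_change_screen"]

UNASSIGNED = "unassigned"

#: Orders whose OTUs count as Glomeromycetes class members (one common
#: variant spelling of Paraglomerales accepted).
GLOMEROMYCETES_ORDERS = frozenset({
    "glomerales", "diversisporales", "archaeosporales", "paraglomerales",
    "paraglomorerales",
})


@dataclass
class TaxaMatrix:
    """Taxon x sample relative abundances (%) at one lineage rank."""

    values: pd.DataFrame
    rank: str

    def __post_init__(self) -> None:
        sums = self.values.sum(axis=0)
        ok = np.isclose(sums, 100.0, atol=1e-9) | np.isclose(sums, 0.0,
                                                             atol=1e-9)
        if not ok.all():
            bad = list(self.values.columns[~ok])
            raise ValidationError(
                f"taxa columns must sum to 100 (or 0 for empty): {bad}")

    @property
    def taxa(self) -> list:
        return list(self.values.index)


def aggregate_taxa(rel: RelAbundanceMatrix, tax: TaxonomyTable,
                   rank: str = "phylum") -> TaxaMatrix:
    """Sum OTU percents by their value at ``rank``.

    OTUs with an empty rank value are pooled into ``unassigned``; column
    sums are conserved.
    """
    if rank not in RANKS:
        raise ValidationError(f"unknown rank {rank!r}; allowed: {RANKS}")
    missing = [o for o in rel.values.index if o not in tax.table.index]
    if missing:
        raise ValidationError(f"OTU(s) without taxonomy: {missing[:10]}")
    labels = tax.table.loc[rel.values.index, rank].astype(str)
    labels = labels.where(labels.str.strip() != "", UNASSIGNED)
    agg = rel.values.groupby(labels).sum()
    agg = agg.sort_index()
    return TaxaMatrix(agg, rank)


def glomeromycetes_mask(tax: TaxonomyTable) -> frozenset:
    """OTUs whose order is one of the four Glomeromycetes orders."""
    orders = tax.table["order"].astype(str).str.strip().str.lower()
    return frozenset(tax.table.index[orders.isin(GLOMEROMYCETES_ORDERS)])


def group_tests(taxa: TaxaMatrix, meta: SampleFrame, factor: str,
                alpha: float = 0.05, samples=None) -> dict:
    """Per-taxon one-way ANOVA plus pairwise Welch-Bonferroni letters.

    Returns ``anova`` (taxon-indexed F/p), ``pairwise`` (long table of
    all pairwise tests) and ``letters`` (taxon x level compact letter
    display: levels sharing a letter are not significantly different at
    ``alpha`` after Bonferroni).
    """
    cols = list(samples) if samples is not None else \
        [s for s in taxa.values.columns if s in meta.table.index]
    if not cols:
        raise ValidationError("no samples in scope")
    groups = meta.table.loc[cols, factor]
    counts = groups.value_counts()
    small = list(counts.index[counts < 2])
    if small:
        raise ValidationError(
            f"factor level(s) with fewer than 2 samples: {small}")
    if len(counts) < 2:
        raise ValidationError("group tests need >= 2 factor levels")
    anova_rows, pairwise_rows, letter_rows = [], [], []
    for taxon in taxa.values.index:
        values = taxa.values.loc[taxon, cols]
        f, p = anova_oneway(values, groups)
        anova_rows.append(dict(taxon=taxon, F=f, p=p))
        pw = pairwise_welch_bonferroni(values, groups)
        pw.insert(0, "taxon", taxon)
        pairwise_rows.append(pw)
        means = values.groupby(groups).mean().sort_values(ascending=False)
        letters = compact_letter_display(pw, order=list(means.index),
                                         alpha=alpha)
        letter_rows.append({"taxon": taxon, **letters})
    return {
        "anova": pd.DataFrame(anova_rows).set_index("taxon"),
        "pairwise": pd.concat(pairwise_rows, ignore_index=True),
        "letters": pd.DataFrame(letter_rows).set_index("taxon"),
    }


def taxon_correlation(taxa: TaxaMatrix, taxon_a: str, taxon_b: str,
                      meta: SampleFrame | None = None,
                      unit: str = "genotype-mean") -> tuple[float, int]:
    """Pearson r between two taxa across samples or genotype means.

    Returns (r, n_units); r is NaN when a taxon has zero variance over
    the chosen units.
    """
    for t in (taxon_a, taxon_b):
        if t not in taxa.values.index:
            raise ValidationError(f"taxon {t!r} not in matrix")
    a = taxa.values.loc[taxon_a]
    b = taxa.values.loc[taxon_b]
    if unit == "genotype-mean":
        if meta is None:
            raise ValidationError("genotype-mean unit requires metadata")
        geno = meta.table.loc[[s for s in a.index
                               if s in meta.table.index], "genotype"]
        a = a.loc[geno.index].groupby(geno).mean()
        b = b.loc[geno.index].groupby(geno).mean()
    elif unit != "sample":
        raise ValidationError(f"unit must be sample/genotype-mean, got {unit!r}")
    if len(a) < 3:
        raise ValidationError("correlation needs >= 3 units")
    if a.std(ddof=0) == 0 or b.std(ddof=0) == 0:
        return float("nan"), len(a)
    r, _ = stats.pearsonr(a.to_numpy(), b.to_numpy())
    return float(r), len(a)


def fold_change_screen(taxa: TaxaMatrix, meta: SampleFrame,
                       factor: str = "species",
                       threshold: float = 2.0, samples=None) -> pd.DataFrame:
    """Flag taxa at least ``threshold``-fold enriched in one factor level.

    The fold for (taxon, level) is the level's mean abundance divided by
    the unweighted mean of the other levels' means.  A zero denominator
    with a positive numerator is flagged with an infinite fold; a taxon
    absent everywhere has fold 1 and is not flagged.
    """
    cols = list(samples) if samples is not None else \
        [s for s in taxa.values.columns if s in meta.table.index]
    groups = meta.table.loc[cols, factor]
    levels = list(pd.unique(groups))
    if len(levels) < 2:
        raise ValidationError("fold screen needs >= 2 factor levels")
    level_means = taxa.values[cols].T.groupby(groups).mean().T
    rows = []
    for taxon in taxa.values.index:
        for level in levels:
            num = float(level_means.loc[taxon, level])
            others = [float(level_means.loc[taxon, lv])
                      for lv in levels if lv != level]
            denom = float(np.mean(others))
            if denom > 0:
                fold = num / denom
            elif num > 0:
                fold = math.inf
            else:
                fold = 1.0
            rows.append(dict(taxon=taxon, level=level, level_mean=num,
                             others_mean=denom, fold=fold,
                             flagged=fold >= threshold))
    return pd.DataFrame(rows)
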