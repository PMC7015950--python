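"""Eukaryote:prokaryote contribution estimation from 16S/18S qPCR.

Each cycle threshold is transformed to a template "value" via 2^(-Ct).
The 18S value is corrected for host-plant contamination by multiplying
with (1 - plant fraction): if half of the 18S amplicons are of
host-plant origin, the 18S value is halved.  The eukaryote contribution
is the corrected 18S value's share of the 16S + 18S value sum, in
percent.  No absolute quantification is attempted; only the relative
16S:18S contribution is comparable across samples, since copy-number
and amplification biases affect all samples alike.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from ._pairwise import (anova_oneway, group_summary,
                        pairwise_welch_bonferroni)
from .data_model import QpcrTable, SampleFrame, ValidationError

__all__ = ["ct_to_value", "correct_host", "eukaryote_fraction",
           "compute_ratios", "compare_ratio_groups"]


def ct_to_value(ct: float) -> float:
    """Transform a cycle threshold to a template value, 2^(-Ct)."""
    ct = float(ct)
    if not math.isfinite(ct):
        raise ValidationError(f"Ct must be finite, got {ct!r}")
    return 2.0 ** (-ct)


def correct_host(value18: float, plant_frac18: float) -> float:
    """Scale the 18S value by the non-plant share, value18 x (1 - frac)."""
    if not 0.0 <= plant_frac18 <= 1.0:
        raise ValidationError(
            f"plant fraction must lie in [0, 1], got {plant_frac18!r}")
    return value18 * (1.0 - plant_frac18)


def eukaryote_fraction(v16: float, v18c: float) -> float:
    """Eukaryote contribution in percent, 100 x v18c / (v16 + v18c)."""
    if v16 + v18c <= 0:
        raise ValidationError("16S and 18S values are both zero")
    return 100.0 * v18c / (v16 + v18c)


def compute_ratios(qpcr: QpcrTable) -> pd.DataFrame:
    """Per-sample value pair and eukaryote/prokaryote percentages.

    Columns: ``v16``, ``v18_corrected``, ``euk_pct``, ``prok_pct``
    (with euk_pct + prok_pct = 100 exactly).
    """
    rows = {}
    for sid, r in qpcr.table.iterrows():
        v16 = ct_to_value(r["ct16"])
        v18c = correct_host(ct_to_value(r["ct18"]), r["plant_frac18"])
        euk = eukaryote_fraction(v16, v18c)
        rows[sid] = dict(v16=v16, v18_corrected=v18c, euk_pct=euk,
                         prok_pct=100.0 - euk)
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "sample_id"
    return out


def compare_ratio_groups(ratios: pd.DataFrame, meta: SampleFrame,
                         factor: str = "species",
                         value_col: str = "euk_pct",
                         alpha: float = 0.05) -> dict:
    """Group comparison of eukaryote percentages across a design factor.

    Returns a dict with ``anova`` (one-way F and p), ``groups``
    (per-level n/mean/SE) and ``pairwise`` (all pairwise two-sided Welch
    t-tests with Bonferroni-adjusted p over the comparison family).
    """
    common = [s for s in ratios.index if s in meta.table.index]
    if len(common) < len(ratios):
        missing = sorted(set(ratios.index) - set(common))
        raise ValidationError(f"sample(s) missing from metadata: {missing}")
    values = ratios.loc[common, value_col]
    groups = meta.table.loc[common, factor]
    counts = groups.value_counts()
    if (counts >= 2).sum() < 2:
        raise ValidationError(
            f"factor {factor!r} needs >= 2 levels with >= 2 samples")
    f, p = anova_oneway(values, groups)
    return {
        "anova": pd.DataFrame([{"factor": factor, "F": f, "p": p}]),
        "groups": group_summary(values, groups),
        "pairwise": pairwise_welch_bonferroni(values, groups),
    }
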