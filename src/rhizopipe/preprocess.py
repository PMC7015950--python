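"""OTU-table preprocessing in the study's fixed order.

Host-plant and organelle OTU removal happens first, on raw counts, and
the per-sample removed fractions are reported (the 18S host fraction
feeds the qPCR correction).  Sequencing depth is then standardized by
subsampling without replacement to a per-library upper threshold, counts
are converted to per-sample relative abundances summing to 100%, and
finally square-root transformed to damp the dominant taxa before
distance computation.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import (CountMatrix, RelAbundanceMatrix, TaxonomyTable,
                         ValidationError)

log = logging.getLogger("rhizopipe")

__all__ = ["HostRemovalReport", "remove_host_taxa", "standardize_depth",
           "to_relative", "sqrt_transform", "preprocess_library"]


@dataclass
class HostRemovalReport:
    """Per-sample fractions of reads removed as host plant / organelle.

    ``table`` is indexed by sample id with columns ``plant_frac``,
    ``organelle_frac`` (fractions of the pre-removal total),
    ``total_before`` and ``total_after``.
    """

    table: pd.DataFrame
    library: str

    def __post_init__(self) -> None:
        f = self.table[["plant_frac", "organelle_frac"]].to_numpy()
        if (f < 0).any() or (f > 1).any():
            raise ValidationError("removal fractions must lie in [0, 1]")

    @property
    def plant_frac(self) -> pd.Series:
        return self.table["plant_frac"]


def remove_host_taxa(counts: CountMatrix, taxonomy: TaxonomyTable,
                     ) -> tuple[CountMatrix, HostRemovalReport]:
    """Remove host-plant and organelle OTUs before any standardization.

    Every OTU in ``counts`` must have a taxonomy entry.  Samples whose
    reads are entirely removed are flagged as empty rather than silently
    kept as zero columns.
    """
    missing = [o for o in counts.otu_ids if o not in taxonomy.table.index]
    if missing:
        raise ValidationError(
            f"OTU(s) without taxonomy entry: {missing[:10]}"
            + (" ..." if len(missing) > 10 else ""))
    t = taxonomy.table.loc[counts.otu_ids]
    plant = t["is_host_plant"].to_numpy()
    organelle = t["is_organelle"].to_numpy() & ~plant
    total = counts.counts.sum(axis=0).astype(float)
    safe_total = total.replace(0, np.nan)
    plant_frac = (counts.counts.loc[plant].sum(axis=0) / safe_total).fillna(0)
    org_frac = (counts.counts.loc[organelle].sum(axis=0)
                / safe_total).fillna(0)
    keep = ~(plant | organelle)
    kept = counts.counts.loc[keep].copy()
    emptied = kept.columns[(kept.sum(axis=0) == 0) & (total > 0)]
    if len(emptied):
        log.warning("%s: sample(s) emptied by host/organelle removal: %s",
                    counts.library, list(emptied))
    out = CountMatrix(kept, counts.library,
                      frozenset(counts.empty_ok) | set(emptied))
    report = HostRemovalReport(pd.DataFrame({
        "plant_frac": plant_frac, "organelle_frac": org_frac,
        "total_before": total.astype(np.int64),
        "total_after": kept.sum(axis=0).astype(np.int64),
    }), counts.library)
    return out, report


def standardize_depth(counts: CountMatrix, threshold: int, seed: int = 0,
                      policy: str = "keep") -> CountMatrix:
    """Standardize sequencing depth to an upper threshold per sample.

    Samples with more than ``threshold`` reads are subsampled without
    replacement (multivariate hypergeometric draw) to exactly
    ``threshold``; samples at or below the threshold are kept unchanged
    (``policy='keep'``, default) or removed (``policy='drop'``).  Each
    sample gets its own RNG stream derived from (seed, sample id), so
    sample order cannot change the result.
    """
    if threshold < 1:
        raise ValidationError(f"threshold must be >= 1, got {threshold}")
    if policy not in ("keep", "drop"):
        raise ValidationError(f"policy must be keep/drop, got {policy!r}")
    cols = {}
    dropped = []
    for sid in counts.sample_ids:
        col = counts.counts[sid].to_numpy()
        total = int(col.sum())
        if total > threshold:
            rng = np.random.default_rng(
                [int(seed) % (2**31), zlib.crc32(str(sid).encode())])
            cols[sid] = rng.multivariate_hypergeometric(col, threshold)
        elif policy == "drop" and total < threshold:
            dropped.append(sid)
        else:
            cols[sid] = col
    if dropped:
        log.info("depth standardization dropped %d sub-threshold "
                 "sample(s): %s", len(dropped), dropped)
    if not cols:
        raise ValidationError("all samples below threshold with policy=drop")
    out = pd.DataFrame(cols, index=counts.otu_ids)
    return CountMatrix(out, counts.library,
                       frozenset(counts.empty_ok) & set(out.columns))


def to_relative(counts: CountMatrix) -> RelAbundanceMatrix:
    """Standardize each sample to a total OTU contribution of 100%."""
    vals = counts.counts.to_numpy(dtype=float)
    totals = vals.sum(axis=0)
    empty = totals == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        rel = np.where(empty[None, :], 0.0, vals / totals[None, :] * 100.0)
    flagged = frozenset(np.asarray(counts.sample_ids)[empty])
    if flagged - set(counts.empty_ok):
        log.warning("empty sample(s) flagged during standardization: %s",
                    sorted(flagged - set(counts.empty_ok)))
    return RelAbundanceMatrix(
        pd.DataFrame(rel, index=counts.otu_ids, columns=counts.sample_ids),
        counts.library, flagged | set(counts.empty_ok))


def sqrt_transform(rel: RelAbundanceMatrix) -> pd.DataFrame:
    """Element-wise square root of the percent abundances."""
    v = rel.values.to_numpy(dtype=float)
    if (v < 0).any():
        raise ValidationError("negative abundances cannot be sqrt-transformed")
    return pd.DataFrame(np.sqrt(v), index=rel.values.index,
                        columns=rel.values.columns)


def preprocess_library(counts: CountMatrix, taxonomy: TaxonomyTable,
                       threshold: int, seed: int = 0,
                       policy: str = "keep") -> dict:
    """Full preprocessing chain for one library.

    Fixed order: host/organelle removal -> depth standardization ->
    relative abundance -> square-root transform.  Returns a dict with
    keys ``report``, ``counts`` (standardized), ``rel`` and ``sqrt``.
    """
    log.info("preprocess %s: threshold=%d seed=%d policy=%s",
             counts.library, threshold, seed, policy)
    cleaned, report = remove_host_taxa(counts, taxonomy)
    std = standardize_depth(cleaned, threshold, seed=seed, policy=policy)
    rel = to_relative(std)
    return {"report": report, "counts": std, "rel": rel,
            "sqrt": sqrt_transform(rel)}
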