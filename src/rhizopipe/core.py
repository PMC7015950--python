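"""Core-microbiota membership and Venn partition.

An OTU belongs to the core of a wheat species when, for every genotype
line of that species, it is present (count or relative abundance > 0,
evaluated after depth standardization) in at least 25% of that line's
biological replicates — "at least" realized as the ceiling of
0.25 x n_replicates.  Species cores are then partitioned into the
shared core (intersection over all species), species-specific sets
(core of exactly one species) and, on request, every Venn region; each
set's community share is the mean per-sample summed relative abundance
over the relevant samples.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import (BULK_GENOTYPE, CountMatrix, RelAbundanceMatrix,
                         SampleFrame, ValidationError)

__all__ = ["CoreSets", "species_core", "venn_partition", "abundance_share",
           "core_region_table"]


@dataclass
class CoreSets:
    """Species cores, shared core, species-specific sets and Venn regions.

    ``regions`` maps a frozenset of species to the OTUs found in the
    cores of exactly those species (every OTU belonging to at least one
    core falls in exactly one region).
    """

    cores: dict
    shared_core: frozenset
    specific: dict
    regions: dict

    def __post_init__(self) -> None:
        for s, core in self.cores.items():
            if not self.shared_core <= core:
                raise ValidationError(
                    f"shared core not contained in core of {s!r}")
        names = list(self.specific)
        for a, b in itertools.combinations(names, 2):
            if self.specific[a] & self.specific[b]:
                raise ValidationError(
                    f"specific sets of {a!r} and {b!r} overlap")
            if self.specific[a] & self.shared_core:
                raise ValidationError("specific set overlaps shared core")


def _presence_frame(matrix) -> pd.DataFrame:
    if isinstance(matrix, CountMatrix):
        return matrix.counts > 0
    if isinstance(matrix, RelAbundanceMatrix):
        return matrix.values > 0
    return pd.DataFrame(matrix) > 0


def species_core(matrix, meta: SampleFrame, min_rep_frac: float = 0.25,
                 fraction: str | None = None) -> dict:
    """Per-species core OTU sets under the prevalence rule.

    An OTU is core for species s iff for EVERY line of s it is present
    in at least ceil(min_rep_frac x n_replicates) replicates of that
    line.  ``fraction`` optionally restricts the sample scope (e.g.
    ``"rhizosphere"``).
    """
    if not 0.0 < min_rep_frac <= 1.0:
        raise ValidationError(
            f"min_rep_frac must lie in (0, 1], got {min_rep_frac}")
    presence = _presence_frame(matrix)
    m = meta.table
    scope = m.index.isin(presence.columns) & (m["genotype"] != BULK_GENOTYPE)
    if fraction is not None:
        scope &= m["fraction"] == fraction
    m = m[scope]
    if m.empty:
        raise ValidationError("no planted samples in scope")
    cores = {}
    for species, sp_meta in m.groupby("species", sort=True):
        ok = np.ones(len(presence.index), dtype=bool)
        for line, line_meta in sp_meta.groupby("genotype", sort=True):
            samples = list(line_meta.index)
            required = math.ceil(min_rep_frac * len(samples))
            n_present = presence[samples].sum(axis=1).to_numpy()
            ok &= n_present >= required
        cores[species] = frozenset(presence.index[ok])
    return cores


def venn_partition(cores: dict) -> CoreSets:
    """Partition species cores into shared, specific and all Venn regions."""
    names = list(cores)
    if len(names) < 2:
        raise ValidationError("Venn partition needs >= 2 species cores")
    shared = frozenset(set.intersection(*(set(c) for c in cores.values())))
    specific = {}
    for s in names:
        others = set().union(*(cores[t] for t in names if t != s))
        specific[s] = frozenset(set(cores[s]) - others)
    regions = {}
    universe = set().union(*(cores[s] for s in names))
    for otu in universe:
        members = frozenset(s for s in names if otu in cores[s])
        regions.setdefault(members, set()).add(otu)
    regions = {k: frozenset(v) for k, v in regions.items()}
    return CoreSets(cores=dict(cores), shared_core=shared,
                    specific=specific, regions=regions)


def abundance_share(rel: RelAbundanceMatrix, otu_set, samples,
                    ) -> tuple[float, float]:
    """Mean (and SE) per-sample summed relative abundance of an OTU set."""
    samples = list(samples)
    if not samples:
        raise ValidationError("empty sample scope")
    missing = sorted(set(otu_set) - set(rel.values.index))
    if missing:
        raise ValidationError(f"OTU(s) not in matrix: {missing[:10]}")
    sub = rel.values.loc[list(otu_set), samples] if otu_set else \
        pd.DataFrame(0.0, index=[], columns=samples)
    shares = sub.sum(axis=0).to_numpy(dtype=float)
    mean = float(shares.mean())
    se = float(shares.std(ddof=1) / np.sqrt(len(shares))) \
        if len(shares) > 1 else float("nan")
    return mean, se


def core_region_table(sets: CoreSets, rel: RelAbundanceMatrix,
                      meta: SampleFrame, fraction: str | None = None,
                      ) -> pd.DataFrame:
    """Venn-region summary: region, n_OTUs, mean share % over its samples.

    Each region's share is computed over the samples of the species in
    the region (all species for the shared core).
    """
    m = meta.table
    rows = []
    for members, otus in sorted(sets.regions.items(),
                                key=lambda kv: (-len(kv[0]), sorted(kv[0]))):
        scope = m.index.isin(rel.values.columns) & m["species"].isin(members)
        if fraction is not None:
            scope &= m["fraction"] == fraction
        samples = list(m.index[scope])
        mean, se = abundance_share(rel, otus, samples)
        rows.append(dict(region="&".join(sorted(members)),
                         n_species=len(members), n_otus=len(otus),
                         share_pct=mean, share_se=se))
    return pd.DataFrame(rows)
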