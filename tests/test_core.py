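"""Core-membership rule, Venn partition and abundance shares."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from rhizopipe.core import (abundance_share, species_core, venn_partition)
from rhizopipe.data_model import (CountMatrix, RelAbundanceMatrix,
                                  ValidationError)
from conftest import make_meta


def _presence_matrix(cols, otus):
    df = pd.DataFrame(cols, index=otus)
    return df


def _meta_for(species_lines, reps):
    """species_lines: {species: [line, ...]}; reps replicates each."""
    rows = []
    for species, lines in species_lines.items():
        for line in lines:
            for rep in range(1, reps + 1):
                rows.append((f"{line}_r{rep}", "rhizosphere", line, species,
                             "modern", 6, "none", rep))
    return make_meta(rows)


def brute_force_core(presence: pd.DataFrame, meta, min_rep_frac):
    """Literal evaluation of the prevalence rule, used as oracle."""
    m = meta.table
    cores = {}
    for species in sorted(m["species"].unique()):
        core = set()
        lines = sorted(m.loc[m["species"] == species, "genotype"].unique())
        for otu in presence.index:
            ok = True
            for line in lines:
                samples = [s for s in m.index
                           if m.loc[s, "genotype"] == line
                           and s in presence.columns]
                need = math.ceil(min_rep_frac * len(samples))
                have = sum(bool(presence.loc[otu, s]) for s in samples)
                if have < need:
                    ok = False
                    break
            if ok:
                core.add(otu)
        cores[species] = frozenset(core)
    return cores


def test_core_rule_quarter_prevalence_boundary():
    meta = _meta_for({"sp": ["L1", "L2"]}, reps=4)
    # OTU 'a': 4/4 in L1, 1/4 in L2 -> core (ceil(0.25*4)=1)
    # OTU 'b': 4/4 in L1, 0/4 in L2 -> not core
    cols = {}
    for rep in range(1, 5):
        cols[f"L1_r{rep}"] = [1, 1]
        cols[f"L2_r{rep}"] = [1 if rep == 1 else 0, 0]
    df = pd.DataFrame(cols, index=["a", "b"])
    counts = CountMatrix(df, "prokaryote16S",
                         frozenset(df.columns[df.sum(axis=0) == 0]))
    cores = species_core(counts, meta)
    assert cores["sp"] == frozenset({"a"})


def test_core_rule_seven_replicates_needs_two():
    meta = _meta_for({"sp": ["L1"]}, reps=7)
    cols = {f"L1_r{r}": [1 if r == 1 else 0, 1 if r <= 2 else 0]
            for r in range(1, 8)}
    counts = CountMatrix(pd.DataFrame(cols, index=["one_hit", "two_hits"]),
                         "prokaryote16S", frozenset(cols) - {"L1_r1", "L1_r2"})
    cores = species_core(counts, meta)
    # ceil(0.25 * 7) = 2: one presence is not enough
    assert cores["sp"] == frozenset({"two_hits"})


def test_invalid_min_rep_frac():
    meta = _meta_for({"sp": ["L1"]}, reps=2)
    counts = CountMatrix(pd.DataFrame({"L1_r1": [1], "L1_r2": [1]},
                                      index=["a"]), "prokaryote16S")
    for bad in (0.0, 1.5, -0.1):
        with pytest.raises(ValidationError):
            species_core(counts, meta, min_rep_frac=bad)


def _random_case(rng, n_otus=30, n_species=3, n_lines=2, reps=5):
    species_lines = {f"sp{i}": [f"sp{i}_L{j}" for j in range(n_lines)]
                     for i in range(n_species)}
    meta = _meta_for(species_lines, reps)
    cols = {s: rng.integers(0, 2, size=n_otus) * rng.integers(1, 5)
            for s in meta.sample_ids}
    counts = pd.DataFrame(cols, index=[f"o{i}" for i in range(n_otus)])
    return counts, meta


def test_species_core_matches_brute_force():
    rng = np.random.default_rng(7)
    for _ in range(50):
        counts, meta = _random_case(rng)
        fast = species_core(counts, meta, min_rep_frac=0.25)
        slow = brute_force_core(counts > 0, meta, 0.25)
        assert fast == slow


def test_core_monotone_in_prevalence_threshold():
    rng = np.random.default_rng(8)
    counts, meta = _random_case(rng, reps=8)
    fracs = (0.1, 0.25, 0.5, 0.9, 1.0)
    cores = [species_core(counts, meta, min_rep_frac=f) for f in fracs]
    for lo, hi in zip(cores, cores[1:]):
        for sp in lo:
            assert hi[sp] <= lo[sp]


def test_venn_partition_example():
    sets = venn_partition({"A": frozenset({1, 2}), "B": frozenset({2, 3})})
    assert sets.shared_core == frozenset({2})
    assert sets.specific["A"] == frozenset({1})
    assert sets.specific["B"] == frozenset({3})


def test_identical_cores_have_no_specific_otus():
    sets = venn_partition({"A": frozenset({1, 2}), "B": frozenset({1, 2})})
    assert sets.specific["A"] == sets.specific["B"] == frozenset()
    assert sets.shared_core == frozenset({1, 2})


def test_every_core_otu_in_exactly_one_region():
    rng = np.random.default_rng(9)
    for _ in range(20):
        names = ["A", "B", "C", "D"][:rng.integers(2, 5)]
        cores = {n: frozenset(rng.choice(20, size=rng.integers(0, 12),
                                         replace=False))
                 for n in names}
        if not any(cores.values()):
            continue
        sets = venn_partition(cores)
        universe = set().union(*cores.values())
        for otu in universe:
            member_regions = [k for k, v in sets.regions.items()
                              if otu in v]
            assert len(member_regions) == 1
            # region key is exactly the species whose cores contain it
            assert member_regions[0] == frozenset(
                n for n in names if otu in cores[n])


def _rel(cols, otus):
    df = pd.DataFrame(cols, index=otus, dtype=float)
    return RelAbundanceMatrix(df, "prokaryote16S")


def test_abundance_share_examples():
    rel = _rel({"S1": [60, 30, 10], "S2": [80, 15, 5]}, ["a", "b", "c"])
    mean, se = abundance_share(rel, {"a", "b", "c"}, ["S1", "S2"])
    assert mean == pytest.approx(100.0)
    mean, _ = abundance_share(rel, set(), ["S1", "S2"])
    assert mean == 0.0
    mean, se = abundance_share(rel, {"a"}, ["S1", "S2"])
    assert mean == pytest.approx(70.0)
    assert se == pytest.approx(np.std([60, 80], ddof=1) / np.sqrt(2))
    with pytest.raises(ValidationError):
        abundance_share(rel, {"a"}, [])


def test_region_shares_partition_species_core_share():
    """Within one species' samples, Venn-region shares add up to that
    species' total core share."""
    rng = np.random.default_rng(10)
    counts, meta = _random_case(rng, n_otus=25)
    from rhizopipe.preprocess import to_relative
    cm = CountMatrix(counts, "prokaryote16S",
                     frozenset(counts.columns[counts.sum(axis=0) == 0]))
    rel = to_relative(cm)
    cores = species_core(cm, meta)
    sets = venn_partition(cores)
    sp = "sp0"
    samples = [s for s in meta.sample_ids
               if meta.table.loc[s, "species"] == sp
               and s not in rel.empty_ok]
    total, _ = abundance_share(rel, cores[sp], samples)
    pieces = sum(abundance_share(rel, otus, samples)[0]
                 for members, otus in sets.regions.items() if sp in members)
    assert pieces == pytest.approx(total, abs=1e-9)
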