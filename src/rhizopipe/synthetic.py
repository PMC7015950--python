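"""Synthetic wheat-microbiota community generator with known ground truth.

Emulates the study design: a panel of 22 wheat lines (modern bread and
pasta wheat, wild progenitors, synthetic hexaploid wheat and F1 crosses)
plus unplanted bulk-soil controls, sampled in rhizosphere and/or root
fractions and profiled with four amplicon libraries (prokaryote 16S,
eukaryote 18S, fungal ITS1, oomycete ITS1).

Per sample, the expected community composition is a baseline log-normal
OTU profile multiplied by per-factor-level fold effects on designated
taxon groups (e.g. a wild-D-genome effect on Nematoda and
Glomeromycetes) and renormalized; read counts are then drawn
Dirichlet-multinomial at a configured depth and overdispersion.  In the
18S library, planted samples additionally receive a host-plant OTU share
drawn uniformly from a contamination interval (default 14-75% of the
eukaryotic amplicons, matching the range reported for wheat).  qPCR
cycle thresholds are generated by inverting the 2^(-Ct) value transform
from a per-sample true eukaryote fraction.

All randomness derives from a single seed fanned out to per-sample
streams keyed by stable labels, so results are independent of sample
order and reproducible.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data_model import (BULK_GENOTYPE, DEPTH_THRESHOLDS, LIBRARIES, RANKS,
                         CountMatrix, QpcrTable, SampleFrame, TaxonomyTable,
                         ValidationError)

__all__ = [
    "SimConfig", "GroundTruth", "LINE_TABLE", "default_effects",
    "simulate_design", "simulate_counts", "simulate_qpcr", "simulate_all",
]

#: The 22 wheat lines of the study panel:
#: (genotype line, species, ancestry, ploidy, D-genome class, replicates).
LINE_TABLE = (
    ("Paragon", "T. aestivum", "modern", 6, "artificial", 9),
    ("Rialto", "T. aestivum", "modern", 6, "artificial", 9),
    ("Avalon", "T. aestivum", "modern", 6, "artificial", 10),
    ("Watkins-1190032", "T. aestivum", "modern", 6, "artificial", 9),
    ("Biensur", "T. durum", "modern", 4, "none", 8),
    ("Hoh-501", "T. durum", "modern", 4, "none", 8),
    ("Kronos", "T. durum", "modern", 4, "none", 9),
    ("Ent-392", "A. tauschii", "wild", 2, "wild", 8),
    ("Ent-336", "A. tauschii", "wild", 2, "wild", 10),
    ("Ent-088", "A. tauschii", "wild", 2, "wild", 7),
    ("WX895", "A. tauschii", "wild", 2, "wild", 8),
    ("TTD140", "T. dicoccoides", "wild", 4, "none", 6),
    ("DIC70", "T. dicoccoides", "wild", 4, "none", 10),
    ("DIC63", "T. dicoccoides", "wild", 4, "none", 8),
    ("SHW-023", "SHW", "synthetic", 6, "wild", 10),
    ("SHW-041", "SHW", "synthetic", 6, "wild", 10),
    ("SHW-054", "SHW", "synthetic", 6, "wild", 10),
    ("SHW-055", "SHW", "synthetic", 6, "wild", 10),
    ("F1-line1", "F1", "synthetic", 6, "mixed", 7),
    ("F1-line2", "F1", "synthetic", 6, "mixed", 6),
    ("F1-line3", "F1", "synthetic", 6, "mixed", 7),
    ("F1-line4", "F1", "synthetic", 6, "mixed", 10),
)

_LINE_INFO = {row[0]: row for row in LINE_TABLE}


def default_effects() -> dict:
    """Study-condition fold effects: {taxon group: {factor: {level: fold}}}.

    Taxon groups are matched case-insensitively against any lineage rank.
    Defaults emulate the reported structure: a strong niche (fraction)
    effect on Proteobacteria, Cyanobacteria enrichment in T. aestivum,
    and wild-D-genome enrichment of Nematoda (4x) and Glomeromycetes
    (3x), with intermediate effects in mixed-D F1 crosses.
    """
    return {
        "Proteobacteria": {"fraction": {"rhizosphere": 3.0, "root": 10.0}},
        "Actinobacteria": {"fraction": {"root": 0.3}},
        "Cyanobacteria": {"species": {"T. aestivum": 8.0}},
        "Nematoda": {"d_genome": {"wild": 4.0, "mixed": 2.0}},
        "Glomeromycetes": {"d_genome": {"wild": 3.0, "mixed": 2.0}},
    }


@dataclass
class SimConfig:
    """Configuration of the synthetic community generator.

    Defaults are the study conditions: the full 22-line panel, 8
    replicates per line, rhizosphere fraction, 8 bulk-soil controls,
    Dirichlet concentration 200 (biological overdispersion), sequencing
    depths drawn log-normal around twice the per-library standardization
    threshold, host 18S contamination uniform on [0.14, 0.75], and true
    eukaryote fractions of 5.4% (bulk soil) / 6.8% (planted
    rhizospheres).
    """

    lines: Sequence[str] = tuple(r[0] for r in LINE_TABLE)
    reps_per_line: int | None = 8  # None = per-line panel replicates
    n_bulk: int = 8
    fractions: Sequence[str] = ("rhizosphere",)
    n_otus: int = 150
    log_mean: float = 0.0
    log_sd: float = 1.0
    concentration: float = 200.0
    effects: Mapping = field(default_factory=default_effects)
    host_contamination_range: tuple = (0.14, 0.75)
    organelle_range: tuple = (0.005, 0.03)
    depth_median_factor: float = 2.0
    depth_log_sd: float = 0.25
    euk_fraction_bulk: float = 0.054
    euk_fraction_planted: float = 0.068
    euk_fraction_sd: float = 0.005
    ct16_baseline: float = 16.0
    ct_noise_sd: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.reps_per_line is not None and self.reps_per_line < 1:
            raise ValidationError("reps_per_line must be >= 1")
        unknown = [l for l in self.lines if l not in _LINE_INFO]
        if unknown:
            raise ValidationError(f"unknown line(s): {unknown}")
        for group, factors in self.effects.items():
            for factor, levels in factors.items():
                for level, fold in levels.items():
                    if not fold > 0:
                        raise ValidationError(
                            f"effect {group}/{factor}={level} fold must "
                            f"be > 0, got {fold}")
        lo, hi = self.host_contamination_range
        if not (0 <= lo <= hi <= 1):
            raise ValidationError(
                "host_contamination_range must be an interval within [0, 1]")
        for name in ("euk_fraction_bulk", "euk_fraction_planted"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValidationError(f"{name} must lie in (0, 1)")


@dataclass
class GroundTruth:
    """True generative state of one simulated library.

    ``composition`` holds the expected OTU proportions per sample
    (columns sum to 1, host/organelle share included); ``euk_fraction``
    and ``plant_frac`` the per-sample true eukaryote fraction and
    host-plant 18S share; ``group_members`` the OTU ids of each effect
    taxon group; ``effects`` the fold-effect map that was injected.
    """

    composition: pd.DataFrame
    euk_fraction: pd.Series
    plant_frac: pd.Series
    group_members: dict
    effects: Mapping

    def __post_init__(self) -> None:
        sums = self.composition.sum(axis=0)
        if not np.allclose(sums, 1.0, atol=1e-8):
            raise ValidationError("true compositions must sum to 1")


def _stream(seed: int, label: str) -> np.random.Generator:
    """Independent RNG stream keyed by (seed, stable label)."""
    return np.random.default_rng(
        [int(seed) % (2**31), zlib.crc32(label.encode())])


# ---------------------------------------------------------------------------
# design
# ---------------------------------------------------------------------------


def simulate_design(config: SimConfig) -> SampleFrame:
    """Build the sample metadata frame for the configured design.

    One sample per (line, replicate, fraction) plus ``n_bulk`` unplanted
    bulk-soil controls.
    """
    rows = {}
    for line in config.lines:
        _, species, ancestry, ploidy, d_gen, panel_reps = _LINE_INFO[line]
        reps = (config.reps_per_line if config.reps_per_line is not None
                else panel_reps)
        for fraction in config.fractions:
            if fraction not in ("rhizosphere", "root"):
                raise ValidationError(
                    f"planted fraction must be rhizosphere/root, "
                    f"got {fraction!r}")
            for rep in range(1, reps + 1):
                sid = f"{line}_{fraction}_r{rep}"
                rows[sid] = dict(fraction=fraction, genotype=line,
                                 species=species, ancestry=ancestry,
                                 ploidy=ploidy, d_genome=d_gen,
                                 replicate=rep)
    for rep in range(1, config.n_bulk + 1):
        rows[f"bulk_r{rep}"] = dict(
            fraction="bulk", genotype=BULK_GENOTYPE, species=BULK_GENOTYPE,
            ancestry="none", ploidy=0, d_genome="none", replicate=rep)
    if not rows:
        raise ValidationError("design has no samples")
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "sample_id"
    return SampleFrame(table)


# ---------------------------------------------------------------------------
# taxonomy and baseline profiles
# ---------------------------------------------------------------------------

# per-library phylum pools: (phylum, baseline share weight)
_PHYLUM_POOLS = {
    "prokaryote16S": (
        ("Proteobacteria", 0.20), ("Actinobacteria", 0.22),
        ("Acidobacteria", 0.18), ("Bacteroidetes", 0.10),
        ("Firmicutes", 0.08), ("Verrucomicrobia", 0.08),
        ("Thaumarchaeota", 0.07), ("Cyanobacteria", 0.02),
        ("Chloroflexi", 0.05),
    ),
    "eukaryote18S": (
        ("Ascomycota", 0.45), ("Basidiomycota", 0.18),
        ("Cercozoa", 0.12), ("Ciliophora", 0.08),
        ("Chlorophyta", 0.06), ("Nematoda", 0.02),
        ("Mucoromycota", 0.09),
    ),
    "fungalITS1": (
        ("Ascomycota", 0.55), ("Basidiomycota", 0.25),
        ("Mortierellomycota", 0.12), ("Mucoromycota", 0.08),
    ),
    "oomyceteITS1": (
        ("Oomycota", 1.0),
    ),
}

_GLOM_ORDERS = ("Glomerales", "Diversisporales", "Archaeosporales",
                "Paraglomerales")

#: number of OTUs carrying the Glomeromycetes class (18S and fungal ITS1)
_N_GLOM = 6
_GLOM_WEIGHT = 0.015
#: host-plant and organelle OTU counts
_N_HOST = 2
_N_ORGANELLE = 3


def _build_taxonomy(library: str, n_otus: int,
                    rng: np.random.Generator) -> TaxonomyTable:
    """Assign each OTU a lineage; returns taxonomy with special OTUs.

    Designated blocks: Glomeromycetes-class OTUs (18S/fungal ITS1),
    host-plant OTUs (18S) and chloroplast/mitochondrial organelle OTUs
    (16S).  Phylum assignment for the remaining OTUs is deterministic
    round-robin weighted by the library's phylum pool.
    """
    pool = _PHYLUM_POOLS[library]
    rows = []
    special = []
    if library in ("eukaryote18S", "fungalITS1"):
        for i in range(_N_GLOM):
            special.append(dict(
                domain="Eukaryota", phylum="Mucoromycota",
                **{"class": "Glomeromycetes"},
                order=_GLOM_ORDERS[i % len(_GLOM_ORDERS)],
                family="", genus="Glomus" if i % 2 == 0 else "",
                is_host_plant=False, is_organelle=False))
    if library == "eukaryote18S":
        for i in range(_N_HOST):
            special.append(dict(
                domain="Eukaryota", phylum="Streptophyta",
                **{"class": "Liliopsida"}, order="Poales", family="Poaceae",
                genus="Triticum", is_host_plant=True, is_organelle=False))
    if library == "prokaryote16S":
        for i in range(_N_ORGANELLE):
            special.append(dict(
                domain="Bacteria", phylum="Cyanobacteria",
                **{"class": "Chloroplast" if i % 2 == 0 else "Oxyphotobacteria"},
                order="Chloroplast" if i % 2 == 0 else "Rickettsiales",
                family="", genus="", is_host_plant=False, is_organelle=True))
    n_plain = n_otus - len(special)
    if n_plain < len(pool):
        raise ValidationError(
            f"n_otus={n_otus} too small for library {library}")
    phyla = [p for p, _ in pool]
    weights = np.array([w for _, w in pool], dtype=float)
    # deterministic proportional allocation of plain OTUs to phyla
    alloc = np.floor(weights / weights.sum() * n_plain).astype(int)
    while alloc.sum() < n_plain:
        alloc[int(np.argmax(weights / weights.sum() * n_plain - alloc))] += 1
    domain = "Bacteria" if library == "prokaryote16S" else "Eukaryota"
    genera = {"Oomycota": ("Pythium", "Phytophthora"),
              "Cyanobacteria": ("Nostoc", "Cylindrospermum"),
              "Mortierellomycota": ("Mortierella",),
              "Ascomycota": ("Fusarium", "Verticillium", ""),
              "Basidiomycota": ("Cryptococcus", "")}
    for phylum, n in zip(phyla, alloc):
        opts = genera.get(phylum, ("",))
        for i in range(n):
            rows.append(dict(domain=domain, phylum=phylum,
                             **{"class": ""}, order="", family="",
                             genus=opts[i % len(opts)],
                             is_host_plant=False, is_organelle=False))
    rows.extend(special)
    table = pd.DataFrame(rows, index=[f"OTU_{i+1:04d}" for i in range(n_otus)])
    table.index.name = "otu_id"
    return TaxonomyTable(table)


def _baseline_profile(library: str, tax: TaxonomyTable, log_mean: float,
                      log_sd: float, rng: np.random.Generator) -> np.ndarray:
    """Baseline expected OTU proportions (host/organelle share excluded).

    Log-normal rank-abundance jitter is applied within each phylum block
    and renormalized to the block's pool weight, so taxon-group baseline
    shares stay at their configured community fractions.
    """
    t = tax.table
    pool = dict(_PHYLUM_POOLS[library])
    w = np.zeros(len(t))
    glom = (t["class"] == "Glomeromycetes").to_numpy()
    flagged = (t["is_host_plant"] | t["is_organelle"]).to_numpy()
    jitter = rng.lognormal(log_mean, log_sd, size=len(t))
    blocks = [(p, ((t["phylum"] == p).to_numpy() & ~flagged & ~glom), wt)
              for p, wt in pool.items()]
    if glom.any():
        blocks.append(("Glomeromycetes", glom, _GLOM_WEIGHT))
    for _, members, weight in blocks:
        if members.sum():
            block = jitter[members]
            w[members] = weight * block / block.sum()
    return w / w.sum()


def _known_groups() -> set:
    """Taxon-group vocabulary recognized across all library taxonomies."""
    names = {"glomeromycetes", "glomus", "nematoda", "streptophyta",
             "triticum", "nostoc", "cylindrospermum", "pythium",
             "phytophthora", "mortierella", "fusarium", "verticillium",
             "cryptococcus"}
    for pool in _PHYLUM_POOLS.values():
        names |= {p.lower() for p, _ in pool}
    return names


def _group_members(tax: TaxonomyTable, group: str) -> list:
    t = tax.table
    g = group.strip().lower()
    flagged = t["is_host_plant"] | t["is_organelle"]
    mask = ~flagged & False
    for rank in RANKS:
        mask |= (t[rank].str.strip().str.lower() == g) & ~flagged
    return list(t.index[mask])


# ---------------------------------------------------------------------------
# counts
# ---------------------------------------------------------------------------


def simulate_counts(design: SampleFrame, config: SimConfig,
                    library: str = "eukaryote18S",
                    ) -> tuple[CountMatrix, TaxonomyTable, GroundTruth]:
    """Simulate one library's OTU count table with known ground truth.

    Per sample the expected composition is the baseline profile times
    the configured multiplicative effects (matched by taxon group and
    the sample's factor levels), renormalized; in the 18S library a
    host-plant share is inserted for planted samples and, in the 16S
    library, a small organelle share.  Counts are Dirichlet-multinomial
    at the configured depth distribution and concentration.
    """
    if library not in LIBRARIES:
        raise ValidationError(f"unknown library {library!r}")
    meta = design.table
    rng_tax = _stream(config.seed, f"{library}:taxonomy")
    tax = _build_taxonomy(library, config.n_otus, rng_tax)
    t = tax.table
    base = _baseline_profile(library, tax, config.log_mean, config.log_sd,
                             rng_tax)

    group_members = {}
    member_mask = {}
    for group in config.effects:
        members = _group_members(tax, group)
        if not members:
            if group.strip().lower() in _known_groups():
                # group belongs to another library's taxonomy; inert here
                continue
            raise ValidationError(
                f"effect taxon group {group!r} has no OTUs in any "
                f"library taxonomy")
        group_members[group] = members
        member_mask[group] = t.index.isin(members)

    host_mask = t["is_host_plant"].to_numpy()
    org_mask = t["is_organelle"].to_numpy()
    threshold = DEPTH_THRESHOLDS[library]
    lo, hi = config.host_contamination_range

    comp_cols, count_cols = {}, {}
    euk_frac, plant_frac = {}, {}
    for sid, row in meta.iterrows():
        rng = _stream(config.seed, f"{library}:sample:{sid}")
        planted = row["genotype"] != BULK_GENOTYPE
        mult = np.ones(len(base))
        for group, factors in config.effects.items():
            if group not in member_mask:
                continue
            for factor, levels in factors.items():
                fold = levels.get(str(row[factor]))
                if fold is not None and fold != 1.0:
                    mult[member_mask[group]] *= fold
        comp = base * mult
        comp = comp / comp.sum()
        # contamination shares
        c_host = 0.0
        if library == "eukaryote18S" and planted:
            c_host = rng.uniform(lo, hi)
            comp = comp * (1.0 - c_host)
            comp[host_mask] = c_host / host_mask.sum()
        if library == "prokaryote16S" and planted:
            c_org = rng.uniform(*config.organelle_range)
            comp = comp * (1.0 - c_org)
            comp[org_mask] = c_org / org_mask.sum()
        depth = int(np.round(rng.lognormal(
            np.log(config.depth_median_factor * threshold),
            config.depth_log_sd)))
        depth = max(depth, 1)
        alpha = config.concentration * comp
        live = alpha > 0
        p = np.zeros_like(comp)
        draw = rng.gamma(np.clip(alpha[live], 1e-9, None))
        if draw.sum() <= 0:
            draw = comp[live]
        p[live] = draw / draw.sum()
        counts = rng.multinomial(depth, p)
        comp_cols[sid] = comp
        count_cols[sid] = counts
        plant_frac[sid] = c_host
        e_target = (config.euk_fraction_planted if planted
                    else config.euk_fraction_bulk)
        e = rng.normal(e_target, config.euk_fraction_sd)
        euk_frac[sid] = float(np.clip(e, 1e-4, 0.5))

    composition = pd.DataFrame(comp_cols, index=t.index)
    counts = pd.DataFrame(count_cols, index=t.index)
    empty = frozenset(counts.columns[counts.sum(axis=0) == 0])
    cm = CountMatrix(counts, library, empty)
    truth = GroundTruth(composition=composition,
                        euk_fraction=pd.Series(euk_frac),
                        plant_frac=pd.Series(plant_frac),
                        group_members=group_members,
                        effects=config.effects)
    return cm, tax, truth


# ---------------------------------------------------------------------------
# qPCR
# ---------------------------------------------------------------------------


def simulate_qpcr(truth: GroundTruth, config: SimConfig) -> QpcrTable:
    """Generate Ct values consistent with the true eukaryote fractions.

    Chooses a value pair (v16, v18) with v18 / (v16 + v18) equal to the
    true eukaryote fraction before host contamination, inflates v18 by
    1 / (1 - plant_frac18), and sets Ct = -log2(value) + N(0, ct_noise).
    """
    rows = {}
    v16 = 2.0 ** (-config.ct16_baseline)
    for sid, e in truth.euk_fraction.items():
        if not 0.0 < e < 1.0:
            raise ValidationError(
                f"true eukaryote fraction for {sid!r} must lie in (0, 1)")
        pf = float(truth.plant_frac[sid])
        if pf >= 1.0:
            raise ValidationError(
                f"plant fraction for {sid!r} must be < 1 to invert")
        v18 = v16 * e / (1.0 - e) / (1.0 - pf)
        rng = _stream(config.seed, f"qpcr:{sid}")
        noise = rng.normal(0.0, config.ct_noise_sd, size=2)
        rows[sid] = dict(ct16=-np.log2(v16) + noise[0],
                         ct18=-np.log2(v18) + noise[1],
                         plant_frac18=pf)
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "sample_id"
    return QpcrTable(table)


def simulate_all(config: SimConfig,
                 libraries: Sequence[str] = LIBRARIES) -> dict:
    """Simulate the design plus every requested library and the qPCR table.

    Returns a dict with keys ``design``, ``libraries`` (mapping library
    name to (CountMatrix, TaxonomyTable, GroundTruth)) and ``qpcr``
    (generated from the 18S ground truth when present, else from the
    first library).
    """
    design = simulate_design(config)
    out = {"design": design, "libraries": {}}
    for lib in libraries:
        out["libraries"][lib] = simulate_counts(design, config, lib)
    key = "eukaryote18S" if "eukaryote18S" in out["libraries"] else libraries[0]
    out["qpcr"] = simulate_qpcr(out["libraries"][key][2], config)
    return out
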