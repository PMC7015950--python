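"""One-command orchestration of the full analysis.

Stages, in the study's order: simulate (or ingest) the four amplicon
libraries -> preprocess (host removal, depth standardization, relative
abundance, sqrt) -> qPCR eukaryote:prokaryote ratios with host
correction -> core/shared/species-specific membership -> ordination,
PERMANOVA and CAP -> taxa-level screens -> consolidated report with a
run manifest (seeds, thresholds, stage checksums).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .core import core_region_table, species_core, venn_partition
from .data_model import (BULK_GENOTYPE, DEPTH_THRESHOLDS, LIBRARIES,
                         SampleFrame, ValidationError, write_count_table,
                         write_frame, write_metadata, write_ordination,
                         write_qpcr, write_rel_abundance, write_taxonomy)
from .ordination import bray_curtis, cap, group_centroids, pcoa, permanova
from .preprocess import preprocess_library
from .qpcr import compare_ratio_groups, compute_ratios
from .synthetic import SimConfig, simulate_all
from .taxa import aggregate_taxa, fold_change_screen, group_tests, \
    taxon_correlation

log = logging.getLogger("rhizopipe")

DEFAULT_FORMULA = ("fraction + ploidy + ancestry + species(ancestry) "
                   "+ genotype(species)")


@dataclass
class PipelineConfig:
    """Configuration for :func:`run_pipeline`.

    Either ``sim`` (synthetic run) or ``inputs`` (paths to counts /
    taxonomy / metadata / qPCR tables per library) must be provided.
    """

    out_dir: str | Path = "results"
    sim: SimConfig | None = None
    inputs: dict | None = None
    libraries: tuple = ("prokaryote16S", "eukaryote18S")
    thresholds: dict = field(default_factory=lambda: dict(DEPTH_THRESHOLDS))
    formula: str = DEFAULT_FORMULA
    n_perm: int = 999
    seed: int = 0
    alpha: float = 0.05
    min_rep_frac: float = 0.25
    core_fraction: str = "rhizosphere"
    taxa_rank: str = "phylum"
    effect_factor: str = "d_genome"

    def __post_init__(self) -> None:
        if self.sim is None and self.inputs is None:
            self.sim = SimConfig(seed=self.seed)


def _usable_terms(formula: str, table: pd.DataFrame) -> list:
    """Drop model terms that are single-level or aliased on this design.

    The full panel supports the complete nested model; reduced line
    panels can collapse a factor into the span of the preceding terms,
    in which case the term is skipped with a log note rather than
    aborting the run.
    """
    from .ordination import _dummies, _hat, parse_terms
    terms = parse_terms(formula)
    kept = []
    x = np.ones((len(table), 1))
    _, rank = _hat(x)
    for t in terms:
        if table[t.factor].nunique() < 2:
            log.info("dropping single-level term %s", t.label)
            continue
        labels = table[t.factor].astype(str)
        if t.parent:
            labels = table[t.parent].astype(str) + "/" + labels
        x_try = np.hstack([x, _dummies(labels)])
        _, rank_try = _hat(x_try)
        if rank_try == rank:
            log.info("dropping aliased term %s", t.label)
            continue
        x, rank = x_try, rank_try
        kept.append(t)
    return kept


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _check_consistency(counts, meta: SampleFrame) -> None:
    in_counts = set(counts.sample_ids)
    in_meta = set(meta.sample_ids)
    orphans = sorted(in_counts - in_meta)
    if orphans:
        raise ValidationError(
            f"{counts.library}: sample(s) in counts but not metadata: "
            f"{orphans}")
    extra = sorted(in_meta - in_counts)
    if extra:
        log.warning("%s: metadata sample(s) without counts (allowed): %s",
                    counts.library, extra[:10])


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write the report bundle to ``config.out_dir``.

    Returns a dict of in-memory stage results plus the headline numbers
    of the run (eukaryote percentages, strongest PERMANOVA factor, core
    shares, taxa screen outcomes).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log.info("pipeline start: seed=%d n_perm=%d thresholds=%s",
             config.seed, config.n_perm, config.thresholds)
    results: dict = {"config": config}

    # ---- stage 1: data ----------------------------------------------------
    if config.sim is not None:
        sim = simulate_all(config.sim, config.libraries)
        design, qpcr_table = sim["design"], sim["qpcr"]
        libs = {lib: dict(counts=trip[0], taxonomy=trip[1], truth=trip[2])
                for lib, trip in sim["libraries"].items()}
    else:
        from .data_model import (read_count_table, read_metadata, read_qpcr,
                                 read_taxonomy)
        design = read_metadata(config.inputs["metadata"])
        qpcr_table = read_qpcr(config.inputs["qpcr"])
        libs = {}
        for lib in config.libraries:
            libs[lib] = dict(
                counts=read_count_table(config.inputs[lib]["counts"], lib),
                taxonomy=read_taxonomy(config.inputs[lib]["taxonomy"]),
                truth=None)
    for lib in config.libraries:
        _check_consistency(libs[lib]["counts"], design)
    write_metadata(design, out / "metadata.tsv")
    write_qpcr(qpcr_table, out / "qpcr_ct.tsv")
    results["design"], results["qpcr_table"] = design, qpcr_table

    # ---- stage 2: preprocessing ------------------------------------------
    for lib in config.libraries:
        entry = libs[lib]
        stage = preprocess_library(
            entry["counts"], entry["taxonomy"],
            threshold=config.thresholds[lib], seed=config.seed)
        entry.update(stage)
        write_count_table(entry["counts"], out / f"{lib}_counts_raw.tsv")
        write_taxonomy(entry["taxonomy"], out / f"{lib}_taxonomy.tsv")
        write_rel_abundance(entry["rel"], out / f"{lib}_relabundance.tsv")
        write_frame(entry["report"].table, out / f"{lib}_host_removal.tsv",
                    index_label="sample_id")
    results["libraries"] = libs

    # ---- stage 3: qPCR ratios --------------------------------------------
    ratios = compute_ratios(qpcr_table)
    rhizo = design.samples_where(fraction="rhizosphere")
    bulk = design.samples_where(fraction="bulk")
    scope = [s for s in ratios.index if s in rhizo + bulk]
    qmeta = design.table.loc[scope].copy()
    ratio_tests = compare_ratio_groups(
        ratios.loc[scope], SampleFrame(qmeta), factor="species",
        alpha=config.alpha)
    write_frame(ratios, out / "qpcr_ratios.tsv", index_label="sample_id")
    write_frame(ratio_tests["groups"], out / "qpcr_group_means.tsv",
                index_label="species")
    write_frame(ratio_tests["pairwise"], out / "qpcr_pairwise.tsv")
    results["ratios"], results["ratio_tests"] = ratios, ratio_tests

    # ---- stage 4: core membership (first library) ------------------------
    lead = config.libraries[0]
    rel = libs[lead]["rel"]
    cores = species_core(libs[lead]["counts"], design,
                         min_rep_frac=config.min_rep_frac,
                         fraction=config.core_fraction)
    sets = venn_partition(cores)
    region_table = core_region_table(sets, rel, design,
                                     fraction=config.core_fraction)
    write_frame(region_table, out / f"{lead}_core_regions.tsv")
    results["core_sets"], results["core_regions"] = sets, region_table

    # ---- stage 5: ordination + PERMANOVA + CAP ---------------------------
    sqrt_mat = libs[lead]["sqrt"]
    usable = [s for s in sqrt_mat.columns
              if s not in libs[lead]["rel"].empty_ok]
    planted = [s for s in usable
               if design.table.loc[s, "genotype"] != BULK_GENOTYPE]
    dmat = bray_curtis(sqrt_mat[usable])
    ordn = pcoa(dmat)
    centroids = group_centroids(ordn, design.table["fraction"])
    write_ordination(ordn.coordinates, ordn.eigenvalues,
                     ordn.proportion_explained,
                     out / f"{lead}_pcoa_coordinates.tsv")
    write_frame(centroids, out / f"{lead}_pcoa_centroids.tsv",
                index_label="level")
    keep_terms = _usable_terms(config.formula, design.table.loc[planted])
    dmat_planted = bray_curtis(sqrt_mat[planted])
    perm = permanova(dmat_planted, design, keep_terms,
                     n_perm=config.n_perm, seed=config.seed)
    write_frame(perm.table, out / f"{lead}_permanova.tsv",
                index_label="term")
    cap_res = cap(dmat_planted, design.table["species"],
                  n_perm=min(config.n_perm, 199), seed=config.seed)
    write_frame(cap_res.m_search, out / f"{lead}_cap_m_search.tsv")
    write_frame(cap_res.coordinates, out / f"{lead}_cap_coordinates.tsv",
                index_label="sample_id")
    results.update(ordination=ordn, centroids=centroids,
                   permanova=perm, cap=cap_res)

    # ---- stage 6: taxa screens -------------------------------------------
    taxa_results = {}
    for lib in config.libraries:
        taxa_mat = aggregate_taxa(libs[lib]["rel"], libs[lib]["taxonomy"],
                                  rank=config.taxa_rank)
        write_frame(taxa_mat.values, out / f"{lib}_taxa_{config.taxa_rank}.tsv",
                    index_label="taxon")
        taxa_results[lib] = {"matrix": taxa_mat}
    if "eukaryote18S" in taxa_results:
        taxa18 = aggregate_taxa(libs["eukaryote18S"]["rel"],
                                libs["eukaryote18S"]["taxonomy"],
                                rank="class")
        # phylum-level matrix for Nematoda, class-level for Glomeromycetes
        phyla18 = taxa_results["eukaryote18S"]["matrix"]
        rh = [s for s in phyla18.values.columns if s in set(rhizo)]
        tests = group_tests(phyla18, design, config.effect_factor,
                            alpha=config.alpha, samples=rh)
        write_frame(tests["anova"], out / "eukaryote18S_taxa_anova.tsv",
                    index_label="taxon")
        write_frame(tests["letters"], out / "eukaryote18S_taxa_letters.tsv",
                    index_label="taxon")
        merged = _merge_nematoda_glomeromycetes(phyla18, taxa18)
        r, n_units = taxon_correlation(merged, "Nematoda", "Glomeromycetes",
                                       meta=design, unit="genotype-mean")
        folds = fold_change_screen(phyla18, design, factor="species",
                                   samples=rh)
        write_frame(folds, out / "eukaryote18S_fold_screen.tsv")
        taxa_results["eukaryote18S"].update(tests=tests, folds=folds,
                                            nematoda_glom_r=r,
                                            r_units=n_units)
    results["taxa"] = taxa_results

    # ---- stage 7: manifest + summary -------------------------------------
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "n_perm": config.n_perm,
        "thresholds": {l: config.thresholds[l] for l in config.libraries},
        "formula": config.formula,
        "alpha": config.alpha,
        "files": {p.name: _checksum(p) for p in sorted(out.glob("*.tsv"))},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    summary = _summarize(results, config)
    (out / "summary.txt").write_text(summary)
    log.info("pipeline done: %s", out)
    return results


def _merge_nematoda_glomeromycetes(phyla, classes):
    """Taxa table carrying Nematoda (phylum) and Glomeromycetes (class).

    Built only for the correlation screen; not a valid 100%-sum matrix,
    so it bypasses TaxaMatrix validation via a thin shim.
    """
    from .taxa import TaxaMatrix
    rows = {}
    if "Nematoda" in phyla.values.index:
        rows["Nematoda"] = phyla.values.loc["Nematoda"]
    if "Glomeromycetes" in classes.values.index:
        rows["Glomeromycetes"] = classes.values.loc["Glomeromycetes"]
    merged = object.__new__(TaxaMatrix)
    merged.values = pd.DataFrame(rows).T
    merged.rank = "mixed"
    return merged


def _summarize(results: dict, config: PipelineConfig) -> str:
    lines = [f"rhizopipe {__version__} run summary",
             f"seed={config.seed} n_perm={config.n_perm} "
             f"alpha={config.alpha}", ""]
    design = results["design"]
    lines.append(f"samples: {len(design.sample_ids)} "
                 f"({len(design.planted())} planted)")
    ratios = results["ratios"]
    bulk = design.samples_where(fraction="bulk")
    if bulk:
        lines.append("bulk-soil eukaryote contribution: "
                     f"{ratios.loc[bulk, 'euk_pct'].mean():.2f}%")
    rhizo = design.samples_where(fraction="rhizosphere")
    if rhizo:
        lines.append("rhizosphere eukaryote contribution: "
                     f"{ratios.loc[[s for s in rhizo if s in ratios.index], 'euk_pct'].mean():.2f}%")
    perm = results["permanova"].table
    terms = perm.drop(index=[i for i in ("Residual", "Total")
                             if i in perm.index])
    strongest = terms["pseudo_F"].idxmax()
    lines.append(f"strongest PERMANOVA factor: {strongest} "
                 f"(pseudo-F={terms.loc[strongest, 'pseudo_F']:.2f}, "
                 f"p={terms.loc[strongest, 'p']:.4g})")
    regions = results["core_regions"]
    shared = regions[regions["n_species"] == regions["n_species"].max()]
    if len(shared):
        row = shared.iloc[0]
        lines.append(f"shared core: {int(row['n_otus'])} OTUs, "
                     f"{row['share_pct']:.1f}% of community abundance")
    taxa18 = results["taxa"].get("eukaryote18S", {})
    if "nematoda_glom_r" in taxa18:
        lines.append("Nematoda-Glomeromycetes Pearson r over genotype "
                     f"means: {taxa18['nematoda_glom_r']:.2f}")
    return "\n".join(lines) + "\n"
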