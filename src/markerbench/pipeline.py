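"""End-to-end drivers chaining the stages into the two benchmark experiments.

``run_classification_benchmark`` runs, per marker region and classifier:
extract -> inject errors -> classify each genome by its best copy ->
per-genus metrics + species confusion matrix.

``run_community_experiment`` takes the k-mer confusion matrices and runs
the community simulation sweep (Pearson correlation by library size),
Aitchison distance / PCoA / ANOSIM of true vs predicted compositions, and
the two-group differential-abundance study with per-region agreement
scoring.

Per-stage seeds are derived from one master seed through a fixed
``SeedSequence(master, spawn_key=(stage, substage))`` scheme, so stages
are independently reproducible and the whole run is byte-deterministic.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import classify, commsim, compost, diffab, errors, evaluate, extract
from . import synthgen

__all__ = ["RunConfig", "BenchmarkResult", "CommunityResult",
           "run_classification_benchmark", "run_community_experiment",
           "run_full", "stage_rng"]

REGIONS = extract.REGIONS
_STAGES = ("taxonomy", "errors", "classify", "community", "ordination",
           "study")


def stage_rng(master_seed: int, stage: str,
              substage: int = 0) -> np.random.Generator:
    """Deterministic per-stage RNG derived from the master seed."""
    key = (_STAGES.index(stage), substage)
    return np.random.default_rng(
        np.random.SeedSequence(master_seed, spawn_key=key))


def stage_seed(master_seed: int, stage: str, substage: int = 0) -> int:
    """A plain integer seed (< 2^31) for configs that carry seeds."""
    key = (_STAGES.index(stage), substage)
    state = np.random.SeedSequence(master_seed, spawn_key=key)
    return int(state.generate_state(1)[0] % (2 ** 31))


@dataclass(frozen=True)
class RunConfig:
    """Configuration for a full benchmark run.

    The default taxonomy is desk-scale — 3 genera x 3 species x 2 genomes
    with 1-2 operon copies — sized so that the alignment classifier over
    all five regions completes in about a minute on one CPU; k-mer-only
    runs support much larger collections.
    """

    master_seed: int = 0
    taxonomy: synthgen.TaxonomyConfig = field(
        default_factory=lambda: synthgen.TaxonomyConfig(
            n_genera=3, species_per_genus=3, genomes_per_species=2,
            copies_per_genome=(1, 2)))
    template: synthgen.OperonTemplate = field(
        default_factory=synthgen.OperonTemplate)
    divergence: synthgen.DivergenceModel = field(
        default_factory=synthgen.DivergenceModel)
    regions: tuple[str, ...] = REGIONS
    methods: tuple[str, ...] = ("kmer", "align")
    kmer_k: int = 31
    sweep: commsim.LibrarySizeSweep = field(
        default_factory=commsim.LibrarySizeSweep)
    study: synthgen.StudyDesignConfig = field(
        default_factory=synthgen.StudyDesignConfig)
    study_library_size: int = 100000
    zero_error: bool = False  # skip error injection (control condition)

    def __post_init__(self) -> None:
        unknown = set(self.regions) - set(REGIONS)
        if unknown:
            raise ValueError(f"unknown regions: {sorted(unknown)}")
        unknown = set(self.methods) - {"kmer", "align"}
        if unknown:
            raise ValueError(f"unknown methods: {sorted(unknown)}")

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        raw = json.loads(Path(path).read_text())
        kw: dict = {}
        if "master_seed" in raw:
            kw["master_seed"] = int(raw["master_seed"])
        for name, typ in (("taxonomy", synthgen.TaxonomyConfig),
                          ("template", synthgen.OperonTemplate),
                          ("divergence", synthgen.DivergenceModel),
                          ("sweep", commsim.LibrarySizeSweep),
                          ("study", synthgen.StudyDesignConfig)):
            if name in raw:
                sub = dict(raw[name])
                for k, v in sub.items():
                    if isinstance(v, list):
                        sub[k] = tuple(v)
                kw[name] = typ(**sub)
        for name in ("regions", "methods"):
            if name in raw:
                kw[name] = tuple(raw[name])
        for name in ("kmer_k", "study_library_size", "zero_error"):
            if name in raw:
                kw[name] = raw[name]
        return cls(**kw)


@dataclass
class BenchmarkResult:
    metrics: pd.DataFrame  # genus x region x method rows
    confusions: dict[tuple[str, str], evaluate.ConfusionMatrix]
    results: dict[tuple[str, str], list[classify.ClassificationResult]]
    extraction_logs: dict[str, extract.ExtractionLog]

    def accuracy_by_genus(self, region: str, method: str) -> dict[str, float]:
        sub = self.metrics[(self.metrics.region == region)
                           & (self.metrics.method == method)]
        return dict(zip(sub.genus, sub.accuracy))


def run_classification_benchmark(
    config: RunConfig,
    outdir: str | Path | None = None,
) -> BenchmarkResult:
    """Run the per-genus species-classification benchmark."""
    taxonomy = dataclasses.replace(
        config.taxonomy, seed=stage_seed(config.master_seed, "taxonomy"))
    genomes = synthgen.generate_reference_set(
        taxonomy, config.template, config.divergence)

    metrics_rows: list[evaluate.GenusMetrics] = []
    confusions: dict[tuple[str, str], evaluate.ConfusionMatrix] = {}
    all_results: dict[tuple[str, str], list] = {}
    logs: dict[str, extract.ExtractionLog] = {}

    for r_idx, region in enumerate(config.regions):
        refs, log = extract.extract_regions(genomes, region)
        logs[region] = log
        profile = errors.builtin_profile(region)
        rng_err = stage_rng(config.master_seed, "errors", r_idx)
        queries: list[extract.MarkerRecord] = []
        for rec in refs:
            if config.zero_error:
                queries.append(rec)
            else:
                mutated, _ = errors.inject_errors(rec.sequence, profile,
                                                  rng_err)
                queries.append(dataclasses.replace(rec, sequence=mutated))

        refs_by_genus: dict[str, list[extract.MarkerRecord]] = {}
        for rec in refs:
            refs_by_genus.setdefault(rec.genus, []).append(rec)
        queries_by_genome: dict[str, list[extract.MarkerRecord]] = {}
        for rec in queries:
            queries_by_genome.setdefault(rec.genome_id, []).append(rec)
        genus_of_genome = {g.genome_id: g.genus for g in genomes}
        species_of_genome = {g.genome_id: g.species for g in genomes}

        for m_idx, method in enumerate(config.methods):
            rng_cls = stage_rng(config.master_seed, "classify",
                                r_idx * 10 + m_idx)
            region_results: list[classify.ClassificationResult] = []
            per_genus: dict[str, list] = {}
            for genus in sorted(refs_by_genus):
                genus_refs = refs_by_genus[genus]
                index = (classify.build_index(genus_refs, config.kmer_k)
                         if method == "kmer" else None)
                genome_ids = sorted({r.genome_id for r in genus_refs})
                for genome_id in genome_ids:
                    copies = queries_by_genome.get(genome_id, [])
                    if not copies:
                        continue
                    copy_results = []
                    for q in copies:
                        if method == "kmer":
                            res = classify.kmer_classify(q, index, rng_cls)
                        else:
                            res = classify.align_classify(q, genus_refs,
                                                          rng_cls)
                        copy_results.append(res)
                    genome_res = classify.classify_genome(
                        copy_results, rng_cls, genome_id=genome_id)
                    region_results.append(genome_res)
                    per_genus.setdefault(genus, []).append(genome_res)
            all_results[(region, method)] = region_results
            for genus in sorted(per_genus):
                metrics_rows.append(evaluate.genus_metrics(
                    per_genus[genus], genus=genus, region=region))
            species = sorted({species_of_genome[g.genome_id]
                              for g in genomes
                              if g.genome_id in queries_by_genome})
            confusions[(region, method)] = evaluate.estimate_confusion(
                region_results, species=species, region=region,
                method=method)

    metrics = evaluate.metrics_to_frame(metrics_rows)
    result = BenchmarkResult(metrics, confusions, all_results, logs)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        metrics.to_csv(outdir / "genus_metrics.tsv", sep="\t", index=False)
        for (region, method), cm in confusions.items():
            cm.to_tsv(outdir / f"confusion_{region}_{method}.tsv")
        log_rows = [(region, lg.n_input, lg.n_kept, lg.n_length_filtered,
                     lg.n_no_amplicon) for region, lg in logs.items()]
        pd.DataFrame(log_rows, columns=["region", "n_input", "n_kept",
                                        "n_length_filtered", "n_no_amplicon"]
                     ).to_csv(outdir / "extraction_log.tsv", sep="\t",
                              index=False)
    return result


@dataclass
class CommunityResult:
    correlation_table: pd.DataFrame   # region x library size, mean Pearson r
    sweep_tables: dict[str, pd.DataFrame]
    distance_matrix: compost.DistanceMatrix
    pcoa_coordinates: pd.DataFrame
    anosim_reports: dict[str, dict]
    study_reference: pd.DataFrame
    study_agreements: dict[str, diffab.AgreementReport]
    study_results: dict[str, pd.DataFrame]
    coefficient_table: pd.DataFrame


def _study_confusion(species: Sequence[str], diagonal: float,
                     rng: np.random.Generator,
                     region: str) -> evaluate.ConfusionMatrix:
    return commsim.random_confusion(species, diagonal, rng,
                                    region=region, method="kmer")


def run_community_experiment(
    config: RunConfig,
    confusions: Mapping[str, evaluate.ConfusionMatrix],
    outdir: str | Path | None = None,
    anosim_permutations: int = 999,
) -> CommunityResult:
    """Community simulation + compositional evaluation + study diffab.

    ``confusions`` maps region -> species confusion matrix (typically the
    k-mer matrices from the benchmark).
    """
    regions = [r for r in config.regions if r in confusions]
    if not regions:
        raise ValueError("no confusion matrix for any requested region")

    # ---- Pearson correlation sweep (fresh Dirichlet truth per cell)
    sweep_tables: dict[str, pd.DataFrame] = {}
    corr_rows = []
    for r_idx, region in enumerate(regions):
        sweep = dataclasses.replace(
            config.sweep,
            seed=stage_seed(config.master_seed, "community", r_idx))
        table = commsim.simulate_sweep(confusions[region], sweep)
        sweep_tables[region] = table
        for size, grp in table.groupby("size"):
            rs = [compost.pearson(g.true_proportion.to_numpy(),
                                  g.predicted_proportion.to_numpy())
                  for _, g in grp.groupby("replicate")]
            corr_rows.append((region, size, float(np.mean(rs)),
                              float(np.std(rs, ddof=1))))
    correlation_table = pd.DataFrame(
        corr_rows, columns=["region", "size", "mean_pearson", "sd_pearson"])

    # ---- Aitchison distance / PCoA / ANOSIM at the study library size.
    # Six shared true profiles; each region predicts each of them once.
    n_reps = config.sweep.n_replicates
    rng_ord = stage_rng(config.master_seed, "ordination")
    species0 = confusions[regions[0]].species
    true_profiles = [synthgen.generate_true_profile(species0, seed=rng_ord)
                     for _ in range(n_reps)]
    profiles = [p.proportions for p in true_profiles]
    labels = [f"actual_rep{i + 1}" for i in range(n_reps)]
    group_of = {lab: "actual" for lab in labels}
    for region in regions:
        for i, true in enumerate(true_profiles):
            counts = commsim.allocate_reads(true, config.study_library_size)
            pred = commsim.assign_reads(counts, confusions[region], rng_ord,
                                        true.species)
            profiles.append(pred / pred.sum())
            lab = f"{region}_rep{i + 1}"
            labels.append(lab)
            group_of[lab] = region
    dm = compost.aitchison_matrix(profiles, labels)
    coords, _eig = compost.pcoa(dm)
    anosim_reports = {}
    for r_idx, region in enumerate(regions):
        keep = [i for i, lab in enumerate(labels)
                if group_of[lab] in ("actual", region)]
        sub = compost.DistanceMatrix(
            [labels[i] for i in keep], dm.matrix[np.ix_(keep, keep)])
        R, p = compost.anosim(
            sub, [group_of[sub.labels[i]] for i in range(len(keep))],
            n_permutations=anosim_permutations,
            seed=stage_rng(config.master_seed, "ordination", 100 + r_idx))
        anosim_reports[region] = {"R": R, "p": p,
                                  "n_permutations": anosim_permutations}

    # ---- Two-group study with per-region prediction and diffab agreement.
    study = dataclasses.replace(
        config.study, seed=stage_seed(config.master_seed, "study"))
    table, truth = synthgen.generate_study_profiles(study)
    group_labels = ["control" if c.startswith("control") else "case"
                    for c in table.columns]
    reference = diffab.fit_group_models(table, group_labels)
    rng_study = stage_rng(config.master_seed, "study", 1)
    study_results: dict[str, pd.DataFrame] = {}
    agreements: dict[str, diffab.AgreementReport] = {}
    for region in regions:
        diag = float(np.mean(np.diag(confusions[region].matrix)))
        cm = _study_confusion(list(table.index), diag, rng_study, region)
        pred_cols = []
        for col in table.columns:
            prof = synthgen.CommunityProfile(list(table.index),
                                             table[col].to_numpy())
            counts = commsim.allocate_reads(prof, config.study_library_size)
            pred = commsim.assign_reads(counts, cm, rng_study,
                                        list(table.index))
            pred_cols.append(pred / pred.sum())
        pred_table = pd.DataFrame(np.column_stack(pred_cols),
                                  index=table.index, columns=table.columns)
        res = diffab.fit_group_models(pred_table, group_labels)
        study_results[region] = res
        agreements[region] = diffab.agreement(reference, res)
    coef_table = diffab.coefficient_table(reference, study_results)

    result = CommunityResult(correlation_table, sweep_tables, dm, coords,
                             anosim_reports, reference, agreements,
                             study_results, coef_table)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        correlation_table.to_csv(outdir / "correlation_by_size.tsv",
                                 sep="\t", index=False)
        dm.to_tsv(outdir / "aitchison_distances.tsv")
        coords.to_csv(outdir / "pcoa_coordinates.tsv", sep="\t")
        (outdir / "anosim.json").write_text(
            json.dumps(anosim_reports, indent=2))
        reference.to_csv(outdir / "diffab_reference.tsv", sep="\t",
                         index=False)
        for region, res in study_results.items():
            res.to_csv(outdir / f"diffab_{region}.tsv", sep="\t",
                       index=False)
        (outdir / "diffab_agreement.json").write_text(json.dumps(
            {r: a.to_dict() for r, a in agreements.items()}, indent=2))
        coef_table.to_csv(outdir / "coefficient_table.tsv", sep="\t",
                          index=False)
    return result


def run_full(config: RunConfig, outdir: str | Path | None = None,
             anosim_permutations: int = 999
             ) -> tuple[BenchmarkResult, CommunityResult]:
    """Benchmark then community experiment, k-mer confusions feeding the
    community stage (the alignment classifier only contributes metrics)."""
    bench_dir = Path(outdir) / "benchmark" if outdir else None
    comm_dir = Path(outdir) / "community" if outdir else None
    bench = run_classification_benchmark(config, bench_dir)
    method = "kmer" if "kmer" in config.methods else config.methods[0]
    confusions = {region: bench.confusions[(region, method)]
                  for region in config.regions
                  if (region, method) in bench.confusions}
    comm = run_community_experiment(config, confusions, comm_dir,
                                    anosim_permutations)
    return bench, comm
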