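"""End-to-end barcoding pipeline.

Orchestrates the full study design: QC -> full/reduced datasets -> distance
matrices under several substitution models -> trees -> five delimitation
analyses on both datasets -> concordance report against morphospecies, with
per-stage error isolation and deterministic seeding.

The configuration is a YAML/dict structure validated up front by
:func:`validate_config`; :func:`run_pipeline` executes it and writes all
artifacts (reduced FASTA, haplotype map, matrices, partitions, trees,
concordance TSV and a consolidated JSON report) into the output directory.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import __version__
from .alignment import (
    Alignment,
    collapse_haplotypes,
    check_coding,
    read_alignment,
    site_statistics,
    write_fasta,
    write_haplotype_map_tsv,
)
from .concordance import (
    ConcordanceRecord,
    concordance_record,
    compare_partitions,
    expand_reduced_partition,
    gap_reassignment_report,
    write_concordance_tsv,
)
from .dist_delim import AbgdConfig, abgd_partition, threshold_linkage
from .distances import DistanceModelConfig, distance_matrix, group_summary, write_matrix_tsv
from .errors import ConfigurationError
from .partition import Partition, read_partition_tsv, write_partition_tsv
from .simulate import SimulationParams, SamplesPerSpecies, generate_dataset
from .tree_delim import gmyc_fit, mptp_ml, ptp_ml
from .trees import nj_tree, read_newick, upgma_tree, write_newick

DELIMITERS = ("ABGD", "RESL-SL", "GMYC", "PTP", "mPTP")


@dataclass(frozen=True)
class PipelineConfig:
    out_dir: Path
    alignment_path: Path | None = None
    simulation: SimulationParams | None = None
    morphospecies_path: Path | None = None
    outgroup: tuple[str, ...] = ()
    models: tuple[str, ...] = ("p", "K2P", "TrN+G")
    alpha: float | None = None
    abgd: AbgdConfig = field(default_factory=AbgdConfig)
    abgd_report_prior: float = 0.02
    linkage_threshold: float = 0.02
    tree_paths: dict[str, Path] = field(default_factory=dict)
    delimiters: tuple[str, ...] = DELIMITERS
    seed: int = 0


@dataclass
class StageError:
    method: str
    dataset: str
    message: str


@dataclass
class PipelineReport:
    n_full: int
    n_reduced: int
    site_stats: dict[str, int]
    qc_flagged: list[str]
    distance_summaries: dict[str, dict]
    records: list[ConcordanceRecord]
    congruent: dict[str, bool]
    clean_gap: dict[str, bool]
    otu_range: tuple[int, int] | None
    errors: list[StageError]
    provenance: dict[str, Any]

    def to_dict(self) -> dict:
        d = asdict(self)
        d["records"] = [asdict(r) for r in self.records]
        return d


def validate_config(source: str | Path | dict) -> PipelineConfig:
    """Validate a YAML file or dict into a PipelineConfig.

    All problems are aggregated into a single error so a bad config fails
    once, fully, before any compute.
    """
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            raw = yaml.safe_load(fh)
    else:
        raw = dict(source)
    if not isinstance(raw, dict):
        raise ConfigurationError("config must be a mapping")

    problems: list[str] = []

    out_dir = raw.get("out")
    if not out_dir:
        problems.append("'out' (output directory) is required")

    alignment_path = raw.get("alignment")
    sim_cfg = raw.get("simulation")
    simulation = None
    if alignment_path and sim_cfg:
        problems.append("give either 'alignment' or 'simulation', not both")
    elif alignment_path:
        if not Path(alignment_path).exists():
            problems.append(f"alignment file not found: {alignment_path}")
    elif sim_cfg is not None:
        try:
            sim_cfg = dict(sim_cfg)
            sps = sim_cfg.pop("samples_per_species", None)
            if isinstance(sps, dict):
                sim_cfg["samples_per_species"] = SamplesPerSpecies(**sps)
            elif isinstance(sps, int):
                sim_cfg["samples_per_species"] = SamplesPerSpecies(fixed=sps)
            simulation = SimulationParams(**sim_cfg)
        except (TypeError, ConfigurationError) as exc:
            problems.append(f"simulation: {exc}")
    else:
        problems.append("one of 'alignment' or 'simulation' is required")

    morph = raw.get("morphospecies")
    if morph and not Path(morph).exists():
        problems.append(f"morphospecies file not found: {morph}")
    if alignment_path and not morph:
        problems.append("'morphospecies' TSV is required with a real alignment")

    models = tuple(raw.get("models", ("p", "K2P", "TrN+G")))
    for m in models:
        try:
            DistanceModelConfig(model=m)
        except ConfigurationError as exc:
            problems.append(str(exc))

    abgd = AbgdConfig()
    try:
        abgd_raw = raw.get("abgd", {})
        abgd = AbgdConfig(**abgd_raw) if abgd_raw else AbgdConfig()
    except (TypeError, ConfigurationError) as exc:
        problems.append(f"abgd: {exc}")

    delimiters = tuple(raw.get("delimiters", DELIMITERS))
    unknown = [d for d in delimiters if d not in DELIMITERS]
    if unknown:
        problems.append(f"unknown delimiters {unknown}; choose from {DELIMITERS}")
    if not delimiters:
        problems.append("at least one delimiter must be enabled")

    tree_paths: dict[str, Path] = {}
    for key, path in (raw.get("trees") or {}).items():
        if key not in ("full_ultrametric", "reduced_ultrametric", "full_ml", "reduced_ml"):
            problems.append(f"unknown tree slot {key!r}")
        elif not Path(path).exists():
            problems.append(f"tree file not found: {path}")
        else:
            tree_paths[key] = Path(path)

    linkage_threshold = float(raw.get("linkage_threshold", 0.02))
    if linkage_threshold < 0:
        problems.append("linkage_threshold must be >= 0")
    abgd_report_prior = float(raw.get("abgd_report_prior", 0.02))

    if problems:
        raise ConfigurationError(
            "invalid pipeline config:\n  - " + "\n  - ".join(problems)
        )

    return PipelineConfig(
        out_dir=Path(out_dir),
        alignment_path=Path(alignment_path) if alignment_path else None,
        simulation=simulation,
        morphospecies_path=Path(morph) if morph else None,
        outgroup=tuple(raw.get("outgroup", ())),
        models=models,
        alpha=raw.get("alpha"),
        abgd=abgd,
        abgd_report_prior=abgd_report_prior,
        linkage_threshold=linkage_threshold,
        tree_paths=tree_paths,
        delimiters=delimiters,
        seed=int(raw.get("seed", 0)),
    )


def _model_config(name: str, cfg: PipelineConfig) -> DistanceModelConfig:
    if name.lower() == "trn+g":
        return DistanceModelConfig(model=name, alpha=cfg.alpha if cfg.alpha else 1.0)
    return DistanceModelConfig(model=name)


def run_pipeline(cfg: PipelineConfig) -> PipelineReport:
    out = cfg.out_dir
    out.mkdir(parents=True, exist_ok=True)
    errors: list[StageError] = []

    # ---- inputs --------------------------------------------------------
    if cfg.simulation is not None:
        ds = generate_dataset(cfg.simulation, out_dir=out / "simulated")
        full: Alignment = ds.alignment
        morph: Partition = ds.truth
    else:
        full = read_alignment(cfg.alignment_path, outgroup_labels=cfg.outgroup)
        morph = read_partition_tsv(cfg.morphospecies_path)

    ingroup = full.drop_outgroup() if full.outgroup_ids else full
    morph_in = {sid: morph[sid] for sid in ingroup.ids if sid in morph}
    missing = set(ingroup.ids) - set(morph_in)
    if missing:
        raise ConfigurationError(
            f"morphospecies assignment missing for {sorted(missing)[:5]}"
        )

    # ---- QC and datasets ----------------------------------------------
    qc = check_coding(full)
    stats = site_statistics(full, exclude_outgroup=True)
    reduced, hmap = collapse_haplotypes(ingroup)
    write_fasta(reduced, out / "reduced.fasta")
    write_haplotype_map_tsv(hmap, out / "haplotype_map.tsv")

    # ---- distances -----------------------------------------------------
    matrices_full: dict[str, Any] = {}
    for name in cfg.models:
        m = distance_matrix(ingroup, _model_config(name, cfg))
        matrices_full[name] = m
        write_matrix_tsv(m, out / f"distances_{name.replace('+', '')}.tsv")
    k2p_full = matrices_full.get("K2P") or distance_matrix(ingroup, DistanceModelConfig())
    k2p_reduced = k2p_full.submatrix(list(reduced.ids))

    # ---- trees ---------------------------------------------------------
    def get_tree(slot: str, builder, matrix):
        if slot in cfg.tree_paths:
            return read_newick(cfg.tree_paths[slot])
        return builder(matrix)

    # ---- delimitation on both datasets ---------------------------------
    partitions: dict[tuple[str, str], Partition] = {}  # (method, dataset) -> full-universe partition

    def run_method(method: str, dataset: str, fn) -> None:
        try:
            part = fn()
        except Exception as exc:  # error isolation: log, keep going
            errors.append(StageError(method, dataset, f"{type(exc).__name__}: {exc}"))
            return
        if dataset == "reduced":
            part = expand_reduced_partition(part, hmap)
        partitions[(method, dataset)] = part
        write_partition_tsv(part, out / f"partition_{method}_{dataset}.tsv")

    for dataset, aln, k2p in (("full", ingroup, k2p_full), ("reduced", reduced, k2p_reduced)):
        if "ABGD" in cfg.delimiters:
            def _abgd(k2p=k2p):
                res = abgd_partition(k2p, cfg.abgd)
                return res.at_prior(cfg.abgd_report_prior).partition
            run_method("ABGD", dataset, _abgd)
        if "RESL-SL" in cfg.delimiters:
            run_method(
                "RESL-SL", dataset,
                lambda k2p=k2p: threshold_linkage(k2p, cfg.linkage_threshold),
            )
        if "GMYC" in cfg.delimiters:
            def _gmyc(dataset=dataset, k2p=k2p):
                t = get_tree(f"{dataset}_ultrametric", upgma_tree, k2p)
                return gmyc_fit(t).entities
            run_method("GMYC", dataset, _gmyc)
        if "PTP" in cfg.delimiters:
            def _ptp(dataset=dataset, k2p=k2p):
                t = get_tree(f"{dataset}_ml", nj_tree, k2p)
                return ptp_ml(t, seed=cfg.seed).partition
            run_method("PTP", dataset, _ptp)
        if "mPTP" in cfg.delimiters:
            def _mptp(dataset=dataset, k2p=k2p):
                t = get_tree(f"{dataset}_ml", nj_tree, k2p)
                return mptp_ml(t, seed=cfg.seed).partition
            run_method("mPTP", dataset, _mptp)

    # ---- concordance ----------------------------------------------------
    records = [
        concordance_record(method, dataset, part, morph_in)
        for (method, dataset), part in sorted(partitions.items())
    ]
    congruent = {}
    for method in cfg.delimiters:
        pf = partitions.get((method, "full"))
        pr = partitions.get((method, "reduced"))
        if pf is not None and pr is not None:
            congruent[method] = (
                compare_partitions(pf, pr).adjusted_rand_index == 1.0
            )
    write_concordance_tsv(records, out / "concordance.tsv")

    # ---- barcode-gap reassignment report -------------------------------
    gap_partitions: dict[str, Partition] = {"a_priori": morph_in}
    if ("ABGD", "full") in partitions:
        gap_partitions["ABGD"] = partitions[("ABGD", "full")]
    if ("mPTP", "full") in partitions:
        gap_partitions["mPTP"] = partitions[("mPTP", "full")]
    gap_entries = gap_reassignment_report(matrices_full, gap_partitions)
    clean_gap = {
        f"{e.model}/{e.partition_label}": e.clean_gap for e in gap_entries
    }

    n_delims = [r.n_delimited for r in records]
    report = PipelineReport(
        n_full=ingroup.n_samples,
        n_reduced=reduced.n_samples,
        site_stats=stats.to_dict(),
        qc_flagged=[s.sample_id for s in qc.samples if not s.coding_clean],
        distance_summaries={
            name: (asdict(s.overall) if s.overall else {})
            for name, s in (
                (name, group_summary(m, morph_in)) for name, m in matrices_full.items()
            )
        },
        records=records,
        congruent=congruent,
        clean_gap=clean_gap,
        otu_range=(min(n_delims), max(n_delims)) if n_delims else None,
        errors=errors,
        provenance={
            "seed": cfg.seed,
            "version": __version__,
            "models": list(cfg.models),
            "delimiters": list(cfg.delimiters),
            "abgd": asdict(cfg.abgd) if hasattr(cfg.abgd, "__dict__") else str(cfg.abgd),
        },
    )
    with open(out / "report.json", "w") as fh:
        json.dump(report.to_dict(), fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    return report
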