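"""Pipeline orchestration: simulate -> qc -> mutmap -> lsv -> pheno.

A :class:`RunConfig` holds stage selection, input paths and every stage
parameter (module defaults unless overridden); :func:`run_pipeline` executes
the selected stages in order, checks stage dependencies, and writes a
:class:`~tillmap.io.RunManifest` recording config hash, input checksums,
outputs and wall-clock per stage.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import io as tio
from . import lsv, mutmap, pheno, synthetic, variant_qc
from .config import SimConfig, sim_config_from_dict, _to_plain

logger = logging.getLogger("tillmap")

__version__ = "0.1.0"

ALL_STAGES = ("simulate", "qc", "mutmap", "lsv", "pheno")


@dataclass
class RunConfig:
    """Full pipeline configuration; round-trips losslessly through YAML."""

    out_dir: str = "tillmap_run"
    stages: tuple[str, ...] = ALL_STAGES
    seed: int = 0
    log_level: str = "INFO"
    sim: SimConfig = field(default_factory=SimConfig)
    # qc
    thresholds: variant_qc.FilterThresholds = field(default_factory=variant_qc.FilterThresholds)
    vcf_dir: str | None = None
    gff: str | None = None
    fasta: str | None = None
    # mutmap
    pileups: str | None = None
    phenotypes: str | None = None
    trait: str = "meal_adf"
    mutant_direction: str | None = None
    n_bulk: int = mutmap.DEFAULT_BULK_SIZE
    k: int = mutmap.DEFAULT_WINDOW
    delta_threshold: float = mutmap.DEFAULT_THRESHOLD
    min_loci: int = mutmap.DEFAULT_MIN_LOCI
    min_bulk_depth: int = mutmap.DEFAULT_MIN_BULK_DEPTH
    # lsv
    coverage: str | None = None
    w: int = lsv.DEFAULT_WINDOW
    s: int = lsv.DEFAULT_STEP
    del_thresh: float = lsv.DEL_THRESH
    dup_thresh: float = lsv.DUP_THRESH
    min_windows: int = lsv.MIN_WINDOWS
    reference_sample: str | None = None
    calibrate_sample: str | None = None
    n_permutations: int = 10_000

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        self.sim.seed = self.seed

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(_to_plain(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        if "sim" in data:
            data["sim"] = sim_config_from_dict(data["sim"])
        if "thresholds" in data:
            data["thresholds"] = variant_qc.FilterThresholds(**data["thresholds"])
        if "stages" in data:
            data["stages"] = tuple(data["stages"])
        return cls(**data)

    def config_hash(self) -> str:
        blob = json.dumps(_to_plain(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


class StageDependencyError(RuntimeError):
    pass


def _require(config: RunConfig, stage: str, attr: str, produced: dict) -> Path:
    explicit = getattr(config, attr)
    if explicit:
        p = Path(explicit)
    elif attr in produced:
        p = Path(produced[attr])
    else:
        raise StageDependencyError(
            f"stage {stage!r} requires {attr!r}: pass a path or run the simulate stage"
        )
    if not p.exists():
        raise StageDependencyError(f"stage {stage!r}: missing input file {p}")
    return p


def run_pipeline(config: RunConfig) -> tio.RunManifest:
    """Execute the selected stages in canonical order and write the manifest."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = tio.RunManifest(version=__version__, config_hash=config.config_hash())
    for attr in ("vcf_dir", "gff", "fasta", "pileups", "phenotypes", "coverage"):
        p = getattr(config, attr)
        if p and Path(p).is_file():
            manifest.inputs[p] = tio.file_checksum(p)
    produced: dict[str, str] = {}
    stages = [s for s in ALL_STAGES if s in config.stages]
    for stage in stages:
        with tio.StageTimer(manifest, stage):
            outputs = _STAGE_FUNCS[stage](config, out, produced)
        manifest.outputs[stage] = sorted(str(p) for p in outputs)
    config.to_yaml(out / "run_config.yaml")
    manifest.write(out / "manifest.json")
    return manifest


def _stage_simulate(config: RunConfig, out: Path, produced: dict) -> list:
    sim_dir = out / "sim"
    cohort = synthetic.simulate_cohort(config.sim, sim_dir)
    produced.update(
        vcf_dir=str(sim_dir / "vcf"),
        gff=cohort.paths["gff"],
        fasta=cohort.paths["fasta"],
        pileups=cohort.paths["pileups"],
        phenotypes=cohort.paths["phenotypes"],
        coverage=cohort.paths["coverage"],
        genotypes=cohort.paths["genotypes"],
    )
    return [v for k, v in cohort.paths.items() if not k.startswith("vcf:")]


def _stage_qc(config: RunConfig, out: Path, produced: dict) -> list:
    vcf_dir = _require(config, "qc", "vcf_dir", produced)
    fasta = _require(config, "qc", "fasta", produced)
    gff = _require(config, "qc", "gff", produced)
    genome = tio.read_genome(fasta, gff)
    records = tio.read_vcf_dir(vcf_dir)
    filtered = variant_qc.apply_variant_filters(records, config.thresholds)
    filtered = variant_qc.remove_shared_variants(
        filtered, limit=config.thresholds.shared_line_limit
    )
    per_line, pop = variant_qc.summarize_mutation_load(
        filtered, genome.total_length, genome=genome
    )
    qc_dir = out / "qc"
    qc_dir.mkdir(exist_ok=True)
    paths = [qc_dir / "per_line_loads.tsv", qc_dir / "population_summary.json",
             qc_dir / "filtered_variants.tsv"]
    per_line.to_csv(paths[0], sep="\t", index=False, float_format="%.4f")
    with open(paths[1], "w") as fh:
        json.dump(pop, fh, indent=2, sort_keys=True)
    filtered.to_csv(paths[2], sep="\t", index=False)
    return paths


def _stage_mutmap(config: RunConfig, out: Path, produced: dict) -> list:
    pileups = tio.read_pileups(_require(config, "mutmap", "pileups", produced))
    phen = tio.read_phenotypes(_require(config, "mutmap", "phenotypes", produced))
    res = mutmap.run_mutmap(
        pileups, phen, config.trait,
        mutant_direction=config.mutant_direction, n_bulk=config.n_bulk,
        k=config.k, threshold=config.delta_threshold,
        min_loci=config.min_loci, min_bulk_depth=config.min_bulk_depth,
    )
    mm_dir = out / "mutmap"
    mm_dir.mkdir(exist_ok=True)
    track_path = mm_dir / "delta_snp_index.tsv"
    bed_path = mm_dir / "candidate_regions.bed"
    res["track"].to_csv(track_path, sep="\t", index=False, float_format="%.6f")
    regions = pd.DataFrame([r.__dict__ for r in res["regions"]])
    if regions.empty:
        bed_path.write_text("")
    else:
        tio.write_bed(regions, bed_path)
    return [track_path, bed_path]


def _stage_lsv(config: RunConfig, out: Path, produced: dict) -> list:
    coverage = tio.read_coverage_table(_require(config, "lsv", "coverage", produced))
    res = lsv.run_lsv(
        coverage, w=config.w, s=config.s,
        del_thresh=config.del_thresh, dup_thresh=config.dup_thresh,
        min_windows=config.min_windows, reference_sample=config.reference_sample,
        calibrate_sample=config.calibrate_sample,
    )
    lsv_dir = out / "lsv"
    lsv_dir.mkdir(exist_ok=True)
    paths = [lsv_dir / "segments.tsv", lsv_dir / "segments.bed",
             lsv_dir / "recurrent_loci.tsv", lsv_dir / "locus_states.tsv"]
    res["segments"].to_csv(paths[0], sep="\t", index=False, float_format="%.4f")
    if res["segments"].empty:
        paths[1].write_text("")
    else:
        tio.write_bed(res["segments"], paths[1], name_col="sample")
    res["loci"].to_csv(paths[2], sep="\t", index=False)
    res["states"].rename_axis("sample").to_csv(paths[3], sep="\t")
    # genotype-phenotype association per recurrent locus, when phenotypes exist
    try:
        phen_path = _require(config, "lsv", "phenotypes", produced)
    except StageDependencyError:
        return paths
    phen = tio.read_phenotypes(phen_path)
    import numpy as np

    rng = np.random.default_rng(config.seed)
    rows = []
    for locus in res["states"].columns:
        stats_ = lsv.genotype_group_association(
            res["states"][locus], phen, config.trait,
            n_permutations=config.n_permutations, rng=rng,
        )
        rows.append(
            dict(locus=locus, statistic=stats_.statistic, p_value=stats_.p_value,
                 **{f"mean_{k}": v for k, v in stats_.group_means.items()},
                 **{f"n_{k}": v for k, v in stats_.group_ns.items()})
        )
    assoc_path = lsv_dir / "association.tsv"
    pd.DataFrame(rows).to_csv(assoc_path, sep="\t", index=False, float_format="%.6g")
    return [*paths, assoc_path]


def _stage_pheno(config: RunConfig, out: Path, produced: dict) -> list:
    phen = tio.read_phenotypes(_require(config, "pheno", "phenotypes", produced))
    traits = [t for t in pheno.TRAITS if t in phen.columns]
    table = pheno.summarize_traits(phen, traits)
    ph_dir = out / "pheno"
    ph_dir.mkdir(exist_ok=True)
    path = ph_dir / "trait_summaries.tsv"
    table.to_csv(path, sep="\t", index=False, float_format="%.4f")
    return [path]


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "qc": _stage_qc,
    "mutmap": _stage_mutmap,
    "lsv": _stage_lsv,
    "pheno": _stage_pheno,
}
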