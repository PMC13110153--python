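"""Configuration objects for the simulation and the pipeline.

All tunable parameters of the synthetic cohort live in :class:`SimConfig`;
pipeline-wide settings (stage selection, paths, thresholds) in
:class:`RunConfig`.  Both round-trip losslessly through YAML so a run can be
reproduced from its config file alone.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import yaml

logger = logging.getLogger("tillmap")

# Pooled EMS substitution spectrum (strand-pooled classes), as fractions.
# The raw percentages sum to 100.01 due to rounding; renormalised here.
_RAW_SPECTRUM = (44.48, 22.02, 12.07, 8.67, 7.63, 5.14)
SPECTRUM_CLASSES = (
    "C/G>T/A",
    "C/G>A/T",
    "A/T>G/C",
    "A/T>T/A",
    "A/T>C/G",
    "C/G>G/C",
)
DEFAULT_SPECTRUM = tuple(p / sum(_RAW_SPECTRUM) for p in _RAW_SPECTRUM)

#: number of mutant lines recovered at each EMS dose in the source study,
#: used only as relative weights when allocating a desk-scale population.
DOSE_LINE_WEIGHTS = {"0.1%": 669, "0.2%": 231, "0.3%": 324, "0.4%": 34}


@dataclass
class SegmentSpec:
    """A structural-variant segment, addressed by gene rank on a chromosome.

    ``start_gene``/``end_gene`` are 0-based inclusive gene indices in the
    chromosome's position-sorted gene list.
    """

    name: str
    chrom: str
    start_gene: int
    end_gene: int
    kind: str  # "deletion" | "duplication"

    def __post_init__(self) -> None:
        if self.kind not in ("deletion", "duplication"):
            raise ValueError(f"segment kind must be deletion/duplication, got {self.kind!r}")
        if self.end_gene < self.start_gene:
            raise ValueError(f"segment {self.name}: end_gene < start_gene")

    @property
    def n_genes(self) -> int:
        return self.end_gene - self.start_gene + 1


@dataclass
class HnrtSpec:
    """Homoeologous non-reciprocal translocation layout.

    Two deletion segments on the A-subgenome chromosome share one
    segregation indicator (they co-segregate exactly); the duplication on
    the homoeologous C chromosome segregates independently.
    """

    deletions: list[SegmentSpec] = field(
        default_factory=lambda: [
            SegmentSpec("D1", "A1", 30, 89, "deletion"),
            SegmentSpec("D2", "A1", 140, 199, "deletion"),
        ]
    )
    duplication: SegmentSpec = field(
        default_factory=lambda: SegmentSpec("P1", "C1", 80, 139, "duplication")
    )
    homoeologous_pair: tuple[str, str] = ("A1", "C1")

    @property
    def segments(self) -> list[SegmentSpec]:
        return [*self.deletions, self.duplication]


@dataclass
class GenomeSpec:
    """Toy genome layout: chromosome lengths and gene packing."""

    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"A1": 500_000, "A2": 500_000, "C1": 500_000, "C2": 500_000}
    )
    genes_per_chrom: dict[str, int] = field(
        default_factory=lambda: {"A1": 220, "A2": 220, "C1": 220, "C2": 220}
    )
    homoeologous_pairs: list[tuple[str, str]] = field(
        default_factory=lambda: [("A1", "C1"), ("A2", "C2")]
    )
    min_cds_codons: int = 60
    max_cds_codons: int = 200
    max_exons: int = 3
    min_intron: int = 60
    max_intron: int = 240

    @property
    def total_length(self) -> int:
        return sum(self.chrom_lengths.values())


@dataclass
class TraitModel:
    """Genetic model for one trait in the F2 cohort.

    ``del_effect_hom`` is the shift of the homozygous-deletion class relative
    to wild type (additive in deletion copies unless ``dominance`` moves the
    heterozygote); ``dup_modulation`` adds
    ``dup_modulation * (d_copies/2) * (p_copies/2)`` so the duplication only
    modulates carriers of the deletion.  Variance components are solved from
    ``h2_target`` on an entry-mean basis.
    """

    baseline: float
    del_effect_hom: float = 0.0
    dominance: float = 0.0  # extra shift of the hemizygote beyond additivity
    dup_modulation: float = 0.0
    v_polygenic: float = 0.1
    h2_target: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 < self.h2_target < 1.0:
            raise ValueError(f"h2_target must lie in (0,1), got {self.h2_target}")


@dataclass
class TraitSpec:
    """Multi-environment phenotype structure for the F2 cohort."""

    traits: dict[str, TraitModel] = field(
        default_factory=lambda: {
            "seed_oil": TraitModel(baseline=45.8, v_polygenic=0.34, h2_target=0.16),
            "seed_protein": TraitModel(baseline=27.1, v_polygenic=0.82, h2_target=0.31),
            "meal_protein": TraitModel(
                baseline=50.0, del_effect_hom=0.9, v_polygenic=0.40, h2_target=0.35
            ),
            "meal_adf": TraitModel(
                baseline=18.1,
                del_effect_hom=-1.8,
                dup_modulation=-0.4,
                v_polygenic=0.02,
                h2_target=0.85,
            ),
        }
    )
    n_locations: int = 2
    n_reps: int = 2
    location_effects: tuple[float, ...] = (-0.4, 0.4)
    # share of the non-genetic entry-mean variance assigned to G×L (rest to residual)
    gl_noise_share: float = 0.3

    def __post_init__(self) -> None:
        if len(self.location_effects) != self.n_locations:
            raise ValueError("location_effects must have n_locations entries")


@dataclass
class SimConfig:
    """Study conditions for the synthetic cohort.

    Defaults are the source study's conditions where stated (mutation density
    155 SNPs/Mb, indel:SNP ratio 60:155, ~8x shotgun depth, 184 F2
    individuals, 2 locations x 2 reps, 1:2:1 segregation) on a desk-scale toy
    genome.
    """

    seed: int = 0
    n_dh_lines: int = 60
    ems_dose_labels: dict[str, float] = field(default_factory=dict)  # label -> mean SNPs/Mb
    spectrum_probs: tuple[float, ...] = DEFAULT_SPECTRUM
    snp_density_per_mb: float = 155.0
    indel_snp_ratio: float = 60.0 / 155.0
    indel_dose_slope: float = 1.0  # scales indel load with dose relative to SNP load
    n_f2: int = 184
    mean_depth: float = 8.0
    read_length: int = 150
    coverage_dispersion: float = 10.0  # negative-binomial size parameter
    vcf_depth_mean: float = 30.0
    vcf_qual_mean: float = 60.0
    vcf_qual_sd: float = 18.0  # ~5% of true variants fall below QUAL 30
    n_shared_artifacts: int = 30
    n_loci_per_chrom: int = 150
    include_parents: bool = True
    genome_spec: GenomeSpec = field(default_factory=GenomeSpec)
    hnrt_spec: HnrtSpec = field(default_factory=HnrtSpec)
    trait_spec: TraitSpec = field(default_factory=TraitSpec)

    def __post_init__(self) -> None:
        if abs(sum(self.spectrum_probs) - 1.0) > 1e-9:
            raise ValueError("spectrum_probs must sum to 1")
        if len(self.spectrum_probs) != 6:
            raise ValueError("spectrum_probs must have 6 entries")
        if not self.ems_dose_labels:
            self.ems_dose_labels = self._default_dose_densities()
        segments = self.hnrt_spec.segments if self.hnrt_spec is not None else []
        for seg in segments:
            if seg.chrom not in self.genome_spec.chrom_lengths:
                raise ValueError(f"segment {seg.name} on undeclared chromosome {seg.chrom}")
            if seg.end_gene >= self.genome_spec.genes_per_chrom[seg.chrom]:
                raise ValueError(f"segment {seg.name} exceeds gene count on {seg.chrom}")

    def _default_dose_densities(self) -> dict[str, float]:
        # per-dose mean load scales linearly with dose; weighted (by the
        # study's per-dose line counts) mean equals snp_density_per_mb.
        doses = {lab: float(lab.rstrip("%")) for lab in DOSE_LINE_WEIGHTS}
        total_w = sum(DOSE_LINE_WEIGHTS.values())
        mean_dose = sum(DOSE_LINE_WEIGHTS[l] * d for l, d in doses.items()) / total_w
        return {l: self.snp_density_per_mb * d / mean_dose for l, d in doses.items()}

    def lines_per_dose(self) -> dict[str, int]:
        """Allocate n_dh_lines across doses in the study's proportions
        (largest-remainder apportionment)."""
        total_w = sum(DOSE_LINE_WEIGHTS.values())
        labs = sorted(DOSE_LINE_WEIGHTS)
        exact = {l: self.n_dh_lines * DOSE_LINE_WEIGHTS[l] / total_w for l in labs}
        alloc = {l: int(exact[l]) for l in labs}
        short = self.n_dh_lines - sum(alloc.values())
        for l in sorted(labs, key=lambda l: exact[l] - alloc[l], reverse=True)[:short]:
            alloc[l] += 1
        return alloc


def _to_plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_plain(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, tuple):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, list):
        return [_to_plain(v) for v in obj]
    return obj


def sim_config_to_yaml(config: SimConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(_to_plain(config), fh, sort_keys=False)


def sim_config_from_yaml(path) -> SimConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return sim_config_from_dict(data)


def sim_config_from_dict(data: dict) -> SimConfig:
    data = dict(data)
    if "genome_spec" in data:
        gs = dict(data["genome_spec"])
        if "homoeologous_pairs" in gs:
            gs["homoeologous_pairs"] = [tuple(p) for p in gs["homoeologous_pairs"]]
        data["genome_spec"] = GenomeSpec(**gs)
    if "hnrt_spec" in data:
        hs = dict(data["hnrt_spec"])
        hs["deletions"] = [SegmentSpec(**d) for d in hs.get("deletions", [])]
        if "duplication" in hs:
            hs["duplication"] = SegmentSpec(**hs["duplication"])
        if "homoeologous_pair" in hs:
            hs["homoeologous_pair"] = tuple(hs["homoeologous_pair"])
        data["hnrt_spec"] = HnrtSpec(**hs)
    if "trait_spec" in data:
        ts = dict(data["trait_spec"])
        ts["traits"] = {k: TraitModel(**v) for k, v in ts.get("traits", {}).items()}
        if "location_effects" in ts:
            ts["location_effects"] = tuple(ts["location_effects"])
        data["trait_spec"] = TraitSpec(**ts)
    if "spectrum_probs" in data:
        data["spectrum_probs"] = tuple(data["spectrum_probs"])
    return SimConfig(**data)
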