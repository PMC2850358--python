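"""Simulation and pipeline run configuration.

The defaults encode the study conditions the pipeline is designed for, at
desk scale: 54 non-reference accessions plus the Col-0 reference, four
admixed source populations, 25-mer probes tiled at 35 bp, a planted sweep
haplotype, and nine quantitative traits generated from the association
model (trait = marker + environment + population structure + error).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

from .types import ConfigError

TRAIT_NAMES = (
    "fresh_weight",
    "starch",
    "sucrose",
    "total_protein",
    "total_amino_acids",
    "threonic_acid",
    "beta_alanine",
    "erythritol",
    "myo_inositol",
)

#: rough continental population centres (lat, lon): Iberia, Central/Western
#: Europe, Eastern Europe, Central Asia
POPULATION_CENTRES = ((40.4, -3.7), (48.8, 8.2), (52.4, 27.6), (41.3, 69.2))


@dataclass(frozen=True)
class SegmentSpec:
    """A planted deletion or duplication: accessions x probe interval."""

    accessions: tuple[int, ...]  # 0-based non-reference accession indices
    chrom: int
    start_probe: int
    n_probes: int

    def __post_init__(self) -> None:
        if self.n_probes < 1:
            raise ConfigError("planted segment must span at least one probe")
        if self.start_probe < 0:
            raise ConfigError("segment start probe must be non-negative")


@dataclass(frozen=True)
class SweepSpec:
    """A planted selective sweep: carriers copy one founder haplotype."""

    chrom: int
    start_probe: int
    n_probes: int
    carrier_fraction: float = 0.45
    marker_rate: float = 0.5       # extra swept-haplotype SNPs per block probe
    background_carry: float = 0.2  # homoplasy rate of marker SNPs elsewhere
    # probes on each side over which carriers still share the swept
    # haplotype without marker SNPs (the sweep's soft shoulders)
    shoulder: int = 80
    # sampling weight multiplier for accessions from the sweep's source
    # populations (the first two): swept alleles spread locally, so
    # carriers cluster geographically
    population_bias: float = 6.0

    def __post_init__(self) -> None:
        if not 0.0 < self.carrier_fraction <= 1.0:
            raise ConfigError("carrier fraction must lie in (0, 1]")
        if self.n_probes < 1:
            raise ConfigError("sweep must span at least one probe")


@dataclass(frozen=True)
class TraitSpec:
    name: str
    causal_chrom: int
    causal_probe: int
    effect_size: float = 2.0
    noise_sd: float = 1.0
    env_effect: float = 0.5


@dataclass(frozen=True)
class SimConfig:
    seed: int = 0
    n_accessions: int = 54          # non-reference accessions
    n_chromosomes: int = 2
    probes_per_chromosome: int = 600
    probe_length: int = 25
    probe_spacing: int = 35
    n_populations: int = 4
    # per-base SNP-event probability; with ~0.3 segregating events per
    # 25-mer, roughly a third of probes are polymorphic somewhere in a
    # 54-accession panel, matching the observed site fraction
    snp_rate: float = 0.012
    founder_carry_prob: float = 0.30  # per-founder carriage of each event
    private_snp_rate: float = 0.006   # per accession per probe
    # founder switch probability per probe: background identity tracts of
    # ~15-20 probes (sub-kb), an order of magnitude shorter than a swept
    # haplotype, as in natural panels where background LD decays within kb
    mosaic_switch_rate: float = 0.06
    admixture_alpha: float = 0.25
    deletion_specs: tuple[SegmentSpec, ...] = (
        SegmentSpec(accessions=(1,), chrom=0, start_probe=60, n_probes=28),
        SegmentSpec(accessions=(2, 7), chrom=1, start_probe=100, n_probes=12),
    )
    duplication_specs: tuple[SegmentSpec, ...] = (
        SegmentSpec(accessions=(3,), chrom=1, start_probe=300, n_probes=15),
    )
    sweep_spec: SweepSpec | None = SweepSpec(chrom=0, start_probe=200, n_probes=120)
    trait_specs: tuple[TraitSpec, ...] = tuple(
        TraitSpec(name=name, causal_chrom=i % 2, causal_probe=80 + 45 * i)
        for i, name in enumerate(TRAIT_NAMES)
    )
    n_experiments: int = 2
    q_effect_scale: float = 0.5
    # intensity model
    ref_log2_mean: float = 10.0
    ref_log2_sd: float = 1.0
    attenuation: float = 2.2        # max log2 drop per centre-of-probe SNP
    gc_modulation: float = 0.4      # linear GC modulation of attenuation
    deletion_drop: float = 4.0      # log2 drop for deleted probes
    # planted duplications are strong amplifications (log2 gain 3), leaving
    # margin over the conservative 4-fold call threshold under noise
    duplication_fold: float = 8.0
    noise_sd: float = 0.25          # per-array multiplicative (log2) noise
    outlier_rate: float = 0.005     # heavy-tail bad-probe rate
    outlier_shift: float = -2.0
    outlier_sd: float = 1.0
    n_replicates: int = 2
    nonunique_fraction: float = 0.05
    gc_beta: tuple[float, float] = (8.0, 12.0)  # probe GC ~ Beta(a, b)
    # genetic map: cM = rate*bp with mild cubic curvature
    cm_per_bp: float = 4e-6
    map_curvature: float = 0.15
    n_map_markers: int = 40         # markers per chromosome in the map table
    geo_dispersion: float = 300.0   # km scatter around population centres
    reference_name: str = "Col-0"

    def __post_init__(self) -> None:
        for name in ("n_accessions", "n_chromosomes", "probes_per_chromosome",
                     "probe_length", "n_populations", "n_replicates",
                     "n_experiments"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1")
        if self.probe_spacing < 1:
            raise ConfigError("probe spacing must be >= 1")
        for name in ("snp_rate", "founder_carry_prob", "private_snp_rate",
                     "mosaic_switch_rate", "nonunique_fraction", "outlier_rate"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1]")
        n_probes = self.probes_per_chromosome
        for spec in (*self.deletion_specs, *self.duplication_specs):
            if spec.chrom >= self.n_chromosomes or spec.start_probe + spec.n_probes > n_probes:
                raise ConfigError("planted segment exceeds chromosome bounds")
            if any(a >= self.n_accessions for a in spec.accessions):
                raise ConfigError("segment accession index out of range")
        if self.sweep_spec is not None:
            s = self.sweep_spec
            if s.chrom >= self.n_chromosomes or s.start_probe + s.n_probes > n_probes:
                raise ConfigError("sweep region exceeds chromosome bounds")
        for t in self.trait_specs:
            if t.causal_chrom >= self.n_chromosomes or t.causal_probe >= n_probes:
                raise ConfigError(f"trait {t.name}: causal marker outside genome")

    @property
    def accession_names(self) -> tuple[str, ...]:
        return tuple(f"Acc{i + 1:02d}" for i in range(self.n_accessions))

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class RunConfig:
    """Full-pipeline parameters with the published defaults."""

    seed: int = 0
    sim: SimConfig = field(default_factory=SimConfig)
    stages: tuple[str, ...] = (
        "simulate", "call-sfp", "call-segments", "enrich",
        "associate", "sweep-scan", "report",
    )
    sfp_threshold: float = -1.5
    min_run: int = 10
    dup_min_log2fc: float = 2.0
    min_maf: float = 0.05
    alpha: float = 1e-3
    pathway_alpha: float = 0.01
    window: int = 1000
    offset: int = 50
    outlier_quantile: float = 0.005
    min_proportion: float = 0.45
    n_shuffles: int = 10000
    map_degree: int = 3

    def __post_init__(self) -> None:
        if self.sfp_threshold >= 0:
            raise ConfigError("SFP threshold must be negative (signal decrease)")
        if self.min_run < 1:
            raise ConfigError("min_run must be >= 1")
        if not 0.0 <= self.min_maf <= 0.5:
            raise ConfigError("min_maf must lie in [0, 0.5]")
        if self.window < 1 or self.offset < 1:
            raise ConfigError("window and offset must be >= 1")
        if not 0.0 < self.outlier_quantile < 1.0:
            raise ConfigError("outlier quantile must lie in (0, 1)")
        unknown = set(self.stages) - {
            "simulate", "call-sfp", "call-segments", "enrich",
            "associate", "sweep-scan", "report"}
        if unknown:
            raise ConfigError(f"unknown stages: {sorted(unknown)}")
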