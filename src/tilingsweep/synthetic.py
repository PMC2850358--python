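"""Synthetic tiling-array study generator.

Emulates the data structure of a 54-accession *A. thaliana* tiling-array
experiment: 25-mer probes tiled along chromosomes, a four-population
admixed panel with founder-haplotype mosaics, SNP events whose
hybridisation attenuation depends on position-in-probe, SNP count and
probe GC, contiguous deleted/duplicated segments, a planted
long-haplotype sweep, traits generated from the association GLM, and a
small reaction-compound metabolic network.

Every generator is a pure function of (config, seed): sub-streams are
derived from ``config.seed`` with fixed spawn keys so stages are
individually reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import POPULATION_CENTRES, SimConfig
from .types import ConfigError, IntensityMatrix, MetabolicNetwork, ProbeMap

# spawn keys for per-stage RNG sub-streams
_KEYS = {
    "probe_map": 1, "annotation": 2, "population": 3, "variants": 4,
    "intensities": 5, "phenotypes": 6, "network": 7, "genetic_map": 8,
}

#: SNP-event rate multipliers per feature class: functional classes are
#: depleted, pseudogenes/transposons/ncRNA enriched, mirroring the
#: selective constraints seen in natural panels
CLASS_RATE = {
    "CDS": 0.55, "intron": 1.0, "ncRNA": 1.7, "miRNA": 1.0, "snRNA": 1.0,
    "snoRNA": 1.0, "rRNA": 0.45, "tRNA": 0.45, "pseudogene": 2.1,
    "transposon": 2.5, "intergenic": 0.8,
}

#: protein-coding gene families; (sampling weight, SNP-rate multiplier).
#: Defence/signalling families are hypervariable, transcription factors
#: conserved.
FAMILIES = {
    "NBS-LRR": (2.0, 2.5),
    "F-box": (2.0, 2.0),
    "receptor-like-kinase": (2.0, 1.8),
    "terpene-synthase": (1.0, 1.6),
    "monooxygenase": (1.0, 1.5),
    "bHLH-TF": (1.5, 0.5),
    "MADS-box-TF": (1.0, 0.5),
    "MYB-TF": (1.5, 0.55),
    "ABC-transporter": (1.0, 0.6),
    "glycosyl-transferase": (1.0, 0.6),
    "cytoplasmic-ribosomal": (1.0, 0.9),
    "RING": (1.0, 1.0),
}

CURRENCY_COMPOUNDS = ("H2O", "ATP", "ADP", "NADH", "NAD+", "CO2", "O2", "H+")


def _rng(config: SimConfig, stage: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(config.seed, spawn_key=(_KEYS[stage],)))


def chrom_name(i: int) -> str:
    return f"chr{i + 1}"


def chromosome_length(config: SimConfig) -> int:
    """bp span covered by the probe tiling of one chromosome."""
    return (config.probes_per_chromosome - 1) * config.probe_spacing + config.probe_length


# ---------------------------------------------------------------------------
# probe map and annotation


def generate_probe_map(config: SimConfig) -> ProbeMap:
    """Tile ``probes_per_chromosome`` 25-mers at the configured spacing.

    GC fractions are Beta-distributed; a configured fraction of probes is
    flagged non-unique (multi-match probes never carry SFP calls).
    """
    rng = _rng(config, "probe_map")
    n, m = config.n_chromosomes, config.probes_per_chromosome
    total = n * m
    starts = np.tile(np.arange(m) * config.probe_spacing, n)
    chroms = np.repeat([chrom_name(i) for i in range(n)], m)
    a, b = config.gc_beta
    gc = rng.beta(a, b, size=total)
    unique = rng.random(total) >= config.nonunique_fraction
    df = pd.DataFrame({
        "probe_id": [f"P{i:07d}" for i in range(total)],
        "chrom": chroms,
        "start": starts,
        "length": config.probe_length,
        "gc": gc,
        "unique": unique,
    })
    return ProbeMap(df)


def generate_annotation(config: SimConfig) -> pd.DataFrame:
    """Genomic feature annotation over the probe-tiled chromosomes.

    Returns intervals (chrom, start, end half-open, klass, gene_id, family,
    pathway). Genes alternate with intergenic gaps; protein-coding genes
    receive CDS/intron subfeatures and a gene-family label; a subset is
    tagged with a metabolic pathway. Regions left uncovered are intergenic
    by convention (no explicit rows emitted for them).
    """
    rng = _rng(config, "annotation")
    classes = ["protein_coding", "ncRNA", "miRNA", "snRNA", "snoRNA",
               "rRNA", "tRNA", "pseudogene", "transposon"]
    probs = np.array([0.52, 0.07, 0.03, 0.03, 0.03, 0.04, 0.04, 0.10, 0.14])
    fam_names = list(FAMILIES)
    fam_w = np.array([FAMILIES[f][0] for f in fam_names], float)
    fam_w /= fam_w.sum()
    rows = []
    gene_i = 0
    for c in range(config.n_chromosomes):
        chrom = chrom_name(c)
        L = chromosome_length(config)
        pos = int(rng.integers(100, 400))
        while pos < L - 600:
            klass = classes[rng.choice(len(classes), p=probs)]
            glen = int(rng.integers(400, 1100))
            end = min(pos + glen, L)
            gene_id = f"G{gene_i:04d}"
            gene_i += 1
            if klass == "protein_coding":
                family = fam_names[rng.choice(len(fam_names), p=fam_w)]
                pathway = f"PWY{int(rng.integers(1, 9)):02d}" if rng.random() < 0.4 else ""
                # alternate CDS/intron blocks inside the gene body
                sub, flip = pos, True
                while sub < end:
                    blen = int(rng.integers(120, 320))
                    bend = min(sub + blen, end)
                    rows.append((chrom, sub, bend, "CDS" if flip else "intron",
                                 gene_id, family, pathway))
                    sub, flip = bend, not flip
            else:
                rows.append((chrom, pos, end, klass, gene_id, "", ""))
            pos = end + int(rng.integers(150, 700))
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "klass", "gene_id", "family", "pathway"])


def _probe_rate_multipliers(probes: ProbeMap, annotation: pd.DataFrame | None) -> np.ndarray:
    """Per-probe SNP-rate multiplier from the feature class (and family)
    overlapping the probe midpoint; intergenic where uncovered."""
    mult = np.full(probes.n_probes, CLASS_RATE["intergenic"])
    if annotation is None:
        return np.ones(probes.n_probes)
    mids = probes.df["start"].to_numpy() + probes.df["length"].to_numpy() // 2
    chroms = probes.df["chrom"].to_numpy()
    for chrom, sub in annotation.groupby("chrom"):
        sel = np.flatnonzero(chroms == chrom)
        if not len(sel):
            continue
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        for s, e, klass, family in zip(starts, ends, sub["klass"], sub["family"]):
            hit = sel[(mids[sel] >= s) & (mids[sel] < e)]
            m = CLASS_RATE.get(klass, 1.0)
            if family:
                m *= FAMILIES[family][1]
            mult[hit] = m
    return mult


# ---------------------------------------------------------------------------
# population structure


@dataclass
class GenotypeTruth:
    """Founder-mosaic ancestry of the panel, before variant planting.

    ``founder_path``: (n_accessions_total, n_probes_total) founder index per
    probe; row 0 is the reference accession.
    """

    accessions: tuple[str, ...]   # reference first
    reference: str
    founder_path: np.ndarray
    qmatrix: pd.DataFrame
    geo: pd.DataFrame


def generate_population(config: SimConfig) -> tuple[GenotypeTruth, pd.DataFrame, pd.DataFrame]:
    """Admixture proportions, founder mosaics and geographic origins.

    Each accession has a primary population; Q rows are Dirichlet draws
    concentrated on it (rows sum to 1). The haplotype is a Markov mosaic of
    founder haplotypes sampled from Q at each switch point. Coordinates
    scatter (Gaussian, ``geo_dispersion`` km) around the primary
    population's centre, so like-population accessions are geographically
    closer in expectation.
    """
    rng = _rng(config, "population")
    k = config.n_populations
    names = (config.reference_name,) + config.accession_names
    n_total = len(names)
    primary = np.array([i % k for i in range(n_total)])
    primary[0] = 1 % k  # reference: Central/Western Europe
    if k == 1:
        q = np.ones((n_total, 1))
    else:
        alpha = np.full(k, config.admixture_alpha)
        q = np.empty((n_total, k))
        for i in range(n_total):
            a = alpha.copy()
            a[primary[i]] += 4.0  # concentrate on the primary population
            q[i] = rng.dirichlet(a)
    n_probes_total = config.n_chromosomes * config.probes_per_chromosome
    path = np.empty((n_total, n_probes_total), dtype=np.int8)
    m = config.probes_per_chromosome
    for i in range(n_total):
        for c in range(config.n_chromosomes):
            seg = np.empty(m, dtype=np.int8)
            cur = rng.choice(k, p=q[i])
            for j in range(m):
                if rng.random() < config.mosaic_switch_rate:
                    cur = rng.choice(k, p=q[i])
                seg[j] = cur
            path[i, c * m:(c + 1) * m] = seg
    centres = np.array(POPULATION_CENTRES[:k] if k <= len(POPULATION_CENTRES)
                       else POPULATION_CENTRES + tuple((30.0 + 5 * i, 10.0 * i)
                                                       for i in range(k - len(POPULATION_CENTRES))))
    km_per_deg_lat = 111.0
    lat = np.empty(n_total)
    lon = np.empty(n_total)
    for i in range(n_total):
        clat, clon = centres[primary[i]]
        dlat = rng.normal(0.0, config.geo_dispersion) / km_per_deg_lat
        dlon = rng.normal(0.0, config.geo_dispersion) / (
            km_per_deg_lat * max(np.cos(np.radians(clat)), 0.2))
        lat[i], lon[i] = clat + dlat, clon + dlon
    qmatrix = pd.DataFrame(q, index=list(names),
                           columns=[f"Q{j + 1}" for j in range(k)])
    qmatrix.index.name = "accession"
    geo = pd.DataFrame({"accession": list(names), "lat": lat, "lon": lon,
                        "population": primary})
    truth = GenotypeTruth(accessions=names, reference=config.reference_name,
                          founder_path=path, qmatrix=qmatrix, geo=geo)
    return truth, qmatrix, geo


# ---------------------------------------------------------------------------
# variant planting


@dataclass
class TruthSet:
    """Ground truth for calibration: SNP events, segments, sweep, traits."""

    accessions: tuple[str, ...]
    reference: str
    snp_probe: np.ndarray        # global probe index per SNP event
    snp_pos: np.ndarray          # 0-based position within the probe
    snp_carriers: np.ndarray     # (n_snps, n_accessions_total) bool
    segments: pd.DataFrame       # accession, chrom, start_probe, n_probes, kind
    sweep_carriers: tuple[str, ...]
    sweep_probes: tuple[int, int] | None   # [start, end) global probe indices
    causal_markers: dict[str, int] = field(default_factory=dict)
    qmatrix: pd.DataFrame | None = None
    geo: pd.DataFrame | None = None

    def snp_count_matrix(self, n_probes: int) -> np.ndarray:
        """(n_probes, n_accessions) count of SNPs carried per probe."""
        out = np.zeros((n_probes, len(self.accessions)), dtype=np.int16)
        np.add.at(out, self.snp_probe, self.snp_carriers.astype(np.int16))
        return out

    def polymorphic(self, n_probes: int, include_deletions: bool = True) -> np.ndarray:
        """(n_probes, n_accessions) bool: probe truly polymorphic per accession."""
        poly = self.snp_count_matrix(n_probes) > 0
        if include_deletions:
            acc_idx = {a: i for i, a in enumerate(self.accessions)}
            for _, row in self.segments.iterrows():
                if row["kind"] != "deletion":
                    continue
                lo = row["start_probe_global"]
                poly[lo:lo + row["n_probes"], acc_idx[row["accession"]]] = True
        return poly

    def genotype_truth(self, probes: ProbeMap) -> pd.DataFrame:
        """Sites x accessions 0/1 matrix of truly polymorphic probes."""
        poly = self.polymorphic(probes.n_probes, include_deletions=False)
        keep = poly.any(axis=1)
        df = pd.DataFrame(poly[keep].astype(np.int8),
                          index=probes.df["probe_id"].to_numpy()[keep],
                          columns=list(self.accessions))
        return df


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def plant_variants(truth: GenotypeTruth, config: SimConfig,
                   probes: ProbeMap | None = None,
                   annotation: pd.DataFrame | None = None) -> TruthSet:
    """Assign SNP events to founder haplotypes and plant segments/sweep.

    SNP events respect population structure (carried via the founder
    mosaic), so allele frequencies follow admixture. Sweep carriers copy
    founder 0 across the region and receive additional swept-haplotype
    marker SNPs, creating a long identical haplotype. Segment truth is
    recorded as probe-index intervals.
    """
    if probes is None:
        probes = generate_probe_map(config)
    rng = _rng(config, "variants")
    n_probes = probes.n_probes
    n_total = len(truth.accessions)
    k = config.n_populations
    m = config.probes_per_chromosome

    # overlapping deletion/duplication in one accession is contradictory
    for dspec in config.deletion_specs:
        for uspec in config.duplication_specs:
            if dspec.chrom == uspec.chrom and set(dspec.accessions) & set(uspec.accessions):
                lo1, hi1 = dspec.start_probe, dspec.start_probe + dspec.n_probes
                lo2, hi2 = uspec.start_probe, uspec.start_probe + uspec.n_probes
                if lo1 < hi2 and lo2 < hi1:
                    raise ConfigError(
                        "deletion and duplication overlap in the same accession")

    path = truth.founder_path.copy()

    # --- sweep: carriers copy founder 0 over the block
    sweep_carriers: tuple[str, ...] = ()
    sweep_probes = None
    carrier_rows = np.array([], dtype=int)
    if config.sweep_spec is not None:
        s = config.sweep_spec
        lo = s.chrom * m + s.start_probe
        hi = lo + s.n_probes
        sweep_probes = (lo, hi)
        shlo = max(s.chrom * m, lo - s.shoulder)
        shhi = min((s.chrom + 1) * m, hi + s.shoulder)
        n_car = min(_round_half_up(s.carrier_fraction * config.n_accessions),
                    config.n_accessions)
        pops = truth.geo["population"].to_numpy()[1:]  # non-reference rows
        weights = np.where(pops < min(2, config.n_populations),
                           s.population_bias, 1.0)
        weights = weights / weights.sum()
        carrier_rows = 1 + rng.choice(config.n_accessions, size=n_car,
                                      replace=False, p=weights)
        carrier_rows.sort()
        path[carrier_rows, shlo:shhi] = 0
        sweep_carriers = tuple(truth.accessions[i] for i in carrier_rows)

    # --- SNP events with founder assignment
    mult = _probe_rate_multipliers(probes, annotation)
    lam = config.probe_length * config.snp_rate * mult
    counts = rng.poisson(lam)
    snp_probe = np.repeat(np.arange(n_probes), counts)
    n_snps = len(snp_probe)
    snp_pos = rng.integers(0, config.probe_length, size=n_snps)
    founder_carry = rng.random((n_snps, k)) < config.founder_carry_prob
    # resample monomorphic events (all founders / no founder) to keep sites
    # segregating among founders
    for _ in range(40):
        bad = ~founder_carry.any(axis=1) | founder_carry.all(axis=1)
        if not bad.any():
            break
        founder_carry[bad] = rng.random((bad.sum(), k)) < config.founder_carry_prob
    if k == 1:
        founder_carry[:] = True

    # carriage: accession carries the event iff its local founder does
    local_founder = path[:, snp_probe]                     # (n_total, n_snps)
    carriers = founder_carry[np.arange(n_snps)[None, :], local_founder].T
    carriers = np.ascontiguousarray(carriers)              # (n_snps, n_total)

    # --- swept-haplotype marker SNPs: derived mutations private to the
    # sweep lineage, with rare homoplasy in the background panel
    if sweep_probes is not None and config.sweep_spec.marker_rate > 0:
        lo, hi = sweep_probes
        block = np.arange(lo, hi)
        chosen = block[rng.random(len(block)) < config.sweep_spec.marker_rate]
        if len(chosen):
            extra_pos = rng.integers(0, config.probe_length, size=len(chosen))
            extra_carry = (rng.random((len(chosen), n_total))
                           < config.sweep_spec.background_carry)
            extra_carry[:, carrier_rows] = True
            snp_probe = np.concatenate([snp_probe, chosen])
            snp_pos = np.concatenate([snp_pos, extra_pos])
            carriers = np.vstack([carriers, extra_carry])
            order = np.argsort(snp_probe, kind="stable")
            snp_probe, snp_pos = snp_probe[order], snp_pos[order]
            carriers = carriers[order]

    # private accession-specific SNPs
    private = rng.random((n_probes, n_total)) < config.private_snp_rate
    private[:, 0] = False
    if sweep_probes is not None:
        lo, hi = sweep_probes
        s = config.sweep_spec
        m_ = config.probes_per_chromosome
        shlo = max(s.chrom * m_, lo - s.shoulder)
        shhi = min((s.chrom + 1) * m_, hi + s.shoulder)
        private[shlo:shhi, carrier_rows] = False
    pp, pa = np.nonzero(private)
    if len(pp):
        priv_carry = np.zeros((len(pp), n_total), dtype=bool)
        priv_carry[np.arange(len(pp)), pa] = True
        snp_probe = np.concatenate([snp_probe, pp])
        snp_pos = np.concatenate([snp_pos, rng.integers(0, config.probe_length, len(pp))])
        carriers = np.vstack([carriers, priv_carry])
        order = np.argsort(snp_probe, kind="stable")
        snp_probe, snp_pos, carriers = snp_probe[order], snp_pos[order], carriers[order]

    carriers[:, 0] = False  # the reference genome defines allele 0 everywhere

    # --- segment truth
    seg_rows = []
    for kind, specs in (("deletion", config.deletion_specs),
                        ("duplication", config.duplication_specs)):
        for spec in specs:
            for a in spec.accessions:
                seg_rows.append({
                    "accession": truth.accessions[1 + a],
                    "chrom": chrom_name(spec.chrom),
                    "start_probe": spec.start_probe,
                    "n_probes": spec.n_probes,
                    "start_probe_global": spec.chrom * m + spec.start_probe,
                    "kind": kind,
                })
    segments = pd.DataFrame(
        seg_rows, columns=["accession", "chrom", "start_probe", "n_probes",
                           "start_probe_global", "kind"])

    out = TruthSet(accessions=truth.accessions, reference=truth.reference,
                   snp_probe=snp_probe, snp_pos=snp_pos, snp_carriers=carriers,
                   segments=segments, sweep_carriers=sweep_carriers,
                   sweep_probes=sweep_probes, qmatrix=truth.qmatrix,
                   geo=truth.geo)

    # resolve causal markers: nearest truly polymorphic probe with decent MAF
    poly = out.polymorphic(n_probes, include_deletions=False)
    freq = poly.mean(axis=1)
    maf = np.minimum(freq, 1 - freq)
    eligible = np.flatnonzero(maf >= 0.10)
    for spec in config.trait_specs:
        want = spec.causal_chrom * m + spec.causal_probe
        if len(eligible):
            out.causal_markers[spec.name] = int(
                eligible[np.argmin(np.abs(eligible - want))])
    return out


# ---------------------------------------------------------------------------
# intensities


def _position_weight(pos: np.ndarray, length: int) -> np.ndarray:
    """Triangular attenuation weight: 1 at probe centre, ~0 at the ends."""
    centre = (length - 1) / 2.0
    return 1.0 - np.abs(pos - centre) / (centre + 1.0)


def simulate_intensities(truth: TruthSet, probes: ProbeMap,
                         config: SimConfig) -> IntensityMatrix:
    """Hybridisation signals under the multiplicative attenuation model.

    Reference probe signals are log-normal. Per accession, each SNP in a
    probe attenuates the log2 signal by ``attenuation * w(pos) * g(GC)``
    with ``w`` triangular (strongest at probe centre) and ``g`` a mild
    linear GC modulation; effects of multiple SNPs compound additively in
    log space. Deleted probes fall to a constant background, duplicated
    probes gain log2(fold). Per-array noise is Gaussian in log2 with a rare
    heavy-tail component emulating bad probes.
    """
    rng = _rng(config, "intensities")
    n_probes = probes.n_probes
    n_total = len(truth.accessions)
    gc = probes.df["gc"].to_numpy()

    ref = rng.normal(config.ref_log2_mean, config.ref_log2_sd, size=n_probes)

    w = _position_weight(truth.snp_pos.astype(float), config.probe_length)
    g = 1.0 + config.gc_modulation * (gc[truth.snp_probe] - 0.5)
    per_snp = config.attenuation * w * g                   # log2 drop per event
    drop = np.zeros((n_probes, n_total))
    np.add.at(drop, truth.snp_probe, truth.snp_carriers * per_snp[:, None])

    expected = ref[:, None] - drop                         # (n_probes, n_total)
    acc_idx = {a: i for i, a in enumerate(truth.accessions)}
    for _, row in truth.segments.iterrows():
        lo = row["start_probe_global"]
        hi = lo + row["n_probes"]
        j = acc_idx[row["accession"]]
        if row["kind"] == "deletion":
            expected[lo:hi, j] = ref[lo:hi] - config.deletion_drop
        else:
            expected[lo:hi, j] = ref[lo:hi] + np.log2(config.duplication_fold)

    arrays, cols = [], []
    values = np.empty((n_probes, n_total * config.n_replicates))
    col = 0
    for j, acc in enumerate(truth.accessions):
        for r in range(config.n_replicates):
            sig = expected[:, j] + rng.normal(0.0, config.noise_sd, n_probes)
            if config.outlier_rate > 0:
                bad = rng.random(n_probes) < config.outlier_rate
                sig[bad] += rng.normal(config.outlier_shift, config.outlier_sd,
                                       bad.sum())
            aid = f"{acc}_r{r + 1}"
            values[:, col] = sig
            cols.append(aid)
            arrays.append((aid, acc))
            col += 1
    vdf = pd.DataFrame(values, index=probes.df["probe_id"].to_numpy(), columns=cols)
    vdf.index.name = "probe_id"
    adf = pd.DataFrame(arrays, columns=["array_id", "accession"])
    return IntensityMatrix(values=vdf, arrays=adf, reference=truth.reference)


# ---------------------------------------------------------------------------
# phenotypes


def simulate_phenotypes(truth: TruthSet, qmatrix: pd.DataFrame,
                        config: SimConfig) -> pd.DataFrame:
    """Traits from the association GLM's generative form.

    value = intercept + effect x causal genotype + environment effect
    + Q-loading effects + Gaussian error, one record per accession per
    experiment (so least-squares means over experiments are non-trivial).
    """
    rng = _rng(config, "phenotypes")
    poly = truth.polymorphic(
        max(truth.snp_probe.max(initial=0) + 1,
            config.n_chromosomes * config.probes_per_chromosome),
        include_deletions=False)
    k = qmatrix.shape[1]
    contrast = np.array([1.0, -1.0, 0.5, -0.5] * ((k + 3) // 4))[:k]
    q = qmatrix.loc[list(truth.accessions)].to_numpy()
    rows = []
    for env in range(config.n_experiments):
        for i, acc in enumerate(truth.accessions):
            rec: dict[str, object] = {"accession": acc, "experiment": f"E{env + 1}"}
            for spec in config.trait_specs:
                marker = truth.causal_markers.get(spec.name)
                geno = float(poly[marker, i]) if marker is not None else 0.0
                val = (10.0 + spec.effect_size * geno
                       + spec.env_effect * env
                       + config.q_effect_scale * float(q[i] @ contrast)
                       + (rng.normal(0.0, spec.noise_sd) if spec.noise_sd > 0 else 0.0))
                rec[spec.name] = val
            rows.append(rec)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# metabolic network and genetic map


def generate_metabolic_network(config: SimConfig,
                               genes: list[str] | None = None,
                               n_compounds: int = 30,
                               n_reactions: int = 40) -> MetabolicNetwork:
    """Random bipartite reaction-compound graph with gene annotation.

    A chain backbone (reaction i: C_i -> C_{i+1}) keeps the non-currency
    compound graph connected; random extra substrates/products and currency
    participants are layered on top. Genes map to 1-2 reactions each and
    carry a pathway label.
    """
    rng = _rng(config, "network")
    compounds = [f"C{i + 1:03d}" for i in range(n_compounds)]
    reactions = []
    for r in range(n_reactions):
        rid = f"R{r + 1:03d}"
        if r < n_compounds - 1:
            subs = {compounds[r]}
            prods = {compounds[r + 1]}
        else:
            subs = {compounds[rng.integers(n_compounds)]}
            prods = {compounds[rng.integers(n_compounds)]}
            while prods == subs:
                prods = {compounds[rng.integers(n_compounds)]}
        if rng.random() < 0.3:
            subs.add(compounds[rng.integers(n_compounds)])
        if rng.random() < 0.3:
            prods.add(compounds[rng.integers(n_compounds)])
        if rng.random() < 0.5:
            subs.add(CURRENCY_COMPOUNDS[rng.integers(len(CURRENCY_COMPOUNDS))])
        if rng.random() < 0.5:
            prods.add(CURRENCY_COMPOUNDS[rng.integers(len(CURRENCY_COMPOUNDS))])
        reactions.append({"reaction_id": rid,
                          "substrates": tuple(sorted(subs)),
                          "products": tuple(sorted(prods))})
    if genes is None:
        genes = [f"G{i:04d}" for i in range(60)]
    gene_reactions = {}
    gene_pathway = {}
    for gi, gene in enumerate(genes):
        n_rx = 1 + int(rng.random() < 0.3)
        rx = rng.choice(n_reactions, size=n_rx, replace=False)
        gene_reactions[gene] = tuple(f"R{r + 1:03d}" for r in sorted(rx))
        gene_pathway[gene] = f"PWY{int(rng.integers(1, 9)):02d}"
    return MetabolicNetwork(reactions=pd.DataFrame(reactions),
                            gene_reactions=gene_reactions,
                            gene_pathway=gene_pathway,
                            currency=frozenset(CURRENCY_COMPOUNDS))


def generate_genetic_map_table(config: SimConfig) -> pd.DataFrame:
    """Marker table (chrom, bp, cM) from a smooth monotone truth map.

    cM(bp) = rate * (bp + curvature * bp^2 / L): monotone with mild
    curvature, plus small measurement noise on the marker cM values.
    """
    rng = _rng(config, "genetic_map")
    rows = []
    L = chromosome_length(config)
    for c in range(config.n_chromosomes):
        bp = np.linspace(0, L - 1, config.n_map_markers).astype(int)
        cm = config.cm_per_bp * (bp + config.map_curvature * bp.astype(float) ** 2 / L)
        cm = np.maximum.accumulate(cm + rng.normal(0.0, config.cm_per_bp * L * 1e-3,
                                                   len(bp)))
        cm -= cm.min()
        for b, g in zip(bp, cm):
            rows.append({"chrom": chrom_name(c), "bp": int(b), "cm": float(g)})
    return pd.DataFrame(rows)
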