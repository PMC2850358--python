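# Methods

This note records the models behind each pipeline stage, the synthetic
study the package generates, the numerical conventions, and the design
choices made where more than one reading was defensible. Nothing here
states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## The synthetic study

The generator emulates a tiling-array genotyping study of 54 inbred
accessions plus the Col-0 reference. Its defaults are the package's
study conditions; all are configurable (`SimConfig`).

**Genome and probes.** Two chromosomes of 25-mer probes tiled every
35 bp (600/chromosome in unit tests, 7,000/chromosome in the end-to-end
desk configuration, `desk_run_config`). Probe GC is Beta(8, 12); 5% of
probes are flagged multi-match and excluded from calling, as on a real
array where only single-hit probes are informative.

**Population structure.** Four source populations with continental
centres (Iberia, Central/Western Europe, Eastern Europe, Central Asia).
Each accession has a primary population; its admixture row is a
Dirichlet draw concentrated there (rows sum to 1), and its chromosomes
are Markov mosaics of founder haplotypes drawn from that row with a
switch probability of 0.06/probe. The switch rate was set so background
identity tracts are sub-kilobase — an order of magnitude shorter than a
swept haplotype — mirroring panels where background LD decays within a
few kb while sweeps extend over hundreds of kb. Coordinates scatter
300 km (Gaussian) around the population centre.

**Variants.** SNP events arrive per probe as Poisson with per-base rate
0.012, each carried by each founder with probability 0.30 (events
monomorphic across founders are resampled). This makes roughly a third
of probes polymorphic somewhere in the panel, matching the observed
fraction of array sites that segregate in a panel of this size; the
per-accession rate is necessarily higher than in the real data because a
four-founder panel caps how rare an allele can be. Private SNPs arrive
at 0.006/probe/accession. Feature classes modulate the rate (transposons
and pseudogenes enriched ~2–2.5×, coding/rRNA/tRNA depleted ~0.5×,
defence gene families such as NBS-LRR further enriched), reproducing the
selective-constraint pattern the enrichment stage is meant to detect.

**Segments.** Deletions and duplications are planted as probe-index
intervals per accession. Planted duplications are strong amplifications
(8-fold signal gain): a planted gain exactly at the 4-fold call boundary
would make noisy recovery a coin flip per probe by construction; the
4-fold boundary itself is exercised noiselessly in the tests.

**The sweep.** Carriers (round-half-up of the carrier fraction, default
0.45) copy founder 0 across the block plus an 80-probe soft shoulder on
each side, and the block carries derived marker mutations private to the
sweep lineage (rate 0.5/probe) with a 0.2 homoplasy rate elsewhere in
the panel. Three structural facts, learned while designing the
generator, matter for anyone re-scaling it:

1. *The sweep must be a small fraction of the scanned genome.* Pair
   moments (z̄_ij, σ_ij) are genome-wide, so a pair's Z inside the block
   is bounded by √((1−f)/f) where f is the block's share of sites; at
   f ≈ 10% the sweep standardises itself away. The desk configuration
   keeps the shared haplotype at ~4% of sites.
2. *Marker alleles must be nearly private to the haplotype.* If other
   founders also carry them, non-carriers flood the allele group and
   dilute the carrier-pair mean; if nobody else ever carries them,
   adjacent sites fall into r² > 0.5 LD and pruning collapses the block.
   A per-accession homoplasy rate of 0.2 keeps allele groups ~80%
   carriers while holding neighbouring-site r² below the pruning cutoff.
3. *Carriers are sampled with a 6× weight on two source populations*, so
   the selected allele clusters geographically, as a locally spread
   allele would.

**Traits.** Nine traits named for the growth/metabolic panel
(fresh weight, starch, sucrose, protein, amino acids, threonic acid,
β-alanine, erythritol, myo-inositol), each generated exactly from the
association model: value = 10 + effect·genotype + env·experiment +
Q-loadings + N(0, σ), two experiments per accession so least-squares
means are non-trivial. Defaults: effect 2.0, σ 1.0, environment 0.5,
Q-loading scale 0.5. Causal markers resolve to the nearest truth site
with MAF ≥ 0.10 so the planted signal exists in every seed.

**Intensities.** Reference log₂ signals are N(10, 1). Each SNP in a
probe attenuates the accession's log₂ signal by a·w(pos)·g(GC) with
a = 2.2, w triangular (1 at the probe centre, →0 at the ends) and
g = 1 + 0.4·(GC − 0.5); multiple SNPs compound additively in log space.
Deleted probes drop 4 log₂ units to background; duplicated probes gain
log₂(fold). Array noise is N(0, 0.25) per replicate (two replicates per
accession) plus a rare heavy tail (0.5% of probe×array values shifted
N(−2, 1)) emulating bad probes. These values place the −1.5 threshold's
FDR in the low single digits and the FNR near 70% — the stringency
trade-off regime of real arrays, where SNP position in the probe drives
most misses. The attenuation magnitudes themselves are a modelling
choice; only their qualitative dependencies (position, count, GC) are
constrained by what arrays are known to do.

**What the generator does not emulate.** Sequence content, base-level
mutation processes, coalescent genealogies, probe cross-hybridisation
structure, and chip spatial artefacts. Consequently, passing tests show
the *statistics* behave as designed on data with the assumed structure;
they do not certify calling accuracy on real CEL-derived intensities.

## Stage conventions

- **Normalisation**: quantile by default (columns mapped onto average
  order statistics; idempotent), median scaling as the alternative.
- **Replicates**: arithmetic mean of replicate log₂ signals per
  accession before the fold change.
- **Call boundary**: log₂FC ≤ threshold, inclusive. Non-unique probes
  never carry calls. Missing probes are skipped, not imputed.
- **Runs**: strict consecutive runs; broken by chromosome ends and by
  non-unique probes (adjacency across masked gaps is ambiguous).
  Deleted probes stay counted as SFPs. Segment length is
  last-probe-end − first-probe-start.
- **Duplication threshold**: log₂FC ≥ 2 by default (the conservative
  4-fold reading); the 2-fold reading is available via
  `--dup-min-log2fc 1`.
- **Enrichment**: a site counts toward every overlapping class; class bp
  is the union of that class's intervals; positions in no feature are
  intergenic. χ² is the default for pooled counts, the unpaired t-test
  when per-accession counts are supplied (per-accession expected =
  accession total × class fraction). Raw p-values are reported with a
  BH-adjusted column.
- **GLM**: OLS via least squares with explicit SSR comparison; the Q
  matrix drops its last column (rows sum to 1); Env is dropped when only
  one experiment is present; rank-deficient designs raise an error
  naming the collinear columns; a perfect fit with a non-trivial marker
  term reports F = ∞. lsmeans set the marker to 0/1 with all covariates
  at their sample means. Empirical p-values pool all site×trait scores
  (per-trait pooling is a caller-side option: pass one trait).
- **Paths**: reactions are traversed undirected; distance is the number
  of reactions on the chain; currency compounds never serve as
  intermediates; unreachable is reported as `None`, never a sentinel
  distance.
- **Genetic map**: polynomial of degree 3 by default, fitted on
  centred/scaled bp for conditioning, evaluation made monotone by a
  running maximum, constant maps rejected.
- **Sharing**: the shared interval ends at the last identical site
  before the first discordant one (not the midpoint); chromosome ends
  truncate; discordance at the focal site gives zero. Pairs whose
  sharing has zero variance across the site grid are excluded with a
  warning. Sample (n−1) standard deviations everywhere.
- **PHS form**: difference form (carrier-pair mean − all-pair mean) by
  default; the single-term carrier mean is available via `form=`.
- **Frequency classes**: exact carrier counts where a count has ≥ 20
  scores, 0.05-wide frequency bins otherwise; degenerate classes
  standardise to 0 with a warning. Each site enters windowing with its
  higher-standardised allele.
- **Pruning**: adjacent retained sites, dropped iteratively until no
  neighbouring pair has r² > 0.5 with r > 0; idempotent by construction.
- **Windows**: outliers are top-quantile genome-wide; the 45% rule is a
  strict inequality; overlapping candidate windows merge; the focal SFP
  is the region's highest standardized score; regions are named SR1…
  in genome order.
- **Geography**: haversine on a 6371-km sphere; permutation = random
  reassignment of the carrier set across accessions; the pooled
  pair-distance comparison is the default, per-shuffle means optional.
- **Seeds**: one global seed; per-stage seeds derive from it by hashing
  the stage name (all below 2³¹), so stages are independently
  reproducible.

## Scaled parameters

The published scan parameters (windows of 1000 SFPs, offset 50, top
0.5% outliers) presuppose ~600k sites. The desk configuration scales
the geometry, not just the sizes: windows of 100 SFPs, offset 5, top
10% outliers over ~3k pruned sites. At 0.5%, the outlier budget
(0.005 × 3000 = 15) could never fill 45% of a 100-SFP window, so the
quantile must scale with the window; the 45% density rule and strict
inequality are kept exactly. Full-scale runs are configuration-only.

Sweep recovery is validated on the generator's genotype matrix (the
scan's documented input). Running the scan on *called* genotypes at desk
scale detects the planted sweep in only about half the seeds: probes
whose expected fold change sits near −1.5 flip per accession under array
noise and break carrier haplotypes. This is a faithful miniature of the
false-negative-rate interference that limits sweep scans on real array
calls; it disappears as panel and window sizes grow.

## Known limitations

- The four-founder mosaic cannot produce a realistic rare-allele
  frequency spectrum; MAF-threshold behaviour near 5% is exercised by
  construction, not by a realistic spectrum.
- The empirical-p machinery is rank-based and cannot resolve p below
  1/(n_sites × n_traits); desk-scale FDR estimates saturate when the
  planted-signal count is of the order of the random expectation.
- The geographic permutation test compares correlated pair distances
  (pairs share members), so its null p-values are only approximately
  uniform; the calibration test asserts exactly that approximate
  uniformity.
- Copy number is binary (duplicated or not); no dosage estimation.
- No kinship/mixed-model association; Q-matrix covariates only.
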