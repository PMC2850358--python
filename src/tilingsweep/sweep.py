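"""Pairwise-haplotype-sharing (PHS) selective sweep scan.

A recent sweep drags a long identical haplotype to intermediate
frequency among carriers of the selected allele. For accessions i, j and
site x, z_ijx is the genetic-map length (cM) of the interval over which
i and j are identical around x; it is standardised per pair as
Z_ijx = (z_ijx - mean_ij) / sd_ij with the moments taken genome-wide, so
overall relatedness (population structure) cancels. The PHS of allele a
at x averages Z_ijx over carrier pairs, minus the average over all pairs
(difference form; the carrier-only single term is available). Scores are
then standardised within allele-frequency classes, (score - median_f) /
SD_f, LD-pruned (drop the lower-scoring of neighbouring sites with
r^2 > 0.5 and r > 0), and swept with windows of fixed SFP count: windows
whose proportion of top-quantile outliers exceeds the cutoff are merged
into candidate regions represented by their highest-scoring (focal) SFP.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .types import ConfigError, DataError

EARTH_RADIUS_KM = 6371.0


# ---------------------------------------------------------------------------
# genetic map


@dataclass
class GeneticMap:
    """Per-chromosome polynomial physical->genetic position mapping.

    Evaluation is made monotone non-decreasing by a running-maximum
    (isotonic) adjustment over the queried positions, since a raw
    polynomial fit need not be monotone.
    """

    coefficients: dict[str, np.ndarray]
    scaling: dict[str, tuple[float, float]]  # (centre, scale) per chromosome
    rmse: dict[str, float]
    markers: pd.DataFrame

    def evaluate(self, chrom: str, bp: np.ndarray) -> np.ndarray:
        if chrom not in self.coefficients:
            raise KeyError(f"no map for chromosome {chrom!r}")
        bp = np.asarray(bp, float)
        centre, scale = self.scaling[chrom]
        order = np.argsort(bp, kind="stable")
        raw = np.polyval(self.coefficients[chrom], (bp[order] - centre) / scale)
        iso = np.maximum.accumulate(raw)
        iso -= iso.min()
        out = np.empty_like(iso)
        out[order] = iso
        return out


def fit_genetic_map(markers: pd.DataFrame, degree: int = 3) -> GeneticMap:
    """Least-squares polynomial fit of cM on bp per chromosome.

    ``markers``: chrom, bp, cm. Requires degree + 1 markers per
    chromosome; a fit that evaluates to a constant over the marker span is
    rejected (the map must distinguish positions).
    """
    coeffs: dict[str, np.ndarray] = {}
    scaling: dict[str, tuple[float, float]] = {}
    rmse: dict[str, float] = {}
    for chrom, sub in markers.groupby("chrom"):
        bp = sub["bp"].to_numpy(float)
        cm = sub["cm"].to_numpy(float)
        if len(bp) < degree + 1:
            raise DataError(
                f"{chrom}: {len(bp)} markers cannot support degree {degree}")
        centre = float(bp.mean())
        scale = float(bp.std()) or 1.0  # centre/scale for conditioning
        x = (bp - centre) / scale
        c = np.polyfit(x, cm, degree)
        pred = np.maximum.accumulate(np.polyval(c, np.sort(x)))
        if np.ptp(pred) == 0:
            raise DataError(f"{chrom}: fitted map is constant (not monotone)")
        rmse[chrom] = float(np.sqrt(np.mean((np.polyval(c, x) - cm) ** 2)))
        coeffs[chrom] = c
        scaling[chrom] = (centre, scale)
    return GeneticMap(coefficients=coeffs, scaling=scaling, rmse=rmse,
                      markers=markers.copy())


# ---------------------------------------------------------------------------
# pairwise sharing


def sites_from_probes(genotypes: pd.DataFrame, probes) -> pd.DataFrame:
    """Site metadata (site, chrom, pos) for genotype rows that are probe
    ids of the given probe map."""
    pm = probes.df.set_index("probe_id")
    sub = pm.loc[genotypes.index]
    return pd.DataFrame({"site": genotypes.index, "chrom": sub["chrom"].to_numpy(),
                         "pos": sub["start"].to_numpy()})


@dataclass
class SharingData:
    """Precomputed pairwise sharing over a genotype panel.

    ``z``: (n_pairs, n_sites) shared-haplotype cM lengths; ``zstd``: the
    per-pair standardised version; ``pair_index``: accession-index matrix
    into the pair axis; ``cm``: genetic position per site.
    """

    genotypes: pd.DataFrame
    sites: pd.DataFrame
    cm: np.ndarray
    chrom_bounds: list[tuple[int, int]]
    pairs: np.ndarray           # (n_pairs, 2) accession indices, i < j
    pair_index: np.ndarray      # (n_acc, n_acc) -> pair axis position
    z: np.ndarray
    zstd: np.ndarray
    excluded_pairs: np.ndarray  # pairs with zero sharing variance

    @property
    def accessions(self) -> list[str]:
        return list(self.genotypes.columns)


def _pair_z_row(eq: np.ndarray, cm: np.ndarray,
                bounds: list[tuple[int, int]]) -> np.ndarray:
    """Per-site shared cM span for one accession pair (0 at mismatches)."""
    z = np.zeros(len(eq))
    for lo, hi in bounds:
        e = eq[lo:hi]
        if not e.any():
            continue
        edges = np.flatnonzero(np.diff(
            np.concatenate(([0], e.view(np.int8), [0]))))
        starts, ends = edges[::2], edges[1::2]
        vals = cm[lo + ends - 1] - cm[lo + starts]
        lengths = ends - starts
        offs = np.repeat(starts, lengths)
        within = np.arange(lengths.sum()) - np.repeat(
            np.cumsum(lengths) - lengths, lengths)
        z[lo + offs + within] = np.repeat(vals, lengths)
    return z


def compute_sharing(genotypes: pd.DataFrame, gmap: GeneticMap,
                    sites: pd.DataFrame) -> SharingData:
    """All-pairs haplotype sharing with genome-wide pair standardisation.

    Genotype rows must be position-sorted within chromosomes and aligned
    with ``sites``. Pairs whose sharing has zero variance across the site
    grid are excluded from Z with a warning.
    """
    if not genotypes.index.equals(pd.Index(sites["site"])):
        raise DataError("genotype rows and site metadata are misaligned")
    g = genotypes.to_numpy(np.int8)
    n_sites, n_acc = g.shape
    if n_acc < 2:
        raise DataError("sharing needs at least two accessions")
    cm = np.empty(n_sites)
    bounds: list[tuple[int, int]] = []
    pos = sites["pos"].to_numpy()
    chroms = sites["chrom"].to_numpy()
    lo = 0
    for i in range(1, n_sites + 1):
        if i == n_sites or chroms[i] != chroms[lo]:
            if (np.diff(pos[lo:i]) < 0).any():
                raise DataError("sites must be position-sorted per chromosome")
            cm[lo:i] = gmap.evaluate(chroms[lo], pos[lo:i])
            bounds.append((lo, i))
            lo = i
    pairs = np.array([(i, j) for i in range(n_acc) for j in range(i + 1, n_acc)])
    pair_index = np.full((n_acc, n_acc), -1, dtype=int)
    for k, (i, j) in enumerate(pairs):
        pair_index[i, j] = pair_index[j, i] = k
    z = np.empty((len(pairs), n_sites))
    for k, (i, j) in enumerate(pairs):
        z[k] = _pair_z_row(g[:, i] == g[:, j], cm, bounds)
    mean = z.mean(axis=1, keepdims=True)
    sd = z.std(axis=1, ddof=1, keepdims=True)
    excluded = (sd[:, 0] == 0)
    if excluded.any():
        warnings.warn(f"{int(excluded.sum())} pair(s) with zero sharing "
                      "variance excluded from PHS", stacklevel=2)
    safe_sd = np.where(sd == 0, 1.0, sd)
    zstd = (z - mean) / safe_sd
    zstd[excluded] = np.nan
    return SharingData(genotypes=genotypes, sites=sites, cm=cm,
                       chrom_bounds=bounds, pairs=pairs, pair_index=pair_index,
                       z=z, zstd=zstd, excluded_pairs=excluded)


def sharing_length(data: SharingData, i: int, j: int, x: int) -> float:
    """cM length of the identical interval around site ``x`` for accession
    indices i, j; zero when they differ at x itself."""
    if i == j:
        raise ValueError("sharing is defined for distinct accessions")
    return float(data.z[data.pair_index[i, j], x])


def _carrier_pair_ids(data: SharingData, carriers: np.ndarray) -> np.ndarray:
    a, b = np.triu_indices(len(carriers), k=1)
    return data.pair_index[carriers[a], carriers[b]]


def phs(data: SharingData, x: int, allele: int,
        form: str = "difference") -> float:
    """Raw PHS of ``allele`` at site index ``x``.

    ``difference``: mean Z over carrier pairs minus mean over all pairs;
    ``single``: the carrier-pair mean alone.
    """
    g = data.genotypes.to_numpy(np.int8)
    carriers = np.flatnonzero(g[x] == allele)
    if len(carriers) < 2:
        raise DataError("PHS needs at least two carriers of the allele")
    ids = _carrier_pair_ids(data, carriers)
    carrier_mean = float(np.nanmean(data.zstd[ids, x]))
    if form == "single":
        return carrier_mean
    if form != "difference":
        raise ValueError(f"unknown PHS form: {form!r}")
    return carrier_mean - float(np.nanmean(data.zstd[:, x]))


def _carrier_pair_stats(data: SharingData, values: np.ndarray,
                        chunk: int = 512) -> dict[int, np.ndarray]:
    """Mean of a (pairs x sites) value matrix over carrier pairs of each
    allele at each site, computed chunk-wise via quadratic forms.

    Returns {allele: (mean per site, n carrier pairs per site)} stacked as
    a (2, n_sites) array tuple.
    """
    g = data.genotypes.to_numpy(np.int8)
    n_sites, n_acc = g.shape
    i_idx, j_idx = data.pairs[:, 0], data.pairs[:, 1]
    valid = ~data.excluded_pairs
    vals = np.where(np.isnan(values), 0.0, values)
    out: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    for allele in (0, 1):
        sums = np.empty(n_sites)
        counts = np.empty(n_sites)
        for lo in range(0, n_sites, chunk):
            hi = min(lo + chunk, n_sites)
            u = (g[lo:hi] == allele).astype(float)          # (c, n_acc)
            ui, uj = u[:, i_idx], u[:, j_idx]
            both = ui * uj                                   # (c, n_pairs)
            sums[lo:hi] = np.einsum("cp,pc->c", both,
                                    np.ascontiguousarray(vals[:, lo:hi]))
            counts[lo:hi] = both @ valid.astype(float)
        out[allele] = (np.divide(sums, counts, out=np.full(n_sites, np.nan),
                                 where=counts > 0), counts)
    return out


def phs_scan(data: SharingData, min_maf: float = 0.05,
             form: str = "difference") -> pd.DataFrame:
    """Raw PHS for each allele of every site with MAF >= ``min_maf``.

    Also records each allele's mean carrier-pair sharing in cM, used to
    pick the selected (longer-haplotype) allele downstream.
    """
    g = data.genotypes.to_numpy(np.int8)
    n_sites, n_acc = g.shape
    all_mean = np.nanmean(data.zstd, axis=0)
    pos = data.sites["pos"].to_numpy()
    chroms = data.sites["chrom"].to_numpy()
    zstats = _carrier_pair_stats(data, data.zstd)
    cmstats = _carrier_pair_stats(data, data.z)
    freq1 = g.mean(axis=1)
    maf_ok = np.minimum(freq1, 1 - freq1) >= min_maf
    rows = []
    for allele in (0, 1):
        mean_z, counts = zstats[allele]
        mean_cm, _ = cmstats[allele]
        keep = maf_ok & (counts >= 1) & ~np.isnan(mean_z)
        raw = mean_z if form == "single" else mean_z - all_mean
        n_car = (g == allele).sum(axis=1)
        for x in np.flatnonzero(keep):
            rows.append({
                "site": data.genotypes.index[x], "site_idx": int(x),
                "chrom": chroms[x], "pos": int(pos[x]), "allele": allele,
                "carriers": int(n_car[x]),
                "freq": n_car[x] / n_acc,
                "raw_phs": float(raw[x]),
                "mean_sharing_cm": float(mean_cm[x]),
            })
    return (pd.DataFrame(rows)
            .sort_values(["site_idx", "allele"], ignore_index=True))


# ---------------------------------------------------------------------------
# standardisation, pruning, windows


def standardize_scores(scores: pd.DataFrame, min_class: int = 20,
                       freq_bin: float = 0.05) -> pd.DataFrame:
    """Standardise raw PHS within allele-frequency classes.

    standardized = (raw - median_f) / SD_f (sample SD). Classes are exact
    carrier counts when each holds >= ``min_class`` scores; sparser counts
    fall back to frequency bins of width ``freq_bin``. Degenerate classes
    (SD 0 or a single member) standardise to 0 with a warning.
    """
    out = scores.copy()
    counts = out["carriers"].value_counts()
    use_exact = set(counts.index[counts >= min_class])
    keys = np.where(out["carriers"].isin(use_exact),
                    "c" + out["carriers"].astype(str),
                    "f" + np.floor(out["freq"] / freq_bin).astype(int).astype(str))
    std = np.zeros(len(out))
    degenerate = 0
    for key in pd.unique(keys):
        sel = keys == key
        vals = out.loc[sel, "raw_phs"].to_numpy(float)
        if len(vals) < 2 or np.std(vals, ddof=1) == 0:
            degenerate += int(sel.sum())
            continue
        std[sel] = (vals - np.median(vals)) / np.std(vals, ddof=1)
    if degenerate:
        warnings.warn(f"{degenerate} score(s) in degenerate frequency "
                      "classes standardised to 0", stacklevel=2)
    out["standardized"] = std
    return out


def site_scores(scored: pd.DataFrame) -> pd.DataFrame:
    """One row per site: the higher-standardised allele represents the
    site in pruning and windowing."""
    idx = scored.groupby("site_idx")["standardized"].idxmax()
    out = scored.loc[idx].sort_values(["chrom", "pos"], ignore_index=True)
    return out


def ld_prune(scores: pd.DataFrame, genotypes: pd.DataFrame,
             r2_max: float = 0.5) -> pd.DataFrame:
    """Drop the lower-scoring site of neighbouring pairs in strong positive
    LD (r^2 > ``r2_max`` and r > 0), repeated until no retained adjacent
    pair qualifies. Neighbours are adjacent retained sites in position
    order within a chromosome.
    """
    g = genotypes.to_numpy(float)
    out_parts = []
    for chrom, sub in scores.groupby("chrom", sort=False):
        sub = sub.sort_values("pos")
        idx = list(sub.index)
        site_pos = {i: sub.at[i, "site_idx"] for i in idx}
        changed = True
        while changed and len(idx) > 1:
            changed = False
            k = 0
            while k < len(idx) - 1:
                a, b = idx[k], idx[k + 1]
                ga, gb = g[site_pos[a]], g[site_pos[b]]
                if ga.std() == 0 or gb.std() == 0:
                    k += 1
                    continue
                r = float(np.corrcoef(ga, gb)[0, 1])
                if r > 0 and r * r > r2_max:
                    drop = a if sub.at[a, "standardized"] <= sub.at[b, "standardized"] else b
                    idx.remove(drop)
                    changed = True
                else:
                    k += 1
        out_parts.append(sub.loc[idx])
    return pd.concat(out_parts).sort_values(["chrom", "pos"], ignore_index=True)


@dataclass
class SweepRegion:
    """Candidate sweep: merged super-threshold windows with a focal SFP."""

    name: str
    chrom: str
    start: int
    end: int
    focal_site: str
    focal_pos: int
    selected_allele: int
    n_sites: int
    max_score: float
    sharing_from: int | None = None
    sharing_to: int | None = None
    sharing_length: int | None = None

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise DataError("region end must exceed start")
        if not self.start <= self.focal_pos <= self.end:
            raise DataError("focal SFP must lie inside the region")


def window_scan(scores: pd.DataFrame, window: int = 1000, offset: int = 50,
                outlier_quantile: float = 0.005,
                min_proportion: float = 0.45) -> list[SweepRegion]:
    """Sliding-window outlier-density scan over pruned per-site scores.

    An outlier is a standardized score in the top ``outlier_quantile``
    genome-wide. Windows of ``window`` SFPs advance by ``offset`` SFPs;
    windows with outlier proportion strictly above ``min_proportion``
    become candidates, and overlapping candidate windows merge into one
    region bounded by its first/last SFP. The focal SFP is the region's
    highest standardized score.
    """
    if window > len(scores):
        raise ConfigError(
            f"window of {window} SFPs exceeds the {len(scores)} available")
    thr = np.quantile(scores["standardized"].to_numpy(float),
                      1.0 - outlier_quantile)
    outlier = scores["standardized"].to_numpy(float) >= thr
    regions: list[SweepRegion] = []
    offset_base = 0
    for chrom, sub in scores.groupby("chrom", sort=False):
        sub = sub.sort_values("pos")
        flags = outlier[sub.index.to_numpy()]
        n = len(sub)
        spans: list[tuple[int, int]] = []
        for s in range(0, n - window + 1, offset):
            prop = flags[s:s + window].mean()
            if prop > min_proportion:
                if spans and s <= spans[-1][1]:
                    spans[-1] = (spans[-1][0], s + window)
                else:
                    spans.append((s, s + window))
        for s, e in spans:
            block = sub.iloc[s:e]
            focal = block.loc[block["standardized"].idxmax()]
            regions.append(SweepRegion(
                name="", chrom=chrom,
                start=int(block["pos"].min()), end=int(block["pos"].max()),
                focal_site=str(focal["site"]), focal_pos=int(focal["pos"]),
                selected_allele=int(focal["allele"]),
                n_sites=len(block), max_score=float(focal["standardized"])))
        offset_base += n
    regions.sort(key=lambda r: (r.chrom, r.start))
    return [replace(r, name=f"SR{i + 1}") for i, r in enumerate(regions)]


# ---------------------------------------------------------------------------
# region descriptors


def avg_sharing_interval(region: SweepRegion, data: SharingData) -> SweepRegion:
    """Mean shared interval (bp) around the focal SFP over carrier pairs of
    the selected allele: from/to are the averaged run endpoints, length
    their difference."""
    x = int(np.flatnonzero(data.genotypes.index == region.focal_site)[0])
    g = data.genotypes.to_numpy(np.int8)
    carriers = np.flatnonzero(g[x] == region.selected_allele)
    if len(carriers) < 2:
        raise DataError("selected allele has fewer than two carriers")
    lo, hi = next(b for b in data.chrom_bounds if b[0] <= x < b[1])
    pos = data.sites["pos"].to_numpy()
    lefts, rights = [], []
    a_idx, b_idx = np.triu_indices(len(carriers), k=1)
    for a, b in zip(carriers[a_idx], carriers[b_idx]):
        eq = g[lo:hi, a] == g[lo:hi, b]
        xi = x - lo
        if not eq[xi]:
            lefts.append(pos[x])
            rights.append(pos[x])
            continue
        s = xi
        while s > 0 and eq[s - 1]:
            s -= 1
        t = xi
        while t < len(eq) - 1 and eq[t + 1]:
            t += 1
        lefts.append(pos[lo + s])
        rights.append(pos[lo + t])
    frm, to = int(round(np.mean(lefts))), int(round(np.mean(rights)))
    return replace(region, sharing_from=frm, sharing_to=to,
                   sharing_length=to - frm)


def haversine_km(lat1, lon1, lat2, lon2) -> np.ndarray:
    """Great-circle distance on a spherical Earth (radius 6371 km)."""
    lat1, lon1, lat2, lon2 = map(np.radians, (lat1, lon1, lat2, lon2))
    dlat, dlon = lat2 - lat1, lon2 - lon1
    a = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(a))


def _pair_distances(lat: np.ndarray, lon: np.ndarray,
                    members: np.ndarray) -> np.ndarray:
    a, b = np.triu_indices(len(members), k=1)
    return haversine_km(lat[members[a]], lon[members[a]],
                        lat[members[b]], lon[members[b]])


def geographic_clustering(carriers: list[str], geo: pd.DataFrame,
                          n_shuffles: int = 10000, seed: int = 0,
                          mode: str = "pooled") -> float:
    """One-sided Mann-Whitney p for geographic clustering of carriers.

    Observed: haversine distances among carrier pairs. Null: the same
    statistic under random reassignment of the carrier labels across
    accessions. ``pooled`` compares observed pair distances against the
    pooled shuffled distances; ``means`` compares the observed mean against
    the per-shuffle means. Deterministic given ``seed``.
    """
    gidx = geo.set_index("accession")
    missing = [c for c in carriers if c not in gidx.index]
    if missing:
        raise DataError(f"no coordinates for carriers: {missing[:3]}")
    if len(carriers) < 2:
        warnings.warn("fewer than two carriers; geographic test skipped",
                      stacklevel=2)
        return float("nan")
    lat = gidx["lat"].to_numpy(float)
    lon = gidx["lon"].to_numpy(float)
    members = np.array([gidx.index.get_loc(c) for c in carriers])
    observed = _pair_distances(lat, lon, members)
    rng = np.random.default_rng(seed)
    n_acc = len(gidx)
    if mode == "pooled":
        null = np.concatenate([
            _pair_distances(lat, lon, rng.choice(n_acc, len(carriers), replace=False))
            for _ in range(n_shuffles)])
        return float(stats.mannwhitneyu(observed, null,
                                        alternative="less").pvalue)
    if mode == "means":
        means = np.array([
            _pair_distances(lat, lon, rng.choice(n_acc, len(carriers), replace=False)).mean()
            for _ in range(n_shuffles)])
        return float(stats.mannwhitneyu([observed.mean()], means,
                                        alternative="less").pvalue)
    raise ValueError(f"unknown mode: {mode!r}")


def sweep_trait_association(regions: list[SweepRegion],
                            genotypes: pd.DataFrame,
                            phenotypes: pd.DataFrame,
                            q: pd.DataFrame | None = None,
                            scan_fits: pd.DataFrame | None = None) -> dict:
    """GLM association of focal SFPs only, plus the within-vs-outside
    sweep F-score shift.

    Returns {"table": region x trait fits with empirical p against the
    genome scan when ``scan_fits`` is given, "shift_p": one-sided
    Mann-Whitney p that in-sweep marker F-scores exceed outside scores}.
    """
    from .association import fit_glm, SingularDesignError

    traits = [c for c in phenotypes.columns
              if c not in ("accession", "experiment")]
    acc = phenotypes["accession"]
    env = phenotypes["experiment"] if phenotypes["experiment"].nunique() > 1 else None
    qrec = q.loc[acc].reset_index(drop=True) if q is not None else None
    pool = scan_fits["fscore"].to_numpy(float) if scan_fits is not None else None
    rows = []
    for region in regions:
        gsite = genotypes.loc[region.focal_site]
        marker = pd.Series(gsite.loc[acc].to_numpy(float), index=phenotypes.index)
        for trait in traits:
            try:
                fit = fit_glm(phenotypes[trait], marker, qrec, env,
                              site=region.focal_site, trait_name=trait)
            except SingularDesignError:
                continue
            emp = (float((pool >= fit.fscore).mean()) if pool is not None
                   and len(pool) else np.nan)
            rows.append({"region": region.name, "trait": trait,
                         "site": region.focal_site, "fscore": fit.fscore,
                         "empirical_p": emp,
                         "lsmean_ref": fit.lsmeans.get(0, np.nan),
                         "lsmean_sfp": fit.lsmeans.get(1, np.nan)})
    table = pd.DataFrame(rows, columns=["region", "trait", "site", "fscore",
                                        "empirical_p", "lsmean_ref",
                                        "lsmean_sfp"])
    shift_p = np.nan
    if scan_fits is not None and len(regions) and {"chrom", "pos"}.issubset(scan_fits.columns):
        inside = np.zeros(len(scan_fits), bool)
        for r in regions:
            inside |= ((scan_fits["chrom"] == r.chrom)
                       & (scan_fits["pos"] >= r.start)
                       & (scan_fits["pos"] <= r.end)).to_numpy()
        if inside.any() and not inside.all():
            shift_p = float(stats.mannwhitneyu(
                scan_fits.loc[inside, "fscore"],
                scan_fits.loc[~inside, "fscore"],
                alternative="greater").pvalue)
    return {"table": table, "shift_p": shift_p}


REGION_COLUMNS = ["name", "chr", "focal_position", "from", "to",
                  "length_avg_haplotype_sharing", "region_start",
                  "region_end", "selected_allele", "n_sites", "max_score"]


def regions_to_frame(regions: list[SweepRegion]) -> pd.DataFrame:
    """Sweep-region table with the published column layout."""
    if not regions:
        return pd.DataFrame(columns=REGION_COLUMNS)
    return pd.DataFrame([{
        "name": r.name, "chr": r.chrom, "focal_position": r.focal_pos,
        "from": r.sharing_from, "to": r.sharing_to,
        "length_avg_haplotype_sharing": r.sharing_length,
        "region_start": r.start, "region_end": r.end,
        "selected_allele": r.selected_allele, "n_sites": r.n_sites,
        "max_score": r.max_score,
    } for r in regions])
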