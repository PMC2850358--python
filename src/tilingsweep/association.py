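"""GLM marker-trait association with population-structure covariates.

The model is v ~ intercept + M + Env + Q + E: v the trait (one record
per accession per experiment), M the biallelic marker (0 reference-like,
1 SFP), Env the experiment factor, Q admixture-proportion covariates
(last column dropped, rows sum to one), E Gaussian error. The marker is
tested with a partial F comparing the model with and without M; p-values
are empirical ranks of F in the pooled scan distribution, and the scan
FDR is estimated as expected-random / observed significant. Pathway
over-representation uses Mann-Whitney U on F-scores with
Benjamini-Hochberg correction, and gene-metabolite connections are
scored as minimum reaction paths in the metabolic network with currency
metabolites removed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .types import DataError, MetabolicNetwork

DEFAULT_MIN_MAF = 0.05


class SingularDesignError(DataError):
    """Design matrix is rank-deficient after assembling covariates."""


def maf_filter(genotypes: pd.DataFrame, min_maf: float = DEFAULT_MIN_MAF) -> pd.DataFrame:
    """Keep sites (rows) with minor allele frequency >= ``min_maf``.

    MAF = min(mean, 1 - mean) over accessions; monomorphic sites are
    dropped at any positive threshold.
    """
    if not 0.0 <= min_maf <= 0.5:
        raise ValueError("min_maf must lie in [0, 0.5]")
    freq = genotypes.mean(axis=1)
    maf = np.minimum(freq, 1.0 - freq)
    keep = maf >= min_maf if min_maf > 0 else maf > 0
    return genotypes.loc[keep]


@dataclass
class GlmFit:
    """Marker term of one site x trait fit."""

    site: str
    trait: str
    fscore: float
    residual_df: int
    lsmeans: dict[int, float]          # genotype class -> adjusted mean
    empirical_p: float | None = None
    marker_df: int = 1
    model_p: float = field(default=np.nan)  # parametric F-test p, for reference

    @property
    def lsmeans_contrast(self) -> float | None:
        """non-reference minus reference adjusted mean, when both classes
        are observed."""
        if 0 in self.lsmeans and 1 in self.lsmeans:
            return self.lsmeans[1] - self.lsmeans[0]
        return None


def _design(marker: np.ndarray, env: np.ndarray | None,
            q: np.ndarray | None) -> tuple[np.ndarray, list[str]]:
    """Assemble [intercept | Env dummies | Q (last col dropped) | M]."""
    n = len(marker)
    cols = [np.ones(n)]
    names = ["intercept"]
    if env is not None:
        levels = sorted(pd.unique(env))
        for lev in levels[1:]:
            cols.append((env == lev).astype(float))
            names.append(f"env[{lev}]")
    if q is not None and q.shape[1] > 1:
        for j in range(q.shape[1] - 1):
            cols.append(q[:, j])
            names.append(f"Q{j + 1}")
    cols.append(marker.astype(float))
    names.append("marker")
    return np.column_stack(cols), names


def _ssr(x: np.ndarray, y: np.ndarray) -> float:
    """Residual sum of squares of OLS y ~ x."""
    beta, _, _, _ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    return float(resid @ resid)


def fit_glm(trait: pd.Series, marker: pd.Series,
            q: pd.DataFrame | None = None,
            env: pd.Series | None = None,
            site: str = "", trait_name: str = "") -> GlmFit:
    """Partial-F marker test of v ~ intercept + M + Env + Q.

    Inputs are positionally aligned, one row per accession-experiment
    record; callers expand ``q`` from per-accession to per-record rows
    before fitting (see :func:`association_scan`).
    """
    y = trait.to_numpy(float)
    m = marker.to_numpy(float)
    if len(np.unique(m)) < 2:
        raise SingularDesignError("marker is monomorphic in the fitted sample")
    for g in np.unique(m):
        if (m == g).sum() < 2:
            raise SingularDesignError(
                f"marker class {g:g} observed fewer than twice")
    envv = env.to_numpy() if env is not None else None
    qv = q.to_numpy(float) if q is not None else None
    x_full, names = _design(m, envv, qv)
    rank = np.linalg.matrix_rank(x_full)
    if rank < x_full.shape[1]:
        # name the collinear columns for the error message
        bad = []
        for j in range(x_full.shape[1]):
            others = np.delete(x_full, j, axis=1)
            if np.linalg.matrix_rank(others) == rank:
                bad.append(names[j])
        raise SingularDesignError(f"design is rank deficient; collinear: {bad}")
    x_red = x_full[:, :-1]
    ssr_full = _ssr(x_full, y)
    ssr_red = _ssr(x_red, y)
    df_resid = len(y) - x_full.shape[1]
    if df_resid <= 0:
        raise SingularDesignError("no residual degrees of freedom")
    mse = ssr_full / df_resid
    if mse > 0:
        f = max(float((ssr_red - ssr_full) / 1.0 / mse), 0.0)
    else:
        # perfect fit: the marker term is infinitely supported unless the
        # reduced model also fits perfectly
        f = float("inf") if ssr_red > ssr_full + 1e-30 else 0.0
    model_p = float(stats.f.sf(f, 1, df_resid)) if np.isfinite(f) else 0.0
    # lsmeans: model-adjusted class means with covariates at their averages
    beta, _, _, _ = np.linalg.lstsq(x_full, y, rcond=None)
    base = x_full.mean(axis=0)
    lsmeans = {}
    for g in (0, 1):
        if (m == g).any():
            row = base.copy()
            row[-1] = float(g)
            lsmeans[g] = float(row @ beta)
    return GlmFit(site=site, trait=trait_name, fscore=f, residual_df=df_resid,
                  lsmeans=lsmeans, model_p=model_p)


def association_scan(genotypes: pd.DataFrame, phenotypes: pd.DataFrame,
                     q: pd.DataFrame | None = None,
                     traits: list[str] | None = None,
                     min_maf: float = DEFAULT_MIN_MAF) -> pd.DataFrame:
    """Fit every (site, trait) pair and attach pooled empirical p-values.

    ``phenotypes``: long frame with accession, experiment and one column
    per trait; the Env factor is the experiment column (dropped
    automatically when only one experiment is present). Returns a frame
    with site, trait, fscore, empirical_p, lsmean_ref, lsmean_sfp.
    """
    geno = maf_filter(genotypes, min_maf)
    if traits is None:
        traits = [c for c in phenotypes.columns
                  if c not in ("accession", "experiment")]
    acc = phenotypes["accession"]
    env = phenotypes["experiment"] if phenotypes["experiment"].nunique() > 1 else None
    qrec = q.loc[acc].reset_index(drop=True) if q is not None else None
    rows = []
    for site in geno.index:
        g = geno.loc[site]
        marker = pd.Series(g.loc[acc].to_numpy(float), index=phenotypes.index)
        for trait in traits:
            try:
                fit = fit_glm(phenotypes[trait], marker, qrec, env,
                              site=site, trait_name=trait)
            except SingularDesignError:
                continue
            rows.append({"site": site, "trait": trait, "fscore": fit.fscore,
                         "lsmean_ref": fit.lsmeans.get(0, np.nan),
                         "lsmean_sfp": fit.lsmeans.get(1, np.nan)})
    out = pd.DataFrame(rows)
    if len(out):
        out["empirical_p"] = empirical_pvalues(out["fscore"].to_numpy())
    return out


def empirical_pvalues(fscores: np.ndarray) -> np.ndarray:
    """p(score) = fraction of pooled scan scores >= score (rank p, in
    (0, 1]; the score itself counts, so the maximum gets 1/N)."""
    f = np.asarray(fscores, float)
    if f.size == 0:
        raise DataError("empirical p-values need at least one score")
    order = np.argsort(f, kind="stable")
    # count >= via descending rank with ties sharing the largest count
    sorted_f = f[order]
    ge_counts = f.size - np.searchsorted(sorted_f, f, side="left")
    return ge_counts / f.size


def estimate_fdr(n_sites: int, n_traits: int, alpha: float,
                 n_significant: int) -> float:
    """Scan-level FDR percentage: 100 x (n_sites x n_traits x alpha) /
    n_significant, capped at 100."""
    if n_significant <= 0:
        raise ValueError("n_significant must be positive")
    expected = n_sites * n_traits * alpha
    fdr = 100.0 * expected / n_significant
    if fdr > 100.0:
        warnings.warn("estimated FDR exceeds 100%; capped", stacklevel=2)
        return 100.0
    return fdr


# ---------------------------------------------------------------------------
# pathway analysis


def pathway_overrepresentation(fits: pd.DataFrame, site_genes: pd.Series,
                               network: MetabolicNetwork,
                               tested_pathways: list[str],
                               trait: str | None = None,
                               alpha: float = 0.01) -> pd.DataFrame:
    """One-sided Mann-Whitney U per pathway: F-scores of SFPs in the
    pathway's genes vs F-scores of SFPs in all remaining metabolic genes,
    BH-adjusted over the tested pathways.

    ``site_genes``: site -> gene_id mapping for metabolic SFPs.
    """
    sub = fits if trait is None else fits[fits["trait"] == trait]
    sub = sub[sub["site"].isin(site_genes.index)]
    genes = site_genes.loc[sub["site"]].to_numpy()
    pathways = np.array([network.gene_pathway.get(g, "") for g in genes])
    scores = sub["fscore"].to_numpy(float)
    rows = []
    for pwy in tested_pathways:
        inset = pathways == pwy
        if not inset.any():
            warnings.warn(f"pathway {pwy}: no SFP-bearing genes; skipped",
                          stacklevel=2)
            continue
        if inset.all():
            warnings.warn(f"pathway {pwy}: empty comparison group; skipped",
                          stacklevel=2)
            continue
        u, p = stats.mannwhitneyu(scores[inset], scores[~inset],
                                  alternative="greater")
        rows.append({"pathway": pwy, "n_in": int(inset.sum()),
                     "n_out": int((~inset).sum()), "u": float(u),
                     "p": float(p)})
    out = pd.DataFrame(rows, columns=["pathway", "n_in", "n_out", "u", "p"])
    if len(out):
        out["p_bh"] = multipletests(out["p"], method="fdr_bh")[1]
        out["significant"] = out["p_bh"] <= alpha
    return out


def geneset_score_shift(fits: pd.DataFrame, in_set: np.ndarray) -> float:
    """Two-sided Mann-Whitney p for F-scores of a gene set vs complement."""
    scores = fits["fscore"].to_numpy(float)
    in_set = np.asarray(in_set, bool)
    if not in_set.any() or in_set.all():
        raise DataError("both the set and its complement must be non-empty")
    a, b = scores[in_set], scores[~in_set]
    if len(a) == 1 and len(b) == 1 and a[0] == b[0]:
        return 1.0
    return float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)


# ---------------------------------------------------------------------------
# metabolic paths


def _network_graph(network: MetabolicNetwork) -> nx.Graph:
    """Undirected bipartite reaction-compound graph with currency
    compounds removed as traversal nodes."""
    g = nx.Graph()
    for _, row in network.reactions.iterrows():
        rid = ("rx", row["reaction_id"])
        g.add_node(rid)
        for comp in (*row["substrates"], *row["products"]):
            if comp in network.currency:
                continue
            g.add_edge(rid, ("cp", comp))
    return g


def min_metabolic_path(gene: str, metabolite: str,
                       network: MetabolicNetwork) -> int | None:
    """Shortest reaction count linking a gene's reactions to a metabolite.

    Distance 1 means the metabolite takes part in one of the gene's own
    reactions; each further reaction on the chain adds 1. Currency
    compounds never serve as intermediates. Returns None when unreachable.
    """
    if gene not in network.gene_reactions:
        raise KeyError(f"gene not annotated in network: {gene!r}")
    g = _network_graph(network)
    target = ("cp", metabolite)
    if metabolite in network.currency or target not in g:
        known = metabolite in network.currency or any(
            metabolite in (*row["substrates"], *row["products"])
            for _, row in network.reactions.iterrows())
        if not known:
            raise KeyError(f"unknown metabolite: {metabolite!r}")
        return None
    best: int | None = None
    for rx in network.gene_reactions[gene]:
        src = ("rx", rx)
        if src not in g:
            continue
        try:
            edges = nx.shortest_path_length(g, src, target)
        except nx.NetworkXNoPath:
            continue
        hops = (edges + 1) // 2  # reaction-compound alternation
        if best is None or hops < best:
            best = hops
    return best


def density_fscore_correlation(fits: pd.DataFrame, sites: pd.DataFrame,
                               gene_intervals: pd.DataFrame,
                               chrom_bp: dict[str, int],
                               window: int) -> pd.DataFrame:
    """Spearman correlation of windowed summed F-scores vs metabolic-gene
    bp density, per chromosome.

    ``sites``: site, chrom, pos for every fitted site. ``gene_intervals``:
    metabolic gene intervals (chrom, start, end). Windows tile each
    chromosome at ``window`` bp; chromosomes with under 3 windows or
    constant vectors report NaN.
    """
    merged = fits.merge(sites, on="site")
    rows = []
    for chrom, limit in chrom_bp.items():
        n_win = int(np.ceil(limit / window))
        if n_win < 3:
            rows.append({"chrom": chrom, "rho": np.nan, "p": np.nan,
                         "n_windows": n_win})
            continue
        fsum = np.zeros(n_win)
        sub = merged[merged["chrom"] == chrom]
        if len(sub):
            idx = (sub["pos"].to_numpy() // window).astype(int)
            np.add.at(fsum, idx, sub["fscore"].to_numpy(float))
        dens = np.zeros(n_win)
        for _, gi in gene_intervals[gene_intervals["chrom"] == chrom].iterrows():
            lo, hi = int(gi["start"]), int(gi["end"])
            for w in range(lo // window, min(hi // window + 1, n_win)):
                ov = min(hi, (w + 1) * window) - max(lo, w * window)
                if ov > 0:
                    dens[w] += ov
        if np.ptp(fsum) == 0 or np.ptp(dens) == 0:
            rows.append({"chrom": chrom, "rho": np.nan, "p": np.nan,
                         "n_windows": n_win})
            continue
        rho, p = stats.spearmanr(fsum, dens)
        rows.append({"chrom": chrom, "rho": float(rho), "p": float(p),
                     "n_windows": n_win})
    return pd.DataFrame(rows)
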