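"""SFP enrichment and depletion in genomic feature classes and families.

The null model distributes SFPs proportionally to the total bp of each
feature class: expected(class) = total_sfps x class_bp / genome_bp.
Departures are tested either with a 2-cell chi-squared goodness of fit on
(in-class, out-of-class) counts, or with an unpaired t-test across
per-accession observed-vs-expected count pairs when per-accession counts
are available. A site overlapping several features counts toward every
overlapping class; class bp is computed on the union of that class's
intervals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .types import DataError

INTERGENIC = "intergenic"


@dataclass
class FeatureIndex:
    """Interval index over an annotation frame (chrom, start, end, klass,
    gene_id, family), plus per-class union bp."""

    annotation: pd.DataFrame
    trees: dict[str, IntervalTree]
    chrom_bp: dict[str, int]

    @classmethod
    def build(cls, annotation: pd.DataFrame,
              chrom_bp: dict[str, int]) -> "FeatureIndex":
        trees: dict[str, IntervalTree] = {}
        for chrom, sub in annotation.groupby("chrom"):
            tree = IntervalTree()
            for _, row in sub.iterrows():
                if row["end"] > row["start"]:
                    tree.addi(row["start"], row["end"], (
                        row["klass"], row.get("gene_id", ""), row.get("family", "")))
            trees[chrom] = tree
        for chrom, sub in annotation.groupby("chrom"):
            if chrom in chrom_bp and int(sub["end"].max()) > chrom_bp[chrom]:
                raise DataError(f"annotation exceeds {chrom} bounds")
        return cls(annotation=annotation, trees=trees, chrom_bp=dict(chrom_bp))

    def class_bp(self) -> pd.Series:
        """Union bp per class (overlaps within a class merged)."""
        out: dict[str, int] = {}
        for klass, sub in self.annotation.groupby("klass"):
            total = 0
            for _, csub in sub.groupby("chrom"):
                tree = IntervalTree.from_tuples(
                    (s, e) for s, e in zip(csub["start"], csub["end"]) if e > s)
                tree.merge_overlaps()
                total += sum(iv.end - iv.begin for iv in tree)
            out[klass] = total
        out[INTERGENIC] = max(self.genome_bp() - self._covered_bp(), 0)
        return pd.Series(out, name="class_bp").sort_index()

    def _covered_bp(self) -> int:
        total = 0
        for tree in self.trees.values():
            merged = IntervalTree(tree)
            merged.merge_overlaps(strict=False)
            total += sum(iv.end - iv.begin for iv in merged)
        return total

    def genome_bp(self) -> int:
        return sum(self.chrom_bp.values())


def map_sites_to_features(sites: pd.DataFrame, index: FeatureIndex) -> pd.DataFrame:
    """Assign every overlapping (class, gene, family) to each site.

    ``sites``: frame with chrom and pos (0-based bp). Positions in no
    feature map to the intergenic class; positions beyond the chromosome
    end raise a coordinate error. Returns one row per (site, hit).
    """
    rows = []
    for i, (chrom, pos) in enumerate(zip(sites["chrom"], sites["pos"])):
        limit = index.chrom_bp.get(chrom)
        if limit is not None and pos >= limit:
            raise DataError(f"site {chrom}:{pos} beyond chromosome end")
        hits = index.trees.get(chrom, IntervalTree())[pos]
        if not hits:
            rows.append((i, chrom, pos, INTERGENIC, "", ""))
        else:
            for iv in sorted(hits):
                klass, gene, family = iv.data
                rows.append((i, chrom, pos, klass, gene, family))
    return pd.DataFrame(rows, columns=["site_idx", "chrom", "pos", "klass",
                                       "gene_id", "family"])


def expected_counts(total_sfps: int, class_bp: pd.Series,
                    genome_bp: int) -> pd.Series:
    """Length-proportional expectation per class."""
    if genome_bp <= 0:
        raise DataError("genome_bp must be positive")
    if (class_bp > genome_bp).any():
        raise DataError("class bp exceeds genome bp")
    return total_sfps * class_bp / genome_bp


def test_enrichment(observed: float, expected: float, total: int,
                    method: str = "chi2",
                    per_accession: pd.DataFrame | None = None) -> dict:
    """One class's enrichment row.

    ``chi2``: 2-cell goodness of fit on (in-class, out-of-class) counts,
    df = 1. ``t_across_accessions``: unpaired t between per-accession
    observed and expected columns of ``per_accession``. Direction from the
    sign of observed - expected.
    """
    if expected <= 0:
        raise DataError("expected count must be positive for testing")
    if total < observed:
        raise DataError("total SFPs smaller than the in-class observation")
    direction = "enriched" if observed > expected else (
        "depleted" if observed < expected else "none")
    if method == "chi2":
        obs = np.array([observed, total - observed], float)
        exp = np.array([expected, total - expected], float)
        stat = float(((obs - exp) ** 2 / exp).sum())
        p = float(stats.chi2.sf(stat, df=1)) if stat > 0 else 1.0
    elif method == "t_across_accessions":
        if per_accession is None:
            raise ValueError("t method requires per-accession counts")
        res = stats.ttest_ind(per_accession["observed"],
                              per_accession["expected"])
        stat, p = float(res.statistic), float(res.pvalue)
    else:
        raise ValueError(f"unknown method: {method!r}")
    return {"observed": observed, "expected": expected, "statistic": stat,
            "p": p, "direction": direction}


def class_enrichment_table(site_hits: pd.DataFrame, index: FeatureIndex,
                           method: str = "chi2",
                           per_accession_hits: pd.DataFrame | None = None) -> pd.DataFrame:
    """Enrichment rows for every class with nonzero bp, BH-adjusted.

    ``site_hits``: output of :func:`map_sites_to_features` over all SFP
    sites. Total SFPs = number of distinct sites.
    """
    class_bp = index.class_bp()
    class_bp = class_bp[class_bp > 0]
    total = site_hits["site_idx"].nunique()
    expected = expected_counts(total, class_bp, index.genome_bp())
    observed = (site_hits.drop_duplicates(["site_idx", "klass"])
                .groupby("klass").size())
    rows = []
    for klass in class_bp.index:
        obs = int(observed.get(klass, 0))
        per_acc = None
        if method == "t_across_accessions" and per_accession_hits is not None:
            frac = class_bp[klass] / index.genome_bp()
            pa = per_accession_hits.copy()
            pa["expected"] = pa["total"] * frac
            pa["observed"] = pa.get(klass, 0.0)
            per_acc = pa[["observed", "expected"]]
        row = test_enrichment(obs, float(expected[klass]), total, method=method,
                              per_accession=per_acc)
        row["klass"] = klass
        row["class_bp"] = int(class_bp[klass])
        rows.append(row)
    out = pd.DataFrame(rows)[["klass", "class_bp", "observed", "expected",
                              "statistic", "p", "direction"]]
    out["p_bh"] = multipletests(out["p"], method="fdr_bh")[1]
    return out.sort_values("p", ignore_index=True)


def gene_family_report(site_hits: pd.DataFrame, index: FeatureIndex,
                       segments: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per gene family: observed/expected SFPs with chi-squared p, plus
    deletion/duplication bp overlapping family genes; sorted by
    significance. Families with no annotated genes are absent by
    construction.
    """
    fam_ann = index.annotation[index.annotation["family"] != ""]
    if fam_ann.empty:
        return pd.DataFrame(columns=["family", "family_bp", "observed",
                                     "expected", "statistic", "p",
                                     "direction", "deletion_bp",
                                     "duplication_bp", "p_bh"])
    fam_bp = {}
    for family, sub in fam_ann.groupby("family"):
        total = 0
        for _, csub in sub.groupby("chrom"):
            tree = IntervalTree.from_tuples(
                (s, e) for s, e in zip(csub["start"], csub["end"]) if e > s)
            tree.merge_overlaps()
            total += sum(iv.end - iv.begin for iv in tree)
        fam_bp[family] = total
    fam_bp = pd.Series(fam_bp)
    total_sfps = site_hits["site_idx"].nunique()
    expected = expected_counts(total_sfps, fam_bp, index.genome_bp())
    observed = (site_hits[site_hits["family"] != ""]
                .drop_duplicates(["site_idx", "family"])
                .groupby("family").size())
    seg_bp = {f: {"deletion": 0, "duplication": 0} for f in fam_bp.index}
    if segments is not None and len(segments):
        for _, seg in segments.iterrows():
            for _, g in fam_ann[fam_ann["chrom"] == seg["chrom"]].iterrows():
                ov = min(seg["end"], g["end"]) - max(seg["start"], g["start"])
                if ov > 0:
                    seg_bp[g["family"]][seg["kind"]] += int(ov)
    rows = []
    for family in fam_bp.index:
        row = test_enrichment(int(observed.get(family, 0)),
                              float(expected[family]), total_sfps, "chi2")
        row.update(family=family, family_bp=int(fam_bp[family]),
                   deletion_bp=seg_bp[family]["deletion"],
                   duplication_bp=seg_bp[family]["duplication"])
        rows.append(row)
    out = pd.DataFrame(rows)[["family", "family_bp", "observed", "expected",
                              "statistic", "p", "direction", "deletion_bp",
                              "duplication_bp"]]
    out["p_bh"] = multipletests(out["p"], method="fdr_bh")[1]
    return out.sort_values("p", ignore_index=True)
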