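"""SFP calling from probe hybridisation intensities.

An SFP (single feature polymorphism) is a probe whose signal for a test
accession is strongly reduced relative to the reference hybridisation,
indicating sequence polymorphism in the probe footprint. Calls are made
on the log2-fold change against the reference at a fixed threshold
(default -1.5, a 2.8-fold signal decrease), restricted to probes with a
single exact genomic match. The threshold is calibrated by ROC against a
sequencing-derived SNP truth set, reporting FDR (false positives among
calls) and FNR (false negatives among truly polymorphic probes).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform, pdist

from .types import DataError, IntensityMatrix, ProbeMap, SfpCallSet

DEFAULT_THRESHOLD = -1.5


def normalize_arrays(raw: IntensityMatrix, method: str = "quantile") -> IntensityMatrix:
    """Cross-array normalisation of log2 signals.

    ``quantile`` (default) maps every array onto the average order
    statistics across arrays, so all columns share one empirical
    distribution; ``median`` subtracts per-array median offsets from the
    grand median. Both are idempotent.
    """
    values = raw.values.to_numpy(float)
    if values.shape[1] < 2:
        raise DataError("normalisation requires at least two arrays")
    if not np.isfinite(values).all():
        raise DataError("non-finite intensities")
    if method == "quantile":
        order = np.argsort(values, axis=0, kind="stable")
        ref_dist = np.sort(values, axis=0).mean(axis=1)
        out = np.empty_like(values)
        for j in range(values.shape[1]):
            out[order[:, j], j] = ref_dist
    elif method == "median":
        med = np.median(values, axis=0)
        out = values - (med - np.median(med))
    else:
        raise ValueError(f"unknown normalisation method: {method!r}")
    norm = raw.values.copy()
    norm.iloc[:, :] = out
    return IntensityMatrix(values=norm, arrays=raw.arrays, reference=raw.reference)


def compute_log2fc(norm: IntensityMatrix, accession: str) -> pd.Series:
    """Per-probe mean log2 signal of the accession's replicate arrays minus
    the reference's replicate mean (signals are already log2)."""
    acc_cols = norm.arrays_for(accession)
    ref_cols = norm.arrays_for(norm.reference)
    return (norm.values[acc_cols].mean(axis=1)
            - norm.values[ref_cols].mean(axis=1))


def log2fc_matrix(norm: IntensityMatrix,
                  accessions: list[str] | None = None) -> pd.DataFrame:
    """Probes x accessions log2FC frame (reference column included)."""
    accessions = accessions or norm.accessions()
    return pd.DataFrame({a: compute_log2fc(norm, a) for a in accessions})


def call_sfps(log2fc: pd.DataFrame, probes: ProbeMap,
              threshold: float = DEFAULT_THRESHOLD) -> SfpCallSet:
    """Call SFPs at ``log2fc <= threshold`` (inclusive boundary).

    Non-unique probes never carry calls regardless of fold change.
    ``log2fc`` may be a single-accession Series or a probes x accessions
    frame aligned with the probe map.
    """
    if threshold >= 0:
        raise ValueError("SFP threshold must be negative (signal decrease)")
    if isinstance(log2fc, pd.Series):
        log2fc = log2fc.to_frame("accession")
    fc = log2fc.reindex(probes.df["probe_id"])
    if fc.isna().to_numpy().any():
        missing = fc.index[fc.isna().any(axis=1)][:3].tolist()
        raise DataError(f"log2fc missing for probes: {missing}")
    unique = probes.df.set_index("probe_id")["unique"].reindex(fc.index)
    called = fc.le(threshold).to_numpy() & unique.to_numpy()[:, None]
    called = pd.DataFrame(called, index=fc.index, columns=fc.columns)
    return SfpCallSet(log2fc=fc, called=called, threshold=threshold, probes=probes)


@dataclass
class CalibrationReport:
    """ROC sweep of the calling threshold against a SNP truth set."""

    roc: pd.DataFrame          # threshold, tp, fp, fn, tn, tpr, fpr, fdr, fnr
    chosen_threshold: float
    fdr: float                 # at the chosen threshold
    fnr: float

    def __post_init__(self) -> None:
        rates = self.roc[["tpr", "fpr", "fdr", "fnr"]].to_numpy(float)
        if ((rates < 0) | (rates > 1)).any():
            raise DataError("rates must lie in [0, 1]")


def confusion_rates(called: np.ndarray, truth: np.ndarray) -> tuple[int, int, int, int]:
    """(TP, FP, FN, TN) of boolean call vs truth arrays."""
    called = np.asarray(called, bool)
    truth = np.asarray(truth, bool)
    tp = int((called & truth).sum())
    fp = int((called & ~truth).sum())
    fn = int((~called & truth).sum())
    tn = int((~called & ~truth).sum())
    return tp, fp, fn, tn


def calibrate_threshold(log2fc: pd.DataFrame, truth: pd.DataFrame,
                        probes: ProbeMap,
                        grid: np.ndarray | None = None,
                        fdr_cap: float = 0.05) -> CalibrationReport:
    """ROC over a threshold grid against per-accession polymorphism truth.

    ``truth``: boolean probes x accessions frame flagging truly polymorphic
    probes. FDR = FP/(TP+FP); FNR = FN/(TP+FN), evaluated over unique
    probes of the accessions shared between the two frames. The chosen
    threshold is the smallest-magnitude one with FDR <= ``fdr_cap``.
    """
    if grid is None:
        grid = np.arange(-0.5, -4.01, -0.25)
    shared = [a for a in log2fc.columns if a in truth.columns]
    if not shared:
        raise DataError("no accessions shared between calls and truth")
    uniq = probes.df.set_index("probe_id")["unique"]
    keep = uniq.reindex(log2fc.index).fillna(False).to_numpy(bool)
    fc = log2fc.loc[keep, shared].to_numpy(float)
    tr = truth.reindex(log2fc.index).loc[keep, shared].to_numpy(bool)
    if not tr.any():
        raise DataError("degenerate truth set: no polymorphic probes")
    rows = []
    for t in np.sort(grid)[::-1]:
        tp, fp, fn, tn = confusion_rates(fc <= t, tr)
        fdr = fp / (tp + fp) if tp + fp else 0.0
        fnr = fn / (tp + fn) if tp + fn else 0.0
        tpr = tp / (tp + fn) if tp + fn else 0.0
        fpr = fp / (fp + tn) if fp + tn else 0.0
        rows.append({"threshold": t, "tp": tp, "fp": fp, "fn": fn, "tn": tn,
                     "tpr": tpr, "fpr": fpr, "fdr": fdr, "fnr": fnr})
    roc = pd.DataFrame(rows)
    ok = roc[roc["fdr"] <= fdr_cap]
    chosen = float(ok.iloc[0]["threshold"]) if len(ok) else float(roc.iloc[-1]["threshold"])
    at = roc.loc[(roc["threshold"] - chosen).abs().idxmin()]
    return CalibrationReport(roc=roc, chosen_threshold=chosen,
                             fdr=float(at["fdr"]), fnr=float(at["fnr"]))


def pairwise_accession_distance(calls: SfpCallSet) -> pd.DataFrame:
    """Hamming-fraction distance between accession call vectors over unique
    probes: symmetric, zero diagonal."""
    uniq = calls.probes.df.set_index("probe_id")["unique"]
    keep = uniq.reindex(calls.called.index).fillna(False).to_numpy(bool)
    mat = calls.called.loc[keep].to_numpy(bool).T
    if mat.shape[0] < 2:
        raise DataError("pairwise distance needs at least two accessions")
    dist = squareform(pdist(mat, metric="hamming"))
    return pd.DataFrame(dist, index=calls.called.columns,
                        columns=calls.called.columns)


def calls_to_bed(calls: SfpCallSet) -> pd.DataFrame:
    """BED-like long table: chrom, start0, end, accession, log2fc, called."""
    pm = calls.probes.df.set_index("probe_id")
    rows = []
    for acc in calls.called.columns:
        fc = calls.log2fc[acc]
        flag = calls.called[acc]
        sub = pm.loc[calls.called.index]
        rows.append(pd.DataFrame({
            "chrom": sub["chrom"].to_numpy(),
            "start": sub["start"].to_numpy(),
            "end": (sub["start"] + sub["length"]).to_numpy(),
            "accession": acc,
            "log2fc": fc.to_numpy(),
            "called": flag.to_numpy().astype(int),
        }))
    return pd.concat(rows, ignore_index=True)
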