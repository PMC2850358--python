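"""Deletion and duplication calling from probe runs.

Runs of consecutive called SFP probes longer than the average exon
(~350 bp, i.e. 10 probes) are classified as deletions; runs of probes
with a strong signal *gain* (default log2FC >= 2, a 4-fold increase) as
duplications. Runs never bridge chromosomes or gaps left by non-unique
probes, because probe adjacency in genome order is ambiguous across
masked positions.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .types import ProbeMap, SegmentCall, SfpCallSet

DEFAULT_MIN_RUN = 10
DEFAULT_DUP_MIN_LOG2FC = 2.0


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal [start, end) runs of True in a boolean vector."""
    if not mask.any():
        return []
    padded = np.concatenate([[False], mask, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return list(zip(edges[::2], edges[1::2]))


def _call_runs(flag: pd.DataFrame, probes: ProbeMap, min_run: int,
               kind: str) -> list[SegmentCall]:
    """Turn per-(probe, accession) qualifying flags into maximal-run
    segments per chromosome, skipping non-unique probes entirely (they
    break runs)."""
    pm = probes.df.set_index("probe_id")
    flag = flag.reindex(probes.df["probe_id"]).fillna(False)
    out: list[SegmentCall] = []
    for chrom, sub in probes.df.groupby("chrom", sort=False):
        uniq = sub["unique"].to_numpy(bool)
        ids = sub["probe_id"].to_numpy()[uniq]
        if not len(ids):
            continue
        starts = pm.loc[ids, "start"].to_numpy()
        ends = starts + pm.loc[ids, "length"].to_numpy()
        # runs must be consecutive in the full probe map: positions of the
        # retained probes within the chromosome tiling
        idx_in_chrom = np.flatnonzero(uniq)
        consecutive = np.diff(idx_in_chrom) == 1
        for acc in flag.columns:
            f = flag.loc[ids, acc].to_numpy(bool)
            # build runs honouring adjacency breaks at masked probes
            i = 0
            n = len(f)
            while i < n:
                if not f[i]:
                    i += 1
                    continue
                j = i
                while j + 1 < n and f[j + 1] and consecutive[j]:
                    j += 1
                if j - i + 1 >= min_run:
                    out.append(SegmentCall(
                        accession=acc, chrom=chrom,
                        start=int(starts[i]), end=int(ends[j]),
                        n_probes=int(j - i + 1), kind=kind))
                i = j + 1
    return out


def call_deletions(calls: SfpCallSet, probes: ProbeMap | None = None,
                   min_run: int = DEFAULT_MIN_RUN) -> list[SegmentCall]:
    """Maximal runs of >= ``min_run`` consecutive called unique probes."""
    probes = probes or calls.probes
    return _call_runs(calls.called, probes, min_run, "deletion")


def call_duplications(log2fc: pd.DataFrame, probes: ProbeMap,
                      min_run: int = DEFAULT_MIN_RUN,
                      min_log2fc: float = DEFAULT_DUP_MIN_LOG2FC) -> list[SegmentCall]:
    """Maximal runs of >= ``min_run`` consecutive unique probes with
    log2FC >= ``min_log2fc`` (signal gain)."""
    if min_log2fc <= 0:
        raise ValueError("duplication threshold must be positive")
    if isinstance(log2fc, pd.Series):
        log2fc = log2fc.to_frame("accession")
    return _call_runs(log2fc.ge(min_log2fc), probes, min_run, "duplication")


def segments_to_frame(segments: list[SegmentCall]) -> pd.DataFrame:
    cols = ["chrom", "start", "end", "accession", "n_probes", "kind"]
    if not segments:
        return pd.DataFrame(columns=cols)
    return pd.DataFrame([{
        "chrom": s.chrom, "start": s.start, "end": s.end,
        "accession": s.accession, "n_probes": s.n_probes, "kind": s.kind,
    } for s in segments], columns=cols)


def _sharing_counts(df: pd.DataFrame) -> pd.Series:
    """For each segment, the number of accessions carrying an overlapping
    segment of the same kind (including its own)."""
    counts = np.ones(len(df), dtype=int)
    for key, sub in df.groupby(["chrom", "kind"]):
        idx = sub.index.to_numpy()
        s = sub["start"].to_numpy()
        e = sub["end"].to_numpy()
        accs = sub["accession"].to_numpy()
        for a in range(len(idx)):
            over = (s < e[a]) & (e > s[a])
            counts[df.index.get_loc(idx[a])] = len(set(accs[over]))
    return pd.Series(counts, index=df.index, name="n_accessions_sharing")


def summarize_segments(segments: list[SegmentCall]) -> dict[str, pd.DataFrame]:
    """Per-accession and overall summary plus per-segment sharing counts.

    Means over an empty set are reported as absent (NaN-free tables with
    zero counts only).
    """
    df = segments_to_frame(segments)
    if df.empty:
        empty = pd.DataFrame(columns=["accession", "kind", "count",
                                      "mean_bp", "total_bp"])
        overall = pd.DataFrame(columns=["kind", "count", "mean_bp", "total_bp"])
        return {"per_accession": empty, "overall": overall, "segments": df}
    df = df.assign(length=df["end"] - df["start"])
    per_acc = (df.groupby(["accession", "kind"])["length"]
               .agg(count="size", mean_bp="mean", total_bp="sum")
               .reset_index())
    overall = (df.groupby("kind")["length"]
               .agg(count="size", mean_bp="mean", total_bp="sum")
               .reset_index())
    df = df.assign(n_accessions_sharing=_sharing_counts(df))
    return {"per_accession": per_acc, "overall": overall, "segments": df}
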