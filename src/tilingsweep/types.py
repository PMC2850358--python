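"""Core in-memory containers shared across pipeline stages.

All tabular state is held in pandas DataFrames with documented column
contracts; the thin dataclass wrappers exist to carry the extra metadata
(reference accession, array-to-accession mapping, currency compounds) that
a bare DataFrame cannot.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: column contract for a probe map table
PROBE_MAP_COLUMNS = ["probe_id", "chrom", "start", "length", "gc", "unique"]


class ConfigError(ValueError):
    """Invalid configuration or parameters."""


class DataError(ValueError):
    """Malformed or inconsistent input data."""


@dataclass
class ProbeMap:
    """Genomic layout of array probes.

    ``df`` columns: probe_id (str), chrom (str), start (0-based bp, int),
    length (bp), gc (fraction), unique (bool). Starts are strictly
    increasing within each chromosome.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in PROBE_MAP_COLUMNS if c not in self.df.columns]
        if missing:
            raise DataError(f"probe map missing columns: {missing}")
        for _, sub in self.df.groupby("chrom", sort=False):
            starts = sub["start"].to_numpy()
            if len(starts) and ((starts < 0).any() or (np.diff(starts) <= 0).any()):
                raise DataError("probe starts must be non-negative and strictly increasing per chromosome")
        gc = self.df["gc"].to_numpy(float)
        if ((gc < 0) | (gc > 1)).any():
            raise DataError("gc fractions must lie in [0, 1]")

    @property
    def n_probes(self) -> int:
        return len(self.df)

    def chromosomes(self) -> list[str]:
        return list(dict.fromkeys(self.df["chrom"]))


@dataclass
class IntensityMatrix:
    """Probe x array log2 hybridisation signals.

    ``values``: DataFrame indexed by probe_id with one column per array.
    ``arrays``: DataFrame with columns array_id, accession.
    ``reference``: accession label hybridised from the array-design genotype.
    """

    values: pd.DataFrame
    arrays: pd.DataFrame
    reference: str

    def __post_init__(self) -> None:
        if not np.isfinite(self.values.to_numpy(float)).all():
            raise DataError("intensity matrix contains non-finite values")
        if set(self.values.columns) != set(self.arrays["array_id"]):
            raise DataError("array metadata does not match intensity columns")
        if self.reference not in set(self.arrays["accession"]):
            raise DataError(f"reference accession {self.reference!r} has no arrays")

    def accessions(self) -> list[str]:
        return list(dict.fromkeys(self.arrays["accession"]))

    def arrays_for(self, accession: str) -> list[str]:
        ids = self.arrays.loc[self.arrays["accession"] == accession, "array_id"]
        if ids.empty:
            raise KeyError(f"unknown accession: {accession!r}")
        return list(ids)


@dataclass
class SfpCallSet:
    """Per-(accession, probe) SFP calls at a fixed log2FC threshold.

    ``log2fc``: DataFrame probes x accessions of log2(accession/reference).
    ``called``: boolean DataFrame of identical shape; True only on
    unique-flagged probes with log2fc <= threshold.
    """

    log2fc: pd.DataFrame
    called: pd.DataFrame
    threshold: float
    probes: ProbeMap

    def n_calls(self) -> pd.Series:
        """Number of SFP calls per accession."""
        return self.called.sum(axis=0)

    def sfp_sites(self) -> pd.Index:
        """Probes called in at least one accession (unique SFP sites)."""
        return self.called.index[self.called.any(axis=1)]

    def genotype_matrix(self) -> pd.DataFrame:
        """Sites x accessions biallelic matrix (0 reference-like, 1 SFP)."""
        sites = self.sfp_sites()
        return self.called.loc[sites].astype(np.int8)


@dataclass(frozen=True)
class SegmentCall:
    """One deletion or duplication: a maximal run of qualifying probes."""

    accession: str
    chrom: str
    start: int  # bp, 0-based, first probe start
    end: int    # bp, half-open, last probe end
    n_probes: int
    kind: str   # "deletion" | "duplication"

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise DataError("segment end must exceed start")
        if self.kind not in ("deletion", "duplication"):
            raise DataError(f"unknown segment kind: {self.kind}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class MetabolicNetwork:
    """Bipartite reaction-compound graph with gene and pathway annotation.

    ``reactions``: DataFrame with columns reaction_id, substrates, products
    (tuples of compound ids). ``gene_reactions``: gene -> tuple of reaction
    ids. ``gene_pathway``: gene -> pathway label. ``currency``: compounds
    excluded from path traversal (water, ATP, ...).
    """

    reactions: pd.DataFrame
    gene_reactions: dict[str, tuple[str, ...]]
    gene_pathway: dict[str, str]
    currency: frozenset[str] = field(default_factory=frozenset)

    def compounds(self) -> set[str]:
        out: set[str] = set()
        for _, row in self.reactions.iterrows():
            out.update(row["substrates"])
            out.update(row["products"])
        return out
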