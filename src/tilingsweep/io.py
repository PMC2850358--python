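"""Readers and writers for the pipeline's plain-text interchange formats.

Everything is tab-separated; GFF3 follows the standard version-3 dialect
(1-based inclusive coordinates on disk, converted to 0-based half-open in
memory). Writing then reading any table round-trips losslessly.
"""

from __future__ import annotations

import tempfile
from pathlib import Path

import gffutils
import pandas as pd

from .types import DataError, IntensityMatrix, MetabolicNetwork, ProbeMap


def write_probe_map(probes: ProbeMap, path: str | Path) -> None:
    df = probes.df.copy()
    df["unique"] = df["unique"].astype(int)
    df.to_csv(path, sep="\t", index=False)


def read_probe_map(path: str | Path) -> ProbeMap:
    df = pd.read_csv(path, sep="\t", dtype={"probe_id": str, "chrom": str})
    df["unique"] = df["unique"].astype(bool)
    return ProbeMap(df)


def write_intensities(mat: IntensityMatrix, values_path: str | Path,
                      arrays_path: str | Path) -> None:
    mat.values.to_csv(values_path, sep="\t")
    arrays = mat.arrays.copy()
    arrays["reference"] = (arrays["accession"] == mat.reference).astype(int)
    arrays.to_csv(arrays_path, sep="\t", index=False)


def read_intensities(values_path: str | Path, arrays_path: str | Path) -> IntensityMatrix:
    values = pd.read_csv(values_path, sep="\t", index_col="probe_id")
    arrays = pd.read_csv(arrays_path, sep="\t", dtype={"array_id": str, "accession": str})
    ref = arrays.loc[arrays["reference"] == 1, "accession"]
    if ref.empty:
        raise DataError("array table does not flag a reference accession")
    return IntensityMatrix(values=values, arrays=arrays[["array_id", "accession"]],
                           reference=ref.iloc[0])


def write_table(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_table(path: str | Path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kwargs)


def write_genotypes(genotypes: pd.DataFrame, path: str | Path) -> None:
    out = genotypes.copy()
    out.index.name = "site"
    out.to_csv(path, sep="\t")


def read_genotypes(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="site")


def write_qmatrix(q: pd.DataFrame, path: str | Path) -> None:
    q.to_csv(path, sep="\t")


def read_qmatrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="accession")


# ---------------------------------------------------------------------------
# GFF3


def write_gff3(annotation: pd.DataFrame, path: str | Path) -> None:
    """Emit feature intervals as GFF3 (1-based inclusive on disk)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for _, row in annotation.iterrows():
            attrs = [f"ID={row['gene_id']}.{row['klass']}.{row['start']}",
                     f"gene_id={row['gene_id']}"]
            if row.get("family"):
                attrs.append(f"family={row['family']}")
            if row.get("pathway"):
                attrs.append(f"pathway={row['pathway']}")
            fh.write("\t".join([
                str(row["chrom"]), "tilingsweep", str(row["klass"]),
                str(int(row["start"]) + 1), str(int(row["end"])),
                ".", "+", ".", ";".join(attrs)]) + "\n")


def read_gff3(path: str | Path) -> pd.DataFrame:
    """Parse GFF3 into the internal 0-based half-open annotation frame."""
    with tempfile.NamedTemporaryFile(suffix=".db") as tmp:
        db = gffutils.create_db(str(path), tmp.name, force=True,
                                merge_strategy="create_unique")
        rows = []
        for feat in db.all_features():
            rows.append({
                "chrom": feat.seqid,
                "start": feat.start - 1,
                "end": feat.end,
                "klass": feat.featuretype,
                "gene_id": feat.attributes.get("gene_id", [""])[0],
                "family": feat.attributes.get("family", [""])[0],
                "pathway": feat.attributes.get("pathway", [""])[0],
            })
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "klass",
                                       "gene_id", "family", "pathway"])


# ---------------------------------------------------------------------------
# metabolic network


def write_network(net: MetabolicNetwork, path: str | Path) -> None:
    """One row per reaction: compounds comma-joined, genes/pathways listed."""
    rx_genes: dict[str, list[str]] = {}
    for gene, rxs in net.gene_reactions.items():
        for rx in rxs:
            rx_genes.setdefault(rx, []).append(gene)
    rows = []
    for _, row in net.reactions.iterrows():
        rid = row["reaction_id"]
        genes = sorted(rx_genes.get(rid, []))
        rows.append({
            "reaction_id": rid,
            "substrates": ",".join(row["substrates"]),
            "products": ",".join(row["products"]),
            "genes": ",".join(genes),
            "pathways": ",".join(net.gene_pathway.get(g, "") for g in genes),
        })
    header = "#currency=" + ",".join(sorted(net.currency)) + "\n"
    with open(path, "w") as fh:
        fh.write(header)
        pd.DataFrame(rows).to_csv(fh, sep="\t", index=False)


def read_network(path: str | Path) -> MetabolicNetwork:
    with open(path) as fh:
        first = fh.readline().strip()
        if not first.startswith("#currency="):
            raise DataError("network file missing currency header")
        currency = frozenset(first.split("=", 1)[1].split(","))
        df = pd.read_csv(fh, sep="\t", keep_default_na=False)
    reactions = []
    gene_reactions: dict[str, list[str]] = {}
    gene_pathway: dict[str, str] = {}
    for _, row in df.iterrows():
        reactions.append({
            "reaction_id": row["reaction_id"],
            "substrates": tuple(row["substrates"].split(",")) if row["substrates"] else (),
            "products": tuple(row["products"].split(",")) if row["products"] else (),
        })
        genes = row["genes"].split(",") if row["genes"] else []
        pwys = row["pathways"].split(",") if row["pathways"] else []
        for g, p in zip(genes, pwys):
            gene_reactions.setdefault(g, []).append(row["reaction_id"])
            if p:
                gene_pathway[g] = p
    return MetabolicNetwork(
        reactions=pd.DataFrame(reactions),
        gene_reactions={g: tuple(r) for g, r in gene_reactions.items()},
        gene_pathway=gene_pathway, currency=currency)
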