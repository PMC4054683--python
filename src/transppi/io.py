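"""Readers and writers for the pipeline's text formats.

All emitted coordinates are 1-based, closed intervals.  The VCF dialect is
deliberately minimal: bi-allelic records, GT as the only FORMAT field,
unphased calls, placeholder REF/ALT alleles (dosages, not sequence, are the
substance here).  Parsers raise :class:`~transppi.errors.FormatError`
naming the offending line.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .datatypes import (
    MISSING, ExpressionMatrix, GeneAnnotation, GeneSetCollection, GenotypeMatrix,
)
from .errors import FormatError
from .network import PPINetwork, network_from_edges

log = logging.getLogger(__name__)

_GT_TO_DOSAGE = {"0/0": 0, "0/1": 1, "1/0": 1, "1/1": 2, "./.": MISSING}
_DOSAGE_TO_GT = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def write_vcf(G: GenotypeMatrix, path: str | Path) -> None:
    """Write the minimal GT-only VCF dialect (unphased, bi-allelic)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=transppi (dosage-only records; REF/ALT are placeholders)\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(G.samples) + "\n")
        for j, (snp_id, row) in enumerate(G.snp_meta.iterrows()):
            calls = "\t".join(_DOSAGE_TO_GT[int(d)] for d in G.dosages[:, j])
            fh.write(f"{row['chromosome']}\t{row['position']}\t{snp_id}"
                     f"\tA\tG\t.\tPASS\t.\tGT\t{calls}\n")


def read_vcf(path: str | Path,
             annotation: Sequence[GeneAnnotation] | None = None) -> GenotypeMatrix:
    """Read the minimal VCF dialect back into a genotype matrix.

    Multi-allelic records are rejected.  When an annotation is supplied,
    each SNP is assigned its host gene and region flags; otherwise the
    region columns are left empty/False.
    """
    path = Path(path)
    samples: list[str] = []
    ids, rows, cols = [], [], []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                fields = line.split("\t")
                if len(fields) < 10:
                    raise FormatError(f"{path}:{lineno}: VCF header has no samples")
                samples = fields[9:]
                continue
            if not samples:
                raise FormatError(f"{path}:{lineno}: record before #CHROM header")
            fields = line.split("\t")
            if len(fields) != 9 + len(samples):
                raise FormatError(
                    f"{path}:{lineno}: expected {9 + len(samples)} columns, "
                    f"got {len(fields)}")
            chrom, pos, snp_id, _ref, alt, _q, _f, _i, fmt = fields[:9]
            if "," in alt:
                raise FormatError(f"{path}:{lineno}: multi-allelic record {snp_id}")
            if fmt.split(":")[0] != "GT":
                raise FormatError(f"{path}:{lineno}: first FORMAT field must be GT")
            calls = []
            for s, call in zip(samples, fields[9:]):
                gt = call.split(":")[0].replace("|", "/")
                if gt not in _GT_TO_DOSAGE:
                    raise FormatError(
                        f"{path}:{lineno}: unsupported genotype {gt!r} for {s}")
                calls.append(_GT_TO_DOSAGE[gt])
            try:
                position = int(pos)
            except ValueError:
                raise FormatError(f"{path}:{lineno}: bad POS {pos!r}") from None
            ids.append(snp_id)
            rows.append({"chromosome": chrom, "position": position})
            cols.append(np.array(calls, dtype=np.int8))
    if not ids:
        raise FormatError(f"{path}: no variant records found")
    meta = pd.DataFrame(rows, index=pd.Index(ids, name="snp_id"))
    meta["source_gene"] = ""
    meta["exonic"] = False
    meta["tf_span"] = False
    if annotation is not None:
        by_chrom: dict[str, list[GeneAnnotation]] = {}
        for gene in annotation:
            by_chrom.setdefault(gene.chromosome, []).append(gene)
        for snp_id, row in meta.iterrows():
            for gene in by_chrom.get(row["chromosome"], []):
                if gene.contains(row["position"]):
                    meta.at[snp_id, "source_gene"] = gene.gene_id
                    meta.at[snp_id, "exonic"] = gene.in_exon(row["position"])
                    meta.at[snp_id, "tf_span"] = gene.is_tf
                    break
    return GenotypeMatrix(samples=samples, dosages=np.column_stack(cols),
                          snp_meta=meta)


def write_dosage_tsv(G: GenotypeMatrix, dosage_path: str | Path,
                     meta_path: str | Path) -> None:
    """Sample x SNP dosage TSV (missing as 'NA') plus a SNP metadata TSV."""
    df = pd.DataFrame(G.dosages, index=pd.Index(G.samples, name="sample"),
                      columns=G.snp_meta.index)
    df = df.replace(MISSING, pd.NA)
    df.to_csv(dosage_path, sep="\t", na_rep="NA")
    G.snp_meta.to_csv(meta_path, sep="\t")


def read_dosage_tsv(dosage_path: str | Path,
                    meta_path: str | Path) -> GenotypeMatrix:
    df = pd.read_csv(dosage_path, sep="\t", index_col=0)
    meta = pd.read_csv(meta_path, sep="\t", index_col=0)
    if list(df.columns) != list(meta.index):
        raise FormatError("dosage columns and SNP metadata rows disagree")
    dosages = df.to_numpy(dtype=float)
    dosages = np.where(np.isnan(dosages), MISSING, dosages).astype(np.int8)
    return GenotypeMatrix(samples=[str(s) for s in df.index],
                          dosages=dosages, snp_meta=meta)


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def write_expression_tsv(E: ExpressionMatrix, path: str | Path) -> None:
    """Genes x samples TSV with a header row of sample ids."""
    pd.DataFrame(E.values.T, index=pd.Index(E.genes, name="gene"),
                 columns=E.samples).to_csv(path, sep="\t")


def read_expression_tsv(path: str | Path) -> ExpressionMatrix:
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except Exception as err:
        raise FormatError(f"{path}: cannot parse expression TSV: {err}") from err
    if df.empty:
        raise FormatError(f"{path}: empty expression table")
    return ExpressionMatrix(samples=[str(s) for s in df.columns],
                            genes=[str(g) for g in df.index],
                            values=df.to_numpy(dtype=float).T)


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

_ANN_COLUMNS = ["chrom", "start", "end", "gene_id", "strand",
                "exon_starts", "exon_sizes", "is_tf"]


def write_annotation_tsv(annotation: Sequence[GeneAnnotation],
                         path: str | Path) -> None:
    """BED-like TSV with exon blocks; 1-based closed coordinates."""
    with Path(path).open("w") as fh:
        fh.write("\t".join(_ANN_COLUMNS) + "\n")
        for g in annotation:
            starts = ",".join(str(s) for (s, _) in g.exons)
            sizes = ",".join(str(e - s + 1) for (s, e) in g.exons)
            fh.write(f"{g.chromosome}\t{g.start}\t{g.end}\t{g.gene_id}"
                     f"\t{g.strand}\t{starts}\t{sizes}\t{int(g.is_tf)}\n")


def read_annotation_tsv(path: str | Path) -> list[GeneAnnotation]:
    path = Path(path)
    out: list[GeneAnnotation] = []
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _ANN_COLUMNS:
            raise FormatError(f"{path}:1: bad annotation header {header}")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != len(_ANN_COLUMNS):
                raise FormatError(
                    f"{path}:{lineno}: expected {len(_ANN_COLUMNS)} fields")
            try:
                starts = [int(x) for x in fields[5].split(",") if x]
                sizes = [int(x) for x in fields[6].split(",") if x]
                exons = tuple((s, s + w - 1) for s, w in zip(starts, sizes))
                out.append(GeneAnnotation(
                    gene_id=fields[3], chromosome=fields[0],
                    start=int(fields[1]), end=int(fields[2]),
                    strand=fields[4], exons=exons, is_tf=bool(int(fields[7]))))
            except (ValueError, IndexError) as err:
                raise FormatError(f"{path}:{lineno}: {err}") from err
    if not out:
        raise FormatError(f"{path}: no annotation records")
    return out


# ---------------------------------------------------------------------------
# network / gene sets / pair lists
# ---------------------------------------------------------------------------

def write_edge_list(network: PPINetwork, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for (u, v) in sorted(tuple(sorted(e)) for e in network.graph.edges):
            fh.write(f"{u}\t{v}\n")


def read_edge_list(path: str | Path) -> PPINetwork:
    """Two-column edge TSV; duplicates collapse, self-loops drop with warning."""
    path = Path(path)
    edges = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 2:
                raise FormatError(f"{path}:{lineno}: expected two columns")
            edges.append((fields[0], fields[1]))
    net = network_from_edges(edges)
    log.info("read %s: %d nodes, %d edges", path, net.n_nodes, net.n_edges)
    return net


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for name in sorted(collection.categories):
            genes = "\t".join(sorted(collection.categories[name]))
            fh.write(f"{name}\ttransppi\t{genes}\n")


def read_gmt(path: str | Path,
             background: set[str] | None = None) -> GeneSetCollection:
    """GMT reader; background defaults to the union of all categories."""
    path = Path(path)
    categories: dict[str, set[str]] = {}
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line needs name, description, genes")
            name = fields[0]
            if name in categories:
                raise FormatError(f"{path}:{lineno}: duplicate category {name}")
            categories[name] = {g for g in fields[2:] if g}
    if not categories:
        raise FormatError(f"{path}: no categories")
    bg = background if background is not None else set().union(*categories.values())
    return GeneSetCollection(categories=categories, background=bg)


def write_pairs_tsv(pairs: Sequence[tuple[str, str]], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for (a, b) in pairs:
            fh.write(f"{a}\t{b}\n")


def read_pairs_tsv(path: str | Path) -> list[tuple[str, str]]:
    path = Path(path)
    out = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 2:
                raise FormatError(f"{path}:{lineno}: expected two columns")
            out.append((fields[0], fields[1]))
    return out
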