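"""Readers and writers for the pipeline's exchange formats.

Files exchange 1-based inclusive coordinates (VCF/GFF3 convention); all
internal arithmetic works on the parsed frames as-is, with converters kept
here.  Round-trips are lossless for the dialects defined below.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import GenotypeMatrix

__all__ = [
    "read_expression_tsv",
    "write_expression_tsv",
    "read_metadata_tsv",
    "write_metadata_tsv",
    "read_vcf_minimal",
    "write_vcf_minimal",
    "read_dosage_tsv",
    "write_dosage_tsv",
    "read_gff3_genes",
    "write_gff3_genes",
    "read_bed_genes",
    "read_phenotype_csv",
    "write_phenotype_csv",
    "write_edge_list",
]


# ---------------------------------------------------------------------------
# expression and metadata
# ---------------------------------------------------------------------------


def read_expression_tsv(path: str | Path) -> pd.DataFrame:
    """Genes x samples TSV: first column gene ids, header sample ids."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"duplicate gene id {dup!r} in {path}")
    if df.columns.duplicated().any():
        dup = df.columns[df.columns.duplicated()][0]
        raise ValueError(f"duplicate sample id {dup!r} in {path}")
    if df.isna().any().any():
        raise ValueError(f"ragged or non-numeric rows in {path}")
    return df


def write_expression_tsv(expr: pd.DataFrame, path: str | Path) -> None:
    expr.to_csv(path, sep="\t", index_label="gene_id")


def read_metadata_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"sample_id": str})


def write_metadata_tsv(meta: pd.DataFrame, path: str | Path) -> None:
    meta.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# genotypes: minimal VCF and dosage TSV
# ---------------------------------------------------------------------------

_GT_TO_DOSAGE = {
    "0/0": 0.0, "0|0": 0.0,
    "0/1": 1.0, "1/0": 1.0, "0|1": 1.0, "1|0": 1.0,
    "1/1": 2.0, "1|1": 2.0,
    "./.": np.nan, ".|.": np.nan, ".": np.nan,
}


def read_vcf_minimal(path: str | Path) -> tuple[GenotypeMatrix, dict]:
    """Parse a VCF with GT fields into a dosage panel.

    Biallelic SNP rows become dosages 0/1/2 (missing "./."); indel and
    multiallelic rows are skipped and counted in the returned report, the
    usual marker-filtering convention.
    """
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover
        raise RuntimeError("cyvcf2 is required to read VCF") from exc
    vcf = VCF(str(path))
    individuals = list(vcf.samples)
    rows, records = [], []
    skipped = {"multiallelic": 0, "indel": 0}
    for v in vcf:
        if len(v.ALT) != 1:
            skipped["multiallelic"] += 1
            continue
        if len(v.REF) != 1 or len(v.ALT[0]) != 1:
            skipped["indel"] += 1
            continue
        gts = v.genotypes  # [a, b, phased]
        dos = [
            np.nan if g[0] < 0 or g[1] < 0 else float(g[0] + g[1]) for g in gts
        ]
        rows.append(dos)
        records.append(
            (str(v.CHROM), int(v.POS), v.ID or f"{v.CHROM}_{v.POS}", v.REF, v.ALT[0])
        )
    if not rows:
        raise ValueError(f"no biallelic SNP records in {path}")
    snps = pd.DataFrame(records, columns=["chrom", "pos", "id", "ref", "alt"])
    gm = GenotypeMatrix(
        dosage=np.asarray(rows, dtype=float).T, snps=snps, individuals=individuals
    )
    return gm, skipped


def write_vcf_minimal(genotypes: GenotypeMatrix, path: str | Path) -> None:
    """Emit a minimal VCF 4.2 (CHROM POS ID REF ALT QUAL FILTER INFO FORMAT GT)."""
    dosage_to_gt = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        chroms = genotypes.snps["chrom"].astype(str).unique()
        for c in chroms:
            sub = genotypes.snps[genotypes.snps["chrom"].astype(str) == c]
            fh.write(f"##contig=<ID={c},length={int(sub['pos'].max()) + 1000}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(genotypes.individuals)
            + "\n"
        )
        for j, rec in enumerate(genotypes.snps.itertuples(index=False)):
            col = genotypes.dosage[:, j]
            gts = [
                "./." if np.isnan(d) else dosage_to_gt[int(round(d))] for d in col
            ]
            fh.write(
                f"{rec.chrom}\t{rec.pos}\t{rec.id}\t{rec.ref}\t{rec.alt}"
                f"\t.\t.\t.\tGT\t" + "\t".join(gts) + "\n"
            )


def write_dosage_tsv(genotypes: GenotypeMatrix, path: str | Path) -> None:
    """Individuals x SNPs dosage table with a 3-line header (chrom, pos, id)."""
    with open(path, "w") as fh:
        fh.write("#chrom\t" + "\t".join(genotypes.snps["chrom"].astype(str)) + "\n")
        fh.write("#pos\t" + "\t".join(genotypes.snps["pos"].astype(str)) + "\n")
        fh.write("#id\t" + "\t".join(genotypes.snps["id"].astype(str)) + "\n")
        for i, ind in enumerate(genotypes.individuals):
            vals = [
                "NA" if np.isnan(d) else str(int(round(d)))
                for d in genotypes.dosage[i]
            ]
            fh.write(ind + "\t" + "\t".join(vals) + "\n")


def read_dosage_tsv(path: str | Path) -> GenotypeMatrix:
    with open(path) as fh:
        chrom_line = fh.readline().rstrip("\n").split("\t")
        pos_line = fh.readline().rstrip("\n").split("\t")
        id_line = fh.readline().rstrip("\n").split("\t")
        if not (chrom_line[0] == "#chrom" and pos_line[0] == "#pos" and id_line[0] == "#id"):
            raise ValueError("dosage TSV must start with #chrom/#pos/#id header lines")
        snps = pd.DataFrame(
            {
                "chrom": chrom_line[1:],
                "pos": [int(p) for p in pos_line[1:]],
                "id": id_line[1:],
                "ref": "A",
                "alt": "T",
            }
        )
        individuals, rows = [], []
        for ln, line in enumerate(fh, start=4):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(snps) + 1:
                raise ValueError(f"ragged row at line {ln}")
            individuals.append(parts[0])
            rows.append([np.nan if v == "NA" else float(v) for v in parts[1:]])
    return GenotypeMatrix(
        dosage=np.asarray(rows, dtype=float), snps=snps, individuals=individuals
    )


# ---------------------------------------------------------------------------
# gene models
# ---------------------------------------------------------------------------


def read_gff3_genes(path: str | Path, feature: str = "gene") -> pd.DataFrame:
    """Gene models (id, chrom, start, end, strand) from GFF3, 1-based inclusive."""
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 9:
                raise ValueError(f"malformed GFF3 line {ln}")
            chrom, _, ftype, start, end, _, strand, _, attrs = parts
            if ftype != feature:
                continue
            gid = None
            for field in attrs.split(";"):
                if field.startswith("ID="):
                    gid = field[3:]
                    break
            if gid is None:
                gid = f"{chrom}:{start}-{end}"
            if strand not in ("+", "-"):
                warnings.warn(f"missing strand at line {ln}; assuming +", stacklevel=2)
                strand = "+"
            rows.append((gid, chrom, int(start), int(end), strand))
    return pd.DataFrame(rows, columns=["id", "chrom", "start", "end", "strand"])


def write_gff3_genes(genes: pd.DataFrame, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for rec in genes.itertuples(index=False):
            fh.write(
                f"{rec.chrom}\tpleionet\tgene\t{rec.start}\t{rec.end}\t.\t"
                f"{rec.strand}\t.\tID={rec.id}\n"
            )


def read_bed_genes(path: str | Path) -> pd.DataFrame:
    """BED gene records converted to 1-based inclusive coordinates."""
    rows = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.rstrip("\n").split("\t")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            gid = parts[3] if len(parts) > 3 else f"{chrom}:{start}-{end}"
            strand = parts[5] if len(parts) > 5 else "+"
            rows.append((gid, chrom, start + 1, end, strand))
    return pd.DataFrame(rows, columns=["id", "chrom", "start", "end", "strand"])


# ---------------------------------------------------------------------------
# phenotypes and networks
# ---------------------------------------------------------------------------


def read_phenotype_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"genotype", "year", "block"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"phenotype CSV missing columns {sorted(missing)}")
    return df


def write_phenotype_csv(records: pd.DataFrame, path: str | Path) -> None:
    records.to_csv(path, index=False)


def write_edge_list(
    adjacency: pd.DataFrame, path: str | Path, threshold: float = 0.0
) -> int:
    """node1/node2/weight TSV for edges with weight >= threshold; returns count."""
    n = 0
    genes = list(adjacency.index)
    A = adjacency.to_numpy()
    with open(path, "w") as fh:
        fh.write("node1\tnode2\tweight\n")
        for i in range(len(genes)):
            for j in range(i + 1, len(genes)):
                if A[i, j] >= threshold:
                    fh.write(f"{genes[i]}\t{genes[j]}\t{A[i, j]:.6g}\n")
                    n += 1
    return n
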