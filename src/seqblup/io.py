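"""Readers and writers for the formats the pipeline touches.

- VCF: read via cyvcf2 when available (falling back to a plain-text
  parser for uncompressed files); written as uncompressed text with a
  ``VT`` INFO tag distinguishing SNPs from INDELs.
- Dosage dialect: tab-separated text; header row is ``sample_id``
  followed by variant ids, one row per sample, ``NA`` for missing.
  Variant metadata travels in a sidecar variant table (TSV) or is
  recovered from ``chrom:pos:ref:alt`` ids.
- PLINK bed/bim/fam: read-only, SNP-major bed layout.
- Phenotype table: TSV with ``sample_id``, trait and factor columns.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataError
from .panels import INDEL, SNP, GenotypeMatrix, VariantPanel
from .pheno import PhenotypeTable

__all__ = [
    "read_vcf",
    "write_vcf",
    "read_dosage",
    "write_dosage",
    "read_variant_table",
    "write_variant_table",
    "write_panel_ids",
    "read_panel_ids",
    "read_plink",
    "read_phenotypes",
    "write_phenotypes",
]


def _classify(ref: str, alt: str) -> str:
    return SNP if len(ref) == 1 and len(alt) == 1 else INDEL


# ---------------------------------------------------------------- VCF
def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Read biallelic records from a VCF into a dosage matrix."""
    try:
        from cyvcf2 import VCF
    except ImportError:
        return _read_vcf_text(path)
    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    rows, dosages = [], []
    for var in vcf:
        if len(var.ALT) != 1:
            continue  # multi-allelic records are out of scope
        alt = var.ALT[0]
        rows.append(
            {
                "variant_id": var.ID
                if var.ID not in (None, ".")
                else f"{var.CHROM}:{var.POS}:{var.REF}:{alt}",
                "chrom": str(var.CHROM),
                "pos": int(var.POS),
                "vtype": _classify(var.REF, alt),
                "ref": var.REF,
                "alt": alt,
            }
        )
        gt = var.gt_types.astype(float)  # 0/1/2, 3 = unknown
        gt[gt == 3] = np.nan
        dosages.append(gt)
    if not rows:
        raise DataError(f"no biallelic records in {path}")
    panel = VariantPanel(pd.DataFrame(rows))
    return GenotypeMatrix(samples, panel, np.column_stack(dosages)).with_stats()


def _read_vcf_text(path: str | Path) -> GenotypeMatrix:
    samples, rows, dosages = [], [], []
    with open(path) as fh:
        for line in fh:
            if line.startswith("##"):
                continue
            fields = line.rstrip("\n").split("\t")
            if line.startswith("#CHROM"):
                samples = fields[9:]
                continue
            chrom, pos, vid, ref, alt = fields[0], fields[1], fields[2], fields[3], fields[4]
            if "," in alt:
                continue
            fmt = fields[8].split(":")
            gt_i = fmt.index("GT")
            row = np.full(len(samples), np.nan)
            for s, cell in enumerate(fields[9:]):
                gt = cell.split(":")[gt_i]
                alleles = gt.replace("|", "/").split("/")
                if "." in alleles:
                    continue
                row[s] = sum(int(a) for a in alleles)
            rows.append(
                {
                    "variant_id": vid if vid != "." else f"{chrom}:{pos}:{ref}:{alt}",
                    "chrom": chrom,
                    "pos": int(pos),
                    "vtype": _classify(ref, alt),
                    "ref": ref,
                    "alt": alt,
                }
            )
            dosages.append(row)
    if not rows:
        raise DataError(f"no biallelic records in {path}")
    panel = VariantPanel(pd.DataFrame(rows))
    return GenotypeMatrix(samples, panel, np.column_stack(dosages)).with_stats()


_GT = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}


def write_vcf(gm: GenotypeMatrix, path: str | Path) -> None:
    """Write an uncompressed VCF with hard genotype calls."""
    t = gm.variants.table
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(
            '##INFO=<ID=VT,Number=1,Type=String,Description="Variant type">\n'
        )
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in pd.unique(t["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(map(str, gm.sample_ids))
            + "\n"
        )
        for j in range(gm.n_variants):
            row = t.iloc[j]
            calls = "\t".join(
                _GT.get(d, "./.") for d in gm.dosage[:, j]
            )
            fh.write(
                f"{row.chrom}\t{row.pos}\t{row.variant_id}\t{row.ref}\t"
                f"{row.alt}\t.\tPASS\tVT={row.vtype}\tGT\t{calls}\n"
            )


# ------------------------------------------------------- dosage dialect
def write_dosage(gm: GenotypeMatrix, path: str | Path) -> None:
    ids = gm.variants.variant_ids
    with open(path, "w") as fh:
        fh.write("sample_id\t" + "\t".join(map(str, ids)) + "\n")
        for i, s in enumerate(gm.sample_ids):
            vals = (
                "NA" if np.isnan(d) else str(int(d)) for d in gm.dosage[i]
            )
            fh.write(f"{s}\t" + "\t".join(vals) + "\n")


def read_dosage(
    path: str | Path, variant_table: str | Path | None = None
) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    if "sample_id" not in df.columns:
        raise DataError("dosage file must start with a 'sample_id' column")
    samples = df["sample_id"].tolist()
    vids = [c for c in df.columns if c != "sample_id"]
    dosage = df[vids].to_numpy(float)
    if variant_table is not None:
        panel = read_variant_table(variant_table)
        if list(panel.variant_ids) != vids:
            panel = panel.subset(
                [list(panel.variant_ids).index(v) for v in vids]
            )
    else:
        rows = []
        for v in vids:
            parts = str(v).split(":")
            if len(parts) == 4:
                chrom, pos, ref, alt = parts
                rows.append(
                    {
                        "variant_id": v,
                        "chrom": chrom,
                        "pos": int(pos),
                        "vtype": _classify(ref, alt),
                        "ref": ref,
                        "alt": alt,
                    }
                )
            else:  # opaque ids: minimal metadata
                rows.append(
                    {
                        "variant_id": v,
                        "chrom": "0",
                        "pos": len(rows) + 1,
                        "vtype": SNP,
                        "ref": "N",
                        "alt": "N",
                    }
                )
        panel = VariantPanel(pd.DataFrame(rows))
    return GenotypeMatrix(samples, panel, dosage).with_stats()


# ----------------------------------------------------- variant tables
def write_variant_table(panel: VariantPanel, path: str | Path) -> None:
    panel.table.to_csv(path, sep="\t", index=False)


def read_variant_table(path: str | Path) -> VariantPanel:
    return VariantPanel(pd.read_csv(path, sep="\t", dtype={"chrom": str}))


def write_panel_ids(panel: VariantPanel, path: str | Path) -> None:
    with open(path, "w") as fh:
        for v in panel.variant_ids:
            fh.write(f"{v}\n")


def read_panel_ids(path: str | Path) -> list:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


# ------------------------------------------------------------- PLINK
_BED_MAGIC = b"\x6c\x1b"


def read_plink(prefix: str | Path) -> GenotypeMatrix:
    """Read PLINK bed/bim/fam (SNP-major bed layout)."""
    prefix = str(prefix)
    fam = pd.read_csv(
        prefix + ".fam",
        sep=r"\s+",
        header=None,
        names=["fid", "iid", "father", "mother", "sex", "pheno"],
        dtype=str,
    )
    bim = pd.read_csv(
        prefix + ".bim",
        sep=r"\s+",
        header=None,
        names=["chrom", "variant_id", "cm", "pos", "a1", "a2"],
        dtype={"chrom": str},
    )
    n, m = len(fam), len(bim)
    with open(prefix + ".bed", "rb") as fh:
        header = fh.read(3)
        if header[:2] != _BED_MAGIC:
            raise DataError(f"{prefix}.bed is not a PLINK bed file")
        if header[2] != 1:
            raise DataError("only SNP-major bed files are supported")
        data = np.frombuffer(fh.read(), dtype=np.uint8)
    bytes_per_variant = (n + 3) // 4
    if data.size != bytes_per_variant * m:
        raise DataError("bed file size does not match bim/fam dimensions")
    data = data.reshape(m, bytes_per_variant)
    # unpack 2-bit codes: 00=hom a1, 01=missing, 10=het, 11=hom a2
    codes = np.zeros((m, bytes_per_variant * 4), dtype=np.uint8)
    for shift in range(4):
        codes[:, shift::4] = (data >> (2 * shift)) & 0b11
    codes = codes[:, :n]
    # a1 is the minor allele in PLINK; count a1 copies as the dosage
    mapping = np.array([2.0, np.nan, 1.0, 0.0])
    dosage = mapping[codes].T
    table = pd.DataFrame(
        {
            "variant_id": bim["variant_id"],
            "chrom": bim["chrom"],
            "pos": bim["pos"].astype(int),
            "vtype": [_classify(r, a) for r, a in zip(bim["a2"], bim["a1"])],
            "ref": bim["a2"],
            "alt": bim["a1"],
        }
    )
    return GenotypeMatrix(
        fam["iid"].tolist(), VariantPanel(table), dosage
    ).with_stats()


# -------------------------------------------------------- phenotypes
def read_phenotypes(
    path: str | Path, traits: list, factors: list | None = None
) -> PhenotypeTable:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    factors = factors if factors is not None else ["farm", "sex", "batch"]
    factors = [f for f in factors if f in df.columns]
    return PhenotypeTable(df, traits=list(traits), factors=factors)


def write_phenotypes(pt: PhenotypeTable, path: str | Path) -> None:
    pt.data.to_csv(path, sep="\t", index=False)
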