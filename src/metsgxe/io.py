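"""Readers and writers for the pipeline's file formats.

Formats: cohort/phenotype tables as TSV (``.`` for missing, ``#``
comment lines for provenance), genotypes as VCF v4.2 (GT only, read via
cyvcf2), gene intervals as BED4 (0-based half-open on disk, converted
once to 1-based inclusive in memory), gene sets as GMT. Readers validate
rather than silently coerce; writers round-trip with their readers.
Chromosome labels have any ``chr`` prefix stripped on read so VCF and
BED sources agree.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from . import constants as C
from .genotypes import GenotypeMatrix
from .gsea import GeneSetCollection

__all__ = [
    "read_vcf",
    "write_vcf",
    "read_pheno",
    "write_table",
    "read_bed",
    "write_bed",
    "read_gmt",
    "write_gmt",
    "provenance_lines",
]


def _norm_chrom(label: str) -> str:
    s = str(label)
    return s[3:] if s.lower().startswith("chr") else s


def read_vcf(path) -> GenotypeMatrix:
    """Parse a VCF into additive ALT dosages; multiallelic rows skipped."""
    vcf = VCF(str(path))
    subjects = np.array(vcf.samples)
    snp_ids, chroms, positions, refs, alts, rows = [], [], [], [], [], []
    n_multi = 0
    # cyvcf2 gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
    lut = np.array([0.0, 1.0, np.nan, 2.0])
    for idx, var in enumerate(vcf):
        if len(var.ALT) != 1:
            n_multi += 1
            continue
        gt = np.asarray(var.gt_types)
        if gt.shape != subjects.shape:
            raise ValueError(f"malformed genotype row at record {idx + 1} of {path}")
        rows.append(lut[gt])
        snp_ids.append(var.ID or f"{var.CHROM}:{var.POS}")
        chroms.append(_norm_chrom(var.CHROM))
        positions.append(var.POS)
        refs.append(var.REF)
        alts.append(var.ALT[0])
    if not rows:
        raise ValueError(f"no biallelic SNP records in {path}")
    gm = GenotypeMatrix(
        dosages=np.column_stack(rows) if len(rows) > 1 else np.asarray(rows).T,
        snp_ids=np.array(snp_ids),
        chromosomes=np.array(chroms),
        positions=np.array(positions, dtype=int),
        ref=np.array(refs),
        alt=np.array(alts),
        subject_ids=subjects,
    )
    gm.n_multiallelic_skipped = n_multi
    return gm


_GT_CODE = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}


def write_vcf(genotypes: GenotypeMatrix, path, header_extra: list[str] | None = None) -> None:
    """Write a minimal VCF v4.2 with GT only; missing calls as ``./.``."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for line in header_extra or []:
            fh.write(f"##{line}\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(map(str, genotypes.subject_ids))
            + "\n"
        )
        D = genotypes.dosages
        for j in range(genotypes.n_snps):
            calls = "\t".join(
                "./." if np.isnan(d) else _GT_CODE[d] for d in D[:, j]
            )
            fh.write(
                f"{genotypes.chromosomes[j]}\t{genotypes.positions[j]}\t"
                f"{genotypes.snp_ids[j]}\t{genotypes.ref[j]}\t{genotypes.alt[j]}\t"
                f".\tPASS\t.\tGT\t{calls}\n"
            )


def read_pheno(path, require=("subject_id", "aam")) -> pd.DataFrame:
    """Read a cohort TSV; mandatory columns are checked by name."""
    df = pd.read_csv(path, sep="\t", comment="#", na_values=["."])
    missing = [c for c in require if c not in df.columns]
    if missing:
        raise ValueError(f"phenotype file {path} lacks mandatory column(s): {missing}")
    return df


def write_table(df: pd.DataFrame, path, provenance: list[str] | None = None) -> None:
    """Write a TSV with ``.`` for missing and optional provenance header."""
    path = Path(path)
    with path.open("w") as fh:
        for line in provenance or []:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False, na_rep=".", float_format="%.6g")


def read_bed(path) -> pd.DataFrame:
    """BED4 -> DataFrame(gene_id, chrom, start, end), 1-based inclusive."""
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None,
        names=["chrom", "start", "end", "gene_id"],
        usecols=[0, 1, 2, 3],
    )
    if (df["start"] >= df["end"]).any():
        bad = df.loc[df["start"] >= df["end"]].head()
        raise ValueError(f"BED interval with start >= end in {path}:\n{bad}")
    out = pd.DataFrame(
        {
            "gene_id": df["gene_id"].astype(str),
            "chrom": df["chrom"].map(_norm_chrom),
            "start": df["start"].astype(int) + 1,  # 0-based half-open -> 1-based inclusive
            "end": df["end"].astype(int),
        }
    )
    return out


def write_bed(gene_intervals: pd.DataFrame, path) -> None:
    """Internal 1-based inclusive intervals -> BED4 on disk."""
    out = pd.DataFrame(
        {
            "chrom": gene_intervals["chrom"],
            "start": gene_intervals["start"].astype(int) - 1,
            "end": gene_intervals["end"].astype(int),
            "gene_id": gene_intervals["gene_id"],
        }
    )
    out.to_csv(path, sep="\t", index=False, header=False)


def read_gmt(path, gene_intervals: pd.DataFrame | None = None) -> GeneSetCollection:
    """GMT (set id, description, gene ids, tab-separated) -> collection.

    Duplicate genes within a line are dropped with a warning-style note
    in ``source_labels``-adjacent metadata; order is preserved.
    """
    import warnings

    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed GMT line {ln} in {path}: needs id, description, genes")
            pid, desc, genes = parts[0], parts[1], parts[2:]
            seen, uniq = set(), []
            for g in genes:
                if g and g not in seen:
                    uniq.append(g)
                    seen.add(g)
            if len(uniq) < len([g for g in genes if g]):
                warnings.warn(f"GMT line {ln}: duplicate gene ids in set {pid}; deduplicated")
            sets[pid] = uniq
            descriptions[pid] = desc
    if gene_intervals is None:
        gene_intervals = pd.DataFrame(
            {"gene_id": sorted({g for gs in sets.values() for g in gs})}
        ).assign(chrom="0", start=1, end=1)
    return GeneSetCollection(
        gene_intervals=gene_intervals, sets=sets, descriptions=descriptions
    )


def write_gmt(sets: dict[str, list[str]], descriptions: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for pid, genes in sets.items():
            fh.write("\t".join([pid, descriptions.get(pid, ""), *genes]) + "\n")


def provenance_lines(config: dict, seed: int | None = None) -> list[str]:
    """Stable provenance header: config hash + seed + package version."""
    from . import __version__

    blob = json.dumps(config, sort_keys=True, default=str).encode()
    digest = hashlib.sha256(blob).hexdigest()[:16]
    lines = [f"metsgxe {__version__}", f"config_sha256 {digest}"]
    if seed is not None:
        lines.append(f"seed {seed}")
    return lines
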