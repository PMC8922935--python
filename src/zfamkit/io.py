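"""File-format boundaries: FASTA, GFF3, VCF, population maps.

Internally everything is 0-based half-open; GFF3 and VCF keep their native
1-based conventions at the boundary.  Genotypes are haploid (selfing crop:
accessions are treated as inbred lines), coded 0 (ref), 1 (alt), -1
(missing) in an int8 samples x sites array.  On VCF input, heterozygous
diploid calls are recoded as missing; on output, haploid calls are written
as homozygous diploid genotypes.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

MISSING = -1

SITE_COLUMNS = ["chromosome", "position", "ref", "alt", "gene_id"]


@dataclass
class GenotypeMatrix:
    """Samples x biallelic sites with haploid 0/1/missing calls."""

    samples: list
    sites: pd.DataFrame  # columns SITE_COLUMNS; position is 1-based bp
    calls: np.ndarray  # int8, shape (n_samples, n_sites)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.samples), len(self.sites)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.samples)} samples x {len(self.sites)} sites"
            )
        self.sites = self.sites.reset_index(drop=True)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def take_sites(self, mask_or_index) -> "GenotypeMatrix":
        idx = np.asarray(mask_or_index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GenotypeMatrix(
            list(self.samples),
            self.sites.iloc[idx].reset_index(drop=True),
            self.calls[:, idx],
        )

    def take_samples(self, mask_or_index) -> "GenotypeMatrix":
        idx = np.asarray(mask_or_index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GenotypeMatrix(
            [self.samples[i] for i in idx],
            self.sites.copy(),
            self.calls[idx, :],
        )


def write_fasta(records: dict, path) -> None:
    """Write {id: sequence} to FASTA, deterministically in dict order."""
    seqs = [SeqRecord(Seq(s), id=k, description="") for k, s in records.items()]
    SeqIO.write(seqs, str(path), "fasta")


def read_fasta(path) -> dict:
    return {r.id: str(r.seq) for r in SeqIO.parse(str(path), "fasta")}


def write_gff3(catalog: pd.DataFrame, path) -> None:
    """Write a gene catalog (gene_id, chromosome, start, end; 1-based
    inclusive) as a minimal GFF3."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for r in catalog.itertuples(index=False):
            fh.write(
                f"{r.chromosome}\tzfamkit\tgene\t{r.start}\t{r.end}\t.\t+\t.\t"
                f"ID={r.gene_id}\n"
            )


def read_gff3(path) -> pd.DataFrame:
    """Read gene features from a GFF3 into a gene catalog table."""
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        header=None,
        names=[
            "chromosome", "source", "type", "start", "end",
            "score", "strand", "phase", "attributes",
        ],
    )
    df = df[df["type"] == "gene"].copy()
    df["gene_id"] = df["attributes"].str.extract(r"ID=([^;]+)")
    return df[["gene_id", "chromosome", "start", "end"]].reset_index(drop=True)


def write_population_map(pop_map: dict, path) -> None:
    with open(path, "w") as fh:
        for sample, pop in pop_map.items():
            fh.write(f"{sample}\t{pop}\n")


def read_population_map(path) -> dict:
    df = pd.read_csv(path, sep="\t", header=None, names=["sample", "population"])
    return dict(zip(df["sample"], df["population"]))


def write_vcf(matrix: GenotypeMatrix, path) -> None:
    """Serialize to VCF v4.2 with homozygous-diploid GT and './.' missing."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=zfamkit\n")
        fh.write('##INFO=<ID=GENE,Number=1,Type=String,Description="Gene id">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in pd.unique(matrix.sites["chromosome"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(matrix.samples)
            + "\n"
        )
        gt_str = {0: "0/0", 1: "1/1", MISSING: "./."}
        for j, site in enumerate(matrix.sites.itertuples(index=False)):
            info = f"GENE={site.gene_id}" if site.gene_id else "."
            gts = "\t".join(gt_str[int(g)] for g in matrix.calls[:, j])
            fh.write(
                f"{site.chromosome}\t{site.position}\t.\t{site.ref}\t{site.alt}"
                f"\t.\tPASS\t{info}\tGT\t{gts}\n"
            )


def read_vcf(path, gene_map: dict | None = None) -> GenotypeMatrix:
    """Load a VCF into a haploid GenotypeMatrix.

    Het calls become missing.  Gene assignment comes from the GENE INFO tag
    when present, else from ``gene_map`` ((chromosome, position) -> gene_id).
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows, calls = [], []
    for var in vcf:
        alt = var.ALT[0] if var.ALT else "."
        gene = var.INFO.get("GENE")
        if gene is None and gene_map is not None:
            gene = gene_map.get((var.CHROM, var.POS))
        rows.append((var.CHROM, var.POS, var.REF, alt, gene or ""))
        # gt_types: 0 HOM_REF, 1 HET, 2 UNKNOWN, 3 HOM_ALT
        gt = var.gt_types
        col = np.full(len(samples), MISSING, dtype=np.int8)
        col[gt == 0] = 0
        col[gt == 3] = 1
        calls.append(col)
    sites = pd.DataFrame(rows, columns=SITE_COLUMNS)
    arr = (
        np.stack(calls, axis=1)
        if calls
        else np.empty((len(samples), 0), dtype=np.int8)
    )
    return GenotypeMatrix(samples, sites, arr)


def write_tsv(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)
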