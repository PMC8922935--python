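"""Physicochemical annotation and positional gene naming.

Computes the classic protein-characterization quartet — molecular weight
(average isotopic masses, kDa), theoretical isoelectric point (Bjellqvist
pKa set, bisection), GRAVY (mean Kyte–Doolittle hydropathy) and the
Guruprasad instability index — plus the family naming convention that
numbers genes along chromosomes (e.g. HvC3H1..HvC3H53).

The numeric kernels are delegated to Biopython's ProtParam, which uses
exactly these conventions.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from importlib import resources

import pandas as pd
from Bio.SeqUtils.ProtParam import ProteinAnalysis

_STANDARD = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class ProteinProperties:
    protein_id: str
    length: int
    molecular_weight: float  # kDa
    isoelectric_point: float
    gravy: float
    instability_index: float


def _check(sequence: str, min_len: int = 1) -> None:
    if len(sequence) < min_len:
        raise ValueError(f"sequence too short (need >= {min_len} residues)")
    bad = set(sequence) - _STANDARD
    if bad:
        raise ValueError(f"non-standard residues not supported: {sorted(bad)}")


def compute_gravy(sequence: str) -> float:
    """Grand average of hydropathicity: mean Kyte–Doolittle score."""
    _check(sequence)
    return ProteinAnalysis(sequence).gravy()


def compute_mw(sequence: str) -> float:
    """Average-isotope molecular weight in kDa (3 decimals)."""
    _check(sequence)
    return round(ProteinAnalysis(sequence).molecular_weight() / 1000.0, 3)


def compute_pi(sequence: str) -> float:
    """Theoretical pI: pH of zero net charge, bisection to 0.01."""
    _check(sequence)
    return ProteinAnalysis(sequence).isoelectric_point()


def compute_instability(sequence: str) -> float:
    """Instability index: (10/L) x sum of DIWV dipeptide weights."""
    _check(sequence, min_len=2)
    return ProteinAnalysis(sequence).instability_index()


def compute_properties(protein_id: str, sequence: str) -> ProteinProperties:
    return ProteinProperties(
        protein_id=protein_id,
        length=len(sequence),
        molecular_weight=compute_mw(sequence),
        isoelectric_point=round(compute_pi(sequence), 2),
        gravy=round(compute_gravy(sequence), 3),
        instability_index=round(compute_instability(sequence), 2),
    )


def _chrom_key(label: str):
    """Natural sort key: 'chr2H' < 'chr10H'; non-numeric labels sort after."""
    parts = re.split(r"(\d+)", str(label))
    return tuple(int(p) if p.isdigit() else p for p in parts)


def assign_names(gene_models: pd.DataFrame, prefix: str) -> dict:
    """Number genes ``prefix``1..N by (chromosome natural order, start).

    ``gene_models`` needs columns gene_id, chromosome, start.  Duplicate
    (chromosome, start) pairs are broken deterministically by gene_id with a
    warning; the result is independent of input row order.
    """
    required = {"gene_id", "chromosome", "start"}
    missing = required - set(gene_models.columns)
    if missing:
        raise ValueError(f"gene catalog missing columns: {sorted(missing)}")
    rows = gene_models[["gene_id", "chromosome", "start"]].copy()
    dup = rows.duplicated(subset=["chromosome", "start"], keep=False)
    if dup.any():
        warnings.warn(
            "duplicate (chromosome, start) coordinates; breaking ties by gene_id",
            stacklevel=2,
        )
    ordered = sorted(
        rows.itertuples(index=False),
        key=lambda r: (_chrom_key(r.chromosome), r.start, str(r.gene_id)),
    )
    return {r.gene_id: f"{prefix}{i}" for i, r in enumerate(ordered, start=1)}


def summarize_properties(table: pd.DataFrame) -> dict:
    """Family-level summary of a per-protein property table.

    Expects columns length_aa, isoelectric_point, molecular_weight_kda,
    gravy, optionally subcellular_location.  Means are reported to 1 d.p.
    (length) and 3 d.p. (GRAVY); extremes are exact.  The nuclear fraction
    counts proteins annotated exclusively to the nucleus.
    """
    if table.empty:
        raise ValueError("empty property table")
    out = {
        "n_proteins": int(len(table)),
        "mean_length_aa": round(float(table["length_aa"].mean()), 1),
        "min_isoelectric_point": float(table["isoelectric_point"].min()),
        "max_isoelectric_point": float(table["isoelectric_point"].max()),
        "min_molecular_weight_kda": float(table["molecular_weight_kda"].min()),
        "max_molecular_weight_kda": float(table["molecular_weight_kda"].max()),
        "mean_gravy": round(float(table["gravy"].mean()), 3),
        "n_negative_gravy": int((table["gravy"] < 0).sum()),
    }
    if "subcellular_location" in table.columns:
        nuclear = (table["subcellular_location"] == "Nucleus").sum()
        out["n_nuclear"] = int(nuclear)
        out["nuclear_fraction_pct"] = round(100.0 * nuclear / len(table), 2)
    return out


def load_barley_table() -> pd.DataFrame:
    """Published property table for the 53 barley CCCH proteins.

    Transcribed printed values (name, id, chromosome, length, pI, MW,
    subcellular location, GRAVY, EST-hit count); the sequences themselves
    are not shipped.
    """
    with resources.files("zfamkit.data").joinpath("barley_ccch_table1.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")
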