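"""Synthetic inputs with known ground truth for every pipeline stage.

Four generators emulate the study inputs of a CCCH-family domestication
analysis:

* :func:`make_proteome` — proteins with planted CCCH / TZF / RR-TZF /
  ANK-RR-TZF architectures.  Background segments are rejection-sampled:
  whole proteins whose greedy scan does not reproduce the planted truth
  exactly are regenerated, so truth tables are exact and scanner checks are
  binary.  Spacer and linker residues exclude C and H so a planted finger
  admits exactly one parse.
* :func:`make_gene_catalog` — chromosome-ordered gene models with planted
  tandem (adjacent) and segmental (cross-chromosome or separated) pairs.
* :func:`make_genotypes` — a wild + landrace haploid genotype panel whose
  domestication bottleneck is modeled as founder-pool subsampling: landrace
  haplotypes are drawn per gene from a subset of the wild founder pool.
  Expected per-site diversity for a pool of K equally likely founders is
  E[pi] ~= 0.5*(1 - 1/K), so the default pools of 20 (wild) and 3
  (landrace) target a ~30% reduction in π.
* :func:`make_expression` — FPKM matrices with planted stress/control fold
  changes.

All generators are deterministic functions of their explicit seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import motif_scan
from .io import MISSING, GenotypeMatrix

#: background residue alphabet; C and H are sampled at reduced frequency so
#: rejection sampling converges quickly while still exercising decoys
_BACKGROUND_AA = "ADEFGIKLMNPQRSTVWY"
_SPACER_AA = "ADEFGIKLMNPQRSTVWY"  # no C/H: planted fingers parse uniquely


@dataclass
class ProteomeSpec:
    n_proteins: int = 50
    architecture_mix: tuple = (
        ("CCCH", 0.6),
        ("TZF", 0.2),
        ("RR-TZF", 0.15),
        ("ANK-RR-TZF", 0.05),
    )
    planted_motif_types: tuple = ((7, 5), (8, 5), (5, 4), (7, 4), (9, 5))
    length_range: tuple = (120, 700)
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(p for _, p in self.architecture_mix)
        if abs(total - 1.0) > 1e-9:
            raise ValueError("architecture_mix proportions must sum to 1")
        for a, b in self.planted_motif_types:
            if not (4 <= a <= 17 and 4 <= b <= 6):
                raise ValueError(f"spacer signature ({a},{b}) out of range")
        # longest footprint: RR window + TZF (finger1 max + linker + finger2)
        footprint = 30 + (8 + 5 + 7 + 4) + 18 + (5 + 4 + 7 + 4)
        if self.length_range[0] < footprint:
            raise ValueError(
                f"min length {self.length_range[0]} below the longest planted "
                f"architecture footprint ({footprint})"
            )


@dataclass
class BottleneckSpec:
    n_wild: int = 51
    n_landrace: int = 95
    n_genes: int = 30
    sites_per_gene: int = 10
    founder_pool_wild: int = 20
    founder_pool_landrace: int = 3
    mutation_rate_per_site: float = 0.005
    missing_rate: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.founder_pool_landrace > self.founder_pool_wild:
            raise ValueError("landrace founder pool must not exceed wild pool")
        for name in ("n_wild", "n_landrace", "n_genes", "sites_per_gene"):
            if getattr(self, name) < 2:
                raise ValueError(f"{name} must be >= 2")
        if self.founder_pool_wild < 1 or self.founder_pool_landrace < 1:
            raise ValueError("founder pools must be >= 1")


def _motif_sequence(rng, a: int, b: int) -> str:
    sp = lambda k: "".join(rng.choice(list(_SPACER_AA), size=k))
    return "C" + sp(a) + "C" + sp(b) + "C" + sp(3) + "H"


def _tzf_sequence(rng) -> tuple:
    """Returns (sequence, [(a1, b1), (a2, b2)]) for a tandem finger."""
    a1 = int(rng.choice([7, 8]))
    linker = int(rng.choice([16, 18]))
    f1 = _motif_sequence(rng, a1, 5)
    f2 = _motif_sequence(rng, 5, 4)
    mid = "".join(rng.choice(list(_SPACER_AA), size=linker))
    return f1 + mid + f2, [(a1, 5), (5, 4)]


def _rr_window(rng, length: int = 30, n_arg: int = 8) -> str:
    residues = list(rng.choice(list(_SPACER_AA), size=length))
    pos = rng.choice(length, size=n_arg, replace=False)
    for p in pos:
        residues[p] = "R"
    return "".join(residues)


def _background(rng, length: int) -> str:
    if length <= 0:
        return ""
    return "".join(rng.choice(list(_BACKGROUND_AA + "CH"), size=length))


def make_proteome(spec: ProteomeSpec):
    """Generate (records, truth, domain_annotations).

    ``records`` maps protein_id -> sequence.  ``truth`` is a DataFrame with
    one row per planted motif (protein_id, start, end, spacer1, spacer2,
    architecture).  ``domain_annotations`` lists external domain spans
    (protein_id, domain, start, end; 1-based inclusive) — the ANK domain of
    every planted ANK-RR-TZF protein.
    """
    rng = np.random.default_rng(spec.seed)
    labels = [a for a, _ in spec.architecture_mix]
    probs = np.array([p for _, p in spec.architecture_mix])
    records: dict = {}
    truth_rows = []
    domain_rows = []
    for i in range(spec.n_proteins):
        pid = f"SYN{i + 1:03d}"
        arch = labels[int(rng.choice(len(labels), p=probs))]
        length = int(rng.integers(spec.length_range[0], spec.length_range[1] + 1))
        for _attempt in range(200):
            seq, motifs, domains = _assemble_protein(rng, pid, arch, length, spec)
            if _scan_matches(seq, motifs, arch):
                break
        else:  # pragma: no cover - rejection loop essentially always succeeds
            raise RuntimeError(f"could not assemble {pid} without stray motifs")
        records[pid] = seq
        for start, end, a, b in motifs:
            truth_rows.append((pid, start, end, a, b, arch))
        domain_rows.extend(domains)
    truth = pd.DataFrame(
        truth_rows,
        columns=["protein_id", "start", "end", "spacer1", "spacer2", "architecture"],
    )
    domain_annotations = pd.DataFrame(
        domain_rows, columns=["protein_id", "domain", "start", "end"]
    )
    return records, truth, domain_annotations


def _assemble_protein(rng, pid, arch, length, spec):
    """One candidate protein; returns (sequence, motif coords, domain rows)."""
    domains = []
    if arch == "CCCH":
        n_motifs = int(rng.integers(1, 4))
        parts, coords = [], []
        # leading background, then motifs separated by background
        remaining = length
        segs = []
        for _ in range(n_motifs):
            a, b = spec.planted_motif_types[
                int(rng.integers(len(spec.planted_motif_types)))
            ]
            segs.append(_motif_sequence(rng, a, b))
        core = sum(len(s) for s in segs)
        gap_total = max(length - core, (n_motifs + 1) * 5)
        cuts = np.sort(rng.integers(0, gap_total + 1, size=n_motifs))
        gaps = np.diff(np.concatenate([[0], cuts, [gap_total]]))
        pos = 0
        for seg, gap in zip(segs, gaps[:-1]):
            bg = _background(rng, int(gap))
            parts.append(bg)
            pos += len(bg)
            parts.append(seg)
            coords.append((pos, pos + len(seg), seg))
            pos += len(seg)
        parts.append(_background(rng, int(gaps[-1])))
        seq = "".join(parts)
        motifs = []
        for start, end, seg in coords:
            a = seg.index("C", 1) - 1
            b = seg.index("C", a + 2) - (a + 2)
            motifs.append((start, end, a, b))
        return seq, motifs, domains

    # TZF-based architectures
    tzf_seq, fingers = _tzf_sequence(rng)
    upstream_len = max(40, int(rng.integers(40, max(41, length // 2))))
    if arch in ("RR-TZF", "ANK-RR-TZF"):
        rr = _rr_window(rng)
        head = _background(rng, upstream_len - len(rr)) + rr
    else:
        head = _background(rng, upstream_len)
    tail_len = max(10, length - len(head) - len(tzf_seq))
    tail = _background(rng, tail_len)
    seq = head + tzf_seq + tail
    start = len(head)
    motifs = []
    pos = start
    a1, b1 = fingers[0]
    len1 = a1 + b1 + 7
    motifs.append((pos, pos + len1, a1, b1))
    a2, b2 = fingers[1]
    linker = len(tzf_seq) - len1 - (a2 + b2 + 7)
    pos2 = pos + len1 + linker
    motifs.append((pos2, pos2 + a2 + b2 + 7, a2, b2))
    if arch == "ANK-RR-TZF":
        # ANK span in the tail (external annotation; sequence content is
        # irrelevant because domains are consumed, not predicted)
        ank_start = len(head) + len(tzf_seq) + 2
        domains.append((pid, "ANK", ank_start + 1, min(ank_start + 33, len(seq))))
    return seq, motifs, domains


def _scan_matches(seq, motifs, arch) -> bool:
    """Accept a candidate only if the greedy scan recovers exactly the
    planted motifs and the architecture call matches the intent."""
    hits = motif_scan.scan_ccch(seq)
    found = [(h.start, h.end, h.spacer1, h.spacer2) for h in hits]
    if found != sorted(motifs):
        return False
    spans = motif_scan.detect_tzf(hits, seq)
    flags = [motif_scan.detect_rr(seq, s) for s in spans]
    wants_tzf = arch in ("TZF", "RR-TZF", "ANK-RR-TZF")
    wants_rr = arch in ("RR-TZF", "ANK-RR-TZF")
    if wants_tzf != bool(spans):
        return False
    if wants_rr != any(flags):
        return False
    return True


def make_gene_catalog(
    n_chromosomes: int,
    genes_per_chromosome: int,
    planted_tandem_pairs: int = 0,
    planted_segmental_pairs: int = 0,
    seed: int = 0,
):
    """Generate (catalog, pairs) with known duplication classes.

    The catalog is a full annotation (gene_id, chromosome, start, end);
    tandem pairs occupy consecutive positions on one chromosome, segmental
    pairs span chromosomes.  ``pairs`` carries gene_a, gene_b, ka, ks and
    the intended class.
    """
    if planted_tandem_pairs > n_chromosomes * (genes_per_chromosome // 2):
        raise ValueError("too many tandem pairs for the catalog size")
    if planted_segmental_pairs > 0 and n_chromosomes < 2:
        raise ValueError("segmental pairs need >= 2 chromosomes")
    rng = np.random.default_rng(seed)
    rows = []
    for c in range(1, n_chromosomes + 1):
        pos = 1000
        for g in range(1, genes_per_chromosome + 1):
            gid = f"GENE.{c}H.{g:03d}"
            glen = int(rng.integers(1_000, 6_000))
            rows.append((gid, f"chr{c}H", pos, pos + glen - 1))
            pos += glen + int(rng.integers(2_000, 20_000))
    catalog = pd.DataFrame(rows, columns=["gene_id", "chromosome", "start", "end"])

    pair_rows = []
    used: set = set()

    def _ks_ka():
        ks = float(rng.uniform(0.05, 1.2))
        ka = ks * float(rng.uniform(0.05, 0.8))  # purifying regime
        return ka, ks

    # tandem: adjacent genes on a chromosome
    chroms = list(range(1, n_chromosomes + 1))
    t = 0
    while t < planted_tandem_pairs:
        c = chroms[t % n_chromosomes]
        starts = [
            g for g in range(1, genes_per_chromosome)
            if (c, g) not in used and (c, g + 1) not in used
        ]
        if not starts:
            raise ValueError("cannot place all tandem pairs")
        g = starts[int(rng.integers(len(starts)))]
        used.update({(c, g), (c, g + 1)})
        ka, ks = _ks_ka()
        pair_rows.append(
            (f"GENE.{c}H.{g:03d}", f"GENE.{c}H.{g + 1:03d}", ka, ks, "tandem")
        )
        t += 1
    # segmental: genes on different chromosomes
    s = 0
    while s < planted_segmental_pairs:
        c1, c2 = rng.choice(chroms, size=2, replace=False)
        g1 = int(rng.integers(1, genes_per_chromosome + 1))
        g2 = int(rng.integers(1, genes_per_chromosome + 1))
        if (c1, g1) in used or (c2, g2) in used:
            continue
        used.update({(c1, g1), (c2, g2)})
        ka, ks = _ks_ka()
        pair_rows.append(
            (f"GENE.{c1}H.{g1:03d}", f"GENE.{c2}H.{g2:03d}", ka, ks, "segmental")
        )
        s += 1
    pairs = pd.DataFrame(
        pair_rows, columns=["gene_a", "gene_b", "ka", "ks", "class"]
    )
    return catalog, pairs


def make_genotypes(spec: BottleneckSpec):
    """Generate (matrix, pop_map) under the founder-pool bottleneck model.

    Per gene, ``founder_pool_wild`` haploid founder haplotypes are drawn
    with allele frequency 1/2 per site; wild samples copy a random founder,
    landrace samples copy a random founder from a fixed subset of size
    ``founder_pool_landrace``.  Mutation flips alleles independently;
    missingness is applied uniformly afterwards.
    """
    rng = np.random.default_rng(spec.seed)
    if spec.founder_pool_wild == 1 and spec.founder_pool_landrace == 1:
        warnings.warn("single founder in both pools: all sites monomorphic",
                      stacklevel=2)
    samples = [f"WB{i + 1:03d}" for i in range(spec.n_wild)] + [
        f"LR{i + 1:03d}" for i in range(spec.n_landrace)
    ]
    pop_map = {s: ("wild" if s.startswith("WB") else "landrace") for s in samples}
    blocks = []
    site_rows = []
    bases = ("A", "C", "G", "T")
    for g in range(spec.n_genes):
        gene_id = f"GENE.{g + 1:03d}"
        founders = rng.integers(
            0, 2, size=(spec.founder_pool_wild, spec.sites_per_gene)
        ).astype(np.int8)
        landrace_pool = rng.choice(
            spec.founder_pool_wild, size=spec.founder_pool_landrace, replace=False
        )
        wild_pick = rng.integers(0, spec.founder_pool_wild, size=spec.n_wild)
        land_pick = landrace_pool[
            rng.integers(0, spec.founder_pool_landrace, size=spec.n_landrace)
        ]
        calls = founders[np.concatenate([wild_pick, land_pick]), :].copy()
        if spec.mutation_rate_per_site > 0:
            flips = rng.random(calls.shape) < spec.mutation_rate_per_site
            calls[flips] = 1 - calls[flips]
        if spec.missing_rate > 0:
            miss = rng.random(calls.shape) < spec.missing_rate
            calls[miss] = MISSING
        blocks.append(calls)
        chrom = f"chr{g % 7 + 1}H"
        base_pos = 10_000 * (g + 1)
        for j in range(spec.sites_per_gene):
            ref, alt = rng.choice(4, size=2, replace=False)
            site_rows.append(
                (chrom, base_pos + j * 97, bases[ref], bases[alt], gene_id)
            )
    calls = np.concatenate(blocks, axis=1)
    sites = pd.DataFrame(
        site_rows, columns=["chromosome", "position", "ref", "alt", "gene_id"]
    )
    return GenotypeMatrix(samples, sites, calls), pop_map


def make_expression(
    n_genes: int,
    conditions: list,
    planted_fold_changes: dict | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    base_fpkm_range: tuple = (1.0, 50.0),
):
    """Generate (fpkm matrix, condition_map, truth).

    ``conditions`` lists (condition, control_or_None); conditions with a
    control get FPKM = control x fold where the fold is taken from
    ``planted_fold_changes`` ({(gene, condition): fold}, default 1.0), plus
    optional Gaussian noise truncated at zero.  ``truth`` records every
    planted fold.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    planted_fold_changes = planted_fold_changes or {}
    rng = np.random.default_rng(seed)
    genes = [f"GENE.{i + 1:03d}" for i in range(n_genes)]
    condition_map = dict(conditions)
    controls = [c for c, ctrl in conditions if ctrl is None]
    data = pd.DataFrame(index=genes, columns=[c for c, _ in conditions], dtype=float)
    for c in controls:
        data[c] = rng.uniform(*base_fpkm_range, size=n_genes)
    truth_rows = []
    for cond, ctrl in conditions:
        if ctrl is None:
            continue
        folds = np.array(
            [planted_fold_changes.get((g, cond), 1.0) for g in genes]
        )
        vals = data[ctrl].to_numpy() * folds
        if noise_sd > 0:
            vals = np.maximum(vals + rng.normal(0, noise_sd, size=n_genes), 0.0)
        data[cond] = vals
        for g, f in zip(genes, folds):
            truth_rows.append((g, cond, f))
    truth = pd.DataFrame(truth_rows, columns=["gene", "condition", "fold"])
    return data, condition_map, truth
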