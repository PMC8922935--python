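"""End-to-end orchestration and the EST-support filter.

``run_all`` drives scan -> properties/naming -> duplication -> population
genetics -> expression on a fully synthetic study (all inputs generated
from the run seed), writes every stage output under one directory, and
emits a single summary table of headline statistics plus a run log.  All
thresholds live in :class:`RunConfig` and are echoed verbatim into the
output directory.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import duplication, expression_utils, motif_scan, popgen, synthetic_data
from . import io as zio
from . import protparam


@dataclass
class RunConfig:
    out_dir: str = "zfamkit_run"
    seed: int = 0
    # motif scan
    spacer1_min: int = 4
    spacer1_max: int = 17
    spacer2_min: int = 4
    spacer2_max: int = 6
    rr_window: int = 30
    rr_min_arg: int = 6
    # duplication
    max_intervening: int = 0
    lambda_rate: float = 6.5e-9
    # popgen
    maf_low: float = 0.05
    maf_high: float = 0.95
    max_missing: float = 0.1
    max_sample_missing: float = 0.1
    mj_epsilon: int = 0
    n_components: int = 3
    # expression
    fold_threshold: float = 2.0
    pseudocount: float = 0.01
    # synthetic study sizes
    n_proteins: int = 53
    n_chromosomes: int = 7
    genes_per_chromosome: int = 8
    tandem_pairs: int = 2
    segmental_pairs: int = 4

    def write(self, path) -> None:
        with open(path, "w") as fh:
            for f in dataclasses.fields(self):
                fh.write(f"{f.name}: {getattr(self, f.name)}\n")


def est_support_filter(hit_table: pd.DataFrame) -> set:
    """Queries with >= 1 hit passing e-value < 1e-5, identity > 70 and
    coverage > 70 (all strict)."""
    required = {"query", "subject", "e_value", "identity", "coverage"}
    missing = required - set(hit_table.columns)
    if missing:
        raise ValueError(f"hit table missing columns: {sorted(missing)}")
    for i, row in enumerate(hit_table.itertuples(index=False)):
        try:
            float(row.e_value), float(row.identity), float(row.coverage)
        except (TypeError, ValueError) as exc:
            raise ValueError(f"malformed hit-table row {i + 1}: {row}") from exc
    ok = hit_table[
        (hit_table["e_value"].astype(float) < 1e-5)
        & (hit_table["identity"].astype(float) > 70)
        & (hit_table["coverage"].astype(float) > 70)
    ]
    return set(ok["query"])


def run_all(config: RunConfig) -> dict:
    """Run every stage on synthetic inputs; returns the summary dict."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines = []

    def log(msg):
        log_lines.append(msg)

    stage = "config"
    try:
        config.write(out / "config.txt")
        import zfamkit

        log(f"zfamkit {zfamkit.__version__}; seed {config.seed}")

        # ------------------------------------------------------------------
        stage = "synthetic inputs"
        pspec = synthetic_data.ProteomeSpec(
            n_proteins=config.n_proteins, seed=config.seed
        )
        records, motif_truth, domains = synthetic_data.make_proteome(pspec)
        zio.write_fasta(records, out / "proteome.fasta")
        zio.write_tsv(domains, out / "domains.tsv")
        catalog, pairs = synthetic_data.make_gene_catalog(
            config.n_chromosomes,
            config.genes_per_chromosome,
            config.tandem_pairs,
            config.segmental_pairs,
            seed=config.seed + 1,
        )
        zio.write_gff3(catalog, out / "genes.gff3")
        bspec = synthetic_data.BottleneckSpec(seed=config.seed + 2)
        matrix, pop_map = synthetic_data.make_genotypes(bspec)
        zio.write_vcf(matrix, out / "genotypes.vcf")
        zio.write_population_map(pop_map, out / "populations.tsv")
        conditions = [("control", None), ("cold", "control"), ("salt", "control")]
        planted = {("GENE.001", "cold"): 8.23, ("GENE.002", "cold"): 4.57,
                   ("GENE.003", "salt"): 2.17}
        fpkm, condition_map, expr_truth = synthetic_data.make_expression(
            20, conditions, planted, noise_sd=0.0, seed=config.seed + 3
        )
        fpkm.to_csv(out / "fpkm.tsv", sep="\t")
        log(
            f"inputs: {len(records)} proteins, {len(catalog)} genes, "
            f"{matrix.n_samples} samples x {matrix.n_sites} sites"
        )

        # ------------------------------------------------------------------
        stage = "motif scan"
        s1 = (config.spacer1_min, config.spacer1_max)
        s2 = (config.spacer2_min, config.spacer2_max)
        dom_by_protein = domains.groupby("protein_id")["domain"].apply(set).to_dict()
        all_hits, calls = [], []
        for pid, seq in records.items():
            hits, spans, call = motif_scan.scan_protein(
                pid, seq, s1, s2, config.rr_window, config.rr_min_arg,
                dom_by_protein.get(pid, ()),
            )
            all_hits.extend(hits)
            if call is not None:
                calls.append(call)
        census = motif_scan.motif_census(all_hits, len(records))
        zio.write_tsv(
            pd.DataFrame(
                [(h.protein_id, h.start, h.end, h.spacer1, h.spacer2, h.type_label)
                 for h in all_hits],
                columns=["protein_id", "start", "end", "spacer1", "spacer2", "type"],
            ),
            out / "motif_hits.tsv",
        )
        zio.write_tsv(
            pd.DataFrame(census.per_type, columns=["type", "count"]),
            out / "motif_census.tsv",
        )
        arch_counts = pd.Series(
            [c.architecture for c in calls]
        ).value_counts().to_dict()
        log(f"scan: {census.total_motifs} motifs, architectures {arch_counts}")

        # ------------------------------------------------------------------
        stage = "properties and naming"
        names = protparam.assign_names(catalog, prefix="SYNC3H")
        props = [
            protparam.compute_properties(pid, seq) for pid, seq in records.items()
        ]
        props_df = pd.DataFrame(
            [(p.protein_id, p.length, p.isoelectric_point, p.molecular_weight,
              p.gravy, p.instability_index) for p in props],
            columns=["protein_id", "length_aa", "isoelectric_point",
                     "molecular_weight_kda", "gravy", "instability_index"],
        )
        zio.write_tsv(props_df, out / "properties.tsv")
        prop_summary = protparam.summarize_properties(props_df)
        log(f"properties: mean length {prop_summary['mean_length_aa']}")

        # ------------------------------------------------------------------
        stage = "duplication"
        dup = duplication.annotate_pairs(
            pairs.drop(columns=["class"]),
            catalog,
            max_intervening=config.max_intervening,
            lambda_rate=config.lambda_rate,
        )
        zio.write_tsv(dup, out / "duplication.tsv")
        log(
            "duplication: "
            f"{(dup['class'] == 'tandem').sum()} tandem, "
            f"{(dup['class'] == 'segmental').sum()} segmental"
        )

        # ------------------------------------------------------------------
        stage = "population genetics"
        n_sites0 = matrix.n_sites
        matrix = popgen.filter_samples(matrix, config.max_sample_missing)
        filtered, filt_log = popgen.filter_sites(
            matrix, config.maf_low, config.maf_high, config.max_missing
        )
        zio.write_tsv(filt_log, out / "site_filter_log.tsv")
        log(f"filters: {n_sites0} -> {filtered.n_sites} sites, "
            f"{filtered.n_samples} samples")
        wild = [s for s, p in pop_map.items() if p == "wild" and s in filtered.samples]
        land = [s for s, p in pop_map.items()
                if p == "landrace" and s in filtered.samples]
        div_w = popgen.nucleotide_diversity(filtered, wild, "wild")
        div_l = popgen.nucleotide_diversity(filtered, land, "landrace")
        reduction = popgen.diversity_reduction(div_w.pi_overall, div_l.pi_overall)
        zio.write_tsv(
            pd.DataFrame(
                [("wild", g, v) for g, v in div_w.pi_per_gene.items()]
                + [("landrace", g, v) for g, v in div_l.pi_per_gene.items()],
                columns=["population", "gene_id", "pi"],
            ),
            out / "pi_per_gene.tsv",
        )
        hap_rows, n_haplotypes, genes_with_haps = [], 0, 0
        network_edges = []
        for gene in pd.unique(filtered.sites["gene_id"]):
            table = popgen.call_haplotypes(filtered, gene, pop_map)
            if not table.haplotypes:
                continue
            genes_with_haps += 1
            n_haplotypes += len(table.haplotypes)
            dom_w = popgen.dominant_haplotype(table, "wild")
            dom_l = popgen.dominant_haplotype(table, "landrace")
            for h, cw, cl in table.haplotypes:
                hap_rows.append(
                    (gene, h, cw, cl, h == dom_w, h == dom_l, table.n_dropped_samples)
                )
            net = popgen.build_mj_network(
                [h for h, _, _ in table.haplotypes], config.mj_epsilon
            )
            for u, v, w in net.graph.edges(data="weight"):
                network_edges.append((gene, u, v, w))
        zio.write_tsv(
            pd.DataFrame(
                hap_rows,
                columns=["gene_id", "haplotype", "count_wild", "count_landrace",
                         "dominant_wild", "dominant_landrace", "n_dropped"],
            ),
            out / "haplotypes.tsv",
        )
        zio.write_tsv(
            pd.DataFrame(network_edges,
                         columns=["gene_id", "node_a", "node_b", "mutations"]),
            out / "mj_network_edges.tsv",
        )
        pca = popgen.genotype_pca(filtered, config.n_components)
        zio.write_tsv(
            pd.DataFrame(
                pca.coordinates,
                columns=[f"PC{i + 1}" for i in range(pca.coordinates.shape[1])],
            ).assign(sample=pca.samples, population=[
                pop_map[s] for s in pca.samples
            ]),
            out / "pca_coordinates.tsv",
        )
        log(f"popgen: pi wild {div_w.pi_overall:.4f}, "
            f"landrace {div_l.pi_overall:.4f}, reduction {reduction:.2f}%")

        # ------------------------------------------------------------------
        stage = "expression"
        transformed = expression_utils.log_transform(fpkm)
        transformed.to_csv(out / "fpkm_log2.tsv", sep="\t")
        calls_df = expression_utils.fold_change_calls(
            fpkm, condition_map, config.fold_threshold, config.pseudocount
        )
        zio.write_tsv(calls_df, out / "expression_calls.tsv")
        n_induced = int((calls_df["direction"] == "induced").sum())
        log(f"expression: {n_induced} induced calls")

        # ------------------------------------------------------------------
        stage = "summary"
        summary = {
            "total_proteins": len(records),
            "total_motifs": census.total_motifs,
            "mean_motifs_per_protein": round(census.mean_motifs_per_protein, 2),
            "n_named_genes": len(names),
            "mean_protein_length_aa": prop_summary["mean_length_aa"],
            "n_tandem_pairs": int((dup["class"] == "tandem").sum()),
            "n_segmental_pairs": int((dup["class"] == "segmental").sum()),
            "n_snps_retained": filtered.n_sites,
            "pi_wild": round(div_w.pi_overall, 4),
            "pi_landrace": round(div_l.pi_overall, 4),
            "pi_reduction_pct": round(reduction, 2),
            "n_haplotypes": n_haplotypes,
            "mean_haplotypes_per_gene": round(
                n_haplotypes / genes_with_haps, 2
            ) if genes_with_haps else 0.0,
            "n_induced_calls": n_induced,
        }
        zio.write_tsv(
            pd.DataFrame(summary.items(), columns=["statistic", "value"]),
            out / "summary.tsv",
        )
        with open(out / "run.log", "w") as fh:
            fh.write("\n".join(log_lines) + "\n")
        return summary
    except Exception:
        (out / "FAILED").write_text(f"stage: {stage}\n")
        with open(out / "run.log", "w") as fh:
            fh.write("\n".join(log_lines) + f"\nFAILED at stage: {stage}\n")
        raise
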