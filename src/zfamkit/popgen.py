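"""Population-level diversity, haplotype and structure analysis.

Works on haploid biallelic genotype matrices (see :mod:`zfamkit.io`).  The
stages mirror a standard domestication-bottleneck workflow:

* site filtering by minor-allele frequency, missing rate and biallelism,
  and sample filtering by per-sample missing rate (strict thresholds);
* nucleotide diversity per site, π_site = n/(n-1) * (1 - p^2 - q^2) with n
  the non-missing call count and p the alternate-allele frequency, averaged
  per gene and over all retained SNP sites per population;
* percent reduction of π from the wild to the domesticated population — the
  bottleneck statistic;
* per-gene haplotype enumeration (complete cases only) with per-population
  counts, dominant haplotypes (strictly more than half of a population);
* median-joining haplotype networks (minimum-spanning network plus
  length-reducing consensus median vectors);
* genotype PCA with allele-frequency scaling.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .io import MISSING, GenotypeMatrix

DEFAULT_MAF_LOW = 0.05
DEFAULT_MAF_HIGH = 0.95
DEFAULT_MAX_MISSING = 0.1


# ---------------------------------------------------------------------------
# filtering

def filter_sites(
    matrix: GenotypeMatrix,
    maf_low: float = DEFAULT_MAF_LOW,
    maf_high: float = DEFAULT_MAF_HIGH,
    max_missing: float = DEFAULT_MAX_MISSING,
):
    """Retain biallelic sites with alt frequency strictly inside
    (maf_low, maf_high) and missing fraction strictly below ``max_missing``.

    Returns ``(filtered_matrix, log)`` where the log lists one row per
    removed site with the first failing rule.
    """
    calls = matrix.calls
    n_samples = matrix.n_samples
    keep = np.ones(matrix.n_sites, dtype=bool)
    reasons = []
    for j in range(matrix.n_sites):
        site = matrix.sites.iloc[j]
        col = calls[:, j]
        obs = col != MISSING
        reason = None
        if (
            not site["ref"]
            or not site["alt"]
            or site["alt"] in (".", "")
            or site["ref"] == site["alt"]
        ):
            reason = "not_biallelic"
        elif n_samples and (col == MISSING).mean() >= max_missing:
            reason = "missing_rate"
        else:
            n_obs = obs.sum()
            freq = col[obs].mean() if n_obs else 0.0
            if not (maf_low < freq < maf_high):
                reason = "allele_frequency"
        if reason is not None:
            keep[j] = False
            reasons.append(
                (site["chromosome"], site["position"], reason)
            )
    log = pd.DataFrame(reasons, columns=["chromosome", "position", "reason"])
    if not keep.any():
        warnings.warn("all sites removed by filtering", stacklevel=2)
    return matrix.take_sites(keep), log


def filter_samples(
    matrix: GenotypeMatrix, max_sample_missing: float = DEFAULT_MAX_MISSING
) -> GenotypeMatrix:
    """Drop samples whose missing fraction exceeds the threshold."""
    if matrix.n_sites == 0:
        return matrix
    miss = (matrix.calls == MISSING).mean(axis=1)
    keep = miss <= max_sample_missing
    if not keep.any():
        warnings.warn("all samples removed by filtering", stacklevel=2)
    return matrix.take_samples(keep)


# ---------------------------------------------------------------------------
# diversity

@dataclass
class DiversityResult:
    population: str
    pi_per_gene: dict
    pi_overall: float
    n_sites_used: int


def site_pi(calls_col: np.ndarray) -> float:
    """Unbiased per-site π: n/(n-1) * (1 - p^2 - q^2) over non-missing calls.

    Equals the mean pairwise difference at the site over all sample pairs.
    Returns NaN when fewer than two calls are observed.
    """
    obs = calls_col[calls_col != MISSING]
    n = obs.size
    if n < 2:
        return float("nan")
    p = obs.mean()
    q = 1.0 - p
    return n / (n - 1.0) * (1.0 - p * p - q * q)


def nucleotide_diversity(
    matrix: GenotypeMatrix, population_samples, population: str = ""
) -> DiversityResult:
    """π per gene and overall for one population subset."""
    idx = [i for i, s in enumerate(matrix.samples) if s in set(population_samples)]
    if len(idx) < 2:
        raise ValueError("population needs at least 2 samples")
    sub = matrix.calls[idx, :]
    pis = np.array([site_pi(sub[:, j]) for j in range(matrix.n_sites)])
    used = ~np.isnan(pis)
    genes = matrix.sites["gene_id"].to_numpy()
    per_gene = {}
    for g in pd.unique(genes):
        sel = used & (genes == g)
        if sel.any():
            per_gene[g] = float(pis[sel].mean())
    overall = float(pis[used].mean()) if used.any() else float("nan")
    return DiversityResult(population, per_gene, overall, int(used.sum()))


def diversity_reduction(pi_wild: float, pi_domesticated: float) -> float:
    """Bottleneck statistic: percent loss of π from wild to domesticated."""
    if pi_wild == 0:
        return float("nan")
    return 100.0 * (pi_wild - pi_domesticated) / pi_wild


# ---------------------------------------------------------------------------
# haplotypes

@dataclass
class HaplotypeTable:
    gene_id: str
    haplotypes: list  # (allele string, count_wild, count_landrace)
    n_dropped_samples: int
    populations: tuple = ("wild", "landrace")

    @property
    def total_retained(self) -> int:
        return sum(cw + cl for _, cw, cl in self.haplotypes)

    def population_total(self, population: str) -> int:
        k = self.populations.index(population) + 1
        return sum(h[k] for h in self.haplotypes)


def call_haplotypes(
    matrix: GenotypeMatrix,
    gene_id: str,
    pop_map: dict,
    populations: tuple = ("wild", "landrace"),
) -> HaplotypeTable:
    """Enumerate complete-case allele strings of one gene's sites.

    Samples with any missing call across the gene's sites are dropped and
    counted.  Haplotypes are ordered by total count descending, then
    lexicographically.
    """
    cols = np.flatnonzero((matrix.sites["gene_id"] == gene_id).to_numpy())
    if cols.size == 0:
        warnings.warn(f"gene {gene_id} has no retained sites", stacklevel=2)
        return HaplotypeTable(gene_id, [], 0, populations)
    sub = matrix.calls[:, cols]
    counts: dict = {}
    dropped = 0
    for i, sample in enumerate(matrix.samples):
        row = sub[i]
        if (row == MISSING).any():
            dropped += 1
            continue
        hap = "".join(str(int(a)) for a in row)
        pop = pop_map.get(sample)
        if hap not in counts:
            counts[hap] = dict.fromkeys(populations, 0)
        if pop in counts[hap]:
            counts[hap][pop] += 1
    ordered = sorted(
        counts.items(), key=lambda kv: (-sum(kv[1].values()), kv[0])
    )
    haps = [
        (h, *[c[p] for p in populations]) for h, c in ordered
    ]
    return HaplotypeTable(gene_id, haps, dropped, populations)


def dominant_haplotype(table: HaplotypeTable, population: str):
    """Haplotype carried by strictly more than half of the population's
    retained samples, or None."""
    total = table.population_total(population)
    if total == 0:
        warnings.warn(
            f"{table.gene_id}: no retained samples for {population}", stacklevel=2
        )
        return None
    k = table.populations.index(population) + 1
    for h in table.haplotypes:
        if h[k] > total / 2.0:
            return h[0]
    return None


# ---------------------------------------------------------------------------
# median-joining network

@dataclass
class MJNetwork:
    graph: nx.Graph  # nodes: haplotype strings; attr inferred=True for medians
    epsilon: int

    @property
    def observed(self) -> list:
        return [n for n, d in self.graph.nodes(data=True) if not d.get("inferred")]

    @property
    def medians(self) -> list:
        return [n for n, d in self.graph.nodes(data=True) if d.get("inferred")]

    @property
    def total_length(self) -> int:
        """Minimum spanning length of the node set (the quantity median
        insertion minimizes); the displayed graph may carry additional
        equally-short alternative edges."""
        return _mst_length(list(self.graph.nodes))


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("haplotypes of unequal length")
    return sum(x != y for x, y in zip(a, b))


def _minimum_spanning_network(nodes: list, epsilon: int) -> nx.Graph:
    """Union of minimum spanning trees, relaxed by ``epsilon``.

    Edge (u, v) is kept iff its Hamming distance is within ``epsilon`` of the
    minimax path distance between u and v (the largest step on the MST path),
    i.e. iff it belongs to some spanning network at relaxation epsilon.
    """
    nodes = sorted(set(nodes))
    g = nx.Graph()
    g.add_nodes_from(nodes)
    if len(nodes) < 2:
        return g
    complete = nx.Graph()
    for u, v in itertools.combinations(nodes, 2):
        complete.add_edge(u, v, weight=hamming(u, v))
    mst = nx.minimum_spanning_tree(complete, algorithm="kruskal")
    # minimax distances via MST paths
    for u, v in itertools.combinations(nodes, 2):
        path = nx.shortest_path(mst, u, v)
        crit = max(
            mst[a][b]["weight"] for a, b in zip(path, path[1:])
        )
        d = complete[u][v]["weight"]
        if d <= crit + epsilon:
            g.add_edge(u, v, weight=d)
    return g


def _mst_length(nodes: list) -> int:
    nodes = sorted(set(nodes))
    if len(nodes) < 2:
        return 0
    complete = nx.Graph()
    for u, v in itertools.combinations(nodes, 2):
        complete.add_edge(u, v, weight=hamming(u, v))
    mst = nx.minimum_spanning_tree(complete, algorithm="kruskal")
    return int(sum(w for _, _, w in mst.edges(data="weight")))


def _median_vector(a: str, b: str, c: str) -> str:
    """Coordinate-wise majority consensus; ties resolved to the first
    argument (arguments are passed in sorted order, so this is
    deterministic)."""
    out = []
    for x, y, z in zip(a, b, c):
        if x == y or x == z:
            out.append(x)
        elif y == z:
            out.append(y)
        else:
            out.append(x)
    return "".join(out)


def build_mj_network(
    haplotypes: list, epsilon: int = 0, max_iterations: int = 200
) -> MJNetwork:
    """Median-joining network over equal-length haplotype strings.

    Starts from the epsilon-relaxed minimum spanning network; repeatedly
    inserts the consensus median of a connected triplet when adding it
    strictly reduces the minimum-spanning length of the node set (the best
    reduction wins, ties broken lexicographically); finally prunes inferred
    medians whose removal leaves the length unchanged.  Observed haplotypes
    are never removed.
    """
    observed = sorted(set(haplotypes))
    if not observed:
        raise ValueError("need at least one haplotype")
    L = len(observed[0])
    if any(len(h) != L for h in observed):
        raise ValueError("haplotypes of unequal length")

    nodes = list(observed)
    current_len = _mst_length(nodes)
    for _ in range(max_iterations):
        msn = _minimum_spanning_network(nodes, epsilon)
        candidates = set()
        for u, v, w in itertools.combinations(sorted(msn.nodes), 3):
            pairs_linked = sum(
                msn.has_edge(x, y) for x, y in ((u, v), (u, w), (v, w))
            )
            if pairs_linked >= 2:
                m = _median_vector(u, v, w)
                if m not in nodes:
                    candidates.add(m)
        best = None
        for m in sorted(candidates):
            new_len = _mst_length(nodes + [m])
            if new_len < current_len and (best is None or new_len < best[1]):
                best = (m, new_len)
        if best is None:
            break
        nodes.append(best[0])
        current_len = best[1]

    # prune obsolete medians: removal must not increase the spanning length
    changed = True
    while changed:
        changed = False
        for m in sorted(set(nodes) - set(observed)):
            remaining = [n for n in nodes if n != m]
            if _mst_length(remaining) <= current_len:
                nodes = remaining
                current_len = _mst_length(nodes)
                changed = True
                break

    g = _minimum_spanning_network(nodes, epsilon)
    for n in g.nodes:
        g.nodes[n]["inferred"] = n not in set(observed)
    net = MJNetwork(g, epsilon)
    assert nx.is_connected(g) or g.number_of_nodes() <= 1
    return net


# ---------------------------------------------------------------------------
# PCA

@dataclass
class PcaResult:
    coordinates: np.ndarray  # samples x components
    explained_variance: np.ndarray  # percent, descending
    samples: list = field(default_factory=list)


def genotype_pca(matrix: GenotypeMatrix, n_components: int = 3) -> PcaResult:
    """PCA of the genotype matrix with allele-frequency scaling.

    Missing calls are mean-imputed per site; each site is centered by its
    alternate-allele frequency p and scaled by sqrt(p(1-p)); monomorphic
    sites are dropped.  Components come from the SVD of the scaled matrix;
    explained variance is the eigenvalue share in percent.  Sign convention:
    the first nonzero loading of each component is positive.
    """
    if matrix.n_samples < 2 or matrix.n_sites < 1:
        raise ValueError("PCA needs >= 2 samples and >= 1 site")
    X = matrix.calls.astype(float)
    X[X == MISSING] = np.nan
    p = np.nanmean(X, axis=0)
    informative = ~np.isnan(p) & (p > 0) & (p < 1)
    X = X[:, informative]
    p = p[informative]
    if X.shape[1] == 0:
        warnings.warn("no informative sites for PCA", stacklevel=2)
        return PcaResult(
            np.zeros((matrix.n_samples, 0)), np.zeros(0), list(matrix.samples)
        )
    inds = np.where(np.isnan(X))
    X[inds] = np.take(p, inds[1])
    Z = (X - p) / np.sqrt(p * (1 - p))
    Z = Z - Z.mean(axis=0)  # recentre after imputation
    U, S, Vt = np.linalg.svd(Z, full_matrices=False)
    eig = S**2
    total = eig.sum()
    k = min(n_components, int((S > 1e-9).sum()))
    if k < n_components:
        warnings.warn(
            f"only {k} informative components available", stacklevel=2
        )
    coords = U[:, :k] * S[:k]
    expl = 100.0 * eig[:k] / total if total > 0 else np.zeros(k)
    # sign convention on loadings
    for c in range(k):
        load = Vt[c]
        nz = np.flatnonzero(np.abs(load) > 1e-12)
        if nz.size and load[nz[0]] < 0:
            coords[:, c] *= -1
    return PcaResult(coords, expl, list(matrix.samples))
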