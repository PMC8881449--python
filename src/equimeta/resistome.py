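"""ARG abundance and the resistance-phenotype / reference-genome
co-assignment network.

ARG gene hits use the same qualified-alignment contract and fractional
weight splitting as the CAZy stage. For the network, a read pair assigned
to both an ARG phenotype and a reference genome lets that genome
contribute to the phenotype; per sample, the co-assignment frequency of a
(phenotype, genome) pair is the number of such read pairs (a pair hitting
several genomes splits its co-assignment weight equally among them)
divided by the sample's subsampled pair count, and the edge weight is the
arithmetic mean of that frequency over all samples of a cohort, samples
without co-assigned reads contributing zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import pandas as pd

from .cazy import fractional_gene_weights
from .records import ARGene, GenomeRecord, InteractionEdge

__all__ = ["arg_abundance", "co_assignment_edges", "edges_to_graph"]


def arg_abundance(pair_hits: dict[str, frozenset], catalog: list[ARGene],
                  relative: bool = True) -> tuple[pd.Series, pd.Series, int]:
    """Per-gene and per-phenotype ARG abundance plus the mapped-ARG count.

    Returns (gene abundances, phenotype abundances, number of distinct
    genes with nonzero weight).
    """
    by_id = {g.gene_id: g for g in catalog}
    weights = fractional_gene_weights(pair_hits)
    unknown = set(weights) - set(by_id)
    if unknown:
        raise KeyError(f"hit genes missing from ARG catalog: {sorted(unknown)[:5]}")
    genes = pd.Series(0.0, index=sorted(by_id))
    for gid, w in weights.items():
        genes[gid] += w
    phenotypes = pd.Series(0.0, index=sorted({g.phenotype for g in catalog}))
    for gid, w in genes.items():
        phenotypes[by_id[gid].phenotype] += w
    n_detected = int((genes > 0).sum())
    if relative:
        if genes.sum() > 0:
            genes = genes / genes.sum()
        if phenotypes.sum() > 0:
            phenotypes = phenotypes / phenotypes.sum()
    return genes, phenotypes, n_detected


def co_assignment_edges(arg_hits: dict[str, dict[str, frozenset]],
                        genome_hits: dict[str, dict[str, frozenset]],
                        n_pairs: dict[str, int], design: pd.DataFrame,
                        catalog: list[ARGene], db: list[GenomeRecord],
                        ) -> tuple[list[InteractionEdge], pd.DataFrame]:
    """Build cohort-mean co-assignment edges and node sizes.

    ``arg_hits`` and ``genome_hits`` map sample id -> pair id -> hit set
    (ARG gene ids / genome accessions); ``n_pairs`` is each sample's
    subsampled pair count (the frequency denominator). Node size is the
    cohort-mean frequency of pairs assigned within a phenotype's gene
    families, or to a genome.
    """
    samples = sorted(arg_hits)
    known = set(design["sample_id"])
    missing = [s for s in samples if s not in known]
    if missing:
        raise ValueError(f"samples missing from design table: {missing}")
    cohort_of = dict(zip(design["sample_id"], design["habitat"]))
    phenotype_of = {g.gene_id: g.phenotype for g in catalog}
    replicon_of = {g.accession: g.replicon for g in db}

    # per-sample frequencies
    edge_freq: dict[tuple[str, str], dict[str, float]] = {}
    phen_freq: dict[str, dict[str, float]] = {}
    genome_freq: dict[str, dict[str, float]] = {}
    for sample in samples:
        denom = n_pairs[sample]
        if denom < 1:
            raise ValueError(f"sample {sample}: non-positive pair count")
        g_hits = genome_hits.get(sample, {})
        for pid, arg_genes in arg_hits[sample].items():
            phens = {phenotype_of[g] for g in arg_genes}
            for ph in phens:
                phen_freq.setdefault(ph, {}).setdefault(sample, 0.0)
                phen_freq[ph][sample] += 1.0 / denom
            genomes = g_hits.get(pid, frozenset())
            if not genomes:
                continue
            share = 1.0 / len(genomes)
            for ph in phens:
                for acc in genomes:
                    key = (ph, acc)
                    edge_freq.setdefault(key, {}).setdefault(sample, 0.0)
                    edge_freq[key][sample] += share / denom
        for pid, genomes in g_hits.items():
            for acc in genomes:
                genome_freq.setdefault(acc, {}).setdefault(sample, 0.0)
                genome_freq[acc][sample] += 1.0 / len(genomes) / denom

    cohorts = sorted(set(cohort_of[s] for s in samples))
    members = {c: [s for s in samples if cohort_of[s] == c] for c in cohorts}

    def cohort_mean(freqs: dict[str, float], cohort: str) -> float:
        return sum(freqs.get(s, 0.0) for s in members[cohort]) / len(members[cohort])

    edges = []
    for (ph, acc), freqs in sorted(edge_freq.items()):
        for cohort in cohorts:
            w = cohort_mean(freqs, cohort)
            if w > 0:
                edges.append(InteractionEdge(ph, acc, replicon_of[acc], cohort, w))

    node_rows = []
    for ph, freqs in sorted(phen_freq.items()):
        for cohort in cohorts:
            node_rows.append({"node": ph, "kind": "phenotype", "replicon": "",
                              "cohort": cohort, "size": cohort_mean(freqs, cohort)})
    for acc, freqs in sorted(genome_freq.items()):
        for cohort in cohorts:
            node_rows.append({"node": acc, "kind": "genome",
                              "replicon": replicon_of[acc], "cohort": cohort,
                              "size": cohort_mean(freqs, cohort)})
    return edges, pd.DataFrame(node_rows)


def edges_to_graph(edges: list[InteractionEdge], nodes: pd.DataFrame,
                   cohort: str) -> nx.Graph:
    """One cohort's network with size/weight carried as attributes
    (styling data for external renderers, nothing is drawn here)."""
    g = nx.Graph()
    for row in nodes[nodes["cohort"] == cohort].itertuples():
        g.add_node(row.node, kind=row.kind, replicon=row.replicon, size=row.size)
    for e in edges:
        if e.cohort == cohort:
            g.add_edge(e.phenotype, e.genome_node, weight=e.weight,
                       replicon=e.replicon)
    return g


def edges_frame(edges: list[InteractionEdge]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "phenotype": [e.phenotype for e in edges],
            "genome": [e.genome_node for e in edges],
            "replicon": [e.replicon for e in edges],
            "cohort": [e.cohort for e in edges],
            "weight": [e.weight for e in edges],
        }
    )
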