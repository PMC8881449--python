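"""Reference genome curation: outlier removal, representative selection,
and clustering of unnamed species.

The three-step procedure:

1. complete and draft genomes are handled separately and then combined;
2. within each species, genomes whose length or GC content falls outside
   Tukey's fences (coefficient 2) are discarded, then the three longest
   survivors are kept per completeness class;
3. genomes without a proper binomial ("Genus sp. N" placeholders) are
   pooled by genus and complete-linkage clustered at distance threshold
   0.9 (distance = 1 - canonical k-mer Jaccard similarity); the longest
   genome of each cluster becomes its representative.

Plasmid records ride along with their parent chromosome: curation
statistics are computed over chromosome/contig records only, and a plasmid
is kept exactly when its parent is kept (a per-replicon record model has
no meaningful per-plasmid length/GC population to fence).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .align import revcomp
from .records import GenomeRecord

__all__ = ["CurationResult", "tukey_fences_filter", "select_representatives",
           "kmer_jaccard_distance_matrix", "cluster_unnamed", "curate"]


@dataclass
class CurationResult:
    kept: list[GenomeRecord]
    discarded: pd.DataFrame        # accession, species, reason
    cluster_assignments: dict[str, int]

    @property
    def report(self) -> pd.DataFrame:
        rows = [{"accession": g.accession, "species": g.species,
                 "decision": "kept",
                 "cluster": self.cluster_assignments.get(g.accession, "")}
                for g in self.kept]
        for row in self.discarded.itertuples():
            rows.append({"accession": row.accession, "species": row.species,
                         "decision": f"discarded_{row.reason}",
                         "cluster": self.cluster_assignments.get(row.accession, "")})
        return pd.DataFrame(rows).sort_values("accession").reset_index(drop=True)


def tukey_fences_filter(values, k: float = 2.0) -> np.ndarray:
    """Keep mask for values inside [Q1 - k*IQR, Q3 + k*IQR].

    Quartiles use linear interpolation between order statistics (the
    common "type 7" rule).
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("tukey_fences_filter: empty value list")
    if k < 0:
        raise ValueError("tukey_fences_filter: k must be >= 0")
    q1, q3 = np.quantile(values, [0.25, 0.75])
    iqr = q3 - q1
    return (values >= q1 - k * iqr) & (values <= q3 + k * iqr)


def _outlier_reasons(group: list[GenomeRecord], k: float) -> dict[str, str]:
    """Map accession -> reason for genomes failing either fence."""
    keep_len = tukey_fences_filter([g.length_bp for g in group], k)
    keep_gc = tukey_fences_filter([g.gc_fraction for g in group], k)
    reasons = {}
    for g, kl, kg in zip(group, keep_len, keep_gc):
        if not kl:
            reasons[g.accession] = "length"
        elif not kg:
            reasons[g.accession] = "gc"
    return reasons


def select_representatives(members: list[GenomeRecord], n: int = 3) -> list[GenomeRecord]:
    """The up-to-``n`` longest genomes per completeness class, combined.

    Ties in length break lexicographically by accession; the combined set
    is deduplicated by accession.
    """
    chosen: dict[str, GenomeRecord] = {}
    for completeness in ("complete", "draft"):
        klass = [g for g in members if g.completeness == completeness]
        klass.sort(key=lambda g: (-g.length_bp, g.accession))
        for g in klass[:n]:
            chosen[g.accession] = g
    return sorted(chosen.values(), key=lambda g: g.accession)


# ------------------------------------------------------------ k-mer distance


def _canonical_kmers(seq: str, k: int) -> set[str]:
    out = set()
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        out.add(min(kmer, revcomp(kmer)))
    return out


def kmer_jaccard_distance_matrix(genomes: list[GenomeRecord], k: int = 12) -> np.ndarray:
    """Pairwise 1 - Jaccard similarity of canonical k-mer sets."""
    sets = [_canonical_kmers(g.sequence, k) for g in genomes]
    n = len(genomes)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            union = len(sets[i] | sets[j])
            jac = len(sets[i] & sets[j]) / union if union else 1.0
            d[i, j] = d[j, i] = 1.0 - jac
    return d


def cluster_unnamed(genus_pool: list[GenomeRecord], threshold: float = 0.9,
                    k: int = 12, method: str = "complete",
                    ) -> tuple[dict[str, int], list[GenomeRecord]]:
    """Agglomerative clustering of a genus pool, cut at ``threshold``.

    Returns (accession -> cluster id, representatives), the representative
    of each cluster being its longest member (ties by accession).
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    if not genus_pool:
        return {}, []
    pool = sorted(genus_pool, key=lambda g: g.accession)
    if len(pool) == 1:
        return {pool[0].accession: 1}, [pool[0]]
    d = kmer_jaccard_distance_matrix(pool, k)
    labels = fcluster(linkage(squareform(d, checks=False), method=method),
                      t=threshold, criterion="distance")
    assignments = {g.accession: int(c) for g, c in zip(pool, labels)}
    reps = []
    for c in sorted(set(labels)):
        members = [g for g, lab in zip(pool, labels) if lab == c]
        reps.append(min(members, key=lambda g: (-g.length_bp, g.accession)))
    return assignments, sorted(reps, key=lambda g: g.accession)


# -------------------------------------------------------------------- curate


def curate(genomes: list[GenomeRecord], k_fence: float = 2.0,
           cluster_threshold: float = 0.9, kmer_k: int = 12,
           linkage_method: str = "complete", n_representatives: int = 3,
           ) -> CurationResult:
    """Run the full curation procedure over a genome set.

    Deterministic under input reordering: genomes are sorted by accession
    before processing. Every input genome appears exactly once in either
    ``kept`` or ``discarded``.
    """
    genomes = sorted(genomes, key=lambda g: g.accession)
    primaries = [g for g in genomes if g.replicon != "plasmid"]
    plasmids = [g for g in genomes if g.replicon == "plasmid"]

    by_species: dict[str, list[GenomeRecord]] = {}
    for g in primaries:
        by_species.setdefault(g.species, []).append(g)

    kept: list[GenomeRecord] = []
    discarded_rows: list[dict] = []
    cluster_assignments: dict[str, int] = {}
    unnamed_survivors: dict[str, list[GenomeRecord]] = {}

    for species in sorted(by_species):
        group = by_species[species]
        reasons = _outlier_reasons(group, k_fence)
        for acc, reason in sorted(reasons.items()):
            g = next(x for x in group if x.accession == acc)
            discarded_rows.append({"accession": acc, "species": g.species,
                                   "reason": reason})
        survivors = [g for g in group if g.accession not in reasons]
        selected = select_representatives(survivors, n_representatives)
        for g in survivors:
            if g not in selected:
                discarded_rows.append({"accession": g.accession,
                                       "species": g.species,
                                       "reason": "not_representative"})
        if selected and not selected[0].named:
            unnamed_survivors.setdefault(selected[0].genus, []).extend(selected)
        else:
            kept.extend(selected)

    cluster_offset = 0
    for genus in sorted(unnamed_survivors):
        pool = unnamed_survivors[genus]
        assignments, reps = cluster_unnamed(pool, cluster_threshold, kmer_k,
                                            linkage_method)
        rep_accs = {g.accession for g in reps}
        for g in pool:
            cluster_assignments[g.accession] = assignments[g.accession] + cluster_offset
            if g.accession in rep_accs:
                kept.append(g)
            else:
                discarded_rows.append({"accession": g.accession,
                                       "species": g.species,
                                       "reason": "cluster_duplicate"})
        cluster_offset += max(assignments.values(), default=0)

    kept_accs = {g.accession for g in kept}
    for p in plasmids:
        if p.parent in kept_accs:
            kept.append(p)
        else:
            discarded_rows.append({"accession": p.accession, "species": p.species,
                                   "reason": "parent_discarded"})

    kept.sort(key=lambda g: g.accession)
    discarded = pd.DataFrame(discarded_rows,
                             columns=["accession", "species", "reason"])
    return CurationResult(kept, discarded, cluster_assignments)
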