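"""Species abundance profiling by subsample, align, profile, repeat, average.

For each sample, a fixed number of read pairs is drawn uniformly without
replacement, aligned against the curated genome database reporting all
qualified hits, and turned into a candidate profile; the procedure is
repeated (100 times at study scale, 10 at desk scale) and the element-wise
mean of the candidate profiles is the sample's final profile. Species
detected in no more than ``rare_sample_threshold`` samples are then removed
and rows renormalized.

The per-subsample profile uses unique-then-proportional fractional
assignment: pairs hitting exactly one species are counted first, then each
multi-species pair's unit weight is split across its hit species
proportionally to those unique counts (uniformly when all are zero); with
``redistribute_iters > 1`` the split is recomputed against the updated
weights, an EM-like refinement. Species weights are divided by the mean
genome length of the species' database records (read sampling is
length-weighted) before scaling to relative abundances; pairs with no hit
fill an explicit ``unassigned`` column so every row sums to one.

Because the internal aligner is deterministic, each sample's full read
pool is aligned once and subsampling selects from the cached per-pair hit
sets — arithmetically identical to aligning each subsample separately.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .align import AlignmentIndex, align_reads
from .records import AlignmentHit, GenomeRecord, ReadPair

__all__ = ["ProfilerConfig", "subsample_pairs", "pair_species_sets",
           "assignment_weights", "profile_once", "profile_cohort",
           "aggregate_kingdoms"]


@dataclass
class ProfilerConfig:
    """Profiling parameters. Study scale uses 15 million pairs and 100
    repeats; the desk-scale defaults keep synthetic runs fast."""

    n_pairs_per_subsample: int = 50_000
    n_repeats: int = 10
    rare_sample_threshold: int = 2
    redistribute_iters: int = 1
    length_normalize: bool = True
    min_identity: float = 0.9
    min_score: float = 0.0
    max_evalue: float = 1e-5
    seed_k: int = 21

    def validate(self) -> None:
        if self.n_pairs_per_subsample < 1 or self.n_repeats < 1:
            raise ValueError("subsample size and repeat count must be >= 1")
        if self.rare_sample_threshold < 0:
            raise ValueError("rare_sample_threshold must be >= 0")
        if self.redistribute_iters < 1:
            raise ValueError("redistribute_iters must be >= 1")


def subsample_pairs(pairs: list[ReadPair], n: int, seed: int) -> list[ReadPair]:
    """Uniform sample of ``n`` pairs without replacement.

    When fewer than ``n`` pairs exist, every pair is used once (no
    resampling) and a warning is issued.
    """
    if not pairs:
        raise ValueError("no read pairs to subsample")
    if n < 1:
        raise ValueError("subsample size must be >= 1")
    if n >= len(pairs):
        if n > len(pairs):
            warnings.warn(f"requested {n} pairs but only {len(pairs)} exist; "
                          "using all pairs once")
        return list(pairs)
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(pairs), size=n, replace=False)
    return [pairs[i] for i in idx]


def pair_species_sets(hits: list[AlignmentHit],
                      accession_to_species: dict[str, str]) -> dict[str, frozenset]:
    """Collapse alignment hits to per-pair species sets.

    A pair counts as one unit; its species set is the union over both
    mates' genome hits (mates share the pair id).
    """
    out: dict[str, set] = {}
    for h in hits:
        out.setdefault(h.read_id, set()).add(accession_to_species[h.target_id])
    return {pid: frozenset(s) for pid, s in out.items()}


def assignment_weights(pair_species: dict[str, frozenset], species: list[str],
                       redistribute_iters: int = 1) -> tuple[dict[str, float], int]:
    """Unique-then-proportional fractional assignment.

    Returns (per-species pair weights, number of assigned pairs); the
    weights sum exactly to the assigned-pair count (conservation).
    """
    unique = {s: 0.0 for s in species}
    multi: list[frozenset] = []
    n_assigned = 0
    for sset in pair_species.values():
        if not sset:
            continue
        n_assigned += 1
        if len(sset) == 1:
            unique[next(iter(sset))] += 1.0
        else:
            multi.append(sset)

    weights = dict(unique)
    for _ in range(redistribute_iters):
        new = dict(unique)
        for sset in multi:
            total = sum(weights[s] for s in sset)
            if total > 0:
                for s in sset:
                    new[s] += weights[s] / total
            else:
                share = 1.0 / len(sset)
                for s in sset:
                    new[s] += share
        weights = new
    return weights, n_assigned


def profile_once(pair_species: dict[str, frozenset], n_pairs: int,
                 species_mean_length: dict[str, float],
                 cfg: ProfilerConfig | None = None) -> pd.Series:
    """One candidate profile from one subsample's per-pair species sets.

    Returns relative abundances over all database species plus an
    ``unassigned`` entry; the row sums to 1.
    """
    cfg = cfg or ProfilerConfig()
    species = sorted(species_mean_length)
    weights, n_assigned = assignment_weights(pair_species, species,
                                             cfg.redistribute_iters)
    values = np.array([weights[s] for s in species])
    if cfg.length_normalize:
        values = values / np.array([species_mean_length[s] for s in species])
    assigned_frac = n_assigned / n_pairs
    total = values.sum()
    if total > 0:
        values = values / total * assigned_frac
    return pd.Series(np.append(values, 1.0 - assigned_frac),
                     index=species + ["unassigned"])


def _species_mean_lengths(db: list[GenomeRecord]) -> dict[str, float]:
    lengths: dict[str, list[int]] = {}
    for g in db:
        lengths.setdefault(g.species, []).append(g.length_bp)
    return {s: float(np.mean(v)) for s, v in lengths.items()}


def profile_cohort(samples: dict[str, list[ReadPair]], db: list[GenomeRecord],
                   cfg: ProfilerConfig | None = None, seed: int = 0,
                   ) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame]:
    """Profile every sample; returns (abundance matrix, mapped-read ratio,
    assigned-pair count matrix).

    The matrix has samples as rows and species (plus ``unassigned``) as
    columns; each row is the mean of ``n_repeats`` candidate profiles, with
    the rare-species filter applied across the whole sample set afterwards.
    ``mapped_read_ratio`` is the mean fraction of subsampled pairs with at
    least one genome hit. The count matrix holds the repeat-mean fractional
    pair weights per species rounded to integers — the raw material for
    count-based richness estimators.
    """
    cfg = cfg or ProfilerConfig()
    cfg.validate()
    if not samples:
        raise ValueError("no samples to profile")
    index = AlignmentIndex({g.accession: g.sequence for g in db},
                           alphabet="dna", k=cfg.seed_k, target_kind="genome")
    acc2sp = {g.accession: g.species for g in db}
    mean_len = _species_mean_lengths(db)
    root = np.random.default_rng(seed)

    species = sorted(mean_len)
    rows: dict[str, pd.Series] = {}
    count_rows: dict[str, pd.Series] = {}
    mapped: dict[str, float] = {}
    for sample_id in sorted(samples):
        pairs = samples[sample_id]
        reads = [r for p in pairs for r in (p.r1, p.r2)]
        hits = align_reads(reads, index, mode="all_hits",
                           min_score=cfg.min_score, max_evalue=cfg.max_evalue,
                           min_identity=cfg.min_identity)
        cached = pair_species_sets(hits, acc2sp)
        profiles = []
        counts = []
        ratios = []
        for _ in range(cfg.n_repeats):
            sub = subsample_pairs(pairs, cfg.n_pairs_per_subsample,
                                  int(root.integers(2**31)))
            sub_sets = {p.pair_id: cached.get(p.pair_id, frozenset())
                        for p in sub}
            profiles.append(profile_once(sub_sets, len(sub), mean_len, cfg))
            w, n_assigned = assignment_weights(sub_sets, species,
                                               cfg.redistribute_iters)
            counts.append(pd.Series([w[s] for s in species], index=species))
            ratios.append(n_assigned / len(sub))
        rows[sample_id] = pd.concat(profiles, axis=1).mean(axis=1)
        count_rows[sample_id] = pd.concat(counts, axis=1).mean(axis=1)
        mapped[sample_id] = float(np.mean(ratios))

    matrix = pd.DataFrame(rows).T
    matrix.index.name = "sample_id"
    count_matrix = pd.DataFrame(count_rows).T.round().astype(int)
    count_matrix.index.name = "sample_id"
    species_cols = [c for c in matrix.columns if c != "unassigned"]
    detected_in = (matrix[species_cols] > 0).sum(axis=0)
    rare = detected_in[detected_in <= cfg.rare_sample_threshold].index
    if len(rare):
        matrix = matrix.drop(columns=list(rare))
        matrix = matrix.div(matrix.sum(axis=1), axis=0)
        count_matrix = count_matrix.drop(columns=list(rare))
    return matrix, pd.Series(mapped, name="mapped_read_ratio"), count_matrix


def aggregate_kingdoms(matrix: pd.DataFrame,
                       species_to_kingdom: dict[str, str]) -> pd.DataFrame:
    """Sum member-species abundances up to kingdom level.

    The ``unassigned`` column, when present, is carried through unchanged.
    """
    out: dict[str, pd.Series] = {}
    for col in matrix.columns:
        if col == "unassigned":
            key = "unassigned"
        else:
            key = species_to_kingdom.get(col)
            if key is None:
                raise KeyError(f"species {col!r} missing from kingdom map")
        out[key] = out.get(key, 0) + matrix[col]
    return pd.DataFrame(out)
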