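"""Ground-truthed synthetic shotgun-metagenome communities.

Generates everything the pipeline consumes — reference genomes with
species/genus/completeness/replicon metadata, ARG and CAZy gene catalogs
spiked into those genomes, paired 150 bp reads with Phred-scored errors and
labeled QC defects, a sample design table with habitat/site structure, and
a taxonomy tree — together with the ground truth needed to score every
downstream stage (per-sample species abundances, per-read defect labels and
expected QC decisions, per-read gene containment).

Modeling choices (the statistical structure the analysis assumes):

* species abundances are log-normal (``sigma`` configurable, default 1.0);
* read sampling weights species abundance by total genome length, so the
  profiler's length normalization is testable;
* designated signal species receive multiplicative habitat/site effects;
* each defective read violates exactly one QC rule (>=2 N bases; >=30
  interior sub-Q20 bases; adapter suffix; fragment drawn from a designated
  host genome excluded from the community truth);
* the adapter is a fixed TruSeq-style 33-mer, configurable.

Error model is substitution-only with i.i.d. per-base qualities; no indels
or quality-by-cycle structure.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .align import revcomp
from .records import ARGene, CAZyGene, GenomeRecord, ReadPair, ReadRecord, SpikedGene

__all__ = [
    "DEFAULT_ADAPTER",
    "generate_genomes",
    "generate_host_genome",
    "spike_genes",
    "simulate_reads",
    "generate_design",
    "taxonomy_newick",
]

# TruSeq-style universal adapter (33-mer).
DEFAULT_ADAPTER = "AGATCGGAAGAGCACACGTCTGAACTCCAGTCA"

_GENERA = [
    "Bacteroides", "Prevotella", "Clostridium", "Fibrobacter", "Streptococcus",
    "Acinetobacter", "Ruminococcus", "Treponema", "Lactobacillus",
    "Methanobrevibacter", "Akkermansia", "Eubacterium",
]
_KINGDOM = {"Methanobrevibacter": "archaea"}
_EPITHETS = [
    "equinus", "fibrisolvens", "intestinalis", "caballi", "pratensis",
    "ruminis", "faecis", "silvaticus", "campestris", "herbivorax",
    "cellulolyticus", "amylophilus",
]

_ARG_PHENOTYPES = [
    ("tet", "tetracycline resistance", "ribosomal protection"),
    ("lnu", "lincosamide resistance", "nucleotidyltransferase"),
    ("erm", "macrolide resistance", "rRNA methyltransferase"),
    ("bla", "beta-lactam resistance", "beta-lactamase"),
    ("aph", "aminoglycoside resistance", "phosphotransferase"),
    ("tetE", "tetracycline resistance", "efflux pump"),
]
_CAZY_FAMILIES = [
    "GT2", "GH2", "GH3", "GT4", "GH13", "GH5", "CE1", "GT35", "GH31",
    "CBM50", "PL1", "AA3", "GH9", "GT41",
]


def _random_seq(rng: random.Random, length: int, gc: float) -> str:
    bases = "ACGT"
    w = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choices(bases, weights=w, k=length))


def _mutate(rng: random.Random, seq: str, rate: float) -> str:
    out = list(seq)
    for pos in range(len(out)):
        if rng.random() < rate:
            out[pos] = rng.choice("ACGT".replace(out[pos], ""))
    return "".join(out)


def generate_genomes(n_species: int, length_range: tuple[int, int] = (30_000, 60_000),
                     plasmid_prob: float = 0.3, seed: int = 0,
                     unnamed_fraction: float = 0.25,
                     within_species_divergence: float = 0.02,
                     members_range: tuple[int, int] = (1, 4)) -> list[GenomeRecord]:
    """Generate a reference genome set with curation-relevant structure.

    Each species gets 1-4 genome records (a complete chromosome plus draft
    contigs diverged by ``within_species_divergence``); a fraction of
    species are unnamed ``Genus sp. N`` placeholders so the genus-pool
    clustering step has work to do; chromosomes acquire a small plasmid
    with probability ``plasmid_prob``.
    """
    if n_species < 1:
        raise ValueError("n_species must be >= 1")
    lo, hi = length_range
    if lo < 1000 or hi < lo:
        raise ValueError("invalid length_range: need 1000 <= lo <= hi")
    if not 0.0 <= plasmid_prob <= 1.0:
        raise ValueError("plasmid_prob must be in [0, 1]")
    rng = random.Random(seed)
    genomes: list[GenomeRecord] = []
    acc_no = 0
    n_unnamed = int(round(unnamed_fraction * n_species))
    for si in range(n_species):
        genus = _GENERA[si % len(_GENERA)]
        if si < n_species - n_unnamed:
            species = f"{genus} {_EPITHETS[(si // len(_GENERA)) % len(_EPITHETS)]}{si}"
        else:
            species = f"{genus} sp. {si}"
        gc = rng.uniform(0.30, 0.65)
        base_len = rng.randint(lo, hi)
        base = _random_seq(rng, base_len, gc)
        n_members = rng.randint(*members_range)
        for mi in range(n_members):
            acc_no += 1
            acc = f"EQM{acc_no:04d}"
            if mi == 0:
                seq, completeness, replicon = base, "complete", "chromosome"
            else:
                cut = rng.randint(int(0.7 * base_len), base_len)
                seq = _mutate(rng, base[:cut], within_species_divergence)
                completeness, replicon = "draft", "contig"
            rec = GenomeRecord(acc, species, genus, seq, completeness, replicon,
                               kingdom=_KINGDOM.get(genus, "bacteria"))
            genomes.append(rec)
            if replicon == "chromosome" and rng.random() < plasmid_prob:
                acc_no += 1
                plasmid = GenomeRecord(
                    f"EQM{acc_no:04d}", species, genus,
                    _random_seq(rng, rng.randint(4000, 9000), gc),
                    completeness, "plasmid", parent=acc,
                    kingdom=_KINGDOM.get(genus, "bacteria"),
                )
                genomes.append(plasmid)
    return genomes


def generate_host_genome(length: int = 60_000, seed: int = 99) -> GenomeRecord:
    """A designated host genome, excluded from the community truth.

    Stands in for the plant/host references whose reads QC removes.
    """
    rng = random.Random(seed)
    return GenomeRecord("HOST0001", "Equus caballus", "Equus",
                        _random_seq(rng, length, 0.41), kingdom="eukaryota")


# ------------------------------------------------------------------- spiking


def spike_genes(genomes: list[GenomeRecord], arg_catalog_size: int,
                cazy_catalog_size: int, seed: int = 0,
                arg_replicons: tuple[str, ...] | None = None,
                arg_length_range: tuple[int, int] = (600, 1200),
                cazy_length_range_aa: tuple[int, int] = (200, 450),
                ) -> tuple[list[ARGene], list[CAZyGene], list[SpikedGene]]:
    """Designate non-overlapping genome regions as ARG and CAZy genes.

    Gene sequences are verbatim substrings of their host genomes (CAZy
    records store the in-frame translation and are matched in protein
    space). ``arg_replicons`` restricts ARG hosts to the given replicon
    types, e.g. ``("plasmid",)`` for a plasmid-only resistome.
    """
    if arg_catalog_size < 0 or cazy_catalog_size < 0:
        raise ValueError("catalog sizes must be >= 0")
    rng = random.Random(seed)
    used: dict[str, list[tuple[int, int]]] = {g.accession: [] for g in genomes}
    by_acc = {g.accession: g for g in genomes}

    def place(hosts: list[GenomeRecord], length: int) -> tuple[str, int, int]:
        for _ in range(200):
            g = rng.choice(hosts)
            if g.length_bp <= length:
                continue
            start = rng.randrange(0, g.length_bp - length)
            span = (start, start + length)
            if all(span[1] <= a or span[0] >= b for a, b in used[g.accession]):
                used[g.accession].append(span)
                return g.accession, span[0], span[1]
        raise RuntimeError("could not place gene: genomes too small or too full")

    args: list[ARGene] = []
    spiked: list[SpikedGene] = []
    arg_hosts = [g for g in genomes
                 if arg_replicons is None or g.replicon in arg_replicons]
    if arg_catalog_size > 0 and not arg_hosts:
        raise ValueError("no genomes match arg_replicons")
    for i in range(arg_catalog_size):
        stem, phenotype, mechanism = _ARG_PHENOTYPES[i % len(_ARG_PHENOTYPES)]
        length = rng.randint(*arg_length_range)
        acc, start, end = place(arg_hosts, length)
        gid = f"{stem}({chr(ord('A') + i % 26)}{i // 26 or ''})"
        args.append(ARGene(gid, phenotype, mechanism, by_acc[acc].sequence[start:end]))
        spiked.append(SpikedGene(gid, acc, start, end, "ARG"))

    from Bio.Seq import Seq

    cazys: list[CAZyGene] = []
    for i in range(cazy_catalog_size):
        family = _CAZY_FAMILIES[i % len(_CAZY_FAMILIES)]
        length_aa = rng.randint(*cazy_length_range_aa)
        acc, start, end = place(genomes, 3 * length_aa)
        gid = f"cazy{i:03d}_{family}"
        protein = str(Seq(by_acc[acc].sequence[start:end]).translate())
        cazys.append(CAZyGene(gid, family, protein))
        spiked.append(SpikedGene(gid, acc, start, end, "CAZy"))
    return args, cazys, spiked


# --------------------------------------------------------------------- reads


@dataclass
class ReadTruth:
    """Per-read ground truth emitted alongside simulated FASTQ."""

    read_id: str
    mate: str
    defect: str             # clean | ambiguous | low_quality | adapter | host
    expected_decision: str  # kept | discarded_* | discarded_mate
    expected_stream: str    # paired | singleton | none
    species: str
    accession: str
    contained_genes: tuple[str, ...] = ()


def _quals(rng: random.Random, n: int) -> list[int]:
    return [rng.randint(33, 40) for _ in range(n)]


def _draw_fragment(rng, genome: GenomeRecord, read_len, insert_mean, insert_sd):
    insert = max(read_len, int(rng.gauss(insert_mean, insert_sd)))
    insert = min(insert, genome.length_bp)
    start = rng.randrange(0, genome.length_bp - insert + 1)
    frag = genome.sequence[start : start + insert]
    return frag, start, insert


def _apply_errors(rng, seq: str, quals: list[int], rate: float) -> str:
    if rate <= 0:
        return seq
    out = list(seq)
    for i in range(len(out)):
        if rng.random() < rate:
            out[i] = rng.choice("ACGT".replace(out[i], ""))
    return "".join(out)


def simulate_reads(genomes: list[GenomeRecord], abundance: dict[str, float],
                   n_pairs: int, read_len: int = 150, error_rate: float = 0.005,
                   defect_rates: dict[str, float] | None = None, seed: int = 0,
                   host_genome: GenomeRecord | None = None,
                   adapter: str = DEFAULT_ADAPTER,
                   spiked: list[SpikedGene] | None = None,
                   sample_id: str = "S1", insert_mean: int = 350,
                   insert_sd: int = 30) -> tuple[list[ReadPair], list[ReadTruth]]:
    """Simulate one sample's paired reads with per-read truth labels.

    Pairs are drawn from species proportionally to ``abundance`` times the
    species' total genome length, then from a genome within the species
    proportionally to its length. ``defect_rates`` maps defect names
    (ambiguous, low_quality, adapter, host) to per-pair probabilities; a
    defective pair has one randomly chosen carrier mate constructed to
    violate exactly that QC rule, except host defects where the whole
    fragment is drawn from the host genome (the carrier is labeled host,
    its mate clean but expected to be co-discarded).

    ``contained_genes`` lists spiked genes whose interval fully contains
    the read, the detectable-by-construction truth for functional stages.
    """
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    if not genomes:
        raise ValueError("empty genome list")
    defect_rates = dict(defect_rates or {})
    bad = set(defect_rates) - {"ambiguous", "low_quality", "adapter", "host"}
    if bad:
        raise ValueError(f"unknown defect classes: {sorted(bad)}")
    if any(not 0 <= v <= 1 for v in defect_rates.values()) or sum(defect_rates.values()) > 1:
        raise ValueError("defect rates must be in [0,1] and sum <= 1")
    if "host" in defect_rates and defect_rates["host"] > 0 and host_genome is None:
        raise ValueError("host defect rate > 0 requires a host genome")

    rng = random.Random(seed)
    by_species: dict[str, list[GenomeRecord]] = {}
    for g in genomes:
        by_species.setdefault(g.species, []).append(g)
    species = [s for s in abundance if s in by_species and abundance[s] > 0]
    if not species:
        raise ValueError("no abundant species present in the genome set")
    weights = [abundance[s] * sum(g.length_bp for g in by_species[s]) for s in species]
    genes_by_acc: dict[str, list[SpikedGene]] = {}
    for sg in spiked or []:
        genes_by_acc.setdefault(sg.accession, []).append(sg)

    defects = list(defect_rates)
    defect_cum = np.cumsum([defect_rates[d] for d in defects])

    pairs: list[ReadPair] = []
    truths: list[ReadTruth] = []
    for i in range(n_pairs):
        u = rng.random()
        j = int(np.searchsorted(defect_cum, u, side="right"))
        defect = defects[j] if j < len(defects) else "clean"
        carrier = rng.choice(["R1", "R2"])
        pid = f"{sample_id}:{i:07d}"

        if defect == "host":
            genome = host_genome
        else:
            sp = rng.choices(species, weights=weights, k=1)[0]
            members = by_species[sp]
            genome = rng.choices(members, weights=[g.length_bp for g in members], k=1)[0]
        frag, fstart, insert = _draw_fragment(rng, genome, read_len, insert_mean, insert_sd)
        r1_seq = frag[:read_len]
        r2_seq = revcomp(frag)[:read_len]
        coords = {
            "R1": (fstart, fstart + len(r1_seq)),
            "R2": (fstart + insert - len(r2_seq), fstart + insert),
        }
        reads = {}
        for mate, seq in (("R1", r1_seq), ("R2", r2_seq)):
            quals = _quals(rng, len(seq))
            seq = _apply_errors(rng, seq, quals, error_rate)
            reads[mate] = (seq, quals)

        decisions = {"R1": ("clean", "kept", "paired"), "R2": ("clean", "kept", "paired")}
        other = "R2" if carrier == "R1" else "R1"
        if defect == "ambiguous":
            seq, quals = reads[carrier]
            out = list(seq)
            for pos in rng.sample(range(len(out)), 2):
                out[pos] = "N"
            reads[carrier] = ("".join(out), quals)
            decisions[carrier] = ("ambiguous", "discarded_ambiguous", "none")
            decisions[other] = ("clean", "kept", "singleton")
        elif defect == "low_quality":
            seq, quals = reads[carrier]
            quals = list(quals)
            # 30 interior low-quality bases: survives the 3' trim, fails rule 2
            for pos in range(10, 40):
                quals[pos] = 10
            reads[carrier] = (seq, quals)
            decisions[carrier] = ("low_quality", "discarded_lowq", "none")
            decisions[other] = ("clean", "kept", "singleton")
        elif defect == "adapter":
            seq, quals = reads[carrier]
            seq = seq[: len(seq) - len(adapter)] + adapter
            reads[carrier] = (seq, quals)
            decisions[carrier] = ("adapter", "discarded_adapter", "none")
            decisions[other] = ("clean", "discarded_mate", "none")
        elif defect == "host":
            decisions[carrier] = ("host", "discarded_host", "none")
            decisions[other] = ("host", "discarded_host", "none")

        pair = ReadPair(
            ReadRecord(pid, reads["R1"][0], reads["R1"][1], "R1"),
            ReadRecord(pid, reads["R2"][0], reads["R2"][1], "R2"),
        )
        pairs.append(pair)
        for mate in ("R1", "R2"):
            d, dec, stream = decisions[mate]
            lo, hi = coords[mate]
            contained = tuple(
                sg.gene_id for sg in genes_by_acc.get(genome.accession, ())
                if defect != "host" and sg.start <= lo and hi <= sg.end
            )
            truths.append(ReadTruth(pid, mate, d, dec, stream,
                                    "host" if defect == "host" else genome.species,
                                    genome.accession, contained))
    return pairs, truths


def truth_frame(truths: list[ReadTruth]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "read_id": [t.read_id for t in truths],
            "mate": [t.mate for t in truths],
            "defect": [t.defect for t in truths],
            "expected_decision": [t.expected_decision for t in truths],
            "expected_stream": [t.expected_stream for t in truths],
            "species": [t.species for t in truths],
            "accession": [t.accession for t in truths],
            "contained_genes": [";".join(t.contained_genes) for t in truths],
        }
    )


# -------------------------------------------------------------------- design


def generate_design(n_samples_per_group: dict, effect_spec: dict | None,
                    species: list[str], seed: int = 0, sigma: float = 1.0,
                    base_sigma: float = 1.5,
                    ) -> tuple[pd.DataFrame, dict[str, dict[str, float]], list[str]]:
    """Design table plus per-sample true relative abundances.

    ``n_samples_per_group`` maps habitat to a sample count (a single site
    per habitat) or to a ``{site: count}`` map. Abundances are log-normal:
    a per-species baseline ``exp(N(0, base_sigma^2))`` shared by all
    samples, times per-sample noise ``exp(N(0, sigma^2))``, times the
    multiplicative effect from ``effect_spec`` — a map
    ``species -> {"variable": "habitat"|"site", "level": ..., "fold": f}``
    applied in matching samples — then normalized to sum to 1.

    Returns (design table, truth abundances, list of signal species).
    """
    if not species:
        raise ValueError("species list is empty")
    effect_spec = effect_spec or {}
    unknown = set(effect_spec) - set(species)
    if unknown:
        raise ValueError(f"effect_spec references unknown species: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    rows = []
    for habitat, val in n_samples_per_group.items():
        sites = val if isinstance(val, dict) else {f"{habitat}_site": val}
        for site, n in sites.items():
            for _ in range(int(n)):
                rows.append({"sample_id": f"S{len(rows) + 1:03d}",
                             "site": site, "habitat": habitat})
    if not rows:
        raise ValueError("no samples requested")
    design = pd.DataFrame(rows)
    if design["habitat"].nunique() < 2 and design["site"].nunique() < 2:
        raise ValueError("need >=2 habitats or >=2 sites")

    base = np.exp(rng.normal(0.0, base_sigma, size=len(species)))
    truth: dict[str, dict[str, float]] = {}
    for row in design.itertuples():
        a = base * np.exp(rng.normal(0.0, sigma, size=len(species)))
        for sp, eff in effect_spec.items():
            level = getattr(row, eff.get("variable", "habitat"))
            if level == eff["level"]:
                a[species.index(sp)] *= float(eff["fold"])
        a = a / a.sum()
        truth[row.sample_id] = dict(zip(species, a.tolist()))
    return design, truth, sorted(effect_spec)


# ------------------------------------------------------------------ taxonomy


def taxonomy_newick(genomes: list[GenomeRecord]) -> str:
    """Newick tree nesting species within genus within kingdom, unit branches."""

    def quote(name: str) -> str:
        return "'" + name.replace("'", "''") + "'"

    tree: dict[str, dict[str, set[str]]] = {}
    for g in genomes:
        tree.setdefault(g.kingdom, {}).setdefault(g.genus, set()).add(g.species)
    kingdom_parts = []
    for kingdom in sorted(tree):
        genus_parts = []
        for genus in sorted(tree[kingdom]):
            sp = ",".join(f"{quote(s)}:1" for s in sorted(tree[kingdom][genus]))
            genus_parts.append(f"({sp}){quote(genus)}:1")
        kingdom_parts.append(f"({','.join(genus_parts)}){quote(kingdom)}:1")
    return f"({','.join(kingdom_parts)})root;"
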