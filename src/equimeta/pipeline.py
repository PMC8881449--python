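"""End-to-end orchestration: simulate -> qc -> build-db -> profile -> cazy
-> resistome -> diversity -> associate, with manifests and resume.

Each stage writes into ``<run_dir>/<stage>/`` and records a manifest
(parameter hash plus SHA-256 of every output file). On re-run, a stage
whose parameters are unchanged and whose outputs all verify is skipped,
so deleting one stage's outputs re-executes only that stage and the
pipeline is resumable after interruption.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd
import yaml

from . import cazy as cazy_mod
from . import io, qc as qc_mod, refdb, resistome as res_mod, stats, synthetic, taxprofile
from .align import AlignmentIndex, align_reads

log = logging.getLogger("equimeta")

STAGES = ["simulate", "qc", "build_db", "profile", "cazy", "resistome",
          "diversity", "associate"]

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "simulate": {
        "n_species": 5,
        "length_range": [20000, 40000],
        "plasmid_prob": 0.5,
        "members_range": [1, 1],
        "n_samples_per_group": {"domestic": 3, "feral": 3},
        "effect_spec": {},
        "n_pairs": 3000,
        "read_len": 150,
        "error_rate": 0.005,
        "defect_rates": {"ambiguous": 0.02, "low_quality": 0.02,
                         "adapter": 0.02, "host": 0.02},
        "arg_catalog_size": 6,
        "cazy_catalog_size": 10,
        "sigma": 1.0,
    },
    "qc": {},
    "build_db": {"k_fence": 2.0, "cluster_threshold": 0.9, "kmer_k": 12,
                 "linkage": "complete"},
    "profile": {"n_pairs_per_subsample": 2000, "n_repeats": 3,
                "rare_sample_threshold": 2, "redistribute_iters": 1},
    "cazy": {"pathway_map": dict(cazy_mod.DEFAULT_PATHWAY_MAP)},
    "resistome": {},
    "diversity": {},
    "associate": {"target": "habitat", "adjust_for": ["site"]},
}


def load_config(path=None) -> dict:
    """Merge a YAML config over the desk-scale defaults (one level deep)."""
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        for key, val in user.items():
            if isinstance(val, dict) and isinstance(cfg.get(key), dict):
                cfg[key].update(val)
            else:
                cfg[key] = val
    return cfg


# ------------------------------------------------------------- manifests


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _params_hash(params) -> str:
    return hashlib.sha256(json.dumps(params, sort_keys=True).encode()).hexdigest()


def _write_manifest(stage_dir: Path, params) -> None:
    files = {p.name: _sha256(p) for p in sorted(stage_dir.iterdir())
             if p.is_file() and p.name != "manifest.json"}
    (stage_dir / "manifest.json").write_text(
        json.dumps({"params_hash": _params_hash(params), "files": files},
                   indent=1, sort_keys=True))


def _stage_current(stage_dir: Path, params) -> bool:
    mf = stage_dir / "manifest.json"
    if not mf.exists():
        return False
    try:
        manifest = json.loads(mf.read_text())
    except json.JSONDecodeError:
        return False
    if manifest.get("params_hash") != _params_hash(params):
        return False
    for name, digest in manifest.get("files", {}).items():
        p = stage_dir / name
        if not p.exists() or _sha256(p) != digest:
            return False
    return True


# ---------------------------------------------------------------- stages


def _sample_ids(run_dir: Path) -> list[str]:
    design = io.read_design(run_dir / "simulate" / "design.tsv")
    return list(design["sample_id"])


def stage_simulate(cfg: dict, run_dir: Path) -> None:
    p = cfg["simulate"]
    seed = int(cfg["seed"])
    out = run_dir / "simulate"
    out.mkdir(parents=True, exist_ok=True)
    genomes = synthetic.generate_genomes(
        p["n_species"], tuple(p["length_range"]), p["plasmid_prob"], seed,
        members_range=tuple(p.get("members_range", [1, 4])))
    host = synthetic.generate_host_genome(seed=seed + 7)
    args, cazys, spiked = synthetic.spike_genes(
        genomes, p["arg_catalog_size"], p["cazy_catalog_size"], seed + 1)
    species = sorted({g.species for g in genomes})
    design, truth, signal = synthetic.generate_design(
        p["n_samples_per_group"], p.get("effect_spec") or {}, species,
        seed + 2, sigma=p.get("sigma", 1.0))
    io.write_genomes(out / "genomes.fasta", out / "genomes.tsv", genomes)
    io.write_genomes(out / "host.fasta", out / "host.tsv", [host])
    io.write_arg_catalog(out / "arg.fasta", out / "arg.tsv", args)
    io.write_cazy_catalog(out / "cazy.fasta", out / "cazy.tsv", cazys)
    io.write_design(out / "design.tsv", design)
    (out / "taxonomy.nwk").write_text(synthetic.taxonomy_newick(genomes) + "\n")
    io.write_truth(out / "truth.json", {
        "abundance": truth, "signal_species": signal,
        "spiked_genes": [vars(s) for s in spiked],
    })
    reads_dir = out / "reads"
    reads_dir.mkdir(exist_ok=True)
    truth_rows = []
    for i, row in enumerate(design.itertuples()):
        pairs, read_truth = synthetic.simulate_reads(
            genomes, truth[row.sample_id], p["n_pairs"],
            read_len=p.get("read_len", 150), error_rate=p.get("error_rate", 0.005),
            defect_rates=p.get("defect_rates") or {}, seed=seed + 100 + i,
            host_genome=host, spiked=spiked, sample_id=row.sample_id)
        io.write_paired_fastq(reads_dir / f"{row.sample_id}_R1.fastq",
                              reads_dir / f"{row.sample_id}_R2.fastq", pairs)
        truth_rows.append(synthetic.truth_frame(read_truth))
    pd.concat(truth_rows).to_csv(out / "read_truth.tsv", sep="\t", index=False)
    _write_manifest(out, {"seed": seed, **p})


def stage_qc(cfg: dict, run_dir: Path) -> None:
    out = run_dir / "qc"
    out.mkdir(parents=True, exist_ok=True)
    sim = run_dir / "simulate"
    host = io.read_genomes(sim / "host.fasta", sim / "host.tsv")
    params = qc_mod.QCParams(**cfg["qc"])
    host_index = qc_mod.build_host_index(
        {g.accession: g.sequence for g in host}, k=params.host_seed_k)
    reports = []
    for sid in _sample_ids(run_dir):
        pairs = io.read_paired_fastq(sim / "reads" / f"{sid}_R1.fastq",
                                     sim / "reads" / f"{sid}_R2.fastq")
        result = qc_mod.run_qc(pairs, synthetic.DEFAULT_ADAPTER, host_index, params)
        io.write_paired_fastq(out / f"{sid}_R1.fastq", out / f"{sid}_R2.fastq",
                              result.kept_pairs)
        io.write_fastq(out / f"{sid}_singletons.fastq", result.singletons)
        rep = result.report.copy()
        rep.insert(0, "sample_id", sid)
        reports.append(rep)
    pd.concat(reports).to_csv(out / "qc_report.tsv", sep="\t", index=False)
    _write_manifest(out, {"seed": cfg["seed"], **cfg["qc"]})


def stage_build_db(cfg: dict, run_dir: Path) -> None:
    out = run_dir / "build_db"
    out.mkdir(parents=True, exist_ok=True)
    sim = run_dir / "simulate"
    genomes = io.read_genomes(sim / "genomes.fasta", sim / "genomes.tsv")
    p = cfg["build_db"]
    result = refdb.curate(genomes, k_fence=p["k_fence"],
                          cluster_threshold=p["cluster_threshold"],
                          kmer_k=p["kmer_k"], linkage_method=p["linkage"])
    io.write_genomes(out / "curated.fasta", out / "curated.tsv", result.kept)
    result.report.to_csv(out / "curation_report.tsv", sep="\t", index=False)
    _write_manifest(out, p)


def stage_profile(cfg: dict, run_dir: Path) -> None:
    out = run_dir / "profile"
    out.mkdir(parents=True, exist_ok=True)
    db = io.read_genomes(run_dir / "build_db" / "curated.fasta",
                         run_dir / "build_db" / "curated.tsv")
    samples = {
        sid: io.read_paired_fastq(run_dir / "qc" / f"{sid}_R1.fastq",
                                  run_dir / "qc" / f"{sid}_R2.fastq")
        for sid in _sample_ids(run_dir)
    }
    pcfg = taxprofile.ProfilerConfig(**cfg["profile"])
    matrix, mapped, counts = taxprofile.profile_cohort(
        samples, db, pcfg, seed=int(cfg["seed"]) + 500)
    matrix.to_csv(out / "species.tsv", sep="\t")
    counts.to_csv(out / "counts.tsv", sep="\t")
    mapped.rename_axis("sample_id").to_frame().to_csv(out / "mapped_ratio.tsv", sep="\t")
    kingdoms = taxprofile.aggregate_kingdoms(
        matrix, {g.species: g.kingdom for g in db})
    kingdoms.to_csv(out / "kingdom.tsv", sep="\t")
    _write_manifest(out, {"seed": cfg["seed"], **cfg["profile"]})


def _qc_pairs(run_dir: Path, sid: str):
    return io.read_paired_fastq(run_dir / "qc" / f"{sid}_R1.fastq",
                                run_dir / "qc" / f"{sid}_R2.fastq")


def stage_cazy(cfg: dict, run_dir: Path) -> None:
    out = run_dir / "cazy"
    out.mkdir(parents=True, exist_ok=True)
    sim = run_dir / "simulate"
    catalog = io.read_cazy_catalog(sim / "cazy.fasta", sim / "cazy.tsv")
    pathway_map = cfg["cazy"].get("pathway_map") or {}
    family_rows, pathway_rows, fam_counts = {}, {}, {}
    if catalog:
        index = AlignmentIndex({g.gene_id: g.sequence for g in catalog},
                               alphabet="protein", target_kind="cazy_gene")
    for sid in _sample_ids(run_dir):
        pairs = _qc_pairs(run_dir, sid)
        if catalog:
            h1 = align_reads([p.r1 for p in pairs], index,
                             min_score=cazy_mod.MIN_SCORE,
                             max_evalue=cazy_mod.MAX_EVALUE)
            h2 = align_reads([p.r2 for p in pairs], index,
                             min_score=cazy_mod.MIN_SCORE,
                             max_evalue=cazy_mod.MAX_EVALUE)
            pair_hits = cazy_mod.merge_mate_hits(h1, h2)
        else:
            pair_hits = {}
        fam = cazy_mod.fractional_family_abundance(pair_hits, catalog) \
            if catalog else pd.Series(dtype=float)
        family_rows[sid] = fam
        pathway_rows[sid] = cazy_mod.pathway_group_abundance(fam, pathway_map)
        fam_counts[sid] = cazy_mod.count_cazy_families(pair_hits, catalog)
    families = pd.DataFrame(family_rows).T.fillna(0.0)
    families.index.name = "sample_id"
    families.to_csv(out / "family.tsv", sep="\t")
    pd.DataFrame(pathway_rows).T.rename_axis("sample_id").to_csv(
        out / "pathway.tsv", sep="\t")
    pd.Series(fam_counts, name="n_families").rename_axis("sample_id").to_csv(
        out / "family_counts.tsv", sep="\t")
    _write_manifest(out, {"seed": cfg["seed"], **cfg["cazy"]})


def stage_resistome(cfg: dict, run_dir: Path) -> None:
    out = run_dir / "resistome"
    out.mkdir(parents=True, exist_ok=True)
    sim = run_dir / "simulate"
    catalog = io.read_arg_catalog(sim / "arg.fasta", sim / "arg.tsv")
    db = io.read_genomes(run_dir / "build_db" / "curated.fasta",
                         run_dir / "build_db" / "curated.tsv")
    design = io.read_design(sim / "design.tsv")
    genome_index = AlignmentIndex({g.accession: g.sequence for g in db},
                                  alphabet="dna", target_kind="genome")
    arg_index = None
    if catalog:
        arg_index = AlignmentIndex({g.gene_id: g.sequence for g in catalog},
                                   alphabet="dna", target_kind="arg_gene")
    arg_hits, genome_hits, n_pairs = {}, {}, {}
    gene_rows, phen_rows, arg_counts = {}, {}, {}
    for sid in _sample_ids(run_dir):
        pairs = _qc_pairs(run_dir, sid)
        n_pairs[sid] = len(pairs)
        reads = [r for p in pairs for r in (p.r1, p.r2)]
        if arg_index is not None:
            h1 = align_reads([p.r1 for p in pairs], arg_index,
                             min_score=cazy_mod.MIN_SCORE,
                             max_evalue=cazy_mod.MAX_EVALUE)
            h2 = align_reads([p.r2 for p in pairs], arg_index,
                             min_score=cazy_mod.MIN_SCORE,
                             max_evalue=cazy_mod.MAX_EVALUE)
            arg_hits[sid] = cazy_mod.merge_mate_hits(h1, h2)
        else:
            arg_hits[sid] = {}
        ghits = align_reads(reads, genome_index, min_identity=0.9)
        gsets: dict[str, set] = {}
        for h in ghits:
            gsets.setdefault(h.read_id, set()).add(h.target_id)
        genome_hits[sid] = {pid: frozenset(s) for pid, s in gsets.items()}
        genes, phens, count = res_mod.arg_abundance(arg_hits[sid], catalog) \
            if catalog else (pd.Series(dtype=float), pd.Series(dtype=float), 0)
        gene_rows[sid], phen_rows[sid], arg_counts[sid] = genes, phens, count
    pd.DataFrame(gene_rows).T.fillna(0.0).rename_axis("sample_id").to_csv(
        out / "arg_genes.tsv", sep="\t")
    pd.DataFrame(phen_rows).T.fillna(0.0).rename_axis("sample_id").to_csv(
        out / "arg_phenotypes.tsv", sep="\t")
    pd.Series(arg_counts, name="n_args").rename_axis("sample_id").to_csv(
        out / "arg_counts.tsv", sep="\t")
    edges, nodes = res_mod.co_assignment_edges(arg_hits, genome_hits, n_pairs,
                                               design, catalog, db)
    res_mod.edges_frame(edges).to_csv(out / "edges.tsv", sep="\t", index=False)
    nodes.to_csv(out / "nodes.tsv", sep="\t", index=False)
    import networkx as nx

    for cohort in sorted(design["habitat"].unique()):
        g = res_mod.edges_to_graph(edges, nodes, cohort)
        nx.write_graphml(g, out / f"network_{cohort}.graphml")
    _write_manifest(out, {"seed": cfg["seed"], **cfg["resistome"]})


def stage_diversity(cfg: dict, run_dir: Path) -> None:
    out = run_dir / "diversity"
    out.mkdir(parents=True, exist_ok=True)
    matrix = pd.read_csv(run_dir / "profile" / "species.tsv", sep="\t",
                         index_col=0)
    counts = pd.read_csv(run_dir / "profile" / "counts.tsv", sep="\t",
                         index_col=0)
    tree = (run_dir / "simulate" / "taxonomy.nwk").read_text()
    report = stats.alpha_diversity(matrix, counts, tree)
    report.rename_axis("sample_id").to_csv(out / "diversity.tsv", sep="\t")
    if len(matrix) >= 3:
        coords, explained = stats.pcoa_spearman(matrix)
        coords.rename_axis("sample_id").to_csv(out / "pcoa.tsv", sep="\t")
        pd.Series(explained, index=coords.columns, name="explained").to_csv(
            out / "pcoa_explained.tsv", sep="\t")
    _write_manifest(out, {"seed": cfg["seed"], **cfg["diversity"]})


def stage_associate(cfg: dict, run_dir: Path) -> None:
    out = run_dir / "associate"
    out.mkdir(parents=True, exist_ok=True)
    matrix = pd.read_csv(run_dir / "profile" / "species.tsv", sep="\t",
                         index_col=0)
    design = io.read_design(run_dir / "simulate" / "design.tsv")
    p = cfg["associate"]
    adjust = [v for v in p.get("adjust_for", [])
              if design[v].nunique() > 1 and v != p["target"]]
    try:
        result = stats.associate(matrix, design, target=p["target"],
                                 adjust_for=adjust)
    except ValueError as exc:
        if "confounded" not in str(exc) or not adjust:
            raise
        log.warning("adjustment variables %s confounded with target %r; "
                    "fitting unadjusted model", adjust, p["target"])
        result = stats.associate(matrix, design, target=p["target"], adjust_for=[])
    result.to_csv(out / "association.tsv", sep="\t", index=False)
    _write_manifest(out, {"seed": cfg["seed"], **p})


_STAGE_FN = {
    "simulate": stage_simulate,
    "qc": stage_qc,
    "build_db": stage_build_db,
    "profile": stage_profile,
    "cazy": stage_cazy,
    "resistome": stage_resistome,
    "diversity": stage_diversity,
    "associate": stage_associate,
}


def _stage_params(cfg: dict, stage: str):
    if stage == "build_db":
        return cfg["build_db"]
    return {"seed": cfg["seed"], **cfg.get(stage, {})}


def run_pipeline(cfg: dict, run_dir, stages: list[str] | None = None,
                 resume: bool = True) -> Path:
    """Execute the pipeline stages in order, skipping up-to-date ones."""
    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    for stage in stages or STAGES:
        if stage not in _STAGE_FN:
            raise ValueError(f"unknown stage {stage!r}")
        params = _stage_params(cfg, stage)
        stage_dir = run_dir / stage
        if resume and _stage_current(stage_dir, params):
            log.info("stage %s up to date, skipping", stage)
            continue
        log.info("running stage %s", stage)
        try:
            _STAGE_FN[stage](cfg, run_dir)
        except Exception:
            log.error("stage %s failed", stage)
            raise
    return run_dir
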