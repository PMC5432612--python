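"""End-to-end orchestration: one config, seeded stages, a run manifest.

The pipeline composes the library stages in order — gene families →
duplicate-pair Ks → age-distribution filtering → mixture/SiZer → dating →
enrichment — with a single global seed that is deterministically
stage-salted, structured logging to stderr, and a JSON manifest of
per-stage input/output checksums and row counts written atomically at the
end of the run. Deterministic stages are byte-reproducible under a fixed
config; stochastic stages (EM restarts) are reproducible under the seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import sys
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .age_distribution import (
    KsSample,
    MixtureFit,
    build_ks_sample,
    classify_wgd_components,
    fit_mixture,
    plot_sizer,
    sizer,
)
from .codonalign_ks import PairDivergence, pair_divergence_from_seqs
from .dating import (
    CalibrationConstraint,
    date_wgd,
    estimate_rate,
    nj_tree,
    ortholog_ks_matrix,
    read_calibrations,
)
from .enrichment import compare_categories
from .gene_families import (
    GeneFamily,
    build_graph,
    mcl_cluster,
    single_copy_orthologs,
    within_species_pairs,
)
from .io_formats import (
    FormatError,
    HitRecord,
    SequenceRecord,
    read_annotations,
    read_fasta,
    read_gene_list,
    read_hit_table,
    species_of,
    write_newick,
)

logger = logging.getLogger("paleoks")

_DEFAULTS = {
    "hit_table": "compute",
    "te_flags": None,
    "annotations": None,
    "outdir": "paleoks_out",
    "seed": 0,
    "ks_max": 2.0,
    "zero_eps": 1e-9,
    "evalue_max": 1e-10,
    "identity_min": 40.0,
    "inflation": 1.5,
    "k_max": 5,
    "restarts": 20,
    "alpha": 0.05,
    "weight_min": 0.05,
    "max_ortholog_groups": None,
    "focal_species": None,
}
_REQUIRED = {"fastas", "calibrations"}


@dataclass
class PipelineConfig:
    fastas: dict[str, str]
    calibrations: str
    hit_table: str = "compute"
    te_flags: str | None = None
    annotations: str | None = None
    outdir: str = "paleoks_out"
    seed: int = 0
    ks_max: float = 2.0
    zero_eps: float = 1e-9
    evalue_max: float = 1e-10
    identity_min: float = 40.0
    inflation: float = 1.5
    k_max: int = 5
    restarts: int = 20
    alpha: float = 0.05
    weight_min: float = 0.05
    max_ortholog_groups: int | None = None
    focal_species: list[str] | None = None

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage seed below 2^31, salted by stage name."""
        return (self.seed * 1000003 + zlib.crc32(stage.encode())) % (2**31)


def validate_config(path: str | Path) -> PipelineConfig:
    """Parse and validate a key: value config file; unknown keys are fatal."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise FormatError(f"{path}: config must be a mapping")
    unknown = set(raw) - _REQUIRED - set(_DEFAULTS)
    if unknown:
        raise FormatError(f"{path}: unknown config key(s): {sorted(unknown)}")
    missing = _REQUIRED - set(raw)
    if missing:
        raise FormatError(f"{path}: missing required key(s): {sorted(missing)}")
    merged = {**_DEFAULTS, **raw}
    if not isinstance(merged["fastas"], dict) or not merged["fastas"]:
        raise FormatError(f"{path}: 'fastas' must map species name -> FASTA path")
    if int(merged["seed"]) < 0:
        raise FormatError(f"{path}: seed must be nonnegative")
    config = PipelineConfig(**merged)
    config.seed = int(config.seed)
    base = path.parent
    resolved = {}
    for sp, p in config.fastas.items():
        full = (base / p) if not os.path.isabs(p) else Path(p)
        if not full.exists():
            raise FormatError(f"{path}: FASTA for {sp!r} not found: {full}")
        resolved[sp] = str(full)
    config.fastas = resolved
    for key in ("calibrations", "te_flags", "annotations"):
        val = getattr(config, key)
        if val is None:
            continue
        full = (base / val) if not os.path.isabs(val) else Path(val)
        if not full.exists():
            raise FormatError(f"{path}: {key} file not found: {full}")
        setattr(config, key, str(full))
    if config.hit_table != "compute":
        full = (base / config.hit_table) if not os.path.isabs(config.hit_table) else Path(config.hit_table)
        if not full.exists():
            raise FormatError(f"{path}: hit_table not found: {full}")
        config.hit_table = str(full)
    return config


def compute_hits(
    species_seqs: dict[str, list[SequenceRecord]], max_genes: int = 2000
) -> list[HitRecord]:
    """All-vs-all protein comparison with the package's own aligner.

    Desk-scale alternative to an external search tool: every gene pair is
    globally aligned and reported with its percent identity; E-values are
    synthesized as 0 so only the identity threshold filters. Guarded to
    small inputs.
    """
    from .codonalign_ks import _aligner, translate
    from .io_formats import validate_cds

    all_recs = [r for recs in species_seqs.values() for r in recs]
    if len(all_recs) > max_genes:
        raise ValueError(
            f"internal all-vs-all comparison is limited to {max_genes} genes "
            f"({len(all_recs)} given); provide a precomputed hit table"
        )
    prots = [(r.id, translate(validate_cds(r).residues)) for r in all_recs]
    hits = []
    aligner = _aligner()
    for i, (ida, pa) in enumerate(prots):
        for idb, pb in prots[i + 1 :]:
            aln = aligner.align(pa, pb)[0]
            sa, sb = str(aln[0]), str(aln[1])
            matches = sum(1 for x, y in zip(sa, sb) if x == y and x != "-")
            aligned = sum(1 for x, y in zip(sa, sb) if x != "-" and y != "-")
            if aligned == 0:
                continue
            identity = 100.0 * matches / aligned
            hits.append(HitRecord(ida, idb, identity, 0.0, float(aln.score)))
    return hits


def duplicate_pair_divergences(
    families: list[GeneFamily],
    species: str,
    seq_index: dict[str, SequenceRecord],
) -> dict[str, dict[tuple[str, str], PairDivergence]]:
    """Per-family NG86 divergences of all within-species duplicate pairs."""
    out: dict[str, dict[tuple[str, str], PairDivergence]] = {}
    for fam in families:
        pairs = within_species_pairs(fam, species)
        if not pairs:
            continue
        fam_out = {}
        for a, b in pairs:
            fam_out[(a, b)] = pair_divergence_from_seqs(seq_index[a], seq_index[b])
        out[fam.family_id] = fam_out
    return out


def ortholog_divergences(
    orthogroups: list[GeneFamily],
    seq_index: dict[str, SequenceRecord],
    max_groups: int | None = None,
    seed: int = 0,
) -> tuple[dict[tuple[str, str], PairDivergence], list[GeneFamily]]:
    """NG86 divergences of cross-species pairs in single-copy orthogroups.

    ``max_groups`` subsamples orthogroups (seeded) to bound runtime; the
    mean ortholog Ks per species pair is insensitive to the subsample size.
    Returns the divergence map and the orthogroups actually used.
    """
    groups = sorted(orthogroups, key=lambda f: f.family_id)
    if max_groups is not None and len(groups) > max_groups:
        rng = np.random.default_rng(seed)
        idx = sorted(rng.choice(len(groups), size=max_groups, replace=False))
        groups = [groups[i] for i in idx]
    out: dict[tuple[str, str], PairDivergence] = {}
    for fam in groups:
        members = sorted(fam.members)
        for i, a in enumerate(members):
            for b in members[i + 1 :]:
                if species_of(a) == species_of(b):
                    continue
                out[(a, b)] = pair_divergence_from_seqs(seq_index[a], seq_index[b])
    return out, groups


def paleolog_genes(
    sample_pairs: list[PairDivergence],
    fit: MixtureFit,
    wgd_components: list,
) -> set[str]:
    """Genes of retained pairs assigned (max posterior) to a WGD component."""
    if not wgd_components:
        return set()
    wgd_idx = {
        i for i, c in enumerate(fit.components) if c in wgd_components
    }
    mus = np.array([c.mu_log for c in fit.components])
    sigmas = np.array([c.sigma_log for c in fit.components])
    weights = np.array([c.weight for c in fit.components])
    out: set[str] = set()
    for p in sample_pairs:
        if p.ks is None or p.ks <= 0:
            continue
        x = np.log(p.ks)
        dens = weights * np.exp(-0.5 * ((x - mus) / sigmas) ** 2) / sigmas
        if int(np.argmax(dens)) in wgd_idx:
            out.update((p.gene_a, p.gene_b))
    return out


@dataclass
class AnalysisResult:
    """In-memory results of the full analysis (one object per run)."""

    families: list[GeneFamily]
    orthogroups: list[GeneFamily]
    ks_samples: dict[str, KsSample]
    fits: dict[str, MixtureFit]
    wgd_components: dict[str, list]
    matrix: object = None
    tree: object = None
    rate: object = None
    ages: dict[str, object] = field(default_factory=dict)
    paleologs: dict[str, set[str]] = field(default_factory=dict)


def run_analysis(
    species_seqs: dict[str, list[SequenceRecord]],
    hits: list[HitRecord],
    te_flags: set[str],
    calibration: CalibrationConstraint,
    config: PipelineConfig | None = None,
    seed: int = 0,
) -> AnalysisResult:
    """Run the whole in-memory analysis on already-loaded inputs.

    This is the computational core shared by the CLI pipeline, the analysis
    scripts and the test suite; file IO lives in :func:`run_pipeline`.
    """
    cfg = config or PipelineConfig(fastas={}, calibrations="", seed=seed)
    species = sorted(species_seqs)
    focal = cfg.focal_species or species
    seq_index = {r.id: r for recs in species_seqs.values() for r in recs}

    graph = build_graph(hits, cfg.evalue_max, cfg.identity_min)
    graph.add_nodes_from(seq_index)  # genes without hits become singletons
    families = mcl_cluster(graph, inflation=cfg.inflation)
    orthogroups = single_copy_orthologs(families, species)
    logger.info(
        "families stage: %d genes -> %d families, %d single-copy orthogroups",
        len(seq_index), len(families), len(orthogroups),
    )

    result = AnalysisResult(families, orthogroups, {}, {}, {})
    sample_pairs: dict[str, list[PairDivergence]] = {}
    for sp in focal:
        fam_pairs = duplicate_pair_divergences(families, sp, seq_index)
        sample = build_ks_sample(sp, fam_pairs, te_flags, cfg.ks_max, cfg.zero_eps)
        result.ks_samples[sp] = sample
        sample_pairs[sp] = [
            p for fam in fam_pairs.values() for p in fam.values()
        ]
        logger.info(
            "agedist stage (%s): %d node-averaged Ks values (%s)",
            sp, len(sample.values), sample.provenance,
        )
        if len(sample.values) >= 30:
            fit = fit_mixture(
                sample, cfg.k_max, cfg.restarts, seed=cfg.stage_seed(f"mixfit:{sp}")
            )
            result.fits[sp] = fit
            result.wgd_components[sp] = classify_wgd_components(
                fit, cfg.weight_min, (0.1, cfg.ks_max)
            )
            logger.info(
                "mixfit stage (%s): k=%d, WGD peaks at %s",
                sp, fit.k, [round(c.peak_ks, 3) for c in result.wgd_components[sp]],
            )

    div, used_groups = ortholog_divergences(
        orthogroups, seq_index, cfg.max_ortholog_groups, cfg.stage_seed("ortholog_ks")
    )
    result.matrix = ortholog_ks_matrix(used_groups, div)
    if len(result.matrix.taxa) >= 3:
        result.tree = nj_tree(result.matrix)
    ks_cal = result.matrix.get(calibration.taxon_a, calibration.taxon_b)
    result.rate = estimate_rate(
        ks_cal, calibration.point_age,
        lineage=f"{calibration.taxon_a}~{calibration.taxon_b}",
    )
    logger.info(
        "dating stage: calibration Ks=%.4f at %.2f Mya -> mu=%.3e /site/yr",
        ks_cal, calibration.point_age, result.rate.mu,
    )
    for sp, comps in result.wgd_components.items():
        if comps:
            # date the dominant WGD signature (heaviest qualifying component)
            peak = max(comps, key=lambda c: c.weight)
            result.ages[sp] = date_wgd(peak, result.rate, species=sp)
            logger.info(
                "dating stage (%s): peak Ks %.3f -> %.2f Mya",
                sp, comps[0].peak_ks, result.ages[sp].t_mya,
            )
        fit = result.fits.get(sp)
        if fit is not None:
            result.paleologs[sp] = paleolog_genes(sample_pairs[sp], fit, comps)
    return result


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """File-level pipeline: read inputs, run the analysis, write outputs.

    Returns the run manifest (also written to ``<outdir>/manifest.json``
    atomically). Fails on the first stage error, naming the stage.
    """
    t0 = time.time()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "tool_version": __version__,
        "seed": config.seed,
        "stages": [],
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    inputs = {}
    species_seqs = {sp: read_fasta(p) for sp, p in config.fastas.items()}
    for sp, recs in species_seqs.items():
        for r in recs:
            if species_of(r.id) != sp:
                raise FormatError(
                    f"gene {r.id!r} in {sp} FASTA lacks the '{sp}|' prefix"
                )
        inputs[config.fastas[sp]] = _sha256(Path(config.fastas[sp]))
    te_flags = read_gene_list(config.te_flags) if config.te_flags else set()
    calibrations = read_calibrations(config.calibrations)
    if not calibrations:
        raise FormatError(f"{config.calibrations}: no calibration constraints")
    if config.hit_table == "compute":
        hits = compute_hits(species_seqs)
    else:
        hits = read_hit_table(config.hit_table)
        inputs[config.hit_table] = _sha256(Path(config.hit_table))
    manifest["config_hash"] = hashlib.sha256(
        json.dumps({k: str(v) for k, v in vars(config).items()}, sort_keys=True).encode()
    ).hexdigest()
    manifest["inputs"] = inputs

    result = run_analysis(species_seqs, hits, te_flags, calibrations[0], config)

    outputs: dict[str, str] = {}

    def emit(name: str, writer) -> None:
        path = outdir / name
        writer(path)
        outputs[name] = _sha256(path)

    def write_families(path: Path) -> None:
        with open(path, "w") as fh:
            fh.write("family_id\tgene_id\n")
            for fam in result.families:
                for g in sorted(fam.members):
                    fh.write(f"{fam.family_id}\t{g}\n")

    emit("families.tsv", write_families)

    def write_orthogroups(path: Path) -> None:
        with open(path, "w") as fh:
            fh.write("family_id\tgene_id\n")
            for fam in result.orthogroups:
                for g in sorted(fam.members):
                    fh.write(f"{fam.family_id}\t{g}\n")

    emit("orthogroups.tsv", write_orthogroups)

    for sp, sample in result.ks_samples.items():
        def write_sample(path: Path, sample=sample) -> None:
            with open(path, "w") as fh:
                fh.write("ks\n")
                for v in sample.values:
                    fh.write(f"{v:.6f}\n")

        emit(f"ks_sample_{sp}.tsv", write_sample)
        emit(
            f"ks_provenance_{sp}.json",
            lambda path, sample=sample: Path(path).write_text(
                json.dumps(sample.provenance, indent=2)
            ),
        )
    for sp, fit in result.fits.items():
        emit(
            f"mixfit_{sp}.json",
            lambda path, fit=fit: Path(path).write_text(
                json.dumps(fit.to_dict(), indent=2)
            ),
        )
        sample = result.ks_samples[sp]
        if len(sample.values) >= 30:
            smap = sizer(sample)
            emit(
                f"sizer_{sp}.tsv",
                lambda path, smap=smap: smap.to_frame().to_csv(path, sep="\t"),
            )
            emit(f"sizer_{sp}.png", lambda path, smap=smap: plot_sizer(smap, path))
    if result.tree is not None:
        emit("ks_tree.nwk", lambda path: write_newick(result.tree, path))
    for sp, age in result.ages.items():
        emit(
            f"wgd_age_{sp}.json",
            lambda path, age=age: Path(path).write_text(
                json.dumps(age.to_dict(), indent=2)
            ),
        )
    if config.annotations:
        annotations = read_annotations(config.annotations)
        for sp, paleo in result.paleologs.items():
            all_genes = {r.id for r in species_seqs[sp]}
            non_paleo = all_genes - paleo
            if not paleo or not non_paleo:
                continue
            enr = compare_categories(
                annotations, annotations, paleo, non_paleo, alpha=config.alpha
            )

            def write_enrichment(path: Path, enr=enr) -> None:
                with open(path, "w") as fh:
                    fh.write(
                        "category\ta\tb\tc\td\todds_ratio\tp\tq\tdirection\tsignificant\n"
                    )
                    for r in enr:
                        t = r.table
                        fh.write(
                            f"{r.category}\t{t.a}\t{t.b}\t{t.c}\t{t.d}\t"
                            f"{r.odds_ratio:.6g}\t{r.p:.6g}\t{r.q:.6g}\t"
                            f"{r.direction}\t{r.significant}\n"
                        )

            emit(f"enrichment_paleolog_{sp}.tsv", write_enrichment)

    manifest["outputs"] = outputs
    manifest["row_counts"] = {
        "genes": sum(len(v) for v in species_seqs.values()),
        "families": len(result.families),
        "orthogroups": len(result.orthogroups),
        **{f"ks_values_{sp}": len(s.values) for sp, s in result.ks_samples.items()},
    }
    manifest["elapsed_s"] = round(time.time() - t0, 2)
    tmp = outdir / "manifest.json.tmp"
    tmp.write_text(json.dumps(manifest, indent=2))
    os.replace(tmp, outdir / "manifest.json")
    return manifest


def setup_logging(level: str = "INFO", logfile: str | Path | None = None) -> None:
    handlers: list[logging.Handler] = [logging.StreamHandler(sys.stderr)]
    if logfile:
        handlers.append(logging.FileHandler(logfile))
    logging.basicConfig(
        level=getattr(logging, level.upper(), logging.INFO),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
        handlers=handlers,
        force=True,
    )
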