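"""End-to-end funnel orchestration.

Stages, in order, for each trait: read summary stats -> p-value filter ->
association blocks -> feature maps + shuffled controls -> chromosome split ->
autoencoder pretraining -> CNN training -> test-partition AUC -> per-SNP
scores on all real blocks -> initial candidates (score > 0.5) -> block-top
candidates -> target-gene assignment. Then across traits: shared-gene
intersection and the LD-sharing filter on the primary trait's block-top
candidates. Every stage writes a plain file under the output directory and
the run manifest records per-stage counts, seeds and input digests, so any
stage can be inspected or re-run in isolation.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

from . import blocks as blocks_mod
from . import features as feat_mod
from . import gwas, ld
from . import model as model_mod
from ._rng import child_rng
from .genes import (
    DEFAULT_PROMOTER_KB,
    GeneIndex,
    read_enhancer_links,
    read_gene_models,
    write_assignments,
)
from .simulate import SimulationConfig, SyntheticDataset, TruthManifest, simulate_dataset, write_dataset

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "RunManifest", "PipelineError", "run_pipeline", "simulate_and_run"]

VERSION = "0.1.0"


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Paths and parameters of one full run. ``sumstats`` maps trait name to
    its summary-statistics file; the first listed trait is the primary one
    (the trait whose candidates pass the final LD-sharing filter)."""

    sumstats: dict  # trait -> path
    track_manifest: str
    genes_path: str
    links_path: str
    panel_vcf: str
    outdir: str
    val_chroms: tuple = ()
    test_chroms: tuple = ()
    pvalue_threshold: float = gwas.DEFAULT_PVALUE_THRESHOLD
    min_lead_separation_bp: int = 1_000_000
    n_neighbors: int = 30
    window_bp: int = 500_000
    model: model_mod.ModelConfig = field(default_factory=model_mod.ModelConfig)
    promoter_kb: float = DEFAULT_PROMOTER_KB
    r2_threshold: float = ld.DEFAULT_R2_THRESHOLD
    seed: int = 0

    def validate(self) -> None:
        if len(self.sumstats) != 2:
            raise ValueError("the cross-trait funnel needs exactly two traits")
        for p in [self.track_manifest, self.genes_path, self.links_path, self.panel_vcf, *self.sumstats.values()]:
            if not os.path.exists(p):
                raise FileNotFoundError(p)

    @property
    def traits(self) -> list[str]:
        return list(self.sumstats)


@dataclass
class RunManifest:
    """Per-stage record counts (the funnel), seeds, digests and AUCs."""

    config_digest: str
    input_digests: dict
    counts: dict
    aucs: dict
    seed: int
    version: str = VERSION
    status: str = "OK"
    failed_stage: str = ""

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True)


def _digest_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def run_pipeline(cfg: PipelineConfig) -> RunManifest:
    """Execute the full funnel for both traits; deterministic given the
    config (including seed). On a stage failure the manifest is written with
    a FAILED marker naming the stage, and a PipelineError is raised."""
    cfg.validate()
    os.makedirs(cfg.outdir, exist_ok=True)
    counts: dict = {}
    aucs: dict = {}
    input_digests = {
        "genes": _digest_file(cfg.genes_path),
        "links": _digest_file(cfg.links_path),
        "panel": _digest_file(cfg.panel_vcf),
        "tracks": _digest_file(cfg.track_manifest),
        **{f"sumstats:{t}": _digest_file(p) for t, p in cfg.sumstats.items()},
    }
    config_digest = hashlib.sha256(repr(cfg).encode()).hexdigest()[:16]
    manifest = RunManifest(
        config_digest=config_digest,
        input_digests=input_digests,
        counts=counts,
        aucs=aucs,
        seed=cfg.seed,
    )
    stage = "setup"

    def fail(err: BaseException) -> PipelineError:
        manifest.status = "FAILED"
        manifest.failed_stage = stage
        manifest.to_json(os.path.join(cfg.outdir, "manifest.json"))
        return PipelineError(stage, err)

    try:
        stage = "load-annotation"
        genes = read_gene_models(cfg.genes_path)
        links = read_enhancer_links(cfg.links_path, genes)
        tracks = feat_mod.read_track_manifest(cfg.track_manifest)
        index = GeneIndex(genes, links, cfg.promoter_kb)

        block_tops: dict = {}
        assignments: dict = {}
        for ti, trait in enumerate(cfg.traits):
            stage = f"read-stats:{trait}"
            table = gwas.read_summary_stats(cfg.sumstats[trait], trait)
            counts[f"{trait}:n_snps"] = len(table)

            stage = f"filter:{trait}"
            filtered = gwas.filter_by_pvalue(table, cfg.pvalue_threshold)
            counts[f"{trait}:n_filtered"] = len(filtered)
            gwas.write_summary_stats(filtered, os.path.join(cfg.outdir, f"{trait}.filtered.tsv"))

            stage = f"blocks:{trait}"
            blks = blocks_mod.build_blocks(
                filtered,
                min_lead_separation_bp=cfg.min_lead_separation_bp,
                n_neighbors=cfg.n_neighbors,
                window_bp=cfg.window_bp,
            )
            counts[f"{trait}:n_blocks"] = len(blks)
            blocks_mod.blocks_to_json(blks, os.path.join(cfg.outdir, f"{trait}.blocks.json"))

            stage = f"feature-maps:{trait}"
            mcfg = dataclasses.replace(cfg.model, seed=cfg.model.seed + cfg.seed + ti)
            pos_maps = [
                feat_mod.build_block_map(b, tracks, mcfg.positive_label_confidence) for b in blks
            ]
            rng = child_rng(cfg.seed, f"ctrl-{trait}")
            ctrl_maps = [
                feat_mod.make_control_block(m, rng, mcfg.control_label_confidence) for m in pos_maps
            ]
            all_maps = pos_maps + ctrl_maps
            counts[f"{trait}:n_maps"] = len(all_maps)

            stage = f"split:{trait}"
            split = model_mod.split_by_chromosome(all_maps, set(cfg.val_chroms), set(cfg.test_chroms))

            stage = f"pretrain:{trait}"
            pre = model_mod.pretrain_autoencoder(split.train, mcfg)

            stage = f"train:{trait}"
            trained = model_mod.train(split, mcfg, encoder_params=pre.member_encoders)

            stage = f"evaluate:{trait}"
            test_labels = {m.label for m in split.test}
            if len(test_labels) == 2:
                report = model_mod.evaluate_auc(trained, split.test)
                report.partition_counts = {
                    "train": len(split.train),
                    "val": len(split.val),
                    "test": len(split.test),
                }
                aucs[trait] = report.auc
            else:
                logger.warning("test partition for %s lacks both classes; AUC not computed", trait)
                aucs[trait] = None

            stage = f"predict:{trait}"
            scores = model_mod.predict_scores(trained, pos_maps)
            cands = model_mod.select_candidates(scores)
            tops = model_mod.select_block_top(cands)
            counts[f"{trait}:n_scored_snps"] = len(scores)
            counts[f"{trait}:n_candidates"] = len(cands)
            counts[f"{trait}:n_block_tops"] = len(tops)
            top_by_key = {(t.block_id, t.snp_id): t for t in tops}
            merged = [top_by_key.get((s.block_id, s.snp_id), s) for s in cands]
            chrom_of = {b.block_id: b.chrom for b in blks}
            model_mod.write_scores(merged, chrom_of, os.path.join(cfg.outdir, f"{trait}.scores.tsv"))
            block_tops[trait] = tops

            stage = f"assign-genes:{trait}"
            snp_lookup = {m.snp_id: m for b in blks for m in b.members}
            assignments[trait] = [index.assign(snp_lookup[s.snp_id]) for s in tops]
            write_assignments(assignments[trait], os.path.join(cfg.outdir, f"{trait}.assignments.tsv"))

        stage = "shared-genes"
        t1, t2 = cfg.traits
        shared = ld.shared_genes(assignments[t1], assignments[t2])
        counts["n_shared_genes"] = len(shared)
        with open(os.path.join(cfg.outdir, "shared_genes.txt"), "w") as fh:
            fh.write("\n".join(sorted(shared)) + ("\n" if shared else ""))

        stage = "load-panel"
        panel = ld.read_vcf(cfg.panel_vcf)

        stage = "ld-filter"
        final = ld.filter_by_ld(
            block_tops[t1],
            block_tops[t2],
            shared,
            assignments[t1],
            assignments[t2],
            panel,
            cfg.r2_threshold,
        )
        counts["n_final_snps"] = len(final.snps)
        counts["n_final_genes"] = len(final.genes)
        ld.write_final_set(final, os.path.join(cfg.outdir, "final_candidates.tsv"))
        with open(os.path.join(cfg.outdir, "final_summary.json"), "w") as fh:
            json.dump(
                {
                    "trait": final.trait,
                    "snps": sorted(s.snp_id for s in final.snps),
                    "genes": sorted(final.genes),
                    "n_supporting_pairs": len(final.supporting_pairs),
                },
                fh,
                indent=1,
                sort_keys=True,
            )
    except Exception as err:  # noqa: BLE001 - convert any stage failure
        raise fail(err) from err

    manifest.to_json(os.path.join(cfg.outdir, "manifest.json"))
    return manifest


def _default_holdout(sim: SimulationConfig) -> tuple[tuple, tuple]:
    labels = [str(c) for c in range(1, sim.n_chromosomes + 1)]
    if len(labels) >= 4:
        return (labels[-3],), tuple(labels[-2:])
    if len(labels) >= 2:
        return (), (labels[-1],)
    return (), ()


def simulate_and_run(
    sim_config: SimulationConfig,
    pipe_overrides: dict | None = None,
    workdir=None,
):
    """Generate a synthetic dataset, run the full pipeline on its files, and
    report recovery of the planted truth.

    Returns ``(truth, manifest, recovery)`` where ``recovery`` holds recall
    and precision of the planted shared causal genes among the final gene
    candidates (recall is None when nothing was planted), the fraction of
    final SNPs that are truly causal, and the hypergeometric tail probability
    of the observed final-gene / planted-gene overlap.
    """
    import tempfile

    from scipy.stats import hypergeom

    ctx = tempfile.TemporaryDirectory() if workdir is None else None
    base = ctx.name if ctx is not None else os.fspath(workdir)
    try:
        ds = simulate_dataset(sim_config)
        data_dir = os.path.join(base, "data")
        paths = write_dataset(ds, data_dir)
        val, test = _default_holdout(sim_config)
        cfg = PipelineConfig(
            sumstats=paths["sumstats"],
            track_manifest=paths["track_manifest"],
            genes_path=paths["genes"],
            links_path=paths["links"],
            panel_vcf=paths["panel"],
            outdir=os.path.join(base, "out"),
            val_chroms=val,
            test_chroms=test,
            seed=sim_config.seed,
        )
        for k, v in (pipe_overrides or {}).items():
            if not hasattr(cfg, k):
                raise AttributeError(f"unknown pipeline override {k!r}")
            setattr(cfg, k, v)
        manifest = run_pipeline(cfg)

        with open(os.path.join(cfg.outdir, "final_summary.json")) as fh:
            final = json.load(fh)
        final_genes = set(final["genes"])
        final_snps = set(final["snps"])
        truth = ds.truth
        planted = truth.shared_gene_ids
        hit = final_genes & planted
        recovery = {
            "recall": (len(hit) / len(planted)) if planted else None,
            "precision": (len(hit) / len(final_genes)) if final_genes else 0.0,
            "n_final_genes": len(final_genes),
            "n_final_snps": len(final_snps),
            "causal_snp_fraction": (
                sum(1 for s in final_snps if truth.is_causal(s)) / len(final_snps)
                if final_snps
                else 0.0
            ),
            "hypergeom_p": float(
                hypergeom.sf(
                    len(hit) - 1, sim_config.n_genes, len(planted), max(len(final_genes), 1)
                )
            )
            if planted
            else 1.0,
        }
        return truth, manifest, recovery
    finally:
        if ctx is not None:
            ctx.cleanup()
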