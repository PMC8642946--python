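"""End-to-end orchestration: simulate -> quantify -> DE/SPE -> inheritance ->
proteogenomics -> pASE -> transcript ASE -> cross-level comparison.

Single-process, stage-per-function execution with TSV file handoffs.  A run
manifest records the seed, per-stage row counts and content digests of every
output, so identical configs reproduce identical outputs (manifests differ
only in their timestamp).  A stage failure aborts the run with the failing
stage named; outputs already written stay in place under the output
directory.
"""

from __future__ import annotations

import datetime
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import diffexpr, inheritance, pase, proteogenomics, synthetic, tmt, transcript_ase
from .config import PipelineConfig
from .design import StrainDesign
from .io import read_tsv, sha256_of, write_matrix_tsv, write_tsv

log = logging.getLogger(__name__)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def _record(manifest: dict, outdir: Path, name: str, path: Path, n_rows: int) -> None:
    manifest["outputs"][name] = {
        "path": str(path.relative_to(outdir)),
        "rows": int(n_rows),
        "sha256": sha256_of(path),
    }


def run_pipeline(cfg: PipelineConfig, outdir) -> dict:
    """Execute all enabled stages in dependency order; return the manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": cfg.seed,
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "inputs": cfg.input_paths(),
        "stages": [],
        "outputs": {},
    }
    rng_seeds = {name: (cfg.seed * 7919 + i) % (2**31)
                 for i, name in enumerate(
                     ["proteome", "variants", "counts", "reference"])}

    sim = cfg.simulation
    design = StrainDesign.default(replicates=sim.replicates)
    write_tsv(design.to_frame(), outdir / "sample_metadata.tsv", index=False)

    def stage(name):
        manifest["stages"].append(name)
        log.info("stage %s", name)

    try:
        stage("simulate")
        params = synthetic.SimParams(
            n_proteins=sim.n_proteins, sigma_additive=sim.sigma_additive,
            sigma_dominance=sim.sigma_dominance, sigma_sex=sim.sigma_sex,
            sigma_residual=sim.sigma_residual, fraction_null=sim.fraction_null,
            psm_mean=sim.psm_mean, psm_cv=sim.psm_cv, seed=rng_seeds["proteome"])
        psms, true_matrix, truth = synthetic.simulate_proteome(design, params)
        impurity = synthetic.default_impurity_matrix(design.n_channels)
        _record(manifest, outdir, "psm_table",
                write_tsv(psms, outdir / "psm_table.tsv"), len(psms))
        _record(manifest, outdir, "true_protein_matrix",
                write_tsv(true_matrix, outdir / "true_protein_matrix.tsv"),
                len(true_matrix))
        _record(manifest, outdir, "protein_truth",
                write_tsv(truth.proteins, outdir / "truth_proteins.tsv"),
                len(truth.proteins))
    except Exception as exc:  # noqa: BLE001
        raise StageError("simulate", exc) from exc

    matrix = None
    if cfg.stages.quant:
        try:
            stage("quant")
            quant = tmt.quantify(
                psms, impurity, min_intensity=cfg.quant.min_intensity,
                min_median=cfg.quant.min_median,
                trim_fraction=cfg.quant.trim_fraction)
            matrix = quant.log2_rel[design.sample_ids]
            _record(manifest, outdir, "protein_matrix",
                    write_tsv(quant.to_frame(), outdir / "protein_matrix.tsv"),
                    len(quant.log2_rel))
            log.info("quant: %d PSMs -> %d proteins", len(psms), len(matrix))
        except Exception as exc:  # noqa: BLE001
            raise StageError("quant", exc) from exc
    else:
        matrix = true_matrix

    if cfg.stages.diffexpr:
        try:
            stage("diffexpr")
            de = diffexpr.moderated_ttest(matrix, design.samples_of("B6"),
                                          design.samples_of("D2"))
            de = diffexpr.call_deps(de, fc_cut=cfg.diffexpr.fc_cut,
                                    fdr=cfg.diffexpr.fdr)
            cv = diffexpr.compute_cv_and_high_variation(matrix)
            spe = diffexpr.call_spe(matrix, design,
                                    high_pct=cfg.diffexpr.spe_high_pct,
                                    low_pct=cfg.diffexpr.spe_low_pct)
            imprint = diffexpr.compare_reciprocal_hybrids(
                matrix, design, p_cut=cfg.diffexpr.hybrid_p_cut,
                fc_cut=cfg.diffexpr.hybrid_fc_cut)
            _record(manifest, outdir, "diffexpr",
                    write_tsv(de.join(cv), outdir / "diffexpr.tsv"), len(de))
            _record(manifest, outdir, "spe",
                    write_tsv(spe, outdir / "spe.tsv"), len(spe))
            _record(manifest, outdir, "imprinting",
                    write_tsv(imprint, outdir / "imprinting.tsv"), len(imprint))
        except Exception as exc:  # noqa: BLE001
            raise StageError("diffexpr", exc) from exc

    if cfg.stages.inheritance:
        try:
            stage("inheritance")
            matrices = inheritance.build_relatedness_matrices(design)
            write_matrix_tsv(inheritance.R1_STRAIN,
                             ["B6", "D2", "B6D2F1", "D2B6F1"],
                             outdir / "r1_strain.tsv")
            write_matrix_tsv(inheritance.R2_STRAIN,
                             ["B6", "D2", "B6D2F1", "D2B6F1"],
                             outdir / "r2_strain.tsv")
            vc = inheritance.variance_components_table(matrix, design)
            _record(manifest, outdir, "inheritance",
                    write_tsv(vc, outdir / "inheritance.tsv"), len(vc))
            log.info("inheritance: median H2 = %.3f", float(vc["h2"].median()))
        except Exception as exc:  # noqa: BLE001
            raise StageError("inheritance", exc) from exc

    pairs = None
    if cfg.stages.proteogenomics:
        try:
            stage("proteogenomics")
            reference, variants = synthetic.simulate_reference_fasta(
                n_proteins=sim.n_reference_proteins, seed=rng_seeds["reference"])
            proteogenomics.write_fasta(reference, outdir / "reference.fasta")
            custom = proteogenomics.apply_missense_variants(reference, variants)
            proteogenomics.write_fasta(custom, outdir / "customized.fasta")
            write_tsv(variants, outdir / "variants.tsv", index=False)
            pairs = proteogenomics.enumerate_variant_peptide_pairs(
                reference, variants,
                missed_cleavages=cfg.digest.missed_cleavages,
                min_len=cfg.digest.min_len, max_len=cfg.digest.max_len,
                proline_rule=cfg.digest.proline_rule)
            _record(manifest, outdir, "variant_pairs",
                    write_tsv(pairs, outdir / "variant_pairs.tsv", index=False),
                    len(pairs))
        except Exception as exc:  # noqa: BLE001
            raise StageError("proteogenomics", exc) from exc

    if cfg.stages.pase:
        try:
            stage("pase")
            usable = (pairs[pairs["status"] == "paired"].reset_index(drop=True)
                      if pairs is not None else None)
            peptides, vtruth = synthetic.simulate_variant_peptides(
                design, n_pairs=sim.n_variant_pairs,
                category_mix=sim.category_mix, effect=sim.variant_effect,
                noise=sim.variant_noise, seed=rng_seeds["variants"],
                pairs=usable)
            _record(manifest, outdir, "variant_peptide_abundance",
                    write_tsv(peptides, outdir / "variant_peptide_abundance.tsv",
                              index=False), len(peptides))
            write_tsv(vtruth.variant_pairs, outdir / "truth_variant_pairs.tsv",
                      index=False)
            ratios = pase.compute_allelic_ratios(peptides, design)
            tests = pase.pase_test(peptides, design)
            calls = pase.classify_table(
                ratios, tau=cfg.pase.tau, mode=cfg.pase.mode,
                significance=tests["p_adjusted"] if cfg.pase.gate_significance
                else None, alpha=cfg.pase.alpha)
            calls = calls.join(tests[["p_value", "p_adjusted"]])
            calls["ase"] = calls["p_adjusted"] < cfg.pase.alpha
            gene_of = vtruth.variant_pairs.set_index("pair_id")["gene"]
            calls["gene"] = gene_of.reindex(calls.index).to_numpy()
            _record(manifest, outdir, "pase_calls",
                    write_tsv(calls, outdir / "pase_calls.tsv"), len(calls))
            summary = pase.category_counts(calls)
            write_tsv(summary.rename("n_pairs").to_frame(),
                      outdir / "pase_category_counts.tsv")
        except Exception as exc:  # noqa: BLE001
            raise StageError("pase", exc) from exc

    if cfg.stages.transcript_ase:
        try:
            stage("transcript_ase")
            counts, parental, gtruth = synthetic.simulate_allele_counts(
                n_genes=sim.n_genes, depth=sim.read_depth,
                category_mix=sim.category_mix, effect=sim.variant_effect,
                seed=rng_seeds["counts"])
            _record(manifest, outdir, "allele_counts",
                    write_tsv(counts, outdir / "allele_counts.tsv"), len(counts))
            write_tsv(parental, outdir / "parental_expression.tsv")
            write_tsv(gtruth.genes, outdir / "truth_genes.tsv")
            ase = transcript_ase.binomial_ase_test(
                counts, min_total=cfg.transcript.min_total)
            tcalls = transcript_ase.classify_transcript_regulation(
                counts, parental, tau=cfg.pase.tau,
                pseudocount=cfg.transcript.pseudocount, mode=cfg.pase.mode)
            tcalls = tcalls.join(ase[["p_value", "p_adjusted", "tested"]])
            tcalls["ase"] = tcalls["p_adjusted"] < cfg.transcript.alpha
            _record(manifest, outdir, "transcript_calls",
                    write_tsv(tcalls, outdir / "transcript_calls.tsv"),
                    len(tcalls))
            if cfg.stages.pase:
                shared = calls.dropna(subset=["gene"])
                overlap_genes = set(shared["gene"]) & set(tcalls.index)
                if overlap_genes:
                    comparison = transcript_ase.compare_levels(
                        shared.reset_index(), tcalls)
                    comp_df = pd.DataFrame(
                        comparison["table"],
                        index=["protein_ase", "protein_non_ase"],
                        columns=["transcript_ase", "transcript_non_ase"])
                    write_tsv(comp_df, outdir / "level_comparison_table.tsv")
                    write_tsv(comparison["category_crosstab"],
                              outdir / "level_comparison_categories.tsv")
                    manifest["level_comparison"] = {
                        "odds_ratio": comparison["odds_ratio"],
                        "p_value": comparison["p_value"],
                        "n_shared": comparison["n_shared"],
                    }
        except Exception as exc:  # noqa: BLE001
            raise StageError("transcript_ase", exc) from exc

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
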