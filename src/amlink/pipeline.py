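"""End-to-end orchestration: simulate (or load) a family cohort, run QC,
two-round reference-anchored ancestry PCA, polygenic scoring with pTDT and
the odd/even theta estimator, spousal-correlation analyses with subgroup
stratification, and the intra-/inter-locus resampling comparison.

Every stochastic stage derives its seed from the run seed; a stratum is
analyzed only when it meets the Fisher-z minimum-sample-size rule
(default: 80% power for r = 0.3 at alpha 0.05, i.e. n >= 85).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import amcorr, ancestry, ldstruct, pgs, qc, simdata
from .core_io import GenotypeMatrix, Pedigree, SummaryStats, harmonize_weights, write_results

logger = logging.getLogger("amlink")


@dataclass
class RunConfig:
    """Configuration for one pipeline run; thresholds default to the
    standard values used throughout the package."""

    sim: simdata.SimConfig = field(default_factory=simdata.SimConfig)
    # stage toggles
    run_qc: bool = True
    run_ancestry: bool = True
    run_pgs: bool = True
    run_amcorr: bool = True
    run_ldstruct: bool = True
    # qc thresholds
    max_sample_missing: float = 0.05
    min_call_rate: float = 0.95
    min_maf: float = 0.01
    min_hwe_p: float = 1e-5
    max_mendel_rate: float = 0.05
    # ancestry
    n_pcs: int = 20
    # amcorr
    m_tests: int = 336
    power_r: float = 0.3
    power_alpha: float = 0.05
    power_target: float = 0.8
    stratify_by: str = "group_label"
    # ldstruct
    ld_prune_r2: float = 0.1
    ld_prune_window_bp: int = 500_000
    n_iterations: int = 1000
    top_k: int = 200
    min_gap_bp: int = 500_000
    ld_roles: tuple = ("father", "mother", "sibling")
    # bookkeeping
    seed: int = 0
    out_dir: str | None = None

    def validate(self) -> None:
        self.sim.validate()
        if self.top_k < 1 or self.n_iterations < 0:
            raise simdata.ConfigError("top_k and n_iterations must be positive")


def _stack(a: GenotypeMatrix, b: GenotypeMatrix) -> GenotypeMatrix:
    """Row-concatenate two genotype matrices sharing a variant set."""
    if list(a.variants["id"]) != list(b.variants["id"]):
        raise ValueError("variant sets differ; harmonize before stacking")
    return GenotypeMatrix(a.samples + b.samples, a.variants,
                          np.vstack([a.dosages, b.dosages]))


def _subset_to_ids(G: GenotypeMatrix, variant_ids) -> GenotypeMatrix:
    mask = G.variants["id"].isin(set(variant_ids)).to_numpy()
    return G.subset_variants(mask)


def synthetic_summary_stats(sim: simdata.SimResult, seed: int,
                            n_case: int = 20_000, n_control: int = 40_000
                            ) -> SummaryStats:
    """Summary statistics emulating an external case-control GWAS of the
    simulated liability trait.

    Effect sizes are the generative causal effects plus sampling noise at
    the standard error implied by the study size; non-causal SNPs get
    null effects with the same error model.  Alleles follow the simulated
    a1/a2 coding.
    """
    rng = np.random.default_rng(seed)
    freqs = sim.freqs
    af = freqs["p"].to_numpy()
    n_eff = 4.0 / (1.0 / n_case + 1.0 / n_control)
    sd_test = np.sqrt(2 * af * (1 - af))
    se = 2.0 / (sd_test * np.sqrt(n_eff))
    beta = np.zeros(len(freqs))
    beta[sim.causal_index] = sim.causal_beta
    beta = beta + rng.normal(0, se)
    return SummaryStats(pd.DataFrame({
        "id": freqs["id"], "effect_allele": freqs["a1"], "other_allele": freqs["a2"],
        "beta": beta, "se": se, "n_case": n_case, "n_control": n_control,
    }))


@dataclass
class PipelineResult:
    tables: dict[str, pd.DataFrame]
    objects: dict[str, object]
    manifest: dict


def run_pipeline(config: RunConfig) -> PipelineResult:
    config.validate()
    rng = np.random.default_rng(config.seed)
    seeds = {name: int(s) for name, s in zip(
        ("panels", "sumstats", "ldstruct"), rng.integers(2**31 - 1, size=3))}

    manifest: dict = {"config_hash": hashlib.sha256(
        json.dumps(asdict(config), sort_keys=True, default=str).encode()).hexdigest()[:16],
        "seed": config.seed, "stage_seeds": seeds, "stages": {}}
    tables: dict[str, pd.DataFrame] = {}
    objects: dict[str, object] = {}

    # ---- simulate -------------------------------------------------------
    sim = simdata.simulate_dataset(config.sim)
    panels = simdata.reference_panels(sim.freqs, np.random.default_rng(seeds["panels"]),
                                      config.sim.ref_panel_size)
    G, ped = sim.genotypes, sim.pedigree
    objects["sim"] = sim
    manifest["stages"]["simulate"] = {"n_families": len(ped), "n_variants": G.n_variants}

    # ---- qc -------------------------------------------------------------
    if config.run_qc:
        G, report = qc.apply_qc_chain(
            G, ped, None,
            max_sample_missing=config.max_sample_missing,
            min_call_rate=config.min_call_rate, min_maf=config.min_maf,
            min_hwe_p=config.min_hwe_p, max_mendel_rate=config.max_mendel_rate)
        tables["qc_report"] = report.to_frame()
        manifest["stages"]["qc"] = {"n_variants_after": G.n_variants,
                                    "n_samples_after": G.n_samples}

    founders = [s for s in ped.founder_ids() if s in G._sample_index]

    # ---- ancestry -------------------------------------------------------
    pc_scores = None
    loadings_abs = None
    pruned_idx = None
    if config.run_ancestry:
        pruned_idx = ldstruct.ld_prune(G, founders, config.ld_prune_r2,
                                       config.ld_prune_window_bp)
        G_pruned = G.subset_variants(pruned_idx)

        # round 1: continental-style contrast panel for inclusion
        panel1 = _subset_to_ids(panels["round1"], G_pruned.variants["id"])
        combined1 = _stack(G_pruned.subset_samples(founders), panel1)
        model1 = ancestry.fit_reference_pca(combined1, combined1.samples, k=2)
        proj1 = model1.project(combined1)
        all_proj1 = pd.concat([proj1, model1.project(
            G_pruned.subset_samples([s for s in ped.child_ids() if s in G._sample_index]))])
        call1 = ancestry.assign_ancestry(all_proj1, simdata.panel_labels(panel1),
                                         "REF_TARGET")
        keep_mask = ancestry.family_retention_mask(call1, ped)
        ped = ped.subset(keep_mask)
        founders = [s for s in ped.founder_ids() if s in G._sample_index]
        manifest["stages"]["ancestry_round1"] = {
            "n_families_retained": len(ped),
            "n_samples_target_like": int((call1.calls["label"] == "target_like").sum())}

        # round 2: target-like subpanels; loadings feed the rest of the run
        panel2 = _subset_to_ids(panels["round2"], G_pruned.variants["id"])
        combined2 = _stack(G_pruned.subset_samples(founders), panel2)
        model2 = ancestry.fit_reference_pca(combined2, combined2.samples,
                                            k=min(config.n_pcs, combined2.n_samples - 1))
        members = [s for s in ped.all_ids() if s in G._sample_index]
        pc_scores = model2.project(G_pruned.subset_samples(members))
        loadings_abs = np.zeros(G.n_variants)
        loadings_abs[pruned_idx] = np.abs(model2.loadings[:, 0])
        objects["pca_round2"] = model2
        tables["pc_scores"] = pc_scores.reset_index(names="sample_id")

    # ---- pgs ------------------------------------------------------------
    pgs_result = None
    if config.run_pgs:
        stats_in = synthetic_summary_stats(sim, seeds["sumstats"])
        weights = harmonize_weights(G, stats_in)
        af = G.allele_freq(founders)
        keep = pgs.sd_filter(weights, af[weights["variant_index"].to_numpy()], binary=True)
        weights = weights.loc[keep].reset_index(drop=True)

        covariates = None
        if pc_scores is not None:
            covariates = pc_scores.iloc[:, :10].copy()
            covariates["age"] = sim.traits.values_for("age", covariates.index.tolist())
            sex = sim.traits.table.set_index("sample_id")["sex"].reindex(covariates.index)
            covariates["sex"] = (sex == "male").astype(float)
            covariates = covariates.loc[[s for s in founders if s in covariates.index]]
        pgs_result = pgs.score(G, weights, founders, covariates=covariates)
        objects["pgs"] = pgs_result

        rows = []
        for role in ("proband", "sibling"):
            try:
                res = pgs.ptdt(pgs_result, ped, child_role=role)
                rows.append({"group": role, **asdict(res)})
            except pgs.PgsError as exc:
                logger.info("pTDT (%s) skipped: %s", role, exc)
        tables["ptdt"] = pd.DataFrame(rows)

        theta = pgs.odd_even_theta(G, weights, founders, k=config.n_pcs)
        tables["theta"] = pd.DataFrame([asdict(theta)])
        manifest["stages"]["pgs"] = {"n_variants_scored": pgs_result.n_variants_used}

    # ---- amcorr ---------------------------------------------------------
    if config.run_amcorr:
        min_n = amcorr.min_n_for_power(config.power_r, config.power_alpha,
                                       config.power_target)
        strata = {"all": list(ped)}
        key = config.stratify_by
        for fam in ped:
            strata.setdefault(getattr(fam, key), []).append(fam)

        corr_rows, skip_rows = [], []
        corr_vars = [("PC1", "pearson"), ("PC2", "pearson"),
                     ("pgs_adjusted", "pearson"),
                     ("srs_total", "spearman"), ("bapq_total", "spearman")]
        per_stratum: dict[str, dict[str, amcorr.SpousalCorr]] = {}
        for label, fams in strata.items():
            if label != "all" and len(fams) < min_n:
                skip_rows.append({"stratum": label, "n": len(fams),
                                  "reason": f"below minimum n {min_n}"})
                continue
            sub = Pedigree(fams)
            fa, mo = sub.father_ids(), sub.mother_ids()
            for var, method in corr_vars:
                if var.startswith("PC"):
                    if pc_scores is None:
                        continue
                    fv = pc_scores[var].reindex(fa).to_numpy()
                    mv = pc_scores[var].reindex(mo).to_numpy()
                elif var == "pgs_adjusted":
                    if pgs_result is None:
                        continue
                    fv, mv = pgs_result.adjusted(fa), pgs_result.adjusted(mo)
                else:
                    fv = sim.traits.values_for(var, fa)
                    mv = sim.traits.values_for(var, mo)
                try:
                    c = amcorr.spousal_correlation(fv, mv, method=method,
                                                   variable=var, stratum=label)
                except (amcorr.CorrelationError, amcorr.DegenerateInputError) as exc:
                    logger.info("correlation %s/%s skipped: %s", label, var, exc)
                    continue
                per_stratum.setdefault(var, {})[label] = c
                corr_rows.append(asdict(c))
        tables["spousal_correlations"] = pd.DataFrame(corr_rows)
        tables["skipped_strata"] = pd.DataFrame(skip_rows)

        comp_rows = []
        for var, by_label in per_stratum.items():
            labels = [l for l in by_label if l != "all"]
            for i, l1 in enumerate(labels):
                for l2 in labels[i + 1:]:
                    comp = amcorr.compare_correlations(by_label[l1], by_label[l2])
                    comp_rows.append({"variable": var, "stratum_1": l1, "stratum_2": l2,
                                      **asdict(comp),
                                      "bonferroni_alpha": amcorr.bonferroni_threshold(
                                          0.05, config.m_tests)})
        tables["correlation_comparisons"] = pd.DataFrame(comp_rows)
        manifest["stages"]["amcorr"] = {"min_n": min_n,
                                        "n_skipped_strata": len(skip_rows)}

    # ---- ldstruct -------------------------------------------------------
    if config.run_ldstruct and loadings_abs is not None:
        result = ldstruct.resampling_comparison(
            G, ped, loadings_abs, pruned_index=pruned_idx,
            n_iter=config.n_iterations, top_k=config.top_k,
            min_gap_bp=config.min_gap_bp, seed=seeds["ldstruct"],
            roles=config.ld_roles)
        tables["ld_comparison"] = result.table
        objects["ld_result"] = result
        manifest["stages"]["ldstruct"] = {"n_iterations_used": config.n_iterations - result.n_skipped,
                                          "n_skipped": result.n_skipped}

    if config.out_dir:
        write_results(tables, config.out_dir, manifest)
    return PipelineResult(tables, objects, manifest)
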