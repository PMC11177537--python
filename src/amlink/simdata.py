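"""Forward simulator of quartet families under ancestry-related and phenotypic
assortative mating.

The generative model:

* Two ancestral subpopulations diverge under the Balding–Nichols model:
  each SNP has an ancestral frequency ``p ~ U[0.05, 0.95]`` and subpopulation
  frequencies ``p1, p2 ~ Beta(p(1-Fst)/Fst, (1-p)(1-Fst)/Fst)``.
* Founders are admixed: individual admixture proportion
  ``alpha ~ Beta(b, b)``; genotypes are Binomial(2, alpha*p1 + (1-alpha)*p2)
  per locus, so loci within one founder share that founder's alpha — the
  source of admixture LD.
* Mating is a Gaussian-copula coupling on a weighted latent combining the
  normal scores of alpha and of the liability, tuned so the realized spousal
  correlations approach ``rho_ancestry`` and ``rho_trait``.
* Each couple has two children; transmission is Mendelian per locus with no
  recombination map (loci unlinked — the downstream analyses only use
  markers >= 500 kb apart or on different chromosomes).
* A liability-threshold model defines "affected"; a family enters the
  simplex-like cohort iff exactly one of its two children is affected,
  emulating proband ascertainment.  CI/ID-like group labels are assigned by
  an independent split so the two strata are exchangeable under the null of
  equal assortative mating.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import MISSING, GenotypeMatrix, FamilyRecord, Pedigree, TraitTable, write_plink


class ConfigError(ValueError):
    pass


@dataclass
class SimConfig:
    """Study conditions for one simulated cohort.

    Defaults aim at a SPARK/SSC-like desk-scale cohort: ~500 quartet
    families, a genome-wide SNP panel with chromosome/position structure,
    mild within-continent divergence (Fst = 0.005), spousal ancestry
    correlation in the middle of the 0.38-0.57 range seen in family autism
    cohorts, a 2% liability-threshold ascertainment, and heritability 0.5.
    ``admixture_beta = 0.5`` gives founder ancestry variance 0.125, which
    puts the induced cross-chromosome D² in parents on the order of 1e-5.

    Chromosome length is scaled down with the SNP count so that marker
    spacing stays array-like (tens of kb): the distance-thinning and
    LD-pruning analyses only behave as designed when a 500 kb gap forces a
    genuine random subsample of the panel, as it does on real arrays.
    """

    n_snps: int = 2000
    n_chromosomes: int = 22
    chrom_length_bp: int = 8_000_000
    fst: float = 0.005
    admixture_beta: float = 0.5
    n_families: int = 500
    rho_ancestry: float = 0.45
    rho_trait: float = 0.0
    n_causal: int = 200
    h2: float = 0.5
    ascertainment_quantile: float = 0.02
    ascertain_simplex: bool = True
    missing_rate: float = 0.0
    ref_panel_size: int = 100
    seed: int = 0

    def validate(self) -> None:
        if not (0 <= self.fst < 1):
            raise ConfigError("fst must be in [0, 1)")
        if not (0 <= self.h2 <= 1):
            raise ConfigError("h2 must be in [0, 1]")
        for name in ("rho_ancestry", "rho_trait"):
            v = getattr(self, name)
            if not (0 <= v < 1):
                raise ConfigError(f"{name} must be in [0, 1)")
        if self.rho_ancestry + self.rho_trait >= 1:
            raise ConfigError("rho_ancestry + rho_trait must be < 1")
        if self.n_causal > self.n_snps:
            raise ConfigError("n_causal cannot exceed n_snps")
        if self.h2 > 0 and self.n_causal == 0:
            raise ConfigError("h2 > 0 requires n_causal > 0")
        if not (0 <= self.missing_rate < 1):
            raise ConfigError("missing_rate must be in [0, 1)")


@dataclass
class FounderPool:
    """Candidate founders: admixture proportions, sexes and genotype rows."""

    alphas: np.ndarray          # (n,)
    sexes: np.ndarray           # (n,) 'male' / 'female'
    genotypes: np.ndarray       # (n, n_snps) int8 dosages
    freqs: pd.DataFrame         # per-variant id/chrom/pos/a1/a2/p/p1/p2


def draw_subpop_freqs(n_snps: int, fst: float, seed_or_rng,
                      n_chromosomes: int = 22,
                      chrom_length_bp: int = 100_000_000) -> pd.DataFrame:
    """Balding–Nichols subpopulation frequencies plus a genomic map.

    Variants are assigned round-robin to chromosomes with uniform 1-based
    positions, then sorted by (chromosome, position).  ``fst = 0`` takes the
    deterministic branch p1 = p2 = p.
    """
    if not (0 <= fst < 1):
        raise ConfigError("fst must be in [0, 1)")
    rng = np.random.default_rng(seed_or_rng) if isinstance(seed_or_rng, (int, np.integer)) else seed_or_rng
    p = rng.uniform(0.05, 0.95, n_snps)
    if fst == 0:
        p1 = p2 = p.copy()
    else:
        a, b = p * (1 - fst) / fst, (1 - p) * (1 - fst) / fst
        p1 = rng.beta(a, b)
        p2 = rng.beta(a, b)
    chrom = np.array([str(i % n_chromosomes + 1) for i in range(n_snps)])
    pos = rng.integers(1, chrom_length_bp + 1, n_snps)
    df = pd.DataFrame({
        "id": [f"snp{i:06d}" for i in range(n_snps)],
        "chrom": chrom, "pos": pos, "a1": "A", "a2": "G",
        "p": p, "p1": p1, "p2": p2,
    })
    df = df.sort_values(["chrom", "pos"], key=lambda s: s.astype(int)).reset_index(drop=True)
    # resolve position collisions so every (chrom, pos) is unique
    while df.duplicated(subset=["chrom", "pos"]).any():
        dup = df.duplicated(subset=["chrom", "pos"]).to_numpy()
        df.loc[dup, "pos"] = df.loc[dup, "pos"] + 1
        df = df.sort_values(["chrom", "pos"], key=lambda s: s.astype(int)).reset_index(drop=True)
    return df


def draw_founders(freqs: pd.DataFrame, n_founders: int, admixture_beta: float,
                  rng: np.random.Generator,
                  fixed_alpha: float | None = None) -> FounderPool:
    """Draw admixed founders; first half male, second half female.

    ``fixed_alpha`` pins every founder to one admixture proportion, which
    is how reference panels (and the no-substructure null population) are
    generated.
    """
    if fixed_alpha is not None:
        alphas = np.full(n_founders, float(fixed_alpha))
    else:
        alphas = rng.beta(admixture_beta, admixture_beta, n_founders)
    p1 = freqs["p1"].to_numpy()
    p2 = freqs["p2"].to_numpy()
    q = alphas[:, None] * p1[None, :] + (1 - alphas[:, None]) * p2[None, :]
    genotypes = rng.binomial(2, q).astype(np.int8)
    sexes = np.array(["male"] * (n_founders // 2) + ["female"] * (n_founders - n_founders // 2))
    return FounderPool(alphas, sexes, genotypes, freqs)


def _normal_scores(x: np.ndarray) -> np.ndarray:
    """Rank-based inverse-normal transform (van der Waerden scores)."""
    ranks = stats.rankdata(x, method="average")
    return stats.norm.ppf(ranks / (len(x) + 1))


def mate_assortatively(alphas_m: np.ndarray, alphas_f: np.ndarray,
                       rho_ancestry: float, rho_trait: float,
                       rng: np.random.Generator,
                       traits_m: np.ndarray | None = None,
                       traits_f: np.ndarray | None = None) -> np.ndarray:
    """Pair males with females by a Gaussian-copula coupling.

    Each individual gets a latent matching score ``L = a*z(alpha) + b*z(trait)``
    built from normal scores, with ``a² : b² = rho_ancestry : rho_trait`` and
    the couple latent correlation ``rho_c = rho_ancestry + rho_trait``, so the
    realized spousal correlation of each component approaches its target.
    Returns an (n_pairs, 2) array of (male_index, female_index).
    """
    for name, v in (("rho_ancestry", rho_ancestry), ("rho_trait", rho_trait)):
        if not (0 <= v < 1):
            raise ConfigError(f"{name} must be in [0, 1)")
    n = len(alphas_m)
    if len(alphas_f) != n:
        raise ConfigError("equal numbers of male and female founders required")
    rho_c = rho_ancestry + rho_trait
    if rho_c >= 1:
        raise ConfigError("rho_ancestry + rho_trait must be < 1")
    if rho_c == 0:
        return np.column_stack([rng.permutation(n), rng.permutation(n)])
    a = np.sqrt(rho_ancestry / rho_c)
    b = np.sqrt(rho_trait / rho_c)
    if b > 0 and (traits_m is None or traits_f is None):
        raise ConfigError("rho_trait > 0 requires trait values at mating time")

    def latent(alphas, traits):
        L = a * _normal_scores(alphas)
        if b > 0:
            L = L + b * _normal_scores(traits)
        return L

    L_m = latent(alphas_m, traits_m)
    L_f = latent(alphas_f, traits_f)
    z = rng.multivariate_normal([0, 0], [[1, rho_c], [rho_c, 1]], size=n)
    # male whose latent rank matches the rank of z[:,0] marries the female
    # whose latent rank matches the rank of z[:,1]
    male_order = np.argsort(L_m)[np.argsort(np.argsort(z[:, 0]))]
    female_order = np.argsort(L_f)[np.argsort(np.argsort(z[:, 1]))]
    return np.column_stack([male_order, female_order])


def simulate_offspring(father_G: np.ndarray, mother_G: np.ndarray,
                       rng: np.random.Generator, n_children: int = 2) -> list[np.ndarray]:
    """Mendelian transmission per locus, loci independent (no recombination map).

    Each parent transmits one allele drawn from its two alleles, i.e.
    Binomial(1, dosage/2).  Parental genotypes must be non-missing.
    """
    if (father_G == MISSING).any() or (mother_G == MISSING).any():
        raise ValueError("parental genotypes must be non-missing at transmission time")
    children = []
    for _ in range(n_children):
        tf = rng.binomial(1, father_G / 2.0)
        tm = rng.binomial(1, mother_G / 2.0)
        children.append((tf + tm).astype(np.int8))
    return children


def genetic_values(genotypes: np.ndarray, causal_index: np.ndarray,
                   beta: np.ndarray) -> np.ndarray:
    return genotypes[:, causal_index].astype(float) @ beta


@dataclass
class SimResult:
    """One simulated cohort plus the generative truth needed by tests."""

    genotypes: GenotypeMatrix
    pedigree: Pedigree
    traits: TraitTable
    freqs: pd.DataFrame
    alphas: dict[str, float]
    liabilities: dict[str, float]
    causal_index: np.ndarray
    causal_beta: np.ndarray
    config: SimConfig
    n_candidate_families: int = 0

    def founder_alphas(self) -> np.ndarray:
        return np.array([self.alphas[s] for s in self.pedigree.founder_ids()])


def simulate_dataset(config: SimConfig) -> SimResult:
    """Run the full generative process and return an ascertained cohort.

    With ``ascertain_simplex`` set, candidate families are generated in
    batches and only those with exactly one affected child are retained,
    until ``n_families`` have been collected — emulating how a simplex
    autism cohort samples from a much larger population.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    freqs = draw_subpop_freqs(config.n_snps, config.fst, rng,
                              config.n_chromosomes, config.chrom_length_bp)

    # causal architecture, fixed across batches
    causal_index = np.sort(rng.choice(config.n_snps, config.n_causal, replace=False))
    raw_beta = rng.standard_normal(config.n_causal)

    # calibrate effect-size scale and the liability threshold on a founder
    # reference sample so "population quantile" means the founder population
    calib = draw_founders(freqs, 4000, config.admixture_beta, rng)
    g_ref = genetic_values(calib.genotypes, causal_index, raw_beta)
    sd_g = g_ref.std()
    if config.h2 > 0 and sd_g == 0:
        raise ConfigError("causal SNPs carry no variance; cannot reach target h2")
    beta = raw_beta * (np.sqrt(config.h2) / sd_g) if config.h2 > 0 else np.zeros_like(raw_beta)
    g_mu = genetic_values(calib.genotypes, causal_index, beta).mean()
    env_sd = np.sqrt(1 - config.h2)
    threshold = stats.norm.ppf(1 - config.ascertainment_quantile) if config.ascertainment_quantile > 0 else np.inf

    prev = config.ascertainment_quantile
    p_simplex = max(2 * prev * (1 - prev), 1e-4)

    kept: list[dict] = []
    n_candidates = 0
    max_rounds = 60
    for _ in range(max_rounds):
        if len(kept) >= config.n_families:
            break
        need = config.n_families - len(kept)
        if config.ascertain_simplex and np.isfinite(threshold):
            n_fam = min(int(np.ceil(need / p_simplex * 1.3)) + 16, 20000)
        else:
            n_fam = need
        pool = draw_founders(freqs, 2 * n_fam, config.admixture_beta, rng)
        males = np.flatnonzero(pool.sexes == "male")
        females = np.flatnonzero(pool.sexes == "female")
        liab_pool = (genetic_values(pool.genotypes, causal_index, beta) - g_mu
                     + rng.normal(0, env_sd, len(pool.alphas)))
        pairs = mate_assortatively(
            pool.alphas[males], pool.alphas[females],
            config.rho_ancestry, config.rho_trait, rng,
            traits_m=liab_pool[males], traits_f=liab_pool[females])
        fa_idx = males[pairs[:, 0]]
        mo_idx = females[pairs[:, 1]]
        kids = simulate_offspring(pool.genotypes[fa_idx], pool.genotypes[mo_idx], rng, 2)
        liab_kids = [
            genetic_values(cg, causal_index, beta) - g_mu + rng.normal(0, env_sd, n_fam)
            for cg in kids
        ]
        affected = [lk > threshold for lk in liab_kids]
        n_candidates += n_fam
        for j in range(n_fam):
            n_aff = int(affected[0][j]) + int(affected[1][j])
            if config.ascertain_simplex and np.isfinite(threshold) and n_aff != 1:
                continue
            kept.append({
                "father_G": pool.genotypes[fa_idx[j]], "mother_G": pool.genotypes[mo_idx[j]],
                "child_G": [kids[0][j], kids[1][j]],
                "father_alpha": pool.alphas[fa_idx[j]], "mother_alpha": pool.alphas[mo_idx[j]],
                "father_liab": liab_pool[fa_idx[j]], "mother_liab": liab_pool[mo_idx[j]],
                "child_liab": [liab_kids[0][j], liab_kids[1][j]],
                "child_affected": [bool(affected[0][j]), bool(affected[1][j])],
            })
            if len(kept) >= config.n_families:
                break
        if not (config.ascertain_simplex and np.isfinite(threshold)):
            break
    if len(kept) < config.n_families:
        raise RuntimeError(
            f"could not collect {config.n_families} simplex families from "
            f"{n_candidates} candidates; raise ascertainment_quantile")

    return _assemble(kept[: config.n_families], freqs, causal_index, beta, config, rng, n_candidates)


def _assemble(kept, freqs, causal_index, beta, config, rng, n_candidates) -> SimResult:
    samples, rows, alphas, liabs, families = [], [], {}, {}, []
    trait_rows = []
    for i, fam in enumerate(kept):
        fid = f"fam{i:05d}"
        fa, mo = f"{fid}_fa", f"{fid}_mo"
        # proband = the affected child when ascertained, else the first child
        if fam["child_affected"][1] and not fam["child_affected"][0]:
            pro_j, sib_j = 1, 0
        else:
            pro_j, sib_j = 0, 1
        pro, sib = f"{fid}_p", f"{fid}_s"
        for sid, G in ((fa, fam["father_G"]), (mo, fam["mother_G"]),
                       (pro, fam["child_G"][pro_j]), (sib, fam["child_G"][sib_j])):
            samples.append(sid)
            rows.append(G)
        alphas[fa], alphas[mo] = fam["father_alpha"], fam["mother_alpha"]
        alphas[pro] = alphas[sib] = (fam["father_alpha"] + fam["mother_alpha"]) / 2
        liabs[fa], liabs[mo] = fam["father_liab"], fam["mother_liab"]
        liabs[pro], liabs[sib] = fam["child_liab"][pro_j], fam["child_liab"][sib_j]

        n_aff = sum(fam["child_affected"])
        family_type = {0: "unknown", 1: "simplex", 2: "multiplex"}[n_aff]
        sexes = rng.choice(["male", "female"], 2)
        families.append(FamilyRecord(
            family_id=fid, father_id=fa, mother_id=mo, proband_id=pro, sibling_id=sib,
            proband_sex=sexes[0], sibling_sex=sexes[1],
            proband_affected=fam["child_affected"][pro_j],
            sibling_affected=fam["child_affected"][sib_j],
            group_label="with_CI_ID" if rng.standard_normal() > 0 else "without_CI_ID",
            family_type=family_type,
            proband_carrier=bool(rng.random() < 0.05),
            sibling_carrier=bool(rng.random() < 0.01),
        ))
        for sid, sex in ((fa, "male"), (mo, "female")):
            t = liabs[sid]
            trait_rows.append({
                "sample_id": sid, "sex": sex,
                "age": float(np.round(rng.normal(40, 5), 1)),
                "highest_education": int(rng.integers(1, 6)),
                "srs_total": t,
                "srs_awareness": 0.8 * t + 0.6 * rng.standard_normal(),
                "srs_cognition": 0.8 * t + 0.6 * rng.standard_normal(),
                "srs_mannerisms": 0.8 * t + 0.6 * rng.standard_normal(),
                "srs_motivation": 0.3 * t + 0.95 * rng.standard_normal(),
                "srs_communication": 0.8 * t + 0.6 * rng.standard_normal(),
                "bapq_total": 0.65 * t + 0.76 * rng.standard_normal(),
                "bapq_aloof": 0.3 * t + 0.95 * rng.standard_normal(),
                "bapq_rigid": 0.4 * t + 0.92 * rng.standard_normal(),
                "bapq_pragmatic": 0.5 * t + 0.87 * rng.standard_normal(),
            })

    dosages = np.vstack(rows)
    if config.missing_rate > 0:
        mask = rng.random(dosages.shape) < config.missing_rate
        dosages = np.where(mask, MISSING, dosages).astype(np.int8)
    G = GenotypeMatrix(samples, freqs[["id", "chrom", "pos", "a1", "a2"]], dosages)
    return SimResult(
        genotypes=G, pedigree=Pedigree(families),
        traits=TraitTable(pd.DataFrame(trait_rows)),
        freqs=freqs, alphas=alphas, liabilities=liabs,
        causal_index=causal_index, causal_beta=beta, config=config,
        n_candidate_families=n_candidates,
    )


def reference_panels(freqs: pd.DataFrame, rng: np.random.Generator,
                     panel_size: int = 100,
                     continental_fst: float = 0.15) -> dict[str, GenotypeMatrix]:
    """Labeled reference panels for the two-round ancestry assignment.

    ``round1`` emulates the continental-contrast stage: the target panel is
    drawn from the cohort's own (within-continent) frequency mix while the
    two contrast panels come from an independent, much larger divergence
    (Balding–Nichols at ``continental_fst``), so the admixed cohort
    clusters with the target.  ``round2`` holds five subpanels of the
    target-like population graded along the within-continent admixture
    axis (alpha = 1, 0.75, 0.5, 0.25, 0), including the two ancestral
    endpoints.
    """

    def _panel_from_q(q_per_variant: np.ndarray, label: str):
        g = rng.binomial(2, np.broadcast_to(q_per_variant, (panel_size, len(q_per_variant)))
                         ).astype(np.int8)
        return [f"{label}_{k:03d}" for k in range(panel_size)], g

    p = freqs["p"].to_numpy()
    a = p * (1 - continental_fst) / continental_fst
    b = (1 - p) * (1 - continental_fst) / continental_fst
    cont_a = rng.beta(a, b)
    cont_b = rng.beta(a, b)
    p1 = freqs["p1"].to_numpy()
    p2 = freqs["p2"].to_numpy()

    panels = {}
    round1_freqs = {"REF_TARGET": 0.5 * p1 + 0.5 * p2,
                    "REF_CONTRAST_A": cont_a, "REF_CONTRAST_B": cont_b}
    round2_freqs = {f"SUB_{s}": alpha * p1 + (1 - alpha) * p2
                    for s, alpha in zip("ABCDE", (1.0, 0.75, 0.5, 0.25, 0.0))}
    for rnd, freq_map in (("round1", round1_freqs), ("round2", round2_freqs)):
        samples, rows = [], []
        for label, q in freq_map.items():
            s, g = _panel_from_q(q, label)
            samples.extend(s)
            rows.append(g)
        panels[rnd] = GenotypeMatrix(samples, freqs[["id", "chrom", "pos", "a1", "a2"]],
                                     np.vstack(rows))
    return panels


def panel_labels(panel: GenotypeMatrix) -> pd.Series:
    """Population label per panel sample (the sample-id prefix)."""
    return pd.Series([s.rsplit("_", 1)[0] for s in panel.samples], index=panel.samples)


def emit_dataset(config: SimConfig, out_dir: str | Path) -> dict[str, str]:
    """Write the cohort as a PLINK triplet + pedigree/trait TSVs + reference
    panels + a JSON manifest.  Returns the paths written."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim = simulate_dataset(config)
    rng = np.random.default_rng(np.random.default_rng(config.seed).integers(2**31 - 1, size=4)[-1])

    fam_rows = []
    for f in sim.pedigree:
        for sid, sex, aff in ((f.father_id, 1, False), (f.mother_id, 2, False),
                              (f.proband_id, 0, f.proband_affected),
                              (f.sibling_id, 0, f.sibling_affected)):
            fam_rows.append({"fid": f.family_id, "iid": sid, "father": "0", "mother": "0",
                             "sex": sex, "phenotype": 2 if aff else 1})
    write_plink(sim.genotypes, out / "cohort", pd.DataFrame(fam_rows))
    sim.pedigree.to_frame().to_csv(out / "pedigree.tsv", sep="\t", index=False)
    sim.traits.table.to_csv(out / "traits.tsv", sep="\t", index=False)

    panels = reference_panels(sim.freqs, rng, config.ref_panel_size)
    for rnd, panel in panels.items():
        write_plink(panel, out / f"ref_panel_{rnd}" / "panel")
        panel_labels(panel).rename("population").rename_axis("sample_id").to_frame().to_csv(
            out / f"ref_panel_{rnd}" / "labels.tsv", sep="\t")

    manifest = {"config": asdict(config), "seed": config.seed,
                "n_candidate_families": sim.n_candidate_families}
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return {"bfile": str(out / "cohort"), "pedigree": str(out / "pedigree.tsv"),
            "traits": str(out / "traits.tsv"), "manifest": str(out / "manifest.json")}
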