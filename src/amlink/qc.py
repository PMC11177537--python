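"""Variant- and sample-level genotype quality control.

The filter chain mirrors the standard array-QC ladder for family cohorts:
sample missingness, variant call rate, extended-LD region exclusion,
minor-allele frequency, Hardy–Weinberg exact test (founders only) and
trio Mendelian-error rate.  Defaults: call rate >= 0.95, MAF >= 0.01,
HWE p >= 1e-5, Mendel error rate <= 0.05, sample missingness <= 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

from .core_io import MISSING, GenotypeMatrix, Pedigree, in_regions


class EmptyResultError(RuntimeError):
    """Every sample or variant was removed by a QC step."""


@dataclass
class QcStep:
    name: str
    before: int
    removed: int

    @property
    def after(self) -> int:
        return self.before - self.removed


@dataclass
class QcReport:
    """Per-step accounting plus the per-variant / per-sample statistics."""

    steps: list[QcStep] = field(default_factory=list)
    sample_missing_fraction: dict[str, float] = field(default_factory=dict)
    variant_stats: dict[str, np.ndarray] = field(default_factory=dict)

    def add(self, name: str, before: int, removed: int) -> None:
        self.steps.append(QcStep(name, before, removed))

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [{"step": s.name, "before": s.before, "removed": s.removed, "after": s.after}
             for s in self.steps]
        )


def sample_missingness_filter(G: GenotypeMatrix, max_missing: float = 0.05
                              ) -> tuple[GenotypeMatrix, dict[str, float]]:
    """Drop samples with missing-genotype fraction strictly above max_missing."""
    frac = G.missing_mask().mean(axis=1)
    keep = frac <= max_missing
    fractions = dict(zip(G.samples, frac.tolist()))
    kept_ids = [s for s, k in zip(G.samples, keep) if k]
    return G.subset_samples(kept_ids), fractions


def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Two-sided exact Hardy–Weinberg test.

    Conditional on the observed allele counts, sums the probabilities of
    all heterozygote counts whose probability does not exceed that of the
    observed count.  Monomorphic markers return p = 1.
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("negative genotype count")
    n = n_AA + n_Aa + n_aa
    if n < 1:
        raise ValueError("empty genotype table")
    n_a = 2 * n_aa + n_Aa  # rarity side is irrelevant: distribution is symmetric
    n_A = 2 * n_AA + n_Aa
    if n_A == 0 or n_a == 0:
        return 1.0
    n_minor = min(n_A, n_a)
    # possible heterozygote counts share the parity of the minor allele count
    hets = np.arange(n_minor % 2, n_minor + 1, 2)
    homs_minor = (n_minor - hets) // 2
    homs_major = (max(n_A, n_a) - hets) // 2
    # log P(het = h | allele counts) up to a common constant
    logp = (
        hets * np.log(2.0)
        - gammaln(hets + 1)
        - gammaln(homs_minor + 1)
        - gammaln(homs_major + 1)
    )
    logp -= logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()
    p_obs = probs[hets == n_Aa]
    if len(p_obs) == 0:  # observed het count has impossible parity
        raise ValueError("heterozygote count inconsistent with allele counts")
    p = probs[probs <= p_obs[0] * (1 + 1e-12)].sum()
    return float(min(1.0, p))


def hwe_pvalues(G: GenotypeMatrix, sample_ids=None) -> np.ndarray:
    """Exact HWE p-value per variant over the given samples (default all)."""
    d = G.dosages if sample_ids is None else G.dosages[G.sample_indices(sample_ids)]
    n_AA = (d == 2).sum(axis=0)
    n_Aa = (d == 1).sum(axis=0)
    n_aa = (d == 0).sum(axis=0)
    return np.array([
        hwe_exact_test(int(a), int(h), int(b)) if (a + h + b) > 0 else 1.0
        for a, h, b in zip(n_AA, n_Aa, n_aa)
    ])


def mendel_error_rate(G: GenotypeMatrix, pedigree: Pedigree) -> np.ndarray:
    """Per-variant Mendelian-error rate over all parent-parent-child trios.

    A child genotype is an error iff it is impossible given both parents'
    non-missing genotypes; trios with any missing member are skipped at
    that variant.  Variants with zero informative trios get NaN.
    """
    trios = pedigree.trios(child_role="all")
    errors = np.zeros(G.n_variants, dtype=int)
    informative = np.zeros(G.n_variants, dtype=int)
    for father, mother, child in trios:
        f = G.dosages[G._sample_index[father]]
        m = G.dosages[G._sample_index[mother]]
        c = G.dosages[G._sample_index[child]]
        ok = (f != MISSING) & (m != MISSING) & (c != MISSING)
        lo = (f == 2).astype(int) + (m == 2).astype(int)
        hi = 2 - (f == 0).astype(int) - (m == 0).astype(int)
        err = ok & ((c < lo) | (c > hi))
        errors += err
        informative += ok
    with np.errstate(invalid="ignore", divide="ignore"):
        rate = np.where(informative > 0, errors / np.maximum(informative, 1), np.nan)
    return rate


def apply_qc_chain(
    G: GenotypeMatrix,
    pedigree: Pedigree,
    regions=None,
    *,
    max_sample_missing: float = 0.05,
    min_call_rate: float = 0.95,
    min_maf: float = 0.01,
    min_hwe_p: float = 1e-5,
    max_mendel_rate: float = 0.05,
) -> tuple[GenotypeMatrix, QcReport]:
    """Run the full QC ladder in its fixed order and account for every step.

    Order: sample missingness -> variant call rate -> extended-LD region
    exclusion -> MAF (founders) -> HWE exact (founders) -> Mendelian error.
    MAF and HWE are computed on founders (parents) only: offspring of the
    same families are not independent draws from the mating pool.
    """
    report = QcReport()

    n0 = G.n_samples
    G, fractions = sample_missingness_filter(G, max_sample_missing)
    report.sample_missing_fraction = fractions
    report.add("sample_missingness", n0, n0 - G.n_samples)
    if G.n_samples == 0:
        raise EmptyResultError("no samples left after sample-missingness filter")

    founders = [s for s in pedigree.founder_ids() if s in G._sample_index]

    def _variant_step(name, keep):
        nonlocal G
        before = G.n_variants
        G = G.subset_variants(np.asarray(keep))
        report.add(name, before, before - G.n_variants)
        if G.n_variants == 0:
            raise EmptyResultError(f"no variants left after {name} filter")

    call_rate = 1.0 - G.missing_mask().mean(axis=0)
    report.variant_stats["call_rate"] = call_rate
    _variant_step("call_rate", call_rate >= min_call_rate)

    if regions:
        chrom = G.variants["chrom"].to_numpy(dtype=str)
        pos = G.variants["pos"].to_numpy(dtype=int)
        _variant_step("extended_ld_regions", ~in_regions(chrom, pos, regions))
    else:
        report.add("extended_ld_regions", G.n_variants, 0)

    af = G.allele_freq(founders)
    maf = np.minimum(af, 1 - af)
    report.variant_stats["maf"] = maf
    _variant_step("maf", np.nan_to_num(maf, nan=0.0) >= min_maf)

    hwe_p = hwe_pvalues(G, founders)
    report.variant_stats["hwe_p"] = hwe_p
    _variant_step("hwe", hwe_p >= min_hwe_p)

    mendel = mendel_error_rate(G, pedigree)
    report.variant_stats["mendel_error_rate"] = mendel
    # variants with zero informative trios (NaN rate) are retained and flagged
    _variant_step("mendel", ~(mendel > max_mendel_rate))

    return G, report
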