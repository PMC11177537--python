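"""Polygenic-score computation, the summary-statistic SD retention filter,
the polygenic transmission disequilibrium test (pTDT), and the
odd/even-chromosome theta estimator of score-based assortative mating.

Scores are plain weighted allele-dosage sums; the per-variant weights are
externally adjusted effect sizes supplied as input (effect-size shrinkage
is out of scope here).  Missing dosages are imputed with the founder mean
dosage of the variant.  Standardization (mean 0, sd 1) is over founders;
the adjusted score is the residual from an OLS fit on age, sex and the top
ancestry PCs.

The theta estimator splits the genome by chromosome parity: scores S_o
(odd) and S_e (even) are built from disjoint variant sets, and theta is
the coefficient of one score regressed on the other with the opposite
parity's top-20 ancestry PCs as covariates — under assortative mating on
the score, cross-chromosome correlation makes theta positive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .core_io import MISSING, GenotypeMatrix, Pedigree, SummaryStats


class PgsError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Summary-statistic SD filter
# ---------------------------------------------------------------------------

def sd_filter(stats_table: pd.DataFrame, founder_af: np.ndarray,
              binary: bool = True) -> np.ndarray:
    """Retention mask for the SD-consistency filter on summary statistics.

    For a binary trait, SD_ss = 2 / (se * sqrt(n_eff)) with
    n_eff = 4 / (1/n_case + 1/n_control); for a quantitative trait,
    SD_ss = 1 / (se * sqrt(n)).  SD_test = sqrt(2 * AF * (1 - AF)) with AF
    the founder allele frequency.  A variant is removed iff any of:
    SD_ss < 0.5*SD_test, SD_ss > 0.1 + SD_test, SD_ss < 0.1, SD_test < 0.05.
    """
    se = stats_table["se"].to_numpy(dtype=float)
    if (se <= 0).any():
        raise PgsError("se must be positive")
    if binary:
        n_case = stats_table["n_case"].to_numpy(dtype=float)
        n_control = stats_table["n_control"].to_numpy(dtype=float)
        n_eff = 4.0 / (1.0 / n_case + 1.0 / n_control)
        sd_ss = 2.0 / (se * np.sqrt(n_eff))
    else:
        n = stats_table["n"].to_numpy(dtype=float)
        sd_ss = 1.0 / (se * np.sqrt(n))
    af = np.asarray(founder_af, dtype=float)
    sd_test = np.sqrt(2.0 * af * (1.0 - af))
    removed = (
        (sd_ss < 0.5 * sd_test)
        | (sd_ss > 0.1 + sd_test)
        | (sd_ss < 0.1)
        | (sd_test < 0.05)
    )
    return ~removed


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------

@dataclass
class PgsResult:
    scores: pd.DataFrame          # index sample_id: raw, standardized, adjusted
    n_variants_used: int
    founder_ids: list[str]

    def standardized(self, sample_ids) -> np.ndarray:
        return self.scores["standardized"].reindex(sample_ids).to_numpy(dtype=float)

    def adjusted(self, sample_ids) -> np.ndarray:
        col = "adjusted" if "adjusted" in self.scores.columns else "standardized"
        return self.scores[col].reindex(sample_ids).to_numpy(dtype=float)


def score(G: GenotypeMatrix, weights: pd.DataFrame, founder_ids,
          covariates: pd.DataFrame | None = None) -> PgsResult:
    """Raw, founder-standardized and covariate-adjusted polygenic scores.

    ``weights`` must carry ``variant_index`` (column position in G) and
    ``beta`` already harmonized to the a1 dosage allele
    (:func:`amlink.core_io.harmonize_weights` produces this).  Missing
    dosages are replaced by the founder mean dosage of the variant.
    ``covariates`` (index sample_id; e.g. age, sex, PC1..PC10) trigger the
    adjusted score: the residual of the standardized score on them.
    """
    if len(weights) == 0:
        raise PgsError("zero overlapping variants between genotypes and weights")
    founder_ids = list(founder_ids)
    idx = weights["variant_index"].to_numpy(dtype=int)
    beta = weights["beta"].to_numpy(dtype=float)

    d = G.dosages[:, idx].astype(float)
    miss = d == MISSING
    d[miss] = np.nan
    founder_rows = G.sample_indices(founder_ids)
    founder_mean = np.nanmean(d[founder_rows], axis=0)
    founder_mean = np.where(np.isfinite(founder_mean), founder_mean, 0.0)
    d = np.where(np.isnan(d), founder_mean[None, :], d)

    raw = d @ beta
    scores = pd.DataFrame({"raw": raw}, index=G.samples)
    mu = scores.loc[founder_ids, "raw"].mean()
    sd = scores.loc[founder_ids, "raw"].std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        # all-zero weights leave every score 0; standardization is identity
        scores["standardized"] = scores["raw"] - mu
    else:
        scores["standardized"] = (scores["raw"] - mu) / sd

    if covariates is not None:
        common = [s for s in scores.index if s in covariates.index]
        X = sm.add_constant(covariates.loc[common].astype(float), has_constant="add")
        y = scores.loc[common, "standardized"]
        ok = X.notna().all(axis=1) & y.notna()
        fit = sm.OLS(y[ok], X[ok]).fit()
        adjusted = pd.Series(np.nan, index=scores.index)
        adjusted[y[ok].index] = y[ok] - fit.predict(X[ok])
        scores["adjusted"] = adjusted
    return PgsResult(scores, n_variants_used=len(weights), founder_ids=founder_ids)


# ---------------------------------------------------------------------------
# pTDT
# ---------------------------------------------------------------------------

@dataclass
class PtdtResult:
    n_trios: int
    mean_deviation: float
    t: float
    p: float
    ci_low: float
    ci_high: float


def ptdt(pgs: PgsResult, pedigree: Pedigree, child_role: str = "proband") -> PtdtResult:
    """Polygenic transmission disequilibrium test.

    Per trio the deviation is (child - midparent) / sd(midparent), where
    midparent = (father + mother)/2 and sd(midparent) is the sample
    standard deviation (n-1 denominator) of midparent scores across the
    included trios.  A one-sample two-sided t-test checks mean deviation
    against zero.
    """
    trios = pedigree.trios(child_role=child_role)
    s = pgs.scores["standardized"]
    rows = [(s.get(f), s.get(m), s.get(c)) for f, m, c in trios]
    rows = [r for r in rows if all(v is not None and np.isfinite(v) for v in r)]
    if len(rows) < 2:
        raise PgsError("pTDT needs at least 2 complete trios")
    arr = np.array(rows, dtype=float)
    midparent = (arr[:, 0] + arr[:, 1]) / 2.0
    sd_mid = midparent.std(ddof=1)
    if sd_mid == 0:
        raise PgsError("sd(midparent) is zero; pTDT deviation undefined")
    dev = (arr[:, 2] - midparent) / sd_mid
    n = len(dev)
    mean = float(dev.mean())
    se = dev.std(ddof=1) / np.sqrt(n)
    if se == 0:
        t_stat, p = 0.0, 1.0
    else:
        t_stat = mean / se
        p = 2 * stats.t.sf(abs(t_stat), df=n - 1)
    half = stats.t.ppf(0.975, df=n - 1) * se
    return PtdtResult(n, mean, float(t_stat), float(p), mean - half, mean + half)


# ---------------------------------------------------------------------------
# Odd/even-chromosome theta
# ---------------------------------------------------------------------------

@dataclass
class ThetaResult:
    theta_odd_on_even: float
    se_odd_on_even: float
    p_odd_on_even: float
    theta_even_on_odd: float
    se_even_on_odd: float
    p_even_on_odd: float
    theta_combined: float
    se_combined: float
    n_samples: int


def odd_even_theta(G: GenotypeMatrix, weights: pd.DataFrame, sample_ids,
                   k: int = 20, prune_r2: float = 0.1,
                   prune_window_bp: int = 1_000_000) -> ThetaResult:
    """Correlation of polygenic scores built from odd vs even chromosomes.

    S_o and S_e come from disjoint variant sets (chromosome parity);
    ancestry is controlled with the top-k PCs of LD-pruned SNPs of the
    *opposite* parity (PCE when predicting S_o from S_e, PCO otherwise).
    Both regressions are reported plus their inverse-variance-weighted
    combination.  Scores and PCs are computed on ``sample_ids``.
    """
    from .ancestry import fit_reference_pca
    from .ldstruct import ld_prune

    sample_ids = list(sample_ids)
    chrom_int = G.variants["chrom"].astype(int).to_numpy()
    odd_mask = chrom_int % 2 == 1

    parts = {}
    for name, mask in (("odd", odd_mask), ("even", ~odd_mask)):
        sub = G.subset_variants(mask)
        w = weights[weights["variant_index"].isin(np.flatnonzero(mask))].copy()
        if len(w) == 0:
            raise PgsError(f"no weighted variants on {name} chromosomes")
        remap = {old: new for new, old in enumerate(np.flatnonzero(mask))}
        w["variant_index"] = w["variant_index"].map(remap)
        s = score(sub, w, founder_ids=sample_ids).standardized(sample_ids)

        pruned = ld_prune(sub, sample_ids, r2_threshold=prune_r2, window_bp=prune_window_bp)
        sub_pruned = sub.subset_variants(pruned)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = fit_reference_pca(sub_pruned, sample_ids, k=k)
        parts[name] = (s, model.scores.loc[sample_ids].to_numpy())

    s_o, pcs_o = parts["odd"]
    s_e, pcs_e = parts["even"]
    return theta_from_scores(s_o, s_e, pcs_o, pcs_e)


def theta_from_scores(s_o: np.ndarray, s_e: np.ndarray,
                      pcs_o: np.ndarray, pcs_e: np.ndarray) -> ThetaResult:
    """The two theta regressions given precomputed scores and parity PCs.

    Fits S_o = theta*S_e + PCE_1..k and S_e = theta*S_o + PCO_1..k and
    combines the two estimates by inverse-variance weighting (a plain mean
    when a regression is an exact fit and its standard error is zero).
    """
    def _fit(y, x, pcs):
        X = sm.add_constant(np.column_stack([x, pcs]))
        fit = sm.OLS(y, X).fit()
        return float(fit.params[1]), float(fit.bse[1]), float(fit.pvalues[1])

    th_oe, se_oe, p_oe = _fit(s_o, s_e, pcs_e)  # S_o = theta*S_e + PCE
    th_eo, se_eo, p_eo = _fit(s_e, s_o, pcs_o)  # S_e = theta*S_o + PCO
    if se_oe == 0 or se_eo == 0:
        combined = (th_oe + th_eo) / 2.0
        se_comb = 0.0
    else:
        w1, w2 = 1.0 / se_oe**2, 1.0 / se_eo**2
        combined = (w1 * th_oe + w2 * th_eo) / (w1 + w2)
        se_comb = float(np.sqrt(1.0 / (w1 + w2)))
    return ThetaResult(th_oe, se_oe, p_oe, th_eo, se_eo, p_eo,
                       float(combined), se_comb, len(s_o))
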