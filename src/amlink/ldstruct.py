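"""Intra-locus (Wright's F) and inter-locus (cross-chromosome D²) correlation
structure, with the pruning / distance-thinning / top-vs-bottom-K resampling
design.

Wright's F at a bi-allelic marker is ``1 - n_oAa / n_eAa``: one minus the
ratio of observed to Hardy–Weinberg-expected heterozygotes.  For two
markers, the squared disequilibrium ``D² = (p_AB - p_A p_B)²`` is computed
from two-locus haplotype frequencies estimated by EM from unphased
genotypes; for unlinked markers only double heterozygotes have ambiguous
phase.  The resampling comparison repeatedly thins the pruned SNP list to a
minimum genomic spacing, splits it into the most and least
ancestry-informative K SNPs by |PC1| loading, and contrasts the mean F and
mean cross-chromosome D² of the two sets per family role with a Welch
two-sample t-test over the iteration means.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import MISSING, GenotypeMatrix, Pedigree

EM_TOL = 1e-10
EM_MAX_ITER = 1000


# ---------------------------------------------------------------------------
# Marker selection
# ---------------------------------------------------------------------------

def ld_prune(G: GenotypeMatrix, sample_ids=None, r2_threshold: float = 0.1,
             window_bp: int = 500_000) -> np.ndarray:
    """Greedy left-to-right LD pruning within a physical window.

    Scanning each chromosome in position order, a variant is dropped iff
    its squared Pearson dosage correlation with any previously kept variant
    within ``window_bp`` exceeds the threshold.  Deterministic given input
    order.  Returns the indices of kept variants.
    """
    d = G.dosages if sample_ids is None else G.dosages[G.sample_indices(sample_ids)]
    X = d.astype(float)
    X[d == MISSING] = np.nan
    chroms = G.variants["chrom"].to_numpy(dtype=str)
    pos = G.variants["pos"].to_numpy(dtype=int)

    kept: list[int] = []
    for chrom in pd.unique(chroms):
        idx = np.flatnonzero(chroms == chrom)
        idx = idx[np.argsort(pos[idx], kind="mergesort")]
        kept_chrom: list[int] = []
        for i in idx:
            ok = True
            for j in reversed(kept_chrom):
                if pos[i] - pos[j] > window_bp:
                    break
                r2 = _pairwise_r2(X[:, i], X[:, j])
                if r2 > r2_threshold:
                    ok = False
                    break
            if ok:
                kept_chrom.append(i)
        kept.extend(kept_chrom)
    return np.array(sorted(kept), dtype=int)


def _pairwise_r2(x: np.ndarray, y: np.ndarray) -> float:
    ok = ~(np.isnan(x) | np.isnan(y))
    if ok.sum() < 2:
        return 0.0
    xs, ys = x[ok], y[ok]
    if xs.std() == 0 or ys.std() == 0:
        return 0.0
    r = np.corrcoef(xs, ys)[0, 1]
    return float(r * r)


def thin_by_distance(variants: pd.DataFrame, min_gap_bp: int = 500_000,
                     seed: int | np.random.Generator = 0) -> np.ndarray:
    """Random maximal spacing-constrained subset.

    Variants are visited in seeded random order; a variant is accepted iff
    no previously accepted variant on the same chromosome lies within
    ``min_gap_bp``.  Returns positional indices into ``variants``.
    """
    rng = np.random.default_rng(seed) if isinstance(seed, (int, np.integer)) else seed
    chroms = variants["chrom"].to_numpy(dtype=str)
    pos = variants["pos"].to_numpy(dtype=int)
    order = rng.permutation(len(variants))
    accepted_pos: dict[str, list[int]] = {}
    accepted: list[int] = []
    for i in order:
        c = chroms[i]
        plist = accepted_pos.setdefault(c, [])
        if all(abs(pos[i] - p) >= min_gap_bp for p in plist):
            plist.append(pos[i])
            accepted.append(i)
    return np.array(sorted(accepted), dtype=int)


# ---------------------------------------------------------------------------
# Intra-locus: Wright's F
# ---------------------------------------------------------------------------

def wrights_f(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """F = 1 - observed/expected heterozygotes; NaN when the marker is
    monomorphic (expected heterozygote count zero)."""
    n = n_AA + n_Aa + n_aa
    if n < 1:
        raise ValueError("empty genotype table")
    p_hat = (2 * n_AA + n_Aa) / (2 * n)
    n_eAa = 2 * p_hat * (1 - p_hat) * n
    if n_eAa == 0:
        return float("nan")
    return 1.0 - n_Aa / n_eAa


def wrights_f_per_variant(G: GenotypeMatrix, sample_ids, variant_index=None) -> np.ndarray:
    """Vectorized Wright's F over the given samples (missing calls dropped)."""
    d = G.dosages[G.sample_indices(sample_ids)]
    if variant_index is not None:
        d = d[:, variant_index]
    n_AA = (d == 2).sum(axis=0).astype(float)
    n_Aa = (d == 1).sum(axis=0).astype(float)
    n_aa = (d == 0).sum(axis=0).astype(float)
    n = n_AA + n_Aa + n_aa
    with np.errstate(invalid="ignore", divide="ignore"):
        p = (2 * n_AA + n_Aa) / (2 * n)
        n_e = 2 * p * (1 - p) * n
        return np.where(n_e > 0, 1.0 - n_Aa / np.maximum(n_e, 1e-300), np.nan)


# ---------------------------------------------------------------------------
# Inter-locus: EM haplotype frequencies and D²
# ---------------------------------------------------------------------------

@dataclass
class HaplotypeFreqs:
    p_AB: float
    p_Ab: float
    p_aB: float
    p_ab: float
    n: int
    iterations: int
    converged: bool
    log_likelihood: float

    def as_array(self) -> np.ndarray:
        return np.array([self.p_AB, self.p_Ab, self.p_aB, self.p_ab])


def _pair_tables(d1: np.ndarray, d2: np.ndarray) -> np.ndarray:
    """3x3 genotype count table(s); d1, d2 are (n,) or (n, m) dosage arrays."""
    if d1.ndim == 1:
        d1, d2 = d1[:, None], d2[:, None]
    tables = np.empty((3, 3) + d1.shape[1:], dtype=float)
    for a in range(3):
        for b in range(3):
            tables[a, b] = ((d1 == a) & (d2 == b)).sum(axis=0)
    return tables


def _em_vectorized(tables: np.ndarray, tol: float = EM_TOL, max_iter: int = EM_MAX_ITER):
    """EM for two-locus haplotype frequencies on a batch of 3x3 tables.

    ``tables[a, b, ...]`` counts individuals with a copies of A and b of B.
    Returns (freqs[4, ...], iterations, converged, loglik, n).  Only the
    double-heterozygote class has ambiguous phase; its AB/ab weight is
    ``p_AB p_ab / (p_AB p_ab + p_Ab p_aB)``.  Initialization is linkage
    equilibrium at the observed allele frequencies.
    """
    n = tables.sum(axis=(0, 1))
    if np.any(n == 0):
        raise ValueError("pair with zero informative individuals")
    a_counts = np.tensordot(np.arange(3), tables.sum(axis=1), axes=(0, 0))
    b_counts = np.tensordot(np.arange(3), tables.sum(axis=0), axes=(0, 0))
    pA = a_counts / (2 * n)
    pB = b_counts / (2 * n)

    # fixed (phase-unambiguous) haplotype count contributions
    t = tables
    fixed_AB = 2 * t[2, 2] + t[2, 1] + t[1, 2]
    fixed_Ab = 2 * t[2, 0] + t[2, 1] + t[1, 0]
    fixed_aB = 2 * t[0, 2] + t[0, 1] + t[1, 2]
    fixed_ab = 2 * t[0, 0] + t[0, 1] + t[1, 0]
    ndh = t[1, 1]

    pAB = pA * pB
    pAb = pA * (1 - pB)
    paB = (1 - pA) * pB
    pab = (1 - pA) * (1 - pB)

    # flatten so converged pairs can be dropped from the working set
    shape = np.shape(n)
    flat = lambda x: np.broadcast_to(x, shape).reshape(-1).astype(float).copy()
    fAB, fAb, faB, fab = flat(fixed_AB), flat(fixed_Ab), flat(fixed_aB), flat(fixed_ab)
    nd, nn = flat(ndh), flat(n)
    cAB, cAb, caB, cab = flat(pAB), flat(pAb), flat(paB), flat(pab)
    iterations = np.zeros(cAB.shape, dtype=int)
    idx = np.arange(cAB.size)
    for it in range(1, max_iter + 1):
        num = cAB[idx] * cab[idx]
        den = num + cAb[idx] * caB[idx]
        w = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.5)
        two_n = 2 * nn[idx]
        new_AB = (fAB[idx] + w * nd[idx]) / two_n
        new_Ab = (fAb[idx] + (1 - w) * nd[idx]) / two_n
        new_aB = (faB[idx] + (1 - w) * nd[idx]) / two_n
        new_ab = (fab[idx] + w * nd[idx]) / two_n
        delta = np.max(np.abs(np.stack([
            new_AB - cAB[idx], new_Ab - cAb[idx],
            new_aB - caB[idx], new_ab - cab[idx]])), axis=0)
        cAB[idx], cAb[idx], caB[idx], cab[idx] = new_AB, new_Ab, new_aB, new_ab
        iterations[idx] = it
        idx = idx[delta >= tol]
        if idx.size == 0:
            break
    converged = np.ones(cAB.shape, dtype=bool)
    converged[idx] = False
    pAB = cAB.reshape(shape)
    pAb = cAb.reshape(shape)
    paB = caB.reshape(shape)
    pab = cab.reshape(shape)
    iterations = iterations.reshape(shape)
    converged = converged.reshape(shape)

    # multinomial genotype log-likelihood under random union of gametes
    ll = np.zeros_like(pAB)
    hap = {(1, 1): pAB, (1, 0): pAb, (0, 1): paB, (0, 0): pab}
    for a in range(3):
        for b in range(3):
            prob = np.zeros_like(pAB)
            for a1 in (0, 1):
                for b1 in (0, 1):
                    a2, b2 = a - a1, b - b1
                    if a2 in (0, 1) and b2 in (0, 1):
                        prob = prob + hap[(a1, b1)] * hap[(a2, b2)]
            with np.errstate(divide="ignore", invalid="ignore"):
                term = t[a, b] * np.log(np.where(prob > 0, prob, 1.0))
            ll = ll + np.where(t[a, b] > 0, term, 0.0)
    return np.stack([pAB, pAb, paB, pab]), iterations, converged, ll, n


def em_haplotype_freqs(d1: np.ndarray, d2: np.ndarray) -> HaplotypeFreqs:
    """Two-locus haplotype frequencies from unphased genotype pairs.

    Individuals missing at either locus are excluded.  A monomorphic locus
    yields the degenerate (still valid) frequency vector with the
    converged flag set.
    """
    d1 = np.asarray(d1)
    d2 = np.asarray(d2)
    ok = (d1 != MISSING) & (d2 != MISSING)
    d1, d2 = d1[ok], d2[ok]
    if len(d1) == 0:
        raise ValueError("no individuals with both loci observed")
    tables = _pair_tables(d1, d2)[:, :, 0]
    freqs, iters, converged, ll, n = _em_vectorized(tables[:, :, None])
    return HaplotypeFreqs(
        p_AB=float(freqs[0, 0]), p_Ab=float(freqs[1, 0]),
        p_aB=float(freqs[2, 0]), p_ab=float(freqs[3, 0]),
        n=int(n[0]), iterations=int(iters[0]),
        converged=bool(converged[0]), log_likelihood=float(ll[0]),
    )


def d_squared(h: HaplotypeFreqs | np.ndarray) -> float | np.ndarray:
    """D² = (p_AB - p_A p_B)²; invariant to allele relabeling at either locus."""
    f = h.as_array() if isinstance(h, HaplotypeFreqs) else np.asarray(h)
    pAB, pAb, paB = f[0], f[1], f[2]
    pA = pAB + pAb
    pB = pAB + paB
    out = (pAB - pA * pB) ** 2
    return float(out) if out.ndim == 0 else out


def mean_d2_cross_chromosome(G: GenotypeMatrix, sample_ids, variant_index: np.ndarray
                             ) -> tuple[float, int]:
    """Mean D² over all different-chromosome pairs within a SNP set.

    Haplotype frequencies come from batched EM on each pair's 3x3 genotype
    table (missing calls excluded pair-wise via the one-hot construction).
    Returns (mean D², number of contributing pairs).
    """
    idx = np.asarray(variant_index, dtype=int)
    d = G.dosages[G.sample_indices(sample_ids)][:, idx]
    chroms = G.variants["chrom"].to_numpy(dtype=str)[idx]
    K = len(idx)
    if K < 2:
        return float("nan"), 0

    onehot = [(d == a).astype(float) for a in range(3)]  # n x K each
    tables = np.empty((3, 3, K, K))
    for a in range(3):
        for b in range(3):
            tables[a, b] = onehot[a].T @ onehot[b]

    iu, ju = np.triu_indices(K, k=1)
    cross = chroms[iu] != chroms[ju]
    iu, ju = iu[cross], ju[cross]
    if len(iu) == 0:
        return float("nan"), 0
    pair_tables = tables[:, :, iu, ju]
    n = pair_tables.sum(axis=(0, 1))
    good = n > 0
    if not good.any():
        return float("nan"), 0
    freqs, _, _, _, _ = _em_vectorized(pair_tables[:, :, good])
    d2 = d_squared(freqs)
    return float(np.mean(d2)), int(good.sum())


# ---------------------------------------------------------------------------
# Resampling comparison
# ---------------------------------------------------------------------------

@dataclass
class IterationSummary:
    iteration: int
    n_thinned: int
    role_means: pd.DataFrame  # index role, columns f_top/f_bottom/d2_top/d2_bottom + counts


@dataclass
class LdComparisonResult:
    table: pd.DataFrame  # per (role, statistic): means, sds, Welch t, p
    iterations: list[IterationSummary]
    n_skipped: int


def resampling_comparison(
    G: GenotypeMatrix,
    pedigree: Pedigree,
    abs_loadings: np.ndarray,
    *,
    pruned_index: np.ndarray | None = None,
    n_iter: int = 1000,
    top_k: int = 200,
    min_gap_bp: int = 500_000,
    seed: int = 0,
    roles: Sequence[str] = ("father", "mother", "sibling"),
) -> LdComparisonResult:
    """The 1000-iteration top-vs-bottom-K comparison of F and cross-chromosome D².

    ``abs_loadings`` gives |PC1| loading per variant of ``G`` (higher =
    more ancestry-informative).  Each iteration i thins the (pre-pruned)
    variant list to a >= ``min_gap_bp`` spacing with derived seed
    ``seed + i``, ranks the thinned SNPs by |loading|, and computes per
    role the mean F over the top-K and bottom-K sets and the mean D² over
    each set's different-chromosome pairs.  Iterations whose thinned set
    has fewer than 2K SNPs are skipped; more than 10% skipped aborts the
    run.  Finally a Welch t-test compares the top vs bottom iteration
    means per role and statistic.
    """
    abs_loadings = np.asarray(abs_loadings, dtype=float)
    if len(abs_loadings) != G.n_variants:
        raise ValueError("abs_loadings length must match the variant count")
    base = np.arange(G.n_variants) if pruned_index is None else np.asarray(pruned_index)
    variants = G.variants.iloc[base].reset_index(drop=True)

    role_ids = {
        "father": pedigree.father_ids(),
        "mother": pedigree.mother_ids(),
        "sibling": pedigree.sibling_ids(),
    }
    role_ids = {r: ids for r, ids in role_ids.items() if r in roles and ids}

    summaries: list[IterationSummary] = []
    n_skipped = 0
    for it in range(n_iter):
        thin_local = thin_by_distance(variants, min_gap_bp, seed=seed + it)
        if len(thin_local) < 2 * top_k:
            n_skipped += 1
            continue
        thinned = base[thin_local]
        order = np.argsort(-abs_loadings[thinned], kind="mergesort")
        top = thinned[order[:top_k]]
        bottom = thinned[order[-top_k:]]

        rows = {}
        for role, ids in role_ids.items():
            f_top = wrights_f_per_variant(G, ids, top)
            f_bot = wrights_f_per_variant(G, ids, bottom)
            d2_top, n_top = mean_d2_cross_chromosome(G, ids, top)
            d2_bot, n_bot = mean_d2_cross_chromosome(G, ids, bottom)
            rows[role] = {
                "f_top": np.nanmean(f_top), "f_bottom": np.nanmean(f_bot),
                "n_f_top": int(np.isfinite(f_top).sum()),
                "n_f_bottom": int(np.isfinite(f_bot).sum()),
                "d2_top": d2_top, "d2_bottom": d2_bot,
                "n_d2_top": n_top, "n_d2_bottom": n_bot,
            }
        summaries.append(IterationSummary(it, len(thinned), pd.DataFrame(rows).T))

    if n_iter > 0 and n_skipped > 0.1 * n_iter:
        raise RuntimeError(
            f"{n_skipped}/{n_iter} iterations had thinned sets smaller than 2K; "
            "reduce top_k or min_gap_bp")

    rows = []
    for role in role_ids:
        for stat in ("f", "d2"):
            top_means = np.array([s.role_means.loc[role, f"{stat}_top"] for s in summaries])
            bot_means = np.array([s.role_means.loc[role, f"{stat}_bottom"] for s in summaries])
            t_stat, p = (np.nan, np.nan)
            if len(top_means) >= 2:
                t_stat, p = stats.ttest_ind(top_means, bot_means, equal_var=False)
            rows.append({
                "role": role, "statistic": stat,
                "mean_top": top_means.mean() if len(top_means) else np.nan,
                "mean_bottom": bot_means.mean() if len(bot_means) else np.nan,
                "sd_top": top_means.std(ddof=1) if len(top_means) > 1 else np.nan,
                "sd_bottom": bot_means.std(ddof=1) if len(bot_means) > 1 else np.nan,
                "t": float(t_stat), "p": float(p),
                "n_iterations": len(top_means),
            })
    return LdComparisonResult(pd.DataFrame(rows), summaries, n_skipped)
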