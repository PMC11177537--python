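"""Reference-anchored ancestry PCA, centroid-based population assignment and
|PC1| SNP-informativeness ranking.

The PCA is fitted jointly on cohort founders plus labeled reference
samples, with per-variant standardization (mean 2p, scale sqrt(2p(1-p)))
estimated from the fitting set; children and any held-out samples are
projected with the fitted standardization and loadings so family structure
does not distort the axes.  A sample is called target-like iff on both PC1
and PC2 it lies strictly closer to the target reference centroid than to
every contrast centroid; ties exclude the sample.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import MISSING, GenotypeMatrix


class AncestryConfigError(ValueError):
    pass


@dataclass
class PcaModel:
    eigenvalues: np.ndarray           # (k,)
    scores: pd.DataFrame              # fitted samples x k, index = sample id
    loadings: np.ndarray              # n_variants x k, unit-norm columns
    mean_: np.ndarray                 # per-variant 2*p_hat
    scale_: np.ndarray                # per-variant sqrt(2*p_hat*(1-p_hat))
    variant_ids: list[str]

    @property
    def k(self) -> int:
        return self.loadings.shape[1]

    def project(self, G: GenotypeMatrix, sample_ids=None) -> pd.DataFrame:
        """Scores for arbitrary samples using the fitted standardization."""
        ids = list(sample_ids) if sample_ids is not None else list(G.samples)
        if list(G.variants["id"]) != self.variant_ids:
            raise AncestryConfigError("variant set differs from the fitted model")
        X = _standardize(G.dosages[G.sample_indices(ids)], self.mean_, self.scale_)
        return pd.DataFrame(X @ self.loadings, index=ids,
                            columns=[f"PC{j+1}" for j in range(self.k)])


def _standardize(dosages: np.ndarray, mean: np.ndarray, scale: np.ndarray) -> np.ndarray:
    X = dosages.astype(float)
    miss = dosages == MISSING
    X[miss] = np.nan
    X = (X - mean) / scale
    X[np.isnan(X)] = 0.0  # missing -> mean after standardization
    return X


@dataclass
class AncestryCall:
    calls: pd.DataFrame  # index sample, columns: label + dist_<pop> per population

    def target_like_ids(self) -> list[str]:
        return self.calls.index[self.calls["label"] == "target_like"].tolist()


def fit_reference_pca(G: GenotypeMatrix, fit_sample_ids, k: int = 20) -> PcaModel:
    """PCA of variance-standardized dosages over the fitting samples.

    Sign convention: in each loading column the entry of largest magnitude
    is made positive, so ranked SNP lists are reproducible across
    eigensolvers.  k is reduced with a warning when it exceeds the rank.
    """
    ids = list(fit_sample_ids)
    D = G.dosages[G.sample_indices(ids)]
    obs = D != MISSING
    with np.errstate(invalid="ignore"):
        p_hat = np.where(obs, D, 0).sum(axis=0) / np.maximum(2 * obs.sum(axis=0), 1)
    p_hat = np.clip(p_hat, 1e-6, 1 - 1e-6)
    mean = 2 * p_hat
    scale = np.sqrt(2 * p_hat * (1 - p_hat))
    X = _standardize(D, mean, scale)

    rank = min(X.shape)
    if k > rank:
        warnings.warn(f"k={k} exceeds rank {rank}; reducing")
        k = rank
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    loadings = Vt[:k].T
    # fix signs: largest-|entry| per column positive
    for j in range(k):
        col = loadings[:, j]
        if col[np.argmax(np.abs(col))] < 0:
            loadings[:, j] = -col
    scores = X @ loadings
    eigenvalues = (s[:k] ** 2) / max(len(ids) - 1, 1)
    return PcaModel(
        eigenvalues=eigenvalues,
        scores=pd.DataFrame(scores, index=ids, columns=[f"PC{j+1}" for j in range(k)]),
        loadings=loadings, mean_=mean, scale_=scale,
        variant_ids=list(G.variants["id"]),
    )


def assign_ancestry(scores: pd.DataFrame, reference_labels: pd.Series,
                    target_population: str) -> AncestryCall:
    """Centroid rule on (PC1, PC2).

    Per-population centroids are the means of the labeled reference
    samples' scores.  A sample is ``target_like`` iff, on PC1 AND on PC2
    separately, its absolute distance to the target centroid is strictly
    smaller than to every contrast centroid.
    """
    pops = reference_labels.unique().tolist()
    if target_population not in pops:
        raise AncestryConfigError(f"no reference samples labeled {target_population}")
    centroids = {}
    for pop in pops:
        members = reference_labels.index[reference_labels == pop]
        members = [m for m in members if m in scores.index]
        if not members:
            raise AncestryConfigError(f"reference population {pop} has no scored samples")
        centroids[pop] = scores.loc[members, ["PC1", "PC2"]].mean()

    out = pd.DataFrame(index=scores.index)
    for pop in pops:
        for pc in ("PC1", "PC2"):
            out[f"dist_{pop}_{pc}"] = (scores[pc] - centroids[pop][pc]).abs()
    contrast = [p for p in pops if p != target_population]
    ok = pd.Series(True, index=scores.index)
    for pc in ("PC1", "PC2"):
        for pop in contrast:
            ok &= out[f"dist_{target_population}_{pc}"] < out[f"dist_{pop}_{pc}"]
    out.insert(0, "label", np.where(ok, "target_like", "other"))
    return AncestryCall(out)


def rank_snps_by_loading(model: PcaModel, variants: pd.DataFrame,
                         component: int = 1) -> pd.DataFrame:
    """Variants ordered by |loading| on the given component, descending.

    Ties break by (chromosome, position) ascending.  The returned frame
    carries an ``abs_loading`` column; head/tail give top-K / bottom-K.
    """
    if component > model.k:
        raise AncestryConfigError(f"component {component} > k={model.k}")
    lo = np.abs(model.loadings[:, component - 1])
    df = variants.copy().reset_index(drop=True)
    df["abs_loading"] = lo
    df["_c"] = df["chrom"].astype(int)
    df = df.sort_values(["abs_loading", "_c", "pos"],
                        ascending=[False, True, True], kind="mergesort")
    return df.drop(columns="_c").reset_index(drop=True)


def family_retention_mask(call: AncestryCall, pedigree) -> list[bool]:
    """Retain a family iff every genotyped member is target-like."""
    labels = call.calls["label"]
    keep = []
    for f in pedigree:
        members = [f.father_id, f.mother_id, f.proband_id]
        if f.sibling_id is not None:
            members.append(f.sibling_id)
        keep.append(all(labels.get(m) == "target_like" for m in members if m in labels.index))
    return keep
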