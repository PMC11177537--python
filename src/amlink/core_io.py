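"""Domain data model and readers/writers for the standard formats the pipeline touches.

Genotypes live in a :class:`GenotypeMatrix` — a samples × variants dosage
matrix with values in {0, 1, 2, MISSING}, where dosage counts copies of
allele ``a1``.  Family structure lives in a :class:`Pedigree` of quartet
records (father, mother, proband, optional unaffected sibling).  GWAS
summary statistics and parental quantitative-trait tables are thin typed
wrappers around pandas DataFrames.

Coordinate conventions: .bim positions are 1-based; BED regions are
0-based half-open; all internal positions are 1-based.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("amlink")

#: Sentinel for a missing dosage.  0 is a valid homozygote and is never
#: used to encode missingness.
MISSING: int = -1

AUTOSOMES = frozenset(str(c) for c in range(1, 23))

_PALINDROMIC = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


class FormatError(ValueError):
    """Malformed file (bad magic bytes, unparseable rows)."""


class IntegrityError(ValueError):
    """Internally inconsistent data (dimension mismatches, duplicate ids)."""


class SchemaError(ValueError):
    """A mandatory column is absent from a tabular input."""


@dataclass(frozen=True)
class Variant:
    """A bi-allelic autosomal SNP.  ``allele_a1`` is the dosage-counted allele."""

    id: str
    chromosome: str
    position: int
    allele_a1: str
    allele_a2: str

    def __post_init__(self):
        if self.position < 1:
            raise IntegrityError(f"variant {self.id}: position must be >= 1")
        if self.allele_a1 == self.allele_a2:
            raise IntegrityError(f"variant {self.id}: alleles must differ")
        if self.chromosome not in AUTOSOMES:
            raise IntegrityError(f"variant {self.id}: non-autosomal chromosome {self.chromosome}")


class GenotypeMatrix:
    """Samples × variants dosage matrix plus variant metadata.

    ``dosages`` is an int8 array with entries in {0, 1, 2, MISSING};
    ``variants`` is a DataFrame with columns id, chrom, pos, a1, a2 in
    variant order.  ``chrom`` is a string, ``pos`` 1-based.
    """

    def __init__(self, samples: Sequence[str], variants: pd.DataFrame, dosages: np.ndarray):
        samples = list(samples)
        dosages = np.asarray(dosages, dtype=np.int8)
        if dosages.shape != (len(samples), len(variants)):
            raise IntegrityError(
                f"dosage shape {dosages.shape} inconsistent with "
                f"{len(samples)} samples x {len(variants)} variants"
            )
        bad = ~np.isin(dosages, (0, 1, 2, MISSING))
        if bad.any():
            raise IntegrityError(f"{bad.sum()} dosage entries outside {{0,1,2,MISSING}}")
        if len(set(samples)) != len(samples):
            raise IntegrityError("duplicate sample ids")
        self.samples = samples
        self.variants = variants.reset_index(drop=True)
        self.dosages = dosages
        self._sample_index = {s: i for i, s in enumerate(samples)}

    # -- shape -------------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def sample_indices(self, ids: Iterable[str]) -> np.ndarray:
        return np.array([self._sample_index[s] for s in ids], dtype=int)

    # -- subsetting --------------------------------------------------------
    def subset_samples(self, ids: Sequence[str]) -> "GenotypeMatrix":
        idx = self.sample_indices(ids)
        return GenotypeMatrix(list(ids), self.variants, self.dosages[idx])

    def subset_variants(self, mask_or_index) -> "GenotypeMatrix":
        arr = np.asarray(mask_or_index)
        if arr.dtype == bool:
            arr = np.flatnonzero(arr)
        return GenotypeMatrix(self.samples, self.variants.iloc[arr], self.dosages[:, arr])

    # -- summaries ---------------------------------------------------------
    def missing_mask(self) -> np.ndarray:
        return self.dosages == MISSING

    def allele_freq(self, sample_ids: Sequence[str] | None = None) -> np.ndarray:
        """Frequency of allele a1 from non-missing calls (NaN if no calls)."""
        d = self.dosages if sample_ids is None else self.dosages[self.sample_indices(sample_ids)]
        obs = d != MISSING
        n = obs.sum(axis=0)
        with np.errstate(invalid="ignore"):
            return np.where(obs, d, 0).sum(axis=0) / np.maximum(2 * n, 1) * np.where(n > 0, 1, np.nan)

    def variant_records(self) -> list[Variant]:
        return [
            Variant(r.id, str(r.chrom), int(r.pos), r.a1, r.a2)
            for r in self.variants.itertuples(index=False)
        ]


@dataclass
class FamilyRecord:
    family_id: str
    father_id: str
    mother_id: str
    proband_id: str
    sibling_id: str | None = None
    proband_sex: str = "unknown"
    sibling_sex: str = "unknown"
    proband_affected: bool = True
    sibling_affected: bool = False
    group_label: str = "unknown"  # with_CI_ID / without_CI_ID / unknown
    family_type: str = "unknown"  # simplex / multiplex / unknown
    proband_carrier: bool = False
    sibling_carrier: bool = False

    def __post_init__(self):
        if self.father_id == self.mother_id:
            raise IntegrityError(f"family {self.family_id}: father and mother ids identical")


class Pedigree:
    """Quartet/trio family structures driving spousal pairing and trios."""

    def __init__(self, families: Sequence[FamilyRecord]):
        self.families = list(families)
        ids = [f.family_id for f in self.families]
        if len(set(ids)) != len(ids):
            raise IntegrityError("duplicate family ids")

    def __len__(self) -> int:
        return len(self.families)

    def __iter__(self):
        return iter(self.families)

    def founder_ids(self) -> list[str]:
        out = []
        for f in self.families:
            out.extend([f.father_id, f.mother_id])
        return out

    def father_ids(self) -> list[str]:
        return [f.father_id for f in self.families]

    def mother_ids(self) -> list[str]:
        return [f.mother_id for f in self.families]

    def child_ids(self) -> list[str]:
        out = []
        for f in self.families:
            out.append(f.proband_id)
            if f.sibling_id is not None:
                out.append(f.sibling_id)
        return out

    def sibling_ids(self) -> list[str]:
        return [f.sibling_id for f in self.families if f.sibling_id is not None]

    def proband_ids(self) -> list[str]:
        return [f.proband_id for f in self.families]

    def all_ids(self) -> list[str]:
        return self.founder_ids() + self.child_ids()

    def trios(self, child_role: str = "proband") -> list[tuple[str, str, str]]:
        """(father, mother, child) triplets; child_role is 'proband', 'sibling' or 'all'."""
        out = []
        for f in self.families:
            if child_role in ("proband", "all"):
                out.append((f.father_id, f.mother_id, f.proband_id))
            if child_role in ("sibling", "all") and f.sibling_id is not None:
                out.append((f.father_id, f.mother_id, f.sibling_id))
        return out

    def spouse_pairs(self) -> list[tuple[str, str]]:
        return [(f.father_id, f.mother_id) for f in self.families]

    def subset(self, keep: Iterable[FamilyRecord] | Iterable[bool]) -> "Pedigree":
        keep = list(keep)
        if keep and isinstance(keep[0], (bool, np.bool_)):
            keep = [f for f, k in zip(self.families, keep) if k]
        return Pedigree(keep)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(f) for f in self.families])

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Pedigree":
        required = {"family_id", "father_id", "mother_id", "proband_id"}
        missing = required - set(df.columns)
        if missing:
            raise SchemaError(f"pedigree table missing columns: {sorted(missing)}")
        recs = []
        for row in df.to_dict("records"):
            kwargs = {k: row[k] for k in row if k in FamilyRecord.__dataclass_fields__}
            sib = kwargs.get("sibling_id")
            if sib is not None and (pd.isna(sib) or sib == ""):
                kwargs["sibling_id"] = None
            recs.append(FamilyRecord(**kwargs))
        return cls(recs)


@dataclass
class SummaryStats:
    """GWAS summary statistics: one row per variant.

    Columns: id, effect_allele, other_allele, beta, se and, for a binary
    trait, n_case / n_control, or n for a quantitative trait.
    """

    table: pd.DataFrame

    def __post_init__(self):
        t = self.table
        required = {"id", "effect_allele", "other_allele", "beta", "se"}
        missing = required - set(t.columns)
        if missing:
            raise SchemaError(f"summary stats missing columns: {sorted(missing)}")
        if (t["se"] <= 0).any():
            raise IntegrityError("summary stats contain se <= 0")
        if (t["effect_allele"].astype(str).str.len() == 0).any() or (
            t["other_allele"].astype(str).str.len() == 0
        ).any():
            raise IntegrityError("empty allele codes in summary stats")
        for col in ("n_case", "n_control", "n"):
            if col in t.columns and (pd.to_numeric(t[col], errors="coerce") <= 0).any():
                raise IntegrityError(f"summary stats column {col} must be positive")

    @property
    def is_binary(self) -> bool:
        return "n_case" in self.table.columns and "n_control" in self.table.columns


@dataclass
class TraitTable:
    """Per-parent quantitative trait scores plus demographic covariates."""

    table: pd.DataFrame

    SCORE_COLUMNS = (
        "srs_total", "srs_awareness", "srs_cognition", "srs_mannerisms",
        "srs_motivation", "srs_communication",
        "bapq_total", "bapq_aloof", "bapq_rigid", "bapq_pragmatic",
    )

    def __post_init__(self):
        t = self.table
        if "sample_id" not in t.columns:
            raise SchemaError("trait table requires a sample_id column")
        if "sex" in t.columns:
            bad = ~t["sex"].isin(["male", "female"]) & t["sex"].notna()
            if bad.any():
                raise IntegrityError("trait table sex must be 'male' or 'female'")

    def values_for(self, column: str, sample_ids: Sequence[str]) -> np.ndarray:
        s = self.table.set_index("sample_id")[column]
        return s.reindex(sample_ids).to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# PLINK 1.x binary triplet
# ---------------------------------------------------------------------------

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])
# PLINK 2-bit codes (SNP-major): 00 hom A1, 01 missing, 10 het, 11 hom A2.
# Dosage counts A1 copies, so 00 -> 2, 10 -> 1, 11 -> 0, 01 -> MISSING.
_CODE_TO_DOSAGE = np.array([2, MISSING, 1, 0], dtype=np.int8)
_DOSAGE_TO_CODE = {2: 0, MISSING: 1, 1: 2, 0: 3}


def read_plink(prefix: str | Path) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Read a .bed/.bim/.fam triplet.

    Non-autosomal and non-biallelic/duplicate-position records are dropped
    with a logged count.  Returns the genotype matrix and the raw .fam
    table (a pedigree skeleton: fid, iid, father, mother, sex, phenotype).
    """
    prefix = Path(prefix)
    bed, bim, fam = prefix.with_suffix(".bed"), prefix.with_suffix(".bim"), prefix.with_suffix(".fam")
    for p in (bed, bim, fam):
        if not p.exists():
            raise FileNotFoundError(p)

    fam_df = pd.read_csv(
        fam, sep=r"\s+", header=None,
        names=["fid", "iid", "father", "mother", "sex", "phenotype"],
        dtype={"fid": str, "iid": str, "father": str, "mother": str},
    )
    if fam_df["iid"].duplicated().any():
        raise IntegrityError(".fam contains duplicate sample ids")
    bim_df = pd.read_csv(
        bim, sep=r"\s+", header=None,
        names=["chrom", "id", "cm", "pos", "a1", "a2"],
        dtype={"chrom": str, "id": str, "a1": str, "a2": str},
    )

    n_samples, n_variants = len(fam_df), len(bim_df)
    raw = np.fromfile(bed, dtype=np.uint8)
    if len(raw) < 3 or bytes(raw[:3]) != _BED_MAGIC:
        raise FormatError(f"{bed}: bad magic bytes (not a SNP-major PLINK 1.x .bed)")
    bytes_per_variant = (n_samples + 3) // 4
    body = raw[3:]
    if len(body) != bytes_per_variant * n_variants:
        raise IntegrityError(
            f"{bed}: size implies a sample/variant count mismatch "
            f"({len(body)} body bytes, expected {bytes_per_variant * n_variants})"
        )
    blocks = body.reshape(n_variants, bytes_per_variant)
    # unpack 2-bit codes, little-endian within each byte
    codes = np.empty((n_variants, bytes_per_variant * 4), dtype=np.uint8)
    for k in range(4):
        codes[:, k::4] = (blocks >> (2 * k)) & 0b11
    dosages = _CODE_TO_DOSAGE[codes[:, :n_samples]].T  # samples x variants

    keep = bim_df["chrom"].isin(AUTOSOMES).to_numpy()
    n_nonauto = int((~keep).sum())
    dup = bim_df.duplicated(subset=["chrom", "pos"], keep="first").to_numpy()
    n_dup = int((dup & keep).sum())
    keep &= ~dup
    if n_nonauto:
        logger.info("read_plink: dropped %d non-autosomal variants", n_nonauto)
    if n_dup:
        logger.info("read_plink: dropped %d duplicate-position variants", n_dup)

    bim_kept = bim_df.loc[keep, ["id", "chrom", "pos", "a1", "a2"]]
    G = GenotypeMatrix(fam_df["iid"].tolist(), bim_kept, dosages[:, keep])
    return G, fam_df


def write_plink(G: GenotypeMatrix, prefix: str | Path, fam: pd.DataFrame | None = None) -> None:
    """Write a GenotypeMatrix as a SNP-major PLINK 1.x triplet."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    if fam is None:
        fam = pd.DataFrame(
            {"fid": G.samples, "iid": G.samples, "father": "0", "mother": "0",
             "sex": 0, "phenotype": -9}
        )
    fam.to_csv(prefix.with_suffix(".fam"), sep="\t", header=False, index=False)
    bim = G.variants
    pd.DataFrame(
        {"chrom": bim["chrom"], "id": bim["id"], "cm": 0, "pos": bim["pos"],
         "a1": bim["a1"], "a2": bim["a2"]}
    ).to_csv(prefix.with_suffix(".bim"), sep="\t", header=False, index=False)

    n_samples = G.n_samples
    bytes_per_variant = (n_samples + 3) // 4
    code_lut = np.zeros(256, dtype=np.uint8)
    for d, c in _DOSAGE_TO_CODE.items():
        code_lut[np.int8(d).view(np.uint8)] = c
    codes = code_lut[G.dosages.T.astype(np.uint8)]  # variants x samples
    padded = np.zeros((G.n_variants, bytes_per_variant * 4), dtype=np.uint8)
    padded[:, :n_samples] = codes
    packed = np.zeros((G.n_variants, bytes_per_variant), dtype=np.uint8)
    for k in range(4):
        packed |= padded[:, k::4] << (2 * k)
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(packed.tobytes())


# ---------------------------------------------------------------------------
# BED regions (extended-LD exclusion)
# ---------------------------------------------------------------------------

def read_bed_regions(path: str | Path) -> list[tuple[str, int, int]]:
    """Read a BED3+ file of (chromosome, start, end), 0-based half-open."""
    regions = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 3:
                raise FormatError(f"{path}:{ln}: BED requires >= 3 columns")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if start >= end:
                raise FormatError(f"{path}:{ln}: start >= end")
            regions.append((chrom.removeprefix("chr"), start, end))
    return regions


def in_regions(chrom: np.ndarray, pos: np.ndarray, regions: Sequence[tuple[str, int, int]]) -> np.ndarray:
    """Mask of variants (1-based positions) falling inside any region.

    A variant at 1-based position p is inside (start, end) iff start < p <= end.
    """
    chrom = np.asarray(chrom, dtype=str)
    pos = np.asarray(pos, dtype=int)
    mask = np.zeros(len(pos), dtype=bool)
    for rc, start, end in regions:
        mask |= (chrom == rc) & (pos > start) & (pos <= end)
    return mask


# ---------------------------------------------------------------------------
# Tabular readers / writers
# ---------------------------------------------------------------------------

def read_summary_stats(path: str | Path, column_map: dict[str, str] | None = None) -> SummaryStats:
    """Read a TSV of GWAS summary statistics; column_map renames source→canonical."""
    df = pd.read_csv(path, sep="\t")
    if column_map:
        df = df.rename(columns={v: k for k, v in column_map.items()})
    return SummaryStats(df)


def read_trait_table(path: str | Path, column_map: dict[str, str] | None = None) -> TraitTable:
    df = pd.read_csv(path, sep="\t")
    if column_map:
        df = df.rename(columns={v: k for k, v in column_map.items()})
    return TraitTable(df)


def read_pedigree(path: str | Path) -> Pedigree:
    return Pedigree.from_frame(pd.read_csv(path, sep="\t", dtype={"family_id": str}))


def write_results(tables: dict[str, pd.DataFrame], out_dir: str | Path,
                  manifest: dict | None = None) -> None:
    """Write one TSV per analysis plus a JSON run manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for name, df in tables.items():
        df.to_csv(out_dir / f"{name}.tsv", sep="\t", index=False)
    if manifest is not None:
        with open(out_dir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)


# ---------------------------------------------------------------------------
# Allele harmonization
# ---------------------------------------------------------------------------

def harmonize_weights(G: GenotypeMatrix, stats: SummaryStats,
                      drop_palindromic: bool = True) -> pd.DataFrame:
    """Align summary-stat effect sizes to the genotype a1 allele.

    Returns a frame with columns (variant_index, id, beta, se, ...) where
    beta is the per-a1-allele effect: if the effect allele matches a2 the
    sign is flipped; variants with incompatible alleles are dropped, as are
    palindromic (A/T, C/G) SNPs when drop_palindromic is set.  No strand
    flipping is attempted.
    """
    v = G.variants.reset_index().rename(columns={"index": "variant_index"})
    merged = v.merge(stats.table, on="id", how="inner", suffixes=("", "_ss"))
    if merged.empty:
        return merged.assign(beta=pd.Series(dtype=float))

    ea, oa = merged["effect_allele"], merged["other_allele"]
    same = (ea == merged["a1"]) & (oa == merged["a2"])
    flipped = (ea == merged["a2"]) & (oa == merged["a1"])
    pal = [tuple(x) in _PALINDROMIC for x in zip(merged["a1"], merged["a2"])]
    pal = pd.Series(pal, index=merged.index)

    keep = (same | flipped) & (~pal if drop_palindromic else True)
    n_pal = int((pal & (same | flipped)).sum()) if drop_palindromic else 0
    n_bad = int((~(same | flipped)).sum())
    if n_pal:
        logger.info("harmonize_weights: dropped %d palindromic variants", n_pal)
    if n_bad:
        logger.info("harmonize_weights: dropped %d allele-incompatible variants", n_bad)

    out = merged.loc[keep].copy()
    out["beta"] = np.where(flipped.loc[keep], -out["beta"], out["beta"])
    return out.reset_index(drop=True)
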