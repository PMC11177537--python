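import numpy as np
import pandas as pd
import pytest

from amlink import GenotypeMatrix, FamilyRecord, Pedigree, SimConfig, simulate_dataset


def make_variants(n, chroms=None, spacing=1000):
    if chroms is None:
        chroms = ["1"] * n
    return pd.DataFrame({
        "id": [f"snp{i}" for i in range(n)],
        "chrom": [str(c) for c in chroms],
        "pos": [(i + 1) * spacing for i in range(n)],
        "a1": "A", "a2": "G",
    })


@pytest.fixture
def tiny_genotypes():
    """4 samples x 3 variants with a deliberate missing call."""
    variants = make_variants(3, chroms=["1", "1", "2"])
    dosages = np.array([
        [0, 1, 2],
        [2, 2, 0],
        [1, 0, -1],
        [0, 1, 1],
    ], dtype=np.int8)
    return GenotypeMatrix(["s1", "s2", "s3", "s4"], variants, dosages)


@pytest.fixture(scope="session")
def quartet_sim():
    """A small ascertained quartet cohort shared across tests."""
    cfg = SimConfig(n_snps=400, n_families=120, n_causal=100, seed=7,
                    rho_ancestry=0.45, missing_rate=0.005)
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def unascertained_sim():
    """Random-retention cohort (no proband ascertainment), clean genotypes."""
    cfg = SimConfig(n_snps=400, n_families=300, n_causal=100, seed=11,
                    rho_ancestry=0.45, ascertain_simplex=False, missing_rate=0.0)
    return simulate_dataset(cfg)


def quartet_pedigree(n_families, prefix="fam"):
    fams = []
    for i in range(n_families):
        fid = f"{prefix}{i}"
        fams.append(FamilyRecord(
            family_id=fid, father_id=f"{fid}_fa", mother_id=f"{fid}_mo",
            proband_id=f"{fid}_p", sibling_id=f"{fid}_s"))
    return Pedigree(fams)
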