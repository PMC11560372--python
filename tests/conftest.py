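"""Shared fixtures: a hand-checked 12-site toy VCF and small helpers."""

from __future__ import annotations

import numpy as np
import pytest

from subgenomics import GenotypeMatrix, SubgenomeMap
import pandas as pd


def vcf_text(records: list[str], samples: list[str], with_dp: bool = False) -> str:
    header = [
        "##fileformat=VCFv4.2",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    ]
    if with_dp:
        header.append('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">')
    header.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples))
    return "\n".join(header + records) + "\n"


def _rec(chrom, pos, ref, alt, gts, dp=None):
    fmt = "GT" if dp is None else "GT:DP"
    cells = gts if dp is None else [f"{g}:{dp}" for g in gts]
    return f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t.\t{fmt}\t" + "\t".join(cells)


# The 12-site cascade fixture (10 samples).  Hand-checked plan, in pipeline
# order depth → biallelic/het/missing → LD prune → MAF(drop_below 0.1):
#   s1, s2   triallelic                     → fail the biallelic filter
#   s3       5 het / 5 hom  (het = 0.5)     → fail het (<0.5 strict)
#   s4       6 het / 4 hom                  → fail het
#   s5       1 missing (0.1 not < 0.1)      → fail missingness
#   s6       2 missing                      → fail missingness
#   s7, s8   identical dosages (r² = 1)     → s8 LD-pruned
#   s9, s10  single het (MAF 0.05)          → removed by MAF drop_below
#   s11, s12 MAF 0.2 / 0.3, low r² to rest  → survive
# Survivors: s7, s11, s12 (3 sites).  Note that LD pruning runs before the
# MAF filter, so s9/s10 are still present during pruning; the hets of s9 and
# s10 sit on samples (smp10, smp6) uncorrelated with the s11/s12 dosages, so
# every pairwise r² among s7, s9, s10, s11, s12 is ≤ 0.26 (hand-checked).
TOY_SAMPLES = [f"smp{i}" for i in range(1, 11)]

TOY_PLAN = {
    "input": 12, "depth": 12, "site_filters": 6, "ld_prune": 5, "maf": 3,
}
TOY_SURVIVOR_POSITIONS = [700, 1100, 1200]


def toy_vcf_records() -> list[str]:
    hom = "0/0"
    rows = [
        _rec("chr1", 100, "A", "T,G", ["0/1", "0/1", "0/2"] + [hom] * 7, dp=30),
        _rec("chr1", 200, "C", "A,G", ["0/2", "0/1"] + [hom] * 8, dp=30),
        _rec("chr1", 300, "G", "A", ["0/1"] * 5 + [hom] * 5, dp=30),
        _rec("chr1", 400, "T", "C", ["0/1"] * 6 + [hom] * 4, dp=30),
        _rec("chr1", 500, "A", "G", ["./."] + [hom] * 7 + ["1/1"] * 2, dp=30),
        _rec("chr1", 600, "C", "T", ["./.", "./."] + [hom] * 6 + ["1/1"] * 2, dp=30),
        _rec("chr1", 700, "G", "C", ["1/1"] * 5 + [hom] * 5, dp=30),
        _rec("chr1", 800, "T", "A", ["1/1"] * 5 + [hom] * 5, dp=30),
        _rec("chr1", 900, "A", "C", [hom] * 9 + ["0/1"], dp=30),
        _rec("chr1", 1000, "G", "T", [hom] * 5 + ["0/1"] + [hom] * 4, dp=30),
        _rec("chr1", 1100, "C", "G", ["1/1", "1/1"] + [hom] * 8, dp=30),
        _rec("chr1", 1200, "T", "G", [hom] * 3 + ["1/1"] * 3 + [hom] * 4, dp=30),
    ]
    return rows


@pytest.fixture
def toy_vcf(tmp_path):
    path = tmp_path / "toy.vcf"
    path.write_text(vcf_text(toy_vcf_records(), TOY_SAMPLES, with_dp=True))
    return path


@pytest.fixture
def toy_sgmap(tmp_path):
    path = tmp_path / "sgmap.tsv"
    pd.DataFrame(
        [{"chrom": "chr1", "subgenome": "SG1", "length_bp": 2000}]
    ).to_csv(path, sep="\t", index=False)
    return path


def random_matrix(rng, n_sites=30, n_samples=12, missing_rate=0.1,
                  chrom="chr1") -> GenotypeMatrix:
    """Random biallelic genotype matrix for oracle comparisons."""
    calls = rng.integers(0, 3, size=(n_sites, n_samples)).astype(np.int8)
    calls[rng.random(calls.shape) < missing_rate] = -1
    pos = np.sort(rng.choice(100_000, size=n_sites, replace=False)) + 1
    sites = pd.DataFrame(
        {"chrom": [chrom] * n_sites, "pos": pos,
         "ref": ["A"] * n_sites, "alts": [("T",)] * n_sites}
    )
    samples = [f"smp{i}" for i in range(n_samples)]
    return GenotypeMatrix(sites=sites, samples=samples, calls=calls)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def simple_sgmap():
    return SubgenomeMap(
        assignment={"chr1": "SG1", "chr2": "SG2", "chr3": "SG3"},
        lengths={"chr1": 100_000, "chr2": 100_000, "chr3": 100_000},
    )
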