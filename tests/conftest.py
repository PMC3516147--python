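import numpy as np
import pytest

from dbmtest.data_model import RegionGenotypes


@pytest.fixture
def toy_region() -> RegionGenotypes:
    """4 subjects (2 cases, 2 controls) x 3 variants, hand-checkable."""
    return RegionGenotypes(
        positions=np.array([100, 150, 300]),
        genotypes=np.array([
            [0, 1, 0],
            [1, 0, 2],
            [1, 0, 0],
            [0, 1, 1],
        ], dtype=float),
        phenotype=np.array([1, 1, 0, 0]),
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240115)


def random_region(rng: np.random.Generator, n_subjects: int = 10,
                  n_variants: int = 5) -> RegionGenotypes:
    positions = np.sort(rng.choice(100_000, size=n_variants, replace=False)) + 1
    genotypes = rng.integers(0, 3, size=(n_subjects, n_variants)).astype(float)
    phenotype = np.zeros(n_subjects, dtype=np.int8)
    phenotype[: n_subjects // 2] = 1
    return RegionGenotypes(positions=positions, genotypes=genotypes,
                           phenotype=phenotype)


def write_toy_vcf(path, positions, genotype_counts, sample_ids,
                  extra_records=()) -> None:
    """Write count-coded genotypes (subjects x variants) as a plain VCF.

    Count -1 encodes a missing call.
    """
    gt_map = {-1: "./.", 0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##contig=<ID=1,length=100000000>\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(sample_ids) + "\n")
        records = []
        for j, pos in enumerate(positions):
            gts = "\t".join(gt_map[int(c)] for c in genotype_counts[:, j])
            records.append((int(pos), f"1\t{pos}\t.\tA\tG\t.\tPASS\t.\tGT\t{gts}\n"))
        for pos, line in extra_records:
            records.append((int(pos), line))
        for _, line in sorted(records):
            fh.write(line)
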