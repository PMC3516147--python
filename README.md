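# dbmtest

A spatial (distance-based) association test for rare genetic variants in
case-control sequencing studies, with an exact tie-aware Ansari–Bradley
scale test at its core and a simulation harness for operating
characteristics.

## The problem

Region-based rare-variant tests usually collapse minor-allele counts into
a burden score, discarding *where* in the region the alleles sit. When
causal variants cluster in a sub-region (a functional domain, a regulatory
element), their carriers' alleles are physically close together, and the
spatial arrangement itself carries association signal that burden-style
collapsing cannot see.

This package implements a test that compares the **inter-allele distance
distributions** of cases and controls. For each group, every rare
variant's position is repeated according to its (weighted) minor-allele
count, producing a sorted position sequence; consecutive differences give
an adjacent-distance vector. If cases harbor a cluster of risk alleles,
their distance distribution is more dispersed toward small values than
the controls' — a difference in *scale*, tested with the Ansari–Bradley
two-sample test.

## Method in brief

For a region with rare-variant positions `p_1 < … < p_k` and per-group
minor-allele counts `c_j` (cases) and `d_j` (controls):

1. **Weights.** Each variant gets weight `w_j ∝ f_j · h_j`, normalized to
   mean 1, where `f_j = 1 / sqrt(q_j (1 − q_j))` with
   `q_j = (r_j + 1) / (2 n_ref + 2)` an up-weighted inverse-frequency
   factor computed from a *reference group* (cases or controls), and
   `h_j = m / (δ_j + m)` a proximity factor from the nearest-neighbor
   distance `δ_j` (`m` = median of all `δ`). Two weighting schemes are
   run: reference = cases and reference = controls.
2. **Distances.** Weighted counts `round(c_j · w_j)` (half away from
   zero) repeat each position; adjacent differences within each group
   form the two distance samples.
3. **Scale test.** An Ansari–Bradley test with midrank tie handling
   compares the two samples per scheme. The exact null distribution is
   computed by a generalized Streitberg/Röhmel shift algorithm on an
   integer score lattice (normal approximation beyond a work bound).
4. **Combination and significance.** The combined statistic is the
   minimum of the two schemes' p-values; its significance is assessed by
   permuting case/control labels and recomputing the *entire* pipeline
   (weights included), with the add-one permutation p-value
   `(1 + #{perm ≤ obs}) / (B + 1)`.

See [docs/methods.md](docs/methods.md) for assumptions, numerical
choices, and the simulator's design.

## Usage

### Python API

```python
import numpy as np
from dbmtest import RegionGenotypes, filter_rare, permutation_test

region = RegionGenotypes(
    positions=np.array([120, 860, 940, 3200, 7700]),
    genotypes=np.array([           # subjects x variants, allele counts
        [0, 1, 1, 0, 0],
        [1, 0, 1, 0, 0],
        [0, 0, 0, 0, 1],
        [0, 0, 0, 1, 0],
        [0, 1, 0, 0, 0],
        [0, 0, 0, 0, 0],
    ], dtype=float),
    phenotype=np.array([1, 1, 1, 0, 0, 0]),   # 1 = case, 0 = control
)
rare = filter_rare(region, 0.5)   # MAF cutoff (inclusive)
res = permutation_test(region, rare, n_permutations=999, seed=1)
print(res.combined, res.pvalue)
```

Output:

```
0.6666666666666667 0.483
```

`res.scheme_results` holds the per-scheme Ansari–Bradley statistics and
p-values; `res.case_based` / `res.control_based` are shortcuts.

### Command line

Test one region from a VCF (biallelic SNVs; optionally a dosage FORMAT
field) or from a plain tabular genotype matrix:

```bash
dbm test --vcf region.vcf --pheno pheno.txt --maf 0.01 \
    --permutations 1000 --seed 1 --out results/region
dbm test --geno geno.txt --pos pos.txt --pheno pheno.txt \
    --maf 0.01 --out results/region
```

`pheno.txt` has one `subject_id 0|1` pair per line. Results are written
as TSV and JSON.

Estimate operating characteristics by simulation:

```bash
dbm simulate --scenario clustered --n-risk 10 --replicates 200 \
    --permutations 500 --seed 1 --out results/power_clustered
```

## Simulator

`dbmtest.simulate` generates case-control data from a pool of 5000
haplotypes over a 500 kb region: 30 rare SNPs drawn from a neutral
site-frequency spectrum truncated at the MAF cutoff, positions placed
uniformly or with causal variants clustered in a contiguous window, a
disease model (per-allele relative risk 3.0, multiplicative on the risk
scale by default, strictly additive on the penetrance scale via
`model="additive"`) calibrated exactly to a population prevalence of
0.15, and rejection sampling to the case/control quotas.

## Layout

- `src/dbmtest/data_model.py` — genotype containers, MAF estimation, rare filter
- `src/dbmtest/weighting.py` — weights, position sequences, distance vectors
- `src/dbmtest/ansari_bradley.py` — tie-aware exact AB scale test
- `src/dbmtest/dbm.py` — scheme combination and permutation significance
- `src/dbmtest/simulate.py` — haplotype pool, disease model, sampling
- `src/dbmtest/evaluate.py` — Monte-Carlo type-I error / power harness
- `src/dbmtest/io.py`, `src/dbmtest/cli.py` — file formats and `dbm` CLI
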