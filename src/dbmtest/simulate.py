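"""Case-control simulator for rare-variant power and type-I-error studies.

The generator emulates the sampling design of a region-based
case-control sequencing study: a large pool of haplotypes carrying rare
SNPs drawn from a neutral site-frequency spectrum, diploid subjects
formed from two pool haplotypes, an additive disease model (per-allele
relative risk, multiplicative on the risk scale) calibrated to a target
population prevalence, and rejection sampling until the case and
control quotas are filled.

Causal (risk) variants can be placed either clustered — within one
contiguous window of the region, with all remaining variants outside
that window — or non-clustered, with every variant placed uniformly at
random.  Protective variants, when present, are drawn from the
non-clustered remainder.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_model import RegionGenotypes

__all__ = [
    "SimulationConfig",
    "simulate_haplotype_pool",
    "place_variants",
    "solve_baseline_risk",
    "disease_probability",
    "assign_phenotype",
    "sample_case_control",
]


@dataclass
class SimulationConfig:
    """Study-design parameters for the simulator.

    Defaults reproduce the reference design: a 500 kb region, 5000
    haplotypes, 30 rare SNPs under the chosen MAF cutoff, an additive
    disease model with prevalence 0.15 and per-allele relative risk 3.0
    for risk variants (1/3.0 for protective ones).  ``mutation_rate``
    is the nominal per-bp per-generation rate of the emulated
    resequencing design; the site-frequency-spectrum generator
    reproduces its rare-variant spectrum directly rather than running a
    forward simulation.
    """

    mutation_rate: float = 1.5e-8
    n_haplotypes: int = 5000
    region_length: int = 500_000
    n_variants: int = 30
    maf_cutoff: float = 0.01
    n_risk: int = 0
    n_protective: int = 0
    risk_ratio: float = 3.0
    prevalence: float = 0.15
    clustered: bool = False
    cluster_span: int = 5000
    n_cases: int = 500
    n_controls: int = 500
    model: str = "multiplicative"
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.model not in ("multiplicative", "additive"):
            raise ValueError(
                "model must be 'multiplicative' (per-allele relative risk, "
                "additive on the log scale) or 'additive' (strictly additive "
                "on the penetrance scale)")
        if self.n_risk + self.n_protective > self.n_variants:
            raise ValueError("more causal variants than variants")
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError("prevalence must be in (0, 1)")
        if self.risk_ratio <= 0:
            raise ValueError("risk_ratio must be positive")
        if not 0.0 < self.maf_cutoff <= 0.5:
            raise ValueError("maf_cutoff must be in (0, 0.5]")
        if self.n_variants < 2:
            raise ValueError("need at least 2 variants")


def simulate_haplotype_pool(
    config: SimulationConfig, rng: np.random.Generator
) -> np.ndarray:
    """Binary haplotype pool, shape (n_haplotypes, n_variants).

    Each variant's pool minor-allele count i is drawn from the neutral
    site-frequency spectrum truncated at the MAF cutoff,
    P(i) ∝ 1/i for i = 1 .. floor(maf_cutoff * n_haplotypes),
    and the i carrier haplotypes are chosen without replacement, so the
    pool frequency never exceeds the cutoff.  Sites are independent
    (linkage equilibrium), a good approximation for rare variants.
    """
    i_max = int(np.floor(config.maf_cutoff * config.n_haplotypes))
    if i_max < 1:
        raise ValueError(
            "maf_cutoff too small: no minor-allele count class available")
    ii = np.arange(1, i_max + 1)
    probs = (1.0 / ii) / np.sum(1.0 / ii)
    counts = rng.choice(ii, size=config.n_variants, p=probs)
    pool = np.zeros((config.n_haplotypes, config.n_variants), dtype=np.uint8)
    for j, c in enumerate(counts):
        carriers = rng.choice(config.n_haplotypes, size=int(c), replace=False)
        pool[carriers, j] = 1
    return pool


def place_variants(
    config: SimulationConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Physical positions plus risk/protective index sets.

    Clustered design: a window anchor is drawn uniformly; the n_risk
    risk-variant positions are distinct uniform integers inside
    [anchor, anchor + cluster_span]; all other variants (including
    protective ones) get distinct uniform positions outside the window.
    Non-clustered: every position uniform over the region; risk and
    protective labels assigned to variants at random.

    Returns (sorted positions, risk indices, protective indices) with
    indices referring to the sorted position vector.
    """
    L, k = config.region_length, config.n_variants
    n_risk, n_prot = config.n_risk, config.n_protective
    if config.clustered and n_risk > 0:
        span = config.cluster_span
        if span + 1 < n_risk:
            raise ValueError("cluster_span too small for n_risk distinct positions")
        if L <= span + 1 + (k - n_risk):
            raise ValueError("region too small for the requested placement")
        anchor = int(rng.integers(1, L - span))
        in_cluster = anchor + rng.choice(span + 1, size=n_risk, replace=False)
        n_outside = k - n_risk
        # uniform over {1..L} \ [anchor, anchor+span]
        idx = rng.choice(L - span - 1, size=n_outside, replace=False)
        outside = np.where(idx + 1 < anchor, idx + 1, idx + span + 2)
        positions = np.concatenate([in_cluster, outside])
        risk_mask = np.zeros(k, dtype=bool)
        risk_mask[:n_risk] = True
        prot_mask = np.zeros(k, dtype=bool)
        if n_prot > 0:
            chosen = rng.choice(n_outside, size=n_prot, replace=False)
            prot_mask[n_risk + chosen] = True
    else:
        positions = 1 + rng.choice(L, size=k, replace=False)
        causal = rng.choice(k, size=n_risk + n_prot, replace=False)
        risk_mask = np.zeros(k, dtype=bool)
        risk_mask[causal[:n_risk]] = True
        prot_mask = np.zeros(k, dtype=bool)
        prot_mask[causal[n_risk:]] = True
    order = np.argsort(positions)
    positions = positions[order]
    risk_idx = np.flatnonzero(risk_mask[order])
    prot_idx = np.flatnonzero(prot_mask[order])
    return positions.astype(np.int64), risk_idx, prot_idx


def _penetrance(a, b, k0: float, risk_ratio: float, model: str) -> np.ndarray:
    """Disease probability for a risk and b protective alleles carried.

    multiplicative: K0 * r^a * (1/r)^b — per-allele relative risk,
    additive on the log scale.
    additive: K0 * (1 + (r-1)*a - (1-1/r)*b) — each allele shifts the
    penetrance by a fixed increment; one allele still gives the quoted
    risk ratio r (resp. 1/r).
    Clipped to [0, 1] in both cases.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    r = risk_ratio
    if model == "multiplicative":
        p = k0 * r ** (a - b)
    else:
        p = k0 * (1.0 + (r - 1.0) * a - (1.0 - 1.0 / r) * b)
    return np.clip(p, 0.0, 1.0)


def _causal_count_pmf(pool, risk_idx, prot_idx) -> np.ndarray:
    """Exact joint pmf of a subject's (risk, protective) allele counts
    under two independent uniform pool haplotypes: the 2D
    self-convolution of the per-haplotype count histogram."""
    a = pool[:, risk_idx].sum(axis=1).astype(np.int64)
    b = pool[:, prot_idx].sum(axis=1).astype(np.int64)
    p1 = np.zeros((int(a.max()) + 1, int(b.max()) + 1))
    np.add.at(p1, (a, b), 1.0 / a.size)
    conv = np.zeros((2 * p1.shape[0] - 1, 2 * p1.shape[1] - 1))
    for i, j in zip(*np.nonzero(p1)):
        conv[i:i + p1.shape[0], j:j + p1.shape[1]] += p1[i, j] * p1
    return conv


def solve_baseline_risk(
    pool: np.ndarray,
    risk_idx: np.ndarray,
    prot_idx: np.ndarray,
    config: SimulationConfig,
    tol: float = 1e-8,
) -> float:
    """Baseline disease probability K0 such that the population
    prevalence E[penetrance(a, b; K0)] equals the target, the
    expectation taken exactly over the joint distribution of causal
    allele counts for two uniform pool haplotypes.  Bisection on (0, 1].
    """
    if risk_idx.size == 0 and prot_idx.size == 0:
        return config.prevalence
    pmf = _causal_count_pmf(pool, risk_idx, prot_idx)
    aa, bb = np.meshgrid(np.arange(pmf.shape[0]), np.arange(pmf.shape[1]),
                         indexing="ij")

    def prevalence_at(k0: float) -> float:
        return float(np.sum(
            pmf * _penetrance(aa, bb, k0, config.risk_ratio, config.model)))

    lo, hi = 0.0, 1.0
    if prevalence_at(hi) < config.prevalence - tol:
        raise ValueError("target prevalence unreachable for this configuration")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if prevalence_at(mid) < config.prevalence:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def disease_probability(
    genotypes: np.ndarray,
    risk_idx: np.ndarray,
    prot_idx: np.ndarray,
    k0: float,
    risk_ratio: float,
    model: str = "multiplicative",
) -> np.ndarray:
    """Per-subject disease probability under the chosen disease model
    (see :func:`_penetrance`)."""
    g = np.atleast_2d(genotypes)
    a = g[:, risk_idx].sum(axis=1)
    b = g[:, prot_idx].sum(axis=1) if prot_idx.size else np.zeros(g.shape[0])
    return _penetrance(a, b, k0, risk_ratio, model)


def assign_phenotype(
    genotype_row: np.ndarray,
    risk_idx: np.ndarray,
    prot_idx: np.ndarray,
    k0: float,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> int:
    """Bernoulli case/control label for one subject."""
    p = disease_probability(genotype_row, risk_idx, prot_idx,
                            k0, config.risk_ratio, config.model)[0]
    return int(rng.random() < p)


def sample_case_control(config: SimulationConfig) -> RegionGenotypes:
    """Simulate one case-control dataset under ``config``.

    Subjects are generated from two uniformly drawn pool haplotypes
    (with replacement), labelled by the calibrated disease model, and
    accepted until both group quotas are filled.
    """
    rng = np.random.default_rng(config.seed)
    pool = simulate_haplotype_pool(config, rng)
    positions, risk_idx, prot_idx = place_variants(config, rng)
    k0 = solve_baseline_risk(pool, risk_idx, prot_idx, config)

    need_cases, need_controls = config.n_cases, config.n_controls
    case_rows: list[np.ndarray] = []
    control_rows: list[np.ndarray] = []
    # expected draws to fill both quotas, with head-room
    batch = max(256, int(2 * (need_cases / config.prevalence
                              + need_controls / (1 - config.prevalence))))
    while len(case_rows) < need_cases or len(control_rows) < need_controls:
        h1 = rng.integers(config.n_haplotypes, size=batch)
        h2 = rng.integers(config.n_haplotypes, size=batch)
        g = pool[h1].astype(np.int16) + pool[h2]
        p = disease_probability(g, risk_idx, prot_idx, k0,
                                config.risk_ratio, config.model)
        is_case = rng.random(batch) < p
        for row, c in zip(g, is_case):
            if c and len(case_rows) < need_cases:
                case_rows.append(row)
            elif not c and len(control_rows) < need_controls:
                control_rows.append(row)
            if len(case_rows) >= need_cases and len(control_rows) >= need_controls:
                break
    genotypes = np.vstack(case_rows + control_rows).astype(float)
    phenotype = np.r_[np.ones(need_cases, dtype=np.int8),
                      np.zeros(need_controls, dtype=np.int8)]
    return RegionGenotypes(positions=positions, genotypes=genotypes,
                           phenotype=phenotype)
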