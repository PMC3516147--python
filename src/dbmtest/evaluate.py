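"""Monte-Carlo harness for type-I error and power of the DBM test.

Each replicate simulates one case-control dataset under a scenario
configuration, runs the permutation test, and records the permutation
p-value; the rejection rate at a significance level alpha estimates the
type-I error (null scenarios, no causal variants) or the power
(scenarios with causal variants).

All simulated variants are rare by construction of the haplotype pool,
so the harness analyzes every polymorphic variant rather than
re-filtering on the noisy sample MAF, mirroring a study design in which
the SNP panel is fixed before sampling.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import filter_rare
from .dbm import permutation_test
from .simulate import SimulationConfig, sample_case_control

__all__ = [
    "OperatingCharacteristics",
    "estimate_type1_error",
    "estimate_power",
    "run_scenario",
    "summarize",
]


@dataclass
class OperatingCharacteristics:
    """Rejection rate of the DBM test under one simulation scenario."""

    scenario: str
    clustered: bool
    maf_cutoff: float
    n_cases: int
    n_controls: int
    n_risk: int
    n_protective: int
    alpha: float
    n_replicates: int
    n_permutations: int
    rejection_rate: float
    mc_se: float
    seed: int | None
    pvalues: np.ndarray | None = None

    def as_row(self) -> dict:
        d = dataclasses.asdict(self)
        d.pop("pvalues")
        return d


def run_scenario(
    config: SimulationConfig,
    alpha: float,
    n_replicates: int,
    n_permutations: int,
    seed: int,
    scenario: str = "",
) -> OperatingCharacteristics:
    """Rejection rate of the permutation test over independent replicates.

    Per-replicate seeds are spawned from the master seed, so each
    replicate is independently reproducible regardless of order.
    """
    if not 0.0 < alpha <= 1.0:
        raise ValueError("alpha must be in (0, 1]")
    pvals = np.empty(n_replicates)
    for rep in range(n_replicates):
        ss = np.random.SeedSequence(entropy=int(seed), spawn_key=(rep,))
        data_seed, perm_seed = (int(s) for s in ss.generate_state(2))
        cfg = dataclasses.replace(config, seed=data_seed)
        geno = sample_case_control(cfg)
        rare = filter_rare(geno, 0.5)  # every polymorphic simulated variant
        if len(rare) < 2:
            pvals[rep] = 1.0
            continue
        res = permutation_test(geno, rare, n_permutations=n_permutations,
                               seed=perm_seed)
        pvals[rep] = res.pvalue
    rate = float(np.mean(pvals <= alpha))
    return OperatingCharacteristics(
        scenario=scenario or ("clustered" if config.clustered else "nonclustered"),
        clustered=config.clustered,
        maf_cutoff=config.maf_cutoff,
        n_cases=config.n_cases,
        n_controls=config.n_controls,
        n_risk=config.n_risk,
        n_protective=config.n_protective,
        alpha=alpha,
        n_replicates=n_replicates,
        n_permutations=n_permutations,
        rejection_rate=rate,
        mc_se=float(np.sqrt(rate * (1.0 - rate) / n_replicates)),
        seed=seed,
        pvalues=pvals,
    )


def estimate_type1_error(
    config: SimulationConfig,
    alpha: float,
    n_replicates: int,
    n_permutations: int,
    seed: int,
) -> OperatingCharacteristics:
    """Type-I error rate: rejection rate under a null configuration."""
    if config.n_risk != 0 or config.n_protective != 0:
        raise ValueError("type-I error requires a null config (no causal variants)")
    return run_scenario(config, alpha, n_replicates, n_permutations, seed,
                        scenario="null")


def estimate_power(
    config: SimulationConfig,
    alpha: float,
    n_replicates: int,
    n_permutations: int,
    seed: int,
) -> OperatingCharacteristics:
    """Power: rejection rate under a configuration with causal variants."""
    if config.n_risk + config.n_protective == 0:
        raise ValueError("power estimation requires causal variants")
    return run_scenario(config, alpha, n_replicates, n_permutations, seed)


def summarize(records: list[OperatingCharacteristics]) -> pd.DataFrame:
    """Scenario-per-row summary table (round-trips through TSV)."""
    cols = [f.name for f in dataclasses.fields(OperatingCharacteristics)
            if f.name != "pvalues"]
    return pd.DataFrame([r.as_row() for r in records], columns=cols)
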