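"""The distance-based rare-variant association test (DBM).

For one genomic region the test builds, under each of the two weighting
schemes (case-based and control-based), the adjacent-distance vectors
of cases and controls and compares their dispersion with the tie-aware
exact Ansari–Bradley test.  The per-scheme evidence is summarized by
the exact AB p-value; the combined statistic is the minimum of the two
scheme p-values (small = strong evidence), so evidence for either a
risk-allele or a protective-allele cluster is picked up without any
assumption on effect direction.

Significance of the combined statistic is obtained by permuting
case/control labels with fixed group sizes and recomputing the entire
pipeline — group counts, weights, weighted counts, sequences, distance
vectors, AB tests — for every permutation.  Because the full statistic
is recomputed under each relabeling, the permutation p-value is valid
regardless of the weight function used.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ansari_bradley import ABResult, DEFAULT_WORK_BOUND, ab_exact_test
from .data_model import RareVariantSet, RegionGenotypes
from .weighting import (
    SCHEMES,
    WeightFunction,
    _default_weight_fn,
    adjacent_distances,
    build_position_sequence,
    compute_weights,
    frequency_factor,
    nearest_neighbor_distances,
    proximity_factor,
    weighted_counts,
)

__all__ = ["DBMResult", "dbm_observed", "permutation_test"]


@dataclass
class DBMResult:
    """Result of the distance-based test.

    ``combined`` is min(p_case_scheme, p_control_scheme); smaller means
    stronger evidence.  ``pvalue`` is the add-one permutation estimate
    (1 + #{perm <= observed}) / (B + 1), never exactly zero.
    """

    scheme_results: dict[str, ABResult]
    combined: float
    pvalue: float
    n_permutations: int
    seed: int | None
    degenerate: bool = False

    @property
    def case_based(self) -> ABResult:
        return self.scheme_results["case_based"]

    @property
    def control_based(self) -> ABResult:
        return self.scheme_results["control_based"]


def _scheme_ab(
    case_counts: np.ndarray,
    control_counts: np.ndarray,
    n_cases: int,
    n_controls: int,
    positions: np.ndarray,
    nn_dist: np.ndarray,
    scheme: str,
    weight_fn: WeightFunction,
    work_bound: float,
) -> ABResult:
    """One scheme's AB test straight from per-variant group counts."""
    if scheme == "case_based":
        ref_counts, n_ref = case_counts, n_cases
    else:
        ref_counts, n_ref = control_counts, n_controls
    w = compute_weights(ref_counts, n_ref, nn_dist, weight_fn)
    wc = weighted_counts(case_counts, control_counts, w, scheme)
    dx = adjacent_distances(build_position_sequence(positions, wc.case_counts))
    dy = adjacent_distances(build_position_sequence(positions, wc.control_counts))
    return ab_exact_test(dx, dy, work_bound=work_bound)


def _combined_from_counts(
    case_counts, control_counts, n_cases, n_controls,
    positions, nn_dist, weight_fn, work_bound,
) -> tuple[dict[str, ABResult], float, bool]:
    results = {}
    for scheme in SCHEMES:
        results[scheme] = _scheme_ab(
            case_counts, control_counts, n_cases, n_controls,
            positions, nn_dist, scheme, weight_fn, work_bound,
        )
    degenerate = all(r.degenerate for r in results.values())
    combined = min(r.pvalue for r in results.values())
    return results, combined, degenerate


def dbm_observed(
    geno: RegionGenotypes,
    rare: RareVariantSet,
    weight_fn: WeightFunction = _default_weight_fn,
    work_bound: float = DEFAULT_WORK_BOUND,
    phenotype: np.ndarray | None = None,
) -> tuple[dict[str, ABResult], float, bool]:
    """Per-scheme AB results and the combined statistic for the observed
    (or supplied) labels.

    Returns (scheme_results, combined, degenerate).
    """
    if len(rare) < 2:
        raise ValueError("need at least 2 rare variants for the spatial test")
    labels = geno.phenotype if phenotype is None else np.asarray(phenotype)
    n_cases = int(np.sum(labels == 1))
    n_controls = int(np.sum(labels == 0))
    if n_cases < 1 or n_controls < 1:
        raise ValueError("both groups must be non-empty")
    positions = geno.positions[rare.indices]
    nn_dist = nearest_neighbor_distances(positions)
    sub = geno.genotypes[:, rare.indices]
    case_counts = sub[labels == 1].sum(axis=0)
    control_counts = sub[labels == 0].sum(axis=0)
    return _combined_from_counts(
        case_counts, control_counts, n_cases, n_controls,
        positions, nn_dist, weight_fn, work_bound,
    )


def _permutation_case_masks(labels: np.ndarray, B: int, seed: int | None) -> np.ndarray:
    """B permuted case indicators, one rng per permutation index.

    Each permutation b draws from a generator keyed on (seed, b), so the
    stream is reproducible and order-independent (parallelizable).
    """
    n = labels.size
    masks = np.empty((B, n), dtype=np.float64)
    base = 0 if seed is None else int(seed)
    for b in range(B):
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=base, spawn_key=(b,)))
        masks[b] = rng.permutation(labels == 1)
    return masks


def permutation_test(
    geno: RegionGenotypes,
    rare: RareVariantSet,
    n_permutations: int = 1000,
    seed: int | None = None,
    weight_fn: WeightFunction = _default_weight_fn,
    work_bound: float = DEFAULT_WORK_BOUND,
) -> DBMResult:
    """DBM test with permutation significance.

    Case/control status is reassigned ``n_permutations`` times with the
    original group sizes maintained and genotypes fixed; the whole
    statistic (weights included — they depend on the labels) is
    recomputed per permutation.  'More extreme' means a combined
    statistic <= the observed one; ties count as extreme.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    obs_results, obs_combined, degenerate = dbm_observed(
        geno, rare, weight_fn=weight_fn, work_bound=work_bound)
    if degenerate:
        return DBMResult(scheme_results=obs_results, combined=obs_combined,
                         pvalue=1.0, n_permutations=n_permutations,
                         seed=seed, degenerate=True)

    labels = geno.phenotype
    n_cases = int(np.sum(labels == 1))
    n_controls = labels.size - n_cases
    positions = geno.positions[rare.indices]
    nn_dist = nearest_neighbor_distances(positions)
    sub = np.ascontiguousarray(geno.genotypes[:, rare.indices])
    totals = sub.sum(axis=0)

    # the proximity factor depends only on positions; precompute it once
    # and keep the default weight function's behaviour bit-identical
    if weight_fn is _default_weight_fn:
        prox = proximity_factor(nn_dist)

        def loop_weight_fn(ref_counts, n_ref, _nn):
            w = frequency_factor(ref_counts, n_ref) * prox
            return w / w.mean()
    else:
        loop_weight_fn = weight_fn

    masks = _permutation_case_masks(labels, n_permutations, seed)
    perm_case_counts = masks @ sub  # (B, k) in one matmul
    n_extreme = 0
    for b in range(n_permutations):
        cc = perm_case_counts[b]
        _, combined_b, _ = _combined_from_counts(
            cc, totals - cc, n_cases, n_controls,
            positions, nn_dist, loop_weight_fn, work_bound,
        )
        if combined_b <= obs_combined:
            n_extreme += 1
    pvalue = (1.0 + n_extreme) / (n_permutations + 1.0)
    return DBMResult(scheme_results=obs_results, combined=obs_combined,
                     pvalue=pvalue, n_permutations=n_permutations, seed=seed)
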