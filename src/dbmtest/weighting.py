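"""Weighted allele-position sequences and inter-allele distance vectors.

The spatial test compares, between cases and controls, the distribution
of base-pair distances between adjacent rare alleles.  Each variant's
allele count is first weighted by a factor that rewards both rarity
(inverse-frequency, estimated in a reference group) and spatial
proximity to other variants (a nearest-neighbor kernel), then rounded
to an integer.  Replicating each variant's position by its weighted
count yields a sorted position sequence per group; consecutive
differences within that sequence are the adjacent-distance vector.
Alleles observed multiple times at one locus contribute zero distances.

Two weighting schemes are run in parallel: one with frequencies taken
from cases (sensitive to risk clusters) and one from controls
(sensitive to protective clusters).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Literal

import numpy as np

from .data_model import RareVariantSet, RegionGenotypes, group_allele_counts

__all__ = [
    "Scheme",
    "WeightedCounts",
    "DistancePair",
    "nearest_neighbor_distances",
    "frequency_factor",
    "proximity_factor",
    "compute_weights",
    "weighted_counts",
    "build_position_sequence",
    "adjacent_distances",
    "distance_pair",
    "round_half_away",
]

Scheme = Literal["case_based", "control_based"]
SCHEMES: tuple[Scheme, Scheme] = ("case_based", "control_based")


@dataclass
class WeightedCounts:
    """Integer weighted allele counts for both groups under one scheme."""

    scheme: str
    case_counts: np.ndarray
    control_counts: np.ndarray


@dataclass
class DistancePair:
    """Adjacent-distance vectors for cases and controls under one scheme.

    ``degenerate`` is set when either group's position sequence has
    fewer than two alleles, leaving no distances to compare.
    """

    scheme: str
    case_distances: np.ndarray
    control_distances: np.ndarray

    @property
    def degenerate(self) -> bool:
        return self.case_distances.size == 0 or self.control_distances.size == 0


def nearest_neighbor_distances(positions: np.ndarray) -> np.ndarray:
    """Distance from each variant to its closest neighbor in the sorted
    position vector.

    For ascending positions p_1 < ... < p_k:
    d_1 = p_2 - p_1, d_k = p_k - p_{k-1}, and for interior j
    d_j = min(p_j - p_{j-1}, p_{j+1} - p_j).
    """
    p = np.asarray(positions, dtype=np.int64)
    if p.size < 2:
        raise ValueError("spatial test undefined for one variant")
    if np.any(np.diff(p) <= 0):
        raise ValueError("positions must be strictly ascending")
    gaps = np.diff(p)
    d = np.empty(p.size, dtype=np.int64)
    d[0] = gaps[0]
    d[-1] = gaps[-1]
    if p.size > 2:
        d[1:-1] = np.minimum(gaps[:-1], gaps[1:])
    return d


def frequency_factor(ref_counts: np.ndarray, n_ref: int) -> np.ndarray:
    """Inverse-frequency factor f_j = 1 / sqrt(q_j (1 - q_j)) with the
    continuity-corrected reference-group frequency
    q_j = (c_j + 1) / (2 n_ref + 2)."""
    q = (np.asarray(ref_counts, dtype=float) + 1.0) / (2.0 * n_ref + 2.0)
    return 1.0 / np.sqrt(q * (1.0 - q))


def proximity_factor(nn_dist: np.ndarray) -> np.ndarray:
    """Proximity factor h_j = m / (d_j + m), m = median nearest-neighbor
    distance; depends only on positions, not on phenotype labels."""
    d = np.asarray(nn_dist, dtype=float)
    m = float(np.median(d))
    return m / (d + m)


def _default_weight_fn(ref_counts: np.ndarray, n_ref: int,
                       nn_dist: np.ndarray) -> np.ndarray:
    """Inverse-frequency × proximity weights, normalized to mean 1."""
    w = frequency_factor(ref_counts, n_ref) * proximity_factor(nn_dist)
    return w / w.mean()


WeightFunction = Callable[[np.ndarray, int, np.ndarray], np.ndarray]


def compute_weights(
    ref_counts: np.ndarray,
    n_ref: int,
    nn_dist: np.ndarray,
    weight_fn: WeightFunction = _default_weight_fn,
) -> np.ndarray:
    """Per-variant weights from the scheme's reference-group allele counts.

    ``ref_counts`` are the rare-allele counts in the reference group
    (cases for the case-based scheme, controls for the control-based
    one); ``n_ref`` is the number of subjects in that group.  The weight
    function is pluggable; the default is documented in
    :func:`_default_weight_fn`.  Weights are strictly positive and
    average 1 over the retained variants.
    """
    ref_counts = np.asarray(ref_counts, dtype=float)
    if ref_counts.size < 2:
        raise ValueError("need at least 2 variants to weight")
    if ref_counts.size != np.asarray(nn_dist).size:
        raise ValueError("counts and nearest-neighbor distances disagree in length")
    w = weight_fn(ref_counts, n_ref, nn_dist)
    if np.any(w <= 0):
        raise ValueError("weight function produced non-positive weights")
    return w


def round_half_away(x: np.ndarray) -> np.ndarray:
    """Round to nearest integer, halves away from zero."""
    x = np.asarray(x, dtype=float)
    return (np.sign(x) * np.floor(np.abs(x) + 0.5)).astype(np.int64)


def weighted_counts(
    case_counts: np.ndarray,
    control_counts: np.ndarray,
    weights: np.ndarray,
    scheme: str,
) -> WeightedCounts:
    """Apply one scheme's weights to both groups and round to integers.

    A variant whose weighted count rounds to 0 simply vanishes from that
    group's position sequence; no floor is imposed.
    """
    return WeightedCounts(
        scheme=scheme,
        case_counts=round_half_away(np.asarray(case_counts) * weights),
        control_counts=round_half_away(np.asarray(control_counts) * weights),
    )


def build_position_sequence(positions: np.ndarray, counts: np.ndarray) -> np.ndarray:
    """Replicate each position by its weighted allele count; sorted output."""
    counts = np.asarray(counts, dtype=np.int64)
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    return np.repeat(np.asarray(positions, dtype=np.int64), counts)


def adjacent_distances(seq: np.ndarray) -> np.ndarray:
    """Consecutive differences within a sorted position sequence.

    Repeated positions yield zeros; a sequence of length < 2 gives an
    empty vector (degenerate for the scale test).
    """
    seq = np.asarray(seq)
    if seq.size < 2:
        return np.empty(0, dtype=np.int64)
    return np.diff(seq)


def distance_pair(
    geno: RegionGenotypes,
    rare: RareVariantSet,
    scheme: Scheme,
    phenotype: np.ndarray | None = None,
    nn_dist: np.ndarray | None = None,
    weight_fn: WeightFunction = _default_weight_fn,
) -> DistancePair:
    """Full weighting pipeline for one scheme: counts -> weights ->
    weighted counts -> position sequences -> adjacent distances.

    Weights are recomputed from the current phenotype labels (pass
    ``phenotype`` to override the stored ones), which is what keeps the
    permutation test exchangeable.  Nearest-neighbor distances depend
    only on positions and may be precomputed and passed in.
    """
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}")
    labels = geno.phenotype if phenotype is None else np.asarray(phenotype)
    case_counts, control_counts, _, _ = group_allele_counts(geno, rare, labels)
    positions = geno.positions[rare.indices]
    if nn_dist is None:
        nn_dist = nearest_neighbor_distances(positions)
    if scheme == "case_based":
        ref_counts, n_ref = case_counts, int(np.sum(labels == 1))
    else:
        ref_counts, n_ref = control_counts, int(np.sum(labels == 0))
    w = compute_weights(ref_counts, n_ref, nn_dist, weight_fn)
    wc = weighted_counts(case_counts, control_counts, w, scheme)
    return DistancePair(
        scheme=scheme,
        case_distances=adjacent_distances(
            build_position_sequence(positions, wc.case_counts)),
        control_distances=adjacent_distances(
            build_position_sequence(positions, wc.control_counts)),
    )
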