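"""Core domain types for region-based rare-variant analysis.

A genomic region is represented as a subjects × variants matrix of
minor-allele counts together with the physical position of each variant
and a binary case/control phenotype.  Dosage data enter as real-valued
expected allele counts and are carried unrounded until the weighting
stage of the test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "RegionGenotypes",
    "RareVariantSet",
    "estimate_maf",
    "filter_rare",
    "group_allele_counts",
    "expected_counts_from_probabilities",
]


@dataclass
class RegionGenotypes:
    """Genotypes of one genomic region in a case-control sample.

    Parameters
    ----------
    positions : ndarray of int
        Base-pair coordinate of each variant, strictly ascending.
    genotypes : ndarray, shape (n_subjects, n_variants)
        Minor-allele count per subject and variant, in [0, 2].  Integer
        for hard calls; real-valued for dosage (expected-count) data.
    phenotype : ndarray of int
        Binary affection status per subject; case = 1, control = 0.
    """

    positions: np.ndarray
    genotypes: np.ndarray
    phenotype: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.genotypes = np.atleast_2d(np.asarray(self.genotypes, dtype=float))
        self.phenotype = np.asarray(self.phenotype, dtype=np.int8)
        if self.positions.ndim != 1:
            raise ValueError("positions must be one-dimensional")
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions not strictly ascending")
        if self.genotypes.shape[1] != self.positions.size:
            raise ValueError(
                f"genotype matrix has {self.genotypes.shape[1]} columns but "
                f"{self.positions.size} positions were given"
            )
        if self.phenotype.size != self.genotypes.shape[0]:
            raise ValueError("phenotype length does not match number of subjects")
        if not np.all(np.isin(self.phenotype, (0, 1))):
            raise ValueError("phenotype must be binary (case=1, control=0)")
        if np.any(self.genotypes < 0) or np.any(self.genotypes > 2):
            raise ValueError("genotype values must lie in [0, 2]")
        if self.n_cases < 1 or self.n_controls < 1:
            raise ValueError("need at least one case and one control")

    @property
    def n_subjects(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_variants(self) -> int:
        return self.genotypes.shape[1]

    @property
    def n_cases(self) -> int:
        return int(np.sum(self.phenotype == 1))

    @property
    def n_controls(self) -> int:
        return int(np.sum(self.phenotype == 0))

    @property
    def case_mask(self) -> np.ndarray:
        return self.phenotype == 1


@dataclass
class RareVariantSet:
    """Indices of variants passing the MAF filter, with their estimates."""

    indices: np.ndarray
    maf: np.ndarray
    threshold: float

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=np.int64)
        self.maf = np.asarray(self.maf, dtype=float)
        if self.indices.size != self.maf.size:
            raise ValueError("indices and maf must have equal length")

    def __len__(self) -> int:
        return int(self.indices.size)


def estimate_maf(geno: RegionGenotypes, orient: bool = True) -> np.ndarray:
    """Pooled per-variant minor-allele frequency.

    frequency_j = (sum of allele counts at variant j) / (2 * n_subjects).

    With ``orient=True`` (default), any variant whose raw frequency
    exceeds 0.5 is re-oriented in place (counts <- 2 - counts) so the
    counted allele is the minor one; re-orientations are logged.
    """
    n2 = 2.0 * geno.n_subjects
    freq = geno.genotypes.sum(axis=0) / n2
    if orient:
        flip = freq > 0.5
        if np.any(flip):
            logger.info("re-orienting %d variant(s) with frequency > 0.5",
                        int(flip.sum()))
            geno.genotypes[:, flip] = 2.0 - geno.genotypes[:, flip]
            freq = geno.genotypes.sum(axis=0) / n2
    return freq


def filter_rare(geno: RegionGenotypes, cutoff: float) -> RareVariantSet:
    """Retain variants with pooled MAF <= cutoff and >= 1 observed minor allele.

    The cutoff is inclusive. An empty result is a warning condition
    (the spatial test then degenerates to p = 1), not an error.
    """
    if not 0.0 < cutoff <= 0.5:
        raise ValueError("cutoff must be in (0, 0.5]")
    maf = estimate_maf(geno)
    keep = (maf <= cutoff) & (maf > 0.0)
    idx = np.flatnonzero(keep)
    if idx.size == 0:
        logger.warning("no variants pass the MAF filter at cutoff %g", cutoff)
    return RareVariantSet(indices=idx, maf=maf[idx], threshold=float(cutoff))


def group_allele_counts(
    geno: RegionGenotypes, rare: RareVariantSet, phenotype: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray, float, float]:
    """Per-variant rare-allele counts in cases and controls, plus group totals.

    ``phenotype`` overrides the stored labels (used by the permutation
    engine, which keeps genotypes fixed and shuffles labels).

    Returns
    -------
    (case_counts, control_counts, case_total, control_total)
    """
    if len(rare) == 0:
        raise ValueError("rare variant set is empty")
    labels = geno.phenotype if phenotype is None else np.asarray(phenotype)
    sub = geno.genotypes[:, rare.indices]
    case_counts = sub[labels == 1].sum(axis=0)
    control_counts = sub[labels == 0].sum(axis=0)
    return case_counts, control_counts, float(case_counts.sum()), float(control_counts.sum())


def expected_counts_from_probabilities(
    p_hom_ref: np.ndarray, p_het: np.ndarray, p_hom_alt: np.ndarray,
    tol: float = 1e-6,
) -> np.ndarray:
    """Expected allele count from genotype probabilities.

    expected = 0*P(hom ref) + 1*P(het) + 2*P(hom alt), elementwise.  The
    three probabilities must be non-negative and sum to 1 within ``tol``.
    """
    p0 = np.asarray(p_hom_ref, dtype=float)
    p1 = np.asarray(p_het, dtype=float)
    p2 = np.asarray(p_hom_alt, dtype=float)
    if p0.shape != p1.shape or p1.shape != p2.shape:
        raise ValueError("probability arrays must share a shape")
    total = p0 + p1 + p2
    bad = (np.abs(total - 1.0) > tol) | (p0 < 0) | (p1 < 0) | (p2 < 0)
    if np.any(bad):
        cell = tuple(int(i) for i in np.argwhere(np.atleast_1d(bad))[0])
        raise ValueError(
            f"genotype probabilities at cell {cell} do not form a distribution"
        )
    return p1 + 2.0 * p2
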