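"""Readers and writers: VCF / tabular genotypes, phenotypes, results."""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np

from .data_model import RegionGenotypes, estimate_maf

logger = logging.getLogger(__name__)

__all__ = [
    "ResultRecord",
    "read_vcf",
    "read_table",
    "read_phenotype",
    "write_results",
    "write_table",
]

# cyvcf2 gt_types codes
_GT_HOM_REF, _GT_HET, _GT_MISSING, _GT_HOM_ALT = 0, 1, 2, 3
_GT_TO_COUNT = np.array([0.0, 1.0, 0.0, 2.0])  # missing counted as 0, logged


@dataclass
class ResultRecord:
    """One analysis result, serializable to TSV and JSON."""

    region: str
    maf_cutoff: float
    n_permutations: int
    combined_statistic: float
    perm_pvalue: float
    case_scheme_statistic: float
    case_scheme_pvalue: float
    control_scheme_statistic: float
    control_scheme_pvalue: float
    seed: int | None

    def __post_init__(self) -> None:
        if not 0.0 < self.perm_pvalue <= 1.0:
            raise ValueError("p-values must lie in (0, 1]")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")


def read_phenotype(path: str | Path) -> tuple[list[str], dict[str, int]]:
    """Phenotype file: one 'subject_id<ws>{0,1}' pair per line.

    Returns (ids in file order, id -> label mapping).
    """
    ids: list[str] = []
    mapping: dict[str, int] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 2 or parts[1] not in ("0", "1"):
            raise ValueError(f"{path}:{lineno}: expected 'id 0|1', got {line!r}")
        ids.append(parts[0])
        mapping[parts[0]] = int(parts[1])
    return ids, mapping


def read_vcf(
    path: str | Path,
    phenotype: Mapping[str, int],
    region: str | None = None,
    dosage_field: str | None = None,
) -> RegionGenotypes:
    """Load a region of biallelic SNVs from a VCF into a count matrix.

    Positions come from the POS column (1-based, as printed); only
    position differences enter the test so no coordinate shifting is
    applied.  Multi-allelic records, non-SNVs and duplicate/unsorted
    positions are skipped with a logged count.  Missing genotypes count
    as 0 minor alleles and are tallied.  With ``dosage_field`` set, the
    per-sample value of that FORMAT field is used as the expected
    allele count instead of the hard GT call.

    Every sample in the VCF must appear in the ``phenotype`` mapping.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = vcf.samples
    missing_pheno = [s for s in samples if s not in phenotype]
    if missing_pheno:
        raise ValueError(
            f"no phenotype for sample(s): {', '.join(missing_pheno[:5])}")
    labels = np.array([phenotype[s] for s in samples], dtype=np.int8)

    columns: list[np.ndarray] = []
    positions: list[int] = []
    n_skipped = 0
    n_missing = 0
    last_pos = -1
    iterator = vcf(region) if region else vcf
    for var in iterator:
        if not var.is_snp or len(var.ALT) != 1:
            n_skipped += 1
            continue
        if var.POS <= last_pos:
            logger.warning("skipping record at %s:%d: position not ascending",
                           var.CHROM, var.POS)
            n_skipped += 1
            continue
        if dosage_field is not None:
            try:
                vals = np.asarray(var.format(dosage_field), dtype=float).reshape(-1)
            except (KeyError, TypeError, ValueError):
                logger.warning("skipping malformed record at %s:%d",
                               var.CHROM, var.POS)
                n_skipped += 1
                continue
            col = np.clip(vals, 0.0, 2.0)
        else:
            gt = np.asarray(var.gt_types)
            n_missing += int(np.sum(gt == _GT_MISSING))
            col = _GT_TO_COUNT[gt]
        columns.append(col)
        positions.append(var.POS)
        last_pos = var.POS
    if n_skipped:
        logger.info("skipped %d record(s) (non-SNV/multi-allelic/malformed)",
                    n_skipped)
    if n_missing:
        logger.info("%d missing genotype call(s) counted as 0 minor alleles",
                    n_missing)
    if not columns:
        raise ValueError(f"no usable biallelic SNV records in {path}")
    geno = RegionGenotypes(
        positions=np.array(positions, dtype=np.int64),
        genotypes=np.column_stack(columns),
        phenotype=labels,
    )
    estimate_maf(geno)  # orient to the minor allele in place
    return geno


def read_table(
    geno_path: str | Path,
    pos_path: str | Path,
    pheno_path: str | Path,
    dosage: bool = False,
) -> RegionGenotypes:
    """Plain-text inputs: whitespace-separated genotype matrix
    (rows = subjects), one position per variant, phenotype file of
    'subject_id {0,1}' rows aligned with the genotype rows."""
    rows: list[list[float]] = []
    for lineno, line in enumerate(Path(geno_path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        try:
            rows.append([float(v) for v in line.split()])
        except ValueError as exc:
            raise ValueError(f"{geno_path}:{lineno}: non-numeric entry") from exc
    if not rows:
        raise ValueError(f"{geno_path}: empty genotype matrix")
    widths = {len(r) for r in rows}
    if len(widths) != 1:
        raise ValueError(f"{geno_path}: ragged rows (widths {sorted(widths)})")
    geno = np.asarray(rows, dtype=float)
    if not dosage:
        bad = ~np.isin(geno, (0.0, 1.0, 2.0))
        if np.any(bad):
            r, c = map(int, np.argwhere(bad)[0])
            raise ValueError(
                f"{geno_path}: entry {geno[r, c]:g} at row {r + 1}, "
                f"column {c + 1} is not an allele count in {{0,1,2}} "
                "(use dosage mode for expected counts)")

    pos_tokens = Path(pos_path).read_text().split()
    try:
        positions = np.array([int(t) for t in pos_tokens], dtype=np.int64)
    except ValueError as exc:
        raise ValueError(f"{pos_path}: non-integer position") from exc
    if positions.size != geno.shape[1]:
        raise ValueError(
            f"{pos_path}: {positions.size} positions for {geno.shape[1]} "
            "genotype columns")
    if np.any(np.diff(positions) <= 0):
        j = int(np.flatnonzero(np.diff(positions) <= 0)[0])
        raise ValueError(f"{pos_path}: positions not ascending at entry {j + 2}")

    ids, mapping = read_phenotype(pheno_path)
    if len(ids) != geno.shape[0]:
        raise ValueError(
            f"{pheno_path}: {len(ids)} phenotype rows for {geno.shape[0]} "
            "genotype rows")
    labels = np.array([mapping[i] for i in ids], dtype=np.int8)
    out = RegionGenotypes(positions=positions, genotypes=geno, phenotype=labels)
    estimate_maf(out)
    return out


def write_table(geno: RegionGenotypes, prefix: str | Path,
                ids: list[str] | None = None) -> None:
    """Emit a RegionGenotypes as the tabular format read_table accepts."""
    prefix = str(prefix)
    fmt = "%g"
    np.savetxt(prefix + ".geno.txt", geno.genotypes, fmt=fmt, delimiter="\t")
    np.savetxt(prefix + ".pos.txt", geno.positions[None, :], fmt="%d",
               delimiter="\t")
    if ids is None:
        ids = [f"S{i + 1}" for i in range(geno.n_subjects)]
    with open(prefix + ".pheno.txt", "w") as fh:
        for sid, lab in zip(ids, geno.phenotype):
            fh.write(f"{sid}\t{int(lab)}\n")


def write_results(records: list[ResultRecord], prefix: str | Path) -> None:
    """One row per analysis; TSV plus a JSON mirror, both carrying the
    seed and configuration for reproducibility."""
    prefix = str(prefix)
    fields = [f.name for f in dataclasses.fields(ResultRecord)]
    with open(prefix + ".tsv", "w") as fh:
        fh.write("\t".join(fields) + "\n")
        for rec in records:
            d = dataclasses.asdict(rec)
            fh.write("\t".join(_fmt(d[f]) for f in fields) + "\n")
    with open(prefix + ".json", "w") as fh:
        json.dump([dataclasses.asdict(r) for r in records], fh, indent=2)
        fh.write("\n")


def read_results(path: str | Path) -> list[ResultRecord]:
    """Re-load results written by :func:`write_results` (JSON form)."""
    with open(path) as fh:
        return [ResultRecord(**d) for d in json.load(fh)]


def _fmt(v) -> str:
    if isinstance(v, float):
        return repr(v)
    return str(v)
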