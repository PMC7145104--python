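"""Locus quality control: missingness, pooled MAF, and map-position filters.

Defaults follow the array-QC recipe the pipeline reproduces: drop loci with
10% or more missing calls, pooled minor-allele frequency of 1% or less, an
unknown map position, or a sex-chromosome assignment.  Boundary semantics
are strict by default (missing fraction strictly below the cap, MAF strictly
above the floor); ``plink_compat=True`` flips both comparisons to the
inclusive semantics of PLINK's ``--geno`` / ``--maf`` for tool comparison.

MAF is computed on the pooled sample — all populations, wild outgroups
included — because filtering precedes any population stratification.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError, EmptyPanelError
from .genotype_io import MISSING, GenotypeDataset, is_autosome


def pooled_allele_frequency(genotypes: np.ndarray) -> np.ndarray:
    """Counted-allele frequency per locus over all non-missing genotypes.

    Loci with no calls get frequency NaN.
    """
    g = np.asarray(genotypes, dtype=float)
    ok = g != MISSING
    calls = ok.sum(axis=0)
    total = np.where(ok, g, 0.0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(calls > 0, total / (2.0 * calls), np.nan)


def minor_allele_frequency(genotypes: np.ndarray) -> np.ndarray:
    """Pooled MAF per locus; NaN-free (no-call loci report MAF 0)."""
    p = pooled_allele_frequency(genotypes)
    p = np.nan_to_num(p, nan=0.0)
    return np.minimum(p, 1.0 - p)


@dataclass
class QCReport:
    """Per-stage locus bookkeeping for one :func:`filter_loci` run."""

    n_input_loci: int
    n_failed_missingness: int
    n_failed_maf: int
    n_failed_position: int
    n_retained: int
    fail_reasons: dict[str, list[str]] = field(default_factory=dict)

    def summary(self) -> str:
        return (
            f"QC: {self.n_input_loci} loci in; "
            f"{self.n_failed_missingness} failed missingness, "
            f"{self.n_failed_maf} failed MAF, "
            f"{self.n_failed_position} failed position/autosome; "
            f"{self.n_retained} retained"
        )

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("locus_id\treason\n")
            for lid, reasons in self.fail_reasons.items():
                for reason in reasons:
                    fh.write(f"{lid}\t{reason}\n")


def filter_loci(
    dataset: GenotypeDataset,
    max_missing_frac: float = 0.10,
    min_maf: float = 0.01,
    autosomes_only: bool = True,
    plink_compat: bool = False,
) -> tuple[GenotypeDataset, QCReport]:
    """Apply locus QC and return the filtered dataset plus a report.

    Retained loci satisfy (strict semantics, the default):

    * missing fraction < ``max_missing_frac``
    * pooled MAF > ``min_maf``
    * known map position (> 0) and, when ``autosomes_only``, a numeric
      autosomal chromosome code

    The sample set and the relative locus order are unchanged.  Raises
    :class:`EmptyPanelError` when nothing survives.
    """
    if dataset.n_loci == 0 or dataset.n_samples == 0:
        raise ConfigError("filter_loci requires a non-empty dataset")
    if not (0 <= max_missing_frac <= 1) or not (0 <= min_maf <= 0.5):
        raise ConfigError("max_missing_frac must be in [0,1], min_maf in [0,0.5]")

    g = dataset.genotypes
    miss_frac = (g == MISSING).mean(axis=0)
    maf = minor_allele_frequency(g)

    if plink_compat:
        ok_miss = miss_frac <= max_missing_frac
        ok_maf = maf >= min_maf
    else:
        ok_miss = miss_frac < max_missing_frac
        ok_maf = maf > min_maf

    pos_known = dataset.loci["position_bp"].to_numpy() > 0
    ok_pos = pos_known.copy()
    if autosomes_only:
        ok_pos &= np.array([is_autosome(c) for c in dataset.loci["chromosome"]])

    keep = ok_miss & ok_maf & ok_pos
    reasons: dict[str, list[str]] = {}
    for j, lid in enumerate(dataset.loci["locus_id"]):
        why = []
        if not ok_miss[j]:
            why.append("missingness")
        if not ok_maf[j]:
            why.append("maf")
        if not ok_pos[j]:
            why.append("position")
        if why:
            reasons[lid] = why

    report = QCReport(
        n_input_loci=dataset.n_loci,
        n_failed_missingness=int((~ok_miss).sum()),
        n_failed_maf=int((~ok_maf).sum()),
        n_failed_position=int((~ok_pos).sum()),
        n_retained=int(keep.sum()),
        fail_reasons=reasons,
    )
    if report.n_retained == 0:
        raise EmptyPanelError("QC removed every locus (empty panel)")
    return dataset.subset_loci(np.flatnonzero(keep)), report
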