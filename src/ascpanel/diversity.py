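"""Observed heterozygosity and inbreeding coefficients.

Per individual *i* over a locus subset:

* ``Ho_i`` — fraction of heterozygous calls among non-missing loci;
* ``F_i = 1 - Ho_i / He_i`` — heterozygosity deficit relative to a reference
  expected heterozygosity ``He_i``, the mean of ``h_l = 2 p_l (1 - p_l)``
  over the loci called in *i*.

The reference frequencies ``p_l`` default to the *pooled* sample (every
population, wild outgroups included).  Under pooled referencing, F mixes
true inbreeding with Wahlund-type divergence from the pooled average, which
is why strongly diverged populations show the largest values; the
``f_reference="within"`` switch recomputes ``p_l`` inside each population
instead, under which F measures departure from within-population
Hardy-Weinberg proportions only.

Population summaries are means and sample standard deviations (n-1
denominator) over member individuals.  F is never clipped: negative values
record an excess of heterozygotes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError
from .genotype_io import MISSING, GenotypeDataset, PopulationPartition
from .qc import pooled_allele_frequency

logger = logging.getLogger("ascpanel")


@dataclass
class PooledFrequencies:
    """Counted-allele frequency and expected heterozygosity per locus."""

    p: np.ndarray           # frequency over all non-missing genotypes
    h: np.ndarray           # 2 p (1 - p)

    @classmethod
    def from_genotypes(cls, genotypes: np.ndarray) -> "PooledFrequencies":
        p = pooled_allele_frequency(genotypes)
        # loci with zero calls carry no expected heterozygosity
        p_filled = np.nan_to_num(p, nan=0.0)
        return cls(p=p, h=2.0 * p_filled * (1.0 - p_filled))

    @classmethod
    def from_dataset(
        cls, dataset: GenotypeDataset, locus_subset: np.ndarray | None = None
    ) -> "PooledFrequencies":
        g = dataset.genotypes
        if locus_subset is not None:
            g = g[:, np.asarray(locus_subset, dtype=int)]
        return cls.from_genotypes(g)


def individual_heterozygosity(
    dataset: GenotypeDataset, locus_subset: np.ndarray
) -> np.ndarray:
    """Per-sample Ho over the subset; NaN for samples fully missing there."""
    locus_subset = np.asarray(locus_subset, dtype=int)
    if locus_subset.size == 0:
        raise ConfigError("locus_subset must be non-empty")
    g = dataset.genotypes[:, locus_subset]
    ok = g != MISSING
    n_called = ok.sum(axis=1)
    n_het = (g == 1).sum(axis=1)
    if (n_called == 0).any():
        logger.warning(
            "%d sample(s) have no calls on the subset; Ho undefined (NaN)",
            int((n_called == 0).sum()),
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(n_called > 0, n_het / n_called, np.nan)


def individual_inbreeding(
    dataset: GenotypeDataset,
    locus_subset: np.ndarray,
    freqs: PooledFrequencies,
) -> np.ndarray:
    """Per-sample F = 1 - Ho_i/He_i against the given reference frequencies.

    ``freqs`` must align with ``locus_subset`` (``freqs.h[k]`` refers to
    ``locus_subset[k]``).  Samples whose called loci are all
    reference-monomorphic (He_i = 0) get NaN with a warning.
    """
    locus_subset = np.asarray(locus_subset, dtype=int)
    if freqs.h.shape[0] != locus_subset.size:
        raise ConfigError("freqs do not align with locus_subset")
    ho = individual_heterozygosity(dataset, locus_subset)
    ok = dataset.genotypes[:, locus_subset] != MISSING
    n_called = ok.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        he = np.where(n_called > 0, (ok * freqs.h).sum(axis=1) / n_called, np.nan)
    undef = (he == 0) & np.isfinite(he)
    if undef.any():
        logger.warning(
            "%d sample(s) have He=0 on the subset; F undefined (NaN)", int(undef.sum())
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        f = 1.0 - ho / he
    f[undef] = np.nan
    return f


@dataclass
class DiversityTable:
    """Per-individual and per-population diversity summaries."""

    per_individual: pd.DataFrame   # sample_id, population_id, n_loci_used, ho, f
    per_population: pd.DataFrame   # population_id, group, n, ho_mean, ho_sd, f_mean, f_sd

    def to_tsv(self, path) -> None:
        self.per_population.to_csv(path, sep="\t", index=False, float_format="%.6g")


def population_diversity(
    dataset: GenotypeDataset,
    partition: PopulationPartition,
    locus_subset: np.ndarray,
    f_reference: str = "pooled",
) -> DiversityTable:
    """Build the per-population Ho/F table over a locus subset.

    ``f_reference`` selects the expected-heterozygosity reference for F:
    ``"pooled"`` (all samples, the default) or ``"within"`` (each
    population's own frequencies).  Individuals with undefined Ho or F are
    excluded from the corresponding population mean with a warning;
    populations with zero usable individuals are omitted.
    """
    if f_reference not in ("pooled", "within"):
        raise ConfigError(f"f_reference must be 'pooled' or 'within', got {f_reference!r}")
    locus_subset = np.asarray(locus_subset, dtype=int)

    ho = individual_heterozygosity(dataset, locus_subset)
    if f_reference == "pooled":
        freqs = PooledFrequencies.from_dataset(dataset, locus_subset)
        f = individual_inbreeding(dataset, locus_subset, freqs)
    else:
        f = np.full(dataset.n_samples, np.nan)
        for pop, members in partition.populations.items():
            sub = dataset.genotypes[np.asarray(members)][:, locus_subset]
            freqs = PooledFrequencies.from_genotypes(sub)
            f_pop = individual_inbreeding(dataset, locus_subset, freqs)
            f[np.asarray(members)] = f_pop[np.asarray(members)]

    n_used = (dataset.genotypes[:, locus_subset] != MISSING).sum(axis=1)
    per_ind = pd.DataFrame(
        {
            "sample_id": dataset.samples["sample_id"],
            "population_id": dataset.samples["population_id"],
            "n_loci_used": n_used,
            "ho": ho,
            "f": f,
        }
    )

    rows = []
    for pop, members in partition.populations.items():
        members = np.asarray(members)
        ho_m, f_m = ho[members], f[members]
        usable = np.isfinite(ho_m)
        if not usable.any():
            logger.warning("population %r has no usable individuals; row omitted", pop)
            continue
        ho_u = ho_m[usable]
        f_u = f_m[np.isfinite(f_m)]
        rows.append(
            {
                "population_id": pop,
                "group": partition.group_of(pop),
                "n": int(members.size),
                "ho_mean": float(ho_u.mean()),
                "ho_sd": float(ho_u.std(ddof=1)) if ho_u.size > 1 else np.nan,
                "f_mean": float(f_u.mean()) if f_u.size else np.nan,
                "f_sd": float(f_u.std(ddof=1)) if f_u.size > 1 else np.nan,
            }
        )
    return DiversityTable(per_individual=per_ind, per_population=pd.DataFrame(rows))


def population_ho(
    dataset: GenotypeDataset,
    partition: PopulationPartition,
    locus_subset: np.ndarray,
) -> dict[str, float]:
    """Population-level Ho (mean of member Ho_i) — the permutation statistic."""
    ho = individual_heterozygosity(dataset, locus_subset)
    out = {}
    for pop, members in partition.populations.items():
        vals = ho[np.asarray(members)]
        vals = vals[np.isfinite(vals)]
        out[pop] = float(vals.mean()) if vals.size else float("nan")
    return out
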