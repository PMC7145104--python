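"""Permutation null for panel effects on heterozygosity.

Does a candidate panel (here: the ancestral, outgroup-polymorphic subset)
shift population-level Ho beyond what an equally sized random subset of the
full array would give?  The null is built by drawing, without replacement,
``m`` loci from the full panel per replicate — one draw shared by every
population within a replicate, since it is the panel that is resampled, not
the population data — and recomputing each population's Ho.  The empirical
p-value follows the resampling convention

    pval = (1 + r) / (1 + n)

with ``r`` the number of null values greater than or equal to the observed
one (ties count as exceedances) and ``n`` the number of permutations.  The
minimum attainable p-value is therefore 1/(1+n), never zero.

Per-replicate random streams are derived from (seed, replicate-index)
counters, so results do not depend on execution order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import ConfigError
from .genotype_io import MISSING, GenotypeDataset, PopulationPartition
from .diversity import population_ho

logger = logging.getLogger("ascpanel")


def empirical_pvalue(observed: float, null: np.ndarray) -> float:
    """(1+r)/(1+n) with r = #{null_j >= observed}; raises on an empty null."""
    null = np.asarray(null, dtype=float)
    if null.size == 0:
        raise ConfigError("empirical_pvalue requires a non-empty null distribution")
    r = int((null >= observed).sum())
    return (1 + r) / (1 + null.size)


def permutation_null(
    dataset: GenotypeDataset,
    partition: PopulationPartition,
    full_panel: np.ndarray,
    m: int,
    n_perm: int = 1000,
    seed: int = 0,
    per_population: bool = False,
) -> dict[str, np.ndarray]:
    """Null Ho distributions from ``n_perm`` draws of ``m`` loci each.

    Returns population_id -> array of length ``n_perm``.  Each replicate
    draws ``m`` distinct loci uniformly from ``full_panel`` (shared across
    populations by default; ``per_population=True`` redraws the subset for
    each population within a replicate) and computes population Ho as the
    mean of member individuals' heterozygous-call fractions.
    """
    full_panel = np.asarray(full_panel, dtype=int)
    if n_perm < 1:
        raise ConfigError("n_perm must be >= 1")
    if m > full_panel.size:
        raise ConfigError(f"cannot draw m={m} loci from a panel of {full_panel.size}")
    if m < 1:
        raise ConfigError("m must be >= 1")
    if m == full_panel.size:
        logger.warning(
            "m equals the full panel size: the permutation null is degenerate "
            "(every replicate draws the whole panel)"
        )

    g = dataset.genotypes[:, full_panel]
    het = (g == 1).astype(np.int32)
    ok = (g != MISSING).astype(np.int32)

    members = {pop: np.asarray(idx) for pop, idx in partition.populations.items()}
    null = {pop: np.empty(n_perm) for pop in partition.populations}

    def pop_ho(cols: np.ndarray, idx: np.ndarray) -> float:
        n_het = het[np.ix_(idx, cols)].sum(axis=1)
        n_ok = ok[np.ix_(idx, cols)].sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            vals = np.where(n_ok > 0, n_het / n_ok, np.nan)
        vals = vals[np.isfinite(vals)]
        return float(vals.mean()) if vals.size else float("nan")

    for rep in range(n_perm):
        rng = np.random.default_rng([seed, rep])
        if per_population:
            for pop, idx in members.items():
                cols = rng.choice(full_panel.size, size=m, replace=False)
                null[pop][rep] = pop_ho(cols, idx)
        else:
            cols = rng.choice(full_panel.size, size=m, replace=False)
            n_het = het[:, cols].sum(axis=1)
            n_ok = ok[:, cols].sum(axis=1)
            with np.errstate(invalid="ignore", divide="ignore"):
                ho_i = np.where(n_ok > 0, n_het / n_ok, np.nan)
            for pop, idx in members.items():
                vals = ho_i[idx]
                vals = vals[np.isfinite(vals)]
                null[pop][rep] = vals.mean() if vals.size else np.nan
    return null


@dataclass
class PermutationResult:
    """Permutation-test outcome for one population."""

    population_id: str
    m: int
    n: int
    null: np.ndarray
    observed_ancestral: float
    observed_full: float
    r: int
    pval: float                 # p-value of the ancestral-panel Ho
    pval_full: float            # same null, full-panel Ho as the observed value

    def __post_init__(self) -> None:
        assert 0 <= self.r <= self.n
        assert 0.0 < self.pval <= 1.0


def run_permutation_test(
    dataset: GenotypeDataset,
    partition: PopulationPartition,
    full_panel: np.ndarray,
    ancestral_panel: np.ndarray,
    n_perm: int = 1000,
    seed: int = 0,
    per_population: bool = False,
) -> dict[str, PermutationResult]:
    """Full test: null from the array panel, observed Ho on both panels."""
    full_panel = np.asarray(full_panel, dtype=int)
    ancestral_panel = np.asarray(ancestral_panel, dtype=int)
    m = ancestral_panel.size
    null = permutation_null(dataset, partition, full_panel, m, n_perm, seed,
                            per_population=per_population)
    obs_anc = population_ho(dataset, partition, ancestral_panel)
    obs_full = population_ho(dataset, partition, full_panel)

    results = {}
    for pop in partition.populations:
        r = int((null[pop] >= obs_anc[pop]).sum())
        results[pop] = PermutationResult(
            population_id=pop,
            m=m,
            n=n_perm,
            null=null[pop],
            observed_ancestral=obs_anc[pop],
            observed_full=obs_full[pop],
            r=r,
            pval=empirical_pvalue(obs_anc[pop], null[pop]),
            pval_full=empirical_pvalue(obs_full[pop], null[pop]),
        )
    return results


def results_to_tsv(results: dict[str, PermutationResult], path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "population\tm\tn\tobserved_ancestral\tobserved_full\tnull_mean\tr\tpval\tpval_full\n"
        )
        for pop, res in results.items():
            fh.write(
                f"{pop}\t{res.m}\t{res.n}\t{res.observed_ancestral:.6g}\t"
                f"{res.observed_full:.6g}\t{np.nanmean(res.null):.6g}\t"
                f"{res.r}\t{res.pval:.6g}\t{res.pval_full:.6g}\n"
            )
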