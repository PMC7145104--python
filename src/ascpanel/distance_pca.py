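"""Population distances (Reynolds' coancestry) and sample-level PCA.

Reynolds' least-squares coancestry distance between two populations, for
biallelic loci with counted-allele frequencies ``p1, p2`` (``q = 1 - p``):

    theta = sum_l (p1_l - p2_l)^2 / sum_l (1 - p1_l p2_l - q1_l q2_l)

summed over loci with defined frequencies in both populations.  The default
is the frequency-only estimator; ``corrected=True`` switches to the
small-sample-corrected least-squares estimator of Reynolds, Weir &
Cockerham, which subtracts the within-population sampling variance using
the per-locus sample sizes.  theta is not linearised (-ln(1-theta) is NOT
applied).  Distance matrices are exported in PHYLIP square format or as a
NEXUS DISTANCES block for SplitsTree-style network rendering.

PCA follows the variance-standardised genotype convention: each locus
column is mean-imputed, centred by ``2p`` and scaled by ``sqrt(2p(1-p))``
with pooled ``p``, then the scores are taken from the singular value
decomposition.  Component signs are fixed by making the largest-magnitude
locus loading positive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import AscPanelError, ConfigError
from .genotype_io import (
    MISSING,
    GenotypeDataset,
    PopulationPartition,
    sanitize_label,
)


@dataclass
class PopulationAlleleFrequencies:
    """Per-population counted-allele frequencies on a locus subset."""

    population_ids: list[str]
    freqs: np.ndarray       # (n_pops, n_loci), NaN where a population has no calls
    counts: np.ndarray      # (n_pops, n_loci) diploid individuals with calls

    @classmethod
    def from_dataset(
        cls,
        dataset: GenotypeDataset,
        partition: PopulationPartition,
        locus_subset: np.ndarray | None = None,
    ) -> "PopulationAlleleFrequencies":
        g = dataset.genotypes
        if locus_subset is not None:
            g = g[:, np.asarray(locus_subset, dtype=int)]
        pops = partition.population_ids
        freqs = np.empty((len(pops), g.shape[1]))
        counts = np.empty((len(pops), g.shape[1]), dtype=int)
        for k, pop in enumerate(pops):
            sub = g[np.asarray(partition.populations[pop]), :].astype(float)
            ok = sub != MISSING
            n = ok.sum(axis=0)
            tot = np.where(ok, sub, 0.0).sum(axis=0)
            with np.errstate(invalid="ignore", divide="ignore"):
                freqs[k] = np.where(n > 0, tot / (2.0 * n), np.nan)
            counts[k] = n
        return cls(population_ids=pops, freqs=freqs, counts=counts)

    def index_of(self, pop: str) -> int:
        try:
            return self.population_ids.index(pop)
        except ValueError:
            raise ConfigError(f"unknown population {pop!r}") from None


def reynolds_distance(
    freqs: PopulationAlleleFrequencies,
    pop_a: str,
    pop_b: str,
    corrected: bool = False,
) -> float:
    """Reynolds' coancestry distance between two populations; in [0, 1]."""
    ia, ib = freqs.index_of(pop_a), freqs.index_of(pop_b)
    p1, p2 = freqs.freqs[ia], freqs.freqs[ib]
    shared = np.isfinite(p1) & np.isfinite(p2)
    if corrected:
        # small-sample corrections need >= 2 individuals per population
        shared &= (freqs.counts[ia] >= 2) & (freqs.counts[ib] >= 2)
    if not shared.any():
        raise AscPanelError(f"no shared loci between {pop_a!r} and {pop_b!r}")
    p1, p2 = p1[shared], p2[shared]
    q1, q2 = 1.0 - p1, 1.0 - p2

    if not corrected:
        num = ((p1 - p2) ** 2).sum()
        den = (1.0 - p1 * p2 - q1 * q2).sum()
        return float(num / den) if den > 0 else 0.0

    n1 = freqs.counts[ia][shared].astype(float)
    n2 = freqs.counts[ib][shared].astype(float)
    # unbiased within-population gene diversities
    h1 = 2.0 * n1 * (1.0 - p1**2 - q1**2) / (2.0 * n1 - 1.0)
    h2 = 2.0 * n2 * (1.0 - p2**2 - q2**2) / (2.0 * n2 - 1.0)
    d2 = (p1 - p2) ** 2                      # = 0.5 * sum over alleles
    samp = (n1 * h1 + n2 * h2) / (4.0 * n1 * n2 * (n1 + n2 - 1.0))
    num = (d2 - (n1 + n2) * samp).sum()
    den = (d2 + (4.0 * n1 * n2 - n1 - n2) * samp).sum()
    if den <= 0:
        return 0.0
    return float(min(max(num / den, 0.0), 1.0))


@dataclass
class DistanceMatrix:
    labels: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.labels), len(self.labels)):
            raise ConfigError("matrix shape does not match labels")
        if not np.isfinite(m).all():
            raise AscPanelError("distance matrix has non-finite entries")
        if not np.allclose(m, m.T) or not np.allclose(np.diag(m), 0.0):
            raise AscPanelError("distance matrix must be symmetric with zero diagonal")
        self.matrix = m


def distance_matrix(
    freqs: PopulationAlleleFrequencies, corrected: bool = False
) -> DistanceMatrix:
    """All-pairs Reynolds distances, computed once per unordered pair."""
    pops = freqs.population_ids
    if len(pops) < 2:
        raise ConfigError("distance_matrix requires >= 2 populations")
    m = np.zeros((len(pops), len(pops)))
    for i in range(len(pops)):
        for j in range(i + 1, len(pops)):
            try:
                d = reynolds_distance(freqs, pops[i], pops[j], corrected=corrected)
            except AscPanelError as exc:
                raise AscPanelError(f"pair ({pops[i]}, {pops[j]}): {exc}") from exc
            m[i, j] = m[j, i] = d
    return DistanceMatrix(labels=list(pops), matrix=m)


def export_distance(matrix: DistanceMatrix, path, format: str = "phylip") -> None:
    """Write a distance matrix as PHYLIP (square) or NEXUS (DISTANCES block)."""
    labels = [sanitize_label(lb) for lb in matrix.labels]
    if any(not lb for lb in labels):
        raise ConfigError("empty population label")
    if len(set(labels)) != len(labels):
        raise ConfigError(f"label collision after sanitization: {labels}")

    n = len(labels)
    if format == "phylip":
        width = max(10, max(len(lb) for lb in labels) + 2)
        with open(path, "w") as fh:
            fh.write(f"{n}\n")
            for i, lb in enumerate(labels):
                row = " ".join(f"{matrix.matrix[i, j]:.6f}" for j in range(n))
                fh.write(f"{lb:<{width}}{row}\n")
    elif format == "nexus":
        with open(path, "w") as fh:
            fh.write("#NEXUS\n\n")
            fh.write("BEGIN TAXA;\n")
            fh.write(f"    DIMENSIONS NTAX={n};\n")
            fh.write("    TAXLABELS " + " ".join(labels) + ";\nEND;\n\n")
            fh.write("BEGIN DISTANCES;\n")
            fh.write(f"    DIMENSIONS NTAX={n};\n")
            fh.write("    FORMAT TRIANGLE=BOTH DIAGONAL LABELS=LEFT;\n")
            fh.write("    MATRIX\n")
            for i, lb in enumerate(labels):
                row = " ".join(f"{matrix.matrix[i, j]:.6f}" for j in range(n))
                fh.write(f"        {lb} {row}\n")
            fh.write("    ;\nEND;\n")
    else:
        raise ConfigError(f"unknown distance format {format!r} (phylip or nexus)")


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

@dataclass
class PCAResult:
    eigenvalues: np.ndarray          # of the sample covariance, descending
    variance_explained: np.ndarray   # proportions, descending, sum <= 1
    scores: pd.DataFrame             # sample_id, population_id, PC1..PCk
    loadings: np.ndarray             # (k, n_loci) right singular vectors


def pca(
    dataset: GenotypeDataset,
    locus_subset: np.ndarray | None = None,
    n_components: int = 10,
) -> PCAResult:
    """Variance-standardised genotype PCA with per-locus mean imputation."""
    if dataset.n_samples < 2:
        raise ConfigError("pca requires >= 2 samples")
    g = dataset.genotypes
    if locus_subset is not None:
        g = g[:, np.asarray(locus_subset, dtype=int)]
    if g.shape[1] < 2:
        raise ConfigError("pca requires >= 2 loci")

    g = g.astype(float)
    ok = g != MISSING
    n = ok.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, np.where(ok, g, 0.0).sum(axis=0) / (2.0 * n), 0.0)
    g = np.where(ok, g, 2.0 * p)          # mean imputation
    scale = np.sqrt(2.0 * p * (1.0 - p))
    mono = scale == 0.0
    scale[mono] = 1.0                      # monomorphic columns contribute zeros
    x = (g - 2.0 * p) / scale
    if mono.all() or not np.any(x):
        raise AscPanelError("zero-variance panel: PCA undefined")

    u, s, vt = np.linalg.svd(x, full_matrices=False)
    k = min(n_components, int((s > 1e-9 * s[0]).sum()))
    u, s, vt = u[:, :k], s[:k], vt[:k]

    # deterministic sign: largest-magnitude loading positive (first on ties)
    for c in range(k):
        jmax = int(np.argmax(np.abs(vt[c])))
        if vt[c, jmax] < 0:
            vt[c] *= -1.0
            u[:, c] *= -1.0

    scores = u * s
    eig = s**2 / (dataset.n_samples - 1)
    var_exp = s**2 / (x**2).sum()
    df = pd.DataFrame(
        {
            "sample_id": dataset.samples["sample_id"],
            "population_id": dataset.samples["population_id"],
        }
    )
    for c in range(k):
        df[f"PC{c + 1}"] = scores[:, c]
    return PCAResult(eigenvalues=eig, variance_explained=var_exp, scores=df, loadings=vt)
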