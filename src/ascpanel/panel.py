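"""Reduced-ascertainment-bias panel construction.

Two steps, run after QC in this order:

1. *Ancestral selection* — keep array loci that are polymorphic within at
   least one named wild outgroup population considered alone.  A variant
   segregating both in domestic cattle and in banteng or gaur most likely
   predates the species split, so the subset is depleted of the
   discovery-panel bias that array design imprints on the full chip.
2. *LD pruning* — greedy windowed pruning of the selected loci so that no
   retained pair within a physical window exceeds an r-squared threshold
   (defaults mirror ``--indep-pairwise 2000kb 10 0.2``: 2000 kb window,
   step of 10 variants, threshold 0.2).

r-squared is the squared Pearson correlation of genotype dosages
(composite LD) over samples non-missing at both loci; it needs no phase
information.  Within a violating pair the locus with the lower pooled MAF
is removed (ties: the one later in map order) — deterministic, and keeps
the more informative variant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError
from .genotype_io import MISSING, GenotypeDataset, PopulationPartition
from .qc import minor_allele_frequency


@dataclass
class PanelSelection:
    """Staged locus subsets with the parameters that produced them.

    Stages nest: ``ld_pruned_retained`` is a subset of ``ancestral`` which is
    a subset of ``qc_pass``.
    """

    qc_pass: list[str]
    ancestral: list[str]
    ld_pruned_retained: list[str]
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        qc, anc = set(self.qc_pass), set(self.ancestral)
        if not anc.issubset(qc) or not set(self.ld_pruned_retained).issubset(anc):
            raise ConfigError("panel stages must nest: pruned ⊆ ancestral ⊆ qc_pass")

    def stage_of(self, locus_id: str) -> str:
        if locus_id in set(self.ld_pruned_retained):
            return "ld_pruned_retained"
        if locus_id in set(self.ancestral):
            return "ancestral"
        return "qc_pass"

    def to_tsv(self, path) -> None:
        pruned, anc = set(self.ld_pruned_retained), set(self.ancestral)
        with open(path, "w") as fh:
            fh.write("locus_id\tstage\n")
            for lid in self.qc_pass:
                stage = (
                    "ld_pruned_retained" if lid in pruned
                    else "ancestral" if lid in anc
                    else "qc_pass"
                )
                fh.write(f"{lid}\t{stage}\n")


def select_ancestral(
    dataset: GenotypeDataset,
    partition: PopulationPartition,
    outgroup_ids: list[str],
) -> np.ndarray:
    """Indices of loci polymorphic within at least one outgroup population.

    A locus qualifies through an outgroup iff both alleles are observed among
    that population's non-missing genotypes (any heterozygote, or both
    homozygote classes).  Hybrid populations are never consulted unless
    explicitly listed.
    """
    unknown = [p for p in outgroup_ids if p not in partition.populations]
    if unknown:
        raise ConfigError(f"unknown outgroup population(s): {unknown}")
    if not outgroup_ids:
        raise ConfigError("at least one outgroup population is required")

    qualifies = np.zeros(dataset.n_loci, dtype=bool)
    for pop in outgroup_ids:
        g = dataset.genotypes[partition.populations[pop], :]
        ok = g != MISSING
        has_het = ((g == 1) & ok).any(axis=0)
        has_a = ((g >= 1) & ok).any(axis=0)
        has_b = ((g <= 1) & ok).any(axis=0)
        qualifies |= has_het | (has_a & has_b)
    return np.flatnonzero(qualifies)


def pairwise_r2(g1: np.ndarray, g2: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors, complete pairs only.

    Returns 0.0 ("no constraint") when fewer than two complete pairs remain
    or either locus is monomorphic on the complete-pairs subset.
    """
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    if g1.shape != g2.shape:
        raise ConfigError("dosage vectors must have equal length")
    ok = (g1 != MISSING) & (g2 != MISSING)
    x, y = g1[ok], g2[ok]
    if x.size < 2:
        return 0.0
    x = x - x.mean()
    y = y - y.mean()
    sxx, syy = (x * x).sum(), (y * y).sum()
    if sxx == 0.0 or syy == 0.0:
        return 0.0
    r = (x * y).sum() / np.sqrt(sxx * syy)
    return min(float(r * r), 1.0)


def _resolve_window(
    retained: np.ndarray,
    window_members: np.ndarray,
    genotypes: np.ndarray,
    maf: np.ndarray,
    r2_threshold: float,
    r2_cache: dict,
) -> None:
    """Drop loci from ``retained`` until no pair in the window violates r2."""
    while True:
        live = [j for j in window_members if retained[j]]
        worst, worst_r2 = None, r2_threshold
        for a_i in range(len(live)):
            for b_i in range(a_i + 1, len(live)):
                a, b = live[a_i], live[b_i]
                key = (a, b)
                r2 = r2_cache.get(key)
                if r2 is None:
                    r2 = pairwise_r2(genotypes[:, a], genotypes[:, b])
                    r2_cache[key] = r2
                if r2 > worst_r2:
                    worst, worst_r2 = (a, b), r2
        if worst is None:
            return
        a, b = worst
        # removal rule: lower pooled MAF; tie -> later map order
        if maf[a] < maf[b] or (maf[a] == maf[b] and a > b):
            retained[a] = False
        else:
            retained[b] = False


def ld_prune(
    dataset: GenotypeDataset,
    window_kb: float = 2000,
    step_count: int = 10,
    r2_threshold: float = 0.2,
    locus_subset: np.ndarray | None = None,
) -> np.ndarray:
    """Greedy windowed LD pruning; returns retained locus indices.

    Windows are physical (``window_kb`` from the anchor locus, never spanning
    chromosomes); the anchor advances by ``step_count`` variants.  After the
    stepped pass an audit loop resolves any residual violating pair with the
    same removal rule, so the post-condition — no retained pair within
    ``window_kb`` with r2 above the threshold — holds unconditionally.
    """
    if window_kb <= 0 or step_count <= 0 or r2_threshold <= 0:
        raise ConfigError("window_kb, step_count and r2_threshold must be positive")

    if locus_subset is None:
        subset = np.arange(dataset.n_loci)
    else:
        subset = np.asarray(locus_subset, dtype=int)
    if subset.size == 0:
        return subset

    window_bp = int(window_kb * 1000)
    chroms = dataset.loci["chromosome"].to_numpy()[subset]
    pos = dataset.loci["position_bp"].to_numpy()[subset]
    maf = minor_allele_frequency(dataset.genotypes[:, subset])
    g = dataset.genotypes[:, subset]

    retained = np.ones(subset.size, dtype=bool)
    r2_cache: dict = {}

    for chrom in pd_unique(chroms):
        idx = np.flatnonzero(chroms == chrom)  # already in map order
        s = 0
        while s < idx.size:
            anchor = idx[s]
            in_win = idx[(pos[idx] >= pos[anchor]) & (pos[idx] <= pos[anchor] + window_bp)]
            in_win = in_win[in_win >= anchor]
            _resolve_window(retained, in_win, g, maf, r2_threshold, r2_cache)
            s += step_count

        # audit: anchor at every locus until a full within-window scan is clean
        dirty = True
        while dirty:
            dirty = False
            for a_i, a in enumerate(idx):
                if not retained[a]:
                    continue
                win = idx[(idx > a) & (pos[idx] - pos[a] <= window_bp)]
                before = retained[win].sum() + 1
                _resolve_window(retained, np.concatenate(([a], win)), g, maf,
                                r2_threshold, r2_cache)
                if retained[win].sum() + retained[a] < before:
                    dirty = True
    return subset[retained]


def pd_unique(values: np.ndarray) -> np.ndarray:
    """Unique values in order of first appearance (map order)."""
    seen: dict = {}
    for v in values:
        seen.setdefault(v, None)
    return np.array(list(seen))
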