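"""Synthetic genotype data with array-style ascertainment and exact truth.

The generator emulates the statistical structure the pipeline assumes:

* a hierarchy of populations drifting away from a common ancestral gene
  pool — shallowly diverged *discovery-clade* populations (the breeds the
  array was designed on), more diverged domestic populations, an admixed
  feral-like population, and deeply diverged wild outgroups;
* an array whose loci were *ascertained* as common variants in a separate
  discovery sample drawn from the discovery clade, reproducing the bias
  that depresses heterozygosity in diverged populations.

Loci come in two classes.  *Ancestral polymorphisms* predate every split:
the root frequency is drawn from a bounded uniform law and drifts down the
hierarchy under the Balding-Nichols model — a daughter frequency is
Beta-distributed around its parent frequency ``p`` with variance
``F p (1-p)``, the divergence parameter ``F`` playing the role of drift
time.  *Young variants* arose after divergence: each is private to one
clade (polymorphic there, absent everywhere else).  The young class is
what makes array ascertainment genuinely biased: discovery-clade young
variants are common where the array was designed and carry zero
heterozygosity in every other population, while wild-lineage young
variants never reach the array at all.  Without it, conditioning on
discovery-sample MAF can only shift the ancestral frequency law toward
intermediate values and would *raise* every population's heterozygosity.

Genotypes are Binomial(2, p_pop) per individual and locus
(within-population Hardy-Weinberg); loci are mutually independent unless
the block-copy knob plants correlated duplicates to exercise LD pruning.
Every population's true allele frequencies are retained, so expected
heterozygosity on any locus subset is available in closed form for
recovery tests.

The default layout mirrors, at reduced scale, a cattle-array study design:
three discovery-clade populations (F ~ 0.03), two mid-divergence domestic
populations (F ~ 0.10), one feral population drawing most of its ancestry
from the discovery clade and the rest from the wild species, and two wild
outgroups (F ~ 0.35), 10-24 samples each, 20,000 genome-wide loci spread
over 29 autosomes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import AscPanelError, ConfigError
from .genotype_io import MISSING, GenotypeDataset

# named substreams of the master seed
_STREAM_FREQS = 0
_STREAM_GENOTYPES = 1
_STREAM_DISCOVERY = 2
_STREAM_MISSING = 3


@dataclass
class PopulationSpec:
    population_id: str
    clade: str
    f_pop: float                 # drift below the clade (or admixture mix)
    n_samples: int
    group: str = "unknown"
    #: optional clade -> weight mixture replacing the single-clade parent
    admixture: dict[str, float] | None = None


@dataclass
class SimulationConfig:
    seed: int = 0
    n_loci: int = 20_000
    freq_low: float = 0.05
    freq_high: float = 0.95
    clades: dict[str, float] = field(default_factory=dict)   # clade -> F from root
    populations: list[PopulationSpec] = field(default_factory=list)
    discovery_populations: list[str] = field(default_factory=list)
    discovery_sample_size: int = 30
    discovery_maf_cutoff: float = 0.05
    missing_rate: float = 0.01
    n_chromosomes: int = 29
    chromosome_length_bp: int = 100_000_000
    #: fraction of loci that are post-divergence, clade-private variants
    young_frac: float = 0.0
    #: frequency band of a young variant within its clade of origin
    young_freq_low: float = 0.10
    young_freq_high: float = 0.40
    #: clade -> probability that a young variant originates there
    young_clade_weights: dict[str, float] = field(default_factory=dict)
    #: optional clade -> (lo, hi) band override; variants on longer (older)
    #: branches have had more time to drift upward in frequency
    young_clade_bands: dict[str, tuple[float, float]] = field(default_factory=dict)
    #: fraction of loci duplicated as high-LD neighbours (0 = independent loci)
    ld_pair_frac: float = 0.0
    #: per-genotype resampling probability within a duplicated pair
    ld_pair_noise: float = 0.05

    def validate(self) -> None:
        if not self.populations:
            raise ConfigError("no populations configured")
        if not (0 <= self.freq_low < self.freq_high <= 1):
            raise ConfigError("ancestral frequency bounds must satisfy 0<=lo<hi<=1")
        pop_ids = [p.population_id for p in self.populations]
        if len(set(pop_ids)) != len(pop_ids):
            raise ConfigError("duplicate population_id in layout")
        for p in self.populations:
            if p.n_samples < 1:
                raise ConfigError(f"{p.population_id}: n_samples must be >= 1")
            if not (0 <= p.f_pop < 1):
                raise ConfigError(f"{p.population_id}: f_pop must be in [0,1)")
            clades = p.admixture or {p.clade: 1.0}
            for c in clades:
                if c not in self.clades:
                    raise ConfigError(f"{p.population_id}: unknown clade {c!r}")
        for c, f in self.clades.items():
            if not (0 <= f < 1):
                raise ConfigError(f"clade {c!r}: F must be in [0,1)")
        missing_disc = set(self.discovery_populations) - set(pop_ids)
        if missing_disc:
            raise ConfigError(f"discovery populations not in layout: {sorted(missing_disc)}")
        if not (0 <= self.missing_rate < 1):
            raise ConfigError("missing_rate must be in [0,1)")
        if not (0 <= self.ld_pair_frac <= 0.5):
            raise ConfigError("ld_pair_frac must be in [0,0.5]")
        if not (0 <= self.young_frac < 1):
            raise ConfigError("young_frac must be in [0,1)")
        if not (0 < self.young_freq_low < self.young_freq_high <= 1):
            raise ConfigError("young frequency band must satisfy 0<lo<hi<=1")
        if self.young_frac > 0:
            bad = set(self.young_clade_weights) - set(self.clades)
            if bad:
                raise ConfigError(f"young_clade_weights name unknown clades: {sorted(bad)}")
            if not self.young_clade_weights or sum(self.young_clade_weights.values()) <= 0:
                raise ConfigError("young_frac > 0 needs positive young_clade_weights")


def default_config(seed: int = 0, **overrides) -> SimulationConfig:
    """The study-design default layout (see module docstring)."""
    cfg = SimulationConfig(
        seed=seed,
        clades={"discovery": 0.03, "domestic": 0.10, "wild_a": 0.35, "wild_b": 0.35},
        populations=[
            PopulationSpec("D1", "discovery", 0.02, 24, group="discovery"),
            PopulationSpec("D2", "discovery", 0.02, 24, group="discovery"),
            PopulationSpec("D3", "discovery", 0.02, 24, group="discovery"),
            PopulationSpec("M1", "domestic", 0.05, 20, group="domestic"),
            PopulationSpec("M2", "domestic", 0.05, 16, group="domestic"),
            PopulationSpec(
                "FER", "discovery", 0.05, 21, group="feral",
                admixture={"discovery": 0.7, "wild_a": 0.15, "wild_b": 0.15},
            ),
            PopulationSpec("OG1", "wild_a", 0.02, 14, group="wild"),
            PopulationSpec("OG2", "wild_b", 0.02, 10, group="wild"),
        ],
        discovery_populations=["D1", "D2", "D3"],
        young_frac=0.5,
        young_clade_weights={
            "discovery": 0.55, "domestic": 0.05, "wild_a": 0.20, "wild_b": 0.20,
        },
        young_clade_bands={
            "discovery": (0.10, 0.40), "domestic": (0.10, 0.45),
            "wild_a": (0.20, 0.60), "wild_b": (0.20, 0.60),
        },
    )
    for key, val in overrides.items():
        if not hasattr(cfg, key):
            raise ConfigError(f"unknown config field {key!r}")
        setattr(cfg, key, val)
    cfg.validate()
    return cfg


@dataclass
class SimulationTruth:
    """Exact per-population allele frequencies plus locus map and array mask."""

    config: SimulationConfig
    locus_ids: list[str]
    chromosomes: np.ndarray
    positions: np.ndarray
    p_ancestral: np.ndarray                  # root frequency per locus
    clade_freqs: dict[str, np.ndarray]
    population_ids: list[str]
    pop_freqs: np.ndarray                    # (n_pops, n_loci)
    #: "" for ancestral polymorphisms, else the clade a young variant is private to
    young_origin: np.ndarray | None = None
    array_mask: np.ndarray | None = None     # boolean per locus, set by ascertain_array

    def freq_of(self, population_id: str) -> np.ndarray:
        return self.pop_freqs[self.population_ids.index(population_id)]

    def expected_heterozygosity(
        self, population_id: str, locus_subset: np.ndarray | None = None
    ) -> float:
        """Mean 2p(1-p) over the subset — the HWE expectation for Ho."""
        p = self.freq_of(population_id)
        if locus_subset is not None:
            p = p[np.asarray(locus_subset, dtype=int)]
        return float(np.mean(2.0 * p * (1.0 - p)))

    def to_tsv(self, path) -> None:
        df = pd.DataFrame(
            {"locus_id": self.locus_ids,
             "chromosome": self.chromosomes,
             "position_bp": self.positions,
             "p_ancestral": self.p_ancestral}
        )
        for k, pop in enumerate(self.population_ids):
            df[f"p_{pop}"] = self.pop_freqs[k]
        if self.young_origin is not None:
            df["young_origin"] = self.young_origin
        if self.array_mask is not None:
            df["on_array"] = self.array_mask.astype(int)
        df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def _balding_nichols(rng: np.random.Generator, parent: np.ndarray, f: float) -> np.ndarray:
    """Daughter frequencies: Beta(p(1-F)/F, (1-p)(1-F)/F); F=0 copies parent."""
    if f == 0.0:
        return parent.copy()
    a = parent * (1.0 - f) / f
    b = (1.0 - parent) * (1.0 - f) / f
    # Beta(0, b) / Beta(a, 0) mean fixation at 0 / 1
    out = np.empty_like(parent)
    fixed0, fixed1 = a == 0.0, b == 0.0
    free = ~(fixed0 | fixed1)
    out[fixed0], out[fixed1] = 0.0, 1.0
    out[free] = rng.beta(a[free], b[free])
    return out


def _locus_map(cfg: SimulationConfig, rng: np.random.Generator):
    """Loci spread uniformly over equal-length autosomes, sorted by position."""
    per = np.full(cfg.n_chromosomes, cfg.n_loci // cfg.n_chromosomes)
    per[: cfg.n_loci % cfg.n_chromosomes] += 1
    chroms, positions = [], []
    for c in range(cfg.n_chromosomes):
        pos = np.sort(
            rng.choice(cfg.chromosome_length_bp, size=per[c], replace=False) + 1
        )
        chroms.extend([str(c + 1)] * per[c])
        positions.extend(pos.tolist())
    return np.array(chroms), np.array(positions, dtype=int)


def simulate_frequencies(config: SimulationConfig) -> SimulationTruth:
    """Draw ancestral, clade, and population frequencies plus the locus map."""
    config.validate()
    rng = np.random.default_rng([config.seed, _STREAM_FREQS])

    chroms, positions = _locus_map(config, rng)
    p0 = rng.uniform(config.freq_low, config.freq_high, config.n_loci)

    # locus class: ancestral polymorphism vs clade-private young variant
    young_origin = np.full(config.n_loci, "", dtype=object)
    if config.young_frac > 0:
        is_young = rng.random(config.n_loci) < config.young_frac
        names = list(config.young_clade_weights)
        w = np.array([config.young_clade_weights[c] for c in names], dtype=float)
        origins = rng.choice(names, size=int(is_young.sum()), p=w / w.sum())
        young_origin[is_young] = origins
        p0[is_young] = 0.0   # the derived allele is absent at the root

    clade_freqs = {}
    for c, f in config.clades.items():
        freqs = _balding_nichols(rng, p0, f)
        mine = young_origin == c
        lo, hi = config.young_clade_bands.get(
            c, (config.young_freq_low, config.young_freq_high)
        )
        freqs[mine] = rng.uniform(lo, hi, int(mine.sum()))
        freqs[(young_origin != c) & (young_origin != "")] = 0.0
        clade_freqs[c] = freqs

    pop_ids = [p.population_id for p in config.populations]
    pop_freqs = np.empty((len(pop_ids), config.n_loci))
    for k, spec in enumerate(config.populations):
        if spec.admixture:
            total = sum(spec.admixture.values())
            parent = sum(
                (w / total) * clade_freqs[c] for c, w in spec.admixture.items()
            )
        else:
            parent = clade_freqs[spec.clade]
        pop_freqs[k] = _balding_nichols(rng, np.asarray(parent), spec.f_pop)

    # plant high-LD duplicate loci next to their sources (optional)
    n_dup = int(round(config.ld_pair_frac * config.n_loci))
    dup_src = rng.choice(config.n_loci, size=n_dup, replace=False) if n_dup else np.array([], dtype=int)

    truth = SimulationTruth(
        config=config,
        locus_ids=[f"snp{j + 1:06d}" for j in range(config.n_loci)],
        chromosomes=chroms,
        positions=positions,
        p_ancestral=p0,
        clade_freqs=clade_freqs,
        population_ids=pop_ids,
        pop_freqs=pop_freqs,
        young_origin=np.asarray(young_origin),
    )
    truth._dup_sources = dup_src  # consumed by sample_genotypes
    return truth


def sample_genotypes(truth: SimulationTruth, config: SimulationConfig | None = None) -> GenotypeDataset:
    """Binomial(2, p_pop) genotypes per individual; independent loci.

    Duplicated high-LD loci (if configured) copy their source genotypes with
    per-entry resampling probability ``ld_pair_noise`` and are appended with
    positions 1 bp after their sources; the truth object is extended to
    cover them.  Missing calls are planted uniformly at ``missing_rate``.
    """
    cfg = config or truth.config
    rng = np.random.default_rng([cfg.seed, _STREAM_GENOTYPES])

    n_total = sum(p.n_samples for p in cfg.populations)
    g = np.empty((n_total, cfg.n_loci), dtype=np.int8)
    sample_ids, pop_col = [], []
    row = 0
    for k, spec in enumerate(cfg.populations):
        p = truth.pop_freqs[k]
        g[row: row + spec.n_samples] = rng.binomial(
            2, p, size=(spec.n_samples, cfg.n_loci)
        ).astype(np.int8)
        sample_ids.extend(f"{spec.population_id}_{i + 1:03d}" for i in range(spec.n_samples))
        pop_col.extend([spec.population_id] * spec.n_samples)
        row += spec.n_samples

    dup_src = getattr(truth, "_dup_sources", np.array([], dtype=int))
    if dup_src.size:
        noise = rng.random((n_total, dup_src.size)) < cfg.ld_pair_noise
        fresh = rng.binomial(2, truth.pop_freqs[
            [truth.population_ids.index(p) for p in pop_col]
        ][:, dup_src]).astype(np.int8)
        g_dup = np.where(noise, fresh, g[:, dup_src])
        g = np.hstack([g, g_dup])
        truth.locus_ids = truth.locus_ids + [f"snp{j + 1:06d}_dup" for j in dup_src]
        truth.chromosomes = np.concatenate([truth.chromosomes, truth.chromosomes[dup_src]])
        truth.positions = np.concatenate([truth.positions, truth.positions[dup_src] + 1])
        truth.p_ancestral = np.concatenate([truth.p_ancestral, truth.p_ancestral[dup_src]])
        truth.pop_freqs = np.hstack([truth.pop_freqs, truth.pop_freqs[:, dup_src]])
        truth.young_origin = np.concatenate([truth.young_origin, truth.young_origin[dup_src]])

    if cfg.missing_rate > 0:
        miss_rng = np.random.default_rng([cfg.seed, _STREAM_MISSING])
        mask = miss_rng.random(g.shape) < cfg.missing_rate
        g[mask] = MISSING

    n_loci = g.shape[1]
    loci = pd.DataFrame(
        {
            "locus_id": truth.locus_ids,
            "chromosome": truth.chromosomes,
            "position_bp": truth.positions,
            "allele_a": ["A"] * n_loci,
            "allele_b": ["C"] * n_loci,
        }
    )
    samples = pd.DataFrame({"sample_id": sample_ids, "population_id": pop_col})
    dataset = GenotypeDataset(genotypes=g, loci=loci, samples=samples).sort_loci()

    # keep the truth arrays aligned with the sorted locus order
    order = dataset.locus_indices(dataset.loci["locus_id"])
    lookup = {lid: j for j, lid in enumerate(truth.locus_ids)}
    perm = np.array([lookup[lid] for lid in dataset.loci["locus_id"]])
    truth.locus_ids = [truth.locus_ids[j] for j in perm]
    truth.chromosomes = truth.chromosomes[perm]
    truth.positions = truth.positions[perm]
    truth.p_ancestral = truth.p_ancestral[perm]
    truth.pop_freqs = truth.pop_freqs[:, perm]
    truth.young_origin = truth.young_origin[perm]
    del order
    return dataset


def ascertain_array(truth: SimulationTruth, config: SimulationConfig | None = None) -> np.ndarray:
    """Ascertained-locus mask from a fresh discovery-clade sample.

    A separate discovery panel (``discovery_sample_size`` individuals drawn
    uniformly across the discovery populations, mimicking array design
    preceding the study) is genotyped from the true frequencies; a locus
    enters the array iff its sample MAF exceeds ``discovery_maf_cutoff``.
    The mask is recorded on the truth object.
    """
    cfg = config or truth.config
    if not cfg.discovery_populations:
        raise ConfigError("no discovery populations configured")
    rng = np.random.default_rng([cfg.seed, _STREAM_DISCOVERY])

    n_loci = truth.pop_freqs.shape[1]
    pop_rows = [truth.population_ids.index(p) for p in cfg.discovery_populations]
    assign = rng.choice(len(pop_rows), size=cfg.discovery_sample_size)
    counts = np.zeros(n_loci)
    for a in assign:
        counts += rng.binomial(2, truth.pop_freqs[pop_rows[a]])
    p_hat = counts / (2.0 * cfg.discovery_sample_size)
    maf = np.minimum(p_hat, 1.0 - p_hat)
    mask = maf > cfg.discovery_maf_cutoff
    if not mask.any():
        raise AscPanelError(
            "ascertainment removed every locus; lower discovery_maf_cutoff"
        )
    truth.array_mask = mask
    return mask


def simulate_dataset(
    config: SimulationConfig,
) -> tuple[GenotypeDataset, GenotypeDataset, SimulationTruth]:
    """Convenience wrapper: (genome-wide dataset, array dataset, truth)."""
    truth = simulate_frequencies(config)
    genome = sample_genotypes(truth, config)
    mask = ascertain_array(truth, config)
    array = genome.subset_loci(np.flatnonzero(mask))
    return genome, array, truth
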