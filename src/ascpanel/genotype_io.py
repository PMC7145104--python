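"""Genotype data model and PLINK-style text I/O.

The central container is :class:`GenotypeDataset`: an ``n_samples x n_loci``
matrix of counted-allele dosages (0, 1, 2, or missing) together with an
ordered locus map and ordered sample records.  Genotypes are read from and
written to whitespace-separated PED/MAP pairs; population membership comes
from the PED family-ID column, optionally overridden by a sample metadata
TSV.

Allele polarity convention: at each locus the *counted* allele is the first
allele observed while scanning samples in file order.  The choice is
deterministic, and every downstream statistic (heterozygosity, inbreeding,
r-squared, Reynolds' distance, PCA variance explained) is invariant to
flipping it (``g -> 2 - g``), so the convention carries no analytical weight.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError

logger = logging.getLogger("ascpanel")

#: Internal sentinel for a missing genotype call.  Reserved: never a dosage.
MISSING: int = -1

#: Chromosome codes treated as non-autosomal in MAP files.
NON_AUTOSOMAL_CODES = frozenset({"0", "X", "Y", "XY", "MT", "M"})

_KNOWN_ALLELES = frozenset({"A", "C", "G", "T", "0"})


def chromosome_sort_key(code: str) -> tuple[int, int, str]:
    """Sort numeric chromosomes numerically, then named codes alphabetically."""
    code = str(code)
    if code.isdigit() and code != "0":
        return (0, int(code), "")
    return (1, 0, code)


def is_autosome(code: str) -> bool:
    code = str(code)
    return code.isdigit() and code != "0"


@dataclass
class GenotypeDataset:
    """Samples x loci dosage matrix with locus map and sample metadata.

    Attributes
    ----------
    genotypes
        ``int8`` array of shape ``(n_samples, n_loci)`` counting copies of
        the counted allele; :data:`MISSING` marks no-calls.
    loci
        DataFrame with columns ``locus_id, chromosome, position_bp,
        allele_a, allele_b`` (``allele_a`` is the counted allele), sorted by
        (chromosome, position).
    samples
        DataFrame with columns ``sample_id, population_id`` in matrix row
        order.
    """

    genotypes: np.ndarray
    loci: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.loci = self.loci.reset_index(drop=True)
        self.samples = self.samples.reset_index(drop=True)
        self.validate()

    # -- invariants ------------------------------------------------------
    def validate(self) -> None:
        n_s, n_l = self.genotypes.shape
        if n_s != len(self.samples) or n_l != len(self.loci):
            raise FormatError(
                f"genotype matrix {self.genotypes.shape} does not match "
                f"{len(self.samples)} samples x {len(self.loci)} loci"
            )
        if self.loci["locus_id"].duplicated().any():
            dup = self.loci.loc[self.loci["locus_id"].duplicated(), "locus_id"].iloc[0]
            raise FormatError(f"duplicate locus_id {dup!r}")
        if self.samples["sample_id"].duplicated().any():
            dup = self.samples.loc[self.samples["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise FormatError(f"duplicate sample_id {dup!r}")
        valid = np.isin(self.genotypes, (0, 1, 2, MISSING))
        if not valid.all():
            bad = self.genotypes[~valid].flat[0]
            raise FormatError(f"genotype entry {bad} outside {{0,1,2,missing}}")

    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_loci(self) -> int:
        return self.genotypes.shape[1]

    def sort_loci(self) -> "GenotypeDataset":
        """Return a copy with loci sorted by (chromosome, position_bp)."""
        keys = [
            (chromosome_sort_key(c), int(p), i)
            for i, (c, p) in enumerate(zip(self.loci["chromosome"], self.loci["position_bp"]))
        ]
        order = [i for *_, i in sorted(keys)]
        return GenotypeDataset(
            genotypes=self.genotypes[:, order],
            loci=self.loci.iloc[order],
            samples=self.samples,
        )

    def subset_loci(self, indices: np.ndarray) -> "GenotypeDataset":
        indices = np.asarray(indices, dtype=int)
        return GenotypeDataset(
            genotypes=self.genotypes[:, indices],
            loci=self.loci.iloc[indices],
            samples=self.samples,
        )

    def locus_indices(self, locus_ids) -> np.ndarray:
        """Map locus ids to column indices, preserving the given order."""
        lookup = {lid: i for i, lid in enumerate(self.loci["locus_id"])}
        try:
            return np.array([lookup[lid] for lid in locus_ids], dtype=int)
        except KeyError as exc:  # pragma: no cover - defensive
            raise KeyError(f"unknown locus_id {exc.args[0]!r}") from None


@dataclass
class PopulationPartition:
    """Disjoint assignment of sample indices to populations.

    ``populations`` maps population_id to a list of row indices into the
    dataset's sample table; ``groups`` optionally labels each population with
    a broader type (e.g. "European taurine", "wild").
    """

    populations: dict[str, list[int]]
    groups: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[int] = set()
        for pop, idx in self.populations.items():
            if not idx:
                raise FormatError(f"population {pop!r} has no samples")
            overlap = seen.intersection(idx)
            if overlap:
                raise FormatError(f"sample index {overlap.pop()} assigned to >1 population")
            seen.update(idx)

    @property
    def population_ids(self) -> list[str]:
        return list(self.populations)

    def group_of(self, pop: str) -> str:
        return self.groups.get(pop, "unknown")

    @classmethod
    def from_dataset(cls, dataset: GenotypeDataset) -> "PopulationPartition":
        pops: dict[str, list[int]] = {}
        for i, pop in enumerate(dataset.samples["population_id"]):
            pops.setdefault(str(pop), []).append(i)
        return cls(populations=pops)


# ---------------------------------------------------------------------------
# PED/MAP reading
# ---------------------------------------------------------------------------

def read_plink_text(ped_path, map_path) -> GenotypeDataset:
    """Read a whitespace-separated PED/MAP pair into a :class:`GenotypeDataset`.

    The counted allele at each locus is the first allele observed scanning
    samples in file order; ``0 0`` encodes a missing call (a half-missing
    pair is treated as missing).  The PED family-ID column is ingested as
    ``population_id``.  Loci are sorted by (chromosome, position) after
    ingestion.
    """
    ped_path, map_path = Path(ped_path), Path(map_path)

    loci_rows = []
    with open(map_path) as fh:
        for ln, line in enumerate(fh, start=1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 4:
                raise FormatError(
                    f"{map_path}:{ln}: expected 4 columns (chrom, id, cM, bp), got {len(fields)}"
                )
            chrom, lid, _cm, pos = fields
            loci_rows.append((lid, chrom, int(pos)))
    locus_ids = [r[0] for r in loci_rows]
    if len(set(locus_ids)) != len(locus_ids):
        seen: set[str] = set()
        for lid in locus_ids:
            if lid in seen:
                raise FormatError(f"{map_path}: duplicate locus_id {lid!r}")
            seen.add(lid)
    n_loci = len(loci_rows)

    sample_rows = []
    counted: list[str] = ["0"] * n_loci   # first allele observed per locus
    other: list[str] = ["0"] * n_loci
    geno_rows: list[np.ndarray] = []
    odd_alleles: set[str] = set()

    with open(ped_path) as fh:
        for ln, line in enumerate(fh, start=1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 6 + 2 * n_loci:
                raise FormatError(
                    f"{ped_path}:{ln}: expected {6 + 2 * n_loci} fields "
                    f"(6 + 2 x {n_loci} loci), got {len(fields)}"
                )
            fid, iid = fields[0], fields[1]
            sample_rows.append((iid, fid))
            alleles = fields[6:]
            row = np.full(n_loci, MISSING, dtype=np.int8)
            for j in range(n_loci):
                a1, a2 = alleles[2 * j], alleles[2 * j + 1]
                for a in (a1, a2):
                    if a not in _KNOWN_ALLELES:
                        odd_alleles.add(a)
                if a1 == "0" or a2 == "0":
                    continue
                if counted[j] == "0":
                    counted[j] = a1
                for a in (a1, a2):
                    if a != counted[j] and other[j] == "0":
                        other[j] = a
                row[j] = (a1 == counted[j]) + (a2 == counted[j])
            geno_rows.append(row)

    if odd_alleles:
        logger.warning(
            "%s: allele symbols beyond {A,C,G,T,0} accepted: %s",
            ped_path, ", ".join(sorted(odd_alleles)),
        )

    samples = pd.DataFrame(sample_rows, columns=["sample_id", "population_id"])
    loci = pd.DataFrame(
        {
            "locus_id": locus_ids,
            "chromosome": [r[1] for r in loci_rows],
            "position_bp": [r[2] for r in loci_rows],
            "allele_a": counted,
            "allele_b": other,
        }
    )
    genotypes = (
        np.vstack(geno_rows) if geno_rows else np.empty((0, n_loci), dtype=np.int8)
    )
    return GenotypeDataset(genotypes=genotypes, loci=loci, samples=samples).sort_loci()


# ---------------------------------------------------------------------------
# PED/MAP writing
# ---------------------------------------------------------------------------

def write_plink_text(dataset: GenotypeDataset, out_prefix) -> tuple[Path, Path]:
    """Write ``<prefix>.ped`` / ``<prefix>.map``; missing becomes ``0 0``.

    The population_id is stored in the PED family-ID column so a write/read
    roundtrip preserves population membership.
    """
    out_prefix = Path(out_prefix)
    map_path = out_prefix.with_suffix(".map")
    ped_path = out_prefix.with_suffix(".ped")

    with open(map_path, "w") as fh:
        for row in dataset.loci.itertuples(index=False):
            fh.write(f"{row.chromosome}\t{row.locus_id}\t0\t{row.position_bp}\n")

    a = dataset.loci["allele_a"].to_numpy()
    b = dataset.loci["allele_b"].to_numpy()
    pair_for = {
        2: lambda j: f"{a[j]} {a[j]}",
        1: lambda j: f"{a[j]} {b[j]}",
        0: lambda j: f"{b[j]} {b[j]}",
        MISSING: lambda j: "0 0",
    }
    with open(ped_path, "w") as fh:
        for i, srow in enumerate(dataset.samples.itertuples(index=False)):
            lead = f"{srow.population_id}\t{srow.sample_id}\t0\t0\t0\t-9"
            body = "\t".join(
                pair_for[int(dataset.genotypes[i, j])](j) for j in range(dataset.n_loci)
            )
            fh.write(lead + ("\t" + body if body else "") + "\n")
    return ped_path, map_path


# ---------------------------------------------------------------------------
# Sample metadata table
# ---------------------------------------------------------------------------

def read_population_table(tsv_path, dataset: GenotypeDataset) -> PopulationPartition:
    """Build a :class:`PopulationPartition` from a metadata TSV.

    Expected columns: ``sample_id``, ``population_id``, optional ``group``.
    Samples absent from the TSV fall back to their PED family-ID population;
    TSV rows for unknown samples are skipped with a warning.  On conflict the
    TSV assignment wins (logged).
    """
    table = pd.read_csv(tsv_path, sep="\t", dtype=str)
    required = {"sample_id", "population_id"}
    if not required.issubset(table.columns):
        raise FormatError(
            f"{tsv_path}: missing required columns {sorted(required - set(table.columns))}"
        )

    row_of = {sid: i for i, sid in enumerate(dataset.samples["sample_id"])}
    assignment = {
        i: str(pop) for i, pop in enumerate(dataset.samples["population_id"])
    }
    groups: dict[str, str] = {}

    for rec in table.itertuples(index=False):
        sid = str(rec.sample_id)
        if sid not in row_of:
            logger.warning("population table: sample %r not in dataset, skipped", sid)
            continue
        i = row_of[sid]
        pop = str(rec.population_id)
        if assignment[i] != pop:
            logger.info(
                "sample %r: population %r from table overrides PED family-ID %r",
                sid, pop, assignment[i],
            )
        assignment[i] = pop
        grp = getattr(rec, "group", None)
        if grp is not None and not pd.isna(grp) and str(grp).strip():
            groups[pop] = str(grp)

    pops: dict[str, list[int]] = {}
    for i in range(dataset.n_samples):
        pops.setdefault(assignment[i], []).append(i)
    empties = [p for p, idx in pops.items() if not idx]
    for p in empties:  # pragma: no cover - construction above cannot make these
        logger.warning("population %r has no samples, dropped", p)
        del pops[p]
    return PopulationPartition(populations=pops, groups=groups)


def sanitize_label(label: str) -> str:
    """Replace characters unsafe for PHYLIP/NEXUS labels with underscores."""
    return re.sub(r"[^A-Za-z0-9_.\-]", "_", str(label))
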