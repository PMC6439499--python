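"""Genotype containers and core population-genetic summaries.

Diploid biallelic genotypes are stored as alternate-allele dosages
(0, 1, 2) with ``MISSING = -1`` sentinel values.  On top of the
containers this module provides per-locus allele/heterozygote counts,
the Weir & Cockerham (1984) two-population FST estimator computed from
observed genotype composition, and composite genotypic LD measured as
the squared Pearson correlation of dosage vectors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "MISSING",
    "LocusInfo",
    "GenotypeMatrix",
    "AlleleCountTable",
    "BaselineSet",
    "allele_counts",
    "wc_fst",
    "ld_r2",
]

MISSING = -1


@dataclass(frozen=True)
class LocusInfo:
    """A biallelic SNP locus with an optional linkage-map position."""

    locus_id: str
    linkage_group: str = ""
    map_pos: float = 0.0
    alleles: tuple[str, str] = ("A", "B")

    def __post_init__(self) -> None:
        if not self.locus_id:
            raise ValueError("locus_id must be non-empty")
        if not np.isfinite(self.map_pos):
            raise ValueError(f"map_pos for {self.locus_id} must be finite")
        if self.map_pos < 0:
            raise ValueError(f"map_pos for {self.locus_id} must be >= 0")


@dataclass
class GenotypeMatrix:
    """Individuals x loci diploid dosage matrix.

    ``dosage[i, l]`` is the number of alternate-allele copies carried by
    individual ``i`` at locus ``l``, in ``{0, 1, 2}``, or ``MISSING``.
    """

    individuals: list[str]
    loci: list[LocusInfo]
    dosage: np.ndarray

    def __post_init__(self) -> None:
        self.individuals = list(self.individuals)
        self.loci = list(self.loci)
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        if len(self.individuals) < 1 or len(self.loci) < 1:
            raise ValueError("need at least one individual and one locus")
        if self.dosage.shape != (len(self.individuals), len(self.loci)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.individuals)} individuals x {len(self.loci)} loci"
            )
        bad = ~np.isin(self.dosage, (MISSING, 0, 1, 2))
        if bad.any():
            i, l = np.argwhere(bad)[0]
            raise ValueError(
                f"invalid dosage {self.dosage[i, l]} for individual "
                f"{self.individuals[i]} at locus {self.loci[l].locus_id}"
            )
        if len(set(self.individuals)) != len(self.individuals):
            raise ValueError("duplicate individual ids")
        ids = [loc.locus_id for loc in self.loci]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate locus ids")

    # -- convenience -------------------------------------------------

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def locus_ids(self) -> list[str]:
        return [loc.locus_id for loc in self.loci]

    @property
    def missing_mask(self) -> np.ndarray:
        return self.dosage == MISSING

    def locus_index(self, locus_id: str) -> int:
        try:
            return self.locus_ids.index(locus_id)
        except ValueError:
            raise KeyError(f"locus {locus_id!r} not in matrix") from None

    def individual_index(self, individual_id: str) -> int:
        try:
            return self.individuals.index(individual_id)
        except ValueError:
            raise KeyError(f"individual {individual_id!r} not in matrix") from None

    def subset_individuals(self, ids: Sequence[str]) -> "GenotypeMatrix":
        idx = [self.individual_index(i) for i in ids]
        return GenotypeMatrix(list(ids), self.loci, self.dosage[idx, :])

    def subset_loci(self, locus_ids: Sequence[str]) -> "GenotypeMatrix":
        idx = [self.locus_index(l) for l in locus_ids]
        return GenotypeMatrix(
            self.individuals, [self.loci[j] for j in idx], self.dosage[:, idx]
        )


@dataclass
class AlleleCountTable:
    """Per-locus allele and genotype counts for one population sample.

    ``n_alt``/``n_total`` are allele *copy* counts derived from full
    diploid genotypes (so ``n_total`` is always even), ``n_het`` and
    ``n_ind`` are heterozygote and non-missing individual counts used by
    the full Weir-Cockerham estimator.
    """

    locus_ids: list[str]
    n_alt: np.ndarray
    n_total: np.ndarray
    n_het: np.ndarray
    n_ind: np.ndarray

    def __post_init__(self) -> None:
        self.locus_ids = list(self.locus_ids)
        self.n_alt = np.asarray(self.n_alt, dtype=np.int64)
        self.n_total = np.asarray(self.n_total, dtype=np.int64)
        self.n_het = np.asarray(self.n_het, dtype=np.int64)
        self.n_ind = np.asarray(self.n_ind, dtype=np.int64)
        L = len(self.locus_ids)
        for name in ("n_alt", "n_total", "n_het", "n_ind"):
            if getattr(self, name).shape != (L,):
                raise ValueError(f"{name} must have length {L}")
        if np.any(self.n_alt < 0) or np.any(self.n_alt > self.n_total):
            raise ValueError("need 0 <= n_alt <= n_total")
        if np.any(self.n_total % 2 != 0):
            raise ValueError("n_total must be even (counts derive from genotypes)")
        if np.any(self.n_total != 2 * self.n_ind):
            raise ValueError("n_total must equal 2 * n_ind")

    @property
    def n_loci(self) -> int:
        return len(self.locus_ids)

    @property
    def freq(self) -> np.ndarray:
        """Sample alternate-allele frequency; NaN where all genotypes missing."""
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.n_total > 0, self.n_alt / self.n_total, np.nan)

    @property
    def all_missing(self) -> np.ndarray:
        return self.n_total == 0

    def __add__(self, other: "AlleleCountTable") -> "AlleleCountTable":
        if self.locus_ids != other.locus_ids:
            raise ValueError("cannot pool count tables over different loci")
        return AlleleCountTable(
            self.locus_ids,
            self.n_alt + other.n_alt,
            self.n_total + other.n_total,
            self.n_het + other.n_het,
            self.n_ind + other.n_ind,
        )


@dataclass
class BaselineSet:
    """Named reference populations sharing one locus list."""

    labels: list[str]
    counts: dict[str, AlleleCountTable]
    provenance: str = ""

    def __post_init__(self) -> None:
        self.labels = list(self.labels)
        if len(self.labels) < 2:
            raise ValueError("a BaselineSet needs at least two populations")
        if set(self.labels) != set(self.counts):
            raise ValueError("labels and counts keys must match")
        ref = self.counts[self.labels[0]].locus_ids
        for lab in self.labels[1:]:
            if self.counts[lab].locus_ids != ref:
                raise ValueError(f"locus list of {lab!r} differs from {self.labels[0]!r}")

    @property
    def locus_ids(self) -> list[str]:
        return self.counts[self.labels[0]].locus_ids

    def subset_loci(self, locus_ids: Sequence[str]) -> "BaselineSet":
        ref = self.locus_ids
        idx = []
        for l in locus_ids:
            try:
                idx.append(ref.index(l))
            except ValueError:
                raise KeyError(f"locus {l!r} not in baseline set") from None
        idx = np.asarray(idx, dtype=int)
        new_counts = {
            lab: AlleleCountTable(
                list(locus_ids),
                t.n_alt[idx],
                t.n_total[idx],
                t.n_het[idx],
                t.n_ind[idx],
            )
            for lab, t in self.counts.items()
        }
        return BaselineSet(self.labels, new_counts, self.provenance)


# ---------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------


def allele_counts(gm: GenotypeMatrix, subset: Iterable[str] | None = None) -> AlleleCountTable:
    """Tally alternate-allele copies, heterozygotes and non-missing
    individuals per locus, optionally over a subset of individuals.

    Loci where every genotype is missing are allowed and end up with
    ``n_total == 0`` (flagged via :attr:`AlleleCountTable.all_missing`).
    """
    if subset is None:
        d = gm.dosage
    else:
        ids = list(subset)
        if not ids:
            raise ValueError("subset of individuals is empty")
        missing_ids = set(ids) - set(gm.individuals)
        if missing_ids:
            raise KeyError(f"individuals not in matrix: {sorted(missing_ids)}")
        idx = [gm.individual_index(i) for i in ids]
        d = gm.dosage[idx, :]
    present = d != MISSING
    n_ind = present.sum(axis=0)
    n_alt = np.where(present, d, 0).sum(axis=0)
    n_het = (d == 1).sum(axis=0)
    return AlleleCountTable(gm.locus_ids, n_alt, 2 * n_ind, n_het, n_ind)


def _wc_components(
    countsA: AlleleCountTable, countsB: AlleleCountTable
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Weir & Cockerham (1984) variance components a, b, c for two
    populations, per locus.  Returns (a, b, c, valid-mask)."""
    if countsA.locus_ids != countsB.locus_ids:
        raise ValueError("count tables must share the same locus list")
    nA = countsA.n_ind.astype(float)
    nB = countsB.n_ind.astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        pA = countsA.n_alt / countsA.n_total
        pB = countsB.n_alt / countsB.n_total
        hA = countsA.n_het / countsA.n_ind
        hB = countsB.n_het / countsB.n_ind

        r = 2.0
        nbar = (nA + nB) / r
        nc = (r * nbar - (nA**2 + nB**2) / (r * nbar)) / (r - 1.0)
        pbar = (nA * pA + nB * pB) / (r * nbar)
        s2 = (nA * (pA - pbar) ** 2 + nB * (pB - pbar) ** 2) / ((r - 1.0) * nbar)
        hbar = (nA * hA + nB * hB) / (r * nbar)

        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - s2 * (r - 1.0) / r - hbar / 4.0) / (nbar - 1.0)
        )
        b = (nbar / (nbar - 1.0)) * (
            pbar * (1 - pbar) - s2 * (r - 1.0) / r - hbar * (2.0 * nbar - 1.0) / (4.0 * nbar)
        )
        c = hbar / 2.0

    # valid: data in both samples, more than one individual on average,
    # and not monomorphic across the pooled pair
    valid = (nA > 0) & (nB > 0) & (nbar > 1) & (pbar > 0) & (pbar < 1)
    return a, b, c, valid


@dataclass
class FstResult:
    """Per-locus Weir-Cockerham theta plus the ratio-of-sums multilocus value."""

    locus_ids: list[str]
    theta: np.ndarray  # NaN where undefined
    multilocus: float
    excluded: list[str] = field(default_factory=list)  # undefined loci


def wc_fst(countsA: AlleleCountTable, countsB: AlleleCountTable) -> FstResult:
    """Two-population Weir & Cockerham (1984) theta.

    Uses observed heterozygote counts (the full 1984 estimator, not an
    HW approximation).  Per-locus theta may be negative.  Loci that are
    monomorphic across both samples, lack data in either sample, or have
    ``a + b + c == 0`` are undefined (NaN, listed in ``excluded``).  The
    multilocus estimate is the ratio of sums ``sum(a) / sum(a+b+c)``
    over defined loci.
    """
    a, b, c, valid = _wc_components(countsA, countsB)
    denom = a + b + c
    with np.errstate(invalid="ignore", divide="ignore"):
        theta = np.where(valid & (denom != 0), a / denom, np.nan)
    ok = valid & (denom != 0)
    if ok.any():
        multi = float(a[ok].sum() / denom[ok].sum())
    else:
        multi = float("nan")
    excluded = [lid for lid, o in zip(countsA.locus_ids, ok) if not o]
    return FstResult(list(countsA.locus_ids), theta, multi, excluded)


def ld_r2(gm: GenotypeMatrix, locus_x: str | int, locus_y: str | int) -> float:
    """Composite genotypic LD: squared Pearson correlation of the 0/1/2
    dosage vectors over individuals non-missing at both loci.

    Returns NaN when undefined (fewer than 2 shared individuals, or
    either locus monomorphic on the shared set).  Callers treat NaN as a
    conservatively failed independence filter.
    """
    ix = gm.locus_index(locus_x) if isinstance(locus_x, str) else int(locus_x)
    iy = gm.locus_index(locus_y) if isinstance(locus_y, str) else int(locus_y)
    x = gm.dosage[:, ix].astype(float)
    y = gm.dosage[:, iy].astype(float)
    shared = (gm.dosage[:, ix] != MISSING) & (gm.dosage[:, iy] != MISSING)
    if shared.sum() < 2:
        return float("nan")
    x = x[shared]
    y = y[shared]
    vx = x.var()
    vy = y.var()
    if vx == 0 or vy == 0:
        return float("nan")
    cov = np.mean((x - x.mean()) * (y - y.mean()))
    return float(cov * cov / (vx * vy))


def pairwise_r2(
    gms: Sequence[GenotypeMatrix], locus_x: str, locus_y: str
) -> float:
    """Max r^2 for a locus pair across one or more genotype matrices.

    LD pruning works within population samples; pooling divergent
    populations would manufacture mixture LD between every pair of
    divergent loci.  The pair is scored in every sample where r^2 is
    defined (a locus fixed within one population -- e.g. a fixed
    difference -- carries no measurable association there); only a pair
    undefined in *all* samples returns NaN, which callers treat as a
    conservatively failed filter."""
    vals = [ld_r2(gm, locus_x, locus_y) for gm in gms]
    defined = [v for v in vals if not np.isnan(v)]
    if not defined:
        return float("nan")
    return max(defined)
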