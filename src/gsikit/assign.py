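"""Likelihood-based individual assignment.

Genotype likelihoods follow the Dirichlet posterior-predictive form of
Rannala & Mountain (1997) with per-allele prior 1/k (k = 2 for SNPs):
for a baseline with ``n_a`` alternate copies out of ``n`` observed,

* P(hom-alt) = (n_a + 1/2)(n_a + 3/2) / ((n + 1)(n + 2))
* P(het)     = 2 (n_a + 1/2)(n - n_a + 1/2) / ((n + 1)(n + 2))
* P(hom-ref) = (n - n_a + 1/2)(n - n_a + 3/2) / ((n + 1)(n + 2))

Assignment scores are 100 * L_b / sum(L), computed in log space.
Power is estimated by leave-one-out self-assignment on hold-out
baselines, summarised by misassignment rates and log10 likelihood-ratio
distributions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .popgen import MISSING, AlleleCountTable, BaselineSet, GenotypeMatrix, allele_counts

__all__ = [
    "AssignmentResult",
    "PowerReport",
    "rm_log_likelihood",
    "genotype_log_probs",
    "assignment_scores",
    "assign_individuals",
    "loo_self_assignment",
    "lr_summary",
]

LN10 = math.log(10.0)


@dataclass
class AssignmentResult:
    individual_id: str
    loglik: dict[str, float]
    score: dict[str, float]
    assigned: str  # baseline label, "ambiguous", or "unusable"
    n_loci_used: int


@dataclass
class PowerRecord:
    individual_id: str
    true_label: str
    loglik: dict[str, float]
    assigned: str
    lr_log10: float  # log10 L(own) / L(other)


@dataclass
class PowerReport:
    records: list[PowerRecord]
    per_population: pd.DataFrame  # index: label; n, n_misassigned, misassignment_rate
    labels: list[str] = field(default_factory=list)


def genotype_log_probs(counts: AlleleCountTable) -> np.ndarray:
    """(L, 3) matrix of log P(dosage = 0, 1, 2) per locus under the
    Dirichlet(1/2, 1/2) posterior predictive for the given baseline
    counts.  Rows for loci with no data fall back to the prior."""
    n_a = counts.n_alt.astype(float)
    n = counts.n_total.astype(float)
    if np.any(n_a < 0) or np.any(n < 0):
        raise ValueError("negative allele counts")
    n_r = n - n_a
    denom = (n + 1.0) * (n + 2.0)
    p0 = (n_r + 0.5) * (n_r + 1.5) / denom
    p1 = 2.0 * (n_a + 0.5) * (n_r + 0.5) / denom
    p2 = (n_a + 0.5) * (n_a + 1.5) / denom
    return np.log(np.column_stack([p0, p1, p2]))


def rm_log_likelihood(dosages: np.ndarray, counts: AlleleCountTable) -> float:
    """Natural-log genotype likelihood of one individual against one
    baseline; loci with missing genotype contribute 0."""
    d = np.asarray(dosages)
    if d.shape != (counts.n_loci,):
        raise ValueError("genotype vector and count table must align locus-wise")
    usable = d != MISSING
    if not usable.any():
        raise ValueError("zero usable loci")
    logp = genotype_log_probs(counts)
    idx = np.flatnonzero(usable)
    return float(logp[idx, d[idx]].sum())


def assignment_scores(logliks: dict[str, float]) -> dict[str, float]:
    """Scores on the 0-100 scale: 100 * exp(loglik_b - logsumexp(all)).

    Log-space computation keeps the result exact for log-likelihood
    differences far beyond float underflow."""
    if len(logliks) < 2:
        raise ValueError("need log-likelihoods for at least two baselines")
    vals = np.array(list(logliks.values()), dtype=float)
    if np.all(np.isneginf(vals)):
        raise ValueError("all log-likelihoods are -inf")
    lse = logsumexp(vals)
    return {k: float(100.0 * math.exp(v - lse)) for k, v in zip(logliks, vals)}


def _loglik_matrix(gm: GenotypeMatrix, counts: AlleleCountTable) -> np.ndarray:
    """Vector of log-likelihoods for every individual in ``gm``."""
    logp = genotype_log_probs(counts)  # (L, 3)
    d = gm.dosage
    usable = d != MISSING
    dc = np.where(usable, d, 0)
    contrib = logp[np.arange(gm.n_loci)[None, :], dc]  # (n, L)
    return np.where(usable, contrib, 0.0).sum(axis=1)


def assign_individuals(gm: GenotypeMatrix, baselines: BaselineSet) -> list[AssignmentResult]:
    """Assign every individual to the baseline with the highest score.

    Exact score ties are labelled ``"ambiguous"``; individuals with zero
    usable loci are labelled ``"unusable"`` (excluded downstream)."""
    base = baselines.subset_loci(gm.locus_ids)
    lls = {lab: _loglik_matrix(gm, base.counts[lab]) for lab in base.labels}
    n_used = (gm.dosage != MISSING).sum(axis=1)
    out: list[AssignmentResult] = []
    for i, ind in enumerate(gm.individuals):
        if n_used[i] == 0:
            out.append(
                AssignmentResult(ind, {}, {}, "unusable", 0)
            )
            continue
        ll = {lab: float(lls[lab][i]) for lab in base.labels}
        sc = assignment_scores(ll)
        best = max(sc.values())
        winners = [lab for lab, s in sc.items() if s == best]
        assigned = winners[0] if len(winners) == 1 else "ambiguous"
        out.append(AssignmentResult(ind, ll, sc, assigned, int(n_used[i])))
    return out


def loo_self_assignment(baseline_gms: dict[str, GenotypeMatrix]) -> PowerReport:
    """Leave-one-out self-assignment across two baseline samples.

    For each individual, its own population's allele counts are reduced
    by that individual's two allele copies at every non-missing locus
    before computing the own-population likelihood; the other
    population's counts are untouched."""
    labels = list(baseline_gms)
    if len(labels) != 2:
        raise ValueError("leave-one-out power estimation expects exactly two baselines")
    la, lb = labels
    if baseline_gms[la].locus_ids != baseline_gms[lb].locus_ids:
        raise ValueError("baseline samples must share the same locus list")
    counts = {lab: allele_counts(g) for lab, g in baseline_gms.items()}

    records: list[PowerRecord] = []
    for own, other in ((la, lb), (lb, la)):
        gm = baseline_gms[own]
        ll_other = _loglik_matrix(gm, counts[other])
        base = counts[own]
        for i, ind in enumerate(gm.individuals):
            d = gm.dosage[i]
            usable = d != MISSING
            if not usable.any():
                continue
            n_alt = base.n_alt - np.where(usable, d, 0)
            n_ind = base.n_ind - usable
            n_het = base.n_het - (d == 1)
            loo = AlleleCountTable(base.locus_ids, n_alt, 2 * n_ind, n_het, n_ind)
            ll_own = rm_log_likelihood(d, loo)
            ll = {own: ll_own, other: float(ll_other[i])}
            sc = assignment_scores(ll)
            best = max(sc.values())
            winners = [lab for lab, s in sc.items() if s == best]
            assigned = winners[0] if len(winners) == 1 else "ambiguous"
            records.append(
                PowerRecord(ind, own, ll, assigned, (ll_own - ll[other]) / LN10)
            )

    rows = []
    for lab in labels:
        mine = [r for r in records if r.true_label == lab]
        n_mis = sum(1 for r in mine if r.assigned != lab)
        rows.append(
            {
                "population": lab,
                "n": len(mine),
                "n_misassigned": n_mis,
                "misassignment_rate": n_mis / len(mine) if mine else float("nan"),
            }
        )
    per_pop = pd.DataFrame(rows).set_index("population")
    return PowerReport(records, per_pop, labels)


def lr_summary(report: PowerReport) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Geometric-mean own-vs-other likelihood ratio per population plus
    the full per-individual lr_log10 distribution for export.

    The geometric mean is 10 ** mean(lr_log10) -- the only average
    consistent with ratios of likelihoods."""
    if not report.records:
        raise ValueError("empty power report")
    dist = pd.DataFrame(
        {
            "individual_id": [r.individual_id for r in report.records],
            "population": [r.true_label for r in report.records],
            "lr_log10": [r.lr_log10 for r in report.records],
        }
    )
    summary = (
        dist.groupby("population")["lr_log10"]
        .agg(mean_lr_log10="mean", n="count")
        .reset_index()
    )
    summary["geometric_mean_ratio"] = 10.0 ** summary["mean_lr_log10"]
    return summary, dist
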