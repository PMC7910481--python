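"""Cohort-level statistics for clonal-hematopoiesis surveillance.

Covers the descriptive and inferential summaries used at cohort scale:
the two-sided Fisher exact test (probability-mass convention) for 2x2
association tables, clonal-hematopoiesis prevalence by age bin, the
classification of biallelic TP53 inactivation mechanisms (second point
mutation, 17p deletion, or copy-neutral LOH), and per-gene mutation
burden summaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "Mutation",
    "PatientRecord",
    "fisher_exact_two_sided",
    "gene_cooccurrence",
    "prevalence_by_age",
    "classify_biallelic_mechanism",
    "mutation_burden_summary",
]

MECHANISMS = ("two_mutations", "mutation+CN_LOH", "mutation+deletion", "monoallelic")


@dataclass
class Mutation:
    """A somatic point mutation in a patient, with optional CCF interval."""

    gene: str
    vaf: float
    ages: tuple[float, ...] = ()
    clone_id: str | None = None
    ccf_interval: tuple[float, float] | None = None


@dataclass
class PatientRecord:
    """Minimal per-patient record for cohort summaries."""

    id: str
    age_years: float
    sex: str = ""
    diagnosis: str = "none"  # none | MDS | AML | severe_BMF
    mutations: list[Mutation] = field(default_factory=list)
    cn_events: list[tuple[str, str]] = field(default_factory=list)  # (region, class)

    def __post_init__(self):
        if self.age_years < 0:
            raise ValueError("age must be nonnegative")
        for m in self.mutations:
            if not 0.0 < m.vaf <= 1.0:
                raise ValueError("VAF must be in (0, 1]")

    @property
    def has_ch(self) -> bool:
        """Clonal hematopoiesis: any somatic mutation or clonal CN event."""
        clonal = [e for e in self.cn_events if e[1] in ("deletion", "cn_loh", "gain")]
        return bool(self.mutations) or bool(clonal)


def fisher_exact_two_sided(table, *, tie_tol: float = 1e-7) -> float:
    """Two-sided Fisher exact p-value, probability-mass convention.

    Sums hypergeometric probabilities of all tables with the observed
    margins whose probability does not exceed the observed table's (within
    relative tolerance ``tie_tol``).  A zero margin makes the test
    degenerate; p = 1 is returned with a warning.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("need a nonnegative 2x2 table")
    a, b = int(t[0, 0]), int(t[0, 1])
    c, d = int(t[1, 0]), int(t[1, 1])
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    if min(r1, r2, c1, b + d) == 0:
        warnings.warn("degenerate margin in 2x2 table; p = 1 by convention")
        return 1.0
    support = np.arange(max(0, c1 - r2), min(r1, c1) + 1)
    pmf = stats.hypergeom.pmf(support, n, r1, c1)
    p_obs = stats.hypergeom.pmf(a, n, r1, c1)
    return float(pmf[pmf <= p_obs * (1.0 + tie_tol)].sum())


def prevalence_by_age(
    records: Sequence[PatientRecord], bin_edges: Sequence[float]
) -> pd.DataFrame:
    """Proportion of patients with clonal hematopoiesis per age bin.

    ``bin_edges`` are increasing; bin i covers (edge[i], edge[i+1]] with
    the first bin closed at its left edge.  Empty bins report a NaN
    proportion.
    """
    edges = list(bin_edges)
    if any(b <= a for a, b in zip(edges, edges[1:])):
        raise ValueError("bin edges must be increasing")
    ages = np.array([r.age_years for r in records])
    ch = np.array([r.has_ch for r in records])
    rows = []
    for lo, hi in zip(edges, edges[1:]):
        mask = (ages > lo) & (ages <= hi)
        if lo == edges[0]:
            mask |= ages == lo
        n = int(mask.sum())
        k = int(ch[mask].sum())
        rows.append(
            {
                "age_low": lo,
                "age_high": hi,
                "n_patients": n,
                "n_ch": k,
                "prevalence": k / n if n else np.nan,
            }
        )
    return pd.DataFrame(rows)


def _interval_covers_one(interval: tuple[float, float] | None) -> bool:
    return interval is not None and interval[0] <= 1.0 <= interval[1]


def classify_biallelic_mechanism(
    patient: PatientRecord, *, gene: str = "TP53", region: str = "17p"
) -> str:
    """Mechanism of biallelic inactivation for a mutated tumor suppressor.

    Requires at least one mutation in ``gene``.  Two mutations count as
    ``two_mutations`` when they share a clone (single-cell evidence) or
    when both CCF central intervals cover 1.0 (bulk evidence that each is
    present in essentially all clonal cells).  Otherwise a single mutation
    combines with the copy-number class on ``region``: ``cn_loh`` ->
    ``mutation+CN_LOH``; ``deletion`` -> ``mutation+deletion``; neither ->
    ``monoallelic``.  Conflicting CN classes on the region raise.
    """
    muts = [m for m in patient.mutations if m.gene == gene]
    if not muts:
        raise ValueError(f"patient {patient.id} has no {gene} mutation")
    classes = {cls for reg, cls in patient.cn_events if reg == region and cls in ("deletion", "cn_loh")}
    if len(classes) > 1:
        raise ValueError(f"conflicting CN classes on {region}: {sorted(classes)}")

    if len(muts) >= 2:
        clones = {m.clone_id for m in muts if m.clone_id is not None}
        same_clone = len(clones) == 1 and len([m for m in muts if m.clone_id]) >= 2
        ccf_compatible = (
            sum(_interval_covers_one(m.ccf_interval) for m in muts) >= 2
        )
        if same_clone or ccf_compatible:
            return "two_mutations"
    if "cn_loh" in classes:
        return "mutation+CN_LOH"
    if "deletion" in classes:
        return "mutation+deletion"
    return "monoallelic"


def gene_cooccurrence(
    records: Sequence[PatientRecord], gene_a: str, gene_b: str
) -> tuple[int, int, float]:
    """Among patients mutated in ``gene_a``: how many also carry ``gene_b``.

    Returns (n_with_a, n_with_both, fraction).
    """
    with_a = [r for r in records if any(m.gene == gene_a for m in r.mutations)]
    both = [r for r in with_a if any(m.gene == gene_b for m in r.mutations)]
    frac = len(both) / len(with_a) if with_a else float("nan")
    return len(with_a), len(both), frac


def mutation_burden_summary(records: Sequence[PatientRecord]) -> dict:
    """Per-gene patient counts/fractions, per-patient counts, VAF spreads."""
    n = len(records)
    per_gene: dict[str, list[float]] = {}
    gene_patients: dict[str, set[str]] = {}
    per_patient = {}
    for r in records:
        per_patient[r.id] = len(r.mutations)
        for m in r.mutations:
            per_gene.setdefault(m.gene, []).append(m.vaf)
            gene_patients.setdefault(m.gene, set()).add(r.id)
    genes = {}
    for g, vafs in per_gene.items():
        pats = len(gene_patients[g])
        genes[g] = {
            "n_patients": pats,
            "fraction_of_cohort": pats / n if n else np.nan,
            "n_mutations": len(vafs),
            "vaf_median": float(np.median(vafs)),
            "vaf_range": (float(min(vafs)), float(max(vafs))),
        }
    n_mutated = sum(1 for r in records if r.mutations)
    return {
        "n_patients": n,
        "n_with_mutation": n_mutated,
        "fraction_with_mutation": n_mutated / n if n else np.nan,
        "genes": genes,
        "mutations_per_patient": per_patient,
    }
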