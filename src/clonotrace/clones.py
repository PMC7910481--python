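"""Clone identification, hierarchy reconstruction, and serial tracking.

Cells with complete (non-missing) genotypes at all somatic loci under test
are grouped by exact genotype vector.  Small groups are discarded; groups
explainable as allelic-dropout (ADO) spillover from a larger clone are
merged into it; groups matching the union of two disjoint clones at a
size consistent with the doublet rate are flagged as putative doublets.

The ADO spillover test: a truly heterozygous cell appears hom-alt when its
ref allele drops and the alt allele survives, and appears wt when the alt
allele drops — each with probability ``d(1-d)`` for per-allele dropout
``d`` — while it appears het with probability ``(1-d)^2``.  Conditional on
being genotyped as either the parent pattern or the spillover pattern, a
cell shows the spillover pattern with probability exactly ``d``.  A
candidate group of size ``g`` next to a parent of size ``p`` is therefore
tested against ``Binomial(g + p, d)``; rejecting the null (one-sided, at
``alpha``) retains it as a genuine (sub)clone, which is also how
homozygous CN-LOH progression subclones are distinguished from dropout
artifacts.

Parent assignment follows mutation-set containment: the parent of a clone
is the retained clone with the largest mutation set that is a strict
subset of its own, or the het version of a clone homozygous at exactly one
locus (an LOH edge).  The result is a forest: independently arising clones
have no parent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genotyping import HET, HOM, MISSING, WT, allele_rate_from_ratio

logger = logging.getLogger(__name__)

__all__ = [
    "Clone",
    "CloneTimeline",
    "identify_clones",
    "build_hierarchy",
    "detect_loh_subclones",
    "track_clones",
    "clone_exclusivity_summary",
]


@dataclass
class Clone:
    """A reconstructed clone: genotype vector over somatic loci plus flags."""

    genotype: dict[str, int]  # locus -> WT/HET/HOM
    n_cells: int
    frequency: float
    clone_id: str = ""
    parent: str | None = None
    flags: set[str] = field(default_factory=set)

    @property
    def mutation_set(self) -> frozenset[str]:
        return frozenset(l for l, g in self.genotype.items() if g != WT)

    def zygosity(self, locus: str) -> int:
        return self.genotype.get(locus, WT)

    def key(self) -> tuple:
        return tuple(sorted(self.genotype.items()))


def _spillover_parent(small: Clone, big: Clone) -> str | None:
    """Locus at which ``small`` is a one-locus dropout image of ``big``.

    Dropout can only erase an allele: het(parent) -> wt or hom(child
    pattern).  Returns the differing locus, or None if the pair does not
    match the single-locus dropout pattern.
    """
    diffs = [l for l in big.genotype if small.zygosity(l) != big.zygosity(l)]
    if len(diffs) != 1:
        return None
    locus = diffs[0]
    if big.zygosity(locus) == HET and small.zygosity(locus) in (WT, HOM):
        return locus
    return None


def _ado_rate_at(ado, locus: str) -> float:
    """Per-allele dropout rate at a locus from a ratio or mapping of ratios."""
    if isinstance(ado, Mapping):
        ratio = ado.get(locus)
        if ratio is None:
            ratio = float(np.mean(list(ado.values())))
    else:
        ratio = float(ado)
    return allele_rate_from_ratio(ratio)


def identify_clones(
    genotypes: pd.DataFrame,
    somatic_loci: Sequence[str],
    ado,
    *,
    min_cells: int = 10,
    min_frequency: float = 0.001,
    alpha: float = 0.01,
    doublet_rate: float = 0.02,
) -> list[Clone]:
    """Group complete cells into clones, merging ADO artifacts.

    ``ado`` is the sample-level ADO ratio (hom/het appearance ratio at
    germline het SNPs) or a per-locus mapping of such ratios.  Returns
    somatic clones only (cells that are wild type at every somatic locus
    form the implicit wild-type population); frequencies are relative to
    all complete cells including wild type.
    """
    missing_loci = [l for l in somatic_loci if l not in genotypes.columns]
    if missing_loci:
        raise ValueError(f"somatic loci absent from matrix: {missing_loci}")
    mat = genotypes[list(somatic_loci)]
    complete = mat.loc[(mat.to_numpy() != MISSING).all(axis=1)]
    n_total = len(complete)
    if n_total == 0:
        raise ValueError("no cells with complete genotypes at the somatic loci")

    grouped = complete.groupby(list(somatic_loci), sort=False).size()
    groups: list[Clone] = []
    for vec, count in grouped.items():
        vec = vec if isinstance(vec, tuple) else (vec,)
        geno = dict(zip(somatic_loci, (int(v) for v in vec)))
        if all(g == WT for g in geno.values()):
            continue  # wild-type population
        groups.append(
            Clone(genotype=geno, n_cells=int(count), frequency=count / n_total)
        )

    retained = [
        g
        for g in groups
        if g.n_cells >= min_cells and g.frequency >= min_frequency
    ]
    retained.sort(key=lambda c: (-c.n_cells, c.key()))

    # ADO-spillover merge, smallest groups first
    merged: list[Clone] = []
    for clone in sorted(retained, key=lambda c: (c.n_cells, c.key())):
        target = None
        for big in retained:
            if big is clone or big.n_cells <= clone.n_cells:
                continue
            if "merged_away" in big.flags:
                continue
            locus = _spillover_parent(clone, big)
            if locus is None:
                continue
            d = _ado_rate_at(ado, locus)
            n = clone.n_cells + big.n_cells
            p = stats.binom.sf(clone.n_cells - 1, n, d)
            if p >= alpha:
                target = big
                break
        if target is not None:
            target.n_cells += clone.n_cells
            target.frequency += clone.frequency
            target.flags.add("ado_merged")
            clone.flags.add("merged_away")
        else:
            merged.append(clone)

    # doublet flagging: union of two disjoint retained clones
    by_set = {c.mutation_set: c for c in merged}
    for clone in merged:
        ms = clone.mutation_set
        for other in merged:
            om = other.mutation_set
            if om >= ms or not om or not (ms - om):
                continue
            rest = ms - om
            mate = by_set.get(frozenset(rest))
            if mate is None or (mate.mutation_set & om):
                continue
            expected = 2.0 * doublet_rate * other.frequency * mate.frequency * n_total
            if clone.n_cells <= expected + 3.0 * np.sqrt(max(expected, 1.0)):
                clone.flags.add("putative_doublet")
                break

    merged.sort(key=lambda c: (-c.n_cells, c.key()))
    for i, clone in enumerate(merged, start=1):
        clone.clone_id = f"clone{i:02d}"
    return merged


def build_hierarchy(clones: Sequence[Clone]) -> list[Clone]:
    """Assign parents by mutation-set containment; returns the forest.

    The parent of clone C is the retained clone with the largest mutation
    set strictly contained in C's (ties break toward the larger clone,
    then lexicographic genotype, flagged ambiguous), or the het version of
    C when C is hom at exactly one locus (LOH edge).  Clones flagged as
    putative doublets are excluded.  Parentless clones are founding clones.
    """
    nodes = [c for c in clones if "putative_doublet" not in c.flags]
    for clone in nodes:
        clone.parent = None
        clone.flags.discard("founding")
        clone.flags.discard("subclone")
        candidates = []
        for other in nodes:
            if other is clone:
                continue
            if other.mutation_set == clone.mutation_set:
                hom_diff = [
                    l
                    for l in clone.mutation_set
                    if clone.zygosity(l) == HOM and other.zygosity(l) == HET
                ]
                same = all(
                    clone.zygosity(l) == other.zygosity(l)
                    for l in clone.mutation_set
                    if l not in hom_diff
                )
                if len(hom_diff) == 1 and same:
                    # LOH edge: parent het where child hom at one locus
                    candidates.append((len(other.mutation_set) + 0.5, other))
            elif other.mutation_set < clone.mutation_set:
                compatible = all(
                    other.zygosity(l) in (clone.zygosity(l), HET)
                    for l in other.mutation_set
                )
                if compatible:
                    candidates.append((len(other.mutation_set), other))
        if not candidates:
            clone.flags.add("founding")
            continue
        best = max(candidates, key=lambda t: (t[0], t[1].n_cells))
        maximal = [c for s, c in candidates if s == best[0]]
        if len(maximal) > 1:
            maximal.sort(key=lambda c: (-c.n_cells, c.key()))
            clone.flags.add("ambiguous_parent")
            logger.warning(
                "clone %s: ambiguous parent, attaching to larger clone %s",
                clone.clone_id,
                maximal[0].clone_id,
            )
            clone.parent = maximal[0].clone_id
        else:
            clone.parent = best[1].clone_id
        clone.flags.add("subclone")
    return list(nodes)


def detect_loh_subclones(
    hierarchy: Sequence[Clone],
    ado,
    *,
    alpha: float = 0.01,
) -> list[Clone]:
    """Flag hom-at-one-locus clones that reject the ADO-spillover null.

    A clone homozygous at exactly one somatic locus whose het counterpart
    exists in the hierarchy is a genuine CN-LOH progression subclone if
    its size cannot be explained by dropout from the het parent (same
    binomial test as clone identification).  Hom clones with no het parent
    are flagged ``orphan_hom``.
    """
    flagged = []
    for clone in hierarchy:
        hom_loci = [l for l in clone.mutation_set if clone.zygosity(l) == HOM]
        if len(hom_loci) != 1:
            continue
        locus = hom_loci[0]
        parent = None
        for other in hierarchy:
            if other is clone:
                continue
            if (
                other.mutation_set == clone.mutation_set
                and other.zygosity(locus) == HET
                and all(
                    other.zygosity(l) == clone.zygosity(l)
                    for l in clone.mutation_set
                    if l != locus
                )
            ):
                parent = other
                break
        if parent is None:
            clone.flags.add("orphan_hom")
            continue
        d = _ado_rate_at(ado, locus)
        n = clone.n_cells + parent.n_cells
        p = stats.binom.sf(clone.n_cells - 1, n, d)
        if p < alpha:
            clone.flags.add("loh_subclone")
            flagged.append(clone)
    return flagged


@dataclass
class CloneTimeline:
    """Per-mutation detection trajectory across serial bulk samples."""

    locus: str
    ages: list[float]
    vafs: list[float]
    detected: list[bool]

    @property
    def first_detection_age(self) -> float | None:
        for a, d in zip(self.ages, self.detected):
            if d:
                return a
        return None

    @property
    def last_detection_age(self) -> float | None:
        last = None
        for a, d in zip(self.ages, self.detected):
            if d:
                last = a
        return last

    @property
    def fold_change(self) -> float | None:
        """VAF(last detection) / VAF(first detection); None if detected < 2 times."""
        pts = [(a, v) for a, v, d in zip(self.ages, self.vafs, self.detected) if d]
        if len(pts) < 2:
            return None
        return pts[-1][1] / pts[0][1]


def track_clones(filtered_calls: pd.DataFrame) -> list[CloneTimeline]:
    """Build per-mutation VAF trajectories from filtered serial bulk calls.

    ``filtered_calls`` is the output of the bulk filter over serial
    samples, with columns locus, age, vaf, status.  A mutation counts as
    detected at a timepoint when its status is ``pass``.  Duplicate ages
    are rejected.
    """
    ages = sorted(filtered_calls["age"].unique())
    per_sample = filtered_calls.groupby("age")["sample_id"].nunique() if "sample_id" in filtered_calls else None
    if per_sample is not None and (per_sample > 1).any():
        raise ValueError("duplicate ages across samples")
    timelines = []
    for locus, grp in filtered_calls.groupby("locus", sort=True):
        grp = grp.sort_values("age")
        if grp["age"].duplicated().any():
            raise ValueError(f"duplicate ages for locus {locus}")
        timelines.append(
            CloneTimeline(
                locus=str(locus),
                ages=list(grp["age"]),
                vafs=list(grp["vaf"]),
                detected=list(grp["status"] == "pass"),
            )
        )
    return timelines


def clone_exclusivity_summary(
    hierarchy: Sequence[Clone],
    gene_of: Mapping[str, str] | None = None,
) -> dict[str, int]:
    """Count clones whose mutations touch exactly one gene.

    ``gene_of`` maps locus -> gene; by default the gene is parsed from the
    locus name (``GENE_suffix``).  Clones flagged as putative doublets are
    excluded; clones touching more than one gene count as ``co_mutated``.
    """
    from .simulate import gene_of_locus

    summary: dict[str, int] = {"co_mutated": 0}
    for clone in hierarchy:
        if "putative_doublet" in clone.flags:
            continue
        genes = set()
        for locus in clone.mutation_set:
            if gene_of is not None:
                if locus not in gene_of:
                    raise ValueError(f"unannotated locus {locus}")
                genes.add(gene_of[locus])
            else:
                genes.add(gene_of_locus(locus))
        if len(genes) == 1:
            g = genes.pop()
            summary[g] = summary.get(g, 0) + 1
        elif genes:
            summary["co_mutated"] += 1
    return summary


def clones_to_frame(clones: Sequence[Clone]) -> pd.DataFrame:
    """Tabular view of a clone list (one row per clone)."""
    rows = []
    for c in clones:
        rows.append(
            {
                "clone_id": c.clone_id,
                "genotype": ";".join(
                    f"{l}:{ {WT: 'wt', HET: 'het', HOM: 'hom'}[g] }"
                    for l, g in sorted(c.genotype.items())
                    if g != WT
                ),
                "n_cells": c.n_cells,
                "frequency": c.frequency,
                "parent": c.parent or "",
                "flags": ",".join(sorted(c.flags)),
            }
        )
    return pd.DataFrame(rows)
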