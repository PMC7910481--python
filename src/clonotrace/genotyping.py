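"""Per-cell genotype calling and dropout quantification.

Genotypes are called from raw per-cell depth/alt counts with fixed
thresholds: a locus is missing below a minimum depth; a variant is present
when the alt count and alt fraction both clear their thresholds; present
calls split into heterozygous and homozygous by alt fraction.

Allelic dropout (ADO) is quantified at germline heterozygous SNPs as the
ratio of hom-appearing to het-appearing cells.  Under independent
per-allele dropout at rate ``d`` this ratio has expectation ``2d/(1-d)``
(a het cell appears hom when exactly one allele drops, ``2d(1-d)``, and
het when both survive, ``(1-d)^2``).

Technical dropout is the fraction of bulk-detected, designable mutations
that were successfully genotyped in at least one cell.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "MISSING",
    "WT",
    "HET",
    "HOM",
    "GENOTYPE_LABELS",
    "call_genotypes",
    "genotype_matrix",
    "AdoEstimate",
    "estimate_ado",
    "ado_ratio_from_rate",
    "allele_rate_from_ratio",
    "select_informative_snps",
    "technical_dropout",
]

# integer genotype codes used throughout
MISSING, WT, HET, HOM = -1, 0, 1, 2
GENOTYPE_LABELS = {MISSING: "missing", WT: "wt", HET: "het", HOM: "hom"}


def call_genotypes(
    depth,
    alt,
    *,
    min_depth: int = 10,
    min_alt: int = 3,
    min_alt_frac: float = 0.30,
    hom_frac: float = 0.90,
):
    """Call genotypes from depth/alt counts (scalar or array, vectorized).

    depth < ``min_depth`` -> missing; the variant is present iff
    ``alt >= min_alt`` and ``alt/depth >= min_alt_frac``; present calls
    with fraction >= ``hom_frac`` are hom, otherwise het; absent -> wt.
    """
    depth_a = np.asarray(depth)
    alt_a = np.asarray(alt)
    if (alt_a > depth_a).any():
        raise ValueError("alt count exceeds depth")
    if (depth_a < 0).any() or (alt_a < 0).any():
        raise ValueError("counts must be nonnegative")
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(depth_a > 0, alt_a / np.maximum(depth_a, 1), 0.0)
    present = (alt_a >= min_alt) & (frac >= min_alt_frac)
    geno = np.where(present, np.where(frac >= hom_frac, HOM, HET), WT)
    geno = np.where(depth_a < min_depth, MISSING, geno)
    if np.isscalar(depth) or depth_a.ndim == 0:
        return int(geno)
    return geno.astype(np.int8)


def genotype_matrix(depth: pd.DataFrame, alt: pd.DataFrame, **kwargs) -> pd.DataFrame:
    """Apply :func:`call_genotypes` to aligned cells x loci count frames."""
    if not depth.index.equals(alt.index) or not depth.columns.equals(alt.columns):
        raise ValueError("depth and alt frames must be aligned")
    codes = call_genotypes(depth.to_numpy(), alt.to_numpy(), **kwargs)
    return pd.DataFrame(codes, index=depth.index, columns=depth.columns)


def ado_ratio_from_rate(d: float) -> float:
    """Expected hom/het appearance ratio for per-allele dropout rate ``d``."""
    return 2.0 * d / (1.0 - d)


def allele_rate_from_ratio(ratio: float) -> float:
    """Invert :func:`ado_ratio_from_rate`: per-allele rate from observed ratio."""
    return ratio / (2.0 + ratio)


@dataclass
class AdoEstimate:
    """Allelic-dropout estimate: per-site ratios, their mean, bootstrap CI."""

    per_site: dict[str, float]
    sample_level: float
    ci: tuple[float, float]
    n_cells: int
    excluded_sites: list[str]

    @property
    def allele_rate(self) -> float:
        """Implied per-allele dropout rate."""
        return allele_rate_from_ratio(self.sample_level)


def _drop_sparse_cells(geno: pd.DataFrame, max_missing_frac: float) -> pd.DataFrame:
    missing_frac = (geno.to_numpy() == MISSING).mean(axis=1)
    return geno.loc[missing_frac <= max_missing_frac]


def estimate_ado(
    genotypes: pd.DataFrame,
    informative_sites: Sequence[str],
    *,
    n_boot: int = 100,
    seed: int = 0,
    max_missing_frac: float = 0.5,
) -> AdoEstimate:
    """Estimate ADO from het-appearing vs hom-appearing cells at het SNPs.

    Per-site ratio: (#hom-ref + #hom-alt) / #het among genotyped cells;
    sites with zero het cells are excluded (and reported).  The sample
    level is the unweighted mean over included sites; the CI is a
    percentile bootstrap over cells.  Cells missing at more than
    ``max_missing_frac`` of loci are dropped first.
    """
    sites = [s for s in informative_sites if s in genotypes.columns]
    if not sites:
        raise ValueError("no informative sites present in the genotype matrix")
    geno = _drop_sparse_cells(genotypes, max_missing_frac)
    mat = geno[sites].to_numpy()

    def site_ratios(m: np.ndarray) -> np.ndarray:
        het = (m == HET).sum(axis=0)
        hom = ((m == WT) | (m == HOM)).sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(het > 0, hom / np.maximum(het, 1), np.nan)

    ratios = site_ratios(mat)
    excluded = [s for s, r in zip(sites, ratios) if np.isnan(r)]
    if excluded:
        logger.warning("excluding %d site(s) with no het cells: %s", len(excluded), excluded)
    kept = ~np.isnan(ratios)
    if not kept.any():
        raise ValueError("no site with heterozygous cells; ADO undefined")
    sample_level = float(np.mean(ratios[kept]))

    rng = np.random.default_rng(seed)
    n = mat.shape[0]
    boots = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        r = site_ratios(mat[idx])
        boots[b] = np.nanmean(r)
    ci = (float(np.percentile(boots, 2.5)), float(np.percentile(boots, 97.5)))
    return AdoEstimate(
        per_site={s: float(r) for s, r in zip(sites, ratios) if not np.isnan(r)},
        sample_level=sample_level,
        ci=ci,
        n_cells=n,
        excluded_sites=excluded,
    )


def select_informative_snps(
    depth: pd.DataFrame,
    alt: pd.DataFrame,
    genotypes: pd.DataFrame,
    candidates: Sequence[str],
    *,
    pseudobulk_range: tuple[float, float] = (0.35, 0.65),
    min_het_frac: float = 0.20,
) -> list[str]:
    """SNPs heterozygous in the individual, judged from the cell population.

    A candidate is informative when its pseudobulk alt fraction (summed
    over cells) lies in ``pseudobulk_range`` and at least ``min_het_frac``
    of its genotyped cells are called het.
    """
    chosen = []
    lo, hi = pseudobulk_range
    for snp in candidates:
        d = depth[snp].to_numpy().sum()
        if d == 0:
            continue
        pb = alt[snp].to_numpy().sum() / d
        g = genotypes[snp].to_numpy()
        genotyped = g != MISSING
        if genotyped.sum() == 0:
            continue
        het_frac = (g == HET).sum() / genotyped.sum()
        if lo <= pb <= hi and het_frac >= min_het_frac:
            chosen.append(snp)
    return chosen


def technical_dropout(
    genotypes: pd.DataFrame,
    bulk_passing: Iterable[str],
    designable: Iterable[str],
) -> tuple[float, pd.Series]:
    """Fraction of targeted mutations genotyped in at least one cell.

    Targeted mutations are those detected by bulk sequencing and located
    in designable amplicons.  A mutation counts as genotyped when at least
    one cell carries a non-missing variant (het or hom) call.
    """
    targeted = sorted(set(bulk_passing) & set(designable))
    if not targeted:
        raise ValueError("empty targeted mutation set")
    detected = {}
    for locus in targeted:
        if locus not in genotypes.columns:
            detected[locus] = False
            continue
        g = genotypes[locus].to_numpy()
        detected[locus] = bool(((g == HET) | (g == HOM)).any())
    flags = pd.Series(detected)
    return float(flags.mean()), flags
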