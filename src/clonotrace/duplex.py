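"""Duplex consensus collapsing and bulk somatic variant filtering.

Duplex sequencing tags both strands of each source molecule; a molecule
yields a consensus read only when both strand families (alpha-beta and
beta-alpha) are observed and neither is degraded (more than 5% N bases).
Counting consensus molecules instead of raw reads suppresses strand-
specific artifacts and permits variant detection near 0.1% VAF.

Candidate somatic calls are then filtered with a fixed, ordered ruleset:
on-target, at least three duplex alternate reads, VAF >= 0.1%, no
excessive strand bias, no excessive call density in the local region, not
synonymous, not a low-VAF indel adjacent to a homopolymer run, and absent
from the matched germline comparator (cultured fibroblasts in the assay
this models).  The first failing rule is recorded as the reason code.

Cutoffs for "excessive" strand bias and regional density are not part of
the published ruleset and are exposed in :class:`FilterConfig`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = ["FilterConfig", "collapse_families", "filter_variants", "RULE_ORDER"]

MAX_N_FRACTION = 0.05
ORIENTATIONS = {"ab", "ba"}

RULE_ORDER = (
    "off_target",
    "min_alt",
    "min_vaf",
    "strand_bias",
    "region_density",
    "synonymous",
    "homopolymer_indel",
    "germline",
)


@dataclass
class FilterConfig:
    """Thresholds of the bulk somatic filter chain.

    ``min_alt`` and ``min_vaf`` are fixed by the assay design (three duplex
    alternate reads, 0.1% VAF); the remaining knobs operationalize rules
    stated only qualitatively: strand bias fails on a two-sided binomial
    test of the alt-read strand split against the site's depth split at
    ``strand_bias_alpha``; more than ``max_region_calls`` co-passing
    candidates within ``region_window`` bp fails them all; an indel below
    ``homopolymer_max_vaf`` flagged as homopolymer-adjacent fails; a
    comparator alt fraction >= ``germline_min_frac`` marks germline.
    """

    min_alt: int = 3
    min_vaf: float = 0.001
    strand_bias_alpha: float = 1e-3
    max_region_calls: int = 3
    region_window: int = 50
    homopolymer_max_vaf: float = 0.01
    germline_min_frac: float = 0.20


def collapse_families(families: pd.DataFrame) -> pd.DataFrame:
    """Collapse strand families to per-site duplex consensus counts.

    ``families`` has one row per strand family with columns ``molecule_id,
    chrom, pos, ref, alt, allele ('ref'|'alt'), orientation ('ab'|'ba'),
    n_reads, n_fraction``.  A molecule contributes one consensus read only
    if both orientations survive the N-fraction cut and agree on the
    allele.  Records with an invalid orientation are rejected and logged.

    Returns a frame with one row per site: chrom, pos, ref, alt,
    duplex_depth, duplex_alt.
    """
    required = {"molecule_id", "chrom", "pos", "ref", "alt", "allele", "orientation", "n_fraction"}
    missing = required - set(families.columns)
    if missing:
        raise ValueError(f"families table missing columns: {sorted(missing)}")
    bad = ~families["orientation"].isin(ORIENTATIONS)
    if bad.any():
        logger.warning("rejecting %d family record(s) with invalid orientation", int(bad.sum()))
        families = families.loc[~bad]
    if ((families["n_fraction"] < 0) | (families["n_fraction"] > 1)).any():
        raise ValueError("n_fraction outside [0, 1]")
    fams = families.loc[families["n_fraction"] <= MAX_N_FRACTION]

    site_cols = ["chrom", "pos", "ref", "alt"]
    rows = []
    for site, site_fams in fams.groupby(site_cols, sort=True):
        depth = 0
        alt_n = 0
        for _, mol in site_fams.groupby("molecule_id", sort=False):
            if set(mol["orientation"]) != ORIENTATIONS:
                continue  # single-strand molecule: no duplex consensus
            alleles = set(mol["allele"])
            if len(alleles) != 1:
                continue  # strand disagreement: discard molecule
            depth += 1
            alt_n += int(alleles == {"alt"})
        rows.append(dict(zip(site_cols, site)) | {"duplex_depth": depth, "duplex_alt": alt_n})
    return pd.DataFrame(rows, columns=site_cols + ["duplex_depth", "duplex_alt"])


def _strand_bias_pvalue(row: pd.Series) -> float:
    alt = int(row["alt_fwd"]) + int(row["alt_rev"])
    if alt == 0:
        return 1.0
    depth_fwd = row.get("depth_fwd")
    depth = row["duplex_depth"]
    p0 = 0.5 if pd.isna(depth_fwd) or depth == 0 else float(depth_fwd) / float(depth)
    p0 = min(max(p0, 1e-9), 1 - 1e-9)
    return float(stats.binomtest(int(row["alt_fwd"]), alt, p0, alternative="two-sided").pvalue)


def filter_variants(
    calls: pd.DataFrame,
    comparator: pd.DataFrame | None = None,
    config: FilterConfig | None = None,
) -> pd.DataFrame:
    """Label candidate calls pass/fail with the first failing rule recorded.

    ``calls`` needs: chrom, pos, ref, alt, duplex_depth, duplex_alt, and
    the annotation columns in_target, consequence, is_indel,
    homopolymer_adjacent plus strand-split counts alt_fwd/alt_rev (and
    optionally depth_fwd/depth_rev).  ``comparator`` gives germline
    reference counts per site (chrom, pos, ref, alt, depth, alt_count);
    sites without a comparator entry end up ``unclassified`` rather than
    silently passing.

    Returns a copy of ``calls`` with ``vaf``, ``status`` and ``reason``.
    """
    cfg = config or FilterConfig()
    out = calls.copy()
    if (out["duplex_alt"] > out["duplex_depth"]).any():
        raise ValueError("duplex_alt exceeds duplex_depth")
    with np.errstate(divide="ignore", invalid="ignore"):
        out["vaf"] = np.where(
            out["duplex_depth"] > 0, out["duplex_alt"] / out["duplex_depth"].clip(lower=1), 0.0
        )

    reason = pd.Series("", index=out.index, dtype=object)

    def fail(mask: pd.Series, code: str) -> None:
        sel = mask & (reason == "")
        reason.loc[sel] = code

    if "in_target" in out.columns:
        fail(~out["in_target"].astype(bool), "off_target")
    fail(out["duplex_alt"] < cfg.min_alt, "min_alt")
    fail(out["vaf"] < cfg.min_vaf, "min_vaf")

    candidates = reason == ""
    if candidates.any() and {"alt_fwd", "alt_rev"}.issubset(out.columns):
        pvals = out.loc[candidates].apply(_strand_bias_pvalue, axis=1)
        fail(pd.Series(pvals < cfg.strand_bias_alpha, index=pvals.index).reindex(out.index, fill_value=False), "strand_bias")

    # regional density: count surviving candidates within the window
    candidates = reason == ""
    group_cols = [c for c in ("sample_id", "chrom") if c in out.columns]
    if group_cols:
        dense = pd.Series(False, index=out.index)
        cand = out.loc[candidates]
        for _, grp in cand.groupby(group_cols, sort=False):
            pos = grp["pos"].to_numpy()
            order = np.argsort(pos)
            pos_sorted = pos[order]
            counts = np.searchsorted(pos_sorted, pos_sorted + cfg.region_window, side="right") - np.searchsorted(
                pos_sorted, pos_sorted - cfg.region_window, side="left"
            )
            over = counts > cfg.max_region_calls
            dense.loc[grp.index[order[over]]] = True
        fail(dense, "region_density")

    if "consequence" in out.columns:
        fail(out["consequence"].eq("synonymous"), "synonymous")
    if {"is_indel", "homopolymer_adjacent"}.issubset(out.columns):
        fail(
            out["is_indel"].astype(bool)
            & out["homopolymer_adjacent"].astype(bool)
            & (out["vaf"] < cfg.homopolymer_max_vaf),
            "homopolymer_indel",
        )

    unclassified = pd.Series(False, index=out.index)
    if comparator is not None:
        key = ["chrom", "pos", "ref", "alt"]
        comp = comparator.set_index(key)
        with np.errstate(divide="ignore", invalid="ignore"):
            comp_frac = comp["alt_count"] / comp["depth"].clip(lower=1)
        idx = pd.MultiIndex.from_frame(out[key])
        frac = comp_frac.reindex(idx)
        germline = pd.Series(
            np.nan_to_num(frac.to_numpy(dtype=float), nan=-1.0) >= cfg.germline_min_frac,
            index=out.index,
        )
        fail(germline, "germline")
        unclassified = pd.Series(frac.isna().to_numpy(), index=out.index) & (reason == "")
    else:
        unclassified = reason == ""

    out["reason"] = reason
    out["status"] = np.where(
        reason != "", "fail", np.where(unclassified, "unclassified", "pass")
    )
    return out
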