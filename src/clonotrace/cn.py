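"""Total and allele-specific copy-ratio analysis with CCF estimation.

The pipeline: per-target total copy ratios (tCR) normalized against a
panel of diploid normals, with noisy targets blacklisted; recursive binary
segmentation of log2 tCR with a permutation stopping rule (optionally
joint across serial samples of one patient so shared breakpoints are
favored); per-segment allelic-imbalance estimation from heterozygous-SNP
allele counts via a two-state haplotype HMM; segment classification into
balanced / deletion / CN-LOH / gain; and a grid posterior over cancer cell
fraction (CCF) for somatic mutations given purity and local copy number.

For a mutation with multiplicity ``m`` on local total copy number ``q`` in
a sample of purity ``rho``, a clone fraction ``c`` (the CCF) implies an
expected alt-read fraction::

    f(c) = rho * m * c / (rho * q + 2 * (1 - rho))

The CCF posterior is the binomial likelihood of the observed alt/depth
under ``f(c)`` on a uniform grid over [0, 1], normalized.  Purity and
multiplicity are inputs here; joint purity/ploidy inference is out of
scope by design.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

logger = logging.getLogger(__name__)

__all__ = [
    "CCFPosterior",
    "compute_tcr",
    "segment_tracks",
    "phase_and_classify",
    "compute_ccf",
]


# ---------------------------------------------------------------------------
# total copy ratio


def compute_tcr(
    sample_counts: pd.DataFrame,
    panel_of_normals: pd.DataFrame,
    *,
    mean_ratio_bounds: tuple[float, float] = (0.25, 4.0),
    max_cv: float = 0.5,
) -> pd.DataFrame:
    """Per-target total copy ratio against a panel of diploid normals.

    ``sample_counts``: target_id, chrom, start, end, count.
    ``panel_of_normals``: target_id plus one count column per normal
    (at least three).  tCR is the sample's per-target coverage fraction
    divided by the panel median per-target fraction.  Targets whose panel
    behavior is unstable — mean normalized ratio outside
    ``mean_ratio_bounds`` or coefficient of variation above ``max_cv`` —
    are blacklisted, as are targets absent from the panel.

    Returns the sample table with ``tcr``, ``log2_tcr``, ``blacklisted``
    and ``blacklist_reason`` columns.
    """
    normal_cols = [c for c in panel_of_normals.columns if c != "target_id"]
    if len(normal_cols) < 3:
        raise ValueError("panel of normals must contain at least 3 samples")
    if (sample_counts["count"] < 0).any():
        raise ValueError("negative counts")

    pon = panel_of_normals.set_index("target_id")[normal_cols].astype(float)
    pon_frac = pon / pon.sum(axis=0)
    median_frac = pon_frac.median(axis=1)
    # per-normal ratio to the panel median fraction: stability diagnostics
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = pon_frac.div(median_frac, axis=0)
    mean_ratio = ratios.mean(axis=1)
    cv = ratios.std(axis=1, ddof=1) / mean_ratio.replace(0, np.nan)

    out = sample_counts.copy()
    total = out["count"].sum()
    sample_frac = out["count"] / total
    med = median_frac.reindex(out["target_id"]).to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        tcr = sample_frac.to_numpy() / med
    out["tcr"] = tcr

    reason = pd.Series("", index=out.index, dtype=object)
    absent = pd.Series(np.isnan(med) | (med <= 0), index=out.index)
    reason.loc[absent] = "absent_from_panel"
    lo, hi = mean_ratio_bounds
    mr = mean_ratio.reindex(out["target_id"]).to_numpy()
    cvv = cv.reindex(out["target_id"]).to_numpy()
    unstable_mean = pd.Series((mr < lo) | (mr > hi), index=out.index).fillna(False) & (reason == "")
    reason.loc[unstable_mean] = "panel_mean_ratio"
    noisy = pd.Series(cvv > max_cv, index=out.index).fillna(False) & (reason == "")
    reason.loc[noisy] = "panel_cv"
    out["blacklisted"] = reason != ""
    out["blacklist_reason"] = reason
    with np.errstate(divide="ignore", invalid="ignore"):
        out["log2_tcr"] = np.log2(np.where(out["tcr"] > 0, out["tcr"], np.nan))
    return out


# ---------------------------------------------------------------------------
# segmentation


def _max_split_stats(x: np.ndarray, min_size: int) -> np.ndarray:
    """T-like statistic of the best mean shift at every admissible split.

    Returns an array of squared t statistics per split index (length
    n-1, zero where the split is inadmissible), computed from cumulative
    sums in O(n).
    """
    n = len(x)
    stats_sq = np.zeros(n - 1)
    if n < 2 * min_size:
        return stats_sq
    cs = np.cumsum(x)
    total = cs[-1]
    k = np.arange(1, n)
    mean_l = cs[:-1] / k
    mean_r = (total - cs[:-1]) / (n - k)
    resid_var = max(np.var(x), 1e-12)
    t_sq = (mean_l - mean_r) ** 2 / (resid_var * (1.0 / k + 1.0 / (n - k)))
    admissible = (k >= min_size) & (n - k >= min_size)
    stats_sq[admissible] = t_sq[admissible]
    return stats_sq


def _best_split(values: np.ndarray, min_size: int) -> tuple[int, float]:
    """Best split of a samples x n block; joint statistic sums over samples."""
    agg = np.zeros(values.shape[1] - 1)
    for row in values:
        agg += _max_split_stats(row, min_size)
    k = int(np.argmax(agg))
    return k + 1, float(agg[k])


def _split_pvalue(
    values: np.ndarray, stat: float, min_size: int, n_perm: int, rng: np.random.Generator
) -> float:
    exceed = 0
    n = values.shape[1]
    for _ in range(n_perm):
        perm = rng.permutation(n)
        _, s = _best_split(values[:, perm], min_size)
        if s >= stat:
            exceed += 1
    return (exceed + 1) / (n_perm + 1)


def segment_tracks(
    tracks: pd.DataFrame,
    value_columns: list[str] | None = None,
    *,
    joint: bool = True,
    alpha: float = 0.01,
    n_perm: int = 200,
    min_size: int = 5,
    min_targets: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Recursive binary segmentation of log2 tCR tracks.

    ``tracks`` has chrom, start, end and one value column per sample
    (default: every column beyond the coordinates).  Splitting recurses
    while a permutation test of the best mean-shift statistic is
    significant at ``alpha``; in joint mode the split statistic sums over
    samples so breakpoints shared across serial samples are favored.
    Chromosomes with fewer than ``min_targets`` targets yield a single
    segment with a warning.

    Returns one row per (chrom, segment) with start/end and the per-sample
    segment means.
    """
    coord_cols = ["chrom", "start", "end"]
    if value_columns is None:
        value_columns = [c for c in tracks.columns if c not in coord_cols + ["target_id"]]
    rng = np.random.default_rng(seed)
    seg_rows = []
    for chrom, grp in tracks.groupby("chrom", sort=False):
        grp = grp.sort_values("start")
        vals = grp[value_columns].to_numpy().T  # samples x n
        vals = np.nan_to_num(vals, nan=0.0)
        n = vals.shape[1]
        if n < min_targets:
            logger.warning("chromosome %s has %d targets; single segment", chrom, n)
            bounds = [(0, n)]
        else:
            bounds = []

            def recurse(lo: int, hi: int) -> None:
                block = vals[:, lo:hi]
                if hi - lo < 2 * min_size:
                    bounds.append((lo, hi))
                    return
                if joint:
                    k, stat = _best_split(block, min_size)
                    p = _split_pvalue(block, stat, min_size, n_perm, rng)
                else:
                    # split on the single most significant sample
                    best = None
                    for i in range(block.shape[0]):
                        k_i, s_i = _best_split(block[i : i + 1], min_size)
                        p_i = _split_pvalue(block[i : i + 1], s_i, min_size, n_perm, rng)
                        if best is None or p_i < best[2]:
                            best = (k_i, s_i, p_i)
                    k, _, p = best
                if p < alpha:
                    recurse(lo, lo + k)
                    recurse(lo + k, hi)
                else:
                    bounds.append((lo, hi))

            recurse(0, n)
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        for lo, hi in sorted(bounds):
            row = {
                "chrom": chrom,
                "start": int(starts[lo]),
                "end": int(ends[hi - 1]),
                "n_targets": hi - lo,
            }
            for i, col in enumerate(value_columns):
                row[f"mean_{col}"] = float(np.mean(vals[i, lo:hi]))
            seg_rows.append(row)
    return pd.DataFrame(seg_rows)


# ---------------------------------------------------------------------------
# allelic imbalance: haplotype HMM, classification


def _mixture_loglik(theta: float, alt: np.ndarray, depth: np.ndarray) -> float:
    la = stats.binom.logpmf(alt, depth, theta)
    lb = stats.binom.logpmf(alt, depth, 1.0 - theta)
    m = np.maximum(la, lb)
    return float(np.sum(m + np.log(0.5 * np.exp(la - m) + 0.5 * np.exp(lb - m))))


def _fit_imbalance(alt: np.ndarray, depth: np.ndarray) -> tuple[float, float]:
    """ML imbalance parameter theta in [0.5, 1) and the LRT p-value vs 0.5."""
    res = optimize.minimize_scalar(
        lambda t: -_mixture_loglik(t, alt, depth),
        bounds=(0.5, 0.995),
        method="bounded",
    )
    theta = float(res.x)
    l1 = -float(res.fun)
    l0 = _mixture_loglik(0.5, alt, depth)
    lrt = max(0.0, 2.0 * (l1 - l0))
    pval = float(stats.chi2.sf(lrt, df=1))
    return theta, pval


def _viterbi_haplotypes(
    alt: np.ndarray,
    depth: np.ndarray,
    theta: float,
    *,
    switch_prob: float = 0.01,
    prior_alt_on_a: np.ndarray | None = None,
) -> np.ndarray:
    """Viterbi path of the over-represented haplotype (0 = A, 1 = B).

    Emission for state "A over-represented": the SNP's alt count is
    binomial with success ``theta`` if its alt allele lies on haplotype A
    (prior probability ``prior_alt_on_a``), else ``1 - theta``; the
    state-B emission mirrors it.  Without priors the two states are
    symmetric and the path is resolved up to a global label swap.
    """
    n = len(alt)
    if prior_alt_on_a is None:
        prior = np.full(n, 0.5)
    else:
        prior = np.clip(np.asarray(prior_alt_on_a, dtype=float), 1e-6, 1 - 1e-6)
    lt = stats.binom.logpmf(alt, depth, theta)
    lf = stats.binom.logpmf(alt, depth, 1.0 - theta)

    def logsum(a, b):
        m = np.maximum(a, b)
        return m + np.log(np.exp(a - m) + np.exp(b - m))

    # state 0: hap A over-represented; state 1: hap B over-represented
    em0 = logsum(np.log(prior) + lt, np.log1p(-prior) + lf)
    em1 = logsum(np.log(prior) + lf, np.log1p(-prior) + lt)
    em = np.vstack([em0, em1])

    stay = np.log1p(-switch_prob)
    move = np.log(switch_prob)
    delta = em[:, 0].copy()
    back = np.zeros((2, n), dtype=np.int8)
    for i in range(1, n):
        for s in range(2):
            cand = delta + np.where(np.arange(2) == s, stay, move)
            back[s, i] = int(np.argmax(cand))
            em[s, i] += cand[back[s, i]]
        delta = em[:, i]
    path = np.zeros(n, dtype=np.int8)
    path[-1] = int(np.argmax(delta))
    for i in range(n - 1, 0, -1):
        path[i - 1] = back[path[i], i]
    return path


def phase_and_classify(
    segments: pd.DataFrame,
    snps: pd.DataFrame,
    *,
    tcr_column: str | None = None,
    switch_prob: float = 0.01,
    alpha: float = 0.01,
    loh_log2_window: float = 0.15,
    min_snps: int = 5,
    prior_weight: float = 0.9,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Estimate per-segment allelic imbalance, phase SNPs, classify events.

    ``segments`` is the output of :func:`segment_tracks` (one mean log2
    tCR column, selected via ``tcr_column`` or the first ``mean_*``
    column).  ``snps`` needs chrom, pos, ref_count, alt_count and may
    carry a ``prior_hap`` column ('A'/'B', e.g. from population phasing)
    used as a per-SNP state prior with weight ``prior_weight``.

    Classification: segments whose imbalance likelihood-ratio test is not
    significant at ``alpha`` are ``balanced``; significant imbalance is a
    ``deletion`` if mean log2 tCR < -``loh_log2_window``, ``cn_loh`` if
    within the window, and ``gain`` above it.  Segments with fewer than
    ``min_snps`` heterozygous SNPs are ``indeterminate``.

    Returns (segments with allelic_ratio/imbalance_p/class, snps with
    hap and phased_vaf).
    """
    if tcr_column is None:
        means = [c for c in segments.columns if c.startswith("mean_")]
        if not means:
            raise ValueError("segments frame has no mean_* column")
        tcr_column = means[0]
    seg_out = segments.copy()
    snp_out = snps.copy()
    snp_out["segment_index"] = -1
    snp_out["hap"] = ""
    snp_out["phased_vaf"] = np.nan
    seg_out["allelic_ratio"] = np.nan
    seg_out["imbalance_p"] = np.nan
    seg_out["n_snps"] = 0
    seg_out["class"] = "indeterminate"

    for idx, seg in seg_out.iterrows():
        mask = (
            (snp_out["chrom"] == seg["chrom"])
            & (snp_out["pos"] >= seg["start"])
            & (snp_out["pos"] <= seg["end"])
        )
        sub = snp_out.loc[mask].sort_values("pos")
        seg_out.loc[idx, "n_snps"] = len(sub)
        if len(sub) < min_snps:
            continue
        alt = sub["alt_count"].to_numpy()
        depth = (sub["alt_count"] + sub["ref_count"]).to_numpy()
        theta, pval = _fit_imbalance(alt, depth)
        seg_out.loc[idx, "allelic_ratio"] = theta
        seg_out.loc[idx, "imbalance_p"] = pval

        prior = None
        if "prior_hap" in sub.columns:
            prior = np.where(sub["prior_hap"].to_numpy() == "A", prior_weight, 1 - prior_weight)
        path = _viterbi_haplotypes(alt, depth, theta, switch_prob=switch_prob, prior_alt_on_a=prior)
        with np.errstate(divide="ignore", invalid="ignore"):
            af = alt / np.maximum(depth, 1)
        # per-SNP MAP of the alt allele's haplotype given the state path
        la = stats.binom.logpmf(alt, depth, theta)
        lb = stats.binom.logpmf(alt, depth, 1.0 - theta)
        pr = np.full(len(sub), 0.5) if prior is None else prior
        alt_on_over = np.log(pr) + la > np.log1p(-pr) + lb
        alt_on_a = np.where(path == 0, alt_on_over, ~alt_on_over)
        snp_out.loc[sub.index, "hap"] = np.where(alt_on_a, "A", "B")
        snp_out.loc[sub.index, "phased_vaf"] = np.where(alt_on_a, af, 1.0 - af)
        snp_out.loc[sub.index, "segment_index"] = idx

        log2_tcr = seg[tcr_column]
        if pval >= alpha:
            seg_out.loc[idx, "class"] = "balanced"
        elif log2_tcr < -loh_log2_window:
            seg_out.loc[idx, "class"] = "deletion"
        elif log2_tcr > loh_log2_window:
            seg_out.loc[idx, "class"] = "gain"
        else:
            seg_out.loc[idx, "class"] = "cn_loh"
    return seg_out, snp_out


# ---------------------------------------------------------------------------
# cancer cell fraction


@dataclass
class CCFPosterior:
    """Discretized posterior over cancer cell fraction in [0, 1]."""

    grid: np.ndarray
    prob: np.ndarray
    mode: float
    ci95: tuple[float, float]

    def central_interval(self, level: float = 0.95) -> tuple[float, float]:
        cdf = np.cumsum(self.prob)
        lo = float(self.grid[np.searchsorted(cdf, (1 - level) / 2)])
        hi = float(self.grid[min(np.searchsorted(cdf, 1 - (1 - level) / 2), len(self.grid) - 1)])
        return lo, hi


def compute_ccf(
    alt: int,
    depth: int,
    purity: float,
    local_total_cn: int,
    multiplicity: int,
    *,
    grid_points: int = 101,
) -> CCFPosterior:
    """Grid posterior over CCF given purity and local copy number.

    Expected alt fraction at CCF ``c`` is
    ``purity * multiplicity * c / (purity * q + 2 * (1 - purity))`` with
    ``q = local_total_cn``; the posterior is the binomial likelihood under
    a uniform prior, normalized on the grid.
    """
    if not 0.0 < purity <= 1.0:
        raise ValueError("purity must be in (0, 1]")
    q, m = local_total_cn, multiplicity
    if q < 1 or not 1 <= m <= q:
        raise ValueError("need local_total_cn >= 1 and 1 <= multiplicity <= local_total_cn")
    if alt > depth:
        raise ValueError("alt exceeds depth")
    grid = np.linspace(0.0, 1.0, grid_points)
    denom = purity * q + 2.0 * (1.0 - purity)
    f = purity * m * grid / denom
    if (f > 1.0 + 1e-12).any():
        raise ValueError("inconsistent purity/copy-number: implied alt fraction > 1")
    f = np.clip(f, 0.0, 1.0)
    loglik = stats.binom.logpmf(alt, depth, np.clip(f, 1e-12, 1 - 1e-12))
    loglik[f <= 0] = stats.binom.logpmf(alt, depth, 1e-12)
    loglik -= loglik.max()
    prob = np.exp(loglik)
    prob /= prob.sum()
    mode = float(grid[int(np.argmax(prob))])
    post = CCFPosterior(grid=grid, prob=prob, mode=mode, ci95=(0.0, 1.0))
    post.ci95 = post.central_interval(0.95)
    return post
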