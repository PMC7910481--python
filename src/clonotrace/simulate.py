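"""Synthetic data generation for clonal-hematopoiesis inference.

Everything downstream of raw sequencing is driven by three kinds of count
tables: per-cell x per-locus depth/alt matrices (single-cell DNA-seq),
per-site duplex-consensus ref/alt counts (bulk error-corrected sequencing),
and per-target coverage plus heterozygous-SNP allele counts (exome-style
copy number).  This module generates all three from a known clonal ground
truth so that genotyping, clone reconstruction, copy-number classification,
and cohort statistics can be validated end to end.

The generative model:

* A clonal hierarchy is a forest of :class:`SimClone` objects.  Each clone
  carries a set of ``(locus, zygosity)`` mutations; cell fractions (plus an
  implicit wild-type remainder) sum to one.  A child either adds mutations
  to its parent's set or converts exactly one heterozygous mutation to
  homozygous (copy-neutral LOH progression).
* Single cells are multinomial draws over clones.  Doublets merge the
  allele sets of two independently drawn cells and double the expected
  depth.  Each allele copy independently drops out with probability
  ``ado_rate``; if every copy at a locus drops, the locus yields no reads
  and the genotype is missing.  Read depth is negative-binomial
  (overdispersed amplicon coverage) and alt counts are binomial around the
  surviving-allele fraction perturbed by a per-base substitution error.
* Bulk duplex counts are binomial draws around the true VAF
  ``sum(clone fraction * multiplicity / 2)`` at a fixed consensus depth,
  with background error-only sites at the substitution rate.
* Exome-style counts follow per-target efficiencies shared with an emitted
  panel of normals, with means proportional to
  ``purity * (a + b) / 2 + (1 - purity)`` for truth allele pair ``(a, b)``.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "SimClone",
    "SimConfig",
    "SimCellData",
    "validate_hierarchy",
    "wild_type_fraction",
    "simulate_cells",
    "simulate_bulk_duplex",
    "simulate_exome_counts",
    "random_hierarchy",
    "simulate_cohort",
    "gene_of_locus",
]

HET = "het"
HOM = "hom"


@dataclass(frozen=True)
class SimClone:
    """One simulated clone: a mutation set plus its sampled-cell fraction.

    ``mutations`` maps locus name -> zygosity ("het" or "hom").  The locus
    naming convention ``GENE_p.X`` lets downstream summaries recover the
    gene; anything before the first underscore is treated as the gene.
    """

    id: str
    parent_id: str | None
    mutations: Mapping[str, str]
    cell_fraction: float

    def __post_init__(self):
        object.__setattr__(self, "mutations", dict(self.mutations))
        for locus, zyg in self.mutations.items():
            if zyg not in (HET, HOM):
                raise ValueError(f"bad zygosity {zyg!r} at {locus}")
        if not 0.0 <= self.cell_fraction <= 1.0:
            raise ValueError("cell_fraction must be in [0, 1]")


@dataclass
class SimConfig:
    """Parameters of the synthetic-data generator.

    Defaults mirror the scale of a targeted single-cell DNA panel on bone
    marrow: thousands of cells per sample, per-allele dropout of 5%, mean
    amplicon depth ~80x, and duplex consensus depth of 20,000 (sufficient
    to resolve clones at 0.1% VAF).
    """

    n_cells: int = 5000
    ado_rate: float = 0.05
    doublet_rate: float = 0.02
    depth_mean: float = 80.0
    depth_dispersion: float = 10.0
    seq_error: float = 1e-3
    bulk_depth: int = 20000
    n_snps: int = 20
    n_background_sites: int = 20
    purity: float = 1.0
    seed: int = 0

    def __post_init__(self):
        for name in ("ado_rate", "doublet_rate", "seq_error"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ValueError(f"{name} must be in [0, 1)")
        if self.depth_mean <= 0 or self.depth_dispersion <= 0:
            raise ValueError("depth parameters must be positive")
        if not 0.0 <= self.purity <= 1.0:
            raise ValueError("purity must be in [0, 1]")
        if self.bulk_depth <= 0 or self.n_cells <= 0:
            raise ValueError("n_cells and bulk_depth must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "seed" not in data:
            raise ValueError("config file must set an explicit seed")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


@dataclass
class SimCellData:
    """Simulated single-cell count matrices plus ground truth.

    ``depth`` and ``alt`` are cells x loci DataFrames; ``truth`` has one
    row per cell (assigned clone, doublet flag and partner clone); ``loci``
    annotates each locus as somatic or germline-het SNP.
    """

    depth: pd.DataFrame
    alt: pd.DataFrame
    truth: pd.DataFrame
    loci: pd.DataFrame

    @property
    def somatic_loci(self) -> list[str]:
        return list(self.loci.loc[self.loci["kind"] == "somatic", "locus"])

    @property
    def snp_loci(self) -> list[str]:
        return list(self.loci.loc[self.loci["kind"] == "snp", "locus"])


def gene_of_locus(locus: str) -> str:
    """Gene symbol encoded in a locus name (``EIF6_p.N106S`` -> ``EIF6``)."""
    return locus.split("_", 1)[0]


def wild_type_fraction(hierarchy: Sequence[SimClone]) -> float:
    return 1.0 - sum(c.cell_fraction for c in hierarchy)


def validate_hierarchy(hierarchy: Sequence[SimClone]) -> None:
    """Check hierarchy invariants; raise ValueError on violation.

    Fractions (with the implicit wild-type remainder) must sum to at most
    one, and each child's mutation set must extend its parent's, or match
    it up to a single het->hom conversion.
    """
    by_id = {c.id: c for c in hierarchy}
    if len(by_id) != len(hierarchy):
        raise ValueError("duplicate clone ids")
    total = sum(c.cell_fraction for c in hierarchy)
    if total > 1.0 + 1e-9:
        raise ValueError(f"clone fractions sum to {total:.4f} > 1")
    for clone in hierarchy:
        if clone.parent_id is None:
            continue
        if clone.parent_id not in by_id:
            raise ValueError(f"{clone.id}: unknown parent {clone.parent_id}")
        parent = by_id[clone.parent_id]
        missing = set(parent.mutations) - set(clone.mutations)
        if missing:
            raise ValueError(f"{clone.id}: lost parental mutations {missing}")
        changed = [
            loc
            for loc, zyg in parent.mutations.items()
            if clone.mutations[loc] != zyg
        ]
        for loc in changed:
            if not (parent.mutations[loc] == HET and clone.mutations[loc] == HOM):
                raise ValueError(f"{clone.id}: illegal zygosity change at {loc}")
        added = set(clone.mutations) - set(parent.mutations)
        if changed and (len(changed) > 1 or added):
            raise ValueError(
                f"{clone.id}: LOH progression must be a single het->hom change"
            )
        if not changed and not added:
            raise ValueError(f"{clone.id}: identical to parent {parent.id}")


def _allele_copies(
    hierarchy: Sequence[SimClone], somatic: Sequence[str], n_snps: int
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Per clone-state x locus (ref_copies, alt_copies); state 0 is wild type."""
    snp_names = [f"SNP{i + 1:02d}" for i in range(n_snps)]
    loci = list(somatic) + snp_names
    n_states = len(hierarchy) + 1
    ref = np.full((n_states, len(loci)), 2, dtype=np.int64)
    alt = np.zeros((n_states, len(loci)), dtype=np.int64)
    # germline het SNPs: every cell carries one ref and one alt copy
    ref[:, len(somatic):] = 1
    alt[:, len(somatic):] = 1
    for si, clone in enumerate(hierarchy, start=1):
        for locus, zyg in clone.mutations.items():
            j = loci.index(locus)
            alt[si, j] = 1 if zyg == HET else 2
            ref[si, j] = 2 - alt[si, j]
    return ref, alt, loci


def simulate_cells(
    hierarchy: Sequence[SimClone], config: SimConfig
) -> SimCellData:
    """Draw a single-cell depth/alt count matrix from a clonal hierarchy.

    Cells are multinomial over clone fractions (remainder wild type);
    doublets merge two draws; each allele copy drops independently with
    probability ``config.ado_rate``; depth is negative binomial and alt
    counts binomial around the surviving-allele fraction with substitution
    error ``config.seq_error``.
    """
    validate_hierarchy(hierarchy)
    rng = np.random.default_rng(config.seed)
    wt = wild_type_fraction(hierarchy)
    if wt < -1e-9:
        raise ValueError("clone fractions exceed 1")
    probs = np.array([max(wt, 0.0)] + [c.cell_fraction for c in hierarchy])
    probs = probs / probs.sum()
    somatic = sorted({loc for c in hierarchy for loc in c.mutations})
    ref_c, alt_c, loci = _allele_copies(hierarchy, somatic, config.n_snps)

    n = config.n_cells
    state = rng.choice(len(probs), size=n, p=probs)
    is_doublet = rng.random(n) < config.doublet_rate
    partner = rng.choice(len(probs), size=n, p=probs)
    partner = np.where(is_doublet, partner, -1)

    ref_copies = ref_c[state] + np.where(
        is_doublet[:, None], ref_c[np.where(partner >= 0, partner, 0)], 0
    )
    alt_copies = alt_c[state] + np.where(
        is_doublet[:, None], alt_c[np.where(partner >= 0, partner, 0)], 0
    )

    keep = 1.0 - config.ado_rate
    surv_ref = rng.binomial(ref_copies, keep)
    surv_alt = rng.binomial(alt_copies, keep)
    surviving = surv_ref + surv_alt

    mean = config.depth_mean * np.where(is_doublet, 2.0, 1.0)[:, None]
    mean = np.broadcast_to(mean, surviving.shape)
    r = config.depth_dispersion
    depth = rng.negative_binomial(r, r / (r + mean))
    depth = np.where(surviving > 0, depth, 0)

    with np.errstate(invalid="ignore", divide="ignore"):
        f0 = np.where(surviving > 0, surv_alt / np.maximum(surviving, 1), 0.0)
    e = config.seq_error
    f = f0 * (1.0 - e) + (1.0 - f0) * e
    alt = rng.binomial(depth, f)

    cell_ids = [f"cell{i:05d}" for i in range(n)]
    clone_names = ["WT"] + [c.id for c in hierarchy]
    truth = pd.DataFrame(
        {
            "cell_id": cell_ids,
            "clone_id": [clone_names[s] for s in state],
            "is_doublet": is_doublet,
            "partner_clone": [
                clone_names[p] if p >= 0 else "" for p in partner
            ],
        }
    )
    loci_df = pd.DataFrame(
        {
            "locus": loci,
            "kind": ["somatic"] * len(somatic) + ["snp"] * config.n_snps,
            "gene": [gene_of_locus(x) for x in loci],
        }
    )
    depth_df = pd.DataFrame(depth, index=cell_ids, columns=loci)
    alt_df = pd.DataFrame(alt, index=cell_ids, columns=loci)
    return SimCellData(depth=depth_df, alt=alt_df, truth=truth, loci=loci_df)


def true_bulk_vaf(
    hierarchy: Sequence[SimClone],
    fractions: Mapping[str, float] | None = None,
) -> dict[str, float]:
    """True VAF of each mutation: sum of carrier fractions x multiplicity/2."""
    fr = (
        {c.id: c.cell_fraction for c in hierarchy}
        if fractions is None
        else dict(fractions)
    )
    vaf: dict[str, float] = {}
    for clone in hierarchy:
        f = fr.get(clone.id, 0.0)
        for locus, zyg in clone.mutations.items():
            mult = 1 if zyg == HET else 2
            vaf[locus] = vaf.get(locus, 0.0) + f * mult / 2.0
    return vaf


def simulate_bulk_duplex(
    hierarchy: Sequence[SimClone],
    timepoints: Sequence[tuple[float, Mapping[str, float]]],
    config: SimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate per-timepoint duplex-consensus count tables.

    ``timepoints`` is an age-sorted sequence of ``(age, fractions)`` where
    fractions map clone id -> cell fraction at that age.  Returns a calls
    table (one row per site per timepoint, with strand-split counts and
    annotation columns consumed by the bulk filter), a germline comparator
    table (fibroblast-like reference counts, error-only at somatic sites),
    and a truth table of per-site true VAFs.
    """
    validate_hierarchy(hierarchy)
    ages = [age for age, _ in timepoints]
    if any(b <= a for a, b in zip(ages, ages[1:])):
        raise ValueError("timepoints must be strictly increasing in age")
    for _, fr in timepoints:
        for f in fr.values():
            if not 0.0 <= f <= 1.0:
                raise ValueError("clone fraction outside [0, 1]")

    rng = np.random.default_rng(config.seed + 1)
    somatic = sorted({loc for c in hierarchy for loc in c.mutations})
    background = [f"ERR_site{i + 1:03d}" for i in range(config.n_background_sites)]
    e = config.seq_error
    rows = []
    truth_rows = []
    comp_rows = []
    all_sites = somatic + background
    for locus in all_sites:
        depth = int(config.bulk_depth)
        alt = rng.binomial(depth, e)
        comp_rows.append(
            {
                "locus": locus,
                "chrom": "chr17" if locus.startswith("TP53") else "chr20",
                "pos": 1_000_000 + all_sites.index(locus) * 10_000,
                "ref": "C",
                "alt": "T",
                "depth": depth,
                "alt_count": int(alt),
            }
        )
    for age, fr in timepoints:
        sample = f"t{age:g}"
        vafs = true_bulk_vaf(hierarchy, fr)
        for locus in somatic + background:
            v = vafs.get(locus, 0.0)
            p = v * (1.0 - e) + (1.0 - v) * e
            depth = int(config.bulk_depth)
            alt = rng.binomial(depth, p)
            alt_fwd = rng.binomial(alt, 0.5)
            depth_fwd = rng.binomial(depth, 0.5)
            rows.append(
                {
                    "sample_id": sample,
                    "age": age,
                    "locus": locus,
                    "chrom": "chr17" if locus.startswith("TP53") else "chr20",
                    "pos": 1_000_000 + all_sites.index(locus) * 10_000,
                    "ref": "C",
                    "alt": "T",
                    "duplex_depth": depth,
                    "ref_count": depth - alt,
                    "alt_count": alt,
                    "duplex_alt": alt,
                    "alt_fwd": alt_fwd,
                    "alt_rev": alt - alt_fwd,
                    "depth_fwd": depth_fwd,
                    "depth_rev": depth - depth_fwd,
                    "in_target": True,
                    "consequence": "nonsynonymous",
                    "is_indel": False,
                    "homopolymer_adjacent": False,
                }
            )
            truth_rows.append(
                {"sample_id": sample, "age": age, "locus": locus, "true_vaf": v}
            )
    return pd.DataFrame(rows), pd.DataFrame(comp_rows), pd.DataFrame(truth_rows)


def simulate_exome_counts(
    segments_truth: pd.DataFrame,
    purity: float,
    config: SimConfig,
    *,
    targets_per_segment: int = 100,
    snps_per_segment: int = 30,
    n_normals: int = 8,
    target_depth: float = 200.0,
    snp_depth: float = 120.0,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate exome-style target coverage and het-SNP allele counts.

    ``segments_truth`` columns: chrom, start, end, cn_a, cn_b (integer
    allele-specific copies of haplotypes A and B).  Per-target capture
    efficiencies are shared between the tumor sample and the emitted panel
    of normals.  Returns (targets, panel_of_normals, snps) DataFrames; the
    snps table records the truth haplotype carrying the alt allele.
    """
    if not 0.0 <= purity <= 1.0:
        raise ValueError("purity must be in [0, 1]")
    if (segments_truth[["cn_a", "cn_b"]].to_numpy() < 0).any():
        raise ValueError("allele-specific copy numbers must be nonnegative")
    rng = np.random.default_rng(config.seed + 2)
    r = config.depth_dispersion

    target_rows, pon_rows, snp_rows = [], [], []
    tid = 0
    sid = 0
    for _, seg in segments_truth.iterrows():
        a, b = int(seg["cn_a"]), int(seg["cn_b"])
        cn_mean = purity * (a + b) / 2.0 + (1.0 - purity)
        span = (seg["end"] - seg["start"]) / targets_per_segment
        eff = rng.lognormal(mean=0.0, sigma=0.25, size=targets_per_segment)
        for k in range(targets_per_segment):
            start = int(seg["start"] + k * span)
            mu = target_depth * eff[k]
            count = rng.negative_binomial(r, r / (r + mu * cn_mean))
            normals = rng.negative_binomial(r, r / (r + mu), size=n_normals)
            target_rows.append(
                {
                    "target_id": f"T{tid:05d}",
                    "chrom": seg["chrom"],
                    "start": start,
                    "end": start + 150,
                    "count": int(count),
                }
            )
            pon_rows.append(
                {
                    "target_id": f"T{tid:05d}",
                    **{f"normal{j + 1}": int(normals[j]) for j in range(n_normals)},
                }
            )
            tid += 1
        tot = purity * (a + b) + (1.0 - purity) * 2.0
        snp_pos = np.sort(
            rng.integers(int(seg["start"]), int(seg["end"]), size=snps_per_segment)
        )
        for pos in snp_pos:
            alt_on_a = rng.random() < 0.5
            c_alt = a if alt_on_a else b
            frac = (purity * c_alt + (1.0 - purity) * 1.0) / tot if tot > 0 else 0.0
            depth = rng.poisson(snp_depth)
            e = config.seq_error
            alt = rng.binomial(depth, frac * (1 - e) + (1 - frac) * e)
            snp_rows.append(
                {
                    "snp_id": f"S{sid:05d}",
                    "chrom": seg["chrom"],
                    "pos": int(pos),
                    "ref_count": int(depth - alt),
                    "alt_count": int(alt),
                    "truth_hap": "A" if alt_on_a else "B",
                }
            )
            sid += 1
    return (
        pd.DataFrame(target_rows),
        pd.DataFrame(pon_rows),
        pd.DataFrame(snp_rows),
    )


_GENES = ("EIF6", "TP53", "PRPF8", "CSNK1A1")
_GENE_PROBS = (0.55, 0.30, 0.09, 0.06)


def random_hierarchy(
    rng: np.random.Generator,
    n_clones: int | None = None,
    *,
    min_fraction: float = 0.005,
    max_total: float = 0.5,
    subclone_prob: float = 0.15,
) -> list[SimClone]:
    """Draw a random clonal hierarchy resembling an observed bone-marrow sample.

    Most clones arise independently (single mutation, wild-type parent);
    with probability ``subclone_prob`` a clone is instead a subclone of an
    existing clone, adding one mutation.  Subclone fractions never exceed
    the residual fraction of their parent, reflecting the predominance of
    recently arisen subclones.  All fractions are at least ``min_fraction``.
    """
    if n_clones is None:
        n_clones = int(rng.integers(3, 7))
    raw = rng.dirichlet(np.ones(n_clones)) * (max_total - n_clones * min_fraction)
    fracs = raw + min_fraction
    order = np.argsort(fracs)[::-1]
    fracs = fracs[order]

    clones: list[SimClone] = []
    used_loci: set[str] = set()
    for i in range(n_clones):
        gene = str(rng.choice(_GENES, p=_GENE_PROBS))
        while True:
            locus = f"{gene}_m{int(rng.integers(1, 1000)):03d}"
            if locus not in used_loci:
                used_loci.add(locus)
                break
        parent: SimClone | None = None
        if clones and rng.random() < subclone_prob:
            candidates = [c for c in clones if c.cell_fraction > fracs[i]]
            if candidates:
                parent = candidates[int(rng.integers(len(candidates)))]
        muts = dict(parent.mutations) if parent else {}
        muts[locus] = HET
        clones.append(
            SimClone(
                id=f"C{i + 1}",
                parent_id=parent.id if parent else None,
                mutations=muts,
                cell_fraction=float(fracs[i]),
            )
        )
    validate_hierarchy(clones)
    return clones


def simulate_cohort(
    n_patients: int,
    seed: int,
    *,
    acquisition_rate: float = 0.08,
    max_age: float = 40.0,
) -> pd.DataFrame:
    """Simulate a patient cohort with age-dependent clone acquisition.

    Each patient acquires somatic clones as a Poisson process in age at
    ``acquisition_rate`` per year; each clone carries one mutation with a
    gene drawn from the recurrently mutated set and a low VAF.  Returns a
    tidy table with one row per mutation (patients without mutations get a
    single row with empty gene).
    """
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_patients):
        age = float(rng.uniform(0.5, max_age))
        k = rng.poisson(acquisition_rate * age)
        pid = f"P{i + 1:03d}"
        if k == 0:
            rows.append({"patient_id": pid, "age_years": age, "gene": "", "vaf": np.nan})
        for j in range(k):
            gene = str(rng.choice(_GENES, p=_GENE_PROBS))
            vaf = float(np.clip(rng.lognormal(np.log(0.005), 1.0), 0.001, 0.4))
            rows.append({"patient_id": pid, "age_years": age, "gene": gene, "vaf": vaf})
    return pd.DataFrame(rows)


def write_truth_json(
    path: str | Path,
    hierarchy: Sequence[SimClone],
    config: SimConfig,
    segments_truth: pd.DataFrame | None = None,
) -> None:
    """Write the ground-truth record of a simulation as JSON."""
    payload = {
        "clones": [
            {
                "id": c.id,
                "parent_id": c.parent_id,
                "mutations": dict(c.mutations),
                "cell_fraction": c.cell_fraction,
            }
            for c in hierarchy
        ],
        "wild_type_fraction": wild_type_fraction(hierarchy),
        "config": asdict(config),
    }
    if segments_truth is not None:
        payload["segments"] = segments_truth.to_dict(orient="records")
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
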