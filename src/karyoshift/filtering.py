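"""Reduction of raw variant records to high-confidence biallelic sites.

Two filter regimes are implemented.  The cohort regime keeps biallelic
records with minor-allele frequency >= 10% and coverage >= 20, then
requires presence in >= 60% of a line's biological replicates.  The
focal-line ("C3") regime is stricter: repeat masking, Phred quality
>= 30, scaffolds > 1 kb, coverage > 10 and detection in all replicates,
followed by a second stage keeping sites whose depth lies within the
replicate's interquartile range with >= 20 reads in at least five
replicates.  Pooled reference-allele frequencies are only computed for
sites whose replicate counts pass a chi-squared homogeneity test
(P > 0.05).

Record tables are long frames with one row per site per replicate, the
shape produced by :func:`karyoshift.io.variants_to_frame` and by the
simulator.  Every filter returns a :class:`FilterReport` so the effect
of each predicate is auditable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .io import GeneModel, RepeatMask
from .stats import TestResult, chi2_homogeneity

SiteKey = Tuple[str, int, str, str]


@dataclass(frozen=True)
class BiallelicSite:
    """A genomic position with exactly two alleles and pooled frequency."""

    scaffold: str
    position: int  # 0-based internal
    ref_allele: str
    alt_allele: str
    replicate_counts: Tuple[Tuple[int, int], ...]
    pooled_f_ref: Optional[float]
    homogeneity: Optional[TestResult]
    n_replicates_detected: int

    @property
    def key(self) -> SiteKey:
        return site_key(self.scaffold, self.position, self.ref_allele, self.alt_allele)


def site_key(scaffold: str, pos: int, ref: str, alt: str) -> SiteKey:
    """Site identity across samples, allele-order normalized."""
    a, b = sorted((ref, alt))
    return (scaffold, int(pos), a, b)


@dataclass
class FilterReport:
    """Ordered (filter_name, records_in, records_out) audit trail."""

    steps: List[Tuple[str, int, int]] = field(default_factory=list)

    def add(self, name: str, n_in: int, n_out: int) -> None:
        if n_out > n_in:
            raise ValueError(f"filter {name} increased the record count")
        self.steps.append((name, int(n_in), int(n_out)))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.steps, columns=["filter", "records_in", "records_out"])


def _apply(df: pd.DataFrame, name: str, mask: pd.Series, report: FilterReport) -> pd.DataFrame:
    out = df[mask]
    report.add(name, len(df), len(out))
    return out


def _biallelic_record_mask(df: pd.DataFrame, snps_only: bool) -> pd.Series:
    mask = df["n_alts"] == 1
    if snps_only and "is_snp" in df:
        mask &= df["is_snp"]
    return mask


def cohort_site_filter(
    records: pd.DataFrame,
    min_af: float = 0.10,
    min_cov: int = 20,
    min_bio_rep_frac: float = 0.60,
    n_bio_reps: Optional[int] = None,
    snps_only: bool = True,
    count_technical: bool = False,
) -> Tuple[pd.DataFrame, FilterReport]:
    """Cohort-regime site filter (48-line study design).

    Keeps biallelic records with minor-allele frequency >= ``min_af``
    and total depth >= ``min_cov``, then keeps sites present in at
    least ceil(``min_bio_rep_frac`` x number of biological replicates)
    biological replicates of that line (``count_technical`` switches
    the presence unit to technical replicates).  Returns one row per
    line per site with counts pooled over the passing records.
    """
    report = FilterReport()
    if records.empty or records.groupby("line")["bio_rep"].nunique().min() == 0:
        raise ValueError("each line needs at least one replicate")
    df = _apply(records, "biallelic_snp", _biallelic_record_mask(records, snps_only), report)
    minor = np.minimum(df["ref_depth"], df["alt_depth"])
    with np.errstate(invalid="ignore"):
        maf = np.where(df["total_depth"] > 0, minor / df["total_depth"], 0.0)
    df = _apply(df, f"minor_af>={min_af}", pd.Series(maf >= min_af, index=df.index), report)
    df = _apply(df, f"coverage>={min_cov}", df["total_depth"] >= min_cov, report)

    rep_col = "replicate" if count_technical else "bio_rep"
    if n_bio_reps is None:
        totals = records.groupby("line")[rep_col].nunique()
    else:
        totals = None
    keys = ["line", "scaffold", "pos", "ref", "alt"]
    presence = df.groupby(keys)[rep_col].nunique().rename("n_reps_present")
    df = df.merge(presence, on=keys)
    if totals is not None:
        needed = df["line"].map(lambda s: math.ceil(min_bio_rep_frac * totals[s]))
    else:
        needed = math.ceil(min_bio_rep_frac * n_bio_reps)
    df = _apply(df, f"present>={min_bio_rep_frac:.0%}_bio_reps", df["n_reps_present"] >= needed, report)

    pooled = (
        df.groupby(keys)
        .agg(
            ref_pooled=("ref_depth", "sum"),
            alt_pooled=("alt_depth", "sum"),
            n_reps_present=("n_reps_present", "first"),
        )
        .reset_index()
    )
    pooled["pooled_f_ref"] = pooled["ref_pooled"] / (pooled["ref_pooled"] + pooled["alt_pooled"])
    return pooled, report


def c3_site_filter(
    records: pd.DataFrame,
    mask: Optional[RepeatMask],
    scaffold_lengths: Dict[str, int],
    min_qual: float = 30.0,
    min_scaffold: int = 1000,
    min_cov_call: int = 10,
    snps_only: bool = True,
    n_replicates: Optional[int] = None,
) -> Tuple[pd.DataFrame, FilterReport]:
    """Focal-line regime, stage 1: candidate biallelic sites.

    Removes repeat-overlapping records, quality < ``min_qual``,
    scaffolds <= ``min_scaffold`` bp (strict >), coverage <=
    ``min_cov_call`` (strict >) and non-biallelic records, then keeps
    sites detected (both alleles observed) in all replicates of the
    line.  Returns the surviving long table (one row per site per
    replicate).
    """
    report = FilterReport()
    df = records
    missing = set(df["scaffold"].unique()) - set(scaffold_lengths)
    if missing:
        raise KeyError(f"scaffolds absent from length table: {sorted(missing)}")

    df = _apply(df, "biallelic_snp", _biallelic_record_mask(df, snps_only), report)
    df = _apply(df, f"qual>={min_qual}", df["qual"] >= min_qual, report)
    lengths = df["scaffold"].map(scaffold_lengths)
    df = _apply(df, f"scaffold>{min_scaffold}bp", lengths > min_scaffold, report)
    if mask is not None:
        in_repeat = df.apply(lambda r: mask.contains(r["scaffold"], r["pos"]), axis=1)
        df = _apply(df, "repeat_mask", ~in_repeat, report)
    df = _apply(df, f"coverage>{min_cov_call}", df["total_depth"] > min_cov_call, report)
    df = _apply(df, "both_alleles_observed", (df["ref_depth"] >= 1) & (df["alt_depth"] >= 1), report)

    if n_replicates is None:
        totals = records.groupby("line")["replicate"].nunique()
    keys = ["line", "scaffold", "pos", "ref", "alt"]
    detected = df.groupby(keys)["replicate"].nunique().rename("n_replicates_detected")
    df = df.merge(detected, on=keys)
    if n_replicates is None:
        required = df["line"].map(totals)
    else:
        required = n_replicates
    df = _apply(df, "detected_in_all_replicates", df["n_replicates_detected"] >= required, report)
    return df.reset_index(drop=True), report


def depth_iqr_filter(
    candidates: pd.DataFrame,
    min_reads: int = 20,
    min_reps: int = 5,
) -> Tuple[pd.DataFrame, FilterReport]:
    """Focal-line regime, stage 2: per-replicate depth-IQR filter.

    For each line and replicate the quartiles of candidate site depths
    are computed (linear-interpolation quartiles, boundaries
    inclusive); a site-replicate passes iff Q1 <= depth <= Q3 and
    depth >= ``min_reads``; a site is retained iff at least
    ``min_reps`` of its replicates pass.  Only passing site-replicates
    are returned.
    """
    report = FilterReport()
    df = candidates.copy()
    passes = pd.Series(False, index=df.index)
    for (line, rep), group in df.groupby(["line", "replicate"]):
        depths = group["total_depth"].to_numpy(dtype=float)
        if len(depths) < 4:
            raise ValueError(
                f"replicate {rep} of line {line} has {len(depths)} candidate sites; "
                "IQR undefined (need >= 4)"
            )
        q1, q3 = np.percentile(depths, [25, 75])
        ok = (group["total_depth"] >= q1) & (group["total_depth"] <= q3)
        ok &= group["total_depth"] >= min_reads
        passes.loc[group.index] = ok
    df = _apply(df, f"depth_in_IQR_and>={min_reads}", passes, report)
    keys = ["line", "scaffold", "pos", "ref", "alt"]
    n_pass = df.groupby(keys)["replicate"].nunique().rename("n_replicates_pass")
    df = df.drop(columns=["n_replicates_pass"], errors="ignore").merge(n_pass, on=keys)
    df = _apply(df, f"passes_in>={min_reps}_replicates", df["n_replicates_pass"] >= min_reps, report)
    return df.reset_index(drop=True), report


def pool_allele_frequency(
    replicate_counts: Sequence[Tuple[int, int]],
    alpha: float = 0.05,
) -> Tuple[Optional[float], TestResult]:
    """Pool one site's replicate (ref, alt) counts if homogeneous.

    Runs the chi-squared homogeneity test across replicates; when its
    p-value exceeds ``alpha`` the pooled reference-allele frequency
    sum(ref)/sum(total) is returned, otherwise ``None`` (the site is
    excluded as heterogeneous but stays reportable).
    """
    counts = np.asarray(replicate_counts, dtype=int)
    if counts.shape[0] < 2:
        raise ValueError("pooling needs at least two retained replicates")
    hom = chi2_homogeneity(counts)
    if hom.p_value > alpha:
        total = counts.sum()
        return float(counts[:, 0].sum() / total), hom
    return None, hom


def pool_site_frequencies(retained: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Pooled reference-allele frequency per line per site.

    One row per (line, site) with the homogeneity statistic; sites
    failing the homogeneity test have ``excluded_heterogeneous`` set
    and no pooled frequency.
    """
    rows = []
    keys = ["line", "scaffold", "pos", "ref", "alt"]
    for key_vals, group in retained.groupby(keys):
        counts = list(zip(group["ref_depth"], group["alt_depth"]))
        f_ref, hom = pool_allele_frequency(counts, alpha=alpha)
        rows.append(
            dict(
                zip(keys, key_vals),
                pooled_f_ref=f_ref,
                ref_pooled=int(group["ref_depth"].sum()),
                alt_pooled=int(group["alt_depth"].sum()),
                homogeneity_stat=hom.statistic,
                homogeneity_p=hom.p_value,
                n_replicates=len(counts),
                excluded_heterogeneous=f_ref is None,
            )
        )
    return pd.DataFrame(
        rows,
        columns=keys
        + [
            "pooled_f_ref",
            "ref_pooled",
            "alt_pooled",
            "homogeneity_stat",
            "homogeneity_p",
            "n_replicates",
            "excluded_heterogeneous",
        ],
    )


def genomic_ba_sites_wgs(
    records: pd.DataFrame,
    genes: Sequence[GeneModel],
    min_depth: int = 25,
    min_allele_reads: int = 10,
    snps_only: bool = True,
) -> Tuple[pd.DataFrame, FilterReport]:
    """Genomic biallelic sites in CDS for the expression-mode analysis.

    Keeps biallelic records with total depth >= ``min_depth`` and both
    allele depths >= ``min_allele_reads`` that fall inside an annotated
    CDS interval; the enclosing gene is attached.
    """
    report = FilterReport()
    df = _apply(records, "biallelic_snp", _biallelic_record_mask(records, snps_only), report)
    df = _apply(df, f"depth>={min_depth}", df["total_depth"] >= min_depth, report)
    both = (df["ref_depth"] >= min_allele_reads) & (df["alt_depth"] >= min_allele_reads)
    df = _apply(df, f"both_alleles>={min_allele_reads}", both, report)

    by_scaffold: Dict[str, List[GeneModel]] = {}
    for g in genes:
        by_scaffold.setdefault(g.scaffold, []).append(g)

    def enclosing(row) -> str:
        for g in by_scaffold.get(row["scaffold"], []):
            if g.contains(row["pos"]):
                return g.gene_id
        return ""

    gene_ids = df.apply(enclosing, axis=1) if len(df) else pd.Series([], dtype=object)
    df = df.assign(gene_id=gene_ids)
    df = _apply(df, "in_cds", df["gene_id"] != "", report)
    return df.reset_index(drop=True), report


def common_sites(
    parent_sites: Set[SiteKey],
    offspring_sites: Sequence[Set[SiteKey]],
    max_subsets: int = 200,
    seed: int = 0,
) -> Tuple[Set[SiteKey], pd.DataFrame]:
    """Common-site intersection and its rarefaction over family size.

    The intersection runs over the parent and every offspring.  The
    rarefaction table reports, for k = 1..n offspring, the mean size of
    parent-and-subset intersections over all subsets of size k when
    C(n, k) <= ``max_subsets``, otherwise over ``max_subsets`` seeded
    random subsets.
    """
    n = len(offspring_sites)
    if n == 0:
        raise ValueError("offspring list is empty")
    common = set(parent_sites)
    for s in offspring_sites:
        common &= s
    rng = np.random.default_rng(seed)
    rows = []
    for k in range(1, n + 1):
        if math.comb(n, k) <= max_subsets:
            subsets: Iterable[Tuple[int, ...]] = combinations(range(n), k)
        else:
            subsets = (tuple(rng.choice(n, size=k, replace=False)) for _ in range(max_subsets))
        sizes = []
        for subset in subsets:
            inter = set(parent_sites)
            for i in subset:
                inter &= offspring_sites[i]
            sizes.append(len(inter))
        rows.append({"k": k, "mean_common_sites": float(np.mean(sizes)), "n_subsets": len(sizes)})
    return common, pd.DataFrame(rows)
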