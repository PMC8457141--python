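"""Quantification of nuclear-genotype proportions across sibling lines.

In a dikaryon, the reference-allele frequency f_ref at single-copy
biallelic sites is a proxy for the mixing proportion p of the two
nucleotypes: sites whose reference allele belongs to nucleotype 1 sit
near p, the others near 1 - p, so an even mixture is unimodal at 0.5
and an uneven one bimodal at p / 1 - p.  This module provides the
qualitative side (presence/absence matrix, binary-distance dendrogram,
PCA on presence calls), the quantitative side (per-site parent-vs-
offspring chi-squared tests, aggregate shift tests, kernel-density mode
detection, PCA on allele frequencies, rarefaction regression), and the
:class:`NucleotypeModel` / :class:`NucleotypeResults` pair that ties
them together for a cohort.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import signal as _signal
from scipy.cluster import hierarchy as _hier
from scipy.spatial.distance import squareform
from skbio import TreeNode

from .filtering import SiteKey, pool_site_frequencies
from .stats import (
    TestResult,
    ZeroVarianceError,
    chi2_2x2,
    holm_adjust,
    linear_fit,
    mann_whitney_u,
    one_sample_t,
)


@dataclass
class LineProfile:
    """One line's allele-frequency profile over a shared site registry."""

    line_id: str
    role: str  # parent | offspring
    karyotype: str  # homokaryon | dikaryon | unknown
    site_keys: List[SiteKey]
    f_ref: np.ndarray
    counts: np.ndarray  # (n_sites, 2) pooled (ref, alt)

    def __post_init__(self) -> None:
        if len(self.site_keys) != len(self.f_ref) or len(self.f_ref) != len(self.counts):
            raise ValueError("site registry, frequencies and counts must align")


@dataclass
class ShiftResult:
    """Aggregate allele-frequency shift of an offspring from its parent."""

    line_id: str
    n_sites_tested: int
    n_sites_significant: int
    mean_delta_f_ref: float
    sd_delta: float
    t_test: Optional[TestResult]
    mw_test: Optional[TestResult]
    direction: str  # increase | decrease | none

    def __post_init__(self) -> None:
        if abs(self.mean_delta_f_ref) > 1:
            raise ValueError("|mean delta f_ref| cannot exceed 1")
        if self.n_sites_significant > self.n_sites_tested:
            raise ValueError("significant sites cannot exceed tested sites")


@dataclass
class ModeReport:
    """Detected modes of a line's allele-frequency distribution."""

    line_id: str
    n_modes: int
    mode_locations: Tuple[float, ...]
    classification: str  # unimodal | bimodal | multimodal
    bandwidth: float


def presence_absence_matrix(
    sample_loci: Dict[str, Set], min_snps: int = 4000
) -> Tuple[pd.DataFrame, List[str]]:
    """Binary presence/absence matrix over the union of polymorphic loci.

    Samples with fewer than ``min_snps`` loci are dropped; a locus
    missing from a sample is recorded as absent (0).
    """
    retained = [s for s, loci in sample_loci.items() if len(loci) >= min_snps]
    if not retained:
        raise ValueError(f"no sample carries >= {min_snps} polymorphic loci")
    all_loci = sorted(set().union(*(sample_loci[s] for s in retained)))
    data = np.zeros((len(retained), len(all_loci)), dtype=np.int8)
    index = {locus: j for j, locus in enumerate(all_loci)}
    for i, s in enumerate(retained):
        for locus in sample_loci[s]:
            data[i, index[locus]] = 1
    matrix = pd.DataFrame(data, index=retained, columns=[str(c) for c in all_loci])
    return matrix, retained


def binary_distance_matrix(matrix: pd.DataFrame) -> pd.DataFrame:
    """Pairwise binary (Jaccard) distances between sample rows.

    d(a, b) = #(exactly one of a, b is 1) / #(at least one is 1); a
    pair with an empty union is assigned distance 0 with a warning.
    """
    x = matrix.to_numpy(dtype=bool)
    inter = (x[:, None, :] & x[None, :, :]).sum(axis=2)
    union = (x[:, None, :] | x[None, :, :]).sum(axis=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        dist = np.where(union > 0, (union - inter) / np.maximum(union, 1), 0.0)
    if np.any((union == 0) & ~np.eye(len(x), dtype=bool)):
        warnings.warn("a sample pair shares no present locus; distance set to 0", stacklevel=2)
    np.fill_diagonal(dist, 0.0)
    return pd.DataFrame(dist, index=matrix.index, columns=matrix.index)


def binary_distance_tree(
    matrix: pd.DataFrame, linkage: str = "average"
) -> Tuple[pd.DataFrame, str]:
    """Binary-distance dendrogram of the presence/absence matrix.

    Returns the distance matrix and the agglomerative-clustering tree
    (default UPGMA linkage) in newick with branch lengths.
    """
    dist = binary_distance_matrix(matrix)
    condensed = squareform(dist.to_numpy(), checks=False)
    z = _hier.linkage(condensed, method=linkage)
    tree = TreeNode.from_linkage_matrix(z, list(matrix.index))
    return dist, str(tree)


def _centered_pca(x: np.ndarray) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Column-centered, unscaled PCA via SVD; variance fractions sum to 1."""
    centered = x - x.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    scores = u * s
    var = s**2
    total = var.sum()
    explained = var / total if total > 0 else np.zeros_like(var)
    return scores, vt.T, explained


def qualitative_pca(matrix: pd.DataFrame) -> Tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """PCA of the binary presence/absence matrix (centered, unscaled)."""
    if matrix.shape[0] < 2:
        raise ValueError("PCA needs at least two samples")
    scores, loadings, explained = _centered_pca(matrix.to_numpy(dtype=float))
    score_df = pd.DataFrame(
        scores, index=matrix.index, columns=[f"PC{i + 1}" for i in range(scores.shape[1])]
    )
    return score_df, loadings, explained


def per_site_shift_tests(
    parent: LineProfile,
    offspring: LineProfile,
    alpha: float = 0.05,
    continuity_correction: bool = False,
    holm: bool = False,
) -> Tuple[pd.DataFrame, ShiftResult]:
    """Per-site chi-squared tests of offspring vs parent allele counts.

    At each common site a 2x2 chi-squared compares (ref, alt) counts of
    the two lines; the aggregate shift takes delta f_ref = f_offspring
    - f_parent at the significant sites, tests the deltas against zero
    with a one-sample t test, and compares the full f_ref vectors with
    an unpaired Mann-Whitney test.  Sites with a zero total in either
    line are skipped and counted.
    """
    off_index = {k: j for j, k in enumerate(offspring.site_keys)}
    common = [
        (i, off_index[k]) for i, k in enumerate(parent.site_keys) if k in off_index
    ]
    if len(common) < 2:
        raise ValueError("lines share fewer than two common sites")
    rows = []
    deltas_sig: List[float] = []
    n_skipped = 0
    for i, j in common:
        p_ref, p_alt = parent.counts[i]
        o_ref, o_alt = offspring.counts[j]
        if p_ref + p_alt == 0 or o_ref + o_alt == 0:
            n_skipped += 1
            continue
        delta = offspring.f_ref[j] - parent.f_ref[i]
        try:
            res = chi2_2x2(
                [[p_ref, p_alt], [o_ref, o_alt]], continuity_correction=continuity_correction
            )
            stat, p_val = res.statistic, res.p_value
        except ValueError:
            n_skipped += 1
            continue
        rows.append(
            {
                "scaffold": parent.site_keys[i][0],
                "pos": parent.site_keys[i][1],
                "delta_f_ref": delta,
                "chi2": stat,
                "p": p_val,
            }
        )
    per_site = pd.DataFrame(rows, columns=["scaffold", "pos", "delta_f_ref", "chi2", "p"])
    if holm and len(per_site):
        per_site["p_adj"] = holm_adjust(per_site["p"].to_numpy())
        sig_col = "p_adj"
    else:
        sig_col = "p"
    sig = per_site[per_site[sig_col] < alpha] if len(per_site) else per_site
    deltas_sig = sig["delta_f_ref"].to_list() if len(sig) else []

    t_res: Optional[TestResult] = None
    if len(deltas_sig) >= 2:
        try:
            t_res = one_sample_t(deltas_sig, 0.0)
        except ZeroVarianceError:
            t_res = None
    mw_res: Optional[TestResult] = None
    pf = parent.f_ref[[i for i, _ in common]]
    of = offspring.f_ref[[j for _, j in common]]
    mw_res = mann_whitney_u(pf, of)

    mean_delta = float(np.mean(deltas_sig)) if deltas_sig else 0.0
    if len(deltas_sig) >= 2 and np.ptp(deltas_sig) > 0:
        sd_delta = float(np.std(deltas_sig, ddof=1))
    else:
        sd_delta = 0.0
    direction = "none"
    if t_res is not None and t_res.p_value < alpha and mean_delta != 0.0:
        direction = "increase" if mean_delta > 0 else "decrease"
    shift = ShiftResult(
        line_id=offspring.line_id,
        n_sites_tested=len(per_site),
        n_sites_significant=len(sig),
        mean_delta_f_ref=mean_delta,
        sd_delta=sd_delta,
        t_test=t_res,
        mw_test=mw_res,
        direction=direction,
    )
    return per_site, shift


def af_mode_report(
    f_ref,
    line_id: str = "",
    bandwidth: Optional[float] = None,
    min_prominence: float = 0.10,
    min_separation: float = 0.05,
    grid_size: int = 512,
) -> ModeReport:
    """Mode analysis of an allele-frequency distribution on [0, 1].

    A Gaussian kernel density with Silverman bandwidth (overridable) is
    evaluated on [0, 1] with boundary reflection; local maxima with
    prominence >= ``min_prominence`` x global maximum and pairwise
    separation >= ``min_separation`` count as modes.  One mode is
    unimodal, two bimodal, more multimodal.
    """
    f = np.asarray(f_ref, dtype=float)
    f = f[np.isfinite(f)]
    if f.size < 50:
        raise ValueError(f"mode analysis needs >= 50 frequencies, got {f.size}")
    sd = float(np.std(f, ddof=1))
    if bandwidth is None:
        # Silverman's rule on the observed frequencies
        iqr = float(np.subtract(*np.percentile(f, [75, 25])))
        scale = min(sd, iqr / 1.349) if iqr > 0 else sd
        bandwidth = 0.9 * (scale if scale > 0 else 1e-3) * f.size ** (-1 / 5)
    reflected = np.concatenate([f, -f, 2.0 - f])
    grid = np.linspace(0.0, 1.0, grid_size)
    diffs = (grid[:, None] - reflected[None, :]) / bandwidth
    density = np.exp(-0.5 * diffs**2).sum(axis=1) / (reflected.size * bandwidth * math.sqrt(2 * math.pi))
    density *= 3.0  # reflection triples the mass; rescale to [0, 1]

    peaks, props = _signal.find_peaks(density, prominence=min_prominence * density.max())
    # boundary maxima are genuine modes after reflection only if interior-adjacent
    order = np.argsort(density[peaks])[::-1]
    kept: List[int] = []
    for idx in order:
        pk = peaks[idx]
        if all(abs(grid[pk] - grid[other]) >= min_separation for other in kept):
            kept.append(pk)
    locations = tuple(sorted(float(grid[pk]) for pk in kept))
    if not locations:
        locations = (float(grid[np.argmax(density)]),)
    n_modes = len(locations)
    classification = {1: "unimodal", 2: "bimodal"}.get(n_modes, "multimodal")
    return ModeReport(
        line_id=line_id,
        n_modes=n_modes,
        mode_locations=locations,
        classification=classification,
        bandwidth=float(bandwidth),
    )


def quantitative_pca(
    profiles: Sequence[LineProfile],
) -> Tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """PCA of lines x common-site allele frequencies (centered, unscaled).

    Only sites present in every profile enter the matrix; fewer than
    three such sites is an error.
    """
    common = set(profiles[0].site_keys)
    for p in profiles[1:]:
        common &= set(p.site_keys)
    registry = sorted(common)
    if len(registry) < 3:
        raise ValueError(f"only {len(registry)} common sites; PCA needs >= 3")
    mat = np.empty((len(profiles), len(registry)))
    for i, p in enumerate(profiles):
        lookup = {k: v for k, v in zip(p.site_keys, p.f_ref)}
        mat[i] = [lookup[k] for k in registry]
    scores, loadings, explained = _centered_pca(mat)
    score_df = pd.DataFrame(
        scores,
        index=[p.line_id for p in profiles],
        columns=[f"PC{i + 1}" for i in range(scores.shape[1])],
    )
    score_df.attrs["n_sites"] = len(registry)
    return score_df, loadings, explained


def rarefaction_regression(
    tables: Dict[str, Tuple[str, pd.DataFrame]],
) -> pd.DataFrame:
    """Family-size regression of common-site counts, per karyotype.

    ``tables`` maps family name -> (karyotype, rarefaction table with
    columns k and mean_common_sites).  Families of the same karyotype
    are pooled into one regression of count on k.
    """
    rows = []
    for karyotype in sorted({k for k, _ in tables.values()}):
        ks: List[float] = []
        counts: List[float] = []
        for _, (kt, table) in tables.items():
            if kt != karyotype:
                continue
            ks.extend(table["k"].to_list())
            counts.extend(table["mean_common_sites"].to_list())
        if len(set(ks)) < 3:
            raise ValueError(f"karyotype {karyotype}: need >= 3 distinct family sizes")
        fit = linear_fit(ks, counts)
        rows.append(
            {
                "karyotype": karyotype,
                "slope": fit.slope,
                "intercept": fit.intercept,
                "adjusted_r_squared": fit.adjusted_r_squared,
                "p": fit.p_value,
                "n": fit.n,
            }
        )
    return pd.DataFrame(rows)


def profiles_from_pooled(
    pooled: pd.DataFrame,
    roles: Optional[Dict[str, str]] = None,
    karyotypes: Optional[Dict[str, str]] = None,
) -> Dict[str, LineProfile]:
    """Build LineProfiles from a pooled site-frequency table.

    Heterogeneous (excluded) sites are dropped.  ``pooled`` is the
    output of :func:`karyoshift.filtering.pool_site_frequencies`.
    """
    ok = pooled[~pooled["excluded_heterogeneous"]]
    profiles = {}
    for line, group in ok.groupby("line"):
        keys = [
            site_key for site_key in (
                tuple(x) for x in group[["scaffold", "pos", "ref", "alt"]].itertuples(index=False)
            )
        ]
        norm_keys = [
            (s, int(p), *sorted((r, a))) for s, p, r, a in keys
        ]
        profiles[str(line)] = LineProfile(
            line_id=str(line),
            role=(roles or {}).get(str(line), "offspring"),
            karyotype=(karyotypes or {}).get(str(line), "unknown"),
            site_keys=norm_keys,
            f_ref=group["pooled_f_ref"].to_numpy(dtype=float),
            counts=group[["ref_pooled", "alt_pooled"]].to_numpy(dtype=int),
        )
    return profiles


class NucleotypeModel:
    """Nuclear-genotype proportion analysis of a parent and its siblings.

    Built from the retained per-replicate site table of the strict
    filter regime (or directly from pooled frequencies); ``fit()``
    pools allele frequencies, runs the per-site and aggregate shift
    tests of every offspring against the parent, classifies each line's
    allele-frequency distribution by kernel-density modes, and runs the
    allele-frequency PCA.
    """

    def __init__(
        self,
        retained_sites: pd.DataFrame,
        parent: str,
        karyotypes: Optional[Dict[str, str]] = None,
    ):
        self.retained_sites = retained_sites
        self.parent = parent
        self.karyotypes = karyotypes or {}

    @classmethod
    def from_pooled(cls, pooled: pd.DataFrame, parent: str, **kw) -> "NucleotypeModel":
        model = cls.__new__(cls)
        model.retained_sites = None
        model.parent = parent
        model.karyotypes = kw.get("karyotypes") or {}
        model._pooled = pooled
        return model

    def fit(
        self,
        alpha: float = 0.05,
        min_sites_for_modes: int = 50,
        mode_kwargs: Optional[dict] = None,
    ) -> "NucleotypeResults":
        pooled = getattr(self, "_pooled", None)
        if pooled is None:
            pooled = pool_site_frequencies(self.retained_sites, alpha=alpha)
        roles = {self.parent: "parent"}
        profiles = profiles_from_pooled(pooled, roles=roles, karyotypes=self.karyotypes)
        if self.parent not in profiles:
            raise ValueError(f"parent line {self.parent!r} absent from the site table")
        shifts: Dict[str, ShiftResult] = {}
        per_site: Dict[str, pd.DataFrame] = {}
        for line_id, profile in profiles.items():
            if line_id == self.parent:
                continue
            try:
                table, shift = per_site_shift_tests(profiles[self.parent], profile, alpha=alpha)
            except ValueError as exc:
                warnings.warn(f"skipping shift tests for {line_id}: {exc}", stacklevel=2)
                continue
            per_site[line_id] = table
            shifts[line_id] = shift
        modes: Dict[str, ModeReport] = {}
        for line_id, profile in profiles.items():
            if profile.f_ref.size >= min_sites_for_modes:
                modes[line_id] = af_mode_report(
                    profile.f_ref, line_id=line_id, **(mode_kwargs or {})
                )
        pca_scores = None
        pca_explained = None
        try:
            pca_scores, _, pca_explained = quantitative_pca(list(profiles.values()))
        except ValueError:
            pass
        return NucleotypeResults(
            model=self,
            pooled=pooled,
            profiles=profiles,
            shifts=shifts,
            per_site_tests=per_site,
            modes=modes,
            pca_scores=pca_scores,
            pca_explained=pca_explained,
        )


@dataclass
class NucleotypeResults:
    """Fitted cohort: pooled frequencies, shifts, modes, PCA."""

    model: NucleotypeModel
    pooled: pd.DataFrame
    profiles: Dict[str, LineProfile]
    shifts: Dict[str, ShiftResult]
    per_site_tests: Dict[str, pd.DataFrame]
    modes: Dict[str, ModeReport]
    pca_scores: Optional[pd.DataFrame]
    pca_explained: Optional[np.ndarray]

    def shift_table(self) -> pd.DataFrame:
        rows = []
        for line_id, s in self.shifts.items():
            rows.append(
                {
                    "line": line_id,
                    "n_sites_tested": s.n_sites_tested,
                    "n_sites_significant": s.n_sites_significant,
                    "mean_delta_f_ref": s.mean_delta_f_ref,
                    "sd_delta": s.sd_delta,
                    "t": s.t_test.statistic if s.t_test else np.nan,
                    "t_p": s.t_test.p_value if s.t_test else np.nan,
                    "mw_p": s.mw_test.p_value if s.mw_test else np.nan,
                    "direction": s.direction,
                }
            )
        return pd.DataFrame(rows)

    def mode_table(self) -> pd.DataFrame:
        rows = []
        for line_id, m in self.modes.items():
            rows.append(
                {
                    "line": line_id,
                    "n_modes": m.n_modes,
                    "modes": ",".join(f"{x:.3f}" for x in m.mode_locations),
                    "classification": m.classification,
                    "bandwidth": m.bandwidth,
                }
            )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = ["Nucleotype proportion analysis", "=" * 32]
        lines.append(f"parent line: {self.model.parent}")
        lines.append(f"lines: {len(self.profiles)}; pooled sites: {len(self.pooled)}")
        n_het = int(self.pooled["excluded_heterogeneous"].sum())
        lines.append(f"heterogeneous sites excluded from pooling: {n_het}")
        if self.modes:
            lines.append("")
            lines.append(self.mode_table().to_string(index=False))
        if self.shifts:
            lines.append("")
            lines.append(self.shift_table().to_string(index=False))
        if self.pca_explained is not None:
            lines.append("")
            pc1 = 100 * self.pca_explained[0]
            lines.append(
                f"allele-frequency PCA: PC1 explains {pc1:.1f}% "
                f"of variance over {self.pca_scores.attrs.get('n_sites', '?')} common sites"
            )
        return "\n".join(lines)

    def plot_af_distributions(self, ax=None):
        """Overlay each line's allele-frequency histogram (convenience)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for line_id, profile in self.profiles.items():
            ax.hist(profile.f_ref, bins=40, range=(0, 1), alpha=0.4, label=line_id)
        ax.set_xlabel("reference-allele frequency")
        ax.set_ylabel("biallelic sites")
        ax.legend()
        return ax
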