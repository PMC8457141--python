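"""Transcriptome side: allelic imbalance and expression-mode analysis.

Per-gene allelic fold-change (aFC) is the ratio of reference to
alternate transcript reads at the gene's deepest biallelic site;
|log2(aFC)| > 0.5 flags allelic imbalance (AI).  Genomically biallelic
genes whose transcripts show only one of the two alleles are called
monoallelically expressed (MA), both alleles biallelically expressed
(BA); the classifier works per replicate with a consensus across
replicates.  MA and BA gene groups are compared on SNP density
(sites per kb of CDS) and expression (log2(FPKM + 1)) with
Mann-Whitney tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .io import GeneModel
from .stats import TestResult, chi2_2x2, chi2_homogeneity, holm_adjust, mann_whitney_u, pearson_r

#: major-allele share at the AI boundary: |log2(r/a)| > 0.5  <=>  max share > this
AI_SHARE_BOUNDARY = math.sqrt(2.0) / (1.0 + math.sqrt(2.0))


@dataclass(frozen=True)
class GeneAFC:
    """Per-gene allelic fold-change at the deepest transcribed site."""

    gene_id: str
    line_id: str
    site_used: Tuple[str, int]
    ref_count: int
    alt_count: int
    log2_afc: Optional[float]  # None when one allele has zero reads
    ai_flag: Optional[bool]


def gene_afc(
    sites: pd.DataFrame, gene_id: str, line_id: str = "", threshold: float = 0.5
) -> GeneAFC:
    """aFC of one gene from its biallelic sites' pooled RNA counts.

    ``sites`` needs columns scaffold, pos, ref_count, alt_count; the
    highest-coverage site is used.  A zero count on either allele
    leaves the fold-change undefined (the gene is a candidate for the
    monoallelic classifier instead, never an AI call).
    """
    if sites.empty:
        raise ValueError(f"gene {gene_id} has no biallelic site with RNA coverage")
    depth = sites["ref_count"] + sites["alt_count"]
    best = sites.loc[depth.idxmax()]
    ref_c, alt_c = int(best["ref_count"]), int(best["alt_count"])
    if ref_c == 0 or alt_c == 0:
        return GeneAFC(gene_id, line_id, (best["scaffold"], int(best["pos"])), ref_c, alt_c, None, None)
    log2_afc = math.log2(ref_c / alt_c)
    return GeneAFC(
        gene_id,
        line_id,
        (best["scaffold"], int(best["pos"])),
        ref_c,
        alt_c,
        log2_afc,
        abs(log2_afc) > threshold,
    )


def gene_afc_table(
    rna_sites: pd.DataFrame,
    line_id: str,
    threshold: float = 0.5,
    pool_replicates: bool = True,
) -> pd.DataFrame:
    """aFC of every gene of one line; counts pooled across replicates."""
    df = rna_sites[rna_sites["line"] == line_id]
    if pool_replicates:
        df = (
            df.groupby(["gene_id", "scaffold", "pos"])[["ref_count", "alt_count"]]
            .sum()
            .reset_index()
        )
    rows = []
    for gid, group in df.groupby("gene_id"):
        res = gene_afc(group, str(gid), line_id, threshold)
        rows.append(
            {
                "gene_id": res.gene_id,
                "line": line_id,
                "scaffold": res.site_used[0],
                "pos": res.site_used[1],
                "ref_count": res.ref_count,
                "alt_count": res.alt_count,
                "log2_afc": res.log2_afc if res.log2_afc is not None else np.nan,
                "afc_defined": res.log2_afc is not None,
                "ai_flag": bool(res.ai_flag) if res.ai_flag is not None else False,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id", "line", "scaffold", "pos", "ref_count", "alt_count",
            "log2_afc", "afc_defined", "ai_flag",
        ],
    )


def ai_cohort_test(
    ai_counts: Dict[str, Tuple[int, int]],
    continuity_correction: bool = False,
) -> Tuple[TestResult, pd.DataFrame]:
    """Compare AI-gene proportions across lines.

    ``ai_counts`` maps line -> (n_AI, n_tested).  A k-sample
    chi-squared proportion test runs over all lines with tested genes
    (empty lines are excluded with a warning), followed by all pairwise
    two-sample proportion tests with Holm adjustment.
    """
    import warnings

    usable = {}
    for line, (n_ai, n_tot) in ai_counts.items():
        if n_tot == 0:
            warnings.warn(f"line {line} has zero tested genes; excluded", stacklevel=2)
            continue
        usable[line] = (n_ai, n_tot)
    if len(usable) < 2:
        raise ValueError("need at least two lines with tested genes")
    lines = list(usable)
    table = [[n_ai, n_tot - n_ai] for n_ai, n_tot in usable.values()]
    overall = chi2_homogeneity(table)

    pairs = []
    raw_p = []
    for i in range(len(lines)):
        for j in range(i + 1, len(lines)):
            a_ai, a_tot = usable[lines[i]]
            b_ai, b_tot = usable[lines[j]]
            res = chi2_2x2(
                [[a_ai, a_tot - a_ai], [b_ai, b_tot - b_ai]],
                continuity_correction=continuity_correction,
            )
            pairs.append((lines[i], lines[j], res.statistic))
            raw_p.append(res.p_value)
    adj = holm_adjust(raw_p) if raw_p else np.array([])
    pairwise = pd.DataFrame(
        {
            "line_a": [a for a, _, _ in pairs],
            "line_b": [b for _, b, _ in pairs],
            "chi2": [s for _, _, s in pairs],
            "p": raw_p,
            "p_holm": adj,
        }
    )
    return overall, pairwise


def cross_line_af_correlation(
    rna_sites: pd.DataFrame, line_a: str, line_b: str
) -> TestResult:
    """Pearson correlation of two lines' transcript allele frequencies.

    Frequencies are pooled across replicates; only sites transcribed in
    both lines enter.
    """
    freqs = {}
    for line in (line_a, line_b):
        df = rna_sites[rna_sites["line"] == line]
        pooled = df.groupby(["scaffold", "pos"])[["ref_count", "alt_count"]].sum()
        total = pooled["ref_count"] + pooled["alt_count"]
        pooled = pooled[total > 0]
        freqs[line] = pooled["ref_count"] / (pooled["ref_count"] + pooled["alt_count"])
    merged = pd.concat([freqs[line_a], freqs[line_b]], axis=1, join="inner", keys=["a", "b"])
    if len(merged) < 3:
        raise ValueError("fewer than three common transcribed sites")
    return pearson_r(merged["a"].to_numpy(), merged["b"].to_numpy())


def classify_expression_mode(
    genomic_sites: pd.DataFrame,
    rna_sites: pd.DataFrame,
    line_id: str,
    min_rna_reads: int = 25,
) -> pd.DataFrame:
    """Per-gene monoallelic/biallelic expression calls for one line.

    Per replicate, a genomically biallelic site with RNA depth >=
    ``min_rna_reads`` is informative: MA if exactly one of its two
    alleles is observed among the reads, BA if both.  A replicate's
    gene call is BA if any site is BA (one biallelically transcribed
    site proves both alleles active), MA if all informative sites are
    MA, otherwise insufficient.  The consensus is MA or BA only when
    all informative replicates agree.
    """
    keys = ["scaffold", "pos"]
    genomic = genomic_sites[keys + ["gene_id"]].drop_duplicates()
    rna = rna_sites[rna_sites["line"] == line_id].merge(genomic, on=keys + ["gene_id"])
    rows = []
    for gid in sorted(genomic["gene_id"].unique()):
        sub = rna[rna["gene_id"] == gid]
        rep_calls: Dict[str, str] = {}
        for (bio, tech), group in sub.groupby(["bio_rep", "tech_rep"]):
            depth = group["ref_count"] + group["alt_count"]
            informative = group[depth >= min_rna_reads]
            if informative.empty:
                rep_calls[f"b{bio}_t{tech}"] = "insufficient"
                continue
            both = (informative["ref_count"] > 0) & (informative["alt_count"] > 0)
            rep_calls[f"b{bio}_t{tech}"] = "BA" if both.any() else "MA"
        informative_calls = [c for c in rep_calls.values() if c != "insufficient"]
        if not informative_calls:
            consensus = "insufficient"
        elif all(c == "MA" for c in informative_calls):
            consensus = "MA"
        elif all(c == "BA" for c in informative_calls):
            consensus = "BA"
        else:
            consensus = "discordant"
        rows.append(
            {
                "gene_id": gid,
                "line": line_id,
                "consensus": consensus,
                "n_replicates_informative": len(informative_calls),
                "replicate_calls": ";".join(f"{k}={v}" for k, v in sorted(rep_calls.items())),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["gene_id", "line", "consensus", "n_replicates_informative", "replicate_calls"],
    )


def cohort_consistent_modes(mode_tables: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Genes whose MA/BA consensus agrees across all lines."""
    merged = pd.concat(mode_tables, ignore_index=True)
    rows = []
    for gid, group in merged.groupby("gene_id"):
        calls = set(group["consensus"]) - {"insufficient"}
        if calls == {"MA"}:
            rows.append({"gene_id": gid, "cohort_call": "MA"})
        elif calls == {"BA"}:
            rows.append({"gene_id": gid, "cohort_call": "BA"})
    return pd.DataFrame(rows, columns=["gene_id", "cohort_call"])


def snp_density(n_sites: int, cds_length: int) -> float:
    """SNPs per kilobase of CDS: 1000 * n_sites / cds_length."""
    if cds_length <= 0:
        raise ValueError("CDS length must be positive")
    return 1000.0 * n_sites / cds_length


def snp_density_table(genomic_sites: pd.DataFrame, genes: Sequence[GeneModel]) -> pd.DataFrame:
    """Genomic biallelic-site density per gene (SNPs/kb of CDS)."""
    counts = genomic_sites.drop_duplicates(["scaffold", "pos"]).groupby("gene_id").size()
    rows = []
    for g in genes:
        n = int(counts.get(g.gene_id, 0))
        rows.append(
            {
                "gene_id": g.gene_id,
                "n_ba_sites": n,
                "cds_length": g.cds_length,
                "snp_density": snp_density(n, g.cds_length),
            }
        )
    return pd.DataFrame(rows)


def fpkm(count: float, length_bp: float, total_fragments: float) -> float:
    """Fragments per kilobase per million mapped fragments."""
    if length_bp <= 0:
        raise ValueError("feature length must be positive")
    if total_fragments <= 0:
        raise ValueError("total mapped fragments must be positive")
    return count * 1e9 / (length_bp * total_fragments)


def fpkm_table(rna_genes: pd.DataFrame, genes: Sequence[GeneModel], line_id: str) -> pd.DataFrame:
    """Per-gene, per-replicate FPKM for one line (CDS length as length)."""
    lengths = {g.gene_id: g.cds_length for g in genes}
    df = rna_genes[rna_genes["line"] == line_id].copy()
    totals = df.groupby(["bio_rep", "tech_rep"])["fragments"].transform("sum")
    df["fpkm"] = [
        fpkm(c, lengths[g], t) for c, g, t in zip(df["fragments"], df["gene_id"], totals)
    ]
    return df[["gene_id", "line", "bio_rep", "tech_rep", "fragments", "fpkm"]]


def ma_ba_comparisons(
    mode_table: pd.DataFrame,
    fpkm_by_gene: pd.DataFrame,
    density_by_gene: pd.DataFrame,
) -> Tuple[TestResult, TestResult]:
    """Compare MA- vs BA-consensus genes on expression and SNP density.

    Mann-Whitney on log2(FPKM + 1) of per-gene mean FPKM, and on SNP
    density, between the MA and BA consensus groups.
    """
    ma = set(mode_table.loc[mode_table["consensus"] == "MA", "gene_id"])
    ba = set(mode_table.loc[mode_table["consensus"] == "BA", "gene_id"])
    if not ma or not ba:
        raise ValueError("both MA and BA groups must be non-empty")
    mean_fpkm = fpkm_by_gene.groupby("gene_id")["fpkm"].mean()
    fpkm_test = mann_whitney_u(
        np.log2(mean_fpkm.loc[sorted(ma & set(mean_fpkm.index))] + 1),
        np.log2(mean_fpkm.loc[sorted(ba & set(mean_fpkm.index))] + 1),
    )
    dens = density_by_gene.set_index("gene_id")["snp_density"]
    density_test = mann_whitney_u(
        dens.loc[sorted(ma & set(dens.index))], dens.loc[sorted(ba & set(dens.index))]
    )
    return fpkm_test, density_test


class AllelicExpressionModel:
    """Allelic imbalance and expression-mode analysis of a cohort.

    Built from the per-site RNA allele counts, the per-gene fragment
    counts, the gene models and the table of genomic CDS biallelic
    sites; ``fit()`` computes per-line aFC tables, the AI proportion
    test across lines, the MA/BA classification with its consensus, and
    the MA-vs-BA SNP-density and expression comparisons.
    """

    def __init__(
        self,
        rna_sites: pd.DataFrame,
        rna_genes: pd.DataFrame,
        genes: Sequence[GeneModel],
        genomic_sites: pd.DataFrame,
    ):
        self.rna_sites = rna_sites
        self.rna_genes = rna_genes
        self.genes = list(genes)
        self.genomic_sites = genomic_sites

    def fit(
        self, threshold: float = 0.5, min_rna_reads: int = 25, alpha: float = 0.05
    ) -> "AllelicExpressionResults":
        lines = sorted(self.rna_sites["line"].unique())
        afc_tables = {line: gene_afc_table(self.rna_sites, line, threshold) for line in lines}
        ai_counts = {}
        for line, table in afc_tables.items():
            defined = table[table["afc_defined"]]
            ai_counts[line] = (int(defined["ai_flag"].sum()), len(defined))
        cohort_test, pairwise = (None, None)
        if len(lines) >= 2:
            cohort_test, pairwise = ai_cohort_test(ai_counts)
        mode_tables = {
            line: classify_expression_mode(
                self.genomic_sites, self.rna_sites, line, min_rna_reads=min_rna_reads
            )
            for line in lines
        }
        density = snp_density_table(self.genomic_sites, self.genes)
        fpkms = {line: fpkm_table(self.rna_genes, self.genes, line) for line in lines}
        comparisons = {}
        for line in lines:
            try:
                comparisons[line] = ma_ba_comparisons(mode_tables[line], fpkms[line], density)
            except ValueError:
                comparisons[line] = None
        return AllelicExpressionResults(
            model=self,
            afc_tables=afc_tables,
            ai_counts=ai_counts,
            cohort_test=cohort_test,
            pairwise_ai=pairwise,
            mode_tables=mode_tables,
            snp_densities=density,
            fpkm_tables=fpkms,
            comparisons=comparisons,
        )


@dataclass
class AllelicExpressionResults:
    """Fitted transcriptome analysis of the cohort."""

    model: AllelicExpressionModel
    afc_tables: Dict[str, pd.DataFrame]
    ai_counts: Dict[str, Tuple[int, int]]
    cohort_test: Optional[TestResult]
    pairwise_ai: Optional[pd.DataFrame]
    mode_tables: Dict[str, pd.DataFrame]
    snp_densities: pd.DataFrame
    fpkm_tables: Dict[str, pd.DataFrame]
    comparisons: Dict[str, Optional[Tuple[TestResult, TestResult]]]

    def ai_proportion_table(self) -> pd.DataFrame:
        rows = []
        for line, (n_ai, n_tot) in self.ai_counts.items():
            rows.append(
                {
                    "line": line,
                    "n_ai": n_ai,
                    "n_tested": n_tot,
                    "proportion_ai": n_ai / n_tot if n_tot else np.nan,
                }
            )
        return pd.DataFrame(rows)

    def correlation(self, line_a: str, line_b: str) -> TestResult:
        return cross_line_af_correlation(self.model.rna_sites, line_a, line_b)

    def summary(self) -> str:
        lines = ["Allelic expression analysis", "=" * 28]
        lines.append(self.ai_proportion_table().to_string(index=False))
        if self.cohort_test is not None:
            lines.append(
                f"AI proportions across lines: chi2 = {self.cohort_test.statistic:.2f}, "
                f"df = {self.cohort_test.df:.0f}, p = {self.cohort_test.p_value:.3g}"
            )
        for line, comp in self.comparisons.items():
            if comp is None:
                continue
            fpkm_test, density_test = comp
            lines.append(
                f"{line}: MA vs BA log2(FPKM+1) MW p = {fpkm_test.p_value:.3g}; "
                f"SNP density MW p = {density_test.p_value:.3g}"
            )
        return "\n".join(lines)

    def plot_afc_distribution(self, line_id: str, threshold: float = 0.5, ax=None):
        """Histogram of a line's per-gene log2 aFC (convenience)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        vals = self.afc_tables[line_id]["log2_afc"].dropna()
        ax.hist(vals, bins=40)
        ax.axvline(threshold, color="red", linestyle=":")
        ax.axvline(-threshold, color="red", linestyle=":")
        ax.set_xlabel("log2 allelic fold-change")
        ax.set_ylabel("genes")
        return ax
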