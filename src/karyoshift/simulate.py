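"""Synthetic dikaryon cohorts with known nuclear-genotype proportions.

The generator emulates the statistical structure of a reduced-
representation sequencing study of clonal fungal sibling lines: two
haploid nucleotypes diverging at a tunable SNP density, mixed in each
line at a known proportion ``p`` (parent near 1:1, offspring drifting
towards 2:3 or 3:2), sequenced as three biological x two technical
replicates with Poisson read depth and binomial allele sampling, plus a
transcriptome layer with planted cis-acting allelic-imbalance genes and
monoallelically silenced genes (elevated SNP density, reduced
expression).  Diploid and tetraploid allele-frequency controls are
produced by the same machinery.

Every stage is driven by one integer seed; a fixed seed yields
byte-identical output files.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd

from .io import GeneModel, write_table, write_vcf

LN2 = math.log(2.0)


@dataclass(frozen=True)
class SimConfig:
    """Study-design parameters of a simulated cohort.

    Defaults mirror the emulated study: five sibling lines of a
    dikaryon parent with a 1:1 nucleotype ratio, three of them retaining
    ~1:1 and two drifting to 2:3 and 3:2; 3 biological x 2 technical
    replicates; DNA depth ~80x and RNA depth ~100x; divergence of
    1 SNP/kb between the two nucleotypes.
    """

    n_scaffolds: int = 8
    scaffold_length: int = 100_000
    snp_density: float = 1.0  # divergent sites per kb between nucleotypes
    n_genes: int = 200
    gene_length: int = 1_500  # summed CDS length per gene
    parent_p: float = 0.5
    offspring_p: Tuple[float, ...] = (0.4, 0.5, 0.5, 0.5, 0.6)
    n_bio_reps: int = 3
    n_tech_reps: int = 2
    dna_depth_mean: float = 80.0
    rna_depth_mean: float = 100.0
    base_error_rate: float = 0.005
    frac_ai_genes: float = 0.10
    ai_log2_effect: float = 1.0
    frac_ma_genes: float = 0.10
    ma_snp_density_multiplier: float = 3.0
    ma_expression_multiplier: float = 0.3
    bio_rep_sigma: float = 0.2  # lognormal sd of per-bio-rep expression factors
    site_depth_sigma: float = 0.4  # lognormal sd of per-site capture efficiency
    n_repeats_per_scaffold: int = 4
    repeat_length: int = 500
    variant_qual: float = 60.0
    tetraploid_weights: Tuple[float, float, float] = (0.25, 0.5, 0.25)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("parent_p", "base_error_rate", "frac_ai_genes", "frac_ma_genes"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if any(not 0.0 <= p <= 1.0 for p in self.offspring_p):
            raise ValueError("offspring proportions must lie in [0, 1]")
        if self.dna_depth_mean <= 0 or self.rna_depth_mean <= 0:
            raise ValueError("depths must be positive")
        if not 0.0 < self.ma_expression_multiplier <= 1.0:
            raise ValueError("ma_expression_multiplier must be in (0, 1]")
        if self.ma_snp_density_multiplier < 1.0:
            raise ValueError("ma_snp_density_multiplier must be >= 1")


@dataclass
class SimGenomes:
    """The divergent-site scaffold between the two nucleotypes.

    ``sites`` has one row per divergent site: scaffold, pos (0-based),
    ref, alt, ref_is_nuc1 (whether the reference assembly carries the
    nucleotype-1 allele) and the enclosing gene_id ('' if intergenic).
    """

    scaffold_lengths: Dict[str, int]
    sites: pd.DataFrame
    genes: List[GeneModel]
    gene_truth: pd.DataFrame  # gene_id, category, ai_sign, silenced_nucleotype
    repeats: pd.DataFrame  # scaffold, start, end


@dataclass
class SimCohort:
    """A fully sampled cohort plus its ground truth."""

    config: SimConfig
    genomes: SimGenomes
    line_truth: pd.DataFrame  # line_id, role, p
    dna: Dict[str, pd.DataFrame]  # line_id -> per-replicate DNA counts
    rna_sites: Dict[str, pd.DataFrame]  # line_id -> per-site RNA counts
    rna_genes: Dict[str, pd.DataFrame]  # line_id -> per-gene fragment counts


_BASES = np.array(list("ACGT"))


def _stage_rng(seed: int, *keys: int) -> np.random.Generator:
    """Stage-specific generator derived deterministically from the seed."""
    return np.random.default_rng(np.random.SeedSequence((seed, *keys)))


def _draw_sites_in(rng: np.random.Generator, start: int, end: int, rate: float) -> np.ndarray:
    n = rng.poisson(rate * (end - start))
    if n == 0:
        return np.empty(0, dtype=int)
    return np.unique(rng.integers(start, end, size=n))


def build_genomes(config: SimConfig) -> SimGenomes:
    """Lay out scaffolds, tile genes, plant repeats and divergent sites.

    Divergent-site positions are uniform at ``snp_density`` per kb,
    elevated by ``ma_snp_density_multiplier`` inside the CDS of genes
    destined for monoallelic silencing.  Each site carries the
    nucleotype-1 allele on the reference with probability 1/2.
    """
    rng = _stage_rng(config.seed, 1)
    scaffold_lengths = {
        f"scaffold_{i + 1}": config.scaffold_length for i in range(config.n_scaffolds)
    }

    # tile genes: two CDS exons separated by a 100 bp intron, spaced evenly
    exon1 = config.gene_length // 2
    exon2 = config.gene_length - exon1
    footprint = config.gene_length + 100
    stride = footprint + 400
    per_scaffold = config.scaffold_length // stride
    if per_scaffold * config.n_scaffolds < config.n_genes:
        raise ValueError(
            f"{config.n_genes} genes do not fit on "
            f"{config.n_scaffolds} x {config.scaffold_length} bp scaffolds"
        )
    genes: List[GeneModel] = []
    scaffolds = list(scaffold_lengths)
    for gi in range(config.n_genes):
        scaffold = scaffolds[gi // per_scaffold]
        offset = (gi % per_scaffold) * stride + 200
        intervals = ((offset, offset + exon1), (offset + exon1 + 100, offset + footprint))
        genes.append(
            GeneModel(
                gene_id=f"gene_{gi + 1:04d}",
                scaffold=scaffold,
                strand="+" if gi % 2 == 0 else "-",
                cds_intervals=intervals,
            )
        )

    # gene categories
    n_ai = int(round(config.frac_ai_genes * config.n_genes))
    n_ma = int(round(config.frac_ma_genes * config.n_genes))
    order = rng.permutation(config.n_genes)
    category = np.array(["neutral"] * config.n_genes, dtype=object)
    category[order[:n_ai]] = "cis_AI"
    category[order[n_ai : n_ai + n_ma]] = "MA_silenced"
    ai_sign = np.where(rng.random(config.n_genes) < 0.5, 1, -1)
    ai_sign[category != "cis_AI"] = 0
    silenced = rng.integers(1, 3, size=config.n_genes)
    silenced[category != "MA_silenced"] = 0
    gene_truth = pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in genes],
            "scaffold": [g.scaffold for g in genes],
            "category": category,
            "ai_sign": ai_sign,
            "silenced_nucleotype": silenced,
        }
    )

    # repeats: intergenic intervals, rejected if they touch a gene footprint
    repeat_rows = []
    for scaffold in scaffolds:
        gene_iv = [
            (g.cds_intervals[0][0] - 10, g.cds_intervals[-1][1] + 10)
            for g in genes
            if g.scaffold == scaffold
        ]
        placed = 0
        attempts = 0
        while placed < config.n_repeats_per_scaffold and attempts < 200:
            attempts += 1
            start = int(rng.integers(0, config.scaffold_length - config.repeat_length))
            end = start + config.repeat_length
            if any(start < ge and gs < end for gs, ge in gene_iv):
                continue
            repeat_rows.append({"scaffold": scaffold, "start": start, "end": end})
            placed += 1
    repeats = pd.DataFrame(repeat_rows, columns=["scaffold", "start", "end"])

    # divergent sites: background rate everywhere, elevated inside MA-gene CDS
    base_rate = config.snp_density / 1000.0
    ma_rate = base_rate * config.ma_snp_density_multiplier
    ma_genes = {g.gene_id for g, c in zip(genes, category) if c == "MA_silenced"}
    site_rows = []
    for scaffold in scaffolds:
        ma_iv = sorted(
            iv for g in genes if g.scaffold == scaffold and g.gene_id in ma_genes
            for iv in g.cds_intervals
        )
        cursor = 0
        segments: List[Tuple[int, int, float]] = []
        for s, e in ma_iv:
            if cursor < s:
                segments.append((cursor, s, base_rate))
            segments.append((s, e, ma_rate))
            cursor = e
        if cursor < config.scaffold_length:
            segments.append((cursor, config.scaffold_length, base_rate))
        for s, e, rate in segments:
            for pos in _draw_sites_in(rng, s, e, rate):
                site_rows.append((scaffold, int(pos)))
    n_sites = len(site_rows)
    ref_base = _BASES[rng.integers(0, 4, size=n_sites)]
    alt_shift = rng.integers(1, 4, size=n_sites)
    base_idx = np.searchsorted(_BASES, ref_base)
    alt_base = _BASES[(base_idx + alt_shift) % 4]
    ref_is_nuc1 = rng.random(n_sites) < 0.5
    # site-specific capture efficiency (fragment/restriction-site effect),
    # shared across replicates and lines; mean 1 so depth_mean is the cohort mean
    sigma = config.site_depth_sigma
    depth_factor = rng.lognormal(mean=-(sigma**2) / 2, sigma=sigma, size=n_sites)

    gene_lookup: Dict[str, List[GeneModel]] = {}
    for g in genes:
        gene_lookup.setdefault(g.scaffold, []).append(g)

    def enclosing_gene(scaffold: str, pos: int) -> str:
        for g in gene_lookup.get(scaffold, []):
            if g.contains(pos):
                return g.gene_id
        return ""

    sites = pd.DataFrame(
        {
            "scaffold": [s for s, _ in site_rows],
            "pos": [p for _, p in site_rows],
            "ref": ref_base,
            "alt": alt_base,
            "ref_is_nuc1": ref_is_nuc1,
            "depth_factor": depth_factor,
            "gene_id": [enclosing_gene(s, p) for s, p in site_rows],
        }
    ).sort_values(["scaffold", "pos"], ignore_index=True)
    return SimGenomes(
        scaffold_lengths=scaffold_lengths,
        sites=sites,
        genes=genes,
        gene_truth=gene_truth,
        repeats=repeats,
    )


def _mixture_share(p: float, e: float) -> float:
    """Expected fraction of reads carrying the nucleotype-1 allele."""
    return p * (1.0 - e) + (1.0 - p) * e


def sample_dna_counts(
    genomes: SimGenomes,
    line_id: str,
    p: float,
    config: SimConfig,
    line_index: int = 0,
) -> pd.DataFrame:
    """Draw per-replicate DNA allele counts at every divergent site.

    Depth is Poisson(``dna_depth_mean``); reads carrying the
    nucleotype-1 allele are Binomial(depth, p(1-e) + (1-p)e); reference
    counts follow the site's ref-assignment flag.  Returns a long frame
    with the same columns :func:`karyoshift.io.variants_to_frame`
    produces, so filters treat simulated and parsed data identically.
    """
    rng = _stage_rng(config.seed, 2, line_index)
    sites = genomes.sites
    n_sites = len(sites)
    q = _mixture_share(p, config.base_error_rate)
    frames = []
    ref_is_nuc1 = sites["ref_is_nuc1"].to_numpy()
    site_mean = config.dna_depth_mean * sites["depth_factor"].to_numpy()
    for bio in range(1, config.n_bio_reps + 1):
        for tech in range(1, config.n_tech_reps + 1):
            depth = rng.poisson(site_mean)
            nuc1 = rng.binomial(depth, q)
            ref_count = np.where(ref_is_nuc1, nuc1, depth - nuc1)
            frames.append(
                pd.DataFrame(
                    {
                        "scaffold": sites["scaffold"],
                        "pos": sites["pos"],
                        "ref": sites["ref"],
                        "alt": sites["alt"],
                        "n_alts": 1,
                        "is_snp": True,
                        "qual": config.variant_qual,
                        "line": line_id,
                        "bio_rep": bio,
                        "tech_rep": tech,
                        "replicate": f"b{bio}_t{tech}",
                        "ref_depth": ref_count,
                        "alt_depth": depth - ref_count,
                        "total_depth": depth,
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)


def sample_rna_counts(
    genomes: SimGenomes,
    line_id: str,
    p: float,
    config: SimConfig,
    line_index: int = 0,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Draw per-site RNA allele counts and per-gene fragment counts.

    A neutral gene transcribes the nucleotype-1 allele in proportion
    ``p``; a cis-AI gene shifts that share by ``ai_log2_effect`` on the
    log-odds (log2) scale; a silenced gene transcribes only one
    nucleotype and its total output is scaled by
    ``ma_expression_multiplier``.  Biological replicates draw a
    lognormal expression factor per gene; technical replicates resample
    reads from the same factor.
    """
    rng = _stage_rng(config.seed, 3, line_index)
    truth = genomes.gene_truth.set_index("gene_id")
    gene_sites = genomes.sites[genomes.sites["gene_id"] != ""]
    cds_len = {g.gene_id: g.cds_length for g in genomes.genes}
    e = config.base_error_rate

    site_rows = []
    gene_rows = []
    for gene in genomes.genes:
        gid = gene.gene_id
        info = truth.loc[gid]
        if info["category"] == "cis_AI":
            if 0.0 < p < 1.0:
                logit = math.log(p / (1 - p)) + info["ai_sign"] * config.ai_log2_effect * LN2
                share = 1.0 / (1.0 + math.exp(-logit))
            else:
                share = p
        elif info["category"] == "MA_silenced":
            share = 0.0 if info["silenced_nucleotype"] == 1 else 1.0
        else:
            share = p
        expr_scale = (
            config.ma_expression_multiplier if info["category"] == "MA_silenced" else 1.0
        )
        s_obs = _mixture_share(share, e)
        sub = gene_sites[gene_sites["gene_id"] == gid]
        ref_is_nuc1 = sub["ref_is_nuc1"].to_numpy()
        n_gsites = len(sub)
        for bio in range(1, config.n_bio_reps + 1):
            factor = expr_scale * rng.lognormal(mean=0.0, sigma=config.bio_rep_sigma)
            for tech in range(1, config.n_tech_reps + 1):
                if n_gsites:
                    depth = rng.poisson(config.rna_depth_mean * factor, size=n_gsites)
                    nuc1 = rng.binomial(depth, s_obs)
                    ref_count = np.where(ref_is_nuc1, nuc1, depth - nuc1)
                    for i in range(n_gsites):
                        site_rows.append(
                            (
                                gid,
                                sub["scaffold"].iat[i],
                                int(sub["pos"].iat[i]),
                                line_id,
                                bio,
                                tech,
                                int(ref_count[i]),
                                int(depth[i] - ref_count[i]),
                            )
                        )
                frag_mean = config.rna_depth_mean * factor * cds_len[gid] / 1000.0
                gene_rows.append((gid, line_id, bio, tech, int(rng.poisson(frag_mean))))
    rna_sites = pd.DataFrame(
        site_rows,
        columns=["gene_id", "scaffold", "pos", "line", "bio_rep", "tech_rep", "ref_count", "alt_count"],
    )
    rna_genes = pd.DataFrame(
        gene_rows, columns=["gene_id", "line", "bio_rep", "tech_rep", "fragments"]
    )
    return rna_sites, rna_genes


def simulate_control(
    ploidy: int,
    config: SimConfig,
    n_sites: int = 2000,
) -> pd.DataFrame:
    """Allele counts for a diploid or tetraploid control organism.

    Diploid sites have a true allele frequency of 0.5; tetraploid sites
    draw from {0.25, 0.5, 0.75} with ``tetraploid_weights``.
    """
    if ploidy not in (2, 4):
        raise ValueError("ploidy must be 2 or 4")
    rng = _stage_rng(config.seed, 4, ploidy)
    if ploidy == 2:
        true_af = np.full(n_sites, 0.5)
    else:
        true_af = rng.choice([0.25, 0.5, 0.75], size=n_sites, p=config.tetraploid_weights)
    depth = rng.poisson(config.dna_depth_mean, size=n_sites)
    depth = np.maximum(depth, 1)
    q = true_af * (1 - config.base_error_rate) + (1 - true_af) * config.base_error_rate
    ref = rng.binomial(depth, q)
    return pd.DataFrame(
        {
            "site": np.arange(n_sites),
            "true_af": true_af,
            "ref_count": ref,
            "alt_count": depth - ref,
            "f_ref": ref / depth,
        }
    )


def simulate_cohort(config: SimConfig) -> SimCohort:
    """Generate the full cohort: genomes, DNA and RNA of every line.

    The parent line is called ``P``; offspring are ``S1``..``Sn`` in
    the order of ``offspring_p``.
    """
    genomes = build_genomes(config)
    lines = [("P", "parent", config.parent_p)] + [
        (f"S{i + 1}", "offspring", p) for i, p in enumerate(config.offspring_p)
    ]
    line_truth = pd.DataFrame(lines, columns=["line_id", "role", "p"])
    dna = {}
    rna_sites = {}
    rna_genes = {}
    for idx, (line_id, _, p) in enumerate(lines):
        dna[line_id] = sample_dna_counts(genomes, line_id, p, config, line_index=idx)
        rs, rg = sample_rna_counts(genomes, line_id, p, config, line_index=idx)
        rna_sites[line_id] = rs
        rna_genes[line_id] = rg
    return SimCohort(
        config=config,
        genomes=genomes,
        line_truth=line_truth,
        dna=dna,
        rna_sites=rna_sites,
        rna_genes=rna_genes,
    )


def _gff_lines(genes: Sequence[GeneModel]) -> List[str]:
    lines = ["##gff-version 3"]
    for g in genes:
        start = g.cds_intervals[0][0] + 1
        end = g.cds_intervals[-1][1]
        lines.append(
            f"{g.scaffold}\tkaryoshift\tgene\t{start}\t{end}\t.\t{g.strand}\t.\tID={g.gene_id}"
        )
        mrna_id = f"{g.gene_id}.t1"
        lines.append(
            f"{g.scaffold}\tkaryoshift\tmRNA\t{start}\t{end}\t.\t{g.strand}\t.\t"
            f"ID={mrna_id};Parent={g.gene_id}"
        )
        for s, e in g.cds_intervals:
            lines.append(
                f"{g.scaffold}\tkaryoshift\tCDS\t{s + 1}\t{e}\t.\t{g.strand}\t0\tParent={mrna_id}"
            )
    return lines


def write_truth(cohort: SimCohort, out_dir: str | Path) -> None:
    """Write the ground-truth tables (lines, sites, genes)."""
    out = Path(out_dir)
    write_table(cohort.line_truth, out / "truth_lines.tsv")
    write_table(cohort.genomes.sites, out / "truth_sites.tsv")
    write_table(cohort.genomes.gene_truth, out / "truth_genes.tsv")


def write_cohort(cohort: SimCohort, out_dir: str | Path) -> None:
    """Emit the cohort in pipeline formats: VCF, GFF3, BED, TSVs + truth.

    One VCF per line carries all six replicate sample columns named
    ``<line>_b<i>_t<j>``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config = cohort.config
    genomes = cohort.genomes

    pd.DataFrame(
        {
            "scaffold": list(genomes.scaffold_lengths),
            "length": list(genomes.scaffold_lengths.values()),
        }
    ).to_csv(out / "scaffold_lengths.tsv", sep="\t", index=False, header=False)

    (out / "genes.gff3").write_text("\n".join(_gff_lines(genomes.genes)) + "\n")

    with open(out / "repeats.bed", "w") as fh:
        for _, row in genomes.repeats.iterrows():
            fh.write(f"{row['scaffold']}\t{row['start']}\t{row['end']}\n")

    for line_id, frame in cohort.dna.items():
        sample_names = [
            f"{line_id}_b{b}_t{t}"
            for b in range(1, config.n_bio_reps + 1)
            for t in range(1, config.n_tech_reps + 1)
        ]
        by_rep = {
            (row.bio_rep, row.tech_rep, row.scaffold, row.pos): (row.ref_depth, row.alt_depth)
            for row in frame.itertuples()
        }
        records = []
        for _, site in genomes.sites.iterrows():
            depths = {}
            for b in range(1, config.n_bio_reps + 1):
                for t in range(1, config.n_tech_reps + 1):
                    depths[f"{line_id}_b{b}_t{t}"] = by_rep[
                        (b, t, site["scaffold"], site["pos"])
                    ]
            records.append(
                {
                    "scaffold": site["scaffold"],
                    "pos": int(site["pos"]),
                    "ref": site["ref"],
                    "alt": site["alt"],
                    "qual": config.variant_qual,
                    "depths": depths,
                }
            )
        write_vcf(out / f"{line_id}.vcf", genomes.scaffold_lengths, sample_names, records)

    rna_sites = pd.concat(cohort.rna_sites.values(), ignore_index=True)
    rna_genes = pd.concat(cohort.rna_genes.values(), ignore_index=True)
    write_table(rna_sites, out / "rna_site_counts.tsv")
    write_table(rna_genes, out / "rna_gene_counts.tsv")
    write_truth(cohort, out)
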