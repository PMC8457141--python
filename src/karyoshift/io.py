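"""Readers and writers for the formats the pipeline touches.

VCF is read through pysam (one record per sample per variant line,
1-based positions retained at the boundary), gene models come from GFF3
via gffutils, repeat annotations from BED3.  Internally every
coordinate is 0-based half-open; only VCF I/O is 1-based, and the
conversion is applied exactly once at this boundary.

Parsing never silently drops data: records skipped for missing fields
are counted on the reader and logged.
"""

from __future__ import annotations

import logging
import re
import warnings
from bisect import bisect_right
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterator, List, Optional, Sequence, Tuple

import gffutils
import pandas as pd
import pysam

logger = logging.getLogger("karyoshift")


class VcfParseError(ValueError):
    """Fatal VCF parse failure (malformed header or truncated body)."""


class TableSchemaError(ValueError):
    """A TSV did not carry the expected header columns."""


@dataclass(frozen=True)
class VariantRecord:
    """One called variant in one sample replicate, with per-allele depths.

    ``allele_depths`` lists the reference allele first, then each
    alternate in VCF order.  ``position`` is 1-based as in the VCF.
    """

    scaffold: str
    position: int
    ref_allele: str
    alt_alleles: Tuple[str, ...]
    quality: float
    sample_id: str
    replicate_id: str
    allele_depths: Tuple[int, ...]
    total_depth: int

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError("VCF positions are 1-based")
        if sum(self.allele_depths) > self.total_depth:
            raise ValueError("allele depths exceed total depth")
        if self.quality < 0:
            raise ValueError("quality must be nonnegative")

    @property
    def is_biallelic_snp(self) -> bool:
        return (
            len(self.alt_alleles) == 1
            and len(self.ref_allele) == 1
            and len(self.alt_alleles[0]) == 1
        )


_REPLICATE_RE = re.compile(r"^(?P<line>.+)_b(?P<bio>\d+)_t(?P<tech>\d+)$")


def split_replicate(sample_name: str) -> Tuple[str, int, int]:
    """Split a ``<line>_b<i>_t<j>`` sample name into (line, bio, tech)."""
    m = _REPLICATE_RE.match(sample_name)
    if m is None:
        raise ValueError(f"sample name {sample_name!r} does not follow <line>_b<i>_t<j>")
    return m.group("line"), int(m.group("bio")), int(m.group("tech"))


class VcfReader:
    """Iterate VariantRecords from a VCF 4.x file with AD/DP sample fields.

    Sample entries without a usable AD field are skipped; the count of
    skipped entries is kept on ``n_skipped`` and logged.  A malformed
    header or a truncated body line raises :class:`VcfParseError`.
    """

    def __init__(self, path: str | Path):
        self.path = Path(path)
        self.n_skipped = 0

    def __iter__(self) -> Iterator[VariantRecord]:
        try:
            vf = pysam.VariantFile(str(self.path))
        except (ValueError, OSError) as exc:
            raise VcfParseError(f"malformed VCF header in {self.path}: {exc}") from exc
        line_no = len(str(vf.header).splitlines())
        with vf:
            it = iter(vf)
            while True:
                line_no += 1
                try:
                    rec = next(it)
                except StopIteration:
                    break
                except Exception as exc:  # htslib parse failure
                    raise VcfParseError(f"parse error at {self.path} line {line_no}: {exc}") from exc
                for sample_name, sample in rec.samples.items():
                    ad = sample.get("AD")
                    if ad is None or any(a is None for a in ad):
                        self.n_skipped += 1
                        logger.warning(
                            "skipping %s:%d sample %s: missing AD", rec.chrom, rec.pos, sample_name
                        )
                        continue
                    dp = sample.get("DP")
                    if dp is None:
                        dp = int(sum(ad))
                    yield VariantRecord(
                        scaffold=rec.chrom,
                        position=rec.pos,
                        ref_allele=rec.ref,
                        alt_alleles=tuple(rec.alts or ()),
                        quality=float(rec.qual) if rec.qual is not None else 0.0,
                        sample_id=sample_name,
                        replicate_id=sample_name,
                        allele_depths=tuple(int(a) for a in ad),
                        total_depth=int(dp),
                    )


def read_vcf(path: str | Path) -> List[VariantRecord]:
    """Read a whole VCF into a list of per-sample VariantRecords."""
    return list(VcfReader(path))


def variants_to_frame(records: Sequence[VariantRecord]) -> pd.DataFrame:
    """Tabulate biallelic-capable fields of VariantRecords.

    Positions are converted to the internal 0-based convention here.
    Multiallelic records keep their first alternate's depth in
    ``alt_depth`` but are flagged by ``n_alts`` for downstream filters.
    """
    rows = []
    for r in records:
        line, bio, tech = split_replicate(r.sample_id)
        rows.append(
            {
                "scaffold": r.scaffold,
                "pos": r.position - 1,
                "ref": r.ref_allele,
                "alt": r.alt_alleles[0] if r.alt_alleles else "",
                "n_alts": len(r.alt_alleles),
                "is_snp": r.is_biallelic_snp,
                "qual": r.quality,
                "line": line,
                "bio_rep": bio,
                "tech_rep": tech,
                "replicate": f"b{bio}_t{tech}",
                "ref_depth": r.allele_depths[0],
                "alt_depth": r.allele_depths[1] if len(r.allele_depths) > 1 else 0,
                "total_depth": r.total_depth,
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class GeneModel:
    """A gene with its CDS footprint (0-based half-open intervals)."""

    gene_id: str
    scaffold: str
    strand: str
    cds_intervals: Tuple[Tuple[int, int], ...]

    def __post_init__(self) -> None:
        prev_end = -1
        for start, end in self.cds_intervals:
            if start >= end:
                raise ValueError(f"empty CDS interval [{start}, {end}) in {self.gene_id}")
            if start < prev_end:
                raise ValueError(f"overlapping/unsorted CDS intervals in {self.gene_id}")
            prev_end = end

    @property
    def cds_length(self) -> int:
        return sum(end - start for start, end in self.cds_intervals)

    def contains(self, pos: int) -> bool:
        """Whether a 0-based position falls inside the CDS."""
        return any(start <= pos < end for start, end in self.cds_intervals)


def read_gff_genes(path: str | Path) -> List[GeneModel]:
    """Load gene models from GFF3, converting to 0-based half-open intervals.

    CDS features whose parentage does not resolve to a gene are skipped
    with a warning.
    """
    text = Path(path).read_text()
    if not text.strip():
        return []
    db = gffutils.create_db(
        text, dbfn=":memory:", from_string=True, keep_order=True, merge_strategy="create_unique"
    )
    cds_by_gene: Dict[str, List[gffutils.Feature]] = {}
    genes: Dict[str, gffutils.Feature] = {g.id: g for g in db.features_of_type("gene")}
    for cds in db.features_of_type("CDS"):
        parents = [p for p in db.parents(cds.id) if p.featuretype == "gene"]
        if not parents:
            warnings.warn(f"CDS {cds.id} has no parent gene; skipped", stacklevel=2)
            continue
        cds_by_gene.setdefault(parents[0].id, []).append(cds)
    models = []
    for gene_id, cds_list in cds_by_gene.items():
        gene = genes[gene_id]
        intervals = sorted((c.start - 1, c.end) for c in cds_list)
        models.append(
            GeneModel(
                gene_id=gene_id,
                scaffold=gene.seqid,
                strand=gene.strand if gene.strand in "+-" else "+",
                cds_intervals=tuple(intervals),
            )
        )
    models.sort(key=lambda g: (g.scaffold, g.cds_intervals[0][0]))
    return models


def _merge_intervals(intervals: List[Tuple[int, int]]) -> List[Tuple[int, int]]:
    """Merge sorted-or-not 0-based half-open intervals; adjacent ones fuse."""
    merged: List[Tuple[int, int]] = []
    for start, end in sorted(intervals):
        if merged and start <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    return merged


@dataclass
class RepeatMask:
    """Per-scaffold merged repeat intervals (0-based half-open)."""

    intervals: Dict[str, List[Tuple[int, int]]] = field(default_factory=dict)

    @classmethod
    def from_bed(cls, path: str | Path) -> "RepeatMask":
        raw: Dict[str, List[Tuple[int, int]]] = {}
        with open(path) as fh:
            for ln, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split("\t")
                scaffold, start, end = parts[0], int(parts[1]), int(parts[2])
                if start >= end:
                    warnings.warn(f"BED line {ln}: start >= end, record rejected", stacklevel=2)
                    continue
                raw.setdefault(scaffold, []).append((start, end))
        return cls(intervals={s: _merge_intervals(iv) for s, iv in raw.items()})

    def contains(self, scaffold: str, pos: int) -> bool:
        """Whether a 0-based position overlaps a repeat."""
        iv = self.intervals.get(scaffold)
        if not iv:
            return False
        starts = [s for s, _ in iv]
        i = bisect_right(starts, pos) - 1
        return i >= 0 and iv[i][0] <= pos < iv[i][1]


def read_bed_mask(path: str | Path) -> RepeatMask:
    """Read a BED3+ repeat annotation into a merged mask."""
    return RepeatMask.from_bed(path)


def read_scaffold_lengths(path: str | Path) -> Dict[str, int]:
    """Read a FASTA-index-style (name, length) TSV."""
    df = pd.read_csv(path, sep="\t", header=None, names=["scaffold", "length"], usecols=[0, 1])
    return dict(zip(df["scaffold"].astype(str), df["length"].astype(int)))


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a result table as TSV with a header row."""
    df.to_csv(path, sep="\t", index=False)


def read_table(path: str | Path, required: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """Read a TSV result table, verifying the expected columns if given."""
    df = pd.read_csv(path, sep="\t")
    if required is not None:
        missing = [c for c in required if c not in df.columns]
        extra = [c for c in df.columns if c not in required]
        if missing or extra:
            raise TableSchemaError(
                f"{path}: header mismatch (missing {missing}, unexpected {extra})"
            )
    return df


def write_vcf(
    path: str | Path,
    scaffold_lengths: Dict[str, int],
    sample_names: Sequence[str],
    records: Sequence[dict],
) -> None:
    """Write a minimal VCF 4.2 with AD/DP FORMAT fields via pysam.

    ``records`` are dicts with keys scaffold, pos (0-based internal,
    written 1-based), ref, alt, qual and per-sample ``depths`` mapping
    sample name -> (ref_depth, alt_depth).
    """
    header = pysam.VariantHeader()
    header.add_line('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">')
    header.add_line('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">')
    for scaffold, length in scaffold_lengths.items():
        header.contigs.add(scaffold, length=length)
    for name in sample_names:
        header.add_sample(name)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for rec in records:
            v = out.new_record(
                contig=rec["scaffold"],
                start=rec["pos"],
                stop=rec["pos"] + 1,
                alleles=(rec["ref"], rec["alt"]),
                qual=rec["qual"],
            )
            for name in sample_names:
                ref_d, alt_d = rec["depths"][name]
                v.samples[name]["AD"] = (int(ref_d), int(alt_d))
                v.samples[name]["DP"] = int(ref_d + alt_d)
            out.write(v)
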