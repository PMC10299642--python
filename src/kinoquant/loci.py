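"""Deafness-locus interval mapping for candidate genes.

Places candidate hearing-loss genes relative to marker-defined critical
regions on GRCh38: a gene is ``inside`` a locus if fully contained,
``overlapping`` if partially, ``outside`` with a gap distance otherwise,
and ``incomparable`` across chromosomes.  Gap distances are plain boundary
differences in bp, also reported in MB rounded to one decimal.

The packaged fixture carries the GRCh38.p13 coordinates of ANKEF1, ODF3L2
and SAXO2 and of the marker-defined critical regions DFNB72, DFNA57 (chr19)
and DFNA30 (chr15) proposed for them.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

__all__ = [
    "GenomicInterval",
    "CandidacyReport",
    "IncomparableChromosomes",
    "interval_gap",
    "assess_candidacy",
    "read_intervals",
    "write_intervals",
    "bundled_genes",
    "bundled_loci",
    "bundled_pairs",
    "candidacy_table",
]


class IncomparableChromosomes(ValueError):
    """Two intervals lie on different chromosomes; no linear distance exists."""


def _norm_chrom(chrom: str) -> str:
    chrom = str(chrom).strip()
    return chrom[3:] if chrom.lower().startswith("chr") else chrom


@dataclass(frozen=True)
class GenomicInterval:
    """1-based inclusive interval on a chromosome."""

    chrom: str
    start: int
    end: int
    label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "chrom", _norm_chrom(self.chrom))
        object.__setattr__(self, "start", int(self.start))
        object.__setattr__(self, "end", int(self.end))
        if self.start < 1 or self.end < 1:
            raise ValueError(f"{self.label or self.chrom}: coordinates are 1-based "
                             f"and must be >= 1 (got {self.start}-{self.end})")
        if self.start > self.end:
            raise ValueError(f"{self.label or self.chrom}: start {self.start} "
                             f"> end {self.end}")

    @property
    def region(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"

    @classmethod
    def from_region(cls, region: str, label: str = "") -> "GenomicInterval":
        m = re.fullmatch(r"\s*([^:\s]+):(\d+)-(\d+)\s*", region)
        if not m:
            raise ValueError(f"cannot parse region {region!r} "
                             "(expected chrom:start-end)")
        return cls(m.group(1), int(m.group(2)), int(m.group(3)), label=label)


@dataclass
class CandidacyReport:
    """Inside/outside call for a gene against one critical region."""

    gene: str
    locus: str
    status: str        # inside | overlapping | outside | incomparable
    gap_bp: int        # 0 unless outside
    gap_mb: float      # gap_bp / 1e6 rounded to 1 decimal

    def __post_init__(self) -> None:
        if self.status == "outside" and self.gap_bp <= 0:
            raise ValueError("outside status requires a positive gap")
        if self.status in ("inside", "overlapping") and self.gap_bp != 0:
            raise ValueError(f"{self.status} status requires gap 0")


def interval_gap(a: GenomicInterval, b: GenomicInterval) -> int:
    """Gap in bp between two same-chromosome intervals (0 if they overlap).

    The distance is the plain difference between the nearest boundaries,
    symmetric and non-negative; touching or overlapping intervals have gap 0.
    """
    if a.chrom != b.chrom:
        raise IncomparableChromosomes(
            f"{a.label or a.region} and {b.label or b.region} lie on "
            f"different chromosomes ({a.chrom} vs {b.chrom})")
    return max(b.start - a.end, a.start - b.end, 0)


def assess_candidacy(gene: GenomicInterval, locus: GenomicInterval
                     ) -> CandidacyReport:
    """Classify a gene's position relative to a marker-defined critical region."""
    if gene.chrom != locus.chrom:
        return CandidacyReport(gene.label, locus.label, "incomparable", 0, 0.0)
    gap = interval_gap(gene, locus)
    if gap > 0:
        status = "outside"
    elif locus.start <= gene.start and gene.end <= locus.end:
        status = "inside"
    else:
        status = "overlapping"
    return CandidacyReport(gene.label, locus.label, status, gap,
                           round(gap / 1e6, 1))


def read_intervals(path: str | Path, dialect: str = "table1_tsv"
                   ) -> list[GenomicInterval]:
    """Read intervals from a TSV of (label, chrom:start-end) or a BED file.

    BED coordinates (0-based half-open) are converted to 1-based inclusive
    (start + 1, end).  Malformed rows raise with their line number.
    """
    path = Path(path)
    out: list[GenomicInterval] = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = re.split(r"\s+", line) if dialect == "bed" else line.split("\t")
            try:
                if dialect == "table1_tsv":
                    if lineno == 1 and fields[0].lower() in ("label", "gene", "locus"):
                        continue
                    label, region = fields[0], fields[1]
                    out.append(GenomicInterval.from_region(region, label=label))
                elif dialect == "bed":
                    chrom, start, end = fields[0], int(fields[1]), int(fields[2])
                    label = fields[3] if len(fields) > 3 else ""
                    out.append(GenomicInterval(chrom, start + 1, end, label=label))
                else:
                    raise ValueError(f"unknown dialect {dialect!r}; "
                                     "use 'table1_tsv' or 'bed'")
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return out


def write_intervals(intervals: list[GenomicInterval], path: str | Path) -> None:
    """Write intervals as a (label, chrom:start-end) TSV; lossless round-trip."""
    with Path(path).open("w") as fh:
        fh.write("label\tregion\n")
        for iv in intervals:
            fh.write(f"{iv.label}\t{iv.region}\n")


# ----------------------------------------------------------- bundled data

def _bundled(name: str) -> list[GenomicInterval]:
    text = resources.files("kinoquant.data").joinpath(name).read_text()
    out = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or lineno == 1:
            continue
        label, region = line.split("\t")[:2]
        out.append(GenomicInterval.from_region(region, label=label))
    return out


def bundled_genes() -> list[GenomicInterval]:
    """GRCh38.p13 coordinates of the candidate genes ANKEF1, ODF3L2, SAXO2."""
    return _bundled("grch38_candidate_genes.tsv")


def bundled_loci() -> list[GenomicInterval]:
    """Marker-defined critical regions DFNB72, DFNA57 and DFNA30 (GRCh38)."""
    return _bundled("grch38_deafness_loci.tsv")


def bundled_pairs() -> list[tuple[str, str]]:
    """Proposed gene-locus pairings; 'n/a' marks a gene with no proposed locus."""
    text = resources.files("kinoquant.data").joinpath(
        "candidate_locus_pairs.tsv").read_text()
    pairs = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or lineno == 1:
            continue
        gene, locus = line.split("\t")[:2]
        pairs.append((gene, locus))
    return pairs


def candidacy_table(genes: list[GenomicInterval] | None = None,
                    loci: list[GenomicInterval] | None = None,
                    pairs: list[tuple[str, str]] | None = None) -> pd.DataFrame:
    """Candidacy report for every proposed gene-locus pairing.

    Defaults to the bundled GRCh38 fixture.  Genes paired with 'n/a' get an
    'n/a' row (no locus to compare against).
    """
    genes = bundled_genes() if genes is None else genes
    loci = bundled_loci() if loci is None else loci
    pairs = bundled_pairs() if pairs is None else pairs
    gene_by = {g.label: g for g in genes}
    locus_by = {l.label: l for l in loci}
    rows = []
    for gene_label, locus_label in pairs:
        if locus_label == "n/a":
            rows.append((gene_label, "n/a", "n/a", 0, 0.0))
            continue
        rep = assess_candidacy(gene_by[gene_label], locus_by[locus_label])
        rows.append((rep.gene, rep.locus, rep.status, rep.gap_bp, rep.gap_mb))
    return pd.DataFrame(rows, columns=["gene", "locus", "status",
                                       "gap_bp", "gap_mb"])
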