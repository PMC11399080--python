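"""Ingestion and bookkeeping of cassette insertion sites.

An insertion site is the deduplicated genomic coordinate + orientation of one
integrated cassette, recovered from inverse-PCR sequencing.  From alignments we
keep first-mate, primary, well-mapped reads (mapq > 30; the screen pipeline
discards mapq <= 30) and take the read's 5' end as the insertion coordinate.
Cassette orientation equals read orientation by default; ``flip_strand``
covers libraries with the opposite iPCR geometry.

Counting in everything downstream is in unique insertions, never reads, so
deduplication by (contig, position, strand) happens here and is idempotent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

__all__ = [
    "InsertionSite",
    "SampleTable",
    "ExtractionStats",
    "extract_insertions",
    "read_insertions_bed",
    "write_insertions_bed",
    "merge_background",
    "replicate_correlation",
    "read_sample_sheet",
]

BACKGROUND = "background"
SORTED = "sorted"


@dataclass(frozen=True, order=True)
class InsertionSite:
    """One deduplicated integration event."""

    contig: str
    position: int  # 0-based; the cassette's splice-donor-proximal base
    strand: str  # cassette orientation, + or -
    sample_id: str = ""
    replicate: int = 1

    def __post_init__(self):
        if self.position < 0:
            raise ValueError(f"negative insertion position: {self}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"insertion strand must be + or -: {self}")

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.contig, self.position, self.strand)


@dataclass
class SampleTable:
    """Insertion sites of one sample (or a merged background)."""

    sample_id: str
    role: str  # background | sorted
    sites: list[InsertionSite] = field(default_factory=list)
    screen: str = ""
    replicate: int = 1

    def __len__(self) -> int:
        return len(self.sites)

    def unique_keys(self) -> set[tuple[str, int, str]]:
        return {s.key for s in self.sites}

    def deduplicated(self) -> "SampleTable":
        seen: dict[tuple[str, int, str], InsertionSite] = {}
        for s in self.sites:
            seen.setdefault(s.key, s)
        return SampleTable(
            sample_id=self.sample_id,
            role=self.role,
            sites=sorted(seen.values()),
            screen=self.screen,
            replicate=self.replicate,
        )


@dataclass
class ExtractionStats:
    """Read accounting for one alignment file; retained + skipped = total."""

    total: int = 0
    retained: int = 0
    skipped_unmapped: int = 0
    skipped_secondary: int = 0
    skipped_supplementary: int = 0
    skipped_not_first_mate: int = 0
    skipped_mapq: int = 0
    duplicate_sites: int = 0

    @property
    def skipped(self) -> int:
        return (
            self.skipped_unmapped
            + self.skipped_secondary
            + self.skipped_supplementary
            + self.skipped_not_first_mate
            + self.skipped_mapq
        )


def extract_insertions(
    alignment_path,
    mapq_min: int = 31,
    sample_id: str = "",
    replicate: int = 1,
    flip_strand: bool = False,
    require_sorted: bool = True,
) -> tuple[list[InsertionSite], ExtractionStats]:
    """Insertion sites from a coordinate-sorted SAM/BAM.

    One candidate site per retained first-mate primary read, at the read's 5'
    end in genome coordinates (reference start for forward reads, last aligned
    base for reverse reads); duplicates collapse by (contig, position, strand).
    Reads with mapq < ``mapq_min`` (default 31, i.e. mapq <= 30 discarded) and
    unmapped/secondary/supplementary reads are skipped with counts.
    """
    import pysam

    stats = ExtractionStats()
    sites: dict[tuple[str, int, str], InsertionSite] = {}
    with pysam.AlignmentFile(str(alignment_path), check_sq=False) as fh:
        if require_sorted:
            so = fh.header.get("HD", {}).get("SO", "unknown")
            if so != "coordinate":
                raise ValueError(
                    f"{alignment_path}: alignment file must be coordinate-sorted "
                    f"(header SO={so!r})"
                )
        for read in fh:
            stats.total += 1
            if read.is_unmapped:
                stats.skipped_unmapped += 1
                continue
            if read.is_secondary:
                stats.skipped_secondary += 1
                continue
            if read.is_supplementary:
                stats.skipped_supplementary += 1
                continue
            if read.is_paired and not read.is_read1:
                stats.skipped_not_first_mate += 1
                continue
            if read.mapping_quality < mapq_min:
                stats.skipped_mapq += 1
                continue
            stats.retained += 1
            if read.is_reverse:
                position = read.reference_end - 1
                strand = "-"
            else:
                position = read.reference_start
                strand = "+"
            if flip_strand:
                strand = "-" if strand == "+" else "+"
            key = (read.reference_name, position, strand)
            if key in sites:
                stats.duplicate_sites += 1
            else:
                sites[key] = InsertionSite(
                    contig=read.reference_name,
                    position=position,
                    strand=strand,
                    sample_id=sample_id,
                    replicate=replicate,
                )
    return sorted(sites.values()), stats


def read_insertions_bed(path, sample_id: Optional[str] = None, replicate: int = 1) -> list[InsertionSite]:
    """BED6 -> insertion sites; the name column carries the sample id.

    Strand is mandatory ('.' rejected); malformed records raise with the line
    number.  The interval's start is the insertion coordinate.
    """
    sites: list[InsertionSite] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 6:
                raise ValueError(f"{path}: line {lineno}: BED6 requires 6 fields, got {len(fields)}")
            contig, start_s, end_s, name, _score, strand = fields[:6]
            try:
                start = int(start_s)
                int(end_s)
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: non-integer coordinates") from exc
            if strand not in ("+", "-"):
                raise ValueError(
                    f"{path}: line {lineno}: strand must be + or - (got {strand!r}); "
                    "cassette orientation is mandatory"
                )
            sites.append(
                InsertionSite(
                    contig=contig,
                    position=start,
                    strand=strand,
                    sample_id=sample_id if sample_id is not None else name,
                    replicate=replicate,
                )
            )
    return sites


def write_insertions_bed(sites: Iterable[InsertionSite], path) -> None:
    """BED6 output, one 1-nt interval per site; round-trips losslessly."""
    with open(path, "w") as fh:
        for s in sorted(sites):
            fh.write(f"{s.contig}\t{s.position}\t{s.position + 1}\t{s.sample_id}\t0\t{s.strand}\n")


def merge_background(replicates: Sequence[SampleTable]) -> SampleTable:
    """Union of unique sites across background replicates.

    Background replicates of one screen are reproducible enough to be pooled;
    merging is a set union of unique (contig, position, strand) events, with
    the first-seen site kept so per-site sample provenance survives.
    """
    if not replicates:
        raise ValueError("merge_background needs at least one replicate")
    roles = {r.role for r in replicates}
    if roles != {BACKGROUND}:
        raise ValueError(f"can only merge background samples, got roles {sorted(roles)}")
    screens = {r.screen for r in replicates}
    if len(screens) > 1:
        raise ValueError(f"refusing to merge backgrounds from different screens: {sorted(screens)}")
    seen: dict[tuple[str, int, str], InsertionSite] = {}
    for table in replicates:
        for s in table.sites:
            seen.setdefault(s.key, s)
    return SampleTable(
        sample_id="background_merged",
        role=BACKGROUND,
        sites=sorted(seen.values()),
        screen=replicates[0].screen,
    )


def replicate_correlation(
    a: SampleTable, b: SampleTable, bin_size: int = 10_000
) -> Optional[float]:
    """Pearson correlation of per-bin insertion counts between two samples.

    The genome is tiled into fixed ``bin_size`` windows and unique insertions
    are counted per bin; the correlation runs over bins non-empty in either
    sample.  Returns None (undefined) with fewer than two informative bins.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    from scipy.stats import pearsonr

    def bin_counts(table: SampleTable) -> dict[tuple[str, int], int]:
        counts: dict[tuple[str, int], int] = {}
        for key in table.unique_keys():
            b_ = (key[0], key[1] // bin_size)
            counts[b_] = counts.get(b_, 0) + 1
        return counts

    ca, cb = bin_counts(a), bin_counts(b)
    bins = sorted(set(ca) | set(cb))
    if len(bins) < 2:
        return None
    xa = np.array([ca.get(k, 0) for k in bins], dtype=float)
    xb = np.array([cb.get(k, 0) for k in bins], dtype=float)
    if xa.std() == 0 or xb.std() == 0:
        return None
    return float(pearsonr(xa, xb)[0])


def read_sample_sheet(path) -> list[dict]:
    """TSV sample sheet: sample_id, role, replicate, path[, screen]."""
    rows = []
    with open(path) as fh:
        header = None
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if header is None:
                header = fields
                required = {"sample_id", "role", "replicate", "path"}
                if not required.issubset(header):
                    raise ValueError(f"{path}: sample sheet must contain columns {sorted(required)}")
                continue
            row = dict(zip(header, fields))
            row["replicate"] = int(row["replicate"])
            if row["role"] not in (BACKGROUND, SORTED):
                raise ValueError(f"{path}: line {lineno}: role must be background or sorted")
            rows.append(row)
    return rows
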