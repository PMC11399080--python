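"""Gene models for splice-acceptor gene-trap analysis.

An ORF-tagging cassette integrates into the genome and splices its donor onto
the next downstream splice-acceptor exon, so the annotation layer has to answer
three questions precisely:

* which exons carry a splice acceptor at all (every exon of a protein-coding
  transcript except the first, which has no acceptor; intronless genes have
  none),
* at which genomic coordinate that acceptor sits (the exon's 5'-in-transcript
  boundary), and
* in which codon phase the exon's coding sequence begins, so that
  cassette-frame / exon-phase compatibility can be evaluated downstream.

Coordinates are stored 0-based half-open internally; GTF input (1-based closed)
is converted on parse.  The acceptor of a ``+`` exon is its ``start``; for a
``-`` exon it is its half-open ``end`` — under the mirror transform
``x -> L - x`` these map onto each other, which keeps all distance and phase
arithmetic strand-symmetric.

Phase follows the GTF/GFF frame convention for CDS features: the number of
bases at the feature start that complete the previous codon, i.e. the number
of bases to skip to reach the first full codon.  For exons whose acceptor
boundary lies upstream of the transcript's start codon the phase is corrected
to the spliced-transcript distance to the ATG modulo 3 (an exon starting 2 nt
upstream of the ATG has corrected phase 2).
"""

from __future__ import annotations

import gzip
import re
from dataclasses import dataclass, field
from statistics import median
from typing import Iterable, Iterator, Optional, Sequence

__all__ = [
    "ExonRecord",
    "TranscriptModel",
    "GeneModel",
    "AnnotationSet",
    "AcceptorIndex",
    "FirstExonStats",
    "GtfParseError",
    "load_annotation",
    "build_acceptor_index",
    "exon_phase",
    "correct_phase_upstream",
    "first_exon_statistics",
    "classify_truncation",
    "FULL_LENGTH",
    "SHORT_TRUNCATION",
    "MAJOR_TRUNCATION",
]

# Truncation classes for a tag fusion entering at a given acceptor exon.
FULL_LENGTH = "full_length"
SHORT_TRUNCATION = "short_truncation"
MAJOR_TRUNCATION = "major_truncation"

_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


class GtfParseError(ValueError):
    """Raised for a malformed GTF line; carries the 1-based line number."""


@dataclass
class ExonRecord:
    """One exon of one transcript, 0-based half-open."""

    contig: str
    start: int
    end: int
    strand: str
    transcript_id: str
    gene_id: str
    rank: int  # 1-based order in transcript, 5'->3'
    phase: Optional[int] = None  # {0,1,2} or None (no CDS relation)

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"exon with start >= end: {self}")

    @property
    def is_first(self) -> bool:
        return self.rank == 1

    @property
    def acceptor_position(self) -> int:
        """Genomic coordinate of the exon's transcript-5' boundary."""
        return self.start if self.strand == "+" else self.end

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class CdsSegment:
    """Per-exon piece of a transcript CDS with its frame (phase)."""

    start: int
    end: int
    frame: int  # bases completing the previous codon at segment start


@dataclass
class TranscriptModel:
    transcript_id: str
    gene_id: str
    biotype: str
    strand: str
    contig: str
    exons: list[ExonRecord] = field(default_factory=list)
    cds_segments: list[CdsSegment] = field(default_factory=list)  # transcript order

    @property
    def is_coding(self) -> bool:
        return bool(self.cds_segments)

    @property
    def cds_length_nt(self) -> int:
        return sum(s.end - s.start for s in self.cds_segments)

    @property
    def cds_length_is_codon_multiple(self) -> bool:
        # Recorded, never enforced: annotations contain non-multiple-of-3 CDS.
        return self.cds_length_nt % 3 == 0

    @property
    def length_nt(self) -> int:
        return sum(len(e) for e in self.exons)

    def genomic_to_transcript(self, pos: int) -> Optional[int]:
        """Spliced-transcript offset of a genomic boundary coordinate.

        ``pos`` is interpreted as a *boundary* in the half-open sense: for a
        ``+`` transcript it is the coordinate of the next transcribed base,
        for a ``-`` transcript the half-open end of the remaining transcript.
        Returns None when the position falls in an intron or outside the
        transcript.
        """
        offset = 0
        for exon in self.exons:
            if exon.strand == "+":
                if exon.start <= pos <= exon.end:
                    return offset + (pos - exon.start)
            else:
                if exon.start <= pos <= exon.end:
                    return offset + (exon.end - pos)
            offset += len(exon)
        return None

    @property
    def cds_start_transcript_coord(self) -> Optional[int]:
        if not self.cds_segments:
            return None
        first = self.cds_segments[0]
        anchor = first.start if self.strand == "+" else first.end
        return self.genomic_to_transcript(anchor)

    @property
    def tss(self) -> int:
        first = self.exons[0]
        return first.start if self.strand == "+" else first.end


@dataclass
class GeneModel:
    gene_id: str
    gene_name: str
    biotype: str
    strand: str
    contig: str
    transcripts: dict[str, TranscriptModel] = field(default_factory=dict)

    @property
    def is_intronless(self) -> bool:
        """True iff no isoform contains a spliced intron."""
        return all(len(t.exons) == 1 for t in self.transcripts.values())

    @property
    def is_coding(self) -> bool:
        return any(t.is_coding for t in self.transcripts.values())

    @property
    def shortest_cds_nt(self) -> Optional[int]:
        lengths = [t.cds_length_nt for t in self.transcripts.values() if t.is_coding]
        return min(lengths) if lengths else None

    @property
    def tss(self) -> int:
        positions = [t.tss for t in self.transcripts.values()]
        return min(positions) if self.strand == "+" else max(positions)


class AnnotationSet:
    """Parsed annotation: genes keyed by gene_id, with derived views."""

    def __init__(self, genes: dict[str, GeneModel], skipped_features: int = 0):
        self.genes = genes
        self.skipped_features = skipped_features

    def __len__(self) -> int:
        return len(self.genes)

    def transcripts(self) -> Iterator[TranscriptModel]:
        for gene in self.genes.values():
            yield from gene.transcripts.values()

    def coding_gene_ids(self) -> set[str]:
        return {g.gene_id for g in self.genes.values() if g.is_coding}

    def intronic_coding_gene_ids(self) -> set[str]:
        """Protein-coding genes with at least one spliced isoform (taggable)."""
        return {
            g.gene_id
            for g in self.genes.values()
            if g.is_coding and not g.is_intronless
        }

    def tss_table(self, coding_only: bool = True) -> list[tuple[str, int, str, str]]:
        """(contig, tss, strand, gene_id) rows, optionally coding genes only."""
        rows = []
        for gene in self.genes.values():
            if coding_only and not gene.is_coding:
                continue
            rows.append((gene.contig, gene.tss, gene.strand, gene.gene_id))
        return rows


def _transcript_is_coding_biotype(tx_biotype: str, gene_biotype: str) -> bool:
    # Transcript biotype wins; fall back to the gene when absent (dialect drift).
    biotype = tx_biotype or gene_biotype
    return biotype == "protein_coding"


def _open_maybe_gzip(path):
    if hasattr(path, "read"):  # file-like (e.g. in-memory GTF)
        return path
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path, "rt")


def _parse_attributes(raw: str) -> dict[str, str]:
    return dict(_ATTR_RE.findall(raw))


def load_annotation(gtf_path, coding_only_for_acceptors: bool = True) -> AnnotationSet:
    """Parse a GENCODE-style GTF into an :class:`AnnotationSet`.

    Accepts plain or gzipped GTF with gene/transcript/exon/CDS features.
    1-based closed coordinates become 0-based half-open.  Exons lacking a
    transcript parent record are tolerated (transcript records are synthesised
    from exon attributes); truly orphan features (no transcript_id) are skipped
    and counted in ``skipped_features``.

    Raises :class:`GtfParseError` naming the line number on malformed lines.
    """
    gene_meta: dict[str, dict] = {}
    tx_meta: dict[str, dict] = {}
    exon_rows: dict[str, list] = {}
    cds_rows: dict[str, list] = {}
    skipped = 0

    with _open_maybe_gzip(gtf_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise GtfParseError(
                    f"{gtf_path}: line {lineno}: expected 9 tab-separated fields, "
                    f"got {len(fields)}"
                )
            contig, _source, feature, start_s, end_s, _score, strand, frame_s, attrs_s = fields
            if feature not in ("gene", "transcript", "exon", "CDS"):
                continue
            try:
                start = int(start_s) - 1  # to 0-based half-open
                end = int(end_s)
            except ValueError as exc:
                raise GtfParseError(
                    f"{gtf_path}: line {lineno}: non-integer coordinates"
                ) from exc
            if strand not in ("+", "-"):
                raise GtfParseError(
                    f"{gtf_path}: line {lineno}: strand must be + or -, got {strand!r}"
                )
            attrs = _parse_attributes(attrs_s)
            gene_id = attrs.get("gene_id")
            if gene_id is None:
                raise GtfParseError(f"{gtf_path}: line {lineno}: missing gene_id")

            if feature == "gene":
                gene_meta.setdefault(gene_id, {}).update(
                    contig=contig,
                    strand=strand,
                    name=attrs.get("gene_name", gene_id),
                    biotype=attrs.get("gene_type", attrs.get("gene_biotype", "")),
                )
                continue

            tx_id = attrs.get("transcript_id")
            if tx_id is None:
                skipped += 1
                continue
            if feature == "transcript" or tx_id not in tx_meta:
                meta = tx_meta.setdefault(tx_id, {})
                meta.setdefault("gene_id", gene_id)
                meta.setdefault("contig", contig)
                meta.setdefault("strand", strand)
                biotype = attrs.get("transcript_type", attrs.get("transcript_biotype", ""))
                if feature == "transcript" or "biotype" not in meta:
                    meta["biotype"] = biotype or tx_meta.get(tx_id, {}).get("biotype", "")
            if feature == "exon":
                rank = attrs.get("exon_number")
                exon_rows.setdefault(tx_id, []).append(
                    (start, end, int(rank) if rank is not None else None)
                )
            elif feature == "CDS":
                frame = None if frame_s == "." else int(frame_s)
                cds_rows.setdefault(tx_id, []).append((start, end, frame))

    genes: dict[str, GeneModel] = {}
    for tx_id, meta in tx_meta.items():
        rows = exon_rows.get(tx_id)
        if not rows:
            skipped += 1
            continue
        gene_id = meta["gene_id"]
        strand = meta["strand"]
        contig = meta["contig"]
        gmeta = gene_meta.get(gene_id, {})
        gene = genes.setdefault(
            gene_id,
            GeneModel(
                gene_id=gene_id,
                gene_name=gmeta.get("name", gene_id),
                biotype=gmeta.get("biotype", ""),
                strand=gmeta.get("strand", strand),
                contig=gmeta.get("contig", contig),
            ),
        )
        tx = TranscriptModel(
            transcript_id=tx_id,
            gene_id=gene_id,
            biotype=meta.get("biotype", ""),
            strand=strand,
            contig=contig,
        )
        # transcript order: ascending coordinate for +, descending for -
        rows.sort(key=lambda r: r[0], reverse=(strand == "-"))
        for i, (start, end, rank) in enumerate(rows, start=1):
            tx.exons.append(
                ExonRecord(
                    contig=contig,
                    start=start,
                    end=end,
                    strand=strand,
                    transcript_id=tx_id,
                    gene_id=gene_id,
                    rank=rank if rank is not None else i,
                )
            )
        crows = cds_rows.get(tx_id, [])
        crows.sort(key=lambda r: r[0], reverse=(strand == "-"))
        running = 0
        for start, end, frame in crows:
            if frame is None:
                frame = (3 - running % 3) % 3  # recompute for minimal GTFs
            tx.cds_segments.append(CdsSegment(start=start, end=end, frame=frame))
            running += end - start
        gene.transcripts[tx_id] = tx

    annotation = AnnotationSet(genes, skipped_features=skipped)
    _annotate_phases(annotation)
    return annotation


def _annotate_phases(annotation: AnnotationSet) -> None:
    for tx in annotation.transcripts():
        if not tx.is_coding:
            continue
        for exon in tx.exons:
            exon.phase = exon_phase(exon, tx)


def correct_phase_upstream(exon: ExonRecord, transcript: TranscriptModel) -> Optional[int]:
    """Phase of an exon whose acceptor boundary lies 5' of the start codon.

    The cassette contributes complete codons, so the fusion frame is set by
    the number of spliced-transcript nucleotides between the exon's acceptor
    boundary and the endogenous ATG, modulo 3: 2 nt upstream -> phase 2,
    exactly at the ATG -> 0, 3 nt upstream -> 0.  Returns None for a
    transcript without CDS.
    """
    cds_start = transcript.cds_start_transcript_coord
    if cds_start is None:
        return None
    boundary = transcript.genomic_to_transcript(exon.acceptor_position)
    if boundary is None:
        return None
    distance = cds_start - boundary
    if distance < 0:
        return None
    return distance % 3


def exon_phase(exon: ExonRecord, transcript: TranscriptModel) -> Optional[int]:
    """Codon phase at the exon's acceptor boundary, or None when undefined.

    Inside the CDS the phase is the GTF frame of the CDS segment starting at
    the boundary (recomputed arithmetically when the boundary falls mid
    segment); upstream of the start codon it is the corrected phase; entirely
    downstream of the stop codon it is undefined.
    """
    cds_start = transcript.cds_start_transcript_coord
    if cds_start is None:
        return None
    boundary = transcript.genomic_to_transcript(exon.acceptor_position)
    if boundary is None:
        return None
    if boundary < cds_start:
        return correct_phase_upstream(exon, transcript)
    cds_end = cds_start + transcript.cds_length_nt
    if boundary >= cds_end:
        return None
    # Prefer the annotated frame of a CDS segment starting exactly here.
    for seg in transcript.cds_segments:
        seg_boundary = seg.start if transcript.strand == "+" else seg.end
        if seg_boundary == exon.acceptor_position:
            return seg.frame
    coding_before = boundary - cds_start
    return (3 - coding_before % 3) % 3


@dataclass
class AcceptorEntry:
    position: int
    gene_id: str
    exon: ExonRecord
    transcript: TranscriptModel


class AcceptorIndex:
    """Sorted splice-acceptor positions per (contig, strand).

    Contains exactly the non-first exons of protein-coding transcripts;
    identical (position, gene) pairs from different isoforms collapse to one
    entry, so intronless genes and noncoding transcripts contribute nothing.
    Entries are sorted by (position, gene_id) so that the first entry at a
    position is the deterministic winner of an equidistance tie.
    """

    def __init__(self) -> None:
        self._entries: dict[tuple[str, str], list[AcceptorEntry]] = {}
        self._positions: dict[tuple[str, str], "np.ndarray"] = {}

    def add(self, entry: AcceptorEntry, strand: str) -> None:
        self._entries.setdefault((entry.exon.contig, strand), []).append(entry)

    def finalize(self) -> None:
        import numpy as np

        for key, entries in self._entries.items():
            seen: dict[tuple[int, str], AcceptorEntry] = {}
            for e in entries:
                k = (e.position, e.gene_id)
                prev = seen.get(k)
                # deterministic representative exon per (position, gene)
                if prev is None or (e.transcript.transcript_id, e.exon.rank) < (
                    prev.transcript.transcript_id,
                    prev.exon.rank,
                ):
                    seen[k] = e
            deduped = sorted(seen.values(), key=lambda e: (e.position, e.gene_id))
            self._entries[key] = deduped
            self._positions[key] = np.array([e.position for e in deduped], dtype=np.int64)

    def entries(self, contig: str, strand: str) -> list[AcceptorEntry]:
        return self._entries.get((contig, strand), [])

    def positions(self, contig: str, strand: str):
        import numpy as np

        return self._positions.get((contig, strand), np.empty(0, dtype=np.int64))

    def keys(self) -> list[tuple[str, str]]:
        return list(self._entries.keys())

    def __len__(self) -> int:
        return sum(len(v) for v in self._entries.values())

    def gene_ids(self) -> set[str]:
        return {e.gene_id for v in self._entries.values() for e in v}

    def to_bed(self, path) -> None:
        """BED6 export: name = gene_id, score = exon rank, strand."""
        rows = []
        for (contig, strand), entries in self._entries.items():
            for e in entries:
                rows.append((contig, e.exon.start, e.exon.end, e.gene_id, e.exon.rank, strand))
        rows.sort()
        with open(path, "w") as fh:
            for contig, start, end, name, score, strand in rows:
                fh.write(f"{contig}\t{start}\t{end}\t{name}\t{score}\t{strand}\n")


def build_acceptor_index(annotation: AnnotationSet) -> AcceptorIndex:
    """Index every splice-acceptor exon of protein-coding transcripts.

    First exons carry no acceptor and are excluded; so are all exons of
    non-protein-coding transcripts, hence intronless genes never appear.
    """
    index = AcceptorIndex()
    for gene in annotation.genes.values():
        for tx in gene.transcripts.values():
            if not _transcript_is_coding_biotype(tx.biotype, gene.biotype):
                continue
            for exon in tx.exons:
                if exon.is_first:
                    continue
                index.add(
                    AcceptorEntry(
                        position=exon.acceptor_position,
                        gene_id=gene.gene_id,
                        exon=exon,
                        transcript=tx,
                    ),
                    strand=tx.strand,
                )
    index.finalize()
    return index


def classify_truncation(exon: ExonRecord, transcript: TranscriptModel) -> Optional[str]:
    """Which part of the endogenous protein a fusion entering here retains.

    Entering at or upstream of the start codon keeps the full protein.
    Otherwise the lost fraction f of the CDS decides: f < 10% is a short
    truncation, f >= 10% a major one.  Returns None for transcripts without
    CDS.
    """
    cds_start = transcript.cds_start_transcript_coord
    if cds_start is None:
        return None
    boundary = transcript.genomic_to_transcript(exon.acceptor_position)
    if boundary is None:
        return None
    if boundary <= cds_start:
        return FULL_LENGTH
    lost = min(boundary - cds_start, transcript.cds_length_nt)
    fraction = lost / transcript.cds_length_nt
    return SHORT_TRUNCATION if fraction < 0.10 else MAJOR_TRUNCATION


@dataclass
class FirstExonStats:
    """Genome-wide statistics over first exons of protein-coding transcripts."""

    n_first_exons: int
    n_noncoding: int
    fraction_noncoding: Optional[float]
    median_peptide_aa: Optional[float]
    n_short: int  # coding, <= 20 aa
    n_long: int  # coding, > 20 aa
    fraction_with_domain: Optional[float]  # CDS covers >=10% of a domain; None w/o table

    @property
    def n_coding(self) -> int:
        return self.n_first_exons - self.n_noncoding


def _first_exon_cds_interval(
    exon: ExonRecord, transcript: TranscriptModel
) -> Optional[tuple[int, int]]:
    """Genomic interval of the CDS part of a first exon, or None if noncoding."""
    best = None
    for seg in transcript.cds_segments:
        lo = max(exon.start, seg.start)
        hi = min(exon.end, seg.end)
        if lo < hi:
            best = (lo, hi) if best is None else (min(best[0], lo), max(best[1], hi))
    return best


def first_exon_statistics(
    annotation: AnnotationSet,
    domain_table: Optional[Iterable[tuple[str, int, int]]] = None,
) -> FirstExonStats:
    """Summarise what gene-trap tagging misses: the first exons.

    First exons have no splice acceptor, so any peptide they encode is absent
    from tag fusions.  Unique first exons (by genomic interval) of
    protein-coding transcripts are classified as noncoding (no CDS overlap) or
    coding; coding ones are split at 20 aa into short/long encoded peptides.
    With a Pfam-style ``domain_table`` of (contig, start, end) intervals, the
    fraction whose CDS covers at least 10% of an annotated protein domain is
    reported; without one it is None (undefined, not zero).
    """
    seen: dict[tuple[str, int, int, str], tuple[ExonRecord, TranscriptModel]] = {}
    for tx in annotation.transcripts():
        gene = annotation.genes[tx.gene_id]
        if not _transcript_is_coding_biotype(tx.biotype, gene.biotype):
            continue
        if not tx.exons:
            continue
        exon = tx.exons[0]
        key = (exon.contig, exon.start, exon.end, exon.strand)
        prev = seen.get(key)
        # prefer a coding representative for a shared interval
        if prev is None or (
            _first_exon_cds_interval(prev[0], prev[1]) is None
            and _first_exon_cds_interval(exon, tx) is not None
        ):
            seen[key] = (exon, tx)

    domains_by_contig: dict[str, list[tuple[int, int]]] = {}
    if domain_table is not None:
        for contig, start, end in domain_table:
            domains_by_contig.setdefault(contig, []).append((int(start), int(end)))

    peptide_lengths: list[int] = []
    n_noncoding = 0
    n_with_domain = 0
    for exon, tx in seen.values():
        interval = _first_exon_cds_interval(exon, tx)
        if interval is None:
            n_noncoding += 1
            continue
        coding_nt = interval[1] - interval[0]
        peptide_lengths.append(coding_nt // 3)
        if domain_table is not None:
            for dstart, dend in domains_by_contig.get(exon.contig, []):
                overlap = min(interval[1], dend) - max(interval[0], dstart)
                dlen = dend - dstart
                if dlen > 0 and overlap / dlen >= 0.10:
                    n_with_domain += 1
                    break

    n_total = len(seen)
    n_coding = len(peptide_lengths)
    return FirstExonStats(
        n_first_exons=n_total,
        n_noncoding=n_noncoding,
        fraction_noncoding=(n_noncoding / n_total) if n_total else None,
        median_peptide_aa=median(peptide_lengths) if peptide_lengths else None,
        n_short=sum(1 for aa in peptide_lengths if aa <= 20),
        n_long=sum(1 for aa in peptide_lengths if aa > 20),
        fraction_with_domain=(n_with_domain / n_total) if (n_total and domain_table is not None) else None,
    )
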