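"""Synthetic gene-trap screens with known ground truth.

Generates a toy genome annotation (GTF + optional FASTA), background and
sorted insertion samples, and cassette-derived RNA-seq reads, with the
statistical structure the analysis assumes:

* genes on both strands, non-overlapping, a declared fraction intronless
  (default 5.9%, the genome-wide share of intronless protein-coding genes)
  and a declared fraction of noncoding first exons (default 45.6%);
* exon phases internally consistent with CDS placement;
* insertions as a mixture of a TSS-proximal exponential component (retroviral
  integration bias) and a uniform genomic component, sense-stranded with
  probability ``p_sense``;
* sorted samples with a fixed library size in which insertion mass is
  *reallocated* toward planted "true regulator" genes at ``enrichment_factor``
  (emulating FACS selection without inflating totals);
* reads carrying the three cassette anchors mixed 1:1:1 followed by real
  acceptor-exon sequence.

All randomness flows from ``SimulationConfig.seed`` through named
``numpy.random.default_rng([seed, stream])`` streams, so every artefact is
byte-reproducible and independent of which other artefacts are generated.

Scale defaults are desk-scale stand-ins for the real screens (which have
~20k genes and millions of reads): 2,000 genes, 50 planted hits, 40,000
background and 15,000 sorted insertions, 8x enrichment.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Dict, Iterable, Optional, Sequence

import numpy as np

from .annotation import AnnotationSet, load_annotation
from .frames import ANCHORS, PAPER_FRAME_PHASE_MAP, PREFIX_LENGTH, FramePhaseMap
from .insertions import BACKGROUND, SORTED, InsertionSite, SampleTable

__all__ = [
    "SimulationConfig",
    "SyntheticGenome",
    "GroundTruth",
    "generate_annotation",
    "simulate_insertions",
    "simulate_frame_reads",
    "simulate_screen",
    "choose_planted",
    "exon_start_lookup",
    "write_fastq",
]

_STREAM_LAYOUT = 0
_STREAM_SEQUENCE = 1
_STREAM_PLANTED = 2
_STREAM_BACKGROUND = 3
_STREAM_SORTED = 4
_STREAM_READS = 5

_BASES = np.frombuffer(b"ACGT", dtype="S1")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass
class SimulationConfig:
    """Stated world of the synthetic screen; defaults are the test conditions."""

    n_genes: int = 2000
    fraction_intronless: float = 0.059
    fraction_noncoding_first_exons: float = 0.456
    exons_per_gene: tuple[int, int] = (3, 10)
    exon_length: tuple[int, int] = (80, 300)
    intronless_exon_length: tuple[int, int] = (400, 1400)
    intron_length: tuple[int, int] = (200, 1800)
    intergenic_gap: tuple[int, int] = (1000, 5000)
    contig: str = "chrS1"
    n_background_insertions: int = 40_000
    n_background_replicates: int = 2
    n_sorted_insertions: int = 15_000
    tss_bias_weight: float = 0.75  # mixture weight of the TSS-proximal component
    tss_decay_nt: float = 1000.0  # exponential decay length around the TSS
    p_sense: float = 0.8  # TSS-component insertions on the gene's sense strand
    n_planted_hits: int = 50
    enrichment_factor: float = 8.0
    frame_mix: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    seed: int = 42

    def __post_init__(self):
        for p in (
            self.fraction_intronless,
            self.fraction_noncoding_first_exons,
            self.tss_bias_weight,
            self.p_sense,
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability out of [0,1]: {p}")
        if min(self.n_genes, self.n_background_insertions, self.n_sorted_insertions) < 0:
            raise ValueError("counts must be non-negative")
        if self.exons_per_gene[0] < 2:
            raise ValueError("spliced genes need at least 2 exons")


@dataclass
class GroundTruth:
    planted_genes: list[str]
    table: "object" = None  # per-insertion/per-read DataFrame


@dataclass
class SyntheticGenome:
    annotation: AnnotationSet
    gtf_text: str
    contig_lengths: Dict[str, int]
    config: SimulationConfig
    genome: Optional[Dict[str, str]] = None  # contig -> sequence, if generated

    def write_gtf(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.gtf_text)

    def write_fasta(self, path, line_width: int = 70) -> None:
        if self.genome is None:
            raise ValueError("genome sequence was not generated (with_sequence=False)")
        with open(path, "w") as fh:
            for contig, seq in self.genome.items():
                fh.write(f">{contig}\n")
                for i in range(0, len(seq), line_width):
                    fh.write(seq[i : i + line_width] + "\n")


def _select_count(fraction: float, n: int) -> int:
    return int(round(fraction * n))


def generate_annotation(config: SimulationConfig, with_sequence: bool = False) -> SyntheticGenome:
    """Toy genome annotation realising the configured gene structure.

    The GTF text is built first and then parsed back through
    :func:`orftag.annotation.load_annotation`, so the returned models are by
    construction consistent with what any downstream consumer of the file
    would see.  Same seed, byte-identical GTF.
    """
    rng = np.random.default_rng([config.seed, _STREAM_LAYOUT])
    n = config.n_genes
    n_intronless = _select_count(config.fraction_intronless, n)
    order = rng.permutation(n)
    intronless_set = set(order[:n_intronless].tolist())
    spliced = [i for i in range(n) if i not in intronless_set]
    n_noncoding_first = _select_count(config.fraction_noncoding_first_exons, len(spliced))
    noncoding_first = set(
        np.array(spliced)[rng.permutation(len(spliced))[:n_noncoding_first]].tolist()
    )

    lines: list[str] = []
    cursor = 0
    contig = config.contig
    for i in range(n):
        gene_id = f"SG{i:04d}"
        tx_id = f"{gene_id}T1"
        strand = "+" if rng.integers(2) == 0 else "-"
        cursor += int(rng.integers(*config.intergenic_gap))
        if i in intronless_set:
            exon_lengths = [int(rng.integers(*config.intronless_exon_length))]
            intron_lengths: list[int] = []
        else:
            n_exons = int(rng.integers(config.exons_per_gene[0], config.exons_per_gene[1] + 1))
            exon_lengths = [int(rng.integers(*config.exon_length)) for _ in range(n_exons)]
            intron_lengths = [int(rng.integers(*config.intron_length)) for _ in range(n_exons - 1)]

        # genomic exon intervals, left to right
        intervals = []
        pos = cursor
        for j, elen in enumerate(exon_lengths):
            intervals.append((pos, pos + elen))
            pos += elen
            if j < len(intron_lengths):
                pos += intron_lengths[j]
        gene_start, gene_end = cursor, pos
        cursor = pos

        # transcript-order exon lengths (5'->3')
        tx_exon_lengths = exon_lengths if strand == "+" else exon_lengths[::-1]
        total = sum(tx_exon_lengths)
        len1 = tx_exon_lengths[0]

        if i in intronless_set:
            t0 = int(rng.integers(6, 60))
        elif i in noncoding_first:
            off_max = max(4, min(tx_exon_lengths[1] - 40, 100))
            t0 = len1 + int(rng.integers(3, off_max))
        else:
            off_max = max(7, min(len1 - 40, 150))
            t0 = int(rng.integers(6, off_max))
        remaining = total - t0
        utr3_max = max(1, min(30, remaining - 33))
        utr3 = int(rng.integers(0, utr3_max))
        t1 = total - utr3
        t1 -= (t1 - t0) % 3

        # map transcript CDS [t0, t1) back to genomic CDS segments
        tx_intervals = intervals if strand == "+" else intervals[::-1]
        cds_segments = []  # genomic (start, end, frame), transcript order
        offset = 0
        coding_before = 0
        for (gstart, gend) in tx_intervals:
            elen = gend - gstart
            lo = max(t0, offset)
            hi = min(t1, offset + elen)
            if lo < hi:
                frame = (3 - coding_before % 3) % 3
                if strand == "+":
                    seg = (gstart + (lo - offset), gstart + (hi - offset), frame)
                else:
                    seg = (gend - (hi - offset), gend - (lo - offset), frame)
                cds_segments.append(seg)
                coding_before += hi - lo
            offset += elen

        attrs_gene = (
            f'gene_id "{gene_id}"; gene_type "protein_coding"; gene_name "{gene_id}";'
        )
        attrs_tx = (
            f'gene_id "{gene_id}"; transcript_id "{tx_id}"; gene_type "protein_coding"; '
            f'transcript_type "protein_coding"; gene_name "{gene_id}";'
        )
        lines.append(
            f"{contig}\torftag_sim\tgene\t{gene_start + 1}\t{gene_end}\t.\t{strand}\t.\t{attrs_gene}"
        )
        lines.append(
            f"{contig}\torftag_sim\ttranscript\t{gene_start + 1}\t{gene_end}\t.\t{strand}\t.\t{attrs_tx}"
        )
        tx_order = intervals if strand == "+" else intervals[::-1]
        for rank, (gstart, gend) in enumerate(tx_order, start=1):
            lines.append(
                f"{contig}\torftag_sim\texon\t{gstart + 1}\t{gend}\t.\t{strand}\t.\t"
                f"{attrs_tx} exon_number {rank};"
            )
        for (gstart, gend, frame) in cds_segments:
            lines.append(
                f"{contig}\torftag_sim\tCDS\t{gstart + 1}\t{gend}\t.\t{strand}\t{frame}\t{attrs_tx}"
            )

    contig_length = cursor + int(rng.integers(*config.intergenic_gap))
    gtf_text = "\n".join(lines) + "\n"
    annotation = load_annotation(io.StringIO(gtf_text))

    genome = None
    if with_sequence:
        seq_rng = np.random.default_rng([config.seed, _STREAM_SEQUENCE])
        raw = seq_rng.integers(0, 4, size=contig_length, dtype=np.uint8)
        genome = {contig: _BASES[raw].tobytes().decode("ascii")}

    return SyntheticGenome(
        annotation=annotation,
        gtf_text=gtf_text,
        contig_lengths={contig: contig_length},
        config=config,
        genome=genome,
    )


def choose_planted(genome: SyntheticGenome, config: Optional[SimulationConfig] = None) -> list[str]:
    """Seeded choice of planted regulator genes among taggable (intronic) genes."""
    config = config or genome.config
    rng = np.random.default_rng([config.seed, _STREAM_PLANTED])
    candidates = sorted(genome.annotation.intronic_coding_gene_ids())
    if config.n_planted_hits > len(candidates):
        raise ValueError("more planted hits requested than taggable genes")
    idx = rng.choice(len(candidates), size=config.n_planted_hits, replace=False)
    return sorted(candidates[i] for i in idx)


def _tagging_windows(genome: SyntheticGenome) -> Dict[str, tuple[int, int]]:
    """Per-gene sense-strand tagging window: upstream gap + body up to last acceptor.

    A sense insertion anywhere in [lo, hi) is assigned to this gene: it lies
    downstream of the previous gene and upstream of the gene's most 3'
    splice acceptor.  Used to place planted enrichment insertions.
    """
    annotation = genome.annotation
    genes = sorted(annotation.genes.values(), key=lambda g: min(t.exons[0].start for t in g.transcripts.values()))
    spans = []
    for g in genes:
        starts = [e.start for t in g.transcripts.values() for e in t.exons]
        ends = [e.end for t in g.transcripts.values() for e in t.exons]
        spans.append((min(starts), max(ends), g))
    windows: Dict[str, tuple[int, int]] = {}
    for i, (start, end, g) in enumerate(spans):
        acceptors = [
            e.acceptor_position
            for t in g.transcripts.values()
            for e in t.exons
            if not e.is_first
        ]
        if not acceptors:
            continue
        prev_end = spans[i - 1][1] if i > 0 else 0
        next_start = (
            spans[i + 1][0] if i + 1 < len(spans) else genome.contig_lengths[g.contig]
        )
        if g.strand == "+":
            lo, hi = prev_end + 1, max(acceptors)
        else:
            lo, hi = min(acceptors) + 1, next_start
        if lo < hi:
            windows[g.gene_id] = (lo, hi)
    return windows


def _simulate_sites(
    genome: SyntheticGenome,
    config: SimulationConfig,
    n_sites: int,
    rng: np.random.Generator,
    gene_weights: np.ndarray,
    sample_id: str,
    replicate: int,
    planted: Optional[set] = None,
) -> tuple[list[InsertionSite], "object"]:
    import pandas as pd

    annotation = genome.annotation
    contig = config.contig
    contig_length = genome.contig_lengths[contig]
    genes = sorted(annotation.genes.values(), key=lambda g: g.gene_id)
    tss = np.array([g.tss for g in genes], dtype=np.int64)
    strands = np.array([1 if g.strand == "+" else -1 for g in genes])
    gene_ids = np.array([g.gene_id for g in genes])
    weights = gene_weights / gene_weights.sum()
    planted = planted or set()
    windows = _tagging_windows(genome) if planted else {}
    # probability that a draw landing on a planted gene is reallocated
    # enrichment mass rather than its baseline share
    extra_share = (
        (config.enrichment_factor - 1.0) / config.enrichment_factor
        if config.enrichment_factor > 1
        else 0.0
    )

    seen: set[tuple[str, int, str]] = set()
    rows: list[tuple] = []
    guard = 0
    while len(rows) < n_sites:
        guard += 1
        if guard > 200:
            raise RuntimeError("insertion simulation failed to reach target unique count")
        need = n_sites - len(rows)
        batch = max(need + 16, int(need * 1.1))
        is_tss = rng.random(batch) < config.tss_bias_weight
        gidx = rng.choice(len(genes), size=batch, p=weights)
        offsets = rng.exponential(config.tss_decay_nt, size=batch)
        into_gene = rng.random(batch) < 0.5
        sense = rng.random(batch) < config.p_sense
        is_enrichment = rng.random(batch) < extra_share
        uniform_pos = rng.integers(0, contig_length, size=batch)
        uniform_strand = rng.integers(0, 2, size=batch)
        for k in range(batch):
            if len(rows) >= n_sites:
                break
            if is_tss[k]:
                g = int(gidx[k])
                gene_id = str(gene_ids[g])
                gene_strand = "+" if strands[g] == 1 else "-"
                delta = int(round(offsets[k])) * (1 if into_gene[k] else -1)
                pos = int(tss[g]) + int(strands[g]) * delta
                if gene_id in planted and is_enrichment[k] and gene_id in windows:
                    # reallocated enrichment mass: sense strand, confined to
                    # the gene's upstream/intronic tagging window
                    lo, hi = windows[gene_id]
                    pos = min(max(pos, lo), hi - 1)
                    strand = gene_strand
                    component = "enrichment"
                else:
                    pos = min(max(pos, 0), contig_length - 1)
                    strand = gene_strand if sense[k] else ("-" if gene_strand == "+" else "+")
                    component = "tss"
                source_gene = gene_id
            else:
                pos = int(uniform_pos[k])
                strand = "+" if uniform_strand[k] == 0 else "-"
                component, source_gene = "uniform", ""
            key = (contig, pos, strand)
            if key in seen:
                continue
            seen.add(key)
            rows.append((contig, pos, strand, component, source_gene))

    truth = pd.DataFrame(
        rows, columns=["contig", "position", "strand", "component", "source_gene"]
    )
    sites = [
        InsertionSite(contig=c, position=p, strand=s, sample_id=sample_id, replicate=replicate)
        for c, p, s, _comp, _src in rows
    ]
    return sites, truth


def simulate_insertions(
    genome: SyntheticGenome,
    role: str,
    config: Optional[SimulationConfig] = None,
    planted: Optional[Sequence[str]] = None,
    replicate: int = 1,
    n_insertions: Optional[int] = None,
) -> tuple[SampleTable, GroundTruth]:
    """One insertion sample (background or sorted) with ground truth.

    Background samples draw genes uniformly; sorted samples multiply the
    TSS-component weight of every planted gene by ``enrichment_factor`` and
    renormalise, which reallocates a fixed library toward the planted hits.
    Requesting a sorted sample with enrichment > 1 and no planted genes is an
    error.
    """
    config = config or genome.config
    if role not in (BACKGROUND, SORTED):
        raise ValueError(f"role must be background or sorted, got {role!r}")
    n_genes = len(genome.annotation.genes)
    weights = np.ones(n_genes, dtype=float)
    if role == SORTED:
        if config.enrichment_factor != 1.0 and not planted:
            raise ValueError("sorted simulation with enrichment needs planted genes")
        gene_ids = sorted(genome.annotation.genes)
        planted_set = set(planted or [])
        for i, g in enumerate(gene_ids):
            if g in planted_set:
                weights[i] *= config.enrichment_factor
        stream = _STREAM_SORTED
        n = config.n_sorted_insertions if n_insertions is None else n_insertions
        sample_id = f"sorted_r{replicate}"
    else:
        stream = _STREAM_BACKGROUND
        n = config.n_background_insertions if n_insertions is None else n_insertions
        sample_id = f"background_r{replicate}"
    rng = np.random.default_rng([config.seed, stream, replicate])
    sites, truth = _simulate_sites(
        genome, config, n, rng, weights, sample_id=sample_id, replicate=replicate,
        planted=set(planted or []) if role == SORTED else None,
    )
    table = SampleTable(
        sample_id=sample_id, role=role, sites=sites, screen="synthetic", replicate=replicate
    )
    return table, GroundTruth(planted_genes=sorted(planted or []), table=truth)


def simulate_screen(config: SimulationConfig, with_sequence: bool = False):
    """Full synthetic screen: annotation, background replicate(s), sorted sample.

    Returns a dict with keys annotation (SyntheticGenome), background
    (list of SampleTable replicates), sorted (SampleTable), planted
    (gene_id list) and truth (per-sample GroundTruth).
    """
    genome = generate_annotation(config, with_sequence=with_sequence)
    planted = choose_planted(genome, config)
    n_reps = max(1, config.n_background_replicates)
    per_rep = config.n_background_insertions // n_reps
    background = []
    truths = {}
    for r in range(1, n_reps + 1):
        table, truth = simulate_insertions(
            genome, BACKGROUND, config, replicate=r, n_insertions=per_rep
        )
        background.append(table)
        truths[table.sample_id] = truth
    sorted_table, sorted_truth = simulate_insertions(
        genome, SORTED, config, planted=planted
    )
    truths[sorted_table.sample_id] = sorted_truth
    return {
        "annotation": genome,
        "background": background,
        "sorted": sorted_table,
        "planted": planted,
        "truth": truths,
    }


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _exon_start_sequence(genome: SyntheticGenome, exon, length: int) -> Optional[str]:
    seq = genome.genome[exon.contig]
    if len(exon) < length:
        return None
    if exon.strand == "+":
        return seq[exon.start : exon.start + length]
    return _revcomp(seq[exon.end - length : exon.end])


def _acceptor_exon_candidates(genome: SyntheticGenome, min_length: int):
    """Non-first exons of coding transcripts with a defined phase."""
    out = []
    for tx in genome.annotation.transcripts():
        if not tx.is_coding:
            continue
        for exon in tx.exons:
            if exon.is_first or exon.phase is None or len(exon) < min_length:
                continue
            out.append((exon, tx))
    # dedup by acceptor position, deterministic order
    seen = {}
    for exon, tx in out:
        key = (exon.contig, exon.acceptor_position, exon.strand)
        if key not in seen:
            seen[key] = (exon, tx)
    return [seen[k] for k in sorted(seen)]


def exon_start_lookup(genome: SyntheticGenome, key_length: int = 24) -> Dict[str, Optional[int]]:
    """First ``key_length`` nt of each acceptor exon -> its (corrected) phase.

    Ambiguous prefixes (shared by exons of different phase) are dropped; with
    random toy-genome sequence they are vanishingly rare.
    """
    if genome.genome is None:
        raise ValueError("genome sequence required (generate with with_sequence=True)")
    lookup: Dict[str, Optional[int]] = {}
    ambiguous: set[str] = set()
    for exon, _tx in _acceptor_exon_candidates(genome, key_length):
        key = _exon_start_sequence(genome, exon, key_length)
        if key is None:
            continue
        if key in lookup and lookup[key] != exon.phase:
            ambiguous.add(key)
        else:
            lookup[key] = exon.phase
    for key in ambiguous:
        del lookup[key]
    return lookup


def simulate_frame_reads(
    genome: SyntheticGenome,
    n_reads: int = 3000,
    remainder_length: int = 30,
    error_rate: float = 0.0,
    selection: str = "selected",
    frame_phase_map: FramePhaseMap = PAPER_FRAME_PHASE_MAP,
    config: Optional[SimulationConfig] = None,
) -> tuple[list[tuple[str, str]], GroundTruth]:
    """Cassette-derived RNA-seq-like reads with known frame and junction.

    Each read is 6 random nt + the true frame's constant anchor + the first
    ``remainder_length`` nt of a real acceptor exon.  ``selection='selected'``
    emulates a functional screen in which only in-frame fusions survive (the
    exon is drawn from those whose phase matches the frame under
    ``frame_phase_map``); ``selection='none'`` draws exons uniformly.  A
    per-base ``error_rate`` substitutes random bases across anchor and
    remainder.
    """
    import pandas as pd

    if genome.genome is None:
        raise ValueError("genome sequence required (generate with with_sequence=True)")
    if selection not in ("selected", "none"):
        raise ValueError("selection must be 'selected' or 'none'")
    config = config or genome.config
    rng = np.random.default_rng([config.seed, _STREAM_READS])
    candidates = _acceptor_exon_candidates(genome, remainder_length)
    by_phase: Dict[int, list] = {0: [], 1: [], 2: []}
    for exon, tx in candidates:
        by_phase[exon.phase].append((exon, tx))
    for phase, pool in by_phase.items():
        if selection == "selected" and not pool:
            raise ValueError(f"no candidate exons of phase {phase} in toy annotation")

    mix = np.asarray(config.frame_mix, dtype=float)
    mix = mix / mix.sum()
    frames = rng.choice([1, 2, 3], size=n_reads, p=mix)
    reads: list[tuple[str, str]] = []
    rows = []
    for i in range(n_reads):
        frame_id = int(frames[i])
        if selection == "selected":
            pool = by_phase[frame_phase_map[frame_id]]
        else:
            pool = candidates
        exon, tx = pool[int(rng.integers(len(pool)))]
        prefix = _BASES[rng.integers(0, 4, size=PREFIX_LENGTH)].tobytes().decode("ascii")
        remainder = _exon_start_sequence(genome, exon, remainder_length)
        seq = prefix + ANCHORS[frame_id] + remainder
        if error_rate > 0:
            chars = list(seq)
            for j in range(PREFIX_LENGTH, len(chars)):  # prefix is degenerate anyway
                if rng.random() < error_rate:
                    alternatives = [b for b in "ACGT" if b != chars[j]]
                    chars[j] = alternatives[int(rng.integers(3))]
            seq = "".join(chars)
        read_id = f"simread{i:06d}"
        reads.append((read_id, seq))
        rows.append(
            {
                "read_id": read_id,
                "true_frame": frame_id,
                "gene_id": exon.gene_id,
                "transcript_id": tx.transcript_id,
                "exon_rank": exon.rank,
                "exon_phase": exon.phase,
                "acceptor_position": exon.acceptor_position,
            }
        )
    truth = GroundTruth(planted_genes=[], table=pd.DataFrame(rows))
    return reads, truth


def write_fastq(reads: Iterable[tuple[str, str]], path) -> None:
    with open(path, "w") as fh:
        for read_id, seq in reads:
            fh.write(f"@{read_id}\n{seq}\n+\n{'I' * len(seq)}\n")
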