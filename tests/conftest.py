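"""Shared fixtures: a hand-built toy annotation and seeded synthetic screens.

The toy GTF is small enough to verify every derived quantity by manual
counting; expectations are documented next to each gene.

Toy layout (GTF 1-based closed; internal coordinates are 0-based half-open):

GA  chr1 '+', 3 exons 101-200 / 301-400 / 501-640.
    CDS 151-200 (frame 0), 301-400 (frame 1), 501-611 (frame 0); 261 nt.
    Acceptors (0-based): exon2 at 300 (phase 1), exon3 at 500 (phase 0).
GB  chr1 '+', single exon 1001-1600, CDS 1101-1400. Intronless; no acceptors.
GC  chr1 '-', exons rank1 2401-2500, rank2 2201-2300, rank3 2001-2100.
    CDS 2201-2298 (frame 0, 98 nt) + 2028-2100 (frame 1, 73 nt); 171 nt.
    Rank2 acceptor (0-based 2300) sits 2 nt upstream of the ATG ->
    corrected phase 2, truncation full_length.  Rank3 acceptor (2100):
    phase 1, removes 98/171 = 57% of the CDS -> major truncation.
GD  chr1 '+', lncRNA, 2 exons 3001-3100 / 3201-3300; never indexed.
GE  chr1 '+', exons 5001-5400 / 5601-6553; CDS 5351-5400 + 5601-6550
    (1000 nt).  Exon2 acceptor removes 50/1000 = 5% -> short truncation.
GF  chr1 '+', exons 7001-7550 / 7701-8200; CDS 7051-7550 + 7701-8200
    (1000 nt).  Exon2 acceptor removes 500/1000 = 50% -> major truncation.

Acceptor index: 4 '+' entries (300, 500, 5600, 7700) + 2 '-' entries
(2100, 2300) = 6.
"""

import pytest

from orftag.annotation import build_acceptor_index, load_annotation
from orftag.simulate import SimulationConfig, simulate_screen


def _gtf_line(contig, feature, start, end, strand, frame, attrs):
    return f"{contig}\ttest\t{feature}\t{start}\t{end}\t.\t{strand}\t{frame}\t{attrs}"


def _gene_block(gene_id, strand, exons, cds, biotype="protein_coding", contig="chr1"):
    """exons: [(start, end)] in transcript order; cds: [(start, end, frame)]."""
    tx_id = gene_id + "T1"
    ga = f'gene_id "{gene_id}"; gene_type "{biotype}"; gene_name "{gene_id}";'
    ta = (
        f'gene_id "{gene_id}"; transcript_id "{tx_id}"; gene_type "{biotype}"; '
        f'transcript_type "{biotype}"; gene_name "{gene_id}";'
    )
    lo = min(s for s, _ in exons)
    hi = max(e for _, e in exons)
    lines = [
        _gtf_line(contig, "gene", lo, hi, strand, ".", ga),
        _gtf_line(contig, "transcript", lo, hi, strand, ".", ta),
    ]
    for rank, (s, e) in enumerate(exons, start=1):
        lines.append(_gtf_line(contig, "exon", s, e, strand, ".", f"{ta} exon_number {rank};"))
    for s, e, frame in cds:
        lines.append(_gtf_line(contig, "CDS", s, e, strand, frame, ta))
    return lines


def toy_gtf_text() -> str:
    lines = []
    lines += _gene_block("GA", "+", [(101, 200), (301, 400), (501, 640)],
                         [(151, 200, 0), (301, 400, 1), (501, 611, 0)])
    lines += _gene_block("GB", "+", [(1001, 1600)], [(1101, 1400, 0)])
    lines += _gene_block("GC", "-", [(2401, 2500), (2201, 2300), (2001, 2100)],
                         [(2201, 2298, 0), (2028, 2100, 1)])
    lines += _gene_block("GD", "+", [(3001, 3100), (3201, 3300)], [], biotype="lncRNA")
    lines += _gene_block("GE", "+", [(5001, 5400), (5601, 6553)],
                         [(5351, 5400, 0), (5601, 6550, 1)])
    lines += _gene_block("GF", "+", [(7001, 7550), (7701, 8200)],
                         [(7051, 7550, 0), (7701, 8200, 1)])
    return "\n".join(lines) + "\n"


@pytest.fixture(scope="session")
def toy_gtf(tmp_path_factory):
    path = tmp_path_factory.mktemp("toy") / "toy.gtf"
    path.write_text(toy_gtf_text())
    return path


@pytest.fixture(scope="session")
def toy_annotation(toy_gtf):
    return load_annotation(toy_gtf)


@pytest.fixture(scope="session")
def toy_index(toy_annotation):
    return build_acceptor_index(toy_annotation)


@pytest.fixture(scope="session")
def small_config():
    """Desk-scale screen used by unit tests (fast, still structured)."""
    return SimulationConfig(
        n_genes=150,
        n_background_insertions=3000,
        n_sorted_insertions=1200,
        n_planted_hits=8,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_screen(small_config):
    return simulate_screen(small_config, with_sequence=True)


@pytest.fixture(scope="session")
def default_screen():
    """The stated default synthetic screen (2,000 genes, 50 planted, 8x)."""
    return simulate_screen(SimulationConfig())
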