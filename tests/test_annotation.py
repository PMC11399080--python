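"""Annotation parsing, acceptor indexing, phase and truncation arithmetic."""

import io

import pytest

from orftag.annotation import (
    FULL_LENGTH,
    MAJOR_TRUNCATION,
    SHORT_TRUNCATION,
    GtfParseError,
    build_acceptor_index,
    classify_truncation,
    correct_phase_upstream,
    exon_phase,
    first_exon_statistics,
    load_annotation,
)

from conftest import _gene_block


class TestLoadAnnotation:
    def test_toy_gene_models(self, toy_annotation):
        ann = toy_annotation
        assert len(ann) == 6
        assert not ann.genes["GA"].is_intronless
        assert ann.genes["GB"].is_intronless
        assert ann.genes["GA"].shortest_cds_nt == 261
        assert ann.genes["GC"].shortest_cds_nt == 171
        # GTF 1-based closed -> 0-based half-open
        exon1 = ann.genes["GA"].transcripts["GAT1"].exons[0]
        assert (exon1.start, exon1.end) == (100, 200)

    def test_minus_strand_exon_order_and_acceptors(self, toy_annotation):
        tx = toy_annotation.genes["GC"].transcripts["GCT1"]
        assert [e.rank for e in tx.exons] == [1, 2, 3]
        assert [e.start for e in tx.exons] == [2400, 2200, 2000]
        # acceptor of a '-' exon is its half-open end (transcript-5' boundary)
        assert tx.exons[1].acceptor_position == 2300
        assert toy_annotation.genes["GC"].tss == 2500

    def test_empty_gtf(self):
        assert len(load_annotation(io.StringIO(""))) == 0

    def test_malformed_line_names_line_number(self, tmp_path):
        path = tmp_path / "bad.gtf"
        path.write_text('chr1\tx\texon\t1\t100\t.\t+\t.\tgene_id "G";\nchr1\tbroken line\n')
        with pytest.raises(GtfParseError, match="line 2"):
            load_annotation(path)

    def test_orphan_feature_skipped_with_count(self):
        text = 'chr1\tx\texon\t1\t100\t.\t+\t.\tgene_id "G1";\n'  # no transcript_id
        ann = load_annotation(io.StringIO(text))
        assert len(ann) == 0
        assert ann.skipped_features == 1

    def test_gzip_transparent(self, tmp_path, toy_annotation):
        import gzip

        from conftest import toy_gtf_text

        path = tmp_path / "toy.gtf.gz"
        with gzip.open(path, "wt") as fh:
            fh.write(toy_gtf_text())
        assert len(load_annotation(path)) == len(toy_annotation)


class TestAcceptorIndex:
    def test_exact_entries(self, toy_index):
        # brute-force listing: non-first exons of coding transcripts only
        assert len(toy_index) == 6
        assert list(toy_index.positions("chr1", "+")) == [300, 500, 5600, 7700]
        assert list(toy_index.positions("chr1", "-")) == [2100, 2300]
        assert toy_index.gene_ids() == {"GA", "GC", "GE", "GF"}

    def test_excludes_first_exons_noncoding_and_intronless(self, toy_index):
        for contig, strand in toy_index.keys():
            for entry in toy_index.entries(contig, strand):
                assert not entry.exon.is_first
                assert entry.gene_id not in ("GB", "GD")

    def test_noncoding_transcript_contributes_nothing(self):
        text = "\n".join(
            _gene_block("GX", "+", [(101, 200), (301, 400)], [], biotype="lncRNA")
        ) + "\n"
        index = build_acceptor_index(load_annotation(io.StringIO(text)))
        assert len(index) == 0

    def test_shared_acceptor_collapsed_per_gene(self):
        # two isoforms of one gene sharing exon 2 -> one index entry
        lines = _gene_block("GS", "+", [(101, 200), (301, 400)], [(301, 400, 0)])
        extra = [
            line.replace("GST1", "GST2")
            for line in _gene_block("GS", "+", [(101, 150), (301, 400)], [(301, 400, 0)])
            if "\tgene\t" not in line
        ]
        index = build_acceptor_index(load_annotation(io.StringIO("\n".join(lines + extra) + "\n")))
        assert len(index) == 1

    def test_bed_export(self, toy_index, tmp_path):
        path = tmp_path / "acceptors.bed"
        toy_index.to_bed(path)
        rows = [line.split("\t") for line in path.read_text().splitlines()]
        assert len(rows) == 6
        assert all(len(r) == 6 for r in rows)
        ranks = {(r[3], int(r[4])) for r in rows}
        assert ("GA", 2) in ranks and ("GA", 3) in ranks

    def test_strand_mirror_symmetry(self, toy_annotation, toy_index):
        """Reflecting the genome (x -> L-x, strands flipped) preserves the index."""
        from conftest import toy_gtf_text

        L = 10_000
        mirrored_lines = []
        for line in toy_gtf_text().splitlines():
            f = line.split("\t")
            start, end = int(f[3]), int(f[4])
            # closed 1-based [start, end] reflects to [L-end+1, L-start+1]... keep
            # half-open algebra: 0-based [start-1, end) -> [L-end, L-start+1)
            f[3], f[4] = str(L - end + 1), str(L - (start - 1))
            f[6] = "-" if f[6] == "+" else "+"
            mirrored_lines.append("\t".join(f))
        mirrored = load_annotation(io.StringIO("\n".join(mirrored_lines) + "\n"))
        mirror_index = build_acceptor_index(mirrored)
        assert len(mirror_index) == len(toy_index)
        orig = {
            (s, p) for (c, s) in toy_index.keys() for p in toy_index.positions(c, s).tolist()
        }
        refl = {
            ("+" if s == "-" else "-", L - p)
            for (c, s) in mirror_index.keys()
            for p in mirror_index.positions(c, s).tolist()
        }
        assert orig == refl
        # phases are invariant under the reflection
        for gene_id, gene in toy_annotation.genes.items():
            for tx_id, tx in gene.transcripts.items():
                mtx = mirrored.genes[gene_id].transcripts[tx_id]
                assert [e.phase for e in tx.exons] == [e.phase for e in mtx.exons]


class TestPhase:
    def test_codon_aligned_exon_phase_zero(self, toy_annotation):
        tx = toy_annotation.genes["GA"].transcripts["GAT1"]
        assert exon_phase(tx.exons[2], tx) == 0  # exon 3 starts on a codon boundary

    def test_phase_from_gtf_frame_column(self, toy_annotation):
        tx = toy_annotation.genes["GA"].transcripts["GAT1"]
        # exon 2 starts 50 coding nt in -> frame column 1
        assert exon_phase(tx.exons[1], tx) == 1

    def test_upstream_of_atg_dispatches_to_correction(self, toy_annotation):
        tx = toy_annotation.genes["GC"].transcripts["GCT1"]
        exon2 = tx.exons[1]
        assert exon_phase(exon2, tx) == correct_phase_upstream(exon2, tx) == 2

    @pytest.mark.parametrize(
        "utr_in_exon2, expected",
        [(2, 2), (0, 0), (3, 0), (4, 1), (7, 1)],
        ids=["2nt->2", "at-ATG->0", "3nt->0", "4nt->1", "7nt->1"],
    )
    def test_correct_phase_upstream_mod3(self, utr_in_exon2, expected):
        """Distance to the ATG mod 3; 2 nt upstream of the ATG gives phase 2."""
        cds_start = 301 + utr_in_exon2
        cds_len_raw = 400 - cds_start + 1
        cds_end = cds_start + (cds_len_raw - cds_len_raw % 3) - 1
        text = "\n".join(
            _gene_block("GU", "+", [(101, 200), (301, 400)], [(cds_start, cds_end, 0)])
        ) + "\n"
        ann = load_annotation(io.StringIO(text))
        tx = ann.genes["GU"].transcripts["GUT1"]
        assert correct_phase_upstream(tx.exons[1], tx) == expected

    def test_no_cds_gives_sentinel(self, toy_annotation):
        tx = toy_annotation.genes["GD"].transcripts["GDT1"]
        assert exon_phase(tx.exons[1], tx) is None
        assert correct_phase_upstream(tx.exons[1], tx) is None

    def test_exon_downstream_of_stop_is_undefined(self):
        text = "\n".join(
            _gene_block("GZ", "+", [(101, 200), (301, 400), (501, 600)], [(101, 199, 0)])
        ) + "\n"
        tx = load_annotation(io.StringIO(text)).genes["GZ"].transcripts["GZT1"]
        assert exon_phase(tx.exons[2], tx) is None

    def test_phase_matches_nucleotide_counting_oracle(self, toy_annotation):
        """Phase equals brute-force coding-nt counting on every toy exon."""
        for tx in toy_annotation.transcripts():
            if not tx.is_coding:
                continue
            cds_start = tx.cds_start_transcript_coord
            cds_end = cds_start + tx.cds_length_nt
            for exon in tx.exons:
                if exon.is_first:
                    continue
                boundary = tx.genomic_to_transcript(exon.acceptor_position)
                if boundary < cds_start:
                    expected = (cds_start - boundary) % 3
                elif boundary >= cds_end:
                    expected = None
                else:
                    expected = (3 - (boundary - cds_start) % 3) % 3
                assert exon_phase(exon, tx) == expected


class TestTruncation:
    @pytest.mark.parametrize(
        "gene, exon_idx, expected",
        [
            ("GC", 1, FULL_LENGTH),  # boundary 2 nt upstream of ATG
            ("GE", 1, SHORT_TRUNCATION),  # removes 50/1000 = 5%
            ("GF", 1, MAJOR_TRUNCATION),  # removes 500/1000 = 50%
            ("GC", 2, MAJOR_TRUNCATION),  # removes 98/171 = 57%
        ],
    )
    def test_classes(self, toy_annotation, gene, exon_idx, expected):
        tx = next(iter(toy_annotation.genes[gene].transcripts.values()))
        assert classify_truncation(tx.exons[exon_idx], tx) == expected

    def test_no_cds_sentinel(self, toy_annotation):
        tx = toy_annotation.genes["GD"].transcripts["GDT1"]
        assert classify_truncation(tx.exons[1], tx) is None


class TestFirstExonStats:
    def _four_gene_annotation(self):
        # 2 noncoding first exons + 2 coding (10 aa and 40 aa peptides)
        lines = []
        lines += _gene_block("N1", "+", [(101, 200), (301, 400)], [(311, 391, 0)])
        lines += _gene_block("N2", "+", [(1101, 1200), (1301, 1400)], [(1311, 1391, 0)])
        lines += _gene_block("C1", "+", [(2101, 2200), (2301, 2400)],
                             [(2171, 2200, 0), (2301, 2360, 0)])  # 30 nt in exon 1
        lines += _gene_block("C2", "+", [(3101, 3300), (3401, 3500)],
                             [(3141, 3260, 0), (3401, 3460, 0)])  # 120 nt in exon 1
        return load_annotation(io.StringIO("\n".join(lines) + "\n"))

    def test_hand_counted_example(self):
        stats = first_exon_statistics(self._four_gene_annotation())
        assert stats.n_first_exons == 4
        assert stats.fraction_noncoding == 0.5
        assert stats.median_peptide_aa == 25  # median of 10 aa and 40 aa
        assert (stats.n_short, stats.n_long) == (1, 1)
        assert stats.fraction_with_domain is None  # no domain table -> undefined

    def test_all_noncoding(self):
        lines = _gene_block("N1", "+", [(101, 200), (301, 400)], [(311, 391, 0)])
        stats = first_exon_statistics(load_annotation(io.StringIO("\n".join(lines) + "\n")))
        assert stats.fraction_noncoding == 1.0
        assert stats.median_peptide_aa is None

    def test_domain_coverage_threshold(self):
        ann = self._four_gene_annotation()
        # C2 first-exon CDS is [3140, 3260); a 200-nt domain overlapping it by
        # 60 nt is 30% covered (counted).  C1's CDS overlaps a 200-nt domain
        # by only 10 nt = 5% (below the 10% bar, not counted).
        domains = [("chr1", 3200, 3400), ("chr1", 2190, 2390)]
        stats = first_exon_statistics(ann, domain_table=domains)
        assert stats.fraction_with_domain == pytest.approx(0.25)  # C2 of 4

    def test_toy_annotation_counts(self, toy_annotation):
        stats = first_exon_statistics(toy_annotation)
        # coding transcripts: GA, GB, GC, GE, GF; GC's first exon is noncoding
        assert stats.n_first_exons == 5
        assert stats.n_noncoding == 1
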