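import random

import numpy as np
import pandas as pd
import pytest

from oracles import brute_force_containing

from pepmap import align6, genemap, synthgen
from pepmap.align6 import HitTable, TABULAR_COLUMNS
from pepmap.genemap import (
    GeneIndex,
    GeneModel,
    assign_hits,
    exon_frames,
    map_peptide_to_genome,
    parse_gff3,
    stitch_frameshift,
)
from pepmap.seqcore import NucleotideSequence, translate_frame

TOY_GFF = """##gff-version 3
chr1\tsrc\tgene\t100\t500\t.\t+\t.\tID=gA
chr1\tsrc\tmRNA\t100\t500\t.\t+\t.\tID=gA.1;Parent=gA
chr1\tsrc\texon\t100\t220\t.\t+\t.\tID=gA.1.e1;Parent=gA.1
chr1\tsrc\tCDS\t100\t219\t.\t+\t0\tID=gA.1.c1;Parent=gA.1
chr1\tsrc\texon\t300\t500\t.\t+\t.\tID=gA.1.e2;Parent=gA.1
chr1\tsrc\tCDS\t300\t500\t.\t+\t0\tID=gA.1.c2;Parent=gA.1
chr2\tsrc\tgene\t1000\t1600\t.\t-\t.\tID=gB
chr2\tsrc\tmRNA\t1000\t1600\t.\t-\t.\tID=gB.1;Parent=gB
chr2\tsrc\texon\t1000\t1299\t.\t-\t.\tID=gB.1.e2;Parent=gB.1
chr2\tsrc\texon\t1400\t1600\t.\t-\t.\tID=gB.1.e1;Parent=gB.1
"""


class TestParseGff3:
    def test_two_genes(self, tmp_path):
        p = tmp_path / "toy.gff3"
        p.write_text(TOY_GFF)
        models = parse_gff3(p, "HC")
        assert len(models) == 2
        byid = {m.gene_id: m for m in models}
        assert byid["gA"].gene_start == 100 and byid["gA"].gene_end == 500
        # CDS preferred over exon features
        assert byid["gA"].exons == ((100, 219), (300, 500))
        assert all(m.confidence == "HC" for m in models)

    def test_minus_strand_transcription_order(self, tmp_path):
        p = tmp_path / "toy.gff3"
        p.write_text(TOY_GFF)
        gB = {m.gene_id: m for m in parse_gff3(p, "LC")}["gB"]
        assert gB.strand == "-"
        # descending genomic order = transcription order
        assert gB.exons == ((1400, 1600), (1000, 1299))

    def test_five_exon_gene(self, tmp_path, bundle):
        b = synthgen.generate(
            synthgen.SynthConfig(seed=11, n_genes=4,
                                 exon_count_range=(5, 5))
        )
        out = tmp_path / "hc.gff3"
        synthgen._write_gff3(b.genes, out, "test")
        models = parse_gff3(out, "HC")
        assert all(len(m.exons) == 5 for m in models)
        assert all(len(m.introns) == 4 for m in models)


class TestExonFrames:
    def _gene(self, exons, strand="+"):
        spans = exons if strand == "+" else exons[::-1]
        return GeneModel("g", "chr1", strand, "HC",
                         min(s for s, _ in exons), max(e for _, e in exons),
                         tuple(spans))

    def test_mod3_intron_same_frame(self):
        g = self._gene([(1, 9), (16, 24)])  # intron length 6
        frames, shift = exon_frames(g)
        assert frames[0] == frames[1]
        assert not shift

    def test_mod3_plus_one_intron_shifts(self):
        g = self._gene([(1, 9), (17, 25)])  # intron length 7
        frames, shift = exon_frames(g)
        assert frames[0] != frames[1]
        assert shift

    def test_translation_invariance_mod3(self):
        g1 = self._gene([(1, 9), (17, 25)])
        g2 = self._gene([(4, 12), (20, 28)])  # shifted by 3
        assert exon_frames(g1) == exon_frames(g2)

    def test_paper_like_structure_one_shifted_exon(self, genome_by_id, bundle):
        """A gene with exactly one frame-shifting intron has exactly one
        run of exons in a different frame, verified by translating each
        exon in its assigned frame."""
        b = synthgen.generate(
            synthgen.SynthConfig(seed=21, n_genes=3, n_chroms=1,
                                 exon_count_range=(3, 3),
                                 minus_strand_prob=0.0,
                                 frameshift_intron_fraction=0.5)
        )
        genome = {c.id: c for c in b.genome}
        checked = 0
        for g in b.genes:
            frames, shift = exon_frames(g, len(genome[g.chrom]))
            prot = g.protein(genome[g.chrom]).residues
            # each exon translated in its own frame must reproduce its
            # protein segment
            contig = genome[g.chrom]
            aa_off = 0
            for (s, e), fr in zip(g.exons, frames):
                n_aa = (e - s + 1) // 3
                tr = translate_frame(contig, fr).residues
                # locate the exon's codons inside the frame translation
                if fr > 0:
                    first = (s - 1 - (fr - 1)) // 3
                else:
                    L = len(contig)
                    first = ((L - e + 1) - 1 - (abs(fr) - 1)) // 3
                seg = tr[first : first + n_aa]
                assert seg == prot[aa_off : aa_off + n_aa]
                aa_off += n_aa
                checked += 1
        assert checked > 0

    def test_frameshift_flag_matches_intron_lengths(self, bundle):
        genome = {c.id: len(c) for c in bundle.genome}
        for g in bundle.genes:
            frames, shift = exon_frames(g, genome[g.chrom])
            expect = any(
                (abs(i_end - i_start) + 1) % 3 != 0
                for i_start, i_end in g.introns
            )
            assert shift == expect


class TestMapPeptideToGenome:
    def _toy(self):
        return GeneModel("g", "chr1", "+", "HC", 1, 24,
                         exons=((1, 9), (16, 24)))

    def test_spanning_blocks(self):
        m = map_peptide_to_genome(2, 5, self._toy())
        assert m.blocks == ((4, 9), (16, 21))

    def test_single_block(self):
        m = map_peptide_to_genome(1, 3, self._toy())
        assert m.blocks == ((1, 9),)

    def test_minus_mirror(self):
        g = GeneModel("g", "chr1", "-", "HC", 1, 24,
                      exons=((16, 24), (1, 9)))
        m = map_peptide_to_genome(2, 5, g)
        assert m.blocks == ((4, 9), (16, 21))
        assert m.strand == "-"

    def test_bounds_error_names_gene(self):
        with pytest.raises(IndexError, match="g"):
            map_peptide_to_genome(1, 99, self._toy())

    def test_block_length_identity(self, bundle):
        for t in bundle.truth.values():
            total = sum(e - s + 1 for s, e in t.blocks)
            assert total == 3 * (t.aa_end - t.aa_start + 1)

    def test_roundtrip_all_truth_peptides(self, bundle, genome_by_id):
        """Splice-extract-translate equals the peptide for 100% of cases."""
        from pepmap.seqcore import reverse_complement

        for t in bundle.truth.values():
            contig = genome_by_id[t.chrom]
            parts = [contig.residues[s - 1 : e] for s, e in t.blocks]
            nt = "".join(parts)
            if t.strand == "-":
                nt = reverse_complement(NucleotideSequence("_", nt)).residues
            aa = translate_frame(NucleotideSequence("_", nt), 1).residues
            assert aa == t.true_sequence


class TestAssignHits:
    def _mk_hits(self, rows):
        df = pd.DataFrame(rows)
        for col in TABULAR_COLUMNS:
            if col not in df.columns:
                df[col] = 0
        return HitTable(df)

    def _genes(self):
        return [
            GeneModel("hc1", "chr1", "+", "HC", 50, 500, ((50, 500),)),
            GeneModel("lc1", "chr1", "+", "LC", 40, 600, ((40, 600),)),
            GeneModel("hc2", "chr2", "+", "HC", 10, 90, ((10, 90),)),
        ]

    def test_containment(self):
        hits = self._mk_hits(
            [{"qaccver": "p", "saccver": "chr1", "sstart": 100, "send": 130,
              "sframe": 1}]
        )
        out = assign_hits(hits, GeneIndex(self._genes()))
        assert out[0].category == "HC"
        assert out[0].gene_id == "hc1"
        assert set(out[0].containing_genes) == {"hc1", "lc1"}

    def test_boundary_touch_not_assigned(self):
        hits = self._mk_hits(
            [{"qaccver": "p", "saccver": "chr1", "sstart": 50, "send": 130,
              "sframe": 1}]
        )
        out = assign_hits(hits, GeneIndex(self._genes()))
        # start == gene start fails the strict inequality; LC still contains
        assert out[0].category == "LC"

    def test_unknown_chromosome_novel(self):
        hits = self._mk_hits(
            [{"qaccver": "p", "saccver": "chrZ", "sstart": 5, "send": 20,
              "sframe": 1}]
        )
        out = assign_hits(hits, GeneIndex(self._genes()))
        assert out[0].category == "NOVEL"
        assert out[0].gene_id is None

    def test_minus_strand_normalized(self):
        hits = self._mk_hits(
            [{"qaccver": "p", "saccver": "chr1", "sstart": 130, "send": 100,
              "sframe": -2}]
        )
        out = assign_hits(hits, GeneIndex(self._genes()))
        assert out[0].category == "HC"
        assert out[0].strand == "-"

    def test_brute_force_equivalence_random(self, bundle):
        rng = random.Random(42)
        genes = bundle.genes
        chroms = [c.id for c in bundle.genome]
        rows = []
        for i in range(1000):
            chrom = rng.choice(chroms)
            start = rng.randint(1, 29000)
            end = start + rng.randint(10, 400)
            rows.append(
                {"qaccver": f"r{i}", "saccver": chrom, "sstart": start,
                 "send": end, "sframe": rng.choice([1, 2, 3, -1, -2, -3])}
            )
        hits = self._mk_hits(rows)
        out = assign_hits(hits, GeneIndex(genes))
        for a, row in zip(out, rows):
            lo, hi = sorted((row["sstart"], row["send"]))
            expect = brute_force_containing(genes, row["saccver"], lo, hi)
            assert set(a.containing_genes) == {g.gene_id for g in expect}
            hc = [g for g in expect if g.confidence == "HC"]
            lc = [g for g in expect if g.confidence == "LC"]
            want = "HC" if hc else ("LC" if lc else "NOVEL")
            assert a.category == want


class TestStitchFrameshift:
    def test_strict_mode_recovers_none(self, fs_bundle):
        fs = {t.peptide_id: t for t in fs_bundle.truth.values()
              if t.crosses_frameshift}
        assert fs, "fixture must contain frameshift-crossing peptides"
        peps = [p for p in fs_bundle.peptides if p.id in fs]
        strict = align6.tblastn_search(peps, fs_bundle.genome)
        for pid, t in fs.items():
            rows = strict.rows[strict.rows.qaccver == pid]
            for r in rows.itertuples():
                lo, hi = sorted((r.sstart, r.send))
                covered = (r.saccver == t.chrom and all(
                    b[0] >= lo and b[1] <= hi for b in t.blocks
                ))
                assert not covered

    def test_stitch_recovers_frameshift_peptides(self, fs_bundle,
                                                 fs_hits_relaxed):
        fs = {t.peptide_id: t for t in fs_bundle.truth.values()
              if t.crosses_frameshift}
        maps = stitch_frameshift(fs_hits_relaxed)
        bym = {}
        for m in maps:
            bym.setdefault(m.peptide_id, []).append(m)
        rec = sum(
            any(m.blocks == t.blocks and m.chrom == t.chrom
                for m in bym.get(pid, []))
            for pid, t in fs.items()
        )
        assert rec / len(fs) >= 0.95

    def test_different_peptides_never_merged(self, fs_hits_relaxed):
        maps = stitch_frameshift(fs_hits_relaxed)
        for m in maps:
            assert m.peptide_id  # mappings are per peptide by construction
        ids = {m.peptide_id for m in maps}
        assert ids <= set(fs_hits_relaxed.rows.qaccver)

    def test_gap_threshold(self, fs_bundle, fs_hits_relaxed):
        merged = [m for m in stitch_frameshift(fs_hits_relaxed)
                  if len(m.blocks) == 2]
        assert merged
        none_merged = [
            m for m in stitch_frameshift(fs_hits_relaxed, max_genomic_gap=0)
            if len(m.blocks) == 2
        ]
        assert len(none_merged) < len(merged)

    def test_passthrough_single_hits(self, hits):
        maps = stitch_frameshift(hits)
        # strict search: one HSP per peptide/contig, nearly all single-block
        assert len(maps) == len(hits.rows)
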