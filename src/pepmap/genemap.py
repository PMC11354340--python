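"""Gene-model handling and spliced peptide-to-genome coordinate mapping.

Covers GFF3 parsing into confidence-labelled gene models, per-exon genomic
reading-frame computation (an intron whose length is not a multiple of 3
shifts the genomic frame of every downstream exon), exact AA-to-genomic
block mapping through exons, containment-based hit-to-gene assignment
(HC > LC > NOVEL) and frame-shift-aware stitching of adjacent partial hits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import gffutils
import pandas as pd

from .align6 import HitTable
from .seqcore import NucleotideSequence, ProteinSequence, STANDARD_CODE

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneModel:
    """A confidence-labelled gene with ordered exon intervals.

    Exons are stored in transcription order: ascending genomic coordinate
    on the + strand, descending on the - strand.  All coordinates are
    1-based inclusive.
    """

    gene_id: str
    chrom: str
    strand: str
    confidence: str  # HC or LC
    gene_start: int
    gene_end: int
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r} for {self.gene_id}")
        if self.confidence not in ("HC", "LC"):
            raise ValueError(f"bad confidence {self.confidence!r}")
        spans = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            if s2 <= e1:
                raise ValueError(f"overlapping exons in {self.gene_id}")
        total = self.cds_length
        if total % 3:
            logger.warning(
                "gene %s: spliced CDS length %d not divisible by 3",
                self.gene_id, total,
            )

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.exons)

    @property
    def protein_length(self) -> int:
        return self.cds_length // 3

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        """Intron intervals in transcription order (genomic ascending pairs)."""
        out = []
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if self.strand == "+":
                out.append((e1 + 1, s2 - 1))
            else:
                out.append((e2 + 1, s1 - 1))
        return tuple(out)

    def spliced_cds(self, contig: NucleotideSequence) -> str:
        parts = []
        for s, e in self.exons:
            block = contig.residues[s - 1 : e]
            if self.strand == "-":
                block = NucleotideSequence("_", block)
                from .seqcore import reverse_complement

                block = reverse_complement(block).residues
            parts.append(block)
        return "".join(parts)

    def protein(self, contig: NucleotideSequence) -> ProteinSequence:
        cds = self.spliced_cds(contig)
        aa = "".join(
            STANDARD_CODE.translate_codon(cds[i : i + 3])
            for i in range(0, len(cds) - len(cds) % 3, 3)
        )
        return ProteinSequence(self.gene_id, aa)


def parse_gff3(path: str | Path, confidence: str) -> list[GeneModel]:
    """Parse a GFF3 file into GeneModels labelled with the given confidence.

    Exons are taken from the CDS features of the first mRNA of each gene
    when present, else from exon features.  Records without an ID attribute
    are skipped with a warning; out-of-order exons are sorted.
    """
    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    models: list[GeneModel] = []
    for gene in db.features_of_type("gene"):
        gid = gene.attributes.get("ID", [None])[0]
        if gid is None:
            logger.warning("gene without ID attribute at %s:%s skipped",
                           gene.seqid, gene.start)
            continue
        mrnas = list(db.children(gene, featuretype="mRNA", order_by="start"))
        parent = mrnas[0] if mrnas else gene
        blocks = list(db.children(parent, featuretype="CDS"))
        if not blocks:
            blocks = list(db.children(parent, featuretype="exon"))
        if not blocks:
            logger.warning("gene %s has no CDS/exon children; skipped", gid)
            continue
        spans = sorted((f.start, f.end) for f in blocks)
        if gene.strand == "-":
            spans = spans[::-1]
        models.append(
            GeneModel(
                gene_id=gid,
                chrom=gene.seqid,
                strand=gene.strand,
                confidence=confidence,
                gene_start=gene.start,
                gene_end=gene.end,
                exons=tuple(spans),
            )
        )
    return models


def exon_frames(
    gene: GeneModel, contig_length: int | None = None
) -> tuple[list[int], bool]:
    """Genomic reading frame of each exon, plus a frame-shift flag.

    The frame of an exon is the six-frame translation whose codon lattice
    contains the exon's first complete codon (phase-corrected).  Each intron
    of length L shifts the downstream frame by L mod 3; the flag is True
    when any two exons land in different frames.

    Minus-strand frame identities depend on the contig length; when it is
    not supplied, minus-strand labels are relative (anchored at -1 for the
    first exon) but shift consistently across introns.
    """
    frames: list[int] = []
    cum = 0  # CDS nt consumed before this exon
    for s, e in gene.exons:
        phase_fill = (3 - cum % 3) % 3  # nt completing the previous codon
        if gene.strand == "+":
            first_codon_pos = s + phase_fill  # genomic, 1-based
            frames.append((first_codon_pos - 1) % 3 + 1)
        else:
            # transcription runs right-to-left: first complete codon starts
            # phase_fill nt in from the exon's genomic end
            if contig_length is not None:
                r = (contig_length - e + 1) + phase_fill  # revcomp coord
                frames.append(-((r - 1) % 3 + 1))
            else:
                r = (e - phase_fill) % 3  # relative lattice class
                frames.append(-(r + 1))
        cum += e - s + 1
    if gene.strand == "-" and contig_length is None:
        # re-anchor relative labels so the first exon reads -1
        shift = (abs(frames[0]) - 1) % 3
        frames = [-(((abs(f) - 1 - shift) % 3) + 1) for f in frames]
    has_frameshift = len(set(frames)) > 1
    return frames, has_frameshift


@dataclass(frozen=True)
class SplicedPeptideMapping:
    """A peptide's exact genomic footprint as ordered blocks across exons."""

    peptide_id: str
    gene_id: str
    chrom: str
    strand: str
    blocks: tuple[tuple[int, int], ...]  # ascending genomic order
    per_block_frame: tuple[int, ...]
    aa_start: int
    aa_end: int

    @property
    def span(self) -> tuple[int, int]:
        return self.blocks[0][0], self.blocks[-1][1]

    @property
    def total_nt(self) -> int:
        return sum(e - s + 1 for s, e in self.blocks)


def map_peptide_to_genome(
    aa_start: int,
    aa_end: int,
    gene: GeneModel,
    peptide_id: str = "",
    contig_length: int | None = None,
) -> SplicedPeptideMapping:
    """Exact AA-interval to genomic-blocks conversion through a gene model.

    The CDS-relative nucleotide interval [3*aa_start-2, 3*aa_end] is walked
    through the exons in transcription order, emitting one block per exon
    touched.  Blocks are stored in ascending genomic order with the strand
    flag; transcription order is recoverable from the strand.
    """
    if not 1 <= aa_start <= aa_end:
        raise IndexError(f"bad AA interval [{aa_start}, {aa_end}]")
    if aa_end > gene.protein_length:
        raise IndexError(
            f"AA {aa_end} beyond protein of gene {gene.gene_id} "
            f"({gene.protein_length} AA)"
        )
    lo = 3 * (aa_start - 1) + 1  # CDS-relative, 1-based
    hi = 3 * aa_end
    blocks: list[tuple[int, int]] = []
    offset = 0  # CDS nt consumed by previous exons
    frames, _ = exon_frames(gene, contig_length)
    block_frames: list[int] = []
    for (s, e), fr in zip(gene.exons, frames):
        exon_len = e - s + 1
        a = max(lo, offset + 1)
        b = min(hi, offset + exon_len)
        if a <= b:
            if gene.strand == "+":
                blocks.append((s + (a - offset - 1), s + (b - offset - 1)))
            else:
                blocks.append((e - (b - offset - 1), e - (a - offset - 1)))
            block_frames.append(fr)
        offset += exon_len
        if offset >= hi:
            break
    order = sorted(range(len(blocks)), key=lambda i: blocks[i][0])
    return SplicedPeptideMapping(
        peptide_id=peptide_id,
        gene_id=gene.gene_id,
        chrom=gene.chrom,
        strand=gene.strand,
        blocks=tuple(blocks[i] for i in order),
        per_block_frame=tuple(block_frames[i] for i in order),
        aa_start=aa_start,
        aa_end=aa_end,
    )


class GeneIndex:
    """Per-chromosome containment index over gene spans."""

    def __init__(self, genes: list[GeneModel]):
        self._by_chrom: dict[str, list[GeneModel]] = {}
        for g in genes:
            self._by_chrom.setdefault(g.chrom, []).append(g)
        for lst in self._by_chrom.values():
            lst.sort(key=lambda g: (g.gene_start, g.gene_end, g.gene_id))

    def containing(self, chrom: str, start: int, end: int) -> list[GeneModel]:
        """Genes whose span strictly contains [start, end]:
        gene_start < start and end < gene_end."""
        return [
            g
            for g in self._by_chrom.get(chrom, [])
            if g.gene_start < start and end < g.gene_end
        ]


@dataclass(frozen=True)
class HitAssignment:
    hit_id: int
    peptide_id: str
    chrom: str
    start: int
    end: int
    strand: str
    category: str  # HC, LC or NOVEL
    gene_id: str | None
    containing_genes: tuple[str, ...]


def assign_hits(hits: HitTable, index: GeneIndex) -> list[HitAssignment]:
    """Assign each hit to a gene by strict span containment.

    Coordinates are normalized to (min, max) before comparison.  When at
    least one HC gene contains the hit the category is HC (the gene with
    the largest overlap, i.e. the tightest containing HC span); else LC
    likewise; else NOVEL.  All containing genes are retained.
    """
    out: list[HitAssignment] = []
    for hit_id, row in enumerate(hits.rows.itertuples(index=False)):
        start, end = sorted((int(row.sstart), int(row.send)))
        strand = "+" if row.sframe > 0 else "-"
        genes = index.containing(row.saccver, start, end)
        if not genes and row.saccver not in index._by_chrom:
            logger.warning("hit on unknown chromosome %r -> NOVEL", row.saccver)
        hc = [g for g in genes if g.confidence == "HC"]
        lc = [g for g in genes if g.confidence == "LC"]
        if hc:
            category, pool = "HC", hc
        elif lc:
            category, pool = "LC", lc
        else:
            category, pool = "NOVEL", []
        gene_id = None
        if pool:
            # highest overlap == smallest containing span
            gene_id = min(
                pool, key=lambda g: (g.gene_end - g.gene_start, g.gene_id)
            ).gene_id
        out.append(
            HitAssignment(
                hit_id=hit_id,
                peptide_id=row.qaccver,
                chrom=row.saccver,
                start=start,
                end=end,
                strand=strand,
                category=category,
                gene_id=gene_id,
                containing_genes=tuple(g.gene_id for g in genes),
            )
        )
    return out


def assignments_to_frame(assignments: list[HitAssignment]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "hit_id": a.hit_id,
                "peptide": a.peptide_id,
                "chrom": a.chrom,
                "start": a.start,
                "end": a.end,
                "strand": a.strand,
                "category": a.category,
                "gene_id": a.gene_id or "",
            }
            for a in assignments
        ],
        columns=["hit_id", "peptide", "chrom", "start", "end", "strand",
                 "category", "gene_id"],
    )


def write_assignments(assignments: list[HitAssignment], path: str | Path) -> None:
    assignments_to_frame(assignments).to_csv(path, sep="\t", index=False)


def _column_profile(row: dict) -> tuple[list[int], list[int], list[bool]]:
    """Per-column query/subject consumption counts and identity flags."""
    qseq, sseq = str(row["qseq"]), str(row["sseq"])
    q_used, s_used = [], []
    ident = []
    q = s = 0
    for qc, sc in zip(qseq, sseq):
        if qc != "-":
            q += 1
        if sc != "-":
            s += 1
        q_used.append(q)
        s_used.append(s)
        ident.append(qc == sc and qc != "-")
    return q_used, s_used, ident


def _split_overlap(r1: dict, r2: dict) -> tuple[tuple[int, int], tuple[int, int]] | None:
    """Resolve a query overlap between two partial hits of one peptide.

    Local alignments over-extend past a frame-shift junction (noisy columns,
    or a residue genuinely alignable in both frames), so the hits are
    trimmed at the split point that keeps the most identical columns; ties
    favor the upstream hit.  Returns the trimmed genomic (lo, hi) blocks,
    or None when no split leaves both sides non-empty.
    """
    q1, s1, id1 = _column_profile(r1)
    q2, s2, id2 = _column_profile(r2)
    qs1, qs2 = int(r1["qstart"]), int(r2["qstart"])
    # identity counts of r1 up to query pos j / of r2 strictly after j
    total2 = sum(id2)

    def ident1_upto(j):  # j in peptide coordinates
        want = j - qs1 + 1
        best = 0
        for k in range(len(q1)):
            if q1[k] > want:
                break
            best += id1[k]
        return best

    def r1_subject_upto(j):
        want = j - qs1 + 1
        s_cons = 0
        for k in range(len(q1)):
            if q1[k] > want:
                break
            s_cons = s1[k]
        return s_cons

    def ident2_after(j):  # drop r2 columns with query pos <= j
        drop = j - qs2 + 1
        dropped = 0
        for k in range(len(q2)):
            if q2[k] > drop:
                break
            dropped += id2[k]
        return total2 - dropped

    def r2_subject_dropped(j):
        drop = j - qs2 + 1
        s_cons = 0
        for k in range(len(q2)):
            if q2[k] > drop:
                break
            s_cons = s2[k]
        return s_cons

    lo_j = max(qs2 - 1, qs1)
    hi_j = min(int(r1["qend"]), int(r2["qend"]) - 1)
    if lo_j > hi_j:
        return None
    best_j = None
    best_score = -1
    for j in range(lo_j, hi_j + 1):
        sc = ident1_upto(j) + ident2_after(j)
        if sc >= best_score:
            best_score = sc
            best_j = j
    s1_keep = r1_subject_upto(best_j)
    s2_drop = r2_subject_dropped(best_j)
    s2_total = s2[-1]
    if s1_keep == 0 or s2_drop >= s2_total:
        return None
    sstart1, sstart2 = int(r1["sstart"]), int(r2["sstart"])
    if int(r1["sframe"]) > 0:
        b1 = (sstart1, sstart1 + 3 * s1_keep - 1)
        b2 = (sstart2 + 3 * s2_drop, int(max(r2["sstart"], r2["send"])))
    else:
        b1 = (sstart1 - 3 * s1_keep + 1, sstart1)
        b2 = (int(min(r2["sstart"], r2["send"])), sstart2 - 3 * s2_drop)
    return b1, b2


def stitch_frameshift(
    hits: HitTable, max_genomic_gap: int = 10_000, qadj_tolerance: int = 1
) -> list[SplicedPeptideMapping]:
    """Merge adjacent partial hits of one peptide across a genomic frame shift.

    Two hits of the same peptide on the same chromosome and strand, in
    different reading frames, adjacent in query coordinates (within the
    tolerance; frame-shift junctions can duplicate one residue) and within
    ``max_genomic_gap`` nt of each other, become a single two-block mapping.
    When the upstream hit over-extends past the downstream hit's query start
    (local alignments pick up noisy columns beyond the junction), its tail
    is trimmed back to restore adjacency before merging.  Unmerged hits
    pass through as single-block mappings.
    """
    df = hits.rows.copy()
    df["_strand"] = df["sframe"].map(lambda f: "+" if f > 0 else "-")
    df["_lo"] = df[["sstart", "send"]].min(axis=1)
    df["_hi"] = df[["sstart", "send"]].max(axis=1)
    out: list[SplicedPeptideMapping] = []
    for (pep, chrom, strand), grp in df.groupby(["qaccver", "saccver", "_strand"]):
        rows = grp.sort_values(["qstart", "_lo"]).to_dict("records")
        used = [False] * len(rows)
        for i in range(len(rows)):
            if used[i]:
                continue
            r1 = rows[i]
            merged = None
            for j in range(len(rows)):
                if used[j] or j == i:
                    continue
                r2 = rows[j]
                if r2["sframe"] == r1["sframe"]:
                    continue
                if r2["qstart"] <= r1["qstart"]:
                    continue
                adj = int(r2["qstart"]) - (int(r1["qend"]) + 1)
                if adj > qadj_tolerance:
                    continue
                if adj < 0:
                    split = _split_overlap(r1, r2)
                    if split is None:
                        continue
                    b1, b2 = split
                else:
                    b1 = (int(r1["_lo"]), int(r1["_hi"]))
                    b2 = (int(r2["_lo"]), int(r2["_hi"]))
                gap = max(b1[0], b2[0]) - min(b1[1], b2[1])
                if gap > max_genomic_gap:
                    continue
                merged = (j, r2, b1, b2)
                break
            if merged is not None:
                j, r2, b1, b2 = merged
                used[i] = used[j] = True
                blocks = tuple(sorted((b1, b2)))
                frames = (
                    (int(r1["sframe"]), int(r2["sframe"]))
                    if b1 <= b2
                    else (int(r2["sframe"]), int(r1["sframe"]))
                )
                out.append(
                    SplicedPeptideMapping(
                        peptide_id=pep,
                        gene_id="",
                        chrom=chrom,
                        strand=strand,
                        blocks=blocks,
                        per_block_frame=frames,
                        aa_start=int(min(r1["qstart"], r2["qstart"])),
                        aa_end=int(max(r1["qend"], r2["qend"])),
                    )
                )
            else:
                used[i] = True
                out.append(
                    SplicedPeptideMapping(
                        peptide_id=pep,
                        gene_id="",
                        chrom=chrom,
                        strand=strand,
                        blocks=((int(r1["_lo"]), int(r1["_hi"])),),
                        per_block_frame=(int(r1["sframe"]),),
                        aa_start=int(r1["qstart"]),
                        aa_end=int(r1["qend"]),
                    )
                )
    return out
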