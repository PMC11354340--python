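"""Seeded synthetic fixtures: genome, HC/LC gene models, proteins, tryptic
peptides and exact ground-truth genomic mappings.

Gene structure is controlled so the fixtures exercise the interesting
cases deliberately:

* exon lengths are forced to multiples of 3, so every exon/intron junction
  falls on a codon boundary;
* a configurable fraction of introns get a length that is not a multiple
  of 3, shifting the genomic reading frame of all downstream exons while
  leaving the spliced reading frame intact;
* proteins are built with lysine/arginine placed so that, whenever
  geometrically possible, at least one tryptic peptide spans each
  exon/intron junction with a comfortable flank on both sides;
* novel ORFs are written into intergenic space, outside every gene span.

Everything is deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import genemap
from .genemap import GeneModel, SplicedPeptideMapping, exon_frames, map_peptide_to_genome
from .seqcore import (
    NucleotideSequence,
    ProteinSequence,
    STANDARD_CODE,
    write_fasta,
)

# Residues used in generated proteins.  K/R are placed only at designed
# cleavage sites and P is excluded entirely, so the tryptic peptide layout
# is exactly the designed one (no accidental sites, no KP suppression).
# G is also excluded: introns are filled with poly-C, which translates to
# P on the forward strand and G on the reverse, so junction-adjacent
# intron codons can never coincidentally match a protein residue.
_BODY_AA = "ACDEFHILMNQSTVWY"
_INTRON_BASE = "C"

_CODONS_FOR: dict[str, list[str]] = {}
for codon, aa in STANDARD_CODE.table.items():
    _CODONS_FOR.setdefault(aa, []).append(codon)

MIN_JUNCTION_FLANK = 11  # AA on each side of a junction inside one peptide


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class DigestParams:
    missed_cleavages: int = 0
    min_len: int = 9
    max_len: int = 50


@dataclass(frozen=True)
class SynthConfig:
    seed: int = 0
    n_chroms: int = 2
    chrom_length_nt: int = 30_000
    n_genes: int = 12
    hc_fraction: float = 0.7
    exon_count_range: tuple[int, int] = (1, 5)
    exon_length_range: tuple[int, int] = (75, 150)  # rounded up to 3k
    intron_length_range: tuple[int, int] = (9, 60)
    frameshift_intron_fraction: float = 0.3
    minus_strand_prob: float = 0.4
    n_novel_orfs: int = 3
    novel_orf_aa_range: tuple[int, int] = (25, 45)
    digest: DigestParams = field(default_factory=DigestParams)
    n_tissues: int = 3
    mutation_rate: float = 0.0

    def __post_init__(self) -> None:
        for name in ("exon_count_range", "exon_length_range",
                     "intron_length_range", "novel_orf_aa_range"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ConfigError(f"{name} must be a non-empty positive range")
        for name in ("hc_fraction", "frameshift_intron_fraction",
                     "minus_strand_prob", "mutation_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1]")
        # conservative feasibility check: worst-case gene footprint
        worst_gene = (
            self.exon_count_range[1] * (self.exon_length_range[1] + 3)
            + (self.exon_count_range[1] - 1) * self.intron_length_range[1]
        )
        need = self.n_genes * (worst_gene + 2 * _GENE_MARGIN)
        have = self.n_chroms * (self.chrom_length_nt - 2 * _CHROM_PAD)
        if need > have:
            raise ConfigError(
                f"geometry infeasible: {self.n_genes} genes need up to "
                f"{need} nt but only {have} nt available"
            )


_CHROM_PAD = 150  # gene-free margin at chromosome ends
_GENE_MARGIN = 200  # minimum intergenic spacing
_SPAN_PAD = 30  # UTR-like extension of the gene span beyond the CDS; keeps
                # boundary peptides strictly inside the gene interval


@dataclass(frozen=True)
class PeptideTruth:
    peptide_id: str
    sequence: str  # possibly mutated (as searched)
    true_sequence: str  # as encoded in the genome
    tissue: str
    chrom: str
    strand: str
    gene_id: str  # "" for novel-ORF peptides
    category: str  # HC, LC or NOVEL
    aa_start: int
    aa_end: int
    blocks: tuple[tuple[int, int], ...]  # ascending genomic, 1-based inclusive
    per_block_frame: tuple[int, ...]
    introns_crossed: tuple[tuple[int, int], ...]
    crosses_frameshift: bool


@dataclass
class SynthBundle:
    config: SynthConfig
    genome: list[NucleotideSequence]
    hc_genes: list[GeneModel]
    lc_genes: list[GeneModel]
    proteins: list[ProteinSequence]
    peptides_by_tissue: dict[str, list[ProteinSequence]]
    truth: dict[str, PeptideTruth]

    @property
    def genes(self) -> list[GeneModel]:
        return self.hc_genes + self.lc_genes

    @property
    def peptides(self) -> list[ProteinSequence]:
        return [p for peps in self.peptides_by_tissue.values() for p in peps]

    def truth_frame(self) -> pd.DataFrame:
        rows = []
        for t in self.truth.values():
            rows.append(
                {
                    "peptide_id": t.peptide_id,
                    "sequence": t.sequence,
                    "tissue": t.tissue,
                    "chrom": t.chrom,
                    "strand": t.strand,
                    "gene_id": t.gene_id,
                    "category": t.category,
                    "aa_start": t.aa_start,
                    "aa_end": t.aa_end,
                    "blocks": ";".join(f"{s}-{e}" for s, e in t.blocks),
                    "frames": ";".join(str(f) for f in t.per_block_frame),
                    "introns_crossed": ";".join(
                        f"{s}-{e}" for s, e in t.introns_crossed
                    ),
                    "crosses_frameshift": t.crosses_frameshift,
                }
            )
        return pd.DataFrame(rows)

    def write(self, outdir: str | Path) -> None:
        """Emit genome FASTA, HC/LC GFF3, protein and per-tissue peptide
        FASTA, ground-truth TSV and BED12."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        header_note = f"seed={self.config.seed}"
        write_fasta(self.genome, outdir / "genome.fa")
        write_fasta(self.proteins, outdir / "proteins.fa")
        for tissue, peps in self.peptides_by_tissue.items():
            write_fasta(peps, outdir / f"peptides_{tissue}.fa")
        _write_gff3(self.hc_genes, outdir / "genes_hc.gff3", header_note)
        _write_gff3(self.lc_genes, outdir / "genes_lc.gff3", header_note)
        self.truth_frame().to_csv(outdir / "ground_truth.tsv", sep="\t",
                                  index=False)
        _write_truth_bed12(self.truth, outdir / "ground_truth.bed")


def _write_gff3(genes: list[GeneModel], path: Path, note: str) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"# synthetic fixture ({note})\n")
        for g in sorted(genes, key=lambda g: (g.chrom, g.gene_start)):
            fh.write(
                f"{g.chrom}\tsynth\tgene\t{g.gene_start}\t{g.gene_end}\t.\t"
                f"{g.strand}\t.\tID={g.gene_id};confidence={g.confidence}\n"
            )
            mrna = f"{g.gene_id}.1"
            fh.write(
                f"{g.chrom}\tsynth\tmRNA\t{g.gene_start}\t{g.gene_end}\t.\t"
                f"{g.strand}\t.\tID={mrna};Parent={g.gene_id}\n"
            )
            phase = 0
            for i, (s, e) in enumerate(
                sorted(g.exons) if g.strand == "+" else g.exons
            ):
                fh.write(
                    f"{g.chrom}\tsynth\texon\t{s}\t{e}\t.\t{g.strand}\t.\t"
                    f"ID={mrna}.exon{i+1};Parent={mrna}\n"
                )
                fh.write(
                    f"{g.chrom}\tsynth\tCDS\t{s}\t{e}\t.\t{g.strand}\t{phase}\t"
                    f"ID={mrna}.cds{i+1};Parent={mrna}\n"
                )
                phase = (3 - (phase + e - s + 1) % 3) % 3


def _write_truth_bed12(truth: dict[str, PeptideTruth], path: Path) -> None:
    with open(path, "w") as fh:
        for t in truth.values():
            start0 = t.blocks[0][0] - 1
            end = t.blocks[-1][1]
            sizes = ",".join(str(e - s + 1) for s, e in t.blocks)
            starts = ",".join(str(s - 1 - start0) for s, e in t.blocks)
            fh.write(
                f"{t.chrom}\t{start0}\t{end}\t{t.peptide_id}\t0\t{t.strand}\t"
                f"{start0}\t{end}\t0,0,0\t{len(t.blocks)}\t{sizes},\t{starts},\n"
            )


def digest(
    protein: ProteinSequence | str,
    missed_cleavages: int = 0,
    min_len: int = 1,
    max_len: int = 10**9,
) -> list[str]:
    """Tryptic digest: cleave after K or R except before P.

    Returns peptides (order preserved) including windows with up to
    ``missed_cleavages`` internal sites, filtered to [min_len, max_len].
    """
    s = protein.residues if isinstance(protein, ProteinSequence) else protein
    cuts = [0]
    for i, c in enumerate(s[:-1]):
        if c in "KR" and s[i + 1] != "P":
            cuts.append(i + 1)
    cuts.append(len(s))
    segments = [s[a:b] for a, b in zip(cuts, cuts[1:])]
    out: list[str] = []
    for i in range(len(segments)):
        for mc in range(missed_cleavages + 1):
            if i + mc >= len(segments):
                break
            pep = "".join(segments[i : i + mc + 1])
            if min_len <= len(pep) <= max_len:
                out.append(pep)
    return out


def _encode_protein(protein: str, rng: np.random.Generator) -> str:
    """Reverse-translate with uniform synonymous codon sampling."""
    return "".join(
        _CODONS_FOR[aa][rng.integers(len(_CODONS_FOR[aa]))] for aa in protein
    )


def _design_protein(
    n_aa: int, junction_positions: list[int], rng: np.random.Generator,
    dig: DigestParams,
) -> str:
    """Random protein with cleavage sites placed so tryptic peptides are
    digest-sized and straddle each junction with MIN_JUNCTION_FLANK AAs."""
    flank = MIN_JUNCTION_FLANK
    forbidden = set()
    for j in junction_positions:  # j = AA count before the junction
        forbidden.update(range(max(1, j - flank + 1), min(n_aa, j + flank)))
    lo = max(dig.min_len, flank + 2)
    hi = min(dig.max_len, 2 * flank + 9)
    sites: list[int] = []
    pos = 0
    while True:
        step = int(rng.integers(lo, hi + 1))
        nxt = pos + step
        # push the site out of any forbidden window (keeps peptide >= lo)
        while nxt in forbidden and nxt < n_aa:
            nxt += 1
        if nxt >= n_aa - 1:
            break
        sites.append(nxt)
        pos = nxt
    aas = [str(c) for c in rng.choice(list(_BODY_AA), size=n_aa)]
    for site in sites:
        aas[site - 1] = "K" if rng.random() < 0.5 else "R"
    return "".join(aas)


def _gene_structure(cfg: SynthConfig, rng: np.random.Generator):
    """Random exon/intron lengths honoring the mod-3 rules."""
    n_exons = int(rng.integers(cfg.exon_count_range[0],
                               cfg.exon_count_range[1] + 1))
    exon_lens = []
    for _ in range(n_exons):
        raw = int(rng.integers(cfg.exon_length_range[0],
                               cfg.exon_length_range[1] + 1))
        exon_lens.append(raw + (-raw) % 3)
    intron_lens = []
    for _ in range(n_exons - 1):
        raw = int(rng.integers(cfg.intron_length_range[0],
                               cfg.intron_length_range[1] + 1))
        if rng.random() < cfg.frameshift_intron_fraction:
            if raw % 3 == 0:
                raw += 1 if raw < cfg.intron_length_range[1] else -1
        else:
            raw += (-raw) % 3
            raw = max(3, raw)
        intron_lens.append(raw)
    return exon_lens, intron_lens


def generate(config: SynthConfig) -> SynthBundle:
    """Build a complete synthetic bundle; deterministic for a fixed seed."""
    rng = np.random.default_rng(config.seed)
    chrom_ids = [f"chr{i+1}" for i in range(config.n_chroms)]
    chrom_arrays = {
        cid: rng.choice(list("ACGT"), size=config.chrom_length_nt)
        for cid in chrom_ids
    }
    genes: list[GeneModel] = []
    proteins: list[ProteinSequence] = []
    truth: dict[str, PeptideTruth] = {}
    peptide_records: list[tuple[str, str]] = []  # (id, sequence)
    gene_spans: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_ids}

    cursor = {cid: _CHROM_PAD for cid in chrom_ids}
    chrom_cycle = 0
    for gi in range(config.n_genes):
        exon_lens, intron_lens = _gene_structure(config, rng)
        gene_len = sum(exon_lens) + sum(intron_lens)
        placed = False
        for _ in range(config.n_chroms):
            cid = chrom_ids[chrom_cycle % config.n_chroms]
            chrom_cycle += 1
            start = cursor[cid]
            if start + gene_len + _CHROM_PAD <= config.chrom_length_nt:
                cursor[cid] = start + gene_len + _GENE_MARGIN
                placed = True
                break
        if not placed:
            raise ConfigError(f"could not place gene {gi + 1}: chromosomes full")
        strand = "-" if rng.random() < config.minus_strand_prob else "+"
        confidence = "HC" if rng.random() < config.hc_fraction else "LC"
        gene_id = f"G{gi+1:04d}{confidence}"
        # genomic exon intervals, ascending
        spans = []
        pos = start
        for k, el in enumerate(exon_lens):
            spans.append((pos, pos + el - 1))
            pos += el
            if k < len(intron_lens):
                pos += intron_lens[k]
        exons = tuple(spans if strand == "+" else spans[::-1])
        gene = GeneModel(
            gene_id=gene_id,
            chrom=cid,
            strand=strand,
            confidence=confidence,
            gene_start=spans[0][0] - _SPAN_PAD,
            gene_end=spans[-1][1] + _SPAN_PAD,
            exons=exons,
        )
        # protein with junction-straddling tryptic peptides; junction AA
        # positions follow transcription order (reversed spans on -)
        n_aa = gene.protein_length
        tx_exon_lens = exon_lens if strand == "+" else exon_lens[::-1]
        junctions = []
        acc = 0
        for el in tx_exon_lens[:-1]:
            acc += el
            junctions.append(acc // 3)
        protein = _design_protein(n_aa, junctions, rng, config.digest)
        cds = _encode_protein(protein, rng)
        # write exon blocks into the chromosome (minus strand: revcomp)
        arr = chrom_arrays[cid]
        cds_seq = cds if strand == "+" else _revcomp_str(cds)
        # distribute CDS across ascending spans; for minus strand the CDS
        # runs right-to-left, so the reverse-complemented CDS laid left to
        # right across ascending spans reproduces it on the minus strand
        off = 0
        for s, e in spans:
            seg = cds_seq[off : off + (e - s + 1)]
            arr[s - 1 : e] = list(seg)
            off += e - s + 1
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            arr[e1 : s2 - 1] = _INTRON_BASE
        genes.append(gene)
        proteins.append(ProteinSequence(gene_id, protein))
        gene_spans[cid].append((gene.gene_start, gene.gene_end))
        # tryptic peptides + ground truth
        pos_aa = 1
        for pep in digest(protein, config.digest.missed_cleavages,
                          config.digest.min_len, config.digest.max_len):
            idx = protein.find(pep, pos_aa - 1)
            aa_start = idx + 1
            aa_end = idx + len(pep)
            pos_aa = aa_end + 1
            pid = f"{gene_id}.p{aa_start}_{aa_end}"
            mapping = map_peptide_to_genome(
                aa_start, aa_end, gene, pid, config.chrom_length_nt
            )
            searched = _mutate(pep, config.mutation_rate, rng)
            truth[pid] = _truth_from_mapping(
                pid, searched, pep, gene, mapping, confidence
            )
            peptide_records.append((pid, searched))

    orf_truth, orf_proteins, orf_peptides = plant_novel_orfs(
        chrom_arrays,
        gene_spans,
        config.n_novel_orfs,
        config.novel_orf_aa_range,
        config.digest,
        rng,
        mutation_rate=config.mutation_rate,
    )
    truth.update(orf_truth)
    proteins.extend(orf_proteins)
    peptide_records.extend(orf_peptides)

    genome = [
        NucleotideSequence(cid, "".join(chrom_arrays[cid])) for cid in chrom_ids
    ]
    # deal peptides to tissues round-robin, deduplicating by sequence
    tissues = [f"tissue{i+1:02d}" for i in range(config.n_tissues)]
    peptides_by_tissue: dict[str, list[ProteinSequence]] = {t: [] for t in tissues}
    seen: set[str] = set()
    for i, (pid, seq) in enumerate(peptide_records):
        if seq in seen:
            continue
        seen.add(seq)
        tissue = tissues[i % config.n_tissues]
        peptides_by_tissue[tissue].append(ProteinSequence(pid, seq))
        t = truth[pid]
        truth[pid] = PeptideTruth(**{**t.__dict__, "tissue": tissue})
    kept = {p.id for peps in peptides_by_tissue.values() for p in peps}
    truth = {k: v for k, v in truth.items() if k in kept}

    hc = [g for g in genes if g.confidence == "HC"]
    lc = [g for g in genes if g.confidence == "LC"]
    return SynthBundle(
        config=config,
        genome=genome,
        hc_genes=hc,
        lc_genes=lc,
        proteins=proteins,
        peptides_by_tissue=peptides_by_tissue,
        truth=truth,
    )


def _revcomp_str(s: str) -> str:
    return s.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


def _mutate(pep: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return pep
    chars = list(pep)
    for i in range(len(chars)):
        if rng.random() < rate:
            chars[i] = str(rng.choice(list(_BODY_AA)))
    return "".join(chars)


def _truth_from_mapping(
    pid: str,
    searched: str,
    true_seq: str,
    gene: GeneModel,
    mapping: SplicedPeptideMapping,
    category: str,
) -> PeptideTruth:
    # introns crossed = gaps between consecutive mapped blocks
    introns = tuple(
        (b1[1] + 1, b2[0] - 1)
        for b1, b2 in zip(mapping.blocks, mapping.blocks[1:])
    )
    frames = mapping.per_block_frame
    return PeptideTruth(
        peptide_id=pid,
        sequence=searched,
        true_sequence=true_seq,
        tissue="",
        chrom=gene.chrom,
        strand=gene.strand,
        gene_id=gene.gene_id,
        category=category,
        aa_start=mapping.aa_start,
        aa_end=mapping.aa_end,
        blocks=mapping.blocks,
        per_block_frame=frames,
        introns_crossed=introns,
        crosses_frameshift=len(set(frames)) > 1,
    )


def _find_intergenic_spot(
    spans: list[tuple[int, int]], chrom_len: int, need: int,
    rng: np.random.Generator,
) -> int | None:
    """A 1-based start position for an interval of ``need`` nt that avoids
    all spans with margin, or None."""
    margin = 50
    occupied = sorted(spans)
    gaps = []
    prev_end = _CHROM_PAD
    for s, e in occupied:
        if s - prev_end - 2 * margin >= need:
            gaps.append((prev_end + margin, s - margin - need))
        prev_end = max(prev_end, e)
    if chrom_len - _CHROM_PAD - prev_end - 2 * margin >= need:
        gaps.append((prev_end + margin, chrom_len - _CHROM_PAD - margin - need))
    if not gaps:
        return None
    lo, hi = gaps[int(rng.integers(len(gaps)))]
    return int(rng.integers(lo, hi + 1))


def plant_novel_orfs(
    chrom_arrays: dict[str, np.ndarray],
    gene_spans: dict[str, list[tuple[int, int]]],
    n: int,
    aa_range: tuple[int, int],
    dig: DigestParams,
    rng: np.random.Generator,
    mutation_rate: float = 0.0,
) -> tuple[dict[str, PeptideTruth], list[ProteinSequence], list[tuple[str, str]]]:
    """Write n ORFs (start codon + stop-free body + stop) into intergenic
    regions, in place.

    ORF intervals never intersect gene spans; their tryptic peptides are
    labelled NOVEL in the returned ground truth.  When intergenic space
    runs out, fewer ORFs are placed and a warning is emitted.
    ``gene_spans`` is extended in place with the placed ORF intervals.
    """
    chrom_ids = list(chrom_arrays)
    chrom_len = {c: len(a) for c, a in chrom_arrays.items()}
    truth: dict[str, PeptideTruth] = {}
    proteins: list[ProteinSequence] = []
    peptide_records: list[tuple[str, str]] = []
    orf_count = 0
    attempts = 0
    while orf_count < n and attempts < 50 * max(1, n):
        attempts += 1
        cid = chrom_ids[int(rng.integers(len(chrom_ids)))]
        n_aa = int(rng.integers(aa_range[0], aa_range[1] + 1))
        body = _design_protein(n_aa, [], rng, dig)
        orf_nt = "ATG" + _encode_protein(body, rng) + "TAA"
        spot = _find_intergenic_spot(
            gene_spans[cid], chrom_len[cid], len(orf_nt), rng
        )
        if spot is None:
            continue
        orf_count += 1
        start = spot
        chrom_arrays[cid][start - 1 : start - 1 + len(orf_nt)] = list(orf_nt)
        gene_spans[cid].append((start, start + len(orf_nt) - 1))
        orf_id = f"ORF{orf_count:03d}"
        orf_protein = "M" + body
        proteins.append(ProteinSequence(orf_id, orf_protein))
        pos_aa = 1
        for pep in digest(orf_protein, dig.missed_cleavages, dig.min_len,
                          dig.max_len):
            idx = orf_protein.find(pep, pos_aa - 1)
            aa_start, aa_end = idx + 1, idx + len(pep)
            pos_aa = aa_end + 1
            pid = f"{orf_id}.p{aa_start}_{aa_end}"
            nt_s = start + 3 * (aa_start - 1)
            nt_e = start + 3 * aa_end - 1
            searched = _mutate(pep, mutation_rate, rng)
            truth[pid] = PeptideTruth(
                peptide_id=pid,
                sequence=searched,
                true_sequence=pep,
                tissue="",
                chrom=cid,
                strand="+",
                gene_id="",
                category="NOVEL",
                aa_start=aa_start,
                aa_end=aa_end,
                blocks=((nt_s, nt_e),),
                per_block_frame=((nt_s - 1) % 3 + 1,),
                introns_crossed=(),
                crosses_frameshift=False,
            )
            peptide_records.append((pid, searched))
    if orf_count < n:
        import warnings

        warnings.warn(
            f"placed only {orf_count}/{n} novel ORFs: "
            "insufficient intergenic space"
        )
    return truth, proteins, peptide_records
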