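"""tBLASTn-style search: peptides vs six-frame translations of a genome.

Every contig is translated in all six reading frames and each peptide is
aligned against every translation with an exact affine-gap Smith-Waterman
DP (no heuristic seeding; desk-scale genomes make full DP affordable).
Surviving hits are reported in 25-column extended BLAST tabular semantics
with genomic nucleotide coordinates (start > end on the minus strand).
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import seqcore
from ._swkernel import OP_GAP_Q, OP_GAP_S, OP_MATCH, sw_align_encoded
from .seqcore import (
    GeneticCode,
    NucleotideSequence,
    ProteinSequence,
    STANDARD_CODE,
    SubstitutionMatrix,
    aa_to_genomic,
    load_matrix,
)

#: Column order of the extended 25-column tabular output.
TABULAR_COLUMNS = [
    "qaccver", "saccver", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
    "sallseqid", "score", "nident", "positive", "gaps", "ppos",
    "qframe", "sframe", "qseq", "sseq", "qlen", "slen", "salltitles",
]


def load_ka_params(path: str | Path | None = None) -> pd.DataFrame:
    """Load the Karlin-Altschul constants table (tab-separated)."""
    if path is None:
        path = seqcore._data_path("ka_params.tsv")
    return pd.read_csv(path, sep="\t", comment="#")


def resolve_ka(matrix: str, gap_open: int, gap_extend: int) -> tuple[float, float]:
    """Lambda/K for a scoring system, falling back to the ungapped row."""
    table = load_ka_params()
    rows = table[table["matrix"] == matrix.upper()]
    if rows.empty:
        raise ValueError(f"no Karlin-Altschul constants for matrix {matrix!r}")
    exact = rows[(rows["gap_open"] == gap_open) & (rows["gap_extend"] == gap_extend)]
    if exact.empty:
        exact = rows[(rows["gap_open"] == 0) & (rows["gap_extend"] == 0)]
    row = exact.iloc[0]
    return float(row["lambda"]), float(row["K"])


@dataclass(frozen=True)
class AlignmentParams:
    """Search parameters; defaults match the optimized production run
    (PAM30, gap existence 10 / extension 1, e-value 0.01, 3 targets,
    1 HSP per target, 25% minimum query coverage)."""

    matrix: str = "PAM30"
    gap_open: int = 10
    gap_extend: int = 1
    evalue_cutoff: float = 0.01
    max_target_seqs: int = 3
    max_hsps_per_target: int = 1
    min_query_coverage_pct: float = 25.0
    ka_lambda: float | None = None
    ka_K: float | None = None
    db_length_nt: int = 0
    edge_correction: bool = False

    def __post_init__(self) -> None:
        if not self.gap_open >= self.gap_extend >= 1:
            raise ValueError("require gap_open >= gap_extend >= 1")
        if self.evalue_cutoff <= 0:
            raise ValueError("evalue_cutoff must be positive")

    def with_ka_resolved(self) -> "AlignmentParams":
        if self.ka_lambda is not None and self.ka_K is not None:
            return self
        lam, k = resolve_ka(self.matrix, self.gap_open, self.gap_extend)
        return replace(
            self,
            ka_lambda=self.ka_lambda if self.ka_lambda is not None else lam,
            ka_K=self.ka_K if self.ka_K is not None else k,
        )


def evalue(
    score: int,
    query_len_aa: int,
    db_len_nt: int,
    ka_lambda: float,
    ka_K: float,
    edge_correction: bool = False,
) -> float:
    """Karlin-Altschul expectation: E = K * m * n * exp(-lambda * S).

    With ``edge_correction`` the expected random-alignment length
    l = ln(K*m*n)/lambda is subtracted from both lengths (floored at 1) —
    a deliberately simple correction, disabled by default.
    """
    if ka_lambda <= 0 or ka_K <= 0:
        raise ValueError("Karlin-Altschul lambda and K must be positive")
    if query_len_aa <= 0 or db_len_nt <= 0:
        raise ValueError("lengths must be positive")
    m, n = float(query_len_aa), float(db_len_nt)
    if edge_correction:
        ell = math.log(ka_K * m * n) / ka_lambda
        m = max(1.0, m - ell)
        n = max(1.0, n - ell)
    return ka_K * m * n * math.exp(-ka_lambda * score)


def bitscore(score: int, ka_lambda: float, ka_K: float) -> float:
    return (ka_lambda * score - math.log(ka_K)) / math.log(2.0)


def _encode(residues: str, index: dict[str, int]) -> np.ndarray:
    x = index["X"]
    return np.fromiter((index.get(c, x) for c in residues), dtype=np.int16,
                       count=len(residues))


def matrix_to_array(matrix: SubstitutionMatrix) -> tuple[np.ndarray, dict[str, int]]:
    letters = sorted({a for a, _ in matrix.scores})
    index = {c: i for i, c in enumerate(letters)}
    arr = np.zeros((len(letters), len(letters)), dtype=np.int16)
    for (a, b), v in matrix.scores.items():
        arr[index[a], index[b]] = v
    return arr, index


@dataclass(frozen=True)
class LocalAlignment:
    """Raw Smith-Waterman result in AA coordinates of query and subject."""

    score: int
    qstart: int
    qend: int
    sstart_aa: int
    send_aa: int
    qseq: str
    sseq: str


def sw_align(
    query: ProteinSequence | str,
    subject: ProteinSequence | str,
    matrix: SubstitutionMatrix | str = "PAM30",
    gap_open: int = 10,
    gap_extend: int = 1,
) -> LocalAlignment | None:
    """Best affine-gap local alignment of two protein sequences.

    Returns None when no positive-scoring alignment exists.  Unknown
    residues score via the matrix X column; never an exception.
    """
    if isinstance(matrix, str):
        matrix = load_matrix(matrix)
    q = query.residues if isinstance(query, ProteinSequence) else query
    s = subject.residues if isinstance(subject, ProteinSequence) else subject
    if not q or not s:
        raise ValueError("sw_align requires non-empty sequences")
    arr, index = matrix_to_array(matrix)
    score, qs, qe, ss, se, ops = sw_align_encoded(
        _encode(q, index), _encode(s, index), arr, gap_open, gap_extend
    )
    if score <= 0:
        return None
    qseq, sseq = _ops_to_strings(q, s, qs, ss, ops)
    return LocalAlignment(score, qs, qe, ss, se, qseq, sseq)


def _ops_to_strings(q, s, qstart, sstart, ops):
    qi, si = qstart - 1, sstart - 1
    qa, sa = [], []
    for op in ops:
        if op == OP_MATCH:
            qa.append(q[qi]); sa.append(s[si]); qi += 1; si += 1
        elif op == OP_GAP_Q:
            qa.append("-"); sa.append(s[si]); si += 1
        else:
            qa.append(q[qi]); sa.append("-"); qi += 1
    return "".join(qa), "".join(sa)


@dataclass
class HitTable:
    """Alignment hits plus provenance (parameters and input digests)."""

    rows: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.rows)

    def write_tabular(self, path: str | Path, header: bool = False) -> None:
        cols = TABULAR_COLUMNS + (["tissue"] if "tissue" in self.rows else [])
        df = self.rows.reindex(columns=cols)
        df.to_csv(path, sep="\t", index=False, header=header)

    @classmethod
    def read_tabular(cls, path: str | Path, header: bool = False) -> "HitTable":
        df = pd.read_csv(path, sep="\t", header=0 if header else None)
        if not header:
            if len(df.columns) == len(TABULAR_COLUMNS) + 1:
                df.columns = TABULAR_COLUMNS + ["tissue"]
            else:
                df.columns = TABULAR_COLUMNS[: len(df.columns)]
        return cls(df)


def _alignment_stats(aln: LocalAlignment, matrix: SubstitutionMatrix):
    nident = sum(a == b for a, b in zip(aln.qseq, aln.sseq) if a != "-" and b != "-")
    positive = sum(
        matrix.score(a, b) > 0
        for a, b in zip(aln.qseq, aln.sseq)
        if a != "-" and b != "-"
    )
    gaps = aln.qseq.count("-") + aln.sseq.count("-")
    mismatch = len(aln.qseq) - nident - gaps
    gapopen = 0
    for seq in (aln.qseq, aln.sseq):
        prev = False
        for c in seq:
            cur = c == "-"
            if cur and not prev:
                gapopen += 1
            prev = cur
    return nident, positive, gaps, mismatch, gapopen


def tblastn_search(
    peptides: Sequence[ProteinSequence],
    genome: Sequence[NucleotideSequence],
    params: AlignmentParams | None = None,
    code: GeneticCode = STANDARD_CODE,
    tissue: str = "",
) -> HitTable:
    """Align every peptide against all six frames of every contig.

    Per (peptide, contig) the best ``max_hsps_per_target`` frame-wise HSPs
    are kept (at most one HSP per frame), then the ``max_target_seqs`` best
    contigs per peptide; hits failing the e-value cutoff or the minimum
    query-coverage filter are dropped.
    """
    params = (params or AlignmentParams()).with_ka_resolved()
    matrix = load_matrix(params.matrix)
    arr, index = matrix_to_array(matrix)
    db_len = params.db_length_nt or sum(len(c) for c in genome)

    translations = []  # (contig, frame, protein, encoded)
    for contig in genome:
        if len(contig) < 3:
            import warnings

            warnings.warn(f"contig {contig.id!r} shorter than 3 nt; skipped")
            continue
        for frame, prot in seqcore.iter_six_frames(contig, code):
            translations.append((contig, frame, prot, _encode(prot.residues, index)))

    records = []
    for pep in peptides:
        enc_q = _encode(pep.residues, index)
        per_contig: dict[str, list] = {}
        for contig, frame, prot, enc_s in translations:
            score, qs, qe, ss, se, ops = sw_align_encoded(
                enc_q, enc_s, arr, params.gap_open, params.gap_extend
            )
            if score <= 0:
                continue
            ev = evalue(score, len(pep), db_len, params.ka_lambda, params.ka_K,
                        params.edge_correction)
            if ev > params.evalue_cutoff:
                continue
            coverage = 100.0 * (qe - qs + 1) / len(pep)
            if coverage < params.min_query_coverage_pct:
                continue
            qseq, sseq = _ops_to_strings(pep.residues, prot.residues, qs, ss, ops)
            aln = LocalAlignment(score, qs, qe, ss, se, qseq, sseq)
            per_contig.setdefault(contig.id, []).append((contig, frame, aln))
        # best HSPs per contig, then best contigs
        contig_best = []
        for cid, hsps in per_contig.items():
            hsps.sort(key=lambda t: (-t[2].score, t[2].qstart, t[2].sstart_aa))
            kept = hsps[: params.max_hsps_per_target]
            contig_best.append((kept[0][2].score, cid, kept))
        contig_best.sort(key=lambda t: (-t[0], t[1]))
        for _, cid, kept in contig_best[: params.max_target_seqs]:
            for contig, frame, aln in kept:
                records.append(
                    _hit_record(pep, contig, frame, aln, matrix, params, db_len,
                                tissue)
                )

    df = pd.DataFrame.from_records(records, columns=TABULAR_COLUMNS + ["tissue"])
    prov = {
        "params": params,
        "n_peptides": len(peptides),
        "n_contigs": len(genome),
        "db_length_nt": db_len,
        "peptide_digest": _digest(p.residues for p in peptides),
        "genome_digest": _digest(c.residues for c in genome),
    }
    return HitTable(df, prov)


def _digest(chunks: Iterable[str]) -> str:
    h = hashlib.sha256()
    for c in chunks:
        h.update(c.encode())
        h.update(b"\0")
    return h.hexdigest()[:16]


def _hit_record(pep, contig, frame, aln, matrix, params, db_len, tissue):
    nident, positive, gaps, mismatch, gapopen = _alignment_stats(aln, matrix)
    length = len(aln.qseq)
    sstart_nt, send_nt = aa_to_genomic(frame, aln.sstart_aa, aln.send_aa, len(contig))
    ev = evalue(aln.score, len(pep), db_len, params.ka_lambda, params.ka_K,
                params.edge_correction)
    return {
        "qaccver": pep.id,
        "saccver": contig.id,
        "pident": round(100.0 * nident / length, 3),
        "length": length,
        "mismatch": mismatch,
        "gapopen": gapopen,
        "qstart": aln.qstart,
        "qend": aln.qend,
        "sstart": sstart_nt,
        "send": send_nt,
        "evalue": ev,
        "bitscore": round(bitscore(aln.score, params.ka_lambda, params.ka_K), 1),
        "sallseqid": contig.id,
        "score": aln.score,
        "nident": nident,
        "positive": positive,
        "gaps": gaps,
        "ppos": round(100.0 * positive / length, 2),
        "qframe": 0,
        "sframe": frame,
        "qseq": aln.qseq,
        "sseq": aln.sseq,
        "qlen": len(pep),
        "slen": len(contig),
        "salltitles": contig.id,
        "tissue": tissue,
    }


def strand_of(row) -> str:
    return "+" if row["sframe"] > 0 else "-"


def frame_distribution(table: HitTable) -> pd.Series:
    """Distinct-peptide hit counts per reading frame (index -3..+3)."""
    df = table.rows
    return (
        df.groupby("sframe")["qaccver"].nunique().reindex(
            [-3, -2, -1, 1, 2, 3], fill_value=0
        )
    )
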