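"""Ground-truth evaluation of alignment output and the matrix/gap-cost sweep.

A peptide is CORRECT when some surviving hit lies on the right chromosome
and its genomic footprint covers every ground-truth block (within an
optional tolerance); WRONG when hits exist but none match; NOT FOUND when
no hit survives the filters.  A ground-truth intron is FOUND when a correct
hit contains an alignment gap whose genomic span overlaps that intron.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, replace
from typing import Mapping, Protocol, Sequence

import pandas as pd

from .align6 import AlignmentParams, HitTable, tblastn_search
from .seqcore import NucleotideSequence, ProteinSequence

logger = logging.getLogger(__name__)


class TruthRecord(Protocol):
    chrom: str
    blocks: tuple[tuple[int, int], ...]
    introns_crossed: tuple[tuple[int, int], ...]


@dataclass(frozen=True)
class EvalResult:
    total_peptides: int
    correct: int
    wrong: int
    not_found: int
    total_gaps: int
    gaps_found: int
    gaps_missed: int

    @property
    def correct_alignment_pct(self) -> float:
        return 100.0 * self.correct / self.total_peptides if self.total_peptides else 0.0

    @property
    def correct_gap_pct(self) -> float:
        return 100.0 * self.gaps_found / self.total_gaps if self.total_gaps else 0.0

    def __post_init__(self) -> None:
        assert self.correct + self.wrong + self.not_found == self.total_peptides
        assert self.gaps_found + self.gaps_missed == self.total_gaps


def hit_gap_spans(row) -> list[tuple[int, int]]:
    """Genomic spans (ascending, 1-based inclusive) of query-side alignment
    gaps, i.e. subject stretches skipped by the peptide."""
    qseq, sseq = row["qseq"], row["sseq"]
    sstart = int(row["sstart"])
    minus = int(row["sframe"]) < 0
    spans = []
    consumed = 0  # subject AA columns consumed so far
    i = 0
    n = len(qseq)
    while i < n:
        if qseq[i] == "-":
            g = 0
            while i < n and qseq[i] == "-":
                g += 1
                i += 1
                consumed += 1
            c0 = consumed - g  # subject AAs before the gap
            if minus:
                spans.append((sstart - 3 * (c0 + g) + 1, sstart - 3 * c0))
            else:
                spans.append((sstart + 3 * c0, sstart + 3 * (c0 + g) - 1))
        else:
            if sseq[i] != "-":
                consumed += 1
            i += 1
    return spans


def _overlaps(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[0] <= b[1] and b[0] <= a[1]


def evaluate(
    hits: HitTable,
    truth: Mapping[str, TruthRecord],
    tolerance_nt: int = 0,
) -> EvalResult:
    """Score a hit table against per-peptide ground truth."""
    by_pep: dict[str, list[dict]] = {}
    for _, row in hits.rows.iterrows():
        pid = row["qaccver"]
        if pid not in truth:
            logger.warning("hit peptide %r absent from ground truth; excluded", pid)
            continue
        by_pep.setdefault(pid, []).append(row)

    correct = wrong = not_found = 0
    total_gaps = gaps_found = 0
    for pid, t in truth.items():
        total_gaps += len(t.introns_crossed)
        rows = by_pep.get(pid, [])
        if not rows:
            not_found += 1
            continue
        matching = []
        for row in rows:
            if row["saccver"] != t.chrom:
                continue
            lo, hi = sorted((int(row["sstart"]), int(row["send"])))
            if all(
                b[0] >= lo - tolerance_nt and b[1] <= hi + tolerance_nt
                for b in t.blocks
            ):
                matching.append(row)
        if not matching:
            wrong += 1
            continue
        correct += 1
        for intron in t.introns_crossed:
            if any(
                _overlaps(intron, g)
                for row in matching
                for g in hit_gap_spans(row)
            ):
                gaps_found += 1
    return EvalResult(
        total_peptides=len(truth),
        correct=correct,
        wrong=wrong,
        not_found=not_found,
        total_gaps=total_gaps,
        gaps_found=gaps_found,
        gaps_missed=total_gaps - gaps_found,
    )


@dataclass(frozen=True)
class SweepConfig:
    label: str
    family: str  # PAM or BLOSUM
    number: int
    existence: int
    extension: int

    @property
    def matrix(self) -> str:
        return f"{self.family}{self.number}"


#: The default 12-configuration sweep (matrix family/number, gap existence
#: and extension costs).
DEFAULT_SWEEP: tuple[SweepConfig, ...] = (
    SweepConfig("1", "BLOSUM", 90, 6, 2),
    SweepConfig("2", "BLOSUM", 90, 8, 2),
    SweepConfig("3", "BLOSUM", 90, 9, 2),
    SweepConfig("4", "BLOSUM", 90, 9, 1),
    SweepConfig("5", "BLOSUM", 90, 11, 1),
    SweepConfig("6", "PAM", 30, 5, 2),
    SweepConfig("7", "PAM", 30, 8, 1),
    SweepConfig("8", "PAM", 30, 10, 1),
    SweepConfig("9", "PAM", 30, 14, 2),
    SweepConfig("10", "PAM", 30, 15, 3),
    SweepConfig("11", "PAM", 250, 21, 1),
    SweepConfig("12", "BLOSUM", 45, 19, 1),
)

SWEEP_COLUMNS = [
    "label", "matrix", "existence", "extension", "elapsed_s",
    "total_peptides", "wrong", "not_found", "correct",
    "correct_alignment_pct", "total_gaps", "gaps_missed", "gaps_found",
    "correct_gap_pct", "status",
]


def run_sweep(
    peptides: Sequence[ProteinSequence],
    genome: Sequence[NucleotideSequence],
    truth: Mapping[str, TruthRecord],
    configs: Sequence[SweepConfig] = DEFAULT_SWEEP,
    base_params: AlignmentParams | None = None,
    tolerance_nt: int = 0,
) -> pd.DataFrame:
    """Evaluate every sweep configuration; one row per config.

    Unsupported matrices mark the row failed and the sweep continues.
    Elapsed time is recorded but is hardware-dependent and never asserted.
    """
    base = base_params or AlignmentParams()
    rows = []
    for cfg in configs:
        rec = {
            "label": cfg.label,
            "matrix": cfg.matrix,
            "existence": cfg.existence,
            "extension": cfg.extension,
            "status": "ok",
        }
        try:
            params = replace(
                base,
                matrix=cfg.matrix,
                gap_open=cfg.existence,
                gap_extend=cfg.extension,
                ka_lambda=None,
                ka_K=None,
            )
            t0 = time.perf_counter()
            hits = tblastn_search(peptides, genome, params)
            res = evaluate(hits, truth, tolerance_nt)
            rec.update(
                elapsed_s=round(time.perf_counter() - t0, 3),
                total_peptides=res.total_peptides,
                wrong=res.wrong,
                not_found=res.not_found,
                correct=res.correct,
                correct_alignment_pct=round(res.correct_alignment_pct, 1),
                total_gaps=res.total_gaps,
                gaps_missed=res.gaps_missed,
                gaps_found=res.gaps_found,
                correct_gap_pct=round(res.correct_gap_pct, 1),
            )
        except (ValueError, KeyError) as exc:
            logger.warning("sweep config %s failed: %s", cfg.label, exc)
            rec["status"] = f"failed: {exc}"
        rows.append(rec)
    return pd.DataFrame(rows, columns=SWEEP_COLUMNS)


def rank_sweep(rows: pd.DataFrame) -> pd.DataFrame:
    """Rank sweep rows: correct peptides desc, gaps found desc, time asc.

    Ties share a rank (competition ranking: 1, 1, 3, ...).
    """
    if rows.empty:
        raise ValueError("rank_sweep requires at least one row")
    df = rows[rows["status"] == "ok"].copy()
    df = df.sort_values(
        ["correct", "gaps_found", "elapsed_s"],
        ascending=[False, False, True],
    ).reset_index(drop=True)
    ranks = []
    for i in range(len(df)):
        if i and (
            df.loc[i, "correct"] == df.loc[i - 1, "correct"]
            and df.loc[i, "gaps_found"] == df.loc[i - 1, "gaps_found"]
            and df.loc[i, "elapsed_s"] == df.loc[i - 1, "elapsed_s"]
        ):
            ranks.append(ranks[-1])
        else:
            ranks.append(i + 1)
    df["rank"] = ranks
    return df
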