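"""Peptide physicochemical properties and the tBLASTn-miss risk flag.

Average (not monoisotopic) molecular weight, Kyte-Doolittle GRAVY,
aromaticity (F/W/Y fraction) and isoelectric point via bisection on the
Henderson-Hasselbalch net charge with a Bjellqvist-style pK set.  The
constant tables are shipped as data files and parsed at import.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Iterable

import pandas as pd

from .seqcore import ProteinSequence, _data_path

WATER_MASS = 18.0153
AROMATIC = frozenset("FWY")


class PropertyError(ValueError):
    """Raised for residues without defined physicochemical constants."""


@lru_cache(maxsize=1)
def _aa_tables() -> tuple[dict[str, float], dict[str, float]]:
    df = pd.read_csv(_data_path("aa_properties.tsv"), sep="\t", comment="#")
    mass = dict(zip(df["aa"], df["avg_mass"]))
    kd = dict(zip(df["aa"], df["kd_hydropathy"]))
    return mass, kd


@lru_cache(maxsize=1)
def _pk_tables() -> dict[str, dict[str, float]]:
    df = pd.read_csv(_data_path("pk_values.tsv"), sep="\t", comment="#")
    out: dict[str, dict[str, float]] = {}
    for group, sub in df.groupby("group"):
        out[group] = dict(zip(sub["key"], sub["pk"]))
    return out


@dataclass(frozen=True)
class PeptideProperties:
    peptide_id: str
    length: int
    mw: float
    gravy: float
    aromaticity: float
    pi: float


@dataclass(frozen=True)
class RiskThresholds:
    """Feature ranges outside which peptides tend to escape translated-search
    hits: GRAVY beyond (-2.2, 0.6), aromaticity above 0.14, or short length."""

    gravy_low: float = -2.2
    gravy_high: float = 0.6
    aromaticity_max: float = 0.14
    min_length: int = 8

    def __post_init__(self) -> None:
        if not self.gravy_low < self.gravy_high:
            raise ValueError("gravy_low must be below gravy_high")


def net_charge(sequence: str, ph: float) -> float:
    """Henderson-Hasselbalch net charge of a peptide at a given pH."""
    pk = _pk_tables()
    pos, neg = pk["positive"], pk["negative"]
    nt_pk = pk["nterm_override"].get(sequence[0], pos["Nterm"])
    ct_pk = pk["cterm_override"].get(sequence[-1], neg["Cterm"])
    charge = 1.0 / (1.0 + 10 ** (ph - nt_pk))
    charge -= 1.0 / (1.0 + 10 ** (ct_pk - ph))
    for aa, p in pos.items():
        if aa != "Nterm":
            charge += sequence.count(aa) / (1.0 + 10 ** (ph - p))
    for aa, p in neg.items():
        if aa != "Cterm":
            charge -= sequence.count(aa) / (1.0 + 10 ** (p - ph))
    return charge


def isoelectric_point(sequence: str, tolerance: float = 0.01) -> float:
    """pH of zero net charge, solved by bisection on [0, 14]."""
    lo, hi = 0.0, 14.0
    while hi - lo > tolerance:
        mid = (lo + hi) / 2.0
        if net_charge(sequence, mid) > 0:
            lo = mid
        else:
            hi = mid
    return round((lo + hi) / 2.0, 2)


def compute_properties(seq: ProteinSequence | str) -> PeptideProperties:
    """Length, average MW, GRAVY, aromaticity and pI of a peptide.

    Only the 20 standard residues are accepted; X or * raise PropertyError.
    """
    pid = seq.id if isinstance(seq, ProteinSequence) else ""
    s = seq.residues if isinstance(seq, ProteinSequence) else seq.upper()
    if not s:
        raise PropertyError("empty sequence")
    mass, kd = _aa_tables()
    for c in s:
        if c not in mass:
            raise PropertyError(f"residue {c!r} has no defined properties")
    return PeptideProperties(
        peptide_id=pid,
        length=len(s),
        mw=round(sum(mass[c] for c in s) + WATER_MASS, 4),
        gravy=round(sum(kd[c] for c in s) / len(s), 4),
        aromaticity=round(sum(c in AROMATIC for c in s) / len(s), 4),
        pi=isoelectric_point(s),
    )


def flag_tblastn_risk(
    props: PeptideProperties, thresholds: RiskThresholds = RiskThresholds()
) -> tuple[bool, list[str]]:
    """True (with reasons) when a peptide's features fall in the ranges
    associated with translated-search misses."""
    reasons: list[str] = []
    if props.gravy > thresholds.gravy_high or props.gravy < thresholds.gravy_low:
        reasons.append("gravy")
    if props.aromaticity > thresholds.aromaticity_max:
        reasons.append("aromaticity")
    if props.length < thresholds.min_length:
        reasons.append("length")
    return bool(reasons), reasons


def properties_table(
    peptides: Iterable[ProteinSequence],
    thresholds: RiskThresholds = RiskThresholds(),
) -> pd.DataFrame:
    """Per-peptide property/risk table (TSV-ready)."""
    rows = []
    for pep in peptides:
        p = compute_properties(pep)
        flagged, reasons = flag_tblastn_risk(p, thresholds)
        rows.append(
            {
                "peptide_id": p.peptide_id,
                "length": p.length,
                "mw": p.mw,
                "gravy": p.gravy,
                "aromaticity": p.aromaticity,
                "pi": p.pi,
                "risk_flag": flagged,
                "risk_reasons": ";".join(reasons),
            }
        )
    return pd.DataFrame(rows)


def write_properties(
    peptides: Iterable[ProteinSequence],
    path: str | Path,
    thresholds: RiskThresholds = RiskThresholds(),
) -> None:
    properties_table(peptides, thresholds).to_csv(path, sep="\t", index=False)
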