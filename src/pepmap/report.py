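"""Aggregation and export: tissue/chromosome summary tables, descriptive
statistics, correlation matrices, BED and Circos track writers.

Percentages are rounded half-up at the printed precision (1 decimal for
rate columns); SUM footers always cover every row, while MIN/MAX/AVERAGE
(and SD) footers honor the per-row ``exclude_from_stats`` flag.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .align6 import HitTable
from .genemap import GeneModel, HitAssignment, SplicedPeptideMapping
from .seqcore import NucleotideSequence, _data_path


def round_half_up(x: float, ndigits: int = 0) -> float:
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# bundled worked-example fixtures (published wheat per-tissue and
# per-chromosome counts)

def load_wheat_tissue_counts() -> pd.DataFrame:
    return pd.read_csv(_data_path("wheat_tissue_summary.tsv"), sep="\t",
                       comment="#")


def load_wheat_chromosome_counts() -> pd.DataFrame:
    return pd.read_csv(_data_path("wheat_chromosome_summary.tsv"), sep="\t",
                       comment="#")


# ---------------------------------------------------------------------------
# tissue summary

TISSUE_COUNT_COLUMNS = ["tissue", "tissue_nb", "total_peptides",
                        "unique_sequences", "hits"]


def tissue_counts_from_hits(
    peptides_by_tissue: Mapping[str, Sequence],
    hits_by_tissue: Mapping[str, HitTable],
) -> pd.DataFrame:
    """Raw per-tissue counts from peptide sets and their hit tables.

    ``hits`` counts distinct peptides with at least one surviving hit,
    not hit rows.
    """
    rows = []
    for nb, (tissue, peps) in enumerate(peptides_by_tissue.items(), start=1):
        table = hits_by_tissue.get(tissue)
        n_hit = table.rows["qaccver"].nunique() if table is not None else 0
        rows.append(
            {
                "tissue": tissue,
                "tissue_nb": nb,
                "total_peptides": len(peps),
                "unique_sequences": len({p.residues for p in peps}),
                "hits": n_hit,
            }
        )
    return pd.DataFrame(rows, columns=TISSUE_COUNT_COLUMNS)


def summarize_by_tissue(counts: pd.DataFrame) -> pd.DataFrame:
    """Tissue summary with hit_pct column and SUM/MIN/MAX/AVERAGE/SD footer.

    Zero-peptide tissues keep their row but are excluded from AVERAGE/SD.
    """
    df = counts.copy()
    df["hit_pct"] = [
        round_half_up(100.0 * h / u, 1) if u else 0.0
        for h, u in zip(df["hits"], df["unique_sequences"])
    ]
    stat_rows = df[df["unique_sequences"] > 0]
    num_cols = ["total_peptides", "unique_sequences", "hits"]
    footer = []
    sums = {c: int(df[c].sum()) for c in num_cols}
    footer.append(
        {
            "tissue": "SUM", "tissue_nb": pd.NA, **sums,
            "hit_pct": round_half_up(
                100.0 * sums["hits"] / sums["unique_sequences"], 1
            ) if sums["unique_sequences"] else 0.0,
        }
    )
    for name, fn in (
        ("MIN", "min"), ("MAX", "max"), ("AVERAGE", "mean"), ("SD", "std")
    ):
        src = stat_rows if name in ("AVERAGE", "SD") else df
        rec = {"tissue": name, "tissue_nb": pd.NA}
        for c in num_cols + ["hit_pct"]:
            v = getattr(src[c], fn)()
            rec[c] = round_half_up(float(v), 1 if c == "hit_pct" else 0)
        footer.append(rec)
    return pd.concat([df, pd.DataFrame(footer)], ignore_index=True)


# ---------------------------------------------------------------------------
# chromosome summary

CHROM_COUNT_COLUMNS = [
    "chrom", "hc_peptides", "lc_peptides", "novel_peptides",
    "hc_mapped_genes", "lc_mapped_genes", "all_hc_genes", "all_lc_genes",
    "chrom_size_nt", "exclude_from_stats",
]


def chromosome_counts_from_assignments(
    assignments: Iterable[HitAssignment],
    genes: Sequence[GeneModel],
    chrom_sizes: Mapping[str, int] | None = None,
    exclude_chroms: Iterable[str] = (),
) -> pd.DataFrame:
    """Raw per-chromosome counts from hit assignments and gene models.

    Peptide counts are distinct (peptide, chromosome, category)
    occurrences; mapped-gene counts are distinct genes with at least one
    assigned peptide.
    """
    gene_conf = {g.gene_id: g.confidence for g in genes}
    excl = set(exclude_chroms)
    chroms = sorted({g.chrom for g in genes} | {a.chrom for a in assignments})
    pep_sets: dict[tuple[str, str], set] = {}
    gene_sets: dict[tuple[str, str], set] = {}
    for a in assignments:
        category = a.category
        if a.gene_id and a.gene_id not in gene_conf:
            import logging

            logging.getLogger(__name__).warning(
                "assignment names unknown gene %r; counted as novel", a.gene_id
            )
            category = "NOVEL"
        pep_sets.setdefault((a.chrom, category), set()).add(a.peptide_id)
        if category in ("HC", "LC") and a.gene_id:
            gene_sets.setdefault((a.chrom, category), set()).add(a.gene_id)
    rows = []
    for chrom in chroms:
        hc_all = sum(1 for g in genes if g.chrom == chrom and g.confidence == "HC")
        lc_all = sum(1 for g in genes if g.chrom == chrom and g.confidence == "LC")
        rows.append(
            {
                "chrom": chrom,
                "hc_peptides": len(pep_sets.get((chrom, "HC"), ())),
                "lc_peptides": len(pep_sets.get((chrom, "LC"), ())),
                "novel_peptides": len(pep_sets.get((chrom, "NOVEL"), ())),
                "hc_mapped_genes": len(gene_sets.get((chrom, "HC"), ())),
                "lc_mapped_genes": len(gene_sets.get((chrom, "LC"), ())),
                "all_hc_genes": hc_all,
                "all_lc_genes": lc_all,
                "chrom_size_nt": (chrom_sizes or {}).get(chrom, 0),
                "exclude_from_stats": chrom in excl,
            }
        )
    return pd.DataFrame(rows, columns=CHROM_COUNT_COLUMNS)


def _pct(num: float, den: float, ndigits: int = 1) -> float:
    return round_half_up(100.0 * num / den, ndigits) if den else 0.0


def summarize_by_chromosome(counts: pd.DataFrame) -> pd.DataFrame:
    """Chromosome summary with sum and percentage columns plus footers.

    The SUM footer covers all rows; MIN/MAX/AVERAGE cover only rows not
    flagged ``exclude_from_stats``.  Percentage columns are recomputable
    from their numerator/denominator columns: hc_pct = mapped HC genes /
    all HC genes, likewise lc_pct and sum_pct.
    """
    df = counts.copy()
    df["sum_peptides"] = (
        df["hc_peptides"] + df["lc_peptides"] + df["novel_peptides"]
    )
    df["sum_mapped_genes"] = df["hc_mapped_genes"] + df["lc_mapped_genes"]
    df["sum_all_genes"] = df["all_hc_genes"] + df["all_lc_genes"]
    df["hc_pct"] = [
        _pct(n, d) for n, d in zip(df["hc_mapped_genes"], df["all_hc_genes"])
    ]
    df["lc_pct"] = [
        _pct(n, d) for n, d in zip(df["lc_mapped_genes"], df["all_lc_genes"])
    ]
    df["sum_pct"] = [
        _pct(n, d) for n, d in zip(df["sum_mapped_genes"], df["sum_all_genes"])
    ]
    num_cols = [
        "hc_peptides", "lc_peptides", "novel_peptides", "sum_peptides",
        "hc_mapped_genes", "lc_mapped_genes", "sum_mapped_genes",
        "all_hc_genes", "all_lc_genes", "sum_all_genes",
    ]
    keep = df[~df["exclude_from_stats"].astype(bool)]
    footer = []
    sums = {c: int(df[c].sum()) for c in num_cols}
    footer.append(
        {
            "chrom": "SUM", **sums,
            "hc_pct": _pct(sums["hc_mapped_genes"], sums["all_hc_genes"]),
            "lc_pct": _pct(sums["lc_mapped_genes"], sums["all_lc_genes"]),
            "sum_pct": _pct(sums["sum_mapped_genes"], sums["sum_all_genes"]),
            "chrom_size_nt": int(df["chrom_size_nt"].sum()),
        }
    )
    for name, fn in (("MIN", "min"), ("MAX", "max"), ("AVERAGE", "mean")):
        rec = {"chrom": name}
        for c in num_cols + ["hc_pct", "lc_pct", "sum_pct", "chrom_size_nt"]:
            v = float(getattr(keep[c], fn)())
            nd = 1 if c.endswith("_pct") else 0
            rec[c] = round_half_up(v, nd)
        footer.append(rec)
    out = pd.concat([df, pd.DataFrame(footer)], ignore_index=True)
    cols = ["chrom"] + num_cols + ["hc_pct", "lc_pct", "sum_pct",
                                   "chrom_size_nt", "exclude_from_stats"]
    return out.reindex(columns=cols)


# ---------------------------------------------------------------------------
# descriptive stats and correlations

STAT_COLUMNS = ["length", "pident", "mismatch", "gapopen", "gaps", "score",
                "evalue", "sstart", "send", "sframe"]


def descriptive_stats(hits: HitTable,
                      columns: Sequence[str] = STAT_COLUMNS) -> pd.DataFrame:
    """count/mean/sd/min/Q1/median/Q3/max per numeric hit column
    (quartiles by linear interpolation)."""
    df = hits.rows
    cols = [c for c in columns if c in df.columns]
    if df.empty:
        out = pd.DataFrame(
            index=["count", "mean", "std", "min", "25%", "50%", "75%", "max"],
            columns=cols, dtype=float,
        )
        out.loc["count"] = 0.0
        return out
    return df[cols].describe()


def correlation_matrix(
    hits: HitTable, columns: Sequence[str] = STAT_COLUMNS
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pearson r and r-squared matrices over the given hit columns.

    Constant columns yield missing values (NaN), never 0.
    """
    df = hits.rows if isinstance(hits, HitTable) else hits
    cols = [c for c in columns if c in df.columns]
    r = df[cols].astype(float).corr(method="pearson")
    return r, r**2


def strand_counts(hits: HitTable) -> pd.Series:
    """Distinct-peptide counts on the + and - strand."""
    df = hits.rows
    strands = np.where(df["sframe"] > 0, "+", "-")
    return (
        pd.DataFrame({"strand": strands, "pep": df["qaccver"]})
        .groupby("strand")["pep"].nunique()
        .reindex(["+", "-"], fill_value=0)
    )


# ---------------------------------------------------------------------------
# track writers

def write_bed(
    items: HitTable | Iterable[SplicedPeptideMapping],
    path: str | Path,
    contig_sizes: Mapping[str, int] | None = None,
) -> int:
    """Write hits as BED6 or spliced mappings as BED12 (0-based half-open).

    Hit rows: chrom = saccver, start = min(sstart, send) - 1,
    end = max(sstart, send), name = ungapped peptide AA sequence,
    score = raw score clamped to [0, 1000].  Records falling outside
    a known contig are dropped with a warning.  Returns records written.
    """
    import logging

    log = logging.getLogger(__name__)
    n = 0
    with open(path, "w") as fh:
        if isinstance(items, HitTable):
            for _, row in items.rows.iterrows():
                lo, hi = sorted((int(row["sstart"]), int(row["send"])))
                if contig_sizes is not None:
                    size = contig_sizes.get(row["saccver"])
                    if size is None or lo < 1 or hi > size:
                        log.warning("hit %s outside contig bounds; dropped",
                                    row["qaccver"])
                        continue
                strand = "+" if row["sframe"] > 0 else "-"
                score = max(0, min(1000, int(row["score"])))
                name = str(row["qseq"]).replace("-", "")
                fh.write(
                    f"{row['saccver']}\t{lo-1}\t{hi}\t{name}\t{score}\t{strand}\n"
                )
                n += 1
        else:
            for m in items:
                start0 = m.blocks[0][0] - 1
                end = m.blocks[-1][1]
                if contig_sizes is not None:
                    size = contig_sizes.get(m.chrom)
                    if size is None or start0 < 0 or end > size:
                        log.warning("mapping %s outside contig bounds; dropped",
                                    m.peptide_id)
                        continue
                sizes = ",".join(str(e - s + 1) for s, e in m.blocks)
                starts = ",".join(str(s - 1 - start0) for s, _ in m.blocks)
                fh.write(
                    f"{m.chrom}\t{start0}\t{end}\t{m.peptide_id}\t0\t{m.strand}"
                    f"\t{start0}\t{end}\t0,0,0\t{len(m.blocks)}\t{sizes},"
                    f"\t{starts},\n"
                )
                n += 1
    return n


def karyotype_from_genome(
    genome: Sequence[NucleotideSequence],
    centromeres: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """Karyotype records (chrom, start, end, centromere); the centromere
    defaults to the chromosome midpoint."""
    rows = []
    for contig in genome:
        mid = (centromeres or {}).get(contig.id, (len(contig) + 1) // 2)
        rows.append(
            {"chrom": contig.id, "start": 1, "end": len(contig),
             "centromere": mid}
        )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "centromere"])


def write_circos_tracks(
    hits_by_tissue: Mapping[str, HitTable],
    karyotype: pd.DataFrame,
    outdir: str | Path,
) -> list[Path]:
    """One 3-column (chrom, sstart, send) track file per tissue plus a
    karyotype file; coordinates stay 1-based inclusive as in the hit table."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    kpath = outdir / "karyotype.txt"
    karyotype.to_csv(kpath, sep="\t", index=False, header=False)
    paths.append(kpath)
    for tissue, table in hits_by_tissue.items():
        p = outdir / f"track_{tissue}.txt"
        table.rows[["saccver", "sstart", "send"]].to_csv(
            p, sep="\t", index=False, header=False
        )
        paths.append(p)
    return paths
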