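import numpy as np
import pandas as pd
import pytest

from pepmap import align6, genemap, report, synthgen
from pepmap.align6 import HitTable, TABULAR_COLUMNS
from pepmap.report import (
    chromosome_counts_from_assignments,
    correlation_matrix,
    descriptive_stats,
    karyotype_from_genome,
    load_wheat_chromosome_counts,
    load_wheat_tissue_counts,
    round_half_up,
    summarize_by_chromosome,
    summarize_by_tissue,
    tissue_counts_from_hits,
    write_bed,
    write_circos_tracks,
)


def test_round_half_up():
    assert round_half_up(10.75, 1) == 10.8
    assert round_half_up(10.74, 1) == 10.7
    assert round_half_up(20.5) == 21.0
    assert round_half_up(2.25, 1) == 2.3  # not banker's rounding


class TestTissueSummary:
    def test_fixture_sum_row(self):
        out = summarize_by_tissue(load_wheat_tissue_counts())
        sum_row = out[out.tissue == "SUM"].iloc[0]
        assert sum_row.total_peptides == 2_705_657
        assert sum_row.unique_sequences == 861_759
        assert sum_row.hits == 92_719
        assert sum_row.hit_pct == 10.8

    def test_stored_grain_row(self):
        out = summarize_by_tissue(load_wheat_tissue_counts())
        row = out[out.tissue == "STORED GRAIN"].iloc[0]
        assert row.hit_pct == 35.9

    def test_min_max_rows(self):
        out = summarize_by_tissue(load_wheat_tissue_counts())
        assert out[out.tissue == "MIN"].iloc[0].hits == 948
        assert out[out.tissue == "MAX"].iloc[0].hits == 9743
        assert out[out.tissue == "MIN"].iloc[0].hit_pct == 3.7
        assert out[out.tissue == "MAX"].iloc[0].hit_pct == 35.9

    def test_single_tissue(self):
        counts = pd.DataFrame(
            [{"tissue": "t", "tissue_nb": 1, "total_peptides": 10,
              "unique_sequences": 10, "hits": 1}]
        )
        out = summarize_by_tissue(counts)
        assert out[out.tissue == "t"].iloc[0].hit_pct == 10.0

    def test_zero_peptide_tissue_excluded_from_average(self):
        counts = pd.DataFrame(
            [
                {"tissue": "a", "tissue_nb": 1, "total_peptides": 10,
                 "unique_sequences": 10, "hits": 5},
                {"tissue": "z", "tissue_nb": 2, "total_peptides": 0,
                 "unique_sequences": 0, "hits": 0},
            ]
        )
        out = summarize_by_tissue(counts)
        assert out[out.tissue == "AVERAGE"].iloc[0].hits == 5

    def test_footer_recomputable(self, bundle, hits):
        counts = tissue_counts_from_hits(
            bundle.peptides_by_tissue,
            {t: HitTable(hits.rows[hits.rows.qaccver.isin(
                [p.id for p in peps])])
             for t, peps in bundle.peptides_by_tissue.items()},
        )
        out = summarize_by_tissue(counts)
        body = out[~out.tissue.isin(["SUM", "MIN", "MAX", "AVERAGE", "SD"])]
        sum_row = out[out.tissue == "SUM"].iloc[0]
        for c in ["total_peptides", "unique_sequences", "hits"]:
            assert sum_row[c] == body[c].sum()


class TestChromosomeSummary:
    def test_fixture_overall_percentages(self):
        out = summarize_by_chromosome(load_wheat_chromosome_counts())
        s = out[out.chrom == "SUM"].iloc[0]
        assert s.hc_mapped_genes == 33_612
        assert s.all_hc_genes == 106_914
        assert s.hc_pct == 31.4
        assert s.lc_pct == 2.3
        assert s.novel_peptides == 2934
        assert s.sum_mapped_genes == 37_314
        assert s.sum_peptides == 92_719

    def test_chr3b_row(self):
        out = summarize_by_chromosome(load_wheat_chromosome_counts())
        r = out[out.chrom == "Chr3B"].iloc[0]
        assert r.sum_mapped_genes == 3206
        assert r.sum_all_genes == 15_292
        assert round_half_up(r.sum_pct) == 21
        assert round_half_up(r.hc_pct) == 46

    def test_category_partition(self):
        out = summarize_by_chromosome(load_wheat_chromosome_counts())
        body = out[~out.chrom.isin(["SUM", "MIN", "MAX", "AVERAGE"])]
        assert (
            body.hc_peptides + body.lc_peptides + body.novel_peptides
            == body.sum_peptides
        ).all()

    def test_excluded_row_skips_min_footer(self):
        out = summarize_by_chromosome(load_wheat_chromosome_counts())
        # ChrUn (64 HC peptides) is excluded: MIN reflects Chr7B instead
        assert out[out.chrom == "MIN"].iloc[0].hc_peptides == 1991
        assert out[out.chrom == "MAX"].iloc[0].sum_peptides == 8287

    def test_empty_assignments(self, bundle):
        counts = chromosome_counts_from_assignments([], bundle.genes)
        out = summarize_by_chromosome(counts)
        assert out[out.chrom == "SUM"].iloc[0].sum_peptides == 0

    def test_end_to_end_counts(self, bundle, hits):
        idx = genemap.GeneIndex(bundle.genes)
        assignments = genemap.assign_hits(hits, idx)
        counts = chromosome_counts_from_assignments(
            assignments, bundle.genes,
            chrom_sizes={c.id: len(c) for c in bundle.genome},
        )
        out = summarize_by_chromosome(counts)
        s = out[out.chrom == "SUM"].iloc[0]
        assert s.sum_peptides > 0
        assert s.hc_mapped_genes <= s.all_hc_genes


class TestDescriptiveStats:
    def test_median_interpolated(self):
        df = pd.DataFrame({c: 0 for c in TABULAR_COLUMNS}, index=[0, 1, 2, 3])
        df["length"] = [1, 2, 3, 4]
        stats = descriptive_stats(HitTable(df))
        assert stats.loc["50%", "length"] == 2.5

    def test_constant_column_sd_zero(self):
        df = pd.DataFrame({c: 0 for c in TABULAR_COLUMNS}, index=range(5))
        df["score"] = 7
        stats = descriptive_stats(HitTable(df))
        assert stats.loc["std", "score"] == 0

    def test_empty_table(self):
        stats = descriptive_stats(HitTable(pd.DataFrame(columns=TABULAR_COLUMNS)))
        assert stats.empty or (stats.loc["count"] == 0).all()

    def test_quartile_ordering(self, hits):
        stats = descriptive_stats(hits)
        for c in stats.columns:
            s = stats[c]
            assert s["min"] <= s["25%"] <= s["50%"] <= s["75%"] <= s["max"]

    def test_against_sorted_array_oracle(self, hits):
        stats = descriptive_stats(hits)
        arr = np.sort(hits.rows["score"].to_numpy(float))
        assert stats.loc["50%", "score"] == pytest.approx(
            np.percentile(arr, 50, method="linear")
        )
        assert stats.loc["25%", "score"] == pytest.approx(
            np.percentile(arr, 25, method="linear")
        )


class TestCorrelationMatrix:
    def _table(self, **cols):
        n = len(next(iter(cols.values())))
        df = pd.DataFrame({c: np.zeros(n) for c in TABULAR_COLUMNS})
        for k, v in cols.items():
            df[k] = v
        return HitTable(df)

    def test_linear_relation(self):
        x = np.arange(50.0)
        r, r2 = correlation_matrix(
            self._table(length=x, score=2 * x), ["length", "score"]
        )
        assert r.loc["length", "score"] == pytest.approx(1.0)
        assert r2.loc["length", "score"] == pytest.approx(1.0)

    def test_anticorrelation(self):
        x = np.arange(50.0)
        r, _ = correlation_matrix(
            self._table(length=x, score=-x), ["length", "score"]
        )
        assert r.loc["length", "score"] == pytest.approx(-1.0)

    def test_symmetric_unit_diagonal(self, hits):
        r, r2 = correlation_matrix(hits)
        assert np.allclose(r.values, r.values.T, equal_nan=True)
        finite = [c for c in r.columns if not np.isnan(r.loc[c, c])]
        for c in finite:
            assert r.loc[c, c] == pytest.approx(1.0)

    def test_constant_column_nan(self):
        x = np.arange(20.0)
        r, _ = correlation_matrix(
            self._table(length=x, score=np.full(20, 3.0)), ["length", "score"]
        )
        assert np.isnan(r.loc["length", "score"])

    def test_independent_samples_small_r(self):
        rng = np.random.default_rng(0)
        n = 10_000
        r, _ = correlation_matrix(
            self._table(length=rng.normal(size=n), score=rng.normal(size=n)),
            ["length", "score"],
        )
        assert abs(r.loc["length", "score"]) < 0.1


def _hit_row(**kw):
    rec = {c: 0 for c in TABULAR_COLUMNS}
    rec.update(kw)
    return pd.DataFrame([rec])


class TestBed:
    def test_plus_strand_hit(self, tmp_path):
        df = _hit_row(qaccver="p", saccver="chr1", sstart=100, send=129,
                      sframe=2, score=55, qseq="WLT")
        p = tmp_path / "x.bed"
        write_bed(HitTable(df), p)
        fields = p.read_text().strip().split("\t")
        assert fields == ["chr1", "99", "129", "WLT", "55", "+"]

    def test_minus_strand_hit(self, tmp_path):
        df = _hit_row(qaccver="p", saccver="chr1", sstart=129, send=100,
                      sframe=-1, score=2000, qseq="WLT")
        p = tmp_path / "x.bed"
        write_bed(HitTable(df), p)
        fields = p.read_text().strip().split("\t")
        assert fields[:3] == ["chr1", "99", "129"]
        assert fields[4] == "1000"  # clamped
        assert fields[5] == "-"

    def test_out_of_bounds_dropped(self, tmp_path):
        df = _hit_row(qaccver="p", saccver="chr1", sstart=100, send=999,
                      sframe=1, score=5, qseq="W")
        n = write_bed(HitTable(df), tmp_path / "x.bed", {"chr1": 500})
        assert n == 0

    def test_bed12_roundtrip(self, fs_bundle, fs_hits_relaxed, tmp_path):
        maps = genemap.stitch_frameshift(fs_hits_relaxed)
        two_block = [m for m in maps if len(m.blocks) == 2]
        assert two_block
        p = tmp_path / "spliced.bed"
        write_bed(two_block, p)
        lines = p.read_text().strip().split("\n")
        assert len(lines) == len(two_block)
        for line, m in zip(lines, two_block):
            f = line.split("\t")
            assert int(f[9]) == 2
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            starts = [int(x) for x in f[11].rstrip(",").split(",")]
            chrom_start = int(f[1])
            blocks = tuple(
                (chrom_start + st + 1, chrom_start + st + sz)
                for st, sz in zip(starts, sizes)
            )
            assert blocks == m.blocks


class TestCircos:
    def test_track_files(self, bundle, hits, tmp_path):
        by_tissue = {
            t: HitTable(hits.rows[hits.rows.qaccver.isin(
                [p.id for p in peps])])
            for t, peps in bundle.peptides_by_tissue.items()
        }
        karyo = karyotype_from_genome(bundle.genome)
        paths = write_circos_tracks(by_tissue, karyo, tmp_path)
        assert len(paths) == len(by_tissue) + 1
        # containment: all track intervals within karyotype bounds
        bounds = {r.chrom: (r.start, r.end) for r in karyo.itertuples()}
        for p in paths[1:]:
            for line in p.read_text().splitlines():
                chrom, s, e = line.split("\t")
                lo, hi = sorted((int(s), int(e)))
                assert bounds[chrom][0] <= lo and hi <= bounds[chrom][1]

    def test_empty_tissue_still_creates_file(self, bundle, tmp_path):
        empty = HitTable(pd.DataFrame(columns=TABULAR_COLUMNS))
        paths = write_circos_tracks(
            {"none": empty}, karyotype_from_genome(bundle.genome), tmp_path
        )
        track = [p for p in paths if "track_none" in str(p)][0]
        assert track.exists() and track.read_text() == ""
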