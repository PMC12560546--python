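from pathlib import Path

import pytest
from click.testing import CliRunner

from resynth import (FilterConfig, RunLog, builtin_score_table, pair_score,
                     plot_top_pairs, read_genotype_table, run_selection,
                     similarity_range, write_accepted_pairs, write_all,
                     write_discarded, write_genotype_table, write_log,
                     write_marker_map)
from resynth.cli import main as cli_main

from conftest import make_matrix, single_chrom_map


@pytest.fixture(scope="module")
def small_result(request):
    cfg_small = dict(max_het=0.5, max_invariable_fraction=0.1,
                     min_score_fraction=0.6)
    from resynth.simulate import default_config, simulate_f2
    gm, mm, _ = simulate_f2(default_config(
        60, n_chromosomes=3, markers_per_chromosome=15, seed=77))
    set3 = builtin_score_table("SET3")
    res = run_selection(gm, mm, set3, FilterConfig(**cfg_small), phased=True)
    return gm, mm, set3, res


class TestWriteAcceptedPairs:
    def test_phased_file_has_eleven_columns(self, small_result, tmp_path):
        _, _, _, res = small_result
        path = tmp_path / "pairs.tsv"
        write_accepted_pairs(res, True, path)
        lines = path.read_text().splitlines()
        assert len(lines) == 1 + len(res.accepted)
        assert all(len(l.split("\t")) == 11 for l in lines)

    def test_unphased_file_has_eight_columns(self, small_result, tmp_path):
        _, _, _, res = small_result
        path = tmp_path / "pairs.tsv"
        write_accepted_pairs(res, False, path)
        assert all(len(l.split("\t")) == 8
                   for l in path.read_text().splitlines())

    def test_empty_result_writes_header_only(self, tmp_path):
        from resynth.pairs import SelectionResult
        res = SelectionResult([], [], {"low_score_enumerated": True})
        path = tmp_path / "pairs.tsv"
        write_accepted_pairs(res, False, path)
        assert path.read_text().splitlines() == [
            "id1\tid2\tfinal_score\tn_invariable\thet1\thet2\t"
            "similarity_lower_pct\tsimilarity_upper_pct"]

    def test_columns_recompute_from_genotypes(self, small_result, tmp_path):
        gm, mm, table, res = small_result
        path = tmp_path / "pairs.tsv"
        write_accepted_pairs(res, True, path)
        header, *rows = path.read_text().splitlines()
        cols = header.split("\t")
        for line in rows:
            rec = dict(zip(cols, line.split("\t")))
            ps = pair_score(gm.row(rec["id1"]), gm.row(rec["id2"]), table)
            assert rec["final_score"] == f"{ps.final_score:.2f}"
            assert int(rec["n_invariable"]) == ps.n_invariable
            sim = similarity_range(gm.n_markers, ps.n_invariable,
                                   ps.n_het_union)
            assert rec["similarity_upper_pct"] == f"{sim.upper_pct:.2f}"
            assert int(rec["rec_total"]) == int(rec["rec1"]) + int(rec["rec2"])


class TestWriteDiscarded:
    def test_individual_rejection_row(self, tmp_path, set3):
        gm = make_matrix({"hot": "HHHB", "a": "ABAB", "b": "BABA"})
        mm = single_chrom_map(4)
        res = run_selection(gm, mm, set3, FilterConfig(
            max_het=0.5, max_invariable_fraction=1.0, min_score_fraction=0.0))
        path = tmp_path / "disc.tsv"
        write_discarded(res, path)
        rows = [l.split("\t") for l in path.read_text().splitlines()[1:]]
        assert ["hot", "HET_RATE", "0.75", "0.5"] in rows

    def test_no_rejections_header_only(self, tmp_path, set3):
        gm = make_matrix({"a": "ABAB", "b": "BABA"})
        res = run_selection(gm, single_chrom_map(4), set3, FilterConfig(
            max_het=1.0, max_invariable_fraction=1.0, min_score_fraction=0.0))
        path = tmp_path / "disc.tsv"
        write_discarded(res, path)
        assert len(path.read_text().splitlines()) == 1

    def test_aggregated_low_score_summary_row(self, tmp_path, set3):
        gm = make_matrix({f"i{k}": "AAAA" for k in range(6)})
        res = run_selection(gm, single_chrom_map(4), set3, FilterConfig(
            max_het=1.0, max_invariable_fraction=1.0, min_score_fraction=0.5),
            low_score_cap=5)
        path = tmp_path / "disc.tsv"
        write_discarded(res, path)
        last = path.read_text().splitlines()[-1]
        assert "aggregated" in last and "LOW_SCORE" in last


class TestWriteLog:
    def test_defaults_and_stats_are_printed(self, tmp_path):
        log = RunLog(arguments={"scores": "SET3", "max_het": 0.5,
                                "min_score_frac": 0.8},
                     stage_stats={"n_pairs_evaluated": 190, "n_accepted": 3})
        path = tmp_path / "run.log"
        write_log(log, path)
        text = path.read_text()
        for needle in ("SET3", "max_het: 0.5", "min_score_frac: 0.8",
                       "n_pairs_evaluated: 190"):
            assert needle in text


class TestPlotTopPairs:
    def test_writes_png_and_pdf(self, small_result, tmp_path):
        gm, mm, _, res = small_result
        paths = plot_top_pairs(gm, mm, res, tmp_path / "top10")
        assert [p.suffix for p in paths] == [".png", ".pdf"]
        assert all(p.exists() and p.stat().st_size > 0 for p in paths)

    def test_zero_accepted_pairs_skips_figure(self, tmp_path, set3):
        from resynth.pairs import SelectionResult
        gm = make_matrix({"a": "ABAB", "b": "BABA"})
        res = SelectionResult([], [], {})
        assert plot_top_pairs(gm, single_chrom_map(4), res,
                              tmp_path / "none") == []

    def test_row_count_matches_pair_count(self, small_result, tmp_path):
        gm, mm, _, res = small_result
        n_pairs = min(10, len(res.accepted))
        paths = plot_top_pairs(gm, mm, res, tmp_path / "fig",
                               n_pairs=n_pairs)
        assert paths  # rendering succeeded with 2*n_pairs rows


class TestCli:
    def test_select_end_to_end(self, tmp_path, small_result):
        gm, mm, _, _ = small_result
        geno, markers = tmp_path / "g.tsv", tmp_path / "m.tsv"
        write_genotype_table(gm, geno)
        write_marker_map(mm, markers)
        out = tmp_path / "run"
        result = CliRunner().invoke(cli_main, [
            "select", str(geno), str(markers), "--phased",
            "--min-score-frac", "0.6", "--max-invariable", "0.1",
            "--out", str(out)])
        assert result.exit_code == 0, result.output
        for suffix in (".pairs.tsv", ".discarded.tsv", ".log"):
            assert Path(f"{out}{suffix}").exists()

    def test_simulate_writes_parsable_inputs(self, tmp_path):
        result = CliRunner().invoke(cli_main, [
            "simulate", "--n-individuals", "20", "--n-chromosomes", "2",
            "--markers-per-chromosome", "5", "--seed", "3",
            "--out", str(tmp_path / "sim")])
        assert result.exit_code == 0, result.output
        gm = read_genotype_table(tmp_path / "sim.geno.tsv")
        assert gm.codes.shape == (20, 10)

    def test_score_pair_reports_score(self, tmp_path):
        geno, markers = tmp_path / "g.tsv", tmp_path / "m.tsv"
        write_genotype_table(make_matrix({"x": "AABB", "y": "BBAA"}), geno)
        write_marker_map(single_chrom_map(4), markers)
        result = CliRunner().invoke(cli_main, [
            "score-pair", str(geno), str(markers), "x", "y", "--phased"])
        assert result.exit_code == 0, result.output
        assert "final score: 4.00" in result.output


def test_write_all_produces_four_products(small_result, tmp_path):
    gm, mm, _, res = small_result
    out = write_all(gm, mm, res, {"scores": "SET3"}, True,
                    tmp_path / "run")
    assert set(out) >= {"pairs", "discarded", "log"}
    assert all(p.exists() for p in out.values())
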