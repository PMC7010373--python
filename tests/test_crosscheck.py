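"""Record parsing, batch verdicts, digit counting, reporting, CLI."""


import pytest
from click.testing import CliRunner

from vfpow.cli import main as cli_main
from vfpow.crosscheck import (
    ParseError,
    VerdictStatus,
    count_correct_sigdigits,
    crosscheck,
    format_report,
    generate_fixtures,
    parse_records,
)
from vfpow.interval import Interval, point

from .data_tables import NONCENTRAL_CDF_CASES


class TestParsing:
    def test_beta_dialect(self):
        recs = parse_records(["0.5 1 0.05 0.10 0.9025 46.1803"])
        assert len(recs) == 1
        r = recs[0]
        assert (r.a, r.b, r.alpha, r.beta_err) == (0.5, 1, 0.05, 0.10)
        assert (r.x_cand, r.lam_cand) == (0.9025, 46.1803)

    def test_f_dialect_maps_degrees_of_freedom(self):
        recs = parse_records(["1 2 0.05 0.10 0.9025 46.1803"], dialect="f")
        assert (recs[0].a, recs[0].b) == (0.5, 1)

    def test_comments_and_blanks_skipped(self):
        recs = parse_records(["# header", "", "  ",
                              "1 1 0.05 0.10 0.95 90.0517  # inline"])
        assert len(recs) == 1 and recs[0].id == "4"

    def test_wrong_field_count(self):
        with pytest.raises(ParseError, match=":1:"):
            parse_records(["1 1 0.05 0.10 0.95"])

    def test_odd_nu2_in_f_dialect(self):
        with pytest.raises(ParseError, match="even"):
            parse_records(["10 7 0.05 0.10 0.5 10.0"], dialect="f")

    def test_non_numeric_field(self):
        with pytest.raises(ParseError):
            parse_records(["1 1 x 0.10 0.95 90.0"])


class TestCrosscheck:
    def test_correct_candidates_verified(self):
        recs = parse_records(["0.5 1 0.05 0.10 0.9025 46.18034458675263"])
        (v,) = crosscheck(recs)
        assert v.x_status is VerdictStatus.VERIFIED
        assert v.lambda_status is VerdictStatus.VERIFIED
        assert v.x_enclosure.contains(0.9025)

    def test_perturbed_lambda_rejected(self):
        recs = parse_records(["0.5 1 0.05 0.10 0.9025 46.6"])
        (v,) = crosscheck(recs)
        assert v.x_status is VerdictStatus.VERIFIED
        assert v.lambda_status is VerdictStatus.REJECTED
        # the refuted record echoes its inflated input interval
        assert v.lambda_enclosure.contains(46.6)

    def test_bad_x_skips_lambda(self):
        recs = parse_records(["0.5 1 0.05 0.10 0.91 46.18"])
        (v,) = crosscheck(recs)
        assert v.x_status is VerdictStatus.REJECTED
        assert v.lambda_status is VerdictStatus.SKIPPED

    def test_invalid_record_yields_error_not_abort(self):
        recs = parse_records([
            "1 1 0.05 0.96 0.95 90.0",      # beta >= 1 - alpha
            "1 1 0.05 0.10 0.95 90.0517",
        ])
        verdicts = crosscheck(recs)
        assert verdicts[0].x_status is VerdictStatus.ERROR
        assert verdicts[1].x_status is VerdictStatus.VERIFIED

    def test_batch_independence_under_shuffle(self):
        lines = [
            "0.5 1 0.05 0.10 0.9025 46.18034458675263",
            "1 1 0.05 0.10 0.95 90.05167194425981",
            "1 2 0.05 0.10 0.776393 30.4220",
        ]
        recs = parse_records(lines)
        base = {r.id: v for r, v in zip(recs, crosscheck(recs))}
        shuffled = recs[::-1]
        for rec, v in zip(shuffled, crosscheck(shuffled)):
            ref = base[rec.id]
            assert v.x_status == ref.x_status
            assert v.lambda_status == ref.lambda_status


class TestSigdigits:
    @pytest.mark.parametrize(
        "cand,correct,expect",
        [(c[5], c[4], c[6]) for c in NONCENTRAL_CDF_CASES]
        + [(c[7], c[4], c[8]) for c in NONCENTRAL_CDF_CASES],
    )
    def test_published_digit_counts(self, cand, correct, expect):
        """All ten published correct-digit counts reproduce."""
        verified = Interval(correct - 4e-8, correct + 4e-8)
        assert count_correct_sigdigits(cand, verified) == expect

    def test_all_digits_correct(self):
        assert count_correct_sigdigits(
            0.4563026, point(0.4563026), max_digits=7
        ) == 7

    def test_total_disagreement(self):
        assert count_correct_sigdigits(0.9, point(0.1)) == 0

    def test_too_wide_enclosure_errors(self):
        with pytest.raises(ValueError, match="wide"):
            count_correct_sigdigits(0.5, Interval(0.4, 0.6), max_digits=7)


class TestFixtures:
    GRID = [(0.5, 1, 0.05, 0.10), (1.0, 1, 0.05, 0.10),
            (5.0, 10, 0.05, 0.10)]

    def test_exact_model_all_verified(self):
        text = generate_fixtures(self.GRID, "exact", seed=7)
        recs = parse_records(text.splitlines())
        for v in crosscheck(recs):
            assert v.x_status is VerdictStatus.VERIFIED
            assert v.lambda_status is VerdictStatus.VERIFIED

    def test_perturbed_model_all_rejected(self):
        text = generate_fixtures(self.GRID, "relative-perturb", seed=7,
                                 delta=1e-3)
        recs = parse_records(text.splitlines())
        for v in crosscheck(recs):
            assert v.lambda_status is VerdictStatus.REJECTED

    def test_overflow_bogus_rejected(self):
        text = generate_fixtures(self.GRID[:1], "overflow-bogus", seed=7)
        (v,) = crosscheck(parse_records(text.splitlines()))
        assert v.lambda_status is VerdictStatus.REJECTED

    def test_deterministic(self):
        t1 = generate_fixtures(self.GRID, "relative-perturb", seed=42)
        t2 = generate_fixtures(self.GRID, "relative-perturb", seed=42)
        assert t1 == t2


class TestReport:
    def _verdicts(self):
        recs = parse_records([
            "0.5 1 0.05 0.10 0.9025 46.18034458675263",
            "0.5 1 0.05 0.10 0.9025 46.6",
        ])
        return crosscheck(recs)

    def test_report_shape(self):
        out = format_report(self._verdicts())
        lines = out.strip().split("\n")
        assert lines[0].split("\t")[0] == "id"
        assert len(lines) == 3
        assert "VERIFIED" in lines[1] and "REJECTED" in lines[2]

    def test_empty_report(self):
        out = format_report([])
        assert out.strip().split("\n") == [out.strip()]  # header only

    def test_printed_bounds_still_enclose(self):
        """Outward-rounded printed bounds re-parse to an interval that
        contains the in-memory enclosure."""
        for v in self._verdicts():
            out = format_report([v], digits=8)
            row = out.strip().split("\n")[1].split("\t")
            if not v.x_enclosure.is_empty:
                assert float(row[6]) <= v.x_enclosure.lo
                assert float(row[7]) >= v.x_enclosure.hi
            if not v.lambda_enclosure.is_empty:
                assert float(row[9]) <= v.lambda_enclosure.lo
                assert float(row[10]) >= v.lambda_enclosure.hi


class TestCli:
    def test_solve_command(self):
        runner = CliRunner()
        res = runner.invoke(cli_main, ["solve", "-a", "0.5", "-b", "1",
                                       "--x-cand", "0.9025",
                                       "--lam-cand", "46.1803"])
        assert res.exit_code == 0
        assert "UNIQUE" in res.output
        assert "4.61803" in res.output

    def test_demo_e_brackets_e(self):
        runner = CliRunner()
        res = runner.invoke(cli_main, ["demo-e"])
        assert res.exit_code == 0
        rows = [l.split("\t") for l in res.output.strip().split("\n")[1:]]
        assert len(rows) == 17
        for row in rows:
            assert float(row[5]) >= 0.0  # e - f_lo
            assert float(row[6]) >= 0.0  # g_hi - e

    def test_crosscheck_command_exit_codes(self, tmp_path):
        runner = CliRunner()
        good = tmp_path / "good.txt"
        good.write_text("1 1 0.05 0.10 0.95 90.05167194425981\n")
        res = runner.invoke(cli_main, ["crosscheck", str(good)])
        assert res.exit_code == 0
        assert "VERIFIED" in res.output

        bad = tmp_path / "bad.txt"
        bad.write_text("1 1 0.05 0.10 0.95\n")  # malformed
        res = runner.invoke(cli_main, ["crosscheck", str(bad)])
        assert res.exit_code == 1

    def test_make_fixtures_roundtrip(self, tmp_path):
        runner = CliRunner()
        out = tmp_path / "fix.txt"
        res = runner.invoke(cli_main, [
            "make-fixtures", str(out), "--error-model", "exact",
            "--grid", "1,1;0.5,1",
        ])
        assert res.exit_code == 0
        res = runner.invoke(cli_main, ["crosscheck", str(out)])
        assert res.exit_code == 0
        assert res.output.count("VERIFIED") >= 4
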