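"""Spectra/metadata I/O: matrix round-trips, JCAMP-DX parsing, table validation."""

import textwrap

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ppmspect import (
    SampleTable, SpectraIOError, Spectrum,
    read_jcampdx, read_sample_table, read_spectra_matrix,
    write_report, write_spectra_matrix,
)


def _write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(textwrap.dedent(text))
    return p


class TestSpectrum:
    def test_rejects_short_and_ragged(self):
        with pytest.raises(SpectraIOError):
            Spectrum("s", [1.0], [2.0])
        with pytest.raises(SpectraIOError):
            Spectrum("s", [1.0, 2.0], [1.0, 2.0, 3.0])

    def test_rejects_nonuniform_grid(self):
        with pytest.raises(SpectraIOError, match="non-uniform"):
            Spectrum("s", [0.0, 1.0, 2.5], [0.0, 0.0, 0.0])

    def test_rejects_duplicate_ppm(self):
        with pytest.raises(SpectraIOError, match="strictly increasing"):
            Spectrum("s", [0.0, 1.0, 1.0], [0.0, 0.0, 0.0])


class TestSpectraMatrix:
    def test_smoke_read(self, tmp_path):
        p = _write(tmp_path, "m.tsv", """\
            ppm\ts1\ts2\ts3
            1.0\t0.1\t0.2\t0.3
            1.1\t0.4\t0.5\t0.6
            1.2\t0.7\t0.8\t0.9
            1.3\t1.0\t1.1\t1.2
            1.4\t1.3\t1.4\t1.5
            """)
        spectra = read_spectra_matrix(p)
        assert [sp.sample_id for sp in spectra] == ["s1", "s2", "s3"]
        assert all(len(sp) == 5 for sp in spectra)
        assert spectra[1].intensity[0] == pytest.approx(0.2)

    def test_comma_delimiter_autodetected(self, tmp_path):
        p = _write(tmp_path, "m.csv", """\
            ppm,a
            1.0,5
            1.5,6
            """)
        assert read_spectra_matrix(p)[0].intensity[1] == 6

    def test_duplicate_ppm_row_is_error(self, tmp_path):
        p = _write(tmp_path, "m.tsv", """\
            ppm\ta
            1.0\t5
            1.0\t6
            """)
        with pytest.raises(SpectraIOError, match="row 1"):
            read_spectra_matrix(p)

    def test_missing_cell_is_error(self, tmp_path):
        p = _write(tmp_path, "m.tsv", "ppm\ta\tb\n1.0\t5\t1\n1.5\t6\n")
        with pytest.raises(SpectraIOError, match="missing|ragged"):
            read_spectra_matrix(p)

    def test_descending_file_normalized_to_ascending(self, tmp_path):
        p = _write(tmp_path, "m.tsv", """\
            ppm\ta
            3.0\t30
            2.0\t20
            1.0\t10
            """)
        sp = read_spectra_matrix(p)[0]
        assert np.array_equal(sp.ppm, [1.0, 2.0, 3.0])
        assert np.array_equal(sp.intensity, [10.0, 20.0, 30.0])

    def test_round_trip_identity(self, tmp_path, rng):
        ppm = np.linspace(0.5, 9.5, 101)
        spectra = [Spectrum(f"s{i}", ppm, rng.random(101)) for i in range(3)]
        path = tmp_path / "rt.tsv"
        write_spectra_matrix(path, spectra)
        back = read_spectra_matrix(path)
        for orig, new in zip(spectra, back):
            assert new.sample_id == orig.sample_id
            np.testing.assert_allclose(new.intensity, orig.intensity, rtol=1e-8)

    @settings(max_examples=20, deadline=None)
    @given(st.lists(st.floats(0, 1e6, allow_nan=False, width=32),
                    min_size=2, max_size=30))
    def test_round_trip_property(self, tmp_path_factory, values):
        tmp = tmp_path_factory.mktemp("rt")
        ppm = 0.5 + 0.01 * np.arange(len(values))
        sp = Spectrum("x", ppm, np.array(values, dtype=float))
        path = tmp / "m.tsv"
        write_spectra_matrix(path, [sp])
        back = read_spectra_matrix(path)[0]
        np.testing.assert_allclose(back.intensity, sp.intensity, rtol=1e-8, atol=0)


JCAMP_MIN = """\
##TITLE=synthetic minimal fixture
##JCAMP-DX=4.24
##DATA TYPE=NMR SPECTRUM
##XUNITS=PPM
##YUNITS=ARBITRARY
##FIRSTX=1.0
##LASTX=4.0
##NPOINTS=4
##YFACTOR=1.0
##XYDATA=(X++(Y..Y))
1.0 10 20 30 40
##END=
"""


class TestJcampDx:
    def test_minimal_fixture(self, tmp_path):
        p = tmp_path / "min.jdx"
        p.write_text(JCAMP_MIN)
        sp = read_jcampdx(p)
        assert len(sp) == 4
        np.testing.assert_allclose(sp.ppm, [1.0, 2.0, 3.0, 4.0])
        np.testing.assert_allclose(sp.intensity, [10, 20, 30, 40])

    def test_yfactor_scales_intensities(self, tmp_path):
        p = tmp_path / "y.jdx"
        p.write_text(JCAMP_MIN.replace("##YFACTOR=1.0", "##YFACTOR=0.5"))
        np.testing.assert_allclose(read_jcampdx(p).intensity, [5, 10, 15, 20])

    def test_descending_grid_reversed_in_lockstep(self, tmp_path):
        """FIRSTX > LASTX (the NMR convention) must reverse both vectors;
        checked against a manual reversal of the ascending fixture."""
        asc = tmp_path / "asc.jdx"
        asc.write_text(JCAMP_MIN)
        desc = tmp_path / "desc.jdx"
        desc.write_text(
            JCAMP_MIN.replace("##FIRSTX=1.0", "##FIRSTX=4.0")
                     .replace("##LASTX=4.0", "##LASTX=1.0")
                     .replace("1.0 10 20 30 40", "4.0 40 30 20 10"))
        a, d = read_jcampdx(asc), read_jcampdx(desc)
        np.testing.assert_allclose(d.ppm, a.ppm)
        manual = np.array([40.0, 30.0, 20.0, 10.0])[::-1]  # raw file order, reversed
        np.testing.assert_allclose(d.intensity, manual)
        np.testing.assert_allclose(d.intensity, a.intensity)

    def test_missing_records_listed(self, tmp_path):
        p = tmp_path / "bad.jdx"
        p.write_text("##TITLE=x\n##XYDATA=(X++(Y..Y))\n1.0 1 2\n##END=\n")
        with pytest.raises(SpectraIOError) as err:
            read_jcampdx(p)
        for rec in ("FIRSTX", "LASTX", "NPOINTS"):
            assert rec in str(err.value)

    def test_npoints_mismatch_is_error(self, tmp_path):
        p = tmp_path / "n.jdx"
        p.write_text(JCAMP_MIN.replace("##NPOINTS=4", "##NPOINTS=5"))
        with pytest.raises(SpectraIOError, match="NPOINTS"):
            read_jcampdx(p)


class TestSampleTable:
    def test_whitespace_in_labels_trimmed(self, tmp_path):
        p = _write(tmp_path, "t.tsv", "sample_id\tgroup\na\tpreterm \nb\t term\n")
        table = read_sample_table(p)
        assert list(table.groups) == ["preterm", "term"]

    def test_unknown_label_rejected(self, tmp_path):
        p = _write(tmp_path, "t.tsv", "sample_id\tgroup\na\tcontrol\n")
        with pytest.raises(SpectraIOError, match="control"):
            read_sample_table(p)

    def test_duplicate_ids_rejected(self):
        with pytest.raises(SpectraIOError, match="duplicate"):
            SampleTable(pd.DataFrame({"sample_id": ["a", "a"],
                                      "group": ["preterm", "term"]}))

    def test_id_mismatch_lists_orphans(self):
        table = SampleTable(pd.DataFrame(
            {"sample_id": ["a", "b"], "group": ["preterm", "term"]}))
        with pytest.raises(SpectraIOError) as err:
            table.labels_for(["a", "c"])
        assert "c" in str(err.value) and "b" in str(err.value)

    def test_labels_aligned_to_requested_order(self):
        table = SampleTable(pd.DataFrame(
            {"sample_id": ["a", "b"], "group": ["preterm", "term"]}))
        assert list(table.labels_for(["b", "a"])) == ["term", "preterm"]


class TestReport:
    def test_metrics_table_has_six_metric_columns(self, tmp_path):
        rows = [{"model": m, "accuracy": 0.7, "f1": 0.82, "fpr": 0.94,
                 "fnr": 0.06, "tpr": 0.94, "tnr": 0.06} for m in ("RF", "GBM")]
        out = tmp_path / "report.json"
        write_report(out, {"metrics": rows, "seed": 1})
        tsv = pd.read_csv(tmp_path / "report_metrics.tsv", sep="\t")
        assert list(tsv.columns) == ["model", "accuracy", "f1",
                                     "fpr", "fnr", "tpr", "tnr"]
        assert len(tsv) == 2
        assert out.exists()
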