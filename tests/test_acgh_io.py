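"""Probe-table parsing, SEG output, and model serialization round trips."""

import json

import numpy as np
import pytest

from ecbs.acgh_io import (
    FilterSpec,
    ModelFormatError,
    ProbeTableFormatError,
    chrom_sort_key,
    load_model,
    read_probe_table,
    save_model,
    write_segments,
)
from ecbs.segmentation import SegmentRecord

HEADER = "sample\tchrom\tposition\tlog2ratio"


def _write(tmp_path, text, name="probes.tsv"):
    p = tmp_path / name
    p.write_text(text)
    return p


def _record(**kw):
    base = dict(
        sample_id="s1", chrom="1", start_index=1, end_index=4,
        start_pos=100, end_pos=400, n_probes=4, seg_mean=0.5, p_value=None,
    )
    base.update(kw)
    return SegmentRecord(**base)


class TestReadProbeTable:
    def test_missing_position_dropped(self, tmp_path):
        path = _write(
            tmp_path,
            f"{HEADER}\ns1\t1\t100\t0.1\ns1\t1\t\t0.2\ns1\t1\t300\t0.3\n"
            "s1\t1\t400\t0.4\n",
        )
        series = read_probe_table(path)
        assert len(series) == 1 and series[0].n == 3

    def test_snr_filter_threshold_one(self, tmp_path):
        path = _write(
            tmp_path,
            f"{HEADER}\tsnr\n"
            "s1\t1\t100\t0.1\t2.0\ns1\t1\t200\t0.2\t0.5\n"
            "s1\t1\t300\t0.3\t0.5\ns1\t1\t400\t0.4\t1.0\n",
        )
        series = read_probe_table(path, FilterSpec(snr_min=1.0))
        np.testing.assert_array_equal(series[0].positions, [100, 400])
        unfiltered = read_probe_table(path, FilterSpec(snr_filter=False))
        assert unfiltered[0].n == 4

    def test_rows_sorted_by_position(self, tmp_path):
        path = _write(
            tmp_path,
            f"{HEADER}\ns1\t1\t300\t0.3\ns1\t1\t100\t0.1\ns1\t1\t200\t0.2\n",
        )
        series = read_probe_table(path)
        np.testing.assert_array_equal(series[0].positions, [100, 200, 300])
        np.testing.assert_allclose(series[0].values, [0.1, 0.2, 0.3])

    def test_header_required(self, tmp_path):
        path = _write(tmp_path, "a\tb\nc\td\n")
        with pytest.raises(ProbeTableFormatError):
            read_probe_table(path)

    def test_natural_chromosome_order(self, tmp_path):
        rows = "".join(
            f"s1\t{c}\t100\t0.1\ns1\t{c}\t200\t0.2\n"
            for c in ("X", "2", "10", "1")
        )
        series = read_probe_table(_write(tmp_path, f"{HEADER}\n{rows}"))
        assert [s.chrom for s in series] == ["1", "2", "10", "X"]

    def test_chrom_sort_key_ordering(self):
        chroms = ["Y", "chr3", "X", "1", "22", "MT", "10"]
        assert sorted(chroms, key=chrom_sort_key) == [
            "1", "chr3", "10", "22", "X", "Y", "MT",
        ]


class TestWriteSegments:
    def test_single_segment_row(self, tmp_path):
        out = tmp_path / "o.seg"
        write_segments([_record()], out)
        lines = out.read_text().splitlines()
        assert len(lines) == 2
        assert lines[1].split("\t") == ["s1", "1", "100", "400", "4", "0.5", "NA"]

    def test_grouped_by_sample_then_chrom(self, tmp_path):
        recs = [
            _record(sample_id="s2"),
            _record(chrom="2"),
            _record(),
        ]
        out = tmp_path / "o.seg"
        write_segments(recs, out)
        rows = [l.split("\t")[:2] for l in out.read_text().splitlines()[1:]]
        assert rows == [["s1", "1"], ["s1", "2"], ["s2", "1"]]

    def test_overlap_is_an_error(self, tmp_path):
        recs = [
            _record(),
            _record(start_index=3, end_index=6, n_probes=4),
        ]
        with pytest.raises(ValueError):
            write_segments(recs, tmp_path / "o.seg")


class TestModelRoundTrip:
    def test_bit_exact_round_trip(self, tiny_model, tmp_path):
        path = tmp_path / "m.json"
        save_model(tiny_model, path)
        back = load_model(path)
        np.testing.assert_array_equal(back.gamma_table, tiny_model.gamma_table)
        np.testing.assert_array_equal(back.sigma_table, tiny_model.sigma_table)
        np.testing.assert_array_equal(back.mu_table, tiny_model.mu_table)
        np.testing.assert_array_equal(back.n_axis, tiny_model.n_axis)
        assert back.replicates_per_cell == tiny_model.replicates_per_cell
        assert back.build_seed == tiny_model.build_seed

    def test_missing_component_named(self, tiny_model, tmp_path):
        path = tmp_path / "m.json"
        save_model(tiny_model, path)
        doc = json.loads(path.read_text())
        del doc["mu_table"]
        path.write_text(json.dumps(doc))
        with pytest.raises(ModelFormatError, match="mu_table"):
            load_model(path)

    def test_version_mismatch(self, tiny_model, tmp_path):
        path = tmp_path / "m.json"
        save_model(tiny_model, path)
        doc = json.loads(path.read_text())
        doc["format_version"] = 99
        path.write_text(json.dumps(doc))
        with pytest.raises(ModelFormatError, match="version"):
            load_model(path)

    def test_truncated_file(self, tiny_model, tmp_path):
        path = tmp_path / "m.json"
        save_model(tiny_model, path)
        path.write_text(path.read_text()[: 100])
        with pytest.raises(ModelFormatError):
            load_model(path)
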