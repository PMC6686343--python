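"""Readers, writers, validation and peak binarization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from selfmeth import core_io
from selfmeth.core_io import (
    MISSING,
    BandMatrix,
    CoreIOError,
    PipelineConfig,
    QMatrix,
    binarize_peaks,
    read_band_matrix,
    read_genotypes,
    read_parasites,
    read_qmatrix,
    write_band_matrix,
    write_genotypes,
    write_parasites,
    write_qmatrix,
)


class TestGenotypeCSV:
    def test_direct_parse_and_missing_sentinel(self, tmp_path):
        path = tmp_path / "g.csv"
        path.write_text(
            "individual_id,site,L1,L1_b,L2,L2_b\n"
            "A,s1,101,101,1,1\nB,s1,103,101,1,1\nC,s1,0,0,1,2\n"
        )
        g = read_genotypes(path)
        assert g.loci_ids == ["L1", "L2"]
        assert tuple(g.calls[0, 0]) == (101, 101)
        # unordered pair canonicalized to (min, max)
        assert tuple(g.calls[1, 0]) == (101, 103)
        # the 0/0 pair is the missing-call sentinel
        assert tuple(g.calls[2, 0]) == (MISSING, MISSING)

    def test_roundtrip_identity(self, tiny_genotypes, tmp_path):
        path = tmp_path / "g.csv"
        write_genotypes(tiny_genotypes, path)
        back = read_genotypes(path)
        assert back.individual_ids == tiny_genotypes.individual_ids
        assert back.site_labels == tiny_genotypes.site_labels
        np.testing.assert_array_equal(back.calls, tiny_genotypes.calls)

    @pytest.mark.parametrize(
        "body",
        [
            "A,s1,101,101\nA,s1,101,101\n",  # duplicate ids
            "A,s1,-5,101\n",  # negative allele code
        ],
    )
    def test_malformed_rows_rejected(self, tmp_path, body):
        path = tmp_path / "bad.csv"
        path.write_text("individual_id,site,L1,L1_b\n" + body)
        with pytest.raises(CoreIOError):
            read_genotypes(path)

    def test_odd_allele_columns_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("individual_id,site,L1,L1_b,L2\nA,s1,1,1,2\n")
        with pytest.raises(CoreIOError, match="odd"):
            read_genotypes(path)


class TestBandMatrix:
    def test_half_missing_promoted(self, caplog):
        hpa = np.array([[1, MISSING]], dtype=np.int8)
        msp = np.array([[1, 1]], dtype=np.int8)
        b = BandMatrix(["A"], ["L1", "L2"], hpa, msp)
        assert b.hpa[0, 1] == MISSING and b.msp[0, 1] == MISSING

    def test_roundtrip(self, tmp_path):
        b = BandMatrix(
            ["A", "B"],
            ["L1", "L2"],
            np.array([[1, 0], [MISSING, 1]], dtype=np.int8),
            np.array([[0, 1], [MISSING, 0]], dtype=np.int8),
        )
        path = tmp_path / "b.csv"
        write_band_matrix(b, path)
        back = read_band_matrix(path)
        np.testing.assert_array_equal(back.hpa, b.hpa)
        np.testing.assert_array_equal(back.msp, b.msp)

    def test_non_binary_cells_rejected(self, tmp_path):
        path = tmp_path / "b.csv"
        path.write_text(
            "individual_id,digest,L1\nA,HPA,2\nA,MSP,1\n"
        )
        with pytest.raises(CoreIOError, match="non-binary"):
            read_band_matrix(path)


class TestQMatrixAndParasites:
    def test_q_row_accepted_and_normalized(self, tmp_path):
        path = tmp_path / "q.csv"
        path.write_text("individual_id,c1,c2\nA,0.28,0.72\nB,0.5005,0.5\n")
        q = read_qmatrix(path)
        np.testing.assert_allclose(q.q.sum(axis=1), 1.0)

    def test_q_row_sum_violation(self, tmp_path):
        path = tmp_path / "q.csv"
        path.write_text("individual_id,c1,c2\nA,0.6,0.6\n")
        with pytest.raises(CoreIOError, match="sum 1"):
            read_qmatrix(path)

    def test_negative_parasite_count_rejected(self, tmp_path):
        path = tmp_path / "p.csv"
        path.write_text("individual_id,cysts\nA,-1\n")
        with pytest.raises(CoreIOError):
            read_parasites(path)

    def test_parasite_roundtrip(self, tmp_path, study_dataset):
        *_, parasites, _ = study_dataset[:4], study_dataset[4]
        table = study_dataset[3]
        path = tmp_path / "p.csv"
        write_parasites(table, path)
        back = read_parasites(path)
        pd.testing.assert_frame_equal(back.counts, table.counts)


class TestBinarizePeaks:
    def make_peaks(self, rows):
        return pd.DataFrame(
            rows, columns=["individual_id", "digest", "fragment_size", "peak_height"]
        )

    @pytest.mark.parametrize(
        "size,height,expected",
        [
            (150.2, 250.0, 1),  # valid peak in bin
            (150.2, 99.0, 0),  # below minimum height
            (99.5, 500.0, 0),  # outside the 100-500 bp analysis range
        ],
    )
    def test_single_peak_rules(self, config, size, height, expected):
        peaks = self.make_peaks(
            [("A", "HPA", size, height), ("A", "MSP", 150.5, 200.0)]
        )
        bins = [("L1", 150.0, 151.0)]
        b = binarize_peaks(peaks, config, bins)
        assert b.hpa[0, 0] == expected

    def test_absent_digest_gives_missing(self, config):
        peaks = self.make_peaks([("A", "HPA", 150.2, 250.0)])
        b = binarize_peaks(peaks, config, [("L1", 150.0, 151.0)])
        # no MSP records at all -> missing, promoted to both digests
        assert b.hpa[0, 0] == MISSING and b.msp[0, 0] == MISSING

    def test_overlapping_bins_rejected(self, config):
        peaks = self.make_peaks([("A", "HPA", 150.2, 250.0)])
        with pytest.raises(CoreIOError, match="overlap"):
            binarize_peaks(peaks, config, [("L1", 150.0, 152.0), ("L2", 151.0, 153.0)])

    @settings(max_examples=30, deadline=None)
    @given(
        st.lists(
            st.tuples(
                st.floats(min_value=100.0, max_value=499.9),
                st.floats(min_value=1.0, max_value=1000.0),
            ),
            min_size=1,
            max_size=12,
        ),
        st.tuples(
            st.floats(min_value=100.0, max_value=498.0),
            st.floats(min_value=100.0, max_value=1000.0),
        ),
    )
    def test_adding_a_peak_is_monotone(self, peak_list, extra):
        """Adding one more peak never turns a scored band from 1 to 0."""
        config = PipelineConfig()
        bins = [(f"L{i}", 100.0 + 40 * i, 140.0 + 40 * i) for i in range(10)]
        rows = [("A", "HPA", s, h) for s, h in peak_list]
        rows += [("A", "MSP", 200.0, 500.0)]
        before = binarize_peaks(pd.DataFrame(rows, columns=["individual_id", "digest", "fragment_size", "peak_height"]), config, bins)
        rows_after = rows + [("A", "HPA", extra[0], extra[1])]
        after = binarize_peaks(pd.DataFrame(rows_after, columns=["individual_id", "digest", "fragment_size", "peak_height"]), config, bins)
        assert not ((before.hpa == 1) & (after.hpa == 0)).any()


class TestPipelineConfig:
    def test_yaml_roundtrip(self, tmp_path):
        cfg = PipelineConfig(error_threshold=0.1, n_permutations=999)
        path = tmp_path / "cfg.yaml"
        cfg.to_yaml(path)
        assert PipelineConfig.from_yaml(path) == cfg

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"error_threshold": 0.0},
            {"q_threshold": 1.5},
            {"n_permutations": 10},
        ],
    )
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(CoreIOError):
            PipelineConfig(**kwargs)
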