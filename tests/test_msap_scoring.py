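"""Methylation-state encoding, MSL/NML classification and summaries."""

import numpy as np
import pytest

from selfmeth.core_io import MISSING, BandMatrix
from selfmeth.msap_scoring import (
    MethylationStateMatrix,
    State,
    classify_loci,
    encode_states,
    group_methylation_percentage,
    methylation_proportion,
    msl_binary_matrix,
    replicate_error_rate,
)


def bands_from(hpa, msp, ids=None, loci=None):
    hpa = np.asarray(hpa, dtype=np.int8)
    ids = ids or [f"i{k}" for k in range(hpa.shape[0])]
    loci = loci or [f"L{j}" for j in range(hpa.shape[1])]
    return BandMatrix(ids, loci, hpa, np.asarray(msp, dtype=np.int8))


def states_from(codes):
    codes = np.asarray(codes, dtype=np.int8)
    return MethylationStateMatrix(
        [f"i{k}" for k in range(codes.shape[0])],
        [f"L{j}" for j in range(codes.shape[1])],
        codes,
    )


class TestEncodeStates:
    @pytest.mark.parametrize(
        "hpa,msp,expected",
        [
            (1, 1, State.UNMETHYLATED),
            (1, 0, State.HEMI),
            (0, 1, State.INTERNAL),
            (0, 0, State.AMBIGUOUS),
            (MISSING, MISSING, MISSING),
        ],
    )
    def test_band_pattern_mapping(self, hpa, msp, expected):
        b = bands_from([[hpa]], [[msp]])
        assert encode_states(b).states[0, 0] == expected

    def test_recovers_simulator_states(self, study_dataset):
        """Encoding the emitted bands recovers the simulator's methylation
        calls wherever cells are neither ambiguous nor missing."""
        _, bands, _, _, truth = study_dataset
        states = encode_states(bands)
        n_msl = len(truth.msl_loci)
        S = states.states[:, :n_msl]
        informative = (S == State.UNMETHYLATED) | (S == State.HEMI) | (S == State.INTERNAL)
        meth_frac = ((S == State.HEMI) | (S == State.INTERNAL))[informative].mean()
        exp = truth.per_individual["methylation_p"].mean()
        assert meth_frac == pytest.approx(exp, abs=0.02)


class TestClassifyLoci:
    def test_all_unmethylated_is_nml(self):
        m = states_from(np.zeros((100, 1)))
        assert classify_loci(m).table.iloc[0]["class"] == "NML"

    def test_ten_percent_hemi_is_msl(self):
        col = np.zeros((100, 1));  col[:10] = State.HEMI
        cls = classify_loci(states_from(col))
        assert cls.table.iloc[0]["class"] == "MSL"
        assert cls.table.iloc[0]["pattern_freq"] == pytest.approx(0.10)

    def test_exactly_at_threshold_is_nml(self):
        """Frequency must strictly exceed the 5% error threshold."""
        col = np.zeros((100, 1)); col[:5] = State.HEMI
        assert classify_loci(states_from(col)).table.iloc[0]["class"] == "NML"

    def test_all_missing_locus_dropped(self):
        codes = np.full((5, 2), MISSING); codes[:, 0] = State.HEMI
        cls = classify_loci(states_from(codes))
        assert cls.dropped == ["L1"] and list(cls.table.index) == ["L0"]

    def test_recovers_simulator_partition(self):
        """MSL/NML recovery error stays under 2% at N=500, default rates."""
        import pandas as pd
        from selfmeth.synthetic_data import SimulationConfig, simulate

        occ = pd.DataFrame([[500]], index=["site1"], columns=["lineage1"])
        cfg = SimulationConfig(
            occupancy=occ,
            n_msap_loci=381,
            fraction_msl=0.70,
            lineage_baseline_logit=np.array([-0.3]),
            rng_seed=42,
        )
        _, bands, _, _, truth = simulate(cfg)
        cls = classify_loci(encode_states(bands))
        called_msl = set(cls.msl_loci)
        true_msl = set(truth.msl_loci)
        all_loci = set(cls.table.index)
        wrong = (called_msl ^ true_msl) & all_loci
        assert len(wrong) / len(all_loci) <= 0.02


class TestMethylationProportion:
    def test_half_methylated(self):
        m = states_from([[State.HEMI, State.INTERNAL, State.UNMETHYLATED, State.UNMETHYLATED]])
        assert methylation_proportion(m)["proportion"].iloc[0] == 0.5

    def test_ambiguous_and_missing_excluded(self):
        m = states_from([[State.HEMI, State.AMBIGUOUS, MISSING, State.UNMETHYLATED]])
        out = methylation_proportion(m)
        assert out["scored"].iloc[0] == 2
        assert out["proportion"].iloc[0] == 0.5

    def test_zero_scored_is_missing(self):
        m = states_from([[State.AMBIGUOUS, MISSING]])
        assert np.isnan(methylation_proportion(m)["proportion"].iloc[0])

    def test_invariant_to_row_and_column_order(self, study_dataset):
        _, bands, _, _, _ = study_dataset
        m = encode_states(bands)
        base = methylation_proportion(m)
        rng = np.random.default_rng(0)
        perm_l = rng.permutation(len(m.loci_ids))
        perm_i = rng.permutation(len(m.individual_ids))
        shuffled = MethylationStateMatrix(
            [m.individual_ids[i] for i in perm_i],
            [m.loci_ids[j] for j in perm_l],
            m.states[np.ix_(perm_i, perm_l)],
        )
        out = methylation_proportion(shuffled).loc[base.index]
        np.testing.assert_allclose(
            out["proportion"].to_numpy(), base["proportion"].to_numpy()
        )


class TestGroupPercentage:
    def test_ratio_reading(self):
        # 10 methylated-pattern cells, 20 cells in the denominator classes
        codes = np.array([[State.HEMI] * 10 + [State.UNMETHYLATED] * 15 + [State.AMBIGUOUS] * 5])
        m = states_from(codes)
        pct = group_methylation_percentage(m, ["g"], method="ratio")
        assert pct["g"] == pytest.approx(50.0)

    def test_no_methylated_patterns_is_zero(self):
        m = states_from([[State.UNMETHYLATED, State.AMBIGUOUS]])
        assert group_methylation_percentage(m, ["g"])["g"] == 0.0

    def test_two_readings_differ_when_ambiguous_present(self):
        codes = np.array([[State.HEMI] * 10 + [State.UNMETHYLATED] * 15 + [State.AMBIGUOUS] * 5])
        m = states_from(codes)
        ratio = group_methylation_percentage(m, ["g"], method="ratio")["g"]
        prop = group_methylation_percentage(m, ["g"], method="proportion")["g"]
        assert ratio == pytest.approx(100 * 10 / 20)
        assert prop == pytest.approx(100 * 10 / 30)
        assert ratio != prop


class TestReplicateErrorRate:
    def test_identical_matrices_zero(self):
        b = bands_from([[1, 0], [0, 1]], [[1, 1], [0, 0]])
        assert replicate_error_rate(b, b) == 0.0

    def test_formula_one_mismatch(self):
        """1 mismatching cell over 100 loci x 2 individuals -> 0.005."""
        rng = np.random.default_rng(1)
        hpa = rng.integers(0, 2, size=(2, 100)).astype(np.int8)
        msp = rng.integers(0, 2, size=(2, 100)).astype(np.int8)
        orig = bands_from(hpa, msp)
        h2 = hpa.copy(); h2[0, 0] = 1 - h2[0, 0]
        rep = bands_from(h2, msp)
        assert replicate_error_rate(orig, rep) == pytest.approx(0.005)

    def test_all_flipped_is_one(self):
        hpa = np.ones((2, 10), dtype=np.int8); msp = np.zeros((2, 10), dtype=np.int8)
        orig = bands_from(hpa, msp)
        rep = bands_from(1 - hpa, 1 - msp)
        assert replicate_error_rate(orig, rep) == 1.0

    def test_no_shared_loci_raises(self):
        a = bands_from([[1]], [[1]], loci=["A"])
        b = bands_from([[1]], [[1]], loci=["B"])
        with pytest.raises(ValueError, match="shared"):
            replicate_error_rate(a, b)
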