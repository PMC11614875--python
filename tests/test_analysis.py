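import types

import numpy as np
import pandas as pd
import pytest

from oracles import mann_whitney_exact

from micromet.analysis import (
    ClassifierThresholds,
    classify_outcome,
    compress_trajectory,
    consensus_labels,
    mann_whitney_u,
    sensitivity_table,
    thresholds_for_population,
)
from micromet.errors import ConfigurationError
from micromet.virtual_patients import PatientParameterSet


class TestClassifier:
    def test_default_thresholds(self):
        thr = ClassifierThresholds()
        assert (thr.T_SC, thr.T_NC) == (100.0, 1500.0)

    @pytest.mark.parametrize(
        "pm,label",
        [(0, "SC"), (99, "SC"), (100, "MC"), (800, "MC"), (1500, "MC"), (1501, "NC")],
    )
    def test_truth_table(self, pm, label):
        assert classify_outcome(pm) == label

    def test_population_derived_thresholds(self):
        thr = thresholds_for_population(560)
        assert thr.T_SC == pytest.approx(28.0)
        assert thr.T_NC == pytest.approx(420.0)

    def test_label_monotone_in_population(self):
        order = {"SC": 0, "MC": 1, "NC": 2}
        labels = [order[classify_outcome(pm)] for pm in range(0, 2500, 7)]
        assert (np.diff(labels) >= 0).all()

    def test_invalid_thresholds_rejected(self):
        with pytest.raises(ConfigurationError):
            ClassifierThresholds(T_SC=200.0, T_NC=100.0)


class TestConsensus:
    def test_consistent_patient(self):
        assert consensus_labels(["SC"] * 10) == {"SC"}

    def test_mixed_replicates(self):
        labels = ["NC", "NC", "MC", "SC", "NC", "MC", "NC", "NC", "SC", "NC"]
        assert consensus_labels(labels) == {"NC", "MC", "SC"}

    def test_empty_rejected(self):
        with pytest.raises(ConfigurationError):
            consensus_labels([])


def synthetic_trajectory(n_snapshots, cells_per_snapshot, domain=380.0, radius=8.4, seed=0):
    """A hand-built trajectory object: random live cells of the three groups."""
    rng = np.random.default_rng(seed)
    tables = []
    for _ in range(n_snapshots):
        rows = []
        for ctype, count in cells_per_snapshot.items():
            for _ in range(count):
                x, y = rng.uniform(0, domain, 2)
                rows.append((ctype, x, y, True))
        tables.append(
            pd.DataFrame(rows, columns=["type", "x", "y", "alive"]).astype(
                {"x": float, "y": float, "alive": bool}
            )
        )
    return types.SimpleNamespace(
        n_snapshots=n_snapshots,
        cell_tables=tables,
        config=types.SimpleNamespace(domain_size=domain, cell_radius=radius),
    )


class TestCompression:
    def test_default_run_dimensionality(self):
        traj = synthetic_trajectory(31, {"cancer": 10, "macrophage": 5, "parenchymal": 50})
        feats = compress_trajectory(traj)
        assert len(feats.vector) == 2325
        assert feats.thumbnails.shape == (31, 5, 5, 3)
        assert (feats.vector >= 0).all() and (feats.vector <= 1).all()

    def test_empty_world_is_all_zero(self):
        traj = synthetic_trajectory(4, {})
        assert not compress_trajectory(traj).vector.any()

    def test_single_snapshot_length(self):
        traj = synthetic_trajectory(1, {"cancer": 3})
        assert len(compress_trajectory(traj).vector) == 5 * 5 * 3

    def test_normalization_linearity(self):
        """Doubling counts and carrying density together leaves features fixed;
        doubling counts alone scales unsaturated bins by two."""
        one = synthetic_trajectory(3, {"cancer": 8}, seed=7)
        two = types.SimpleNamespace(
            n_snapshots=3,
            cell_tables=[pd.concat([t, t]) for t in one.cell_tables],
            config=one.config,
        )
        base = compress_trajectory(one, carrying_density=40.0).vector
        doubled_both = compress_trajectory(two, carrying_density=80.0).vector
        assert np.allclose(doubled_both, base)
        doubled_counts = compress_trajectory(two, carrying_density=40.0).vector
        unsaturated = doubled_counts < 1.0
        assert np.allclose(doubled_counts[unsaturated], 2.0 * base[unsaturated])


class TestMannWhitney:
    def test_identical_samples_centered(self):
        u, p = mann_whitney_u([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert u == pytest.approx(4.5)  # nm/2
        assert p == pytest.approx(1.0, abs=1e-6)

    def test_fully_separated_small_case(self):
        u, p = mann_whitney_u([1.0, 2.0], [3.0, 4.0])
        assert u in (0.0, 4.0)
        assert p == pytest.approx(1.0 / 3.0)

    def test_agreement_with_enumeration_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(200):
            n = int(rng.integers(2, 6))
            m = int(rng.integers(2, 6))
            a = rng.normal(size=n)
            b = rng.normal(rng.uniform(-2, 2), size=m)
            u_impl, p_impl = mann_whitney_u(a, b)
            u_oracle, p_oracle = mann_whitney_exact(a, b)
            assert u_impl == pytest.approx(u_oracle, abs=1e-12)
            assert p_impl == pytest.approx(min(1.0, p_oracle), abs=1e-12)

    def test_empty_sample_rejected(self):
        with pytest.raises(ConfigurationError):
            mann_whitney_u([], [1.0])


def make_cohort(n_per_class, rng, shift=None):
    """Synthetic labeled patients; optionally shift one parameter's NC values."""
    names = ["r_recruit_M", "r_recruit_D", "delta_C", "r_leave"]
    out = []
    for label, n in (("NC", n_per_class), ("SC", n_per_class)):
        for _ in range(n):
            values = {k: float(rng.normal()) for k in names}
            if shift and label == "NC":
                values[shift[0]] += shift[1]
            out.append((PatientParameterSet(len(out), values), label))
    return out


class TestSensitivity:
    def test_constructed_separability_ranks_first(self):
        rng = np.random.default_rng(3)
        names = ["r_recruit_M", "r_recruit_D", "delta_C", "r_leave"]
        patients = []
        for k in range(60):
            values = {n: float(rng.normal()) for n in names}
            label = "NC" if values["r_recruit_M"] < 0.0 else "SC"
            patients.append((PatientParameterSet(k, values), label))
        table = sensitivity_table(patients)
        assert table.iloc[0]["parameter"] == "r_recruit_M"
        assert table.iloc[0]["significant"]
        assert (table["p_value"].diff().dropna() >= 0).all()  # ascending order

    def test_large_location_shift_is_detected(self):
        rng = np.random.default_rng(4)
        # shift ≈ 3 interquartile ranges of a standard normal (IQR ≈ 1.35)
        patients = make_cohort(50, rng, shift=("delta_C", 3 * 1.349))
        table = sensitivity_table(patients)
        row = table[table["parameter"] == "delta_C"].iloc[0]
        assert row["p_value"] < 1e-4

    def test_type_one_error_calibration_under_random_labels(self):
        rng = np.random.default_rng(5)
        flagged = total = 0
        for _ in range(300):
            patients = make_cohort(30, rng)
            table = sensitivity_table(patients)
            flagged += int(table["significant"].sum())
            total += len(table)
        assert 0.02 <= flagged / total <= 0.08  # ≈ α = 0.05

    def test_missing_class_rejected(self):
        rng = np.random.default_rng(6)
        patients = [(p, "NC") for p, _ in make_cohort(5, rng)]
        with pytest.raises(ConfigurationError):
            sensitivity_table(patients)
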