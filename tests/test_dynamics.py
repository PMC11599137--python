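"""Morphoclass assignment, distributions, transition statistics, indices."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from gscmorph.dynamics import (
    MORPHOCLASSES,
    ClassifierConfig,
    interphase_transitions,
    invasion_index,
    mitotic_inheritance,
    morphoclass_distribution,
    mst_length,
    ttc_density,
)
from gscmorph.errors import ValidationError
from gscmorph.pipeline import analyze_cell
from gscmorph.synth.cells import CellSpec, ProtrusionSpec, generate_cell_mask
from gscmorph.synth.tracks import TrackSimSpec, generate_tracks


def _track_df(rows):
    return pd.DataFrame(
        rows, columns=["cell_id", "parent_id", "frame", "class", "x_px", "y_px", "mitosis"]
    )


def _archetype(kind, seed=0):
    """Build a synthetic cell whose intended morphoclass is unambiguous."""
    rng = np.random.default_rng(seed)
    j = lambda lo, hi: float(rng.uniform(lo, hi))
    if kind == "nonpolar":
        spec = CellSpec(soma_radius_px=j(10, 14), image_shape=(64, 64))
    elif kind == "elongated":
        prot = ProtrusionSpec(origin_angle=0.0, segments=[(j(45, 55), 0.0)], width_px=1.5)
        spec = CellSpec(
            soma_radius_px=j(7, 9),
            soma_aspect=3.5,
            protrusions=[prot],
            image_shape=(192, 192),
        )
    elif kind == "circular_multipolar":
        n = int(rng.integers(4, 7))
        prots = [
            ProtrusionSpec(
                origin_angle=2 * np.pi * i / n + j(-0.15, 0.15),
                segments=[(j(12, 18), 0.0)],
                width_px=1.5,
            )
            for i in range(n)
        ]
        spec = CellSpec(soma_radius_px=j(9, 11), protrusions=prots, image_shape=(96, 96))
    else:  # flat_polar
        prots = [
            ProtrusionSpec(origin_angle=0.3, segments=[(j(15, 22), 0.0)], width_px=1.5),
            ProtrusionSpec(origin_angle=3.1, segments=[(j(15, 22), 0.0)], width_px=1.5),
        ]
        spec = CellSpec(soma_radius_px=j(21, 24), protrusions=prots, image_shape=(128, 128))
    mask, truth = generate_cell_mask(spec, seed=seed)
    return mask, truth


class TestClassifier:
    def test_no_protrusions_is_always_nonpolar(self):
        mask, _ = _archetype("nonpolar")
        assert analyze_cell(mask).morphoclass == "nonpolar"

    @pytest.mark.parametrize("kind", MORPHOCLASSES)
    def test_archetypes_classify_as_intended(self, kind):
        mask, truth = _archetype(kind, seed=3)
        assert truth.intended_morphoclass == kind
        assert analyze_cell(mask).morphoclass == kind

    def test_archetype_panel_agreement(self):
        """Classifier agrees with generator intent on a 60-cell panel."""
        hits = total = 0
        for seed in range(15):
            for kind in MORPHOCLASSES:
                mask, truth = _archetype(kind, seed=seed)
                total += 1
                hits += analyze_cell(mask).morphoclass == truth.intended_morphoclass
        assert hits / total >= 0.9

    def test_invalid_config_rejected(self):
        with pytest.raises(ValidationError):
            ClassifierConfig(ecc_threshold=1.2).validate()


class TestDistribution:
    def test_single_class_replicate(self):
        per_rep, summary = morphoclass_distribution([["elongated"] * 5])
        assert per_rep.loc[0, "elongated"] == 1.0
        assert per_rep.loc[0, "nonpolar"] == 0.0

    def test_mean_over_two_replicates(self):
        reps = [
            ["nonpolar"] * 2 + ["flat_polar"] * 2,
            ["circular_multipolar"] * 2 + ["elongated"] * 2,
        ]
        _per, summary = morphoclass_distribution(reps)
        assert np.allclose(summary["mean"].to_numpy(), 0.25)

    def test_rows_sum_to_one_and_empty_replicates_excluded(self):
        with pytest.warns(UserWarning, match="empty"):
            per_rep, _ = morphoclass_distribution([["nonpolar", "elongated"], []])
        assert len(per_rep) == 1
        assert per_rep.sum(axis=1).to_numpy() == pytest.approx(1.0)


class TestTransitions:
    def test_constant_track_gives_identity_row(self):
        df = _track_df(
            [(1, None, f, "elongated", 0.0, 0.0, False) for f in range(5)]
        )
        tm, change = interphase_transitions(df)
        assert tm.counts.loc["elongated", "elongated"] == 4
        assert tm.proportions.loc["elongated", "elongated"] == 1.0
        assert change["elongated"] == 0.0

    def test_hand_built_transition_counts(self):
        df = _track_df(
            [
                (1, None, 0, "nonpolar", 0, 0, False),
                (1, None, 1, "nonpolar", 0, 0, False),
                (1, None, 2, "elongated", 0, 0, False),
            ]
        )
        tm, change = interphase_transitions(df)
        assert tm.counts.loc["nonpolar", "nonpolar"] == 1
        assert tm.counts.loc["nonpolar", "elongated"] == 1
        assert change["nonpolar"] == 1.0

    def test_step_into_mitosis_frame_is_excluded(self):
        df = _track_df(
            [
                (1, None, 0, "nonpolar", 0, 0, False),
                (1, None, 1, "elongated", 0, 0, True),
                (2, 1, 2, "flat_polar", 0, 0, False),
            ]
        )
        tm, _ = interphase_transitions(df)
        assert tm.counts.to_numpy().sum() == 0

    def test_simulated_tracks_recover_planted_matrix(self, markov_matrices):
        trans, _ = markov_matrices
        tracks = generate_tracks(
            TrackSimSpec(
                n_cells=400, n_frames=80, transition_matrix=trans, mitosis_rate=0.0, seed=5
            )
        )
        tm, _ = interphase_transitions(tracks)
        n = tm.row_totals.to_numpy()[:, None]
        se = np.sqrt(trans * (1 - trans) / n)
        assert np.all(np.abs(tm.proportions.to_numpy() - trans) <= 3 * np.maximum(se, 1e-12))
        assert np.allclose(tm.proportions.sum(axis=1), 1.0, atol=1e-12)


class TestInheritance:
    def test_two_elongated_daughters(self):
        df = _track_df(
            [
                (1, None, 0, "elongated", 0, 0, True),
                (2, 1, 1, "elongated", 0, 0, False),
                (3, 1, 1, "elongated", 0, 0, False),
            ]
        )
        tm = mitotic_inheritance(df)
        assert tm.proportions.loc["elongated", "elongated"] == 1.0
        assert tm.counts.attrs["mothers"]["elongated"] == 1
        assert tm.row_totals["elongated"] == 2

    def test_mixed_daughters_split_fifty_fifty(self):
        df = _track_df(
            [
                (1, None, 0, "nonpolar", 0, 0, True),
                (2, 1, 1, "flat_polar", 0, 0, False),
                (3, 1, 1, "elongated", 0, 0, False),
            ]
        )
        tm = mitotic_inheritance(df)
        assert tm.proportions.loc["nonpolar", "flat_polar"] == 0.5
        assert tm.proportions.loc["nonpolar", "elongated"] == 0.5

    def test_orphan_daughter_raises_with_ids(self):
        df = _track_df(
            [
                (1, None, 0, "nonpolar", 0, 0, False),
                (2, 1, 1, "flat_polar", 0, 0, False),
            ]
        )
        with pytest.raises(ValidationError, match=r"\[2\]"):
            mitotic_inheritance(df)

    def test_simulated_inheritance_recovers_planted_matrix(self, markov_matrices):
        trans, inherit = markov_matrices
        tracks = generate_tracks(
            TrackSimSpec(
                n_cells=400,
                n_frames=80,
                transition_matrix=trans,
                mitosis_rate=0.02,
                inheritance_matrix=inherit,
                seed=6,
            )
        )
        tm = mitotic_inheritance(tracks)
        n = np.maximum(tm.row_totals.to_numpy()[:, None], 1)
        se = np.sqrt(inherit * (1 - inherit) / n)
        assert np.all(np.abs(tm.proportions.to_numpy() - inherit) <= 3 * np.maximum(se, 1e-12))
        # mother counts across classes equal the number of mitosis rows
        assert tm.counts.attrs["mothers"].sum() == int(tracks["mitosis"].sum())


class TestScalarMeasures:
    def test_mst_pythagorean_displacement(self):
        df = _track_df(
            [
                (1, None, 0, "nonpolar", 0.0, 0.0, False),
                (1, None, 1, "nonpolar", 3.0, 4.0, True),
            ]
        )
        assert mst_length(df, pixel_size_um=0.5) == pytest.approx(2.5)
        still = _track_df(
            [
                (1, None, 0, "nonpolar", 2.0, 2.0, False),
                (1, None, 1, "nonpolar", 2.0, 2.0, True),
            ]
        )
        assert mst_length(still) == 0.0

    def test_mst_at_first_frame_is_flagged_undefined(self):
        df = _track_df([(1, None, 0, "nonpolar", 0.0, 0.0, True)])
        with pytest.warns(UserWarning, match="undefined"):
            assert mst_length(df) is None

    def test_mean_mst_matches_rayleigh_step_length(self):
        sd = 2.0
        tracks = generate_tracks(
            TrackSimSpec(
                n_cells=300,
                n_frames=30,
                transition_matrix=np.eye(4),
                mitosis_rate=0.05,
                inheritance_matrix=np.full((4, 4), 0.25),
                nucleus_step_sd_px=sd,
                seed=8,
            )
        )
        ms = []
        for cid in tracks.loc[tracks["mitosis"], "cell_id"]:
            val = mst_length(tracks[tracks["cell_id"] == cid])
            if val is not None:
                ms.append(val)
        expected = sd * np.sqrt(np.pi / 2)  # mean of a Rayleigh step
        rayleigh_sd = sd * np.sqrt(2 - np.pi / 2)
        assert np.mean(ms) == pytest.approx(
            expected, abs=3 * rayleigh_sd / np.sqrt(len(ms))
        )

    @given(
        n=st.integers(min_value=0, max_value=50),
        perimeter=st.floats(min_value=1.0, max_value=1e4),
    )
    def test_ttc_density_is_linear(self, n, perimeter):
        assert ttc_density(n, perimeter) == pytest.approx(n / perimeter * 100.0)

    def test_ttc_density_examples_and_errors(self):
        assert ttc_density(2, 100.0) == 2.0
        assert ttc_density(0, 73.0) == 0.0
        assert ttc_density(3, 150.0) == 2.0
        with pytest.raises(ValidationError):
            ttc_density(1, 0.0)

    @given(
        core=st.floats(min_value=1e-3, max_value=1e6),
        factor=st.floats(min_value=1.0, max_value=1e3),
    )
    def test_invasion_index_matches_division_and_reciprocal(self, core, factor):
        total = core * factor
        idx = invasion_index(core, total)
        assert idx == pytest.approx(total / core)
        assert idx >= 1.0
        assert invasion_index(core, total, core_over_total=True) == pytest.approx(
            1.0 / idx
        )

    def test_invasion_index_rejects_core_larger_than_total(self):
        with pytest.raises(ValidationError):
            invasion_index(10.0, 5.0)
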