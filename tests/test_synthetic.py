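"""Simulator, renderer and annotation-fixture generator."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from allelenoise import (
    GeometryError,
    NucleusGeometry,
    ParameterError,
    SimulationParams,
    classify_intronless,
    expected_intrinsic_noise,
    generate_annotation_fixture,
    normalize_per_experiment,
    parse_gff3,
    per_cell_intrinsic_noise,
    render_image_stack,
    simulate_population,
)


class TestSimulatePopulation:
    def test_all_noise_off_is_deterministic_diagonal(self, quiet_params):
        cells, truth = simulate_population(quiet_params)
        assert np.allclose(cells["x"], 5.0)
        assert np.allclose(cells["y"], 5.0)
        assert (truth["active_copies_red"] == quiet_params.ploidy_N).all()

    def test_full_silencing_gives_zero_signal(self):
        params = SimulationParams(silencing_q=1.0, measurement_sd=0.0, seed=1)
        cells, truth = simulate_population(params)
        assert (cells["x"] == 0).all() and (cells["y"] == 0).all()
        assert (truth["active_copies_red"] == 0).all()

    def test_identical_seed_reproduces_identical_dataset(self):
        p = SimulationParams(seed=42)
        c1, t1 = simulate_population(p)
        c2, t2 = simulate_population(SimulationParams(seed=42))
        pd.testing.assert_frame_equal(c1, c2)
        pd.testing.assert_frame_equal(t1, t2)
        assert c1.to_csv(index=False) == c2.to_csv(index=False)

    def test_population_mean_matches_law_of_large_numbers(self):
        q, gain, base = 0.2, 2.0, 100.0
        # log-normal factors have unit median, not unit mean, so the clean
        # LLN target applies with the dispersion factors off
        p = SimulationParams(
            n_experiments=1, cells_per_experiment=40000, silencing_q=q,
            gain_red=gain, base_expression=base, measurement_sd=0.0,
            sigma_extrinsic=0.0, sigma_intrinsic=0.0, seed=5,
        )
        cells, _ = simulate_population(p)
        x = cells["x"].to_numpy()
        target = gain * base * (1 - q)
        se = x.std(ddof=1) / np.sqrt(x.size)
        assert abs(x.mean() - target) < 3 * se

    def test_experiment_and_cell_ids_are_unique_pairs(self):
        cells, _ = simulate_population(SimulationParams(seed=2))
        assert not cells.duplicated(["experiment_id", "cell_id"]).any()

    def test_per_experiment_gains_are_applied(self):
        p = SimulationParams(
            n_experiments=2, cells_per_experiment=10, silencing_q=0.0,
            sigma_extrinsic=0.0, sigma_intrinsic=0.0, measurement_sd=0.0,
            gain_red=[1.0, 3.0], base_expression=10.0, seed=0,
        )
        cells, _ = simulate_population(p)
        assert np.allclose(cells.loc[cells.experiment_id == "exp1", "x"], 10.0)
        assert np.allclose(cells.loc[cells.experiment_id == "exp2", "x"], 30.0)

    @pytest.mark.parametrize(
        "field,value",
        [
            ("silencing_q", 1.5),
            ("ploidy_N", 0),
            ("sigma_extrinsic", -0.1),
            ("gain_red", 0.0),
            ("measurement_sd", -1.0),
            ("base_expression", 0.0),
        ],
    )
    def test_invalid_parameters_name_the_field(self, field, value):
        with pytest.raises(ParameterError, match=field):
            SimulationParams(**{field: value})


class TestExpectedIntrinsicNoise:
    @pytest.mark.parametrize(
        "N,q,expected",
        [(2, 0.0, 0.0), (2, 0.2, 0.125), (32, 0.2, 0.0078125), (1, 0.5, 1.0)],
    )
    def test_closed_form_values(self, N, q, expected):
        assert expected_intrinsic_noise(N, q) == pytest.approx(expected)

    def test_complete_silencing_is_out_of_domain(self):
        with pytest.raises(ParameterError):
            expected_intrinsic_noise(2, 1.0)

    @pytest.mark.parametrize("N,q", [(1, 0.2), (2, 0.2), (8, 0.05), (8, 0.5)])
    def test_monte_carlo_agreement_pure_silencing(self, N, q):
        """Mean per-cell noise from the simulator matches q/(N(1-q))."""
        p = SimulationParams(
            n_experiments=1, cells_per_experiment=50000, ploidy_N=N,
            silencing_q=q, sigma_extrinsic=0.0, sigma_intrinsic=0.0,
            measurement_sd=0.0, group_label="g", seed=100 + N,
        )
        cells, _ = simulate_population(p)
        norm = normalize_per_experiment(cells)
        noise = per_cell_intrinsic_noise(norm, "g")["intrinsic_noise"].to_numpy()
        se = noise.std(ddof=1) / np.sqrt(noise.size)
        assert abs(noise.mean() - expected_intrinsic_noise(N, q)) < 3 * se


class TestRenderImageStack:
    def test_single_cell_interior_mean_matches_value(self):
        cells = pd.DataFrame(
            {"cell_id": ["c1"], "experiment_id": ["e1"], "group_label": ["g"],
             "tissue": ["t"], "x": [100.0], "y": [100.0]}
        )
        geom = NucleusGeometry(radius=3, background=5.0, rendering_noise_sd=0.0)
        stack, rois = render_image_stack(cells, geom, seed=0)
        cz, cy, cx, r = (int(rois.loc[0, k]) for k in ("z", "y", "x", "radius"))
        zz, yy, xx = np.mgrid[: stack.shape[0], : stack.shape[1], : stack.shape[2]]
        mask = (zz - cz) ** 2 + (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2
        assert stack.channel("red")[mask].mean() == pytest.approx(100.0)
        assert stack.channel("green")[mask].mean() == pytest.approx(100.0)

    def test_three_cells_make_three_components_per_channel(self):
        from skimage import measure

        cells = pd.DataFrame(
            {"cell_id": [f"c{i}" for i in range(3)], "experiment_id": "e1",
             "group_label": "g", "tissue": "t",
             "x": [200.0, 300.0, 400.0], "y": [250.0, 350.0, 450.0]}
        )
        stack, _ = render_image_stack(cells, NucleusGeometry(rendering_noise_sd=0.0), seed=0)
        for ch in ("red", "green"):
            img = stack.channel(ch)
            labels = measure.label(img > 100, connectivity=3)
            assert labels.max() == 3

    def test_overcrowded_scene_raises_geometry_error(self):
        cells = pd.DataFrame(
            {"cell_id": [f"c{i}" for i in range(30)], "experiment_id": "e1",
             "group_label": "g", "tissue": "t", "x": 100.0, "y": 100.0}
        )
        geom = NucleusGeometry(radius=4, shape=(12, 12, 12))
        with pytest.raises(GeometryError):
            render_image_stack(cells, geom, seed=0)

    def test_rendering_is_seed_deterministic(self):
        cells = pd.DataFrame(
            {"cell_id": ["c1"], "experiment_id": ["e1"], "group_label": ["g"],
             "tissue": ["t"], "x": [100.0], "y": [50.0]}
        )
        s1, _ = render_image_stack(cells, seed=9)
        s2, _ = render_image_stack(cells, seed=9)
        assert np.array_equal(s1.voxels, s2.voxels)


class TestAnnotationFixture:
    def test_intronless_count_is_deterministic_rounding(self):
        fx = generate_annotation_fixture(100, frac_intronless=0.06, seed=0)
        assert len(fx.intronless_ids) == 6

    def test_gff3_round_trips_through_parser(self):
        fx = generate_annotation_fixture(100, frac_intronless=0.06, seed=1)
        models = parse_gff3(fx.gff3)
        assert len(models) == 100
        assert classify_intronless(models) == set(fx.intronless_ids)

    def test_mae_rates_within_binomial_error(self):
        fx = generate_annotation_fixture(
            10000, frac_intronless=0.1, frac_mae_intronless=0.64,
            frac_mae_intronful=0.20, seed=2,
        )
        mae = fx.mae_table.set_index("gene_id")["mae_call"] == "monoallelic"
        inside = mae[mae.index.isin(fx.intronless_ids)]
        outside = mae[~mae.index.isin(fx.intronless_ids)]
        for series, rate in ((inside, 0.64), (outside, 0.20)):
            n = len(series)
            se = np.sqrt(rate * (1 - rate) / n)
            assert abs(series.mean() - rate) < 4 * se

    def test_fixture_is_seed_deterministic(self):
        a = generate_annotation_fixture(200, seed=5)
        b = generate_annotation_fixture(200, seed=5)
        assert a.gff3 == b.gff3
        pd.testing.assert_frame_equal(a.mae_table, b.mae_table)
        pd.testing.assert_frame_equal(a.term_map, b.term_map)

    def test_fraction_out_of_range_raises(self):
        with pytest.raises(ParameterError, match="frac_intronless"):
            generate_annotation_fixture(10, frac_intronless=1.2)


@settings(deadline=None, max_examples=25)
@given(
    N=st.integers(min_value=1, max_value=16),
    q=st.floats(min_value=0.0, max_value=0.95),
)
def test_active_copy_counts_stay_within_ploidy(N, q):
    p = SimulationParams(
        n_experiments=1, cells_per_experiment=50, ploidy_N=N, silencing_q=q, seed=3
    )
    _, truth = simulate_population(p)
    for col in ("active_copies_red", "active_copies_green"):
        assert truth[col].between(0, N).all()
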