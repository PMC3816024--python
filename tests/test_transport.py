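"""Monte Carlo transport engine: scoring, tagging, estimators, reproducibility."""

import dataclasses
import math

import numpy as np
import pytest

import irkwall as ik
from irkwall.transport import (
    CAPSULE_STANDOFF_CM,
    PhotonState,
    RunConfig,
    TallyAccumulator,
    monitoring_distances,
    source_point,
)


@pytest.fixture(scope="module")
def air():
    return ik.load_material("air")


@pytest.fixture(scope="module")
def quiet_cavity():
    """Near-transparent purely-absorbing cavity: scores track-length kerma
    but can never Compton-scatter, so wall-isolation identities are exact."""
    return ik.fictitious_material(1e-6, 1.0, 1.0, name="quiet-cavity")


@pytest.fixture(scope="module")
def transparent_chamber(transparent, quiet_cavity):
    return ik.ChamberSpec(2.899, 3.200, transparent, quiet_cavity, transparent, 100.0)


class TestRunConfig:
    def test_validation(self):
        with pytest.raises(ValueError):
            RunConfig(n_histories=0)
        with pytest.raises(ValueError):
            RunConfig(photon_cutoff=0.0)
        with pytest.raises(ValueError):
            RunConfig(estimator="nonsense")


class TestCavityTrackScoring:
    def _accumulator(self, air):
        return TallyAccumulator(cavity_material=air)

    def test_closed_form_deposit(self, air):
        """Single traversal equals the hand-multiplied product
        w * E * muen/rho * rho * chord."""
        state = PhotonState(np.zeros(3), np.array([0, 0, 1.0]), energy=0.4)
        acc = self._accumulator(air)
        deposit = ik.score_cavity_track(state, 5.798, acc)
        expected = (
            1.0
            * 0.4
            * ik.energy_absorption_coefficient(air, 0.4)
            * air.density
            * 5.798
        )
        assert deposit == pytest.approx(expected, rel=1e-12)
        assert acc.sum_primary == pytest.approx(expected, rel=1e-12)

    def test_zero_chord_no_op(self, air):
        state = PhotonState(np.zeros(3), np.array([0, 0, 1.0]), energy=0.4)
        acc = self._accumulator(air)
        ik.score_cavity_track(state, 0.0, acc)
        assert acc.sum_primary == 0.0 and acc.sum_scatter == 0.0

    def test_negative_chord_rejected(self, air):
        state = PhotonState(np.zeros(3), np.array([0, 0, 1.0]), energy=0.4)
        with pytest.raises(ValueError):
            ik.score_cavity_track(state, -1.0, self._accumulator(air))

    def test_zero_optical_depth_matches_unattenuated(self, air):
        state = PhotonState(
            np.zeros(3), np.array([0, 0, 1.0]), energy=0.4, wall_optical_depth=0.0
        )
        acc = self._accumulator(air)
        ik.score_cavity_track(state, 2.0, acc)
        assert acc.sum_primary == acc.sum_primary_unattenuated

    def test_scattered_photon_goes_to_scatter_sum(self, air):
        state = PhotonState(
            np.zeros(3), np.array([0, 0, 1.0]), energy=0.3, n_scatters=2
        )
        acc = self._accumulator(air)
        ik.score_cavity_track(state, 2.0, acc)
        assert acc.sum_primary == 0.0 and acc.sum_scatter > 0.0


class TestChamberTransport:
    def test_transparent_wall_identities(self, transparent_chamber):
        """No wall interactions: no scatter deposit, zero optical depth,
        so the attenuation-unfolded primary sum equals the primary sum."""
        acc = ik.simulate_chamber(
            transparent_chamber, 0.4, RunConfig(n_histories=50_000, seed=1)
        )
        assert acc.sum_scatter == 0.0
        assert acc.sum_primary_unattenuated == acc.sum_primary
        assert acc.sum_primary > 0

    def test_pure_absorber_pencil_beam(self, transparent, quiet_cavity):
        """Central pencil beam through a purely absorbing wall: every
        surviving primary carries exactly exp(mu t) with t the
        perpendicular wall thickness, so k_att is the analytic value and
        no scattered photon exists."""
        absorber = ik.fictitious_material(0.5, 1.0, 1.0, name="absorber")
        chamber = ik.ChamberSpec(2.899, 3.200, absorber, quiet_cavity, transparent, 100.0)
        acc = ik.simulate_chamber(
            chamber, 0.4, RunConfig(n_histories=30_000, seed=2, beam_half_angle=1e-5)
        )
        wf = ik.wall_factors(acc)
        assert wf.k_att == pytest.approx(math.exp(0.5 * 0.301), rel=1e-6)
        assert wf.k_sc == 1.0
        assert acc.sum_scatter == 0.0

    def test_bit_identical_reproducibility(self, iner_chamber):
        runs = [
            ik.simulate_chamber(iner_chamber, 0.4, RunConfig(n_histories=50_000, seed=3))
            for _ in range(2)
        ]
        for field in dataclasses.fields(TallyAccumulator):
            if field.name == "cavity_material":
                continue
            assert getattr(runs[0], field.name) == getattr(runs[1], field.name)

    def test_unattenuated_sum_dominates(self, iner_chamber):
        acc = ik.simulate_chamber(
            iner_chamber, 0.4, RunConfig(n_histories=50_000, seed=4)
        )
        assert acc.sum_primary_unattenuated >= acc.sum_primary > 0

    def test_cavity_density_cancels_in_factors(self, iner_chamber):
        """The wall factors are deposit ratios, so scaling the cavity air
        density leaves them unchanged within statistics."""
        dense = dataclasses.replace(
            iner_chamber,
            cavity_material=iner_chamber.cavity_material.with_density(
                iner_chamber.cavity_material.density * 10
            ),
        )
        wf_a = ik.wall_factors(
            ik.simulate_chamber(iner_chamber, 0.4, RunConfig(n_histories=200_000, seed=5))
        )
        wf_b = ik.wall_factors(
            ik.simulate_chamber(dense, 0.4, RunConfig(n_histories=200_000, seed=6))
        )
        combined = math.hypot(wf_a.rel_unc_wall, wf_b.rel_unc_wall)
        assert abs(wf_b.k_wall / wf_a.k_wall - 1) < 3 * combined + 3e-3

    def test_cone_importance_sampling_unbiased(self, iner_chamber):
        """Halving the cone margin must not shift the factors."""
        wf = [
            ik.wall_factors(
                ik.simulate_chamber(
                    iner_chamber,
                    0.4,
                    RunConfig(n_histories=300_000, seed=7 + i, cone_half_angle_margin=m),
                )
            )
            for i, m in enumerate((0.05, 0.025))
        ]
        combined = math.hypot(wf[0].rel_unc_wall, wf[1].rel_unc_wall)
        assert abs(wf[0].k_wall / wf[1].k_wall - 1) < 3 * combined

    def test_energy_bookkeeping_total_capture(self, transparent, air):
        """With a transparent wall and an effectively black cavity (analog
        scoring), every photon aimed at the cavity deposits its full
        energy: the mean primary deposit per history is the source energy."""
        black = ik.fictitious_material(1e6, 1.0, 1.0, name="black")
        chamber = ik.ChamberSpec(2.899, 3.200, transparent, black, transparent, 100.0)
        half = math.asin(2.899 / 100.0) * 0.999
        acc = ik.simulate_chamber(
            chamber,
            0.4,
            RunConfig(n_histories=20_000, seed=8, estimator="analog", beam_half_angle=half),
        )
        assert acc.sum_primary / acc.n_histories == pytest.approx(0.4, rel=1e-3)

    def test_source_energy_above_tables_rejected(self, iner_chamber):
        with pytest.raises(ValueError):
            ik.simulate_chamber(iner_chamber, 2.0, RunConfig(n_histories=10))


class TestEstimatorEquivalence:
    def test_analog_dense_cavity_matches_track_length(self, iner_chamber):
        """Analog interaction scoring in a 100x denser cavity agrees with
        the track-length estimator at true density within the combined
        statistics.  (The inflation itself feeds a small second-order
        cavity-scatter term, so moderate statistics are the regime where
        the equivalence is meaningful.)"""
        dense = dataclasses.replace(
            iner_chamber,
            cavity_material=iner_chamber.cavity_material.with_density(
                iner_chamber.cavity_material.density * 100
            ),
        )
        wf_track = ik.wall_factors(
            ik.simulate_chamber(iner_chamber, 0.4, RunConfig(n_histories=100_000, seed=9))
        )
        wf_analog = ik.wall_factors(
            ik.simulate_chamber(
                dense, 0.4, RunConfig(n_histories=100_000, seed=10, estimator="analog")
            )
        )
        for name in ("k_att", "k_sc", "k_wall"):
            a, b = getattr(wf_track, name), getattr(wf_analog, name)
            unc = {
                "k_att": ("rel_unc_att",),
                "k_sc": ("rel_unc_sc",),
                "k_wall": ("rel_unc_wall",),
            }[name][0]
            combined = math.hypot(getattr(wf_track, unc), getattr(wf_analog, unc))
            assert abs(b / a - 1) < 3 * combined


class TestPhantomTransport:
    def test_monitoring_grid(self):
        distances = monitoring_distances(ik.PhantomSpec())
        assert distances[0] == pytest.approx(1.25)
        assert distances[-1] == pytest.approx(9.75)
        assert len(distances) == 18
        assert np.allclose(np.diff(distances), 0.5)

    def test_source_points(self):
        phantom = ik.PhantomSpec()
        assert np.allclose(source_point(phantom, "central_axis"), [0, 0, 7])
        b = source_point(phantom, "B")
        a = source_point(phantom, "A")
        assert b[0] == pytest.approx(1.0 - CAPSULE_STANDOFF_CM)
        assert a[0] == pytest.approx(-(1.0 - CAPSULE_STANDOFF_CM))
        assert np.allclose(a + b, [0, 0, 14])  # diametrically opposite
        with pytest.raises(ValueError):
            source_point(phantom, "C")
        with pytest.raises(ValueError):
            source_point(phantom, "B", standoff=2.0)

    def test_vacuum_body_inverse_square(self, ir192_spectrum):
        """With an (almost) non-attenuating body the cube doses follow the
        solid-angle-exact inverse-square average over each cube, computed
        here by an independent midpoint quadrature."""
        thin = ik.fictitious_material(1e-6, 1.0, 1.0, name="near-vacuum")
        phantom = ik.PhantomSpec(body_material=thin)
        profile = ik.simulate_phantom(
            phantom, "central_axis", ir192_spectrum,
            RunConfig(n_histories=2_000_000, seed=11),
        )
        grid = np.linspace(-0.25, 0.25, 21)[:-1] + 0.0125
        oracle = []
        for cx in profile.distances:
            xs = cx + grid
            r2 = (
                xs[:, None, None] ** 2
                + grid[None, :, None] ** 2
                + grid[None, None, :] ** 2
            )
            oracle.append(np.mean(1.0 / r2))
        oracle = np.array(oracle)
        ratio = profile.dose_per_history / oracle
        ratio /= ratio[0]
        sigma = np.hypot(profile.rel_std_err, profile.rel_std_err[0])
        assert np.all(np.abs(ratio - 1) < 3 * sigma + 0.01)

    def test_central_dose_strictly_decreasing(self, phantom_profiles):
        dose = phantom_profiles["central_axis"].dose_per_history
        assert np.all(np.diff(dose) < 0)

    def test_bit_identical_reproducibility(self, ir192_spectrum):
        phantom = ik.PhantomSpec()
        runs = [
            ik.simulate_phantom(
                phantom, "B", ir192_spectrum, RunConfig(n_histories=100_000, seed=12)
            )
            for _ in range(2)
        ]
        assert np.array_equal(runs[0].dose_per_history, runs[1].dose_per_history)
        assert np.array_equal(runs[0].rel_std_err, runs[1].rel_std_err)

    def test_requires_spectrum_source(self):
        with pytest.raises(TypeError):
            ik.simulate_phantom(
                ik.PhantomSpec(), "central_axis", 0.4, RunConfig(n_histories=10)
            )

    def test_profile_csv_round_trip(self, tmp_path, phantom_profiles):
        path = tmp_path / "profile.csv"
        profile = phantom_profiles["central_axis"]
        profile.to_csv(path)
        restored = ik.DoseProfile.from_csv(path, "central_axis")
        assert np.allclose(restored.dose_per_history, profile.dose_per_history)
        assert np.allclose(restored.distances, profile.distances)
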