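"""Reactive-configuration geometry, histograms, Boltzmann inversion, H-bonds."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from methylspec import (
    HBondSpec,
    RoleMap,
    boltzmann_invert,
    build_histogram2d,
    compute_geometry,
    hbond_occupancy,
    lone_pair_direction,
    marginal_free_energy,
)
from methylspec.constants import KB
from methylspec.errors import DegenerateGeometryError, EmptyDataError, ParameterError
from methylspec.geometry import GeometryRecord, Histogram2D
from methylspec.io import AtomRecord, Frame
from methylspec.synthetic import gen_frames, preset_spec

from conftest import TET, make_sn2_frame, series_of, tetrahedral_substituents


def _frame_with_subs(p_n, sub_positions):
    atoms = [
        AtomRecord("SD", "S", [0, 0, 1.8]),
        AtomRecord("CM", "C", [0, 0, 0]),
        AtomRecord("NZ", "N", p_n),
        AtomRecord("CE", "C", sub_positions[0]),
        AtomRecord("HZ1", "H", sub_positions[1]),
        AtomRecord("HZ2", "H", sub_positions[2]),
    ]
    return Frame(index=0, atoms=tuple(atoms))


@pytest.fixture
def roles():
    return RoleMap("SD", "CM", "NZ", ("CE", "HZ1", "HZ2"))


class TestLonePairDirection:
    def test_axis_aligned_substituents(self, roles):
        frame = _frame_with_subs([0, 0, 0], [[1, 0, 0], [0, 1, 0], [0, 0, 1]])
        u = lone_pair_direction(frame, roles)
        np.testing.assert_allclose(u, -np.ones(3) / np.sqrt(3), atol=1e-12)

    def test_planar_nitrogen_is_degenerate(self, roles):
        subs = [
            [np.cos(a), np.sin(a), 0.0] for a in (0, 2 * np.pi / 3, 4 * np.pi / 3)
        ]
        frame = _frame_with_subs([0, 0, 0], subs)
        with pytest.raises(DegenerateGeometryError):
            lone_pair_direction(frame, roles)

    def test_ideal_tetrahedron_points_at_missing_vertex(self, roles):
        # brute-force oracle: build a regular tetrahedron from scratch and
        # check the construction returns the fourth-vertex direction
        rng = np.random.default_rng(3)
        for _ in range(5):
            v = rng.normal(size=3)
            v /= np.linalg.norm(v)
            p_n = rng.normal(size=3)
            subs = tetrahedral_substituents(p_n, v, azimuth=rng.uniform(0, 2 * np.pi))
            frame = _frame_with_subs(p_n, subs)
            u = lone_pair_direction(frame, roles)
            # u is the missing tetrahedral vertex: antiparallel to the
            # substituent bond-vector sum, and 109.47° from every bond
            assert np.dot(u, v) == pytest.approx(1.0, abs=1e-6)
            s = sum(
                (np.asarray(p) - p_n) / np.linalg.norm(np.asarray(p) - p_n)
                for p in subs
            )
            assert np.dot(u, s / np.linalg.norm(s)) == pytest.approx(-1.0, abs=1e-9)
            for p in subs:
                b = (np.asarray(p) - p_n) / np.linalg.norm(np.asarray(p) - p_n)
                assert math.degrees(math.acos(np.dot(u, b))) == pytest.approx(TET, abs=1e-6)


class TestComputeGeometry:
    def test_perfect_sn2_alignment(self, roles):
        frame = make_sn2_frame(3.0, 1.8, u_lone_pair=[0, 0, 1])
        (rec,) = compute_geometry(series_of([frame], roles))
        assert rec.r_CN == pytest.approx(3.0)
        assert rec.r_CS == pytest.approx(1.8)
        assert rec.R == pytest.approx(-1.2)
        assert rec.theta == pytest.approx(0.0, abs=1e-9)

    def test_perpendicular_lone_pair(self, roles):
        frame = make_sn2_frame(3.0, 1.8, u_lone_pair=[1, 0, 0])
        (rec,) = compute_geometry(series_of([frame], roles))
        assert rec.theta == pytest.approx(90.0, abs=1e-9)

    def test_matches_independent_vector_arithmetic(self, roles):
        # independent oracle: plain Python loops + math module
        rng = np.random.default_rng(0)
        frames = []
        for i in range(50):
            p_n = rng.normal(scale=2.0, size=3)
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            subs = tetrahedral_substituents(p_n, u, azimuth=rng.uniform(0, 2 * np.pi))
            atoms = [
                AtomRecord("SD", "S", rng.normal(scale=2.0, size=3)),
                AtomRecord("CM", "C", rng.normal(scale=2.0, size=3)),
                AtomRecord("NZ", "N", p_n),
                AtomRecord("CE", "C", subs[0]),
                AtomRecord("HZ1", "H", subs[1]),
                AtomRecord("HZ2", "H", subs[2]),
            ]
            frames.append(Frame(index=i, atoms=tuple(atoms)))
        records = compute_geometry(series_of(frames, roles))
        for frame, rec in zip(frames, records):
            pos = {a.name: [float(x) for x in a.position] for a in frame.atoms}

            def dist(a, b):
                return math.sqrt(sum((x - y) ** 2 for x, y in zip(pos[a], pos[b])))

            lone = [0.0, 0.0, 0.0]
            for s in ("CE", "HZ1", "HZ2"):
                d = dist(s, "NZ")
                for k in range(3):
                    lone[k] += (pos[s][k] - pos["NZ"][k]) / d
            norm = math.sqrt(sum(x * x for x in lone))
            lone = [-x / norm for x in lone]
            vec_cs = [pos["SD"][k] - pos["CM"][k] for k in range(3)]
            ncs = math.sqrt(sum(x * x for x in vec_cs))
            cosang = sum(l * v / ncs for l, v in zip(lone, vec_cs))
            assert rec.r_CN == pytest.approx(dist("CM", "NZ"), abs=1e-10)
            assert rec.r_CS == pytest.approx(dist("CM", "SD"), abs=1e-10)
            assert rec.R == pytest.approx(dist("CM", "SD") - dist("CM", "NZ"), abs=1e-10)
            assert rec.theta == pytest.approx(math.degrees(math.acos(cosang)), abs=1e-10)

    @settings(deadline=None, max_examples=25)
    @given(
        angles=st.tuples(
            st.floats(0, 2 * np.pi), st.floats(0, np.pi), st.floats(0, 2 * np.pi)
        ),
        shift=st.tuples(*[st.floats(-50, 50) for _ in range(3)]),
    )
    def test_rigid_motion_invariance(self, angles, shift):
        """θ and all distances unchanged under rotation + translation."""
        from scipy.spatial.transform import Rotation

        roles = RoleMap("SD", "CM", "NZ", ("CE", "HZ1", "HZ2"))
        frame = make_sn2_frame(3.1, 1.8, u_lone_pair=[0.3, 0.2, 0.9])
        (ref,) = compute_geometry(series_of([frame], roles))
        rot = Rotation.from_euler("zyz", angles).as_matrix()
        moved = Frame(
            index=0,
            atoms=tuple(
                AtomRecord(a.name, a.element, rot @ a.position + np.asarray(shift))
                for a in frame.atoms
            ),
        )
        (rec,) = compute_geometry(series_of([moved], roles))
        assert rec.r_CN == pytest.approx(ref.r_CN, abs=1e-8)
        assert rec.r_CS == pytest.approx(ref.r_CS, abs=1e-8)
        assert rec.theta == pytest.approx(ref.theta, abs=1e-8)

    def test_uniform_scaling_doubles_distances_keeps_theta(self, roles):
        frame = make_sn2_frame(3.1, 1.8, u_lone_pair=[0.3, 0.2, 0.9])
        (ref,) = compute_geometry(series_of([frame], roles))
        scaled = Frame(
            index=0,
            atoms=tuple(
                AtomRecord(a.name, a.element, 2.0 * a.position) for a in frame.atoms
            ),
        )
        (rec,) = compute_geometry(series_of([scaled], roles))
        assert rec.r_CN == pytest.approx(2 * ref.r_CN, rel=1e-12)
        assert rec.r_CS == pytest.approx(2 * ref.r_CS, rel=1e-12)
        assert rec.theta == pytest.approx(ref.theta, abs=1e-10)


def _records(rs, thetas):
    return [
        GeometryRecord(frame_index=i, r_CN=r, r_CS=r + 1.0, R=1.0, theta=t)
        for i, (r, t) in enumerate(zip(rs, thetas))
    ]


class TestHistogram2D:
    edges_r = np.array([2.0, 3.0, 4.0])
    edges_t = np.array([0.0, 90.0, 180.0])

    def test_four_records_one_cell(self):
        h = build_histogram2d(_records([2.5] * 4, [45.0] * 4), self.edges_r, self.edges_t)
        assert h.counts[0, 0] == 4 and h.n_total == 4

    def test_interior_edge_goes_up(self):
        h = build_histogram2d(_records([3.0], [90.0]), self.edges_r, self.edges_t)
        assert h.counts[1, 1] == 1

    def test_last_bin_closed(self):
        h = build_histogram2d(_records([4.0], [180.0]), self.edges_r, self.edges_t)
        assert h.counts[1, 1] == 1

    def test_out_of_range_counted_not_binned(self):
        h = build_histogram2d(
            _records([2.5, 9.0], [45.0, 45.0]), self.edges_r, self.edges_t
        )
        assert h.n_total == 1 and h.n_out_of_range == 1

    def test_all_out_of_range_is_empty(self):
        with pytest.raises(EmptyDataError):
            build_histogram2d(_records([9.0], [45.0]), self.edges_r, self.edges_t)

    def test_matches_brute_force_double_loop(self):
        spec = preset_spec("reactive_wt_like", n_frames=10_000, seed=2)
        recs = compute_geometry(gen_frames(spec))
        r_edges = np.arange(2.0, 6.01, 0.25)
        t_edges = np.arange(0.0, 180.01, 15.0)
        h = build_histogram2d(recs, r_edges, t_edges)
        brute = np.zeros_like(h.counts)
        for rec in recs:
            for i in range(len(r_edges) - 1):
                for j in range(len(t_edges) - 1):
                    hi_r = rec.r_CN < r_edges[i + 1] or (
                        i == len(r_edges) - 2 and rec.r_CN == r_edges[i + 1]
                    )
                    hi_t = rec.theta < t_edges[j + 1] or (
                        j == len(t_edges) - 2 and rec.theta == t_edges[j + 1]
                    )
                    if r_edges[i] <= rec.r_CN and hi_r and t_edges[j] <= rec.theta and hi_t:
                        brute[i, j] += 1
        np.testing.assert_array_equal(h.counts, brute)


class TestBoltzmannInversion:
    def test_uniform_counts_give_zero_surface(self):
        h = Histogram2D(
            r_edges=np.array([2.0, 3.0, 4.0]),
            theta_edges=np.array([0.0, 90.0, 180.0]),
            counts=np.full((2, 2), 7),
            n_total=28,
        )
        surf = boltzmann_invert(h, 283.15)
        np.testing.assert_allclose(surf.free_energy, 0.0, atol=1e-14)

    def test_count_ratio_e_gives_kbt(self):
        n = 100_000
        h = Histogram2D(
            r_edges=np.array([2.0, 3.0, 4.0]),
            theta_edges=np.array([0.0, 180.0]),
            counts=np.array([[n], [round(n / np.e)]]),
            n_total=n + round(n / np.e),
        )
        surf = boltzmann_invert(h, 283.15)
        # kB*T at 283.15 K = 1.987204259e-3 * 283.15 = 0.56268 kcal/mol
        assert KB * 283.15 == pytest.approx(0.56268, abs=5e-6)
        assert surf.free_energy[1, 0] == pytest.approx(KB * 283.15, rel=1e-4)

    def test_algebraic_inverse_recovers_probabilities(self):
        rng = np.random.default_rng(5)
        counts = rng.integers(0, 50, size=(8, 6))
        h = Histogram2D(
            r_edges=np.linspace(2, 6, 9),
            theta_edges=np.linspace(0, 180, 7),
            counts=counts,
            n_total=int(counts.sum()),
        )
        surf = boltzmann_invert(h, 283.15)
        kbt = KB * 283.15
        defined = counts > 0
        p_hat = np.exp(-surf.free_energy[defined] / kbt)
        p_hat /= p_hat.sum()
        p_emp = counts[defined] / counts[defined].sum()
        np.testing.assert_allclose(p_hat, p_emp, atol=1e-12)

    def test_negative_temperature_rejected(self):
        h = Histogram2D(
            r_edges=np.array([2.0, 3.0]),
            theta_edges=np.array([0.0, 90.0]),
            counts=np.array([[1]]),
            n_total=1,
        )
        with pytest.raises(ParameterError):
            boltzmann_invert(h, -1.0)

    def test_inversion_recovers_harmonic_potential(self):
        """Sampling exp(−U/kBT) and inverting recovers U to 0.1 kcal/mol."""
        kbt = KB * 283.15
        kappa = 8.0  # kcal/mol/Å^2 → sd = sqrt(kbt/kappa)
        rng = np.random.default_rng(12)
        r = rng.normal(3.5, np.sqrt(kbt / kappa), size=100_000)
        recs = _records(r, np.full(r.size, 45.0))
        h = build_histogram2d(recs, np.arange(2.0, 6.01, 0.05), np.array([0.0, 180.0]))
        prof = marginal_free_energy(h, "r", 283.15)
        heavy = prof["count"].to_numpy() >= 100
        centers = prof["center"].to_numpy()[heavy]
        f = prof["free_energy"].to_numpy()[heavy]
        u = 0.5 * kappa * (centers - 3.5) ** 2
        # compare up to an additive constant
        resid = f - u
        assert np.max(np.abs(resid - resid.mean())) < 0.1


class TestMarginals:
    def test_single_theta_row(self):
        counts = np.zeros((3, 4), dtype=int)
        counts[:, 2] = [1, 2, 3]
        h = Histogram2D(
            r_edges=np.linspace(2, 5, 4),
            theta_edges=np.linspace(0, 180, 5),
            counts=counts,
            n_total=6,
        )
        prof = marginal_free_energy(h, "theta", 283.15)
        defined = ~prof["free_energy"].isna()
        assert defined.sum() == 1
        assert prof.loc[defined, "free_energy"].iloc[0] == 0.0

    def test_separable_counts_marginalize_exactly(self):
        a = np.array([4, 8, 2])
        b = np.array([1, 3, 5, 1])
        counts = np.outer(a, b)
        h = Histogram2D(
            r_edges=np.linspace(2, 5, 4),
            theta_edges=np.linspace(0, 180, 5),
            counts=counts,
            n_total=int(counts.sum()),
        )
        prof = marginal_free_energy(h, "r", 283.15)
        kbt = KB * 283.15
        expected = -kbt * np.log(a * b.sum() / (a.max() * b.sum()))
        np.testing.assert_allclose(prof["free_energy"], expected, atol=1e-12)

    def test_alignment_cost_matches_brute_force(self):
        """Free-energy rise of the θ-marginal into the 0–15° range."""
        spec = preset_spec("reactive_wt_like", n_frames=20_000, seed=9)
        recs = compute_geometry(gen_frames(spec))
        h = build_histogram2d(recs)
        prof = marginal_free_energy(h, "theta", 283.15)
        kbt = KB * 283.15
        # brute force from the binned counts
        c = h.counts.sum(axis=0)
        low = slice(0, 3)  # 0–15° at 5° bins
        rise = -kbt * np.log(c[low].max() / c.max())
        f = prof["free_energy"].to_numpy()
        assert np.isfinite(rise) and rise > 0
        assert np.nanmin(f[low]) == pytest.approx(rise, abs=1e-12)


class TestHBond:
    def _frames(self, d_list, ang_list):
        frames = []
        for i, (d, ang) in enumerate(zip(d_list, ang_list)):
            p_d = np.array([0.0, 0.0, 0.0])
            p_h = np.array([0.0, 0.0, 1.0])
            # place acceptor at distance d from donor, with D–H…A angle = ang
            a = np.radians(180.0 - ang)
            p_a = p_h + (d - 1.0) * np.array([np.sin(a), 0.0, np.cos(a)])
            extra = [
                AtomRecord("OD", "O", p_d),
                AtomRecord("HD", "H", p_h),
                AtomRecord("OA", "O", p_a),
            ]
            frames.append(make_sn2_frame(3.0, 1.8, [0, 0, 1], index=i, extra_atoms=extra))
        return frames

    def test_bound_frame(self, sn2_role_map):
        frames = self._frames([2.8], [160.0])
        spec = HBondSpec(donor="OD", hydrogen="HD", acceptor="OA")
        occ = hbond_occupancy(series_of(frames, sn2_role_map), spec)
        assert occ == 1.0

    def test_distant_frame(self, sn2_role_map):
        frames = self._frames([4.0], [160.0])
        spec = HBondSpec(donor="OD", hydrogen="HD", acceptor="OA")
        assert hbond_occupancy(series_of(frames, sn2_role_map), spec) == 0.0

    def test_fraction_matches_brute_force_count(self, sn2_role_map):
        rng = np.random.default_rng(8)
        d = rng.uniform(2.0, 5.0, size=1000)
        ang = rng.uniform(90.0, 180.0, size=1000)
        frames = self._frames(d, ang)
        spec = HBondSpec(donor="OD", hydrogen="HD", acceptor="OA",
                         distance_cutoff=3.5, angle_cutoff=120.0)
        occ = hbond_occupancy(series_of(frames, sn2_role_map), spec)
        # brute-force count with independent plain-Python arithmetic
        n_ok = 0
        for frame in frames:
            pos = {a.name: [float(x) for x in a.position] for a in frame.atoms}
            dx = [pos["OD"][k] - pos["OA"][k] for k in range(3)]
            dist = math.sqrt(sum(x * x for x in dx))
            hd = [pos["OD"][k] - pos["HD"][k] for k in range(3)]
            ha = [pos["OA"][k] - pos["HD"][k] for k in range(3)]
            nd = math.sqrt(sum(x * x for x in hd))
            na = math.sqrt(sum(x * x for x in ha))
            cosang = sum(a * b for a, b in zip(hd, ha)) / (nd * na)
            angle = math.degrees(math.acos(max(-1.0, min(1.0, cosang))))
            if dist <= 3.5 and angle >= 120.0:
                n_ok += 1
        assert occ == n_ok / 1000
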