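"""Geometric ensemble statistics against brute-force and constructed oracles."""

import numpy as np
import pytest

from cyclosense.ensemble_analysis import (
    CoordinationMatrix,
    Ensemble,
    HBondCensus,
    build_coordination_matrix,
    coordination_occupancy,
    hbond_census,
    nearest_atom_attribution,
    representative_frame,
    ring_centroid_distances,
    subsample_and_average,
)
from cyclosense import synthetic_data as syn


def make_ensemble(frames, names, resids):
    return Ensemble(np.asarray(frames, dtype=float),
                    np.array(names, dtype=object), np.array(resids))


def random_rigid_transform(rng):
    # random rotation via QR of a Gaussian matrix, plus translation
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    t = rng.normal(scale=10.0, size=3)
    return q, t


def apply_rigid(ensemble, q, t):
    return Ensemble(ensemble.coordinates @ q.T + t, ensemble.names,
                    ensemble.resids, ensemble.elements, ensemble.masses)


class TestCoordinationMatrix:
    def collinear_ensemble(self):
        # N at origin, H 1 A along +x, acceptor X 3 A along +x: angle 180
        frames = [[[0, 0, 0], [1, 0, 0], [3, 0, 0]]]
        return make_ensemble(frames, ["N", "H", "CL"], [1, 1, 2])

    def test_collinear_geometry(self):
        e = self.collinear_ensemble()
        cm = build_coordination_matrix(e, donor_pairs=[(0, 1)],
                                       acceptors=np.array([2]))
        assert cm.block("dNX")[0, 0, 0] == pytest.approx(3.0)
        assert cm.block("dHX")[0, 0, 0] == pytest.approx(2.0)
        assert cm.block("angle")[0, 0, 0] == pytest.approx(180.0)

    def test_two_frame_hand_computed(self):
        # frame 2 puts X at right angle from the N-H axis, 2 A from H
        frames = [
            [[0, 0, 0], [1, 0, 0], [3, 0, 0]],
            [[0, 0, 0], [1, 0, 0], [1, 2, 0]],
        ]
        e = make_ensemble(frames, ["N", "H", "CL"], [1, 1, 2])
        cm = build_coordination_matrix(e, donor_pairs=[(0, 1)],
                                       acceptors=np.array([2]))
        assert cm.block("dNX")[1, 0, 0] == pytest.approx(np.sqrt(5.0))
        assert cm.block("dHX")[1, 0, 0] == pytest.approx(2.0)
        assert cm.block("angle")[1, 0, 0] == pytest.approx(90.0)

    def test_atom_permutation_invariance(self):
        frames = [[[0, 0, 0], [1, 0, 0], [3, 0.5, 0.2]],
                  [[0.1, 0, 0], [1.2, 0, 0], [2.5, 0, 1.0]]]
        e = make_ensemble(frames, ["N", "H", "CL"], [1, 1, 2])
        cm = build_coordination_matrix(e, donor_pairs=[(0, 1)],
                                       acceptors=np.array([2]))
        perm = [2, 0, 1]  # CL first now
        e2 = make_ensemble(np.asarray(frames)[:, perm],
                           ["CL", "N", "H"], [2, 1, 1])
        cm2 = build_coordination_matrix(e2, donor_pairs=[(1, 2)],
                                        acceptors=np.array([0]))
        assert np.allclose(cm.values, cm2.values)

    def test_empty_acceptors_rejected(self):
        e = self.collinear_ensemble()
        with pytest.raises(ValueError):
            build_coordination_matrix(e, donor_pairs=[(0, 1)],
                                      acceptors="name XX")

    def test_rigid_invariance(self, rng):
        ens, _ = syn.gen_ensemble(syn.EnsembleConfig(n_frames=20), seed=3)
        cm = build_coordination_matrix(ens, acceptors="resid 6")
        for _ in range(5):
            q, t = random_rigid_transform(rng)
            cm2 = build_coordination_matrix(apply_rigid(ens, q, t),
                                            acceptors="resid 6")
            assert np.allclose(cm.values, cm2.values, atol=1e-8)


class TestHBondCensus:
    def test_far_apart_counts_zero(self):
        frames = [[[0, 0, 0], [1, 0, 0], [10, 0, 0]]]
        e = make_ensemble(frames, ["N", "H", "O"], [1, 1, 2])
        c = hbond_census(e, donor_pairs=[(0, 1)], acceptors=np.array([2]))
        assert c.counts.tolist() == [0]

    def test_constructed_two_bonds(self):
        # two N-H...O pairs at d(N...O) = 2.9, nearly collinear
        frames = [[
            [0, 0, 0], [1, 0, 0], [2.9, 0.1, 0],       # donor 1, acceptor 1
            [0, 10, 0], [1, 10, 0], [2.9, 10.1, 0],    # donor 2, acceptor 2
        ]]
        e = make_ensemble(frames, ["N", "H", "O", "N", "H", "O"],
                          [1, 1, 2, 3, 3, 4])
        c = hbond_census(e)
        assert c.counts.tolist() == [2]

    def test_same_residue_excluded(self):
        frames = [[[0, 0, 0], [1, 0, 0], [2.9, 0, 0]]]
        e = make_ensemble(frames, ["N", "H", "O"], [1, 1, 1])
        c = hbond_census(e, donor_pairs=[(0, 1)], acceptors=np.array([2]))
        assert c.counts.tolist() == [0]

    def test_distribution_arithmetic(self):
        census = HBondCensus.from_counts(np.array([0, 1, 1, 2]))
        assert census.mean == pytest.approx(1.0)
        assert census.fractions == {0: 0.25, 1: 0.5, 2: 0.25}
        assert sum(census.fractions.values()) == pytest.approx(1.0)

    def test_matches_brute_force_triple_loop(self, rng):
        # random small ensembles vs an independent O(frames*donors*acceptors)
        # loop re-deriving the criterion from raw coordinates
        n_frames, d_cut, angle_min = 8, 3.5, 150.0
        coords = rng.uniform(-3, 6, size=(n_frames, 12, 3))
        names = ["N", "H", "O"] * 4
        resids = [1, 1, 1, 2, 2, 2, 3, 3, 3, 4, 4, 4]
        e = make_ensemble(coords, names, resids)
        donor_pairs = [(0, 1), (3, 4), (6, 7), (9, 10)]
        acceptors = np.array([2, 5, 8, 11])
        got = hbond_census(e, donor_pairs=donor_pairs, acceptors=acceptors,
                           d_cut=d_cut, angle_min=angle_min)
        for f in range(n_frames):
            n = 0
            for (ni, hi) in donor_pairs:
                for ai in acceptors:
                    if resids[ai] == resids[ni]:
                        continue
                    dNO = np.linalg.norm(coords[f, ni] - coords[f, ai])
                    v1 = coords[f, ni] - coords[f, hi]
                    v2 = coords[f, ai] - coords[f, hi]
                    cosang = v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2))
                    ang = np.degrees(np.arccos(np.clip(cosang, -1, 1)))
                    if dNO <= d_cut and ang >= angle_min:
                        n += 1
            assert got.counts[f] == n


class TestOccupancy:
    def frame_matrix(self, dists):
        """CoordinationMatrix with given dHX distances (frames x donors)."""
        dists = np.asarray(dists, dtype=float)[:, :, None]
        nf, nd, na = dists.shape
        vals = np.concatenate([dists + 1.0, dists,
                               np.full_like(dists, 170.0)], axis=1)
        labels = ([f"dNX:res{d}-X" for d in range(nd)]
                  + [f"dHX:res{d}-X" for d in range(nd)]
                  + [f"angle:res{d}-X" for d in range(nd)])
        return CoordinationMatrix(vals.reshape(nf, -1), labels,
                                  [f"res{d}" for d in range(nd)], ["X"])

    def test_all_below_cutoff(self):
        m = self.frame_matrix(np.full((10, 5), 2.0))
        assert np.allclose(coordination_occupancy(m, 2.8), 1.0)

    def test_counting_oracle_40_percent(self):
        d = np.full((100, 5), 5.0)
        d[:40, 2] = 2.0  # amide 3 bound in 40 of 100 frames
        occ = coordination_occupancy(self.frame_matrix(d), 2.8)
        assert occ[2] == pytest.approx(0.40)
        assert occ[0] == 0.0

    def test_zero_cutoff(self):
        m = self.frame_matrix(np.full((10, 5), 2.0))
        assert np.allclose(coordination_occupancy(m, 0.0), 0.0)

    def test_monotone_in_cutoff(self, rng):
        m = self.frame_matrix(rng.uniform(1.5, 6.0, size=(50, 5)))
        occs = [coordination_occupancy(m, c) for c in (3.5, 2.8, 2.0, 1.0)]
        for tight, loose in zip(occs[1:], occs[:-1]):
            assert np.all(tight <= loose + 1e-12)


class TestRepresentativeFrame:
    def gaussian_clusters(self, rng, sizes=(70, 30), sep=10.0):
        pts = []
        for k, n in enumerate(sizes):
            pts.append(rng.normal(loc=k * sep, scale=1.0, size=(n, 6)))
        V = np.vstack(pts)
        labels = [f"dHX:res{j}-X" for j in range(6)]
        return CoordinationMatrix(V, labels, [f"res{j}" for j in range(6)],
                                  ["X"][:1]), np.repeat(np.arange(len(sizes)), sizes)

    def test_majority_cluster_selected(self, rng):
        m, truth = self.gaussian_clusters(rng)
        rep = representative_frame(m, seed=0)
        assert truth[rep.frame_index] == 0            # from the 70-frame cluster
        assert sorted(rep.cluster_sizes, reverse=True)[0] == 70
        # representative lies within 1 SD of its cluster centroid in PC space
        members = np.nonzero(rep.labels == rep.cluster_of_frame)[0]
        centroid = rep.pc_coordinates[members].mean(axis=0)
        spread = rep.pc_coordinates[members].std()
        dist = np.linalg.norm(rep.pc_coordinates[rep.frame_index] - centroid)
        assert dist <= spread * np.sqrt(rep.n_components)

    def test_stable_across_seeds(self, rng):
        m, truth = self.gaussian_clusters(rng)
        picks = {representative_frame(m, seed=s).frame_index for s in range(10)}
        assert all(truth[p] == 0 for p in picks)

    def test_single_cluster_matches_nearest_to_mean(self, rng):
        m, _ = self.gaussian_clusters(rng, sizes=(60,))
        rep = representative_frame(m, seed=1)
        assert rep.n_clusters == 1
        sd = m.values.std(axis=0)
        Z = (m.values - m.values.mean(axis=0)) / sd
        from sklearn.decomposition import PCA
        P = PCA(n_components=2, random_state=1).fit_transform(Z)
        brute = int(np.argmin(np.linalg.norm(P - P.mean(axis=0), axis=1)))
        assert rep.frame_index == brute

    def test_duplicate_frames_tie(self):
        V = np.tile(np.array([[1.0, 2.0, 3.0]]), (5, 1)) \
            + np.array([[0], [0], [0], [1e-9], [0]])
        labels = [f"dHX:res{j}-X" for j in range(3)]
        m = CoordinationMatrix(V, labels, [f"res{j}" for j in range(3)], ["X"])
        rep = representative_frame(m, seed=0)
        assert 0 <= rep.frame_index < 5

    def test_constant_matrix_rejected(self):
        V = np.ones((10, 4))
        labels = [f"dHX:res{j}-X" for j in range(4)]
        m = CoordinationMatrix(V, labels, [f"res{j}" for j in range(4)], ["X"])
        with pytest.raises(ValueError):
            representative_frame(m)

    def test_endo_exo_mixture_across_seeds(self, endo_exo_ensemble):
        ens, truth = endo_exo_ensemble
        cm = build_coordination_matrix(ens, acceptors="resid 6")
        for seed in range(10):
            rep = representative_frame(cm, seed=seed)
            assert truth["states"][rep.frame_index] == 1   # endo = majority


class TestRingDistances:
    def test_symmetric_ring_at_5A(self):
        # 6-atom ring centered 5 A above the Ca centroid
        ring = [[np.cos(a), np.sin(a), 5.0]
                for a in np.linspace(0, 2 * np.pi, 6, endpoint=False)]
        cas = [[np.cos(a), np.sin(a), 0.0]
               for a in np.linspace(0, 2 * np.pi, 5, endpoint=False)]
        names = ["CG", "CD1", "CD2", "CE1", "CE2", "CZ"] + ["CA"] * 5
        resids = [1] * 6 + [1, 2, 3, 4, 5]
        e = make_ensemble([ring + cas], names, resids)
        d = ring_centroid_distances(e)
        assert d.shape == (1, 1)
        assert d[0, 0] == pytest.approx(5.0, abs=1e-12)

    def test_translation_invariance(self):
        ens, _ = syn.gen_ensemble(syn.EnsembleConfig(n_frames=5), seed=2)
        d1 = ring_centroid_distances(ens)
        shifted = Ensemble(ens.coordinates + np.array([3.0, -7.0, 11.0]),
                           ens.names, ens.resids, ens.elements, ens.masses)
        assert np.allclose(d1, ring_centroid_distances(shifted), atol=1e-10)

    def test_two_state_bimodal(self, rng):
        # synthetic near/far mixture: histogram modes at 4 and 8
        ring_template = np.array([[np.cos(a), np.sin(a), 0.0]
                                  for a in np.linspace(0, 2 * np.pi, 6,
                                                       endpoint=False)])
        cas = np.array([[np.cos(a), np.sin(a), 0.0]
                        for a in np.linspace(0, 2 * np.pi, 5, endpoint=False)])
        frames = []
        for f in range(200):
            z = 4.0 if f % 2 == 0 else 8.0
            ring = ring_template + [0, 0, z] + rng.normal(0, 0.05, (6, 3))
            frames.append(np.vstack([ring, cas]))
        names = ["CG", "CD1", "CD2", "CE1", "CE2", "CZ"] + ["CA"] * 5
        resids = [1] * 6 + [1, 2, 3, 4, 5]
        e = make_ensemble(frames, names, resids)
        d = ring_centroid_distances(e)[:, 0]
        hist, edges = np.histogram(d, bins=np.arange(2.0, 10.5, 1.0))
        modes = edges[:-1][hist > 50]
        assert {3.0, 7.0} <= set(modes) or {4.0, 8.0} <= set(np.round(modes + 0.5))


class TestSpectrumAveraging:
    def test_identical_spectra(self):
        spec = np.tile(np.linspace(0, 1, 20), (100, 1))
        avg = subsample_and_average(spec, stride=10)
        assert np.allclose(avg, np.linspace(0, 1, 20))

    def test_alternating_midpoint(self):
        a = np.zeros(10)
        b = np.ones(10)
        spectra = np.array([a, b] * 50)
        avg = subsample_and_average(spectra, stride=1)
        assert np.allclose(avg, 0.5)

    def test_known_mean_recovered(self, rng):
        spectra = rng.normal(2.0, 0.1, size=(1000, 30))
        avg = subsample_and_average(spectra, stride=1, count=1000)
        assert np.allclose(avg, spectra.mean(axis=0))

    def test_strided_subset(self):
        spectra = np.arange(100, dtype=float)[:, None]
        avg = subsample_and_average(spectra, stride=50)
        assert avg[0] == pytest.approx(25.0)  # mean of frames 0 and 50

    def test_axis_mismatch_rejected(self):
        spectra = np.ones((4, 3))
        axes = np.array([[1, 2, 3], [1, 2, 4], [1, 2, 3], [1, 2, 3]])
        with pytest.raises(ValueError):
            subsample_and_average(spectra, stride=1, axes=axes)


class TestAttribution:
    def test_thiocyanate_binds_through_nitrogen(self):
        ens, _ = syn.gen_ensemble(
            syn.EnsembleConfig(anion="SCN", n_frames=80), seed=5)
        cm = build_coordination_matrix(ens, acceptors="resid 6")
        frac = nearest_atom_attribution(cm)
        n_label = [k for k in frac if k.startswith("N")][0]
        assert frac[n_label] > 0.95
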