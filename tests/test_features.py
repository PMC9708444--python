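"""The 19-component feature vector and its components."""

import math

import numpy as np
import pytest

import protqa as pq
from protqa.features import (
    FEATURE_NAMES,
    ca_geometry_outliers,
    clash_score,
    extract_features,
    g_scores,
    molprobity_composite,
    profitfun_features,
    rotamer_features,
)
from conftest import random_rotation


class TestFeatureVectorContract:
    def test_nineteen_values_fixed_order(self, mixed_native, small_tables):
        fv = extract_features(mixed_native, small_tables)
        assert len(fv) == 19
        assert fv.values.shape == (19,)
        assert fv.names == FEATURE_NAMES
        assert np.all(np.isfinite(fv.values))

    def test_deterministic(self, mixed_native, small_tables):
        a = extract_features(mixed_native, small_tables)
        b = extract_features(mixed_native.copy(), small_tables)
        np.testing.assert_array_equal(a.values, b.values)

    def test_rigid_motion_invariance(self, mixed_native, small_tables, rng):
        base = extract_features(mixed_native, small_tables)
        moved = mixed_native.transformed(random_rotation(rng), rng.normal(size=3) * 30)
        after = extract_features(moved, small_tables)
        np.testing.assert_allclose(after.values, base.values, atol=1e-9)

    def test_identity_f11_and_f19(self, mixed_native, small_tables):
        fv = extract_features(mixed_native, small_tables)
        assert fv.values[10] == pytest.approx(np.mean(fv.values[:10]), abs=1e-12)
        assert fv.values[18] == pytest.approx(
            0.5 * fv.values[16] + 0.5 * fv.values[17], abs=1e-12)

    def test_native_beats_heavy_decoy(self, mixed_native, small_tables):
        decoy = pq.perturb(mixed_native, pq.NoiseSpec(mode="cartesian",
                                                      sigma=4.0, seed=77))
        nat = extract_features(mixed_native, small_tables).values
        dec = extract_features(decoy, small_tables).values
        assert nat[14] <= dec[14]   # clash score can only grow
        assert nat[0] >= dec[0]     # dihedral preference can only degrade


class TestProfitfunFeatures:
    def test_on_distribution_beats_scrambled_bins(self, small_tables, rng):
        """A structure from the reference family outscores the same
        sequence rebuilt with uniformly random (phi, psi) bins."""
        st = pq.make_native(60, seed=500)
        f_true = profitfun_features(st, small_tables)
        angles = [(rng.uniform(-180, 180), rng.uniform(-180, 180))
                  for _ in range(st.n_residues)]
        scrambled = pq.build_chain(st.sequence, angles)
        f_scr = profitfun_features(scrambled, small_tables)
        assert f_true[0] > f_scr[0]

    def test_conditioning_sharpens_on_matched_data(self):
        helix = pq.build_chain("A" * 40, (-57.0, -47.0))
        tables = pq.build_preference_tables([helix])
        f = profitfun_features(helix, tables)
        assert f[2] >= f[0]  # joint (aa, ss) context at least as sharp as aa

    def test_f10_in_unit_interval(self, mixed_native, small_tables):
        f = profitfun_features(mixed_native, small_tables)
        assert 0.0 < f[9] <= 1.0


class TestClashScore:
    def test_ideal_helix_clash_free(self, ideal_helix):
        assert clash_score(ideal_helix) == 0.0

    def test_forced_cb_contact_counts_once(self, ideal_helix):
        # CB atoms of residues far apart in sequence forced to 1.0 A
        # apart, isolated from everything else: exactly one clash
        st = ideal_helix.copy()
        st.residues[5].get("CB").coord = np.array([200.0, 0.0, 0.0])
        st.residues[20].get("CB").coord = np.array([201.0, 0.0, 0.0])
        assert clash_score(st) == pytest.approx(100.0 * 1 / 30)

    def test_grid_matches_brute_force(self, small_tables, rng):
        """Tree-accelerated counting equals the all-pairs oracle."""
        from protqa.features import _bond_graph, _within_bond_separation
        for k in range(10):
            st = pq.perturb(pq.make_native(30, seed=600 + k),
                            pq.NoiseSpec(mode="cartesian",
                                         sigma=float(rng.uniform(0, 2)),
                                         seed=700 + k))
            atoms, adj = _bond_graph(st)
            coords = np.array([a.coord for _, a in atoms])
            radii = np.array([a.radius for _, a in atoms])
            brute = 0
            for i in range(len(atoms)):
                for j in range(i + 1, len(atoms)):
                    if np.linalg.norm(coords[i] - coords[j]) < radii[i] + radii[j] - 0.4 \
                            and not _within_bond_separation(adj, i, j):
                        brute += 1
            assert clash_score(st) == pytest.approx(100.0 * brute / st.n_residues)

    def test_per_1000_atoms_switch(self, ideal_helix):
        assert clash_score(ideal_helix, per_1000_atoms=True) == 0.0


class TestRotamerFeatures:
    def test_modal_rotamers_all_favored(self, small_tables):
        st = pq.make_native(50, seed=901)  # built at modal chi1 values
        f12, f13, defined = rotamer_features(st, small_tables)
        assert defined
        assert f13 == 1.0
        assert f12 == 0.0

    def test_poly_gly_flagged_undefined(self, small_tables):
        st = pq.build_chain("G" * 20, (-57.0, -47.0))
        f12, f13, defined = rotamer_features(st, small_tables)
        assert not defined
        assert (f12, f13) == (0.0, 0.0)

    def test_randomized_chi_raises_outliers(self, small_tables, rng):
        st = pq.make_native(50, seed=902)
        base_f12, _, _ = rotamer_features(st, small_tables)
        chis = [float(rng.uniform(-180, 180)) for _ in range(st.n_residues)]
        from protqa.structure import backbone_dihedrals
        tors = backbone_dihedrals(st)
        angles = [(t.phi if t.phi is not None else 180.0,
                   t.psi if t.psi is not None else 180.0) for t in tors]
        randomized = pq.build_chain(st.sequence, angles, chi1=chis)
        rand_f12, _, _ = rotamer_features(randomized, small_tables)
        assert rand_f12 > base_f12


class TestCaGeometry:
    def test_ideal_helix_no_outliers(self, ideal_helix):
        assert ca_geometry_outliers(ideal_helix) == 0.0

    def test_displaced_ca_flags_outlier(self, ideal_helix):
        st = ideal_helix.copy()
        st.residues[10].get("CA").coord += np.array([2.0, 0.0, 0.0])
        assert ca_geometry_outliers(st) > 0.0

    def test_fraction_arithmetic(self):
        """10 residues, 8 evaluable interiors, 2 forced outliers -> 25 %."""
        st = pq.build_chain("A" * 10, (-57.0, -47.0))
        st.residues[3].get("CA").coord += np.array([0.0, 0.0, 3.0])
        base = ca_geometry_outliers(st)
        assert base * 8 / 100.0 == pytest.approx(round(base * 8 / 100.0))
        # construct exactly two outliers: shrink one CA-CA distance only
        st2 = pq.build_chain("A" * 10, (-57.0, -47.0))
        ca4 = st2.residues[4].get("CA")
        ca5 = st2.residues[5].get("CA")
        ca5.coord = ca4.coord + 0.5 * (ca5.coord - ca4.coord)  # ~1.9 A apart
        pct = ca_geometry_outliers(st2)
        assert pct == pytest.approx(100.0 * 2 / 8)


class TestComposite:
    def test_clean_structure_baseline(self):
        assert molprobity_composite(0.0, 0.0, 100.0) == pytest.approx(0.5)

    def test_hand_arithmetic(self):
        expected = 0.426 * math.log(11.0) + 0.5
        assert molprobity_composite(10.0, 0.0, 100.0) == pytest.approx(expected)
        assert expected == pytest.approx(1.5216, abs=5e-4)

    def test_monotone_in_clash(self, rng):
        vals = [molprobity_composite(c, 0.1, 90.0) for c in np.linspace(0, 50, 20)]
        assert all(a <= b for a, b in zip(vals, vals[1:]))


class TestGScores:
    def test_ideal_chain_covalent_zero(self, ideal_helix, small_tables):
        _, f18, _ = g_scores(ideal_helix, small_tables)
        assert f18 == pytest.approx(0.0, abs=1e-9)

    def test_stretched_bonds_analytic_value(self, small_tables):
        """Stretching every backbone bond by +2 sigma scores -0.5 * 2^2 on
        each bond term while angle terms stay 0, so the pooled mean is
        -2 * n_bonds / n_terms."""
        st = pq.build_chain("A" * 2, (-57.0, -47.0))
        # scale all coordinates isotropically: every bond grows by the same
        # relative factor (angles are scale-invariant and stay ideal)
        factor = 1.0 + 2.0 * 0.02 / 1.458  # +2 sigma on the N-CA bond
        st2 = st.copy()
        for _, atom in st2.atoms():
            atom.coord = atom.coord * factor
        f17a, f18a, f19a = g_scores(st2, small_tables)
        # angles are scale-invariant; bond z-values are (L*(f-1))/sigma
        zs = []
        for L in (1.458, 1.525, 1.231, 1.458, 1.525, 1.231, 1.329):
            zs.append(L * (factor - 1.0) / 0.02)
        n_angles = 2 + 2  # N-CA-C per residue + CA-C-N + C-N-CA at the junction
        expected = sum(-0.5 * z * z for z in zs) / (len(zs) + n_angles)
        assert f18a == pytest.approx(expected, abs=1e-9)

    def test_overall_is_mean_of_parts(self, mixed_native, small_tables):
        f17, f18, f19 = g_scores(mixed_native, small_tables)
        assert f19 == pytest.approx(0.5 * f17 + 0.5 * f18, abs=1e-12)


class TestMonotoneQualitySignal:
    def test_f11_tracks_gdt(self, small_tables):
        """Spearman correlation between observed GDT-TS and the averaged
        preference feature is clearly positive across the noise grid."""
        from scipy.stats import spearmanr
        native = pq.make_native(60, seed=31)
        gdts, f11s = [], []
        k = 0
        for sigma in (1.0, 2.0, 5.0, 10.0, 20.0, 40.0):
            for _ in range(5):
                decoy = pq.perturb(native, pq.NoiseSpec(mode="dihedral",
                                                        sigma=sigma, seed=800 + k))
                k += 1
                gdts.append(pq.gdt_ts(decoy, native).gdt_ts)
                f11s.append(extract_features(decoy, small_tables).values[10])
        assert spearmanr(gdts, f11s).statistic > 0.3
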