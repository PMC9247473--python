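"""Contact matrices, order parameters, splay and correlations."""

import numpy as np
import pytest

from curvsort import (
    Composition,
    CompositionEntry,
    MembraneFrame,
    SortingModel,
    contact_matrix,
    curvature_descriptor_correlation,
    descriptor_table,
    make_buckle_profile,
    sample_frame,
    splay_angle,
    tail_order_parameter,
)
from curvsort.errors import GeometryError, NotApplicableError, ValidationError
from curvsort.species import default_registry


def two_lipid_frame(separation):
    """Two single-bead POPC lipids a given x-distance apart."""
    frame = MembraneFrame(
        box=(40.0, 20.0, 20.0),
        residue_id=[1, 2],
        species=["POPC", "POPC"],
        bead_name=["PO4", "PO4"],
        positions=[[5.0, 5.0, 10.0], [5.0 + separation, 5.0, 10.0]],
    )
    frame.leaflet = {1: "outer", 2: "outer"}
    return frame


class TestContactMatrix:
    @pytest.mark.parametrize("sep,expected", [(0.9, 1.0), (1.1, 0.0)])
    def test_cutoff_threshold(self, sep, expected):
        cm = contact_matrix([two_lipid_frame(sep)] * 4, "outer")
        assert cm.raw[0, 0] == expected

    def test_bead_level_counting(self):
        frame = MembraneFrame(
            box=(40.0, 20.0, 20.0),
            residue_id=[1, 1, 2, 2],
            species=["POPC"] * 4,
            bead_name=["PO4", "C1A", "PO4", "C1A"],
            positions=[[5.0, 5.0, 10.0], [5.0, 5.0, 9.7],
                       [5.5, 5.0, 10.0], [5.5, 5.0, 9.7]],
        )
        frame.leaflet = {1: "outer", 2: "outer"}
        pair = contact_matrix([frame] * 4, "outer")
        beads = contact_matrix([frame] * 4, "outer", bead_level=True)
        assert pair.raw[0, 0] == 1.0
        assert beads.raw[0, 0] == 4.0

    def test_cutoff_vs_minimum_image(self):
        with pytest.raises(GeometryError):
            contact_matrix([two_lipid_frame(0.9)] * 4, "outer", cutoff=15.0)

    def test_random_mixing_normalizes_to_unity(self):
        rng = np.random.default_rng(12)
        frames = []
        n = 360
        for _ in range(16):
            pos = np.stack([rng.uniform(0, 30, n), rng.uniform(0, 15, n),
                            rng.normal(10, 0.3, n)], axis=1)
            frame = MembraneFrame(
                box=(30.0, 15.0, 20.0),
                residue_id=np.arange(1, n + 1),
                species=rng.permutation(np.repeat(["POPC", "DIPE"], n // 2)),
                bead_name=np.full(n, "PO4"),
                positions=pos,
            )
            frame.leaflet = {int(r): "outer" for r in frame.residue_id}
            frames.append(frame)
        cm = contact_matrix(frames, "outer")
        # 3-sigma band around the ideal-mixing expectation of 1
        tol = np.maximum(3.0 * cm.norm_sd, 0.05)
        assert np.all(np.abs(cm.norm - 1.0) <= tol)
        np.testing.assert_allclose(cm.norm, cm.norm.T)

    def test_curvature_clustered_species_self_contacts(self, registry):
        # a species strongly driven to the bend concentrates there and
        # raises its self-contact enrichment above every other pair
        entries = (CompositionEntry(species="POPC", count=240),
                   CompositionEntry(species="PAP6", count=60))
        comp = Composition(leaflets={"outer": entries, "inner": entries})
        p = make_buckle_profile(40.0, 0.25)
        model = SortingModel(slopes={("inner", "PAP6"): -6.0})
        frames = [sample_frame(p, comp, model, seed=40 + s,
                               headgroup_only=True)[0] for s in range(32)]
        cm = contact_matrix(frames, "inner")
        i = cm.species.index("PAP6")
        assert cm.norm[i, i] == cm.norm.max()


def oriented_popc_frame(direction, n=120, rng_seed=2):
    """Flat membrane of POPC lipids whose successive beads all step along
    ``direction`` (unit 3-vector)."""
    rng = np.random.default_rng(rng_seed)
    spec = default_registry()["POPC"]
    nb = spec.n_beads
    heads = np.stack([rng.uniform(0, 40, n), rng.uniform(0, 20, n),
                      np.full(n, 12.0)], axis=1)
    step = 0.3 * np.asarray(direction, dtype=float)
    pos = heads[:, None, :] + np.arange(nb)[None, :, None] * step[None, None, :]
    frame = MembraneFrame(
        box=(40.0, 20.0, 30.0),
        residue_id=np.repeat(np.arange(1, n + 1), nb),
        species=np.full(n * nb, "POPC"),
        bead_name=np.tile(np.array(spec.bead_names), n),
        positions=pos.reshape(-1, 3),
    )
    frame.leaflet = {int(r): "outer" for r in np.arange(1, n + 1)}
    return frame


class TestOrderParameter:
    def test_bonds_parallel_to_normal(self):
        frame = oriented_popc_frame([0, 0, -1])
        p2 = tail_order_parameter([frame] * 4, "POPC",
                                  use_local_normal=False)
        assert p2.mean == pytest.approx(1.0, abs=1e-12)

    def test_bonds_perpendicular_to_normal(self):
        frame = oriented_popc_frame([1, 0, 0])
        p2 = tail_order_parameter([frame] * 4, "POPC",
                                  use_local_normal=False)
        assert p2.mean == pytest.approx(-0.5, abs=1e-12)

    def test_isotropic_bonds_average_zero(self):
        rng = np.random.default_rng(9)
        spec = default_registry()["POPC"]
        n, nb = 400, spec.n_beads
        steps = rng.normal(size=(n, nb, 3))
        pos = np.cumsum(0.3 * steps / np.linalg.norm(steps, axis=2,
                                                     keepdims=True), axis=1)
        pos[:, :, 0] += rng.uniform(0, 40, n)[:, None]
        pos[:, :, 1] += rng.uniform(0, 20, n)[:, None]
        pos[:, :, 2] += 12.0
        frame = MembraneFrame(
            box=(40.0, 20.0, 60.0),
            residue_id=np.repeat(np.arange(1, n + 1), nb),
            species=np.full(n * nb, "POPC"),
            bead_name=np.tile(np.array(spec.bead_names), n),
            positions=pos.reshape(-1, 3),
        )
        frame.leaflet = {int(r): "outer" for r in np.arange(1, n + 1)}
        p2 = tail_order_parameter([frame] * 4, "POPC",
                                  use_local_normal=False)
        # Monte-Carlo tolerance ~ 2/sqrt(n_bonds)
        assert abs(p2.mean) < 2.0 / np.sqrt(6 * n)

    def test_flat_membrane_local_equals_global_normal(
            self, profile_01, small_composition, registry):
        flat = make_buckle_profile(40.0, 0.0)
        frame, _ = sample_frame(flat, small_composition,
                                SortingModel(sigma_z=0.0), seed=5)
        local = tail_order_parameter([frame] * 4, "POPC", registry,
                                     use_local_normal=True)
        global_z = tail_order_parameter([frame] * 4, "POPC", registry,
                                        use_local_normal=False)
        assert local.mean == pytest.approx(global_z.mean, abs=1e-12)


class TestSplay:
    def _frame_with_tail_angle(self, angle_deg):
        spec = default_registry()["POPC"]
        pos = {b: np.zeros(3) for b in spec.bead_names}
        pos["NC3"] = np.array([5.0, 5.0, 13.2])
        pos["PO4"] = np.array([5.0, 5.0, 12.9])
        pos["GL1"] = np.array([5.0, 5.0, 12.6])
        pos["GL2"] = np.array([5.3, 5.0, 12.6])
        theta = np.radians(angle_deg)
        v1 = np.array([0.0, 0.0, -1.0])
        v2 = np.array([np.sin(theta), 0.0, -np.cos(theta)])
        for i, b in enumerate(spec.tails[0]):
            pos[b] = pos["GL1"] + 0.3 * (i + 1) * v1
        for i, b in enumerate(spec.tails[1]):
            pos[b] = pos["GL2"] + 0.3 * (i + 1) * v2
        arr = np.stack([pos[b] for b in spec.bead_names])
        frame = MembraneFrame(
            box=(40.0, 20.0, 20.0),
            residue_id=np.full(spec.n_beads, 1),
            species=np.full(spec.n_beads, "POPC"),
            bead_name=np.array(spec.bead_names),
            positions=arr,
        )
        frame.leaflet = {1: "outer"}
        return frame

    @pytest.mark.parametrize("angle", [0.0, 60.0, 180.0])
    def test_hand_placed_angles(self, angle):
        frame = self._frame_with_tail_angle(angle)
        st = splay_angle([frame] * 4, "POPC")
        assert st.mean == pytest.approx(angle, abs=1e-6)

    def test_cholesterol_not_applicable(self):
        with pytest.raises(NotApplicableError):
            splay_angle([], "CHOL")


class TestDescriptors:
    def test_head_tail_ratio_arithmetic(self, registry):
        from curvsort import LipidSpec
        spec = LipidSpec(
            name="TEST", headgroup_bead="H1",
            bead_names=tuple(f"H{i}" for i in range(1, 3))
            + tuple(f"T{i}" for i in range(1, 9)),
            n_head_beads=2, n_tail_beads=8, n_tail_bonds=6,
            n_unsaturated_bonds=0,
            tails=(tuple(f"T{i}" for i in range(1, 9)),),
        )
        assert spec.head_tail_ratio == 0.25

    def test_cholesterol_martini_bead_count(self, registry):
        # Martini 2.2 cholesterol topology: ROH + 5 ring + 2 chain beads
        assert registry["CHOL"].n_beads == 8

    def test_saturated_species_zero_unsaturation(self, registry):
        table = descriptor_table(registry)
        row = table[table.species == "DPSM"].iloc[0]
        assert row.unsaturation_fraction == 0.0


class TestCorrelation:
    def test_exact_negative_linear(self):
        mc = {"A": 0.1, "B": 0.2, "C": 0.3, "D": 0.4}
        d = {k: 5.0 - 10.0 * v for k, v in mc.items()}
        assert curvature_descriptor_correlation(mc, d) == pytest.approx(-1.0)

    def test_affine_invariance(self):
        rng = np.random.default_rng(7)
        mc = {f"s{i}": float(v) for i, v in enumerate(rng.normal(size=6))}
        d = {f"s{i}": float(v) for i, v in enumerate(rng.normal(size=6))}
        r1 = curvature_descriptor_correlation(mc, d)
        d2 = {k: 3.0 * v - 11.0 for k, v in d.items()}
        assert curvature_descriptor_correlation(mc, d2) == pytest.approx(
            r1, abs=1e-12)

    def test_permuted_labels_average_zero(self):
        rng = np.random.default_rng(11)
        keys = [f"s{i}" for i in range(8)]
        mc = {k: float(v) for k, v in zip(keys, rng.normal(size=8))}
        dvals = rng.normal(size=8)
        rs = []
        for _ in range(1000):
            perm = rng.permutation(dvals)
            d = {k: float(v) for k, v in zip(keys, perm)}
            rs.append(curvature_descriptor_correlation(mc, d))
        assert abs(np.mean(rs)) < 0.05

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValidationError):
            curvature_descriptor_correlation({"A": 1.0, "B": 2.0},
                                             {"A": 1.0, "B": 2.0})
        mc = {"A": 0.1, "B": 0.2, "C": 0.3}
        with pytest.raises(ValidationError):
            curvature_descriptor_correlation(mc, {k: 1.0 for k in mc})
        with pytest.raises(ValidationError):
            curvature_descriptor_correlation(mc, {k: mc[k] for k in mc},
                                             exclude=("A",))
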