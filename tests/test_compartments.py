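"""HU-range schemes, thresholding, region growing and priority subtraction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import phantomforge as pf
from phantomforge.compartments import HURange, validate_partition
from phantomforge.errors import ConfigError, GeometryError, SegmentationError
from tests.conftest import lesion_seeds


def _vol(voxels, spacing=(1, 1, 1)):
    return pf.CTVolume(np.asarray(voxels, dtype=float), spacing)


class TestBuiltinSchemes:
    def test_patient_printed_ranges(self, patient_scheme):
        assert patient_scheme["fat"].range.as_tuple() == (-124, -25)
        assert patient_scheme["lesion_nv"].range.as_tuple() == (-425, -375)
        assert patient_scheme["lungs"].range.as_tuple() == (-1024, -749)
        assert patient_scheme["vascular"].range.as_tuple() == (70, 225)

    def test_phantom_printed_ranges_with_repairs(self):
        ph = pf.builtin_scheme("phantom")
        assert ph["lesion_nv"].range.as_tuple() == (-431, -237)
        assert ph["lesion_v"].range.as_tuple() == (-586, -432)  # printed "586/-432"
        assert ph["bone"].range.as_tuple() == (-236, 2400)  # printed "-236/-361"

    def test_printed_infills(self, patient_scheme):
        assert patient_scheme.infill_map() == {
            "lungs": 10.0, "interstitium": 35.0, "fat": 40.0, "muscle": 55.0,
            "vascular": 70.0, "bone": 100.0, "lesion_nv": 50.0, "lesion_v": 62.5,
        }

    def test_unknown_label(self):
        with pytest.raises(ConfigError):
            pf.builtin_scheme("dog")


class TestValidatePartition:
    def _scheme(self, ranges, domain=(-1024, 2400)):
        comps = [
            pf.Compartment(f"c{i}", HURange(lo, hi)) for i, (lo, hi) in enumerate(ranges)
        ]
        return pf.CompartmentScheme(comps, HURange(*domain))

    def test_exact_tiling(self):
        rep = validate_partition(self._scheme([(-1024, -1), (0, 2400)]))
        assert rep.gaps == [] and rep.overlaps == []

    def test_gap_detection(self):
        rep = validate_partition(self._scheme([(-1024, -100), (0, 2400)]))
        assert rep.gaps == [(-99.0, -1.0)]

    def test_patient_overlaps_match_interval_oracle(self, patient_scheme):
        rep = validate_partition(patient_scheme)
        assert rep.gaps == []
        got = {(a, b): (lo, hi) for a, b, lo, hi in rep.overlaps}
        # independent interval-intersection oracle over the printed ranges
        printed = {c.name: c.range.as_tuple() for c in patient_scheme.compartments}
        names = list(printed)
        expected = {}
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                lo = max(printed[a][0], printed[b][0])
                hi = min(printed[a][1], printed[b][1])
                if lo <= hi:
                    expected[(a, b)] = (float(lo), float(hi))
        assert got == expected
        assert got[("muscle", "vascular")] == (70.0, 150.0)
        assert got[("vascular", "lesion_v")] == (70.0, 225.0)
        assert got[("lungs", "interstitium")] == (-750.0, -749.0)


class TestThresholdMask:
    def test_ramp_count_equals_interval_width(self, ramp_volume):
        m = pf.threshold_mask(ramp_volume, HURange(-124, -25))
        assert int(m.sum()) == 100

    @given(
        lo=st.integers(-1024, 2400), width=st.integers(0, 500)
    )
    @settings(max_examples=30, deadline=None)
    def test_ramp_count_property(self, lo, width, ramp_volume):
        hi = min(lo + width, 2400)
        m = pf.threshold_mask(ramp_volume, HURange(lo, hi))
        assert int(m.sum()) == hi - lo + 1

    def test_full_domain_all_ones(self, ramp_volume):
        assert pf.threshold_mask(ramp_volume, HURange(-1024, 2400)).all()

    def test_range_above_max_empty(self, ramp_volume):
        assert not pf.threshold_mask(ramp_volume, HURange(3000, 3500)).any()


def _flood_fill_oracle(in_range, seed, connectivity):
    """Brute-force BFS flood fill."""
    offsets = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                if (dx, dy, dz) == (0, 0, 0):
                    continue
                manhattan = abs(dx) + abs(dy) + abs(dz)
                if connectivity == 6 and manhattan > 1:
                    continue
                if connectivity == 18 and manhattan > 2:
                    continue
                offsets.append((dx, dy, dz))
    out = np.zeros_like(in_range)
    stack = [seed]
    out[seed] = True
    shape = in_range.shape
    while stack:
        x, y, z = stack.pop()
        for dx, dy, dz in offsets:
            p = (x + dx, y + dy, z + dz)
            if all(0 <= p[i] < shape[i] for i in range(3)) and in_range[p] and not out[p]:
                out[p] = True
                stack.append(p)
    return out


class TestRegionGrow:
    def test_only_seeded_blob_returned(self):
        vox = np.full((10, 10, 3), -1000.0)
        vox[1:3, 1:3, 1] = 0.0
        vox[6:9, 6:9, 1] = 0.0
        m = pf.region_grow(_vol(vox), HURange(-50, 50), seeds=[(1, 1, 1)])
        assert m[1:3, 1:3, 1].all() and not m[6:9, 6:9, 1].any()

    def test_border_clipping_no_wraparound(self):
        vox = np.full((6, 6, 6), 0.0)
        m = pf.region_grow(_vol(vox), HURange(-50, 50), seeds=[(0, 0, 0)])
        assert m.all()  # one block, growth stops at borders

    def test_seed_out_of_range_rejected(self):
        vox = np.full((4, 4, 4), -1000.0)
        with pytest.raises(SegmentationError):
            pf.region_grow(_vol(vox), HURange(0, 100), seeds=[(0, 0, 0)])

    @pytest.mark.parametrize("connectivity", [6, 18, 26])
    def test_random_pattern_matches_flood_fill_oracle(self, connectivity):
        rng = np.random.default_rng(11)
        in_range = rng.random((9, 9, 9)) < 0.45
        seed = tuple(np.argwhere(in_range)[0])
        vox = np.where(in_range, 0.0, -1000.0)
        got = pf.region_grow(_vol(vox), HURange(-50, 50), [seed], connectivity)
        assert np.array_equal(got, _flood_fill_oracle(in_range, seed, connectivity))

    def test_26_superset_of_6(self):
        rng = np.random.default_rng(5)
        in_range = rng.random((8, 8, 8)) < 0.5
        seed = tuple(np.argwhere(in_range)[0])
        vox = np.where(in_range, 0.0, -1000.0)
        m6 = pf.region_grow(_vol(vox), HURange(-50, 50), [seed], 6)
        m26 = pf.region_grow(_vol(vox), HURange(-50, 50), [seed], 26)
        assert not (m6 & ~m26).any()


class TestSubtractMasks:
    def test_identities(self):
        rng = np.random.default_rng(1)
        a = rng.random((6, 6, 6)) < 0.4
        empty = np.zeros_like(a)
        assert np.array_equal(pf.subtract_masks(a, empty), a)
        assert not pf.subtract_masks(a, a).any()

    def test_shape_mismatch(self):
        with pytest.raises(GeometryError):
            pf.subtract_masks(np.zeros((2, 2, 2), bool), np.zeros((3, 3, 3), bool))

    @given(seed=st.integers(0, 1000))
    @settings(max_examples=25, deadline=None)
    def test_cardinality_conservation(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.random((5, 5, 5)) < 0.5
        b = rng.random((5, 5, 5)) < 0.5
        assert pf.subtract_masks(a, b).sum() + (a & b).sum() == a.sum()


class TestSegmentCompartments:
    def test_noiseless_chest_recovers_resolvable_compartments(
        self, chest_noiseless, patient_scheme
    ):
        """With exact compartment means, every compartment whose published
        mean lies (uniquely) inside its printed range comes back voxel-exact.
        The NV-lesion's published mean (-36.27) is OUTSIDE its printed range
        (-425..-375) - an inconsistency of the published numbers - so it is
        unrecoverable and its voxels land in fat's range instead."""
        vol, truth = chest_noiseless
        res = pf.segment_compartments(vol, patient_scheme)
        dscs = {n: pf.dice(truth.masks[n], res.maskset.masks[n]).dsc for n in truth.names}
        for n in ("lungs", "interstitium", "muscle", "vascular", "bone", "lesion_v"):
            assert dscs[n] == 1.0, (n, dscs[n])
        assert dscs["lesion_nv"] == 0.0
        assert 0.97 < dscs["fat"] < 1.0

    def test_noisy_chest_lungs_and_lesion(self, chest_sd30, patient_scheme):
        """30 HU voxel noise: lungs and the (seeded) V-lesion stay above the
        pilot-run thresholds."""
        vol, truth = chest_sd30
        scheme = patient_scheme.with_seeds(lesion_seeds(truth))
        res = pf.segment_compartments(vol, scheme)
        assert pf.dice(truth.masks["lungs"], res.maskset.masks["lungs"]).dsc >= 0.95
        assert pf.dice(truth.masks["lesion_v"], res.maskset.masks["lesion_v"]).dsc >= 0.8

    def test_priority_rule_on_contested_voxel(self):
        vox = np.full((3, 3, 3), -1000.0)
        vox[1, 1, 1] = 100.0  # contested between muscle and vascular
        scheme = pf.CompartmentScheme(
            [
                pf.Compartment("muscle", HURange(-24, 150), priority=10),
                pf.Compartment("vascular", HURange(70, 225), priority=60),
            ],
            HURange(-1024, 2400),
        )
        res = pf.segment_compartments(_vol(vox), scheme, body=None)
        assert res.maskset.masks["vascular"][1, 1, 1]
        assert not res.maskset.masks["muscle"][1, 1, 1]

    def test_disjoint_after_subtraction(self, chest_sd30, patient_scheme):
        vol, truth = chest_sd30
        res = pf.segment_compartments(vol, patient_scheme.with_seeds(lesion_seeds(truth)))
        assert res.maskset.pairwise_disjoint()

    def test_threshold_only_scheme_equals_independent_thresholds(self, chest_sd30):
        vol, _ = chest_sd30
        scheme = pf.CompartmentScheme(
            [
                pf.Compartment("low", HURange(-1024, -500)),
                pf.Compartment("high", HURange(-499, 2400)),
            ],
            HURange(-1024, 2400),
        )
        res = pf.segment_compartments(vol, scheme, body=None)
        for name, rng_ in (("low", HURange(-1024, -500)), ("high", HURange(-499, 2400))):
            assert np.array_equal(res.maskset.masks[name], pf.threshold_mask(vol, rng_))

    def test_range_centered_constant_volume_exact_recovery(self, patient_scheme):
        """Synthesizing from masks with constant range-centred HU and re-
        segmenting recovers every mask exactly."""
        spec = pf.DigitalChestSpec(noise_sd=0.0, seed=4, shape=(64, 64, 40),
                                   spacing=(6.0, 6.0, 6.0))
        _, truth = pf.make_digital_chest(spec)
        centered = {
            c.name: (c.range.lo + c.range.hi) / 2.0 for c in patient_scheme.compartments
        }
        scan = pf.simulate_phantom_scan(
            truth, pf.VirtualScanConfig(transfer=centered, noise_sd=0.0)
        )
        res = pf.segment_compartments(scan, patient_scheme.with_seeds(lesion_seeds(truth, ("lesion_v", "lesion_nv"))))
        for n in truth.names:
            assert pf.dice(truth.masks[n], res.maskset.masks[n]).dsc == 1.0, n

    def test_skin_shell_option(self, chest_noiseless, patient_scheme):
        vol, _ = chest_noiseless
        res = pf.segment_compartments(vol, patient_scheme, skin_shell_voxels=2)
        assert res.maskset.masks["skin"].any()
        assert res.maskset.pairwise_disjoint()
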