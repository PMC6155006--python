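from collections import deque

import numpy as np
import pytest
from hypothesis import given, strategies as st
from hypothesis.extra import numpy as hnp

from mpcsim.geometry import TubuleKind
from mpcsim.phantom import Calibration, LABELS, ScanPreset, Tomogram, voxelize
from mpcsim.quant import (
    COMPARTMENTS,
    auto_seeds,
    classify_compartments,
    density_stats,
    region_grow,
    segment_minerals,
    watershed_segment,
)

from test_phantom import small_scene


def tomo_of(volume, voxel=1.0):
    return Tomogram(volume=np.asarray(volume, dtype=np.uint16),
                    voxel_size=voxel, calibration=Calibration())


def brute_force_region_grow(volume, seeds, delta):
    """Independent oracle: synchronous-sweep seeded growth with explicit
    queues and python arithmetic.  Each sweep floods, at the current
    region mean, to every unclaimed 26-connected voxel within delta;
    the mean is recomputed between sweeps; regions are processed in
    seed order and a claimed voxel is never revisited."""
    vol = np.asarray(volume, dtype=float)
    labels = np.zeros(vol.shape, dtype=int)
    regions = []
    for sd in seeds:
        if labels[sd] != 0:
            continue
        labels[sd] = len(regions) + 1
        regions.append({"members": [sd]})
    nbrs = [
        (dz, dy, dx)
        for dz in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dx in (-1, 0, 1)
        if (dz, dy, dx) != (0, 0, 0)
    ]
    while True:
        grew = False
        for rid, reg in enumerate(regions, start=1):
            mean = sum(vol[m] for m in reg["members"]) / len(reg["members"])
            queue = deque(reg["members"])
            added = []
            seen = set(reg["members"])
            while queue:
                z, y, x = queue.popleft()
                for dz, dy, dx in nbrs:
                    p = (z + dz, y + dy, x + dx)
                    if any(c < 0 or c >= n for c, n in zip(p, vol.shape)):
                        continue
                    if p in seen or labels[p] != 0:
                        continue
                    if abs(vol[p] - mean) <= delta:
                        seen.add(p)
                        labels[p] = rid
                        added.append(p)
                        queue.append(p)
            if added:
                reg["members"] += added
                grew = True
        if not grew:
            return labels


class TestRegionGrow:
    def test_uniform_volume_single_region(self):
        tomo = tomo_of(np.full((6, 6, 6), 500))
        seg = region_grow(tomo, [(3, 3, 3)], delta=1.0)
        assert (seg.label_volume == 1).all()

    def test_two_blocks_exact_recovery(self):
        vol = np.zeros((4, 4, 8))
        vol[:, :, :4] = 1000
        vol[:, :, 4:] = 5000
        tomo = tomo_of(vol)
        seg = region_grow(tomo, [(0, 0, 0), (0, 0, 7)], delta=500.0)
        assert ((seg.label_volume == 1) == (vol == 1000)).all()
        assert ((seg.label_volume == 2) == (vol == 5000)).all()

    def test_seed_outside_volume(self):
        tomo = tomo_of(np.zeros((3, 3, 3)))
        with pytest.raises(ValueError):
            region_grow(tomo, [(5, 0, 0)], delta=1.0)

    def test_background_seed_skipped_with_warning(self):
        vol = np.zeros((3, 3, 3))
        vol[1, 1, 1] = 900
        tomo = tomo_of(vol)
        with pytest.warns(UserWarning, match="skipped"):
            seg = region_grow(tomo, [(0, 0, 0)], delta=10.0,
                              background_threshold=100.0)
        assert not seg.region_mask().any()
        assert seg.seeds_used == []

    @given(
        hnp.arrays(
            np.int64,
            hnp.array_shapes(min_dims=3, max_dims=3, min_side=2, max_side=5),
            elements=st.integers(0, 3),
        ),
        st.integers(0, 10**6),
        st.sampled_from([500.0, 1500.0]),
    )
    def test_matches_brute_force_oracle(self, levels, seedpos, delta):
        vol = levels * 1000
        shape = vol.shape
        n = vol.size
        flat1 = seedpos % n
        flat2 = (seedpos // n) % n
        seeds = [tuple(int(c) for c in np.unravel_index(f, shape))
                 for f in (flat1, flat2)]
        tomo = tomo_of(vol)
        seg = region_grow(tomo, seeds, delta=delta)
        oracle = brute_force_region_grow(vol, seeds, delta)
        assert np.array_equal(seg.label_volume, oracle)

    def test_noiseless_phantom_recovers_ground_truth(self):
        net, state, preset = small_scene(radius=10.0, deposit=4.0, length=80.0)
        tomo = voxelize(net, state, preset, seed=0)
        seg = segment_minerals(tomo, delta=4000.0, density_threshold=300.0)
        truth = tomo.labels == LABELS["intratubular_mineral"]
        assert np.array_equal(seg.region_mask(), truth)


class TestClassification:
    def test_compartments_by_containment(self):
        net, state, preset = small_scene(radius=10.0, deposit=4.0, length=80.0)
        tomo = voxelize(net, state, preset, seed=0)
        seg = segment_minerals(tomo, delta=4000.0)
        comp = classify_compartments(seg, net, tomo)
        got = comp.label_volume[seg.region_mask()]
        assert (got == COMPARTMENTS["intratubular"]).all()

    def test_unclassified_without_network(self):
        net, state, preset = small_scene()
        tomo = voxelize(net, state, preset, seed=0)
        seg = segment_minerals(tomo, delta=4000.0)
        comp = classify_compartments(seg, None, tomo)
        got = comp.label_volume[seg.region_mask()]
        assert (got == COMPARTMENTS["unclassified"]).all()


class TestDensityStats:
    def test_constant_region_stats(self):
        net, state, preset = small_scene(radius=10.0, deposit=4.0)
        tomo = voxelize(net, state, preset, seed=0)
        seg = segment_minerals(tomo, delta=4000.0)
        comp = classify_compartments(seg, net, tomo)
        rep = density_stats(tomo, comp, tomo.labels > 0)
        st_ = rep.compartments["intratubular"]
        assert st_.mean_md == pytest.approx(800.0, abs=1.0)
        assert st_.sd_md == pytest.approx(0.0, abs=1.0)
        assert st_.min_md == pytest.approx(st_.max_md, abs=1.0)

    def test_vf_half_mask(self):
        vol = np.zeros((4, 4, 4))
        vol[:2] = 20000
        tomo = tomo_of(vol)
        seg = region_grow(tomo, [(0, 0, 0)], delta=100.0)
        comp = classify_compartments(seg, None, tomo)
        rep = density_stats(tomo, comp)
        assert rep.compartments["unclassified"].vf_percent == pytest.approx(50.0)

    def test_axis_permutation_invariance(self):
        rng = np.random.default_rng(0)
        vol = rng.integers(0, 30000, size=(5, 6, 7))
        tomo = tomo_of(vol)
        seg = region_grow(tomo, [(2, 3, 4)], delta=15000.0)
        comp = classify_compartments(seg, None, tomo)
        rep = density_stats(tomo, comp)
        tomo_t = tomo_of(np.transpose(vol, (2, 0, 1)))
        seg_t = region_grow(tomo_t, [(4, 2, 3)], delta=15000.0)
        comp_t = classify_compartments(seg_t, None, tomo_t)
        rep_t = density_stats(tomo_t, comp_t)
        a = rep.compartments["unclassified"]
        b = rep_t.compartments["unclassified"]
        assert a.mean_md == pytest.approx(b.mean_md)
        assert a.sd_md == pytest.approx(b.sd_md)
        assert a.vf_percent == pytest.approx(b.vf_percent)

    def test_empty_compartment_absent(self):
        tomo = tomo_of(np.zeros((3, 3, 3)))
        seg = region_grow(tomo, [(0, 0, 0)], delta=1.0)
        seg.label_volume[:] = 0  # nothing segmented
        comp = classify_compartments(seg, None, tomo)
        rep = density_stats(tomo, comp)
        assert rep.compartments == {}


class TestAlternatives:
    def test_watershed_flag_recovers_blob(self):
        net, state, preset = small_scene(radius=10.0, deposit=4.0)
        tomo = voxelize(net, state, preset, seed=0)
        seg = watershed_segment(tomo, density_threshold=300.0)
        truth = tomo.labels == LABELS["intratubular_mineral"]
        assert np.array_equal(seg.region_mask(), truth)

    def test_auto_seeds_inside_mineral(self):
        net, state, preset = small_scene(radius=10.0, deposit=4.0)
        tomo = voxelize(net, state, preset, seed=0)
        seeds = auto_seeds(tomo, density_threshold=300.0)
        assert seeds
        dens = tomo.density()
        for sd in seeds:
            assert dens[sd] > 300.0
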