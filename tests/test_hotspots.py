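"""Hot-spot scanning: oracle equivalence with brute-force disc counting."""

import math

import numpy as np
import pytest

from gist_mvd import DomainError, FieldGeometry, density_map, select_hotspots
from gist_mvd.errors import ConfigError

from conftest import mask_from


def brute_force_density(mask, radius, stride=1):
    """Independent nested-loop disc scan: vessel-pixel fraction per center."""
    h, w = mask.shape
    ry = int(math.floor(radius))
    out = np.full((h, w), np.nan)
    disc = [
        (dy, dx)
        for dy in range(-ry, ry + 1)
        for dx in range(-ry, ry + 1)
        if dy * dy + dx * dx <= radius * radius
    ]
    for y in range(ry, h - ry, 1):
        for x in range(ry, w - ry, 1):
            if y % stride or x % stride:
                continue
            hits = sum(mask[y + dy, x + dx] for dy, dx in disc)
            out[y, x] = hits / len(disc)
    return out


def brute_force_greedy(mask, radius, k, stride=1):
    """Greedy top-k selection over the full lattice, dumbest possible way."""
    dens = brute_force_density(mask, radius, stride)
    cands = sorted(
        ((float(dens[y, x]), y, x)
         for y, x in zip(*np.nonzero(~np.isnan(dens)))),
        key=lambda t: (-t[0], t[1], t[2]),
    )
    chosen = []
    for d, y, x in cands:
        if all(math.hypot(x - cx, y - cy) >= 2 * radius for cy, cx in
               [(cy, cx) for _, cy, cx in chosen]):
            chosen.append((d, y, x))
            if len(chosen) == k:
                break
    return chosen


class TestDensityMap:
    def test_empty_mask_density_zero(self):
        vm = mask_from(np.zeros((20, 20)))
        dens = density_map(vm, FieldGeometry(field_diameter_um=6.0))
        valid = ~np.isnan(dens)
        assert valid.any()
        assert (dens[valid] == 0.0).all()

    def test_full_mask_density_one(self):
        vm = mask_from(np.ones((15, 15)))
        dens = density_map(vm, FieldGeometry(field_diameter_um=6.0))
        valid = ~np.isnan(dens)
        assert (dens[valid] == 1.0).all()

    @pytest.mark.parametrize("seed,p", [(0, 0.1), (1, 0.4), (2, 0.8)])
    def test_matches_bruteforce_oracle(self, seed, p):
        rng = np.random.default_rng(seed)
        mask = rng.random((20, 20)) < p
        vm = mask_from(mask)
        geometry = FieldGeometry(field_diameter_um=6.0)  # radius 3 px
        np.testing.assert_allclose(
            density_map(vm, geometry),
            brute_force_density(mask, geometry.radius_px(1.0)),
            equal_nan=True,
        )

    def test_stride_excludes_offlattice_centers(self):
        vm = mask_from(np.ones((20, 20)))
        dens = density_map(vm, FieldGeometry(field_diameter_um=6.0, scan_stride_px=3))
        ys, xs = np.nonzero(~np.isnan(dens))
        assert (ys % 3 == 0).all() and (xs % 3 == 0).all()

    def test_field_larger_than_image_rejected(self):
        vm = mask_from(np.ones((10, 10)))
        with pytest.raises(DomainError, match="does not fit"):
            density_map(vm, FieldGeometry(field_diameter_um=50.0))

    def test_invalid_geometry_rejected(self):
        with pytest.raises(ConfigError):
            FieldGeometry(field_diameter_um=0.0)
        with pytest.raises(ConfigError):
            FieldGeometry(scan_stride_px=0)


class TestSelectHotspots:
    def test_top_field_lands_on_dense_cluster(self):
        mask = np.zeros((60, 60), dtype=bool)
        mask[28:35, 28:35] = True  # one dense cluster
        fields = select_hotspots(mask_from(mask), 3, FieldGeometry(field_diameter_um=10.0))
        (x, y) = fields[0].center_xy
        assert abs(x - 31) <= 1 and abs(y - 31) <= 1
        assert fields[0].density == max(f.density for f in fields)

    def test_empty_mask_tie_break_matches_oracle(self):
        mask = np.zeros((30, 30), dtype=bool)
        geometry = FieldGeometry(field_diameter_um=8.0)
        fields = select_hotspots(mask_from(mask), 3, geometry)
        oracle = brute_force_greedy(mask, geometry.radius_px(1.0), 3)
        assert [(f.center_xy[1], f.center_xy[0]) for f in fields] == [
            (y, x) for _, y, x in oracle
        ]
        assert all(f.density == 0.0 for f in fields)

    @pytest.mark.parametrize("seed,k", [(0, 3), (1, 4), (2, 5), (3, 3)])
    def test_greedy_matches_bruteforce_oracle(self, seed, k):
        rng = np.random.default_rng(seed)
        mask = rng.random((50, 50)) < 0.3
        geometry = FieldGeometry(field_diameter_um=8.0)
        fields = select_hotspots(mask_from(mask), k, geometry)
        oracle = brute_force_greedy(mask, geometry.radius_px(1.0), k)
        got = [(round(f.density, 12), f.center_xy[1], f.center_xy[0]) for f in fields]
        want = [(round(d, 12), y, x) for d, y, x in oracle]
        assert got == want

    def test_pairwise_distance_at_least_diameter(self):
        rng = np.random.default_rng(9)
        mask = rng.random((80, 80)) < 0.2
        geometry = FieldGeometry(field_diameter_um=12.0)
        fields = select_hotspots(mask_from(mask), 5, geometry)
        for i in range(len(fields)):
            for j in range(i + 1, len(fields)):
                (xi, yi), (xj, yj) = fields[i].center_xy, fields[j].center_xy
                assert math.hypot(xi - xj, yi - yj) >= geometry.field_diameter_um

    def test_sorted_by_descending_density(self):
        rng = np.random.default_rng(4)
        mask = rng.random((60, 60)) < 0.3
        fields = select_hotspots(mask_from(mask), 4, FieldGeometry(field_diameter_um=10.0))
        dens = [f.density for f in fields]
        assert dens == sorted(dens, reverse=True)

    def test_deterministic(self):
        rng = np.random.default_rng(5)
        mask = rng.random((50, 50)) < 0.25
        geometry = FieldGeometry(field_diameter_um=10.0)
        assert select_hotspots(mask_from(mask), 3, geometry) == select_hotspots(
            mask_from(mask), 3, geometry
        )

    def test_k_out_of_protocol_range_rejected(self):
        vm = mask_from(np.ones((50, 50)))
        for k in (2, 6):
            with pytest.raises(DomainError):
                select_hotspots(vm, k, FieldGeometry(field_diameter_um=8.0))

    def test_image_too_small_for_k_fields(self):
        vm = mask_from(np.ones((12, 12)))
        with pytest.raises(DomainError, match="too small"):
            select_hotspots(vm, 5, FieldGeometry(field_diameter_um=10.0))

    def test_adding_pixels_in_top_field_never_lowers_its_density(self):
        rng = np.random.default_rng(6)
        mask = rng.random((40, 40)) < 0.15
        geometry = FieldGeometry(field_diameter_um=10.0)
        before = select_hotspots(mask_from(mask), 3, geometry)[0]
        (cx, cy), r = before.center_xy, before.radius_px
        ys, xs = np.mgrid[0 : mask.shape[0], 0 : mask.shape[1]]
        disc = (xs - cx) ** 2 + (ys - cy) ** 2 <= r**2
        grown = mask | (disc & (rng.random(mask.shape) < 0.5))
        dens_after = density_map(mask_from(grown), geometry)[cy, cx]
        assert dens_after >= before.density
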