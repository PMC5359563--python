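"""Zone change components, the LUCDI index, kernel surfaces, covariates."""

import numpy as np
import pandas as pd
import pytest

from landchange.dynamics import (
    covariate_report,
    default_bandwidth,
    kernel_surface,
    lucdi,
    zone_change_components,
)
from landchange.dynamics import _kernel_2d
from landchange.maps import Zone, ZoneSet
from landchange.synthetic import generate_zones


def one_zone(shape):
    return ZoneSet([Zone(zone_id=1, mask=np.ones(shape, dtype=bool))])


def components_oracle(m1, m2, zone_grid, zids, codes):
    """Per-cell loop oracle for the zone components."""
    rows = []
    for zid in zids:
        per = {c: {"nochange": 0, "increase": 0, "decrease": 0} for c in codes}
        ny, nx = m1.shape
        for r in range(ny):
            for c in range(nx):
                if zone_grid[r, c] != zid:
                    continue
                a, b = m1.grid[r, c], m2.grid[r, c]
                if a == b:
                    per[a]["nochange"] += 1
                else:
                    per[b]["increase"] += 1
                    per[a]["decrease"] += 1
        for code in codes:
            rows.append({"zone_id": zid, "code": code, **per[code]})
    return pd.DataFrame(rows)


class TestZoneComponents:
    def test_identical_maps_have_zero_change(self, random_map_pair):
        m1, _ = random_map_pair(shape=(10, 10))
        comp = zone_change_components(m1, m1, one_zone(m1.shape))
        assert (comp["increase"] == 0).all() and (comp["decrease"] == 0).all()
        assert comp["nochange"].sum() == 100

    def test_two_cell_hand_count(self, make_map):
        m1 = make_map(np.array([[1, 1]]))
        m2 = make_map(np.array([[1, 2]]))
        m2.legend = {1: "class_1", 2: "class_2"}
        m1.legend = dict(m2.legend)
        comp = zone_change_components(m1, m2, one_zone((1, 2))).set_index("class")
        assert comp.loc["class_1", "nochange"] == 1
        assert comp.loc["class_1", "decrease"] == 1
        assert comp.loc["class_2", "increase"] == 1
        assert comp.loc["class_2", "nochange"] == 0

    def test_quadrant_zones_match_loop_oracle(self, random_map_pair):
        m1, m2 = random_map_pair(shape=(100, 100), seed=21)
        zones = generate_zones(m1, 4, seed=3)
        comp = zone_change_components(m1, m2, zones)
        zone_grid = np.zeros(m1.shape, dtype=int)
        for z in zones:
            zone_grid[z.mask] = z.zone_id
        codes = sorted(m1.legend)
        oracle = components_oracle(m1, m2, zone_grid, [z.zone_id for z in zones], codes)
        merged = comp.merge(
            oracle.assign(**{"class": oracle["code"].map(m1.legend)}),
            on=["zone_id", "class"],
            suffixes=("", "_oracle"),
        )
        for col in ("nochange", "increase", "decrease"):
            assert (merged[col] == merged[f"{col}_oracle"]).all()

    def test_components_aggregate_to_whole_map_budget(self, random_map_pair):
        """Summing zone components over wall-to-wall zones reproduces the
        map-level gross gain/loss cell counts."""
        from landchange.crosstab import change_budget, cross_tabulate

        m1, m2 = random_map_pair(shape=(60, 60), seed=8)
        zones = generate_zones(m1, 9, seed=5)
        comp = zone_change_components(m1, m2, zones)
        by_class = comp.groupby("class")[["increase", "decrease", "nochange"]].sum()
        T = cross_tabulate(m1, m2, basis="cells")
        b = change_budget(T.to_percent())
        total = T.P.sum()
        for k, cls in enumerate(T.classes):
            assert by_class.loc[cls, "increase"] == pytest.approx(b.gain[k] * total / 100)
            assert by_class.loc[cls, "decrease"] == pytest.approx(b.loss[k] * total / 100)
            assert by_class.loc[cls, "nochange"] == pytest.approx(
                b.persistence[k] * total / 100
            )

    def test_empty_zone_flagged(self, make_map):
        m = make_map(np.array([[0, 1]]), nodata=0)
        zs = ZoneSet(
            [
                Zone(zone_id=1, mask=np.array([[True, False]])),  # only nodata
                Zone(zone_id=2, mask=np.array([[False, True]])),
            ]
        )
        comp = zone_change_components(m, m, zs)
        assert comp.attrs["empty_zones"] == [1]


class TestLucdi:
    def test_unchanged_zone_is_zero(self, random_map_pair):
        m1, _ = random_map_pair(shape=(8, 8))
        comp = zone_change_components(m1, m1, one_zone(m1.shape))
        zd = lucdi(comp, 2000.0, 2013.0)
        assert zd.lucdi_of(1) == 0.0

    def test_fully_changed_zone_is_one(self, make_map):
        m1 = make_map(np.ones((5, 5), dtype=int), legend={1: "a", 2: "b"})
        m2 = make_map(np.full((5, 5), 2), legend={1: "a", 2: "b"})
        comp = zone_change_components(m1, m2, one_zone((5, 5)))
        assert lucdi(comp, 2000.0, 2013.0).lucdi_of(1) == 1.0

    def test_partial_change_exact_fraction(self, make_map):
        """10-cell zone with 4 changed cells: index 0.4, annualized 0.4/13."""
        g1 = np.ones((2, 5), dtype=int)
        g2 = g1.copy()
        g2.flat[:4] = 2
        legend = {1: "a", 2: "b"}
        m1 = make_map(g1, legend=legend)
        m2 = make_map(g2, legend=legend)
        comp = zone_change_components(m1, m2, one_zone((2, 5)))
        zd = lucdi(comp, 2000.0, 2013.0)
        assert zd.lucdi_of(1) == pytest.approx(0.4)
        row = zd.summary_table.iloc[0]
        assert row["lucdi_annual"] == pytest.approx(0.4 / 13.0)

    def test_reversed_period_rejected(self, make_map):
        m = make_map(np.ones((2, 2), dtype=int))
        comp = zone_change_components(m, m, one_zone((2, 2)))
        with pytest.raises(ValueError, match="t_2 must exceed"):
            lucdi(comp, 2013.0, 2000.0)

    def test_zero_area_zone_undefined(self, make_map):
        m = make_map(np.array([[0, 1]]), nodata=0)
        zs = ZoneSet([Zone(1, mask=np.array([[True, False]]))])
        zd = lucdi(zone_change_components(m, m, zs), 2000.0, 2013.0)
        assert np.isnan(zd.lucdi_of(1))
        assert zd.summary_table["flagged"].iloc[0]

    def test_invariant_to_class_relabelling(self, random_map_pair):
        """The index depends only on the changed/unchanged partition."""
        m1, m2 = random_map_pair(shape=(20, 20), seed=30)
        zs = one_zone(m1.shape)
        base = lucdi(zone_change_components(m1, m2, zs), 2000.0, 2013.0).lucdi_of(1)
        # apply the same permutation of class codes to both maps
        perm = {1: 4, 2: 6, 3: 1, 4: 5, 5: 3, 6: 2}
        for m in (m1, m2):
            m.grid = np.vectorize(perm.get)(m.grid)
            m.legend = {perm[c]: f"class_{perm[c]}" for c in perm}
        again = lucdi(zone_change_components(m1, m2, zs), 2000.0, 2013.0).lucdi_of(1)
        assert again == pytest.approx(base)

    def test_union_zone_is_area_weighted_mean(self, random_map_pair):
        m1, m2 = random_map_pair(shape=(30, 30), seed=31)
        left = np.zeros(m1.shape, dtype=bool)
        left[:, :10] = True
        zs_split = ZoneSet([Zone(1, mask=left), Zone(2, mask=~left)])
        zs_union = ZoneSet([Zone(9, mask=np.ones(m1.shape, dtype=bool))])
        zd = lucdi(zone_change_components(m1, m2, zs_split), 2000.0, 2013.0)
        t = zd.summary_table.set_index("zone_id")
        w = t["valid_area"]
        expected = (t["lucdi"] * w).sum() / w.sum()
        union = lucdi(zone_change_components(m1, m2, zs_union), 2000.0, 2013.0)
        assert union.lucdi_of(9) == pytest.approx(expected)


class TestKernelSurface:
    def test_single_point_peaks_at_its_cell(self, make_map):
        m = make_map(np.ones((21, 21), dtype=int))
        t = m.transform
        cx = t.x_origin + 5.5 * t.dx
        cy = t.y_origin - 15.5 * t.dy
        surf = kernel_surface(np.array([[cx, cy]]), np.array([1.0]), m, bandwidth=200.0)
        r, c = np.unravel_index(surf.grid.argmax(), surf.grid.shape)
        assert (r, c) == (15, 5)
        assert (surf.grid >= 0).all()

    def test_two_distant_points_equal_maxima(self, make_map):
        m = make_map(np.ones((40, 40), dtype=int))
        t = m.transform
        h = 3 * t.dx
        p1 = (t.x_origin + 5.5 * t.dx, t.y_origin - 5.5 * t.dy)
        p2 = (t.x_origin + 34.5 * t.dx, t.y_origin - 34.5 * t.dy)
        surf = kernel_surface(np.array([p1, p2]), np.array([1.0, 1.0]), m, bandwidth=h)
        g = surf.grid
        assert g[5, 5] == pytest.approx(g[34, 34], abs=1e-9)
        assert g[5, 5] == g.max()

    @pytest.mark.parametrize("kernel", ["quartic", "gaussian"])
    def test_matches_double_loop_oracle(self, make_map, kernel):
        rng = np.random.default_rng(12)
        m = make_map(np.ones((25, 25), dtype=int))
        t = m.transform
        pts = np.column_stack(
            [
                rng.uniform(t.x_origin, t.x_origin + 25 * t.dx, 5),
                rng.uniform(t.y_origin - 25 * t.dy, t.y_origin, 5),
            ]
        )
        w = rng.uniform(0.1, 1.0, 5)
        h = 6 * t.dx
        surf = kernel_surface(pts, w, m, bandwidth=h, kernel_name=kernel)
        oracle = np.zeros((25, 25))
        for r in range(25):
            for c in range(25):
                x = t.x_origin + (c + 0.5) * t.dx
                y = t.y_origin - (r + 0.5) * t.dy
                for (px, py), wk in zip(pts, w):
                    d2 = (x - px) ** 2 + (y - py) ** 2
                    oracle[r, c] += wk * _kernel_2d(np.array(d2), h, kernel)
        assert np.allclose(surf.grid, oracle, atol=1e-9)

    def test_linear_in_weights(self, make_map):
        rng = np.random.default_rng(13)
        m = make_map(np.ones((15, 15), dtype=int))
        t = m.transform
        pts = np.column_stack(
            [
                rng.uniform(t.x_origin, t.x_origin + 15 * t.dx, 4),
                rng.uniform(t.y_origin - 15 * t.dy, t.y_origin, 4),
            ]
        )
        w = rng.uniform(0.0, 1.0, 4)
        s1 = kernel_surface(pts, w, m, bandwidth=100.0)
        s2 = kernel_surface(pts, 2 * w, m, bandwidth=100.0)
        assert np.allclose(s2.grid, 2 * s1.grid)

    def test_zero_bandwidth_rejected(self, make_map):
        m = make_map(np.ones((3, 3), dtype=int))
        with pytest.raises(ValueError, match="bandwidth"):
            kernel_surface(np.array([[0.0, 0.0]]), np.array([1.0]), m, bandwidth=0.0)

    def test_default_bandwidth_is_tenth_of_extent(self, make_map):
        m = make_map(np.ones((10, 20), dtype=int))  # 20 cols * 30 m = 600 m
        assert default_bandwidth(m) == pytest.approx(60.0)


class TestCovariateReport:
    def _zd(self, values):
        comp = pd.DataFrame(
            {
                "zone_id": np.repeat(np.arange(len(values)), 1),
                "class": "a",
                "nochange": 100 * (1 - np.asarray(values)),
                "increase": 100 * np.asarray(values),
                "decrease": 100 * np.asarray(values),
            }
        )
        return lucdi(comp, 2000.0, 2013.0)

    def test_identical_covariate_correlates_perfectly(self):
        vals = np.linspace(0.05, 0.8, 10)
        zd = self._zd(vals)
        cov = pd.DataFrame({"zone_id": np.arange(10), "driver": vals})
        rep = covariate_report(zd, cov)
        assert rep.loc[0, "spearman_rho"] == pytest.approx(1.0)

    def test_negated_covariate_anticorrelates(self):
        vals = np.linspace(0.05, 0.8, 10)
        zd = self._zd(vals)
        cov = pd.DataFrame({"zone_id": np.arange(10), "driver": -vals})
        rep = covariate_report(zd, cov)
        assert rep.loc[0, "spearman_rho"] == pytest.approx(-1.0)

    def test_independent_covariate_weakly_correlated(self):
        """Under independence the rank correlation stays small for most seeds."""
        rng = np.random.default_rng(0)
        hits = 0
        for _ in range(20):
            vals = rng.uniform(0.01, 0.99, 100)
            zd = self._zd(vals)
            cov = pd.DataFrame({"zone_id": np.arange(100), "driver": rng.normal(size=100)})
            rho = covariate_report(zd, cov).loc[0, "spearman_rho"]
            hits += abs(rho) < 0.3
        assert hits >= 19

    def test_too_few_matching_zones_rejected(self):
        zd = self._zd([0.1, 0.2, 0.3])
        cov = pd.DataFrame({"zone_id": [0, 1], "driver": [1.0, 2.0]})
        with pytest.raises(ValueError, match="at least 3"):
            covariate_report(zd, cov)
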