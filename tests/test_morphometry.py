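import itertools
import math

import numpy as np
import pytest

from inhibmap.datasets import load_basket_proportions, load_cs56_synapses
from inhibmap.morphology import Morphology, Section
from inhibmap.morphometry import (
    SynapseMorphometryRecord,
    area_target_regression,
    basket_terminal_proportion,
    class_area_comparison,
    sholl_intersections,
)


def records_from(areas_by_class, sizes=None):
    recs = []
    for cls, areas in areas_by_class.items():
        for k, a in enumerate(areas):
            size = None if cls == "soma" else (
                sizes[cls][k] if sizes else 1.0 + 0.1 * k
            )
            recs.append(
                SynapseMorphometryRecord(
                    junction_area=a, target_class=cls, target_size=size
                )
            )
    return recs


class TestClassComparison:
    def test_cs56_class_means(self):
        sites = load_cs56_synapses()
        recs = records_from({
            cls: [s.junction_area for s in sites if s.target == cls]
            for cls in ("soma", "shaft", "spine")
        })
        summary = class_area_comparison(recs)
        assert summary.loc["soma", "mean_area_um2"] == pytest.approx(0.2375)
        assert summary.loc["shaft", "mean_area_um2"] == pytest.approx(0.102)
        assert summary.loc["spine", "mean_area_um2"] == pytest.approx(0.0497, abs=1e-4)
        assert (
            summary.loc["soma", "mean_area_um2"]
            > summary.loc["shaft", "mean_area_um2"]
            > summary.loc["spine", "mean_area_um2"]
        )

    def test_identical_samples_not_distinguishable(self):
        recs = records_from({"soma": [0.2] * 5, "shaft": [0.2] * 5})
        summary = class_area_comparison(recs)
        _u, p = summary.attrs["pairwise"][("soma", "shaft")]
        assert p > 0.99

    def test_u_statistic_matches_pair_counting(self, rng):
        """Exact-oracle check: U = #{(x, y): x > y} + ties/2 on small
        samples."""
        x = rng.normal(0.3, 0.1, size=6).round(3)
        y = rng.normal(0.2, 0.1, size=5).round(3)
        recs = records_from({"soma": np.abs(x), "shaft": np.abs(y)})
        summary = class_area_comparison(recs)
        u, _p = summary.attrs["pairwise"][("soma", "shaft")]
        brute = sum(
            1.0 if xi > yi else 0.5 if xi == yi else 0.0
            for xi, yi in itertools.product(np.abs(x), np.abs(y))
        )
        assert u == pytest.approx(brute)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            class_area_comparison(records_from({"soma": [0.1, 0.2]}))


class TestRegression:
    def test_exact_line(self):
        sizes = {"spine": [0.1, 0.2, 0.3, 0.4]}
        areas = [2 * s + 0.1 for s in sizes["spine"]]
        recs = records_from({"spine": areas}, sizes=sizes)
        fit = area_target_regression(recs, "spine")
        assert fit["slope"] == pytest.approx(2.0)
        assert fit["intercept"] == pytest.approx(0.1)
        assert fit["r"] == pytest.approx(1.0)

    def test_hand_computed_five_points(self):
        """Closed-form OLS on x = 1..5, y = (0.2, 0.5, 0.4, 0.8, 0.7):
        slope = Σ(x−x̄)(y−ȳ)/Σ(x−x̄)² = 1.3/10, intercept = ȳ − slope·x̄."""
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        y = [0.2, 0.5, 0.4, 0.8, 0.7]
        recs = [
            SynapseMorphometryRecord(junction_area=yi, target_class="shaft",
                                     target_size=xi)
            for xi, yi in zip(x, y)
        ]
        fit = area_target_regression(recs, "shaft")
        assert fit["slope"] == pytest.approx(0.13, rel=1e-12)
        assert fit["intercept"] == pytest.approx(0.52 - 0.13 * 3.0, rel=1e-12)

    def test_order_invariance(self, rng):
        sizes = list(rng.uniform(0.1, 1.0, size=8))
        areas = list(0.3 * np.asarray(sizes) + rng.normal(0, 0.01, size=8))
        recs = [
            SynapseMorphometryRecord(junction_area=a, target_class="spine",
                                     target_size=s)
            for a, s in zip(areas, sizes)
        ]
        f1 = area_target_regression(recs, "spine")
        f2 = area_target_regression(list(reversed(recs)), "spine")
        assert f1 == f2

    def test_residuals_orthogonal_to_predictor(self, rng):
        sizes = rng.uniform(0.5, 2.0, size=30)
        areas = 0.25 * sizes + rng.normal(0, 0.02, size=30)
        recs = [
            SynapseMorphometryRecord(junction_area=a, target_class="shaft",
                                     target_size=s)
            for a, s in zip(areas, sizes)
        ]
        fit = area_target_regression(recs, "shaft")
        resid = areas - (fit["slope"] * sizes + fit["intercept"])
        assert abs(np.dot(resid, sizes)) < 1e-10

    def test_degenerate_predictor_rejected(self):
        recs = [
            SynapseMorphometryRecord(junction_area=a, target_class="spine",
                                     target_size=0.5)
            for a in (0.1, 0.2, 0.3)
        ]
        with pytest.raises(ValueError, match="degenerate"):
            area_target_regression(recs, "spine")

    def test_soma_has_no_covariate(self):
        with pytest.raises(ValueError):
            area_target_regression([], "soma")


class TestBasketProportions:
    def test_cs55_percentage(self):
        df = basket_terminal_proportion(load_basket_proportions())
        cs55 = df[df["pair"] == "CS55"]["percent"].iloc[0]
        assert round(cs55, 1) == 37.2

    def test_mean_and_sd_across_pairs(self):
        df = basket_terminal_proportion(load_basket_proportions())
        assert round(df.attrs["mean_percent"], 1) == 28.4
        assert round(df.attrs["sd_percent"], 1) == 7.6

    def test_single_pair_sd_zero(self):
        df = basket_terminal_proportion([(10, 40)])
        assert df["percent"].iloc[0] == pytest.approx(25.0)
        assert df.attrs["sd_percent"] == 0.0

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            basket_terminal_proportion([(0, 0)])


def axon_tree(segments):
    """Build an axon morphology from a list of (parent_index, start, end)."""
    m = Morphology([
        Section(id=1, parent_id=None, kind="soma", length=1.0, diameter=1.0,
                points=np.array([[0.0, 0.0, 0.0, 0.5]]))
    ])
    ids = {}
    for k, (parent, p0, p1) in enumerate(segments):
        pid = 1 if parent is None else ids[parent]
        pts = np.array([[*p0, 0.2], [*p1, 0.2]])
        sec = Section(
            id=m.next_id(), parent_id=pid, kind="axon",
            length=float(np.linalg.norm(np.subtract(p1, p0))), diameter=0.4,
            points=pts,
        )
        m.add(sec)
        ids[k] = sec.id
    return m


class TestSholl:
    def test_straight_axon_single_crossing(self):
        m = axon_tree([(None, (0, 0, 0), (100, 0, 0))])
        prof = sholl_intersections(m, (0, 0, 0), [10, 50, 90, 150])
        assert list(prof.counts) == [1, 1, 1, 0]

    def test_y_branch_doubles_beyond_fork(self):
        m = axon_tree([
            (None, (0, 0, 0), (50, 0, 0)),
            (0, (50, 0, 0), (100, 30, 0)),
            (0, (50, 0, 0), (100, -30, 0)),
        ])
        prof = sholl_intersections(m, (0, 0, 0), [25, 75])
        assert list(prof.counts) == [1, 2]

    def test_counts_match_dense_sampling_oracle(self, rng):
        """Brute force: sample each segment densely and count sign changes
        of |p| − r."""
        segs = []
        pos = (0.0, 0.0, 0.0)
        for k in range(12):
            end = tuple(rng.uniform(-80, 80, size=3))
            segs.append((k - 1 if k else None, pos, end))
            pos = end if rng.uniform() < 0.6 else (0.0, 0.0, 0.0)
            if pos == (0.0, 0.0, 0.0):
                pos = segs[0][1]
        # rebuild as a simple chain rooted at the first point to keep the
        # tree valid
        chain = [(None, segs[0][1], segs[0][2])]
        for k in range(1, 12):
            chain.append((k - 1, chain[k - 1][2], tuple(rng.uniform(-80, 80, 3))))
        m = axon_tree(chain)
        radii = [15.0, 35.0, 55.0, 75.0]
        prof = sholl_intersections(m, (0, 0, 0), radii)
        for r, count in zip(radii, prof.counts):
            brute = 0
            for (_p, a, b) in chain:
                ts = np.linspace(0.0, 1.0, 4001)[:-1]
                pts = np.outer(1 - ts, a) + np.outer(ts, b)
                d = np.linalg.norm(pts, axis=1) - r
                brute += int(np.sum(np.abs(np.diff(np.sign(d))) > 1))
            assert count == brute

    def test_rotation_invariance(self, rng):
        chain = [(None, (0.0, 0.0, 0.0), (40.0, 10.0, 5.0)),
                 (0, (40.0, 10.0, 5.0), (90.0, -20.0, 30.0))]
        m = axon_tree(chain)
        radii = [20.0, 60.0, 95.0]
        base = sholl_intersections(m, (0, 0, 0), radii)
        theta = 1.1
        R = np.array([
            [math.cos(theta), -math.sin(theta), 0.0],
            [math.sin(theta), math.cos(theta), 0.0],
            [0.0, 0.0, 1.0],
        ])
        rot_chain = [
            (p, tuple(R @ np.asarray(a)), tuple(R @ np.asarray(b)))
            for (p, a, b) in chain
        ]
        rot = sholl_intersections(axon_tree(rot_chain), (0, 0, 0), radii)
        assert list(base.counts) == list(rot.counts)
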