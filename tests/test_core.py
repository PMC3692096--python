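"""CircleMap core: universes, sorting, grouping, aggregation, geometry, color."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from circlemapviz import (
    ColorScale,
    GroupPartition,
    RingSpec,
    SampleAnnotation,
    SampleOrder,
    SortKey,
    aggregate_ring,
    build_glyph,
    colorize,
    partition_samples,
    sample_universe,
    sort_samples,
    spoke_geometry,
)
from circlemapviz.errors import ConfigurationError, KeyResolutionError
from circlemapviz.fixtures import random_matrix

from conftest import make_matrix, oracle_sort, random_annotation


class TestSampleUniverse:
    def test_union_first_appearance(self):
        m1 = make_matrix([[1, 2]], ["g"], ["s1", "s2"])
        m2 = make_matrix([[1, 2]], ["g"], ["s2", "s3"])
        assert sample_universe([m1, m2], "union").samples == ["s1", "s2", "s3"]

    def test_intersection_ordered_by_first(self):
        m1 = make_matrix([[1, 2]], ["g"], ["s1", "s2"])
        m2 = make_matrix([[1, 2]], ["g"], ["s2", "s3"])
        assert sample_universe([m1, m2], "intersection").samples == ["s2"]

    def test_empty_intersection_errors(self):
        m1 = make_matrix([[1]], ["g"], ["s1"])
        m2 = make_matrix([[1]], ["g"], ["s2"])
        with pytest.raises(ConfigurationError):
            sample_universe([m1, m2], "intersection")

    @pytest.mark.parametrize("policy", ["union", "intersection"])
    def test_matches_set_semantics_on_random_matrices(self, policy):
        rng = np.random.default_rng(4)
        mats = []
        for k in range(5):
            cols = [f"s{int(i):02d}" for i in
                    rng.choice(20, size=rng.integers(8, 15), replace=False)]
            mats.append(make_matrix(rng.standard_normal((2, len(cols))),
                                    ["a", "b"], cols, label=f"m{k}"))
        out = sample_universe(mats, policy).samples
        if policy == "union":
            expected = set().union(*(set(m.samples) for m in mats))
            assert set(out) == expected
            # ordered by first appearance across the matrix list
            seen = {}
            for m in mats:
                for s in m.samples:
                    seen.setdefault(s)
            assert out == list(seen)
        else:
            common = set(mats[0].samples)
            for m in mats[1:]:
                common &= set(m.samples)
            assert out == [s for s in mats[0].samples if s in common]


class TestSortSamples:
    def _ring(self, values, samples, gene="g", label="expr"):
        return make_matrix([values], [gene], samples, label=label)

    def test_single_ascending_key(self):
        m = self._ring([3, 1, 2], ["s1", "s2", "s3"])
        key = SortKey("ring_value", gene="g", ring="expr")
        out = sort_samples(SampleOrder(["s1", "s2", "s3"]), [key], [m])
        assert out.samples == ["s2", "s3", "s1"]

    def test_primary_annotation_secondary_ring(self):
        ann = SampleAnnotation("grp", {"s1": "B", "s2": "A", "s3": "A"})
        m = self._ring([9, 5, 1], ["s1", "s2", "s3"])
        keys = [
            SortKey("annotation", annotation_name="grp"),
            SortKey("ring_value", gene="g", ring="expr"),
        ]
        out = sort_samples(SampleOrder(["s1", "s2", "s3"]), keys, [m], [ann])
        assert out.samples == ["s3", "s2", "s1"]

    def test_all_equal_keeps_input_order(self):
        m = self._ring([2, 2, 2], ["s3", "s1", "s2"])
        key = SortKey("ring_value", gene="g", ring="expr")
        out = sort_samples(SampleOrder(["s3", "s1", "s2"]), [key], [m])
        assert out.samples == ["s3", "s1", "s2"]

    def test_missing_sorts_last_both_directions(self):
        m = self._ring([float("nan"), 1, 2], ["s1", "s2", "s3"])
        for direction in ("ascending", "descending"):
            key = SortKey("ring_value", gene="g", ring="expr", direction=direction)
            out = sort_samples(SampleOrder(["s1", "s2", "s3"]), [key], [m])
            assert out.samples[-1] == "s1"

    def test_unresolvable_key(self):
        m = self._ring([1], ["s1"])
        with pytest.raises(KeyResolutionError):
            sort_samples(
                SampleOrder(["s1"]),
                [SortKey("ring_value", gene="nope", ring="expr")],
                [m],
            )

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 15))
        samples = [f"s{int(i):02d}" for i in rng.permutation(n)]
        n_keys = int(rng.integers(1, 4))
        matrices, annotations, keys = [], [], []
        key_values, directions = [], []
        for k in range(n_keys):
            direction = "ascending" if rng.random() < 0.5 else "descending"
            if rng.random() < 0.6:
                vals = np.round(rng.standard_normal(n) * 2, 1)
                vals[rng.random(n) < 0.25] = np.nan
                m = make_matrix([vals], ["g"], samples, label=f"ring{k}")
                matrices.append(m)
                keys.append(SortKey("ring_value", gene="g", ring=f"ring{k}",
                                    direction=direction))
                key_values.append({
                    s: (None if math.isnan(v) else float(v))
                    for s, v in zip(samples, vals)
                })
            else:
                ann = random_annotation(samples, ["x", "y", "z"],
                                        seed=seed * 10 + k, missing_rate=0.2)
                ann = SampleAnnotation(f"ann{k}", ann.assignments)
                annotations.append(ann)
                keys.append(SortKey("annotation", annotation_name=f"ann{k}",
                                    direction=direction))
                key_values.append({s: ann.category(s) for s in samples})
            directions.append(direction)
        out = sort_samples(SampleOrder(samples), keys, matrices, annotations)
        assert out.samples == oracle_sort(samples, key_values, directions)

    def test_idempotence_and_direction_reversal(self):
        rng = np.random.default_rng(77)
        samples = [f"s{i:02d}" for i in range(12)]
        vals = rng.standard_normal(12)
        m = make_matrix([vals], ["g"], samples, label="expr")
        asc = SortKey("ring_value", gene="g", ring="expr")
        desc = SortKey("ring_value", gene="g", ring="expr", direction="descending")
        once = sort_samples(SampleOrder(samples), [asc], [m])
        twice = sort_samples(once, [asc], [m])
        assert once.samples == twice.samples
        assert sorted(once.samples) == sorted(samples)  # permutation
        rev = sort_samples(SampleOrder(samples), [desc], [m])
        # all values distinct -> exact reversal
        assert rev.samples == list(reversed(once.samples))


class TestPartitionSamples:
    def test_first_appearance_order(self):
        ann = SampleAnnotation("t", {"s1": "X", "s2": "Y", "s3": "X"})
        p = partition_samples(SampleOrder(["s1", "s2", "s3"]), ann)
        assert p.groups == [("X", ["s1", "s3"]), ("Y", ["s2"])]

    def test_single_category(self):
        ann = SampleAnnotation("t", {"s1": "X", "s2": "X"})
        p = partition_samples(SampleOrder(["s1", "s2"]), ann)
        assert p.groups == [("X", ["s1", "s2"])]

    def test_unannotated_trailing_group(self):
        ann = SampleAnnotation("t", {"s1": "X"})
        p = partition_samples(SampleOrder(["s1", "s2"]), ann)
        assert p.groups[-1] == ("unannotated", ["s2"])

    def test_zero_coverage_errors(self):
        ann = SampleAnnotation("t", {})
        with pytest.raises(ConfigurationError):
            partition_samples(SampleOrder(["s1"]), ann)

    def test_matches_brute_force_on_random_annotation(self):
        samples = [f"s{i:02d}" for i in range(50)]
        ann = random_annotation(samples, ["a", "b", "c", "d"], seed=2)
        p = partition_samples(SampleOrder(samples), ann)
        # disjoint cover in universe order
        flat = [s for _, members in p for s in members]
        assert sorted(flat) == sorted(samples)
        for label, members in p:
            for s in members:
                expected = ann.category(s)
                assert (expected or "unannotated") == label
            assert members == [s for s in samples if s in set(members)]


class TestAggregateRing:
    def test_mean(self):
        m = make_matrix([[1, 3]], ["g"], ["s1", "s2"])
        p = GroupPartition([("all", ["s1", "s2"])])
        assert aggregate_ring(m, "g", p) == [("all", 2.0)]

    def test_missing_skipped_and_all_missing(self):
        m = make_matrix([[float("nan"), 4, float("nan")]], ["g"],
                        ["s1", "s2", "s3"])
        p = GroupPartition([("a", ["s1", "s2"]), ("b", ["s3"])])
        out = aggregate_ring(m, "g", p)
        assert out[0] == ("a", 4.0)
        assert out[1][0] == "b" and math.isnan(out[1][1])

    def test_gene_absent_is_key_error(self):
        m = make_matrix([[1]], ["g"], ["s1"])
        with pytest.raises(KeyResolutionError):
            aggregate_ring(m, "nope", GroupPartition([("a", ["s1"])]))

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force_group_means(self, seed):
        from conftest import oracle_group_means

        rng = np.random.default_rng(seed)
        m = random_matrix(3, 24, seed=seed, missing_rate=0.3)
        samples = list(m.samples)
        rng.shuffle(samples)
        cuts = sorted(rng.choice(range(1, 24), 3, replace=False))
        groups = []
        prev = 0
        for gi, cut in enumerate([*cuts, 24]):
            groups.append((f"grp{gi}", samples[prev:cut]))
            prev = cut
        p = GroupPartition(groups)
        got = aggregate_ring(m, "G001", p)
        expected = oracle_group_means(m, "G001", groups)
        for (gl, gv), (el, ev) in zip(got, expected):
            assert gl == el
            if ev is None:
                assert math.isnan(gv)
            else:
                assert gv == pytest.approx(ev)

    def test_invariant_to_within_group_order(self):
        m = random_matrix(2, 10, seed=1, missing_rate=0.2)
        fwd = GroupPartition([("a", m.samples[:5]), ("b", m.samples[5:])])
        rev = GroupPartition([("a", m.samples[:5][::-1]),
                              ("b", m.samples[5:][::-1])])
        a = aggregate_ring(m, "G000", fwd)
        b = aggregate_ring(m, "G000", rev)
        for (l1, v1), (l2, v2) in zip(a, b):
            assert l1 == l2
            assert (math.isnan(v1) and math.isnan(v2)) or v1 == v2


class TestSpokeGeometry:
    def test_unweighted_quarters(self):
        cells = spoke_geometry(4)
        assert cells == [(0.0, 90.0), (90.0, 90.0), (180.0, 90.0), (270.0, 90.0)]

    def test_single_cell_full_turn(self):
        assert spoke_geometry(1) == [(0.0, 360.0)]

    def test_weight_proportionality(self):
        cells = spoke_geometry(2, [3.0, 1.0])
        assert cells[0] == (0.0, 270.0)
        assert cells[1] == (270.0, 90.0)

    def test_nonpositive_weight_rejected(self):
        with pytest.raises(ConfigurationError):
            spoke_geometry(2, [1.0, 0.0])

    @given(st.integers(min_value=1, max_value=200),
           st.randoms(use_true_random=False))
    @settings(max_examples=50, deadline=None)
    def test_extents_sum_to_full_turn(self, n, rnd):
        weights = [rnd.uniform(0.1, 5.0) for _ in range(n)]
        cells = spoke_geometry(n, weights)
        assert math.isclose(sum(e for _, e in cells), 360.0, abs_tol=1e-9)
        # contiguous: each cell starts where the previous ended
        for (s0, e0), (s1, _) in zip(cells, cells[1:]):
            assert math.isclose(s0 + e0, s1, abs_tol=1e-9)


class TestColorize:
    scale = ColorScale("continuous", -2.0, 0.0, 2.0,
                       low_color="#0000ff", mid_color="#ffffff",
                       high_color="#ff0000")

    def test_midpoint_exact(self):
        assert colorize(0.0, self.scale) == "#ffffff"

    def test_clipping(self):
        assert colorize(-99, self.scale) == "#0000ff"
        assert colorize(99, self.scale) == "#ff0000"

    def test_linear_interpolation_channelwise(self):
        # value halfway between mid and max -> channel-wise midpoint
        assert colorize(1.0, self.scale) == "#ff8080"

    def test_missing_color(self):
        assert colorize(float("nan"), self.scale, "#abcdef") == "#abcdef"

    def test_binary_lookup(self):
        scale = ColorScale.binary("#ffffff", "#000000")
        assert colorize(0, scale) == "#ffffff"
        assert colorize(1, scale) == "#000000"

    def test_degenerate_range_rejected(self):
        with pytest.raises(ConfigurationError):
            ColorScale("continuous", 1.0, 1.0, 1.0)


class TestBuildGlyph:
    def test_full_mode_scale_endpoints(self):
        m = make_matrix([[-1, 0, 1]], ["g"], ["s1", "s2", "s3"])
        scale = ColorScale("continuous", -1, 0, 1, low_color="#0000ff",
                           mid_color="#ffffff", high_color="#ff0000")
        glyph = build_glyph("g", [RingSpec(m, 0, scale)],
                            order=SampleOrder(["s1", "s2", "s3"]))
        colors = [c.color for c in glyph.cells[0]]
        assert colors == ["#0000ff", "#ffffff", "#ff0000"]

    def test_gene_absent_from_one_ring(self):
        m1 = make_matrix([[1.0]], ["g"], ["s1"], label="a")
        m2 = make_matrix([[2.0]], ["other"], ["s1"], label="b")
        glyph = build_glyph("g", [RingSpec(m1, 0), RingSpec(m2, 1)],
                            order=SampleOrder(["s1"]), missing_color="#999999")
        assert not math.isnan(glyph.cells[0][0].value)
        assert math.isnan(glyph.cells[1][0].value)
        assert glyph.cells[1][0].color == "#999999"

    def test_aggregated_cells_are_group_means(self, cohort):
        matrices, annotation, _ = cohort
        mut = matrices[0]
        universe = SampleOrder(mut.samples)
        partition = partition_samples(universe, annotation)
        glyph = build_glyph("BRAF", [RingSpec(mut, 0)], partition=partition)
        expected = dict(aggregate_ring(mut, "BRAF", partition))
        for cell in glyph.cells[0]:
            assert cell.value == pytest.approx(expected[cell.key])

    def test_exactly_one_of_order_partition(self):
        m = make_matrix([[1]], ["g"], ["s1"])
        with pytest.raises(ConfigurationError):
            build_glyph("g", [RingSpec(m, 0)])

    def test_empty_rings_rejected(self):
        with pytest.raises(ConfigurationError):
            build_glyph("g", [], order=SampleOrder(["s1"]))

    def test_aggregated_binary_colorized_from_fraction(self):
        m = make_matrix([[1, 1, 0, 0]], ["g"], list("abcd"), kind="binary")
        p = GroupPartition([("hi", ["a", "b"]), ("lo", ["c", "d"])])
        glyph = build_glyph("g", [RingSpec(m, 0)], partition=p)
        hi, lo = glyph.cells[0]
        assert hi.value == 1.0 and lo.value == 0.0
        assert lo.color == "#ffffff"  # zero frequency -> white end of ramp
        assert hi.color != lo.color
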