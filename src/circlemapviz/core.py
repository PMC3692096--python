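"""CircleMap construction: coordinated rings, spoke sorting, aggregation.

A CircleMap is a per-gene glyph of nested rings, one ring per data
platform, each ring divided into angular cells.  In *full* mode every
cell is one sample's spoke; in *aggregated* mode every cell is one
sample group's segment, colored by the group's mean value.  The defining
property is coordination: all rings of all glyphs in a scene share one
cell order, so sorting the spokes by any single ring's values (or by a
phenotype annotation) rearranges every glyph identically and lets the
eye trace a sample across the whole pathway.

Angular convention: origin at 12 o'clock, angles grow clockwise, units
are degrees.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, KeyResolutionError
from .model import MISSING, OmicsMatrix, SampleAnnotation, is_missing

#: Cell color used for MISSING values everywhere.
DEFAULT_MISSING_COLOR = "#c8c8c8"

UNANNOTATED_LABEL = "unannotated"


# ---------------------------------------------------------------------------
# colors


def _hex_to_rgb(color: str) -> tuple[int, int, int]:
    color = color.lstrip("#")
    return tuple(int(color[i : i + 2], 16) for i in (0, 2, 4))  # type: ignore[return-value]


def _rgb_to_hex(rgb: tuple[float, float, float]) -> str:
    return "#%02x%02x%02x" % tuple(int(round(max(0.0, min(255.0, c)))) for c in rgb)


def _lerp(c0: str, c1: str, t: float) -> str:
    r0, g0, b0 = _hex_to_rgb(c0)
    r1, g1, b1 = _hex_to_rgb(c1)
    return _rgb_to_hex((r0 + (r1 - r0) * t, g0 + (g1 - g0) * t, b0 + (b1 - b0) * t))


@dataclass
class ColorScale:
    """Value -> color map for one ring.

    Continuous scales interpolate linearly low -> mid -> high between
    ``vmin``/``vmid``/``vmax`` and clip outside [vmin, vmax].  Binary and
    discrete scales look colors up in ``categories`` keyed by the numeric
    code.  ``for_aggregation`` returns the scale suitable for group means:
    a binary ring's mean is a mutation *frequency* in [0, 1], shown on a
    white -> full-color ramp; continuous scales are unchanged.
    """

    kind: str = "continuous"
    vmin: float = -1.0
    vmid: float = 0.0
    vmax: float = 1.0
    low_color: str = "#2166ac"
    mid_color: str = "#f7f7f7"
    high_color: str = "#b2182b"
    categories: dict[float, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind == "continuous":
            if not (self.vmin < self.vmax):
                raise ConfigurationError(
                    f"continuous scale requires vmin < vmax, got "
                    f"[{self.vmin}, {self.vmax}]"
                )
            if not (self.vmin <= self.vmid <= self.vmax):
                raise ConfigurationError("vmid must lie within [vmin, vmax]")

    # -- constructors -------------------------------------------------------

    @classmethod
    def diverging(
        cls,
        vmax: float,
        vmid: float = 0.0,
        low_color: str = "#2166ac",
        mid_color: str = "#f7f7f7",
        high_color: str = "#b2182b",
    ) -> "ColorScale":
        """Symmetric blue-white-red scale on [-vmax, +vmax] around vmid."""
        return cls(
            "continuous",
            vmid - vmax,
            vmid,
            vmid + vmax,
            low_color,
            mid_color,
            high_color,
        )

    @classmethod
    def binary(
        cls, zero_color: str = "#f7f7f7", one_color: str = "#404040"
    ) -> "ColorScale":
        return cls("binary", categories={0.0: zero_color, 1.0: one_color})

    @classmethod
    def categorical(cls, categories: dict[float, str]) -> "ColorScale":
        return cls("discrete", categories=dict(categories))

    @classmethod
    def from_matrix(cls, matrix: OmicsMatrix, clip_quantile: float = 0.95) -> "ColorScale":
        """Default scale for a matrix.

        Continuous: symmetric around 0, clipping at the ``clip_quantile``
        quantile of |values| (outlier-robust, the heatmap convention).
        Binary: two fixed colors.  Discrete: a fixed categorical palette
        over the observed codes.
        """
        if matrix.value_kind == "binary":
            return cls.binary()
        values = matrix.data.to_numpy(dtype=float).ravel()
        values = values[~np.isnan(values)]
        if matrix.value_kind == "discrete":
            palette = [
                "#1b9e77", "#d95f02", "#7570b3", "#e7298a",
                "#66a61e", "#e6ab02", "#a6761d", "#666666",
            ]
            codes = sorted(set(values.tolist()))
            return cls.categorical(
                {code: palette[i % len(palette)] for i, code in enumerate(codes)}
            )
        if values.size == 0:
            return cls.diverging(1.0)
        vmax = float(np.quantile(np.abs(values), clip_quantile))
        if vmax == 0.0:
            vmax = 1.0
        return cls.diverging(vmax)

    # -- behavior -----------------------------------------------------------

    def for_aggregation(self) -> "ColorScale":
        if self.kind == "binary":
            one = self.categories.get(1.0, "#404040")
            return ColorScale(
                "continuous", 0.0, 0.0, 1.0,
                low_color="#ffffff", mid_color="#ffffff", high_color=one,
            )
        return self

    def __call__(self, value, missing_color: str = DEFAULT_MISSING_COLOR) -> str:
        return colorize(value, self, missing_color)


def colorize(
    value, scale: ColorScale, missing_color: str = DEFAULT_MISSING_COLOR
) -> str:
    """Resolve one value to a color under a scale; MISSING -> missing color."""
    if is_missing(value):
        return missing_color
    value = float(value)
    if scale.kind == "continuous":
        v = min(max(value, scale.vmin), scale.vmax)
        if v <= scale.vmid:
            span = scale.vmid - scale.vmin
            t = 1.0 if span == 0 else (v - scale.vmin) / span
            return _lerp(scale.low_color, scale.mid_color, t)
        span = scale.vmax - scale.vmid
        t = (v - scale.vmid) / span
        return _lerp(scale.mid_color, scale.high_color, t)
    try:
        return scale.categories[value]
    except KeyError:
        raise ConfigurationError(
            f"value {value!r} has no color in {scale.kind} scale"
        ) from None


# ---------------------------------------------------------------------------
# sample ordering


@dataclass
class SampleOrder:
    """The shared spoke permutation every ring in a scene obeys."""

    samples: list[str]

    def __post_init__(self) -> None:
        if len(self.samples) != len(set(self.samples)):
            raise ConfigurationError("sample order contains duplicates")

    def __iter__(self):
        return iter(self.samples)

    def __len__(self) -> int:
        return len(self.samples)


@dataclass(frozen=True)
class SortKey:
    """One level of the spoke sort.

    ``kind="ring_value"`` sorts by a gene's values in one ring
    (``gene`` + ``ring`` = platform label); ``kind="annotation"`` sorts by
    a categorical sample annotation (``annotation_name``).  MISSING values
    sort after all non-missing under either direction.
    """

    kind: str
    gene: str | None = None
    ring: str | None = None
    annotation_name: str | None = None
    direction: str = "ascending"

    def __post_init__(self) -> None:
        if self.kind not in ("ring_value", "annotation"):
            raise ConfigurationError(f"unknown sort-key kind {self.kind!r}")
        if self.direction not in ("ascending", "descending"):
            raise ConfigurationError(f"unknown direction {self.direction!r}")
        if self.kind == "ring_value" and (self.gene is None or self.ring is None):
            raise ConfigurationError("ring_value key requires gene and ring")
        if self.kind == "annotation" and self.annotation_name is None:
            raise ConfigurationError("annotation key requires annotation_name")


def sample_universe(
    matrices: list[OmicsMatrix], policy: str = "union"
) -> SampleOrder:
    """Build the sample universe from a list of matrices.

    ``union``: every sample appearing in any matrix, ordered by first
    appearance.  ``intersection``: samples present in all matrices,
    ordered as in the first matrix; empty intersection is an error.
    """
    if not matrices:
        raise ConfigurationError("need at least one matrix")
    if policy == "union":
        seen: dict[str, None] = {}
        for m in matrices:
            for s in m.samples:
                seen.setdefault(s)
        return SampleOrder(list(seen))
    if policy == "intersection":
        common = set(matrices[0].samples)
        for m in matrices[1:]:
            common &= set(m.samples)
        ordered = [s for s in matrices[0].samples if s in common]
        if not ordered:
            raise ConfigurationError("sample intersection is empty")
        return SampleOrder(ordered)
    raise ConfigurationError(f"unknown universe policy {policy!r}")


def _resolve_key_values(
    key: SortKey,
    universe: SampleOrder,
    matrices: list[OmicsMatrix],
    annotations: list[SampleAnnotation],
) -> list:
    if key.kind == "ring_value":
        matrix = next(
            (m for m in matrices if m.platform_label == key.ring), None
        )
        if matrix is None:
            raise KeyResolutionError(f"no matrix with platform label {key.ring!r}")
        if key.gene not in matrix:
            raise KeyResolutionError(
                f"gene {key.gene!r} absent from ring {key.ring!r}"
            )
        return [matrix.value(key.gene, s) for s in universe]
    annotation = next(
        (a for a in annotations if a.name == key.annotation_name), None
    )
    if annotation is None:
        raise KeyResolutionError(f"unknown annotation {key.annotation_name!r}")
    return [annotation.category(s) for s in universe]


def sort_samples(
    universe: SampleOrder,
    keys: list[SortKey],
    matrices: list[OmicsMatrix] | None = None,
    annotations: list[SampleAnnotation] | None = None,
) -> SampleOrder:
    """Lexicographic multi-key spoke sort, first key primary.

    The sort is stable with respect to the input order (which therefore
    acts as the final tie-break), and MISSING values rank after every
    non-missing value regardless of direction.  Direction is applied by
    rank so numeric ring values and string annotation categories sort the
    same way.
    """
    matrices = matrices or []
    annotations = annotations or []
    subkeys: list[dict[str, tuple[int, int]]] = []
    for key in keys:
        values = _resolve_key_values(key, universe, matrices, annotations)
        present = sorted(
            {v for v in values if v is not None and not is_missing(v)}
        )
        rank = {v: i for i, v in enumerate(present)}
        sign = -1 if key.direction == "descending" else 1
        per_sample = {}
        for sample, v in zip(universe, values):
            if v is None or is_missing(v):
                per_sample[sample] = (1, 0)
            else:
                per_sample[sample] = (0, sign * rank[v])
        subkeys.append(per_sample)
    ordered = sorted(
        universe.samples, key=lambda s: tuple(k[s] for k in subkeys)
    )
    return SampleOrder(ordered)


# ---------------------------------------------------------------------------
# grouping & aggregation


@dataclass
class GroupPartition:
    """Disjoint ordered sample groups covering the universe; none empty."""

    groups: list[tuple[str, list[str]]]

    def __post_init__(self) -> None:
        all_samples: list[str] = []
        for label, members in self.groups:
            if not members:
                raise ConfigurationError(f"group {label!r} is empty")
            all_samples.extend(members)
        if len(all_samples) != len(set(all_samples)):
            raise ConfigurationError("groups are not disjoint")

    def __iter__(self):
        return iter(self.groups)

    def __len__(self) -> int:
        return len(self.groups)

    @property
    def labels(self) -> list[str]:
        return [label for label, _ in self.groups]

    @property
    def sizes(self) -> list[int]:
        return [len(members) for _, members in self.groups]


def partition_samples(
    universe: SampleOrder, annotation: SampleAnnotation
) -> GroupPartition:
    """Group the universe by an annotation.

    One group per category, ordered by first appearance along the
    universe; samples with MISSING annotation form a trailing
    ``unannotated`` group.  Within each group samples keep universe order.
    """
    groups: dict[str, list[str]] = {}
    unannotated: list[str] = []
    covered = 0
    for sample in universe:
        cat = annotation.category(sample)
        if cat is None:
            unannotated.append(sample)
        else:
            groups.setdefault(cat, []).append(sample)
            covered += 1
    if covered == 0:
        raise ConfigurationError(
            f"annotation {annotation.name!r} covers no sample of the universe"
        )
    ordered = [(label, members) for label, members in groups.items()]
    if unannotated:
        ordered.append((UNANNOTATED_LABEL, unannotated))
    return GroupPartition(ordered)


def aggregate_ring(
    matrix: OmicsMatrix, gene: str, partition: GroupPartition
) -> list[tuple[str, float]]:
    """Per-group arithmetic mean of a gene's non-missing values.

    A group whose values are all MISSING yields MISSING.  For a binary
    mutation ring the mean is the group's mutation frequency.  The mean is
    taken in value space; colorization happens afterwards.
    """
    if gene not in matrix:
        raise KeyResolutionError(
            f"gene {gene!r} absent from matrix {matrix.platform_label!r}"
        )
    out: list[tuple[str, float]] = []
    for label, members in partition:
        vals = [
            matrix.value(gene, s)
            for s in members
            if not is_missing(matrix.value(gene, s))
        ]
        # summed in sorted order so the mean is exactly invariant to
        # within-group sample order
        mean = math.fsum(sorted(vals)) / len(vals) if vals else MISSING
        out.append((label, mean))
    return out


# ---------------------------------------------------------------------------
# geometry & glyphs


def spoke_geometry(
    n_cells: int, weights: list[float] | None = None
) -> list[tuple[float, float]]:
    """Angular (start, extent) per cell, degrees, 12-o'clock origin, clockwise.

    Unweighted cells split the turn evenly; weighted cells (aggregated
    mode) get extents proportional to their weights.  Extents sum to 360
    within numerical tolerance.
    """
    if n_cells < 1:
        raise ConfigurationError("need at least one cell")
    if weights is None:
        weights = [1.0] * n_cells
    if len(weights) != n_cells:
        raise ConfigurationError("weights length must equal n_cells")
    if any(w <= 0 for w in weights):
        raise ConfigurationError("weights must be positive")
    total = float(sum(weights))
    cells: list[tuple[float, float]] = []
    start = 0.0
    for w in weights:
        extent = 360.0 * w / total
        cells.append((start, extent))
        start += extent
    return cells


@dataclass
class RingSpec:
    """One ring of a glyph: a matrix, its radial position, its color scale.

    ``position`` 0 is the innermost ring; a glyph's ring positions must be
    0..k-1 with no gaps.
    """

    matrix: OmicsMatrix
    position: int
    color_scale: ColorScale | None = None

    def scale(self) -> ColorScale:
        if self.color_scale is None:
            self.color_scale = ColorScale.from_matrix(self.matrix)
        return self.color_scale


@dataclass(frozen=True)
class Cell:
    """One rendered angular cell: geometry, resolved color, raw value."""

    start: float
    extent: float
    color: str
    value: float
    key: str  # sample id (full) or group label (aggregated)


@dataclass
class CircleMapGlyph:
    """A gene's nested-ring glyph, ready for rendering.

    ``cells[r]`` is the ordered cell list of ring ``r`` (inner to outer);
    the (cell index -> key) map is identical across rings and, by
    construction in :func:`build_glyph`, across all glyphs sharing one
    order or partition.
    """

    gene: str
    rings: list[RingSpec]
    mode: str
    cell_keys: list[str]
    cells: list[list[Cell]]

    @property
    def n_rings(self) -> int:
        return len(self.rings)

    @property
    def n_cells(self) -> int:
        return len(self.cell_keys)


def _check_rings(rings: list[RingSpec]) -> list[RingSpec]:
    if not rings:
        raise ConfigurationError("glyph needs at least one ring")
    rings = sorted(rings, key=lambda r: r.position)
    if [r.position for r in rings] != list(range(len(rings))):
        raise ConfigurationError(
            f"ring positions must be 0..k-1, got {[r.position for r in rings]}"
        )
    return rings


def build_glyph(
    gene: str,
    rings: list[RingSpec],
    order: SampleOrder | None = None,
    partition: GroupPartition | None = None,
    missing_color: str = DEFAULT_MISSING_COLOR,
    proportional_segments: bool = True,
) -> CircleMapGlyph:
    """Assemble a gene's CircleMap glyph in full or aggregated mode.

    Exactly one of ``order`` (full mode: one spoke per sample) or
    ``partition`` (aggregated mode: one segment per group, colored by the
    group mean) must be given.  A gene absent from a ring's matrix yields
    an all-missing ring rather than an error, so a pathway can include
    genes with partial data coverage.  Aggregated segment widths are
    proportional to group sizes unless ``proportional_segments`` is off.
    """
    rings = _check_rings(rings)
    if (order is None) == (partition is None):
        raise ConfigurationError("supply exactly one of order or partition")

    if order is not None:
        keys = list(order)
        geometry = spoke_geometry(len(keys))
        ring_cells: list[list[Cell]] = []
        for spec in rings:
            scale = spec.scale()
            cells = []
            for (start, extent), sample in zip(geometry, keys):
                v = spec.matrix.value(gene, sample) if gene in spec.matrix else MISSING
                cells.append(
                    Cell(start, extent, colorize(v, scale, missing_color), v, sample)
                )
            ring_cells.append(cells)
        return CircleMapGlyph(gene, rings, "full", keys, ring_cells)

    assert partition is not None
    keys = partition.labels
    weights = (
        [float(s) for s in partition.sizes]
        if proportional_segments
        else None
    )
    geometry = spoke_geometry(len(keys), weights)
    ring_cells = []
    for spec in rings:
        scale = spec.scale().for_aggregation()
        if gene in spec.matrix:
            means = dict(aggregate_ring(spec.matrix, gene, partition))
        else:
            means = {label: MISSING for label in keys}
        cells = []
        for (start, extent), label in zip(geometry, keys):
            v = means[label]
            cells.append(
                Cell(start, extent, colorize(v, scale, missing_color), v, label)
            )
        ring_cells.append(cells)
    return CircleMapGlyph(gene, rings, "aggregated", keys, ring_cells)
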