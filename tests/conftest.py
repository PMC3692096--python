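"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest

from circlemapviz import (
    GeneSet,
    Inputs,
    OmicsMatrix,
    PathwayGraph,
    SampleAnnotation,
    generate_cohort,
    generate_toy,
)
from circlemapviz.fixtures import CohortSpec, ToySpec


def make_matrix(grid, genes, samples, label="m", kind="continuous") -> OmicsMatrix:
    return OmicsMatrix(label, pd.DataFrame(np.asarray(grid, dtype=float),
                                           index=genes, columns=samples), kind)


@pytest.fixture
def toy():
    return generate_toy(ToySpec(seed=11))


@pytest.fixture
def cohort():
    return generate_cohort(CohortSpec(n_samples=80, seed=7))


@pytest.fixture
def toy_inputs(toy):
    meth, expr, graph = toy
    return Inputs(
        matrices=[expr, meth],
        gene_set=GeneSet("toy", ["geneA", "geneB"]),
        networks=[("toy_pathway", graph)],
        annotations=[],
    )


# ---------------------------------------------------------------------------
# independent oracles


def oracle_sort(universe, key_values, directions):
    """Brute-force stable insertion sort by explicit pairwise comparison.

    ``key_values`` is a list (one entry per key) of dicts sample -> value
    (None = MISSING); ``directions`` the matching list of "ascending" /
    "descending".  MISSING ranks after everything under either direction;
    ties keep input order.
    """

    def before(a, b):
        for values, direction in zip(key_values, directions):
            va, vb = values[a], values[b]
            am = va is None or (isinstance(va, float) and math.isnan(va))
            bm = vb is None or (isinstance(vb, float) and math.isnan(vb))
            if am and bm:
                continue
            if am:
                return False
            if bm:
                return True
            if va == vb:
                continue
            if direction == "ascending":
                return va < vb
            return va > vb
        return False  # tie: not strictly before

    out = []
    for sample in universe:
        i = len(out)
        # insert after every element that must come before sample
        while i > 0 and before(sample, out[i - 1]):
            i -= 1
        out.insert(i, sample)
    return out


def oracle_group_means(matrix: OmicsMatrix, gene: str, groups):
    """Plain-loop per-group mean skipping MISSING; all-missing -> None."""
    out = []
    for label, members in groups:
        total, count = 0.0, 0
        for s in members:
            v = matrix.value(gene, s)
            if not (isinstance(v, float) and math.isnan(v)):
                total += v
                count += 1
        out.append((label, total / count if count else None))
    return out


def oracle_induced_edges(background: PathwayGraph, selected: set[str]):
    """Brute-force filter keeping edges with both endpoints selected."""
    return sorted(
        (e.source, e.target, e.edge_type, e.track)
        for e in background.edges
        if e.source in selected and e.target in selected
    )


def random_annotation(samples, categories, seed, missing_rate=0.1) -> SampleAnnotation:
    rng = np.random.default_rng(seed)
    assignments = {}
    for s in samples:
        if rng.random() < missing_rate:
            assignments[s] = None
        else:
            assignments[s] = str(categories[int(rng.integers(len(categories)))])
    return SampleAnnotation(f"ann{seed}", assignments)
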