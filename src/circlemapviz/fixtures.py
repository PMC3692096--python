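"""Seeded synthetic data generators.

Two scenarios make every pipeline stage testable without any download:

* :func:`generate_toy` — two genes measured on methylation and expression
  platforms.  A shared latent factor makes the genes' promoter
  methylation positively correlated (they would co-cluster in a
  methylation heatmap), methylation silences expression (negative
  meth->expr loading), and gene A's product inhibits gene B, so the two
  expression profiles are anti-correlated.  Sorting spokes by gene A's
  expression ring should reveal gene B's opposing trend in one glance.

* :func:`generate_cohort` — a tumor-cohort-style data set with binary
  somatic mutation calls, continuous copy-number / expression / inferred
  pathway-activity matrices, and a hypermutated-vs-non-hypermutated
  phenotype annotation.  A designated driver gene is preferentially
  mutated in the hypermutated subgroup, so aggregating the mutation ring
  over the two phenotype groups shows a strong frequency contrast.

All randomness flows from one integer seed per generator call.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import SpecificationError
from .model import OmicsMatrix, PathwayGraph, SampleAnnotation


def _sample_ids(n: int, prefix: str = "s") -> list[str]:
    width = max(2, len(str(n)))
    return [f"{prefix}{i + 1:0{width}d}" for i in range(n)]


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    if sd == 0:
        return np.zeros_like(x)
    return (x - x.mean()) / sd


# ---------------------------------------------------------------------------
# toy scenario


@dataclass
class ToySpec:
    """Generative settings for the two-gene inhibition scenario.

    ``rho_meth`` (positive) is the shared-factor methylation correlation
    between the genes; ``rho_meth_expr`` (negative) the methylation ->
    expression silencing loading per gene; ``rho_inhibit`` (negative) the
    exact population correlation between gene A's and gene B's expression
    induced by the inhibitory interaction; ``noise_sd`` the measurement
    noise added to each observed value, which attenuates all sample
    correlations by 1/(1+noise_sd^2).
    """

    n_samples: int = 10
    rho_meth: float = 0.8
    rho_meth_expr: float = -0.8
    rho_inhibit: float = -0.8
    noise_sd: float = 0.3
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples < 4:
            raise SpecificationError("toy scenario needs n_samples >= 4")
        if not (0.0 < self.rho_meth < 1.0):
            raise SpecificationError(
                "rho_meth must lie in (0, 1): the genes share a methylation factor"
            )
        if not (-1.0 < self.rho_meth_expr < 1.0):
            raise SpecificationError("rho_meth_expr must lie in (-1, 1)")
        if not (-1.0 <= self.rho_inhibit <= 1.0):
            raise SpecificationError("rho_inhibit must lie in [-1, 1]")
        if not self.noise_sd > 0:
            raise SpecificationError("noise_sd must be positive")


def generate_toy(
    spec: ToySpec | None = None,
) -> tuple[OmicsMatrix, OmicsMatrix, PathwayGraph]:
    """Generate (methylation matrix, expression matrix, pathway graph).

    Latent construction on standardized unit-variance variables:

    * ``meth_A = sqrt(rho_meth) * F + sqrt(1 - rho_meth) * e1`` (same for
      gene B with independent ``e2``), so corr(meth_A, meth_B) =
      ``rho_meth`` exactly in population;
    * ``expr_A = rho_me * meth_A + sqrt(1 - rho_me^2) * e3``;
    * ``expr_B = rho_inh * z(expr_A) + sqrt(1 - rho_inh^2) * w``, where
      ``w`` mixes the part of meth_B orthogonal to expr_A (the silencing
      pathway) with fresh noise, so corr(expr_A, expr_B) = ``rho_inhibit``
      exactly in population.

    Observed values add ``noise_sd``-scaled measurement noise.  In the
    noise-free limit with ``rho_inhibit = -1`` the two expression profiles
    are exactly anti-correlated.  Identical seeds give identical grids.
    """
    spec = spec or ToySpec()
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_samples
    rm, rme, rinh, s = (
        spec.rho_meth,
        spec.rho_meth_expr,
        spec.rho_inhibit,
        spec.noise_sd,
    )

    factor = rng.standard_normal(n)
    e1, e2, e3, e4 = (rng.standard_normal(n) for _ in range(4))

    meth_a = math.sqrt(rm) * factor + math.sqrt(1 - rm) * e1
    meth_b = math.sqrt(rm) * factor + math.sqrt(1 - rm) * e2
    expr_a = rme * meth_a + math.sqrt(1 - rme * rme) * e3

    # component of meth_B orthogonal to expr_A, standardized
    za = _standardize(expr_a)
    resid = meth_b - (meth_b @ za / max(za @ za, 1e-12)) * za
    u = _standardize(resid)
    w = rme * u + math.sqrt(1 - rme * rme) * e4
    w = _standardize(w) if abs(rinh) < 1.0 else np.zeros(n)
    expr_b = rinh * za + math.sqrt(max(0.0, 1 - rinh * rinh)) * w

    def _observe(x: np.ndarray) -> np.ndarray:
        return x + s * rng.standard_normal(n)

    samples = _sample_ids(n)
    meth = OmicsMatrix(
        "methylation",
        pd.DataFrame(
            [_observe(meth_a), _observe(meth_b)],
            index=["geneA", "geneB"],
            columns=samples,
        ),
        "continuous",
    )
    expr = OmicsMatrix(
        "expression",
        pd.DataFrame(
            [_observe(expr_a), _observe(expr_b)],
            index=["geneA", "geneB"],
            columns=samples,
        ),
        "continuous",
    )

    graph = PathwayGraph()
    graph.add_node("geneA", "protein")
    graph.add_node("geneB", "protein")
    graph.add_edge("geneA", "geneB", "inhibits", "toy_pathway")
    return meth, expr, graph


# ---------------------------------------------------------------------------
# cohort scenario


#: Colorectal-cancer-flavored default gene panel; the first is the driver.
DEFAULT_GENE_PANEL = [
    "BRAF", "KRAS", "MYC", "APC", "CTNNB1", "TP53", "PIK3CA", "SMAD4",
]

ALL_PLATFORMS = ("mutation", "copynumber", "expression", "activity")

HYPER_LABEL = "hypermutated"
NONHYPER_LABEL = "non-hypermutated"


@dataclass
class CohortSpec:
    """Generative settings for the tumor cohort scenario."""

    n_genes: int = 8
    n_samples: int = 120
    fraction_hypermutated: float = 0.25
    mut_rate_hyper: float = 0.6
    mut_rate_nonhyper: float = 0.05
    background_mut_rate: float = 0.05
    driver_gene: str = "BRAF"
    coupling: float = 0.7
    platforms: tuple[str, ...] = ALL_PLATFORMS
    seed: int = 0
    gene_panel: list[str] = field(default_factory=list)

    def genes(self) -> list[str]:
        panel = list(self.gene_panel) or list(DEFAULT_GENE_PANEL)
        while len(panel) < self.n_genes:
            panel.append(f"GENE{len(panel) + 1}")
        return panel[: self.n_genes]

    def validate(self) -> None:
        if self.n_genes < 2:
            raise SpecificationError("cohort needs at least 2 genes")
        if not (0.0 < self.fraction_hypermutated < 1.0):
            raise SpecificationError("fraction_hypermutated must lie in (0, 1)")
        if self.fraction_hypermutated * self.n_samples < 1:
            raise SpecificationError(
                "fraction_hypermutated * n_samples < 1: no hypermutated sample"
            )
        for name in ("mut_rate_hyper", "mut_rate_nonhyper", "background_mut_rate"):
            rate = getattr(self, name)
            if not (0.0 <= rate <= 1.0):
                raise SpecificationError(f"{name} must lie in [0, 1]")
        if self.driver_gene not in self.genes():
            raise SpecificationError(
                f"driver gene {self.driver_gene!r} not among the {self.n_genes} genes"
            )
        unknown = set(self.platforms) - set(ALL_PLATFORMS)
        if unknown:
            raise SpecificationError(f"unknown platforms {sorted(unknown)}")
        if not (0.0 <= self.coupling < 1.0):
            raise SpecificationError("coupling must lie in [0, 1)")


def generate_cohort(
    spec: CohortSpec | None = None,
) -> tuple[list[OmicsMatrix], SampleAnnotation, PathwayGraph]:
    """Generate (platform matrices, hypermutation annotation, pathway graph).

    The driver gene's mutation indicator is Bernoulli(``mut_rate_hyper``)
    in hypermutated samples and Bernoulli(``mut_rate_nonhyper``)
    otherwise; other genes mutate at ``background_mut_rate`` everywhere.
    Copy number is standard normal per gene; expression loads on copy
    number and inferred activity loads on expression with the configured
    ``coupling``, each topped up with independent noise to unit variance.
    The pathway graph is a small typed network over the gene panel
    containing activating edges, one inhibitory edge and one complex node
    with component links.
    """
    spec = spec or CohortSpec()
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    genes = spec.genes()
    n = spec.n_samples
    samples = _sample_ids(n, prefix="p")

    n_hyper = max(1, int(round(spec.fraction_hypermutated * n)))
    hyper_idx = np.sort(rng.choice(n, size=n_hyper, replace=False))
    is_hyper = np.zeros(n, dtype=bool)
    is_hyper[hyper_idx] = True

    annotation = SampleAnnotation(
        "hypermutated",
        {
            s: (HYPER_LABEL if h else NONHYPER_LABEL)
            for s, h in zip(samples, is_hyper)
        },
    )

    matrices: list[OmicsMatrix] = []
    mut = np.empty((len(genes), n))
    for gi, gene in enumerate(genes):
        if gene == spec.driver_gene:
            rates = np.where(is_hyper, spec.mut_rate_hyper, spec.mut_rate_nonhyper)
        else:
            rates = np.full(n, spec.background_mut_rate)
        mut[gi] = (rng.random(n) < rates).astype(float)
    if "mutation" in spec.platforms:
        matrices.append(
            OmicsMatrix(
                "mutation",
                pd.DataFrame(mut, index=genes, columns=samples),
                "binary",
            )
        )

    c = spec.coupling
    cna = rng.standard_normal((len(genes), n))
    expr = c * cna + math.sqrt(1 - c * c) * rng.standard_normal((len(genes), n))
    activity = c * expr + math.sqrt(1 - c * c) * rng.standard_normal((len(genes), n))
    for label, grid in (
        ("copynumber", cna),
        ("expression", expr),
        ("activity", activity),
    ):
        if label in spec.platforms:
            matrices.append(
                OmicsMatrix(
                    label,
                    pd.DataFrame(grid, index=genes, columns=samples),
                    "continuous",
                )
            )

    graph = _cohort_graph(genes, spec.driver_gene)
    return matrices, annotation, graph


def _cohort_graph(genes: list[str], driver: str) -> PathwayGraph:
    """Small typed pathway over the panel: a signaling chain feeding the
    last gene, one inhibitory edge, one complex with component links."""
    graph = PathwayGraph()
    for gene in genes:
        graph.add_node(gene, "protein")
    # activating chain driver -> ... -> terminal gene
    chain = [driver] + [g for g in genes if g != driver]
    for a, b in zip(chain, chain[1:]):
        graph.add_edge(a, b, "activates", "pathway")
    # one inhibitory feedback from the terminal gene onto the driver
    graph.add_edge(chain[-1], chain[0], "inhibits", "pathway")
    if len(genes) >= 3:
        complex_name = "signaling_complex"
        graph.add_node(complex_name, "complex")
        graph.add_edge(chain[1], complex_name, "component", "pathway")
        graph.add_edge(chain[2], complex_name, "component", "pathway")
    return graph


def random_graph(
    n_nodes: int, n_edges: int, seed: int, track: str = ""
) -> PathwayGraph:
    """Random typed graph for property tests and overlay fixtures."""
    rng = np.random.default_rng(seed)
    names = [f"N{i:03d}" for i in range(n_nodes)]
    graph = PathwayGraph()
    for name in names:
        graph.add_node(name, "protein")
    edge_types = ["activates", "inhibits", "undirected", "component", "member"]
    for _ in range(n_edges):
        a, b = rng.choice(n_nodes, size=2, replace=True)
        etype = edge_types[int(rng.integers(len(edge_types)))]
        graph.add_edge(names[int(a)], names[int(b)], etype, track)
    return graph


def random_matrix(
    n_genes: int,
    n_samples: int,
    seed: int,
    platform_label: str = "random",
    value_kind: str = "continuous",
    missing_rate: float = 0.1,
) -> OmicsMatrix:
    """Random matrix with a configurable fraction of MISSING cells."""
    rng = np.random.default_rng(seed)
    genes = [f"G{i:03d}" for i in range(n_genes)]
    samples = _sample_ids(n_samples)
    if value_kind == "binary":
        grid = (rng.random((n_genes, n_samples)) < 0.3).astype(float)
    elif value_kind == "discrete":
        grid = rng.integers(0, 4, size=(n_genes, n_samples)).astype(float)
    else:
        grid = rng.standard_normal((n_genes, n_samples))
    if missing_rate > 0:
        mask = rng.random((n_genes, n_samples)) < missing_rate
        grid = grid.copy()
        grid[mask] = np.nan
    return OmicsMatrix(
        platform_label,
        pd.DataFrame(grid, index=genes, columns=samples),
        value_kind,
    )
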