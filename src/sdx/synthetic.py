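"""Seeded synthetic cohorts with known ground truth.

Generates (1) a dependency-score matrix mixing unimodal background genes
with differential genes whose responsive minority is shifted by a known
separation, (2) a sparse binary feature matrix with planted approximately
mutually exclusive feature sets enriched in the responsive samples plus
gamma-heterogeneous background mutations (hypermutator-like column sums),
and (3) a cancer-type partition. Everything is a pure function of the
spec's seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Literal

import numpy as np

from ._util import rng_for
from .features import FeatureMatrix
from .scoring import DependencyMatrix

__all__ = ["CohortSpec", "Cohort", "generate_dependency_matrix", "generate_feature_matrix", "generate_cohort"]


@dataclass
class CohortSpec:
    n_samples: int = 200
    n_genes: int = 20
    n_differential: int = 5
    responsive_fraction: float = 0.2
    separation: float = 4.0  # distance between component means, in pooled-scale units
    scale: float = 1.0
    family: Literal["gaussian", "t"] = "gaussian"
    t_dof: float = 8.0
    direction: Literal["increased", "decreased"] = "increased"
    n_planted_features: int = 2
    planted_coverage: float = 0.9
    exclusivity: float = 1.0
    background_rate: float = 0.03
    rate_heterogeneity: float = 0.5  # gamma shape = 1/h; 0 = homogeneous
    n_background_features: int = 20
    n_cancer_types: int = 0
    plant_two_hit: bool = False
    seed: int = 0

    def __post_init__(self):
        for name in ("responsive_fraction", "planted_coverage", "exclusivity"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")
        if self.n_differential > self.n_genes:
            raise ValueError("n_differential cannot exceed n_genes")


@dataclass
class Cohort:
    spec: CohortSpec
    dependency: DependencyMatrix
    features: FeatureMatrix
    metadata: dict  # sample -> cancer type ('' rows absent if n_cancer_types == 0)
    responsive_sets: dict  # gene -> sorted list of responsive sample indices
    planted_features: dict  # gene -> list of planted feature labels

    def truth_manifest(self) -> dict:
        return {
            "spec": asdict(self.spec),
            "differential_genes": sorted(self.responsive_sets),
            "responsive_sets": {g: list(map(int, v)) for g, v in self.responsive_sets.items()},
            "planted_features": self.planted_features,
        }


def _draw_background(rng: np.random.Generator, size, spec: CohortSpec) -> np.ndarray:
    if spec.family == "t":
        return spec.scale * rng.standard_t(spec.t_dof, size=size)
    return rng.normal(0.0, spec.scale, size=size)


def generate_dependency_matrix(spec: CohortSpec) -> tuple[DependencyMatrix, dict]:
    """Scores for n_genes profiles; the first n_differential are two-component.

    Responsive samples of an increased-direction gene are shifted by
    -separation * scale (positive shift for decreased). Returns the
    matrix and the gene -> responsive-sample-index ground truth.
    """
    rng = rng_for(spec.seed, "dependency")
    n, g = spec.n_samples, spec.n_genes
    gene_ids = [f"G{i:04d}" for i in range(g)]
    sample_ids = [f"S{j:04d}" for j in range(n)]
    scores = _draw_background(rng, (g, n), spec)
    shift = spec.separation * spec.scale * (-1.0 if spec.direction == "increased" else 1.0)
    n_resp = int(round(spec.responsive_fraction * n))
    responsive: dict = {}
    for i in range(spec.n_differential):
        idx = np.sort(rng.choice(n, size=n_resp, replace=False))
        scores[i, idx] += shift
        responsive[gene_ids[i]] = idx.tolist()
    return DependencyMatrix(gene_ids, sample_ids, scores), responsive


def generate_feature_matrix(
    spec: CohortSpec, responsive_sets: dict
) -> tuple[FeatureMatrix, dict]:
    """Planted + background mutation features.

    For each differential gene, ``planted_coverage`` of its responsive
    samples are split round-robin among ``n_planted_features`` features;
    each covered sample independently gains a second planted feature with
    probability 1 - exclusivity. Background features use gamma-mixed
    Bernoulli rates so per-sample mutation counts overdisperse.
    """
    rng = rng_for(spec.seed, "features")
    n = spec.n_samples
    sample_ids = [f"S{j:04d}" for j in range(n)]
    labels: list[str] = []
    rows: list[np.ndarray] = []
    planted: dict = {}

    for gene, resp in sorted(responsive_sets.items()):
        resp = np.asarray(resp, dtype=int)
        n_cov = int(round(spec.planted_coverage * resp.size))
        if spec.n_planted_features > 0 and n_cov < spec.n_planted_features and n_cov > 0:
            raise ValueError(
                f"{gene}: coverage {n_cov} cannot support {spec.n_planted_features} non-empty features"
            )
        covered = rng.choice(resp, size=n_cov, replace=False)
        nf = spec.n_planted_features
        if spec.plant_two_hit and nf < 2:
            nf = 2
        gene_rows = [np.zeros(n, dtype=np.int8) for _ in range(nf)]
        order = rng.permutation(n_cov)
        for pos, s in enumerate(covered[order]):
            f = pos % nf
            gene_rows[f][s] = 1
            if nf > 1 and rng.random() > spec.exclusivity:
                other = (f + 1 + rng.integers(nf - 1)) % nf
                gene_rows[other][s] = 1
        if spec.plant_two_hit:
            classes = ["I", "O"] + ["A"] * (nf - 2)
            gene_labels = [f"{gene}_P{f}({classes[f]})" if f >= 2 else f"{gene}_P({classes[f]})" for f in range(nf)]
        else:
            gene_labels = [f"{gene}_P{f}(A)" for f in range(nf)]
        keep = [f for f in range(nf) if gene_rows[f].any()]
        labels.extend(gene_labels[f] for f in keep)
        rows.extend(gene_rows[f] for f in keep)
        planted[gene] = [gene_labels[f] for f in keep]

    if spec.n_background_features > 0:
        if spec.rate_heterogeneity > 0:
            lam = rng.gamma(1.0 / spec.rate_heterogeneity, spec.rate_heterogeneity, size=n)
        else:
            lam = np.ones(n)
        p = np.clip(spec.background_rate * lam, 0.0, 0.95)
        bg = (rng.random((spec.n_background_features, n)) < p[None, :]).astype(np.int8)
        for b in range(spec.n_background_features):
            if bg[b].any():
                labels.append(f"BG{b:04d}(O)")
                rows.append(bg[b])

    a = np.vstack(rows) if rows else np.zeros((0, n), dtype=np.int8)
    return FeatureMatrix(labels, sample_ids, a, ["mutation"] * len(labels)), planted


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Compose dependency scores, features, and cancer-type labels."""
    dep, responsive = generate_dependency_matrix(spec)
    fm, planted = generate_feature_matrix(spec, responsive)
    metadata: dict = {}
    if spec.n_cancer_types > 0:
        rng = rng_for(spec.seed, "cancer_types")
        assign = rng.integers(0, spec.n_cancer_types, size=spec.n_samples)
        metadata = {s: f"Type{assign[j]:02d}" for j, s in enumerate(dep.sample_ids)}
    return Cohort(spec, dep, fm, metadata, responsive, planted)
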