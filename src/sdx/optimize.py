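"""Exclusive-coverage set optimization.

Scores feature sets with a phenotype-weighted, exclusivity-penalized
coverage weight and finds the optimal set exactly, either with a MILP
(HiGHS via scipy) or by exhaustive enumeration (the test oracle).

Weight definition
-----------------
For a feature set M, Gamma(M) is the set of covered samples and c_j(M)
the number of features of M covering sample j, counted on *penalty
groups*: the (I) and (O) features of the same gene form one group (the
two-hit exception), every other feature is its own group.

    W(M) = sum_{j in Gamma(M)} d'_j - (c_j(M) - 1) * rho_j

with rho_j = -|d'_j| for increased-dependency search and +|d'_j| for
decreased. Increased dependencies minimize W; decreased maximize it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import comb
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy.optimize import LinearConstraint, milp
from scipy.sparse import csr_matrix

from .features import FeatureMatrix, parse_feature_label

__all__ = [
    "WeightedInstance",
    "AssociationResult",
    "normalize_scores",
    "build_instance",
    "set_weight",
    "solve_owxtc_ilp",
    "solve_owxtc_bruteforce",
    "solve_owxtc",
]

BRUTE_FORCE_BUDGET = 10**6
_TIE_TOL = 1e-12


class NoResponsiveMassError(ValueError):
    """All scores on the non-responsive side: normalization undefined."""


def normalize_scores(
    d: Sequence[float], direction: Literal["increased", "decreased"]
) -> tuple[np.ndarray, np.ndarray]:
    """Normalize 2C scores so the responsive-sign mass sums to unit magnitude.

    S is the sum of negative scores (increased) or positive scores
    (decreased); d' = d / |S|, preserving signs, and rho = -|d'|
    (increased) or +|d'| (decreased). Missing scores are treated as 0
    (such samples never contribute weight).
    """
    d = np.asarray(d, dtype=float)
    d = np.where(np.isfinite(d), d, 0.0)
    if direction == "increased":
        s = d[d < 0].sum()
    elif direction == "decreased":
        s = d[d > 0].sum()
    else:
        raise ValueError(f"unknown direction {direction!r}")
    if s == 0:
        raise NoResponsiveMassError(f"no {direction}-responsive mass in profile")
    d_prime = d / abs(s)
    rho = -np.abs(d_prime) if direction == "increased" else np.abs(d_prime)
    return d_prime, rho


@dataclass
class WeightedInstance:
    """One profile's normalized scores, penalties, and candidate features."""

    d_prime: np.ndarray
    rho: np.ndarray
    direction: Literal["increased", "decreased"]
    features: FeatureMatrix
    twohit_pairs: list = field(default_factory=list)  # [(i_idx, o_idx), ...]

    def __post_init__(self):
        self.d_prime = np.asarray(self.d_prime, dtype=float)
        self.rho = np.asarray(self.rho, dtype=float)
        n = self.features.n
        if self.d_prime.shape != (n,) or self.rho.shape != (n,):
            raise ValueError("score vectors must match the feature matrix sample count")

    @property
    def responsive_mask(self) -> np.ndarray:
        return self.d_prime < 0 if self.direction == "increased" else self.d_prime > 0


def _find_twohit_pairs(fm: FeatureMatrix) -> list[tuple[int, int]]:
    by_gene: dict[str, dict[str, int]] = {}
    for i, (lab, kind) in enumerate(zip(fm.feature_ids, fm.feature_kind)):
        if kind != "mutation":
            continue
        parsed = parse_feature_label(lab)
        if parsed:
            by_gene.setdefault(parsed[0], {})[parsed[1]] = i
    pairs = []
    for classes in by_gene.values():
        if "I" in classes and "O" in classes:
            pairs.append((classes["I"], classes["O"]))
    return pairs


def build_instance(
    d: Sequence[float],
    direction: Literal["increased", "decreased"],
    features: FeatureMatrix,
) -> WeightedInstance:
    """Normalize a 2C score vector against a feature matrix's samples."""
    d_prime, rho = normalize_scores(d, direction)
    return WeightedInstance(d_prime, rho, direction, features, _find_twohit_pairs(features))


@dataclass
class AssociationResult:
    gene_id: object
    direction: str
    feature_set: list  # labels, sorted
    weight: float
    covered_samples: list
    coverage_counts: np.ndarray | None = None
    p_features: dict | None = None
    p_set: float | None = None
    q: float | None = None
    n_perm: int | None = None


def _indices(inst: WeightedInstance, M: Iterable) -> list[int]:
    idx = []
    for f in M:
        if isinstance(f, (int, np.integer)):
            idx.append(int(f))
        else:
            try:
                idx.append(inst.features.feature_ids.index(f))
            except ValueError:
                raise KeyError(f"unknown feature label {f!r}") from None
    return idx


def penalty_counts(inst: WeightedInstance, idx: Sequence[int]) -> tuple[np.ndarray, np.ndarray]:
    """(raw coverage counts, penalty-group counts) per sample for a set."""
    a = inst.features.a
    if len(idx) == 0:
        z = np.zeros(inst.features.n, dtype=np.int64)
        return z, z.copy()
    raw = a[list(idx)].sum(axis=0).astype(np.int64)
    grouped = raw.copy()
    sel = set(int(i) for i in idx)
    for i1, i2 in inst.twohit_pairs:
        if i1 in sel and i2 in sel:
            grouped -= a[i1] * a[i2]
    return raw, grouped


def set_weight(M: Iterable, inst: WeightedInstance) -> float:
    """Closed-form W(M); accepts feature labels or row indices."""
    idx = _indices(inst, M)
    raw, c = penalty_counts(inst, idx)
    covered = raw > 0
    return float(
        (inst.d_prime[covered] + inst.rho[covered]).sum() - (c * inst.rho).sum()
    )


def _result(inst: WeightedInstance, idx: Sequence[int], weight: float, gene_id=None) -> AssociationResult:
    labels = sorted(inst.features.feature_ids[i] for i in idx)
    raw, _ = penalty_counts(inst, idx)
    covered = [s for s, r in zip(inst.features.sample_ids, raw) if r > 0]
    return AssociationResult(gene_id, inst.direction, labels, float(weight), covered, raw)


# ---------------------------------------------------------------------------
# exact MILP


class SolverError(RuntimeError):
    pass


def solve_owxtc_ilp(
    inst: WeightedInstance,
    k: int | None = None,
    time_limit: float | None = None,
    gene_id: object = None,
    mip_gap: float = 0.0,
) -> AssociationResult:
    """Solve the optimal-weight exclusive coverage problem exactly as a MILP.

    Variables: x_i per feature, y_j per sample, plus one binary per
    same-gene two-hit pair linearizing AND(x_I, x_O) for the penalty
    correction. Objective (increased; negated for decreased):

        min  sum_{d'_j < 0} (d'_j + rho_j) y_j
             - sum_i x_i sum_{j in Gamma(i)} rho_j
             + sum_pairs b_p sum_j a_{Ij} a_{Oj} rho_j

    subject to y_j <= sum_{i: a_ij=1} x_i, y_j >= x_i for covered
    responsive-sign samples, b_p <= x_I, b_p <= x_O, b_p >= x_I + x_O - 1
    and optionally sum_i x_i <= k. Returns the empty set with weight 0
    when no set improves on 0.
    """
    fm = inst.features
    m, n = fm.m, fm.n
    a = fm.a.astype(float)
    npair = len(inst.twohit_pairs)
    nvar = m + n + npair
    sign = 1.0 if inst.direction == "increased" else -1.0
    resp = inst.responsive_mask

    c = np.zeros(nvar)
    c[m : m + n] = np.where(resp, inst.d_prime + inst.rho, 0.0)
    c[:m] = -(a * inst.rho[None, :]).sum(axis=1)
    for p, (i1, i2) in enumerate(inst.twohit_pairs):
        c[m + n + p] = float((a[i1] * a[i2] * inst.rho).sum())
    c *= sign

    rows, cols, vals, lb, ub = [], [], [], [], []
    r = 0

    def add_row(entries, lo, hi):
        nonlocal r
        for col, val in entries:
            rows.append(r)
            cols.append(col)
            vals.append(val)
        lb.append(lo)
        ub.append(hi)
        r += 1

    for j in range(n):
        covering = np.flatnonzero(fm.a[:, j])
        if covering.size == 0:
            continue
        # y_j - sum x_i <= 0
        add_row([(m + j, 1.0)] + [(int(i), -1.0) for i in covering], -np.inf, 0.0)
        if resp[j]:
            for i in covering:
                add_row([(int(i), 1.0), (m + j, -1.0)], -np.inf, 0.0)
    for p, (i1, i2) in enumerate(inst.twohit_pairs):
        bcol = m + n + p
        add_row([(bcol, 1.0), (i1, -1.0)], -np.inf, 0.0)
        add_row([(bcol, 1.0), (i2, -1.0)], -np.inf, 0.0)
        add_row([(i1, 1.0), (i2, 1.0), (bcol, -1.0)], -np.inf, 1.0)
    if k is not None:
        add_row([(i, 1.0) for i in range(m)], -np.inf, float(k))

    constraints = []
    if r:
        A = csr_matrix((vals, (rows, cols)), shape=(r, nvar))
        constraints = [LinearConstraint(A, lb, ub)]

    options = {"mip_rel_gap": mip_gap}
    if time_limit is not None:
        options["time_limit"] = time_limit
    res = milp(
        c,
        constraints=constraints,
        integrality=np.ones(nvar),
        bounds=(0, 1),
        options=options,
    )
    if res.status != 0 or res.x is None:
        raise SolverError(f"MILP failed: status={res.status} message={res.message!r}")

    idx = [i for i in range(m) if res.x[i] > 0.5]
    weight = set_weight(idx, inst)
    improves = weight < -1e-9 if inst.direction == "increased" else weight > 1e-9
    if not improves:
        return AssociationResult(gene_id, inst.direction, [], 0.0, [], np.zeros(n, dtype=np.int64))
    return _result(inst, idx, weight, gene_id)


# ---------------------------------------------------------------------------
# exhaustive oracle


def enumerate_weights(
    inst: WeightedInstance, k: int | None = None
) -> tuple[list[tuple[int, ...]], np.ndarray]:
    """All subsets of size <= k with their weights (vectorized).

    The grouped penalty count is raw count minus, for every selected
    same-gene (I, O) pair, their per-sample overlap.
    """
    m = inst.features.m
    k = m if k is None else min(k, m)
    if sum(comb(m, s) for s in range(k + 1)) > BRUTE_FORCE_BUDGET:
        raise ValueError("combinatorial budget exceeded")
    a = inst.features.a.astype(np.float64)
    subsets: list[tuple[int, ...]] = [()]
    for size in range(1, k + 1):
        subsets.extend(combinations(range(m), size))
    sel = np.zeros((len(subsets), m))
    for row, sub in enumerate(subsets):
        sel[row, list(sub)] = 1.0
    raw = sel @ a  # (n_sub, n) coverage counts
    grouped = raw.copy()
    for i1, i2 in inst.twohit_pairs:
        overlap = (a[i1] * a[i2])[None, :]
        both = (sel[:, i1] * sel[:, i2])[:, None]
        grouped -= both * overlap
    covered = raw > 0
    w = covered @ (inst.d_prime + inst.rho) - grouped @ inst.rho
    return subsets, w


def solve_owxtc_bruteforce(
    inst: WeightedInstance, k: int | None = None, gene_id: object = None
) -> AssociationResult:
    """Exhaustive-enumeration oracle; deterministic lexicographic tie-break."""
    subsets, w = enumerate_weights(inst, k)
    best_w = w.min() if inst.direction == "increased" else w.max()
    tied = np.flatnonzero(np.abs(w - best_w) <= _TIE_TOL)
    labels = inst.features.feature_ids

    def sort_key(row: int):
        sub = subsets[row]
        return (len(sub) > 0, tuple(sorted(labels[i] for i in sub)))

    pick = min(tied, key=sort_key)
    idx = list(subsets[pick])
    weight = float(w[pick])
    improves = weight < -1e-9 if inst.direction == "increased" else weight > 1e-9
    if not improves or not idx:
        return AssociationResult(
            gene_id, inst.direction, [], 0.0, [], np.zeros(inst.features.n, dtype=np.int64)
        )
    return _result(inst, idx, weight, gene_id)


def solve_owxtc(
    inst: WeightedInstance, k: int | None = None, gene_id: object = None, **ilp_kwargs
) -> AssociationResult:
    """Auto-dispatch: enumeration when small enough, MILP otherwise."""
    m = inst.features.m
    kk = m if k is None else min(k, m)
    if sum(comb(m, s) for s in range(kk + 1)) <= 5000:
        return solve_owxtc_bruteforce(inst, k, gene_id=gene_id)
    return solve_owxtc_ilp(inst, k, gene_id=gene_id, **ilp_kwargs)
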