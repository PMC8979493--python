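"""Model selection and permutation-based significance of associations.

Three layers:

* ``conditional_model_selection`` — per-feature conditional permutation
  test inside the selected set; iteratively drops the worst feature
  until all retained features are individually supported.
* ``curveball_randomize`` + ``association_significance`` — empirical
  significance of the retained set's weight against optimal weights on
  fixed-margin randomizations of the full mutation matrix.
* ``bh_fdr`` — Benjamini-Hochberg step-up q-values across profiles.

All empirical p-values use an add-one pseudocount:
p = (1 + #extreme) / (1 + N), so p >= 1/(N+1) > 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from statsmodels.stats.multitest import multipletests

from ._util import log_event
from .features import FeatureMatrix
from .optimize import (
    WeightedInstance,
    _find_twohit_pairs,
    penalty_counts,
    set_weight,
    solve_owxtc,
)

__all__ = [
    "ModelSelectionReport",
    "SignificanceReport",
    "conditional_model_selection",
    "curveball_randomize",
    "association_significance",
    "bh_fdr",
]

FDR_THRESHOLD = 0.2


@dataclass
class ModelSelectionReport:
    initial_set: list
    retained_set: list
    p_features: dict
    n_permutations: int
    removed: list = field(default_factory=list)


@dataclass
class SignificanceReport:
    observed_weight: float
    p: float
    n_permutations: int
    permutation_weights_mean: float
    permutation_weights_sd: float
    n_extreme: int
    q: float | None = None


def _empirical_p(n_extreme: int, n: int) -> float:
    return (1 + n_extreme) / (1 + n)


def _is_extreme(perm_w: np.ndarray, observed: float, direction: str) -> np.ndarray:
    # "at least as good as observed" in the search direction
    if direction == "increased":
        return perm_w <= observed
    return perm_w >= observed


def _feature_perm_pvalue(
    inst: WeightedInstance,
    current: list[int],
    m_idx: int,
    n_perm: int,
    rng: np.random.Generator,
) -> float:
    """p_m for one feature: permute its row across samples, keep the rest fixed.

    Vectorized: draw n_perm random placements of the feature's coverage
    count, rebuild raw/grouped counts against the fixed remainder, and
    evaluate W for all permutations at once.
    """
    a = inst.features.a
    n = inst.features.n
    observed = set_weight(current, inst)
    others = [i for i in current if i != m_idx]
    raw_o, grp_o = penalty_counts(inst, others)
    count = int(a[m_idx].sum())
    if count == 0 or count == n:
        return 1.0  # permutation cannot change the weight

    # top-`count` positions of random keys = uniform random subset per draw
    keys = rng.random((n_perm, n))
    part = np.argpartition(keys, count - 1, axis=1)[:, :count]
    R = np.zeros((n_perm, n), dtype=np.int8)
    np.put_along_axis(R, part, 1, axis=1)

    raw = raw_o[None, :] + R
    grp = grp_o[None, :] + R
    sel = set(others)
    for i1, i2 in inst.twohit_pairs:
        partner = None
        if i1 == m_idx and i2 in sel:
            partner = i2
        elif i2 == m_idx and i1 in sel:
            partner = i1
        if partner is not None:
            grp = grp - R * a[partner][None, :]
    covered = raw > 0
    w = covered @ (inst.d_prime + inst.rho) - grp @ inst.rho
    n_extreme = int(_is_extreme(w, observed, inst.direction).sum())
    return _empirical_p(n_extreme, n_perm)


def conditional_model_selection(
    Mstar: Sequence,
    inst: WeightedInstance,
    n_perm: int = 10000,
    alpha_remove: float = 1e-4,
    seed: int = 0,
) -> ModelSelectionReport:
    """Iteratively drop the least-supported feature of the optimal set.

    Each round permutes every current feature's coverage across samples
    (count preserved, other rows fixed) and computes
    p_m = Pr[W_perm at least as good as W_observed]; the single feature
    with the largest p_m is removed if p_m > alpha_remove, and the
    process repeats on the reduced set with the reduced set's weight as
    the new observed statistic. Note alpha_remove must exceed the
    add-one floor 1/(n_perm+1) for anything to be retainable.
    """
    labels = inst.features.feature_ids
    current = [labels.index(f) if not isinstance(f, (int, np.integer)) else int(f) for f in Mstar]
    initial = sorted(labels[i] for i in current)
    removed: list = []
    pvals: dict = {}
    rng = np.random.default_rng(seed)
    while current:
        pvals = {i: _feature_perm_pvalue(inst, current, i, n_perm, rng) for i in current}
        worst = max(current, key=lambda i: (pvals[i], labels[i]))
        if pvals[worst] > alpha_remove:
            current.remove(worst)
            removed.append(labels[worst])
            log_event("model_selection", removed=labels[worst], p=pvals[worst])
        else:
            break
    retained = sorted(labels[i] for i in current)
    return ModelSelectionReport(
        initial, retained, {labels[i]: p for i, p in pvals.items() if labels[i] in retained},
        n_perm, removed,
    )


# ---------------------------------------------------------------------------
# curveball fixed-margin randomization


def curveball_randomize(
    A: np.ndarray, n_trades: int | None = None, seed: int | np.random.Generator = 0
) -> np.ndarray:
    """Fixed-margin randomization of a binary matrix by curveball trades.

    Each trade picks two distinct rows and randomly reallocates the
    columns in their symmetric difference while keeping both row sums;
    column sums are untouched by construction. ``n_trades`` defaults to
    5x the number of rows. Returns a new matrix.
    """
    A = np.asarray(A)
    if not np.isin(A, (0, 1)).all():
        raise ValueError("curveball requires a binary matrix")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    m = A.shape[0]
    if m < 2:
        return A.copy()
    if n_trades is None:
        n_trades = 5 * m
    rows = [set(np.flatnonzero(r)) for r in A]
    pick = rng.integers(0, m, size=(n_trades, 2))
    for i, j in pick:
        if i == j:
            continue
        ri, rj = rows[i], rows[j]
        a_only = ri - rj
        b_only = rj - ri
        pool = list(a_only | b_only)
        if len(a_only) == 0 or len(b_only) == 0:
            continue
        take = rng.permutation(len(pool))[: len(a_only)]
        new_a = {pool[t] for t in take}
        shared = ri & rj
        rows[i] = shared | new_a
        rows[j] = shared | (set(pool) - new_a)
    out = np.zeros_like(A)
    for i, cols in enumerate(rows):
        out[i, sorted(cols)] = 1
    return out


def association_significance(
    Mbar: Sequence,
    inst: WeightedInstance,
    full_matrix: np.ndarray,
    derive_features: Callable[[np.ndarray], FeatureMatrix],
    k: int | None,
    max_perm: int = 500000,
    seed: int = 0,
    n_trades: int | None = None,
    early_stop_above: float | None = 0.25,
    check_every: int = 100,
) -> SignificanceReport:
    """Empirical significance of the retained set's weight.

    Each permutation randomizes the *full* mutation matrix (all rows,
    fixed margins), re-derives the candidate feature matrix through
    ``derive_features``, re-solves the coverage problem at the same k
    (no model selection), and records the optimal weight. The empirical
    p-value compares the observed weight to this distribution with an
    add-one pseudocount. Stops early once the 99% CI for p lies entirely
    above ``early_stop_above``.
    """
    if full_matrix is None:
        raise ValueError("full mutation matrix required to condition on true margins")
    if len(Mbar) == 0:
        return SignificanceReport(0.0, 1.0, 0, np.nan, np.nan, 0)
    observed = set_weight(list(Mbar), inst)
    rng = np.random.default_rng(seed)
    weights = []
    n_extreme = 0
    for t in range(1, max_perm + 1):
        Ahat = curveball_randomize(full_matrix, n_trades=n_trades, seed=rng)
        fm = derive_features(Ahat)
        perm_inst = WeightedInstance(
            inst.d_prime, inst.rho, inst.direction, fm, _find_twohit_pairs(fm)
        )
        w = solve_owxtc(perm_inst, k).weight
        weights.append(w)
        if _is_extreme(np.array([w]), observed, inst.direction)[0]:
            n_extreme += 1
        if early_stop_above is not None and t % check_every == 0:
            p_hat = _empirical_p(n_extreme, t)
            half = 2.576 * np.sqrt(p_hat * (1 - p_hat) / t)
            if p_hat - half > early_stop_above:
                break
    warr = np.asarray(weights)
    p = _empirical_p(n_extreme, len(weights))
    log_event("significance", n_perm=len(weights), p=p, observed=observed)
    return SignificanceReport(
        observed, p, len(weights), float(warr.mean()), float(warr.std()), n_extreme
    )


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
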