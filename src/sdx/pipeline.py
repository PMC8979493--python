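"""Top-level pipeline: score -> features -> associate -> significance -> FDR."""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

from ._util import log_event, subseed
from . import io as sio
from .features import (
    FeatureMatrix,
    cancer_type_features,
    group_mutation_features,
    merge_feature_matrices,
    classify_mutation,
)
from .optimize import NoResponsiveMassError, SolverError, build_instance, solve_owxtc, solve_owxtc_ilp
from .scoring import (
    DegenerateProfileError,
    DependencyMatrix,
    FitFailureError,
    compute_2c_profile,
    select_two_component,
    sigma_outlier_filter,
    zscore_profile,
)
from .significance import (
    association_significance,
    bh_fdr,
    conditional_model_selection,
)

__all__ = ["RunConfig", "run_pipeline", "build_full_mutation_matrix", "score_profiles"]


@dataclass
class RunConfig:
    dependency_path: str = ""
    mutation_path: str = ""
    metadata_path: str | None = None
    out_dir: str = "sdx-out"
    genes_in: str = "rows"
    n_sigma: float = 6.0
    min_outlier_fraction: float = 0.0
    k: int | None = None  # default 3 mutations-only, 5 with cancer types
    direction_policy: str = "auto"  # auto | increased | decreased | both
    n_model_select: int = 10000
    n_significance_max: int = 500000
    alpha_remove: float = 1e-4
    fdr_threshold: float = 0.2
    seed: int = 0
    solver: str = "auto"  # auto | ilp
    time_limit: float | None = None
    min_freq: int = 1
    n_restarts: int = 5
    type_column: str = "Cancer_type"
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        for name in ("n_model_select", "n_significance_max"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.direction_policy not in {"auto", "increased", "decreased", "both"}:
            raise ValueError(f"bad direction_policy {self.direction_policy!r}")

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        kwargs = {k: v for k, v in data.items() if k in known}
        kwargs["extra"] = {k: v for k, v in data.items() if k not in known}
        return cls(**kwargs)

    def to_yaml(self, path: str) -> None:
        sio.atomic_write_text(path, yaml.safe_dump(asdict(self), sort_keys=True))

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def score_profiles(dep: DependencyMatrix, config: RunConfig) -> dict:
    """Stage 1: z-score, sigma prefilter, BIC model selection, 2C profiles.

    Returns gene_id -> TwoComponentProfile for the 2C calls, plus a table
    of per-gene bookkeeping under key "_table".
    """
    kept = sigma_outlier_filter(dep, config.n_sigma, config.min_outlier_fraction)
    profiles: dict = {}
    table = []
    for gid in kept:
        row = dep.row(gid)
        try:
            z = zscore_profile(row)
            seed = subseed(config.seed, "scoring", gid)
            from .scoring import fit_mixture

            fit1 = fit_mixture(z, 1, "t", seed=seed, n_restarts=config.n_restarts)
            fit2 = fit_mixture(z, 2, "t", seed=seed, n_restarts=config.n_restarts)
            is_2c = fit2.bic < fit1.bic
            rec = {"gene_id": gid, "is_2C": is_2c, "bic_1c": fit1.bic, "bic_2c": fit2.bic,
                   "direction": "", "responsive_n": ""}
            if is_2c:
                prof = compute_2c_profile(z, seed=seed, gene_id=gid, n_restarts=config.n_restarts)
                profiles[gid] = prof
                rec["direction"] = prof.direction
                rec["responsive_n"] = prof.responsive_n
            table.append(rec)
        except (DegenerateProfileError, FitFailureError) as exc:
            log_event("scoring", gene=gid, skipped=str(exc))
    profiles["_table"] = table
    return profiles


def build_full_mutation_matrix(records, sample_ids) -> tuple[list, np.ndarray]:
    """Binary matrix of *all* non-silent mutations for margin conditioning.

    Rows are (gene, A/I/O class) for knowledge-base genes — labelled like
    the corresponding features — plus one ``GENE:all`` row per other
    gene, so curveball preserves per-sample mutation burden including
    unannotated genes.
    """
    sidx = {s: j for j, s in enumerate(sample_ids)}
    cells: dict[str, set] = {}
    from .features import NON_CODING_CLASSES

    for r in records:
        if r.variant_class.strip().lower() in NON_CODING_CLASSES:
            continue
        if r.sample not in sidx:
            continue
        if r.in_oncokb:
            label = f"{r.gene}({classify_mutation(r.oncogenic, r.mutation_effect)})"
        else:
            label = f"{r.gene}:all"
        cells.setdefault(label, set()).add(sidx[r.sample])
    labels = sorted(cells)
    a = np.zeros((len(labels), len(sample_ids)), dtype=np.int8)
    for i, lab in enumerate(labels):
        a[i, sorted(cells[lab])] = 1
    return labels, a


def make_feature_deriver(full_labels: list, candidate: FeatureMatrix, fixed: FeatureMatrix | None):
    """Closure mapping a randomized full matrix to a candidate feature matrix.

    Keeps the rows whose labels are mutation features of the candidate
    matrix (their margins are preserved by curveball, so none die), and
    appends the fixed cancer-type rows unchanged.
    """
    mut_labels = [
        lab for lab, kind in zip(candidate.feature_ids, candidate.feature_kind) if kind == "mutation"
    ]
    rows = [full_labels.index(lab) for lab in mut_labels]

    def derive(Ahat: np.ndarray) -> FeatureMatrix:
        a = Ahat[rows]
        labels = list(mut_labels)
        kinds = ["mutation"] * len(labels)
        if fixed is not None and fixed.m:
            a = np.vstack([a, fixed.a])
            labels = labels + list(fixed.feature_ids)
            kinds = kinds + list(fixed.feature_kind)
        return FeatureMatrix(labels, list(candidate.sample_ids), a, kinds)

    return derive


def _associate_one(gid, prof_d, direction, fm, full_labels, full_matrix, fixed_ct, k, config):
    """Optimize, model-select, and test one profile in one direction."""
    inst = build_instance(prof_d, direction, fm)
    seed_opt = subseed(config.seed, "associate", gid, direction)
    solver = solve_owxtc if config.solver == "auto" else solve_owxtc_ilp
    mstar = solver(inst, k, gene_id=gid)
    if not mstar.feature_set:
        return None
    ms = conditional_model_selection(
        mstar.feature_set, inst,
        n_perm=config.n_model_select, alpha_remove=config.alpha_remove,
        seed=subseed(config.seed, "model_select", gid, direction),
    )
    if not ms.retained_set:
        return None
    derive = make_feature_deriver(full_labels, fm, fixed_ct)
    sig = association_significance(
        ms.retained_set, inst, full_matrix, derive, k,
        max_perm=config.n_significance_max,
        seed=subseed(config.seed, "significance", gid, direction),
        early_stop_above=max(0.25, 1.25 * config.fdr_threshold),
    )
    from .optimize import set_weight

    return {
        "profile": gid,
        "direction": direction,
        "features": "|".join(ms.retained_set),
        "weight": set_weight(ms.retained_set, inst),
        "p_features": "|".join(f"{f}:{ms.p_features[f]:.6g}" for f in ms.retained_set),
        "p_set": sig.p,
        "q": None,
        "n_perm": sig.n_permutations,
        "covered_responsive": int(
            np.sum((inst.features.a[[inst.features.feature_ids.index(f) for f in ms.retained_set]].sum(0) > 0)
                   & inst.responsive_mask)
        ),
        "total_responsive": int(inst.responsive_mask.sum()),
        "_seed_opt": seed_opt,
    }


def run_pipeline(config: RunConfig) -> list[dict]:
    """Execute the full pipeline and write result files to config.out_dir."""
    os.makedirs(config.out_dir, exist_ok=True)
    dep = sio.read_dependency_matrix(config.dependency_path, genes_in=config.genes_in)
    records = sio.read_mutation_table(config.mutation_path)
    metadata = sio.read_metadata(config.metadata_path, config.type_column) if config.metadata_path else None

    profiles = score_profiles(dep, config)
    table = profiles.pop("_table")

    mut_fm = group_mutation_features(records, sample_ids=dep.sample_ids, min_freq=config.min_freq)
    fixed_ct = None
    if metadata is not None:
        fixed_ct = cancer_type_features(metadata, sample_ids=dep.sample_ids)
        fm = merge_feature_matrices(mut_fm, fixed_ct)
        default_k = 5
    else:
        fm = mut_fm
        default_k = 3
    k = config.k if config.k is not None else default_k
    full_labels, full_matrix = build_full_mutation_matrix(records, dep.sample_ids)

    rows = []
    for gid, prof in sorted(profiles.items()):
        directions = (
            [prof.direction]
            if config.direction_policy == "auto"
            else (["increased", "decreased"] if config.direction_policy == "both" else [config.direction_policy])
        )
        d = np.where(np.isfinite(prof.d), prof.d, 0.0)
        for direction in directions:
            try:
                row = _associate_one(
                    gid, d, direction, fm, full_labels, full_matrix, fixed_ct, k, config
                )
            except (NoResponsiveMassError, SolverError) as exc:
                log_event("associate", gene=gid, direction=direction, error=str(exc))
                continue
            if row is not None:
                rows.append(row)

    if rows:
        qs = bh_fdr([r["p_set"] for r in rows])
        for r, q in zip(rows, qs):
            r["q"] = float(q)
    for r in rows:
        r.pop("_seed_opt", None)

    chash = config.config_hash()
    sio.write_associations(rows, os.path.join(config.out_dir, "associations.tsv"),
                           seed=config.seed, config_hash=chash)
    import pandas as pd

    dd = pd.DataFrame(table, columns=["gene_id", "is_2C", "direction", "responsive_n", "bic_1c", "bic_2c"])
    sio.atomic_write_text(
        os.path.join(config.out_dir, "differential_dependencies.tsv"),
        sio.manifest_line(config.seed, chash) + dd.to_csv(sep="\t", index=False),
    )
    score_rows = {gid: prof.d for gid, prof in profiles.items()}
    if score_rows:
        sc = pd.DataFrame(score_rows, index=dep.sample_ids).T
        sio.atomic_write_text(
            os.path.join(config.out_dir, "two_component_scores.csv"),
            sio.manifest_line(config.seed, chash) + sc.to_csv(),
        )
    sio.write_json(
        {"config": asdict(config), "config_hash": chash, "n_associations": len(rows),
         "n_2c_profiles": len(profiles), "k": k},
        os.path.join(config.out_dir, "run_manifest.json"),
    )
    return rows
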