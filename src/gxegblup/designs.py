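"""Training/validation designs for genomic prediction.

Five masking schemes decide which (line, environment) phenotype cells are
hidden from the training fit and predicted genomically:

- ``KFOLD``  : k-fold cross-validation; each fold's lines are masked in
  every environment.
- ``DTS``    : dedicated training set; a random half of the lines is masked
  in every environment and predicted from the other half.
- ``FSTS``   : full-sib training split; within each bi-parental family a
  random half of the lines is masked in every environment.
- ``ST2``    : two-environment sparse testing; complementary halves are
  masked in each environment, so every line is phenotyped in exactly one.
- ``ST3``    : three-environment sparse testing within families. The default
  balanced variant splits each family into quarters Q1-Q4 and masks
  Q1+Q2 in the primary environment, Q1+Q3 in the first secondary and
  Q2+Q4 in the second, so each environment loses ceil(size/2) lines of
  the family, every line keeps at least one observed environment, and
  the retained cell count matches FSTS exactly (about 1.5 cells per
  line). A literal variant that masks only one extra quarter from the
  retained half is available via ``balanced=False``.

Masking is by ceiling convention: the masked half of an odd set takes
``ceil(n/2)`` lines. All plans are reproducible from (scheme, seed, line
list) alone via :class:`numpy.random.default_rng`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

from .evaluate import AccuracyReport, accuracy, summarize
from .kinship import GenomicRelationship
from .model import (ModelSpec, MultiEnvGBLUP, PhenotypeTable, compute_blues)

logger = logging.getLogger("gxegblup")

__all__ = [
    "Scheme", "MaskPlan", "DesignConfig",
    "make_kfold_plan", "make_dts_plan", "make_fsts_plan",
    "make_st2_plan", "make_st3_plan", "apply_mask", "run_evaluation",
]


class Scheme(Enum):
    KFOLD = "kfold"
    DTS = "dts"
    FSTS = "fsts"
    ST2 = "st2"
    ST3 = "st3"


@dataclass(frozen=True)
class MaskPlan:
    """A set of (line, environment) cells hidden from training."""

    scheme: Scheme
    masked_cells: frozenset
    replicate_index: int = 0
    seed: int | None = None
    fold_assignments: dict | None = None

    def __post_init__(self):
        object.__setattr__(self, "masked_cells", frozenset(self.masked_cells))

    @property
    def masked_lines(self) -> set:
        return {l for l, _ in self.masked_cells}

    def to_frame(self) -> pd.DataFrame:
        rows = sorted(self.masked_cells)
        return pd.DataFrame(rows, columns=["line", "env"]).assign(
            replicate_index=self.replicate_index)


@dataclass(frozen=True)
class DesignConfig:
    """Configuration of a replicated design evaluation."""

    scheme: Scheme
    n_replicates: int = 10
    k: int = 10
    family_map: dict | None = None
    env_roles: tuple | None = None
    base_seed: int = 0
    balanced_st3: bool = True

    def __post_init__(self):
        if isinstance(self.scheme, str):
            object.__setattr__(self, "scheme", Scheme(self.scheme.lower()))
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.scheme in (Scheme.FSTS, Scheme.ST3) and self.family_map is None:
            raise ValueError(f"{self.scheme.name} requires family_map")


def _shuffled(items, rng) -> list:
    items = sorted(items)
    rng.shuffle(items)
    return items


def _mask_everywhere(lines, envs) -> set:
    return {(l, e) for l in lines for e in envs}


def make_kfold_plan(lines, envs, k: int, seed: int,
                    replicate_index: int = 0) -> list:
    """Partition lines into k seeded folds; plan i masks fold i everywhere."""
    lines = list(lines)
    n = len(lines)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError(f"k = {k} exceeds {n} lines")
    order = _shuffled(lines, np.random.default_rng(seed))
    folds = np.array_split(order, k)
    plans = []
    assignments = {}
    for i, fold in enumerate(folds):
        assignments.update({l: i for l in fold})
    for i, fold in enumerate(folds):
        plans.append(MaskPlan(Scheme.KFOLD,
                              _mask_everywhere(fold, envs),
                              replicate_index, seed,
                              fold_assignments=dict(assignments)))
    return plans


def make_dts_plan(lines, envs, seed: int, replicate_index: int = 0) -> MaskPlan:
    """Mask a random ceil(n/2) half of the lines in every environment."""
    lines = list(lines)
    if len(lines) < 4:
        raise ValueError("need >= 4 lines")
    order = _shuffled(lines, np.random.default_rng(seed))
    n_mask = -(-len(order) // 2)
    return MaskPlan(Scheme.DTS, _mask_everywhere(order[:n_mask], envs),
                    replicate_index, seed)


def make_fsts_plan(family_map: dict, envs, seed: int,
                   replicate_index: int = 0) -> MaskPlan:
    """Mask a random ceil(size/2) half within each family, everywhere."""
    fams = {}
    for line, fam in family_map.items():
        fams.setdefault(fam, []).append(line)
    for fam, members in fams.items():
        if len(members) < 2:
            raise ValueError(f"family {fam!r} has fewer than 2 lines")
    rng = np.random.default_rng(seed)
    masked = set()
    for fam in sorted(fams):
        order = _shuffled(fams[fam], rng)
        n_mask = -(-len(order) // 2)
        masked |= _mask_everywhere(order[:n_mask], envs)
    return MaskPlan(Scheme.FSTS, masked, replicate_index, seed)


def make_st2_plan(lines, env_pair, seed: int,
                  replicate_index: int = 0) -> MaskPlan:
    """Complementary halves: half masked in env 1, the rest in env 2."""
    env_pair = tuple(env_pair)
    if len(env_pair) != 2:
        raise ValueError("ST2 needs exactly 2 environments")
    lines = list(lines)
    order = _shuffled(lines, np.random.default_rng(seed))
    n_a = -(-len(order) // 2)
    masked = {(l, env_pair[0]) for l in order[:n_a]}
    masked |= {(l, env_pair[1]) for l in order[n_a:]}
    return MaskPlan(Scheme.ST2, masked, replicate_index, seed)


def make_st3_plan(family_map: dict, env_roles, seed: int,
                  replicate_index: int = 0, balanced: bool = True) -> MaskPlan:
    """Three-environment sparse testing within families (see module docs)."""
    env_roles = tuple(env_roles)
    if len(env_roles) != 3:
        raise ValueError("ST3 needs exactly 3 environments (primary, a, b)")
    primary, sec_a, sec_b = env_roles
    fams = {}
    for line, fam in family_map.items():
        fams.setdefault(fam, []).append(line)
    for fam, members in fams.items():
        if len(members) < 4:
            raise ValueError(
                f"family {fam!r} has {len(members)} lines; ST3 needs >= 4 "
                "per family (merge or exclude small families)")
    rng = np.random.default_rng(seed)
    masked = set()
    for fam in sorted(fams):
        order = _shuffled(fams[fam], rng)
        n = len(order)
        k, r = divmod(n, 4)
        # quarter sizes chosen so every environment masks exactly
        # ceil(n/2) lines (exact plot parity with the full-sib split)
        sizes = [k, k, k, k]
        if r == 1:
            sizes[0] += 1
        elif r == 2:
            sizes[0] += 1
            sizes[3] += 1
        elif r == 3:
            sizes[0] += 1
            sizes[1] += 1
            sizes[2] += 1
        cuts = np.cumsum(sizes)[:-1]
        q1, q2, q3, q4 = np.split(np.array(order), cuts)
        masked |= {(l, primary) for l in np.concatenate([q1, q2])}
        if balanced:
            masked |= {(l, sec_a) for l in np.concatenate([q1, q3])}
            masked |= {(l, sec_b) for l in np.concatenate([q2, q4])}
            if n % 2 == 1:
                # odd family: one more cell needed for parity; a Q3 line
                # keeps the primary environment observed
                masked.add((q3[0], sec_b))
        else:
            # literal variant: the masked half splits across the secondary
            # environments, plus a single extra quarter from the retained half
            masked |= {(l, sec_a) for l in q1}
            masked |= {(l, sec_b) for l in q2}
            masked |= {(l, sec_a) for l in q3}
    return MaskPlan(Scheme.ST3, masked, replicate_index, seed)


def apply_mask(pheno: PhenotypeTable, plan: MaskPlan) -> PhenotypeTable:
    """Drop every plot record of the plan's masked cells; leave the rest.

    Raises if the plan references a cell with no observed records, which
    guards against applying a stale plan to the wrong table.
    """
    observed = pheno.observed_cells()
    stale = plan.masked_cells - observed
    if stale:
        raise ValueError(
            f"plan masks {len(stale)} unobserved cells, e.g. "
            f"{sorted(stale)[:3]}")
    if not plan.masked_cells:
        return pheno
    df = pheno.df
    key = list(zip(df["line"], df["env"]))
    keep = ~pd.Series(key, index=df.index).isin(plan.masked_cells)
    return PhenotypeTable(df[keep.to_numpy()].reset_index(drop=True))


def _family_map_for(family_map: dict, lines) -> dict:
    missing = [l for l in lines if l not in family_map]
    if missing:
        raise ValueError(
            f"{len(missing)} phenotyped lines missing from family_map, "
            f"e.g. {missing[:3]}")
    return {l: family_map[l] for l in lines}


def _plans_for_replicate(pheno, cfg: DesignConfig, rep: int) -> list:
    seed = cfg.base_seed + rep
    envs = pheno.environments
    lines = pheno.lines
    if cfg.scheme is Scheme.KFOLD:
        return make_kfold_plan(lines, envs, cfg.k, seed, rep)
    if cfg.scheme is Scheme.DTS:
        return [make_dts_plan(lines, envs, seed, rep)]
    if cfg.scheme is Scheme.FSTS:
        fam = _family_map_for(cfg.family_map, lines)
        return [make_fsts_plan(fam, envs, seed, rep)]
    if cfg.scheme is Scheme.ST2:
        roles = cfg.env_roles or tuple(envs)
        if any(e not in envs for e in roles):
            raise ValueError(f"env_roles {roles} not all present in data")
        return [make_st2_plan(lines, roles, seed, rep)]
    if cfg.scheme is Scheme.ST3:
        roles = cfg.env_roles or tuple(envs)
        if any(e not in envs for e in roles):
            raise ValueError(f"env_roles {roles} not all present in data")
        fam = _family_map_for(cfg.family_map, lines)
        return [make_st3_plan(fam, roles, seed, rep,
                              balanced=cfg.balanced_st3)]
    raise ValueError(f"unknown scheme {cfg.scheme}")


def run_evaluation(pheno, K: GenomicRelationship, spec: ModelSpec | None,
                   design: DesignConfig, tol: float = 1e-6,
                   max_iter: int = 100, blues: pd.DataFrame | None = None,
                   center_envs: bool = False,
                   fit_hook=None) -> AccuracyReport:
    """Replicated fit-predict-score loop for one masking scheme.

    For each replicate, plans are built from ``base_seed + replicate``, the
    masked table is fitted, predictions for masked cells are collected
    (pooled over folds for KFOLD) and scored against BLUEs computed once
    from the full data. Reports per-environment and pooled (combined)
    Pearson accuracies, averaged over replicates.

    ``fit_hook``, if given, is called with each training PhenotypeTable
    before fitting (used by leakage audits).
    """
    if isinstance(pheno, pd.DataFrame):
        pheno = PhenotypeTable(pheno)
    spec = spec or ModelSpec()
    if blues is None:
        blues = compute_blues(pheno, spec)
    envs = pheno.environments
    per_rep = []
    seeds, convergence = [], []
    for rep in range(design.n_replicates):
        seeds.append(design.base_seed + rep)
        plans = _plans_for_replicate(pheno, design, rep)
        preds = []
        rep_converged = True
        for plan in plans:
            training = apply_mask(pheno, plan)
            if fit_hook is not None:
                fit_hook(training)
            res = MultiEnvGBLUP(training, K, spec).fit(tol=tol,
                                                       maxiter=max_iter)
            rep_converged &= res.converged
            logger.info(
                "scheme=%s replicate=%d seed=%d logREML=%.4f converged=%s",
                design.scheme.value, rep, design.base_seed + rep, res.llf,
                res.converged)
            cells = sorted(plan.masked_cells)
            preds.append(res.predict(cells))
        preds = pd.concat(preds, ignore_index=True)
        acc = accuracy(preds, blues, envs=envs, center_envs=center_envs)
        per_rep.append(acc)
        convergence.append(rep_converged)
    return summarize(per_rep, scheme=design.scheme.value,
                     seeds=seeds, convergence=convergence)
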