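"""Covariate-matched subsampling of a reference group.

Each bootstrap iteration draws a subsample of the larger (reference) group
matched one-to-one to the smaller (target) group on sex, diagnosis, age,
and education: exact stratification on the sex x diagnosis cells, and
within each cell nearest-neighbor selection without replacement on the
Euclidean distance of jointly standardized age and education (SDs taken
from the full reference pool). To keep the resampling genuinely stochastic
— the percentile CIs of the bootstrap t distribution are only meaningful
if different iterations draw substantively different subsamples — each
target selects uniformly at random among its ``k_nearest`` closest
available candidates (default 25; ``k_nearest=1`` is pure greedy
matching). Target order is shuffled per iteration seed, so different seeds
yield different but reproducible subsamples.

:class:`Matcher` caches the strata and distance matrices, which do not
change across iterations; the resampling pipeline reuses one matcher for
all its draws.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import baseline_rows

__all__ = [
    "MatchPlan",
    "Matcher",
    "MatchingInfeasibleError",
    "build_matched_subsample",
    "balance_diagnostics",
    "expand_to_visits",
]


class MatchingInfeasibleError(RuntimeError):
    """A sex x diagnosis cell has fewer reference candidates than targets."""


@dataclass
class MatchPlan:
    """One iteration's matched subsample, with audit information.

    ``reference_indices`` / ``target_indices`` are row labels of the
    baseline rows in the cohort the plan was built from. ``balance`` is
    filled by :func:`balance_diagnostics` (the single-plan construction
    path does this automatically; the bulk pipeline leaves it empty and
    audits balance separately).
    """

    iteration_seed: int
    reference_group: str
    target_group: str
    reference_indices: list
    target_indices: list
    strata_report: pd.DataFrame
    balance: pd.DataFrame = field(default_factory=pd.DataFrame)
    with_replacement: bool = False

    def __post_init__(self) -> None:
        if len(self.reference_indices) != len(self.target_indices):
            raise ValueError("plan must select one reference row per target row")

    def to_json(self, path: str | Path | None = None) -> str:
        """Serialize the plan (seed, indices, balance) as JSON text."""
        payload = {
            "iteration_seed": int(self.iteration_seed),
            "reference_group": self.reference_group,
            "target_group": self.target_group,
            "reference_indices": [str(i) for i in self.reference_indices],
            "target_indices": [str(i) for i in self.target_indices],
            "strata": self.strata_report.to_dict(orient="records"),
            "balance": self.balance.reset_index().to_dict(orient="records")
            if len(self.balance)
            else [],
            "with_replacement": self.with_replacement,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def _smd(x_t: np.ndarray, x_r: np.ndarray) -> float:
    """Standardized mean difference with a guarded pooled-SD denominator."""
    v_t = np.var(x_t, ddof=1) if len(x_t) > 1 else 0.0
    v_r = np.var(x_r, ddof=1) if len(x_r) > 1 else 0.0
    pooled = np.sqrt((v_t + v_r) / 2.0)
    diff = float(np.mean(x_t) - np.mean(x_r))
    if pooled == 0.0:
        return 0.0 if diff == 0.0 else np.inf * np.sign(diff)
    return diff / pooled


class Matcher:
    """Reusable matched-subsampling engine for one contrast.

    Precomputes baseline rows, sex x diagnosis strata, reference-pool
    standardization of age/education and per-cell distance matrices;
    :meth:`draw` then produces a :class:`MatchPlan` for any seed.
    """

    def __init__(
        self,
        cohort: pd.DataFrame,
        reference_group: str,
        target_group: str,
        allow_replacement: bool = False,
        baseline: pd.DataFrame | None = None,
        k_nearest: int = 25,
    ):
        if k_nearest < 1:
            raise ValueError("k_nearest must be >= 1")
        self.reference_group = reference_group
        self.target_group = target_group
        self.allow_replacement = allow_replacement
        self.k_nearest = int(k_nearest)
        base = baseline_rows(cohort) if baseline is None else baseline
        self.baseline = base
        ref = base[base["group"] == reference_group]
        tgt = base[base["group"] == target_group]
        if len(ref) == 0 or len(tgt) == 0:
            raise ValueError(
                f"both groups must be present (reference={reference_group!r} "
                f"n={len(ref)}, target={target_group!r} n={len(tgt)})"
            )
        self.reference_pool = ref
        self.target = tgt

        # Standardize age/education by reference-pool SDs (guarded for
        # degenerate single-participant pools).
        sds = {}
        for col in ("age", "education"):
            sd = float(pd.to_numeric(ref[col]).std(ddof=1)) if len(ref) > 1 else 0.0
            sds[col] = sd if sd > 0 else 1.0
        ref_z = np.column_stack(
            [pd.to_numeric(ref[c]).to_numpy() / sds[c] for c in ("age", "education")]
        )
        tgt_z = np.column_stack(
            [pd.to_numeric(tgt[c]).to_numpy() / sds[c] for c in ("age", "education")]
        )
        ref_cell = np.array(
            [f"{s}|{d}" for s, d in zip(ref["sex"], ref["diagnosis"])]
        )
        tgt_cell = np.array(
            [f"{s}|{d}" for s, d in zip(tgt["sex"], tgt["diagnosis"])]
        )

        self.cells: list[dict] = []
        for cell in sorted(set(tgt_cell)):
            t_pos = np.flatnonzero(tgt_cell == cell)
            r_pos = np.flatnonzero(ref_cell == cell)
            n_t, n_r = len(t_pos), len(r_pos)
            if n_r < n_t and not allow_replacement:
                raise MatchingInfeasibleError(
                    f"cell sex|diagnosis={cell}: {n_r} reference candidates "
                    f"for {n_t} targets"
                )
            dt = tgt_z[t_pos]
            dr = ref_z[r_pos]
            # Squared Euclidean distance; monotone in the true distance so
            # nearest neighbors and ties are identical.
            d0 = dt[:, 0][:, None] - dr[:, 0][None, :]
            d1 = dt[:, 1][:, None] - dr[:, 1][None, :]
            self.cells.append(
                {
                    "cell": cell,
                    "dist": d0 * d0 + d1 * d1,
                    "ref_labels": ref.index[r_pos].to_numpy(),
                    "n_t": n_t,
                    "n_r": n_r,
                }
            )

    def draw(self, seed: int, compute_balance: bool = False) -> MatchPlan:
        """Draw one matched subsample under ``seed``."""
        rng = np.random.default_rng(seed)
        selected: list = []
        strata_records = []
        any_replacement = False
        for cell in self.cells:
            n_t, n_r = cell["n_t"], cell["n_r"]
            use_replacement = n_r < n_t
            if use_replacement:
                any_replacement = True
                warnings.warn(
                    f"cell {cell['cell']}: sampling reference with replacement "
                    f"({n_r} candidates for {n_t} targets)",
                    stacklevel=2,
                )
            dists = cell["dist"]
            k = self.k_nearest
            available = np.ones(n_r, dtype=bool)
            chosen = np.empty(n_t, dtype=int)
            for ti in rng.permutation(n_t):
                n_avail = int(available.sum())
                if n_avail == 0:
                    # pool exhausted: only reachable with allow_replacement
                    chosen[ti] = int(rng.integers(n_r))
                    continue
                row = np.where(available, dists[ti], np.inf)
                kk = min(k, n_avail)
                if kk == 1:
                    m = row.min()
                    cand = np.flatnonzero(row == m)
                else:
                    cand = np.argpartition(row, kk - 1)[:kk]
                j = int(cand[0]) if len(cand) == 1 else int(rng.choice(cand))
                chosen[ti] = j
                available[j] = False
            selected.extend(cell["ref_labels"][chosen].tolist())
            strata_records.append(
                {
                    "cell": cell["cell"],
                    "target_count": n_t,
                    "selected_count": n_t,
                    "reference_candidates": n_r,
                    "with_replacement": use_replacement,
                }
            )
        plan = MatchPlan(
            iteration_seed=int(seed),
            reference_group=self.reference_group,
            target_group=self.target_group,
            reference_indices=selected,
            target_indices=self.target.index.tolist(),
            strata_report=pd.DataFrame.from_records(strata_records),
            with_replacement=any_replacement,
        )
        if compute_balance:
            plan.balance = balance_diagnostics(
                self.baseline, plan, baseline=self.baseline
            )
        return plan


def build_matched_subsample(
    cohort: pd.DataFrame,
    reference_group: str,
    target_group: str,
    seed: int,
    allow_replacement: bool = False,
    k_nearest: int = 25,
) -> MatchPlan:
    """Build one matched reference subsample of the target group's size.

    Matching runs on baseline rows (one per participant). A cell with fewer
    reference candidates than targets raises
    :class:`MatchingInfeasibleError` naming the cell, unless
    ``allow_replacement`` permits within-cell sampling with replacement for
    the shortfall (emitted as a warning). The returned plan carries pre-
    and post-match balance diagnostics.
    """
    matcher = Matcher(
        cohort,
        reference_group,
        target_group,
        allow_replacement=allow_replacement,
        k_nearest=k_nearest,
    )
    return matcher.draw(seed, compute_balance=True)


def balance_diagnostics(
    cohort: pd.DataFrame, plan: MatchPlan, baseline: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Pre- and post-match balance for the matching variables.

    Standardized mean differences (target minus reference over pooled SD)
    for age and education; raw proportion differences for male sex and each
    diagnosis level. ``pre`` compares the target group with the full
    reference pool, ``post`` with the selected subsample.
    """
    if len(plan.reference_indices) == 0:
        raise ValueError("empty selection in plan")
    base = baseline_rows(cohort) if baseline is None else baseline
    tgt = base.loc[plan.target_indices]
    pool = base[base["group"] == plan.reference_group]
    sub = base.loc[plan.reference_indices]

    rows = []
    for col in ("age", "education"):
        x_t = pd.to_numeric(tgt[col]).to_numpy()
        rows.append(
            {
                "variable": col,
                "metric": "smd",
                "pre": _smd(x_t, pd.to_numeric(pool[col]).to_numpy()),
                "post": _smd(x_t, pd.to_numeric(sub[col]).to_numpy()),
            }
        )
    binaries = [("male", tgt["sex"], pool["sex"], sub["sex"])]
    for level in ("NC", "MCI", "AD"):
        binaries.append(
            (
                f"dx_{level.lower()}",
                tgt["diagnosis"] == level,
                pool["diagnosis"] == level,
                sub["diagnosis"] == level,
            )
        )
    for name, t_vals, pool_vals, sub_vals in binaries:
        pt = float(np.mean(np.asarray(t_vals, dtype=float)))
        rows.append(
            {
                "variable": name,
                "metric": "prop_diff",
                "pre": pt - float(np.mean(np.asarray(pool_vals, dtype=float))),
                "post": pt - float(np.mean(np.asarray(sub_vals, dtype=float))),
            }
        )
    return pd.DataFrame.from_records(rows).set_index("variable")


def expand_to_visits(cohort: pd.DataFrame, plan: MatchPlan) -> pd.DataFrame:
    """All visit rows of the plan's selected reference and target participants.

    Participants selected more than once (replacement fallback) contribute
    their visits once per selection so longitudinal fits see the resampled
    weights.
    """
    base = baseline_rows(cohort)
    ids = pd.concat(
        [base.loc[plan.reference_indices, "id"], base.loc[plan.target_indices, "id"]]
    )
    if not plan.with_replacement:
        mask = cohort["id"].isin(set(ids))
        return cohort[mask].reset_index(drop=True)
    # Duplicated selections keep one visit block per selection.
    pieces = []
    grouped = {pid: block for pid, block in cohort.groupby("id", sort=False)}
    for pid in ids:
        pieces.append(grouped[pid])
    return pd.concat(pieces, ignore_index=True)
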