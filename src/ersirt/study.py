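"""Cross-design bias study: generator x condition x estimator.

One *condition* fixes the generating family, the number of items, the base
thresholds and the focal group's ERS mean shift.  Per replication a fresh
two-group sample is drawn and every requested estimator is fit to the
identical dataset.  The bias outcomes are the mean over converged
replications of the focal-group substantive-trait mean estimate (true value
0) and of the variance estimate minus one (true value 1), each shipped with
its Monte-Carlo standard error.

The module also renders the model-contrast probability curves: agreement
probability and conditional extreme-agreement probability as functions of
the ERS trait at several substantive-trait levels, and full category-
probability curves at theta1 = 0 — the quantities in which the two ERS
corrections visibly disagree for asymmetric item thresholds.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import estimation
from .response_models import (
    ModelStructureError,
    ScoringMatrix,
    agreement_prob,
    conditional_extreme_agreement,
    category_probs,
)
from .synthetic_data import (
    ConditionSpec,
    derive_irtree_truth,
    make_item_set,
    sample_persons,
    simulate,
)

__all__ = [
    "BiasCell",
    "CurveReport",
    "run_condition",
    "bias_table",
    "curves_report",
    "run_study",
    "format_bias_table",
    "PRESETS",
]

log = logging.getLogger("ersirt")

#: Preset study sizes.  "full" is the reference design (500 replications);
#: "desk" is the default working scale; "smoke" is a minutes-scale shakedown
#: that skips the expensive tree-truth calibration by limiting generators.
PRESETS = {
    "smoke": dict(n_reps=5, n_per_group=200, truth_n_per_group=20_000,
                  generators=("mnrm", "gpcm")),
    "desk": dict(n_reps=100, n_per_group=1000, truth_n_per_group=100_000,
                 generators=("gpcm", "mnrm", "irtree")),
    "full": dict(n_reps=500, n_per_group=1000, truth_n_per_group=500_000,
                 generators=("gpcm", "mnrm", "irtree")),
}

#: Estimator quadrature for the study loops: None = per-dimension defaults
#: of the estimation module (fine 1-D rule, 31 points per dimension in 2-D).
STUDY_QUAD_POINTS = None


@dataclass
class BiasCell:
    """One generator x condition x estimator cell of a bias table."""

    generator: str
    estimator: str
    delta_ers: float
    n_items: int
    base_thresholds: tuple
    mu_bias: float
    var_bias: float
    mu_mc_se: float
    var_mc_se: float
    n_converged: int
    n_reps: int
    mu_flagged: bool
    var_flagged: bool


@dataclass
class CurveReport:
    """Numeric model-contrast curves (all probabilities, item-averaged)."""

    theta2_grid: np.ndarray
    theta1_levels: tuple
    agreement: pd.DataFrame  # model, theta1, theta2, prob
    conditional_extreme: pd.DataFrame  # model, theta1, theta2, prob
    category_probs: pd.DataFrame  # model, category, theta2, prob (theta1 = 0)

    def to_csv(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.agreement.to_csv(out / "agreement_curves.csv", index=False)
        self.conditional_extreme.to_csv(
            out / "conditional_extreme_curves.csv", index=False
        )
        self.category_probs.to_csv(out / "category_prob_curves.csv", index=False)


def _estimator_spec(name: str, n_categories: int = 4) -> estimation.ModelSpec:
    return estimation.ModelSpec(family=name, n_categories=n_categories)


def run_condition(
    cond: ConditionSpec,
    estimators: Sequence[str],
    seed=None,
    *,
    quad_points: Optional[int] = STUDY_QUAD_POINTS,
    tree_items: Optional[list] = None,
    truth_n_per_group: int = 100_000,
) -> pd.DataFrame:
    """Run every replication of one condition and fit every estimator.

    Per replication, persons and responses are drawn from dedicated RNG
    substreams of the root seed, so the generated data do not depend on the
    estimator list (estimators are deterministic given the data).  Estimator
    failures are logged and marked as non-converged rows; the run continues.

    Returns a tidy frame: one row per replication x estimator with the
    focal-group estimates, convergence flag and fit indices, plus the
    condition labels.
    """
    if seed is None:
        seed = cond.seed
    root = (
        seed
        if isinstance(seed, np.random.SeedSequence)
        else np.random.SeedSequence(seed)
    )
    truth_ss, *rep_ss = root.spawn(cond.n_reps + 1)

    mnrm_items = make_item_set(cond.base_thresholds, n_items=cond.n_items)
    if cond.generator == "irtree" and tree_items is None:
        log.info(
            "deriving tree-generating truth (n_per_group=%d)", truth_n_per_group
        )
        tree_items = derive_irtree_truth(
            mnrm_items, n_per_group=truth_n_per_group, seed=truth_ss
        )
    gen_items = tree_items if cond.generator == "irtree" else mnrm_items

    rows = []
    for rep, ss in enumerate(rep_ss):
        persons_ss, resp_ss = ss.spawn(2)
        persons = sample_persons(cond.group_specs, cond.n_per_group, persons_ss)
        data = simulate(
            cond.generator, gen_items, persons, np.random.default_rng(resp_ss)
        )
        for est in estimators:
            spec = _estimator_spec(est)
            t0 = time.perf_counter()
            try:
                fr = estimation.fit(data, spec, quad_points=quad_points)
                row = {
                    "rep": rep,
                    "estimator": est,
                    "converged": fr.converged,
                    "mu_theta": fr.mu_theta,
                    "var_theta": fr.var_theta,
                    "loglik": fr.loglik,
                    "n_params": fr.n_params,
                    "n_evals": fr.n_evals,
                    **fr.indices,
                }
                if fr.focal_mean.size > 1:
                    row.update(
                        mu_ers=float(fr.focal_mean[1]),
                        cov_theta_ers=float(fr.focal_cov[0, 1]),
                        var_ers=float(fr.focal_cov[1, 1]),
                    )
            except Exception as exc:  # noqa: BLE001 - replication must continue
                log.warning("rep %d estimator %s failed: %s", rep, est, exc)
                row = {
                    "rep": rep,
                    "estimator": est,
                    "converged": False,
                    "mu_theta": np.nan,
                    "var_theta": np.nan,
                }
            row["seconds"] = time.perf_counter() - t0
            rows.append(row)
    out = pd.DataFrame(rows)
    out["generator"] = cond.generator
    out["delta_ers"] = cond.delta_ers
    out["n_items"] = cond.n_items
    out["base_thresholds"] = str(list(cond.base_thresholds))
    out["n_per_group"] = cond.n_per_group
    return out


_CELL_KEYS = ["generator", "estimator", "delta_ers", "n_items", "base_thresholds"]


def bias_table(results: pd.DataFrame) -> pd.DataFrame:
    """Aggregate per-replication results into bias cells.

    Means are taken over converged replications only; non-convergent counts
    are reported alongside.  A cell with no converged replication is kept as
    a missing (NaN) row, never as zero.  The "flagged" columns mark biases
    that are both larger than 0.05 and larger than three Monte-Carlo
    standard errors — the rendering equivalent of bold table entries.
    """
    need = set(_CELL_KEYS + ["converged", "mu_theta", "var_theta"])
    if not need.issubset(results.columns):
        raise ModelStructureError(f"results frame lacks columns {need - set(results.columns)}")
    cells = []
    for keys, grp in results.groupby(_CELL_KEYS, sort=False):
        conv = grp[grp["converged"].astype(bool)]
        n_conv = len(conv)
        if n_conv == 0:
            mu = var = mu_se = var_se = np.nan
        else:
            mu = float(conv["mu_theta"].mean())
            var = float(conv["var_theta"].mean()) - 1.0
            mu_se = float(conv["mu_theta"].std(ddof=1) / np.sqrt(n_conv)) if n_conv > 1 else np.nan
            var_se = float(conv["var_theta"].std(ddof=1) / np.sqrt(n_conv)) if n_conv > 1 else np.nan
        d = dict(zip(_CELL_KEYS, keys))
        cells.append(
            BiasCell(
                generator=d["generator"],
                estimator=d["estimator"],
                delta_ers=d["delta_ers"],
                n_items=d["n_items"],
                base_thresholds=d["base_thresholds"],
                mu_bias=mu,
                var_bias=var,
                mu_mc_se=mu_se,
                var_mc_se=var_se,
                n_converged=n_conv,
                n_reps=len(grp),
                mu_flagged=bool(
                    n_conv and np.isfinite(mu_se) and abs(mu) > 3 * mu_se and abs(mu) > 0.05
                ),
                var_flagged=bool(
                    n_conv and np.isfinite(var_se) and abs(var) > 3 * var_se and abs(var) > 0.05
                ),
            )
        )
    return pd.DataFrame([asdict(c) for c in cells])


def format_bias_table(table: pd.DataFrame) -> str:
    """Text rendering of a bias table, one generator block per condition
    grid, flagged (bold-equivalent) entries marked with ``*``."""
    lines = []
    for gen, block in table.groupby("generator", sort=False):
        lines.append(f"Generating model: {gen.upper()}")
        header = f"{'dERS':>5} {'J':>3} {'tau':>12}"
        ests = list(dict.fromkeys(block["estimator"]))
        for e in ests:
            header += f" | {e:>7} mu  {e:>7} s2"
        lines.append(header)
        sub = block.pivot_table(
            index=["delta_ers", "n_items", "base_thresholds"],
            columns="estimator",
            values=["mu_bias", "var_bias", "mu_flagged", "var_flagged"],
            aggfunc="first",
            sort=False,
        )
        for idx, row in sub.iterrows():
            d, j, tau = idx
            line = f"{d:>5} {j:>3} {tau:>12}"
            for e in ests:
                mu = row.get(("mu_bias", e), np.nan)
                va = row.get(("var_bias", e), np.nan)
                mf = "*" if row.get(("mu_flagged", e), False) else " "
                vf = "*" if row.get(("var_flagged", e), False) else " "
                line += f" | {mu:>9.3f}{mf} {va:>9.3f}{vf}"
            lines.append(line)
        lines.append("")
    return "\n".join(lines)


def curves_report(
    mnrm_items: Sequence,
    tree_items: Sequence,
    theta2_grid: Optional[np.ndarray] = None,
    theta1_levels: Sequence[float] = (-2.0, -1.0, 0.0, 1.0, 2.0),
    scoring: Optional[ScoringMatrix] = None,
) -> CurveReport:
    """Item-averaged probability curves contrasting the MNRM and the tree.

    ``tree_items`` must be the calibration of ``mnrm_items`` (same length).
    The report carries, per model: agreement probability P(Y in {3,4}) and
    conditional extreme agreement P(4 | {1,4}) on a theta2 grid at several
    theta1 levels, and the four category-probability curves at theta1 = 0.
    """
    if len(mnrm_items) != len(tree_items):
        raise ModelStructureError("matched MNRM and tree item sets are required")
    if theta2_grid is None:
        theta2_grid = np.linspace(-3.0, 3.0, 121)
    theta2_grid = np.asarray(theta2_grid, dtype=float)
    if scoring is None:
        scoring = ScoringMatrix.ers(mnrm_items[0].n_categories)

    models = {"mnrm": mnrm_items, "irtree": tree_items}
    agree_rows, cond_rows, cat_rows = [], [], []
    for name, items in models.items():
        for t1 in theta1_levels:
            grid = np.column_stack([np.full_like(theta2_grid, t1), theta2_grid])
            ag = np.mean(
                [agreement_prob(name, grid, it, scoring) for it in items], axis=0
            )
            ce = np.mean(
                [conditional_extreme_agreement(name, grid, it, scoring) for it in items],
                axis=0,
            )
            for t2, a, c in zip(theta2_grid, ag, ce):
                agree_rows.append({"model": name, "theta1": t1, "theta2": t2, "prob": a})
                cond_rows.append({"model": name, "theta1": t1, "theta2": t2, "prob": c})
        grid0 = np.column_stack([np.zeros_like(theta2_grid), theta2_grid])
        probs = np.mean(
            [category_probs(name, grid0, it, scoring) for it in items], axis=0
        )
        for k in range(probs.shape[1]):
            for t2, p in zip(theta2_grid, probs[:, k]):
                cat_rows.append(
                    {"model": name, "category": k + 1, "theta2": t2, "prob": p}
                )
    return CurveReport(
        theta2_grid=theta2_grid,
        theta1_levels=tuple(theta1_levels),
        agreement=pd.DataFrame(agree_rows),
        conditional_extreme=pd.DataFrame(cond_rows),
        category_probs=pd.DataFrame(cat_rows),
    )


DEFAULT_CONFIG = {
    "generators": ["gpcm", "mnrm", "irtree"],
    "delta_ers": [-1.0, 0.0, 1.0],
    "n_items": [10, 20],
    "base_thresholds": [[-1.0, 0.0, 1.0], [0.0, 1.0, 2.0]],
    "estimators": ["mnrm", "irtree", "gpcm"],
    "n_per_group": 1000,
    "n_reps": 100,
    "truth_n_per_group": 100_000,
    "quad_points": STUDY_QUAD_POINTS,
    "seed": 20230217,
}


def run_study(config: Optional[dict] = None, out_dir=None) -> dict:
    """Run the full cross design and write tables, curves and a manifest.

    The control (no-response-style) generator contributes one cell per
    (n_items, thresholds) pair; the MNRM and tree generators additionally
    cross the focal ERS mean shifts.  Tree-generating item parameters are
    derived once per (n_items, thresholds) pair at a zero ERS shift and
    reused across shifts.  Per-cell results are checkpointed to CSV and
    reloaded on rerun, so a partial run resumes where it stopped.
    """
    cfg = dict(DEFAULT_CONFIG)
    cfg.update(config or {})
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        (out / "cells").mkdir(parents=True, exist_ok=True)

    root = np.random.SeedSequence(int(cfg["seed"]))
    # one deterministic child per potential cell / truth derivation, keyed by name
    all_results = []
    manifest = {
        "config": cfg,
        "root_seed": int(cfg["seed"]),
        "cells": {},
        "versions": _versions(),
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }

    truth_cache: dict = {}
    cell_index = 0
    for gen in cfg["generators"]:
        deltas = [0.0] if gen == "gpcm" else cfg["delta_ers"]
        for n_items in cfg["n_items"]:
            for base in cfg["base_thresholds"]:
                base_t = tuple(float(b) for b in base)
                if gen == "irtree":
                    key = (n_items, base_t)
                    if key not in truth_cache:
                        truth_ss = np.random.SeedSequence(
                            entropy=int(cfg["seed"]), spawn_key=(10_000 + cell_index,)
                        )
                        truth_cache[key] = derive_irtree_truth(
                            make_item_set(base_t, n_items=n_items),
                            n_per_group=int(cfg["truth_n_per_group"]),
                            seed=truth_ss,
                        )
                for delta in deltas:
                    cell_index += 1
                    name = f"{gen}_J{n_items}_base{'_'.join(str(b) for b in base_t)}_d{delta}"
                    cell_seed = np.random.SeedSequence(
                        entropy=int(cfg["seed"]), spawn_key=(cell_index,)
                    )
                    ckpt = out / "cells" / f"{name}.csv" if out is not None else None
                    if ckpt is not None and ckpt.exists():
                        res = pd.read_csv(ckpt)
                        log.info("cell %s loaded from checkpoint", name)
                    else:
                        cond = ConditionSpec(
                            generator=gen,
                            n_items=n_items,
                            base_thresholds=base_t,
                            delta_ers=float(delta),
                            n_per_group=int(cfg["n_per_group"]),
                            n_reps=int(cfg["n_reps"]),
                        )
                        res = run_condition(
                            cond,
                            cfg["estimators"],
                            seed=cell_seed,
                            quad_points=(None if cfg["quad_points"] in (None, "none")
                                         else int(cfg["quad_points"])),
                            tree_items=truth_cache.get((n_items, base_t)),
                        )
                        if ckpt is not None:
                            res.to_csv(ckpt, index=False)
                    manifest["cells"][name] = {
                        "spawn_key": cell_index,
                        "n_converged": int(res["converged"].sum()),
                        "n_rows": len(res),
                    }
                    all_results.append(res)

    results = pd.concat(all_results, ignore_index=True)
    table = bias_table(results)

    curves = {}
    for base in cfg["base_thresholds"]:
        base_t = tuple(float(b) for b in base)
        key = (min(cfg["n_items"]), base_t)
        if key in truth_cache:
            curves[str(list(base_t))] = curves_report(
                make_item_set(base_t, n_items=key[0]), truth_cache[key]
            )

    manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    if out is not None:
        results.to_csv(out / "replications.csv", index=False)
        table.to_csv(out / "bias_table.csv", index=False)
        (out / "bias_table.txt").write_text(format_bias_table(table))
        for label, rep in curves.items():
            rep.to_csv(out / f"curves_{label.replace(' ', '').replace(',', '_').strip('[]')}")
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return {"results": results, "bias_table": table, "curves": curves, "manifest": manifest}


def _versions() -> dict:
    from importlib.metadata import version

    import scipy

    from . import __version__

    return {
        "ersirt": __version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "click": version("click"),
    }
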