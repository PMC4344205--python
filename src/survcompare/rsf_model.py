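"""Random survival forest: bootstrap survival trees with log-rank splitting.

Each of ``n_trees`` trees is grown on a bootstrap resample of the cohort (a
resample excludes about 37% of patients, the out-of-bag set).  At every node
a random subset of ``n_candidates`` covariates is drawn and the admissible
split maximizing the two-sample log-rank statistic between the daughters is
taken; a split is admissible only if both daughters retain at least
``min_unique_deaths`` distinct death times, and a node with no admissible
split becomes a leaf carrying the Nelson-Aalen cumulative hazard of its
patients.  Prediction routes a patient to a leaf in every tree and averages
the leaf CHFs; survival is S(t) = exp(-CHF(t)).  Out-of-bag curves average
only over trees whose bootstrap missed the patient, giving an internal
error estimate untouched by the training data.

Ordered covariates (discretized expression low<medium<high, ordinal clinical
bins) split by threshold on the level code; unordered covariates split one
level against the rest.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .curves import StepCurve

__all__ = [
    "RSFConfig",
    "RSFFit",
    "RSFError",
    "log_rank_split_score",
    "fit_rsf",
    "predict_survival_curve_rsf",
    "predict_survival_curves_rsf",
    "oob_error",
    "oob_survival_curves",
    "bootstrap_oob_fraction",
]


class RSFError(ValueError):
    pass


@dataclass(frozen=True)
class RSFConfig:
    """Forest hyperparameters: number of bootstrap trees, covariates tried
    per node (default ceil(sqrt(p))), and the unique-death stopping bound."""

    n_trees: int = 500
    n_candidates: int | None = None
    min_unique_deaths: int = 3
    seed: int = 0

    def validate(self) -> None:
        if self.n_trees < 1:
            raise RSFError("n_trees must be >= 1")
        if self.n_candidates is not None and self.n_candidates < 1:
            raise RSFError("n_candidates must be >= 1")
        if self.min_unique_deaths < 1:
            raise RSFError("min_unique_deaths must be >= 1 (D > 0)")


# --- log-rank split statistic ----------------------------------------------

def _events_bool(status) -> np.ndarray:
    s = np.asarray(status)
    if s.dtype == bool:
        return s
    return s == "dead"


def log_rank_split_score(day, status, left_mask) -> float:
    """Two-sample log-rank statistic (O-E)^2 / V between the daughters.

    Larger means a greater survival difference; identical daughters score 0;
    the statistic is symmetric under swapping the daughter labels.  An empty
    daughter or a node without events is not a valid split and raises.
    """
    day = np.asarray(day, dtype=float)
    ev = _events_bool(status)
    left = np.asarray(left_mask, dtype=bool)
    if not left.any() or left.all():
        raise RSFError("both daughters must be non-empty")
    if not ev.any():
        raise RSFError("a split needs at least one event in the node")
    et, d = np.unique(day[ev], return_counts=True)
    sd_all = np.sort(day)
    sd_left = np.sort(day[left])
    Y = len(day) - np.searchsorted(sd_all, et, side="left")
    Y1 = len(sd_left) - np.searchsorted(sd_left, et, side="left")
    d1 = np.zeros_like(d)
    ul, cl = np.unique(day[ev & left], return_counts=True)
    d1[np.searchsorted(et, ul)] = cl
    return _score_from_counts(d, d1, Y, Y1)


def _score_from_counts(d, d1, Y, Y1) -> float:
    frac = Y1 / Y
    E1 = d * frac
    with np.errstate(divide="ignore", invalid="ignore"):
        v = np.where(Y > 1, d * frac * (1 - frac) * (Y - d) / np.maximum(Y - 1, 1), 0.0)
    V = float(v.sum())
    if V <= 0:
        return 0.0
    return float((d1.sum() - E1.sum()) ** 2 / V)


# --- feature encoding -------------------------------------------------------

def _feature_meta(df: pd.DataFrame) -> list[dict]:
    meta = []
    for col in df.columns:
        s = df[col]
        if isinstance(s.dtype, pd.CategoricalDtype):
            meta.append(
                {
                    "name": col,
                    "levels": [str(v) for v in s.cat.categories],
                    "ordered": bool(s.cat.ordered),
                    "numeric": False,
                }
            )
        elif s.dtype == object:
            meta.append(
                {"name": col, "levels": sorted(map(str, pd.unique(s))), "ordered": False, "numeric": False}
            )
        else:
            levels = np.unique(s.to_numpy(dtype=float))
            meta.append({"name": col, "levels": levels.tolist(), "ordered": True, "numeric": True})
    return meta


def _encode_with_meta(df: pd.DataFrame, meta: list[dict]) -> np.ndarray:
    cols = []
    for info in meta:
        col = info["name"]
        if col not in df.columns:
            raise RSFError(f"missing column {col!r}")
        s = df[col]
        if info["numeric"]:
            levels = np.asarray(info["levels"], dtype=float)
            codes = np.searchsorted(levels, s.to_numpy(dtype=float), side="left")
            codes = np.clip(codes, 0, len(levels) - 1)
        else:
            lookup = {lv: i for i, lv in enumerate(info["levels"])}
            codes = np.array([lookup.get(str(v), -1) for v in s], dtype=np.int64)
        cols.append(codes)
    return np.column_stack(cols).astype(np.int16)


# --- trees ------------------------------------------------------------------

def _nelson_aalen(day: np.ndarray, ev: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    if not ev.any():
        return np.empty(0), np.empty(0)
    et, d = np.unique(day[ev], return_counts=True)
    sd = np.sort(day)
    Y = len(day) - np.searchsorted(sd, et, side="left")
    return et, np.cumsum(d / Y)


def _grow_tree(X, day, ev, ordered, cfg: RSFConfig, rng: np.random.Generator) -> list[dict]:
    p = X.shape[1]
    ncand = cfg.n_candidates or max(1, math.ceil(math.sqrt(p)))
    ncand = min(ncand, p)
    D = cfg.min_unique_deaths
    nodes: list[dict] = []

    def leaf(idx) -> int:
        t, chf = _nelson_aalen(day[idx], ev[idx])
        nodes.append({"leaf": True, "times": t, "chf": chf})
        return len(nodes) - 1

    def build(idx) -> int:
        d_node = day[idx]
        e_node = ev[idx]
        et, d = np.unique(d_node[e_node], return_counts=True)
        if len(et) < 2 * D or len(idx) < 2:
            return leaf(idx)
        sd_all = np.sort(d_node)
        Y = len(idx) - np.searchsorted(sd_all, et, side="left")
        cands = np.sort(rng.choice(p, size=ncand, replace=False))
        best = None  # (score, j, kind, value, left_mask)
        for j in cands:
            vals = X[idx, j]
            u = np.unique(vals)
            if len(u) < 2:
                continue
            if ordered[j]:
                splits = [("le", int(c)) for c in u[:-1]]
            else:
                splits = [("eq", int(c)) for c in (u if len(u) > 2 else u[:1])]
            for kind, c in splits:
                left = vals <= c if kind == "le" else vals == c
                sd_left = np.sort(d_node[left])
                Y1 = left.sum() - np.searchsorted(sd_left, et, side="left")
                d1 = np.zeros_like(d)
                ul, cl = np.unique(d_node[e_node & left], return_counts=True)
                d1[np.searchsorted(et, ul)] = cl
                if (d1 > 0).sum() < D or ((d - d1) > 0).sum() < D:
                    continue
                score = _score_from_counts(d, d1, Y, Y1)
                if best is None or score > best[0]:
                    best = (score, int(j), kind, c, left)
        if best is None:
            return leaf(idx)
        _, j, kind, c, left = best
        majority = "L" if left.sum() >= (~left).sum() else "R"
        nid = len(nodes)
        nodes.append({"leaf": False, "feature": j, "kind": kind, "value": c, "majority": majority})
        nodes[nid]["left"] = build(idx[left])
        nodes[nid]["right"] = build(idx[~left])
        return nid

    build(np.arange(len(day)))
    return nodes


def _route(nodes: list[dict], X: np.ndarray) -> np.ndarray:
    leaf_of = np.zeros(len(X), dtype=np.int64)
    stack = [(0, np.arange(len(X)))]
    while stack:
        nid, rows = stack.pop()
        if rows.size == 0:
            continue
        node = nodes[nid]
        if node["leaf"]:
            leaf_of[rows] = nid
            continue
        v = X[rows, node["feature"]]
        if node["kind"] == "le":
            go_left = v <= node["value"]
        else:
            go_left = v == node["value"]
        unseen = v < 0
        if unseen.any():
            go_left = np.where(unseen, node["majority"] == "L", go_left)
        stack.append((node["left"], rows[go_left]))
        stack.append((node["right"], rows[~go_left]))
    return leaf_of


def _leaf_chf_on_grid(nodes: list[dict], grid: np.ndarray) -> dict[int, np.ndarray]:
    out = {}
    for nid, node in enumerate(nodes):
        if not node["leaf"]:
            continue
        t, chf = node["times"], node["chf"]
        if len(t) == 0:
            out[nid] = np.zeros(len(grid))
        else:
            idx = np.searchsorted(t, grid, side="right") - 1
            vals = np.concatenate(([0.0], chf))
            out[nid] = vals[idx + 1]
    return out


@dataclass
class RSFFit:
    trees: list[list[dict]]
    in_bag: list[np.ndarray]
    meta: list[dict]
    grid: np.ndarray
    config: RSFConfig
    horizon: float
    n_patients: int

    def to_json(self) -> str:
        def node_ser(n):
            if n["leaf"]:
                return {"leaf": True, "times": n["times"].tolist(), "chf": n["chf"].tolist()}
            return {k: v for k, v in n.items()}

        return json.dumps(
            {
                "trees": [[node_ser(n) for n in t] for t in self.trees],
                "in_bag": [b.tolist() for b in self.in_bag],
                "meta": self.meta,
                "grid": self.grid.tolist(),
                "config": {
                    "n_trees": self.config.n_trees,
                    "n_candidates": self.config.n_candidates,
                    "min_unique_deaths": self.config.min_unique_deaths,
                    "seed": self.config.seed,
                },
                "horizon": self.horizon,
                "n_patients": self.n_patients,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "RSFFit":
        d = json.loads(text)

        def node_de(n):
            if n["leaf"]:
                return {
                    "leaf": True,
                    "times": np.asarray(n["times"], dtype=float),
                    "chf": np.asarray(n["chf"], dtype=float),
                }
            return n

        return cls(
            trees=[[node_de(n) for n in t] for t in d["trees"]],
            in_bag=[np.asarray(b, dtype=np.int64) for b in d["in_bag"]],
            meta=d["meta"],
            grid=np.asarray(d["grid"], dtype=float),
            config=RSFConfig(**d["config"]),
            horizon=d["horizon"],
            n_patients=d["n_patients"],
        )


def fit_rsf(
    features: pd.DataFrame, day, status, horizon: float | None, config: RSFConfig
) -> RSFFit:
    """Grow the bootstrap forest on follow-up truncated at ``horizon``."""
    from .cox_model import truncate_followup

    config.validate()
    day_t, status_t = truncate_followup(day, status, horizon)
    ev = _events_bool(status_t)
    if not ev.any():
        raise RSFError("no events within the horizon; cannot fit")
    meta = _feature_meta(features)
    X = _encode_with_meta(features, meta)
    ordered = np.array([m["ordered"] for m in meta])
    n = len(day_t)
    rng = np.random.default_rng(config.seed)
    trees, bags = [], []
    for _ in range(config.n_trees):
        child = np.random.default_rng(rng.integers(0, 2**31))
        bag = child.integers(0, n, size=n)
        Xb, db, eb = X[bag], day_t[bag], ev[bag]
        if not eb.any():  # a pathological resample with no events: root leaf
            trees.append([{"leaf": True, "times": np.empty(0), "chf": np.empty(0)}])
        else:
            trees.append(_grow_tree(Xb, db, eb, ordered, config, child))
        bags.append(bag)
    grid = np.unique(day_t[ev])
    if horizon is not None:
        grid = grid[grid <= horizon]
    return RSFFit(
        trees=trees,
        in_bag=bags,
        meta=meta,
        grid=grid,
        config=config,
        horizon=float(horizon) if horizon is not None else float(day_t.max()),
        n_patients=n,
    )


def _ensemble_chf(fit: RSFFit, X: np.ndarray, tree_mask: np.ndarray | None = None) -> np.ndarray:
    """Mean CHF over (a subset of) trees, evaluated on the fit grid.

    ``tree_mask`` is an optional (n_rows, n_trees) boolean matrix selecting,
    per row, which trees contribute (used for out-of-bag curves)."""
    n = len(X)
    g = len(fit.grid)
    total = np.zeros((n, g))
    counts = np.zeros(n) if tree_mask is not None else float(len(fit.trees))
    for t_i, nodes in enumerate(fit.trees):
        chf_by_leaf = _leaf_chf_on_grid(nodes, fit.grid)
        leaf_of = _route(nodes, X)
        contrib = np.stack([chf_by_leaf[l] for l in leaf_of]) if n else np.zeros((0, g))
        if tree_mask is None:
            total += contrib
        else:
            sel = tree_mask[:, t_i]
            total[sel] += contrib[sel]
            counts[sel] += 1
    if tree_mask is None:
        return total / counts
    if np.any(counts == 0):
        raise RSFError("some rows are in-bag for every tree; no OOB estimate")
    return total / counts[:, None]


def predict_survival_curves_rsf(fit: RSFFit, rows: pd.DataFrame, horizon: float) -> list[StepCurve]:
    X = _encode_with_meta(rows, fit.meta)
    chf = _ensemble_chf(fit, X)
    keep = fit.grid <= horizon
    return [StepCurve(times=fit.grid[keep], values=np.exp(-c[keep])) for c in chf]


def predict_survival_curve_rsf(fit: RSFFit, x: pd.Series | pd.DataFrame, horizon: float) -> StepCurve:
    rows = x.to_frame().T if isinstance(x, pd.Series) else x
    return predict_survival_curves_rsf(fit, rows, horizon)[0]


def oob_survival_curves(
    fit: RSFFit, features: pd.DataFrame, horizon: float
) -> tuple[list[StepCurve], np.ndarray]:
    """Out-of-bag curves for the training patients.

    Returns ``(curves, included_mask)``: a patient in-bag for every tree has
    no OOB estimate and is excluded from the mask."""
    X = _encode_with_meta(features, fit.meta)
    n = len(X)
    oob = np.ones((n, len(fit.trees)), dtype=bool)
    for t_i, bag in enumerate(fit.in_bag):
        oob[np.unique(bag), t_i] = False
    included = oob.any(axis=1)
    chf = _ensemble_chf(fit, X[included], tree_mask=oob[included])
    keep = fit.grid <= horizon
    curves = [StepCurve(times=fit.grid[keep], values=np.exp(-c[keep])) for c in chf]
    return curves, included


def oob_error(fit: RSFFit, features: pd.DataFrame, day, status, horizon: float):
    """Out-of-bag concordance of the forest (error = 1 - index).

    Evaluates the area-under-curve concordance on patients that are
    out-of-bag for at least one tree."""
    from .evaluation import concordance_index

    curves, included = oob_survival_curves(fit, features, horizon)
    day = np.asarray(day, dtype=float)[included]
    status = np.asarray(status, dtype=object)[included]
    return concordance_index(curves, day, status, horizon)


def bootstrap_oob_fraction(n: int, n_resamples: int, seed: int = 0) -> float:
    """Monte-Carlo mean fraction of items absent from a bootstrap resample
    of size n (theory: (1 - 1/n)^n -> e^-1, about 37%)."""
    rng = np.random.default_rng(seed)
    fracs = np.empty(n_resamples)
    for i in range(n_resamples):
        bag = rng.integers(0, n, size=n)
        fracs[i] = 1.0 - len(np.unique(bag)) / n
    return float(fracs.mean())
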