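"""Partial least squares path modeling (PLS-PM).

A minimal reflective (mode A) PLS-PM engine with the centroid inner
scheme: latent variables are iteratively estimated as weighted sums of
their manifest variables, path coefficients come from OLS of each
endogenous latent on its predecessors' scores, and model quality is
summarised by block communalities, per-latent R2 and the global
goodness-of-fit GOF = sqrt(mean communality x mean R2). Bootstrap
case-resampling gives confidence intervals and significance for the
path coefficients.

Latent scores are standardised to unit variance and the sign of each
score is fixed to correlate positively with the block's first manifest
variable — PLS scores are otherwise sign-indeterminate, which would
break reproducibility.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["PathModel", "PLSPMResult", "fit_plspm", "gof", "bootstrap_paths"]


@dataclass
class PathModel:
    """Latent blocks and the directed inner (structural) paths.

    ``blocks`` maps latent names to their manifest variable columns;
    ``paths`` is a list of (source, target) latent pairs. The path graph
    must be acyclic and every manifest may appear in exactly one block.
    """

    blocks: dict[str, list[str]]
    paths: list[tuple[str, str]]

    def __post_init__(self) -> None:
        if not self.blocks:
            raise ValueError("model needs at least one block")
        seen: dict[str, str] = {}
        for name, mans in self.blocks.items():
            if not mans:
                raise ValueError(f"block {name!r} is empty")
            for m in mans:
                if m in seen:
                    raise ValueError(
                        f"manifest {m!r} appears in blocks {seen[m]!r} and {name!r}")
                seen[m] = name
        names = set(self.blocks)
        for s, t in self.paths:
            if s not in names or t not in names:
                raise ValueError(f"path ({s!r}, {t!r}) references unknown block")
            if s == t:
                raise ValueError("self-loop in path model")
        self.topological_order()  # raises on cycles

    def topological_order(self) -> list[str]:
        order, temp, perm = [], set(), set()

        def visit(v):
            if v in perm:
                return
            if v in temp:
                raise ValueError("inner path model contains a cycle")
            temp.add(v)
            for s, t in self.paths:
                if t == v:
                    visit(s)
            temp.discard(v)
            perm.add(v)
            order.append(v)

        for v in self.blocks:
            visit(v)
        return order

    def predecessors(self, block: str) -> list[str]:
        return [s for s, t in self.paths if t == block]

    def neighbors(self, block: str) -> list[str]:
        return ([s for s, t in self.paths if t == block]
                + [t for s, t in self.paths if s == block])

    @property
    def endogenous(self) -> list[str]:
        return [b for b in self.blocks if self.predecessors(b)]

    @classmethod
    def from_dict(cls, spec: dict) -> "PathModel":
        return cls(blocks={k: list(v) for k, v in spec["blocks"].items()},
                   paths=[tuple(p) for p in spec["paths"]])

    @classmethod
    def from_json(cls, path) -> "PathModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def to_dot(self) -> str:
        """GraphViz DOT source of the structural diagram."""
        lines = ["digraph pathmodel {", "  rankdir=LR;"]
        for b in self.blocks:
            lines.append(f'  "{b}" [shape=ellipse];')
        for s, t in self.paths:
            lines.append(f'  "{s}" -> "{t}";')
        lines.append("}")
        return "\n".join(lines)


@dataclass
class PLSPMResult:
    model: PathModel
    scores: pd.DataFrame                 # samples x latents, unit variance
    outer_weights: dict[str, pd.Series]  # per block
    loadings: dict[str, pd.Series]       # corr(manifest, score)
    path_coefficients: pd.DataFrame      # source, target, coefficient
    r_squared: dict[str, float]          # per endogenous latent
    communality: dict[str, float]        # mean squared loading per block
    gof: float
    converged: bool = True
    n_iter: int = 0

    def path(self, source: str, target: str) -> float:
        sel = self.path_coefficients[
            (self.path_coefficients["source"] == source)
            & (self.path_coefficients["target"] == target)]
        if sel.empty:
            raise KeyError(f"no path {source} -> {target}")
        return float(sel["coefficient"].iloc[0])


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std(axis=0, ddof=1)
    if (sd == 0).any():
        raise ValueError("zero-variance manifest variable")
    return (x - x.mean(axis=0)) / sd


def fit_plspm(data: pd.DataFrame, model: PathModel, tol: float = 1e-6,
              max_iter: int = 300) -> PLSPMResult:
    """Fit a reflective PLS path model (mode A outer, centroid inner).

    ``data`` holds one column per manifest variable; rows with missing
    values are dropped (complete-case analysis). Raises on
    non-convergence or a singular structural regression.
    """
    manifests = [m for mans in model.blocks.values() for m in mans]
    missing = [m for m in manifests if m not in data.columns]
    if missing:
        raise ValueError(f"manifest variables missing from data: {missing}")
    frame = data[manifests].dropna()
    n = len(frame)
    if n <= len(model.blocks):
        raise ValueError("need more samples than latent variables")
    x = {b: _standardize(frame[mans].to_numpy(dtype=float))
         for b, mans in model.blocks.items()}

    # initial outer weights: equal
    w = {b: np.ones(len(mans)) for b, mans in model.blocks.items()}

    def scores_from(wts):
        out = {}
        for b in model.blocks:
            y = x[b] @ wts[b]
            sd = y.std(ddof=1)
            if sd == 0:
                raise ValueError(f"degenerate latent score for block {b!r}")
            y = y / sd
            if np.corrcoef(y, x[b][:, 0])[0, 1] < 0:
                y, wts[b] = -y, -wts[b]
            out[b] = y
        return out

    y = scores_from(w)
    converged, it = False, 0
    for it in range(1, max_iter + 1):
        w_old = {b: w[b] / np.linalg.norm(w[b]) for b in w}
        # centroid inner estimation
        z = {}
        for b in model.blocks:
            nbrs = model.neighbors(b)
            if not nbrs:
                z[b] = y[b].copy()  # isolated latent keeps its own score
                continue
            acc = np.zeros(n)
            for c in nbrs:
                acc += np.sign(np.corrcoef(y[b], y[c])[0, 1]) * y[c]
            z[b] = acc
        # mode A outer update: weights proportional to cov(manifest, inner proxy)
        for b in model.blocks:
            w[b] = x[b].T @ z[b] / (n - 1)
        y = scores_from(w)
        delta = max(np.max(np.abs(w[b] / np.linalg.norm(w[b]) - w_old[b]))
                    for b in w)
        if delta < tol:
            converged = True
            break
    if not converged:
        raise RuntimeError(
            f"PLS-PM did not converge in {max_iter} iterations (last delta {delta:.2e})")

    scores = pd.DataFrame({b: y[b] for b in model.blocks}, index=frame.index)
    loadings = {
        b: pd.Series([np.corrcoef(x[b][:, k], y[b])[0, 1]
                      for k in range(x[b].shape[1])], index=model.blocks[b])
        for b in model.blocks
    }
    communality = {b: float((loadings[b] ** 2).mean()) for b in model.blocks}
    outer_weights = {b: pd.Series(w[b] / np.linalg.norm(w[b]), index=model.blocks[b])
                     for b in model.blocks}

    rows, r2 = [], {}
    for b in model.endogenous:
        preds = model.predecessors(b)
        design = np.column_stack([y[p] for p in preds])
        rank = np.linalg.matrix_rank(design)
        if rank < design.shape[1]:
            raise np.linalg.LinAlgError(
                f"singular structural design for latent {b!r}")
        coef, *_ = np.linalg.lstsq(design, y[b], rcond=None)
        resid = y[b] - design @ coef
        r2[b] = float(1.0 - resid.var(ddof=0) / y[b].var(ddof=0))
        rows.extend({"source": p, "target": b, "coefficient": float(c)}
                    for p, c in zip(preds, coef))
    path_coefficients = pd.DataFrame(rows, columns=["source", "target", "coefficient"])

    g = _gof(communality, r2)
    return PLSPMResult(model=model, scores=scores, outer_weights=outer_weights,
                       loadings=loadings, path_coefficients=path_coefficients,
                       r_squared=r2, communality=communality, gof=g,
                       converged=converged, n_iter=it)


def _gof(communality: dict[str, float], r2: dict[str, float]) -> float:
    if not r2:
        raise ValueError("GOF undefined: model has no endogenous latent")
    return float(np.sqrt(np.mean(list(communality.values()))
                         * np.mean(list(r2.values()))))


def gof(result: PLSPMResult) -> float:
    """Goodness-of-fit: sqrt(mean block communality x mean endogenous R2)."""
    return _gof(result.communality, result.r_squared)


def bootstrap_paths(data: pd.DataFrame, model: PathModel, n_boot: int = 999,
                    seed: int | None = None, alpha: float = 0.05) -> pd.DataFrame:
    """Bootstrap CIs and significance for the path coefficients.

    Case resampling with ``n_boot`` replicates; resamples where a
    manifest collapses to zero variance (or the fit fails) are skipped
    and counted. A path is flagged significant when its percentile CI
    excludes 0; the two-sided bootstrap p is 2 min(P(b<=0), P(b>=0)).
    """
    if n_boot < 99:
        raise ValueError("use at least 99 bootstrap replicates")
    base = fit_plspm(data, model)
    keys = [(r.source, r.target) for r in base.path_coefficients.itertuples()]
    draws = {k: [] for k in keys}
    rng = np.random.default_rng(seed)
    n = len(data)
    skipped = 0
    for _ in range(n_boot):
        idx = rng.integers(0, n, n)
        try:
            res = fit_plspm(data.iloc[idx], model)
        except (ValueError, RuntimeError, np.linalg.LinAlgError):
            skipped += 1
            continue
        for r in res.path_coefficients.itertuples():
            draws[(r.source, r.target)].append(r.coefficient)
    if skipped:
        warnings.warn(f"{skipped} of {n_boot} bootstrap resamples skipped")
    rows = []
    for (s, t) in keys:
        b = np.asarray(draws[(s, t)])
        lo, hi = np.percentile(b, [100 * alpha / 2, 100 * (1 - alpha / 2)])
        p = 2 * min((b <= 0).mean(), (b >= 0).mean())
        p = max(p, 1.0 / (len(b) + 1))
        rows.append({"source": s, "target": t,
                     "coefficient": base.path(s, t),
                     "ci_lower": float(lo), "ci_upper": float(hi),
                     "p_boot": float(min(p, 1.0)),
                     "significant": bool(lo > 0 or hi < 0),
                     "n_effective": len(b)})
    return pd.DataFrame(rows)
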