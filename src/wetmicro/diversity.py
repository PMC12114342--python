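"""Alpha/beta diversity, ordination and niche breadth.

Chao1 (bias-corrected) and Shannon (nats) richness/diversity, Bray-Curtis
dissimilarity, principal coordinates analysis (PCoA), a permutation
PERMANOVA, and Levins' niche breadth.

PCoA and PERMANOVA are implemented directly on the Gower-centred distance
matrix; the PERMANOVA permutation loop is vectorised so that large
simulation studies (hundreds of null datasets) stay cheap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix

from .tables import AbundanceTable

__all__ = [
    "chao1",
    "shannon",
    "alpha_diversity",
    "bray_curtis",
    "OrdinationResult",
    "pcoa",
    "PermanovaResult",
    "permanova",
    "levins_niche_breadth",
]


def chao1(counts) -> float:
    """Bias-corrected Chao1 richness: ``S_obs + F1(F1-1) / (2(F2+1))``.

    Requires integer counts — the estimator is built on singleton and
    doubleton frequencies and is undefined on relative abundances.
    """
    x = np.asarray(counts, dtype=float)
    if x.size and not np.allclose(x, np.round(x)):
        raise ValueError("Chao1 requires integer counts, not relative abundances")
    if (x < 0).any():
        raise ValueError("negative counts")
    x = np.round(x).astype(np.int64)
    s_obs = int((x > 0).sum())
    f1 = int((x == 1).sum())
    f2 = int((x == 2).sum())
    return s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))


def shannon(counts) -> float:
    """Shannon diversity H = -sum p_i ln p_i (natural log)."""
    x = np.asarray(counts, dtype=float)
    if (x < 0).any():
        raise ValueError("negative counts")
    total = x.sum()
    if total <= 0:
        raise ValueError("Shannon index undefined for an all-zero vector")
    p = x[x > 0] / total
    return float(-(p * np.log(p)).sum())


def alpha_diversity(table: AbundanceTable) -> pd.DataFrame:
    """Per-sample Chao1, Shannon and observed richness."""
    rows = {}
    for sid, row in table.counts.iterrows():
        v = row.to_numpy()
        rows[sid] = {
            "observed_richness": int((v > 0).sum()),
            "chao1": chao1(v),
            "shannon": shannon(v),
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def bray_curtis(table: AbundanceTable) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarity, ``sum|a-b| / sum(a+b)``."""
    x = table.counts.to_numpy(dtype=float)
    d = squareform(pdist(x, metric="braycurtis"))
    return DistanceMatrix(d, ids=table.sample_ids)


@dataclass
class OrdinationResult:
    """PCoA output: coordinates scaled by sqrt(eigenvalue), per-axis shares."""

    coordinates: pd.DataFrame  # samples x axes, positive-eigenvalue axes only
    eigenvalues: np.ndarray    # all eigenvalues, descending (negatives kept)
    proportion_explained: np.ndarray  # over positive eigenvalues only


def pcoa(d: DistanceMatrix, n_axes: int | None = None) -> OrdinationResult:
    """Principal coordinates analysis of a distance matrix.

    Eigendecomposition of the Gower-centred matrix ``-0.5 J D^2 J``.
    Negative eigenvalues (non-Euclidean input, e.g. Bray-Curtis) are
    reported but only positive-eigenvalue axes yield coordinates;
    the proportion explained is computed over the positive part.
    """
    dm = np.asarray(d.data, dtype=float)
    n = dm.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (dm ** 2) @ j
    evals, evecs = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    tol = max(1e-12, 1e-10 * max(abs(evals.max(initial=0.0)), 1.0))
    pos = evals > tol
    n_pos = int(pos.sum())
    if n_axes is None:
        n_axes = n_pos
    elif n_axes > n_pos:
        warnings.warn(
            f"requested {n_axes} axes but only {n_pos} positive eigenvalues; truncating")
        n_axes = n_pos
    coords = evecs[:, :n_axes] * np.sqrt(evals[:n_axes]) if n_axes else np.zeros((n, 0))
    prop = evals[pos] / evals[pos].sum() if n_pos else np.zeros(0)
    cols = [f"PCo{i + 1}" for i in range(n_axes)]
    return OrdinationResult(
        coordinates=pd.DataFrame(coords, index=list(d.ids), columns=cols),
        eigenvalues=evals,
        proportion_explained=prop[:n_axes],
    )


@dataclass
class PermanovaResult:
    pseudo_f: float
    p_value: float
    n_permutations: int


def permanova(d: DistanceMatrix, groups, n_perm: int = 999,
              seed: int | None = None) -> PermanovaResult:
    """One-way PERMANOVA on a distance matrix.

    Pseudo-F from the among/within partition of squared distances;
    p = (1 + #{F_perm >= F_obs}) / (1 + n_perm), permuting group labels.
    """
    dm = np.asarray(d.data, dtype=float) ** 2
    labels = np.asarray(pd.factorize(np.asarray(groups))[0])
    n = dm.shape[0]
    if labels.shape[0] != n:
        raise ValueError("group labels do not match distance matrix size")
    uniq, sizes = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("PERMANOVA needs at least two groups")
    if (sizes < 2).any():
        raise ValueError("every group needs at least two members")
    a = len(uniq)
    ss_total = dm[np.triu_indices(n, k=1)].sum() / n

    def f_stat(lab: np.ndarray) -> float:
        ss_within = 0.0
        for g in uniq:
            idx = np.flatnonzero(lab == g)
            sub = dm[np.ix_(idx, idx)]
            ss_within += sub.sum() / (2.0 * idx.size)
        ss_among = ss_total - ss_within
        if ss_within == 0:  # identical replicates within every group
            return np.inf
        return (ss_among / (a - 1)) / (ss_within / (n - a))

    f_obs = f_stat(labels)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        if f_stat(rng.permutation(labels)) >= f_obs:
            hits += 1
    p = (1 + hits) / (1 + n_perm)
    return PermanovaResult(float(f_obs), float(p), n_perm)


def levins_niche_breadth(table: AbundanceTable) -> tuple[pd.Series, pd.Series]:
    """Levins' niche breadth per taxon and abundance-weighted community mean.

    ``B_j = 1 / sum_i P_ij^2`` where ``P_ij`` is the share of taxon j's
    total abundance found in sample i; B ranges from 1 (specialist,
    single sample) to n_samples (perfectly even generalist). ``Bcom`` for
    each sample is the mean of B over the taxa present, weighted by their
    within-sample relative abundance. Taxa absent everywhere are skipped
    with a warning.
    """
    counts = table.counts
    totals = counts.sum(axis=0)
    absent = totals.index[totals == 0]
    if len(absent):
        warnings.warn(f"{len(absent)} taxa absent from all samples; skipped")
        counts = counts.loc[:, totals > 0]
        totals = totals[totals > 0]
    p = counts.div(totals, axis=1)
    b = 1.0 / (p ** 2).sum(axis=0)
    b.name = "levins_B"
    rel = counts.div(counts.sum(axis=1), axis=0)
    bcom = (rel * b).sum(axis=1)
    bcom.name = "Bcom"
    return b, bcom
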