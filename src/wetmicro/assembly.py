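"""Phylogenetic null-model analysis of community assembly.

Quantifies the balance of deterministic and stochastic assembly between
pairs of communities with two null-model z-scores and partitions sample
pairs into five ecological processes:

* beta mean nearest taxon distance (bMNTD), abundance-weighted, between
  two communities on a shared phylogeny;
* beta nearest taxon index (bNTI): the z-score of observed bMNTD against
  a null distribution obtained by shuffling taxa across the tree tips
  (richness and abundances untouched);
* abundance-based Raup-Crick on Bray-Curtis (RC): the null-standardised
  compositional dissimilarity in [-1, 1], with null communities that
  preserve each sample's richness and read total, drawing taxa in
  proportion to occurrence frequency and filling reads in proportion to
  metacommunity relative abundance;
* the (bNTI, RC) decision rules: bNTI > +2 heterogeneous selection,
  bNTI < -2 homogeneous selection, else RC > +0.95 dispersal limitation,
  RC < -0.95 homogenizing dispersal, otherwise undominated.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
from scipy.spatial.distance import braycurtis

from .tables import AbundanceTable

__all__ = [
    "patristic_distances",
    "bmntd_weighted",
    "bmntd_matrix",
    "beta_nti",
    "raup_crick_bray",
    "AssemblyPartition",
    "partition_processes",
    "assembly_partition",
    "BNTI_THRESHOLD",
    "RC_THRESHOLD",
]

BNTI_THRESHOLD = 2.0
RC_THRESHOLD = 0.95

PROCESSES = [
    "heterogeneous_selection",
    "homogeneous_selection",
    "dispersal_limitation",
    "homogenizing_dispersal",
    "undominated",
]


def patristic_distances(tree: dendropy.Tree, taxa=None) -> pd.DataFrame:
    """Tip-to-tip patristic distance matrix as a labelled DataFrame.

    Computed once per tree and reused for every sample pair and null
    draw. ``taxa`` restricts/reorders the output; an error lists any
    taxon without a matching tip.
    """
    pdm = tree.phylogenetic_distance_matrix()
    labels = [t.label for t in tree.taxon_namespace]
    if taxa is None:
        taxa = labels
    missing = sorted(set(taxa) - set(labels))
    if missing:
        raise ValueError(f"taxa missing from tree: {missing}")
    tax_by_label = {t.label: t for t in tree.taxon_namespace}
    n = len(taxa)
    d = np.zeros((n, n))
    for i, a in enumerate(taxa):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = pdm.patristic_distance(tax_by_label[a],
                                                       tax_by_label[taxa[j]])
    return pd.DataFrame(d, index=list(taxa), columns=list(taxa))


def bmntd_weighted(freq_a, freq_b, dist) -> float:
    """Abundance-weighted beta mean nearest taxon distance.

    ``0.5 * [sum_i fA_i min_{j in B} d(i,j) + sum_j fB_j min_{i in A} d(i,j)]``
    over taxa present in each community; frequencies are normalised to
    relative abundances internally. Symmetric, non-negative, and zero for
    identical communities (a shared taxon is its own nearest neighbour).
    """
    fa = np.asarray(freq_a, dtype=float)
    fb = np.asarray(freq_b, dtype=float)
    d = np.asarray(dist, dtype=float)
    ia = np.flatnonzero(fa > 0)
    ib = np.flatnonzero(fb > 0)
    if ia.size == 0 or ib.size == 0:
        raise ValueError("both communities must be non-empty")
    wa = fa[ia] / fa[ia].sum()
    wb = fb[ib] / fb[ib].sum()
    sub = d[np.ix_(ia, ib)]
    return 0.5 * float(wa @ sub.min(axis=1) + wb @ sub.min(axis=0))


def _pair_list(sample_ids, groups=None):
    """Within-group sample pairs (or all pairs when groups is None)."""
    if groups is None:
        return list(itertools.combinations(sample_ids, 2))
    g = pd.Series(groups)
    pairs = []
    for _, members in g.loc[list(sample_ids)].groupby(g, sort=True):
        pairs.extend(itertools.combinations(members.index, 2))
    return pairs


def bmntd_matrix(table: AbundanceTable, tree: dendropy.Tree | None = None,
                 dist: pd.DataFrame | None = None) -> pd.DataFrame:
    """Pairwise observed bMNTD among all samples."""
    if dist is None:
        if tree is None:
            raise ValueError("provide a tree or a precomputed distance matrix")
        dist = patristic_distances(tree, table.taxon_ids)
    d = dist.loc[table.taxon_ids, table.taxon_ids].to_numpy()
    x = table.relative_abundance().to_numpy()
    n = table.n_samples
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = bmntd_weighted(x[i], x[j], d)
    return pd.DataFrame(out, index=table.sample_ids, columns=table.sample_ids)


def beta_nti(table: AbundanceTable, tree: dendropy.Tree | None = None,
             dist: pd.DataFrame | None = None, n_null: int = 999,
             seed: int | None = None, groups=None) -> pd.DataFrame:
    """Pairwise beta nearest taxon index.

    For each sample pair, ``bNTI = (bMNTD_obs - mean(bMNTD_null)) /
    sd(bMNTD_null)`` where each null draw shuffles the taxon labels
    across all tree tips (equivalently, jointly permutes the rows and
    columns of the patristic matrix) while leaving community abundances
    untouched. ``|bNTI| > 2`` marks deterministic assembly.

    Pairs with a degenerate null (sd = 0, e.g. on a star phylogeny) get
    bNTI = 0 and ``degenerate_null = True``.

    Returns a long DataFrame: sample_i, sample_j, bmntd_obs, bnti,
    degenerate_null. ``groups`` (mapping sample id -> group) restricts
    pairs to within-group comparisons.
    """
    if n_null < 99:
        raise ValueError("use at least 99 null draws")
    if dist is None:
        if tree is None:
            raise ValueError("provide a tree or a precomputed distance matrix")
        dist = patristic_distances(tree, table.taxon_ids)
    d = dist.loc[table.taxon_ids, table.taxon_ids].to_numpy()
    x = table.relative_abundance().to_numpy()
    sample_ids = table.sample_ids
    idx_of = {s: i for i, s in enumerate(sample_ids)}
    pairs = _pair_list(sample_ids, groups)
    if not pairs:
        raise ValueError("no sample pairs to compare")

    obs = np.array([bmntd_weighted(x[idx_of[a]], x[idx_of[b]], d) for a, b in pairs])
    rng = np.random.default_rng(seed)
    nt = d.shape[0]
    nulls = np.empty((n_null, len(pairs)))
    for k in range(n_null):
        perm = rng.permutation(nt)
        dp = d[np.ix_(perm, perm)]
        for q, (a, b) in enumerate(pairs):
            nulls[k, q] = bmntd_weighted(x[idx_of[a]], x[idx_of[b]], dp)
    mu = nulls.mean(axis=0)
    sd = nulls.std(axis=0, ddof=1)
    degenerate = sd == 0
    bnti = np.zeros(len(pairs))
    ok = ~degenerate
    bnti[ok] = (obs[ok] - mu[ok]) / sd[ok]
    return pd.DataFrame({
        "sample_i": [a for a, _ in pairs],
        "sample_j": [b for _, b in pairs],
        "bmntd_obs": obs,
        "bnti": bnti,
        "degenerate_null": degenerate,
    })


# ---------------------------------------------------------------------------
# Raup-Crick (Bray-Curtis flavour)


def _weighted_sample_no_replace(rng, weights: np.ndarray, k: int) -> np.ndarray:
    """k indices without replacement, P(pick) proportional to weight.

    Efraimidis-Spirakis exponential-keys trick: the k smallest values of
    Exp(1)/w are a weighted sample without replacement.
    """
    keys = rng.exponential(size=weights.size)
    with np.errstate(divide="ignore"):
        keys = np.where(weights > 0, keys / weights, np.inf)
    return np.argpartition(keys, k - 1)[:k]


def _null_community(rng, occ_w, p_meta, richness, n_reads):
    chosen = _weighted_sample_no_replace(rng, occ_w, richness)
    vec = np.zeros(occ_w.size)
    vec[chosen] = 1.0
    extra = int(n_reads) - richness
    if extra > 0:
        pr = p_meta[chosen]
        pr = pr / pr.sum() if pr.sum() > 0 else np.full(len(chosen), 1 / len(chosen))
        vec[chosen] += rng.multinomial(extra, pr)
    return vec


def raup_crick_bray(table: AbundanceTable, n_null: int = 999,
                    seed: int | None = None, groups=None) -> pd.DataFrame:
    """Abundance-based Raup-Crick dissimilarity on Bray-Curtis.

    For each sample pair, ``n_null`` pairs of null communities are drawn:
    each null preserves the sample's observed richness and read total,
    selects that many taxa with probability proportional to metacommunity
    occurrence frequency, seeds each with one read, and distributes the
    remaining reads multinomially in proportion to metacommunity relative
    abundance. With BC_obs the observed Bray-Curtis,

        RC = 2 * [(#{BC_null < BC_obs} + 0.5 #{BC_null = BC_obs}) / n_null] - 1

    RC near +1: observed pair more dissimilar than the stochastic
    expectation; near -1: more similar; ties give 0.
    """
    if n_null < 99:
        raise ValueError("use at least 99 null draws")
    counts = table.counts.to_numpy(dtype=float)
    if (counts.sum(axis=1) <= 0).any():
        raise ValueError("sample with zero total abundance")
    counts_int = np.round(counts).astype(np.int64)
    occ_w = (counts > 0).mean(axis=0)
    p_meta = counts.sum(axis=0) / counts.sum()
    richness = (counts > 0).sum(axis=1)
    depth = counts_int.sum(axis=1)
    sample_ids = table.sample_ids
    idx_of = {s: i for i, s in enumerate(sample_ids)}
    pairs = _pair_list(sample_ids, groups)
    if not pairs:
        raise ValueError("no sample pairs to compare")

    rng = np.random.default_rng(seed)
    rows = []
    for a, b in pairs:
        ia, ib = idx_of[a], idx_of[b]
        bc_obs = braycurtis(counts[ia], counts[ib])
        null_bc = np.empty(n_null)
        for k in range(n_null):
            na = _null_community(rng, occ_w, p_meta, int(richness[ia]), depth[ia])
            nb = _null_community(rng, occ_w, p_meta, int(richness[ib]), depth[ib])
            null_bc[k] = braycurtis(na, nb)
        less = int((null_bc < bc_obs - 1e-12).sum())
        ties = int((np.abs(null_bc - bc_obs) <= 1e-12).sum())
        rc = 2.0 * ((less + 0.5 * ties) / n_null) - 1.0
        rows.append({"sample_i": a, "sample_j": b, "bc_obs": bc_obs, "rc": rc})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# process partition


@dataclass
class AssemblyPartition:
    """Five-process partition of sample pairs with the underlying table."""

    pairs: pd.DataFrame  # sample_i, sample_j, bnti, rc, process
    fractions: dict[str, float]

    def __post_init__(self) -> None:
        total = sum(self.fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"process fractions sum to {total}, not 1")


def _classify(bnti: float, rc: float | None) -> str:
    if bnti > BNTI_THRESHOLD:
        return "heterogeneous_selection"
    if bnti < -BNTI_THRESHOLD:
        return "homogeneous_selection"
    if rc is None or np.isnan(rc):
        raise ValueError("RC value required for a |bNTI| <= 2 pair")
    if rc > RC_THRESHOLD:
        return "dispersal_limitation"
    if rc < -RC_THRESHOLD:
        return "homogenizing_dispersal"
    return "undominated"


def partition_processes(bnti: pd.DataFrame, rc: pd.DataFrame | None = None) -> AssemblyPartition:
    """Assign each sample pair to one of five assembly processes.

    ``bnti`` is the long frame from :func:`beta_nti`; ``rc`` the frame
    from :func:`raup_crick_bray` (only required for pairs with
    |bNTI| <= 2). Fractions over all pairs sum to 1.
    """
    if bnti.empty:
        raise ValueError("empty pair set")
    merged = bnti.copy()
    if rc is not None:
        merged = merged.merge(rc[["sample_i", "sample_j", "rc"]],
                              on=["sample_i", "sample_j"], how="left")
    else:
        merged["rc"] = np.nan
    merged["process"] = [
        _classify(row.bnti, row.rc) for row in merged.itertuples()
    ]
    frac = merged["process"].value_counts(normalize=True)
    fractions = {p: float(frac.get(p, 0.0)) for p in PROCESSES}
    return AssemblyPartition(pairs=merged, fractions=fractions)


def assembly_partition(table: AbundanceTable, tree: dendropy.Tree,
                       n_null: int = 999, seed: int | None = None,
                       groups=None) -> AssemblyPartition:
    """bNTI + RC + process partition in one call (within-group pairs).

    ``groups=None`` falls back to treatment x flooding groups from the
    table metadata when present, else all pairs.
    """
    if groups is None and table.metadata is not None:
        cols = [c for c in ("treatment", "flooding") if c in table.metadata.columns]
        if cols:
            groups = table.metadata[cols].astype(str).agg("|".join, axis=1)
    ss = np.random.SeedSequence(seed) if seed is not None else np.random.SeedSequence()
    s1, s2 = ss.spawn(2)
    bnti = beta_nti(table, tree=tree, n_null=n_null,
                    seed=int(s1.generate_state(1)[0] % (2**31)), groups=groups)
    rc = raup_crick_bray(table, n_null=n_null,
                         seed=int(s2.generate_state(1)[0] % (2**31)), groups=groups)
    return partition_processes(bnti, rc)
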