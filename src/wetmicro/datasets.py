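"""Bundled example data.

Two kinds of files ship with the package:

* published field summaries from a one-year *Phragmites australis*
  belowground-litter decomposition study in a lacustrine wetland
  (group-mean litter statistics per organ x flooding regime, and the
  topology table of the soil bacterial/fungal co-occurrence networks) —
  used as worked-example inputs and for internal-consistency checks;
* small synthetic community fixtures (12 samples x 300 taxa per assembly
  regime, plus the phylogeny and a litter-bag table) generated by the
  :mod:`wetmicro.synth` module with the seeds recorded in
  :data:`FIXTURE_SEEDS`; :func:`regenerate` rebuilds them bit-for-bit.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import dendropy
import pandas as pd

from .tables import AbundanceTable

__all__ = [
    "FIXTURE_SEEDS",
    "load_field_litter_summary",
    "load_field_network_table",
    "load_neutral_table",
    "load_selection_table",
    "load_tree",
    "load_litter_bags",
    "regenerate",
]

#: seeds and sizes used to generate the synthetic fixtures
FIXTURE_SEEDS = {
    "tree": 7,
    "neutral": 101,
    "selection": 202,
    "litter": 11,
    "n_samples": 12,
    "n_taxa": 300,
}


def _path(name: str) -> Path:
    return Path(resources.files("wetmicro") / "data" / name)


def load_field_litter_summary() -> pd.DataFrame:
    """Group-mean litter statistics (mass loss R, rate SL, C, N, C/N).

    One row per litter treatment (L rhizome, LR root, M mixed) and
    flooding regime (LO non-flooded, ME intermittent, HI permanent).
    """
    return pd.read_csv(_path("field_litter_summary.csv"), comment="#")


def load_field_network_table() -> pd.DataFrame:
    """Topology indices of the field study's co-occurrence networks."""
    return pd.read_csv(_path("field_network_topology.csv"), comment="#")


def load_neutral_table() -> AbundanceTable:
    """Synthetic neutral-assembly fixture (12 samples x 300 taxa)."""
    df = pd.read_csv(_path("neutral_table.tsv"), sep="\t", index_col=0)
    return AbundanceTable(df)


def load_selection_table() -> AbundanceTable:
    """Synthetic environmental-filtering fixture (12 samples x 300 taxa)."""
    df = pd.read_csv(_path("selection_table.tsv"), sep="\t", index_col=0)
    return AbundanceTable(df)


def load_tree() -> dendropy.Tree:
    """The 300-tip birth-death phylogeny shared by the community fixtures."""
    return dendropy.Tree.get(path=str(_path("tree.nwk")), schema="newick")


def load_litter_bags() -> pd.DataFrame:
    """Synthetic litter-bag records (tidy, one row per bag per time point)."""
    return pd.read_csv(_path("litter_bags.csv"))


def regenerate(out_dir=None) -> None:
    """Rebuild the synthetic fixtures from their recorded seeds."""
    from .synth import clustered_tree, neutral_config, selection_config, \
        simulate_litter, simulate_neutral, simulate_selection

    out = Path(out_dir) if out_dir is not None else _path("").parent / "data"
    s = FIXTURE_SEEDS
    tree = clustered_tree(n_taxa=s["n_taxa"], seed=s["tree"])
    tree.write(path=str(out / "tree.nwk"), schema="newick")
    neutral = simulate_neutral(neutral_config(
        s["neutral"], n_samples=s["n_samples"], n_taxa=s["n_taxa"]))
    neutral.counts.to_csv(out / "neutral_table.tsv", sep="\t", index_label="sample_id")
    selection = simulate_selection(selection_config(
        s["selection"], n_samples=s["n_samples"], n_taxa=s["n_taxa"]), tree)
    selection.counts.to_csv(out / "selection_table.tsv", sep="\t",
                            index_label="sample_id")
    sim = simulate_litter(seed=s["litter"])
    rows = []
    for r in sim.records:
        for (t, m), c, n in zip(r.masses, r.c_conc, r.n_conc):
            rows.append({"litter_id": r.litter_id, "organ": r.organ,
                         "flooding": r.flooding, "time_days": t,
                         "dry_mass_g": m, "C_g_per_kg": c, "N_g_per_kg": n})
    pd.DataFrame(rows).to_csv(out / "litter_bags.csv", index=False)
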