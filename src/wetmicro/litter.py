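"""Litter-bag decomposition statistics.

Implements the standard litter-bag bookkeeping for single-organ and mixed
litter: fractional mass loss, the two-time-point decomposition rate, the
mass-weighted expected nutrient retention of a two-component mixture, and
the relative non-additive mixing effect (YME) with its
antagonism/synergism classification.

Quantities are held as fractions internally; multiply by 100 (or pass
``percent=True``) only for presentation. The one exception is
:func:`decomposition_rate`, which reproduces the conventional field
formula ``(m_t1 - m_t2) / (t2 - t1) * 100`` literally ("formula units":
g/day scaled by 100), because that is how rates are tabulated in
litter-bag studies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, NamedTuple, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LitterRecord",
    "MixtureSpec",
    "MixingEffect",
    "mass_loss",
    "decomposition_rate",
    "nutrient_retention",
    "expected_mixture_retention",
    "mixing_effect",
    "mixture_effect",
    "ratio_table",
    "ratio_range",
    "read_litter_csv",
    "summarize_litter",
]


class MassGainWarning(UserWarning):
    """Remaining mass exceeds initial mass (mineral accretion in the bag)."""


@dataclass
class LitterRecord:
    """One litter bag: dry-mass and nutrient-concentration time series.

    ``masses`` is an ordered list of ``(time_days, dry_mass_g)`` pairs with
    strictly increasing times; ``c_conc`` / ``n_conc`` are g/kg
    concentrations aligned with the time points.
    """

    litter_id: str
    organ: Literal["root", "rhizome", "mixed"]
    flooding: Literal["LO", "ME", "HI"]
    m_t0: float
    masses: list[tuple[float, float]]
    c_conc: list[float] = field(default_factory=list)
    n_conc: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.m_t0 <= 0:
            raise ValueError("initial dry mass must be positive")
        times = [t for t, _ in self.masses]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("time points must be strictly increasing")
        if any(m < 0 for _, m in self.masses):
            raise ValueError("dry masses must be non-negative")
        for conc in (self.c_conc, self.n_conc):
            if conc and any(c < 0 for c in conc):
                raise ValueError("concentrations must be non-negative")

    @property
    def final_time(self) -> float:
        return self.masses[-1][0]

    @property
    def final_mass(self) -> float:
        return self.masses[-1][1]


@dataclass
class MixtureSpec:
    """Two-component litter mixture for non-additive-effect analysis.

    Component masses ``m_ta``/``m_tb`` are the initial masses of organs
    a and b in the mixed bag, ``x_ta``/``x_tb`` their initial nutrient
    concentrations (g/kg), ``y_ta``/``y_tb`` the nutrient retention
    fractions each organ shows when decomposed alone, and
    ``observed_retention`` the measured retention of the physically mixed
    bag. Retentions may exceed 1 (nutrient import into the bag).
    """

    m_ta: float
    m_tb: float
    x_ta: float
    x_tb: float
    y_ta: float
    y_tb: float
    observed_retention: float | None = None

    def __post_init__(self) -> None:
        if self.m_ta < 0 or self.m_tb < 0 or self.m_ta + self.m_tb <= 0:
            raise ValueError("component masses must be non-negative, not both zero")
        for y in (self.y_ta, self.y_tb):
            if y < 0:
                raise ValueError("retention fractions must be >= 0")

    @property
    def mass_fractions(self) -> tuple[float, float]:
        tot = self.m_ta + self.m_tb
        return self.m_ta / tot, self.m_tb / tot


class MixingEffect(NamedTuple):
    yme: float
    classification: Literal["antagonism", "synergism", "additive"]


def mass_loss(m_t0: float, m_t: float, *, percent: bool = False,
              allow_gain: bool = False) -> float:
    """Fractional mass loss ``(m_t0 - m_t) / m_t0``.

    Negative loss (mass gain) is allowed only with ``allow_gain=True``;
    otherwise a :class:`MassGainWarning` is raised and the negative value
    kept, because litter bags can gain mineral mass.
    """
    if m_t0 <= 0:
        raise ValueError("initial mass must be positive")
    if m_t < 0:
        raise ValueError("remaining mass must be non-negative")
    loss = (m_t0 - m_t) / m_t0
    if loss < 0 and not allow_gain:
        warnings.warn(
            f"remaining mass {m_t} exceeds initial mass {m_t0}; "
            "keeping negative loss", MassGainWarning, stacklevel=2)
    return loss * 100.0 if percent else loss


def decomposition_rate(m_t1: float, m_t2: float, t1: float, t2: float) -> float:
    """Two-time-point decomposition rate ``(m_t1 - m_t2)/(t2 - t1) * 100``.

    Reproduces the field formula literally; the result is in "formula
    units" (g/day x 100). Ratios of rates are unit-free and are the
    quantities used for between-group comparison.
    """
    if t2 <= t1:
        raise ValueError("t2 must exceed t1")
    if m_t1 < 0 or m_t2 < 0:
        raise ValueError("masses must be non-negative")
    return (m_t1 - m_t2) / (t2 - t1) * 100.0


def nutrient_retention(m_t0: float, conc_t0: float, m_t: float, conc_t: float) -> float:
    """Nutrient retention fraction ``(m_t * conc_t) / (m_t0 * conc_t0)``.

    The fraction of a bag's initial nutrient pool (mass x concentration)
    still present at time t; may exceed 1 when the nutrient is imported.
    """
    pool0 = m_t0 * conc_t0
    if pool0 <= 0:
        raise ValueError("initial nutrient pool must be positive")
    return (m_t * conc_t) / pool0


def expected_mixture_retention(mix: MixtureSpec) -> float:
    """Expected mixture nutrient retention under additivity.

    The nutrient-pool-weighted mean of the two single-organ retentions:
    ``(M_ta X_ta Y_ta + M_tb X_tb Y_tb) / (M_ta X_ta + M_tb X_tb)``.
    Always lies within the closed interval of the component retentions.
    """
    pool_a = mix.m_ta * mix.x_ta
    pool_b = mix.m_tb * mix.x_tb
    total = pool_a + pool_b
    if total <= 0:
        raise ValueError("total initial nutrient pool is zero; expectation undefined")
    return (pool_a * mix.y_ta + pool_b * mix.y_tb) / total


def mixing_effect(observed: float, expected: float) -> MixingEffect:
    """Relative non-additive effect ``(observed - expected) / expected``.

    Positive values indicate antagonism (more nutrient retained in the
    litter than the additive expectation, less released to soil);
    negative values indicate synergism; zero is additive.
    """
    if expected <= 0:
        raise ValueError("expected retention must be positive")
    yme = (observed - expected) / expected
    if yme > 0:
        cls = "antagonism"
    elif yme < 0:
        cls = "synergism"
    else:
        cls = "additive"
    return MixingEffect(yme, cls)


def mixture_effect(mix: MixtureSpec) -> MixingEffect:
    """Convenience: mixing effect straight from a :class:`MixtureSpec`."""
    if mix.observed_retention is None:
        raise ValueError("MixtureSpec has no observed retention")
    return mixing_effect(mix.observed_retention, expected_mixture_retention(mix))


# ---------------------------------------------------------------------------
# group-level ratio tables


def ratio_table(groups: pd.DataFrame, metric: str, contrast: str,
                other: str | None = None) -> pd.DataFrame:
    """Pairwise ratios of per-group metric values along one factor.

    ``groups`` is a tidy frame with a grouping column per factor (e.g.
    ``organ`` and ``flooding``) and a ``metric`` column; replicate rows
    are averaged. For each ordered pair of levels of ``contrast`` the
    ratio of their metric values is computed at every level of the
    ``other`` factor (guessed from common column names if omitted).

    Returns a long frame with columns ``numerator``, ``denominator``,
    the other factor's name, and ``ratio``.
    """
    if other is None:
        candidates = [c for c in ("organ", "treatment", "flooding")
                      if c in groups.columns and c != contrast]
        if not candidates:
            raise ValueError("cannot infer the second grouping factor")
        other = candidates[0]
    for col in (contrast, other, metric):
        if col not in groups.columns:
            raise ValueError(f"missing column {col!r}")
    means = groups.groupby([contrast, other], sort=True)[metric].mean()
    levels = means.index.get_level_values(0).unique()
    rows = []
    for num in levels:
        for den in levels:
            if num == den:
                continue
            for o in means.index.get_level_values(1).unique():
                if (num, o) not in means.index or (den, o) not in means.index:
                    continue
                d = means[(den, o)]
                if d == 0:
                    raise ZeroDivisionError(
                        f"zero denominator for {contrast}={den}, {other}={o}")
                rows.append({"numerator": num, "denominator": den,
                             other: o, "ratio": means[(num, o)] / d})
    if not rows:
        raise ValueError("contrast levels not covered by the records")
    return pd.DataFrame(rows)


def ratio_range(groups: pd.DataFrame, metric: str, contrast: str,
                numerator: str, denominator: str,
                other: str | None = None) -> tuple[float, float]:
    """(min, max) of the numerator/denominator ratio across the other factor."""
    tab = ratio_table(groups, metric, contrast, other=other)
    sel = tab[(tab["numerator"] == numerator) & (tab["denominator"] == denominator)]
    if sel.empty:
        raise ValueError(f"no ratios for {numerator}/{denominator}")
    return float(sel["ratio"].min()), float(sel["ratio"].max())


# ---------------------------------------------------------------------------
# I/O


def read_litter_csv(path) -> list[LitterRecord]:
    """Read litter-bag records from a tidy CSV.

    Expected columns: ``litter_id, organ, flooding, time_days,
    dry_mass_g, C_g_per_kg, N_g_per_kg`` with one row per bag per time
    point (time 0 row carries the initial mass).
    """
    df = pd.read_csv(path)
    records = []
    for lid, sub in df.groupby("litter_id", sort=True):
        sub = sub.sort_values("time_days")
        t0 = sub.iloc[0]
        if t0["time_days"] != 0:
            raise ValueError(f"bag {lid}: first row must be time 0")
        records.append(LitterRecord(
            litter_id=str(lid),
            organ=t0["organ"],
            flooding=t0["flooding"],
            m_t0=float(t0["dry_mass_g"]),
            masses=list(zip(sub["time_days"].astype(float), sub["dry_mass_g"].astype(float))),
            c_conc=list(sub["C_g_per_kg"].astype(float)),
            n_conc=list(sub["N_g_per_kg"].astype(float)),
        ))
    return records


def summarize_litter(records: Sequence[LitterRecord]) -> pd.DataFrame:
    """Tidy per-bag summary: mass loss R, rate SL, final C, N, C/N, retentions."""
    rows = []
    for r in records:
        (t1, m1), (t2, m2) = r.masses[0], r.masses[-1]
        row = {
            "litter_id": r.litter_id, "organ": r.organ, "flooding": r.flooding,
            "mass_loss": mass_loss(r.m_t0, r.final_mass, allow_gain=True),
            "rate": decomposition_rate(m1, m2, t1, t2),
        }
        if r.c_conc and r.n_conc:
            c, n = r.c_conc[-1], r.n_conc[-1]
            row.update({
                "C_g_per_kg": c, "N_g_per_kg": n,
                "CN_ratio": c / n if n > 0 else np.nan,
                "C_retention": nutrient_retention(r.m_t0, r.c_conc[0], r.final_mass, c),
                "N_retention": nutrient_retention(r.m_t0, r.n_conc[0], r.final_mass, n),
            })
        rows.append(row)
    return pd.DataFrame(rows)
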