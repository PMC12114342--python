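"""Sloan neutral community model (NCM) fitting.

The NCM predicts, for a neutrally assembled community sampled at depth N
with migration rate m, the probability that a taxon of metacommunity
relative abundance p is detected in a local sample:

    F(p) = 1 - BetaCDF(d; N m p, N m (1 - p))

where d is the detection limit (one read, d = 1/N, by default). Fitting
m to the observed occurrence-frequency vs mean-relative-abundance cloud,
and comparing taxa against the 95% prediction envelope, quantifies how
far a community departs from neutral dispersal-drift assembly. Nm (= N x
m) is the dispersal index reported alongside R2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.proportion import proportion_confint

from .tables import AbundanceTable

__all__ = ["NCMFit", "occurrence_abundance", "predict_frequency", "fit_sloan"]


@dataclass
class NCMFit:
    """Fitted Sloan model: migration rate, dispersal index, fit quality.

    ``taxa`` has one row per fitted taxon: mean relative abundance ``p``,
    observed frequency ``f``, predicted frequency, Wilson 95% envelope
    bounds, and class (above / within / below the envelope).
    """

    m: float
    N: float
    Nm: float
    r_squared: float
    detection_limit: float
    taxa: pd.DataFrame
    m_ci: tuple[float, float] | None = None
    n_boot: int = 0

    @property
    def class_counts(self) -> pd.Series:
        return self.taxa["class"].value_counts().reindex(
            ["above", "within", "below"], fill_value=0)


def occurrence_abundance(table: AbundanceTable):
    """Per-taxon (mean relative abundance, occurrence frequency), N and d.

    N is the mean sample read depth (rounded); the detection limit d is
    1/N. Taxa absent from every sample are excluded.
    """
    if table.n_samples < 2:
        raise ValueError("need at least 2 samples")
    counts = table.counts.loc[:, table.counts.sum(axis=0) > 0]
    rel = counts.div(counts.sum(axis=1), axis=0)
    p = rel.mean(axis=0)
    f = (counts > 0).mean(axis=0)
    n_reads = float(np.round(table.counts.sum(axis=1).mean()))
    d = 1.0 / n_reads
    df = pd.DataFrame({"p": p, "f": f})
    return df, n_reads, d


def predict_frequency(p, N: float, m: float, d: float):
    """Expected detection frequency ``1 - BetaCDF(d; Nmp, Nm(1-p))``.

    Monotone increasing in p and in m. A non-positive detection limit is
    degenerate (everything detectable) and returns 1 with a warning.
    """
    p = np.asarray(p, dtype=float)
    if N <= 0 or m <= 0:
        raise ValueError("N and m must be positive")
    if d <= 0:
        warnings.warn("non-positive detection limit: predicted frequency is 1")
        return np.where(p > 0, 1.0, 0.0)
    nm = N * m
    return stats.beta.sf(d, nm * p, nm * (1.0 - p))


def _r_squared(f_obs: np.ndarray, f_pred: np.ndarray) -> float:
    ss_res = float(((f_obs - f_pred) ** 2).sum())
    ss_tot = float(((f_obs - f_obs.mean()) ** 2).sum())
    return 1.0 - ss_res / ss_tot


def _fit_m(p: np.ndarray, f: np.ndarray, N: float, d: float) -> float:
    def sse(m):
        return float(((f - predict_frequency(p, N, m, d)) ** 2).sum())

    res = optimize.minimize_scalar(sse, bounds=(1e-6, 1.0), method="bounded",
                                   options={"xatol": 1e-8})
    if not res.success:
        raise RuntimeError(f"migration-rate optimisation failed: {res.message}")
    return float(res.x)


def fit_sloan(table: AbundanceTable, n_boot: int = 999, seed: int | None = None,
              N: float | None = None, d: float | None = None,
              detection: str = "reads") -> NCMFit:
    """Fit the Sloan NCM to an abundance table.

    m minimises the sum of squared deviations between observed and
    predicted occurrence frequencies (bounded scalar optimisation on
    (1e-6, 1]). The 95% prediction envelope uses Wilson binomial bounds
    on the predicted frequency at n = number of samples; taxa are classed
    above / within / below. R2 is 1 - SSres/SStot and may legitimately be
    negative (worse than the mean-frequency predictor) — it is never
    clipped. A taxon-level bootstrap (``n_boot`` resamples) yields a
    percentile CI on m; set ``n_boot=0`` to skip.

    Detection limit: for count tables a taxon is "detected" when it
    draws at least one read, an event with probability 1 - (1-q)^N given
    true relative abundance q, whose median crossing sits at
    q = ln2 / N. The default ``detection="reads"`` therefore uses
    d = ln2 / N, which makes m recovery consistent under multinomial
    read sampling; ``detection="threshold"`` is the classical hard
    threshold d = 1/N. An explicit ``d`` overrides both.
    """
    df, n_mean, d_default = occurrence_abundance(table)
    if N is None:
        N = n_mean
    if d is None:
        if detection == "reads":
            d = np.log(2.0) / N
        elif detection == "threshold":
            d = 1.0 / N
        else:
            raise ValueError("detection must be 'reads' or 'threshold'")
    p = df["p"].to_numpy()
    f = df["f"].to_numpy()
    if np.all(f == 1.0) or np.all(f == 0.0):
        raise ValueError("degenerate table: all occurrence frequencies are 0 or 1")
    interior = int(((f > 0) & (f < 1)).sum())
    if interior < 10:
        warnings.warn(f"only {interior} taxa with 0 < f < 1; fit may be unstable")

    m_hat = _fit_m(p, f, N, d)
    pred = predict_frequency(p, N, m_hat, d)
    r2 = _r_squared(f, pred)

    n_samp = table.n_samples
    lo, hi = proportion_confint(pred * n_samp, n_samp, alpha=0.05, method="wilson")
    cls = np.where(f > hi, "above", np.where(f < lo, "below", "within"))
    taxa = df.assign(predicted=pred, ci_lower=lo, ci_upper=hi)
    taxa["class"] = cls

    m_ci = None
    if n_boot:
        rng = np.random.default_rng(seed)
        boots = np.empty(n_boot)
        for b in range(n_boot):
            idx = rng.integers(0, len(p), len(p))
            fb = f[idx]
            if np.all(fb == fb[0]):  # degenerate resample
                boots[b] = np.nan
                continue
            boots[b] = _fit_m(p[idx], fb, N, d)
        boots = boots[~np.isnan(boots)]
        m_ci = tuple(np.percentile(boots, [2.5, 97.5]))

    return NCMFit(m=m_hat, N=N, Nm=N * m_hat, r_squared=r2, detection_limit=d,
                  taxa=taxa, m_ci=m_ci, n_boot=n_boot)
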