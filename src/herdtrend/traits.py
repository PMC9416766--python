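"""Derived traits and model keys.

Conception status (CS) is the inverse of the number of inseminations to
conception, in percent: a cow conceiving at her third service scores
100/3.  Cows still open when observation ends get an imputed expected
service count (observed services plus the geometric expectation 1/p at the
herd-year per-service conception rate), so every inseminated cow has a
record and culling bias against low producers is minimized.

Herd-life is days from first calving to culling; cows still alive are
projected with a Kaplan-Meier restricted-mean of the remaining survival
time estimated from the culled cows in the same data.

Herd-year-season classes split each herd-year into two six-month freshening
seasons starting in April and October; January-March freshenings belong to
the *previous* year's October season so every class is a contiguous block.

Pre-adjustment removes least-squares class effects of calving/birth month
and days open estimated within the data set, recentering so the overall
trait mean is preserved.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

__all__ = ["conception_status", "herd_life", "hys_classes", "preadjust"]

log = logging.getLogger(__name__)


def hys_classes(herd, date):
    """Herd-year-season key(s) for freshening dates.

    April-September -> season 1 of that calendar year; October-December ->
    season 2 of that year; January-March -> season 2 of the previous year.
    Vectorized: pass array-likes to get a DataFrame, scalars to get a tuple.
    """
    scalar = np.isscalar(herd) and not hasattr(date, "__len__")
    dates = pd.to_datetime(pd.Series(np.atleast_1d(np.asarray(date, dtype="datetime64[D]"))))
    if dates.isna().any():
        raise ValueError("missing freshening date")
    month = dates.dt.month
    year = dates.dt.year
    season = np.where((month >= 4) & (month <= 9), 1, 2)
    year = np.where(month <= 3, year - 1, year)
    herds = np.broadcast_to(np.atleast_1d(np.asarray(herd, dtype=object)), season.shape)
    if scalar:
        return (herds[0], int(year[0]), int(season[0]))
    return pd.DataFrame({"herd": herds, "year": year, "season": season})


def conception_status(
    inseminations: pd.DataFrame,
    herd_of: pd.Series | None = None,
    herd_rates: pd.Series | None = None,
) -> pd.DataFrame:
    """Per cow-parity conception status in (0, 100].

    Parameters
    ----------
    inseminations : table with columns animal, parity, service_no, outcome
        (outcome in {"conceived", "failed", "censored"}).
    herd_of : optional mapping animal -> herd; with it, censored records are
        imputed at the herd's empirical per-service conception rate,
        otherwise at the global rate.
    herd_rates : optional precomputed per-herd rates overriding the
        empirical ones.

    Returns a frame (animal, parity, cs, censored).
    """
    df = inseminations
    last = df.sort_values("service_no").groupby(["animal", "parity"]).tail(1)
    n_services = df.groupby(["animal", "parity"])["service_no"].max()
    conceptions = (df["outcome"] == "conceived").sum()
    total_services = len(df)
    global_rate = conceptions / total_services if total_services else np.nan
    if global_rate == 0 or np.isnan(global_rate):
        raise ValueError("no conceptions at all; conception rates undefined")

    if herd_of is not None and herd_rates is None:
        herd_col = df["animal"].map(herd_of)
        grp = df.assign(_herd=herd_col).groupby("_herd")["outcome"]
        herd_rates = grp.apply(lambda s: (s == "conceived").mean())

    rows = []
    for (animal, parity), tail in last.set_index(["animal", "parity"]).iterrows():
        n = int(n_services.loc[(animal, parity)])
        if tail["outcome"] == "conceived":
            rows.append((animal, parity, 100.0 / n, False))
        else:
            rate = global_rate
            if herd_rates is not None and herd_of is not None:
                r = herd_rates.get(herd_of.get(animal))
                if r is not None and r > 0:
                    rate = r
                else:
                    log.info("herd rate unavailable for %s; using global rate", animal)
            rows.append((animal, parity, 100.0 / (n + 1.0 / rate), True))
    return pd.DataFrame(rows, columns=["animal", "parity", "cs", "censored"])


def herd_life(
    cows: pd.DataFrame,
    projection: "SurvivalProjection | None" = None,
) -> pd.DataFrame:
    """Herd-life in days with censoring handled by survival projection.

    ``cows`` has columns animal, first_calving, cull_date (NaT if alive).
    Culled cows get the exact day count; live cows get observed days (to the
    last cull date seen in the data) plus the Kaplan-Meier expected
    remaining days given survival so far.
    """
    cows = cows.copy()
    cows["first_calving"] = pd.to_datetime(cows["first_calving"])
    cows["cull_date"] = pd.to_datetime(cows["cull_date"])
    culled = cows["cull_date"].notna()
    days = (cows["cull_date"] - cows["first_calving"]).dt.days.astype(float)
    if (days[culled] < 0).any():
        raise ValueError("cull date before first calving")
    horizon = cows["cull_date"].max()
    observed = (horizon - cows["first_calving"]).dt.days.astype(float).clip(lower=0.0)
    if projection is None:
        projection = SurvivalProjection.fit(days[culled].to_numpy())
    out = days.copy()
    alive = ~culled
    out[alive] = observed[alive] + projection.expected_remaining(observed[alive].to_numpy())
    return pd.DataFrame(
        {"animal": cows["animal"], "herd_life": out, "censored": alive}
    )


class SurvivalProjection:
    """Kaplan-Meier restricted-mean projection of remaining herd-life."""

    def __init__(self, kmf):
        self._kmf = kmf

    @classmethod
    def fit(cls, durations: np.ndarray, event_observed: np.ndarray | None = None):
        from lifelines import KaplanMeierFitter

        kmf = KaplanMeierFitter()
        durations = np.asarray(durations, dtype=float)
        if durations.size == 0:
            raise ValueError("no complete herd-life records to estimate a projection from")
        kmf.fit(durations, event_observed=event_observed)
        return cls(kmf)

    def expected_remaining(self, t: np.ndarray) -> np.ndarray:
        """E[T - t | T > t] from the fitted survival curve (0 beyond support)."""
        sf = self._kmf.survival_function_
        times = sf.index.to_numpy(dtype=float)
        surv = sf.iloc[:, 0].to_numpy(dtype=float)
        t = np.atleast_1d(np.asarray(t, dtype=float))
        out = np.zeros_like(t)
        # integrate the step survival function from t to the last event time
        for i, ti in enumerate(t):
            grid = np.unique(np.concatenate([[ti], times[times > ti]]))
            if len(grid) < 2:
                continue
            s_at = np.interp(grid[:-1], times, surv, left=1.0)
            s_t = np.interp(ti, times, surv, left=1.0)
            if s_t <= 0:
                continue
            out[i] = np.sum(s_at * np.diff(grid)) / s_t
        return out


def preadjust(
    phenotypes: pd.DataFrame,
    covariates: list[str],
    value_col: str = "value",
    min_class: int = 5,
) -> pd.DataFrame:
    """Subtract least-squares covariate-class effects, preserving the mean.

    Each covariate column is treated as a class variable; classes with fewer
    than ``min_class`` records are pooled into the nearest class by sort
    order.  With no registered covariates the table passes through
    unchanged (logged).
    """
    out = phenotypes.copy()
    present = [c for c in covariates if c in out.columns]
    if not present:
        log.info("no registered covariates; phenotypes passed through unadjusted")
        return out
    y = out[value_col].to_numpy(dtype=float)
    overall = y.mean()
    dummies = []
    for cov in present:
        classes = out[cov].copy()
        counts = classes.value_counts()
        small = counts[counts < min_class].index
        if len(small):
            keys = sorted(counts.index)
            for s in small:
                pos = keys.index(s)
                neighbor = keys[pos - 1] if pos > 0 else (keys[pos + 1] if len(keys) > 1 else s)
                classes = classes.replace({s: neighbor})
                log.info("pooled covariate class %r of %r into %r", s, cov, neighbor)
        dummies.append(pd.get_dummies(classes, prefix=cov, dtype=float))
    X = pd.concat(dummies, axis=1).to_numpy()
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    out[value_col] = y - X @ beta + overall
    return out
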