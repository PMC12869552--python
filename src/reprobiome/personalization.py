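"""Temporal-autocorrelation analysis of microbiota personalization.

Within each reproductive state, all same-state sample pairs are
classified into three categories — (1) same female, same reproductive
event; (2) same female, different events; (3) different females sharing
a social group — and binned by "reproductive-month" lag: the absolute
difference of the two samples' day positions within the state, in
30-day blocks (so day 40 and day 60 of two pregnancies are one
reproductive month apart regardless of calendar dates).  Mean Aitchison
similarity per (state, category, lag) with t-based confidence intervals
traces how quickly an individual's community signature decays, and
Welch t-tests with Benjamini-Hochberg correction contrast the
categories at each lag.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .association import bh_adjust

__all__ = ["subset_for_personalization", "lag_bin", "enumerate_pairs",
           "similarity_curves", "compare_curves", "SubsetReport"]

MONTH_DAYS = 30
MAX_LAG = 6
STATES = ("CYCLING", "PREGNANT", "PPA")


@dataclass
class SubsetReport:
    n_females: int
    n_events: int
    n_samples: int


def subset_for_personalization(labels: pd.DataFrame,
                               min_samples: int = 10,
                               min_per_state: int = 2,
                               min_same_event: int = 2,
                               ) -> tuple[pd.DataFrame, SubsetReport]:
    """Retain females suitable for the autocorrelation analysis.

    A female is kept if she has at least ``min_samples`` retained
    samples, at least ``min_per_state`` in every reproductive state, and
    at least one event with ``min_same_event`` samples.
    """
    kept = labels[~labels["excluded"]]

    def ok(g: pd.DataFrame) -> bool:
        if len(g) < min_samples:
            return False
        per_state = g["state"].value_counts()
        if any(per_state.get(s, 0) < min_per_state for s in STATES):
            return False
        return (g["event_id"].value_counts() >= min_same_event).any()

    good = [fid for fid, g in kept.groupby("female_id") if ok(g)]
    sub = kept[kept["female_id"].isin(good)]
    if sub.empty:
        raise ValueError("no female meets the personalization criteria")
    rep = SubsetReport(n_females=len(good),
                       n_events=sub["event_id"].nunique(),
                       n_samples=len(sub))
    return sub, rep


def lag_bin(day_i: int, day_j: int, month_days: int = MONTH_DAYS,
            max_lag: int = MAX_LAG) -> int | None:
    """Reproductive-month lag bin: [0,30) -> 1, [30,60) -> 2, ...; None
    beyond ``max_lag`` months."""
    delta = abs(int(day_i) - int(day_j))
    b = delta // month_days + 1
    return int(b) if b <= max_lag else None


def enumerate_pairs(labels: pd.DataFrame, similarity: pd.DataFrame,
                    month_days: int = MONTH_DAYS, max_lag: int = MAX_LAG,
                    ) -> pd.DataFrame:
    """Enumerate and classify all same-state sample pairs.

    ``labels`` must carry sample_id, female_id, state, event_id,
    day_in_state and social_group (group at collection); ``similarity``
    is a square sample-labelled similarity matrix.  Category-3 pairs
    require the two females to share a social group at both collection
    dates; cross-group different-female pairs and pairs beyond the
    maximum lag are dropped.
    """
    lab = labels[~labels.get("excluded", pd.Series(False, index=labels.index))]
    frames = []
    for state, g in lab.groupby("state"):
        g = g.reset_index(drop=True)
        n = len(g)
        if n < 2:
            continue
        days = g["day_in_state"].to_numpy(dtype=int)
        fem = g["female_id"].to_numpy()
        ev = g["event_id"].to_numpy()
        grp = g["social_group"].to_numpy()
        iu, ju = np.triu_indices(n, k=1)
        delta = np.abs(days[iu] - days[ju])
        bins = delta // month_days + 1
        in_lag = bins <= max_lag
        same_fem = fem[iu] == fem[ju]
        same_ev = same_fem & (ev[iu] == ev[ju])
        same_grp = grp[iu] == grp[ju]
        category = np.where(same_ev, 1, np.where(same_fem, 2, 3))
        keep = in_lag & (same_fem | same_grp)
        iu, ju, bins, category = iu[keep], ju[keep], bins[keep], category[keep]
        sims = similarity.to_numpy()[
            similarity.index.get_indexer(g.loc[iu, "sample_id"]),
            similarity.columns.get_indexer(g.loc[ju, "sample_id"])]
        frames.append(pd.DataFrame({
            "sample_i": g.loc[iu, "sample_id"].to_numpy(),
            "sample_j": g.loc[ju, "sample_id"].to_numpy(),
            "state": state,
            "category": category.astype(int),
            "lag_bin": bins.astype(int),
            "similarity": sims,
        }))
    if not frames:
        return pd.DataFrame(columns=["sample_i", "sample_j", "state",
                                     "category", "lag_bin", "similarity"])
    return pd.concat(frames, ignore_index=True)


def similarity_curves(pairs: pd.DataFrame, ci: float = 0.95) -> pd.DataFrame:
    """Mean similarity and t-based CI per (state, category, lag)."""
    rows = []
    for (state, cat, lag), g in pairs.groupby(["state", "category",
                                               "lag_bin"]):
        vals = g["similarity"].to_numpy(dtype=float)
        n = len(vals)
        mean = vals.mean()
        if n > 1 and vals.std(ddof=1) > 0:
            half = (stats.t.ppf(0.5 + ci / 2, n - 1)
                    * vals.std(ddof=1) / np.sqrt(n))
        else:
            half = 0.0
        rows.append({"state": state, "category": int(cat),
                     "lag_bin": int(lag), "mean": mean,
                     "ci_low": mean - half, "ci_high": mean + half, "n": n})
    return pd.DataFrame(rows).sort_values(
        ["state", "category", "lag_bin"]).reset_index(drop=True)


def compare_curves(pairs: pd.DataFrame, min_n: int = 2) -> pd.DataFrame:
    """Welch t-tests between pair categories within each (state, lag).

    The Benjamini-Hochberg family is all category contrasts within one
    state across all lags (up to 18 tests per state).
    """
    rows = []
    for state, gs in pairs.groupby("state"):
        state_rows = []
        for lag, gl in gs.groupby("lag_bin"):
            by_cat = {c: v["similarity"].to_numpy(dtype=float)
                      for c, v in gl.groupby("category")}
            for a, b in [(1, 2), (1, 3), (2, 3)]:
                if a not in by_cat or b not in by_cat:
                    continue
                xa, xb = by_cat[a], by_cat[b]
                if len(xa) < min_n or len(xb) < min_n:
                    warnings.warn(f"{state} lag {lag}: contrast {a} vs {b} "
                                  "skipped (too few pairs)")
                    continue
                if xa.std() == 0 and xb.std() == 0:
                    t, p = 0.0, 1.0
                else:
                    t, p = stats.ttest_ind(xa, xb, equal_var=False)
                state_rows.append({
                    "state": state, "lag_bin": int(lag),
                    "category_a": a, "category_b": b,
                    "mean_a": xa.mean(), "mean_b": xb.mean(),
                    "t": float(t), "p": float(p)})
        if not state_rows:
            continue
        df = pd.DataFrame(state_rows)
        df["q"] = bh_adjust(df["p"].to_numpy())
        rows.append(df)
    if not rows:
        return pd.DataFrame(columns=["state", "lag_bin", "category_a",
                                     "category_b", "mean_a", "mean_b",
                                     "t", "p", "q"])
    return pd.concat(rows, ignore_index=True)
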