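"""Daily summarisation of feature samples and visit-window cluster scores.

Each feature is summarised per subject-day as the average of the day's mean
and median sample value — the two summaries are highly collinear, so their
average keeps one interpretable value per day on the seconds scale.  Days
with fewer than ``min_events`` raw keystroke events (default 50) are
removed as insufficient data.  Daily values of a cluster's member features
are averaged into a daily cluster value, and the daily cluster values
within a symmetric window around each clinical visit (±14 days for the
fine-motor cluster, ±7 for the cognition cluster, inclusive) are averaged
into the per-visit cluster score used by the longitudinal models.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

DAILY_COLUMNS = ["subject_id", "date", "feature", "n_samples", "daily_value"]
WINDOW_COLUMNS = ["subject_id", "visit_label", "cluster", "value_s", "n_days"]

_MS_PER_DAY = 86_400_000


def _subject_codes(s: pd.Series) -> tuple[np.ndarray, pd.Index]:
    if isinstance(s.dtype, pd.CategoricalDtype):
        return s.cat.codes.to_numpy(dtype=np.int64), s.cat.categories
    codes, cats = pd.factorize(s, sort=True)
    return codes.astype(np.int64), pd.Index(cats)


def _grouped_mean_median(key: np.ndarray, value: np.ndarray):
    """Exact per-group mean and median via one lexsort (keys returned sorted)."""
    order = np.lexsort((value, key))
    k, v = key[order], value[order]
    starts = np.r_[0, np.flatnonzero(k[1:] != k[:-1]) + 1]
    counts = np.diff(np.r_[starts, len(k)])
    mean = np.add.reduceat(v, starts) / counts
    lo = starts + (counts - 1) // 2
    hi = starts + counts // 2
    median = (v[lo] + v[hi]) / 2.0
    return k[starts], counts, mean, median


def daily_event_counts(events: pd.DataFrame) -> pd.DataFrame:
    """Raw press+release event count per subject and UTC calendar day."""
    if events.empty:
        return pd.DataFrame(columns=["subject_id", "date", "day_event_count"])
    codes, cats = _subject_codes(events["subject_id"])
    day = events["timestamp_ms"].to_numpy(dtype=np.int64) // _MS_PER_DAY
    day_min = int(day.min())
    span = int(day.max()) - day_min + 1
    key = codes * span + (day - day_min)
    uniq, counts = np.unique(key, return_counts=True)
    return pd.DataFrame(
        {
            "subject_id": cats.take(uniq // span),
            "date": pd.to_datetime((uniq % span + day_min) * _MS_PER_DAY, unit="ms"),
            "day_event_count": counts,
        }
    )


def aggregate_daily(
    samples: pd.DataFrame,
    event_counts: pd.DataFrame,
    min_events: int = 50,
) -> pd.DataFrame:
    """Collapse feature samples to one value per subject/day/feature.

    ``daily_value = (mean + median) / 2`` of the day's samples.  Days whose
    raw event count (from ``event_counts``, computed on press+release
    events, not feature samples) is below ``min_events`` emit no records.
    """
    if min_events < 1:
        raise ValueError("min_events must be >= 1")
    if samples.empty or event_counts.empty:
        return pd.DataFrame(columns=DAILY_COLUMNS)

    codes, cats = _subject_codes(samples["subject_id"])
    day = pd.to_datetime(samples["date"]).to_numpy().astype("datetime64[D]").astype(np.int64)
    ec_codes = pd.Categorical(event_counts["subject_id"], categories=cats).codes.astype(
        np.int64
    )
    ec_day = (
        pd.to_datetime(event_counts["date"]).to_numpy().astype("datetime64[D]").astype(np.int64)
    )
    day_min = int(min(day.min(), ec_day.min()))
    span = int(max(day.max(), ec_day.max())) - day_min + 1

    ok = (event_counts["day_event_count"].to_numpy() >= min_events) & (ec_codes >= 0)
    eligible_keys = np.unique(ec_codes[ok] * span + (ec_day[ok] - day_min))
    subject_day_key = codes * span + (day - day_min)
    pos = np.searchsorted(eligible_keys, subject_day_key)
    pos_clip = np.minimum(pos, max(len(eligible_keys) - 1, 0))
    keep = (len(eligible_keys) > 0) & (eligible_keys[pos_clip] == subject_day_key)
    if not keep.any():
        return pd.DataFrame(columns=DAILY_COLUMNS)

    feat = samples["feature"]
    if isinstance(feat.dtype, pd.CategoricalDtype):
        f_codes, f_cats = feat.cat.codes.to_numpy(np.int64), feat.cat.categories
    else:
        f_codes, f_cats = pd.factorize(feat)
        f_codes, f_cats = f_codes.astype(np.int64), pd.Index(f_cats)
    nf = max(len(f_cats), 1)
    key = subject_day_key[keep] * nf + f_codes[keep]
    gkey, counts, mean, median = _grouped_mean_median(
        key, samples["value_s"].to_numpy(dtype=float)[keep]
    )
    sd_key = gkey // nf
    return pd.DataFrame(
        {
            "subject_id": cats.take(sd_key // span),
            "date": pd.to_datetime((sd_key % span + day_min) * _MS_PER_DAY, unit="ms"),
            "feature": f_cats.take(gkey % nf),
            "n_samples": counts,
            "daily_value": (mean + median) / 2.0,
        }
    )


def daily_feature_matrix(daily_records: pd.DataFrame) -> pd.DataFrame:
    """Pivot daily records to a subject-day × feature matrix (NaN = absent)."""
    return daily_records.pivot_table(
        index=["subject_id", "date"], columns="feature", values="daily_value", aggfunc="first", observed=True
    )


def cluster_daily_scores(
    daily_records: pd.DataFrame, member_features: list[str] | tuple[str, ...]
) -> pd.DataFrame:
    """Unweighted mean of available member features per subject-day.

    A day contributes a value when at least one member feature has a daily
    record; absent members are simply left out of the mean.
    """
    members = daily_records[daily_records["feature"].isin(member_features)]
    if members.empty:
        return pd.DataFrame(columns=["subject_id", "date", "daily_value"])
    out = (
        members.groupby(["subject_id", "date"], sort=True, observed=True)["daily_value"]
        .mean()
        .reset_index()
    )
    return out


def window_aggregate(
    daily_cluster: pd.DataFrame,
    visits: pd.DataFrame,
    cluster: str,
    half_width_days: int,
) -> pd.DataFrame:
    """Per-visit cluster score: mean daily value within ±half_width days.

    The window is inclusive of the visit day itself, so it spans at most
    ``2*half_width + 1`` calendar days.  Visits with no valid day in the
    window yield no row (the visit is then excluded from models pairwise).

    Parameters
    ----------
    daily_cluster
        ``subject_id, date, daily_value`` as from :func:`cluster_daily_scores`.
    visits
        Must carry ``subject_id, visit_label, visit_date``.
    """
    if half_width_days < 0:
        raise ValueError("half_width_days must be nonnegative")
    if daily_cluster.empty:
        return pd.DataFrame(columns=WINDOW_COLUMNS)
    dc = daily_cluster.copy()
    dc["date"] = pd.to_datetime(dc["date"])
    vis = visits[["subject_id", "visit_label", "visit_date"]].copy()
    vis["visit_date"] = pd.to_datetime(vis["visit_date"])
    merged = dc.merge(vis, on="subject_id", how="inner")
    lag = (merged["date"] - merged["visit_date"]).dt.days.abs()
    merged = merged[lag <= half_width_days]
    if merged.empty:
        return pd.DataFrame(columns=WINDOW_COLUMNS)
    out = (
        merged.groupby(["subject_id", "visit_label"], sort=True, observed=True)["daily_value"]
        .agg(value_s="mean", n_days="size")
        .reset_index()
    )
    out.insert(2, "cluster", cluster)
    return out[WINDOW_COLUMNS]


def cluster_window_scores(
    daily_records: pd.DataFrame,
    visits: pd.DataFrame,
    cluster_defs: dict,
    order: str = "days_first",
) -> pd.DataFrame:
    """Window scores for every cluster definition.

    ``order="days_first"`` (default) averages member features into a daily
    cluster value and then averages days in the window, weighting days
    equally.  ``order="features_first"`` computes per-feature window means
    first and then averages features — a sensitivity alternative that
    differs when features have unequal day coverage.
    """
    frames = []
    for name, cdef in cluster_defs.items():
        if order == "days_first":
            daily = cluster_daily_scores(daily_records, cdef.member_features)
            frames.append(window_aggregate(daily, visits, name, cdef.window_half_width_days))
        elif order == "features_first":
            per_feature = []
            for feat in cdef.member_features:
                one = daily_records[daily_records["feature"] == feat][
                    ["subject_id", "date", "daily_value"]
                ]
                w = window_aggregate(one, visits, name, cdef.window_half_width_days)
                per_feature.append(w.assign(feature=feat))
            if not per_feature:
                continue
            allf = pd.concat(per_feature, ignore_index=True)
            if allf.empty:
                continue
            out = (
                allf.groupby(["subject_id", "visit_label", "cluster"], sort=True, observed=True)
                .agg(value_s=("value_s", "mean"), n_days=("n_days", "max"))
                .reset_index()
            )
            frames.append(out[WINDOW_COLUMNS])
        else:
            raise ValueError(f"unknown aggregation order: {order!r}")
    if not frames:
        return pd.DataFrame(columns=WINDOW_COLUMNS)
    return pd.concat(frames, ignore_index=True)
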