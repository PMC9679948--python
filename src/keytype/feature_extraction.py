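"""Derivation of the eight keystroke-dynamics features from typing sessions.

For alphanumeric keys: hold time (HT, release minus press of one key),
press-press latency (PPL), release-release latency (RRL) and flight time
(FT, press of the next key minus release of the previous; negative under
rollover typing and deliberately not clamped).  For the backspace key:
precorrection slowing (preCS, pause before a correction burst), correction
duration (CD, first press to last release of the burst) and postcorrection
slowing (postCS, pause after the burst).  For punctuation keys: the
after-punctuation pause (APP, punctuation release to the next press of any
key).

All values are in seconds.  A feature sample is dated to the UTC calendar
day of its first contributing event.  Computation is vectorized over the
whole event frame; sessions (see :func:`keytype.events_io.segment_sessions`)
bound every latency so that no sample spans a typing pause.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

FEATURES = ("PPL", "RRL", "HT", "FT", "preCS", "CD", "postCS", "APP")
TIMING_FEATURES = ("HT", "PPL", "RRL", "FT")
CORRECTION_FEATURES = ("preCS", "CD", "postCS")
PUNCTUATION_FEATURES = ("APP",)

SAMPLE_COLUMNS = ["subject_id", "date", "feature", "value_s"]

_MS = 86_400_000  # ms per day


def _dates_from_ms(ts_ms: np.ndarray) -> np.ndarray:
    """UTC calendar date for epoch-millisecond timestamps."""
    days = np.floor_divide(ts_ms.astype(np.int64), _MS)
    return days.astype("datetime64[D]")


def _cumcount(keys: np.ndarray) -> np.ndarray:
    """Occurrence index of each element within its key group (stable order)."""
    n = len(keys)
    if n == 0:
        return np.zeros(0, dtype=np.int64)
    order = np.argsort(keys, kind="stable")
    sorted_keys = keys[order]
    start = np.r_[True, sorted_keys[1:] != sorted_keys[:-1]]
    pos = np.arange(n)
    group_first = np.maximum.accumulate(np.where(start, pos, 0))
    out = np.empty(n, dtype=np.int64)
    out[order] = pos - group_first
    return out


def pair_key_instances(events: pd.DataFrame) -> pd.DataFrame:
    """Pair press and release events into key instances.

    Within each ``(session_id, key_token)`` group the k-th release is
    matched to the k-th press (FIFO order, which equals stack order for
    non-overlapping instances of the same key).  Presses without a release
    are retained with a missing release time so press-based latencies still
    see them; releases without a press, and releases that precede their
    press, are discarded and tallied in ``result.attrs["n_discarded"]``.

    Returns one row per key instance, sorted by press time within session:
    ``subject_id, session_id, key_class, press_ms, release_ms``.
    """
    if "session_id" not in events.columns:
        events = events.assign(session_id=0)
    is_press = (events["action"] == "press").to_numpy()
    is_release = (events["action"] == "release").to_numpy()
    ts = events["timestamp_ms"].to_numpy(dtype=np.int64)
    sid = events["session_id"].to_numpy(dtype=np.int64)
    if "key_token" in events.columns:
        tok = events["key_token"]
        tok_codes = (
            tok.cat.codes.to_numpy(dtype=np.int64)
            if isinstance(tok.dtype, pd.CategoricalDtype)
            else pd.factorize(tok)[0].astype(np.int64)
        )
        tok_codes = np.maximum(tok_codes, 0)  # NaN token -> shared code
    else:
        tok_codes = np.zeros(len(events), dtype=np.int64)
    ntok = int(tok_codes.max()) + 1 if len(tok_codes) else 1
    ckey = sid * ntok + tok_codes

    p = np.flatnonzero(is_press)
    r = np.flatnonzero(is_release)
    cc_p = _cumcount(ckey[p])
    cc_r = _cumcount(ckey[r])
    rank_span = int(max(cc_p.max(initial=0), cc_r.max(initial=0))) + 1
    pc = ckey[p] * rank_span + cc_p
    rc = ckey[r] * rank_span + cc_r
    order_p = np.argsort(pc, kind="stable")
    pos = np.searchsorted(pc[order_p], rc)
    pos_clip = np.minimum(pos, len(pc) - 1) if len(pc) else pos
    matched = (len(pc) > 0) & (pos < len(pc)) & (pc[order_p][pos_clip] == rc)
    release_ms = np.full(len(p), np.nan)
    if len(pc):
        release_ms[order_p[pos_clip[matched]]] = ts[r][matched]
    n_discarded = int((~matched).sum()) if len(rc) else 0

    press_ms = ts[p].astype(np.float64)
    inverted = release_ms < press_ms
    if inverted.any():
        n_discarded += int(inverted.sum())
        release_ms[inverted] = np.nan

    out = pd.DataFrame(
        {
            "subject_id": events["subject_id"].iloc[p].to_numpy()
            if not isinstance(events["subject_id"].dtype, pd.CategoricalDtype)
            else events["subject_id"].iloc[p].array,
            "session_id": sid[p],
            "key_class": events["key_class"].iloc[p].to_numpy()
            if not isinstance(events["key_class"].dtype, pd.CategoricalDtype)
            else events["key_class"].iloc[p].array,
            "press_ms": press_ms,
            "release_ms": release_ms,
        }
    )
    # presses are normally already in (session, time) order; sort only if not
    if not (np.all(np.diff(sid[p]) >= 0) and np.all((np.diff(press_ms) >= 0) | (np.diff(sid[p]) > 0))):
        out = out.sort_values(["session_id", "press_ms"], kind="stable")
    out = out.reset_index(drop=True)
    out.attrs["n_discarded"] = int(n_discarded)
    if n_discarded:
        logger.warning("discarded %d unmatched or inverted press/release events", n_discarded)
    return out


def _emit(
    subject: np.ndarray,
    t_first: np.ndarray,
    t_second: np.ndarray,
    feature: str,
    frames: list,
    allow_negative: bool = False,
) -> None:
    """Append samples ``(t_second - t_first)/1000`` dated to the first event."""
    valid = ~(np.isnan(t_first) | np.isnan(t_second))
    value = (t_second[valid] - t_first[valid]) / 1000.0
    if not allow_negative:
        neg = value < 0
        if neg.any():
            logger.warning("discarded %d negative %s samples", int(neg.sum()), feature)
            value = value[~neg]
            valid_idx = np.flatnonzero(valid)[~neg]
        else:
            valid_idx = np.flatnonzero(valid)
    else:
        valid_idx = np.flatnonzero(valid)
    code = FEATURES.index(feature)
    frames.append(
        pd.DataFrame(
            {
                "subject_id": subject[valid_idx],
                "date": _dates_from_ms(t_first[valid_idx]),
                "feature": pd.Categorical.from_codes(
                    np.full(len(valid_idx), code, dtype=np.int8), categories=list(FEATURES)
                ),
                "value_s": value,
            }
        )
    )


def extract_features(
    events: pd.DataFrame, features: tuple[str, ...] = FEATURES
) -> pd.DataFrame:
    """Extract keystroke-dynamics feature samples from sessionized events.

    Parameters
    ----------
    events
        Event frame with a ``session_id`` column (one typing session per id).
    features
        Subset of :data:`FEATURES` to compute.

    Returns
    -------
    DataFrame with columns ``subject_id, date, feature, value_s``; the
    ``date`` is the UTC day of the sample's first contributing event.
    """
    inst = pair_key_instances(events)
    frames: list[pd.DataFrame] = []
    if inst.empty:
        return pd.DataFrame(columns=SAMPLE_COLUMNS)

    subj = inst["subject_id"].array
    sess = inst["session_id"].to_numpy()
    kc = inst["key_class"]
    press = inst["press_ms"].to_numpy()
    release = inst["release_ms"].to_numpy()
    same_session = np.r_[sess[1:] == sess[:-1], False]  # k and k+1 in one session
    is_alnum = (kc == "alphanumeric").to_numpy()
    is_bs = (kc == "backspace").to_numpy()
    is_punct = (kc == "punctuation").to_numpy()

    if "HT" in features:
        _emit(subj[is_alnum], press[is_alnum], release[is_alnum], "HT", frames)

    # consecutive alphanumeric pairs: adjacent instances, no other class between
    pair = same_session & is_alnum & np.r_[is_alnum[1:], False]
    idx = np.flatnonzero(pair)
    if "PPL" in features:
        _emit(subj[idx], press[idx], press[idx + 1], "PPL", frames)
    if "RRL" in features:
        _emit(subj[idx], release[idx], release[idx + 1], "RRL", frames)
    if "FT" in features:
        _emit(subj[idx], release[idx], press[idx + 1], "FT", frames, allow_negative=True)

    if any(f in features for f in CORRECTION_FEATURES):
        # maximal runs of backspace instances within a session
        same_prev = np.r_[False, sess[1:] == sess[:-1]]  # shares session with previous
        prev_is_bs = np.r_[False, is_bs[:-1]]
        next_is_bs = np.r_[is_bs[1:], False]
        burst_start = is_bs & ~(same_prev & prev_is_bs)
        burst_end = is_bs & ~(same_session & next_is_bs)
        first = np.flatnonzero(burst_start)
        last = np.flatnonzero(burst_end)
        assert len(first) == len(last)
        if "preCS" in features:
            has_prev = (first > 0) & same_prev[first]
            f = first[has_prev]
            _emit(subj[f], release[f - 1], press[f], "preCS", frames)
        if "CD" in features:
            _emit(subj[first], press[first], release[last], "CD", frames)
        if "postCS" in features:
            has_next = same_session[last]
            la = last[has_next]
            _emit(subj[la], release[la], press[la + 1], "postCS", frames)

    if "APP" in features:
        pi = np.flatnonzero(is_punct & same_session)
        _emit(subj[pi], release[pi], press[pi + 1], "APP", frames)

    if not frames:
        return pd.DataFrame(columns=SAMPLE_COLUMNS)
    out = pd.concat(frames, ignore_index=True)
    out["date"] = pd.to_datetime(out["date"])
    return out[SAMPLE_COLUMNS]


def extract_timing_features(session: pd.DataFrame) -> pd.DataFrame:
    """HT/PPL/RRL/FT samples for one typing session (convenience wrapper)."""
    return extract_features(session, TIMING_FEATURES)


def extract_correction_features(session: pd.DataFrame) -> pd.DataFrame:
    """preCS/CD/postCS samples for one typing session."""
    return extract_features(session, CORRECTION_FEATURES)


def extract_punctuation_features(session: pd.DataFrame) -> pd.DataFrame:
    """APP samples for one typing session."""
    return extract_features(session, PUNCTUATION_FEATURES)
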