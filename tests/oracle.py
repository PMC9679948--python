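"""Brute-force reference implementation of the keystroke features.

Pure-Python, event-by-event recomputation used as an independent oracle
against the vectorized extractor.  Deliberately simple: explicit queues
and loops, no numpy.
"""

from __future__ import annotations

from collections import defaultdict


def pair_instances_bruteforce(events: list[dict]) -> list[dict]:
    """FIFO press/release pairing per (session_id, key_token).

    ``events`` are dicts with keys ``timestamp_ms, action, key_class,
    key_token, session_id`` in time order.  Returns key instances sorted
    by press time (stable), each with ``press, release (or None), key_class,
    session_id``.
    """
    pending: dict = defaultdict(list)  # (session, token) -> instance refs
    instances: list[dict] = []
    for ev in events:
        key = (ev["session_id"], ev["key_token"])
        if ev["action"] == "press":
            inst = {
                "press": ev["timestamp_ms"],
                "release": None,
                "key_class": ev["key_class"],
                "session_id": ev["session_id"],
            }
            instances.append(inst)
            pending[key].append(inst)
        elif ev["action"] == "release":
            if pending[key]:
                inst = pending[key].pop(0)
                if ev["timestamp_ms"] >= inst["press"]:
                    inst["release"] = ev["timestamp_ms"]
                # release before its press: discarded (release stays None)
    instances.sort(key=lambda i: (i["session_id"], i["press"]))
    return instances


def bruteforce_features(events: list[dict]) -> dict[str, list[float]]:
    """All eight features from one subject's sessionized events, by loops."""
    inst = pair_instances_bruteforce(events)
    out: dict[str, list[float]] = {
        f: [] for f in ("HT", "PPL", "RRL", "FT", "preCS", "CD", "postCS", "APP")
    }

    def sec(a, b):
        return (b - a) / 1000.0

    def emit(feature, a, b):
        if a is None or b is None:
            return
        v = sec(a, b)
        if v < 0 and feature != "FT":
            return  # negative non-flight samples are discarded
        out[feature].append(v)

    for k in inst:
        if k["key_class"] == "alphanumeric":
            emit("HT", k["press"], k["release"])

    for a, b in zip(inst, inst[1:]):
        if a["session_id"] != b["session_id"]:
            continue
        if a["key_class"] == "alphanumeric" and b["key_class"] == "alphanumeric":
            emit("PPL", a["press"], b["press"])
            emit("RRL", a["release"], b["release"])
            emit("FT", a["release"], b["press"])
        if a["key_class"] == "punctuation":
            emit("APP", a["release"], b["press"])

    # maximal backspace bursts within a session
    i = 0
    while i < len(inst):
        if inst[i]["key_class"] != "backspace":
            i += 1
            continue
        j = i
        while (
            j + 1 < len(inst)
            and inst[j + 1]["key_class"] == "backspace"
            and inst[j + 1]["session_id"] == inst[j]["session_id"]
        ):
            j += 1
        first, last = inst[i], inst[j]
        if i > 0 and inst[i - 1]["session_id"] == first["session_id"]:
            emit("preCS", inst[i - 1]["release"], first["press"])
        emit("CD", first["press"], last["release"])
        if j + 1 < len(inst) and inst[j + 1]["session_id"] == last["session_id"]:
            emit("postCS", last["release"], inst[j + 1]["press"])
        i = j + 1
    return out


def random_session_events(rng, max_events: int = 20) -> list[dict]:
    """Random well-formed event stream: every release follows its own press.

    Key instances may overlap (rollover) and occasionally lack a release
    (missing-release error path); long gaps induce multiple sessions once
    the stream is sessionized.
    """
    n_keys = int(rng.integers(1, max_events // 2 + 1))
    classes = ["alphanumeric", "backspace", "punctuation", "other"]
    events = []
    t = 0
    for i in range(n_keys):
        t += int(rng.integers(1, 800))
        if rng.random() < 0.08:
            t += int(rng.integers(6_000, 20_000))  # session break
        hold = int(rng.integers(1, 600))
        cls = classes[int(rng.integers(0, 4))]
        tok = f"k{int(rng.integers(0, 3))}"
        events.append(
            {"subject_id": "S0", "timestamp_ms": t, "action": "press",
             "key_class": cls, "key_token": tok}
        )
        if rng.random() > 0.05:  # occasionally drop the release
            events.append(
                {"subject_id": "S0", "timestamp_ms": t + hold, "action": "release",
                 "key_class": cls, "key_token": tok}
            )
    events.sort(key=lambda e: e["timestamp_ms"])
    return events
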