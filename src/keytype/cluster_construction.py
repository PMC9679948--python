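"""Construction and validation of the fine-motor and cognition clusters.

Candidate features are grouped by concept: timing of alphanumeric keys
(PPL, RRL, HT, FT) for the fine motor score cluster (FMSC) and
error/paralinguistic latencies (preCS, CD, postCS, APP) for the cognition
score cluster (CSC).  Within each group, membership in the final cluster
requires (a) high mutual correlation on the pooled subject-day daily-value
matrix (every pairwise Pearson r strictly above ``r_min``, default 0.50)
and (b) an approximately equal contribution to the first principal
component of the standardized candidate matrix (|loading| at least
``tau`` times the largest |loading|, default 0.7, with the majority
loading sign).  The expected outcome on cohort-scale data is
FMSC = {PPL, RRL, FT} and CSC = {preCS, postCS, APP}; memberships can also
be pinned by configuration to reproduce those clusters on any dataset.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

FMSC_CANDIDATES = ("PPL", "RRL", "HT", "FT")
CSC_CANDIDATES = ("preCS", "CD", "postCS", "APP")

#: final memberships reported by the validation study, available for pinning
PINNED_MEMBERS = {"FMSC": ("PPL", "RRL", "FT"), "CSC": ("preCS", "postCS", "APP")}

WINDOW_HALF_WIDTH = {"FMSC": 14, "CSC": 7}


class ClusterConfigurationError(ValueError):
    """Screening left a cluster without members; thresholds need review."""


@dataclass
class ClusterDefinition:
    name: str
    candidate_features: tuple[str, ...]
    member_features: tuple[str, ...]
    window_half_width_days: int

    def __post_init__(self) -> None:
        if not set(self.member_features) <= set(self.candidate_features):
            raise ValueError("member_features must be a subset of candidate_features")


@dataclass
class ScreenReport:
    """Diagnostics from one concept group's screens."""

    correlation_matrix: pd.DataFrame = field(default_factory=pd.DataFrame)
    correlation_survivors: tuple[str, ...] = ()
    loadings: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))
    pca_pass: dict = field(default_factory=dict)
    members: tuple[str, ...] = ()


def _usable_columns(daily_matrix: pd.DataFrame, candidates: tuple[str, ...]) -> list[str]:
    """Candidates present in the matrix with nonzero variance."""
    cols = []
    for c in candidates:
        if c not in daily_matrix.columns:
            logger.warning("candidate feature %s absent from daily matrix", c)
            continue
        col = daily_matrix[c].dropna()
        if len(col) < 2 or np.isclose(col.std(ddof=1), 0.0):
            logger.warning("candidate feature %s has no variance; dropped", c)
            continue
        cols.append(c)
    return cols


def correlation_screen(
    daily_matrix: pd.DataFrame,
    candidates: tuple[str, ...],
    r_min: float = 0.50,
) -> tuple[tuple[str, ...], pd.DataFrame]:
    """Largest candidate subset whose pairwise correlations all exceed r_min.

    Correlations are Pearson, computed pairwise on the pooled subject-day
    daily-value matrix.  Strict inequality at the boundary (r == r_min is
    excluded).  Ties between equally large subsets are broken by the higher
    mean pairwise correlation.  Returns the retained features (in candidate
    order) and the full candidate correlation matrix.
    """
    cols = _usable_columns(daily_matrix, candidates)
    corr = daily_matrix[cols].corr(method="pearson") if cols else pd.DataFrame()
    if len(cols) <= 1:
        return tuple(cols), corr
    best: tuple[str, ...] = ()
    best_key = (-1, -np.inf)
    for size in range(len(cols), 1, -1):
        for subset in combinations(cols, size):
            pair_r = [corr.loc[a, b] for a, b in combinations(subset, 2)]
            if all(r > r_min for r in pair_r):
                key = (size, float(np.mean(pair_r)))
                if key > best_key:
                    best, best_key = subset, key
        if best:
            break
    if not best:
        # no correlated pair: fall back to single features (vacuously valid)
        best = (cols[0],)
    return tuple(f for f in cols if f in best), corr


def pca_screen(
    daily_matrix: pd.DataFrame,
    candidates: tuple[str, ...],
    tau: float = 0.7,
) -> tuple[pd.Series, dict]:
    """First-principal-component loadings and equal-contribution flags.

    Columns are standardized (correlation-matrix PCA) and complete rows
    used.  A feature "contributes equally" iff its |loading| is at least
    ``tau`` times the largest |loading| and its sign matches the majority
    loading sign.  Zero-variance columns are excluded beforehand.
    """
    cols = _usable_columns(daily_matrix, candidates)
    if not cols:
        return pd.Series(dtype=float), {}
    X = daily_matrix[cols].dropna()
    if len(X) < 3:
        raise ValueError("pca_screen needs at least 3 complete rows")
    Z = (X - X.mean()) / X.std(ddof=1)
    _, _, vt = np.linalg.svd(Z.to_numpy(), full_matrices=False)
    load = pd.Series(vt[0], index=cols, name="pc1_loading")
    if load.sum() < 0:  # orient toward positive majority for readability
        load = -load
    majority_sign = np.sign(load).value_counts().idxmax()
    thresh = tau * load.abs().max()
    passed = {
        f: bool(abs(load[f]) >= thresh and np.sign(load[f]) == majority_sign) for f in cols
    }
    return load, passed


def build_cluster_definitions(
    daily_matrix: pd.DataFrame,
    r_min: float = 0.50,
    tau: float = 0.7,
    pinned_memberships: dict | None = None,
) -> tuple[dict, dict]:
    """Screen both concept groups and assemble the cluster definitions.

    Members are the intersection of the correlation-screen and PCA-screen
    survivors within each concept group.  ``pinned_memberships`` (e.g.
    :data:`PINNED_MEMBERS`) bypasses the screens for the given clusters.

    Returns ``(cluster_defs, reports)`` keyed by cluster name.
    """
    groups = {"FMSC": FMSC_CANDIDATES, "CSC": CSC_CANDIDATES}
    defs: dict[str, ClusterDefinition] = {}
    reports: dict[str, ScreenReport] = {}
    for name, candidates in groups.items():
        report = ScreenReport()
        if pinned_memberships and name in pinned_memberships:
            members = tuple(pinned_memberships[name])
        else:
            survivors, corr = correlation_screen(daily_matrix, candidates, r_min)
            load, passed = pca_screen(daily_matrix, candidates, tau)
            report.correlation_matrix = corr
            report.correlation_survivors = survivors
            report.loadings = load
            report.pca_pass = passed
            members = tuple(
                f for f in candidates if f in survivors and passed.get(f, False)
            )
        if not members:
            raise ClusterConfigurationError(
                f"{name}: screening retained no features; review r_min/tau thresholds"
            )
        report.members = members
        reports[name] = report
        defs[name] = ClusterDefinition(
            name=name,
            candidate_features=candidates,
            member_features=members,
            window_half_width_days=WINDOW_HALF_WIDTH[name],
        )
    return defs, reports


def default_cluster_definitions() -> dict:
    """The validated cluster definitions, pinned (no screening)."""
    return {
        name: ClusterDefinition(
            name=name,
            candidate_features=FMSC_CANDIDATES if name == "FMSC" else CSC_CANDIDATES,
            member_features=members,
            window_half_width_days=WINDOW_HALF_WIDTH[name],
        )
        for name, members in PINNED_MEMBERS.items()
    }
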