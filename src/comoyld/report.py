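"""Aggregation of per-sequela results to cause / group / total level, percent
changes with repetition-based uncertainty, and ranking-shift detection.

Rates aggregate additively across sequelae → cause → disease group → total
within a stratum.  Uncertainty intervals of an aggregate are recomputed from
the per-repetition aggregated means retained in each
:class:`~comoyld.engine.StratumResult` — never by summing CI endpoints, which
would overstate the interval.  Percent changes are computed on unrounded
rates and rounded only for display; their CIs are likewise derived per
repetition (the change is computed within each repetition, then the
percentiles are taken).

Age or sex margins of "per 1,000 population" rates need population weights;
when none are supplied the unweighted mean of stratum rates is reported and
flagged as such in the output.
"""

from __future__ import annotations

from dataclasses import dataclass
from os import PathLike
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .engine import StratumResult
from .registry import Registry, Stratum, sequela_groups, stratum_slice

__all__ = [
    "LEVELS",
    "RankingChange",
    "percent_change",
    "percentile_ci",
    "aggregate",
    "ranking_changes",
    "write_report",
    "write_rankings",
]

LEVELS = ("sequela", "cause", "group", "total")

REPORT_COLUMNS = [
    "level",
    "key",
    "sex",
    "age_group",
    "year",
    "prevalence_per_1000",
    "unadjusted_per_1000",
    "adjusted_per_1000",
    "ci_low",
    "ci_high",
    "pct_change",
    "pct_change_ci_low",
    "pct_change_ci_high",
    "weighting",
]


def percent_change(unadjusted: float, adjusted: float) -> float:
    """Percent change 100 × (adjusted − unadjusted) / unadjusted.

    Computed on unrounded rates; negative means the multimorbidity correction
    lowered the estimated burden.  A zero unadjusted rate has no defined
    change and yields NaN (the undefined-change signal).
    """
    if unadjusted == 0.0:
        return float("nan")
    return 100.0 * (adjusted - unadjusted) / unadjusted


def percentile_ci(values: Sequence[float], level: float = 0.95) -> tuple[float, float]:
    """Empirical (1−level)/2 and 1−(1−level)/2 quantiles of repetition means.

    Uses linear interpolation between order statistics.  Requires at least
    two values and 0 < level < 1.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError("percentile_ci needs at least 2 values")
    if not 0.0 < level < 1.0:
        raise ValueError("ci level must be in (0, 1)")
    alpha = 1.0 - level
    lo, hi = np.quantile(arr, [alpha / 2.0, 1.0 - alpha / 2.0])
    return float(lo), float(hi)


@dataclass(frozen=True)
class RankingChange:
    """A cause whose rank moved by at least the reporting threshold."""

    cause_id: str
    rank_unadjusted: int
    rank_adjusted: int
    delta: int  # rank_unadjusted − rank_adjusted; positive = moved up
    direction: str  # "up" | "down"


# ---------------------------------------------------------------------------
# Aggregation
# ---------------------------------------------------------------------------


def _level_key(level: str, sid: str, cause_id: str, group: str) -> str:
    if level == "sequela":
        return sid
    if level == "cause":
        return cause_id
    if level == "group":
        return group
    if level == "total":
        return "total"
    raise ValueError(f"level must be one of {LEVELS}, got {level!r}")


def _stratum_tables(
    result: StratumResult, reg: Registry, level: str, ci: bool
) -> tuple[dict[str, float], dict[str, float], dict[str, float], dict[str, np.ndarray] | None]:
    """Per-key (prevalence, unadjusted, adjusted, per-rep adjusted) in one stratum."""
    groups = sequela_groups(reg)
    prev = {
        sid: 1000.0 * p for sid, p, _ in stratum_slice(reg, result.stratum)
    }
    ids = result.sequela_ids
    if ci:
        if result.rep_means is None:
            raise ValueError(
                "aggregate CIs requested but StratumResult.rep_means was not "
                "retained; rerun the engine keeping rep_means or pass ci=False"
            )
        reps = 1000.0 * result.rep_means  # repetitions × sequelae, per-1,000
    prev_by_key: dict[str, float] = {}
    unadj_by_key: dict[str, float] = {}
    adj_by_key: dict[str, float] = {}
    reps_by_key: dict[str, np.ndarray] | None = {} if ci else None
    for i, sid in enumerate(ids):
        cause_id, group = groups[sid]
        key = _level_key(level, sid, cause_id, group)
        prev_by_key[key] = prev_by_key.get(key, 0.0) + prev.get(sid, 0.0)
        unadj_by_key[key] = unadj_by_key.get(key, 0.0) + result.unadjusted[sid]
        adj_by_key[key] = adj_by_key.get(key, 0.0) + result.per_sequela[sid][0]
        if ci:
            col = reps[:, i]
            if key in reps_by_key:
                reps_by_key[key] = reps_by_key[key] + col
            else:
                reps_by_key[key] = col.copy()
    return prev_by_key, unadj_by_key, adj_by_key, reps_by_key


def _row(
    level: str,
    key: str,
    scope: dict[str, object],
    prevalence: float,
    unadjusted: float,
    adjusted: float,
    reps: np.ndarray | None,
    ci_level: float,
    weighting: str,
) -> dict[str, object]:
    if reps is not None:
        lo, hi = percentile_ci(reps, ci_level) if reps.size >= 2 else (adjusted,) * 2
        pct_reps = (
            100.0 * (reps - unadjusted) / unadjusted if unadjusted > 0 else None
        )
        if pct_reps is not None and pct_reps.size >= 2:
            pct_lo, pct_hi = percentile_ci(pct_reps, ci_level)
        else:
            pct_lo = pct_hi = float("nan")
    else:
        lo = hi = pct_lo = pct_hi = float("nan")
    return {
        "level": level,
        "key": key,
        **scope,
        "prevalence_per_1000": prevalence,
        "unadjusted_per_1000": unadjusted,
        "adjusted_per_1000": adjusted,
        "ci_low": lo,
        "ci_high": hi,
        "pct_change": percent_change(unadjusted, adjusted),
        "pct_change_ci_low": pct_lo,
        "pct_change_ci_high": pct_hi,
        "weighting": weighting,
    }


def aggregate(
    results: Iterable[StratumResult],
    reg: Registry,
    level: str = "cause",
    margins: Sequence[str] = (),
    population_weights: Mapping[Stratum, float] | None = None,
    ci: bool = True,
    ci_level: float = 0.95,
) -> pd.DataFrame:
    """Aggregate stratum results to one reporting level, optionally marginal.

    Parameters
    ----------
    results
        Stratum results from :func:`comoyld.engine.run_stratum`.
    reg
        The registry the results were computed from (supplies the
        sequela → cause → disease-group mapping and prevalences).
    level
        ``"sequela"``, ``"cause"``, ``"group"`` or ``"total"``; rates are
        summed additively over the sequelae under each key.
    margins
        Stratum fields to collapse, e.g. ``("age_group",)`` for all-age rows
        per sex × year.  Collapsed rates are population-weighted means of the
        stratum rates when ``population_weights`` is given (keyed by
        :class:`Stratum`), otherwise unweighted means flagged
        ``weighting="unweighted"``.
    ci
        Recompute uncertainty intervals from the retained per-repetition
        means.  Raises if a result lacks ``rep_means``.

    Returns
    -------
    pandas.DataFrame
        One row per (key, stratum scope) with point estimates, percentile
        CIs, and percent change with its CI.
    """
    results = list(results)
    margins = tuple(margins)
    for m in margins:
        if m not in ("sex", "age_group", "year"):
            raise ValueError(f"unknown margin field {m!r}")

    per_stratum = []
    for res in results:
        prev_k, unadj_k, adj_k, reps_k = _stratum_tables(res, reg, level, ci)
        per_stratum.append((res.stratum, prev_k, unadj_k, adj_k, reps_k))

    rows: list[dict[str, object]] = []
    if not margins:
        for stratum, prev_k, unadj_k, adj_k, reps_k in per_stratum:
            scope = {
                "sex": stratum.sex,
                "age_group": stratum.age_group,
                "year": stratum.year,
            }
            for key in sorted(unadj_k):
                rows.append(
                    _row(
                        level,
                        key,
                        scope,
                        prev_k[key],
                        unadj_k[key],
                        adj_k[key],
                        reps_k[key] if ci else None,
                        ci_level,
                        "stratum",
                    )
                )
    else:
        weighting = "population" if population_weights is not None else "unweighted"
        cells: dict[tuple, list] = {}
        for entry in per_stratum:
            stratum = entry[0]
            scope_key = tuple(
                "all" if f in margins else getattr(stratum, f)
                for f in ("sex", "age_group", "year")
            )
            cells.setdefault(scope_key, []).append(entry)
        for scope_key in sorted(cells, key=str):
            members = cells[scope_key]
            scope = dict(zip(("sex", "age_group", "year"), scope_key))
            if population_weights is not None:
                w = np.array(
                    [population_weights[s] for s, *_ in members], dtype=float
                )
            else:
                w = np.ones(len(members))
            w = w / w.sum()
            keys = sorted({k for _, _, unadj_k, _, _ in members for k in unadj_k})
            for key in keys:
                prevalence = sum(
                    wi * prev_k.get(key, 0.0)
                    for wi, (_, prev_k, _, _, _) in zip(w, members)
                )
                unadjusted = sum(
                    wi * unadj_k.get(key, 0.0)
                    for wi, (_, _, unadj_k, _, _) in zip(w, members)
                )
                adjusted = sum(
                    wi * adj_k.get(key, 0.0)
                    for wi, (_, _, _, adj_k, _) in zip(w, members)
                )
                if ci:
                    lengths = {
                        reps_k[key].size
                        for _, _, _, _, reps_k in members
                        if key in reps_k
                    }
                    if len(lengths) > 1:
                        raise ValueError(
                            "margin CI needs equal repetition counts across "
                            f"strata; got {sorted(lengths)}"
                        )
                    (n_rep,) = lengths
                    reps = np.zeros(n_rep)
                    for wi, (_, _, _, _, reps_k) in zip(w, members):
                        if key in reps_k:
                            reps = reps + wi * reps_k[key]
                else:
                    reps = None
                rows.append(
                    _row(
                        level,
                        key,
                        scope,
                        prevalence,
                        unadjusted,
                        adjusted,
                        reps,
                        ci_level,
                        weighting,
                    )
                )

    return pd.DataFrame(rows, columns=REPORT_COLUMNS)


# ---------------------------------------------------------------------------
# Rankings
# ---------------------------------------------------------------------------


def _as_rate_map(rows, rate_column: str) -> dict[str, float]:
    if isinstance(rows, pd.DataFrame):
        return dict(zip(rows["key"], rows[rate_column]))
    return dict(rows)


def _rank(rates: Mapping[str, float]) -> dict[str, int]:
    # rank 1 = largest rate; ties broken by cause_id ascending
    ordered = sorted(rates, key=lambda c: (-rates[c], c))
    return {c: i + 1 for i, c in enumerate(ordered)}


def ranking_changes(
    rows_unadjusted,
    rows_adjusted,
    threshold: int = 3,
) -> list[RankingChange]:
    """Causes whose YLD-rate rank shifts by ≥ ``threshold`` steps after COMO.

    Inputs are cause-level rate tables — either mappings ``cause_id → rate``
    or cause-level :func:`aggregate` frames (ranked on
    ``unadjusted_per_1000`` and ``adjusted_per_1000`` respectively).  Causes
    are ranked descending by rate (rank 1 = largest burden), ties broken by
    cause_id; ``direction`` is ``"up"`` when the adjusted rank is better
    (smaller).  Both inputs must cover the same causes.
    """
    unadj = _as_rate_map(rows_unadjusted, "unadjusted_per_1000")
    adj = _as_rate_map(rows_adjusted, "adjusted_per_1000")
    if set(unadj) != set(adj):
        diff = sorted(set(unadj) ^ set(adj))
        raise ValueError(f"cause sets differ; symmetric difference: {diff}")
    rank_u = _rank(unadj)
    rank_a = _rank(adj)
    out = []
    for cause in sorted(unadj):
        delta = rank_u[cause] - rank_a[cause]
        if abs(delta) >= threshold:
            out.append(
                RankingChange(
                    cause_id=cause,
                    rank_unadjusted=rank_u[cause],
                    rank_adjusted=rank_a[cause],
                    delta=delta,
                    direction="up" if delta > 0 else "down",
                )
            )
    out.sort(key=lambda rc: (-abs(rc.delta), rc.cause_id))
    return out


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------


def write_report(frame: pd.DataFrame, path: str | PathLike) -> None:
    frame.to_csv(path, index=False)


def write_rankings(changes: Sequence[RankingChange], path: str | PathLike) -> None:
    pd.DataFrame(
        [
            (c.cause_id, c.rank_unadjusted, c.rank_adjusted, c.delta, c.direction)
            for c in changes
        ],
        columns=["cause_id", "rank_unadjusted", "rank_adjusted", "delta", "direction"],
    ).to_csv(path, index=False)
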