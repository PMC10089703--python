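"""Exact expectation of the multimorbidity-adjusted YLD rate by enumeration.

For a slice of K independent sequelae with exposure probabilities p_k and
disability weights dw_k, the Monte-Carlo estimator's expectation has a closed
form: sum over all 2^K exposure subsets S of

    P(S) · ADW_k(S),   P(S) = ∏_{j∈S} p_j ∏_{j∉S} (1 − p_j),
    ADW_k(S) = [k ∈ S] · dw_k / Σ_{j∈S} dw_j · (1 − ∏_{j∈S} (1 − dw_j)),

with the all-zero-DW subset contributing zero.  This module enumerates that
sum exactly (plain double precision, no sampling) and serves as the
independent verification oracle for the simulation engine.  Enumeration is
capped at K = 20 and the cap is a hard refusal, never a silent fall-back to
Monte-Carlo: an oracle must not be approximate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "OracleResult",
    "OracleSizeError",
    "MAX_SEQUELAE",
    "exact_adjusted_yld",
    "exact_unadjusted_yld",
    "exact_adw_moments",
]

Slice = list[tuple[str, float, float]]

MAX_SEQUELAE = 20

_CHUNK = 1 << 14  # subsets enumerated per block, bounds peak memory


class OracleSizeError(ValueError):
    """Slice too large for exact 2^K enumeration."""


@dataclass(frozen=True)
class OracleResult:
    """Exact expected adjusted YLD rates per 1,000, and their total."""

    per_sequela: dict[str, float]
    total: float


def _validate(slice_: Slice) -> tuple[list[str], np.ndarray, np.ndarray]:
    k = len(slice_)
    if k > MAX_SEQUELAE:
        raise OracleSizeError(
            f"exact enumeration refused: slice has K={k} sequelae, "
            f"cap is K={MAX_SEQUELAE} (2^K subsets)"
        )
    ids = [s for s, _, _ in slice_]
    p = np.array([pk for _, pk, _ in slice_], dtype=float)
    dw = np.array([dwk for _, _, dwk in slice_], dtype=float)
    for arr, what in ((p, "exposure probability"), (dw, "disability weight")):
        if arr.size and (arr.min() < 0.0 or arr.max() > 1.0):
            raise ValueError(f"{what} outside [0, 1]")
    return ids, p, dw


def _enumerate_moments(p: np.ndarray, dw: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(E[ADW_k], E[ADW_k^2]) per sequela by subset enumeration, chunked."""
    k = p.size
    first = np.zeros(k)
    second = np.zeros(k)
    for start in range(0, 1 << k, _CHUNK):
        masks = np.arange(start, min(start + _CHUNK, 1 << k), dtype=np.int64)
        present = ((masks[:, None] >> np.arange(k)) & 1).astype(bool)
        prob = np.prod(np.where(present, p, 1.0 - p), axis=1)
        weights = present * dw
        total = weights.sum(axis=1)
        combined = 1.0 - np.prod(1.0 - weights, axis=1)
        np.divide(combined, total, out=combined, where=total > 0.0)
        # a single weighted sequela keeps its own DW exactly (ratio is 1)
        combined[(weights > 0.0).sum(axis=1) == 1] = 1.0
        adw = weights * combined[:, None]  # subsets × K
        first += prob @ adw
        second += prob @ (adw * adw)
    return first, second


def exact_adjusted_yld(slice_: Slice) -> OracleResult:
    """Exact expected multimorbidity-adjusted YLD rate per 1,000 per sequela.

    Enumerates all 2^K exposure subsets; refuses slices with more than
    ``MAX_SEQUELAE`` sequelae.  Reordering the slice permutes the output
    identically, and each rate is bounded above by the unadjusted rate.
    """
    ids, p, dw = _validate(slice_)
    if not ids:
        return OracleResult(per_sequela={}, total=0.0)
    first, _ = _enumerate_moments(p, dw)
    rates = 1000.0 * first
    return OracleResult(
        per_sequela=dict(zip(ids, rates.tolist())), total=float(rates.sum())
    )


def exact_unadjusted_yld(slice_: Slice) -> dict[str, float]:
    """Unadjusted prevalence-based YLD rate per 1,000 (prevalence × DW)."""
    ids, p, dw = _validate(slice_)
    return dict(zip(ids, (1000.0 * p * dw).tolist()))


def exact_adw_moments(slice_: Slice) -> dict[str, tuple[float, float]]:
    """Exact per-person (mean, variance) of one simulant's attributed DW.

    The variance divided by the simulant count is the sampling variance of a
    single simulation's per-sequela mean — the yardstick for judging how far
    a Monte-Carlo estimate may stray from ``exact_adjusted_yld``.
    """
    ids, p, dw = _validate(slice_)
    if not ids:
        return {}
    first, second = _enumerate_moments(p, dw)
    var = np.maximum(second - first**2, 0.0)
    return {sid: (float(first[i]), float(var[i])) for i, sid in enumerate(ids)}
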