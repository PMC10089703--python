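"""Monte-Carlo multimorbidity (COMO) correction of prevalence-based YLD rates.

The unadjusted, prevalence-based YLD rate of a sequela is prevalence × DW.
Summing it over the sequelae a person carries overstates total disability:
disability weights are not additive.  The COMO correction instead simulates a
virtual population.  Each simulant is exposed to every sequela of its stratum
independently, with probability equal to the sequela's prevalence.  A simulant
carrying sequelae with weights DW_1..DW_j has combined disability

    DW_combined = 1 − ∏_k (1 − DW_k),

which is then attributed back to the contributing sequelae in proportion to
their own weights,

    ADW_k = DW_k / Σ_j DW_j × DW_combined.

Averaging ADW_k over the whole simulant population (simulants without the
sequela contribute zero) gives the multimorbidity-adjusted YLD rate of
sequela k.  Repeating the simulation many times with fresh random draws gives
a percentile uncertainty interval around each adjusted rate.

One simulant population is shared by all sequelae within a repetition — a
simulant is a person, not a per-sequela draw — which is what makes the
attribution step meaningful.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np

from .registry import Stratum

__all__ = [
    "SimulationConfig",
    "SimulantProfile",
    "StratumResult",
    "combined_dw",
    "attribute_dw",
    "simulate_once",
    "run_stratum",
    "unadjusted_yld",
]

Slice = list[tuple[str, float, float]]  # (sequela_id, p_k, dw_k)


@dataclass(frozen=True)
class SimulationConfig:
    """Simulation sizes and seeding.

    Defaults mirror the published protocol: 40,000 simulants per simulation
    and 1,000 repetitions per stratum for the uncertainty interval.
    """

    n_simulants: int = 40_000
    n_repetitions: int = 1_000
    master_seed: int = 0
    ci_level: float = 0.95

    def __post_init__(self) -> None:
        if self.n_simulants < 1:
            raise ValueError("n_simulants must be >= 1")
        if self.n_repetitions < 1:
            raise ValueError("n_repetitions must be >= 1")
        if not 0.0 < self.ci_level < 1.0:
            raise ValueError("ci_level must be in (0, 1)")


@dataclass(frozen=True)
class SimulantProfile:
    """One virtual person: the sequelae present and the combined DW."""

    present: frozenset[int]
    combined_dw: float


@dataclass
class StratumResult:
    """Adjusted and unadjusted per-sequela YLD rates for one stratum.

    ``per_sequela`` maps sequela_id → (adjusted rate per 1,000, ci_low,
    ci_high); ``rep_means`` retains the per-repetition per-sequela means (in
    per-person DW units, repetitions × sequelae) so that aggregate-level
    uncertainty intervals can be recomputed without rerunning the engine.
    """

    stratum: Stratum
    sequela_ids: list[str]
    per_sequela: dict[str, tuple[float, float, float]]
    unadjusted: dict[str, float]
    rep_means: np.ndarray | None = field(default=None, repr=False)


def _check_unit_interval(values: np.ndarray, what: str) -> None:
    if values.size and (values.min() < 0.0 or values.max() > 1.0):
        raise ValueError(f"{what} outside [0, 1]")


def combined_dw(dws: "list[float] | np.ndarray") -> float:
    """Combined disability weight 1 − ∏(1 − dw_k) of co-occurring sequelae.

    The empty set combines to 0 (full health); the result is order-invariant
    and never exceeds 1.
    """
    arr = np.asarray(dws, dtype=float)
    _check_unit_interval(arr, "disability weight")
    if arr.size == 0:
        return 0.0
    if arr.size == 1:  # mathematically the identity; keep it exact
        return float(arr[0])
    return float(1.0 - np.prod(1.0 - arr))


def attribute_dw(dws: "list[float] | np.ndarray") -> np.ndarray:
    """Split the combined DW across the sequelae present, ∝ their own DWs.

    ADW_k = dw_k / Σ_j dw_j × (1 − ∏_j (1 − dw_j)).  The attributed weights
    sum exactly to the combined DW whenever Σ dw > 0; if every weight is zero
    (or the list is empty) each share is zero, the continuous limit of the
    formula.
    """
    arr = np.asarray(dws, dtype=float)
    _check_unit_interval(arr, "disability weight")
    total = arr.sum()
    if arr.size == 0 or total == 0.0:
        return np.zeros_like(arr)
    if arr.size == 1:  # single sequela keeps its own DW exactly
        return arr.copy()
    return arr / total * combined_dw(arr)


def _simulate_mean_adw(
    p: np.ndarray, dw: np.ndarray, n_simulants: int, rng: np.random.Generator
) -> np.ndarray:
    """Per-sequela mean attributed DW over one simulated population.

    Vectorised over the whole population: ``present`` is the n × K Bernoulli
    exposure matrix; the combined DW of simulant l is 1 − ∏_k (1 − present_lk
    · dw_k), split proportionally over the sequelae present.  The population
    sums are accumulated in extended precision so 40,000-term means are
    order-stable and degenerate populations (every simulant identical) average
    to their exact common value.
    """
    k = p.size
    if k == 0:
        return np.zeros(0)
    present = rng.random((n_simulants, k)) < p
    weights = present * dw
    combined = 1.0 - np.prod(1.0 - weights, axis=1)
    total = weights.sum(axis=1)
    # simulants with no (weighted) sequelae contribute 0 but stay in n
    np.divide(combined, total, out=combined, where=total > 0.0)
    # a single weighted sequela keeps its own DW exactly (ratio is 1)
    combined[(weights > 0.0).sum(axis=1) == 1] = 1.0
    adw = weights * combined[:, None]
    sums = adw.sum(axis=0, dtype=np.longdouble)
    return (sums / n_simulants).astype(np.float64)


def simulate_once(
    slice_: Slice, n_simulants: int, rng: np.random.Generator
) -> dict[str, float]:
    """Run one simulation of ``n_simulants`` people over a stratum slice.

    Each simulant draws an independent Bernoulli(p_k) exposure per sequela;
    the combined DW is attributed back over the present set.  Returns the
    per-sequela mean attributed DW (per-person units); simulants without a
    sequela contribute 0 to its mean but are counted in the denominator.
    Deterministic given the generator state.
    """
    if not slice_:
        return {}
    ids = [s for s, _, _ in slice_]
    p = np.array([pk for _, pk, _ in slice_], dtype=float)
    dw = np.array([dwk for _, _, dwk in slice_], dtype=float)
    _check_unit_interval(p, "exposure probability")
    _check_unit_interval(dw, "disability weight")
    means = _simulate_mean_adw(p, dw, n_simulants, rng)
    return dict(zip(ids, means.tolist()))


def unadjusted_yld(slice_: Slice) -> dict[str, float]:
    """Prevalence-based YLD rate per 1,000: prevalence × DW, no simulation."""
    return {sid: 1000.0 * pk * dwk for sid, pk, dwk in slice_}


def _rep_seed_sequence(
    master_seed: int, stratum: Stratum, repetition: int
) -> np.random.SeedSequence:
    """Stable sub-seed for one (stratum, repetition) cell.

    The stratum identity and repetition index are hashed (SHA-256) into four
    32-bit words appended to the master seed, so results are identical no
    matter in which order — or on how many workers — strata are run.
    """
    key = f"{stratum.sex}|{stratum.age_group}|{stratum.year}|{repetition}"
    digest = hashlib.sha256(key.encode("utf-8")).digest()
    words = [int.from_bytes(digest[i : i + 4], "little") for i in range(0, 16, 4)]
    return np.random.SeedSequence([int(master_seed), *words])


def run_stratum(
    slice_: Slice, config: SimulationConfig, stratum: Stratum
) -> StratumResult:
    """COMO-correct one stratum: repeated simulations plus percentile CIs.

    Runs ``config.n_repetitions`` independent simulations of
    ``config.n_simulants`` simulants each; the adjusted rate per 1,000 of a
    sequela is 1,000 × the mean over repetitions of its per-repetition mean
    attributed DW, and the uncertainty interval is the (1−ci_level)/2 and
    1−(1−ci_level)/2 empirical percentiles of those per-repetition means.
    Each repetition draws from its own sub-seed derived from
    (master_seed, stratum, repetition), so identical inputs give bit-identical
    results regardless of execution order.
    """
    ids = [s for s, _, _ in slice_]
    p = np.array([pk for _, pk, _ in slice_], dtype=float)
    dw = np.array([dwk for _, _, dwk in slice_], dtype=float)
    _check_unit_interval(p, "exposure probability")
    _check_unit_interval(dw, "disability weight")

    rep_means = np.empty((config.n_repetitions, len(ids)))
    for rep in range(config.n_repetitions):
        rng = np.random.default_rng(
            _rep_seed_sequence(config.master_seed, stratum, rep)
        )
        rep_means[rep] = _simulate_mean_adw(p, dw, config.n_simulants, rng)

    alpha = 1.0 - config.ci_level
    if len(ids):
        point = 1000.0 * (
            rep_means.sum(axis=0, dtype=np.longdouble) / config.n_repetitions
        ).astype(np.float64)
        lo, hi = 1000.0 * np.quantile(
            rep_means, [alpha / 2.0, 1.0 - alpha / 2.0], axis=0
        )
    else:
        point = lo = hi = np.zeros(0)
    per_sequela = {
        sid: (float(point[i]), float(lo[i]), float(hi[i]))
        for i, sid in enumerate(ids)
    }
    return StratumResult(
        stratum=stratum,
        sequela_ids=ids,
        per_sequela=per_sequela,
        unadjusted=unadjusted_yld(slice_),
        rep_means=rep_means,
    )
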