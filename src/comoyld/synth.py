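"""Synthetic registry generator with the structure the COMO analysis assumes.

The claims-derived prevalence inputs behind published multimorbidity-adjusted
YLD studies are not public, so this module generates registries that emulate
their *marginal* structure — independent sequela exposure, disability weights
in [0, 1], and per-sequela prevalence rising with age so the multimorbidity
load (expected number of co-occurring sequelae) grows with age.  It makes no
attempt to mimic disease-specific national values.

Disability weights are drawn once per health state from a Beta distribution
(bounded support on [0, 1], right-skewed at the defaults, like empirical DW
sets).  Prevalence in age band b is ``base × gradient^b × noise`` with one
lognormal noise factor per (sequela, sex, year), held constant across bands so
that the expected multimorbidity load is increasing in age by construction.
Generated prevalences are clipped to [0, 1000] per 1,000.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from os import PathLike
from pathlib import Path

import numpy as np

from .registry import (
    AGE_BANDS,
    Cause,
    DiseaseGroup,
    HealthState,
    PrevalenceRecord,
    Registry,
    Sequela,
    Stratum,
    write_registry,
)

__all__ = ["SynthSpec", "generate_registry", "oracle_fixture", "FIXTURE_NAMES"]


@dataclass(frozen=True)
class SynthSpec:
    """Parameters of the synthetic registry.

    ``base_prevalence_per_1000`` applies to the youngest band (5–9 years);
    each successive band multiplies it by ``age_gradient``.  With the defaults
    (60 sequelae, base 2 per 1,000, gradient 1.5 over 9 bands) the expected
    number of co-occurring sequelae rises from ≈0.12 in children to ≈3 in the
    80+ band — a realistic multimorbidity gradient.
    """

    causes_per_group: int = 4
    sequelae_per_cause: int = 3
    dw_shape: tuple[float, float] = (2.0, 8.0)
    base_prevalence_per_1000: float = 2.0
    age_gradient: float = 1.5
    prevalence_noise_sigma: float = 0.5
    sexes: tuple[str, ...] = ("male", "female")
    years: tuple[int, ...] = (2015,)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.causes_per_group < 1:
            raise ValueError("causes_per_group must be >= 1")
        if self.sequelae_per_cause < 1:
            raise ValueError("sequelae_per_cause must be >= 1")
        if self.age_gradient < 1.0:
            raise ValueError("age_gradient must be >= 1")
        if min(self.dw_shape) <= 0.0:
            raise ValueError("dw_shape parameters must be positive")


def generate_registry(
    spec: SynthSpec, out_dir: str | PathLike | None = None
) -> Registry:
    """Generate a registry per ``spec``; optionally write the four CSVs.

    Deterministic given ``spec.seed``: the same spec produces byte-identical
    files.  All five disease groups are populated with
    ``causes_per_group × sequelae_per_cause`` sequelae each, one health state
    per sequela.  When ``out_dir`` is given the registry CSVs plus a
    ``manifest.txt`` recording the spec are written there.
    """
    rng = np.random.default_rng(spec.seed)
    reg = Registry()

    sequela_ids: list[str] = []
    for group in DiseaseGroup:
        tag = group.value.lower()
        for c in range(spec.causes_per_group):
            cause_id = f"{tag}-c{c + 1:02d}"
            reg.causes[cause_id] = Cause(
                cause_id, f"{group.value} cause {c + 1}", group
            )
            for s in range(spec.sequelae_per_cause):
                sid = f"{cause_id}-s{s + 1}"
                hsid = f"hs-{sid}"
                dw = float(rng.beta(*spec.dw_shape))
                reg.health_states[hsid] = HealthState(hsid, dw)
                reg.sequelae[sid] = Sequela(
                    sid, cause_id, hsid, f"sequela {s + 1} of {cause_id}"
                )
                sequela_ids.append(sid)

    for year in spec.years:
        for sex in spec.sexes:
            # one noise factor per sequela, constant across bands: keeps the
            # expected multimorbidity load strictly increasing with age
            noise = np.exp(
                rng.normal(0.0, spec.prevalence_noise_sigma, size=len(sequela_ids))
            )
            for b, band in enumerate(AGE_BANDS):
                stratum = Stratum(sex, band, year)
                rates = np.clip(
                    spec.base_prevalence_per_1000 * spec.age_gradient**b * noise,
                    0.0,
                    1000.0,
                )
                for sid, rate in zip(sequela_ids, rates):
                    reg.prevalence.append(
                        PrevalenceRecord(sid, stratum, float(rate))
                    )

    if out_dir is not None:
        write_registry(reg, out_dir)
        manifest = Path(out_dir) / "manifest.txt"
        lines = [f"{k} = {v}" for k, v in asdict(spec).items()]
        manifest.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return reg


#: Small hand-specified slices with exactly computable adjusted rates.
_FIXTURES: dict[str, list[tuple[str, float, float]]] = {
    # one sequela: adjusted reduces to unadjusted, 30 per 1,000
    "single": [("s1", 0.1, 0.3)],
    # certain co-occurrence of two dw=0.5 sequelae: each gets 0.75/2 = 0.375
    "pair-certain": [("s1", 1.0, 0.5), ("s2", 1.0, 0.5)],
    # four-case enumeration: s1 → 186.667, s2 → 93.333 per 1,000
    "pair-half": [("s1", 0.5, 0.4), ("s2", 0.5, 0.2)],
    "triple": [("s1", 0.2, 0.1), ("s2", 0.5, 0.3), ("s3", 0.8, 0.6)],
    "ten": [
        (f"s{i + 1:02d}", p, d)
        for i, (p, d) in enumerate(
            [
                (0.05, 0.05),
                (0.10, 0.10),
                (0.15, 0.15),
                (0.20, 0.20),
                (0.25, 0.25),
                (0.30, 0.30),
                (0.35, 0.35),
                (0.40, 0.40),
                (0.45, 0.45),
                (0.50, 0.50),
            ]
        )
    ],
}

FIXTURE_NAMES = tuple(sorted(_FIXTURES))


def oracle_fixture(name: str) -> list[tuple[str, float, float]]:
    """Return one of the packaged oracle slices (copies are safe to mutate).

    Available fixtures: ``single`` (1 sequela), ``pair-certain`` and
    ``pair-half`` (2), ``triple`` (3) and ``ten`` (10) — sized so the exact
    enumeration oracle can verify the engine on each.
    """
    try:
        return list(_FIXTURES[name])
    except KeyError:
        raise KeyError(
            f"unknown fixture {name!r}; available: {', '.join(FIXTURE_NAMES)}"
        ) from None
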