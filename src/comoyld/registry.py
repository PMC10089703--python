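"""Domain data model and CSV registries for the cause–sequela–health-state hierarchy.

The burden-of-disease input data are organised as four flat tables:

* ``health_states.csv`` — health states carrying disability weights (DW),
* ``causes.csv`` — causes (diseases) labelled with one of five disease groups,
* ``sequelae.csv`` — sequelae linking a cause to the health state whose DW it
  contributes,
* ``prevalence.csv`` — per-stratum (sex × age band × year) sequela prevalence
  per 1,000 population.

Prevalence is stored per 1,000 population, matching published burden-of-disease
tables, and converted to a per-person probability only when a stratum slice is
handed to the simulation engine.  A missing (sequela, stratum) prevalence row
means prevalence zero, not an error: sparse registries are the norm (e.g.
maternal conditions absent in males).  Identifiers are case-sensitive opaque
strings.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from os import PathLike
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "AGE_BANDS",
    "SEXES",
    "DiseaseGroup",
    "HealthState",
    "Cause",
    "Sequela",
    "Stratum",
    "PrevalenceRecord",
    "Registry",
    "RegistryValidationError",
    "load_registry",
    "write_registry",
    "validate_registry",
    "stratum_slice",
]

#: The nine analysis age bands; ages 0–4 are excluded by construction.
AGE_BANDS: tuple[str, ...] = (
    "5-9",
    "10-19",
    "20-29",
    "30-39",
    "40-49",
    "50-59",
    "60-69",
    "70-79",
    "80+",
)

SEXES: tuple[str, ...] = ("male", "female")


class DiseaseGroup(enum.Enum):
    """The five disease groups used to categorise causes."""

    NCDS = "NCDs"
    CDS = "CDs"
    INJURIES = "Injuries"
    MNNS = "MNNs"
    MDS = "MDs"

    @classmethod
    def from_label(cls, label: str) -> "DiseaseGroup":
        for member in cls:
            if member.value == label:
                return member
        raise ValueError(
            f"unknown disease group {label!r}; expected one of "
            f"{[m.value for m in cls]}"
        )


@dataclass(frozen=True)
class HealthState:
    """A health state with its disability weight, 0 ≤ dw ≤ 1."""

    health_state_id: str
    dw: float


@dataclass(frozen=True)
class Cause:
    cause_id: str
    name: str
    group: DiseaseGroup


@dataclass(frozen=True)
class Sequela:
    """A consequence of a cause, mapped to the health state carrying its DW."""

    sequela_id: str
    cause_id: str
    health_state_id: str
    name: str


@dataclass(frozen=True, order=True)
class Stratum:
    """One sex × age-band × year cell of the analysis."""

    sex: str
    age_group: str
    year: int

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}, got {self.sex!r}")
        if self.age_group not in AGE_BANDS:
            raise ValueError(
                f"age_group must be one of {AGE_BANDS}, got {self.age_group!r}"
            )

    def label(self) -> str:
        return f"{self.sex}/{self.age_group}/{self.year}"


@dataclass(frozen=True)
class PrevalenceRecord:
    """Sequela prevalence per 1,000 population within one stratum."""

    sequela_id: str
    stratum: Stratum
    prevalence_per_1000: float


@dataclass
class Registry:
    """A validated collection of health states, causes, sequelae and prevalence."""

    health_states: dict[str, HealthState] = field(default_factory=dict)
    causes: dict[str, Cause] = field(default_factory=dict)
    sequelae: dict[str, Sequela] = field(default_factory=dict)
    prevalence: list[PrevalenceRecord] = field(default_factory=list)

    def strata(self) -> list[Stratum]:
        """All strata appearing in the prevalence table, sorted."""
        return sorted({rec.stratum for rec in self.prevalence})


class RegistryValidationError(ValueError):
    """Raised when a registry fails integrity checks; carries every violation."""

    def __init__(self, violations: list[str]):
        self.violations = list(violations)
        joined = "\n  - ".join(self.violations)
        super().__init__(f"registry validation failed:\n  - {joined}")


# ---------------------------------------------------------------------------
# Loading / writing
# ---------------------------------------------------------------------------

_REQUIRED_COLUMNS: Mapping[str, tuple[str, ...]] = {
    "health_states": ("health_state_id", "dw"),
    "causes": ("cause_id", "name", "group"),
    "sequelae": ("sequela_id", "cause_id", "health_state_id", "name"),
    "prevalence": ("sequela_id", "sex", "age_group", "year", "prevalence_per_1000"),
}


def _read_table(path: Path, table: str, violations: list[str]) -> pd.DataFrame | None:
    if not path.exists():
        violations.append(f"{table}: file {path} does not exist")
        return None
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in _REQUIRED_COLUMNS[table] if c not in df.columns]
    if missing:
        violations.append(f"{table}: missing column(s) {missing} in {path}")
        return None
    return df


def _parse_float(
    raw: str, table: str, row: int, col: str, violations: list[str]
) -> float | None:
    try:
        return float(raw)
    except ValueError:
        violations.append(f"{table} row {row}: {col}={raw!r} is not numeric")
        return None


def load_registry(paths: Mapping[str, str | PathLike] | str | PathLike) -> Registry:
    """Load and validate the four registry CSVs.

    Parameters
    ----------
    paths
        Either a directory containing ``health_states.csv``, ``causes.csv``,
        ``sequelae.csv`` and ``prevalence.csv``, or a mapping from those table
        names (without extension) to file paths.

    Returns
    -------
    Registry
        A fully validated registry.

    Raises
    ------
    RegistryValidationError
        If any file is missing a required column, any reference fails to
        resolve, or any numeric field is out of range.  Every violation found
        is collected and reported; loading never fails on only the first.
    """
    if isinstance(paths, (str, PathLike)):
        root = Path(paths)
        paths = {name: root / f"{name}.csv" for name in _REQUIRED_COLUMNS}
    violations: list[str] = []
    tables = {
        name: _read_table(Path(paths[name]), name, violations)
        for name in _REQUIRED_COLUMNS
    }
    reg = Registry()

    hs = tables["health_states"]
    if hs is not None:
        for i, row in hs.iterrows():
            dw = _parse_float(row["dw"], "health_states", i, "dw", violations)
            if dw is None:
                continue
            if not 0.0 <= dw <= 1.0:
                violations.append(
                    f"health_states row {i}: dw={dw} outside [0, 1] "
                    f"for {row['health_state_id']!r}"
                )
                continue
            hsid = row["health_state_id"]
            if hsid in reg.health_states:
                violations.append(f"health_states row {i}: duplicate id {hsid!r}")
                continue
            reg.health_states[hsid] = HealthState(hsid, dw)

    causes = tables["causes"]
    if causes is not None:
        for i, row in causes.iterrows():
            try:
                group = DiseaseGroup.from_label(row["group"])
            except ValueError as exc:
                violations.append(f"causes row {i}: {exc}")
                continue
            cid = row["cause_id"]
            if cid in reg.causes:
                violations.append(f"causes row {i}: duplicate cause_id {cid!r}")
                continue
            reg.causes[cid] = Cause(cid, row["name"], group)

    seq = tables["sequelae"]
    if seq is not None:
        for i, row in seq.iterrows():
            sid = row["sequela_id"]
            if sid in reg.sequelae:
                violations.append(f"sequelae row {i}: duplicate sequela_id {sid!r}")
                continue
            if row["cause_id"] not in reg.causes:
                violations.append(
                    f"sequelae row {i}: unresolvable cause_id {row['cause_id']!r}"
                )
                continue
            if row["health_state_id"] not in reg.health_states:
                violations.append(
                    f"sequelae row {i}: unresolvable health_state_id "
                    f"{row['health_state_id']!r}"
                )
                continue
            reg.sequelae[sid] = Sequela(
                sid, row["cause_id"], row["health_state_id"], row["name"]
            )

    prev = tables["prevalence"]
    if prev is not None:
        seen: set[tuple[str, Stratum]] = set()
        for i, row in prev.iterrows():
            sid = row["sequela_id"]
            if sid not in reg.sequelae:
                violations.append(
                    f"prevalence row {i}: unresolvable sequela_id {sid!r}"
                )
                continue
            try:
                stratum = Stratum(row["sex"], row["age_group"], int(row["year"]))
            except ValueError as exc:
                violations.append(f"prevalence row {i}: {exc}")
                continue
            rate = _parse_float(
                row["prevalence_per_1000"], "prevalence", i,
                "prevalence_per_1000", violations,
            )
            if rate is None:
                continue
            if not 0.0 <= rate <= 1000.0:
                violations.append(
                    f"prevalence row {i}: prevalence_per_1000={rate} "
                    f"outside [0, 1000] for {sid!r}"
                )
                continue
            key = (sid, stratum)
            if key in seen:
                violations.append(
                    f"prevalence row {i}: duplicate record for "
                    f"({sid!r}, {stratum.label()})"
                )
                continue
            seen.add(key)
            reg.prevalence.append(PrevalenceRecord(sid, stratum, rate))

    if violations:
        raise RegistryValidationError(violations)
    return reg


def write_registry(reg: Registry, out_dir: str | PathLike) -> dict[str, Path]:
    """Write the four registry CSVs to ``out_dir``; returns the paths written.

    Numeric fields are written with ``repr`` so a load/write round trip
    reproduces every value to full double precision.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    def _dump(name: str, frame: pd.DataFrame) -> None:
        path = out / f"{name}.csv"
        frame.to_csv(path, index=False)
        paths[name] = path

    _dump(
        "health_states",
        pd.DataFrame(
            [(h.health_state_id, repr(h.dw)) for h in reg.health_states.values()],
            columns=["health_state_id", "dw"],
        ),
    )
    _dump(
        "causes",
        pd.DataFrame(
            [(c.cause_id, c.name, c.group.value) for c in reg.causes.values()],
            columns=["cause_id", "name", "group"],
        ),
    )
    _dump(
        "sequelae",
        pd.DataFrame(
            [
                (s.sequela_id, s.cause_id, s.health_state_id, s.name)
                for s in reg.sequelae.values()
            ],
            columns=["sequela_id", "cause_id", "health_state_id", "name"],
        ),
    )
    _dump(
        "prevalence",
        pd.DataFrame(
            [
                (
                    r.sequela_id,
                    r.stratum.sex,
                    r.stratum.age_group,
                    r.stratum.year,
                    repr(r.prevalence_per_1000),
                )
                for r in reg.prevalence
            ],
            columns=["sequela_id", "sex", "age_group", "year", "prevalence_per_1000"],
        ),
    )
    return paths


# ---------------------------------------------------------------------------
# Validation and slicing
# ---------------------------------------------------------------------------


def validate_registry(reg: Registry) -> list[str]:
    """Check every registry invariant; return a description of each violation.

    Returns an empty list iff the registry is internally consistent: unique
    identifiers, resolvable references, DWs in [0, 1], prevalences in
    [0, 1000], and at most one prevalence record per (sequela, stratum).
    Validation reports; it never raises.
    """
    violations: list[str] = []
    for hsid, hs in reg.health_states.items():
        if hsid != hs.health_state_id:
            violations.append(f"health state key {hsid!r} != id {hs.health_state_id!r}")
        if not 0.0 <= hs.dw <= 1.0:
            violations.append(f"health state {hsid!r}: dw={hs.dw} outside [0, 1]")
    for cid, cause in reg.causes.items():
        if cid != cause.cause_id:
            violations.append(f"cause key {cid!r} != id {cause.cause_id!r}")
        if not isinstance(cause.group, DiseaseGroup):
            violations.append(f"cause {cid!r}: group {cause.group!r} not a DiseaseGroup")
    for sid, seq in reg.sequelae.items():
        if sid != seq.sequela_id:
            violations.append(f"sequela key {sid!r} != id {seq.sequela_id!r}")
        if seq.cause_id not in reg.causes:
            violations.append(f"sequela {sid!r}: unresolvable cause_id {seq.cause_id!r}")
        if seq.health_state_id not in reg.health_states:
            violations.append(
                f"sequela {sid!r}: unresolvable health_state_id "
                f"{seq.health_state_id!r}"
            )
    seen: set[tuple[str, Stratum]] = set()
    for rec in reg.prevalence:
        if rec.sequela_id not in reg.sequelae:
            violations.append(
                f"prevalence record: unresolvable sequela_id {rec.sequela_id!r}"
            )
        if not 0.0 <= rec.prevalence_per_1000 <= 1000.0:
            violations.append(
                f"prevalence record ({rec.sequela_id!r}, {rec.stratum.label()}): "
                f"prevalence_per_1000={rec.prevalence_per_1000} outside [0, 1000]"
            )
        key = (rec.sequela_id, rec.stratum)
        if key in seen:
            violations.append(
                f"duplicate prevalence record for ({rec.sequela_id!r}, "
                f"{rec.stratum.label()})"
            )
        seen.add(key)
    return violations


def stratum_slice(
    reg: Registry, stratum: Stratum
) -> list[tuple[str, float, float]]:
    """Extract the ``(sequela_id, p_k, dw_k)`` triples for one stratum.

    ``p_k`` is the per-person exposure probability, prevalence_per_1000 / 1000.
    Sequelae with no prevalence record in the stratum are omitted (treated as
    p = 0); an entirely absent stratum yields an empty list.  Output is sorted
    by sequela_id, so the slice is a pure, deterministic function of
    (registry, stratum).
    """
    rows = []
    for rec in reg.prevalence:
        if rec.stratum != stratum:
            continue
        seq = reg.sequelae[rec.sequela_id]
        dw = reg.health_states[seq.health_state_id].dw
        rows.append((rec.sequela_id, rec.prevalence_per_1000 / 1000.0, dw))
    rows.sort(key=lambda t: t[0])
    return rows


def sequela_groups(reg: Registry) -> dict[str, tuple[str, str]]:
    """Map sequela_id → (cause_id, disease-group label) for aggregation."""
    out = {}
    for sid, seq in reg.sequelae.items():
        cause = reg.causes[seq.cause_id]
        out[sid] = (cause.cause_id, cause.group.value)
    return out


def iter_slices(
    reg: Registry, strata: Iterable[Stratum] | None = None
):
    """Yield (stratum, slice) pairs for each requested (default: all) stratum."""
    for stratum in strata if strata is not None else reg.strata():
        yield stratum, stratum_slice(reg, stratum)
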