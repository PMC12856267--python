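"""SF-36 domain scores to EQ-5D utilities.

When direct EQ-5D data are unavailable, a published linear regression
algorithm maps the eight SF-36 domain scores (each 0-100) onto the EQ-5D
utility scale (0 = dead, 1 = full health; UK tariff allows values down to
-0.594).  The mapping is a fixed affine function

    utility = intercept + sum_d slope_d * score_d

whose coefficients ship as a versioned data file.  The mapping is applied
per patient-visit; utilities are then assembled into per-patient
longitudinal series for QALY estimation.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

#: Canonical domain order: physical functioning, role physical, bodily pain,
#: general health, vitality, social functioning, role emotional, mental health.
SF36_DOMAINS = ("pf", "rp", "bp", "gh", "vt", "sf", "re", "mh")

#: EQ-5D UK tariff bounds, used only when clamping is requested.
EQ5D_BOUNDS = (-0.594, 1.0)


class DomainScoreError(ValueError):
    """An SF-36 domain score is outside the legal 0-100 range."""


@dataclass(frozen=True)
class SF36Visit:
    """One patient-visit: eight SF-36 domain scores plus timing.

    Domain attributes use the conventional two-letter abbreviations:
    pf physical functioning, rp role physical, bp bodily pain,
    gh general health, vt vitality, sf social functioning,
    re role emotional, mh mental health.
    """

    patient_id: str
    month: float
    pf: float
    rp: float
    bp: float
    gh: float
    vt: float
    sf: float
    re: float
    mh: float

    def __post_init__(self) -> None:
        if self.month < 0:
            raise ValueError(f"month must be non-negative, got {self.month}")
        for domain in SF36_DOMAINS:
            score = getattr(self, domain)
            if not 0.0 <= score <= 100.0:
                raise DomainScoreError(
                    f"domain {domain!r} score {score} outside [0, 100] "
                    f"for patient {self.patient_id!r} at month {self.month}"
                )

    def scores(self) -> dict[str, float]:
        return {d: getattr(self, d) for d in SF36_DOMAINS}


@dataclass(frozen=True)
class MappingCoefficients:
    """Intercept and per-domain slopes of the SF-36 -> EQ-5D mapping."""

    intercept: float
    slopes: Mapping[str, float]
    name: str = "sf36-to-eq5d-linear"

    def __post_init__(self) -> None:
        missing = set(SF36_DOMAINS) - set(self.slopes)
        extra = set(self.slopes) - set(SF36_DOMAINS)
        if missing or extra:
            raise ValueError(
                f"slopes must cover exactly the eight SF-36 domains; "
                f"missing={sorted(missing)}, unexpected={sorted(extra)}"
            )

    @classmethod
    def default(cls) -> "MappingCoefficients":
        """The published mapping coefficients bundled with the package."""
        ref = importlib.resources.files("masld_cua.data") / "sf36_to_eq5d.yaml"
        return cls.from_yaml(ref.read_text())

    @classmethod
    def from_yaml(cls, text: str) -> "MappingCoefficients":
        raw = yaml.safe_load(text)
        return cls(
            intercept=float(raw["intercept"]),
            slopes={k: float(v) for k, v in raw["slopes"].items()},
            name=str(raw.get("name", "custom")),
        )

    @classmethod
    def from_file(cls, path: str | Path) -> "MappingCoefficients":
        return cls.from_yaml(Path(path).read_text())


@dataclass(frozen=True)
class UtilitySeries:
    """Per-patient longitudinal EQ-5D utilities, ordered by month."""

    patient_id: str
    months: tuple[float, ...]
    utilities: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.months) != len(self.utilities):
            raise ValueError("months and utilities must have equal length")
        if any(b <= a for a, b in zip(self.months, self.months[1:])):
            raise ValueError(
                f"months must be strictly increasing for patient "
                f"{self.patient_id!r}: {self.months}"
            )

    def __len__(self) -> int:
        return len(self.months)


def map_sf36_to_eq5d(
    visit: SF36Visit,
    coeffs: MappingCoefficients | None = None,
    clamp: bool = False,
) -> float:
    """Map one SF-36 visit to an EQ-5D utility.

    Parameters
    ----------
    visit
        Validated SF-36 domain scores.
    coeffs
        Mapping coefficients; defaults to the bundled published algorithm.
    clamp
        If true, truncate the result to the EQ-5D UK tariff bounds
        [-0.594, 1.0].  Off by default: the linear mapping can exceed 1
        for respondents near the SF-36 ceiling, and truncation is a
        reporting choice, not part of the algorithm.
    """
    if coeffs is None:
        coeffs = MappingCoefficients.default()
    utility = coeffs.intercept + sum(
        coeffs.slopes[d] * getattr(visit, d) for d in SF36_DOMAINS
    )
    if clamp:
        lo, hi = EQ5D_BOUNDS
        utility = min(max(utility, lo), hi)
    return utility


def build_utility_series(
    visits: Iterable[SF36Visit],
    coeffs: MappingCoefficients | None = None,
    clamp: bool = False,
) -> list[UtilitySeries]:
    """Map a collection of visits and assemble per-patient utility series.

    Returns one :class:`UtilitySeries` per patient, sorted by month within
    a patient and by patient id across patients.  Duplicate
    (patient, month) pairs are rejected.
    """
    visits = list(visits)
    if not visits:
        raise ValueError("visits collection is empty")
    if coeffs is None:
        coeffs = MappingCoefficients.default()

    seen: dict[tuple[str, float], int] = {}
    duplicates = []
    for v in visits:
        key = (v.patient_id, v.month)
        seen[key] = seen.get(key, 0) + 1
        if seen[key] == 2:
            duplicates.append(key)
    if duplicates:
        raise ValueError(f"duplicate (patient, month) visits: {sorted(duplicates)}")

    by_patient: dict[str, list[tuple[float, float]]] = {}
    for v in visits:
        u = map_sf36_to_eq5d(v, coeffs, clamp=clamp)
        by_patient.setdefault(v.patient_id, []).append((v.month, u))

    series = []
    for pid in sorted(by_patient):
        pts = sorted(by_patient[pid])
        series.append(
            UtilitySeries(
                patient_id=pid,
                months=tuple(m for m, _ in pts),
                utilities=tuple(u for _, u in pts),
            )
        )
    return series


# ---------------------------------------------------------------------------
# Tabular I/O

SF36_CSV_COLUMNS = ("patient_id", "month") + SF36_DOMAINS


def visits_to_frame(visits: Sequence[SF36Visit]) -> pd.DataFrame:
    rows = [
        {"patient_id": v.patient_id, "month": v.month, **v.scores()} for v in visits
    ]
    return pd.DataFrame(rows, columns=list(SF36_CSV_COLUMNS))


def frame_to_visits(frame: pd.DataFrame) -> list[SF36Visit]:
    missing = set(SF36_CSV_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"SF-36 table missing columns: {sorted(missing)}")
    return [
        SF36Visit(
            patient_id=str(row.patient_id),
            month=float(row.month),
            **{d: float(getattr(row, d)) for d in SF36_DOMAINS},
        )
        for row in frame.itertuples(index=False)
    ]


def read_sf36_csv(path: str | Path) -> list[SF36Visit]:
    """Read an sf36_visits.csv table (patient_id, month, eight domains)."""
    return frame_to_visits(pd.read_csv(path))


def series_to_frame(series: Sequence[UtilitySeries]) -> pd.DataFrame:
    rows = [
        {"patient_id": s.patient_id, "month": m, "utility": u}
        for s in series
        for m, u in zip(s.months, s.utilities)
    ]
    return pd.DataFrame(rows, columns=["patient_id", "month", "utility"])
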