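"""Species-level dental traits from per-tooth maxillary measurement tables.

A :class:`ToothRow` is one maxilla's worth of measurements from a single
specimen: an ordered list of tooth positions (1 = anterior-most), each
present (and measured, if ankylosed to the bone) or inferred missing from
its empty socket, plus grooving measurements taken at 5 equidistant
semilandmarks along each grooved tooth.  Replacement (non-ankylosed) teeth
are excluded from the table entirely.

The headline derived statistic is the relative posterior tooth length
(RPTL): many rear-fanged snakes show a background anterior-to-posterior
increase in tooth size, so fang enlargement is quantified as the median
residual of the three posterior-most teeth from an ordinary least-squares
line of tooth length on position fitted to all the other teeth.
"""

from __future__ import annotations

import math
import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Tooth",
    "ToothRow",
    "DentalTraitSet",
    "UndefinedTraitError",
    "relative_posterior_tooth_length",
    "derive_dental_traits",
    "log_transform_counts",
    "aggregate_specimens",
    "read_tooth_table",
    "write_tooth_table",
    "trait_table",
]

N_SEMILANDMARKS = 5


class UndefinedTraitError(ValueError):
    """A derived trait is undefined for the given tooth row."""


@dataclass
class Tooth:
    """One maxillary tooth position.

    ``length_mm`` is measured from the ankylosis base to the apical tip
    and is present only for teeth that are both present and ankylosed;
    a record with ``present=False`` is a socket-inferred missing tooth.
    """

    position: int
    present: bool = True
    ankylosed: bool = True
    length_mm: float | None = None
    grooved: bool = False
    groove_length_mm: float | None = None
    tooth_width_mm: tuple[float, ...] | None = None
    groove_width_mm: tuple[float, ...] | None = None
    tooth_depth_mm: tuple[float, ...] | None = None
    groove_depth_mm: tuple[float, ...] | None = None

    @property
    def measurable(self) -> bool:
        return self.present and self.ankylosed and self.length_mm is not None

    def validate(self) -> None:
        if self.present and self.ankylosed and self.length_mm is not None:
            if self.length_mm <= 0:
                raise ValueError(
                    f"tooth at position {self.position}: non-positive length"
                )
        if self.length_mm is not None and not (self.present and self.ankylosed):
            raise ValueError(
                f"tooth at position {self.position}: length recorded for a "
                "missing or non-ankylosed tooth"
            )
        if self.grooved and not self.present:
            raise ValueError(
                f"tooth at position {self.position}: grooved but not present"
            )
        for name in ("tooth_width_mm", "groove_width_mm", "tooth_depth_mm", "groove_depth_mm"):
            v = getattr(self, name)
            if v is not None and len(v) != N_SEMILANDMARKS:
                raise ValueError(
                    f"tooth at position {self.position}: {name} needs "
                    f"{N_SEMILANDMARKS} semilandmark values"
                )


@dataclass
class ToothRow:
    """Per-tooth measurements for one specimen's maxilla."""

    species: str
    specimen_id: str
    cranium_length_mm: float
    maxilla_length_mm: float
    teeth: list[Tooth] = field(default_factory=list)
    n_palatine_teeth: int | None = None
    n_pterygoid_teeth: int | None = None
    n_dentary_teeth: int | None = None

    def __post_init__(self) -> None:
        positions = [t.position for t in self.teeth]
        if any(b <= a for a, b in zip(positions, positions[1:])):
            raise ValueError(
                f"{self.species}/{self.specimen_id}: tooth positions must be "
                "strictly increasing"
            )
        for t in self.teeth:
            t.validate()


@dataclass
class DentalTraitSet:
    """Species-level dental traits."""

    species: str
    n_maxillary_teeth: int
    log_n_maxillary_teeth: float
    maxilla_length_mm: float
    largest_tooth_position: int
    fang_size_mm: float
    mean_groove_width_mm: float | None
    has_grooves: bool
    rptl_mm: float | None
    cranium_length_mm: float
    n_palatine_teeth: int | None = None
    n_pterygoid_teeth: int | None = None
    n_dentary_teeth: int | None = None

    def to_dict(self) -> dict:
        return {
            "species": self.species,
            "n_maxillary_teeth": self.n_maxillary_teeth,
            "log_n_maxillary_teeth": self.log_n_maxillary_teeth,
            "maxilla_length_mm": self.maxilla_length_mm,
            "largest_tooth_position": self.largest_tooth_position,
            "fang_size_mm": self.fang_size_mm,
            "mean_groove_width_mm": self.mean_groove_width_mm,
            "has_grooves": self.has_grooves,
            "rptl_mm": self.rptl_mm,
            "cranium_length_mm": self.cranium_length_mm,
            "n_palatine_teeth": self.n_palatine_teeth,
            "n_pterygoid_teeth": self.n_pterygoid_teeth,
            "n_dentary_teeth": self.n_dentary_teeth,
        }


def relative_posterior_tooth_length(row: ToothRow) -> float:
    """Relative posterior tooth length (RPTL) of one maxilla.

    Fits an OLS line of tooth length on position using all measurable
    teeth except the three posterior-most tooth positions (positions count
    socket-inferred missing teeth), predicts the posterior teeth from the
    line, and returns the median of (actual - predicted) over the
    measurable posterior teeth.  Positive values mean posterior
    enlargement (a rear fang); negative values mean reduction.
    """
    if not row.teeth:
        raise UndefinedTraitError(f"{row.species}: empty tooth row")
    posterior = row.teeth[-3:]
    anterior = row.teeth[:-3]
    ant = [(t.position, t.length_mm) for t in anterior if t.measurable]
    post = [(t.position, t.length_mm) for t in posterior if t.measurable]
    if len(ant) < 2:
        raise UndefinedTraitError(
            f"{row.species}: fewer than 2 measurable anterior teeth; RPTL undefined"
        )
    if not post:
        raise UndefinedTraitError(
            f"{row.species}: no measurable posterior teeth; RPTL undefined"
        )
    px = np.array([p for p, _ in ant], dtype=float)
    py = np.array([l for _, l in ant], dtype=float)
    slope, intercept = np.polyfit(px, py, 1)
    resid = [l - (slope * p + intercept) for p, l in post]
    return float(np.median(resid))


def derive_dental_traits(row: ToothRow) -> DentalTraitSet:
    """Species-level trait set from one specimen's tooth row.

    Tooth count includes socket-inferred missing teeth.  Fang size is the
    longest measurable tooth; its position is the ordinal position
    (counting missing-socket positions), ties resolved toward the most
    posterior position.  Groove width per tooth is the mean over the 5
    semilandmarks, averaged over grooved teeth.
    """
    if not row.teeth:
        raise ValueError(f"{row.species}: empty tooth row")
    n_teeth = len(row.teeth)
    measurable = [t for t in row.teeth if t.measurable]
    if not measurable:
        raise UndefinedTraitError(f"{row.species}: no measurable teeth")
    max_len = max(t.length_mm for t in measurable)
    ties = [t.position for t in measurable if t.length_mm == max_len]
    if len(ties) > 1:
        warnings.warn(
            f"{row.species}: tie for largest tooth at positions {ties}; "
            "using most posterior"
        )
    largest_pos = max(ties)
    grooved = [t for t in row.teeth if t.grooved]
    groove_width = None
    widths = [
        float(np.mean(t.groove_width_mm))
        for t in grooved
        if t.groove_width_mm is not None
    ]
    if widths:
        groove_width = float(np.mean(widths))
    try:
        rptl = relative_posterior_tooth_length(row)
    except UndefinedTraitError as err:
        warnings.warn(str(err))
        rptl = None
    return DentalTraitSet(
        species=row.species,
        n_maxillary_teeth=n_teeth,
        log_n_maxillary_teeth=math.log(n_teeth),
        maxilla_length_mm=row.maxilla_length_mm,
        largest_tooth_position=largest_pos,
        fang_size_mm=float(max_len),
        mean_groove_width_mm=groove_width,
        has_grooves=bool(grooved),
        rptl_mm=rptl,
        cranium_length_mm=row.cranium_length_mm,
        n_palatine_teeth=row.n_palatine_teeth,
        n_pterygoid_teeth=row.n_pterygoid_teeth,
        n_dentary_teeth=row.n_dentary_teeth,
    )


def log_transform_counts(counts) -> np.ndarray:
    """Natural log of per-species tooth counts (counts must be >= 1)."""
    arr = np.asarray(counts, dtype=float)
    if np.any(arr < 1):
        raise ValueError(
            "tooth counts must be >= 1 for log transform; zero-tooth species "
            "must be handled upstream"
        )
    return np.log(arr)


def _mode_largest(values) -> object:
    """Most common value; ties resolved toward the larger value."""
    counts = Counter(values)
    top = max(counts.values())
    return max(v for v, c in counts.items() if c == top)


def aggregate_specimens(rows: list[ToothRow]) -> DentalTraitSet:
    """Combine specimens of one species into a composite trait set.

    Continuous traits are averaged over the specimens for which they are
    defined; counts, ordinal positions and flags take the mode (ties
    toward the larger value).
    """
    if not rows:
        raise ValueError("need at least one specimen")
    species = {r.species for r in rows}
    if len(species) > 1:
        raise ValueError(f"mixed species labels: {sorted(species)}")
    per = [derive_dental_traits(r) for r in rows]

    def mean_defined(vals):
        vals = [v for v in vals if v is not None]
        return float(np.mean(vals)) if vals else None

    n_teeth = int(_mode_largest([p.n_maxillary_teeth for p in per]))
    groove_width = mean_defined([p.mean_groove_width_mm for p in per])
    opt_counts = {}
    for name in ("n_palatine_teeth", "n_pterygoid_teeth", "n_dentary_teeth"):
        vals = [getattr(p, name) for p in per if getattr(p, name) is not None]
        opt_counts[name] = int(_mode_largest(vals)) if vals else None
    return DentalTraitSet(
        species=per[0].species,
        n_maxillary_teeth=n_teeth,
        log_n_maxillary_teeth=math.log(n_teeth),
        maxilla_length_mm=mean_defined([p.maxilla_length_mm for p in per]),
        largest_tooth_position=int(_mode_largest([p.largest_tooth_position for p in per])),
        fang_size_mm=mean_defined([p.fang_size_mm for p in per]),
        mean_groove_width_mm=groove_width,
        has_grooves=bool(_mode_largest([p.has_grooves for p in per])),
        rptl_mm=mean_defined([p.rptl_mm for p in per]),
        cranium_length_mm=mean_defined([p.cranium_length_mm for p in per]),
        **opt_counts,
    )


# ---------------------------------------------------------------------------
# CSV schema
# ---------------------------------------------------------------------------

_SEMI_COLS = [
    f"{base}_{i}"
    for base in ("tooth_width_mm", "groove_width_mm", "tooth_depth_mm", "groove_depth_mm")
    for i in range(1, N_SEMILANDMARKS + 1)
]

TOOTH_TABLE_COLUMNS = [
    "species",
    "specimen_id",
    "cranium_length_mm",
    "maxilla_length_mm",
    "n_palatine_teeth",
    "n_pterygoid_teeth",
    "n_dentary_teeth",
    "position",
    "present",
    "ankylosed",
    "length_mm",
    "grooved",
    "groove_length_mm",
    *_SEMI_COLS,
]


def write_tooth_table(rows: list[ToothRow], path) -> None:
    """Write tooth rows to CSV, one line per tooth position."""
    records = []
    for row in rows:
        for t in row.teeth:
            rec = {
                "species": row.species,
                "specimen_id": row.specimen_id,
                "cranium_length_mm": row.cranium_length_mm,
                "maxilla_length_mm": row.maxilla_length_mm,
                "n_palatine_teeth": row.n_palatine_teeth,
                "n_pterygoid_teeth": row.n_pterygoid_teeth,
                "n_dentary_teeth": row.n_dentary_teeth,
                "position": t.position,
                "present": int(t.present),
                "ankylosed": int(t.ankylosed),
                "length_mm": t.length_mm,
                "grooved": int(t.grooved),
                "groove_length_mm": t.groove_length_mm,
            }
            for base in ("tooth_width_mm", "groove_width_mm", "tooth_depth_mm", "groove_depth_mm"):
                vals = getattr(t, base)
                for i in range(N_SEMILANDMARKS):
                    rec[f"{base}_{i + 1}"] = vals[i] if vals is not None else None
            records.append(rec)
    pd.DataFrame.from_records(records, columns=TOOTH_TABLE_COLUMNS).to_csv(
        path, index=False
    )


def read_tooth_table(path) -> list[ToothRow]:
    """Read and validate a per-tooth CSV into ToothRow objects."""
    df = pd.read_csv(path)
    missing = [c for c in TOOTH_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"tooth table missing columns: {', '.join(missing)}")
    rows: list[ToothRow] = []
    for (species, spec_id), grp in df.groupby(["species", "specimen_id"], sort=True):
        teeth = []
        for _, r in grp.sort_values("position").iterrows():
            def semi(base):
                vals = [r[f"{base}_{i + 1}"] for i in range(N_SEMILANDMARKS)]
                if all(pd.isna(v) for v in vals):
                    return None
                return tuple(float(v) for v in vals)

            teeth.append(
                Tooth(
                    position=int(r["position"]),
                    present=bool(r["present"]),
                    ankylosed=bool(r["ankylosed"]),
                    length_mm=None if pd.isna(r["length_mm"]) else float(r["length_mm"]),
                    grooved=bool(r["grooved"]),
                    groove_length_mm=None
                    if pd.isna(r["groove_length_mm"])
                    else float(r["groove_length_mm"]),
                    tooth_width_mm=semi("tooth_width_mm"),
                    groove_width_mm=semi("groove_width_mm"),
                    tooth_depth_mm=semi("tooth_depth_mm"),
                    groove_depth_mm=semi("groove_depth_mm"),
                )
            )
        first = grp.iloc[0]

        def opt_int(col):
            return None if pd.isna(first[col]) else int(first[col])

        rows.append(
            ToothRow(
                species=str(species),
                specimen_id=str(spec_id),
                cranium_length_mm=float(first["cranium_length_mm"]),
                maxilla_length_mm=float(first["maxilla_length_mm"]),
                teeth=teeth,
                n_palatine_teeth=opt_int("n_palatine_teeth"),
                n_pterygoid_teeth=opt_int("n_pterygoid_teeth"),
                n_dentary_teeth=opt_int("n_dentary_teeth"),
            )
        )
    return rows


def trait_table(rows: list[ToothRow]) -> pd.DataFrame:
    """Aggregate tooth rows by species into a species-by-trait DataFrame."""
    by_species: dict[str, list[ToothRow]] = {}
    for r in rows:
        by_species.setdefault(r.species, []).append(r)
    records = [
        aggregate_specimens(specs).to_dict()
        for _, specs in sorted(by_species.items())
    ]
    return pd.DataFrame.from_records(records).set_index("species")
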