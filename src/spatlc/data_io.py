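"""Mortality count data containers and index conventions.

Everything downstream (the spatial graph, the model densities, the
sampler, the simulator) speaks in terms of the three types defined here:

``MortalityDataset``
    dense deaths/exposures arrays over (age, year, province) with a
    province-to-region map and a sex label;
``AgeGrouping``
    the 10-year age classes (0-10, 11-20, ...) that index the spatial
    effect;
``PeriodMapping``
    the optional two-period split of the calendar years used by the
    time-varying spatial specification.

Ages and years are stored as their literal values (not offsets) with
explicit coordinate vectors, so there is no off-by-one ambiguity between
modules.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "MortalityDataset",
    "AgeGrouping",
    "PeriodMapping",
    "ValidationError",
    "read_mortality_csv",
    "write_mortality_csv",
    "default_age_grouping",
    "make_period_mapping",
    "read_config",
]

#: canonical CSV column names; ``read_mortality_csv`` accepts a schema map
#: from these names to whatever the file actually uses.
CSV_COLUMNS = ("age", "year", "province_id", "region_id", "deaths", "exposure")


class ValidationError(ValueError):
    """Raised when input data violates a documented precondition."""


# ---------------------------------------------------------------------------
# containers


@dataclass(frozen=True)
class MortalityDataset:
    """Death counts and exposures on a dense (age, year, province) grid.

    Parameters
    ----------
    deaths
        Non-negative integer array, shape ``(n_ages, n_years, n_provinces)``.
    exposures
        Positive person-years at risk, same shape as ``deaths``.
    age_values, year_values, province_ids
        Sorted coordinate vectors for the three axes.  ``year_values`` must
        be contiguous.
    region_of
        Map ``province_id -> region_id``; every province must appear.
    sex
        Free-form label ("male"/"female"); sexes are modelled by
        independent runs, so no cross-sex structure is carried.
    """

    deaths: np.ndarray
    exposures: np.ndarray
    age_values: np.ndarray
    year_values: np.ndarray
    province_ids: np.ndarray
    region_of: dict[int, int]
    sex: str = "all"

    def __post_init__(self) -> None:
        object.__setattr__(self, "deaths", np.asarray(self.deaths))
        object.__setattr__(self, "exposures", np.asarray(self.exposures, dtype=float))
        object.__setattr__(self, "age_values", np.asarray(self.age_values, dtype=int))
        object.__setattr__(self, "year_values", np.asarray(self.year_values, dtype=int))
        object.__setattr__(self, "province_ids", np.asarray(self.province_ids, dtype=int))
        shape = (len(self.age_values), len(self.year_values), len(self.province_ids))
        if self.deaths.shape != shape or self.exposures.shape != shape:
            raise ValidationError(
                f"deaths/exposures must have shape {shape}, got "
                f"{self.deaths.shape} / {self.exposures.shape}"
            )
        if np.any(self.deaths < 0):
            idx = np.argwhere(self.deaths < 0)[0]
            raise ValidationError(f"negative death count at (age,year,province) index {tuple(idx)}")
        if np.any(~(self.exposures > 0)):
            idx = np.argwhere(~(self.exposures > 0))[0]
            raise ValidationError(f"non-positive exposure at (age,year,province) index {tuple(idx)}")
        if len(self.year_values) > 1 and np.any(np.diff(self.year_values) != 1):
            raise ValidationError("year_values must be contiguous")
        missing = [int(p) for p in self.province_ids if int(p) not in self.region_of]
        if missing:
            raise ValidationError(f"provinces without a region: {missing}")

    # -- convenience -------------------------------------------------------

    @property
    def n_ages(self) -> int:
        return len(self.age_values)

    @property
    def n_years(self) -> int:
        return len(self.year_values)

    @property
    def n_provinces(self) -> int:
        return len(self.province_ids)

    @property
    def region_ids(self) -> np.ndarray:
        """Sorted unique region identifiers."""
        return np.unique([self.region_of[int(p)] for p in self.province_ids])

    def region_index(self) -> np.ndarray:
        """0-based region index per province (aligned with ``province_ids``)."""
        rid = self.region_ids
        lookup = {int(r): i for i, r in enumerate(rid)}
        return np.array([lookup[self.region_of[int(p)]] for p in self.province_ids])


@dataclass(frozen=True)
class AgeGrouping:
    """Partition of ages 0..max_age into closed intervals.

    The first class spans 11 single ages (0-10) and subsequent classes 10,
    with the last class truncated at ``max_age``.  Group indices are
    1-based in ``group_of`` (group 1 = ages 0-10); ``index_of`` gives the
    0-based index used for array work.
    """

    boundaries: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        prev_hi = -1
        for lo, hi in self.boundaries:
            if lo != prev_hi + 1 or hi < lo:
                raise ValidationError(f"intervals must partition the age range, got {self.boundaries}")
            prev_hi = hi

    @property
    def n_groups(self) -> int:
        return len(self.boundaries)

    @property
    def max_age(self) -> int:
        return self.boundaries[-1][1]

    def group_of(self, age: int) -> int:
        """1-based group index containing ``age``."""
        return self.index_of(age) + 1

    def index_of(self, age: int) -> int:
        """0-based group index containing ``age``."""
        for i, (lo, hi) in enumerate(self.boundaries):
            if lo <= age <= hi:
                return i
        raise ValidationError(f"age {age} outside grouping range [0, {self.max_age}]")

    def index_array(self, ages: np.ndarray) -> np.ndarray:
        """0-based group index for each entry of ``ages``."""
        return np.array([self.index_of(int(a)) for a in np.asarray(ages)])

    def labels(self) -> list[str]:
        return [f"{lo}-{hi}" for lo, hi in self.boundaries]


@dataclass(frozen=True)
class PeriodMapping:
    """Map calendar years to period 1/2 around a cutpoint (or all to 1).

    ``period_of(t) == 1`` iff ``t <= cutpoint_year``.  With
    ``cutpoint_year=None`` the map is the single-period identity.
    """

    years: tuple[int, ...]
    cutpoint_year: int | None = None

    def __post_init__(self) -> None:
        years = tuple(int(y) for y in self.years)
        object.__setattr__(self, "years", years)
        if self.cutpoint_year is not None:
            if not (years[0] <= self.cutpoint_year < years[-1]):
                raise ValidationError(
                    f"cutpoint {self.cutpoint_year} must lie strictly inside "
                    f"the year range [{years[0]}, {years[-1]}] so both periods are non-empty"
                )

    @property
    def n_periods(self) -> int:
        return 1 if self.cutpoint_year is None else 2

    def period_of(self, year: int) -> int:
        """1-based period index for ``year``."""
        if self.cutpoint_year is None:
            return 1
        return 1 if year <= self.cutpoint_year else 2

    def index_array(self, years: np.ndarray | None = None) -> np.ndarray:
        """0-based period index per year (defaults to the stored years)."""
        ys = self.years if years is None else np.asarray(years)
        return np.array([self.period_of(int(y)) - 1 for y in ys])


# ---------------------------------------------------------------------------
# constructors


def default_age_grouping(max_age: int) -> AgeGrouping:
    """10-year age classes 0-10, 11-20, 21-30, ... truncated at ``max_age``."""
    if max_age < 0:
        raise ValidationError("max_age must be >= 0")
    bounds: list[tuple[int, int]] = []
    lo = 0
    hi = 10
    while lo <= max_age:
        bounds.append((lo, min(hi, max_age)))
        lo, hi = hi + 1, hi + 10
    return AgeGrouping(tuple(bounds))


def make_period_mapping(years, cutpoint: int | None = None) -> PeriodMapping:
    """Two-period split at ``cutpoint`` (inclusive on the left), else identity."""
    return PeriodMapping(tuple(int(y) for y in years), cutpoint)


# ---------------------------------------------------------------------------
# CSV round trip


def read_mortality_csv(path, schema: dict[str, str] | None = None, sex: str = "all") -> MortalityDataset:
    """Read one-row-per-cell mortality counts into a dense dataset.

    ``schema`` maps canonical names (``age, year, province_id, region_id,
    deaths, exposure``) to the file's column names.  The (age, year,
    province) grid must be complete: missing cells are an error, never
    silently zero-filled.
    """
    schema = schema or {}
    cols = {name: schema.get(name, name) for name in CSV_COLUMNS}
    df = pd.read_csv(path)
    missing_cols = [c for c in cols.values() if c not in df.columns]
    if missing_cols:
        raise ValidationError(f"missing columns in {path}: {missing_cols}")
    df = df.rename(columns={v: k for k, v in cols.items()})

    bad = df.index[df["deaths"] < 0]
    if len(bad):
        raise ValidationError(f"negative deaths in rows {list(bad[:10])}")
    bad = df.index[~(df["exposure"] > 0)]
    if len(bad):
        raise ValidationError(f"non-positive exposure in rows {list(bad[:10])}")
    nreg = df.groupby("province_id")["region_id"].nunique()
    incoherent = nreg.index[nreg > 1]
    if len(incoherent):
        raise ValidationError(f"provinces mapped to multiple regions: {list(incoherent)}")

    ages = np.sort(df["age"].unique())
    years = np.sort(df["year"].unique())
    provs = np.sort(df["province_id"].unique())
    expected = len(ages) * len(years) * len(provs)
    if len(df) != expected or df.duplicated(["age", "year", "province_id"]).any():
        raise ValidationError(
            f"(age, year, province) grid incomplete or duplicated: "
            f"{len(df)} rows for a {len(ages)}x{len(years)}x{len(provs)} grid"
        )

    df = df.sort_values(["age", "year", "province_id"])
    shape = (len(ages), len(years), len(provs))
    deaths = df["deaths"].to_numpy(dtype=int).reshape(shape)
    expo = df["exposure"].to_numpy(dtype=float).reshape(shape)
    region_of = {int(p): int(r) for p, r in df.groupby("province_id")["region_id"].first().items()}
    return MortalityDataset(deaths, expo, ages, years, provs, region_of, sex=sex)


def write_mortality_csv(dataset: MortalityDataset, path) -> None:
    """Write the dataset in the one-row-per-cell dialect ``read_mortality_csv`` reads."""
    a, t, s = np.meshgrid(
        dataset.age_values, dataset.year_values, dataset.province_ids, indexing="ij"
    )
    df = pd.DataFrame(
        {
            "age": a.ravel(),
            "year": t.ravel(),
            "province_id": s.ravel(),
            "region_id": [dataset.region_of[int(p)] for p in s.ravel()],
            "deaths": dataset.deaths.ravel(),
            "exposure": dataset.exposures.ravel(),
        }
    )
    df.to_csv(path, index=False)


def read_config(path) -> dict:
    """Read a key-value (YAML) run configuration file."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return cfg or {}
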