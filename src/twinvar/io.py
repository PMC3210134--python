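"""Reading individual-level tables and constructing relative-pair tables.

Individuals are conscript-like records: a person id, parent ids linking full
siblings, birth year, BMI (or height+weight convertible to BMI), and a
zygosity label for twins. Pairs are emitted as a flat table with one row per
unordered pair, member *a* being the lexicographically smaller id, so that
every downstream statistic must be order-invariant (the double-entry
estimators in :mod:`twinvar.sibling` are).

Filters mirror the register-based exclusions of large conscription studies:
a strict BMI plausibility window (both members), a maximum within-pair birth
spacing, and removal of same-birth-year sibling sets whose zygosity is not
known.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ConfigError

logger = logging.getLogger(__name__)

INDIVIDUAL_COLUMNS = [
    "person_id", "father_id", "mother_id", "birth_year", "sex", "bmi", "zygosity",
]

PAIR_COLUMNS = [
    "relation", "id_a", "id_b", "bmi_a", "bmi_b",
    "birth_year_a", "birth_year_b", "cohort_year",
]

ZYGOSITY_LEVELS = {"MZ", "DZ", "unknown", "not_twin"}


@dataclass(frozen=True)
class ColumnMap:
    """Maps canonical field names to the column names of a delimited file.

    Either ``bmi``, or both ``height`` (cm) and ``weight`` (kg), must be
    given; in the latter case BMI is computed as weight / (height/100)^2.
    """

    id: str = "person_id"
    father: str = "father_id"
    mother: str = "mother_id"
    birth_year: str = "birth_year"
    bmi: str | None = "bmi"
    height: str | None = None
    weight: str | None = None
    sex: str | None = "sex"
    zygosity: str | None = "zygosity"

    @classmethod
    def from_dict(cls, d: Mapping[str, str]) -> "ColumnMap":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown column-map keys: {sorted(unknown)}")
        return cls(**dict(d))


def read_individuals(
    path,
    columns: ColumnMap | Mapping[str, str] | None = None,
    delimiter: str = ",",
) -> pd.DataFrame:
    """Read an individuals table into canonical form.

    Rows with unparseable or non-positive BMI (or height/weight), or an
    unparseable birth year, are dropped and counted; duplicate person ids
    keep their first occurrence. Counts are logged and attached to the
    returned frame as ``.attrs['n_skipped']`` and ``.attrs['n_duplicates']``.

    Raises
    ------
    ConfigError
        If a mandatory column is absent from the file header.
    """
    if columns is None:
        columns = ColumnMap()
    elif not isinstance(columns, ColumnMap):
        columns = ColumnMap.from_dict(columns)

    raw = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)

    mandatory = {"id": columns.id, "birth_year": columns.birth_year}
    if columns.bmi is not None:
        mandatory["bmi"] = columns.bmi
    elif columns.height is not None and columns.weight is not None:
        mandatory["height"] = columns.height
        mandatory["weight"] = columns.weight
    else:
        raise ConfigError("column map must provide 'bmi' or both 'height' and 'weight'")
    missing = [name for name in mandatory.values() if name not in raw.columns]
    if missing:
        raise ConfigError(f"mandatory columns missing from {path}: {missing}")

    out = pd.DataFrame(index=raw.index)
    out["person_id"] = raw[columns.id].str.strip()
    for canon, col in (("father_id", columns.father), ("mother_id", columns.mother)):
        if col is not None and col in raw.columns:
            vals = raw[col].str.strip()
            out[canon] = vals.where(vals != "", other=pd.NA)
        else:
            out[canon] = pd.NA
    out["birth_year"] = pd.to_numeric(raw[columns.birth_year], errors="coerce")
    if columns.sex is not None and columns.sex in raw.columns:
        out["sex"] = raw[columns.sex].str.strip()
    else:
        out["sex"] = "male"
    if columns.bmi is not None:
        out["bmi"] = pd.to_numeric(raw[columns.bmi], errors="coerce")
    else:
        height = pd.to_numeric(raw[columns.height], errors="coerce")
        weight = pd.to_numeric(raw[columns.weight], errors="coerce")
        out["bmi"] = weight / (height / 100.0) ** 2
    if columns.zygosity is not None and columns.zygosity in raw.columns:
        zyg = raw[columns.zygosity].str.strip()
        out["zygosity"] = zyg.where(zyg.isin(sorted(ZYGOSITY_LEVELS)), other="not_twin")
    else:
        out["zygosity"] = "not_twin"

    bad = out["bmi"].isna() | (out["bmi"] <= 0) | out["birth_year"].isna()
    n_skipped = int(bad.sum())
    out = out.loc[~bad].copy()
    dup = out["person_id"].duplicated(keep="first")
    n_duplicates = int(dup.sum())
    out = out.loc[~dup].copy()
    out["birth_year"] = out["birth_year"].astype(np.int64)
    out = out[INDIVIDUAL_COLUMNS].reset_index(drop=True)
    if n_skipped or n_duplicates:
        logger.info(
            "read_individuals(%s): %d rows kept, %d malformed rows skipped, "
            "%d duplicate ids dropped", path, len(out), n_skipped, n_duplicates,
        )
    out.attrs["n_skipped"] = n_skipped
    out.attrs["n_duplicates"] = n_duplicates
    return out


def write_individuals(individuals: pd.DataFrame, path) -> None:
    """Write an individuals table in the canonical CSV dialect."""
    individuals[INDIVIDUAL_COLUMNS].to_csv(path, index=False)


def make_pair_frame(
    relation, id_a, id_b, bmi_a, bmi_b, birth_year_a, birth_year_b, cohort_year=None,
) -> pd.DataFrame:
    """Assemble a pair table, swapping members so ``id_a < id_b`` row-wise."""
    df = pd.DataFrame({
        "relation": relation,
        "id_a": np.asarray(id_a, dtype=object),
        "id_b": np.asarray(id_b, dtype=object),
        "bmi_a": np.asarray(bmi_a, dtype=float),
        "bmi_b": np.asarray(bmi_b, dtype=float),
        "birth_year_a": np.asarray(birth_year_a, dtype=np.int64),
        "birth_year_b": np.asarray(birth_year_b, dtype=np.int64),
    })
    if cohort_year is None:
        df["cohort_year"] = pd.array([pd.NA] * len(df), dtype="Int64")
    else:
        df["cohort_year"] = pd.array(cohort_year, dtype="Int64")
    flip = df["id_a"] > df["id_b"]
    if flip.any():
        for a, b in (("id_a", "id_b"), ("bmi_a", "bmi_b"), ("birth_year_a", "birth_year_b")):
            df.loc[flip, [a, b]] = df.loc[flip, [b, a]].to_numpy()
    return df[PAIR_COLUMNS]


def _twin_sets(family: pd.DataFrame):
    """Split one family's sons into twin pairs, dropped ids, and FS-eligible ids.

    Within a family, sons sharing a birth year are putative twins: if every
    member of such a set carries the same MZ or DZ label they form twin
    pairs; otherwise (unknown or conflicting zygosity) they are dropped from
    all pairing, mirroring the register practice of excluding twin pairs
    without zygosity information. Twins never enter full-sibling pairing.
    """
    twin_rows = []
    dropped: set = set()
    fs_ids: list = []
    for year, grp in family.groupby("birth_year", sort=False):
        if len(grp) == 1:
            row = grp.iloc[0]
            if row["zygosity"] in ("MZ", "DZ"):
                dropped.add(row["person_id"])  # lone twin, co-twin absent
            else:
                fs_ids.append(row.name)
            continue
        labels = set(grp["zygosity"])
        if labels == {"MZ"} or labels == {"DZ"}:
            rel = labels.pop()
            for i, j in combinations(range(len(grp)), 2):
                twin_rows.append((rel, grp.iloc[i], grp.iloc[j]))
        elif labels == {"not_twin"}:
            fs_ids.extend(grp.index)  # register affirms non-twin status
        else:  # unknown or conflicting zygosity: excluded from both sets
            dropped.update(grp["person_id"])
    return twin_rows, dropped, fs_ids


def _paired_parents(individuals: pd.DataFrame) -> pd.DataFrame:
    both = individuals["father_id"].notna() & individuals["mother_id"].notna()
    return individuals.loc[both]


def build_full_sib_pairs(individuals: pd.DataFrame) -> pd.DataFrame:
    """Emit one FS pair per unordered pair of sons sharing both parents.

    Twins (and same-birth-year sibling sets of unknown zygosity) are excluded
    from full-sibling pairing. Families with k eligible sons contribute all
    C(k,2) pairs.
    """
    rows = []
    for _, fam in _paired_parents(individuals).groupby(["father_id", "mother_id"], sort=False):
        if len(fam) < 2:
            continue
        _, _, fs_idx = _twin_sets(fam)
        if len(fs_idx) < 2:
            continue
        sibs = fam.loc[fs_idx]
        for i, j in combinations(range(len(sibs)), 2):
            rows.append((sibs.iloc[i], sibs.iloc[j]))
    if not rows:
        return make_pair_frame("FS", [], [], [], [], [], [])
    ra = pd.DataFrame([r[0] for r in rows])
    rb = pd.DataFrame([r[1] for r in rows])
    return make_pair_frame(
        "FS", ra["person_id"].to_numpy(), rb["person_id"].to_numpy(),
        ra["bmi"].to_numpy(), rb["bmi"].to_numpy(),
        ra["birth_year"].to_numpy(), rb["birth_year"].to_numpy(),
    )


def build_twin_pairs(individuals: pd.DataFrame) -> pd.DataFrame:
    """Emit MZ and DZ pairs: same parents, same birth year, same zygosity label."""
    rows = []
    for _, fam in _paired_parents(individuals).groupby(["father_id", "mother_id"], sort=False):
        if len(fam) < 2:
            continue
        twin_rows, _, _ = _twin_sets(fam)
        rows.extend(twin_rows)
    if not rows:
        return make_pair_frame("MZ", [], [], [], [], [], [])
    rel = [r[0] for r in rows]
    ra = pd.DataFrame([r[1] for r in rows])
    rb = pd.DataFrame([r[2] for r in rows])
    return make_pair_frame(
        rel, ra["person_id"].to_numpy(), rb["person_id"].to_numpy(),
        ra["bmi"].to_numpy(), rb["bmi"].to_numpy(),
        ra["birth_year"].to_numpy(), rb["birth_year"].to_numpy(),
    )


def filter_bmi_range(pairs: pd.DataFrame, low: float = 15.0, high: float = 50.0) -> pd.DataFrame:
    """Keep pairs in which BOTH members have ``low < bmi < high`` (strict).

    The plausibility window guards against measurement and data-entry errors;
    both endpoints are excluded.
    """
    if low >= high:
        raise ConfigError(f"BMI bounds inverted: low={low} >= high={high}")
    keep = (
        (pairs["bmi_a"] > low) & (pairs["bmi_a"] < high)
        & (pairs["bmi_b"] > low) & (pairs["bmi_b"] < high)
    )
    out = pairs.loc[keep].reset_index(drop=True)
    logger.info("filter_bmi_range(%g, %g): %d retained, %d excluded",
                low, high, len(out), len(pairs) - len(out))
    return out


def filter_age_gap(pairs: pd.DataFrame, max_gap_years: int = 3) -> pd.DataFrame:
    """Keep pairs born at most ``max_gap_years`` apart (inclusive bound)."""
    if max_gap_years < 0:
        raise ConfigError("max_gap_years must be >= 0")
    gap = (pairs["birth_year_a"] - pairs["birth_year_b"]).abs()
    out = pairs.loc[gap <= max_gap_years].reset_index(drop=True)
    logger.info("filter_age_gap(%d): %d retained, %d excluded",
                max_gap_years, len(out), len(pairs) - len(out))
    return out


def assign_cohort(pairs: pd.DataFrame, seed: int) -> pd.DataFrame:
    """Assign each pair the birth year of a randomly selected member.

    Stratifying full-sibling pairs by the birth year of one randomly chosen
    brother avoids systematically picking the elder or younger of each pair.
    Deterministic given ``seed``; same-year pairs get that year regardless of
    the draw.
    """
    rng = np.random.default_rng(seed)
    pick_b = rng.integers(0, 2, size=len(pairs)).astype(bool)
    cohort = np.where(pick_b, pairs["birth_year_b"], pairs["birth_year_a"])
    out = pairs.copy()
    out["cohort_year"] = pd.array(cohort, dtype="Int64")
    return out


def write_pairs(pairs: pd.DataFrame, path) -> None:
    """Write a pair table as CSV (the canonical on-disk pair dialect)."""
    pairs[PAIR_COLUMNS].to_csv(path, index=False)


def read_pairs(path) -> pd.DataFrame:
    """Read a pair table written by :func:`write_pairs`; exact round-trip."""
    df = pd.read_csv(
        path,
        dtype={
            "relation": str, "id_a": str, "id_b": str,
            "bmi_a": float, "bmi_b": float,
            "birth_year_a": np.int64, "birth_year_b": np.int64,
            "cohort_year": "Int64",
        },
    )
    df["id_a"] = df["id_a"].astype(object)
    df["id_b"] = df["id_b"].astype(object)
    return df[PAIR_COLUMNS]
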