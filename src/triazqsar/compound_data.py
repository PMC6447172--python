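"""Compound activity tables for competitive-immunoassay QSAR.

Handles the bookkeeping that precedes any modelling: IC50 values in nmol/L
(with ``>limit`` censoring as reported for weakly recognized analytes),
conversion to pIC50 = -log10(IC50 in mol/L), antibody cross-reactivity
(CR = 100 * IC50_reference / IC50), and range-constrained random train/test
splits in which the test set must lie inside the training activity range.
"""

from __future__ import annotations

import importlib.resources
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "CompoundRecord",
    "ActivityTable",
    "SplitResult",
    "SplitError",
    "ParseError",
    "to_pic50",
    "cross_reactivity",
    "format_cr",
    "split_train_test",
    "read_compound_table",
    "write_compound_table",
    "load_triazine_table",
]

#: pIC50 assigned when IC50 is at or beyond the 500 nmol/L assay limit.
CENSOR_PIC50_AT_500 = 6.30103


class ParseError(ValueError):
    """Raised for malformed activity tables."""


class SplitError(RuntimeError):
    """Raised when a constrained train/test split cannot be found."""


@dataclass
class CompoundRecord:
    """One analyte with per-antibody-system IC50 values.

    ``ic50`` maps system name -> (value in nmol/L, censored flag); a censored
    entry means the assay reported ``> value`` and the value is the table's
    censor limit.  ``cr`` optionally carries the printed cross-reactivity in
    percent (None where the source prints a below-limit marker such as
    ``<0.1``).
    """

    id: int
    name: str
    ic50: dict[str, tuple[float, bool]]
    smiles: str | None = None
    cr: dict[str, float | None] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.id <= 0:
            raise ValueError(f"compound id must be positive, got {self.id}")
        for system, (value, _) in self.ic50.items():
            if not value > 0:
                raise ValueError(
                    f"compound {self.id}: IC50 for {system!r} must be > 0, got {value}"
                )

    def pic50(self, system: str, censor_limit: float) -> float:
        value, censored = self.ic50[system]
        return to_pic50(value, censored, censor_limit)


@dataclass
class ActivityTable:
    """A set of compounds measured against one or more antibody systems."""

    records: list[CompoundRecord]
    reference_id: int = 1
    censor_limit: float = 500.0

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ParseError(f"duplicate compound ids: {dupes}")
        if self.reference_id not in set(ids):
            raise ValueError(f"reference compound {self.reference_id} not in table")
        if not self.censor_limit > 0:
            raise ValueError("censor_limit must be > 0")
        for r in self.records:
            for system, (value, censored) in r.ic50.items():
                if censored and value != self.censor_limit:
                    raise ValueError(
                        f"compound {r.id}: censored IC50 for {system!r} must equal "
                        f"the censor limit {self.censor_limit}, got {value}"
                    )

    @property
    def ids(self) -> list[int]:
        return [r.id for r in self.records]

    @property
    def systems(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.records:
            for s in r.ic50:
                seen.setdefault(s)
        return list(seen)

    def record(self, compound_id: int) -> CompoundRecord:
        for r in self.records:
            if r.id == compound_id:
                return r
        raise KeyError(f"no compound with id {compound_id}")

    def pic50(self, system: str) -> pd.Series:
        """pIC50 per compound for one antibody system, indexed by id."""
        return pd.Series(
            {r.id: r.pic50(system, self.censor_limit) for r in self.records},
            name=f"pIC50_{system}",
        )

    def reconstructed_cr(self, system: str) -> pd.Series:
        """Cross-reactivity recomputed from the IC50 ratios, in percent."""
        ref_value, _ = self.record(self.reference_id).ic50[system]
        return pd.Series(
            {r.id: cross_reactivity(ref_value, r.ic50[system][0]) for r in self.records},
            name=f"CR_{system}",
        )


@dataclass(frozen=True)
class SplitResult:
    train_ids: list[int]
    test_ids: list[int]
    fraction: float
    seed: int


def to_pic50(ic50_nmol: float, censored: bool, censor_limit: float) -> float:
    """Convert an IC50 in nmol/L to pIC50 = -log10(IC50 in mol/L).

    Censored measurements (``> limit``) are assigned the pIC50 of the limit
    itself, i.e. a 500 nmol/L limit yields exactly 6.30103, matching how
    at-limit and beyond-limit compounds are treated identically.
    """
    if not ic50_nmol > 0:
        raise ValueError(f"IC50 must be > 0 nmol/L, got {ic50_nmol}")
    if censored:
        return -math.log10(censor_limit * 1e-9)
    return -math.log10(ic50_nmol * 1e-9)


def cross_reactivity(ic50_ref: float, ic50: float) -> float:
    """CR in percent: 100 * IC50(reference) / IC50(analyte)."""
    if not ic50_ref > 0 or not ic50 > 0:
        raise ValueError("IC50 values must be > 0")
    return 100.0 * ic50_ref / ic50


def format_cr(cr_percent: float) -> str:
    """Format CR the way assay tables print it: integers at >=10%, one
    decimal below 10%."""
    if cr_percent >= 10:
        return str(int(round(cr_percent)))
    return f"{cr_percent:.1f}"


def split_train_test(
    table: ActivityTable,
    system: str,
    fraction: float = 0.8,
    seed: int = 0,
    max_tries: int = 1000,
) -> SplitResult:
    """Random train/test split with the activity-range constraints.

    The test set's maximum pIC50 must not exceed the training maximum and its
    minimum must not fall below the training minimum, so that test compounds
    are interpolated, never extrapolated.  Candidate splits are drawn by
    rejection sampling; a fixed seed gives a reproducible result.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    ids = np.asarray(table.ids)
    if len(ids) < 3:
        raise ValueError("need at least 3 compounds to split")
    y = table.pic50(system)
    n_train = max(2, int(round(fraction * len(ids))))
    if n_train >= len(ids):
        n_train = len(ids) - 1
    rng = np.random.default_rng(seed)
    for _ in range(max_tries):
        perm = rng.permutation(len(ids))
        train = ids[perm[:n_train]]
        test = ids[perm[n_train:]]
        if check_split_constraints(y, train, test):
            return SplitResult(
                sorted(int(i) for i in train),
                sorted(int(i) for i in test),
                fraction,
                seed,
            )
    raise SplitError(
        f"no split satisfying the range constraints in {max_tries} tries "
        f"(system {system!r}, fraction {fraction})"
    )


def check_split_constraints(
    pic50: pd.Series, train_ids: Iterable[int], test_ids: Iterable[int]
) -> bool:
    """True when max(test) <= max(train) and min(test) >= min(train)."""
    tr = pic50.loc[list(train_ids)]
    te = pic50.loc[list(test_ids)]
    return bool(te.max() <= tr.max() and te.min() >= tr.min())


_CENSOR_RE = re.compile(r"^[>＞]\s*(\S+)$")


def _parse_ic50(raw: str, row: int) -> tuple[float, bool]:
    text = str(raw).strip()
    censored = False
    m = _CENSOR_RE.match(text)
    if m:
        censored = True
        text = m.group(1)
    try:
        value = float(text)
    except ValueError:
        raise ParseError(f"row {row}: non-numeric IC50 value {raw!r}") from None
    if not value > 0:
        raise ParseError(f"row {row}: IC50 must be positive, got {raw!r}")
    return value, censored


def _parse_cr(raw: str) -> float | None:
    text = str(raw).strip()
    if not text or text.lower() == "nan":
        return None
    if text.startswith(("<", "＜")):
        return None  # below reporting limit
    return float(text)


def read_compound_table(
    path: str | Path,
    reference_id: int = 1,
    censor_limit: float = 500.0,
) -> ActivityTable:
    """Read a wide-format activity CSV into an :class:`ActivityTable`.

    Expected header: ``id,name[,smiles]`` plus one ``ic50_<system>`` column
    per antibody system and optionally ``cr_<system>`` columns.  IC50 cells
    may carry a ``>`` prefix to mark censoring at the table limit.
    """
    try:
        df = pd.read_csv(path, dtype=str)
    except pd.errors.EmptyDataError:
        raise ParseError(f"{path}: empty file") from None
    if df.empty:
        raise ParseError(f"{path}: no data rows")
    cols = list(df.columns)
    ic50_cols = [c for c in cols if c.startswith("ic50_")]
    if "id" not in cols or "name" not in cols or not ic50_cols:
        raise ParseError(
            f"{path}: need columns id, name and at least one ic50_<system>, got {cols}"
        )
    records = []
    for idx, row in df.iterrows():
        rownum = int(idx) + 2  # header is line 1
        try:
            cid = int(row["id"])
        except (TypeError, ValueError):
            raise ParseError(f"row {rownum}: bad compound id {row['id']!r}") from None
        ic50 = {c[len("ic50_"):]: _parse_ic50(row[c], rownum) for c in ic50_cols}
        cr = {
            c[len("cr_"):]: _parse_cr(row[c])
            for c in cols
            if c.startswith("cr_") and not pd.isna(row[c])
        }
        smiles = row.get("smiles")
        records.append(
            CompoundRecord(
                id=cid,
                name=str(row["name"]),
                ic50=ic50,
                smiles=None if pd.isna(smiles) else str(smiles),
                cr=cr,
            )
        )
    return ActivityTable(records, reference_id=reference_id, censor_limit=censor_limit)


def write_compound_table(table: ActivityTable, path: str | Path) -> None:
    """Write an :class:`ActivityTable` back to the wide CSV dialect."""
    systems = table.systems
    rows = []
    for r in table.records:
        row: dict[str, object] = {"id": r.id, "name": r.name}
        if r.smiles is not None:
            row["smiles"] = r.smiles
        for s in systems:
            if s in r.cr and r.cr[s] is not None:
                row[f"cr_{s}"] = format_cr(r.cr[s])
            value, censored = r.ic50[s]
            row[f"ic50_{s}"] = f">{value:g}" if censored else f"{value:g}"
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def load_triazine_table() -> ActivityTable:
    """The packaged 20-triazine table (atrazine = compound 1, limit 500 nmol/L)
    for the polyclonal S2 and monoclonal K4E7 assay systems."""
    ref = importlib.resources.files("triazqsar.data") / "triazine_activities.csv"
    with importlib.resources.as_file(ref) as p:
        return read_compound_table(p, reference_id=1, censor_limit=500.0)
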