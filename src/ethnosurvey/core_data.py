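"""Domain types, CSV ingestion/validation and the informant age-scoring rule.

An ethnobotanical survey is a collection of *use reports*: informant ``i``
mentions species ``s`` for ailment category ``u``.  This module defines the
in-memory containers for informants, species records, ailment categories and
use reports, loads them from the package's CSV dialect (UTF-8, comma-separated,
``;``-delimited lists inside cells) and validates referential integrity.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable

import pandas as pd

GENDERS = {"female", "male", "unknown"}
MODES = {"oral", "topical", "both", "missing"}
LIFE_FORMS = {"Th", "G", "H", "P", "C"}

#: age bins are left-closed/right-open except the last, which includes 81
AGE_BINS = ((28, 40, 1), (40, 50, 2), (50, 60, 3), (60, 70, 4), (70, 82, 5))


class SchemaError(ValueError):
    """A mandatory column is missing or a cell cannot be parsed."""


class ReferentialError(ValueError):
    """A foreign key does not resolve or a key is duplicated."""


def age_to_score(age: int) -> int:
    """Map an informant age in years to the 1-5 knowledge-score bin.

    Bins are [28,40) -> 1, [40,50) -> 2, [50,60) -> 3, [60,70) -> 4 and
    [70,81] -> 5, covering the survey's stated age span.  Ages outside
    [28, 81] raise ``ValueError``.
    """
    if not 28 <= age <= 81:
        raise ValueError(f"age {age} outside the surveyed span [28, 81]")
    for lo, hi, score in AGE_BINS:
        if lo <= age < hi:
            return score
    raise AssertionError("unreachable")  # pragma: no cover


@dataclass(frozen=True)
class Informant:
    id: str
    age: int
    gender: str = "unknown"

    @property
    def age_score(self) -> int:
        return age_to_score(self.age)


@dataclass(frozen=True)
class SpeciesRecord:
    code: int
    family: str
    scientific_name: str
    vernacular_name: str
    parts_used: tuple[str, ...]
    medicinal_uses: tuple[str, ...]
    preparation: tuple[str, ...]
    mode_of_application: str  # raw cell; canonicalized by preprocessing
    life_form: str
    voucher_no: str


@dataclass(frozen=True)
class UseReport:
    informant_id: str
    species_code: int
    category_id: str


@dataclass(frozen=True)
class AilmentCategory:
    id: str
    name: str


@dataclass
class Dataset:
    informants: list[Informant]
    species: list[SpeciesRecord]
    use_reports: list[UseReport]
    categories: list[AilmentCategory]

    @property
    def n_informants(self) -> int:
        """Denominator N for RFC/CI; always the roster size, so informants
        who cite nothing still count."""
        return len(self.informants)

    def species_by_code(self) -> dict[int, SpeciesRecord]:
        return {s.code: s for s in self.species}

    def category_ids(self) -> set[str]:
        return {c.id for c in self.categories}


@dataclass
class PresenceMatrix:
    """Species x prior-study 0/1 matrix (columns A..N)."""

    species_codes: list[int]
    study_labels: list[str]
    cells: list[list[int]]  # row-major, aligned with species_codes
    novel_flags: dict[int, bool] = field(default_factory=dict)

    def row(self, code: int) -> list[int]:
        return self.cells[self.species_codes.index(code)]


@dataclass
class CheckResult:
    name: str
    passed: bool
    offenders: list = field(default_factory=list)


@dataclass
class ValidationReport:
    checks: list[CheckResult]

    @property
    def ok(self) -> bool:
        return all(c.passed for c in self.checks)

    def failed(self) -> list[CheckResult]:
        return [c for c in self.checks if not c.passed]


# ---------------------------------------------------------------------------
# CSV ingestion

_LIST_SEP = ";"


def _split_list(cell: object) -> tuple[str, ...]:
    if cell is None or (isinstance(cell, float) and pd.isna(cell)):
        return ()
    return tuple(p.strip() for p in str(cell).split(_LIST_SEP) if p.strip())


def _require_columns(df: pd.DataFrame, cols: Iterable[str], path: object) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing mandatory column(s) {missing}")


SPECIES_COLUMNS = [
    "code", "family", "scientific_name", "vernacular_name", "parts_used",
    "medicinal_uses", "preparation", "mode_of_application", "life_form",
    "voucher_no",
]


def read_species_csv(path) -> list[SpeciesRecord]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(df, SPECIES_COLUMNS, path)
    records, bad = [], []
    for i, row in df.iterrows():
        try:
            records.append(SpeciesRecord(
                code=int(row["code"]),
                family=row["family"].strip(),
                scientific_name=row["scientific_name"].strip(),
                vernacular_name=row["vernacular_name"].strip(),
                parts_used=_split_list(row["parts_used"]),
                medicinal_uses=_split_list(row["medicinal_uses"]),
                preparation=_split_list(row["preparation"]),
                mode_of_application=row["mode_of_application"].strip(),
                life_form=row["life_form"].strip(),
                voucher_no=row["voucher_no"].strip(),
            ))
        except (ValueError, TypeError) as exc:
            bad.append((i, str(exc)))
    if bad:
        raise SchemaError(f"{path}: unparseable rows {bad}")
    codes = [r.code for r in records]
    dupes = sorted({c for c in codes if codes.count(c) > 1})
    if dupes:
        raise ReferentialError(f"{path}: duplicated species code(s) {dupes}")
    return records


def read_species_workbook(path, sheet=0) -> list[SpeciesRecord]:
    """Ingest a species table from a supplementary-style Excel workbook.

    Accepts the same column names as ``species.csv``; list-valued cells may use
    either ``;`` or the workbook's comma convention.
    """
    df = pd.read_excel(path, sheet_name=sheet, dtype=str).fillna("")
    df.columns = [str(c).strip().lower().replace(" ", "_") for c in df.columns]
    _require_columns(df, SPECIES_COLUMNS, path)
    tmp = Path(str(path) + ".converted.csv")
    df.to_csv(tmp, index=False)
    try:
        return read_species_csv(tmp)
    finally:
        tmp.unlink(missing_ok=True)


def read_informants_csv(path) -> list[Informant]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(df, ["informant_id", "age", "gender"], path)
    informants = []
    for _, row in df.iterrows():
        gender = row["gender"].strip().lower() or "unknown"
        if gender not in GENDERS:
            raise SchemaError(f"{path}: unknown gender {gender!r}")
        informants.append(Informant(row["informant_id"].strip(), int(row["age"]), gender))
    ids = [i.id for i in informants]
    dupes = sorted({i for i in ids if ids.count(i) > 1})
    if dupes:
        raise ReferentialError(f"{path}: duplicated informant id(s) {dupes}")
    return informants


def read_categories_csv(path) -> list[AilmentCategory]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(df, ["category_id", "name"], path)
    cats = [AilmentCategory(r["category_id"].strip(), r["name"].strip())
            for _, r in df.iterrows()]
    ids = [c.id for c in cats]
    dupes = sorted({i for i in ids if ids.count(i) > 1})
    if dupes:
        raise ReferentialError(f"{path}: duplicated category id(s) {dupes}")
    return cats


def read_use_reports_csv(path) -> list[UseReport]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(df, ["informant_id", "species_code", "category_id"], path)
    return [UseReport(r["informant_id"].strip(), int(r["species_code"]),
                      r["category_id"].strip())
            for _, r in df.iterrows()]


def load_dataset(species_path, use_reports_path, informants_path,
                 categories_path) -> Dataset:
    """Load and referentially validate a survey from four CSV files."""
    d = Dataset(
        informants=read_informants_csv(informants_path),
        species=read_species_csv(species_path),
        use_reports=read_use_reports_csv(use_reports_path),
        categories=read_categories_csv(categories_path),
    )
    report = validate_dataset(d)
    hard = [c for c in report.failed() if c.name in ("species foreign keys",
                                                     "informant foreign keys",
                                                     "category foreign keys")]
    if hard:
        raise ReferentialError("; ".join(
            f"{c.name}: offending rows {c.offenders[:10]}" for c in hard))
    return d


def load_presence_matrix(path) -> PresenceMatrix:
    df = pd.read_csv(path)
    if "code" not in df.columns:
        raise SchemaError(f"{path}: missing mandatory column 'code'")
    novel = {}
    if "novel" in df.columns:
        novel = {int(r.code): bool(r.novel) for r in df.itertuples()}
        df = df.drop(columns=["novel"])
    labels = [c for c in df.columns if c != "code"]
    cells = df[labels].astype(int).values.tolist()
    bad = [v for row in cells for v in row if v not in (0, 1)]
    if bad:
        raise SchemaError(f"{path}: non-binary cells {sorted(set(bad))}")
    return PresenceMatrix(df["code"].astype(int).tolist(), labels, cells, novel)


# ---------------------------------------------------------------------------
# Validation

def validate_dataset(d: Dataset) -> ValidationReport:
    """Run every structural check; always returns a report, never raises."""
    checks: list[CheckResult] = []

    codes = [s.code for s in d.species]
    checks.append(CheckResult("species code uniqueness", len(codes) == len(set(codes)),
                              sorted({c for c in codes if codes.count(c) > 1})))
    iids = [i.id for i in d.informants]
    checks.append(CheckResult("informant id uniqueness", len(iids) == len(set(iids)),
                              sorted({i for i in iids if iids.count(i) > 1})))
    cids = [c.id for c in d.categories]
    checks.append(CheckResult("category id uniqueness", len(cids) == len(set(cids)),
                              sorted({c for c in cids if cids.count(c) > 1})))

    bad_lf = [s.code for s in d.species if s.life_form not in LIFE_FORMS]
    checks.append(CheckResult("life-form enum membership", not bad_lf, bad_lf))

    bad_age = [i.id for i in d.informants if not 18 <= i.age <= 120]
    checks.append(CheckResult("informant age range", not bad_age, bad_age))

    code_set, iid_set, cid_set = set(codes), set(iids), set(cids)
    dangling_s = [r for r in d.use_reports if r.species_code not in code_set]
    dangling_i = [r for r in d.use_reports if r.informant_id not in iid_set]
    dangling_c = [r for r in d.use_reports if r.category_id not in cid_set]
    checks.append(CheckResult("species foreign keys", not dangling_s, dangling_s))
    checks.append(CheckResult("informant foreign keys", not dangling_i, dangling_i))
    checks.append(CheckResult("category foreign keys", not dangling_c, dangling_c))

    checks.append(CheckResult("informant count consistency",
                              d.n_informants == len(d.informants), []))
    return ValidationReport(checks)


def dedupe_reports(reports: Iterable[UseReport]) -> list[UseReport]:
    """Collapse repeated (informant, species, category) triples: a use report
    counts informants, not repetitions within an interview."""
    seen, out = set(), []
    for r in reports:
        key = (r.informant_id, r.species_code, r.category_id)
        if key not in seen:
            seen.add(key)
            out.append(r)
    return out


# ---------------------------------------------------------------------------
# Writers

def write_dataset(d: Dataset, out_dir) -> dict[str, Path]:
    """Write the four CSVs in the package dialect; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}

    sp = pd.DataFrame([{
        "code": s.code, "family": s.family, "scientific_name": s.scientific_name,
        "vernacular_name": s.vernacular_name,
        "parts_used": _LIST_SEP.join(s.parts_used),
        "medicinal_uses": _LIST_SEP.join(s.medicinal_uses),
        "preparation": _LIST_SEP.join(s.preparation),
        "mode_of_application": s.mode_of_application,
        "life_form": s.life_form, "voucher_no": s.voucher_no,
    } for s in d.species])
    paths["species"] = out / "species.csv"
    sp.to_csv(paths["species"], index=False)

    inf = pd.DataFrame([{"informant_id": i.id, "age": i.age, "gender": i.gender}
                        for i in d.informants])
    paths["informants"] = out / "informants.csv"
    inf.to_csv(paths["informants"], index=False)

    cat = pd.DataFrame([{"category_id": c.id, "name": c.name} for c in d.categories])
    paths["categories"] = out / "categories.csv"
    cat.to_csv(paths["categories"], index=False)

    ur = pd.DataFrame([{"informant_id": r.informant_id,
                        "species_code": r.species_code,
                        "category_id": r.category_id} for r in d.use_reports],
                      columns=["informant_id", "species_code", "category_id"])
    paths["use_reports"] = out / "use_reports.csv"
    ur.to_csv(paths["use_reports"], index=False)
    return paths


def dataset_to_json(d: Dataset) -> str:
    """JSON export of the whole dataset for downstream tooling."""
    return json.dumps({
        "n_informants": d.n_informants,
        "informants": [asdict(i) for i in d.informants],
        "species": [asdict(s) for s in d.species],
        "categories": [asdict(c) for c in d.categories],
        "use_reports": [asdict(r) for r in d.use_reports],
    }, indent=2)
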