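"""Tabular input/output and shared domain types.

The pipeline consumes four kinds of tables: a participant questionnaire with
free-text medication entries, a semi-quantitative metabolite abundance matrix
with run-day labels and process-blank areas, an open drug vocabulary
(name/synonym -> active molecule, DrugBank ID, ATC codes), and a metabolite
annotation table.  All files are plain CSV/TSV with a header row; missing
values are empty cells or the literal ``NA`` and are written back as empty.

Column names are config-driven (YAML) because no canonical export schema
exists for these questionnaires; the defaults below define this package's
own dialect.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("medimatch")

#: Maximum number of free-text medication entries per participant.
MAX_MED_ENTRIES = 30

#: Indications with a dedicated treated-with-tablets questionnaire flag.
TABLET_INDICATIONS = ("hypertension", "dyslipidemia", "diabetes")

_NA_STRINGS = ("", "NA")


class SchemaError(ValueError):
    """A required column is missing or the file layout is wrong."""


class ValidationError(ValueError):
    """A value violates a domain invariant (range, uniqueness, cardinality)."""


class ParseError(ValueError):
    """The file is not a rectangular table of the expected shape."""


def setup_logging(level: int = logging.INFO) -> None:
    """Route package logs to stderr with a structured one-line format."""
    handler = logging.StreamHandler()
    handler.setFormatter(
        logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s")
    )
    logger.handlers[:] = [handler]
    logger.setLevel(level)


def load_config(path: str | Path) -> dict:
    """Load a YAML configuration file into a plain dict."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return cfg or {}


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class ParticipantRecord:
    """One participant: demographics, treatment flags and raw med entries."""

    participant_id: str
    age: int
    sex: str  # "male" | "female"
    bmi: float | None = None
    hba1c: float | None = None
    diagnosed_diabetes: bool = False
    treated_tablets: dict[str, bool] = field(default_factory=dict)
    med_entries: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.age < 18:
            raise ValidationError(
                f"participant {self.participant_id}: age {self.age} < 18"
            )
        if self.sex not in ("male", "female"):
            raise ValidationError(
                f"participant {self.participant_id}: sex must be male/female"
            )
        if len(self.med_entries) > MAX_MED_ENTRIES:
            raise ValidationError(
                f"participant {self.participant_id}: "
                f"{len(self.med_entries)} medication entries exceed the "
                f"questionnaire maximum of {MAX_MED_ENTRIES}"
            )


@dataclass
class MetaboliteInfo:
    """Platform annotation of one metabolite.

    ``confidence_tag`` is parsed from the display-name suffix convention:
    a trailing ``*`` marks an identification without an authentic standard,
    ``**`` a tentative one, and ``(<number>)`` a structural isomer; no suffix
    means the identity was confirmed against a standard.  Unknowns carry
    names beginning with ``X-`` and have no drug category.
    """

    metabolite_id: str
    display_name: str
    confidence_tag: str  # confirmed | star | double_star | isomer
    is_unknown: bool
    drug_category: str | None = None
    platform_mode: str | None = None  # neg | pos_early | pos_late | polar
    retention_index: float | None = None
    mass: float | None = None

    def __post_init__(self) -> None:
        if self.is_unknown and self.drug_category:
            raise ValidationError(
                f"{self.metabolite_id}: unknowns cannot carry a drug category"
            )


_ISOMER_RE = re.compile(r"\s*\((\d+)\)$")


def parse_confidence(display_name: str) -> tuple[str, str]:
    """Split a display name into (bare name, confidence tag).

    The suffix convention is lossless: ``name + suffix`` reconstructs the
    original display name.
    """
    name = display_name.strip()
    if name.endswith("**"):
        return name[:-2].rstrip(), "double_star"
    if name.endswith("*"):
        return name[:-1].rstrip(), "star"
    m = _ISOMER_RE.search(name)
    if m:
        return name[: m.start()].rstrip(), "isomer"
    return name, "confirmed"


@dataclass
class VocabularyEntry:
    """An active molecule in the drug vocabulary.

    ATC codes come through the DrugBank annotation, so a nonempty
    ``atc_codes`` requires a DrugBank identifier.  Combination products
    (``components``) carry the component molecule names and are split into
    one annotated item per component during curation.
    """

    molecule_name: str
    drugbank_id: str | None = None
    atc_codes: list[str] = field(default_factory=list)
    synonyms: list[str] = field(default_factory=list)
    components: list[str] | None = None

    def __post_init__(self) -> None:
        if self.atc_codes and not self.drugbank_id:
            raise ValidationError(
                f"{self.molecule_name}: ATC codes require a DrugBank ID"
            )
        if self.components is not None and len(self.components) < 2:
            raise ValidationError(
                f"{self.molecule_name}: a combination product needs >=2 components"
            )


@dataclass
class AbundanceMatrix:
    """Samples x metabolites area counts with run-day labels and blanks.

    ``areas`` keeps missing peaks as NaN — never zero: a missing value means
    "no approved peak", which is informative for detection calling.
    ``blank_area`` is a per-metabolite Series, or a run-day x metabolite
    DataFrame when per-run-day blanks are available.
    """

    areas: pd.DataFrame  # index = sample_ids, columns = metabolite_ids
    runday: pd.Series  # index = sample_ids
    blank_area: pd.Series | pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if not self.areas.index.equals(self.runday.index):
            raise ValidationError("every sample needs a run-day label")
        if (self.areas.to_numpy() < 0).any():
            raise ValidationError("negative area counts are not allowed")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.areas.index)

    @property
    def metabolite_ids(self) -> list[str]:
        return list(self.areas.columns)


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

DEFAULT_QUESTIONNAIRE_COLUMNS = {
    "participant_id": "participant_id",
    "age": "age",
    "sex": "sex",
    "bmi": "bmi",
    "hba1c": "hba1c",
    "diagnosed_diabetes": "diagnosed_diabetes",
    "treated_tablets_prefix": "treated_tablets_",
    "med_prefix": "med_",
}

_TRUE = {"1", "true", "yes", "y"}
_FALSE = {"0", "false", "no", "n", ""}


def _as_bool(value, column: str) -> bool:
    s = str(value).strip().lower()
    if s in _TRUE:
        return True
    if s in _FALSE or s == "nan":
        return False
    raise ValidationError(f"column {column}: cannot interpret {value!r} as boolean")


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    try:
        df = pd.read_csv(
            path, sep=sep, dtype=str, keep_default_na=False, na_values=_NA_STRINGS
        )
    except pd.errors.ParserError as exc:  # ragged rows etc.
        raise ParseError(f"{path}: {exc}") from exc
    return df


def read_questionnaire(
    path: str | Path, columns: Mapping[str, str] | None = None
) -> list[ParticipantRecord]:
    """Read a questionnaire table into participant records.

    One record per row; empty medication cells are dropped while the entry
    order of the remaining ones is preserved.
    """
    cols = dict(DEFAULT_QUESTIONNAIRE_COLUMNS)
    if columns:
        cols.update(columns)
    df = _read_table(path)
    for key in ("participant_id", "age", "sex"):
        if cols[key] not in df.columns:
            raise SchemaError(f"{path}: missing required column {cols[key]!r}")
    med_cols = [c for c in df.columns if c.startswith(cols["med_prefix"])]
    tt_prefix = cols["treated_tablets_prefix"]
    tt_cols = [c for c in df.columns if c.startswith(tt_prefix)]

    ids = df[cols["participant_id"]]
    dup = ids[ids.duplicated()]
    if len(dup):
        raise ValidationError(f"duplicate participant_id: {sorted(set(dup))}")

    records = []
    for _, row in df.iterrows():
        entries = [
            str(row[c]).strip()
            for c in med_cols
            if pd.notna(row[c]) and str(row[c]).strip()
        ]
        treated = {
            c[len(tt_prefix):]: _as_bool(row[c], c) for c in tt_cols
        }
        records.append(
            ParticipantRecord(
                participant_id=str(row[cols["participant_id"]]),
                age=int(float(row[cols["age"]])),
                sex=str(row[cols["sex"]]).strip().lower(),
                bmi=_opt_float(row, cols.get("bmi", "bmi")),
                hba1c=_opt_float(row, cols.get("hba1c", "hba1c")),
                diagnosed_diabetes=_as_bool(
                    row.get(cols["diagnosed_diabetes"], ""), cols["diagnosed_diabetes"]
                ),
                treated_tablets=treated,
                med_entries=entries,
            )
        )
    logger.info("read %d participant records from %s", len(records), path)
    return records


def _opt_float(row, col: str) -> float | None:
    if col not in row.index or pd.isna(row[col]) or str(row[col]).strip() == "":
        return None
    return float(row[col])


def write_questionnaire(
    records: Sequence[ParticipantRecord], path: str | Path
) -> None:
    """Write participant records back in the default questionnaire dialect."""
    n_med = max((len(r.med_entries) for r in records), default=0)
    tt_keys = sorted({k for r in records for k in r.treated_tablets})
    rows = []
    for r in records:
        row: dict[str, object] = {
            "participant_id": r.participant_id,
            "age": r.age,
            "sex": r.sex,
            "bmi": "" if r.bmi is None else r.bmi,
            "hba1c": "" if r.hba1c is None else r.hba1c,
            "diagnosed_diabetes": int(r.diagnosed_diabetes),
        }
        for k in tt_keys:
            row[f"treated_tablets_{k}"] = int(r.treated_tablets.get(k, False))
        for i in range(n_med):
            row[f"med_{i + 1:02d}"] = (
                r.med_entries[i] if i < len(r.med_entries) else ""
            )
        rows.append(row)
    write_results(pd.DataFrame(rows), path)


def read_abundance_matrix(
    path: str | Path,
    blank_path: str | Path | None = None,
    runday_column: str = "runday",
) -> AbundanceMatrix:
    """Read a samples x metabolites area table.

    The first column holds sample IDs and a ``runday`` column is required.
    Missing cells stay missing (NaN) — they are never coerced to zero.
    An optional blank table (``metabolite_id, blank_area[, runday]``)
    supplies process-blank areas.
    """
    df = _read_table(path)
    if runday_column not in df.columns:
        raise SchemaError(f"{path}: missing run-day column {runday_column!r}")
    sample_col = df.columns[0]
    df = df.set_index(sample_col)
    runday = df.pop(runday_column).astype(str)
    try:
        areas = df.apply(pd.to_numeric)
    except (ValueError, TypeError) as exc:
        raise ParseError(f"{path}: non-numeric area value ({exc})") from exc
    if (areas.to_numpy() < 0).any():
        raise ValidationError(f"{path}: negative area counts")
    blank = None
    if blank_path is not None:
        bdf = _read_table(blank_path)
        if "runday" in bdf.columns:
            blank = (
                bdf.pivot(index="runday", columns="metabolite_id", values="blank_area")
                .apply(pd.to_numeric)
            )
        else:
            blank = pd.Series(
                pd.to_numeric(bdf["blank_area"]).to_numpy(),
                index=bdf["metabolite_id"].astype(str),
            )
    mat = AbundanceMatrix(areas=areas, runday=runday, blank_area=blank)
    logger.info(
        "read abundance matrix %s: %d samples x %d metabolites",
        path, len(mat.sample_ids), len(mat.metabolite_ids),
    )
    return mat


def write_abundance_matrix(matrix: AbundanceMatrix, path: str | Path) -> None:
    out = matrix.areas.copy()
    out.insert(0, "runday", matrix.runday)
    out.index.name = "sample_id"
    write_results(out.reset_index(), path)


_DRUGBANK_ID_RE = re.compile(r"^DB\d{5}$")


def read_vocabulary(path: str | Path) -> list[VocabularyEntry]:
    """Read an open drug-vocabulary table.

    Expected columns: ``common_name, drugbank_id, atc_codes, synonyms,
    components`` with pipe-separated multi-valued cells.  Rows with a
    malformed DrugBank ID (not ``DB`` + 5 digits) are skipped with a warning.
    """
    df = _read_table(path)
    if "common_name" not in df.columns:
        raise SchemaError(f"{path}: missing required column 'common_name'")
    entries = []
    for _, row in df.iterrows():
        dbid = _cell(row, "drugbank_id")
        if dbid and not _DRUGBANK_ID_RE.match(dbid):
            logger.warning(
                "skipping vocabulary row %r: malformed DrugBank ID %r",
                row["common_name"], dbid,
            )
            continue
        components = _split_cell(row, "components") or None
        entries.append(
            VocabularyEntry(
                molecule_name=str(row["common_name"]).strip(),
                drugbank_id=dbid or None,
                atc_codes=_split_cell(row, "atc_codes"),
                synonyms=_split_cell(row, "synonyms"),
                components=components,
            )
        )
    if not entries:
        logger.warning("vocabulary %s is empty", path)
    return entries


def _cell(row, col: str) -> str:
    if col not in row.index or pd.isna(row[col]):
        return ""
    return str(row[col]).strip()


def _split_cell(row, col: str) -> list[str]:
    raw = _cell(row, col)
    return [tok.strip() for tok in raw.split("|") if tok.strip()]


def read_metabolite_annotations(path: str | Path) -> list[MetaboliteInfo]:
    """Read the metabolite annotation table.

    Expected columns: ``metabolite_id, display_name, drug_category,
    platform_mode, retention_index, mass``; confidence suffixes are parsed
    from ``display_name``, and names beginning ``X-`` mark unknowns.
    """
    df = _read_table(path)
    for col in ("metabolite_id", "display_name"):
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")
    infos = []
    for _, row in df.iterrows():
        display = str(row["display_name"]).strip()
        bare, tag = parse_confidence(display)
        is_unknown = bare.startswith("X-")
        infos.append(
            MetaboliteInfo(
                metabolite_id=str(row["metabolite_id"]).strip(),
                display_name=display,
                confidence_tag=tag,
                is_unknown=is_unknown,
                drug_category=(_cell(row, "drug_category") or None)
                if not is_unknown
                else None,
                platform_mode=_cell(row, "platform_mode") or None,
                retention_index=_opt_float(row, "retention_index"),
                mass=_opt_float(row, "mass"),
            )
        )
    return infos


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------


def write_results(
    table: pd.DataFrame, path: str | Path, float_precision: int = 6
) -> None:
    """Write a result table as TSV/CSV with a deterministic layout.

    Column order is taken from the frame as given; floats are rendered at a
    fixed precision so re-writing identical inputs is byte-identical.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    try:
        table.to_csv(
            path, sep=sep, index=False, float_format=f"%.{float_precision}g",
            na_rep="",
        )
    except OSError as exc:
        raise IOError(f"cannot write {path}: {exc}") from exc
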