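"""Curation of free-text medication responses into annotated molecules.

Free-text questionnaire answers ("Aspirin 81mg daily", "tablets for blood
pressure", misspellings) are resolved against a drug vocabulary into active
molecules with DrugBank IDs and ATC codes.  The resolution order is:

1. exact match of the normalized text against molecule names and synonyms;
2. bounded edit-distance (fuzzy) match, to absorb spelling errors;
3. combination products are split into one item per active component;
4. indication-phrase fallback: answers that only name a disease become
   ``unspecified [indication]`` items;
5. anything else is kept as ``not_annotated``.

Dose and frequency tokens (numbers, mg/ml/IU units, "daily", ...) carry no
information for molecule identity and are stripped before matching.
"""

from __future__ import annotations

import re
import string
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import edlib
import pandas as pd

from .io import ParticipantRecord, VocabularyEntry, logger

#: Age bands used for usage-by-age tabulation.
AGE_BANDS = ((18, 24), (25, 34), (35, 44), (45, 54), (55, 64), (65, 120))

#: ATC code prefix length per hierarchy level.
_ATC_LEVEL_LEN = {1: 1, 2: 3, 3: 4, 4: 5, 5: 7}


@dataclass
class AnnotatedMedication:
    """One curated medication item derived from a free-text entry."""

    participant_id: str
    raw_text: str
    status: str  # annotated | unspecified_indication | not_annotated
    molecule_name: str | None = None
    drugbank_id: str | None = None
    atc_codes: list[str] = field(default_factory=list)
    indication: str | None = None

    def __post_init__(self) -> None:
        if self.status == "annotated" and not self.molecule_name:
            raise ValueError("annotated items need a molecule name")
        if self.status == "unspecified_indication":
            if not self.indication:
                raise ValueError("unspecified items need an indication")
            self.molecule_name = f"unspecified {self.indication}"
        if self.status == "not_annotated" and self.drugbank_id:
            raise ValueError("not_annotated items cannot carry a DrugBank ID")


@dataclass
class MatchCandidate:
    entry: VocabularyEntry
    distance: int
    matched_text: str


_DOSE_UNIT_RE = re.compile(
    r"\b\d+(?:[.,]\d+)?\s*(?:mg|mcg|ug|µg|g|kg|ml|l|iu|units?|%)\b", re.IGNORECASE
)
_NUMBER_RE = re.compile(r"\b\d+(?:[.,]\d+)?\b")
_FREQ_TOKENS = {
    "daily", "weekly", "monthly", "nightly", "once", "twice", "every",
    "morning", "evening", "night", "day", "week", "month", "per", "a",
    "tablet", "tablets", "tab", "tabs", "capsule", "capsules", "cap", "caps",
    "pill", "pills", "injection", "injections", "dose", "doses", "od", "bd",
    "tds", "prn",
}
_PUNCT_TABLE = str.maketrans({c: " " for c in string.punctuation})


def normalize_text(raw: str) -> str:
    """Case-fold and strip punctuation, dose and frequency tokens."""
    s = raw.casefold()
    s = _DOSE_UNIT_RE.sub(" ", s)
    s = s.translate(_PUNCT_TABLE)
    s = _NUMBER_RE.sub(" ", s)
    tokens = [t for t in s.split() if t not in _FREQ_TOKENS]
    return " ".join(tokens)


class Vocabulary:
    """Indexed drug vocabulary supporting exact and fuzzy lookup."""

    def __init__(self, entries: Sequence[VocabularyEntry]):
        self.entries = list(entries)
        self.by_name: dict[str, VocabularyEntry] = {}
        self._index: dict[str, VocabularyEntry] = {}
        for entry in self.entries:
            self.by_name[entry.molecule_name.casefold()] = entry
            for key in (entry.molecule_name, *entry.synonyms):
                norm = normalize_text(key)
                if norm:
                    # first-registered entry wins on key collisions
                    self._index.setdefault(norm, entry)

    def lookup_exact(self, normalized: str) -> VocabularyEntry | None:
        return self._index.get(normalized)

    def lookup_fuzzy(
        self, normalized: str, max_edit_distance: int
    ) -> MatchCandidate | None:
        """Best bounded-edit-distance match; deterministic tie-breaking.

        The distance cap shrinks to 1 for short queries (<=5 characters) so
        that short drug names cannot be merged by aggressive fuzzing.  Ties
        are broken by (distance, shorter canonical name, lexicographic).
        """
        cap = max_edit_distance if len(normalized) > 5 else min(1, max_edit_distance)
        if cap <= 0 or not normalized:
            return None
        best: tuple[int, int, str] | None = None
        best_match: MatchCandidate | None = None
        for key, entry in self._index.items():
            res = edlib.align(normalized, key, task="distance", k=cap)
            dist = res["editDistance"]
            if dist < 0:
                continue
            rank = (dist, len(entry.molecule_name), entry.molecule_name)
            if best is None or rank < best:
                best = rank
                best_match = MatchCandidate(entry, dist, key)
        return best_match


def normalize_entry(
    raw: str, vocabulary: Vocabulary, max_edit_distance: int = 2
) -> MatchCandidate | None:
    """Resolve a raw free-text entry to a vocabulary candidate, or None."""
    normalized = normalize_text(raw)
    if not normalized:
        return None
    exact = vocabulary.lookup_exact(normalized)
    if exact is not None:
        return MatchCandidate(exact, 0, normalized)
    return vocabulary.lookup_fuzzy(normalized, max_edit_distance)


def split_combination(
    entry: VocabularyEntry, vocabulary: Vocabulary
) -> list[VocabularyEntry]:
    """Expand a combination product into its component molecules.

    Single-molecule entries return themselves.  A component missing from the
    vocabulary is kept as an annotated molecule without a DrugBank ID.
    """
    if not entry.components:
        return [entry]
    out = []
    for name in entry.components:
        comp = vocabulary.by_name.get(name.casefold())
        if comp is None:
            logger.warning(
                "component %r of %r not in vocabulary; keeping without DrugBank ID",
                name, entry.molecule_name,
            )
            comp = VocabularyEntry(molecule_name=name)
        out.append(comp)
    return out


def annotate_entry(
    raw: str,
    participant_id: str,
    vocabulary: Vocabulary,
    indication_lexicon: Mapping[str, str],
    max_edit_distance: int = 2,
) -> list[AnnotatedMedication]:
    """Annotate one free-text entry; combination products yield >=1 item."""
    candidate = normalize_entry(raw, vocabulary, max_edit_distance)
    if candidate is not None:
        meds = []
        for comp in split_combination(candidate.entry, vocabulary):
            meds.append(
                AnnotatedMedication(
                    participant_id=participant_id,
                    raw_text=raw,
                    status="annotated",
                    molecule_name=comp.molecule_name,
                    drugbank_id=comp.drugbank_id,
                    atc_codes=list(comp.atc_codes),
                )
            )
        return meds
    normalized = normalize_text(raw)
    for phrase, indication in indication_lexicon.items():
        if normalize_text(phrase) and normalize_text(phrase) in normalized:
            return [
                AnnotatedMedication(
                    participant_id=participant_id,
                    raw_text=raw,
                    status="unspecified_indication",
                    indication=indication,
                )
            ]
    return [
        AnnotatedMedication(
            participant_id=participant_id, raw_text=raw, status="not_annotated"
        )
    ]


def assign_atc(
    med: AnnotatedMedication, vocabulary: Vocabulary
) -> AnnotatedMedication:
    """Copy ATC codes from the vocabulary onto an annotated item.

    Items whose molecule has no DrugBank entry (or whose entry carries no
    codes) keep an empty list.
    """
    if med.status != "annotated" or med.molecule_name is None:
        return med
    entry = vocabulary.by_name.get(med.molecule_name.casefold())
    if entry is not None:
        med.atc_codes = list(entry.atc_codes)
        med.drugbank_id = entry.drugbank_id
    return med


def annotate_cohort(
    participants: Sequence[ParticipantRecord],
    vocabulary: Vocabulary,
    indication_lexicon: Mapping[str, str],
    max_edit_distance: int = 2,
) -> list[AnnotatedMedication]:
    """Annotate every medication entry of every participant."""
    meds = []
    for rec in participants:
        for raw in rec.med_entries:
            meds.extend(
                annotate_entry(
                    raw, rec.participant_id, vocabulary, indication_lexicon,
                    max_edit_distance,
                )
            )
    n_status = pd.Series([m.status for m in meds]).value_counts().to_dict()
    logger.info("annotated %d items: %s", len(meds), n_status)
    return meds


def atc_prefix(code: str, level: int) -> str:
    """Truncate a 7-character ATC code to the requested hierarchy level."""
    if level not in _ATC_LEVEL_LEN:
        raise ValueError(f"ATC level must be 1..5, got {level}")
    return code[: _ATC_LEVEL_LEN[level]]


def usage_sets(
    meds: Iterable[AnnotatedMedication],
) -> dict[str, set[str]]:
    """Participant-ID set per medication item (molecule or unspecified-X)."""
    sets: dict[str, set[str]] = {}
    for m in meds:
        if m.molecule_name is None:
            continue
        sets.setdefault(m.molecule_name, set()).add(m.participant_id)
    return sets


def tabulate_usage(
    meds: Sequence[AnnotatedMedication],
    participants: Sequence[ParticipantRecord],
    atc_level: int = 2,
) -> dict[str, pd.DataFrame]:
    """Usage counts per molecule, per ATC class, and by age band and sex.

    Molecule counts are entry-level (one response item = one count); ATC
    class counts de-duplicate participants, so a participant reporting two
    drugs of one class counts once.  Frequencies are the fraction of
    participants in each age-band x sex stratum reporting at least one drug
    of the class.
    """
    demo = {p.participant_id: p for p in participants}

    mol_counts = (
        pd.Series([m.molecule_name for m in meds if m.molecule_name])
        .value_counts()
        .rename_axis("molecule")
        .reset_index(name="n_entries")
    )

    class_members: dict[str, set[str]] = {}
    for m in meds:
        for code in m.atc_codes:
            class_members.setdefault(atc_prefix(code, atc_level), set()).add(
                m.participant_id
            )
    class_counts = pd.DataFrame(
        sorted((c, len(ids)) for c, ids in class_members.items()),
        columns=["atc_class", "n_participants"],
    )

    rows = []
    for lo, hi in AGE_BANDS:
        for sex in ("male", "female"):
            stratum = {
                pid for pid, p in demo.items() if lo <= p.age <= hi and p.sex == sex
            }
            if not stratum:
                continue
            for cls, ids in sorted(class_members.items()):
                rows.append(
                    {
                        "age_band": f"{lo}-{hi}",
                        "sex": sex,
                        "atc_class": cls,
                        "n": len(stratum & ids),
                        "frequency": len(stratum & ids) / len(stratum),
                    }
                )
    by_age_sex = pd.DataFrame(rows)
    return {
        "molecules": mol_counts,
        "atc_classes": class_counts,
        "by_age_sex": by_age_sex,
    }


def meds_to_frame(meds: Sequence[AnnotatedMedication]) -> pd.DataFrame:
    """Flatten annotated items for TSV export."""
    return pd.DataFrame(
        {
            "participant_id": [m.participant_id for m in meds],
            "raw_text": [m.raw_text for m in meds],
            "status": [m.status for m in meds],
            "molecule": [m.molecule_name or "" for m in meds],
            "drugbank_id": [m.drugbank_id or "" for m in meds],
            "atc_codes": ["|".join(m.atc_codes) for m in meds],
        }
    )
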