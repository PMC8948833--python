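"""Three-way concordance per indication.

For a frequent disorder (hypertension, dyslipidemia, diabetes) three
participant sets are compared: A — answered yes to "treated for <disorder>
with tablets"; B — self-reported at least one medication whose ATC code
falls in the disorder's drug classes (or an unspecified-<disorder> answer);
C — has at least one metabolite of such a drug detected in their blood
sample.  Overlap is summarized as Venn region counts and the discordance
percentages of interest (triple overlap, questionnaire-internal
disagreement, detected-only, reported-but-not-detected).
"""

from __future__ import annotations

import importlib.resources
import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd
import yaml

from .curation import AnnotatedMedication
from .detection import DetectionMatrix
from .io import MetaboliteInfo, ParticipantRecord, ValidationError


@dataclass
class IndicationMap:
    """ATC prefixes and metabolites assigned to one indication."""

    indication: str
    atc_prefixes: list[str]
    metabolite_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.atc_prefixes = [p.upper() for p in self.atc_prefixes]
        for p in self.atc_prefixes:
            if not 1 <= len(p) <= 7:
                raise ValidationError(f"bad ATC prefix {p!r}")


@dataclass
class VennSummary:
    """Region counts of a 2- or 3-way set overlap."""

    set_labels: list[str]
    region_counts: dict[str, int]  # signature "110" -> |A ∩ B \ C|
    totals: dict[str, int]

    @property
    def union_size(self) -> int:
        return sum(self.region_counts.values())


def load_indication_maps(
    path: str | None = None,
    annotations: Sequence[MetaboliteInfo] | None = None,
    category_to_indication: Mapping[str, str] | None = None,
) -> dict[str, IndicationMap]:
    """Load the shipped (or a custom) indication -> ATC-prefix map.

    When platform annotations and a category->indication mapping are given,
    each indication's metabolite list is filled from the drug-category
    column, plus any per-indication overrides in the file.
    """
    if path is None:
        ref = importlib.resources.files("medimatch.data") / "indication_atc_map.yaml"
        with importlib.resources.as_file(ref) as p:
            raw = yaml.safe_load(p.read_text())
    else:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    maps = {}
    for name, spec in raw.items():
        mets = list(spec.get("metabolite_overrides") or [])
        if annotations and category_to_indication:
            for info in annotations:
                if (
                    info.drug_category
                    and category_to_indication.get(info.drug_category) == name
                ):
                    mets.append(info.metabolite_id)
        maps[name] = IndicationMap(
            indication=name,
            atc_prefixes=list(spec["atc_prefixes"]),
            metabolite_ids=sorted(set(mets)),
        )
    return maps


def indication_sets(
    participants: Sequence[ParticipantRecord],
    annotated_meds: Sequence[AnnotatedMedication],
    det: DetectionMatrix,
    imap: IndicationMap,
) -> tuple[set[str], set[str], set[str]]:
    """Build the (tablet-flag, self-report, blood-detection) sets."""
    flagged = set()
    for p in participants:
        if imap.indication not in p.treated_tablets:
            raise ValidationError(
                f"questionnaire lacks a tablet flag for {imap.indication!r}"
            )
        if p.treated_tablets[imap.indication]:
            flagged.add(p.participant_id)

    reported = set()
    for m in annotated_meds:
        if m.status == "unspecified_indication" and m.indication == imap.indication:
            reported.add(m.participant_id)
        elif any(
            code.upper().startswith(tuple(imap.atc_prefixes)) for code in m.atc_codes
        ):
            reported.add(m.participant_id)

    mets = [m for m in imap.metabolite_ids if m in det.detected.columns]
    detected = set()
    if mets:
        any_det = det.detected[mets].any(axis=1)
        detected = set(any_det.index[any_det])
    return flagged, reported, detected


def venn_regions(sets: Mapping[str, set]) -> VennSummary:
    """Exact region counts for 2 or 3 labelled sets."""
    labels = list(sets)
    if len(labels) not in (2, 3):
        raise ValidationError("venn_regions supports 2 or 3 sets")
    region_counts = {}
    for signature in itertools.product((1, 0), repeat=len(labels)):
        if not any(signature):
            continue
        members = set.intersection(
            *(sets[l] for l, bit in zip(labels, signature) if bit)
        )
        for l, bit in zip(labels, signature):
            if not bit:
                members = members - sets[l]
        region_counts["".join(map(str, signature))] = len(members)
    return VennSummary(
        set_labels=labels,
        region_counts=region_counts,
        totals={l: len(sets[l]) for l in labels},
    )


def concordance_report(
    summaries: Mapping[str, VennSummary],
) -> pd.DataFrame:
    """Summary percentages per indication, relative to the union.

    Expects 3-set summaries labelled (tablet_flag, self_report, detected)
    in that order.  Reported percentages: triple overlap; questionnaire-
    internal discordance (tablet flag XOR self-report); detected-only; and
    reported (either way) but not detected.  An empty union yields missing
    values.
    """
    rows = []
    for indication, s in summaries.items():
        rc = s.region_counts
        union = s.union_size
        if union == 0:
            rows.append(
                {
                    "indication": indication, "union": 0,
                    "triple_overlap_pct": float("nan"),
                    "questionnaire_discordance_pct": float("nan"),
                    "detected_only_pct": float("nan"),
                    "reported_not_detected_pct": float("nan"),
                }
            )
            continue
        triple = rc.get("111", 0)
        q_discord = rc.get("100", 0) + rc.get("101", 0) + rc.get("010", 0) + rc.get("011", 0)
        detected_only = rc.get("001", 0)
        reported_not_det = rc.get("100", 0) + rc.get("010", 0) + rc.get("110", 0)
        rows.append(
            {
                "indication": indication,
                "union": union,
                "triple_overlap_pct": 100 * triple / union,
                "questionnaire_discordance_pct": 100 * q_discord / union,
                "detected_only_pct": 100 * detected_only / union,
                "reported_not_detected_pct": 100 * reported_not_det / union,
            }
        )
    return pd.DataFrame(rows)


def venn_to_frame(summary: VennSummary) -> pd.DataFrame:
    rows = [
        {"region": sig, "count": n,
         "pct_of_union": 100 * n / summary.union_size if summary.union_size else 0.0}
        for sig, n in sorted(summary.region_counts.items(), reverse=True)
    ]
    return pd.DataFrame(rows)
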