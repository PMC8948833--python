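"""False-positive analysis: detection rates and abundance levels by group.

The canonical contrast is metformin: participants who self-reported the
drug versus participants who are very unlikely to take it (BMI < 25 kg/m²,
HbA1c < 5.7%, no diabetes diagnosis, no self-reported diabetes medication —
all strict inequalities).  If detections in the unlikely group were true
positives one would expect user-like abundance levels; much lower levels
point to misidentification or experimental artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .curation import AnnotatedMedication
from .detection import DetectionMatrix
from .io import AbundanceMatrix, ParticipantRecord, ValidationError

#: Below this bound a p-value is reported as the bound ("p < 1e-16").
P_FLOOR = 1e-16


@dataclass
class GroupDefinition:
    """Predicate over a participant and their annotated medication.

    Either ``required_molecule`` (membership = self-reported that molecule)
    or threshold criteria (all strict ``<`` comparisons, plus exclusions by
    diagnosis, ATC prefix and unspecified indication).
    """

    name: str
    required_molecule: str | None = None
    bmi_max: float | None = None
    hba1c_max: float | None = None
    exclude_diagnosed_diabetes: bool = False
    excluded_atc_prefixes: list[str] = field(default_factory=list)
    excluded_indications: list[str] = field(default_factory=list)

    def matches(
        self, participant: ParticipantRecord, meds: Sequence[AnnotatedMedication]
    ) -> bool:
        if self.required_molecule is not None:
            return any(
                m.molecule_name == self.required_molecule for m in meds
            )
        if self.bmi_max is not None and not (
            participant.bmi is not None and participant.bmi < self.bmi_max
        ):
            return False
        if self.hba1c_max is not None and not (
            participant.hba1c is not None and participant.hba1c < self.hba1c_max
        ):
            return False
        if self.exclude_diagnosed_diabetes and participant.diagnosed_diabetes:
            return False
        for m in meds:
            if any(
                code.upper().startswith(tuple(p.upper() for p in self.excluded_atc_prefixes))
                for code in m.atc_codes
            ) and self.excluded_atc_prefixes:
                return False
            if (
                m.status == "unspecified_indication"
                and m.indication in self.excluded_indications
            ):
                return False
        return True


METFORMIN_CONTRAST = (
    GroupDefinition(name="self_reported_metformin", required_molecule="metformin"),
    GroupDefinition(
        name="unlikely_user",
        bmi_max=25.0,
        hba1c_max=5.7,
        exclude_diagnosed_diabetes=True,
        excluded_atc_prefixes=["A10"],
        excluded_indications=["diabetes"],
    ),
)


def assign_groups(
    participants: Sequence[ParticipantRecord],
    annotated_meds: Sequence[AnnotatedMedication],
    contrast: tuple[GroupDefinition, GroupDefinition] = METFORMIN_CONTRAST,
) -> tuple[set[str], set[str]]:
    """Split participants into the two contrast groups (disjoint)."""
    meds_by_pid: dict[str, list[AnnotatedMedication]] = {}
    for m in annotated_meds:
        meds_by_pid.setdefault(m.participant_id, []).append(m)
    g1, g2 = set(), set()
    for p in participants:
        meds = meds_by_pid.get(p.participant_id, [])
        in1 = contrast[0].matches(p, meds)
        in2 = contrast[1].matches(p, meds)
        if in1:
            g1.add(p.participant_id)
        elif in2:
            g2.add(p.participant_id)
    assert not (g1 & g2), "contrast groups must be disjoint"
    return g1, g2


def detection_rates(
    groups: Mapping[str, set[str]], det: DetectionMatrix, metabolite: str
) -> pd.DataFrame:
    """Count and fraction of each group with the metabolite detected."""
    detected = det.detected_in(metabolite)
    rows = []
    for name, members in groups.items():
        linked = members & set(det.sample_ids)
        n_det = len(linked & detected)
        rows.append(
            {
                "group": name,
                "n": len(linked),
                "n_detected": n_det,
                "fraction": n_det / len(linked) if linked else float("nan"),
            }
        )
    return pd.DataFrame(rows)


def compare_levels(
    groups: Mapping[str, set[str]],
    matrix: AbundanceMatrix,
    det: DetectionMatrix,
    metabolite: str,
    test: str = "welch",
) -> dict:
    """Compare log2 abundance levels between two groups, among detections.

    Levels only exist where the metabolite was detected, so the comparison
    conditions on detection.  The default test is Welch's two-sample t on
    the log2-scaled normalized areas; ``test="ranksum"`` switches to a
    Mann-Whitney U.  p-values below 1e-16 are reported at that floor with
    ``p_below_floor`` set.  A group with fewer than 2 detected samples
    yields a missing p.
    """
    if len(groups) != 2:
        raise ValidationError("compare_levels needs exactly two groups")
    detected = det.detected_in(metabolite)
    names = list(groups)
    levels = {}
    for name in names:
        samples = sorted(groups[name] & detected & set(matrix.areas.index))
        vals = matrix.areas.loc[samples, metabolite].dropna()
        levels[name] = np.log2(vals.to_numpy())
    x, y = levels[names[0]], levels[names[1]]
    out = {
        "metabolite": metabolite,
        "groups": names,
        "n": {names[0]: len(x), names[1]: len(y)},
        "mean_log2": {
            names[0]: float(np.mean(x)) if len(x) else float("nan"),
            names[1]: float(np.mean(y)) if len(y) else float("nan"),
        },
    }
    if len(x) < 2 or len(y) < 2:
        out.update(difference=float("nan"), p_value=None, p_below_floor=False)
        return out
    out["difference"] = float(np.mean(x) - np.mean(y))
    if test == "welch":
        p = float(stats.ttest_ind(x, y, equal_var=False).pvalue)
    elif test == "ranksum":
        p = float(stats.mannwhitneyu(x, y, alternative="two-sided").pvalue)
    else:
        raise ValidationError(f"unknown test {test!r}")
    out["p_below_floor"] = p < P_FLOOR
    out["p_value"] = max(p, P_FLOOR) if out["p_below_floor"] else p
    return out
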