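"""Joint detection of multiple metabolites of one parent drug.

A drug that is cleared through several detoxification routes (sulfation by
SULT enzymes, glucuronidation by UGT, glutathione conjugation via CYP
intermediates) leaves a panel of correlated metabolites in plasma.  Their
joint detection across samples is strong evidence that the detections are
true positives even when self-reports are rare — the acetaminophen panel
(the parent compound plus eight conjugates) is the canonical example.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .concordance import VennSummary, venn_regions
from .detection import DetectionMatrix
from .io import ValidationError

PATHWAYS = ("SULT", "UGT", "CYP", "parent", "mixed")


@dataclass
class MetaboliteSet:
    """Metabolites of one parent drug with their pathway labels."""

    parent_drug: str
    members: list[str]
    pathway_labels: dict[str, str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValidationError("a metabolite set needs >=1 member")
        for m in self.members:
            label = self.pathway_labels.get(m)
            if label is None:
                raise ValidationError(f"member {m!r} has no pathway label")
            if label not in PATHWAYS:
                raise ValidationError(f"member {m!r}: unknown pathway {label!r}")

    def pathway_members(self, pathway: str) -> list[str]:
        """Members of one route; 'mixed' members belong to SULT and CYP."""
        return [
            m for m in self.members
            if self.pathway_labels[m] == pathway
            or (self.pathway_labels[m] == "mixed" and pathway in ("SULT", "CYP"))
        ]


def load_acetaminophen_set() -> MetaboliteSet:
    """The shipped nine-metabolite acetaminophen panel with pathway labels."""
    ref = importlib.resources.files("medimatch.data") / "acetaminophen_panel.csv"
    with importlib.resources.as_file(ref) as path:
        df = pd.read_csv(path)
    return MetaboliteSet(
        parent_drug="acetaminophen",
        members=list(df["metabolite_id"]),
        pathway_labels=dict(zip(df["metabolite_id"], df["pathway"])),
    )


def joint_detection(det: DetectionMatrix, mset: MetaboliteSet) -> dict:
    """Counts of samples with all / any / each member detected."""
    missing = [m for m in mset.members if m not in det.detected.columns]
    if missing:
        raise ValidationError(f"members not in detection matrix: {missing}")
    sub = det.detected[mset.members]
    n = len(sub)
    per_member = sub.sum(axis=0).astype(int)
    return {
        "parent_drug": mset.parent_drug,
        "n_samples": n,
        "n_all": int(sub.all(axis=1).sum()),
        "n_any": int(sub.any(axis=1).sum()),
        "per_member": per_member.to_dict(),
        "per_member_fraction": (per_member / n).to_dict() if n else {},
    }


def pathway_grouping(
    det: DetectionMatrix, mset: MetaboliteSet
) -> dict[str, VennSummary]:
    """Venn summaries per detox pathway, plus one across representatives.

    For each pathway, the overlap of the detection sample-sets of the
    members *specific* to it (mixed-route members are excluded from the
    per-pathway Venns but still eligible as representatives); the
    ``representatives`` summary compares the most frequently detected
    member of each of SULT, UGT and CYP.
    """
    out: dict[str, VennSummary] = {}
    counts = det.detected[mset.members].sum(axis=0)
    reps = {}
    for pathway in ("SULT", "UGT", "CYP"):
        members = mset.pathway_members(pathway)
        if members:
            reps[pathway] = max(members, key=lambda m: (counts[m], m))
        specific = [m for m in members if mset.pathway_labels[m] == pathway]
        if len(specific) < 2 or len(specific) > 3:
            continue
        out[pathway] = venn_regions(
            {m: det.detected_in(m) for m in specific}
        )
    if len(reps) in (2, 3):
        out["representatives"] = venn_regions(
            {f"{pw}:{m}": det.detected_in(m) for pw, m in reps.items()}
        )
    return out


def conditional_codetection(
    det: DetectionMatrix,
    mset: MetaboliteSet,
    reporters: set[str],
    sample_of: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Per-member detection count and fraction among reporting participants.

    ``sample_of`` maps participant to sample ID when they differ; reporters
    without a linked sample are excluded with a warning.
    """
    from .io import logger

    sample_map = sample_of or {}
    samples = []
    for pid in sorted(reporters):
        sid = sample_map.get(pid, pid)
        if sid in det.detected.index:
            samples.append(sid)
        else:
            logger.warning("reporter %s has no linked sample; excluded", pid)
    rows = []
    n = len(samples)
    for m in mset.members:
        n_det = int(det.detected.loc[samples, m].sum()) if n else 0
        rows.append(
            {
                "metabolite": m,
                "pathway": mset.pathway_labels[m],
                "n_reporters": n,
                "n_detected": n_det,
                "fraction": n_det / n if n else float("nan"),
            }
        )
    return pd.DataFrame(rows)
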