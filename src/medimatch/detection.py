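"""Detection calling on semi-quantitative metabolomics matrices.

Two preprocessing rules turn area counts into boolean presence calls:

* run-day normalization — areas are scaled within each run-day block so the
  per-metabolite block median equals one, removing day-to-day instrument
  drift;
* blank thresholding — a peak counts as detected only when its area is at
  least ``blank_multiplier`` times the process-blank area for that
  metabolite (peaks below 3x blank are instrument artifacts of sample
  preparation, e.g. plasticizers).  An area exactly at the threshold is
  kept: only areas strictly below it are rejected.

Missing areas are never detections.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .io import AbundanceMatrix, MetaboliteInfo, ValidationError, logger


@dataclass
class DetectionMatrix:
    """Boolean samples x metabolites presence calls with provenance."""

    detected: pd.DataFrame  # bool, same shape/labels as the source areas
    source: AbundanceMatrix | None = None
    blank_multiplier: float | None = None

    @property
    def sample_ids(self) -> list[str]:
        return list(self.detected.index)

    @property
    def metabolite_ids(self) -> list[str]:
        return list(self.detected.columns)

    def detected_in(self, metabolite_id: str) -> set[str]:
        """Sample IDs in which the metabolite was detected."""
        col = self.detected[metabolite_id]
        return set(col.index[col])


def normalize_rundays(matrix: AbundanceMatrix) -> AbundanceMatrix:
    """Register per-metabolite medians to one within each run-day block.

    Present values in a block are divided by their median; missing values
    stay missing.  A block in which a metabolite has no present value is
    left untouched (with a warning): there is nothing to scale.

    Blank areas are divided by the same per-block medians (scalar blanks
    become a run-day x metabolite table), so detection calls are invariant
    under normalization.
    """
    out = matrix.areas.copy()
    medians = {}
    for day, block in matrix.areas.groupby(matrix.runday, sort=False):
        med = block.median(axis=0, skipna=True)
        all_missing = med.isna()
        if all_missing.any():
            logger.warning(
                "run-day %s: %d metabolites all-missing, left unnormalized",
                day, int(all_missing.sum()),
            )
        med = med.where(~all_missing & (med != 0), 1.0)
        out.loc[block.index] = block / med
        medians[day] = med
    med_df = pd.DataFrame(medians).T  # run-day x metabolite
    blank = matrix.blank_area
    if isinstance(blank, pd.Series):
        blank = blank.reindex(matrix.areas.columns) / med_df
    elif isinstance(blank, pd.DataFrame):
        blank = blank.reindex(columns=matrix.areas.columns) / med_df
    return AbundanceMatrix(areas=out, runday=matrix.runday.copy(), blank_area=blank)


def call_detection(
    matrix: AbundanceMatrix, blank_multiplier: float = 3.0,
    presence_only: bool = False,
) -> DetectionMatrix:
    """Call a metabolite detected when its area is >= multiplier x blank.

    Metabolites without a blank area are treated as blank 0 (always
    detected when present), with a warning.  ``presence_only`` degrades the
    call to "any present value is a detection" for exports that carry no
    raw areas.
    """
    if blank_multiplier <= 0:
        raise ValidationError("blank_multiplier must be positive")
    present = matrix.areas.notna()
    if presence_only:
        return DetectionMatrix(detected=present, source=matrix,
                               blank_multiplier=None)
    blank = matrix.blank_area
    if blank is None:
        logger.warning("no blank areas available; treating blanks as 0")
        threshold = pd.DataFrame(
            0.0, index=matrix.areas.index, columns=matrix.areas.columns
        )
    elif isinstance(blank, pd.DataFrame):  # per-run-day blanks
        blank = blank.reindex(columns=matrix.areas.columns)
        missing = blank.isna().any(axis=0)
        if missing.any():
            logger.warning(
                "%d metabolites lack blanks; treated as 0", int(missing.sum())
            )
        per_sample = blank.fillna(0.0).loc[matrix.runday.to_numpy()]
        per_sample.index = matrix.areas.index
        threshold = per_sample * blank_multiplier
    else:
        blank = blank.reindex(matrix.areas.columns)
        missing = blank.isna()
        if missing.any():
            logger.warning(
                "%d metabolites lack blanks; treated as 0", int(missing.sum())
            )
        threshold = pd.DataFrame(
            np.broadcast_to(
                (blank.fillna(0.0) * blank_multiplier).to_numpy(),
                matrix.areas.shape,
            ),
            index=matrix.areas.index,
            columns=matrix.areas.columns,
        )
    detected = present & (matrix.areas >= threshold)
    return DetectionMatrix(
        detected=detected.fillna(False).astype(bool),
        source=matrix,
        blank_multiplier=blank_multiplier,
    )


def category_prevalence(
    det: DetectionMatrix, annotations: Sequence[MetaboliteInfo]
) -> pd.DataFrame:
    """Fraction of samples with >=1 detection per drug category."""
    by_cat: dict[str, list[str]] = {}
    for info in annotations:
        if info.drug_category and info.metabolite_id in det.detected.columns:
            by_cat.setdefault(info.drug_category, []).append(info.metabolite_id)
    n = len(det.sample_ids)
    rows = [
        {
            "drug_category": cat,
            "n_metabolites": len(mets),
            "n_samples": int(det.detected[mets].any(axis=1).sum()),
            "fraction": det.detected[mets].any(axis=1).sum() / n if n else np.nan,
        }
        for cat, mets in sorted(by_cat.items())
    ]
    return pd.DataFrame(rows)


def select_unknowns(
    matrix: AbundanceMatrix,
    annotations: Sequence[MetaboliteInfo],
    min_missing_fraction: float = 0.5,
) -> list[str]:
    """Unknowns whose missing fraction strictly exceeds the cutoff.

    Unknowns with many missing values are candidate drug metabolites (drugs
    are present in only a fraction of a population's samples, unlike
    endogenous compounds); these are the ones worth re-screening against
    self-reported medication.
    """
    unknown_ids = {a.metabolite_id for a in annotations if a.is_unknown}
    missing_frac = matrix.areas.isna().mean(axis=0)
    return [
        m
        for m in matrix.metabolite_ids
        if m in unknown_ids and missing_frac[m] > min_missing_fraction
    ]
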