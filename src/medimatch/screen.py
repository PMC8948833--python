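"""All-pairs Fisher-exact screen of self-reported medication vs detections.

For every (medication item, metabolite) pair a 2x2 contingency table is
built over the linked cohort — participants counted as *both* (reported and
detected), *self-only*, *blood-only*, or *neither* — and tested for
deviation from independence with a two-sided Fisher exact test.  Pairs are
thresholded at a Bonferroni level of ``alpha / n_items / n_metabolites``,
and a stringent mutual-best-hit rule keeps a pair only when each member is
the other's smallest-p partner across the whole grid, which yields a
partial matching between medications and metabolites.

The Fisher p-value is the sum of hypergeometric probabilities of all tables
with the observed margins whose probability does not exceed that of the
observed table.  It is computed from cumulative log-factorials so that the
extreme associations this screen produces (p down to ~1e-92 and below) do
not underflow.
"""

from __future__ import annotations

import importlib.resources
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .detection import DetectionMatrix
from .io import ValidationError

#: Relative slack when deciding which tables are "as extreme as" the
#: observed one (the convention of mainstream stats packages; absorbs
#: floating-point noise in exact pmf ties).
_EXTREME_EPS = math.log1p(1e-7)


@dataclass(frozen=True)
class ContingencyTable:
    """A 2x2 of both / self-only / blood-only / neither counts."""

    both: int
    self_only: int
    blood_only: int
    neither: int

    def __post_init__(self) -> None:
        if min(self.both, self.self_only, self.blood_only, self.neither) < 0:
            raise ValidationError("contingency counts must be non-negative")

    @property
    def n(self) -> int:
        return self.both + self.self_only + self.blood_only + self.neither

    @property
    def n_self(self) -> int:
        return self.both + self.self_only

    @property
    def n_blood(self) -> int:
        return self.both + self.blood_only

    @property
    def union(self) -> int:
        return self.both + self.self_only + self.blood_only


@dataclass
class AssociationResult:
    medication_item: str
    metabolite_id: str
    table: ContingencyTable
    p_value: float
    degenerate: bool = False
    bonferroni_significant: bool = False
    mutual_best_hit: bool = False


# ---------------------------------------------------------------------------
# Fisher exact test in log space
# ---------------------------------------------------------------------------

_logfact_cache = np.zeros(1)


def _logfact(n: int) -> np.ndarray:
    """Cumulative log-factorials 0..n (cached, grown on demand)."""
    global _logfact_cache
    if n >= len(_logfact_cache):
        grow = max(n + 1, 2 * len(_logfact_cache))
        lf = np.zeros(grow)
        lf[1:] = np.cumsum(np.log(np.arange(1, grow)))
        _logfact_cache = lf
    return _logfact_cache


def hypergeom_support_logpmf(
    n_self: int, n_blood: int, n: int
) -> tuple[np.ndarray, np.ndarray]:
    """Log-pmf of the `both` count over its support, at fixed margins."""
    lf = _logfact(n)
    kmin = max(0, n_self + n_blood - n)
    kmax = min(n_self, n_blood)
    k = np.arange(kmin, kmax + 1)
    logpmf = (
        lf[n_self] - lf[k] - lf[n_self - k]
        + lf[n - n_self] - lf[n_blood - k] - lf[n - n_self - n_blood + k]
        + lf[n_blood] + lf[n - n_blood] - lf[n]
    )
    return k, logpmf


def fisher_exact_2x2(table: ContingencyTable) -> tuple[float, bool]:
    """Two-sided Fisher exact p-value; returns ``(p, degenerate)``.

    A degenerate table (an empty margin: no users, no detections, or their
    complements) carries no information and yields p = 1 with the flag set.
    """
    n = table.n
    r1, c1 = table.n_self, table.n_blood
    if r1 == 0 or c1 == 0 or r1 == n or c1 == n or n == 0:
        return 1.0, True
    k, logpmf = hypergeom_support_logpmf(r1, c1, n)
    obs = logpmf[table.both - k[0]]
    p = float(np.exp(logsumexp(logpmf[logpmf <= obs + _EXTREME_EPS])))
    return min(p, 1.0), False


def build_table(
    med_users: set[str], detected_in: set[str], cohort: set[str]
) -> ContingencyTable:
    """Cross-classify the cohort by reported use and blood detection."""
    if not med_users <= cohort or not detected_in <= cohort:
        raise ValidationError("users/detections must be subsets of the cohort")
    both = len(med_users & detected_in)
    self_only = len(med_users) - both
    blood_only = len(detected_in) - both
    return ContingencyTable(
        both=both,
        self_only=self_only,
        blood_only=blood_only,
        neither=len(cohort) - both - self_only - blood_only,
    )


def bonferroni_threshold(alpha: float, n_meds: int, n_metabolites: int) -> float:
    """Family-wise significance level for an all-pairs screen."""
    if n_meds < 1 or n_metabolites < 1:
        raise ValidationError("tested-item counts must be >= 1")
    return alpha / (n_meds * n_metabolites)


# ---------------------------------------------------------------------------
# The screen
# ---------------------------------------------------------------------------


def screen_all_pairs(
    med_usage: Mapping[str, set[str]],
    det: DetectionMatrix,
    cohort: set[str],
    alpha: float = 0.05,
    restrict_metabolites: Sequence[str] | None = None,
    fixed_denominators: tuple[int, int] | None = None,
) -> list[AssociationResult]:
    """Fisher-test every (medication item, metabolite) pair over the cohort.

    ``cohort`` is the set of participants with both a questionnaire and a
    linked sample; samples outside it are ignored.  Medication items with no
    user in the cohort are dropped before the multiple-testing denominator
    is computed; ``fixed_denominators`` overrides the (n_items,
    n_metabolites) pair, for reproduction runs against published counts.
    Zero-margin pairs are retained with p = 1 and the degenerate flag.
    """
    if not cohort:
        raise ValidationError("empty cohort")
    metabolites = (
        list(restrict_metabolites)
        if restrict_metabolites is not None
        else det.metabolite_ids
    )
    usage = {
        item: users & cohort
        for item, users in med_usage.items()
        if users & cohort
    }
    detected_sets = {m: det.detected_in(m) & cohort for m in metabolites}

    n_items, n_mets = len(usage), len(metabolites)
    if fixed_denominators is not None:
        n_items, n_mets = fixed_denominators
    threshold = bonferroni_threshold(alpha, max(n_items, 1), max(n_mets, 1))

    results = []
    for item in sorted(usage):
        users = usage[item]
        for met in metabolites:
            table = build_table(users, detected_sets[met], cohort)
            p, degenerate = fisher_exact_2x2(table)
            results.append(
                AssociationResult(
                    medication_item=item,
                    metabolite_id=met,
                    table=table,
                    p_value=p,
                    degenerate=degenerate,
                    bonferroni_significant=(not degenerate and p < threshold),
                )
            )
    mutual_best_hits(results)
    return results


def _rank_key(r: AssociationResult) -> tuple[float, int, str, str]:
    # smaller p wins; ties by larger `both`, then lexicographic ids
    return (r.p_value, -r.table.both, r.metabolite_id, r.medication_item)


def mutual_best_hits(results: list[AssociationResult]) -> list[AssociationResult]:
    """Flag pairs that are each other's smallest-p partner.

    For each medication the minimum-p metabolite is found, and vice versa;
    a pair is flagged only when both argmins coincide.  Exact p ties are
    broken deterministically by larger ``both`` and then lexicographic IDs,
    so the flagged set is a partial matching: no medication or metabolite
    appears in more than one flagged pair.  Flags are set in place and the
    flagged subset is returned.
    """
    best_for_med: dict[str, AssociationResult] = {}
    best_for_met: dict[str, AssociationResult] = {}
    for r in results:
        r.mutual_best_hit = False
        if (
            r.medication_item not in best_for_med
            or _rank_key(r) < _rank_key(best_for_med[r.medication_item])
        ):
            best_for_med[r.medication_item] = r
        if (
            r.metabolite_id not in best_for_met
            or _rank_key(r) < _rank_key(best_for_met[r.metabolite_id])
        ):
            best_for_met[r.metabolite_id] = r
    flagged = []
    for r in best_for_med.values():
        if best_for_met.get(r.metabolite_id) is r:
            r.mutual_best_hit = True
            flagged.append(r)
    return flagged


def aggregate_overlap_metrics(
    hits: Sequence[AssociationResult],
) -> dict[str, float]:
    """Unweighted per-pair means of the overlap fractions.

    * ``detected_given_reported`` — mean(both / N_self): how often a
      reported drug shows up in the reporter's blood;
    * ``reported_given_detected`` — mean(both / N_blood): how often a
      detected metabolite was actually reported;
    * ``self_only_frac`` / ``blood_only_frac`` / ``both_frac`` — means of
      the respective cell over the union (both + self-only + blood-only).

    Pairs with an empty margin are excluded from the affected mean.
    """
    if not hits:
        raise ValidationError("no hits to aggregate")
    dgr, rgd, so, bo, bu = [], [], [], [], []
    for h in hits:
        t = h.table
        if t.n_self > 0:
            dgr.append(t.both / t.n_self)
        if t.n_blood > 0:
            rgd.append(t.both / t.n_blood)
        if t.union > 0:
            so.append(t.self_only / t.union)
            bo.append(t.blood_only / t.union)
            bu.append(t.both / t.union)
    return {
        "detected_given_reported": float(np.mean(dgr)),
        "reported_given_detected": float(np.mean(rgd)),
        "self_only_frac": float(np.mean(so)),
        "blood_only_frac": float(np.mean(bo)),
        "both_frac": float(np.mean(bu)),
        "n_pairs": float(len(hits)),
    }


def results_to_frame(results: Sequence[AssociationResult]) -> pd.DataFrame:
    """Flatten screen results for TSV export (one row per tested pair)."""
    return pd.DataFrame(
        {
            "medication": [r.medication_item for r in results],
            "n_self": [r.table.n_self for r in results],
            "metabolite": [r.metabolite_id for r in results],
            "n_blood": [r.table.n_blood for r in results],
            "p_value": [r.p_value for r in results],
            "self_only": [r.table.self_only for r in results],
            "blood_only": [r.table.blood_only for r in results],
            "both": [r.table.both for r in results],
            "bonferroni": [int(r.bonferroni_significant) for r in results],
            "mutual_best_hit": [int(r.mutual_best_hit) for r in results],
        }
    )


# ---------------------------------------------------------------------------
# Published reference hits (for reproduction of the aggregate metrics)
# ---------------------------------------------------------------------------


def load_reference_hits() -> list[AssociationResult]:
    """The 22 published Bonferroni-significant mutual-best-hit pairs.

    The shipped table carries, for each pair, the reported/detected counts
    over the 2807-sample linked cohort and the published p-value; the
    contingency tables it implies are the inputs for reproducing the
    screen's summary statistics.
    """
    ref = importlib.resources.files("medimatch.data") / "reference_hits.csv"
    with importlib.resources.as_file(ref) as path:
        df = pd.read_csv(path)
    results = []
    for _, row in df.iterrows():
        table = ContingencyTable(
            both=int(row["both"]),
            self_only=int(row["self_only"]),
            blood_only=int(row["blood_only"]),
            neither=int(row["cohort_n"]) - int(row["both"])
            - int(row["self_only"]) - int(row["blood_only"]),
        )
        results.append(
            AssociationResult(
                medication_item=row["medication"],
                metabolite_id=row["metabolite"],
                table=table,
                p_value=float(row["published_p"]),
                bonferroni_significant=True,
                mutual_best_hit=True,
            )
        )
    return results
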