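"""Synthetic biobank generator with known ground truth.

Emulates the statistical structure every pipeline stage assumes, so the
whole chain (curation -> detection -> screen -> concordance -> comparison)
is testable without access-restricted cohort data:

* medication use rises linearly with age: P(>=1 drug | age a) =
  clamp(0.25 + 0.75 * (a - 20) / 50, 0, 1);
* per-drug self-report rates below 1 model under-reporting;
* per-metabolite detection sensitivity P(area | use) and false-positive
  rate P(area | non-use), with user areas drawn from a high lognormal and
  spurious areas from a lower one over a process-blank baseline;
* free-text noise: brand names, bounded-edit-distance typos and
  "tablets for <indication>" responses at configured rates;
* multiplicative run-day batch effects removed by median normalization.

All randomness flows from one master seed through per-stage named streams,
so editing one stage's parameters does not perturb the draws of another.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri

from .curation import Vocabulary
from .io import (
    AbundanceMatrix,
    MetaboliteInfo,
    ParticipantRecord,
    TABLET_INDICATIONS,
    ValidationError,
    parse_confidence,
    read_vocabulary,
    write_questionnaire,
    write_results,
)

# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass
class MetaboliteSpec:
    """Generative parameters of one drug metabolite."""

    metabolite_id: str
    sensitivity: float  # P(peak generated | drug used)
    false_positive_rate: float  # P(peak generated | drug not used)
    mu_user: float = 8.0  # ln-scale location of user areas
    mu_fp: float = 6.5  # ln-scale location of spurious areas (lower)
    sigma: float = 0.6
    blank_area: float = 100.0

    def __post_init__(self) -> None:
        for p in (self.sensitivity, self.false_positive_rate):
            if not 0.0 <= p <= 1.0:
                raise ValidationError(
                    f"{self.metabolite_id}: probabilities must be in [0,1]"
                )


@dataclass
class DrugSpec:
    """One drug of the panel; ``name`` must resolve in the vocabulary."""

    name: str
    usage_rate: float  # P(use | participant takes >=1 medication)
    report_probability: float  # 1 - under-reporting
    metabolites: list[MetaboliteSpec]
    indication: str | None = None

    def __post_init__(self) -> None:
        if not self.metabolites:
            raise ValidationError(f"{self.name}: every drug needs >=1 metabolite")
        for p in (self.usage_rate, self.report_probability):
            if not 0.0 <= p <= 1.0:
                raise ValidationError(f"{self.name}: probabilities must be in [0,1]")


@dataclass
class SimulationConfig:
    n_participants: int = 3000
    n_samples_linked: int = 2807
    seed: int = 1
    age_mean: float = 39.7
    age_sd: float = 12.8
    age_range: tuple[int, int] = (18, 80)
    female_fraction: float = 0.57
    n_rundays: int = 10
    runday_sigma: float = 0.1  # sd of the ln of the multiplicative day effect
    typo_rate: float = 0.05
    brand_name_rate: float = 0.2
    unspecified_rate: float = 0.1
    drugs: list[DrugSpec] = field(default_factory=lambda: default_panel())
    n_unknown_metabolites: int = 12

    def __post_init__(self) -> None:
        if self.n_samples_linked > self.n_participants:
            raise ValidationError("n_samples_linked must be <= n_participants")
        for r in (self.typo_rate, self.brand_name_rate, self.unspecified_rate,
                  self.female_fraction):
            if not 0.0 <= r <= 1.0:
                raise ValidationError("rates must be in [0,1]")


@dataclass
class GroundTruth:
    """Per-participant use/report sets and per-peak TP/FP labels."""

    used: dict[str, set[str]]  # participant -> drug names
    reported: dict[str, set[str]]
    true_positive: pd.DataFrame | None = None  # sample x metabolite bool
    false_positive: pd.DataFrame | None = None


def _rng(seed: int, label: str) -> np.random.Generator:
    """A named pseudo-random stream derived from the master seed."""
    return np.random.default_rng([seed, zlib.crc32(label.encode())])


def usage_probability(age: float) -> float:
    """P(>=1 medication | age): linear from 0.25 at 20 to 1.0 at 70."""
    return float(np.clip(0.25 + 0.75 * (age - 20.0) / 50.0, 0.0, 1.0))


#: Molecule taken by medication users who draw no panel drug (supplements
#: dominate real questionnaires and have no metabolite on the drug panel).
SUPPLEMENT_NAME = "cholecalciferol"


# ---------------------------------------------------------------------------
# Default drug panel
# ---------------------------------------------------------------------------


def _met(mid, sens, fp, mu_user=8.0, mu_fp=6.5, sigma=0.6, blank=100.0):
    return MetaboliteSpec(mid, sens, fp, mu_user, mu_fp, sigma, blank)


def default_panel() -> list[DrugSpec]:
    """Twenty drugs / 28 drug metabolites mirroring the field's archetypes.

    Includes a metformin-like drug (high false-positive rate), an
    acetaminophen-like drug (nine pathway metabolites, heavy
    under-reporting), an atorvastatin-like drug (metabolite differs from
    the parent), and a rosuvastatin-like drug (metabolite not captured by
    the platform: never detected).
    """
    aceta_members = [
        ("4-acetaminophen sulfate", 0.85),
        ("4-acetamidophenyl glucuronide", 0.80),
        ("4-acetamidophenol", 0.65),
        ("3-(methylthio) acetaminophen sulfate", 0.60),
        ("2-hydroxyacetaminophen sulfate", 0.55),
        ("2-methoxyacetaminophen glucuronide", 0.50),
        ("2-methoxyacetaminophen sulfate", 0.50),
        ("3-(N-acetyl-L-cystein-S-yl) acetaminophen", 0.45),
        ("3-(cystein-S-yl) acetaminophen", 0.48),
    ]
    panel = [
        DrugSpec(
            "metformin", usage_rate=0.15, report_probability=0.90,
            indication="diabetes",
            # spurious-peak median ~8-fold below the user median
            metabolites=[_met("metformin", 0.92, 0.23, mu_fp=5.92)],
        ),
        DrugSpec(
            "acetaminophen", usage_rate=0.30, report_probability=0.05,
            metabolites=[_met(mid, s, 0.01) for mid, s in aceta_members],
        ),
        DrugSpec(
            "atorvastatin", usage_rate=0.08, report_probability=0.80,
            indication="dyslipidemia",
            metabolites=[_met("o-hydroxyatorvastatin", 0.70, 0.01)],
        ),
        DrugSpec(
            "rosuvastatin", usage_rate=0.05, report_probability=0.80,
            indication="dyslipidemia",
            metabolites=[_met("rosuvastatin", 0.0, 0.0)],
        ),
    ]
    generics = [
        # name, usage|user, report, sensitivity, fp, metabolite, indication
        ("gliclazide", 0.06, 0.85, 0.90, 0.15, "gliclazide", "diabetes"),
        ("valsartan", 0.05, 0.85, 0.90, 0.05, "valsartan", "hypertension"),
        ("losartan", 0.04, 0.85, 0.85, 0.005, "losartan", "hypertension"),
        ("indapamide", 0.03, 0.85, 0.85, 0.008, "indapamide", "hypertension"),
        ("warfarin", 0.02, 0.90, 0.95, 0.002, "10-hydroxywarfarin", None),
        ("atenolol", 0.04, 0.85, 0.90, 0.04, "atenolol", "hypertension"),
        ("escitalopram", 0.02, 0.60, 0.90, 0.008, "citalopram/escitalopram", None),
        ("esomeprazole", 0.05, 0.80, 0.65, 0.02, "omeprazole", None),
        ("glimepiride", 0.04, 0.85, 0.60, 0.006, "glimepiride", "diabetes"),
        ("topiramate", 0.02, 0.80, 0.95, 0.005, "topiramate", None),
        ("pantoprazole", 0.04, 0.80, 0.75, 0.03, "pantoprazole", None),
        ("celecoxib", 0.04, 0.80, 0.55, 0.018, "celecoxib", None),
        ("pregabalin", 0.02, 0.80, 0.75, 0.004, "pregabalin", None),
        ("fexofenadine", 0.04, 0.75, 0.60, 0.018, "fexofenadine", None),
        ("perindopril", 0.03, 0.85, 0.45, 0.003, "perindopril", "hypertension"),
        ("pioglitazone", 0.02, 0.85, 0.80, 0.007, "hydroxypioglitazone", "diabetes"),
    ]
    for name, rate, rep, sens, fp, mid, ind in generics:
        panel.append(
            DrugSpec(
                name, usage_rate=rate, report_probability=rep, indication=ind,
                metabolites=[_met(mid, sens, fp)],
            )
        )
    return panel


_CATEGORY_BY_INDICATION = {
    "diabetes": "metabolic",
    "hypertension": "cardiovascular",
    "dyslipidemia": "lipid lowering",
}

#: Platform drug-category -> indication, for concordance metabolite maps.
DEFAULT_CATEGORY_TO_INDICATION = {
    "metabolic": "diabetes",
    "cardiovascular": "hypertension",
    "lipid lowering": "dyslipidemia",
}


def panel_annotations(config: SimulationConfig) -> list[MetaboliteInfo]:
    """Platform-style annotation rows for the simulated metabolite panel."""
    infos = []
    for drug in config.drugs:
        category = (
            "analgesics/anesthetics"
            if drug.name == "acetaminophen"
            else _CATEGORY_BY_INDICATION.get(drug.indication or "", "other")
        )
        for met in drug.metabolites:
            bare, tag = parse_confidence(met.metabolite_id)
            infos.append(
                MetaboliteInfo(
                    metabolite_id=met.metabolite_id,
                    display_name=met.metabolite_id,
                    confidence_tag=tag,
                    is_unknown=False,
                    drug_category=category,
                )
            )
    for i in range(config.n_unknown_metabolites):
        mid = f"X-{10001 + i}"
        infos.append(
            MetaboliteInfo(
                metabolite_id=mid, display_name=mid,
                confidence_tag="confirmed", is_unknown=True,
            )
        )
    return infos


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------


def simulate_cohort(
    config: SimulationConfig,
) -> tuple[list[ParticipantRecord], GroundTruth]:
    """Draw participants with demographics, drug use and report sets.

    Free-text entries are left empty here; :func:`render_free_text` fills
    them from the ground truth.  BMI and HbA1c are drawn with
    diabetes-linked shifts so the metformin-style contrast groups are
    populated.
    """
    rng = _rng(config.seed, "cohort")
    rng_report = _rng(config.seed, "report")
    n = config.n_participants
    lo, hi = config.age_range
    ages = np.clip(
        np.round(rng.normal(config.age_mean, config.age_sd, size=n)), lo, hi
    ).astype(int)
    sexes = np.where(rng.random(n) < config.female_fraction, "female", "male")

    drug_names = [d.name for d in config.drugs]
    rates = np.array([d.usage_rate for d in config.drugs])
    used: dict[str, set[str]] = {}
    reported: dict[str, set[str]] = {}
    participants: list[ParticipantRecord] = []
    for i in range(n):
        pid = f"P{i + 1:05d}"
        takes_any = rng.random() < usage_probability(ages[i])
        use: set[str] = set()
        if takes_any:
            mask = rng.random(len(rates)) < rates
            use = {drug_names[j] for j in np.flatnonzero(mask)}
            if not use:
                # medication users without a panel drug take a supplement
                # (always reported): keeps P(>=1 medication | age) on the
                # linear model without inflating panel-drug usage rates
                use = {SUPPLEMENT_NAME}
        rep = {
            d.name
            for d in config.drugs
            if d.name in use and rng_report.random() < d.report_probability
        }
        if SUPPLEMENT_NAME in use:
            rep.add(SUPPLEMENT_NAME)
        used[pid] = use
        reported[pid] = rep

        uses_antidiabetic = any(
            d.indication == "diabetes" for d in config.drugs if d.name in use
        )
        diagnosed = rng.random() < (0.85 if uses_antidiabetic else 0.03)
        bmi = max(16.0, rng.normal(28.9 + (2.0 if diagnosed else 0.0), 6.2))
        hba1c = max(
            4.0,
            rng.normal(7.3, 1.4) if diagnosed else rng.normal(5.35, 0.45),
        )
        treated = {}
        for indication in TABLET_INDICATIONS:
            uses_class = any(
                d.indication == indication for d in config.drugs if d.name in use
            )
            treated[indication] = bool(
                rng.random() < (0.85 if uses_class else 0.01)
            )
        participants.append(
            ParticipantRecord(
                participant_id=pid,
                age=int(ages[i]),
                sex=str(sexes[i]),
                bmi=round(float(bmi), 1),
                hba1c=round(float(hba1c), 2),
                diagnosed_diabetes=diagnosed,
                treated_tablets=treated,
                med_entries=[],
            )
        )
    return participants, GroundTruth(used=used, reported=reported)


_INDICATION_PHRASES = {
    "diabetes": "diabetes",
    "hypertension": "blood pressure",
    "dyslipidemia": "cholesterol",
}

_LETTERS = "abcdefghijklmnopqrstuvwxyz"


def _typo(name: str, rng: np.random.Generator) -> str:
    """Corrupt a name by 1-2 random edits (distance <= 2 by construction)."""
    n_ops = 1 if len(name) <= 6 else int(rng.integers(1, 3))
    s = list(name)
    for _ in range(n_ops):
        op = rng.integers(0, 3)
        pos = int(rng.integers(0, len(s)))
        if op == 0 and len(s) > 3:  # deletion
            del s[pos]
        elif op == 1:  # substitution
            s[pos] = _LETTERS[rng.integers(0, 26)]
        else:  # insertion
            s.insert(pos, _LETTERS[rng.integers(0, 26)])
    return "".join(s)


def render_free_text(
    participants: Sequence[ParticipantRecord],
    truth: GroundTruth,
    config: SimulationConfig,
    vocabulary: Vocabulary | None = None,
) -> list[ParticipantRecord]:
    """Write each reported drug as a noisy free-text questionnaire entry.

    Renderings, drawn per entry: brand synonym, typo'd canonical name
    (edit distance <= 2), "tablets for <indication>" phrase, or the
    canonical name.  Under-reported drugs are simply absent.
    """
    if vocabulary is None:
        vocabulary = load_default_vocabulary()
    rng = _rng(config.seed, "freetext")
    by_name = {d.name: d for d in config.drugs}
    out = []
    for p in participants:
        entries = []
        for drug_name in sorted(truth.reported[p.participant_id]):
            drug = by_name.get(drug_name)
            entry = vocabulary.by_name.get(drug_name.casefold())
            u = rng.random()
            if drug is None:  # off-panel supplement: name or synonym only
                if u < 0.5 and entry and entry.synonyms:
                    text = str(entry.synonyms[rng.integers(0, len(entry.synonyms))])
                else:
                    text = drug_name
                entries.append(text)
                continue
            if u < config.unspecified_rate and drug.indication:
                phrase = _INDICATION_PHRASES.get(drug.indication, drug.indication)
                text = f"tablets for {phrase}"
            elif u < config.unspecified_rate + config.brand_name_rate and (
                entry and entry.synonyms
            ):
                text = str(entry.synonyms[rng.integers(0, len(entry.synonyms))])
            elif u < (
                config.unspecified_rate + config.brand_name_rate + config.typo_rate
            ):
                text = _typo(drug_name, rng)
            else:
                text = drug_name
            entries.append(text)
        out.append(replace(p, med_entries=entries))
    return out


# ---------------------------------------------------------------------------
# Abundance simulation
# ---------------------------------------------------------------------------


def simulate_abundances(
    participants: Sequence[ParticipantRecord],
    truth: GroundTruth,
    config: SimulationConfig,
) -> tuple[AbundanceMatrix, GroundTruth]:
    """Generate the samples x metabolites area matrix with TP/FP labels.

    The first ``n_samples_linked`` participants provide samples (sample ID
    = participant ID).  Users of a drug get each of its metabolites with
    probability ``sensitivity`` at a high lognormal level; non-users with
    probability ``false_positive_rate`` at a lower level.  Spurious areas
    are drawn from the lognormal truncated at the 3x-blank detection
    threshold so that ``false_positive_rate`` is exactly P(detect |
    non-use) — a spurious peak below the threshold would be rejected and
    is unobservable anyway — while user areas are untruncated and can
    naturally fall below it.  Unknowns are drug-free features present in
    a random 30-70% of samples.  Areas carry a multiplicative per-run-day
    batch effect.
    """
    rng = _rng(config.seed, "abundance")
    sample_ids = [p.participant_id for p in participants[: config.n_samples_linked]]
    n = len(sample_ids)
    runday = pd.Series(
        [f"day{(i % config.n_rundays) + 1:02d}" for i in range(n)],
        index=sample_ids,
    )
    day_effect = {
        f"day{d + 1:02d}": float(np.exp(rng.normal(0.0, config.runday_sigma)))
        for d in range(config.n_rundays)
    }
    day_factor = runday.map(day_effect).to_numpy()

    used_mask = {}
    for drug in config.drugs:
        used_mask[drug.name] = np.array(
            [drug.name in truth.used[s] for s in sample_ids]
        )

    columns: dict[str, np.ndarray] = {}
    blank = {}
    tp = {}
    fp = {}
    for drug in config.drugs:
        mask = used_mask[drug.name]
        for met in drug.metabolites:
            present_user = mask & (rng.random(n) < met.sensitivity)
            present_fp = ~mask & (rng.random(n) < met.false_positive_rate)
            area = np.full(n, np.nan)
            area[present_user] = rng.lognormal(
                met.mu_user, met.sigma, present_user.sum()
            )
            if present_fp.any():
                # ln-scale lower bound per sample: the 3x-blank threshold
                # net of that sample's run-day factor
                lo = (
                    np.log(3.0 * met.blank_area / day_factor[present_fp])
                    - met.mu_fp
                ) / met.sigma
                u = rng.uniform(ndtr(lo), 1.0)
                area[present_fp] = np.exp(
                    met.mu_fp + met.sigma * ndtri(np.clip(u, 1e-12, 1 - 1e-12))
                )
            columns[met.metabolite_id] = area * day_factor
            blank[met.metabolite_id] = met.blank_area
            tp[met.metabolite_id] = present_user
            fp[met.metabolite_id] = present_fp
    for i in range(config.n_unknown_metabolites):
        mid = f"X-{10001 + i}"
        prevalence = float(rng.uniform(0.3, 0.7))
        present = rng.random(n) < prevalence
        area = np.full(n, np.nan)
        area[present] = rng.lognormal(7.5, 0.8, present.sum())
        columns[mid] = area * day_factor
        blank[mid] = 100.0
        tp[mid] = np.zeros(n, bool)
        fp[mid] = present

    areas = pd.DataFrame(columns, index=sample_ids)
    matrix = AbundanceMatrix(
        areas=areas,
        runday=runday,
        blank_area=pd.Series(blank),
    )
    truth = replace(
        truth,
        true_positive=pd.DataFrame(tp, index=sample_ids),
        false_positive=pd.DataFrame(fp, index=sample_ids),
    )
    return matrix, truth


# ---------------------------------------------------------------------------
# End-to-end bundle
# ---------------------------------------------------------------------------


@dataclass
class SyntheticBundle:
    config: SimulationConfig
    participants: list[ParticipantRecord]
    truth: GroundTruth
    matrix: AbundanceMatrix
    annotations: list[MetaboliteInfo]
    expected_hits: pd.DataFrame  # planted (drug, metabolite) pairs


def load_default_vocabulary() -> Vocabulary:
    """The shipped synthetic vocabulary subset (open DrugBank dialect)."""
    import importlib.resources

    ref = importlib.resources.files("medimatch.data") / "vocabulary.csv"
    with importlib.resources.as_file(ref) as path:
        return Vocabulary(read_vocabulary(path))


def end_to_end_fixture(
    config: SimulationConfig | None = None,
    outdir: str | Path | None = None,
) -> SyntheticBundle:
    """Generate the full input bundle and its expected-result manifest.

    With ``outdir`` set, the questionnaire, abundance matrix, blanks,
    annotations and ground-truth manifest are written in the same formats
    the pipeline consumes.
    """
    config = config or SimulationConfig()
    vocabulary = load_default_vocabulary()
    participants, truth = simulate_cohort(config)
    participants = render_free_text(participants, truth, config, vocabulary)
    matrix, truth = simulate_abundances(participants, truth, config)

    linked = {p.participant_id for p in participants[: config.n_samples_linked]}
    rows = []
    for drug in config.drugs:
        users = {pid for pid, u in truth.used.items() if drug.name in u} & linked
        reporters = {
            pid for pid, r in truth.reported.items() if drug.name in r
        } & linked
        for met in drug.metabolites:
            rows.append(
                {
                    "drug": drug.name,
                    "metabolite": met.metabolite_id,
                    "n_users_linked": len(users),
                    "n_reporters_linked": len(reporters),
                    "sensitivity": met.sensitivity,
                    "false_positive_rate": met.false_positive_rate,
                    "report_probability": drug.report_probability,
                }
            )
    expected = pd.DataFrame(rows)
    bundle = SyntheticBundle(
        config=config,
        participants=participants,
        truth=truth,
        matrix=matrix,
        annotations=panel_annotations(config),
        expected_hits=expected,
    )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_questionnaire(participants, outdir / "questionnaire.tsv")
        from .io import write_abundance_matrix

        write_abundance_matrix(matrix, outdir / "areas.tsv")
        write_results(
            pd.DataFrame(
                {
                    "metabolite_id": list(matrix.metabolite_ids),
                    "blank_area": [
                        matrix.blank_area[m] for m in matrix.metabolite_ids
                    ],
                }
            ),
            outdir / "blanks.csv",
        )
        write_results(
            pd.DataFrame(
                {
                    "metabolite_id": [a.metabolite_id for a in bundle.annotations],
                    "display_name": [a.display_name for a in bundle.annotations],
                    "drug_category": [a.drug_category or "" for a in bundle.annotations],
                }
            ),
            outdir / "annotations.csv",
        )
        write_results(expected, outdir / "expected_hits.csv")
    return bundle
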