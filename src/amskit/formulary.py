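"""Machine-readable medication unit-score policy.

Each drug in the policy carries a *unit score*: the points assigned to one
reference dose, ranked by pharmacological class from saline irrigation
(0.1 points) up to adrenaline (1 mg = 1000 points). Scores scale
proportionally with dose — if 80 μg of inhaled budesonide is 0.5 points,
100 μg is 0.625 points. Fixed-dose combination inhalers are scored
additively over their dose-scaled components, so Symbicort 160/4.5
(budesonide 160 μg + formoterol 4.5 μg) scores 1.0 + 1.0 = 2 points per
inhalation.

The packaged fixture encodes 112 drugs (24 rhinitis, 51 asthma,
37 dermatitis). Entries not individually dosed in the source policy are
placeholders carrying their policy row's class-level score and are flagged
``placeholder=True``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterator, Optional, Sequence

import pandas as pd

from .errors import DomainError, DrugLookupError, FixtureError
from .units import Dose

DISEASE_CATEGORIES = ("rhinitis", "asthma", "dermatitis")

#: The 16 policy rows, in ascending order of class-level score.
STATEMENT_CLASSES = (
    "drainage",                        # 0.1  saline irrigation
    "topical_low",                     # 0.5  e.g. mometasone cream
    "topical_mid",                     # 0.625 budesonide 100 μg line
    "topical_standard",                # 1    e.g. Flixotide 125 μg
    "low_dose_ics_laba",               # 1.5  e.g. Symbicort 80/4.5
    "symptomatic_relief",              # 2    SABA/SAMA, antihistamines, mucolytics
    "leukotriene_antagonist",          # 2.5-3.5
    "high_dose_ics_laba",              # 4-5  e.g. Symbicort 320/9
    "ics_laba_high_or_antihistamine",  # 6    Seretide 500/50, diphenhydramine
    "nebulized_corticosteroid",        # 10
    "oral_corticosteroid",             # 20-25
    "immunosuppressant",               # 40
    "iv_bronchodilator",               # 80
    "biologic",                        # 100
    "iv_corticosteroid",               # 150 / 250
    "antianaphylaxis",                 # 1000 adrenaline
)

ROUTES = (
    "irrigation", "inhale", "spray", "nebulization", "ointment", "oral",
    "intramuscular", "subcutaneous", "intravenous",
)


@dataclass(frozen=True)
class DrugEntry:
    """One formulary row.

    For simple drugs ``reference_unit_score`` is the points earned by one
    ``reference_dose``. Combination products instead list ``components``
    as ``(drug_id, dose_ug)`` pairs and their score is computed.
    """

    drug_id: str
    name: str
    disease_category: str
    statement_class: str
    route: str
    reference_dose: Dose
    reference_unit_score: Optional[float] = None
    components: tuple = ()
    placeholder: bool = False
    override_unit_score: Optional[float] = None

    def __post_init__(self) -> None:
        if self.disease_category not in DISEASE_CATEGORIES:
            raise FixtureError(
                f"{self.drug_id}: unknown category {self.disease_category!r}"
            )
        if self.statement_class not in STATEMENT_CLASSES:
            raise FixtureError(
                f"{self.drug_id}: unknown statement class "
                f"{self.statement_class!r}"
            )
        if self.route not in ROUTES:
            raise FixtureError(f"{self.drug_id}: unknown route {self.route!r}")
        if self.is_combination:
            if self.reference_unit_score is not None:
                raise FixtureError(
                    f"{self.drug_id}: combination entries have a computed "
                    "score, not an independent reference_unit_score"
                )
        else:
            if self.reference_unit_score is None or self.reference_unit_score <= 0:
                raise FixtureError(
                    f"{self.drug_id}: reference_unit_score must be > 0"
                )

    @property
    def is_combination(self) -> bool:
        return len(self.components) > 0


@dataclass
class Formulary:
    """Indexed collection of :class:`DrugEntry`, keyed by ``drug_id``."""

    entries: dict = field(default_factory=dict)
    provenance: str = "unversioned"

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[DrugEntry]:
        return iter(self.entries.values())

    def __contains__(self, drug_id: str) -> bool:
        return drug_id in self.entries

    def get(self, drug_id: str) -> DrugEntry:
        try:
            return self.entries[drug_id]
        except KeyError:
            raise DrugLookupError(f"drug {drug_id!r} not in formulary") from None

    def by_category(self, category: str) -> list:
        if category not in DISEASE_CATEGORIES:
            raise DomainError(f"unknown disease category {category!r}")
        return [e for e in self if e.disease_category == category]

    def find_by_name(self, fragment: str) -> list:
        """Case-insensitive substring match on the display name."""
        f = fragment.lower()
        return [e for e in self if f in e.name.lower()]


def _parse_components(raw: str) -> tuple:
    if not raw or not raw.strip():
        return ()
    try:
        pairs = json.loads(raw)
        return tuple((str(d), float(v)) for d, v in pairs)
    except (ValueError, TypeError) as exc:
        raise FixtureError(f"bad components field {raw!r}: {exc}") from exc


def load_formulary(path: Optional[str] = None) -> Formulary:
    """Load a formulary from CSV; with no path, the packaged 112-drug fixture.

    Raises :class:`FixtureError` on duplicate drug_ids, missing required
    fields, or unresolvable combination components.
    """
    if path is None:
        src = resources.files("amskit.data").joinpath("formulary.csv")
        with resources.as_file(src) as p:
            df = pd.read_csv(p, dtype=str, keep_default_na=False)
        provenance = "packaged"
    else:
        df = pd.read_csv(Path(path), dtype=str, keep_default_na=False)
        provenance = str(path)

    required = {
        "drug_id", "name", "disease_category", "statement_class", "route",
        "reference_dose", "reference_dose_unit",
    }
    missing = required - set(df.columns)
    if missing:
        raise FixtureError(f"formulary missing columns: {sorted(missing)}")

    entries: dict = {}
    for row in df.to_dict("records"):
        did = row["drug_id"].strip()
        if not did:
            raise FixtureError("formulary row with empty drug_id")
        if did in entries:
            raise FixtureError(f"duplicate drug_id {did!r}")
        score_raw = row.get("reference_unit_score", "")
        ovr_raw = row.get("override_unit_score", "")
        entry = DrugEntry(
            drug_id=did,
            name=row["name"],
            disease_category=row["disease_category"],
            statement_class=row["statement_class"],
            route=row["route"],
            reference_dose=Dose(
                float(row["reference_dose"]), row["reference_dose_unit"]
            ),
            reference_unit_score=float(score_raw) if score_raw else None,
            components=_parse_components(row.get("components", "")),
            placeholder=str(row.get("placeholder", "")).lower() == "true",
            override_unit_score=float(ovr_raw) if ovr_raw else None,
        )
        entries[did] = entry

    form = Formulary(entries=entries, provenance=provenance)
    for entry in form:
        for comp_id, _ in entry.components:
            if comp_id not in form:
                raise FixtureError(
                    f"{entry.drug_id}: component {comp_id!r} not in formulary"
                )
    return form


def unit_score(entry: DrugEntry, dose: Dose) -> float:
    """Points for one administration of ``dose`` of a simple (non-combination)
    drug, scaled linearly from the reference: score = ref_score × dose/ref_dose.

    Zero dose scores zero. Combination entries must go through
    :func:`combination_unit_score`.
    """
    if entry.is_combination:
        raise DomainError(
            f"{entry.drug_id} is a combination product; use "
            "combination_unit_score"
        )
    if dose.value == 0:
        return 0.0
    return entry.reference_unit_score * dose.ratio_to(entry.reference_dose)


def combination_unit_score(
    entry: DrugEntry,
    formulary: Formulary,
    *,
    use_override: bool = False,
) -> float:
    """Per-administration points of a fixed-dose combination: the sum of each
    component's dose-scaled score.

    ``use_override`` returns the fixture's literal row assignment where one
    exists (some policy rows pin a combination to a different value than its
    component arithmetic); the computed additive convention is the default.
    """
    if not entry.components:
        raise DomainError(f"{entry.drug_id} has no components")
    if use_override and entry.override_unit_score is not None:
        return entry.override_unit_score
    total = 0.0
    for comp_id, comp_dose_ug in entry.components:
        comp = formulary.get(comp_id)
        total += unit_score(comp, Dose(comp_dose_ug, "ug"))
    return total


def points_per_administration(
    entry: DrugEntry, dose: Dose, formulary: Formulary
) -> float:
    """Points earned by a single administration of ``dose``.

    Dispatches simple entries to :func:`unit_score`; for combinations the
    dose is a count of inhalations/applications multiplying the computed
    per-inhalation score.
    """
    if entry.is_combination:
        return combination_unit_score(entry, formulary) * dose.ratio_to(
            entry.reference_dose
        )
    return unit_score(entry, dose)


def load_element_registry(path: Optional[str] = None) -> pd.DataFrame:
    """Load the standard-element registry (533 rows: 210 common + 323
    specific), columns element_name, module, label, common_or_specific."""
    if path is None:
        src = resources.files("amskit.data").joinpath("element_registry.csv")
        with resources.as_file(src) as p:
            df = pd.read_csv(p, dtype=str)
    else:
        df = pd.read_csv(Path(path), dtype=str)
    expected = {"element_name", "module", "label", "common_or_specific"}
    if set(df.columns) != expected:
        raise FixtureError(f"registry columns {list(df.columns)} != {sorted(expected)}")
    if df["element_name"].duplicated().any():
        raise FixtureError("registry has duplicate element names")
    return df
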