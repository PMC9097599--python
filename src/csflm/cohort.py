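"""Clinical cohort table: parsing and descriptive statistics.

The packaged fixture transcribes the published clinical table of the
33-patient NSCLC leptomeningeal-metastasis cohort: demographics, driver
alteration of the primary tumor, ECOG performance status, extracranial and
brain-parenchymal disease status at LM diagnosis, EGFR-TKI treatment
history, and overall survival from LM (">"-prefixed values are alive at
last follow-up, i.e. right-censored).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .survival import SurvivalRecord

SEXES = ("man", "woman")
STATUS_LEVELS = ("progressive", "stable", "regressive", "without_metastases")
DRIVER_GENES = ("EGFR", "ALK", "ERBB2")
TKI_VOCABULARY = frozenset({
    "gefitinib", "erlotinib", "icotinib", "afatinib", "osimertinib",
    "crizotinib", "brigatinib", "capmatinib", "cabozantinib",
})
# first-/second-generation EGFR TKIs; osimertinib is third-generation
FIRST_SECOND_GEN_EGFR_TKIS = frozenset(
    {"gefitinib", "erlotinib", "icotinib", "afatinib"}
)

COLUMNS = [
    "patient_id", "age_at_lm", "sex", "driver_alteration", "ecog_ps",
    "extracranial_status", "brain_parenchymal_status", "tki_history",
    "os_months", "profiling_test",
]


class SchemaError(ValueError):
    """The clinical table does not match the expected fixture schema."""


@dataclass(frozen=True)
class ClinicalRecord:
    patient_id: str
    age_at_lm: int
    sex: str
    driver_alteration: str
    ecog_ps: int
    extracranial_status: str
    brain_parenchymal_status: str
    tki_history: tuple[str, ...]
    os_months: float
    os_censored: bool
    profiling_test: str

    def __post_init__(self) -> None:
        if not 18 <= self.age_at_lm <= 120:
            raise ValueError(f"{self.patient_id}: age {self.age_at_lm} implausible")
        if self.sex not in SEXES:
            raise ValueError(f"{self.patient_id}: sex must be man/woman")
        if self.ecog_ps not in range(5):
            raise ValueError(f"{self.patient_id}: ECOG PS outside 0-4")
        for status in (self.extracranial_status, self.brain_parenchymal_status):
            if status not in STATUS_LEVELS:
                raise ValueError(f"{self.patient_id}: unknown status {status!r}")
        if self.os_months <= 0:
            raise ValueError(f"{self.patient_id}: OS must be positive")
        unknown = set(self.tki_history) - TKI_VOCABULARY
        if unknown:
            raise ValueError(
                f"{self.patient_id}: unknown TKI name(s) {sorted(unknown)}"
            )

    @property
    def driver_gene(self) -> str:
        """Driver gene symbol derived from the alteration string."""
        for gene in DRIVER_GENES:
            if gene in self.driver_alteration:
                return gene
        raise ValueError(
            f"driver gene of {self.driver_alteration!r} not in {DRIVER_GENES}"
        )

    def to_survival(self) -> SurvivalRecord:
        return SurvivalRecord(
            patient_id=self.patient_id,
            time=self.os_months,
            event=not self.os_censored,
        )


@dataclass
class CohortSummary:
    n_patients: int
    n_male: int
    pct_male: float
    median_age: float
    age_min: int
    age_max: int
    driver_counts: dict[str, int] = field(default_factory=dict)
    pct_egfr: float = 0.0
    n_no_brain_parenchymal_mets: int = 0
    n_no_extracranial_mets: int = 0
    n_osimertinib_exposed: int = 0
    n_first_second_gen_egfr_tki: int = 0

    def to_dict(self) -> dict:
        return {
            "n_patients": self.n_patients,
            "n_male": self.n_male,
            "pct_male": self.pct_male,
            "median_age": self.median_age,
            "age_min": self.age_min,
            "age_max": self.age_max,
            "driver_counts": dict(self.driver_counts),
            "pct_egfr": self.pct_egfr,
            "n_no_brain_parenchymal_mets": self.n_no_brain_parenchymal_mets,
            "n_no_extracranial_mets": self.n_no_extracranial_mets,
            "n_osimertinib_exposed": self.n_osimertinib_exposed,
            "n_first_second_gen_egfr_tki": self.n_first_second_gen_egfr_tki,
        }


def packaged_table_path():
    """Path-like handle to the packaged clinical table fixture."""
    return resources.files("csflm").joinpath("data/table1.tsv")


def _parse_status(cell: str) -> str:
    return cell.strip().lower().replace(" ", "_")


def _parse_tki(cell: str) -> tuple[str, ...]:
    cell = cell.strip()
    if cell in ("", "-", "–", "—"):
        return ()
    drugs = []
    for token in cell.replace("+", " ").split():
        name = token.strip().lower()
        if name:
            drugs.append(name)
    return tuple(drugs)


def _parse_os(cell: str, patient_id: str) -> tuple[float, bool]:
    cell = str(cell).strip()
    censored = cell.startswith(">")
    try:
        months = float(cell.lstrip(">"))
    except ValueError as exc:
        raise ValueError(
            f"{patient_id}: cannot parse OS cell {cell!r}"
        ) from exc
    return months, censored


def parse_clinical_table(path=None) -> list[ClinicalRecord]:
    """Parse the tab-separated clinical table (packaged fixture by default).

    ">"-prefixed OS cells are right-censored at the stated value; "–" in
    the TKI column is an empty history; multi-drug cells split on "+" and
    whitespace with case-insensitive drug names.
    """
    source = packaged_table_path() if path is None else path
    try:
        table = pd.read_csv(source, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError as exc:
        raise SchemaError("clinical table is empty") from exc
    missing = [col for col in COLUMNS if col not in table.columns]
    if missing:
        raise SchemaError(f"clinical table missing column(s): {missing}")
    if len(table) == 0:
        raise SchemaError("clinical table has a header but no rows")
    records = []
    for row in table.to_dict("records"):
        patient_id = str(row["patient_id"]).strip()
        os_months, censored = _parse_os(row["os_months"], patient_id)
        records.append(
            ClinicalRecord(
                patient_id=patient_id,
                age_at_lm=int(row["age_at_lm"]),
                sex=str(row["sex"]).strip().lower(),
                driver_alteration=str(row["driver_alteration"]).strip(),
                ecog_ps=int(row["ecog_ps"]),
                extracranial_status=_parse_status(row["extracranial_status"]),
                brain_parenchymal_status=_parse_status(
                    row["brain_parenchymal_status"]
                ),
                tki_history=_parse_tki(str(row["tki_history"])),
                os_months=os_months,
                os_censored=censored,
                profiling_test=str(row["profiling_test"]).strip(),
            )
        )
    return records


def records_to_tsv(records: list[ClinicalRecord], path) -> None:
    """Write records back in a form that re-parses to identical records."""
    rows = []
    for r in records:
        rows.append({
            "patient_id": r.patient_id,
            "age_at_lm": r.age_at_lm,
            "sex": r.sex,
            "driver_alteration": r.driver_alteration,
            "ecog_ps": r.ecog_ps,
            "extracranial_status": r.extracranial_status.replace("_", " "),
            "brain_parenchymal_status": r.brain_parenchymal_status.replace("_", " "),
            "tki_history": "+".join(r.tki_history) if r.tki_history else "–",
            "os_months": (">" if r.os_censored else "") + f"{r.os_months:g}",
            "profiling_test": r.profiling_test,
        })
    pd.DataFrame(rows, columns=COLUMNS).to_csv(path, sep="\t", index=False)


def summarize_cohort(records: list[ClinicalRecord]) -> CohortSummary:
    """Descriptive statistics of the cohort.

    Percentages are stored at full precision (round only for display).
    ``n_first_second_gen_egfr_tki`` counts EGFR-mutant patients whose TKI
    history includes any first-/second-generation EGFR inhibitor;
    ``n_osimertinib_exposed`` counts any osimertinib exposure.
    """
    if not records:
        raise ValueError("no clinical records")
    ages = np.array([r.age_at_lm for r in records])
    n = len(records)
    n_male = sum(r.sex == "man" for r in records)
    driver_counts: dict[str, int] = {}
    for r in records:
        driver_counts[r.driver_gene] = driver_counts.get(r.driver_gene, 0) + 1
    n_egfr = driver_counts.get("EGFR", 0)
    return CohortSummary(
        n_patients=n,
        n_male=n_male,
        pct_male=100.0 * n_male / n,
        median_age=float(np.median(ages)),
        age_min=int(ages.min()),
        age_max=int(ages.max()),
        driver_counts=driver_counts,
        pct_egfr=100.0 * n_egfr / n,
        n_no_brain_parenchymal_mets=sum(
            r.brain_parenchymal_status == "without_metastases" for r in records
        ),
        n_no_extracranial_mets=sum(
            r.extracranial_status == "without_metastases" for r in records
        ),
        n_osimertinib_exposed=sum(
            "osimertinib" in r.tki_history for r in records
        ),
        n_first_second_gen_egfr_tki=sum(
            r.driver_gene == "EGFR"
            and bool(set(r.tki_history) & FIRST_SECOND_GEN_EGFR_TKIS)
            for r in records
        ),
    )


def cross_tab_status(
    records: list[ClinicalRecord], detected: dict[str, bool]
) -> pd.DataFrame:
    """2xk table of plasma driver detection against extracranial status.

    Rows are ("detected", "not_detected"); columns follow the fixed
    clinical ordering progressive, stable, regressive, without_metastases.
    """
    by_id = {r.patient_id: r for r in records}
    unknown = set(detected) - set(by_id)
    if unknown:
        raise ValueError(f"unknown patient id(s) in detection map: {sorted(unknown)}")
    table = pd.DataFrame(
        0, index=["detected", "not_detected"], columns=list(STATUS_LEVELS)
    )
    for pid, was_detected in detected.items():
        row = "detected" if was_detected else "not_detected"
        table.loc[row, by_id[pid].extracranial_status] += 1
    return table
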