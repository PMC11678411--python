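"""Sparse TDM pharmacokinetic datasets and their NONMEM-style event-record format.

The on-disk dialect is a comma- or tab-delimited table with one row per
event: columns ``ID, TIME, AMT, DV, EVID, MDV`` followed by covariates
``AGE, SEX, RACE, WT, HT, SCR, FPG, DM`` (and optionally ``AKI``).
``EVID=1`` rows are dose events (AMT in mg), ``EVID=0`` rows are
concentration observations (DV in ug/mL).  SEX is coded 0 = male,
1 = female; RACE is a string token (white/black/asian/other); DM and AKI
are 0/1 flags.  MDV is optional; when absent it is taken as 0 for
observation rows.

Times are hours; on read, every subject's clock is shifted so that time 0
is that subject's first recorded dose.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from .covariates import classify_metabolic, derive_body_size, derive_renal

__all__ = [
    "DoseEvent",
    "Observation",
    "CovariateRecord",
    "Subject",
    "PKDataset",
    "FormatError",
    "ValidationError",
    "read_dataset",
    "write_dataset",
    "validate_dataset",
]

REQUIRED_COLUMNS = ("ID", "TIME", "AMT", "DV", "EVID")
COVARIATE_COLUMNS = ("AGE", "SEX", "RACE", "WT", "HT", "SCR", "FPG", "DM")


class FormatError(ValueError):
    """Raised when an event-record file violates the expected dialect."""


class ValidationError(ValueError):
    """Raised when a dataset violates a structural invariant."""


@dataclass(frozen=True)
class DoseEvent:
    """A single oral dose: time in hours since the subject's first dose, amount in mg."""

    time: float
    amount: float

    def __post_init__(self):
        # only cheap local checks here; dataset-level rules (positive amount,
        # observation-after-dose) are raised at read time and reported by
        # validate_dataset so that flawed in-memory data can still be audited
        if self.amount < 0:
            raise ValidationError(f"dose amount must be >= 0, got {self.amount}")
        if self.time < 0:
            raise ValidationError(f"dose time must be >= 0, got {self.time}")


@dataclass(frozen=True)
class Observation:
    """A plasma concentration observation (ug/mL) at a time in hours."""

    time: float
    concentration: float
    below_limit: bool = False

    def __post_init__(self):
        if self.time < 0:
            raise ValidationError(f"observation time must be >= 0, got {self.time}")
        if not np.isfinite(self.concentration):
            raise ValidationError("observed concentration must be finite")


@dataclass(frozen=True)
class CovariateRecord:
    """Raw demographics plus every derived clinical covariate.

    Derived fields are computed once from the raw fields via the covariate
    formulas (Devine IBW, Janmahasatian LBW, MDRD eGFR, Cockcroft-Gault
    CrCl, BMI-based obesity, combined metabolic category) and are therefore
    always recomputable.
    """

    age: float
    sex: str  # 'male' / 'female'
    race: str  # 'white' / 'black' / 'asian' / 'other'
    weight: float  # actual body weight, kg
    height: float  # cm
    scr: float  # serum creatinine, mg/dL
    fpg: float  # fasting plasma glucose, mg/dL
    diabetes: bool
    aki: bool = False
    # derived
    bmi: float = field(default=0.0)
    ibw: float = field(default=0.0)
    abw: float = field(default=0.0)
    lbw: float = field(default=0.0)
    egfr: float = field(default=0.0)
    crcl: float = field(default=0.0)
    obesity: bool = field(default=False)
    metabolic_category: str = field(default="")

    @classmethod
    def from_raw(
        cls,
        age: float,
        sex: str,
        race: str,
        weight: float,
        height: float,
        scr: float,
        fpg: float,
        diabetes: bool,
        aki: bool = False,
    ) -> "CovariateRecord":
        body = derive_body_size(weight, height, sex)
        renal = derive_renal(scr, age, sex, race, weight, body.ibw)
        cat, obese = classify_metabolic(body.bmi, diabetes)
        return cls(
            age=age, sex=sex, race=race, weight=weight, height=height,
            scr=scr, fpg=fpg, diabetes=bool(diabetes), aki=bool(aki),
            bmi=body.bmi, ibw=body.ibw, abw=body.abw, lbw=body.lbw,
            egfr=renal.egfr, crcl=renal.crcl,
            obesity=obese, metabolic_category=cat,
        )

    def value(self, name: str) -> float:
        """Numeric value of a covariate by its column-style name.

        Continuous covariates return their value; categorical covariates
        return a 0/1 indicator (SEX: female = 1).
        """
        name = name.upper()
        table = {
            "AGE": self.age, "WT": self.weight, "HT": self.height,
            "SCR": self.scr, "FPG": self.fpg, "BMI": self.bmi,
            "IBW": self.ibw, "ABW": self.abw, "LBW": self.lbw,
            "EGFR": self.egfr, "CRCL": self.crcl,
            "DM": float(self.diabetes), "AKI": float(self.aki),
            "OBESE": float(self.obesity),
            "SEX": float(self.sex == "female"),
            # indicator expansion of the 4-level metabolic category
            # (reference level: non-diabetic and non-obese)
            "METCAT_DM": float(self.metabolic_category == "diabetic but not obese"),
            "METCAT_OB": float(
                self.metabolic_category == "obese but metabolically healthy"
            ),
            "METCAT_DMOB": float(self.metabolic_category == "both diabetic and obese"),
        }
        if name in table:
            return float(table[name])
        raise KeyError(f"unknown covariate {name!r}")


CONTINUOUS_COVARIATES = (
    "AGE", "WT", "HT", "SCR", "FPG", "BMI", "IBW", "ABW", "LBW", "EGFR", "CRCL",
)
CATEGORICAL_COVARIATES = ("SEX", "DM", "AKI", "OBESE", "METCAT")


@dataclass
class Subject:
    """One subject: dose history, observations and covariates."""

    id: str
    doses: List[DoseEvent]
    observations: List[Observation]
    covariates: CovariateRecord

    def __post_init__(self):
        if not self.doses:
            raise ValidationError(f"subject {self.id}: at least one dose required")
        if not self.observations:
            raise ValidationError(
                f"subject {self.id}: at least one observation required"
            )
        times = [d.time for d in self.doses]
        if any(b < a for a, b in zip(times, times[1:])):
            raise ValidationError(f"subject {self.id}: dose times not ascending")


@dataclass
class PKDataset:
    """A collection of subjects with shared units (mg, h, ug/mL)."""

    subjects: List[Subject]
    provenance: str = ""
    units: Dict[str, str] = field(
        default_factory=lambda: {"amount": "mg", "time": "h", "concentration": "ug/mL"}
    )

    def __post_init__(self):
        if not self.subjects:
            raise ValidationError("dataset must contain at least one subject")
        ids = [s.id for s in self.subjects]
        if len(set(ids)) != len(ids):
            raise ValidationError("subject ids must be unique")

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_observations(self) -> int:
        return sum(len(s.observations) for s in self.subjects)

    def to_dataframe(self) -> pd.DataFrame:
        """Long event-record table, one row per dose or observation."""
        rows = []
        for s in self.subjects:
            cov = s.covariates
            base = {
                "AGE": cov.age, "SEX": 1 if cov.sex == "female" else 0,
                "RACE": cov.race, "WT": cov.weight, "HT": cov.height,
                "SCR": cov.scr, "FPG": cov.fpg, "DM": int(cov.diabetes),
                "AKI": int(cov.aki),
            }
            events = [
                {"ID": s.id, "TIME": d.time, "AMT": d.amount, "DV": np.nan,
                 "EVID": 1, "MDV": 1, **base}
                for d in s.doses
            ] + [
                {"ID": s.id, "TIME": o.time, "AMT": np.nan,
                 "DV": o.concentration, "EVID": 0, "MDV": 0, **base}
                for o in s.observations
            ]
            events.sort(key=lambda r: (r["TIME"], -r["EVID"]))
            rows.extend(events)
        return pd.DataFrame(rows)


def _subject_from_rows(sid: str, rows: pd.DataFrame) -> Subject:
    doses_raw = rows[rows["EVID"] == 1]
    if doses_raw.empty:
        raise ValidationError(f"subject {sid}: no dose rows (DV rows only?)")
    t0 = float(doses_raw["TIME"].min())
    doses = [
        DoseEvent(time=float(r.TIME) - t0, amount=float(r.AMT))
        for r in doses_raw.sort_values("TIME").itertuples()
    ]
    mdv = rows["MDV"] if "MDV" in rows else pd.Series(0, index=rows.index)
    obs_raw = rows[(rows["EVID"] == 0) & (mdv.fillna(0) == 0)]
    if obs_raw.empty:
        raise ValidationError(f"subject {sid}: no observation rows")
    times = obs_raw["TIME"].to_numpy(dtype=float)
    if np.any(times - t0 < 0):
        raise ValidationError(
            f"subject {sid}: observation precedes the first dose"
        )
    observations = [
        Observation(time=float(r.TIME) - t0, concentration=float(r.DV))
        for r in obs_raw.sort_values("TIME").itertuples()
    ]
    first = rows.iloc[0]
    sex = "female" if int(first["SEX"]) == 1 else "male"
    cov = CovariateRecord.from_raw(
        age=float(first["AGE"]), sex=sex, race=str(first["RACE"]).lower(),
        weight=float(first["WT"]), height=float(first["HT"]),
        scr=float(first["SCR"]), fpg=float(first["FPG"]),
        diabetes=bool(int(first["DM"])),
        aki=bool(int(first["AKI"])) if "AKI" in rows.columns else False,
    )
    return Subject(id=str(sid), doses=doses, observations=observations, covariates=cov)


def read_dataset(path, column_map: Optional[Dict[str, str]] = None) -> PKDataset:
    """Read a NONMEM-style event-record CSV/TSV into a validated PKDataset.

    Parameters
    ----------
    path : str or file-like
    column_map : dict, optional
        Mapping from file column names to the canonical names
        (e.g. ``{"SUBJ": "ID"}``).
    """
    # sniff the delimiter ourselves: the C parser (needed for round-trip
    # float precision) cannot autodetect, and the python engine cannot
    # parse floats exactly
    if hasattr(path, "read"):
        content = path.read()
    else:
        with open(path, "r") as fh:
            content = fh.read()
    header_line = content.splitlines()[0] if content else ""
    sep = "\t" if "\t" in header_line else ","
    df = pd.read_csv(io.StringIO(content), sep=sep,
                     float_precision="round_trip")
    if column_map:
        df = df.rename(columns=column_map)
    df.columns = [str(c).strip().upper() for c in df.columns]
    for col in REQUIRED_COLUMNS + COVARIATE_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"required column {col!r} missing from {path}")
    subjects = []
    for sid, rows in df.groupby("ID", sort=False):
        rows = rows.reset_index(drop=True)
        t = rows["TIME"].to_numpy(dtype=float)
        if np.any(np.diff(t) < 0):
            raise ValidationError(f"subject {sid}: event times not monotone")
        subjects.append(_subject_from_rows(str(sid), rows))
    return PKDataset(subjects=subjects, provenance=str(path))


def write_dataset(dataset: PKDataset, path) -> None:
    """Write a PKDataset in the same event-record dialect read_dataset consumes.

    Numeric fields are written at full precision (repr round-trip), so a
    write/read cycle reproduces every concentration bit-identically.
    """
    if not isinstance(dataset, PKDataset):
        raise ValidationError("write_dataset expects a PKDataset")
    df = dataset.to_dataframe()
    cols = ["ID", "TIME", "AMT", "DV", "EVID", "MDV",
            "AGE", "SEX", "RACE", "WT", "HT", "SCR", "FPG", "DM", "AKI"]
    df = df[cols]
    df.to_csv(path, index=False, float_format="%.17g")


def validate_dataset(dataset: PKDataset) -> List[str]:
    """Report (never repair) rule violations; an empty list means clean.

    Checks the study's inclusion rules and structural sanity: adult age
    (>= 18 years), serum creatinine present and positive, every
    observation at or after the first dose, strictly positive dose
    amounts, finite observed concentrations.
    """
    issues: List[str] = []
    for s in dataset.subjects:
        cov = s.covariates
        if cov.age < 18:
            issues.append(
                f"subject {s.id}: age {cov.age:g} violates the adult (>=18 y) "
                "inclusion rule"
            )
        if not np.isfinite(cov.scr) or cov.scr <= 0:
            issues.append(f"subject {s.id}: missing or nonpositive serum creatinine")
        first = s.doses[0].time
        for o in s.observations:
            if o.time < first:
                issues.append(
                    f"subject {s.id}: observation at {o.time:g} h precedes first dose"
                )
        for d in s.doses:
            if d.amount <= 0:
                issues.append(f"subject {s.id}: nonpositive dose amount {d.amount:g}")
    return issues
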