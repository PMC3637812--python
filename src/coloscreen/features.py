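"""Claims-derived binary predictors.

Converts raw administrative claims (billing, diagnosis, hospitalization and
surgery records) into the per-patient binary predictor vector used by every
downstream classifier.  Each predictor category (e.g. ``colonoscopy``,
``rectal_bleeding``) is defined by a set of ``(code_system, code)`` pairs and
a lookback window anchored at the index colonoscopy date: the flag is 1 iff
the patient has at least one matching claim inside the window.

Windows are half-open, ``[index_date - lookback_days, index_date)``: a claim
on the index day is the index exam itself, not history, and is excluded.
Years are rendered as fixed day counts (1 y = 365 d, 4 y = 1460 d,
5 y = 1825 d), ignoring leap days for reproducibility.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd
import yaml

CLAIMS_COLUMNS = ["patient_id", "date", "code", "code_system", "record_type"]

#: canonical predictor categories, in the order they enter the models
CATEGORY_ORDER = [
    "colonoscopy",
    "polypectomy",
    "sigmoidoscopy",
    "dcbe",
    "rectal_bleeding",
    "anemia",
    "diarrhea",
    "vomiting",
    "weight_loss",
    "ibd",
    "colorectal_polyps",
    "crc",
    "large_bowel_hospitalization",
    "large_bowel_surgery",
]


class ConfigError(ValueError):
    """Raised when a configuration file or object is invalid."""


class InputError(ValueError):
    """Raised when an input table violates a precondition."""


@dataclass(frozen=True)
class CodeCategory:
    """One predictor category: a code set plus its lookback window."""

    name: str
    codes: frozenset  # of (code_system, code) tuples
    lookback_days: int
    record_type: str = ""

    def __post_init__(self):
        if not self.codes:
            raise ConfigError(f"category {self.name!r}: empty code set")
        if self.lookback_days <= 0:
            raise ConfigError(f"category {self.name!r}: lookback_days must be positive")


@dataclass
class CodeDictionary:
    """Mapping of predictor categories to code sets and lookback windows."""

    categories: dict = field(default_factory=dict)  # name -> CodeCategory

    def __post_init__(self):
        missing = [c for c in CATEGORY_ORDER if c not in self.categories]
        if missing:
            raise ConfigError(f"code dictionary missing categories: {missing}")

    def __getitem__(self, name: str) -> CodeCategory:
        return self.categories[name]

    @property
    def names(self) -> list:
        ordered = [c for c in CATEGORY_ORDER if c in self.categories]
        extra = [c for c in self.categories if c not in CATEGORY_ORDER]
        return ordered + extra

    @classmethod
    def from_mapping(cls, mapping: dict) -> "CodeDictionary":
        cats = {}
        for name, spec in mapping.items():
            codes = frozenset(
                (entry["system"], entry["code"]) for entry in spec.get("codes", [])
            )
            cats[name] = CodeCategory(
                name=name,
                codes=codes,
                lookback_days=int(spec["lookback_days"]),
                record_type=spec.get("record_type", ""),
            )
        return cls(cats)

    @classmethod
    def from_yaml(cls, path) -> "CodeDictionary":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls.from_mapping(raw["categories"])

    @classmethod
    def default(cls) -> "CodeDictionary":
        ref = resources.files("coloscreen.data") / "codes.yaml"
        raw = yaml.safe_load(ref.read_text())
        return cls.from_mapping(raw["categories"])


def _parse_dates(values, what: str) -> pd.Series:
    parsed = pd.to_datetime(values, format="%Y-%m-%d", errors="coerce")
    if parsed.isna().any():
        bad = list(pd.Series(values)[pd.Series(parsed).isna().to_numpy()].head(5))
        raise InputError(f"unparseable {what} date(s), e.g. {bad}")
    return pd.Series(parsed)


def in_window(claim_date, index_date, lookback_days: int) -> int:
    """1 iff ``index_date - lookback_days <= claim_date < index_date``.

    The index day itself is excluded (a same-day code is the index exam,
    not history); the lower bound is inclusive.
    """
    claim = pd.Timestamp(claim_date)
    index = pd.Timestamp(index_date)
    lo = index - pd.Timedelta(days=int(lookback_days))
    return int(lo <= claim < index)


def extract_features(
    claims: pd.DataFrame,
    cohort: pd.DataFrame,
    dictionary: CodeDictionary | None = None,
) -> pd.DataFrame:
    """Build the per-patient feature table: age, sex and one binary flag per
    predictor category.

    A flag is 1 iff the patient has >= 1 claim whose ``(code_system, code)``
    belongs to the category and whose date falls in the category's lookback
    window before that patient's index date.  Deterministic and independent
    of claim row order.
    """
    if dictionary is None:
        dictionary = CodeDictionary.default()

    known = set(cohort["patient_id"])
    unknown = sorted(set(claims["patient_id"]) - known)
    if unknown:
        raise InputError(f"claims reference unknown patient ids: {unknown[:10]}")

    out = cohort[["patient_id", "age", "sex"]].copy().reset_index(drop=True)
    index_dates = _parse_dates(cohort["index_date"], "index")
    index_by_patient = dict(zip(cohort["patient_id"], index_dates))

    if len(claims):
        cdates = _parse_dates(claims["date"].reset_index(drop=True), "claim")
        cindex = claims["patient_id"].map(index_by_patient).reset_index(drop=True)
        pairs = list(zip(claims["code_system"], claims["code"]))
        days_before = (pd.Series(cindex.to_numpy()) - cdates).dt.days
    for name in dictionary.names:
        cat = dictionary[name]
        if len(claims):
            code_hit = pd.Series([p in cat.codes for p in pairs])
            inside = (days_before >= 1) & (days_before <= cat.lookback_days)
            hit_patients = set(
                claims["patient_id"].reset_index(drop=True)[code_hit & inside]
            )
        else:
            hit_patients = set()
        out[name] = out["patient_id"].isin(hit_patients).astype(int)
    return out


def read_claims(path) -> pd.DataFrame:
    claims = pd.read_csv(path, dtype=str)
    missing = [c for c in CLAIMS_COLUMNS if c not in claims.columns]
    if missing:
        raise InputError(f"claims file {path} missing columns: {missing}")
    return claims


def read_cohort(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_features(features: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    features.to_csv(path, index=False)
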