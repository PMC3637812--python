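"""Expert-opinion comparator rule (El-Serag-style).

Classifies an exam as screening iff the patient has no disqualifying
symptom/condition diagnosis code within its lookback window AND no prior
colonoscopy procedure code in the past 4 years.  Being absence-based, the
rule is monotone: adding claims can only move an exam from screening to
non-screening.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
import yaml

from .features import ConfigError, InputError, _parse_dates


@dataclass(frozen=True)
class DisqualifyingEntry:
    name: str
    codes: frozenset  # (system, code) pairs
    lookback_days: int


@dataclass
class ExpertRuleConfig:
    disqualifying: tuple          # DisqualifyingEntry, 28 in the default config
    colonoscopy_codes: frozenset  # (system, code) pairs
    colonoscopy_lookback_days: int = 1460

    def __post_init__(self):
        if not self.disqualifying:
            raise ConfigError("expert rule needs at least one disqualifying entry")
        if not self.colonoscopy_codes:
            raise ConfigError("expert rule needs colonoscopy procedure codes")
        for e in self.disqualifying:
            if not e.codes:
                raise ConfigError(f"disqualifying entry {e.name!r} has an empty code set")
            if e.lookback_days <= 0:
                raise ConfigError(f"disqualifying entry {e.name!r}: window must be positive")
        if self.colonoscopy_lookback_days <= 0:
            raise ConfigError("colonoscopy lookback must be positive")

    @classmethod
    def from_mapping(cls, raw: dict) -> "ExpertRuleConfig":
        entries = tuple(
            DisqualifyingEntry(
                name=e["name"],
                codes=frozenset((c["system"], c["code"]) for c in e["codes"]),
                lookback_days=int(e["lookback_days"]),
            )
            for e in raw["disqualifying"]
        )
        return cls(
            disqualifying=entries,
            colonoscopy_codes=frozenset(
                (c["system"], c["code"]) for c in raw["colonoscopy_codes"]
            ),
            colonoscopy_lookback_days=int(raw.get("colonoscopy_lookback_days", 1460)),
        )

    @classmethod
    def from_yaml(cls, path) -> "ExpertRuleConfig":
        with open(path) as fh:
            return cls.from_mapping(yaml.safe_load(fh))

    @classmethod
    def default(cls) -> "ExpertRuleConfig":
        ref = resources.files("coloscreen.data") / "elserag.yaml"
        return cls.from_mapping(yaml.safe_load(ref.read_text()))


def el_serag_classify(
    claims: pd.DataFrame,
    cohort: pd.DataFrame,
    config: ExpertRuleConfig | None = None,
) -> pd.DataFrame:
    """Apply the expert rule; returns a (patient_id, label) table, 1 = screening.

    A patient with no claims at all is screening by vacuous absence.
    """
    if config is None:
        config = ExpertRuleConfig.default()
    known = set(cohort["patient_id"])
    unknown = sorted(set(claims["patient_id"]) - known)
    if unknown:
        raise InputError(f"claims reference unknown patient ids: {unknown[:10]}")

    disqualified: set = set()
    if len(claims):
        index_dates = _parse_dates(cohort["index_date"], "index")
        index_by_patient = dict(zip(cohort["patient_id"], index_dates))
        cdates = _parse_dates(claims["date"].reset_index(drop=True), "claim")
        pids = claims["patient_id"].reset_index(drop=True)
        cindex = pids.map(index_by_patient)
        days_before = (pd.Series(cindex.to_numpy()) - cdates).dt.days
        pairs = pd.Series(list(zip(claims["code_system"], claims["code"])))
        for entry in config.disqualifying:
            hit = pairs.isin(entry.codes) & (days_before >= 1) & (
                days_before <= entry.lookback_days
            )
            disqualified.update(pids[hit.to_numpy()])
        colo = pairs.isin(config.colonoscopy_codes) & (days_before >= 1) & (
            days_before <= config.colonoscopy_lookback_days
        )
        disqualified.update(pids[colo.to_numpy()])

    labels = (~cohort["patient_id"].isin(disqualified)).astype(int)
    return pd.DataFrame(
        {"patient_id": cohort["patient_id"].to_numpy(), "label": labels.to_numpy()}
    )
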