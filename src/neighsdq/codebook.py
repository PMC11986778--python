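"""Covariate codebook: maps model-term names to cohort columns and codings.

Every covariate a model specification may name resolves to exactly one
codebook entry.  Entries carry the treatment-coding reference level for
categorical variables (female sex, White ethnicity, normal weight,
couple-parent family, NVQ level 1, IMD deciles 1-3) and, for continuous
exposures, their units and whether they are standardized before modelling.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import pandas as pd
import yaml

from .errors import SchemaError, SpecError

__all__ = ["CodebookEntry", "CovariateCodebook", "default_codebook"]


@dataclass(frozen=True)
class CodebookEntry:
    name: str
    source: str
    role: str  # individual | household | neighborhood | neighborhood_time_varying
    kind: str  # indicator | categorical | continuous | threshold_ge | range
    level: object = None
    reference: object = None
    levels: tuple = ()
    threshold: float | None = None
    lo: float | None = None
    hi: float | None = None
    units: str | None = None
    standardize: bool = False

    def column_names(self) -> list[str]:
        """Design-matrix column labels this entry expands to."""
        if self.kind == "categorical":
            return [f"{self.name}_{lv}" for lv in self.levels if lv != self.reference]
        return [self.name]

    def expand(self, df: pd.DataFrame) -> pd.DataFrame:
        """Numeric design columns for this entry (NaN propagates from source)."""
        if self.source not in df.columns:
            raise SchemaError(f"cohort lacks source column {self.source!r} for {self.name!r}")
        s = df[self.source]
        if self.kind == "indicator":
            out = (s == self.level).astype(float)
            out[s.isna()] = float("nan")
            return out.to_frame(self.name)
        if self.kind == "categorical":
            cols = {}
            for lv in self.levels:
                if lv == self.reference:
                    continue
                col = (s == lv).astype(float)
                col[s.isna()] = float("nan")
                cols[f"{self.name}_{lv}"] = col
            return pd.DataFrame(cols, index=df.index)
        if self.kind == "continuous":
            return pd.to_numeric(s, errors="coerce").to_frame(self.name)
        if self.kind == "threshold_ge":
            out = (pd.to_numeric(s, errors="coerce") >= self.threshold).astype(float)
            out[s.isna()] = float("nan")
            return out.to_frame(self.name)
        if self.kind == "range":
            v = pd.to_numeric(s, errors="coerce")
            out = ((v >= self.lo) & (v <= self.hi)).astype(float)
            out[s.isna()] = float("nan")
            return out.to_frame(self.name)
        raise SpecError(f"unknown codebook kind {self.kind!r}")


@dataclass
class CovariateCodebook:
    entries: dict[str, CodebookEntry] = field(default_factory=dict)

    def __getitem__(self, name: str) -> CodebookEntry:
        try:
            return self.entries[name]
        except KeyError:
            raise SpecError(f"covariate {name!r} not in codebook") from None

    def __contains__(self, name: str) -> bool:
        return name in self.entries

    def names(self) -> list[str]:
        return list(self.entries)

    @classmethod
    def from_dict(cls, raw: dict) -> "CovariateCodebook":
        entries = {}
        for name, spec in raw.get("covariates", raw).items():
            spec = dict(spec)
            if "levels" in spec:
                spec["levels"] = tuple(spec["levels"])
            entries[name] = CodebookEntry(name=name, **spec)
        return cls(entries)

    @classmethod
    def from_yaml(cls, path) -> "CovariateCodebook":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))


def default_codebook() -> CovariateCodebook:
    """The shipped default roster (see ``data/codebook.yaml``)."""
    ref = importlib.resources.files("neighsdq.data").joinpath("codebook.yaml")
    return CovariateCodebook.from_dict(yaml.safe_load(ref.read_text(encoding="utf-8")))
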