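"""Polynomial CpG clocks and DNAmAge evaluation.

A clock is an intercept plus a sum of linear and quadratic terms in
percent methylation:

    DNAmAge_s = beta0 + sum_i  coef_i * m(s, site_i) ** power_i,   power in {1, 2}

with ``m`` in percent (0-100).  The two built-in tissue-specific clocks
ship with their published coefficient sets and normality half-widths
(the MAD of training DeltaAge): 2.78 years for blood, 3.46 for heart.
A site may carry a quadratic term with no linear mate; no hierarchy is
imposed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from decimal import Decimal
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd

from .io import MethylationMatrix
from .panel import CpGSite, parse_site_id

__all__ = [
    "ClockTerm",
    "ClockModel",
    "builtin_blood_clock",
    "builtin_cardiac_clock",
    "predict_age",
    "load_clock_json",
    "save_clock_json",
]

MissingPolicy = Literal["fail", "median_impute"]


@dataclass(frozen=True)
class ClockTerm:
    """One polynomial term: ``coefficient * methylation(site) ** power``."""

    site: CpGSite
    power: int
    coefficient: float

    def __post_init__(self) -> None:
        if self.power not in (1, 2):
            raise ValueError(f"term power must be 1 or 2, got {self.power}")
        if not np.isfinite(self.coefficient):
            raise ValueError(f"non-finite coefficient for {self.site.site_id}")


@dataclass(frozen=True)
class ClockModel:
    """An intercept + term set with a tissue tag and MAD band half-width."""

    name: str
    tissue: str
    intercept: float
    terms: tuple[ClockTerm, ...]
    halfwidth: Optional[float] = None

    def __post_init__(self) -> None:
        keys = [(t.site.site_id, t.power) for t in self.terms]
        if len(set(keys)) != len(keys):
            dupes = sorted({k for k in keys if keys.count(k) > 1})
            raise ValueError(f"duplicate (site, power) terms: {dupes}")
        if self.halfwidth is not None and not self.halfwidth > 0:
            raise ValueError(f"halfwidth must be > 0, got {self.halfwidth}")

    @property
    def required_sites(self) -> list[str]:
        seen: dict[str, None] = {}
        for t in self.terms:
            seen.setdefault(t.site.site_id, None)
        return list(seen)

    @property
    def genes(self) -> list[str]:
        seen: dict[str, None] = {}
        for t in self.terms:
            seen.setdefault(t.site.gene, None)
        return list(seen)

    def coefficient(self, site_id: str, power: int) -> Optional[float]:
        for t in self.terms:
            if t.site.site_id == site_id and t.power == power:
                return t.coefficient
        return None

    def predict(
        self, matrix: MethylationMatrix, missing_policy: MissingPolicy = "fail"
    ) -> pd.Series:
        return predict_age(self, matrix, missing_policy=missing_policy)

    def with_halfwidth(self, halfwidth: float) -> "ClockModel":
        return replace(self, halfwidth=halfwidth)


def _terms(spec: Sequence[tuple[str, int, str]]) -> tuple[ClockTerm, ...]:
    return tuple(
        ClockTerm(site=parse_site_id(sid), power=p, coefficient=float(coef))
        for sid, p, coef in spec
    )


# Published blood formula: 10 linear + 7 quadratic terms over 12 CpGs in
# 6 genes.  Coefficients carried verbatim as decimal strings.
_BLOOD_TERMS = _terms(
    [
        ("EDARADD_CpG2", 1, "-0.3019982767"),
        ("ELOVL2_CpG2", 1, "0.2328338368"),
        ("ELOVL2_CpG3", 1, "-0.5749152672"),
        ("ELOVL2_CpG6", 1, "-0.9899312404"),
        ("FHL2_CpG10", 1, "0.6160217020"),
        ("FHL2_CpG2", 1, "-0.9602220285"),
        ("FHL2_CpG3", 1, "2.4305557761"),
        ("FHL2_CpG4", 1, "-0.1896789356"),
        ("ITGA2B_CpG2", 1, "-0.0865888452"),
        ("PDE4C_CpG5", 1, "1.0970579110"),
        ("ASPA_CpG1", 2, "-0.0006750886"),
        ("ELOVL2_CpG4", 2, "0.0025856173"),
        ("ELOVL2_CpG6", 2, "0.0111994179"),
        ("FHL2_CpG10", 2, "-0.0131271779"),
        ("FHL2_CpG2", 2, "0.0095023800"),
        ("FHL2_CpG3", 2, "-0.0185023682"),
        ("PDE4C_CpG5", 2, "-0.0102953607"),
    ]
)

# Published cardiac formula: 11 linear + 6 quadratic terms over 14 CpGs
# in 5 genes (no ASPA term).
_CARDIAC_TERMS = _terms(
    [
        ("EDARADD_CpG1", 1, "0.182565872"),
        ("ELOVL2_CpG2", 1, "0.848763871"),
        ("ELOVL2_CpG5", 1, "0.100544271"),
        ("ELOVL2_CpG7", 1, "-1.531702946"),
        ("FHL2_CpG1", 1, "1.000713439"),
        ("FHL2_CpG4", 1, "-0.674486107"),
        ("FHL2_CpG5", 1, "1.170946852"),
        ("FHL2_CpG7", 1, "0.816922873"),
        ("FHL2_CpG8", 1, "-0.641544097"),
        ("ITGA2B_CpG1", 1, "-0.958506956"),
        ("ITGA2B_CpG2", 1, "0.211886446"),
        ("ELOVL2_CpG3", 2, "-0.008128604"),
        ("ELOVL2_CpG7", 2, "0.016263489"),
        ("FHL2_CpG5", 2, "-0.026586745"),
        ("ITGA2B_CpG1", 2, "0.008172081"),
        ("PDE4C_CpG3", 2, "-0.026087696"),
        ("PDE4C_CpG5", 2, "0.014023034"),
    ]
)


def builtin_blood_clock() -> ClockModel:
    """The blood-specific clock (12 CpGs from all 6 panel genes)."""
    return ClockModel(
        name="MP-blood",
        tissue="blood",
        intercept=float("44.6227153511"),
        terms=_BLOOD_TERMS,
        halfwidth=2.78,
    )


def builtin_cardiac_clock() -> ClockModel:
    """The cardiac-specific clock (14 CpGs from 5 genes; ASPA absent)."""
    return ClockModel(
        name="MP-cardiac",
        tissue="heart",
        intercept=float("70.773560858"),
        terms=_CARDIAC_TERMS,
        halfwidth=3.46,
    )


def predict_age(
    model: ClockModel,
    matrix: MethylationMatrix,
    missing_policy: MissingPolicy = "fail",
) -> pd.Series:
    """Evaluate DNAmAge (years) for every sample in ``matrix``.

    Under ``fail`` (default) every required site must be present and
    observed for every sample; ``median_impute`` fills missing values
    with the per-site median of the evaluated matrix.
    """
    required = model.required_sites
    absent = [s for s in required if s not in matrix.values.columns]
    if absent:
        raise KeyError(
            f"matrix lacks required CpG sites for clock {model.name!r}: {absent}"
        )
    sub = matrix.values[required]
    if sub.isna().to_numpy().any():
        if missing_policy == "fail":
            bad = sub.index[sub.isna().any(axis=1)]
            raise ValueError(
                f"missing required methylation values for samples {list(bad)}; "
                "use missing_policy='median_impute' to impute"
            )
        elif missing_policy == "median_impute":
            sub = sub.fillna(sub.median(axis=0))
        else:  # pragma: no cover - guarded by typing
            raise ValueError(f"unknown missing policy {missing_policy!r}")

    ages = np.full(len(sub), model.intercept, dtype=float)
    for term in model.terms:
        ages += term.coefficient * sub[term.site.site_id].to_numpy() ** term.power
    return pd.Series(ages, index=sub.index, name="dnam_age")


def save_clock_json(model: ClockModel, path) -> None:
    """Serialize a clock; coefficients stored as decimal strings so the
    published precision survives round-trips."""
    payload = {
        "name": model.name,
        "tissue": model.tissue,
        "intercept": format(Decimal(repr(model.intercept)), "f"),
        "halfwidth": model.halfwidth,
        "terms": [
            {
                "site": t.site.site_id,
                "power": t.power,
                "coefficient": format(Decimal(repr(t.coefficient)), "f"),
            }
            for t in model.terms
        ],
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=1)


def load_clock_json(path) -> ClockModel:
    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)
    try:
        terms = tuple(
            ClockTerm(
                site=parse_site_id(rec["site"]),
                power=int(rec["power"]),
                coefficient=float(rec["coefficient"]),
            )
            for rec in payload["terms"]
        )
    except (KeyError, TypeError) as exc:
        raise ValueError(f"{path}: malformed clock term: {exc}") from exc
    return ClockModel(
        name=payload["name"],
        tissue=payload.get("tissue", "other"),
        intercept=float(payload["intercept"]),
        terms=terms,
        halfwidth=payload.get("halfwidth"),
    )
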