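"""Acylcarnitine ratio panel: enzyme-activity proxies for fatty-acid β-oxidation.

Chain-length-specific acylcarnitine ratios track flux through individual
β-oxidation steps: (C16+C18)/free carnitine rises with carnitine
palmitoyltransferase 1 (CPT1) activity, C14:1/C16 falls with very-long-chain
acyl-CoA dehydrogenase (VLCAD) activity, C4/C3 with short-chain (SCAD) and
C8/C10 with medium-chain (MCAD) acyl-CoA dehydrogenase activity, and the
hydroxyacylcarnitine/acylcarnitine ratios (C10-OH/C10, C8-OH/C8, C4-OH/C4)
fall as enoyl-CoA hydratase short chain 1 (ECHS1) activity rises.  C2/C0
summarizes overall acetyl turnover.

Ratios are computed per sample as sum(numerator)/sum(denominator) and are
exactly invariant to per-sample multiplicative factors, so normalization
errors cancel.  Tumor-vs-adjacent shifts are assessed with the paired
Wilcoxon test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_data import PeakTable, SampleRecord, paired_patient_samples
from .univariate import paired_wilcoxon

# canonical acylcarnitine ids used by the synthetic generator and the panel
FREE_CARNITINE = "carnitine_C0"

# alias map tolerating the spellings that appear in annotation exports
_ALIASES = {
    "carnitine_C4_0-OH": "carnitine_C4-OH",
    "carnitine_C8_0-OH": "carnitine_C8-OH",
    "carnitine_C10_0-OH": "carnitine_C10-OH",
    "C4-OH": "carnitine_C4-OH",
    "C8-OH": "carnitine_C8-OH",
    "C10-OH": "carnitine_C10-OH",
    "carnitine_C14_1": "carnitine_C14:1",
    "free_carnitine": FREE_CARNITINE,
}


def canonical_id(metabolite_id: str) -> str:
    return _ALIASES.get(metabolite_id, metabolite_id)


@dataclass
class RatioDefinition:
    name: str
    numerator: list[str]
    denominator: list[str]
    enzyme_interpretation: str = ""

    def __post_init__(self) -> None:
        if not self.numerator or not self.denominator:
            raise ValueError(f"ratio {self.name!r}: empty numerator/denominator")
        if set(self.numerator) & set(self.denominator):
            raise ValueError(f"ratio {self.name!r}: numerator and denominator overlap")


@dataclass
class RatioPanelResult:
    name: str
    values: pd.Series  # per-sample ratio, NaN when flagged-missing
    p_value: float = np.nan
    statistic: float = np.nan
    n_pairs: int = 0
    direction: str = ""
    definition: RatioDefinition | None = None


def builtin_ratio_panel() -> list[RatioDefinition]:
    """The eight-ratio β-oxidation proxy panel."""
    return [
        RatioDefinition(
            "CPT1", ["carnitine_C16", "carnitine_C18"], [FREE_CARNITINE],
            "proportional to carnitine palmitoyltransferase 1 activity",
        ),
        RatioDefinition(
            "VLCAD", ["carnitine_C14:1"], ["carnitine_C16"],
            "inversely proportional to very-long-chain acyl-CoA dehydrogenase activity",
        ),
        RatioDefinition(
            "SCAD", ["carnitine_C4"], ["carnitine_C3"],
            "inversely proportional to short-chain acyl-CoA dehydrogenase activity",
        ),
        RatioDefinition(
            "C2/C0", ["carnitine_C2"], [FREE_CARNITINE],
            "acetylcarnitine over free carnitine; overall acetyl turnover",
        ),
        RatioDefinition(
            "MCAD", ["carnitine_C8"], ["carnitine_C10"],
            "inversely proportional to medium-chain acyl-CoA dehydrogenase activity",
        ),
        RatioDefinition(
            "ECHS1_C10", ["carnitine_C10-OH"], ["carnitine_C10"],
            "inversely proportional to enoyl-CoA hydratase short chain 1 activity",
        ),
        RatioDefinition(
            "ECHS1_C8", ["carnitine_C8-OH"], ["carnitine_C8"],
            "inversely proportional to enoyl-CoA hydratase short chain 1 activity",
        ),
        RatioDefinition(
            "ECHS1_C4", ["carnitine_C4-OH"], ["carnitine_C4"],
            "inversely proportional to enoyl-CoA hydratase short chain 1 activity",
        ),
    ]


def compute_ratio_panel(
    pt: PeakTable,
    samples: list[SampleRecord],
    defs: list[RatioDefinition] | None = None,
) -> list[RatioPanelResult]:
    """Per-sample ratios plus paired tumor-vs-adjacent Wilcoxon tests.

    A sample missing any component of a ratio (or with a zero denominator)
    is flagged missing for that ratio; a ratio referencing a metabolite the
    table lacks entirely is skipped with a warning.
    """
    if defs is None:
        defs = builtin_ratio_panel()
    colmap = {canonical_id(c): c for c in pt.metabolite_ids}
    pairs = paired_patient_samples(samples)
    results = []
    for d in defs:
        needed = [canonical_id(m) for m in d.numerator + d.denominator]
        absent = [m for m in needed if m not in colmap]
        if absent:
            warnings.warn(f"ratio {d.name!r} skipped: metabolites absent {absent}")
            continue
        num = pt.data[[colmap[canonical_id(m)] for m in d.numerator]].sum(
            axis=1, skipna=False)
        den = pt.data[[colmap[canonical_id(m)] for m in d.denominator]].sum(
            axis=1, skipna=False)
        with np.errstate(divide="ignore", invalid="ignore"):
            vals = num / den
        vals[den == 0] = np.nan
        res = RatioPanelResult(name=d.name, values=vals, definition=d)
        if pairs:
            t = vals.loc[[t for _, t, _ in pairs]].to_numpy()
            a = vals.loc[[a for _, _, a in pairs]].to_numpy()
            ok = ~np.isnan(t) & ~np.isnan(a)
            if ok.sum() >= 4:
                w, p = paired_wilcoxon(t[ok], a[ok])
                res.statistic, res.p_value = w, p
                res.n_pairs = int(ok.sum())
                res.direction = "up" if np.median(t[ok] - a[ok]) > 0 else "down"
        results.append(res)
    return results


def ratio_table(results: list[RatioPanelResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "ratio": [r.name for r in results],
            "n_pairs": [r.n_pairs for r in results],
            "statistic": [r.statistic for r in results],
            "p_value": [r.p_value for r in results],
            "direction": [r.direction for r in results],
        }
    )


def read_ratio_definitions(path) -> list[RatioDefinition]:
    """Read ratio definitions from TSV: name, numerator ids ;-separated, denominator ids."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    return [
        RatioDefinition(
            name=row["name"],
            numerator=row["numerator"].split(";"),
            denominator=row["denominator"].split(";"),
            enzyme_interpretation=row.get("enzyme_interpretation", "") or "",
        )
        for _, row in df.iterrows()
    ]
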