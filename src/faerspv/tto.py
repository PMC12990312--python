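"""Time-to-onset (TTO) analysis: days from therapy start of the
primary-suspect drug to the adverse event, summarized per drug class.

Onset times in spontaneous reports are right-skewed and span days to
years; the per-class summary therefore reports the arithmetic mean with
the first and third quartiles, and cumulative-incidence (ECDF) points are
emitted for plotting temporal risk profiles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .ingest import CaseStore, ReportCase

logger = logging.getLogger(__name__)

#: Plausibility cap: onsets beyond 25 years are treated as data errors.
MAX_ONSET_DAYS = 9125.0

DRUG_CLASSES = ("anticancer", "immunosuppressant", "anti-inflammatory",
                "antiviral", "orthopedic", "digestive", "hematologic")

#: Packaged class map for the 21 proteinuria-associated drugs.
DRUG_CLASS_MAP: dict[str, str] = {
    "lenvatinib": "anticancer",
    "rituximab": "anticancer",
    "voclosporin": "anticancer",
    "everolimus": "anticancer",
    "sunitinib": "anticancer",
    "oxaliplatin": "anticancer",
    "carboplatin": "anticancer",
    "axitinib": "anticancer",
    "irinotecan": "anticancer",
    "paclitaxel": "anticancer",
    "pembrolizumab": "immunosuppressant",
    "atezolizumab": "immunosuppressant",
    "tacrolimus": "immunosuppressant",
    "budesonide": "immunosuppressant",
    "ibuprofen": "anti-inflammatory",
    "prednisone": "anti-inflammatory",
    "tenofovir disoproxil": "antiviral",
    "efavirenz/emtricitabine/tenofovir disoproxil": "antiviral",
    "zoledronic acid": "orthopedic",
    "lansoprazole": "digestive",
    "deferasirox": "hematologic",
}


@dataclass(frozen=True)
class OnsetRecord:
    """One case's time to onset for one primary-suspect drug."""

    drug: str
    drug_class: str
    onset_days: float
    imprecise_date: bool = False

    def __post_init__(self):
        if self.onset_days < 0:
            raise ValueError("onset_days must be nonnegative")


def compute_onset_days(case: ReportCase, drug: str) -> float:
    """Days from the PS drug's therapy start to the event; NaN if unknown.

    Negative onsets (event before start) and onsets beyond 25 years are
    implausible and excluded (NaN, logged).  When the drug has several
    therapy episodes, ingest already kept the earliest start.
    """
    if case.event_date is None:
        return np.nan
    starts = [m.therapy_start for m in case.ps_drugs
              if m.generic_name == drug and m.therapy_start is not None]
    if not starts:
        return np.nan
    onset = (case.event_date - min(starts)) / pd.Timedelta(days=1)
    if onset < 0 or onset > MAX_ONSET_DAYS:
        logger.info("implausible onset %.0f d for %s in case %s; excluded",
                    onset, drug, case.caseid)
        return np.nan
    return float(onset)


def onset_records(
    store: CaseStore,
    target_pts: Iterable[str],
    class_map: Mapping[str, str] | None = None,
    include_imprecise: bool = False,
) -> pd.DataFrame:
    """All per-(case, PS drug) onset records for target-event cases.

    Vectorized over the store; one row per PS mention of a class-mapped
    drug in a case reporting the target event, with columns ``drug``,
    ``drug_class``, ``onset_days``, ``imprecise_date``.  Records with
    imprecise (imputed) start or event dates are excluded by default.
    """
    class_map = DRUG_CLASS_MAP if class_map is None else dict(class_map)
    event_pids = pd.Index(store.event_primaryids(target_pts))
    ps = store.ps_drugs()
    ps = ps[ps["primaryid"].isin(event_pids) & ps["generic_name"].isin(class_map)]
    demo = store.demo[["primaryid", "event_date", "event_date_imprecise"]]
    merged = ps.merge(demo, on="primaryid", how="left")
    onset = (merged["event_date"] - merged["therapy_start"]) / pd.Timedelta(days=1)
    n_implausible = int(((onset < 0) | (onset > MAX_ONSET_DAYS)).sum())
    if n_implausible:
        logger.info("excluded %d implausible onset(s)", n_implausible)
    onset = onset.mask((onset < 0) | (onset > MAX_ONSET_DAYS))
    imprecise = merged["event_date_imprecise"] | merged["start_imprecise"]
    out = pd.DataFrame({
        "drug": merged["generic_name"],
        "drug_class": merged["generic_name"].map(class_map),
        "onset_days": onset,
        "imprecise_date": imprecise.astype(bool),
    }).dropna(subset=["onset_days"])
    if not include_imprecise:
        out = out[~out["imprecise_date"]]
    return out.reset_index(drop=True)


def class_tto_summary(records: pd.DataFrame) -> pd.DataFrame:
    """Per-class onset summary: n, arithmetic mean, Q1, Q3.

    Quartiles use linear interpolation between order statistics.  Classes
    with no records are omitted.
    """
    if records.empty:
        return pd.DataFrame(columns=["n", "mean", "q1", "q3"])
    rows = {}
    for cls, group in records.groupby("drug_class", sort=True):
        x = group["onset_days"].to_numpy(dtype=float)
        rows[cls] = {
            "n": len(x),
            "mean": float(np.mean(x)),
            "q1": float(np.percentile(x, 25)),
            "q3": float(np.percentile(x, 75)),
        }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "drug_class"
    out["n"] = out["n"].astype(int)
    return out


def cumulative_incidence(
    records: pd.DataFrame,
    grid: Sequence[float] | None = None,
) -> pd.DataFrame:
    """Per-class ECDF of onset time evaluated on a shared day grid.

    Values are monotone nondecreasing in [0, 1] and reach 1 at the last
    grid point at or past the class maximum.  The default grid spans 0 to
    the overall maximum in 200 steps.
    """
    if records.empty:
        raise ValueError("cumulative_incidence needs at least one record")
    if grid is None:
        top = float(records["onset_days"].max())
        grid = np.linspace(0.0, top, 201)
    grid = np.asarray(grid, dtype=float)
    frames = []
    for cls, group in records.groupby("drug_class", sort=True):
        x = np.sort(group["onset_days"].to_numpy(dtype=float))
        ecdf = np.searchsorted(x, grid, side="right") / len(x)
        frames.append(pd.DataFrame({"drug_class": cls, "days": grid,
                                    "cumulative_incidence": ecdf}))
    return pd.concat(frames, ignore_index=True)
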