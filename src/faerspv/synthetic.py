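"""Synthetic FAERS-like report generator with known ground truth.

Emits the quarterly "$"-delimited tables (DEMO, DRUG, REAC, THER, plus
schema-valid INDI/OUTC/RPSR placeholders) for a cohort of spontaneous
reports in which the drug-event association structure is known exactly:
each case carries one primary-suspect drug d and reports the target
adverse event with probability ``p0 * theta(d)``, so ``theta`` is the true
rate ratio a disproportionality analysis should recover.  Onset times,
demographics with FAERS unit-code quirks, partial dates, missingness, and
duplicate case versions are all generated so every downstream stage has
something realistic to chew on.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

TARGET_PT = "Proteinuria"

#: Background preferred terms assigned independently of the target event.
BACKGROUND_PTS = (
    "Nausea", "Headache", "Fatigue", "Diarrhoea", "Dizziness", "Vomiting",
    "Rash", "Pyrexia", "Pruritus", "Dyspnoea", "Arthralgia", "Insomnia",
    "Anaemia", "Hypertension", "Oedema peripheral", "Cough", "Constipation",
    "Decreased appetite", "Abdominal pain", "Myalgia", "Alopecia",
    "Hyperglycaemia", "Thrombocytopenia", "Neutropenia",
)


@dataclass(frozen=True)
class DrugSpec:
    """One catalog drug: report share, true rate ratio, onset distribution.

    ``share`` is the drug's marginal probability of being a case's primary
    suspect; ``rate_ratio`` multiplies the background target-event
    probability (1 encodes a null drug).  Onset is log-normal with the
    given median (days) and log-scale SD.
    """

    name: str
    share: float
    rate_ratio: float = 1.0
    onset_median_days: float = 60.0
    onset_log_sd: float = 1.0


@dataclass
class DemographicsSpec:
    """Marginal distributions for the DEMO fields, missingness included."""

    sex_probs: tuple[float, float, float] = (0.44, 0.38, 0.18)  # male, female, missing
    age_mean: float = 62.0
    age_sd: float = 16.0
    age_child_rate: float = 0.08  # pediatric mass, uniform on 0.5-17.5 years
    age_missing_rate: float = 0.08
    age_unit_mix: Mapping[str, float] = field(
        default_factory=lambda: {"YR": 0.85, "DEC": 0.05, "MON": 0.05, "DY": 0.05})
    weight_mean: float = 74.0
    weight_sd: float = 16.0
    weight_missing_rate: float = 0.25
    weight_unit_mix: Mapping[str, float] = field(
        default_factory=lambda: {"KG": 0.8, "LBS": 0.15, "GMS": 0.05})
    country_weights: Mapping[str, float] = field(
        default_factory=lambda: {
            "US": 0.32, "JP": 0.17, "FR": 0.06, "CA": 0.04, "DE": 0.04,
            "GB": 0.03, "IT": 0.03, "OTHER": 0.31,
        })


@dataclass
class SyntheticConfig:
    """Full specification of one synthetic cohort."""

    n_reports: int
    drug_catalog: Sequence[DrugSpec]
    background_event_probability: float = 0.01
    target_pt: str = TARGET_PT
    background_pts: Sequence[str] = BACKGROUND_PTS
    mean_background_pts: float = 1.5
    demographics: DemographicsSpec = field(default_factory=DemographicsSpec)
    duplicate_rate: float = 0.0
    partial_date_rate: float = 0.05
    concomitant_rate: float = 0.3
    seed: int = 0

    def validate(self) -> None:
        if self.n_reports < 0:
            raise ValueError("n_reports must be nonnegative")
        p0 = self.background_event_probability
        if not 0.0 < p0 < 1.0:
            raise ValueError("background_event_probability must lie in (0,1)")
        if not self.drug_catalog:
            raise ValueError("drug_catalog is empty")
        shares = np.array([d.share for d in self.drug_catalog], dtype=float)
        if np.any((shares <= 0) | (shares >= 1)):
            raise ValueError("drug shares must lie in (0,1)")
        if shares.sum() > 1.0 + 1e-9:
            raise ValueError("drug shares sum above 1")
        thetas = np.array([d.rate_ratio for d in self.drug_catalog], dtype=float)
        if np.any(thetas < 0):
            raise ValueError("rate ratios must be nonnegative")
        if p0 * thetas.max() > 1.0:
            raise ValueError(
                "probability overflow: background_event_probability * max rate "
                "ratio exceeds 1")
        if np.any(np.array([d.onset_median_days for d in self.drug_catalog]) < 0):
            raise ValueError("onset medians must be nonnegative")
        if not 0.0 <= self.duplicate_rate < 1.0:
            raise ValueError("duplicate_rate must lie in [0,1)")
        names = [d.name for d in self.drug_catalog]
        if len(set(names)) != len(names):
            raise ValueError("duplicate drug names in catalog")


@dataclass
class GroundTruth:
    """What the generator actually planted, for recovery checks."""

    theta: dict[str, float]
    onset_median_days: dict[str, float]
    true_signals: list[str]
    n_cases: int
    ps_report_counts: dict[str, int]
    ps_event_counts: dict[str, int]  # a-cell per drug: PS drug AND target event
    n_event_cases: int
    latest_primaryid: dict[int, int]  # caseid -> primaryid of the latest version
    duplicated_caseids: list[int]

    def to_json(self, path: str | Path) -> None:
        payload = asdict(self)
        payload["latest_primaryid"] = {str(k): v for k, v in self.latest_primaryid.items()}
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        payload = json.loads(Path(path).read_text())
        payload["latest_primaryid"] = {int(k): v for k, v in payload["latest_primaryid"].items()}
        return cls(**payload)


def default_catalog() -> list[DrugSpec]:
    """A 21-drug catalog shaped like the proteinuria signal landscape.

    Planted rate ratios span the range seen for real nephrotoxic drugs
    (strong anti-angiogenics and calcineurin inhibitors near 40-60, ICIs
    and antivirals near 8-17, weak signals near 2-3), over a bed of null
    background drugs.
    """
    named = [
        DrugSpec("lenvatinib", 0.010, 40.0, 45.0, 1.2),
        DrugSpec("voclosporin", 0.004, 60.0, 90.0, 1.0),
        DrugSpec("lansoprazole", 0.010, 27.0, 900.0, 1.1),
        DrugSpec("atezolizumab", 0.008, 16.0, 60.0, 1.0),
        DrugSpec("tenofovir disoproxil", 0.007, 12.5, 700.0, 1.3),
        DrugSpec("irinotecan", 0.005, 10.0, 30.0, 1.0),
        DrugSpec("axitinib", 0.005, 9.5, 40.0, 1.0),
        DrugSpec("pembrolizumab", 0.012, 8.4, 60.0, 1.0),
        DrugSpec("deferasirox", 0.006, 7.5, 180.0, 1.2),
        DrugSpec("everolimus", 0.008, 6.3, 50.0, 1.0),
        DrugSpec("tacrolimus", 0.012, 6.0, 120.0, 1.3),
        DrugSpec("budesonide", 0.006, 6.0, 90.0, 1.2),
        DrugSpec("oxaliplatin", 0.007, 5.2, 25.0, 0.9),
        DrugSpec("sunitinib", 0.007, 4.8, 35.0, 1.0),
        DrugSpec("carboplatin", 0.008, 3.3, 20.0, 0.9),
        DrugSpec("paclitaxel", 0.008, 3.3, 20.0, 0.9),
        DrugSpec("rituximab", 0.012, 3.2, 40.0, 1.2),
        DrugSpec("prednisone", 0.010, 3.3, 7.0, 0.8),
        DrugSpec("ibuprofen", 0.012, 2.2, 5.0, 0.3),
        DrugSpec("zoledronic acid", 0.008, 2.2, 60.0, 1.5),
        DrugSpec("efavirenz/emtricitabine/tenofovir disoproxil", 0.005, 14.7, 500.0, 1.2),
    ]
    used = sum(d.share for d in named)
    n_null = 30
    null_share = (1.0 - used) / n_null
    nulls = [DrugSpec(f"backgrounddrug{i:02d}", null_share, 1.0, 60.0, 1.0)
             for i in range(1, n_null + 1)]
    return named + nulls


def default_config(n_reports: int = 60000, seed: int = 0, **overrides) -> SyntheticConfig:
    cfg = SyntheticConfig(
        n_reports=n_reports, drug_catalog=default_catalog(),
        background_event_probability=0.012, seed=seed, duplicate_rate=0.05)
    for key, value in overrides.items():
        setattr(cfg, key, value)
    return cfg


# ---------------------------------------------------------------------------
# generation

_EPOCH = np.datetime64("2004-01-01")
_DAYS = int((np.datetime64("2024-12-31") - _EPOCH) / np.timedelta64(1, "D"))


def _fmt_dates(days_since_epoch: np.ndarray, partial_kind: np.ndarray) -> np.ndarray:
    """Render day offsets as YYYYMMDD strings, degrading some to YYYYMM/YYYY.

    ``partial_kind``: 0 full, 1 month precision, 2 year precision.
    """
    dates = _EPOCH + days_since_epoch.astype("timedelta64[D]")
    text = np.char.replace(np.datetime_as_string(dates, unit="D"), "-", "")
    month = np.array([t[:6] for t in text], dtype=object)
    year = np.array([t[:4] for t in text], dtype=object)
    full = text.astype(object)
    return np.where(partial_kind == 1, month, np.where(partial_kind == 2, year, full))


def _sample_cohort(config: SyntheticConfig) -> dict:
    """Draw the typed cohort arrays shared by both output paths."""
    rng = np.random.default_rng(config.seed)
    n = config.n_reports
    catalog = list(config.drug_catalog)
    names = np.array([d.name for d in catalog], dtype=object)
    shares = np.array([d.share for d in catalog], dtype=float)
    thetas = np.array([d.rate_ratio for d in catalog], dtype=float)
    medians = np.array([d.onset_median_days for d in catalog], dtype=float)
    log_sds = np.array([d.onset_log_sd for d in catalog], dtype=float)

    leftover = 1.0 - shares.sum()
    if leftover > 1e-12:
        # leftover marginal mass is spread over the null drugs so the
        # catalog drugs keep their exact shares
        probs = np.append(shares, leftover)
        drug_idx = rng.choice(len(probs), size=n, p=probs)
        null_pool = np.flatnonzero(thetas == 1.0)
        if null_pool.size == 0:
            null_pool = np.arange(len(catalog))
        overflow = drug_idx == len(catalog)
        drug_idx[overflow] = rng.choice(null_pool, size=int(overflow.sum()))
    else:
        drug_idx = rng.choice(len(catalog), size=n, p=shares / shares.sum())

    caseid = 10_000_001 + np.arange(n)
    primaryid = caseid * 10 + 1  # FAERS-style: caseid plus version digit

    p_event = np.clip(config.background_event_probability * thetas[drug_idx], 0.0, 1.0)
    has_event = rng.random(n) < p_event

    # demographics
    demo_spec = config.demographics
    sex_code = rng.choice(np.array(["M", "F", ""], dtype=object), size=n,
                          p=np.asarray(demo_spec.sex_probs) / np.sum(demo_spec.sex_probs))
    age_years = np.clip(rng.normal(demo_spec.age_mean, demo_spec.age_sd, n), 0.2, 100.0)
    child = rng.random(n) < demo_spec.age_child_rate
    age_years = np.where(child, rng.uniform(0.5, 17.5, n), age_years)
    age_missing = rng.random(n) < demo_spec.age_missing_rate
    age_codes = np.array(list(demo_spec.age_unit_mix), dtype=object)
    age_code = rng.choice(age_codes, size=n,
                          p=np.asarray(list(demo_spec.age_unit_mix.values())))
    age_factor = {"YR": 1.0, "DEC": 0.1, "MON": 12.0, "WK": 52.0,
                  "DY": 365.25, "HR": 8766.0}
    age_value = age_years * np.vectorize(age_factor.__getitem__)(age_code)
    weight_kg = np.clip(rng.normal(demo_spec.weight_mean, demo_spec.weight_sd, n), 2.0, 250.0)
    weight_missing = rng.random(n) < demo_spec.weight_missing_rate
    wt_codes = np.array(list(demo_spec.weight_unit_mix), dtype=object)
    wt_code = rng.choice(wt_codes, size=n,
                         p=np.asarray(list(demo_spec.weight_unit_mix.values())))
    wt_factor = {"KG": 1.0, "LBS": 1.0 / 0.453592, "GMS": 1000.0}
    wt_value = weight_kg * np.vectorize(wt_factor.__getitem__)(wt_code)
    countries = np.array(list(demo_spec.country_weights), dtype=object)
    cprobs = np.asarray(list(demo_spec.country_weights.values()), dtype=float)
    country = rng.choice(countries, size=n, p=cprobs / cprobs.sum())
    country = np.where(country == "OTHER", "", country)

    # dates: event day uniform over the window; receipt lags the event
    event_day = rng.integers(400, _DAYS, size=n)
    receipt_day = np.minimum(event_day + rng.integers(7, 120, size=n), _DAYS)
    onset_days = np.exp(rng.normal(np.log(np.maximum(medians[drug_idx], 0.5)),
                                   log_sds[drug_idx], size=n))
    onset_days = np.maximum(np.rint(onset_days), 1).astype(np.int64)
    start_day = event_day - onset_days

    partial = rng.random(n) < config.partial_date_rate
    partial_kind = np.where(partial, rng.integers(1, 3, size=n), 0)
    start_partial = np.where(rng.random(n) < config.partial_date_rate,
                             rng.integers(1, 3, size=n), 0)

    # concomitant drug mentions (role C) drawn from the catalog
    n_conc = rng.poisson(config.concomitant_rate, size=n)
    conc_total = int(n_conc.sum())
    conc_name = names[rng.choice(len(catalog), size=conc_total)]

    # background preferred terms, 1..k per case
    bg_pool = np.array(list(config.background_pts), dtype=object)
    k_bg = 1 + rng.poisson(max(config.mean_background_pts - 1.0, 0.0), size=n)
    bg_pt = bg_pool[rng.choice(len(bg_pool), size=int(k_bg.sum()))]

    return {
        "n": n, "names": names, "catalog": catalog, "drug_idx": drug_idx,
        "caseid": caseid, "primaryid": primaryid, "has_event": has_event,
        "sex_code": sex_code, "age_years": age_years, "age_missing": age_missing,
        "age_code": age_code, "age_value": age_value,
        "weight_kg": weight_kg, "weight_missing": weight_missing,
        "wt_code": wt_code, "wt_value": wt_value, "country": country,
        "event_day": event_day, "receipt_day": receipt_day,
        "onset_days": onset_days, "start_day": start_day,
        "partial_kind": partial_kind, "start_partial": start_partial,
        "n_conc": n_conc, "conc_name": conc_name, "k_bg": k_bg, "bg_pt": bg_pt,
    }


def _ground_truth(config: SyntheticConfig, s: dict | None) -> GroundTruth:
    catalog = list(config.drug_catalog)
    truth = GroundTruth(
        theta={d.name: d.rate_ratio for d in catalog},
        onset_median_days={d.name: d.onset_median_days for d in catalog},
        true_signals=[d.name for d in catalog if d.rate_ratio > 1.0],
        n_cases=config.n_reports, ps_report_counts={}, ps_event_counts={},
        n_event_cases=0, latest_primaryid={}, duplicated_caseids=[],
    )
    if s is None:
        return truth
    names, drug_idx, has_event = s["names"], s["drug_idx"], s["has_event"]
    ps_counts = np.bincount(drug_idx, minlength=len(catalog))
    a_counts = np.bincount(drug_idx[has_event], minlength=len(catalog))
    truth.ps_report_counts = {names[i]: int(ps_counts[i]) for i in range(len(catalog))}
    truth.ps_event_counts = {names[i]: int(a_counts[i]) for i in range(len(catalog))}
    truth.n_event_cases = int(has_event.sum())
    truth.latest_primaryid = {int(c): int(p)
                              for c, p in zip(s["caseid"], s["primaryid"])}
    return truth


def generate_reports(config: SyntheticConfig) -> tuple[dict[str, pd.DataFrame], GroundTruth]:
    """Generate one synthetic cohort: raw tables plus its ground truth.

    Deterministic given ``config`` (including its seed).  Duplicate case
    versions are injected afterwards when ``config.duplicate_rate > 0``;
    the ground truth records the latest version of every case.
    """
    config.validate()
    if config.n_reports == 0:
        return _empty_tables(), _ground_truth(config, None)
    s = _sample_cohort(config)
    truth = _ground_truth(config, s)
    n = s["n"]
    names = s["names"]
    primaryid, caseid = s["primaryid"], s["caseid"]
    drug_idx, has_event = s["drug_idx"], s["has_event"]
    age_missing, weight_missing = s["age_missing"], s["weight_missing"]

    demo = pd.DataFrame({
        "primaryid": primaryid.astype(str),
        "caseid": caseid.astype(str),
        "caseversion": "1",
        "fda_dt": _fmt_dates(s["receipt_day"], np.zeros(n, dtype=int)),
        "event_dt": _fmt_dates(s["event_day"], s["partial_kind"]),
        "sex": s["sex_code"],
        "age": np.where(age_missing, "", np.char.mod("%.1f", s["age_value"])),
        "age_cod": np.where(age_missing, "", s["age_code"].astype(str)),
        "wt": np.where(weight_missing, "", np.char.mod("%.1f", s["wt_value"])),
        "wt_cod": np.where(weight_missing, "", s["wt_code"].astype(str)),
        "occr_country": s["country"],
    })

    # DRUG: one PS row per case, plus concomitants drawn from the catalog
    n_conc = s["n_conc"]
    conc_total = int(n_conc.sum())
    conc_pid = np.repeat(primaryid, n_conc)
    conc_cid = np.repeat(caseid, n_conc)
    conc_seq = (np.concatenate([np.arange(2, k + 2) for k in n_conc])
                if conc_total else np.array([], dtype=int))
    drug = pd.DataFrame({
        "primaryid": np.concatenate([primaryid, conc_pid]).astype(str),
        "caseid": np.concatenate([caseid, conc_cid]).astype(str),
        "drug_seq": np.concatenate([np.ones(n, dtype=int), conc_seq]).astype(str),
        "role_cod": np.array(["PS"] * n + ["C"] * conc_total, dtype=object),
        "drugname": np.concatenate([names[drug_idx], s["conc_name"]]),
    })
    drug = drug.sort_values(["caseid", "drug_seq"], kind="mergesort").reset_index(drop=True)

    # REAC: target PT where drawn + 1..k background PTs
    k_bg = s["k_bg"]
    bg_pid = np.repeat(primaryid, k_bg)
    bg_cid = np.repeat(caseid, k_bg)
    reac = pd.DataFrame({
        "primaryid": np.concatenate([primaryid[has_event], bg_pid]).astype(str),
        "caseid": np.concatenate([caseid[has_event], bg_cid]).astype(str),
        "pt": np.concatenate([np.full(int(has_event.sum()), config.target_pt,
                                      dtype=object), s["bg_pt"]]),
    })
    reac = reac.drop_duplicates().sort_values(["caseid", "pt"], kind="mergesort").reset_index(drop=True)

    # THER: therapy episode for the PS drug
    ther = pd.DataFrame({
        "primaryid": primaryid.astype(str),
        "caseid": caseid.astype(str),
        "dsg_drug_seq": "1",
        "start_dt": _fmt_dates(np.maximum(s["start_day"], 0), s["start_partial"]),
        "end_dt": _fmt_dates(s["event_day"], np.zeros(n, dtype=int)),
    })

    placeholder = pd.DataFrame({"primaryid": primaryid.astype(str),
                                "caseid": caseid.astype(str)})
    indi = placeholder.assign(indi_drug_seq="1",
                              indi_pt="Product used for unknown indication")
    outc = placeholder.assign(outc_cod="OT")
    rpsr = placeholder.assign(rpsr_cod="HP")

    tables = {"DEMO": demo, "DRUG": drug, "REAC": reac, "THER": ther,
              "INDI": indi, "OUTC": outc, "RPSR": rpsr}

    if config.duplicate_rate > 0:
        tables = inject_duplicates(tables, config.duplicate_rate,
                                   seed=config.seed + 1, truth=truth)
    return tables, truth


def simulate_store(config: SyntheticConfig):
    """Build the deduplicated, normalized case store directly in memory.

    Samples the identical cohort model as :func:`generate_reports` but
    skips the ASCII encode/parse round trip, producing the
    :class:`faerspv.ingest.CaseStore` an ingest of those files would
    yield (duplicate injection is skipped: the result is already one row
    per case).  Intended for simulation studies that run many seeded
    replicates.
    """
    from .ingest import COUNTRY_ALIASES, CaseStore, IngestLog

    config.validate()
    if config.n_reports == 0:
        empty = CaseStore(
            demo=pd.DataFrame(columns=["primaryid", "caseid", "receipt_date",
                                       "event_date", "event_date_imprecise",
                                       "sex", "age_years", "weight_kg", "country"]),
            drugs=pd.DataFrame(columns=["primaryid", "generic_name", "role",
                                        "therapy_start", "therapy_end",
                                        "start_imprecise"]),
            reacs=pd.DataFrame(columns=["primaryid", "pt"]),
        )
        return empty, _ground_truth(config, None)
    s = _sample_cohort(config)
    truth = _ground_truth(config, s)
    n = s["n"]
    primaryid, caseid = s["primaryid"], s["caseid"]

    def days(day_offsets):
        return pd.to_datetime(_EPOCH) + pd.to_timedelta(day_offsets, unit="D")

    sex = pd.Series(s["sex_code"]).map({"M": "male", "F": "female"}).fillna("missing")
    country = pd.Series(s["country"]).map(
        lambda c: COUNTRY_ALIASES.get(c, c) if c else "missing")
    demo = pd.DataFrame({
        "primaryid": primaryid,
        "caseid": caseid,
        "receipt_date": days(s["receipt_day"]),
        "event_date": days(s["event_day"]),
        "event_date_imprecise": s["partial_kind"] > 0,
        "sex": sex.to_numpy(),
        "age_years": np.where(s["age_missing"], np.nan, s["age_years"]),
        "weight_kg": np.where(s["weight_missing"], np.nan, s["weight_kg"]),
        "country": country.to_numpy(),
    })

    n_conc = s["n_conc"]
    conc_total = int(n_conc.sum())
    drugs = pd.DataFrame({
        "primaryid": np.concatenate([primaryid, np.repeat(primaryid, n_conc)]),
        "generic_name": np.concatenate([s["names"][s["drug_idx"]], s["conc_name"]]),
        "role": np.array(["PS"] * n + ["C"] * conc_total, dtype=object),
        "therapy_start": np.concatenate([
            days(np.maximum(s["start_day"], 0)).to_numpy(),
            np.full(conc_total, np.datetime64("NaT"))]),
        "therapy_end": np.concatenate([
            days(s["event_day"]).to_numpy(),
            np.full(conc_total, np.datetime64("NaT"))]),
        "start_imprecise": np.concatenate([s["start_partial"] > 0,
                                           np.zeros(conc_total, dtype=bool)]),
    })

    reacs = pd.DataFrame({
        "primaryid": np.concatenate([primaryid[s["has_event"]],
                                     np.repeat(primaryid, s["k_bg"])]),
        "pt": np.concatenate([
            np.full(int(s["has_event"].sum()), config.target_pt, dtype=object),
            s["bg_pt"]]),
    }).drop_duplicates().reset_index(drop=True)

    log = IngestLog(cases_retained=n)
    return CaseStore(demo=demo, drugs=drugs, reacs=reacs, log=log), truth


def inject_duplicates(
    tables: Mapping[str, pd.DataFrame],
    duplicate_rate: float,
    seed: int,
    truth: GroundTruth | None = None,
) -> dict[str, pd.DataFrame]:
    """Add amended case versions for a random fraction of cases.

    Each selected case gains one extra row per table with a new (larger)
    ``primaryid``, a receipt date at or after the original, and weight
    filled in when it was missing (amendments often complete fields).
    When ``truth`` is given, its ``latest_primaryid`` map is updated so
    deduplication can be checked exactly.
    """
    if not 0.0 <= duplicate_rate < 1.0:
        raise ValueError("duplicate_rate must lie in [0,1)")
    tables = {k: v.copy() for k, v in tables.items()}
    if duplicate_rate == 0.0 or tables["DEMO"].empty:
        return tables
    rng = np.random.default_rng(seed)
    demo = tables["DEMO"]
    pick = rng.random(len(demo)) < duplicate_rate
    if not pick.any():
        return tables
    dup = demo.loc[pick].copy()
    old_pid = dup["primaryid"].astype(np.int64)
    new_pid = old_pid + 1  # caseid*10+2 > caseid*10+1, and receipt is later
    dup["primaryid"] = new_pid.astype(str)
    dup["caseversion"] = "2"
    old_receipt = pd.to_datetime(dup["fda_dt"], format="%Y%m%d")
    lag = rng.integers(1, 180, size=len(dup))
    new_receipt = old_receipt + pd.to_timedelta(lag, unit="D")
    dup["fda_dt"] = new_receipt.dt.strftime("%Y%m%d")
    missing_wt = dup["wt"] == ""
    dup.loc[missing_wt, "wt"] = "70.0"
    dup.loc[missing_wt, "wt_cod"] = "KG"
    tables["DEMO"] = pd.concat([demo, dup], ignore_index=True)

    remap = dict(zip(old_pid.astype(str), new_pid.astype(str)))
    for name in ("DRUG", "REAC", "THER", "INDI", "OUTC", "RPSR"):
        frame = tables.get(name)
        if frame is None or frame.empty:
            continue
        extra = frame[frame["primaryid"].isin(remap)].copy()
        extra["primaryid"] = extra["primaryid"].map(remap)
        tables[name] = pd.concat([frame, extra], ignore_index=True)

    if truth is not None:
        dup_cases = dup["caseid"].astype(int).tolist()
        truth.duplicated_caseids = sorted(dup_cases)
        for cid, pid in zip(dup_cases, new_pid):
            truth.latest_primaryid[int(cid)] = int(pid)
    return tables


def _empty_tables() -> dict[str, pd.DataFrame]:
    cols = {
        "DEMO": ["primaryid", "caseid", "caseversion", "fda_dt", "event_dt",
                 "sex", "age", "age_cod", "wt", "wt_cod", "occr_country"],
        "DRUG": ["primaryid", "caseid", "drug_seq", "role_cod", "drugname"],
        "REAC": ["primaryid", "caseid", "pt"],
        "THER": ["primaryid", "caseid", "dsg_drug_seq", "start_dt", "end_dt"],
        "INDI": ["primaryid", "caseid", "indi_drug_seq", "indi_pt"],
        "OUTC": ["primaryid", "caseid", "outc_cod"],
        "RPSR": ["primaryid", "caseid", "rpsr_cod"],
    }
    return {name: pd.DataFrame(columns=c) for name, c in cols.items()}


def write_tables(tables: Mapping[str, pd.DataFrame], outdir: str | Path) -> list[Path]:
    """Write tables as per-quarter "$"-delimited files (DEMOyyQq.txt, ...).

    The quarter is derived from each report's receipt date; companion
    tables follow their DEMO row's quarter so a quarter's files are
    self-contained.  Output is byte-stable for a fixed input.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    demo = tables["DEMO"]
    written: list[Path] = []
    if demo.empty:
        for name, frame in tables.items():
            path = outdir / f"{name}04Q1.txt"
            frame.to_csv(path, sep="$", index=False, lineterminator="\n")
            written.append(path)
        return written
    receipt = pd.to_datetime(demo["fda_dt"], format="%Y%m%d")
    quarter = receipt.dt.strftime("%y") + "Q" + receipt.dt.quarter.astype(str)
    pid_quarter = dict(zip(demo["primaryid"], quarter))
    for name, frame in tables.items():
        q = frame["primaryid"].map(pid_quarter) if len(frame) else pd.Series(dtype=str)
        for qlabel in sorted(q.dropna().unique()):
            part = frame[q == qlabel]
            path = outdir / f"{name}{qlabel}.txt"
            part.to_csv(path, sep="$", index=False, lineterminator="\n")
            written.append(path)
    return written
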