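"""Published summary statistics of the aspirin-prophylaxis FAERS screen.

A published disproportionality screen of aspirin used as prophylaxis
medication (FAERS, 2004Q1-2021Q2; 858 deduplicated cases) reported its
results only as summary tables: the top-10 signal rows per indication with
the four algorithms' statistics, time-to-onset bin counts, the SOC
distribution, demographic marginals and outcome counts.  Those printed
numbers are reproduced here as plain data.  They serve two purposes:

* calibration targets for :func:`pvsignal.synthetic.default_paper_config`,
  so synthetic databases look like the real cohort; and
* regression fixtures for the screening criteria and descriptive stages.

Nothing here is computed; the values are the published ones.
"""

from __future__ import annotations

from typing import Dict, List, Tuple

#: total deduplicated cases in the published cohort
TOTAL_CASES = 858

# --- top-10 signal rows ----------------------------------------------------
# Each row: (reaction, indication, n, ror, ror_lo, ror_hi,
#            prr, prr_lo, prr_hi, chi2, ic, ic_low, ebgm, ebgm05)
TOP10_SIGNAL_ROWS: List[Tuple] = [
    # indication: Prophylaxis (NEC)
    ("Melaena", "Prophylaxis (NEC)", 101, 1.55, 1.28, 1.89, 1.55, 1.35, 1.75, 19.08, 0.62, 0.60, 1.55, 1.38),
    ("Duodenal ulcer", "Prophylaxis (NEC)", 48, 2.29, 1.72, 3.04, 2.29, 2.01, 2.57, 33.38, 1.15, 1.11, 2.28, 2.04),
    ("Gastritis erosive", "Prophylaxis (NEC)", 46, 3.29, 2.46, 4.40, 3.29, 3.00, 3.58, 70.10, 1.64, 1.59, 3.26, 3.02),
    ("Gastric ulcer hemorrhage", "Prophylaxis (NEC)", 42, 2.29, 1.69, 3.11, 2.29, 1.99, 2.60, 29.16, 1.15, 1.11, 2.28, 2.03),
    ("Blood loss anemia", "Prophylaxis (NEC)", 33, 1.54, 1.09, 2.16, 1.54, 1.20, 1.88, 5.63, 0.59, 0.56, 1.53, 1.25),
    ("Duodenal ulcer hemorrhage", "Prophylaxis (NEC)", 21, 2.06, 1.34, 3.16, 2.06, 1.63, 2.49, 10.29, 0.97, 0.91, 2.05, 1.69),
    ("Dyspnoea at rest", "Prophylaxis (NEC)", 13, 1.78, 1.03, 3.07, 1.78, 1.24, 2.33, 3.69, 0.75, 0.69, 1.78, 1.32),
    ("Urinary tract discomfort", "Prophylaxis (NEC)", 9, 13.46, 6.90, 26.25, 13.46, 12.79, 14.13, 87.65, 2.56, 2.35, 12.91, 12.35),
    ("Erosive duodenitis", "Prophylaxis (NEC)", 7, 2.43, 1.15, 5.10, 2.43, 1.68, 3.17, 4.48, 1.04, 0.94, 2.41, 1.79),
    ("Naevus flammeus", "Prophylaxis (NEC)", 5, 8.10, 3.33, 19.69, 8.10, 7.21, 8.99, 23.73, 1.87, 1.66, 7.91, 7.16),
    # indication: Thrombosis prophylaxis
    ("Melaena", "Thrombosis prophylaxis", 127, 1.95, 1.64, 2.33, 1.95, 1.78, 2.13, 57.64, 0.95, 0.93, 1.95, 1.80),
    ("Duodenal ulcer", "Thrombosis prophylaxis", 31, 1.48, 1.04, 2.10, 1.48, 1.12, 1.83, 4.26, 0.54, 0.50, 1.47, 1.18),
    ("Microcytic anemia", "Thrombosis prophylaxis", 25, 3.59, 2.42, 5.32, 3.58, 3.19, 3.98, 43.51, 1.69, 1.63, 3.55, 3.22),
    ("Lip erosion", "Thrombosis prophylaxis", 22, 3.85, 2.53, 5.86, 3.85, 3.42, 4.27, 42.94, 1.76, 1.69, 3.81, 3.46),
    ("Vascular stent thrombosis", "Thrombosis prophylaxis", 22, 3.99, 2.62, 6.07, 3.99, 3.57, 4.41, 45.67, 1.81, 1.73, 3.95, 3.60),
    ("Mucosal erosion", "Thrombosis prophylaxis", 21, 3.86, 2.51, 5.94, 3.86, 3.43, 4.29, 41.12, 1.76, 1.69, 3.82, 3.46),
    ("Nikolsky's sign", "Thrombosis prophylaxis", 18, 4.02, 2.53, 6.41, 4.02, 3.56, 4.49, 37.42, 1.78, 1.70, 3.98, 3.59),
    ("Hematoma muscle", "Thrombosis prophylaxis", 16, 8.02, 4.88, 13.17, 8.02, 7.52, 8.51, 88.91, 2.48, 2.36, 7.83, 7.41),
    ("Vascular stent stenosis", "Thrombosis prophylaxis", 8, 3.58, 1.78, 7.19, 3.58, 2.88, 4.28, 12.25, 1.47, 1.35, 3.55, 2.97),
    ("Thalamus hemorrhage", "Thrombosis prophylaxis", 8, 3.13, 1.56, 6.28, 3.13, 2.43, 3.83, 9.46, 1.33, 1.23, 3.11, 2.53),
]

# --- time to onset (months after therapy start) ----------------------------
ONSET_BIN_LABELS = (
    "0~1 month", "1~3 months", "3~6 months", "6~9 months",
    "9~12 months", "12~24 months", "24~60 months", "60~ months",
)

#: indication -> per-bin counts of cases with known onset
ONSET_BIN_COUNTS: Dict[str, Tuple[int, ...]] = {
    "Thrombosis prophylaxis": (19, 35, 53, 37, 26, 20, 18, 8),
    "Prophylaxis (NEC)": (21, 12, 15, 10, 6, 34, 33, 43),
    "Cardiovascular event prophylaxis": (1, 5, 0, 1, 0, 1, 1, 5),
    "Ischemic heart disease prophylaxis": (2, 0, 2, 0, 0, 0, 1, 1),
    "Cerebrovascular accident prophylaxis": (2, 0, 1, 0, 0, 0, 2, 0),
}

#: indication -> mean onset in days among known-onset cases
ONSET_MEAN_DAYS: Dict[str, float] = {
    "Thrombosis prophylaxis": 471.0,
    "Prophylaxis (NEC)": 1324.8,
    "Cardiovascular event prophylaxis": 1637.6,
    "Ischemic heart disease prophylaxis": 606.7,
    "Cerebrovascular accident prophylaxis": 538.2,
}

#: case-weighted mean over all known-onset cases, days
ONSET_OVERALL_MEAN_DAYS = 871.1
ONSET_OVERALL_STD_DAYS = 1498.9

# --- SOC distribution (case counts; cases may occur under several SOCs) ----
SOC_CASE_COUNTS: Dict[str, int] = {
    "Gastrointestinal disorders": 542,
    "General disorders and administration site conditions": 57,
    "Blood and lymphatic system disorders": 39,
    "Injury, poisoning, and procedural complications": 33,
    "Skin and subcutaneous tissue disorders": 32,
    "Cardiac disorders": 26,
    "Investigations": 25,
    "Renal and urinary disorders": 23,
    "Musculoskeletal and connective tissue disorders": 18,
    "Respiratory, thoracic, and mediastinal disorders": 17,
    "Nervous system disorders": 16,
    "Vascular disorders": 14,
    "Infections and infestations": 10,
    "Neoplasms benign, malignant, and unspecified (incl cysts and polyps)": 6,
    "Metabolism and nutrition disorders": 5,
    "Reproductive system and breast disorders": 5,
    "Eye disorders": 2,
    "Endocrine disorders": 1,
    "Surgical and medical procedures": 1,
    "Psychiatric disorders": 1,
    "Social circumstances": 1,
}

# --- demographics -----------------------------------------------------------
REGION_COUNTS: Dict[str, int] = {
    "Europe": 552, "Oceania": 3, "Americas": 188,
    "Asia": 76, "Africa": 4, "Unknown": 35,
}
REPORTER_COUNTS: Dict[str, int] = {
    "consumer": 178, "other health professional": 243,
    "pharmacist": 138, "physician": 254, "unknown": 45,
}
SEX_COUNTS: Dict[str, int] = {"F": 394, "M": 401, "UNK": 63}
AGE_BAND_COUNTS: Dict[str, int] = {
    "0 to 18": 5, "18 to 45": 83, "45 to 65": 93,
    "65 to 75": 238, "75 to": 342, "Unknown": 97,
}
YEAR_COUNTS: Dict[int, int] = {
    2004: 26, 2005: 34, 2006: 13, 2007: 4, 2008: 12, 2009: 7, 2010: 8,
    2011: 23, 2012: 18, 2013: 43, 2014: 58, 2015: 95, 2016: 92, 2017: 72,
    2018: 141, 2019: 119, 2020: 66, 2021: 27,
}
THERAPY_DURATION_COUNTS: Dict[str, int] = {
    "0~1 month": 45, "1~3 months": 52, "3~6 months": 71, "6~9 months": 48,
    "9~12 months": 32, "12~24 months": 55, "24~60 months": 55,
    "60~ months": 57, "Unknown": 443,
}

# --- outcomes by indication (column order HO, OT, DE, LT, DS, RI) ----------
OUTCOME_COLUMNS = ("HO", "OT", "DE", "LT", "DS", "RI")
OUTCOME_COUNTS: Dict[str, Tuple[int, ...]] = {
    "Prophylaxis (NEC)": (350, 228, 19, 26, 0, 2),
    "Thrombosis prophylaxis": (231, 148, 95, 53, 6, 3),
    "Cardiovascular event prophylaxis": (13, 21, 2, 21, 6, 0),
    "Ischemic heart disease prophylaxis": (14, 34, 1, 7, 1, 0),
    "Cerebrovascular accident prophylaxis": (37, 14, 4, 0, 1, 0),
    "Blood disorder prophylaxis": (8, 8, 0, 6, 0, 0),
    "Prophylaxis of abortion": (1, 2, 0, 1, 1, 0),
    "Atherosclerosis prophylaxis": (1, 1, 1, 0, 0, 0),
    "Renal disorder prophylaxis": (0, 1, 0, 0, 0, 0),
}
OUTCOME_COLUMN_TOTALS = (655, 457, 122, 114, 15, 5)

# --- indication shares of the cohort (percent) ------------------------------
INDICATION_SHARES_PCT: Dict[str, float] = {
    "Prophylaxis (NEC)": 48.0,
    "Thrombosis prophylaxis": 38.0,
    "Cardiovascular event prophylaxis": 5.0,
    "Cerebrovascular accident prophylaxis": 4.0,
    "Ischemic heart disease prophylaxis": 4.0,
    # remaining 1% split across the four rare prophylaxis categories
    "Blood disorder prophylaxis": 0.25,
    "Prophylaxis of abortion": 0.25,
    "Atherosclerosis prophylaxis": 0.25,
    "Renal disorder prophylaxis": 0.25,
}
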