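"""Built-in fixture vocabularies.

These small tables stand in for the licensed RxNorm / SNOMED-CT / MedDRA
distributions that a production deployment would plug in: a country-to-region
lookup covering the most frequent reporter countries, drug-name synonyms for
the aspirin family, the prophylaxis indication categories, and a preferred
term (PT) to system organ class (SOC) map wide enough to cover every reaction
a screen of an aspirin prophylaxis cohort is expected to surface.  Users with
licensed dictionaries override any of them via two-column CSV files
(see :mod:`pvsignal.cleaning`).
"""

from __future__ import annotations

# ISO-2 country -> reporting region; anything absent maps to "Unknown".
COUNTRY_TO_REGION = {
    # Europe
    "GB": "Europe", "DE": "Europe", "FR": "Europe", "IT": "Europe",
    "ES": "Europe", "NL": "Europe", "BE": "Europe", "CH": "Europe",
    "AT": "Europe", "SE": "Europe", "NO": "Europe", "DK": "Europe",
    "FI": "Europe", "PT": "Europe", "IE": "Europe", "PL": "Europe",
    "CZ": "Europe", "HU": "Europe", "GR": "Europe", "RO": "Europe",
    "RU": "Europe", "UA": "Europe", "TR": "Europe",
    # Americas
    "US": "Americas", "CA": "Americas", "MX": "Americas", "BR": "Americas",
    "AR": "Americas", "CL": "Americas", "CO": "Americas", "PE": "Americas",
    "VE": "Americas",
    # Asia
    "JP": "Asia", "CN": "Asia", "KR": "Asia", "IN": "Asia", "TW": "Asia",
    "TH": "Asia", "SG": "Asia", "MY": "Asia", "PH": "Asia", "ID": "Asia",
    "IL": "Asia", "SA": "Asia", "VN": "Asia",
    # Oceania
    "AU": "Oceania", "NZ": "Oceania",
    # Africa
    "ZA": "Africa", "EG": "Africa", "NG": "Africa", "MA": "Africa",
    "KE": "Africa", "TN": "Africa",
}

# Upper-cased verbatim drug name -> canonical ingredient name.
DRUG_SYNONYMS = {
    "ASPIRIN": "aspirin",
    "ACETYLSALICYLIC ACID": "aspirin",
    "ACETYLSALICYLIC-ACID": "aspirin",
    "ASA": "aspirin",
    "BAYER ASPIRIN": "aspirin",
    "ASPIRIN ENTERIC COATED": "aspirin",
    "ECOTRIN": "aspirin",
    "ASPEGIC": "aspirin",
    "KARDEGIC": "aspirin",
    "ASCRIPTIN": "aspirin",
    "BUFFERIN": "aspirin",
    "ASPIRINE": "aspirin",
    "LYSINE ACETYLSALICYLATE": "aspirin",
    "CLOPIDOGREL": "clopidogrel",
    "PLAVIX": "clopidogrel",
    "WARFARIN": "warfarin",
    "COUMADIN": "warfarin",
    "OMEPRAZOLE": "omeprazole",
    "PRILOSEC": "omeprazole",
    "ATORVASTATIN": "atorvastatin",
    "LIPITOR": "atorvastatin",
    "SIMVASTATIN": "simvastatin",
    "METOPROLOL": "metoprolol",
    "RAMIPRIL": "ramipril",
    "LISINOPRIL": "lisinopril",
    "AMLODIPINE": "amlodipine",
    "METFORMIN": "metformin",
    "IBUPROFEN": "ibuprofen",
    "PARACETAMOL": "paracetamol",
    "ACETAMINOPHEN": "paracetamol",
}

# The nine prophylaxis indication categories used to stratify the cohort.
PROPHYLAXIS_CATEGORIES = (
    "Prophylaxis (NEC)",
    "Thrombosis prophylaxis",
    "Cardiovascular event prophylaxis",
    "Ischemic heart disease prophylaxis",
    "Cerebrovascular accident prophylaxis",
    "Blood disorder prophylaxis",
    "Prophylaxis of abortion",
    "Atherosclerosis prophylaxis",
    "Renal disorder prophylaxis",
)

OTHER_INDICATION = "other"

# The 21 system organ classes a screen can report, plus "Unmapped".
SOC_LABELS = (
    "Gastrointestinal disorders",
    "General disorders and administration site conditions",
    "Blood and lymphatic system disorders",
    "Injury, poisoning, and procedural complications",
    "Skin and subcutaneous tissue disorders",
    "Cardiac disorders",
    "Investigations",
    "Renal and urinary disorders",
    "Musculoskeletal and connective tissue disorders",
    "Respiratory, thoracic, and mediastinal disorders",
    "Nervous system disorders",
    "Vascular disorders",
    "Infections and infestations",
    "Neoplasms benign, malignant, and unspecified (incl cysts and polyps)",
    "Metabolism and nutrition disorders",
    "Reproductive system and breast disorders",
    "Eye disorders",
    "Endocrine disorders",
    "Surgical and medical procedures",
    "Psychiatric disorders",
    "Social circumstances",
)

UNMAPPED_SOC = "Unmapped"

# Fixture PT -> SOC map (~120 preferred terms).  Covers every reaction in the
# published aspirin top-10 signal tables plus several terms per SOC so that
# synthetic databases exercise the whole SOC distribution.
PT_TO_SOC = {
    # Gastrointestinal disorders
    "Melaena": "Gastrointestinal disorders",
    "Duodenal ulcer": "Gastrointestinal disorders",
    "Gastritis erosive": "Gastrointestinal disorders",
    "Gastric ulcer hemorrhage": "Gastrointestinal disorders",
    "Duodenal ulcer hemorrhage": "Gastrointestinal disorders",
    "Erosive duodenitis": "Gastrointestinal disorders",
    "Lip erosion": "Gastrointestinal disorders",
    "Mucosal erosion": "Gastrointestinal disorders",
    "Gastrointestinal haemorrhage": "Gastrointestinal disorders",
    "Gastric ulcer": "Gastrointestinal disorders",
    "Peptic ulcer": "Gastrointestinal disorders",
    "Haematemesis": "Gastrointestinal disorders",
    "Rectal haemorrhage": "Gastrointestinal disorders",
    "Haematochezia": "Gastrointestinal disorders",
    "Gastritis": "Gastrointestinal disorders",
    "Dyspepsia": "Gastrointestinal disorders",
    "Nausea": "Gastrointestinal disorders",
    "Vomiting": "Gastrointestinal disorders",
    "Diarrhoea": "Gastrointestinal disorders",
    "Abdominal pain upper": "Gastrointestinal disorders",
    "Abdominal discomfort": "Gastrointestinal disorders",
    "Gastrooesophageal reflux disease": "Gastrointestinal disorders",
    "Oesophagitis": "Gastrointestinal disorders",
    "Mouth ulceration": "Gastrointestinal disorders",
    "Gingival bleeding": "Gastrointestinal disorders",
    "Duodenitis": "Gastrointestinal disorders",
    "Gastric haemorrhage": "Gastrointestinal disorders",
    "Intestinal perforation": "Gastrointestinal disorders",
    "Constipation": "Gastrointestinal disorders",
    "Stomatitis": "Gastrointestinal disorders",
    # General disorders and administration site conditions
    "Fatigue": "General disorders and administration site conditions",
    "Pyrexia": "General disorders and administration site conditions",
    "Asthenia": "General disorders and administration site conditions",
    "Malaise": "General disorders and administration site conditions",
    "Chest pain": "General disorders and administration site conditions",
    "Oedema peripheral": "General disorders and administration site conditions",
    "Drug ineffective": "General disorders and administration site conditions",
    "Mucosal haemorrhage": "General disorders and administration site conditions",
    # Blood and lymphatic system disorders
    "Blood loss anemia": "Blood and lymphatic system disorders",
    "Microcytic anemia": "Blood and lymphatic system disorders",
    "Anaemia": "Blood and lymphatic system disorders",
    "Iron deficiency anaemia": "Blood and lymphatic system disorders",
    "Thrombocytopenia": "Blood and lymphatic system disorders",
    "Coagulopathy": "Blood and lymphatic system disorders",
    # Injury, poisoning, and procedural complications
    "Vascular stent thrombosis": "Injury, poisoning, and procedural complications",
    "Vascular stent stenosis": "Injury, poisoning, and procedural complications",
    "Overdose": "Injury, poisoning, and procedural complications",
    "Fall": "Injury, poisoning, and procedural complications",
    "Contusion": "Injury, poisoning, and procedural complications",
    "Post procedural haemorrhage": "Injury, poisoning, and procedural complications",
    "Subdural haematoma": "Injury, poisoning, and procedural complications",
    # Skin and subcutaneous tissue disorders
    "Naevus flammeus": "Skin and subcutaneous tissue disorders",
    "Nikolsky's sign": "Skin and subcutaneous tissue disorders",
    "Rash": "Skin and subcutaneous tissue disorders",
    "Pruritus": "Skin and subcutaneous tissue disorders",
    "Urticaria": "Skin and subcutaneous tissue disorders",
    "Ecchymosis": "Skin and subcutaneous tissue disorders",
    "Petechiae": "Skin and subcutaneous tissue disorders",
    "Angioedema": "Skin and subcutaneous tissue disorders",
    # Cardiac disorders
    "Myocardial infarction": "Cardiac disorders",
    "Atrial fibrillation": "Cardiac disorders",
    "Cardiac failure": "Cardiac disorders",
    "Palpitations": "Cardiac disorders",
    "Angina pectoris": "Cardiac disorders",
    # Investigations
    "Haemoglobin decreased": "Investigations",
    "Platelet count decreased": "Investigations",
    "International normalised ratio increased": "Investigations",
    "Occult blood positive": "Investigations",
    "Blood pressure increased": "Investigations",
    # Renal and urinary disorders
    "Urinary tract discomfort": "Renal and urinary disorders",
    "Haematuria": "Renal and urinary disorders",
    "Renal failure": "Renal and urinary disorders",
    "Renal impairment": "Renal and urinary disorders",
    "Dysuria": "Renal and urinary disorders",
    # Musculoskeletal and connective tissue disorders
    "Hematoma muscle": "Musculoskeletal and connective tissue disorders",
    "Arthralgia": "Musculoskeletal and connective tissue disorders",
    "Myalgia": "Musculoskeletal and connective tissue disorders",
    "Back pain": "Musculoskeletal and connective tissue disorders",
    "Muscular weakness": "Musculoskeletal and connective tissue disorders",
    # Respiratory, thoracic, and mediastinal disorders
    "Dyspnoea at rest": "Respiratory, thoracic, and mediastinal disorders",
    "Dyspnoea": "Respiratory, thoracic, and mediastinal disorders",
    "Epistaxis": "Respiratory, thoracic, and mediastinal disorders",
    "Cough": "Respiratory, thoracic, and mediastinal disorders",
    "Haemoptysis": "Respiratory, thoracic, and mediastinal disorders",
    "Asthma": "Respiratory, thoracic, and mediastinal disorders",
    # Nervous system disorders
    "Thalamus hemorrhage": "Nervous system disorders",
    "Cerebral haemorrhage": "Nervous system disorders",
    "Haemorrhagic stroke": "Nervous system disorders",
    "Dizziness": "Nervous system disorders",
    "Headache": "Nervous system disorders",
    "Cerebrovascular accident": "Nervous system disorders",
    "Transient ischaemic attack": "Nervous system disorders",
    "Syncope": "Nervous system disorders",
    # Vascular disorders
    "Haemorrhage": "Vascular disorders",
    "Hypertension": "Vascular disorders",
    "Hypotension": "Vascular disorders",
    "Deep vein thrombosis": "Vascular disorders",
    "Haematoma": "Vascular disorders",
    # Infections and infestations
    "Pneumonia": "Infections and infestations",
    "Urinary tract infection": "Infections and infestations",
    "Helicobacter infection": "Infections and infestations",
    "Sepsis": "Infections and infestations",
    # Neoplasms
    "Gastric cancer": "Neoplasms benign, malignant, and unspecified (incl cysts and polyps)",
    "Colon cancer": "Neoplasms benign, malignant, and unspecified (incl cysts and polyps)",
    "Colonic polyp": "Neoplasms benign, malignant, and unspecified (incl cysts and polyps)",
    # Metabolism and nutrition disorders
    "Decreased appetite": "Metabolism and nutrition disorders",
    "Dehydration": "Metabolism and nutrition disorders",
    "Hyperkalaemia": "Metabolism and nutrition disorders",
    # Reproductive system and breast disorders
    "Menorrhagia": "Reproductive system and breast disorders",
    "Vaginal haemorrhage": "Reproductive system and breast disorders",
    # Eye disorders
    "Conjunctival haemorrhage": "Eye disorders",
    "Vitreous haemorrhage": "Eye disorders",
    "Visual impairment": "Eye disorders",
    # Endocrine disorders
    "Hypothyroidism": "Endocrine disorders",
    "Adrenal insufficiency": "Endocrine disorders",
    # Surgical and medical procedures
    "Blood transfusion": "Surgical and medical procedures",
    "Gastrectomy": "Surgical and medical procedures",
    # Psychiatric disorders
    "Anxiety": "Psychiatric disorders",
    "Confusional state": "Psychiatric disorders",
    "Insomnia": "Psychiatric disorders",
    # Social circumstances
    "Loss of personal independence in daily activities": "Social circumstances",
    "Tobacco user": "Social circumstances",
}
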