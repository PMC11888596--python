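"""Single registry of the long-format cohort table columns.

Every stage of the pipeline exchanges one long-format table (one row per
person x wave) whose columns are named here. Units are taken as-given; no
conversion layer exists downstream.
"""

ID_COLS = ["person_id", "wave"]

AGE = "age"  # chronological age, years
SEX = "sex"  # {"male", "female"}

#: the 15 clinical measures used for the comprehensive clock
BIOMARKERS = [
    "sbp",     # systolic blood pressure, mmHg
    "whr",     # waist-to-hip ratio
    "pef",     # peak expiratory flow, L/min
    "ggt",     # gamma-glutamyl transpeptidase, U/L
    "alb",     # albumin, g/L
    "ldl_ch",  # LDL cholesterol, mmol/L
    "hdl_ch",  # HDL cholesterol, mmol/L
    "tg",      # triglycerides, mmol/L
    "ast",     # aspartate aminotransferase, U/L
    "cr",      # creatinine, umol/L
    "alp",     # alkaline phosphatase, U/L
    "urea",    # blood urea, mmol/L
    "mcv",     # mean corpuscular volume, fL
    "hba1c",   # glycated haemoglobin, %
    "plt",     # platelet count, 10^9/L
]

LIFESTYLE_FACTORS = ["smoking", "alcohol", "diet", "exercise", "sleep"]

SMOKING_STATUS = "smoking_status"        # {"never", "former", "current"}
DRINK_FREQ = "drink_freq_per_week"       # drinking occasions per week
EXERCISE_FREQ = "exercise_freq"          # ordered categories, see below
SLEEP_HOURS = "sleep_hours"              # hours per night

EXERCISE_LEVELS = ["never", "1-2_per_week", "3-5_per_week", "daily"]

#: 7-component modified alternate Mediterranean diet inputs (intake scale is
#: arbitrary but must be consistent within a cohort; scoring is rank-based)
DIET_COMPONENTS = [
    "diet_vegetables",
    "diet_legumes",
    "diet_fruits",
    "diet_nuts",
    "diet_whole_grains",
    "diet_fish",
    "diet_red_meat",  # red/processed meat: protective when LOW
]

#: components for which lower intake is protective
DIET_REVERSE_COMPONENTS = ["diet_red_meat"]

TIME_INVARIANT_COVARIATES = ["sex", "ethnicity", "urbanicity", "education"]
TIME_VARYING_COVARIATES = [
    "age",
    "occupation",
    "marital",
    "energy_kcal",
    "depression",
    "anxiety",
    "menopausal",
    "beverage",
    "supplement",
    "diabetes",
    "cvd",
    "cancer",
]

CATEGORICAL_COVARIATES = [
    "sex",
    "ethnicity",
    "urbanicity",
    "education",
    "occupation",
    "marital",
    "menopausal",
    "beverage",
]

DISEASES = [
    "cvd",
    "diabetes",
    "cancer",
    "chronic_bronchitis",
    "chronic_hepatitis",
    "rheumatoid_arthritis",
]

BMI = "bmi"  # kg/m^2, used only by the BMI-adjusted sensitivity variant

#: menopausal status is coded against a pooled reference (premenopausal women
#: and men, who are "not_applicable"): full dummy coding would be exactly
#: collinear with sex in any model adjusting for both
MENOPAUSAL_DUMMY_LEVELS = ["perimenopausal", "postmenopausal"]
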