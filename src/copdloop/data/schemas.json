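{
  "format_version": 1,
  "encoding": "UTF-8 comma-separated text with a header row; a JSON mirror bundles the same streams in one object keyed by stream name",
  "streams": {
    "patients": {
      "file": "patients.csv",
      "columns": {
        "patient_id": {"type": "string", "required": true},
        "age": {"type": "integer", "required": true, "constraint": ">= 40 (inclusion criterion)"},
        "sex": {"type": "enum", "values": ["male", "female"], "required": true},
        "height_cm": {"type": "float", "required": false, "constraint": "0 < x < 250"},
        "education": {"type": "string", "required": false},
        "smoking_status": {"type": "enum", "values": ["ex", "current", "never"], "required": true},
        "fev1_pct_pred": {"type": "float", "required": true, "constraint": "0 < x <= 200"},
        "fev1_fvc": {"type": "float", "required": true, "constraint": "0 < x <= 100"},
        "enrollment_date": {"type": "date", "required": true, "format": "ISO-8601"}
      }
    },
    "symptoms": {
      "file": "symptoms.csv",
      "columns": {
        "patient_id": {"type": "string", "required": true},
        "date": {"type": "date", "required": true},
        "dyspnea": {"type": "bool", "required": true, "note": "major symptom"},
        "sputum_purulence": {"type": "bool", "required": true, "note": "major symptom"},
        "sputum_volume": {"type": "bool", "required": true, "note": "major symptom"},
        "nasal_discharge_or_congestion": {"type": "bool", "required": true, "note": "minor symptom"},
        "sore_throat": {"type": "bool", "required": true, "note": "minor symptom"},
        "cough": {"type": "bool", "required": true, "note": "minor symptom"},
        "wheeze": {"type": "bool", "required": true, "note": "minor symptom"}
      },
      "duplicate_policy": "same patient+date entries are OR-merged per symptom"
    },
    "pef": {
      "file": "pef.csv",
      "columns": {
        "patient_id": {"type": "string", "required": true},
        "date": {"type": "date", "required": true},
        "attempt1": {"type": "float", "required": true, "constraint": "0 < x <= 1000 L/min"},
        "attempt2": {"type": "float", "required": false},
        "attempt3": {"type": "float", "required": false}
      },
      "duplicate_policy": "same patient+date sessions keep the record with the higher best value"
    },
    "questionnaires": {
      "file": "questionnaires.csv",
      "columns": {
        "patient_id": {"type": "string", "required": true},
        "date": {"type": "date", "required": true},
        "instrument": {"type": "enum", "values": ["CAT", "PHQ9", "GAD7"], "required": true},
        "item1": {"type": "integer", "required": true},
        "item2": {"type": "integer", "required": true},
        "item3": {"type": "integer", "required": true},
        "item4": {"type": "integer", "required": true},
        "item5": {"type": "integer", "required": true},
        "item6": {"type": "integer", "required": true},
        "item7": {"type": "integer", "required": true},
        "item8": {"type": "integer", "required": false, "note": "CAT/PHQ9 only"},
        "item9": {"type": "integer", "required": false, "note": "PHQ9 only"}
      },
      "item_ranges": {"CAT": "8 items 0-5", "PHQ9": "9 items 0-3", "GAD7": "7 items 0-3"},
      "duplicate_policy": "same patient+date+instrument keeps the latest row"
    },
    "adverse_events": {
      "file": "adverse_events.csv",
      "columns": {
        "patient_id": {"type": "string", "required": true},
        "date": {"type": "date", "required": true},
        "kind": {"type": "enum", "values": ["death", "hospitalization", "clinic_visit"], "required": true},
        "copd_related": {"type": "bool", "required": true},
        "period": {"type": "enum", "values": ["pre_study", "study"], "required": true}
      },
      "note": "only copd_related events enter outcome counts"
    }
  }
}
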