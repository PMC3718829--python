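{
  "$defs": {
    "CohortSummary": {
      "properties": {
        "biomarker_median_favourable": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Biomarker Median Favourable"
        },
        "biomarker_median_unfavourable": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Biomarker Median Unfavourable"
        },
        "median_age": {
          "title": "Median Age",
          "type": "number"
        },
        "median_nihss": {
          "title": "Median Nihss",
          "type": "number"
        },
        "n": {
          "title": "N",
          "type": "integer"
        },
        "n_deaths": {
          "title": "N Deaths",
          "type": "integer"
        },
        "n_events": {
          "title": "N Events",
          "type": "integer"
        },
        "n_nonevents": {
          "title": "N Nonevents",
          "type": "integer"
        },
        "recanalization_rate": {
          "title": "Recanalization Rate",
          "type": "number"
        }
      },
      "required": [
        "n",
        "n_events",
        "n_nonevents",
        "n_deaths",
        "median_age",
        "median_nihss",
        "recanalization_rate"
      ],
      "title": "CohortSummary",
      "type": "object"
    },
    "Provenance": {
      "properties": {
        "cohort_provenance": {
          "default": "",
          "title": "Cohort Provenance",
          "type": "string"
        },
        "config_hash": {
          "title": "Config Hash",
          "type": "string"
        },
        "seed": {
          "anyOf": [
            {
              "type": "integer"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Seed"
        },
        "software": {
          "title": "Software",
          "type": "string"
        },
        "version": {
          "title": "Version",
          "type": "string"
        }
      },
      "required": [
        "software",
        "version",
        "config_hash"
      ],
      "title": "Provenance",
      "type": "object"
    },
    "Section": {
      "description": "One report section: either computed data or an explicit skip reason.",
      "properties": {
        "data": {
          "anyOf": [
            {
              "additionalProperties": true,
              "type": "object"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Data"
        },
        "reason": {
          "anyOf": [
            {
              "type": "string"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Reason"
        },
        "status": {
          "enum": [
            "ok",
            "skipped"
          ],
          "title": "Status",
          "type": "string"
        }
      },
      "required": [
        "status"
      ],
      "title": "Section",
      "type": "object"
    }
  },
  "description": "Full structured report; every section is present or explicitly skipped.",
  "properties": {
    "auc_comparison": {
      "$ref": "#/$defs/Section"
    },
    "category_free_nri": {
      "$ref": "#/$defs/Section"
    },
    "cohort_summary": {
      "$ref": "#/$defs/CohortSummary"
    },
    "model1": {
      "$ref": "#/$defs/Section"
    },
    "model2": {
      "$ref": "#/$defs/Section"
    },
    "provenance": {
      "$ref": "#/$defs/Provenance"
    },
    "reclassification": {
      "$ref": "#/$defs/Section"
    },
    "survival": {
      "$ref": "#/$defs/Section"
    }
  },
  "required": [
    "cohort_summary",
    "model1",
    "model2",
    "auc_comparison",
    "category_free_nri",
    "reclassification",
    "survival",
    "provenance"
  ],
  "title": "AnalysisReport",
  "type": "object"
}
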