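{
  "$defs": {
    "CompositionRecord": {
      "properties": {
        "sample": {
          "title": "Sample",
          "type": "string"
        },
        "percent": {
          "additionalProperties": {
            "type": "number"
          },
          "title": "Percent",
          "type": "object"
        },
        "volumes": {
          "additionalProperties": {
            "type": "number"
          },
          "title": "Volumes",
          "type": "object"
        },
        "total": {
          "title": "Total",
          "type": "number"
        }
      },
      "required": [
        "sample",
        "percent",
        "volumes",
        "total"
      ],
      "title": "CompositionRecord",
      "type": "object"
    },
    "DNPRecord": {
      "properties": {
        "name": {
          "title": "Name",
          "type": "string"
        },
        "base": {
          "title": "Base",
          "type": "string"
        },
        "epsilon": {
          "title": "Epsilon",
          "type": "number"
        },
        "time_saving": {
          "title": "Time Saving",
          "type": "number"
        }
      },
      "required": [
        "name",
        "base",
        "epsilon",
        "time_saving"
      ],
      "title": "DNPRecord",
      "type": "object"
    },
    "DeconvRecord": {
      "properties": {
        "sample": {
          "title": "Sample",
          "type": "string"
        },
        "g_fa_pct": {
          "title": "G Fa Pct",
          "type": "number"
        },
        "s_pct": {
          "title": "S Pct",
          "type": "number"
        },
        "g_center": {
          "title": "G Center",
          "type": "number"
        },
        "s_center": {
          "title": "S Center",
          "type": "number"
        },
        "residual_norm": {
          "title": "Residual Norm",
          "type": "number"
        },
        "converged": {
          "title": "Converged",
          "type": "boolean"
        }
      },
      "required": [
        "sample",
        "g_fa_pct",
        "s_pct",
        "g_center",
        "s_center",
        "residual_norm",
        "converged"
      ],
      "title": "DeconvRecord",
      "type": "object"
    },
    "FoldChangeRecord": {
      "properties": {
        "mutant": {
          "title": "Mutant",
          "type": "string"
        },
        "wt": {
          "title": "Wt",
          "type": "string"
        },
        "ratios": {
          "additionalProperties": {
            "type": "number"
          },
          "title": "Ratios",
          "type": "object"
        },
        "flags": {
          "additionalProperties": {
            "type": "string"
          },
          "title": "Flags",
          "type": "object"
        }
      },
      "required": [
        "mutant",
        "wt",
        "ratios",
        "flags"
      ],
      "title": "FoldChangeRecord",
      "type": "object"
    },
    "IncorporationRecord": {
      "properties": {
        "sample": {
          "title": "Sample",
          "type": "string"
        },
        "control": {
          "title": "Control",
          "type": "string"
        },
        "aromatic_integral": {
          "title": "Aromatic Integral",
          "type": "number"
        },
        "norm_peak": {
          "title": "Norm Peak",
          "type": "number"
        },
        "index": {
          "title": "Index",
          "type": "number"
        },
        "labeling_pct": {
          "title": "Labeling Pct",
          "type": "number"
        }
      },
      "required": [
        "sample",
        "control",
        "aromatic_integral",
        "norm_peak",
        "index",
        "labeling_pct"
      ],
      "title": "IncorporationRecord",
      "type": "object"
    },
    "Provenance": {
      "properties": {
        "config_sha256": {
          "title": "Config Sha256",
          "type": "string"
        },
        "seed": {
          "title": "Seed",
          "type": "integer"
        },
        "version": {
          "title": "Version",
          "type": "string"
        }
      },
      "required": [
        "config_sha256",
        "seed",
        "version"
      ],
      "title": "Provenance",
      "type": "object"
    }
  },
  "properties": {
    "incorporation": {
      "items": {
        "$ref": "#/$defs/IncorporationRecord"
      },
      "title": "Incorporation",
      "type": "array"
    },
    "deconvolution": {
      "items": {
        "$ref": "#/$defs/DeconvRecord"
      },
      "title": "Deconvolution",
      "type": "array"
    },
    "composition": {
      "items": {
        "$ref": "#/$defs/CompositionRecord"
      },
      "title": "Composition",
      "type": "array"
    },
    "fold_change": {
      "items": {
        "$ref": "#/$defs/FoldChangeRecord"
      },
      "title": "Fold Change",
      "type": "array"
    },
    "dnp": {
      "items": {
        "$ref": "#/$defs/DNPRecord"
      },
      "title": "Dnp",
      "type": "array"
    },
    "provenance": {
      "$ref": "#/$defs/Provenance"
    }
  },
  "required": [
    "provenance"
  ],
  "title": "StudyReport",
  "type": "object"
}
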