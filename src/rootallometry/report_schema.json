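{
  "$defs": {
    "StageReport": {
      "properties": {
        "n_in": {
          "anyOf": [
            {
              "type": "integer"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "N In"
        },
        "n_out": {
          "anyOf": [
            {
              "type": "integer"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "N Out"
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
        "results": {
          "additionalProperties": true,
          "title": "Results",
          "type": "object"
        },
        "status": {
          "enum": [
            "ok",
            "skipped",
            "error"
          ],
          "title": "Status",
          "type": "string"
        }
      },
      "required": [
        "status"
      ],
      "title": "StageReport",
      "type": "object"
    }
  },
  "properties": {
    "method_notes": {
      "items": {
        "type": "string"
      },
      "title": "Method Notes",
      "type": "array"
    },
    "package_version": {
      "title": "Package Version",
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
    "stages": {
      "additionalProperties": {
        "$ref": "#/$defs/StageReport"
      },
      "title": "Stages",
      "type": "object"
    }
  },
  "required": [
    "package_version"
  ],
  "title": "AnalysisReport",
  "type": "object"
}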