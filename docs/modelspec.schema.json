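{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "rri ModelSpec",
  "description": "Declarative constrained-SEM description: observed endogenous variables, exogenous covariates, latents, and a parameter table of loadings, regressions (including product terms), intercepts and (co)variances. Free parameters carry unique labels; equality constraints share a label.",
  "type": "object",
  "required": ["observed", "exogenous", "latents", "params"],
  "properties": {
    "observed": {"type": "array", "items": {"type": "string"}},
    "exogenous": {"type": "array", "items": {"type": "string"}},
    "latents": {"type": "array", "items": {"type": "string"}},
    "params": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["matrix", "row", "col", "free", "value"],
        "properties": {
          "matrix": {
            "enum": ["lambda", "kappa", "nu", "beta", "gamma", "alpha",
                      "psi", "theta"]
          },
          "row": {"type": "string"},
          "col": {
            "oneOf": [
              {"type": "string"},
              {"type": "null"},
              {"type": "array", "items": {"type": "string"},
               "minItems": 2,
               "description": "product term of previously declared variables"}
            ]
          },
          "free": {"type": "boolean"},
          "value": {"type": "number",
                    "description": "fixed value, or starting value if free"},
          "label": {"type": ["string", "null"]}
        }
      }
    }
  }
}
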