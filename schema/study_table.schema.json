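{
  "format": "csv",
  "encoding": "utf-8",
  "columns": [
    {
      "name": "publication_id",
      "type": "string",
      "required": true
    },
    {
      "name": "observation_id",
      "type": "string",
      "required": true
    },
    {
      "name": "pub_year",
      "type": "integer",
      "required": true
    },
    {
      "name": "country",
      "type": "string",
      "required": true
    },
    {
      "name": "region",
      "type": "string",
      "required": false
    },
    {
      "name": "taxon_group",
      "type": "enum",
      "levels": [
        "arthropods",
        "birds",
        "microbes",
        "plants"
      ]
    },
    {
      "name": "functional_group",
      "type": "enum",
      "levels": [
        "producers",
        "herbivores",
        "pollinators",
        "predators",
        "decomposers",
        "other"
      ]
    },
    {
      "name": "crop_type",
      "type": "enum",
      "levels": [
        "cereals",
        "grassland",
        "mixed",
        "orchard",
        "vegetables",
        "miscellaneous"
      ]
    },
    {
      "name": "scale",
      "type": "enum",
      "levels": [
        "plot",
        "field",
        "farm"
      ]
    },
    {
      "name": "mean_org",
      "type": "number",
      "constraint": "> 0"
    },
    {
      "name": "sd_org",
      "type": "number",
      "constraint": ">= 0"
    },
    {
      "name": "n_org",
      "type": "integer",
      "constraint": "> 1"
    },
    {
      "name": "mean_conv",
      "type": "number",
      "constraint": "> 0"
    },
    {
      "name": "sd_conv",
      "type": "number",
      "constraint": ">= 0"
    },
    {
      "name": "n_conv",
      "type": "integer",
      "constraint": "> 1"
    },
    {
      "name": "pct_arable",
      "type": "number",
      "constraint": "[0, 100]",
      "required": false
    },
    {
      "name": "n_habitats",
      "type": "number",
      "constraint": ">= 1",
      "required": false
    },
    {
      "name": "avg_field_size",
      "type": "number",
      "constraint": "> 0 (ha)",
      "required": false
    }
  ],
  "notes": "landscape covariates must be all present or all missing per row"
}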