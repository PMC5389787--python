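{
    "title": "Replicate",
    "id": "/profiles/replicate.json",
    "collection": "replicates",
    "schema_version": 1,
    "type": "object",
    "required": ["experiment"],
    "properties": {
        "aliases": {
            "type": "array",
            "items": {"type": "string"},
            "uniqueKey": "alias"
        },
        "experiment": {"type": "string", "linkTo": "experiment"},
        "library": {"type": "string", "linkTo": "library"},
        "biological_replicate_number": {"type": "integer", "default": 1},
        "technical_replicate_number": {"type": "integer", "default": 1},
        "description": {"type": "string"},
        "status": {
            "type": "string",
            "enum": ["in progress", "released", "deleted"],
            "default": "in progress"
        }
    }
}
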