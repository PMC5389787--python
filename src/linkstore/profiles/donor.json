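{
    "title": "Donor",
    "id": "/profiles/donor.json",
    "collection": "donors",
    "schema_version": 1,
    "type": "object",
    "required": ["organism"],
    "properties": {
        "accession": {
            "type": "string",
            "format": "accession",
            "accessionType": "DO",
            "uniqueKey": "accession",
            "serverDefault": "accession"
        },
        "aliases": {
            "type": "array",
            "items": {"type": "string"},
            "uniqueKey": "alias"
        },
        "organism": {"type": "string", "enum": ["human", "mouse"]},
        "sex": {
            "type": "string",
            "enum": ["male", "female", "unknown"],
            "default": "unknown"
        },
        "life_stage": {
            "type": "string",
            "enum": ["embryonic", "child", "adult", "unknown"]
        },
        "age": {"type": "string"},
        "lab": {"type": "string", "linkTo": "lab"},
        "award": {"type": "string", "linkTo": "award"},
        "description": {"type": "string"},
        "status": {
            "type": "string",
            "enum": ["in progress", "released", "deleted"],
            "default": "in progress"
        }
    },
    "facets": {"organism": {"title": "Organism"}}
}
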