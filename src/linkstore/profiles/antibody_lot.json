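{
    "title": "Antibody Lot",
    "id": "/profiles/antibody_lot.json",
    "collection": "antibody-lots",
    "schema_version": 1,
    "type": "object",
    "required": ["target"],
    "properties": {
        "accession": {
            "type": "string",
            "format": "accession",
            "accessionType": "AB",
            "uniqueKey": "accession",
            "serverDefault": "accession"
        },
        "target": {"type": "string"},
        "host_organism": {
            "type": "string",
            "enum": ["rabbit", "mouse", "goat"]
        },
        "clonality": {"type": "string", "enum": ["monoclonal", "polyclonal"]},
        "lot_id": {"type": "string"},
        "lab": {"type": "string", "linkTo": "lab"},
        "award": {"type": "string", "linkTo": "award"},
        "description": {"type": "string"},
        "status": {
            "type": "string",
            "enum": ["in progress", "released", "deleted"],
            "default": "in progress"
        }
    }
}
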