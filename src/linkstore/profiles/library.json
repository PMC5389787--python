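{
    "title": "Library",
    "id": "/profiles/library.json",
    "collection": "libraries",
    "schema_version": 1,
    "type": "object",
    "required": ["biosample"],
    "properties": {
        "accession": {
            "type": "string",
            "format": "accession",
            "accessionType": "LB",
            "uniqueKey": "accession",
            "serverDefault": "accession"
        },
        "biosample": {"type": "string", "linkTo": "biosample"},
        "nucleic_acid_term_name": {"type": "string", "enum": ["DNA", "RNA"]},
        "size_range": {"type": "string", "pattern": "^[0-9]+-[0-9]+$"},
        "strand_specificity": {"type": "boolean"},
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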