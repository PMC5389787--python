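{
    "title": "Biosample",
    "id": "/profiles/biosample.json",
    "collection": "biosamples",
    "schema_version": 2,
    "type": "object",
    "required": ["biosample_term_name", "organism"],
    "properties": {
        "accession": {
            "type": "string",
            "format": "accession",
            "accessionType": "BS",
            "uniqueKey": "accession",
            "serverDefault": "accession"
        },
        "aliases": {
            "type": "array",
            "items": {"type": "string"},
            "uniqueKey": "alias"
        },
        "biosample_term_name": {"type": "string"},
        "biosample_term_id": {"type": "string", "pattern": "^[A-Z]+:[0-9]+$"},
        "biosample_type": {
            "type": "string",
            "enum": ["tissue", "immortalized cell line", "primary cell", "stem cell"]
        },
        "organism": {"type": "string", "enum": ["human", "mouse"]},
        "donor": {"type": "string", "linkTo": "donor"},
        "starting_amount": {"type": "number"},
        "starting_amount_units": {"type": "string", "enum": ["ng", "cells"]},
        "date_obtained": {"type": "string", "format": "date"},
        "lab": {"type": "string", "linkTo": "lab"},
        "award": {"type": "string", "linkTo": "award"},
        "description": {"type": "string"},
        "summary": {"type": "string", "calculatedProperty": true},
        "status": {
            "type": "string",
            "enum": ["in progress", "released", "deleted"],
            "default": "in progress"
        }
    },
    "facets": {
        "organism": {"title": "Organism"},
        "biosample_type": {"title": "Biosample type"},
        "status": {"title": "Status"}
    }
}
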