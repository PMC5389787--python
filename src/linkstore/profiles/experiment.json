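{
    "title": "Experiment",
    "id": "/profiles/experiment.json",
    "collection": "experiments",
    "schema_version": 2,
    "type": "object",
    "required": ["assay_term_name"],
    "properties": {
        "accession": {
            "type": "string",
            "format": "accession",
            "accessionType": "SR",
            "uniqueKey": "accession",
            "serverDefault": "accession"
        },
        "aliases": {
            "type": "array",
            "items": {"type": "string"},
            "uniqueKey": "alias"
        },
        "assay_term_name": {
            "type": "string",
            "enum": ["ChIP-seq", "RNA-seq", "DNase-seq"]
        },
        "assay_term_id": {"type": "string", "pattern": "^OBI:[0-9]+$"},
        "target": {"type": "string"},
        "antibody": {"type": "string", "linkTo": "antibody_lot"},
        "possible_controls": {
            "type": "array",
            "items": {"type": "string", "linkTo": "experiment"}
        },
        "date_released": {"type": "string", "format": "date"},
        "lab": {"type": "string", "linkTo": "lab"},
        "award": {"type": "string", "linkTo": "award"},
        "description": {"type": "string"},
        "status": {
            "type": "string",
            "enum": ["in progress", "released", "deleted"],
            "default": "in progress"
        }
    },
    "rev": {
        "replicates": {"type": "replicate", "field": "experiment"},
        "files": {"type": "file", "field": "dataset"}
    },
    "facets": {
        "assay_term_name": {"title": "Assay"},
        "status": {"title": "Status"},
        "award.project": {"title": "Project"}
    }
}
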