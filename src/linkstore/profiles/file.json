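{
    "title": "File",
    "id": "/profiles/file.json",
    "collection": "files",
    "schema_version": 1,
    "type": "object",
    "required": ["dataset", "file_format"],
    "properties": {
        "accession": {
            "type": "string",
            "format": "accession",
            "accessionType": "FF",
            "uniqueKey": "accession",
            "serverDefault": "accession"
        },
        "dataset": {"type": "string", "linkTo": "experiment"},
        "replicate": {"type": "string", "linkTo": "replicate"},
        "file_format": {"type": "string", "enum": ["fastq", "bam"]},
        "output_type": {"type": "string", "enum": ["reads", "alignments"]},
        "read_count": {"type": "integer"},
        "md5sum": {"type": "string", "pattern": "^[0-9a-f]{32}$"},
        "submitted_file_name": {"type": "string"},
        "lab": {"type": "string", "linkTo": "lab"},
        "award": {"type": "string", "linkTo": "award"},
        "description": {"type": "string"},
        "status": {
            "type": "string",
            "enum": ["in progress", "released", "deleted"],
            "default": "in progress"
        }
    },
    "facets": {
        "file_format": {"title": "File format"},
        "output_type": {"title": "Output type"},
        "status": {"title": "Status"}
    }
}
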