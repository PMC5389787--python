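{
    "title": "Award",
    "id": "/profiles/award.json",
    "collection": "awards",
    "schema_version": 1,
    "type": "object",
    "required": ["name", "project"],
    "properties": {
        "name": {
            "type": "string",
            "pattern": "^[a-z0-9\\-]+$",
            "uniqueKey": true
        },
        "title": {"type": "string"},
        "description": {"type": "string"},
        "project": {"type": "string", "enum": ["ENCODE", "GGR"]},
        "status": {
            "type": "string",
            "enum": ["in progress", "released", "deleted"],
            "default": "in progress"
        }
    },
    "facets": {"project": {"title": "Project"}}
}
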