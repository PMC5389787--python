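{
    "title": "Lab",
    "id": "/profiles/lab.json",
    "collection": "labs",
    "schema_version": 1,
    "type": "object",
    "required": ["name"],
    "properties": {
        "name": {
            "type": "string",
            "pattern": "^[a-z0-9\\-]+$",
            "uniqueKey": true
        },
        "title": {"type": "string"},
        "institute": {"type": "string"},
        "description": {"type": "string"},
        "status": {
            "type": "string",
            "enum": ["in progress", "released", "deleted"],
            "default": "in progress"
        }
    }
}
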