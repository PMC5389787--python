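{
    "title": "User",
    "id": "/profiles/user.json",
    "collection": "users",
    "schema_version": 1,
    "type": "object",
    "required": ["email"],
    "properties": {
        "email": {"type": "string", "format": "email", "uniqueKey": true},
        "first_name": {"type": "string"},
        "last_name": {"type": "string"},
        "job_title": {"type": "string"},
        "lab": {"type": "string", "linkTo": "lab"},
        "description": {"type": "string"},
        "status": {
            "type": "string",
            "enum": ["in progress", "released", "deleted"],
            "default": "in progress"
        }
    }
}
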