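# linkstore

A desk-scale hybrid object database: a transactional JSON document store with
schema-validated, link-typed documents, frame-based denormalized rendering, an
incremental invalidation indexer, cross-object audits, a permissioned REST
API, a genomics-flavoured demonstration schema set with a seeded synthetic
graph generator, and RDF export.

## Layout

| module | role |
| --- | --- |
| `linkstore.storage` | sqlite-backed document store: typed JSON documents, unique-key aliasing, write-ahead transaction log, atomic writes |
| `linkstore.schemas` | per-type JSON schemas with `linkTo` / `rev` / `calculatedProperty` / `facets` extensions; validation; versioned upgrade chain; `/profiles/` content |
| `linkstore.rendering` | the four frames (raw, object, embedded, page) with recording of embedded vs linked identifiers |
| `linkstore.indexing` | incremental index driven by the transaction log (invalidation = updates hitting embedded sets, renames hitting linked sets) plus faceted search |
| `linkstore.audits` | severity-flagged cross-object integrity rules evaluated on embedded renderings |
| `linkstore.api` | request handler + WSGI adapter; four-tier ACL (admin / submitter / consortium / base) |
| `linkstore.fixtures` | ten demonstration schemas (`src/linkstore/profiles/`), seeded graph generator with planted-violation manifest, randomized workload driver |
| `linkstore.rdf` | object-frame graph to RDF triples; ntriples and turtle serialization |

## Quick start

```python
from linkstore import Service, Principal
from linkstore.fixtures import FixtureConfig

svc = Service()                              # in-memory store, fixture schemas
svc.load_fixture(FixtureConfig(seed=1, n_experiments=5))
svc.reindex()                                # one incremental index pass

admin = Principal("wrangler", "admin")
status, body = svc.handle_request("GET", "/search/",
                                  {"type": ["Experiment"]}, principal=admin)
status, body = svc.handle_request(
    "POST", "/biosamples/",
    body={"biosample_term_name": "K562", "organism": "human"},
    principal=admin)                         # -> 200; invalid bodies -> 422
```

Frames are selected per item URL with `?frame=raw|object|embedded|page`
(default `page`, which attaches audit findings grouped by severity). Objects
resolve by uuid, accession, alias, or bare accession without the collection
prefix (`GET /TSTSR000AAA`).

## CLI

```sh
linkstore fixtures generate --seed 1 --n-experiments 10 --out fixture/
linkstore store load fixture/ --db store.db
linkstore store log --db store.db            # transaction log as JSON lines
linkstore store dump dump/ --db store.db
linkstore export rdf --db store.db --syntax turtle \
    --base-uri http://example.org --out graph.ttl
linkstore serve --db store.db --port 8000    # wsgiref development server
```

The HTTP layer authenticates via a pluggable test shim: send the principal as
a JSON `X-Test-Principal` header, e.g.
`{"user_id": "w", "tier": "admin"}` (tiers: `admin`, `submitter` with
`lab_groups`, `consortium`/`submitter` with `project_scope`, `base`).

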