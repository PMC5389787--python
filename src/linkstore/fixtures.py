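"""Demonstration schema set and seeded synthetic metadata-graph generator.

Ten linked item types (award, lab, user, donor, biosample, library,
replicate, experiment, file, antibody lot) cover every mechanism in the
system: links, reverse links, calculated fields, audits, upgrades, unique
keys and facets. ``generate`` emits a referentially-closed document graph —
a pure function of its config — together with a manifest of deliberately
planted audit violations.
"""

from __future__ import annotations

import random
import uuid as uuidlib
from dataclasses import dataclass, field
from pathlib import Path

from .audits import AuditRule
from .errors import InvalidConfig
from .rendering import CalculatedProperties
from .schemas import SchemaRegistry
from .storage import _letters3

PROFILES_DIR = Path(__file__).parent / "profiles"

#: embed paths per item type (segments are link or rev fields)
DEFAULT_EMBEDS = {
    "experiment": ["replicates.library.biosample.donor", "award", "files"],
    "file": ["dataset"],
    "library": ["biosample"],
    "biosample": ["donor"],
    "replicate": ["library.biosample"],
}

#: minimum uniquely-mapped reads per assay for alignment files; standards are
#: configuration, not constants
DEFAULT_READ_DEPTH_MINIMUMS = {
    "ChIP-seq": 10_000_000,
    "RNA-seq": 20_000_000,
    "DNase-seq": 20_000_000,
}

MISSING_DONOR = "missing donor"
INCONSISTENT_TERM = "inconsistent biosample term"
LOW_READ_DEPTH = "insufficient read depth"

_ACCESSION_CODES = {
    "donor": "DO", "biosample": "BS", "library": "LB",
    "experiment": "SR", "file": "FF", "antibody_lot": "AB",
}

_TERMS = {
    "human": [("GM12878", "EFO:0002784"), ("K562", "EFO:0002067"),
              ("keratinocyte", "CL:0000312"), ("liver", "UBERON:0002107")],
    "mouse": [("liver", "UBERON:0002107"), ("heart", "UBERON:0000948"),
              ("MEL cell line", "EFO:0003971")],
}

_TARGETS = ["CTCF", "POLR2A", "H3K27ac"]
_ASSAY_IDS = {"ChIP-seq": "OBI:0000716", "RNA-seq": "OBI:0001271",
              "DNase-seq": "OBI:0001853"}


def default_registry() -> SchemaRegistry:
    """Registry loaded with the packaged schema set and its upgrade chain."""
    registry = SchemaRegistry(PROFILES_DIR)
    register_upgrade_steps(registry)
    return registry


def register_upgrade_steps(registry: SchemaRegistry) -> None:
    @registry.upgrade_step("biosample", 1)
    def biosample_1_2(properties):
        # legacy submissions carried starting_amount as a string
        props = dict(properties)
        amount = props.get("starting_amount")
        if isinstance(amount, str):
            try:
                number = float(amount)
                props["starting_amount"] = (
                    int(number) if number.is_integer() else number
                )
            except ValueError:
                del props["starting_amount"]
        return props

    @registry.upgrade_step("experiment", 1)
    def experiment_1_2(properties):
        props = dict(properties)
        if "assay_name" in props:
            props["assay_term_name"] = props.pop("assay_name")
        return props


def default_calculated() -> CalculatedProperties:
    calculated = CalculatedProperties()

    def biosample_summary(renderer, document, body, ctx):
        # composed from the biosample's own fields only
        term = body.get("biosample_term_name", "")
        organism = body.get("organism", "")
        return f"{organism} {term}".strip() or None

    calculated.register("biosample", "summary", biosample_summary)
    return calculated


def builtin_audit_rules(read_depth_minimums: dict | None = None,
                        default_minimum: int = 10_000_000) -> list[AuditRule]:
    """The three shipped cross-object rules."""
    minimums = dict(read_depth_minimums or DEFAULT_READ_DEPTH_MINIMUMS)

    def missing_donor(body):
        if body.get("organism") == "human" and not body.get("donor"):
            return ["human biosample is missing its donor"]
        return []

    def inconsistent_term(body):
        terms = set()
        for replicate in body.get("replicates", []):
            if not isinstance(replicate, dict):
                continue
            library = replicate.get("library")
            if not isinstance(library, dict):
                continue
            biosample = library.get("biosample")
            if isinstance(biosample, dict):
                term = biosample.get("biosample_term_name")
                if term is not None:
                    terms.add(term)
        if len(terms) > 1:
            return ["replicates use differing biosample terms: "
                    + ", ".join(sorted(terms))]
        return []

    def low_read_depth(body):
        if body.get("file_format") != "bam" or \
                body.get("output_type") != "alignments":
            return []
        count = body.get("read_count")
        if count is None:
            return []
        dataset = body.get("dataset")
        assay = dataset.get("assay_term_name") if isinstance(dataset, dict) \
            else None
        minimum = minimums.get(assay, default_minimum)
        if count < minimum:
            return [f"alignment file has {count} reads; {assay or 'assay'} "
                    f"standards expect at least {minimum}"]
        return []

    return [
        AuditRule("biosample", MISSING_DONOR, "ERROR", missing_donor),
        AuditRule("experiment", INCONSISTENT_TERM, "ERROR", inconsistent_term),
        AuditRule("file", LOW_READ_DEPTH, "WARNING", low_read_depth),
    ]


# ---------------------------------------------------------------------------
# generator


@dataclass
class FixtureConfig:
    seed: int = 0
    n_experiments: int = 10
    assays: tuple = (("ChIP-seq", 0.5), ("RNA-seq", 0.3), ("DNase-seq", 0.2))
    n_labs: int = 3
    replicate_rate: float = 2.0
    file_rate: float = 2.0
    released_fraction: float = 0.7
    violation_rates: dict = field(default_factory=dict)

    def validate(self):
        if self.n_experiments < 0 or self.n_labs < 1:
            raise InvalidConfig("need n_experiments >= 0 and n_labs >= 1")
        if not self.assays or any(w <= 0 for _, w in self.assays):
            raise InvalidConfig("assay weights must be positive")
        if not 0.0 <= self.released_fraction <= 1.0:
            raise InvalidConfig("released_fraction must be in [0, 1]")
        for category, rate in self.violation_rates.items():
            if not 0.0 <= rate <= 1.0:
                raise InvalidConfig(
                    f"violation rate for {category!r} must be in [0, 1]")


class _Minter:
    """Deterministic accession/uuid minting for the generator."""

    def __init__(self, rng: random.Random):
        self.rng = rng
        self.counters: dict[str, int] = {}

    def uuid(self) -> str:
        return str(uuidlib.UUID(int=self.rng.getrandbits(128), version=4))

    def accession(self, item_type: str) -> str:
        i = self.counters.get(item_type, 0)
        self.counters[item_type] = i + 1
        digits, letters = divmod(i, 17576)
        return f"TST{_ACCESSION_CODES[item_type]}{digits:03d}{_letters3(letters)}"


def generate(config: FixtureConfig) -> tuple[list, list]:
    """Emit ``(documents, manifest)``: (item_type, properties) pairs in
    dependency order, and the ground-truth planted audit findings."""
    config.validate()
    rng = random.Random(config.seed)
    mint = _Minter(rng)
    rates = config.violation_rates
    documents: list[tuple[str, dict]] = []
    manifest: list[dict] = []

    def emit(item_type, **props):
        props["uuid"] = mint.uuid()
        documents.append((item_type, props))
        return props

    def status():
        return ("released" if rng.random() < config.released_fraction
                else "in progress")

    awards = [
        emit("award", name="tst-encode-award", title="Fixture ENCODE award",
             project="ENCODE", status="released"),
        emit("award", name="tst-ggr-award", title="Fixture GGR award",
             project="GGR", status="released"),
    ]
    labs = [
        emit("lab", name=f"lab-{i}", title=f"Fixture Lab {i}",
             institute="Fixture University", status="released")
        for i in range(config.n_labs)
    ]
    for i, lab in enumerate(labs):
        emit("user", email=f"user{i}@example.org", first_name="User",
             last_name=f"Number{i}", lab=lab["uuid"], status="released")
    antibodies = [
        emit("antibody_lot", accession=mint.accession("antibody_lot"),
             target=target, host_organism="rabbit", lot_id=f"lot-{n}",
             lab=labs[n % len(labs)]["uuid"], award=awards[0]["uuid"],
             status="released")
        for n, target in enumerate(_TARGETS)
    ]
    donors = {"human": [], "mouse": []}
    n_donors = max(2, config.n_experiments // 2 + 1)
    for organism in ("human", "mouse"):
        for _ in range(n_donors):
            donors[organism].append(
                emit("donor", accession=mint.accession("donor"),
                     organism=organism, sex=rng.choice(["male", "female"]),
                     life_stage=rng.choice(["child", "adult"]),
                     lab=rng.choice(labs)["uuid"],
                     award=rng.choice(awards)["uuid"], status="released")
            )

    assay_names = [a for a, _ in config.assays]
    assay_weights = [w for _, w in config.assays]

    for _ in range(config.n_experiments):
        assay = rng.choices(assay_names, weights=assay_weights, k=1)[0]
        lab = rng.choice(labs)
        award = rng.choice(awards)
        organism = "human" if rng.random() < 0.7 else "mouse"
        term, term_id = rng.choice(_TERMS[organism])

        n_replicates = max(1, min(3, round(rng.gauss(config.replicate_rate,
                                                     0.7))))
        plant_mismatch = (rng.random() < rates.get(INCONSISTENT_TERM, 0.0))
        if plant_mismatch:
            n_replicates = max(2, n_replicates)

        replicate_specs = []
        for r in range(n_replicates):
            rep_term, rep_term_id = term, term_id
            if plant_mismatch and r == 1:
                others = [t for t in _TERMS[organism] if t[0] != term]
                rep_term, rep_term_id = others[0]
            plant_no_donor = (organism == "human"
                              and rng.random() < rates.get(MISSING_DONOR, 0.0))
            biosample = emit(
                "biosample", accession=mint.accession("biosample"),
                biosample_term_name=rep_term, biosample_term_id=rep_term_id,
                biosample_type=rng.choice(
                    ["tissue", "immortalized cell line", "primary cell"]),
                organism=organism,
                starting_amount=rng.randint(10, 500),
                starting_amount_units="ng",
                lab=lab["uuid"], award=award["uuid"], status=status())
            if plant_no_donor:
                manifest.append({
                    "category": MISSING_DONOR, "severity": "ERROR",
                    "path": f"/biosamples/{biosample['accession']}/"})
            else:
                biosample["donor"] = rng.choice(donors[organism])["uuid"]
            library = emit(
                "library", accession=mint.accession("library"),
                biosample=biosample["uuid"],
                nucleic_acid_term_name="RNA" if assay == "RNA-seq" else "DNA",
                size_range=f"{rng.randint(100, 300)}-{rng.randint(301, 600)}",
                lab=lab["uuid"], award=award["uuid"], status=status())
            replicate_specs.append(library)

        experiment_props = dict(
            accession=mint.accession("experiment"), assay_term_name=assay,
            assay_term_id=_ASSAY_IDS[assay],
            description=f"fixture {assay} in {term}",
            lab=lab["uuid"], award=award["uuid"], status=status())
        if assay == "ChIP-seq":
            antibody = rng.choice(antibodies)
            experiment_props["antibody"] = antibody["uuid"]
            experiment_props["target"] = antibody["target"]
        experiment = emit("experiment", **experiment_props)
        if plant_mismatch:
            manifest.append({
                "category": INCONSISTENT_TERM, "severity": "ERROR",
                "path": f"/experiments/{experiment['accession']}/"})

        replicates = []
        for r, library in enumerate(replicate_specs):
            replicates.append(
                emit("replicate", experiment=experiment["uuid"],
                     library=library["uuid"], biological_replicate_number=r + 1,
                     technical_replicate_number=1,
                     status=experiment["status"]))

        n_files = max(1, min(5, round(rng.gauss(config.file_rate, 1.0))))
        minimum = DEFAULT_READ_DEPTH_MINIMUMS.get(assay, 10_000_000)
        for f in range(n_files):
            file_format = "fastq" if f == 0 else "bam"
            props = dict(
                accession=mint.accession("file"), dataset=experiment["uuid"],
                replicate=replicates[f % len(replicates)]["uuid"],
                file_format=file_format,
                output_type="reads" if file_format == "fastq"
                else "alignments",
                lab=lab["uuid"], award=award["uuid"],
                status=experiment["status"])
            if file_format == "bam":
                if rng.random() < rates.get(LOW_READ_DEPTH, 0.0):
                    props["read_count"] = rng.randint(1_000, minimum - 1)
                    manifest.append({
                        "category": LOW_READ_DEPTH, "severity": "WARNING",
                        "path": f"/files/{props['accession']}/"})
                else:
                    props["read_count"] = minimum + rng.randint(0, 50_000_000)
            else:
                props["read_count"] = rng.randint(20_000_000, 80_000_000)
            emit("file", **props)

    manifest.sort(key=lambda m: (m["category"], m["path"]))
    return documents, manifest


def apply_random_operations(store, rng: random.Random, n_ops: int) -> list:
    """Randomized mixed workload over an already-loaded fixture store:
    creates, scalar patches, renames, status deletes and link retargets.
    Returns the op descriptions applied (for debugging)."""
    applied = []

    def pick(item_type):
        docs = [d for d in store.items_of_type(item_type)
                if d.status != "deleted"]
        return rng.choice(docs) if docs else None

    def fresh_accession(item_type):
        code = _ACCESSION_CODES[item_type]
        while True:
            candidate = "TST{}{:03d}{}".format(
                code, rng.randint(0, 999),
                "".join(rng.choice("ABCDEFGHIJKLMNOPQRSTUVWXYZ")
                        for _ in range(3)))
            if not store.exists(candidate):
                return candidate

    for i in range(n_ops):
        op = rng.choices(
            ["create_file", "create_biosample", "patch", "rename",
             "delete", "retarget"],
            weights=[0.20, 0.10, 0.30, 0.15, 0.10, 0.15], k=1)[0]
        if op == "create_file":
            experiment = pick("experiment")
            if experiment is None:
                continue
            doc = store.create_item("file", {
                "accession": fresh_accession("file"),
                "dataset": experiment.uuid, "file_format": "bam",
                "output_type": "alignments",
                "read_count": rng.randint(1_000, 90_000_000)})
            applied.append(("create_file", doc.uuid))
        elif op == "create_biosample":
            donor = pick("donor")
            doc = store.create_item("biosample", {
                "accession": fresh_accession("biosample"),
                "biosample_term_name": rng.choice(
                    [t for t, _ in _TERMS["human"]]),
                "organism": "human",
                **({"donor": donor.uuid} if donor else {})})
            applied.append(("create_biosample", doc.uuid))
        elif op == "patch":
            doc = pick(rng.choice(
                ["experiment", "biosample", "file", "lab", "library"]))
            if doc is None:
                continue
            store.update_item(doc.uuid, {"description": f"edit {i}"})
            applied.append(("patch", doc.uuid))
        elif op == "rename":
            item_type = rng.choice(["experiment", "biosample", "file"])
            doc = pick(item_type)
            if doc is None:
                continue
            store.update_item(doc.uuid,
                              {"accession": fresh_accession(item_type)})
            applied.append(("rename", doc.uuid))
        elif op == "delete":
            doc = pick(rng.choice(["file", "biosample", "replicate"]))
            if doc is None:
                continue
            store.update_item(doc.uuid, {"status": "deleted"})
            applied.append(("delete", doc.uuid))
        elif op == "retarget":
            file = pick("file")
            experiment = pick("experiment")
            if file is None or experiment is None:
                continue
            store.update_item(file.uuid, {"dataset": experiment.uuid})
            applied.append(("retarget", file.uuid))
    return applied


def load_fixture(config: FixtureConfig, store, principal=None) -> dict:
    """POST the generated documents in dependency order; per-type counts."""
    documents, _ = generate(config)
    counts: dict[str, int] = {}
    for item_type, properties in documents:
        store.create_item(item_type, properties, principal=principal)
        counts[item_type] = counts.get(item_type, 0) + 1
    return counts
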