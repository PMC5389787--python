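"""REST layer: authorization tiers, request handling, status codes, URL
aliasing and content negotiation."""

import itertools
import json

import pytest

from linkstore import Principal, Service, authorize, make_wsgi_app
from linkstore.fixtures import FixtureConfig

from conftest import make_submitter


class TestAuthorize:
    def test_admin_always_allowed(self, admin):
        for action in ("view", "edit", "create"):
            for status in ("released", "in progress", "deleted"):
                decision = authorize(admin, action=action, status=status,
                                     lab="L", project="ENCODE")
                assert decision.allowed

    def test_released_public(self, base):
        assert authorize(base, action="view", status="released",
                         lab=None, project=None).allowed

    def test_base_cannot_view_unreleased(self, base):
        assert not authorize(base, action="view", status="in progress",
                             lab="L", project="ENCODE").allowed

    def test_consortium_views_unreleased_same_project_only(self):
        member = Principal("m", "consortium", project_scope="ENCODE")
        assert authorize(member, action="view", status="in progress",
                         lab="L", project="ENCODE").allowed
        assert not authorize(member, action="view", status="in progress",
                             lab="L", project="GGR").allowed

    def test_submitter_edit_truth_table(self):
        """lab-membership x release-status, enumerated exhaustively."""
        submitter = Principal("s", "submitter",
                              lab_groups=frozenset(["lab-mine"]),
                              project_scope="ENCODE")
        for lab, status in itertools.product(
                ["lab-mine", "lab-other"],
                ["released", "in progress", "deleted"]):
            decision = authorize(submitter, action="edit", status=status,
                                 lab=lab, project="ENCODE")
            expected = (lab == "lab-mine" and status == "in progress")
            assert decision.allowed == expected, (lab, status)

    def test_nonsubmitters_never_edit(self, base, consortium):
        for principal in (base, consortium):
            assert not authorize(principal, action="edit",
                                 status="in progress", lab="L",
                                 project="ENCODE").allowed

    def test_anonymous_must_be_base(self):
        with pytest.raises(ValueError):
            Principal("anonymous", "admin")

    def test_visibility_monotonicity(self, loaded, admin, base, consortium):
        def visible(principal):
            return {uid for uid in loaded.store.all_uuids()
                    if loaded.can_view(principal,
                                       loaded.store.get_item(uid))}

        v_base = visible(base)
        v_consortium = visible(consortium)
        v_admin = visible(admin)
        assert v_base <= v_consortium <= v_admin


class TestWrites:
    def test_post_valid_biosample_returns_200(self, service, admin):
        status, body = service.handle_request(
            "POST", "/biosamples/",
            body={"biosample_term_name": "K562", "organism": "human"},
            principal=admin)
        assert status == 200
        assert body["status"] == "success"
        assert body["@graph"][0]["@id"].startswith("/biosamples/")

    def test_post_unknown_property_returns_422(self, service, admin):
        status, body = service.handle_request(
            "POST", "/biosamples/",
            body={"biosample_term_name": "K562", "organism": "human",
                  "lifestage": "adult"},
            principal=admin)
        assert status == 422
        assert any("lifestage" in e["name"] for e in body["errors"])

    def test_invalid_write_leaves_store_unchanged(self, service, admin):
        before = service.store.dump()
        status, _ = service.handle_request(
            "POST", "/biosamples/", body={"nope": 1}, principal=admin)
        assert status == 422
        assert service.store.dump() == before

    def test_patch_experiment_assay(self, loaded, admin):
        status, body = loaded.handle_request(
            "PATCH", "/experiments/TSTSR000AAA/",
            body={"assay_term_name": "RNA-seq",
                  "assay_term_id": "OBI:0001271"},
            principal=admin)
        assert status == 200
        assert body["@graph"][0]["assay_term_name"] == "RNA-seq"

    def test_put_replaces_entirely(self, loaded, admin):
        status, body = loaded.handle_request(
            "PUT", "/experiments/TSTSR000AAA/",
            body={"assay_term_name": "DNase-seq"}, principal=admin)
        assert status == 200
        assert "lab" not in body["@graph"][0]

    def test_post_without_body_400(self, service, admin):
        status, _ = service.handle_request("POST", "/biosamples/",
                                           principal=admin)
        assert status == 400

    def test_submitter_lab_scoped_editing(self):
        svc = Service()
        svc.load_fixture(FixtureConfig(seed=4, n_experiments=6,
                                       released_fraction=0.0))
        mine = others = None
        for exp in svc.store.items_of_type("experiment"):
            lab_name = svc.store.get_item(
                exp.properties["lab"]).properties["name"]
            if mine is None:
                mine = exp
                mine_lab = lab_name
            elif lab_name != mine_lab and others is None:
                others = exp
        assert mine is not None and others is not None
        project = svc.store.get_item(
            mine.properties["award"]).properties["project"]
        submitter = make_submitter(svc, mine_lab, project=project)
        path = svc.store.canonical_path(mine)
        status, _ = svc.handle_request("PATCH", path,
                                       body={"description": "mine"},
                                       principal=submitter)
        assert status == 200
        # someone else's unreleased cross-project data is invisible -> 404
        others_project = svc.store.get_item(
            others.properties["award"]).properties["project"]
        foreign_scope = "GGR" if others_project == "ENCODE" else "ENCODE"
        status, _ = svc.handle_request(
            "PATCH", svc.store.canonical_path(others),
            body={"description": "x"},
            principal=Principal("s2", "submitter",
                                lab_groups=frozenset(["nope"]),
                                project_scope=foreign_scope))
        assert status == 404

    def test_edit_of_visible_but_uneditable_is_403(self, loaded, admin):
        released = next(e for e in loaded.store.items_of_type("experiment")
                        if e.status == "released")
        lab_uuid = released.properties["lab"]
        submitter = Principal("s", "submitter",
                              lab_groups=frozenset([lab_uuid]),
                              project_scope="ENCODE")
        status, _ = loaded.handle_request(
            "PATCH", loaded.store.canonical_path(released),
            body={"description": "x"}, principal=submitter)
        assert status == 403


class TestReads:
    def test_url_stability(self, loaded, admin):
        exp = loaded.store.items_of_type("experiment")[0]
        accession = exp.properties["accession"]
        bodies = []
        for path in (f"/experiments/{exp.uuid}/",
                     f"/experiments/{accession}/",
                     f"/{accession}"):
            status, body = loaded.handle_request(
                "GET", path, {"frame": "object"}, principal=admin)
            assert status == 200
            bodies.append(body)
        assert bodies[0] == bodies[1] == bodies[2]

    def test_frame_query_parameter(self, loaded, admin):
        exp = loaded.store.items_of_type("experiment")[0]
        raw = loaded.handle_request("GET", f"/{exp.uuid}", {"frame": "raw"},
                                    principal=admin)[1]
        page = loaded.handle_request("GET", f"/{exp.uuid}",
                                     {"frame": "page"}, principal=admin)[1]
        assert "@id" not in raw
        assert "audit" in page

    def test_unreleased_get_by_base_is_404(self, loaded, base, admin):
        unreleased = next(e for e in loaded.store.items_of_type("experiment")
                          if e.status != "released")
        path = loaded.store.canonical_path(unreleased)
        assert loaded.handle_request("GET", path, principal=base)[0] == 404
        assert loaded.handle_request("GET", path, principal=admin)[0] == 200

    def test_collection_listing_visibility(self, admin, base):
        svc = Service()
        svc.store.create_item("experiment", {"assay_term_name": "ChIP-seq",
                                             "status": "released"})
        svc.store.create_item("experiment", {"assay_term_name": "RNA-seq"})
        _, for_admin = svc.handle_request("GET", "/experiments/",
                                          principal=admin)
        _, for_base = svc.handle_request("GET", "/experiments/",
                                         principal=base)
        assert for_admin["total"] == 2
        assert for_base["total"] == 1

    def test_empty_collection(self, service, admin):
        status, body = service.handle_request("GET", "/experiments/",
                                              principal=admin)
        assert status == 200
        assert body["@graph"] == []

    def test_collections_partition_by_type(self, loaded, admin):
        _, listing = loaded.handle_request("GET", "/biosamples/",
                                           principal=admin)
        assert all("Biosample" in b["@type"] for b in listing["@graph"])

    def test_unknown_collection_404(self, service, admin):
        assert service.handle_request("GET", "/frobnicators/",
                                      principal=admin)[0] == 404

    def test_profiles_endpoints(self, service):
        status, body = service.handle_request("GET", "/profiles/")
        assert status == 200
        assert len(body) == 10
        status, one = service.handle_request("GET",
                                             "/profiles/experiment.json")
        assert status == 200
        assert one == body["experiment"]
        assert service.handle_request("GET", "/profiles/nope.json")[0] == 404

    def test_search_endpoint(self, loaded, admin):
        status, body = loaded.handle_request(
            "GET", "/search/", {"type": ["Experiment"], "limit": ["all"],
                                "format": ["json"]},
            principal=admin)
        assert status == 200
        assert body["total"] == 5
        assert "assay_term_name" in body["facets"]


class TestWSGI:
    def _call(self, app, method, path, body=None, principal=None,
              accept="application/json", query=""):
        from io import BytesIO

        payload = json.dumps(body).encode() if body is not None else b""
        environ = {
            "REQUEST_METHOD": method,
            "PATH_INFO": path,
            "QUERY_STRING": query,
            "CONTENT_LENGTH": str(len(payload)),
            "wsgi.input": BytesIO(payload),
            "HTTP_ACCEPT": accept,
        }
        if principal is not None:
            environ["HTTP_X_TEST_PRINCIPAL"] = json.dumps(principal)
        captured = {}

        def start_response(status, headers):
            captured["status"] = int(status.split()[0])
            captured["headers"] = dict(headers)

        chunks = app(environ, start_response)
        captured["body"] = b"".join(chunks).decode()
        return captured

    def test_json_negotiation(self, loaded):
        app = make_wsgi_app(loaded)
        result = self._call(app, "GET", "/profiles/")
        assert result["status"] == 200
        assert result["headers"]["Content-Type"] == "application/json"
        assert "experiment" in json.loads(result["body"])

    def test_html_placeholder_same_payload(self, loaded):
        app = make_wsgi_app(loaded)
        result = self._call(app, "GET", "/profiles/", accept="text/html")
        assert result["headers"]["Content-Type"].startswith("text/html")
        assert "experiment" in result["body"]

    def test_malformed_json_is_400(self, loaded):
        from io import BytesIO

        app = make_wsgi_app(loaded)
        environ = {
            "REQUEST_METHOD": "POST", "PATH_INFO": "/biosamples/",
            "QUERY_STRING": "", "CONTENT_LENGTH": "9",
            "wsgi.input": BytesIO(b"not json!"),
            "HTTP_ACCEPT": "application/json",
        }
        captured = {}
        app(environ, lambda s, h: captured.update(status=int(s.split()[0])))
        assert captured["status"] == 400

    def test_post_via_wsgi(self, loaded):
        app = make_wsgi_app(loaded)
        result = self._call(
            app, "POST", "/biosamples/",
            body={"biosample_term_name": "K562", "organism": "human"},
            principal={"user_id": "w", "tier": "admin"})
        assert result["status"] == 200
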