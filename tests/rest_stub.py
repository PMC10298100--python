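"""A tiny conformant FHIR read/search stub serving a fixture directory.

Answers ``GET /{ResourceType}?params`` with searchset Bundles, paginating
via ``_count``/``_offset`` and advertising ``next`` links.  Filtering is
implemented here independently (plain dict walking) so the transport
equivalence check does not reuse the package's matcher."""

import json
import threading
from http.server import BaseHTTPRequestHandler, ThreadingHTTPServer
from pathlib import Path
from urllib.parse import parse_qs, urlencode, urlsplit


def _matches(resource, name, value):
    if name == "_id":
        return resource.get("id") == value
    if name == "identifier":
        return value in [
            i.get("value") for i in resource.get("identifier", []) if isinstance(i, dict)
        ]
    if name == "given":
        for n in resource.get("name", []):
            if value in n.get("given", []):
                return True
        return False
    if name == "birthDate":
        bd = resource.get("birthDate")
        return isinstance(bd, str) and bd.startswith(value)
    return False


class _Handler(BaseHTTPRequestHandler):
    fixture_dir = None

    def log_message(self, *args):  # silence test output
        pass

    def do_GET(self):
        parts = urlsplit(self.path)
        type_name = parts.path.strip("/")
        query = {k: v[0] for k, v in parse_qs(parts.query).items()}
        count = int(query.pop("_count", 100))
        offset = int(query.pop("_offset", 0))

        path = Path(self.fixture_dir) / f"{type_name}.ndjson"
        resources = []
        if path.exists():
            with open(path, encoding="utf-8") as fh:
                for line in fh:
                    if line.strip():
                        resources.append(json.loads(line))
        for name, value in query.items():
            resources = [r for r in resources if _matches(r, name, value)]

        page = resources[offset : offset + count]
        bundle = {
            "resourceType": "Bundle",
            "type": "searchset",
            "total": len(resources),
            "entry": [{"resource": r} for r in page],
        }
        if offset + count < len(resources):
            next_query = dict(query)
            next_query["_count"] = str(count)
            next_query["_offset"] = str(offset + count)
            bundle["link"] = [
                {
                    "relation": "next",
                    "url": f"http://127.0.0.1:{self.server.server_port}"
                    f"/{type_name}?{urlencode(next_query)}",
                }
            ]
        body = json.dumps(bundle).encode("utf-8")
        self.send_response(200)
        self.send_header("Content-Type", "application/fhir+json")
        self.send_header("Content-Length", str(len(body)))
        self.end_headers()
        self.wfile.write(body)


class RestStub:
    """Context manager running the stub on an ephemeral port."""

    def __init__(self, fixture_dir):
        handler = type("Handler", (_Handler,), {"fixture_dir": str(fixture_dir)})
        self.server = ThreadingHTTPServer(("127.0.0.1", 0), handler)
        self.thread = threading.Thread(target=self.server.serve_forever, daemon=True)

    @property
    def base_url(self):
        return f"http://127.0.0.1:{self.server.server_port}"

    def __enter__(self):
        self.thread.start()
        return self

    def __exit__(self, *exc):
        self.server.shutdown()
        self.server.server_close()
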