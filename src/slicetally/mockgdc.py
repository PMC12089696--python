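"""A small in-process mock of a GDC-style BAM-slicing REST endpoint.

Serves a fixture catalog and sliced BAMs from local backing files so the
remote client can be exercised end to end without any network access. The
contract mirrors the real slicing API:

* ``GET /projects`` — JSON list of project ids
* ``GET /files`` — JSON list of catalog records
* ``GET /slicing/view/<file_id>?region=chr1:1-100&region=...`` with an
  ``X-Auth-Token`` header — BAM bytes (403 on a wrong token, 404 on an
  unknown file id). An empty slice returns a valid header-only BAM.
"""

from __future__ import annotations

import json
import tempfile
import threading
import urllib.parse
from http.server import BaseHTTPRequestHandler, ThreadingHTTPServer
from pathlib import Path
from typing import Mapping, Sequence

from .bamio import slice_local
from .regions import parse_region


class MockGdcServer:
    """Context-managed HTTP server on an ephemeral localhost port.

    Parameters
    ----------
    catalog : list of dict
        Records with at least file_id / project_id / experimental_strategy /
        workflow keys, as served by ``/files``.
    bam_paths : mapping file_id -> path
        Backing indexed BAMs to slice from.
    token : str
        The only value accepted in ``X-Auth-Token``.
    """

    def __init__(self, catalog: Sequence[Mapping], bam_paths: Mapping[str, str],
                 token: str = "fixture-token"):
        self.catalog = [dict(r) for r in catalog]
        self.bam_paths = {k: str(v) for k, v in bam_paths.items()}
        self.token = token
        self._server: ThreadingHTTPServer | None = None
        self._thread: threading.Thread | None = None
        self.request_count = 0
        # cache slices so identical requests are served byte-identically
        self._slice_cache: dict[tuple, bytes] = {}

    @property
    def base_url(self) -> str:
        assert self._server is not None, "server not started"
        host, port = self._server.server_address[:2]
        return f"http://{host}:{port}"

    def __enter__(self) -> "MockGdcServer":
        outer = self

        class Handler(BaseHTTPRequestHandler):
            def log_message(self, *args):  # silence test output
                pass

            def _json(self, obj, code=200):
                body = json.dumps(obj).encode()
                self.send_response(code)
                self.send_header("Content-Type", "application/json")
                self.send_header("Content-Length", str(len(body)))
                self.end_headers()
                self.wfile.write(body)

            def do_GET(self):
                outer.request_count += 1
                parsed = urllib.parse.urlparse(self.path)
                if parsed.path == "/projects":
                    seen = []
                    for r in outer.catalog:
                        if r["project_id"] not in seen:
                            seen.append(r["project_id"])
                    self._json(seen)
                elif parsed.path == "/files":
                    self._json(outer.catalog)
                elif parsed.path.startswith("/slicing/view/"):
                    self._slice(parsed)
                else:
                    self._json({"error": "not found"}, 404)

            def _slice(self, parsed):
                if self.headers.get("X-Auth-Token") != outer.token:
                    self._json({"error": "forbidden"}, 403)
                    return
                file_id = parsed.path.rsplit("/", 1)[1]
                bam = outer.bam_paths.get(file_id)
                if bam is None:
                    self._json({"error": f"unknown file {file_id}"}, 404)
                    return
                region_strs = urllib.parse.parse_qs(parsed.query).get("region", [])
                cache_key = (file_id, tuple(region_strs))
                body = outer._slice_cache.get(cache_key)
                if body is None:
                    regions = [parse_region(v) for v in region_strs]
                    with tempfile.TemporaryDirectory() as tmp:
                        out = Path(tmp) / "slice.bam"
                        slice_local(bam, regions, out)
                        body = out.read_bytes()
                    outer._slice_cache[cache_key] = body
                self.send_response(200)
                self.send_header("Content-Type", "application/octet-stream")
                self.send_header("Content-Length", str(len(body)))
                self.end_headers()
                self.wfile.write(body)

        self._server = ThreadingHTTPServer(("127.0.0.1", 0), Handler)
        self._thread = threading.Thread(target=self._server.serve_forever, daemon=True)
        self._thread.start()
        return self

    def __exit__(self, *exc):
        if self._server is not None:
            self._server.shutdown()
            self._server.server_close()
        if self._thread is not None:
            self._thread.join(timeout=5)
        return False
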