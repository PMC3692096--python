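"""Minimal read-only HTTP GET endpoint for remote CircleMap generation.

The server preloads a data directory's matrices, networks and
annotations at startup (described by the same declarative JSON config
the CLI accepts) and answers ``GET /render`` requests whose query
parameters mirror the render settings.  The response body is produced
by the exact pipeline function the CLI uses, so equivalent requests are
byte-identical to command-line output.  There are no sessions and no
uploads.

Query parameters
----------------
genes
    Comma-separated gene symbols (required).  Symbols unknown to every
    matrix and network yield 404.
rings
    Comma-separated platform labels, inner to outer (required); each
    must be a configured matrix.
sort
    Repeatable sort-key spec (``ring:GENE:PLATFORM[:asc|desc]`` or
    ``annotation:NAME[:asc|desc]``).
group_by, mode, seed
    As on the command line; ``mode=aggregated`` requires ``group_by``.
"""

from __future__ import annotations

import logging
from http.server import BaseHTTPRequestHandler, ThreadingHTTPServer
from urllib.parse import parse_qs, urlparse

from .errors import CircleMapError, ConfigurationError
from .model import GeneSet
from .pipeline import Inputs, RenderConfig, load_inputs, render_svg_bytes

log = logging.getLogger("circlemapviz.serve")


class CircleMapService:
    """Render requests against a preloaded data directory."""

    def __init__(self, config: RenderConfig):
        self.inputs = load_inputs(config)
        self.known_genes = self._collect_genes()

    def _collect_genes(self) -> set[str]:
        known = set()
        for m in self.inputs.matrices:
            known.update(m.genes)
        for _, graph in self.inputs.networks:
            known.update(graph.nodes)
        return known

    def handle(self, query: dict[str, list[str]]) -> bytes:
        """Render one request; raises ConfigurationError (400) or KeyError (404)."""
        if "genes" not in query or not query["genes"][0]:
            raise ConfigurationError("missing required parameter 'genes'")
        if "rings" not in query or not query["rings"][0]:
            raise ConfigurationError("missing required parameter 'rings'")
        genes = query["genes"][0].split(",")
        unknown = [g for g in genes if g not in self.known_genes]
        if unknown:
            raise KeyError(f"unknown gene(s): {', '.join(unknown)}")

        labels = query["rings"][0].split(",")
        by_label = {m.platform_label: m for m in self.inputs.matrices}
        missing = [lbl for lbl in labels if lbl not in by_label]
        if missing:
            raise ConfigurationError(f"unknown ring platform(s): {missing}")
        matrices = [by_label[lbl] for lbl in labels]

        mode = query.get("mode", ["full"])[0]
        if mode not in ("full", "aggregated"):
            raise ConfigurationError(f"unknown mode {mode!r}")
        group_by = query.get("group_by", [None])[0]
        sort = query.get("sort", [])
        try:
            seed = int(query.get("seed", ["0"])[0])
        except ValueError:
            raise ConfigurationError("seed must be an integer") from None

        request_inputs = Inputs(
            matrices=matrices,
            gene_set=GeneSet("request", genes),
            networks=self.inputs.networks,
            annotations=self.inputs.annotations,
        )
        return render_svg_bytes(
            request_inputs, sort=sort, group_by=group_by, mode=mode, seed=seed
        )


def make_handler(service: CircleMapService):
    class Handler(BaseHTTPRequestHandler):
        def do_GET(self):  # noqa: N802 (http.server API)
            parsed = urlparse(self.path)
            if parsed.path not in ("/render", "/"):
                self._fail(404, f"no such endpoint {parsed.path!r}")
                return
            try:
                payload = service.handle(parse_qs(parsed.query))
            except KeyError as exc:
                self._fail(404, str(exc))
            except CircleMapError as exc:
                self._fail(400, str(exc))
            else:
                self.send_response(200)
                self.send_header("Content-Type", "image/svg+xml")
                self.send_header("Content-Length", str(len(payload)))
                self.end_headers()
                self.wfile.write(payload)

        def _fail(self, code: int, message: str) -> None:
            body = message.encode("utf-8")
            self.send_response(code)
            self.send_header("Content-Type", "text/plain; charset=utf-8")
            self.send_header("Content-Length", str(len(body)))
            self.end_headers()
            self.wfile.write(body)

        def log_message(self, fmt, *args):  # route to logging, not stderr prints
            log.info(fmt, *args)

    return Handler


def make_server(config: RenderConfig, host: str = "127.0.0.1", port: int = 0):
    """Build a ThreadingHTTPServer; port 0 picks an ephemeral port."""
    service = CircleMapService(config)
    return ThreadingHTTPServer((host, port), make_handler(service))


def serve_forever(config: RenderConfig, host: str, port: int) -> None:
    server = make_server(config, host, port)
    log.info("serving on http://%s:%d/render", *server.server_address)
    try:
        server.serve_forever()
    except KeyboardInterrupt:
        server.shutdown()
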