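"""Batched delivery of sensor frames to pluggable sinks.

Opening a session per frame is wasteful, so frames are grouped into batches
(default 10 — one second of frames) before upload.  A sink is anything with
an ``accept(batch)`` method: an NDJSON file, a binary ``VBF1`` stream file,
an in-process mock ingest server, or a real HTTP endpoint (a persistent
connection stands in for keep-alive reuse).  Delivery retries each batch a
configurable number of times and never loses subsequent batches because an
earlier one failed.
"""

from __future__ import annotations

import http.client
import json
import threading
import time
import urllib.parse
from dataclasses import dataclass, field
from http.server import BaseHTTPRequestHandler, ThreadingHTTPServer
from pathlib import Path
from typing import Callable, Iterable, Sequence

from .fusion import (PAYLOAD_BYTES, SensorFrame, VBF_MAGIC, encode_frame,
                     frame_to_obj, obj_to_frame)

__all__ = [
    "UploadBatch", "DeliveryReport", "DeliveryError", "SinkError",
    "batch_frames", "batch_payload_bytes", "frames_to_json", "json_to_batch",
    "deliver", "NDJSONFileSink", "BinaryFileSink", "MockIngestServer",
    "HttpSink", "HttpIngestServer", "make_sink",
]


class SinkError(RuntimeError):
    """A sink refused or failed to store a batch."""


class DeliveryError(RuntimeError):
    """Some batches could not be delivered after retries."""

    def __init__(self, failed_seqs: Sequence[int], report: "DeliveryReport"):
        super().__init__(f"delivery failed for batch seq(s) {list(failed_seqs)}")
        self.failed_seqs = tuple(failed_seqs)
        self.report = report


@dataclass(frozen=True)
class UploadBatch:
    """An ordered run of frames from one device, with an upload sequence number."""

    device_id: str
    seq: int
    frames: tuple[SensorFrame, ...]


@dataclass
class DeliveryReport:
    accepted: int = 0
    rejected: int = 0
    retried: int = 0
    failed_seqs: tuple[int, ...] = ()


def batch_frames(frames: Iterable[SensorFrame], batch_size: int,
                 device_id: str = "vigilband-0") -> list[UploadBatch]:
    """Group consecutive frames into batches of ``batch_size`` (final batch
    may be short); sequence numbers run 0, 1, 2, …"""
    if batch_size < 1:
        raise ValueError("batch_size must be at least 1")
    frames = list(frames)
    batches = []
    for seq, i in enumerate(range(0, len(frames), batch_size)):
        batches.append(UploadBatch(device_id=device_id, seq=seq,
                                   frames=tuple(frames[i:i + batch_size])))
    return batches


def batch_payload_bytes(batch: UploadBatch) -> bytes:
    """Concatenated 24-byte payloads of the batch's frames."""
    return b"".join(encode_frame(f) for f in batch.frames)


def frames_to_json(batch: UploadBatch) -> str:
    """Serialise a batch as the upload JSON document."""
    return json.dumps({"device_id": batch.device_id, "seq": batch.seq,
                       "frames": [frame_to_obj(f) for f in batch.frames]})


def json_to_batch(text: str) -> UploadBatch:
    obj = json.loads(text)
    return UploadBatch(device_id=str(obj["device_id"]), seq=int(obj["seq"]),
                       frames=tuple(obj_to_frame(o) for o in obj["frames"]))


class NDJSONFileSink:
    """Appends one JSON object per frame to a file."""

    def __init__(self, path: str | Path):
        self.path = Path(path)
        self.path.write_text("")

    def accept(self, batch: UploadBatch) -> None:
        with open(self.path, "a") as fh:
            for frame in batch.frames:
                fh.write(json.dumps(frame_to_obj(frame)) + "\n")


class BinaryFileSink:
    """Appends ``(uint64 ts, 24-byte payload)`` records to a VBF1 file."""

    def __init__(self, path: str | Path):
        self.path = Path(path)
        self.path.write_bytes(VBF_MAGIC)

    def accept(self, batch: UploadBatch) -> None:
        import struct
        with open(self.path, "ab") as fh:
            for frame in batch.frames:
                fh.write(struct.pack("<Q", frame.timestamp_ms))
                fh.write(encode_frame(frame))


class MockIngestServer:
    """In-process stand-in for the ingest web service.

    Stores accepted batches and answers simple queries by device and time
    range.  Thread-safe so the HTTP wrapper can share it.
    """

    def __init__(self) -> None:
        self._batches: list[UploadBatch] = []
        self._lock = threading.Lock()

    def accept(self, batch: UploadBatch) -> None:
        with self._lock:
            self._batches.append(batch)

    def query(self, device_id: str | None = None, t0_ms: int | None = None,
              t1_ms: int | None = None) -> list[UploadBatch]:
        with self._lock:
            batches = list(self._batches)
        if device_id is not None:
            batches = [b for b in batches if b.device_id == device_id]
        if t0_ms is not None or t1_ms is not None:
            lo = -1 if t0_ms is None else t0_ms
            hi = float("inf") if t1_ms is None else t1_ms
            batches = [b for b in batches
                       if b.frames and lo <= b.frames[0].timestamp_ms
                       and b.frames[-1].timestamp_ms < hi]
        return batches

    def frames(self, device_id: str | None = None) -> list[SensorFrame]:
        return [f for b in self.query(device_id) for f in b.frames]


def deliver(batches: Iterable[UploadBatch], sink, retries: int = 2,
            backoff_s: float = 1.0,
            sleep: Callable[[float], None] = time.sleep) -> DeliveryReport:
    """Deliver batches in sequence order with per-batch retries.

    Each batch gets up to ``1 + retries`` attempts with a fixed backoff; a
    batch that still fails is recorded and delivery continues with the next
    one.  If any batch was lost a :class:`DeliveryError` (carrying the full
    report) is raised after the stream is exhausted.
    """
    report = DeliveryReport()
    failed: list[int] = []
    for batch in batches:
        for attempt in range(1 + retries):
            try:
                sink.accept(batch)
                report.accepted += 1
                break
            except Exception:
                report.rejected += 1
                if attempt < retries:
                    report.retried += 1
                    sleep(backoff_s)
        else:
            failed.append(batch.seq)
    report.failed_seqs = tuple(failed)
    if failed:
        raise DeliveryError(failed, report)
    return report


class _IngestHandler(BaseHTTPRequestHandler):
    store: MockIngestServer  # set on the subclass

    def do_POST(self) -> None:  # noqa: N802 (http.server API)
        length = int(self.headers.get("Content-Length", 0))
        body = self.rfile.read(length)
        try:
            batch = json_to_batch(body.decode())
        except Exception:
            self.send_response(400)
            self.end_headers()
            return
        self.store.accept(batch)
        self.send_response(200)
        self.send_header("Content-Type", "application/json")
        self.end_headers()
        self.wfile.write(b'{"status": "ok"}')

    def log_message(self, *args) -> None:  # keep test output quiet
        pass


class HttpIngestServer:
    """Minimal HTTP wrapper around :class:`MockIngestServer` (POST /ingest)."""

    def __init__(self, host: str = "127.0.0.1", port: int = 0):
        self.store = MockIngestServer()
        handler = type("Handler", (_IngestHandler,), {"store": self.store})
        self._httpd = ThreadingHTTPServer((host, port), handler)
        self._thread: threading.Thread | None = None

    @property
    def port(self) -> int:
        return self._httpd.server_address[1]

    @property
    def url(self) -> str:
        host, port = self._httpd.server_address[:2]
        return f"http://{host}:{port}/ingest"

    def start(self) -> "HttpIngestServer":
        self._thread = threading.Thread(target=self._httpd.serve_forever,
                                        daemon=True)
        self._thread.start()
        return self

    def stop(self) -> None:
        self._httpd.shutdown()
        self._httpd.server_close()
        if self._thread is not None:
            self._thread.join(timeout=5)

    def serve_forever(self) -> None:
        self._httpd.serve_forever()


class HttpSink:
    """POSTs batch JSON to an ingest URL over one persistent connection."""

    def __init__(self, url: str):
        self.url = url
        parsed = urllib.parse.urlsplit(url)
        self._host = parsed.hostname or "127.0.0.1"
        self._port = parsed.port or 80
        self._path = parsed.path or "/"
        self._conn: http.client.HTTPConnection | None = None

    def _connection(self) -> http.client.HTTPConnection:
        if self._conn is None:
            self._conn = http.client.HTTPConnection(self._host, self._port,
                                                    timeout=10)
        return self._conn

    def accept(self, batch: UploadBatch) -> None:
        body = frames_to_json(batch).encode()
        try:
            conn = self._connection()
            conn.request("POST", self._path, body=body,
                         headers={"Content-Type": "application/json"})
            resp = conn.getresponse()
            resp.read()
        except Exception as exc:
            self.close()
            raise SinkError(f"POST to {self.url} failed: {exc}") from exc
        if resp.status != 200:
            raise SinkError(f"ingest returned HTTP {resp.status}")

    def close(self) -> None:
        if self._conn is not None:
            self._conn.close()
            self._conn = None


def make_sink(target: str | Path):
    """Build a sink from a URL or file path (scheme/extension dispatch)."""
    text = str(target)
    if text.startswith(("http://", "https://")):
        return HttpSink(text)
    if text.endswith(".ndjson") or text.endswith(".jsonl"):
        return NDJSONFileSink(target)
    return BinaryFileSink(target)
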