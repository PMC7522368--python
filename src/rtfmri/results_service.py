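"""Request/reply server handing per-volume results to remote clients.

A client (stimulus software, monitoring script, ...) asks for one volume's
results by sending its 0-based index as fixed-width, zero-padded decimal
text (4 digits, supporting runs shorter than 10000 timepoints). The reply
is a UTF-8 JSON object: ``{"foundResults": false}`` when that volume has not
been processed yet, otherwise ``{"foundResults": true, ...}`` with every
name/value pair recorded for that volume (nulls preserved). Requests never
block waiting for processing, and a malformed request yields the false
reply with a logged warning, never a crash.
"""

from __future__ import annotations

import json
import logging
import socket
import threading

from .volume_stream import DEFAULT_HOST, RESULTS_PORT, recv_frame, send_frame

log = logging.getLogger(__name__)

__all__ = [
    "ResultsStore",
    "ResultsServer",
    "request_result",
    "format_request",
    "REQUEST_WIDTH",
]

REQUEST_WIDTH = 4


class ResultsStore:
    """Thread-safe volume-index -> result-mapping lookup.

    Once a volume's results are stored they are never removed, so a client
    that saw ``foundResults: true`` will keep seeing it (monotone
    availability).
    """

    def __init__(self) -> None:
        self._results: dict[int, dict] = {}
        self._lock = threading.Lock()

    def update(self, vol_idx: int, values: dict) -> None:
        with self._lock:
            self._results[int(vol_idx)] = dict(values)

    def get(self, vol_idx: int) -> dict | None:
        with self._lock:
            vals = self._results.get(int(vol_idx))
            return None if vals is None else dict(vals)

    def __len__(self) -> int:
        with self._lock:
            return len(self._results)

    def as_dict(self) -> dict[int, dict]:
        with self._lock:
            return {k: dict(v) for k, v in self._results.items()}


def handle_request(store: ResultsStore, request_text: str) -> dict:
    """Resolve one request against the store (pure; no sockets)."""
    try:
        vol_idx = int(request_text)
        if vol_idx < 0:
            raise ValueError(request_text)
    except (TypeError, ValueError):
        log.warning("malformed results request %r", request_text)
        return {"foundResults": False}
    values = store.get(vol_idx)
    if values is None:
        return {"foundResults": False}
    reply = {"foundResults": True}
    reply.update(values)
    return reply


def format_request(vol_idx: int) -> bytes:
    return f"{int(vol_idx):0{REQUEST_WIDTH}d}".encode("ascii")


class ResultsServer:
    """Background TCP thread answering results requests during the scan.

    Each client connection may issue any number of length-prefixed requests;
    replies are length-prefixed JSON on the same connection.
    """

    def __init__(self, store: ResultsStore, host: str = DEFAULT_HOST,
                 port: int = RESULTS_PORT) -> None:
        self.store = store
        self._listener = socket.socket(socket.AF_INET, socket.SOCK_STREAM)
        self._listener.setsockopt(socket.SOL_SOCKET, socket.SO_REUSEADDR, 1)
        self._listener.bind((host, port))
        self._listener.listen(8)
        self.host, self.port = self._listener.getsockname()
        self._stop = threading.Event()
        self._thread = threading.Thread(target=self._serve, daemon=True)

    def start(self) -> None:
        self._thread.start()
        log.info("results server listening on %s:%d", self.host, self.port)

    def _serve(self) -> None:
        self._listener.settimeout(0.1)
        workers = []
        while not self._stop.is_set():
            try:
                conn, _ = self._listener.accept()
            except socket.timeout:
                continue
            except OSError:
                break
            t = threading.Thread(target=self._serve_client, args=(conn,), daemon=True)
            t.start()
            workers.append(t)
        self._listener.close()

    def _serve_client(self, conn: socket.socket) -> None:
        conn.settimeout(10.0)
        with conn:
            while not self._stop.is_set():
                try:
                    raw = recv_frame(conn)
                except (ConnectionError, socket.timeout, OSError):
                    return
                try:
                    text = raw.decode("ascii", errors="replace")
                except Exception:  # pragma: no cover - decode never raises here
                    text = ""
                reply = handle_request(self.store, text)
                try:
                    send_frame(conn, json.dumps(reply).encode("utf-8"))
                except OSError:
                    return

    def stop(self) -> None:
        self._stop.set()
        self._thread.join(timeout=5.0)


def request_result(
    vol_idx: int, host: str = DEFAULT_HOST, port: int = RESULTS_PORT,
    timeout: float = 5.0,
) -> dict:
    """One-shot client: ask the results server about a single volume."""
    with socket.create_connection((host, port), timeout=timeout) as sock:
        sock.settimeout(timeout)
        send_frame(sock, format_request(vol_idx))
        return json.loads(recv_frame(sock).decode("utf-8"))


def request_raw(
    payload: bytes, host: str = DEFAULT_HOST, port: int = RESULTS_PORT,
    timeout: float = 5.0,
) -> dict:
    """Send arbitrary request bytes (used to probe malformed-input handling)."""
    with socket.create_connection((host, port), timeout=timeout) as sock:
        sock.settimeout(timeout)
        send_frame(sock, payload)
        return json.loads(recv_frame(sock).decode("utf-8"))
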