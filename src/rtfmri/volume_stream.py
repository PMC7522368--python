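"""Two-part volume transmission: JSON header frame + raw array frame.

Each volume crosses the wire in two waves on a single reliable, ordered TCP
connection: first a UTF-8 JSON header carrying the timepoint index, spatial
shape, element type, and byte/axis order; then the contiguous array buffer
itself. The receiver acknowledges every volume so the sender can pace and
log. Frames are length-prefixed with a 4-byte big-endian unsigned integer.

The payload axis order is fixed as Fortran ("F": x fastest), and the header
records it so the stream is self-describing.
"""

from __future__ import annotations

import json
import logging
import socket
import struct
from dataclasses import dataclass

import numpy as np

from .errors import ProtocolError
from .scanner_formats import AssembledVolume
from .geometry import VolumeGeometry

log = logging.getLogger(__name__)

__all__ = [
    "VolumeHeader",
    "encode_volume",
    "decode_volume",
    "VolumeSender",
    "VolumeReceiver",
    "DEFAULT_HOST",
    "SCANNER_PORT",
    "RESULTS_PORT",
]

DEFAULT_HOST = "127.0.0.1"
SCANNER_PORT = 5555
RESULTS_PORT = 5558

_ACK = b"got it"
_SUPPORTED_DTYPES = {
    "int16", "uint16", "int32", "uint32", "int64", "uint64", "float32", "float64",
}


@dataclass(frozen=True)
class VolumeHeader:
    """Metadata sufficient to reconstruct one streamed volume."""

    vol_idx: int
    shape: tuple[int, int, int]
    element_type: str
    byte_order: str = "little"
    axis_order: str = "F"
    voxel_size_mm: tuple[float, float, float] | None = None
    num_timepts: int | None = None

    def to_json(self) -> bytes:
        d = {
            "volIdx": self.vol_idx,
            "shape": list(self.shape),
            "dtype": self.element_type,
            "byteOrder": self.byte_order,
            "axisOrder": self.axis_order,
        }
        if self.voxel_size_mm is not None:
            d["voxelSizeMm"] = list(self.voxel_size_mm)
        if self.num_timepts is not None:
            d["numTimepts"] = self.num_timepts
        return json.dumps(d).encode("utf-8")

    @classmethod
    def from_json(cls, raw: bytes) -> "VolumeHeader":
        try:
            d = json.loads(raw.decode("utf-8"))
        except (UnicodeDecodeError, json.JSONDecodeError) as exc:
            raise ProtocolError(f"malformed volume header: {exc}") from exc
        try:
            return cls(
                vol_idx=int(d["volIdx"]),
                shape=tuple(int(s) for s in d["shape"]),
                element_type=str(d["dtype"]),
                byte_order=str(d.get("byteOrder", "little")),
                axis_order=str(d.get("axisOrder", "F")),
                voxel_size_mm=tuple(d["voxelSizeMm"]) if "voxelSizeMm" in d else None,
                num_timepts=d.get("numTimepts"),
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise ProtocolError(f"incomplete volume header: {exc}") from exc


def encode_volume(v: AssembledVolume) -> tuple[VolumeHeader, bytes]:
    """Serialize an assembled volume into (header, payload) deterministically."""
    dtype = v.data.dtype.newbyteorder("<")
    name = np.dtype(dtype).name
    if name not in _SUPPORTED_DTYPES:
        raise ProtocolError(f"unsupported element type {name}")
    header = VolumeHeader(
        vol_idx=v.vol_idx,
        shape=tuple(v.data.shape),
        element_type=name,
        byte_order="little",
        axis_order="F",
        voxel_size_mm=v.geometry.voxel_size_mm,
        num_timepts=v.geometry.expected_timepts,
    )
    payload = np.asarray(v.data, dtype=dtype).tobytes(order="F")
    return header, payload


def decode_volume(header: VolumeHeader, payload: bytes) -> AssembledVolume:
    """Reconstruct the sent array bit-exactly from header + payload."""
    if header.element_type not in _SUPPORTED_DTYPES:
        raise ProtocolError(f"unknown element type tag {header.element_type!r}")
    dtype = np.dtype(header.element_type)
    if header.byte_order == "little":
        dtype = dtype.newbyteorder("<")
    elif header.byte_order == "big":
        dtype = dtype.newbyteorder(">")
    else:
        raise ProtocolError(f"unknown byte order {header.byte_order!r}")
    expected = int(np.prod(header.shape)) * dtype.itemsize
    if len(payload) != expected:
        raise ProtocolError(
            f"payload length {len(payload)} != shape/dtype implied {expected}"
        )
    arr = np.frombuffer(payload, dtype=dtype).reshape(
        header.shape, order=header.axis_order
    )
    vox = header.voxel_size_mm or (1.0, 1.0, 1.0)
    geom = VolumeGeometry(
        dims=header.shape,
        voxel_size_mm=vox,
        expected_timepts=header.num_timepts,
    )
    return AssembledVolume(vol_idx=header.vol_idx, data=arr, geometry=geom)


# ---------------------------------------------------------------------------
# framing over a TCP socket
# ---------------------------------------------------------------------------

def send_frame(sock: socket.socket, payload: bytes) -> None:
    sock.sendall(struct.pack(">I", len(payload)) + payload)


def recv_frame(sock: socket.socket) -> bytes:
    raw_len = _recv_exact(sock, 4)
    (length,) = struct.unpack(">I", raw_len)
    return _recv_exact(sock, length)


def _recv_exact(sock: socket.socket, n: int) -> bytes:
    chunks = []
    remaining = n
    while remaining:
        chunk = sock.recv(min(remaining, 1 << 20))
        if not chunk:
            raise ConnectionError("peer closed connection mid-frame")
        chunks.append(chunk)
        remaining -= len(chunk)
    return b"".join(chunks)


class VolumeSender:
    """Scanner-side end of the stream; connects and pushes volumes."""

    def __init__(self, host: str = DEFAULT_HOST, port: int = SCANNER_PORT,
                 connect_timeout: float = 30.0) -> None:
        self.host = host
        self.port = port
        self._sock: socket.socket | None = None
        self._connect_timeout = connect_timeout

    def connect(self) -> None:
        """Connect to the analysis side, waiting for it to start listening."""
        log.info("connecting to analysis host at %s:%d ...", self.host, self.port)
        import time as _time

        deadline = _time.monotonic() + self._connect_timeout
        while True:
            try:
                sock = socket.create_connection((self.host, self.port), timeout=1.0)
                break
            except (ConnectionRefusedError, socket.timeout, OSError):
                if _time.monotonic() > deadline:
                    raise
                log.info("waiting for connection ...")
                _time.sleep(0.05)
        sock.settimeout(self._connect_timeout)
        self._sock = sock
        log.info("connected")

    def send_volume(self, v: AssembledVolume) -> None:
        if self._sock is None:
            self.connect()
        header, payload = encode_volume(v)
        send_frame(self._sock, header.to_json())
        send_frame(self._sock, payload)
        ack = recv_frame(self._sock)
        if ack != _ACK:
            raise ProtocolError(f"unexpected acknowledgment {ack!r}")

    def close(self) -> None:
        if self._sock is not None:
            try:
                self._sock.close()
            finally:
                self._sock = None

    def __enter__(self):
        self.connect()
        return self

    def __exit__(self, *exc):
        self.close()


class VolumeReceiver:
    """Analysis-side end of the stream; listens, then yields volumes in order."""

    def __init__(self, host: str = DEFAULT_HOST, port: int = SCANNER_PORT) -> None:
        self._listener = socket.socket(socket.AF_INET, socket.SOCK_STREAM)
        self._listener.setsockopt(socket.SOL_SOCKET, socket.SO_REUSEADDR, 1)
        self._listener.bind((host, port))
        self._listener.listen(1)
        self.host, self.port = self._listener.getsockname()
        self._conn: socket.socket | None = None

    def accept(self, timeout: float | None = None) -> None:
        self._listener.settimeout(timeout)
        conn, addr = self._listener.accept()
        conn.settimeout(timeout)
        self._conn = conn
        log.info("scanner stream connected from %s", addr)

    def receive_volume(self) -> AssembledVolume | None:
        """Receive one volume; returns None on clean end-of-stream."""
        if self._conn is None:
            self.accept()
        try:
            header_raw = recv_frame(self._conn)
        except ConnectionError:
            return None
        header = VolumeHeader.from_json(header_raw)
        payload = recv_frame(self._conn)
        vol = decode_volume(header, payload)
        send_frame(self._conn, _ACK)
        return vol

    def close(self) -> None:
        for s in (self._conn, self._listener):
            if s is not None:
                try:
                    s.close()
                except OSError:
                    pass
        self._conn = None

    def __enter__(self):
        return self

    def __exit__(self, *exc):
        self.close()
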