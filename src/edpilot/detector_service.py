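"""Client/server acquisition split and client-side frame operators.

The detector runs behind a small TCP service (mirroring the physical
split between the microscope computer and the detector computer).  The
wire dialect is original and documented here: every message is a 4-byte
big-endian payload length, a JSON header line terminated by ``\\n``, then
an optional raw little-endian pixel payload.  Header fields: ``request_id``,
``command`` (or ``reply``/``error``), and for frames ``shape``, ``dtype``,
``exposure``, ``seq``.

Client-side operators: flat-field and dead-pixel correction (applied to
every frame before analysis), local-maximum peak finding for the "Peaks"
overlay, and the multi-position diffraction preview that steers the beam
between marked crystals via the beam-shift calibration.
"""

from __future__ import annotations

import json
import select
import socket
import socketserver
import struct
import threading
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from . import beam_calibration as bc
from .virtual_microscope import DetectorFrame

__all__ = [
    "AcquisitionRequest",
    "CorrectionMaps",
    "DetectorServer",
    "DetectorClient",
    "encode_message",
    "decode_message",
    "flat_field_correct",
    "dead_pixel_correct",
    "find_peaks",
    "multi_position_preview",
    "derive_gain_map",
]

COMMANDS = ("set_exposure", "acquire_single", "stream_start", "stream_stop", "status")


class ProtocolError(RuntimeError):
    pass


@dataclass(frozen=True)
class AcquisitionRequest:
    command: str
    request_id: int
    exposure: float | None = None  # ms, for set_exposure

    def __post_init__(self) -> None:
        if self.command not in COMMANDS:
            raise ProtocolError(f"unknown command {self.command!r}")
        if self.exposure is not None and self.exposure <= 0:
            raise ProtocolError("exposure must be > 0 ms")

    def to_header(self) -> dict:
        h = {"command": self.command, "request_id": self.request_id}
        if self.exposure is not None:
            h["exposure"] = self.exposure
        return h

    @classmethod
    def from_header(cls, header: dict) -> "AcquisitionRequest":
        try:
            return cls(
                command=header["command"],
                request_id=int(header["request_id"]),
                exposure=header.get("exposure"),
            )
        except KeyError as exc:
            raise ProtocolError(f"missing header field {exc}") from exc


@dataclass
class CorrectionMaps:
    """Per-pixel flat-field gain and dead-pixel mask."""

    gain_map: np.ndarray
    dead_mask: np.ndarray  # bool

    def __post_init__(self) -> None:
        self.gain_map = np.asarray(self.gain_map, dtype=float)
        self.dead_mask = np.asarray(self.dead_mask, dtype=bool)
        if self.gain_map.shape != self.dead_mask.shape:
            raise ValueError("gain_map and dead_mask shapes must match")
        if np.any(self.gain_map[~self.dead_mask] <= 0):
            raise ValueError("gain_map must be > 0 off the dead mask")


# --- wire format ---------------------------------------------------------

def encode_message(header: dict, payload: bytes = b"") -> bytes:
    head = json.dumps(header).encode() + b"\n"
    return struct.pack(">I", len(payload)) + head + payload


def _read_exact(stream, n: int) -> bytes:
    chunks = []
    got = 0
    while got < n:
        chunk = stream.read(n - got)
        if not chunk:
            raise ProtocolError("stream closed mid-message")
        chunks.append(chunk)
        got += len(chunk)
    return b"".join(chunks)


def decode_message(stream) -> tuple[dict, bytes]:
    """Read one message from a file-like byte stream."""
    (payload_len,) = struct.unpack(">I", _read_exact(stream, 4))
    head = stream.readline()
    if not head.endswith(b"\n"):
        raise ProtocolError("malformed header: missing newline terminator")
    try:
        header = json.loads(head.decode())
    except json.JSONDecodeError as exc:
        raise ProtocolError(f"malformed header: {exc}") from exc
    payload = _read_exact(stream, payload_len) if payload_len else b""
    return header, payload


def _frame_message(frame: DetectorFrame, request_id: int, seq: int | None = None) -> bytes:
    pixels = np.ascontiguousarray(frame.pixels, dtype="<u2")
    header = {
        "reply": "frame",
        "request_id": request_id,
        "shape": list(pixels.shape),
        "dtype": "<u2",
        "exposure": frame.exposure,
        "timestamp": frame.timestamp,
        "alpha": frame.stage_alpha_at_exposure,
    }
    if seq is not None:
        header["seq"] = seq
    return encode_message(header, pixels.tobytes())


def frame_from_message(header: dict, payload: bytes) -> DetectorFrame:
    pixels = np.frombuffer(payload, dtype=header["dtype"]).reshape(header["shape"])
    return DetectorFrame(
        pixels=pixels.astype(np.uint16),
        exposure=header["exposure"],
        timestamp=header.get("timestamp", 0.0),
        stage_alpha_at_exposure=header.get("alpha", 0.0),
    )


# --- server --------------------------------------------------------------

class _Handler(socketserver.StreamRequestHandler):
    # unbuffered reads so select() on the raw socket sees pending commands
    rbufsize = 0

    def handle(self) -> None:
        server: DetectorServer = self.server  # type: ignore[assignment]
        streaming = False
        seq = 0
        stream_request_id = 0
        while True:
            try:
                if streaming:
                    # push frames while polling for a stop command
                    ready, _, _ = select.select([self.connection], [], [], 0.0)
                    if ready:
                        header, _ = decode_message(self.rfile)
                        req = AcquisitionRequest.from_header(header)
                        if req.command == "stream_stop":
                            streaming = False
                            self._reply({"reply": "stream_stopped",
                                         "request_id": req.request_id, "frames_sent": seq})
                            continue
                    frame = server.backend.acquire_frame(server.exposure_ms)
                    self.wfile.write(_frame_message(frame, stream_request_id, seq))
                    seq += 1
                    continue
                header, _ = decode_message(self.rfile)
            except ProtocolError as exc:
                if "closed" in str(exc):
                    return
                self._reply({"error": str(exc), "request_id": -1})
                continue
            try:
                req = AcquisitionRequest.from_header(header)
            except ProtocolError as exc:
                self._reply({"error": str(exc),
                             "request_id": header.get("request_id", -1)})
                continue
            if req.command == "set_exposure":
                server.exposure_ms = float(req.exposure)
                self._reply({"reply": "ok", "request_id": req.request_id,
                             "exposure": server.exposure_ms})
            elif req.command == "acquire_single":
                frame = server.backend.acquire_frame(server.exposure_ms)
                self.wfile.write(_frame_message(frame, req.request_id))
            elif req.command == "stream_start":
                streaming = True
                seq = 0
                stream_request_id = req.request_id
                self._reply({"reply": "streaming", "request_id": req.request_id})
            elif req.command == "stream_stop":
                self._reply({"reply": "stream_stopped", "request_id": req.request_id,
                             "frames_sent": 0})
            elif req.command == "status":
                self._reply({"reply": "status", "request_id": req.request_id,
                             "exposure": server.exposure_ms, "streaming": streaming})

    def _reply(self, header: dict) -> None:
        self.wfile.write(encode_message(header))


class DetectorServer(socketserver.ThreadingTCPServer):
    """Loopback TCP service wrapping a detector backend.

    The backend needs one method, ``acquire_frame(exposure_ms)``; a
    VirtualMicroscope qualifies.  Use port 0 to bind an ephemeral port.
    """

    allow_reuse_address = True
    daemon_threads = True

    def __init__(self, backend, address: tuple[str, int] = ("127.0.0.1", 0)):
        super().__init__(address, _Handler)
        self.backend = backend
        self.exposure_ms = 500.0

    def serve_in_background(self) -> threading.Thread:
        thread = threading.Thread(target=self.serve_forever, daemon=True)
        thread.start()
        return thread


class DetectorClient:
    """Minimal client for the acquisition service."""

    def __init__(self, address: tuple[str, int]):
        self._sock = socket.create_connection(address)
        self._rfile = self._sock.makefile("rb")
        self._next_id = 0

    def close(self) -> None:
        self._rfile.close()
        self._sock.close()

    def _request(self, command: str, **fields) -> dict:
        self._next_id += 1
        req = AcquisitionRequest(command=command, request_id=self._next_id,
                                 exposure=fields.get("exposure"))
        self._sock.sendall(encode_message(req.to_header()))
        return req.to_header()

    def _read(self) -> tuple[dict, bytes]:
        return decode_message(self._rfile)

    def set_exposure(self, exposure_ms: float) -> dict:
        self._request("set_exposure", exposure=exposure_ms)
        header, _ = self._read()
        return header

    def acquire_single(self) -> DetectorFrame:
        self._request("acquire_single")
        header, payload = self._read()
        if "error" in header:
            raise ProtocolError(header["error"])
        return frame_from_message(header, payload)

    def status(self) -> dict:
        self._request("status")
        header, _ = self._read()
        return header

    def send_raw(self, header: dict) -> dict:
        """Send an arbitrary header (protocol testing); returns the reply."""
        self._sock.sendall(encode_message(header))
        reply, _ = self._read()
        return reply

    def stream(self, n_frames: int) -> list[tuple[int, DetectorFrame]]:
        """Start a stream, collect ``n_frames``, stop, return (seq, frame)s."""
        self._request("stream_start")
        header, _ = self._read()
        if header.get("reply") != "streaming":
            raise ProtocolError(f"stream refused: {header}")
        out: list[tuple[int, DetectorFrame]] = []
        while len(out) < n_frames:
            header, payload = self._read()
            if header.get("reply") == "frame":
                out.append((header["seq"], frame_from_message(header, payload)))
        self._request("stream_stop")
        while True:
            header, payload = self._read()
            if header.get("reply") == "stream_stopped":
                break
        return out


# --- corrections ---------------------------------------------------------

def flat_field_correct(raw: DetectorFrame, maps: CorrectionMaps) -> DetectorFrame:
    """Divide out the per-pixel gain, renormalized so the mean level of the
    frame is preserved: corrected = raw / gain × mean(gain | non-dead).

    Dead pixels pass through unchanged; they are the next stage's job.
    """
    pixels = np.asarray(raw.pixels, dtype=float)
    if pixels.shape != maps.gain_map.shape:
        raise ValueError("frame and correction-map shapes differ")
    live = ~maps.dead_mask
    scale = float(maps.gain_map[live].mean())
    corrected = pixels.copy()
    corrected[live] = pixels[live] / maps.gain_map[live] * scale
    return DetectorFrame(
        pixels=np.clip(np.rint(corrected), 0, 65535).astype(np.uint16),
        exposure=raw.exposure,
        timestamp=raw.timestamp,
        stage_alpha_at_exposure=raw.stage_alpha_at_exposure,
    )


def dead_pixel_correct(frame: DetectorFrame, maps: CorrectionMaps) -> DetectorFrame:
    """Replace each dead pixel by the median of its non-dead 8-neighbours.

    Clusters whose members have no live neighbour on the first pass are
    resolved iteratively, using values filled in earlier rounds, until no
    flagged pixel remains.
    """
    if maps.dead_mask.all():
        raise ValueError("all pixels are dead; nothing to interpolate from")
    pixels = np.asarray(frame.pixels, dtype=float)
    if pixels.shape != maps.dead_mask.shape:
        raise ValueError("frame and correction-map shapes differ")
    out = pixels.copy()
    remaining = maps.dead_mask.copy()
    rows, cols = out.shape
    while remaining.any():
        filled_this_round = []
        for r, c in zip(*np.nonzero(remaining)):
            vals = [
                out[rr, cc]
                for rr in range(max(r - 1, 0), min(r + 2, rows))
                for cc in range(max(c - 1, 0), min(c + 2, cols))
                if (rr, cc) != (r, c) and not remaining[rr, cc]
            ]
            if vals:
                filled_this_round.append((r, c, float(np.median(vals))))
        if not filled_this_round:  # fully enclosed region; cannot happen off a
            raise ValueError("dead region has no live boundary")  # pathological mask
        for r, c, val in filled_this_round:
            out[r, c] = val
            remaining[r, c] = False
    return DetectorFrame(
        pixels=np.clip(np.rint(out), 0, 65535).astype(np.uint16),
        exposure=frame.exposure,
        timestamp=frame.timestamp,
        stage_alpha_at_exposure=frame.stage_alpha_at_exposure,
    )


def find_peaks(
    frame: DetectorFrame | np.ndarray,
    min_intensity: float,
    min_separation: float = 5.0,
) -> list[tuple[float, float]]:
    """Local maxima above ``min_intensity``, greedily pruned so surviving
    peaks are at least ``min_separation`` px apart; strongest first.

    Returns (u, v) positions; an empty list is a valid result.
    """
    pixels = (frame.pixels if isinstance(frame, DetectorFrame) else np.asarray(frame)).astype(float)
    footprint = np.ones((3, 3), dtype=bool)
    is_max = (pixels == ndimage.maximum_filter(pixels, footprint=footprint)) & (
        pixels >= min_intensity
    )
    vs, us = np.nonzero(is_max)
    order = np.argsort(-pixels[vs, us], kind="stable")
    kept: list[tuple[float, float]] = []
    for idx in order:
        u, v = float(us[idx]), float(vs[idx])
        if all((u - ku) ** 2 + (v - kv) ** 2 >= min_separation**2 for ku, kv in kept):
            kept.append((u, v))
    return kept


def multi_position_preview(
    scope,
    positions: list[tuple[float, float]],
    calib: bc.CalibrationMatrix,
    *,
    exposure_ms: float = 500.0,
    presets=None,
) -> list[tuple[tuple[float, float], DetectorFrame]]:
    """Steer the beam to each marked position in turn and grab one
    diffraction pattern per position (the interactive multi-crystal check).

    All positions are validated against the detector bounds before any mode
    switch or exposure; an empty list is a no-op.
    """
    if not positions:
        return []
    rows, cols = scope.scene.detector_shape
    for u, v in positions:
        if not (0 <= u < cols and 0 <= v < rows):
            raise ValueError(f"position ({u}, {v}) outside detector bounds")
    if presets is not None:
        if presets.get("diffraction") is None:
            raise RuntimeError("no stored diffraction preset")
        presets.apply(scope, "diffraction")
    else:
        scope.set_mode("diffraction")
    out = []
    for pos in positions:
        di = bc.pixel_to_currents(pos, calib)
        scope.set_deflectors(calib.ref_currents[0] + di[0], calib.ref_currents[1] + di[1])
        out.append((pos, scope.acquire_frame(exposure_ms)))
    return out


def derive_gain_map(flood_frames: list[DetectorFrame | np.ndarray]) -> CorrectionMaps:
    """Build correction maps from a stack of flood-field (flat) exposures.

    The gain is the pixelwise mean of the stack normalized to unit mean;
    pixels that never fire are flagged dead.
    """
    if not flood_frames:
        raise ValueError("need at least one flood-field frame")
    stack = np.stack(
        [np.asarray(f.pixels if isinstance(f, DetectorFrame) else f, dtype=float)
         for f in flood_frames]
    )
    mean = stack.mean(axis=0)
    dead = mean <= 0
    gain = np.ones_like(mean)
    live_mean = mean[~dead].mean()
    gain[~dead] = mean[~dead] / live_mean
    return CorrectionMaps(gain_map=gain, dead_mask=dead)
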