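"""Standard MIDI File (SMF) reading and writing for plain note streams.

Reads format 0 and 1 files (multi-track files are flattened to one note
stream: the study material is a single piano timbre), applies the tempo map
to convert ticks to seconds, and treats a note-on with velocity 0 as a
note-off.  Writes format 0 at a fixed convention -- 480 ticks per quarter,
one 120 BPM tempo event -- so that write/read round trips are bit-stable.

Only the event kinds needed for keyboard note streams are interpreted; other
channel messages, sysex and meta events are parsed (so the byte stream stays
in sync) and discarded.
"""

from __future__ import annotations

import logging
import struct
from pathlib import Path
from typing import Sequence

from .corpus_io import Improvisation, NoteEvent

log = logging.getLogger(__name__)

PPQ = 480
DEFAULT_TEMPO = 500_000  # microseconds per quarter note: 120 BPM
_TICKS_PER_SECOND = PPQ * 1_000_000 / DEFAULT_TEMPO  # 960 at the write convention


class SmfFormatError(ValueError):
    """File is not a parseable SMF format 0/1."""


class EmptyImprovisationError(ValueError):
    """SMF parsed correctly but contains no notes."""


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------


def _encode_varlen(value: int) -> bytes:
    if value < 0:
        raise ValueError("negative delta time")
    chunks = [value & 0x7F]
    value >>= 7
    while value:
        chunks.append(0x80 | (value & 0x7F))
        value >>= 7
    return bytes(reversed(chunks))


def write_smf(improv: Improvisation | Sequence[NoteEvent], path: str | Path) -> None:
    """Write a format-0 SMF; ``read_smf`` inverts it to within one tick."""
    notes = improv.notes if isinstance(improv, Improvisation) else tuple(improv)
    if not notes:
        raise EmptyImprovisationError("refusing to write an empty improvisation")

    # (tick, order, status, data1, data2); note-offs sort before note-ons at
    # equal ticks so re-struck pitches never nest
    events: list[tuple[int, int, int, int, int]] = []
    for n in notes:
        on_tick = round(n.onset * _TICKS_PER_SECOND)
        off_tick = round(n.offset * _TICKS_PER_SECOND)
        if off_tick <= on_tick:
            off_tick = on_tick + 1
        events.append((on_tick, 1, 0x90, n.pitch, n.velocity))
        events.append((off_tick, 0, 0x80, n.pitch, 0))
    events.sort()

    track = bytearray()
    track += _encode_varlen(0) + bytes([0xFF, 0x51, 0x03]) + DEFAULT_TEMPO.to_bytes(3, "big")
    prev_tick = 0
    for tick, _, status, d1, d2 in events:
        track += _encode_varlen(tick - prev_tick) + bytes([status, d1, d2])
        prev_tick = tick
    track += _encode_varlen(0) + bytes([0xFF, 0x2F, 0x00])

    with open(path, "wb") as fh:
        fh.write(b"MThd" + struct.pack(">IHHH", 6, 0, 1, PPQ))
        fh.write(b"MTrk" + struct.pack(">I", len(track)) + bytes(track))


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------


class _Reader:
    def __init__(self, data: bytes):
        self.data = data
        self.pos = 0

    def read(self, n: int) -> bytes:
        if self.pos + n > len(self.data):
            raise SmfFormatError("unexpected end of file")
        out = self.data[self.pos : self.pos + n]
        self.pos += n
        return out

    def byte(self) -> int:
        return self.read(1)[0]

    def varlen(self) -> int:
        value = 0
        for _ in range(4):
            b = self.byte()
            value = (value << 7) | (b & 0x7F)
            if not b & 0x80:
                return value
        raise SmfFormatError("variable-length quantity longer than 4 bytes")


def _parse_track(reader: _Reader, length: int):
    """Yield (abs_tick, kind, data) with kind in {'on', 'off', 'tempo'}."""
    end = reader.pos + length
    tick = 0
    status = None
    while reader.pos < end:
        tick += reader.varlen()
        first = reader.byte()
        if first < 0x80:  # running status
            if status is None:
                raise SmfFormatError("data byte with no running status")
            reader.pos -= 1
        else:
            status = first
        if status == 0xFF:
            meta_type = reader.byte()
            meta_len = reader.varlen()
            payload = reader.read(meta_len)
            if meta_type == 0x51:
                if meta_len != 3:
                    raise SmfFormatError("malformed tempo event")
                yield tick, "tempo", int.from_bytes(payload, "big")
            elif meta_type == 0x2F:
                yield tick, "eot", None
                reader.pos = end
                return
            status = None  # meta/sysex clear running status
        elif status in (0xF0, 0xF7):
            reader.read(reader.varlen())
            status = None
        else:
            kind = status & 0xF0
            if kind in (0x80, 0x90, 0xA0, 0xB0, 0xE0):
                d1, d2 = reader.byte(), reader.byte()
                if kind == 0x90:
                    yield tick, ("off" if d2 == 0 else "on"), (d1, d2)
                elif kind == 0x80:
                    yield tick, "off", (d1, d2)
            elif kind in (0xC0, 0xD0):
                reader.byte()
            else:
                raise SmfFormatError(f"unexpected status byte 0x{status:02x}")
    reader.pos = end


def _ticks_to_seconds(ticks, tempo_map, division):
    """Piecewise-linear tick->second conversion under a sorted tempo map."""
    out = []
    for target in ticks:
        seconds = 0.0
        prev_tick, tempo = 0, DEFAULT_TEMPO
        for t_tick, t_tempo in tempo_map:
            if t_tick >= target:
                break
            seconds += (t_tick - prev_tick) * tempo / (division * 1_000_000)
            prev_tick, tempo = t_tick, t_tempo
        seconds += (target - prev_tick) * tempo / (division * 1_000_000)
        out.append(seconds)
    return out


def read_smf(path: str | Path) -> list[NoteEvent]:
    """Parse an SMF into note events with onset/offset in seconds.

    A note-on left open at end of track is closed there with a warning.
    Re-struck pitches are matched first-on/first-off.
    """
    data = Path(path).read_bytes()
    reader = _Reader(data)
    if reader.read(4) != b"MThd":
        raise SmfFormatError("missing MThd header")
    header_len, fmt, ntracks, division = struct.unpack(">IHHH", reader.read(10))
    if header_len != 6:
        reader.read(header_len - 6)
    if fmt not in (0, 1):
        raise SmfFormatError(f"unsupported SMF format {fmt}")
    if division & 0x8000:
        raise SmfFormatError("SMPTE time division is not supported")

    events = []
    for _ in range(ntracks):
        chunk = reader.read(4)
        length = struct.unpack(">I", reader.read(4))[0]
        if chunk != b"MTrk":  # alien chunk: skip per SMF spec
            reader.read(length)
            continue
        events.extend(_parse_track(reader, length))
    events.sort(key=lambda e: e[0])

    tempo_map = [(t, v) for t, v, in ((t, d) for t, k, d in events if k == "tempo")]
    end_tick = max((t for t, _, _ in events), default=0)

    open_notes: dict[int, list[tuple[int, int]]] = {}
    raw_notes: list[tuple[int, int, int, int]] = []  # on_tick, off_tick, pitch, vel
    for tick, kind, payload in events:
        if kind == "on":
            pitch, vel = payload
            open_notes.setdefault(pitch, []).append((tick, vel))
        elif kind == "off":
            pitch, _ = payload
            stack = open_notes.get(pitch)
            if stack:
                on_tick, vel = stack.pop(0)
                raw_notes.append((on_tick, max(tick, on_tick + 1), pitch, vel))
    for pitch, stack in open_notes.items():
        for on_tick, vel in stack:
            log.warning("note-on pitch %d at tick %d has no note-off; closing at end of track", pitch, on_tick)
            raw_notes.append((on_tick, max(end_tick, on_tick + 1), pitch, vel))

    if not raw_notes:
        raise EmptyImprovisationError(f"{path} contains no notes")

    raw_notes.sort()
    onsets = _ticks_to_seconds([n[0] for n in raw_notes], tempo_map, division)
    offsets = _ticks_to_seconds([n[1] for n in raw_notes], tempo_map, division)
    return [
        NoteEvent(onset=on, offset=off, pitch=p, velocity=v)
        for (_, _, p, v), on, off in zip(raw_notes, onsets, offsets)
    ]
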