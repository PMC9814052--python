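"""Software model of the receiver <-> host buffer protocol.

The host grants free one-module buffer slots by posting work requests (WRs);
the receiver claims one slot per new (module, frame) pair, writes packet
payloads into it and reports a work completion (WC) when the frame is
finished.  A frame N is finalized when any packet of frame N+2 for the same
module is delivered (tolerating bounded packet reordering) or when the
acquisition ends.  When no WR is available the receiver stalls: packets
accumulate in a bounded internal buffer (default 4 MiB) and are dropped once
it would overflow.  Every ingested packet is classified exactly once -
delivered, dropped (overflow), late (frame already finalized), discarded
(idle) or still buffered - so conservation identities hold at all times.
"""

from __future__ import annotations

import json
from collections import deque
from dataclasses import dataclass

import numpy as np

from .detector_model import (PACKET_BYTES, PACKETS_PER_MODULE, DetectorPacket)

DEFAULT_BUFFER_CAPACITY = 4 * 1024 * 1024  # stall buffer, ~4 MB (configurable)


class ProtocolError(RuntimeError):
    """Violation of the WR/WC queue protocol (e.g. duplicate slot post)."""


@dataclass(frozen=True)
class WorkRequest:
    location_number: int
    address: int = 0


@dataclass(frozen=True)
class WorkCompletion:
    location_number: int
    all_packets_received: bool
    frame_number: int
    module_number: int
    timestamp: int


@dataclass
class _OpenFrame:
    slot: int
    bitmap: np.ndarray  # bool, packets_per_frame
    data: bytearray
    timestamp: int


@dataclass
class Counters:
    packets_in: int = 0
    packets_delivered: int = 0
    packets_dropped: int = 0
    packets_late: int = 0
    packets_discarded_idle: int = 0
    frames_started: int = 0
    frames_complete: int = 0
    frames_incomplete: int = 0

    def as_dict(self) -> dict:
        return dict(self.__dict__)


class FrameReceiver:
    """Flow-controlled frame assembler with WR/WC semantics."""

    def __init__(self,
                 packets_per_frame: int = PACKETS_PER_MODULE,
                 payload_bytes: int = PACKET_BYTES,
                 buffer_capacity: int = DEFAULT_BUFFER_CAPACITY) -> None:
        self.packets_per_frame = packets_per_frame
        self.payload_bytes = payload_bytes
        self.buffer_capacity = buffer_capacity
        self.wr_queue: deque[WorkRequest] = deque()
        self._outstanding: set[int] = set()
        self._open: dict[tuple[int, int], _OpenFrame] = {}
        self._highest_finalized: dict[int, int] = {}
        self._internal: deque[DetectorPacket] = deque()
        self._occupancy = 0
        self.receiving = True
        self.counters = Counters()
        self._slot_data: dict[int, _OpenFrame] = {}

    # -- WR side ----------------------------------------------------------
    def post_work_request(self, slot: int, address: int = 0) -> list[WorkCompletion]:
        """Grant a free buffer slot; drains any stalled packets afterwards."""
        if slot in self._outstanding:
            raise ProtocolError(f"slot {slot} already outstanding")
        self._outstanding.add(slot)
        self.wr_queue.append(WorkRequest(slot, address))
        return self._drain()

    @property
    def wr_depth(self) -> int:
        return len(self.wr_queue)

    @property
    def buffer_occupancy(self) -> int:
        return self._occupancy

    @property
    def packets_buffered(self) -> int:
        return len(self._internal)

    # -- packet side ------------------------------------------------------
    def ingest_packet(self, packet: DetectorPacket) -> list[WorkCompletion]:
        """Accept one packet; returns any WCs triggered by it."""
        self.counters.packets_in += 1
        if not self.receiving:
            self.counters.packets_discarded_idle += 1
            return []
        if len(packet.payload) != self.payload_bytes:
            raise ProtocolError("unexpected payload size")
        if self._occupancy + self.payload_bytes > self.buffer_capacity:
            self.counters.packets_dropped += 1
            return []
        self._internal.append(packet)
        self._occupancy += self.payload_bytes
        return self._drain()

    def _drain(self) -> list[WorkCompletion]:
        """Deliver buffered packets in FIFO order while slots are available."""
        wcs: list[WorkCompletion] = []
        if not self.receiving:
            # idle: leftover stalled packets are not delivered any more
            return wcs
        while self._internal:
            pkt = self._internal[0]
            key = (pkt.module_id, pkt.frame_number)
            if key not in self._open:
                late = pkt.frame_number <= self._highest_finalized.get(
                    pkt.module_id, 0)
                if not late and not self.wr_queue:
                    break  # stall: wait for a WR
            self._internal.popleft()
            self._occupancy -= self.payload_bytes
            wcs.extend(self._deliver(pkt))
        return wcs

    def _deliver(self, pkt: DetectorPacket) -> list[WorkCompletion]:
        wcs: list[WorkCompletion] = []
        module, frame = pkt.module_id, pkt.frame_number
        # N+2 rule: delivery of any packet of frame F finalizes all open
        # frames <= F-2 of the same module (frame-number skips implicitly
        # finalize everything older as well)
        for key in sorted(k for k in self._open
                          if k[0] == module and k[1] <= frame - 2):
            wcs.append(self._finalize(key))
        if frame <= self._highest_finalized.get(module, 0):
            self.counters.packets_late += 1
            return wcs
        key = (module, frame)
        if key not in self._open:
            wr = self.wr_queue.popleft()
            self._open[key] = _OpenFrame(
                slot=wr.location_number,
                bitmap=np.zeros(self.packets_per_frame, dtype=bool),
                data=bytearray(self.packets_per_frame * self.payload_bytes),
                timestamp=pkt.timestamp)
            self.counters.frames_started += 1
        entry = self._open[key]
        if not 0 <= pkt.packet_index < self.packets_per_frame:
            raise ProtocolError("packet index out of range")
        entry.bitmap[pkt.packet_index] = True
        off = pkt.packet_index * self.payload_bytes
        entry.data[off:off + self.payload_bytes] = pkt.payload
        self.counters.packets_delivered += 1
        return wcs

    def _finalize(self, key: tuple[int, int]) -> WorkCompletion:
        module, frame = key
        entry = self._open.pop(key)
        complete = bool(entry.bitmap.all())
        if complete:
            self.counters.frames_complete += 1
        else:
            self.counters.frames_incomplete += 1
        self._highest_finalized[module] = max(
            self._highest_finalized.get(module, 0), frame)
        self._outstanding.discard(entry.slot)
        self._slot_data[entry.slot] = entry
        return WorkCompletion(entry.slot, complete, frame, module,
                              entry.timestamp)

    # -- acquisition control ----------------------------------------------
    def end_acquisition(self) -> list[WorkCompletion]:
        """Finalize every open frame and switch to the idle state."""
        wcs = self._drain()
        for key in sorted(self._open):
            wcs.append(self._finalize(key))
        self.receiving = False
        return wcs

    # -- host access to completed slots -----------------------------------
    def slot_data(self, slot: int) -> bytes:
        """Payload bytes of a completed slot (missing packets are zero)."""
        return bytes(self._slot_data[slot].data)

    def slot_bitmap(self, slot: int) -> np.ndarray:
        return self._slot_data[slot].bitmap.copy()

    def release_slot(self, slot: int) -> None:
        """Forget a completed slot's contents (before re-posting the WR)."""
        self._slot_data.pop(slot, None)

    # -- accounting --------------------------------------------------------
    def conservation_ok(self) -> bool:
        c = self.counters
        return c.packets_in == (c.packets_delivered + c.packets_dropped +
                                c.packets_late + c.packets_discarded_idle +
                                len(self._internal))

    def status_record(self) -> dict:
        """Structured status snapshot (the gRPC-status analogue)."""
        rec = self.counters.as_dict()
        rec.update(
            wr_depth=self.wr_depth,
            packets_buffered=self.packets_buffered,
            buffer_occupancy_bytes=self._occupancy,
            buffer_capacity_bytes=self.buffer_capacity,
            receiving=self.receiving,
            open_frames=len(self._open),
            conservation_ok=self.conservation_ok(),
        )
        return rec

    def status_json(self) -> str:
        return json.dumps(self.status_record(), sort_keys=True)
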