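"""Bitshuffle pre-filter and chunk compression codecs.

Three codecs are offered, all operating on bitshuffled 16-bit image buffers
with the filter's fixed block size of 4096 pixels x 16 bits (= one 8 kB
detector packet):

* ``bslz4``      - per-block LZ4, framed after the bitshuffle/HDF5 filter
  convention (8-byte big-endian total size, 4-byte big-endian block size,
  then size-prefixed LZ4 blocks);
* ``bszstd``     - the same framing with one Zstandard frame per block;
* ``bsrle_zstd`` - the custom run-length encoder: maximal runs of 0x00 or
  0xFF bytes become Zstandard RLE blocks, everything else raw (literal)
  blocks, emitted as a single standard-compliant Zstandard frame that any
  reference decoder can decompress.  No entropy coding is performed.

Bitshuffle transposes each block's (elements x bits) matrix so that equal
significance bits are stored together; diffraction images, whose pixel
values occupy few low bits, then consist mostly of long zero runs.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass

import numpy as np
from numcodecs import LZ4 as _LZ4Codec
from numcodecs import Zstd as _ZstdCodec

BLOCK_PIXELS = 4096
ELEM_BYTES = 2
BLOCK_BYTES = BLOCK_PIXELS * ELEM_BYTES  # 8192, one detector packet

CODECS = ("bslz4", "bszstd", "bsrle_zstd")

ZSTD_MAGIC = 0xFD2FB528
#: Zstandard Block_Maximum_Size for large windows
_ZSTD_MAX_BLOCK = 128 * 1024
#: minimum run length (bytes) worth an RLE block; shorter runs fold into
#: neighbouring raw blocks since the 3-byte block header erases the benefit
MIN_RLE_RUN = 64

_lz4 = _LZ4Codec()
_zstd = _ZstdCodec(level=3)


class IntegrityError(RuntimeError):
    """Corrupt chunk payload; the message names the failing stage."""


# ---------------------------------------------------------------------------
# bitshuffle
# ---------------------------------------------------------------------------

def _shuffle_blocks(elems: np.ndarray) -> np.ndarray:
    """Bit-plane transpose of (n_blocks, n_pix) uint16; n_pix % 8 == 0.

    Output plane ``j`` holds bit ``j`` (LSB first) of every element, packed
    little-endian eight elements per byte.
    """
    bits = ((elems[..., None] >> np.arange(16, dtype=np.uint16)) & 1)
    planes = bits.astype(np.uint8).transpose(0, 2, 1)
    packed = np.packbits(planes, axis=-1, bitorder="little")
    return packed.reshape(elems.shape[0], -1)


def _unshuffle_blocks(data: np.ndarray, n_pix: int) -> np.ndarray:
    """Inverse of :func:`_shuffle_blocks`; data is (n_blocks, 2*n_pix) uint8."""
    planes = data.reshape(data.shape[0], 16, n_pix // 8)
    bits = np.unpackbits(planes, axis=-1, bitorder="little")
    weights = (np.uint16(1) << np.arange(16, dtype=np.uint16))
    return (bits.transpose(0, 2, 1).astype(np.uint16) * weights).sum(
        axis=-1, dtype=np.uint16)


def bitshuffle_block(block) -> bytes:
    """Shuffle one block of 16-bit elements (up to 4096 pixels).

    The element count must be a multiple of 8 so that every bit plane packs
    into whole bytes.
    """
    elems = np.frombuffer(bytes(block), dtype="<u2") if not isinstance(
        block, np.ndarray) else np.ascontiguousarray(block, dtype=np.uint16)
    if elems.size == 0 or elems.size % 8:
        raise ValueError("block length must be a positive multiple of 8 elements")
    if elems.size > BLOCK_PIXELS:
        raise ValueError(f"block exceeds {BLOCK_PIXELS} pixels")
    return _shuffle_blocks(elems.reshape(1, -1)).tobytes()


def bitunshuffle_block(data: bytes, n_pix: int) -> bytes:
    arr = np.frombuffer(data, dtype=np.uint8).reshape(1, -1)
    return _unshuffle_blocks(arr, n_pix).astype("<u2").tobytes()


def bitshuffle_buffer(buf: bytes) -> bytes:
    """Blockwise bitshuffle of an arbitrary buffer.

    Full 4096-pixel blocks are shuffled; trailing bytes that do not fill a
    whole block are copied verbatim (they are a negligible fraction of an
    image chunk and keep the transform trivially invertible).
    """
    n_full = len(buf) // BLOCK_BYTES
    out = bytearray(len(buf))
    if n_full:
        elems = np.frombuffer(buf[:n_full * BLOCK_BYTES], dtype="<u2")
        out[:n_full * BLOCK_BYTES] = _shuffle_blocks(
            elems.reshape(n_full, BLOCK_PIXELS)).tobytes()
    out[n_full * BLOCK_BYTES:] = buf[n_full * BLOCK_BYTES:]
    return bytes(out)


def bitunshuffle_buffer(buf: bytes) -> bytes:
    n_full = len(buf) // BLOCK_BYTES
    out = bytearray(len(buf))
    if n_full:
        data = np.frombuffer(buf[:n_full * BLOCK_BYTES],
                             dtype=np.uint8).reshape(n_full, BLOCK_BYTES)
        out[:n_full * BLOCK_BYTES] = _unshuffle_blocks(
            data, BLOCK_PIXELS).astype("<u2").tobytes()
    out[n_full * BLOCK_BYTES:] = buf[n_full * BLOCK_BYTES:]
    return bytes(out)


# ---------------------------------------------------------------------------
# custom Zstandard-compliant RLE encoder / decoder
# ---------------------------------------------------------------------------

def _zstd_frame_header(content_size: int) -> bytes:
    # single-segment frame, 8-byte content size, no dictionary, no checksum
    return struct.pack("<IBQ", ZSTD_MAGIC, 0xE0, content_size)


def _block_header(block_type: int, size: int, last: bool) -> bytes:
    value = (1 if last else 0) | (block_type << 1) | (size << 3)
    return struct.pack("<I", value)[:3]


def rle_zstd_encode(buffer: bytes, min_run: int = MIN_RLE_RUN) -> bytes:
    """Encode a buffer as one Zstandard frame of RLE and raw blocks only.

    Maximal runs of 0x00 or 0xFF at least ``min_run`` bytes long become RLE
    blocks; everything else is emitted as raw (uncompressed) blocks.  The
    output is decodable by any conformant Zstandard decoder; incompressible
    input grows only by the frame and block headers.
    """
    buffer = bytes(buffer)
    if not buffer:
        raise ValueError("cannot encode an empty buffer")
    a = np.frombuffer(buffer, dtype=np.uint8)
    change = np.nonzero(np.diff(a))[0] + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [a.size]])
    vals = a[starts]
    lens = ends - starts
    is_rle = (lens >= min_run) & ((vals == 0) | (vals == 255))
    rle_idx = np.nonzero(is_rle)[0]

    # (type, start, length, value) spans covering the buffer
    spans: list[tuple[int, int, int, int]] = []
    pos = 0
    for i in rle_idx:
        s, e = int(starts[i]), int(ends[i])
        if s > pos:
            spans.append((0, pos, s - pos, 0))
        spans.append((1, s, e - s, int(vals[i])))
        pos = e
    if pos < a.size:
        spans.append((0, pos, a.size - pos, 0))

    pieces = [_zstd_frame_header(len(buffer))]
    blocks: list[tuple[int, int, int, int]] = []  # type, start, size, value
    for kind, start, length, value in spans:
        while length > 0:
            size = min(length, _ZSTD_MAX_BLOCK)
            blocks.append((kind, start, size, value))
            start += size
            length -= size
    for i, (kind, start, size, value) in enumerate(blocks):
        last = i == len(blocks) - 1
        pieces.append(_block_header(kind, size, last))
        if kind == 1:
            pieces.append(bytes([value]))
        else:
            pieces.append(buffer[start:start + size])
    return b"".join(pieces)


def rle_zstd_decode(frame: bytes) -> bytes:
    """Minimal decoder for the RLE/raw-block subset of the Zstandard format.

    Understands any frame built exclusively from raw and RLE blocks (with or
    without the single-segment flag); entropy-coded blocks are rejected.
    """
    view = memoryview(frame)
    if len(view) < 6:
        raise IntegrityError("zstd frame: truncated header")
    (magic,) = struct.unpack_from("<I", view, 0)
    if magic != ZSTD_MAGIC:
        raise IntegrityError("zstd frame: bad magic")
    fhd = view[4]
    pos = 5
    single_segment = bool(fhd & 0x20)
    if fhd & 0x03:
        raise IntegrityError("zstd frame: dictionaries not supported")
    if not single_segment:
        pos += 1  # window descriptor
    fcs_flag = fhd >> 6
    fcs_bytes = {0: 1 if single_segment else 0, 1: 2, 2: 4, 3: 8}[fcs_flag]
    content_size = None
    if fcs_bytes:
        raw = bytes(view[pos:pos + fcs_bytes])
        content_size = int.from_bytes(raw, "little")
        if fcs_flag == 1:
            content_size += 256
        pos += fcs_bytes
    out = bytearray()
    while True:
        if pos + 3 > len(view):
            raise IntegrityError("zstd frame: truncated block header")
        header = int.from_bytes(view[pos:pos + 3], "little")
        pos += 3
        last = header & 1
        btype = (header >> 1) & 3
        size = header >> 3
        if btype == 0:  # raw
            out += view[pos:pos + size]
            pos += size
        elif btype == 1:  # RLE
            out += bytes([view[pos]]) * size
            pos += 1
        else:
            raise IntegrityError("zstd frame: entropy-coded block "
                                 "unsupported by the RLE decoder")
        if last:
            break
    if content_size is not None and len(out) != content_size:
        raise IntegrityError("zstd frame: content size mismatch")
    return bytes(out)


# ---------------------------------------------------------------------------
# chunk framing
# ---------------------------------------------------------------------------

_CHUNK_HEADER = struct.Struct(">QI")  # total uncompressed size, block size


@dataclass(frozen=True)
class CompressedChunk:
    """One compressed image chunk plus the metadata needed to restore it."""

    codec: str
    uncompressed_size: int
    block_size: int
    payload: bytes

    @property
    def compressed_size(self) -> int:
        return len(self.payload)

    @property
    def compression_factor(self) -> float:
        return self.uncompressed_size / max(1, self.compressed_size)


def _lz4_block_encode(block: bytes) -> bytes:
    return bytes(_lz4.encode(block))[4:]  # strip numcodecs' LE size prefix


def _lz4_block_decode(data: bytes, expected: int) -> bytes:
    try:
        return bytes(_lz4.decode(struct.pack("<I", expected) + bytes(data)))
    except Exception as exc:
        raise IntegrityError(f"lz4 block decode failed: {exc}") from exc


def _zstd_block_encode(block: bytes) -> bytes:
    return bytes(_zstd.encode(block))


def _zstd_block_decode(data: bytes, expected: int) -> bytes:
    try:
        out = bytes(_zstd.decode(bytes(data)))
    except Exception as exc:
        raise IntegrityError(f"zstd block decode failed: {exc}") from exc
    if len(out) != expected:
        raise IntegrityError("zstd block decode: size mismatch")
    return out


def compress_chunk(buffer, codec: str = "bszstd") -> CompressedChunk:
    """Bitshuffle an image buffer blockwise, then apply the chosen codec."""
    if codec not in CODECS:
        raise ValueError(f"codec must be one of {CODECS}")
    if isinstance(buffer, np.ndarray):
        buffer = np.ascontiguousarray(buffer).tobytes()
    buffer = bytes(buffer)
    shuffled = bitshuffle_buffer(buffer)
    header = _CHUNK_HEADER.pack(len(buffer), BLOCK_BYTES)
    if codec == "bsrle_zstd":
        payload = header + rle_zstd_encode(shuffled)
    else:
        encode = _lz4_block_encode if codec == "bslz4" else _zstd_block_encode
        parts = [header]
        for off in range(0, len(shuffled), BLOCK_BYTES):
            block = shuffled[off:off + BLOCK_BYTES]
            comp = encode(block)
            parts.append(struct.pack(">I", len(comp)))
            parts.append(comp)
        payload = b"".join(parts)
    return CompressedChunk(codec, len(buffer), BLOCK_BYTES, payload)


def decompress_chunk(chunk: CompressedChunk) -> bytes:
    """Invert :func:`compress_chunk`; raises IntegrityError on corruption."""
    view = memoryview(chunk.payload)
    if len(view) < _CHUNK_HEADER.size:
        raise IntegrityError("chunk framing: truncated header")
    total, block_size = _CHUNK_HEADER.unpack_from(view, 0)
    if total != chunk.uncompressed_size:
        raise IntegrityError("chunk framing: size header mismatch")
    body = view[_CHUNK_HEADER.size:]
    if chunk.codec == "bsrle_zstd":
        shuffled = rle_zstd_decode(bytes(body))
    elif chunk.codec in ("bslz4", "bszstd"):
        decode = (_lz4_block_decode if chunk.codec == "bslz4"
                  else _zstd_block_decode)
        out = bytearray()
        pos = 0
        remaining = total
        while remaining > 0:
            if pos + 4 > len(body):
                raise IntegrityError("chunk framing: truncated block")
            (clen,) = struct.unpack_from(">I", body, pos)
            pos += 4
            expected = min(block_size, remaining)
            out += decode(body[pos:pos + clen], expected)
            pos += clen
            remaining -= expected
        shuffled = bytes(out)
    else:
        raise IntegrityError(f"unknown codec {chunk.codec!r}")
    if len(shuffled) != total:
        raise IntegrityError("decompressed size mismatch after byte codec")
    return bitunshuffle_buffer(shuffled)
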