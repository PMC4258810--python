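"""Minimal uncompressed RIFF AVI reader/writer for 8-bit grayscale video.

Only the plain-DIB ('00db', biCompression=0) payload is handled: 8-bit
palettized frames are mapped through their palette, 24/32-bit frames are
converted to luminance (ITU-R BT.601). This is enough to round-trip the
sequences written by the phantom generator and to ingest uncompressed
exports of tonometer recordings; compressed codecs are rejected.
"""

from __future__ import annotations

import struct

import numpy as np

from .errors import UnsupportedFormatError

_AVIH = struct.Struct("<10I")  # first 10 dwords of the main header we use
_BMIH = struct.Struct("<IiiHHIIiiII")


def _gray_palette() -> bytes:
    # 256 BGR0 entries, identity gray ramp
    out = bytearray()
    for v in range(256):
        out += bytes((v, v, v, 0))
    return bytes(out)


def write_avi(path, frames: np.ndarray, frame_interval_us: float = 230.0) -> None:
    """Write an (I, M, N) uint8 cube as an uncompressed 8-bit palettized AVI."""
    frames = np.asarray(frames, dtype=np.uint8)
    if frames.ndim != 3:
        raise ValueError("frames must be a 3-D (frame, row, column) array")
    n_frames, height, width = frames.shape
    stride = (width + 3) & ~3
    frame_bytes = stride * height
    usec = max(1, int(round(frame_interval_us)))

    avih = _AVIH.pack(usec, frame_bytes * 10 ** 6 // usec, 0, 0x10,  # HASINDEX
                      n_frames, 0, 1, frame_bytes, width, height) + b"\0" * 16
    strh = (b"vids" + b"DIB " + struct.pack("<IHHIIIIIIIi", 0, 0, 0, 0,
                                            usec, 10 ** 6, 0, n_frames,
                                            frame_bytes, 0xFFFFFFFF, 0)
            + struct.pack("<4h", 0, 0, width, height))
    strf = _BMIH.pack(40, width, height, 1, 8, 0, frame_bytes,
                      0, 0, 256, 0) + _gray_palette()

    def chunk(fourcc: bytes, payload: bytes) -> bytes:
        pad = b"\0" if len(payload) & 1 else b""
        return fourcc + struct.pack("<I", len(payload)) + payload + pad

    def list_chunk(kind: bytes, payload: bytes) -> bytes:
        return chunk(b"LIST", kind + payload)

    hdrl = list_chunk(b"hdrl", chunk(b"avih", avih)
                      + list_chunk(b"strl", chunk(b"strh", strh) + chunk(b"strf", strf)))

    movi_frames = []
    for i in range(n_frames):
        dib = np.zeros((height, stride), dtype=np.uint8)
        dib[:, :width] = frames[i, ::-1, :]  # DIB rows are bottom-up
        movi_frames.append(chunk(b"00db", dib.tobytes()))
    movi = list_chunk(b"movi", b"".join(movi_frames))

    idx, offset = [], 4  # offsets relative to the start of 'movi' list data
    for fr in movi_frames:
        idx.append(struct.pack("<4sIII", b"00db", 0x10, offset, frame_bytes))
        offset += len(fr)
    idx1 = chunk(b"idx1", b"".join(idx))

    body = b"AVI " + hdrl + movi + idx1
    with open(path, "wb") as fh:
        fh.write(b"RIFF" + struct.pack("<I", len(body)) + body)


def _iter_chunks(buf: bytes, start: int, end: int):
    pos = start
    while pos + 8 <= end:
        fourcc = buf[pos:pos + 4]
        (size,) = struct.unpack_from("<I", buf, pos + 4)
        yield fourcc, pos + 8, size
        pos += 8 + size + (size & 1)


def read_avi(path) -> tuple[np.ndarray, float]:
    """Read an uncompressed AVI into an (I, M, N) uint8 cube.

    Returns the cube and the frame interval in microseconds as declared by
    the AVI main header.
    """
    with open(path, "rb") as fh:
        buf = fh.read()
    if len(buf) < 12 or buf[:4] != b"RIFF" or buf[8:12] != b"AVI ":
        raise UnsupportedFormatError(f"{path}: not a RIFF AVI file")

    frame_interval_us = 230.0
    width = height = bitcount = None
    compression = 0
    palette = None
    raw_frames: list[bytes] = []

    def walk(start: int, end: int) -> None:
        nonlocal frame_interval_us, width, height, bitcount, compression, palette
        for fourcc, data_off, size in _iter_chunks(buf, start, end):
            data_end = data_off + size
            if fourcc == b"LIST":
                walk(data_off + 4, data_end)
            elif fourcc == b"avih":
                fields = _AVIH.unpack_from(buf, data_off)
                if fields[0] > 0:
                    frame_interval_us = float(fields[0])
            elif fourcc == b"strf" and width is None:
                (_, w, h, _, bc, comp, _, _, _, clr_used, _) = _BMIH.unpack_from(buf, data_off)
                width, height, bitcount, compression = w, abs(h), bc, comp
                if bc == 8:
                    n_colors = clr_used or 256
                    palette = np.frombuffer(
                        buf[data_off + 40:data_off + 40 + 4 * n_colors],
                        dtype=np.uint8).reshape(-1, 4)
            elif fourcc in (b"00db", b"00dc") and size > 0:
                raw_frames.append(buf[data_off:data_end])

    walk(12, len(buf))

    if width is None or not raw_frames:
        raise UnsupportedFormatError(f"{path}: no video stream found in AVI")
    if compression != 0:
        raise UnsupportedFormatError(
            f"{path}: compressed AVI (biCompression={compression:#x}) is not "
            "supported; re-export as uncompressed/raw AVI")

    if bitcount == 8:
        stride = (width + 3) & ~3
        # collapse the palette to gray via BT.601 luminance of its entries
        pal = palette if palette is not None else np.tile(
            np.arange(256, dtype=np.uint8)[:, None], (1, 4))
        lut = (0.114 * pal[:, 0] + 0.587 * pal[:, 1] + 0.299 * pal[:, 2])
        lut = np.clip(np.round(lut), 0, 255).astype(np.uint8)
        if len(lut) < 256:
            lut = np.pad(lut, (0, 256 - len(lut)))
        frames = [
            lut[np.frombuffer(fr, dtype=np.uint8)[:stride * height]
                .reshape(height, stride)[::-1, :width]]
            for fr in raw_frames
        ]
    elif bitcount in (24, 32):
        nch = bitcount // 8
        stride = (width * nch + 3) & ~3
        frames = []
        for fr in raw_frames:
            rows = np.frombuffer(fr, dtype=np.uint8)[:stride * height]
            rows = rows.reshape(height, stride)[::-1, :width * nch]
            bgr = rows.reshape(height, width, nch)[..., :3].astype(np.float64)
            lum = 0.114 * bgr[..., 0] + 0.587 * bgr[..., 1] + 0.299 * bgr[..., 2]
            frames.append(np.clip(np.round(lum), 0, 255).astype(np.uint8))
    else:
        raise UnsupportedFormatError(
            f"{path}: unsupported AVI bit depth {bitcount}")

    return np.stack(frames), frame_interval_us
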