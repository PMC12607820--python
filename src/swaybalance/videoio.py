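"""Uncompressed AVI container I/O for grayscale video.

Writes and reads RIFF/AVI files carrying raw 8-bit device-independent
bitmap ('DIB ') frames with a grayscale palette.  This is the plainest
legal AVI layout: every mainstream player and decoder opens it, no codec
is involved, and frame data round-trips exactly (up to 8-bit
quantization of the [0, 1] intensities).

Layout written::

    RIFF('AVI '
      LIST('hdrl' avih LIST('strl' strh strf))
      LIST('movi' '00db' ...)
      idx1)

DIB frames are stored bottom-up with rows padded to 4 bytes, per the
BMP convention.  The reader accepts both bottom-up (positive biHeight)
and top-down (negative) uncompressed 8-bit streams.
"""

from __future__ import annotations

import struct
from fractions import Fraction
from pathlib import Path

import numpy as np

__all__ = ["write_avi", "read_avi"]

_AVIF_HASINDEX = 0x00000010
_AVIIF_KEYFRAME = 0x00000010


def _chunk(fourcc: bytes, payload: bytes) -> bytes:
    data = fourcc + struct.pack("<I", len(payload)) + payload
    if len(payload) % 2:  # RIFF chunks are word-aligned
        data += b"\x00"
    return data


def _list(list_type: bytes, payload: bytes) -> bytes:
    return _chunk(b"LIST", list_type + payload)


def _dib_rows(frame_u8: np.ndarray) -> bytes:
    """Bottom-up, 4-byte padded rows of one 8-bit frame."""
    h, w = frame_u8.shape
    stride = (w + 3) & ~3
    padded = np.zeros((h, stride), dtype=np.uint8)
    padded[:, :w] = frame_u8
    return padded[::-1].tobytes()


def write_avi(path: str | Path, frames: np.ndarray, fps: float) -> None:
    """Write frames (T, H, W) with intensities on [0, 1] as uncompressed AVI.

    Intensities are quantized to 8 bits by rounding ``value * 255``.
    """
    frames = np.asarray(frames)
    if frames.ndim != 3 or frames.shape[0] < 1:
        raise ValueError("frames must be a non-empty (T, H, W) array")
    if not fps > 0:
        raise ValueError(f"fps must be positive, got {fps}")
    n, h, w = frames.shape
    u8 = np.clip(np.round(frames * 255.0), 0, 255).astype(np.uint8)

    rate = Fraction(fps).limit_denominator(100_000)
    dw_scale, dw_rate = rate.denominator, rate.numerator

    stride = (w + 3) & ~3
    frame_bytes = stride * h

    avih = _chunk(b"avih", struct.pack(
        "<14I",
        round(1_000_000 / fps),  # dwMicroSecPerFrame
        frame_bytes * max(1, round(fps)),  # dwMaxBytesPerSec
        0,  # dwPaddingGranularity
        _AVIF_HASINDEX,
        n,  # dwTotalFrames
        0,  # dwInitialFrames
        1,  # dwStreams
        frame_bytes,  # dwSuggestedBufferSize
        w, h, 0, 0, 0, 0,
    ))
    strh = _chunk(b"strh", struct.pack(
        "<4s4sIHHIIIIIIIi4H",
        b"vids", b"DIB ",
        0, 0, 0, 0,
        dw_scale, dw_rate,
        0, n, frame_bytes, 0xFFFFFFFF, 0,
        0, 0, w, h,
    ))
    # BITMAPINFOHEADER + 256-entry grayscale palette
    bmih = struct.pack("<IiiHHIIiiII", 40, w, h, 1, 8, 0, frame_bytes, 0, 0, 256, 0)
    palette = b"".join(struct.pack("<BBBB", i, i, i, 0) for i in range(256))
    strf = _chunk(b"strf", bmih + palette)

    hdrl = _list(b"hdrl", avih + _list(b"strl", strh + strf))

    movi_payload = b"movi"
    index_entries = []
    for i in range(n):
        offset = len(movi_payload)  # offset of chunk fourcc relative to 'movi'
        movi_payload += _chunk(b"00db", _dib_rows(u8[i]))
        index_entries.append(struct.pack(
            "<4sIII", b"00db", _AVIIF_KEYFRAME, offset, frame_bytes
        ))
    movi = _chunk(b"LIST", movi_payload)
    idx1 = _chunk(b"idx1", b"".join(index_entries))

    riff_payload = b"AVI " + hdrl + movi + idx1
    Path(path).write_bytes(
        b"RIFF" + struct.pack("<I", len(riff_payload)) + riff_payload
    )


def _iter_chunks(buf: bytes, start: int, end: int):
    pos = start
    while pos + 8 <= end:
        fourcc = buf[pos:pos + 4]
        (size,) = struct.unpack_from("<I", buf, pos + 4)
        yield fourcc, pos + 8, size
        pos += 8 + size + (size % 2)


def read_avi(path: str | Path) -> tuple[np.ndarray, float]:
    """Read an uncompressed 8-bit AVI; returns (frames (T,H,W) on [0,1], fps).

    Raises ``OSError`` for files that are not RIFF/AVI and ``ValueError``
    for compressed or non-8-bit streams this reader does not handle.
    """
    buf = Path(path).read_bytes()
    if len(buf) < 12 or buf[:4] != b"RIFF" or buf[8:12] != b"AVI ":
        raise OSError(f"not a RIFF/AVI file: {path}")

    width = height = None
    bitcount = compression = None
    fps = None
    frame_chunks: list[tuple[int, int]] = []

    def walk(start: int, end: int) -> None:
        nonlocal width, height, bitcount, compression, fps
        for fourcc, off, size in _iter_chunks(buf, start, end):
            if fourcc == b"LIST":
                walk(off + 4, off + size)
            elif fourcc == b"strh":
                fcc_type, _handler = struct.unpack_from("<4s4s", buf, off)
                if fcc_type == b"vids":
                    scale, rate = struct.unpack_from("<II", buf, off + 20)
                    if scale and rate:
                        fps = rate / scale
            elif fourcc == b"strf" and width is None:
                (_, w, h, _, bc, comp) = struct.unpack_from("<IiiHHI", buf, off)
                width, height, bitcount, compression = w, h, bc, comp
            elif fourcc in (b"00db", b"00dc") and size > 0:
                frame_chunks.append((off, size))

    walk(12, len(buf))

    if width is None or not frame_chunks:
        raise OSError(f"no video stream found in {path}")
    if compression != 0 or bitcount != 8:
        raise ValueError(
            "only uncompressed 8-bit AVI streams are supported "
            f"(biCompression={compression}, biBitCount={bitcount})"
        )
    if fps is None:
        raise ValueError(
            f"no frame-rate metadata in {path}; pass fps explicitly"
        )

    bottom_up = height > 0
    h = abs(height)
    stride = (width + 3) & ~3
    frames = np.empty((len(frame_chunks), h, width), dtype=np.uint8)
    for i, (off, size) in enumerate(frame_chunks):
        if size < stride * h:
            raise OSError(f"truncated frame {i} in {path}")
        rows = np.frombuffer(buf, dtype=np.uint8, count=stride * h, offset=off)
        rows = rows.reshape(h, stride)[:, :width]
        frames[i] = rows[::-1] if bottom_up else rows
    return frames.astype(np.float32) / 255.0, fps
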