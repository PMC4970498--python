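"""Export to multi-event HDF5 and CBF for downstream crystallography programs.

HDF5 output places each named per-event result into a user-defined group,
optionally zlib-compressed, either one file per event or appended along a
leading event axis of a multi-event file.  Sub-directory batching keeps the
number of files per directory bounded so that file-system listing stays fast
on large runs.

CBF output implements the x-CBF_BYTE_OFFSET compression: pixel values are
converted to signed 32-bit integers and stored as successive deltas — one
signed byte when the delta fits in [−127, 127], otherwise an 0x80 escape
followed by a little-endian int16, with a further int16 escape (−32768) to a
little-endian int32 for large jumps.  A miniCBF-style header carries only the
binary-section essentials (element type, byte order, counts, dimensions); no
experiment metadata is added since downstream readers ignore it.
"""

from __future__ import annotations

import re
import struct
from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np

from .darkcal import CalibrationSet

__all__ = [
    "OutputItem",
    "write_event_h5",
    "write_multi_event_h5",
    "batched_path",
    "encode_byte_offset",
    "decode_byte_offset",
    "write_cbf",
    "read_cbf",
    "export_dark_cbf",
    "CbfError",
]

#: start-of-binary marker preceding the byte-offset payload in a CBF file
BINARY_MARKER = b"\x0c\x1a\x04\xd5"
_SECTION = b"--CIF-BINARY-FORMAT-SECTION--"

INT32_MIN, INT32_MAX = -(2**31), 2**31 - 1


class CbfError(ValueError):
    """Malformed, truncated or out-of-range CBF content."""


@dataclass(frozen=True)
class OutputItem:
    """One result to export: producer label, dataset name and target group.

    ``dataset_name`` defaults to ``source_name`` when omitted.
    """

    source_name: str
    dataset_name: str | None = None
    group_path: str = "/"

    @property
    def target(self) -> str:
        name = self.dataset_name or self.source_name
        group = "/" + self.group_path.strip("/")
        return f"{group.rstrip('/')}/{name}"


def _create_dataset(parent: h5py.File, target: str, data, compress: bool) -> None:
    arr = np.asarray(data)
    kwargs: dict = {"track_times": False}
    if compress and arr.ndim > 0 and arr.size > 0:
        kwargs["compression"] = "gzip"
    parent.create_dataset(target, data=arr, **kwargs)


def write_event_h5(event_results: dict, items, path, compress: bool = False) -> Path:
    """Write one event's named results to a single HDF5 file.

    ``event_results`` maps source names to scalars/arrays, or to
    ``(array, attrs_dict)`` pairs whose attributes (e.g. axis metadata) are
    stored on the dataset.  Duplicate target paths abort before anything is
    written.
    """
    items = list(items)
    targets = [it.target for it in items]
    dupes = {t for t in targets if targets.count(t) > 1}
    if dupes:
        raise ValueError(f"duplicate HDF5 target path(s): {sorted(dupes)}")
    missing = [it.source_name for it in items if it.source_name not in event_results]
    if missing:
        raise KeyError(f"event results missing source(s): {missing}")

    path = Path(path)
    with h5py.File(path, "w") as f:
        for it in items:
            value = event_results[it.source_name]
            attrs = {}
            if isinstance(value, tuple) and len(value) == 2 and isinstance(value[1], dict):
                value, attrs = value
            _create_dataset(f, it.target, value, compress)
            for k, v in attrs.items():
                f[it.target].attrs[k] = v
    return path


def write_multi_event_h5(events, items, path, compress: bool = False) -> Path:
    """Append a stream of events along a leading event axis per dataset.

    ``events`` yields ``(event_id, results_dict)`` pairs.  Every dataset gains
    a leading axis of length n_events; event ids are recorded in
    ``/event_id``.  A shape change between events raises an error naming the
    offending event.
    """
    items = list(items)
    targets = [it.target for it in items]
    dupes = {t for t in targets if targets.count(t) > 1}
    if dupes:
        raise ValueError(f"duplicate HDF5 target path(s): {sorted(dupes)}")

    path = Path(path)
    with h5py.File(path, "w") as f:
        dsets: dict[str, h5py.Dataset] = {}
        id_dset = None
        n = 0
        for event_id, results in events:
            for it in items:
                if it.source_name not in results:
                    raise KeyError(
                        f"event {event_id}: missing result {it.source_name!r}"
                    )
                arr = np.asarray(results[it.source_name])
                if it.target not in dsets:
                    kwargs: dict = {"track_times": False}
                    if compress and arr.size > 0:
                        kwargs["compression"] = "gzip"
                    dsets[it.target] = f.create_dataset(
                        it.target,
                        shape=(0,) + arr.shape,
                        maxshape=(None,) + arr.shape,
                        dtype=arr.dtype,
                        chunks=(1,) + arr.shape if arr.ndim else (1024,),
                        **kwargs,
                    )
                d = dsets[it.target]
                if arr.shape != d.shape[1:]:
                    raise ValueError(
                        f"event {event_id}: result {it.source_name!r} changed shape "
                        f"from {d.shape[1:]} to {arr.shape}"
                    )
                d.resize(n + 1, axis=0)
                d[n] = arr
            if id_dset is None:
                id_dset = f.create_dataset(
                    "event_id", shape=(0,), maxshape=(None,), dtype=np.int64,
                    chunks=(1024,), track_times=False,
                )
            id_dset.resize(n + 1, axis=0)
            id_dset[n] = int(event_id)
            n += 1
    return path


def batched_path(base_dir, event_index: int, files_per_dir: int) -> Path:
    """Deterministic sub-directory for an event: at most files_per_dir each.

    Event 0..N−1 goes into sub-directory str(index // files_per_dir).
    """
    if files_per_dir < 1:
        raise ValueError("files_per_dir must be >= 1")
    if event_index < 0:
        raise ValueError("event_index must be >= 0")
    return Path(base_dir) / str(event_index // files_per_dir)


def encode_byte_offset(values: np.ndarray) -> bytes:
    """Byte-offset compress a flat int32 sequence.

    The first element is stored as a delta from zero (i.e. absolutely); each
    subsequent delta takes 1 signed byte in [−127, 127], or an 0x80 escape
    plus little-endian int16 in [−32767, 32767], or a further −32768 int16
    escape plus little-endian int32.
    """
    out = bytearray()
    prev = 0
    for v in np.asarray(values, dtype=np.int64).ravel():
        # two's-complement wrap keeps every delta in int32 range; lossless
        # for 32-bit data since the decoder wraps identically
        d = ((int(v) - prev + 2**31) % 2**32) - 2**31
        if -127 <= d <= 127:
            out += struct.pack("b", d)
        elif -32767 <= d <= 32767:
            out += b"\x80" + struct.pack("<h", d)
        else:
            out += b"\x80" + struct.pack("<h", -32768) + struct.pack("<i", d)
        prev = int(v)
    return bytes(out)


def decode_byte_offset(payload: bytes, n_elements: int) -> np.ndarray:
    """Invert :func:`encode_byte_offset`; truncation errors name the byte offset."""
    out = np.empty(n_elements, dtype=np.int64)
    pos = 0
    prev = 0
    for i in range(n_elements):
        if pos >= len(payload):
            raise CbfError(f"truncated byte-offset stream at byte {pos} (element {i})")
        b = payload[pos]
        if b != 0x80:
            d = struct.unpack("b", payload[pos: pos + 1])[0]
            pos += 1
        else:
            if pos + 3 > len(payload):
                raise CbfError(f"truncated 16-bit escape at byte {pos} (element {i})")
            d = struct.unpack("<h", payload[pos + 1: pos + 3])[0]
            pos += 3
            if d == -32768:
                if pos + 4 > len(payload):
                    raise CbfError(f"truncated 32-bit escape at byte {pos} (element {i})")
                d = struct.unpack("<i", payload[pos: pos + 4])[0]
                pos += 4
        prev = ((prev + d + 2**31) % 2**32) - 2**31
        out[i] = prev
    return out


def _round_half_away(values: np.ndarray) -> np.ndarray:
    """Round to nearest integer, ties away from zero."""
    v = np.asarray(values, dtype=float)
    return np.copysign(np.floor(np.abs(v) + 0.5), v)


def write_cbf(image: np.ndarray, path) -> Path:
    """Write a 2D image as a minimal byte-offset-compressed CBF file.

    Floating-point input is rounded to the nearest integer (ties away from
    zero) and must fit a signed 32-bit range; out-of-range values abort
    before anything is written.
    """
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError(f"CBF output requires a 2D image, got shape {image.shape}")
    rounded = _round_half_away(image) if np.issubdtype(image.dtype, np.floating) else image
    if np.nanmin(rounded) < INT32_MIN or np.nanmax(rounded) > INT32_MAX:
        raise CbfError("image values exceed the signed 32-bit range")
    data = np.ascontiguousarray(rounded, dtype=np.int32)
    payload = encode_byte_offset(data.ravel())

    nrows, ncols = data.shape
    header = (
        "###CBF: VERSION 1.5\n"
        "# CBF file written by sfxprep\n"
        "\n"
        "data_image_1\n"
        "\n"
        "_array_data.data\n"
        ";\n"
        "--CIF-BINARY-FORMAT-SECTION--\n"
        "Content-Type: application/octet-stream;\n"
        '     conversions="x-CBF_BYTE_OFFSET"\n'
        "Content-Transfer-Encoding: BINARY\n"
        f"X-Binary-Size: {len(payload)}\n"
        "X-Binary-ID: 1\n"
        'X-Binary-Element-Type: "signed 32-bit integer"\n'
        "X-Binary-Element-Byte-Order: LITTLE_ENDIAN\n"
        f"X-Binary-Number-of-Elements: {data.size}\n"
        f"X-Binary-Size-Fastest-Dimension: {ncols}\n"
        f"X-Binary-Size-Second-Dimension: {nrows}\n"
        "\n"
    ).encode("ascii")
    footer = b"\n" + _SECTION + b"--\n;\n"

    path = Path(path)
    path.write_bytes(header + BINARY_MARKER + payload + footer)
    return path


_HEADER_FIELD = re.compile(rb"X-Binary-([A-Za-z-]+):\s*(\S+)")


def read_cbf(path) -> np.ndarray:
    """Read a byte-offset CBF file written by :func:`write_cbf` (int32 image)."""
    blob = Path(path).read_bytes()
    marker = blob.find(BINARY_MARKER)
    if marker < 0:
        raise CbfError(f"{path}: no binary-section marker found")
    head = blob[:marker]
    fields = {m.group(1).decode(): m.group(2).decode() for m in _HEADER_FIELD.finditer(head)}
    try:
        n = int(fields["Number-of-Elements"])
        ncols = int(fields["Size-Fastest-Dimension"])
        nrows = int(fields["Size-Second-Dimension"])
        nbytes = int(fields["Size"])
    except KeyError as exc:
        raise CbfError(f"{path}: missing binary header field {exc}") from exc
    if nrows * ncols != n:
        raise CbfError(f"{path}: dimensions {nrows}x{ncols} do not match {n} elements")
    payload = blob[marker + len(BINARY_MARKER): marker + len(BINARY_MARKER) + nbytes]
    values = decode_byte_offset(payload, n)
    if values.min() < INT32_MIN or values.max() > INT32_MAX:
        raise CbfError(f"{path}: decoded values exceed the signed 32-bit range")
    return values.astype(np.int32).reshape(nrows, ncols)


def export_dark_cbf(cal: CalibrationSet, path) -> Path:
    """Write the trained offset map as a separate dark CBF.

    The file can serve as the dark-current image of downstream indexing
    software; it intentionally carries no experiment metadata.  An untrained
    calibration (no contributing frames) is an error.
    """
    if cal.train_size < 1 or not (cal.counts > 0).any():
        raise ValueError("calibration is untrained: no frames contributed to the offset map")
    return write_cbf(cal.offset, path)
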