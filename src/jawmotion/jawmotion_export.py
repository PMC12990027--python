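"""XML serialization of motion trajectories for dental CAD import.

The vendor jaw-motion schema is not public, so this module defines an open,
documented dialect (see ``docs/jawmotion-schema.md``): a ``<JawMotion>`` root
carrying a schema version, a metadata block, and one ``<Frame>`` per pose with
a time in seconds and a row-major 4x4 homogeneous matrix whose translation
column is in millimetres.  CAD ecosystems consume 4x4 matrices, so quaternions
stay internal to the package.  Additional dialects can be registered in
``DIALECTS`` once a vendor mapping is known; the file payload is identical
whether it is written under the ``.xml`` or the ``.jawMotion`` extension.
"""
from __future__ import annotations

import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Union

import numpy as np

from .errors import MotionFormatError
from .motion import MotionTrajectory

__all__ = [
    "FrameRecord",
    "MotionDocument",
    "SCHEMA_VERSION",
    "read_xml",
    "to_document",
    "write_xml",
]

SCHEMA_VERSION = "1.0"
GENERATOR = "jawmotion/0.1.0"

#: Serialization dialects.  Only the open "generic" dialect exists today; a
#: vendor-specific mapping can be plugged in here without touching callers.
DIALECTS = ("generic",)

PathLike = Union[str, Path]

# 12 significant digits keep matrix entries (mm scale, < 1e3) reproducible to
# well below 1e-9 on re-parse while staying human-readable.
_NUM_FMT = ".12g"


@dataclass(frozen=True, eq=False)
class FrameRecord:
    time: float
    matrix: np.ndarray  # 4x4 homogeneous, row-major


@dataclass(eq=False)
class MotionDocument:
    """Serializable trajectory: timestamped homogeneous matrices plus metadata."""

    schema_version: str
    frame_records: tuple[FrameRecord, ...]
    metadata: Mapping[str, str] = field(default_factory=dict)

    def validate(self) -> None:
        """Enforce document invariants, naming the offending frame index.

        Every matrix must be a proper rigid motion (orthonormal 3x3 block,
        determinant +1, exact ``(0, 0, 0, 1)`` bottom row) and frame times
        must be strictly increasing.
        """
        if not self.frame_records:
            raise MotionFormatError("motion document has no frames")
        prev_time = None
        for i, record in enumerate(self.frame_records):
            m = np.asarray(record.matrix, dtype=np.float64)
            if m.shape != (4, 4):
                raise MotionFormatError(f"frame {i}: matrix is not 4x4")
            if not np.array_equal(m[3], [0.0, 0.0, 0.0, 1.0]):
                raise MotionFormatError(f"frame {i}: bottom row is not (0, 0, 0, 1)")
            r = m[:3, :3]
            if np.max(np.abs(r.T @ r - np.eye(3))) > 1e-6:
                raise MotionFormatError(f"frame {i}: rotation block is not orthonormal")
            if np.linalg.det(r) < 0:
                raise MotionFormatError(
                    f"frame {i}: rotation block has negative determinant (reflection)"
                )
            if prev_time is not None and record.time <= prev_time:
                raise MotionFormatError(f"frame {i}: times are not strictly increasing")
            prev_time = record.time


def to_document(
    trajectory: MotionTrajectory, extra_metadata: Mapping[str, str] | None = None
) -> MotionDocument:
    """Convert a trajectory to its serializable form, one record per frame.

    The quaternion-to-matrix conversion is bijective (up to floating point),
    so :func:`read_xml` output can be mapped back to poses losslessly.
    """
    records = tuple(
        FrameRecord(time=f.time, matrix=f.pose.matrix) for f in trajectory.frames
    )
    metadata: dict[str, str] = {
        "generator": GENERATOR,
        "frames_per_segment": str(trajectory.frames_per_segment),
        "keyframe_indices": ",".join(str(i) for i in trajectory.keyframe_indices),
        "keyframe_labels": ",".join(
            trajectory.frames[i].segment_label for i in trajectory.keyframe_indices
        ),
    }
    if extra_metadata:
        metadata.update({str(k): str(v) for k, v in extra_metadata.items()})
    return MotionDocument(
        schema_version=SCHEMA_VERSION, frame_records=records, metadata=metadata
    )


def _serialize(doc: MotionDocument) -> bytes:
    root = ET.Element("JawMotion", attrib={"schemaVersion": doc.schema_version})
    meta = ET.SubElement(root, "Metadata")
    for key, value in doc.metadata.items():
        entry = ET.SubElement(meta, "Entry", attrib={"key": key})
        entry.text = value
    frames = ET.SubElement(root, "Frames", attrib={"count": str(len(doc.frame_records))})
    for i, record in enumerate(doc.frame_records):
        frame = ET.SubElement(
            frames, "Frame", attrib={"index": str(i), "time": repr(float(record.time))}
        )
        matrix = ET.SubElement(frame, "Matrix")
        matrix.text = " ".join(
            format(v, _NUM_FMT) for v in np.asarray(record.matrix).ravel()
        )
    ET.indent(root)
    return ET.tostring(root, encoding="utf-8", xml_declaration=True) + b"\n"


def write_xml(doc: MotionDocument, path: PathLike, extension_mode: str = "xml") -> Path:
    """Write the document; returns the path actually written.

    ``extension_mode`` selects the file extension only — ``"jawMotion"``
    writes a byte-identical payload under ``.jawMotion`` for CAD versions
    that key the import on the extension.
    """
    if extension_mode not in ("xml", "jawMotion"):
        raise ValueError(f"extension_mode must be 'xml' or 'jawMotion', got {extension_mode!r}")
    doc.validate()
    path = Path(path)
    suffix = ".xml" if extension_mode == "xml" else ".jawMotion"
    if path.suffix != suffix:
        path = path.with_suffix(suffix)
    path.write_bytes(_serialize(doc))
    return path


def read_xml(path: PathLike) -> MotionDocument:
    """Parse and validate a motion document written by :func:`write_xml`."""
    try:
        tree = ET.parse(Path(path))
    except ET.ParseError as exc:
        raise MotionFormatError(f"{path}: malformed XML: {exc}") from exc
    root = tree.getroot()
    if root.tag != "JawMotion":
        raise MotionFormatError(f"{path}: root element is {root.tag!r}, expected 'JawMotion'")
    schema_version = root.get("schemaVersion")
    if schema_version is None:
        raise MotionFormatError(f"{path}: missing required schemaVersion attribute")

    metadata: dict[str, str] = {}
    meta = root.find("Metadata")
    if meta is not None:
        for entry in meta.findall("Entry"):
            key = entry.get("key")
            if key is None:
                raise MotionFormatError(f"{path}: metadata entry without a key")
            metadata[key] = entry.text or ""

    frames_el = root.find("Frames")
    if frames_el is None:
        raise MotionFormatError(f"{path}: missing Frames element")
    records: list[FrameRecord] = []
    for i, frame in enumerate(frames_el.findall("Frame")):
        time_attr = frame.get("time")
        if time_attr is None:
            raise MotionFormatError(f"{path}: frame {i} has no time attribute")
        matrix_el = frame.find("Matrix")
        if matrix_el is None or not matrix_el.text:
            raise MotionFormatError(f"{path}: frame {i} has no Matrix element")
        try:
            time = float(time_attr)
            values = np.array([float(v) for v in matrix_el.text.split()], dtype=np.float64)
        except ValueError as exc:
            raise MotionFormatError(f"{path}: frame {i}: bad numeric field: {exc}") from exc
        if values.size != 16:
            raise MotionFormatError(
                f"{path}: frame {i}: matrix has {values.size} values, expected 16"
            )
        records.append(FrameRecord(time=time, matrix=values.reshape(4, 4)))
    declared = frames_el.get("count")
    if declared is not None and int(declared) != len(records):
        raise MotionFormatError(
            f"{path}: Frames count attribute {declared} != {len(records)} frames found"
        )
    doc = MotionDocument(
        schema_version=schema_version, frame_records=tuple(records), metadata=metadata
    )
    doc.validate()
    return doc
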