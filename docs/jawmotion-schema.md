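# Jaw-motion XML schema (dialect `generic`, version 1.0)

The vendor jaw-motion format is not publicly documented, so `jawmotion`
defines an open XML dialect.  The payload is identical whether the file is
written with a `.xml` or a `.jawMotion` extension; the latter exists only for
CAD versions that key the import on the extension.  Additional dialects can be
added behind `jawmotion.jawmotion_export.DIALECTS` once a vendor mapping is
known.

## Document structure

```xml
<?xml version='1.0' encoding='utf-8'?>
<JawMotion schemaVersion="1.0">
  <Metadata>
    <Entry key="generator">jawmotion/0.1.0</Entry>
    <Entry key="frames_per_segment">100</Entry>
    <Entry key="keyframe_indices">0,101,202,303,404,505,606</Entry>
    <Entry key="keyframe_labels">MIP,PROTRUSIVE,MIP,...</Entry>
  </Metadata>
  <Frames count="607">
    <Frame index="0" time="0.0">
      <Matrix>1 0 0 0 0 1 0 0 0 0 1 0 0 0 0 1</Matrix>
    </Frame>
    <!-- ... -->
  </Frames>
</JawMotion>
```

## Elements and attributes

- **`JawMotion`** (root) — required attribute `schemaVersion`.  A document
  without it is rejected (no silent defaulting).
- **`Metadata`** — optional; zero or more `Entry` elements, each with a
  required `key` attribute and a text value.  Keys and values are opaque
  strings and round-trip exactly.
- **`Frames`** — required; optional `count` attribute, checked against the
  number of child `Frame` elements when present.
- **`Frame`** — required attribute `time` (seconds, printed with Python
  `repr` so times round-trip exactly); one required `Matrix` child.
- **`Matrix`** — 16 whitespace-separated decimal numbers, the row-major 4x4
  homogeneous transform of the mandibular arch relative to its MIP pose.
  The translation column is in millimetres.  Numbers are printed with 12
  significant digits, keeping matrices reproducible to well below 1e-9.

## Validation rules

Applied on both write and read; violations name the offending frame index:

1. at least one frame;
2. each matrix's bottom row is exactly `0 0 0 1`;
3. each upper-left 3x3 block is orthonormal within 1e-6 and has positive
   determinant (reflections are rejected);
4. frame times are strictly increasing.
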