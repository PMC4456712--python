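"""Binary molecular fingerprints and FPS-like text serialization.

A fingerprint is a fixed-length bit vector; a library is an ordered list of
fingerprints with unique identifiers.  Hex serialization follows the FPS
convention: bytes in order, most-significant bit of each byte first, so bit 0
of the fingerprint is the MSB of the first hex byte.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "BinaryFingerprint",
    "to_dense_matrix",
    "read_fps",
    "write_fps",
]


@dataclass(frozen=True)
class BinaryFingerprint:
    """Fixed-length bit vector standing for one molecule.

    Parameters
    ----------
    id : str
        Opaque molecule identifier, unique within a library.
    length : int
        Number of bits (positive).
    on_bits : frozenset of int
        Positions of set bits, each in ``[0, length)``.
    """

    id: str
    length: int
    on_bits: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"fingerprint length must be positive, got {self.length}")
        bits = frozenset(int(b) for b in self.on_bits)
        object.__setattr__(self, "on_bits", bits)
        if bits and (min(bits) < 0 or max(bits) >= self.length):
            raise ValueError(
                f"on-bit positions must lie in [0, {self.length}); "
                f"got range [{min(bits)}, {max(bits)}]"
            )

    @property
    def count(self) -> int:
        """Number of on bits."""
        return len(self.on_bits)

    def to_dense(self) -> np.ndarray:
        """Return the fingerprint as a boolean vector of shape ``(length,)``."""
        v = np.zeros(self.length, dtype=bool)
        if self.on_bits:
            v[np.fromiter(self.on_bits, dtype=np.intp)] = True
        return v

    def to_hex(self) -> str:
        """Hex string, most-significant-bit-first within each byte (FPS style)."""
        nbytes = (self.length + 7) // 8
        buf = bytearray(nbytes)
        for b in self.on_bits:
            buf[b // 8] |= 0x80 >> (b % 8)
        return bytes(buf).hex()

    @classmethod
    def from_hex(cls, hexstr: str, id: str, length: int | None = None) -> "BinaryFingerprint":
        """Build a fingerprint from an FPS-style hex string."""
        raw = bytes.fromhex(hexstr)
        if length is None:
            length = 8 * len(raw)
        elif (length + 7) // 8 != len(raw):
            raise ValueError(f"hex string encodes {8 * len(raw)} bits, expected length {length}")
        bits = set()
        for i, byte in enumerate(raw):
            for j in range(8):
                if byte & (0x80 >> j):
                    bits.add(8 * i + j)
        if bits and max(bits) >= length:
            raise ValueError("set bit beyond declared fingerprint length")
        return cls(id=id, length=length, on_bits=frozenset(bits))


def to_dense_matrix(library: Sequence[BinaryFingerprint]) -> np.ndarray:
    """Stack a library into a boolean matrix of shape ``(n_molecules, length)``.

    All fingerprints must share one length.
    """
    if not library:
        raise ValueError("empty library")
    length = library[0].length
    for fp in library:
        if fp.length != length:
            raise ValueError(
                f"fingerprint length mismatch: {fp.id} has {fp.length}, expected {length}"
            )
    mat = np.zeros((len(library), length), dtype=bool)
    for i, fp in enumerate(library):
        if fp.on_bits:
            mat[i, np.fromiter(fp.on_bits, dtype=np.intp)] = True
    return mat


def write_fps(library: Iterable[BinaryFingerprint], path: str | Path | io.TextIOBase,
              num_bits: int | None = None) -> None:
    """Write fingerprints as FPS-like text: ``#`` header lines, then ``hex<TAB>id``."""
    fps = list(library)
    if num_bits is None:
        num_bits = fps[0].length if fps else 0
    lines = [f"#num_bits={num_bits}\n"]
    for fp in fps:
        lines.append(f"{fp.to_hex()}\t{fp.id}\n")
    if isinstance(path, (str, Path)):
        Path(path).write_text("".join(lines))
    else:
        path.write("".join(lines))


def read_fps(path: str | Path | io.TextIOBase) -> list[BinaryFingerprint]:
    """Read an FPS-like file written by :func:`write_fps`."""
    if isinstance(path, (str, Path)):
        text = Path(path).read_text()
    else:
        text = path.read()
    num_bits: int | None = None
    out: list[BinaryFingerprint] = []
    seen: set[str] = set()
    for raw in text.splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            if line[1:].startswith("num_bits="):
                num_bits = int(line.split("=", 1)[1])
            continue
        hexstr, _, fid = line.partition("\t")
        if not fid:
            raise ValueError(f"malformed FPS record (no tab-separated id): {line!r}")
        if fid in seen:
            raise ValueError(f"duplicate fingerprint id {fid!r}")
        seen.add(fid)
        out.append(BinaryFingerprint.from_hex(hexstr, id=fid, length=num_bits))
    return out
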