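"""Reads, read sets, and the 2-bit packed text they are stored in.

A :class:`ReadSet` is the in-memory representation of one multi-FASTA
input: an ordered list of :class:`Read` objects plus a single packed
buffer holding every base at two bits (A=00, C=01, G=10, T=11).  The
packed buffer is the "text" that the compact prefix tree indexes into;
per-read byte arrays of base codes (values 0..3) are kept alongside it
because they are what the construction and matching inner loops touch.

Identification numbers (``Read.id``) are lexicographic ranks, assigned
either by :func:`sof.prefix_trie.sort_reads` or by the DFS relabelling
pass of the unsorted construction.  ``Read.original_index`` is the
1-based position in the input file and never changes.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

ALPHABET = "ACGT"

#: base character -> 2-bit code
BASE_TO_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
CODE_TO_BASE = {v: k for k, v in BASE_TO_CODE.items()}

_ENCODE_TABLE = np.full(256, 255, dtype=np.uint8)
for _b, _c in BASE_TO_CODE.items():
    _ENCODE_TABLE[ord(_b)] = _c
    _ENCODE_TABLE[ord(_b.lower())] = _c

_DECODE_TABLE = np.zeros(4, dtype=np.uint8)
for _b, _c in BASE_TO_CODE.items():
    _DECODE_TABLE[_c] = ord(_b)


class ReadSetError(ValueError):
    """Invalid read material (empty set, bad characters, bad sizes)."""


def encode_codes(sequence: str) -> bytes:
    """Map an ACGT string (case-insensitive) to a bytes object of 2-bit codes.

    Raises :class:`ReadSetError` on any character outside the DNA alphabet.
    """
    raw = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
    codes = _ENCODE_TABLE[raw]
    if codes.max(initial=0) > 3:
        bad = chr(raw[int(np.argmax(codes))])
        raise ReadSetError(f"non-ACGT character {bad!r} in sequence")
    return codes.tobytes()


def decode_codes(codes: bytes) -> str:
    """Inverse of :func:`encode_codes`."""
    arr = np.frombuffer(codes, dtype=np.uint8)
    return _DECODE_TABLE[arr].tobytes().decode("ascii")


def pack_2bit(codes: np.ndarray) -> np.ndarray:
    """Pack an array of 2-bit codes (uint8, values 0..3) four to a byte.

    The last byte is zero-padded.  Base ``i`` occupies bits ``6-2*(i%4)``
    of byte ``i//4`` (big-endian within the byte), the fixed-length
    encoding used for the on-disk/in-memory text.
    """
    codes = np.asarray(codes, dtype=np.uint8)
    pad = (-len(codes)) % 4
    if pad:
        codes = np.concatenate([codes, np.zeros(pad, dtype=np.uint8)])
    quads = codes.reshape(-1, 4)
    return (
        (quads[:, 0] << 6) | (quads[:, 1] << 4) | (quads[:, 2] << 2) | quads[:, 3]
    ).astype(np.uint8)


def unpack_2bit(packed: np.ndarray, n: int) -> np.ndarray:
    """Unpack ``n`` 2-bit codes from a packed byte array."""
    packed = np.asarray(packed, dtype=np.uint8)
    out = np.empty(len(packed) * 4, dtype=np.uint8)
    out[0::4] = (packed >> 6) & 3
    out[1::4] = (packed >> 4) & 3
    out[2::4] = (packed >> 2) & 3
    out[3::4] = packed & 3
    return out[:n]


class Read:
    """One DNA read.

    ``id`` is the 1-based lexicographic rank within its read set (None
    until ranks have been assigned); ``original_index`` is the 1-based
    position in input order.
    """

    __slots__ = ("id", "original_index", "header", "sequence", "codes")

    def __init__(self, original_index: int, header: str, sequence: str):
        if not sequence:
            raise ReadSetError(f"read {header!r} has an empty sequence")
        self.id: int | None = None
        self.original_index = original_index
        self.header = header
        self.sequence = sequence.upper()
        self.codes = encode_codes(sequence)

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def length(self) -> int:
        return len(self.sequence)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return (
            f"Read(id={self.id}, orig={self.original_index}, "
            f"header={self.header!r}, len={len(self)})"
        )


class ReadSet:
    """An ordered collection of reads plus the packed 2-bit text.

    Attributes
    ----------
    reads:
        Reads in the current order of the set (input order, or id order
        after sorting).
    k, n:
        Number of reads and total base count.
    text:
        numpy uint8 array: all sequences concatenated and packed at two
        bits per base.
    offsets:
        ``offsets[i]`` is the base (not byte) offset of ``reads[i]``
        inside the packed text.
    """

    def __init__(self, reads: Sequence[Read]):
        if not reads:
            raise ReadSetError("read set is empty")
        self.reads: list[Read] = list(reads)
        self.k = len(self.reads)
        self.n = sum(len(r) for r in self.reads)
        all_codes = np.frombuffer(b"".join(r.codes for r in self.reads), dtype=np.uint8)
        self.text = pack_2bit(all_codes)
        self.offsets = np.zeros(self.k, dtype=np.int64)
        np.cumsum([len(r) for r in self.reads[:-1]], out=self.offsets[1:])

    @classmethod
    def from_sequences(
        cls, pairs: Iterable[tuple[str, str]], *, skip_invalid: bool = False
    ) -> "ReadSet":
        """Build a read set from (header, sequence) pairs in file order.

        With ``skip_invalid`` reads containing non-ACGT characters are
        dropped (callers are expected to log them); otherwise they raise.
        """
        reads = []
        idx = 0
        for header, seq in pairs:
            idx += 1
            try:
                reads.append(Read(idx, header, seq))
            except ReadSetError:
                if not skip_invalid:
                    raise
        # re-number after skipping so original_index stays 1..k
        for i, r in enumerate(reads, start=1):
            r.original_index = i
        return cls(reads)

    def decode(self, index: int) -> str:
        """Decode read ``reads[index]`` back out of the packed text."""
        read = self.reads[index]
        start = int(self.offsets[index])
        codes = unpack_2bit(self.text, start + len(read))[start:]
        return _DECODE_TABLE[codes].tobytes().decode("ascii")

    def __len__(self) -> int:
        return self.k

    def __iter__(self):
        return iter(self.reads)
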