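"""Succinct full-text index: suffix array, BWT, C array and Occ rank structure.

The index answers, for a pattern ``Q`` over a sentinel-terminated text ``X``,
the suffix-array interval ``[sp, ep]`` of all suffixes of ``X`` prefixed by
``Q`` in ``O(|Q|)`` interval updates (backward search), and maps interval rows
back to text positions through the stored suffix array.

The sentinel ``$`` terminates the text and compares smaller than every other
symbol.  A text may contain *internal* sentinels when it is a
sentinel-concatenation of equal-length k-mers (see :mod:`offscan.offtarget`);
suffix order remains a total order because all suffixes have distinct lengths.
"""

from __future__ import annotations

import json
import zipfile
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

SENTINEL = "$"
DNA_ALPHABET = ("A", "C", "G", "T")

_FORMAT_MAGIC = "offscan-fm-index"
_FORMAT_VERSION = 1


class AlphabetError(ValueError):
    """A symbol falls outside the declared alphabet."""


@dataclass(frozen=True)
class Text:
    """A ``$``-terminated symbol string over a declared alphabet.

    Parameters
    ----------
    symbols
        The text, last symbol must be the sentinel ``$``.
    alphabet
        Non-sentinel symbols permitted in the text, default ``A,C,G,T``.
    allow_internal_sentinels
        Permit ``$`` before the final position.  Only sensible for
        sentinel-concatenations of k-mers; plain texts reject internal ``$``.
    """

    symbols: str
    alphabet: tuple[str, ...] = DNA_ALPHABET
    allow_internal_sentinels: bool = False

    def __post_init__(self) -> None:
        if not self.symbols:
            raise ValueError("text must be non-empty")
        if self.symbols[-1] != SENTINEL:
            raise ValueError("text must be terminated with the sentinel '$'")
        allowed = set(self.alphabet)
        body = self.symbols[:-1]
        if self.allow_internal_sentinels:
            allowed = allowed | {SENTINEL}
        bad = set(body) - allowed
        if bad:
            raise AlphabetError(
                f"symbols outside alphabet {sorted(self.alphabet)}: {sorted(bad)}"
            )

    @property
    def n(self) -> int:
        """Length in symbols, terminal sentinel included."""
        return len(self.symbols)

    def sorted_alphabet(self) -> tuple[str, ...]:
        """``$`` first, then the declared alphabet in sorted order."""
        return (SENTINEL, *sorted(self.alphabet))


def _encode(symbols: str, sorted_alphabet: Sequence[str]) -> np.ndarray:
    """Map symbols to small integer codes, sentinel = 0."""
    lut = np.full(128, -1, dtype=np.int8)
    for code, sym in enumerate(sorted_alphabet):
        lut[ord(sym)] = code
    raw = np.frombuffer(symbols.encode("ascii"), dtype=np.uint8)
    codes = lut[raw]
    if (codes < 0).any():
        bad = sorted({chr(b) for b in raw[codes < 0]})
        raise AlphabetError(f"symbols outside alphabet: {bad}")
    return codes.astype(np.int64)


def build_suffix_array(text: Text) -> np.ndarray:
    """Suffix array of ``text`` by prefix doubling (O(n log^2 n) with numpy).

    Returns the permutation ``SA`` of ``0..n-1`` with ``SA[i]`` the start of
    the i-th lexicographically smallest suffix; the sentinel suffix sorts
    first.
    """
    codes = _encode(text.symbols, text.sorted_alphabet())
    n = len(codes)
    rank = codes
    k = 1
    while True:
        second = np.full(n, -1, dtype=np.int64)
        second[: n - k] = rank[k:]
        order = np.lexsort((second, rank))
        changed = (rank[order[1:]] != rank[order[:-1]]) | (
            second[order[1:]] != second[order[:-1]]
        )
        new_rank = np.empty(n, dtype=np.int64)
        new_rank[order] = np.concatenate(([0], np.cumsum(changed)))
        rank = new_rank
        if rank[order[-1]] == n - 1:
            return order.astype(np.int64)
        k *= 2


def build_bwt(text: Text, sa: np.ndarray) -> str:
    """Burrows-Wheeler transform: ``B[i] = X[SA[i]-1]``, ``$`` when ``SA[i]=0``."""
    if len(sa) != text.n:
        raise ValueError("suffix array length does not match text length")
    chars = np.frombuffer(text.symbols.encode("ascii"), dtype=np.uint8)
    out = chars[np.asarray(sa) - 1].copy()  # SA[i]-1 == -1 wraps to last char = $
    return out.tobytes().decode("ascii")


@dataclass
class SaInterval:
    """Suffix-array interval ``[sp, ep]``; empty iff ``sp > ep``."""

    sp: int
    ep: int

    @property
    def is_empty(self) -> bool:
        return self.sp > self.ep

    def __len__(self) -> int:
        return 0 if self.is_empty else self.ep - self.sp + 1


@dataclass
class FmIndex:
    """FM-index over a :class:`Text`: SA + BWT + C array + checkpointed Occ.

    ``C[a]`` counts symbols of the text strictly smaller than ``a``;
    ``Occ[a, i]`` counts occurrences of ``a`` in ``B[0..i]`` (inclusive),
    answered from absolute checkpoints every ``occ_block`` BWT positions plus
    a scan within the block.
    """

    text: Text
    sa: np.ndarray
    bwt: str
    occ_block: int = 128
    dense_occ_threshold: int = 4_000_000
    # derived fields
    _bwt_codes: np.ndarray = field(init=False, repr=False)
    _checkpoints: np.ndarray = field(init=False, repr=False)
    _dense_occ: np.ndarray | None = field(init=False, repr=False)
    _c: np.ndarray = field(init=False, repr=False)
    _sym_to_code: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        alpha = self.text.sorted_alphabet()
        self._sym_to_code = {s: i for i, s in enumerate(alpha)}
        self._bwt_codes = _encode(self.bwt, alpha)
        sigma = len(alpha)
        counts = np.bincount(self._bwt_codes, minlength=sigma)
        self._c = np.concatenate(([0], np.cumsum(counts)[:-1]))
        nb = len(self._bwt_codes)
        n_blocks = nb // self.occ_block + 1
        block_of = np.arange(nb) // self.occ_block
        per_block = np.bincount(
            block_of * sigma + self._bwt_codes, minlength=n_blocks * sigma
        ).reshape(n_blocks, sigma)
        cp = np.zeros((n_blocks, sigma), dtype=np.int64)
        np.cumsum(per_block[: n_blocks - 1], axis=0, out=cp[1:])
        self._checkpoints = cp
        # dense cumulative ranks give O(1) Occ and vectorized batch
        # extension; only built at desk scale, checkpoints remain the
        # fallback for large texts
        if nb <= self.dense_occ_threshold:
            dense = np.zeros((nb + 1, sigma), dtype=np.int64)
            onehot = np.zeros((nb, sigma), dtype=np.int64)
            onehot[np.arange(nb), self._bwt_codes] = 1
            np.cumsum(onehot, axis=0, out=dense[1:])
            self._dense_occ = dense
        else:
            self._dense_occ = None

    # -- accessors -------------------------------------------------------
    @property
    def n(self) -> int:
        return self.text.n

    @property
    def alphabet(self) -> tuple[str, ...]:
        return self.text.sorted_alphabet()

    def c_array(self) -> dict[str, int]:
        """C as a mapping symbol -> count of strictly smaller symbols."""
        return {s: int(self._c[i]) for s, i in self._sym_to_code.items()}

    def _code(self, a: str) -> int:
        try:
            return self._sym_to_code[a]
        except KeyError:
            raise AlphabetError(f"symbol {a!r} outside alphabet") from None

    # -- core queries ----------------------------------------------------
    def occ(self, a: str, i: int) -> int:
        """Occurrences of symbol ``a`` in ``B[0..i]``; ``i = -1`` gives 0."""
        return self._occ_code(self._code(a), i)

    def _occ_code(self, code: int, i: int) -> int:
        if i < 0:
            return 0
        if i >= self.n:
            raise IndexError(f"occ index {i} out of range for n={self.n}")
        if self._dense_occ is not None:
            return int(self._dense_occ[i + 1, code])
        block, rem = divmod(i + 1, self.occ_block)
        base = int(self._checkpoints[block, code])
        if rem:
            start = block * self.occ_block
            base += int(
                np.count_nonzero(self._bwt_codes[start : start + rem] == code)
            )
        return base

    def backward_extend(self, interval: SaInterval, a: str) -> SaInterval:
        """SA interval of ``a + Q`` given the interval of ``Q``."""
        code = self._code(a)
        return self._extend_code(interval, code)

    def _extend_code(self, interval: SaInterval, code: int) -> SaInterval:
        c = int(self._c[code])
        sp = c + self._occ_code(code, interval.sp - 1)
        ep = c + self._occ_code(code, interval.ep) - 1
        return SaInterval(sp, ep)

    def _extend_codes_batch(
        self, sp: np.ndarray, ep: np.ndarray, code: int
    ) -> tuple[np.ndarray, np.ndarray]:
        """Backward-extend many intervals by one symbol code at once.

        ``sp``/``ep`` are parallel arrays of non-empty intervals; empty
        results come back with ``sp > ep`` and are the caller's to drop.
        """
        c = int(self._c[code])
        if self._dense_occ is not None:
            col = self._dense_occ[:, code]
            return c + col[sp], c + col[ep + 1] - 1
        sp2 = np.fromiter(
            (c + self._occ_code(code, int(s) - 1) for s in sp), np.int64, len(sp)
        )
        ep2 = np.fromiter(
            (c + self._occ_code(code, int(e)) - 1 for e in ep), np.int64, len(ep)
        )
        return sp2, ep2

    def full_interval(self) -> SaInterval:
        """Interval of the empty pattern: every suffix."""
        return SaInterval(0, self.n - 1)

    def exact_search(self, q: str) -> SaInterval:
        """Backward search: interval of all suffixes prefixed by ``q``.

        Queries may not contain the sentinel.
        """
        if not q:
            raise ValueError("query must be non-empty")
        if SENTINEL in q:
            raise AlphabetError("queries may not contain the sentinel '$'")
        interval = self.full_interval()
        for a in reversed(q):
            interval = self.backward_extend(interval, a)
            if interval.is_empty:
                return interval
        return interval

    def locate(self, interval: SaInterval) -> list[int]:
        """Text start positions of an interval's suffixes, ascending."""
        if interval.is_empty:
            return []
        if interval.sp < 0 or interval.ep >= self.n:
            raise IndexError("interval out of suffix-array bounds")
        return sorted(int(p) for p in self.sa[interval.sp : interval.ep + 1])

    def count(self, q: str) -> int:
        """Number of occurrences of ``q`` in the text."""
        return len(self.exact_search(q))

    # -- LF mapping ------------------------------------------------------
    def lf(self, i: int) -> int:
        """Last-to-first mapping: SA row of the suffix starting at SA[i]-1."""
        code = int(self._bwt_codes[i])
        return int(self._c[code]) + self._occ_code(code, i) - 1

    def reconstruct_text(self) -> str:
        """Rebuild the text by walking the LF mapping from row 0.

        Row 0 holds the sentinel suffix, whose BWT symbol is the last
        non-sentinel character; repeated LF steps emit the text right to
        left.
        """
        out = [SENTINEL]
        row = 0
        for _ in range(self.n - 1):
            out.append(self.bwt[row])
            row = self.lf(row)
        return "".join(reversed(out))

    # -- serialization ---------------------------------------------------
    def save(self, path) -> None:
        """Serialize to a single zip archive (versioned header + arrays)."""
        header = {
            "magic": _FORMAT_MAGIC,
            "version": _FORMAT_VERSION,
            "n": self.n,
            "alphabet": list(self.text.alphabet),
            "allow_internal_sentinels": self.text.allow_internal_sentinels,
            "occ_block": self.occ_block,
        }
        with zipfile.ZipFile(path, "w") as zf:
            zf.writestr("header.json", json.dumps(header))
            zf.writestr("text.txt", self.text.symbols)
            zf.writestr("bwt.txt", self.bwt)
            zf.writestr("sa.npy", _np_bytes(self.sa))

    @classmethod
    def load(cls, path) -> "FmIndex":
        with zipfile.ZipFile(path, "r") as zf:
            header = json.loads(zf.read("header.json"))
            if header.get("magic") != _FORMAT_MAGIC:
                raise ValueError(f"{path}: not an offscan FM-index file")
            if header.get("version") != _FORMAT_VERSION:
                raise ValueError(f"unsupported index version {header.get('version')}")
            text = Text(
                zf.read("text.txt").decode("ascii"),
                alphabet=tuple(header["alphabet"]),
                allow_internal_sentinels=header["allow_internal_sentinels"],
            )
            sa = _np_from_bytes(zf.read("sa.npy"))
            bwt = zf.read("bwt.txt").decode("ascii")
        return cls(text=text, sa=sa, bwt=bwt, occ_block=int(header["occ_block"]))


def _np_bytes(arr: np.ndarray) -> bytes:
    import io

    buf = io.BytesIO()
    np.save(buf, arr, allow_pickle=False)
    return buf.getvalue()


def _np_from_bytes(data: bytes) -> np.ndarray:
    import io

    return np.load(io.BytesIO(data), allow_pickle=False)


def build_fm_index(
    text: Text | str,
    alphabet: Iterable[str] = DNA_ALPHABET,
    allow_internal_sentinels: bool = False,
    occ_block: int = 128,
) -> FmIndex:
    """Build a complete FM-index (SA, BWT, C, Occ) over ``text``.

    Accepts either a :class:`Text` or a raw ``$``-terminated string.
    """
    if isinstance(text, str):
        text = Text(
            text,
            alphabet=tuple(alphabet),
            allow_internal_sentinels=allow_internal_sentinels,
        )
    sa = build_suffix_array(text)
    bwt = build_bwt(text, sa)
    return FmIndex(text=text, sa=sa, bwt=bwt, occ_block=occ_block)
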