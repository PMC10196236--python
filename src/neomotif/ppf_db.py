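"""Pentamer frequency tables (hPPF / giPPF analogues) over the full 20^5 key space.

Every possible pentamer over the 20-letter alphabet gets a key (base-20
integer, A=0 ... Y=19); a table stores the count of reference windows whose
TCEM-position pentamer matches each key, zeros included.  Class I tables
tally the p4-p8 pentamer of every clean 9mer window, class II the
discontinuous 5,6,8,10,11 pentamer of every clean 15mer window.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from .motif_core import (
    AMINO_ACIDS,
    AA_INDEX,
    MotifClass,
    ProteinRecord,
    SequenceError,
)

N_PENTAMERS = 20**5  # 3,200,000

# 0-based positions of the TCEM pentamer within the window, per class.
_TCEM_POSITIONS = {"I": (3, 4, 5, 6, 7), "II": (4, 5, 7, 9, 10)}
_WIDTHS = {"I": 9, "II": 15}

_POWERS = 20 ** np.arange(5, dtype=np.int64)

# residue letter -> code, -1 for anything non-canonical
_CODE = np.full(256, -1, dtype=np.int16)
for _aa, _i in AA_INDEX.items():
    _CODE[ord(_aa)] = _i

FREQ_CLASSES = ("absent", "singleton", "doubleton", "3+")

_FORMAT_VERSION = "neomotif-ppf/1"


class PpfIntegrityError(ValueError):
    """Persisted table is truncated, corrupted, or of an unknown version."""


def encode_pentamer(pentamer: str) -> int:
    """Base-20 key of a 5-residue string over ACDEFGHIKLMNPQRSTVWY."""
    if len(pentamer) != 5:
        raise SequenceError(f"pentamer must have length 5, got {pentamer!r}")
    key = 0
    for i, aa in enumerate(pentamer):
        code = AA_INDEX.get(aa)
        if code is None:
            raise SequenceError(f"non-canonical residue {aa!r} in {pentamer!r}")
        key += code * 20**i
    return key


def decode_pentamer(key: int) -> str:
    if not 0 <= key < N_PENTAMERS:
        raise ValueError(f"key out of range: {key}")
    out = []
    for _ in range(5):
        out.append(AMINO_ACIDS[key % 20])
        key //= 20
    return "".join(out)


@dataclass
class PentamerTable:
    motif_class: MotifClass
    reference_name: str
    counts: np.ndarray  # int64, length 20^5
    n_windows: int
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (N_PENTAMERS,):
            raise ValueError(
                f"counts must cover all {N_PENTAMERS} pentamer keys, "
                f"got shape {self.counts.shape}"
            )
        if (self.counts < 0).any():
            raise ValueError("negative pentamer count")
        total = int(self.counts.sum())
        if total != self.n_windows:
            raise ValueError(
                f"sum of counts ({total}) != n_windows ({self.n_windows})"
            )

    def lookup(self, pentamer: str) -> int:
        return int(self.counts[encode_pentamer(pentamer)])

    def lookup_keys(self, keys: np.ndarray) -> np.ndarray:
        return self.counts[np.asarray(keys, dtype=np.int64)]


def frequency_class(count: int) -> str:
    """Bin a reference count: 0 absent, 1 singleton, 2 doubleton, else '3+'."""
    if count < 0:
        raise ValueError(f"count must be non-negative, got {count}")
    return FREQ_CLASSES[count] if count < 3 else "3+"


def _sequence_pentamer_keys(sequence: str, motif_class: MotifClass) -> np.ndarray:
    """Pentamer keys of the TCEM of every clean window of one sequence."""
    width = _WIDTHS[motif_class]
    n = len(sequence)
    if n < width:
        return np.empty(0, dtype=np.int64)
    codes = _CODE[np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)]
    wins = np.lib.stride_tricks.sliding_window_view(codes, width)
    clean = (wins >= 0).all(axis=1)
    sel = wins[clean][:, list(_TCEM_POSITIONS[motif_class])].astype(np.int64)
    return sel @ _POWERS


def build_ppf(
    proteome: Iterable[ProteinRecord],
    motif_class: MotifClass,
    reference_name: str = "reference",
) -> PentamerTable:
    """Tally TCEM pentamers over all clean windows of a proteome.

    Class I uses 9mer windows, class II 15mer windows.  Errors on an empty
    proteome or a repeated protein_id (one sequence per protein expected).
    """
    if motif_class not in ("I", "II"):
        raise ValueError(f"motif_class must be 'I' or 'II', got {motif_class!r}")
    counts = np.zeros(N_PENTAMERS, dtype=np.int64)
    seen_ids: set[str] = set()
    n_prot = 0
    for protein in proteome:
        if protein.protein_id in seen_ids:
            raise ValueError(f"duplicate protein_id {protein.protein_id!r}")
        seen_ids.add(protein.protein_id)
        n_prot += 1
        keys = _sequence_pentamer_keys(protein.sequence, motif_class)
        if keys.size:
            counts += np.bincount(keys, minlength=N_PENTAMERS)
    if n_prot == 0:
        raise ValueError("empty proteome")
    n_windows = int(counts.sum())
    meta = {"n_proteins": n_prot, "motif_class": motif_class}
    return PentamerTable(motif_class, reference_name, counts, n_windows, meta)


def _table_digest(counts: np.ndarray) -> str:
    nz = np.flatnonzero(counts)
    h = hashlib.sha256()
    h.update(nz.tobytes())
    h.update(counts[nz].tobytes())
    return h.hexdigest()


def save_ppf(table: PentamerTable, path) -> None:
    """Write a table as a JSON metadata header line plus pentamer\\tcount rows.

    Zero-count keys are omitted on disk; rows are in lexicographic pentamer
    order so output is deterministic and diff-able.
    """
    nz = np.flatnonzero(table.counts)
    pentamers = [decode_pentamer(int(k)) for k in nz]
    order = np.argsort(np.asarray(pentamers))
    header = {
        "format": _FORMAT_VERSION,
        "motif_class": table.motif_class,
        "reference_name": table.reference_name,
        "n_windows": table.n_windows,
        "n_nonzero": int(nz.size),
        "digest": _table_digest(table.counts),
        "metadata": table.metadata,
    }
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("#" + json.dumps(header, sort_keys=True) + "\n")
        for i in order:
            fh.write(f"{pentamers[i]}\t{int(table.counts[nz[i]])}\n")


def load_ppf(path) -> PentamerTable:
    """Round-trip counterpart of :func:`save_ppf`; verifies digest and totals."""
    with open(path, "r", encoding="utf-8") as fh:
        first = fh.readline()
        if not first.startswith("#"):
            raise PpfIntegrityError(f"{path}: missing metadata header")
        try:
            header = json.loads(first[1:])
        except json.JSONDecodeError as e:
            raise PpfIntegrityError(f"{path}: unreadable header: {e}") from e
        if header.get("format") != _FORMAT_VERSION:
            raise PpfIntegrityError(
                f"{path}: unknown format version {header.get('format')!r}"
            )
        counts = np.zeros(N_PENTAMERS, dtype=np.int64)
        n_rows = 0
        for line in fh:
            if not line.strip():
                continue
            pentamer, value = line.rstrip("\n").split("\t")
            counts[encode_pentamer(pentamer)] = int(value)
            n_rows += 1
    if n_rows != header["n_nonzero"]:
        raise PpfIntegrityError(
            f"{path}: truncated (expected {header['n_nonzero']} rows, got {n_rows})"
        )
    if _table_digest(counts) != header["digest"]:
        raise PpfIntegrityError(f"{path}: digest mismatch")
    return PentamerTable(
        header["motif_class"],
        header["reference_name"],
        counts,
        header["n_windows"],
        header.get("metadata", {}),
    )
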