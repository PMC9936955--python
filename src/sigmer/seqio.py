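"""Sequence and raw-signal IO plus k-mer profiling.

FASTA goes through Biopython.  Raw signal uses a small documented native
container in either HDF5 (``.h5``/``.hdf5``; one group per read holding a
float32 ``signal`` dataset, optional ``segment_bounds``, and string/int
attributes for the ground truth) or NPZ (``.npz``; ``signal__<id>`` and
``bounds__<id>`` arrays plus one JSON metadata blob) flavour.  A minimal
FAST5 reader adapter shares the reader signature.

K-mer profiles are plain count maps; "canonical" counting collapses each
window onto the lexicographic minimum of the k-mer and its reverse
complement, so both-strand occurrences share a key.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
from Bio import SeqIO
from scipy.stats import rankdata

from .sim import Squiggle, encode_bases, revcomp

_BASES = "ACGT"


class FormatError(ValueError):
    """Malformed input file."""


class InputError(ValueError):
    """Invalid argument combination."""


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a FASTA file into ``[(record id, uppercased sequence), ...]``.

    Ambiguity codes are preserved here; k-mer counting skips any window
    containing a non-ACGT symbol.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    records = [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    return records


def write_fasta(path: str | Path, records: list[tuple[str, str]]) -> None:
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")


# ---------------------------------------------------------------------------
# k-mer profiles


@dataclass
class KmerProfile:
    """Counts of k-mers over one genome or readset."""

    k: int
    counts: dict[str, int]
    canonical: bool = True
    source_label: str = ""

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def get(self, kmer: str) -> int:
        key = canonical_kmer(kmer) if self.canonical else kmer
        return self.counts.get(key, 0)


@dataclass
class KmerRanking:
    """Fractional (average-tie) abundance ranks over a fixed k-mer list.

    Rank 1 is the most abundant k-mer.  Ties receive the average of the
    positions they straddle, so the rank sum is always N(N+1)/2.
    """

    kmers: list[str]
    rank: dict[str, float]

    def vector(self, order: list[str] | None = None) -> np.ndarray:
        order = order if order is not None else self.kmers
        return np.array([self.rank[m] for m in order], dtype=float)


def canonical_kmer(kmer: str) -> str:
    rc = revcomp(kmer)
    return kmer if kmer <= rc else rc


def _window_codes(seq: str, k: int) -> np.ndarray:
    """Base-4 codes of all valid (ACGT-only) k windows; invalid windows dropped."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    table = np.full(128, -1, dtype=np.int64)
    for i, b in enumerate(_BASES):
        table[ord(b)] = i
    codes = table[raw]
    if codes.size < k:
        return np.empty(0, dtype=np.int64)
    win = np.lib.stride_tricks.sliding_window_view(codes, k)
    valid = (win >= 0).all(axis=1)
    powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    fwd = win[valid] @ powers
    return fwd


def _rc_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Reverse-complement codes computed digit-wise."""
    out = np.zeros_like(codes)
    c = codes.copy()
    for j in range(k):
        digit = c % 4
        out = out * 4 + (3 - digit)
        c //= 4
    return out


def _decode(code: int, k: int) -> str:
    out = []
    for _ in range(k):
        out.append(_BASES[code % 4])
        code //= 4
    return "".join(reversed(out))


def count_kmers(
    sequences,
    k: int,
    canonical: bool = True,
    source_label: str = "",
) -> KmerProfile:
    """Sliding-window k-mer counts over one or more sequences.

    ``sequences`` may be strings or ``(id, sequence)`` pairs.  Windows
    containing non-ACGT symbols are skipped; sequences shorter than ``k``
    contribute nothing.
    """
    if k < 1:
        raise InputError(f"k must be >= 1, got {k}")
    if isinstance(sequences, str):
        sequences = [sequences]
    agg: dict[int, int] = {}
    for item in sequences:
        seq = item[1] if isinstance(item, tuple) else item
        codes = _window_codes(seq.upper(), k)
        if codes.size == 0:
            continue
        if canonical:
            codes = np.minimum(codes, _rc_codes(codes, k))
        uniq, cnt = np.unique(codes, return_counts=True)
        for u, c in zip(uniq.tolist(), cnt.tolist()):
            agg[u] = agg.get(u, 0) + c
    counts = {_decode(u, k): c for u, c in sorted(agg.items())}
    return KmerProfile(k=k, counts=counts, canonical=canonical, source_label=source_label)


def rank_by_abundance(profile: KmerProfile, kmer_set: list[str]) -> KmerRanking:
    """Rank ``kmer_set`` by abundance in ``profile`` (rank 1 = most abundant).

    Absent k-mers count zero; ties get fractional (average) ranks.
    """
    if not kmer_set:
        raise InputError("kmer_set must be non-empty")
    if len(set(kmer_set)) != len(kmer_set):
        raise InputError("kmer_set contains duplicates")
    counts = np.array([profile.get(m) for m in kmer_set], dtype=float)
    ranks = rankdata(-counts, method="average")
    return KmerRanking(kmers=list(kmer_set), rank=dict(zip(kmer_set, ranks.tolist())))


# ---------------------------------------------------------------------------
# signal containers

_SIGNAL_VERSION = "sigmer-signal-1"
_ATTR_FIELDS = ("source_sequence", "model_k", "source_ref", "source_start", "source_end", "strand")


def write_signals(
    path: str | Path,
    squiggles: list[Squiggle],
    subset_ids: list[str] | None = None,
) -> None:
    """Write squiggles to the native container (.h5/.hdf5 or .npz).

    ``subset_ids`` stores only the named reads (e.g. the flagged target-read
    archive); an unknown id raises ``LookupError``.
    """
    path = Path(path)
    by_id = {sq.read_id: sq for sq in squiggles}
    if subset_ids is None:
        chosen = list(squiggles)
    else:
        missing = [i for i in subset_ids if i not in by_id]
        if missing:
            raise LookupError(f"unknown read ids: {missing}")
        chosen = [by_id[i] for i in subset_ids]
    if path.suffix == ".npz":
        _write_npz(path, chosen)
    elif path.suffix in (".h5", ".hdf5"):
        _write_h5(path, chosen)
    else:
        raise FormatError(f"unsupported signal container extension: {path.suffix}")


def read_signals(path: str | Path) -> list[Squiggle]:
    """Read squiggles back in stored order (round-trip identity on samples)."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    if path.suffix == ".npz":
        return _read_npz(path)
    if path.suffix in (".h5", ".hdf5"):
        return _read_h5(path)
    raise FormatError(f"unsupported signal container extension: {path.suffix}")


def _meta(sq: Squiggle) -> dict:
    return {f: getattr(sq, f) for f in _ATTR_FIELDS if getattr(sq, f) is not None}


def _write_h5(path: Path, squiggles: list[Squiggle]) -> None:
    with h5py.File(path, "w") as fh:
        fh.attrs["version"] = _SIGNAL_VERSION
        for order, sq in enumerate(squiggles):
            grp = fh.create_group(sq.read_id)
            grp.attrs["order"] = order
            grp.create_dataset("signal", data=np.asarray(sq.samples, dtype=np.float32))
            if sq.segment_bounds is not None:
                grp.create_dataset("segment_bounds", data=np.asarray(sq.segment_bounds, dtype=np.int64))
            for key, val in _meta(sq).items():
                grp.attrs[key] = val


def _read_h5(path: Path) -> list[Squiggle]:
    out = []
    with h5py.File(path, "r") as fh:
        groups = sorted(fh.values(), key=lambda g: g.attrs.get("order", 0))
        for grp in groups:
            attrs = dict(grp.attrs)
            sq = Squiggle(
                read_id=grp.name.lstrip("/"),
                samples=np.asarray(grp["signal"][...], dtype=np.float32),
                segment_bounds=(
                    np.asarray(grp["segment_bounds"][...]) if "segment_bounds" in grp else None
                ),
            )
            for f in _ATTR_FIELDS:
                if f in attrs:
                    val = attrs[f]
                    if isinstance(val, bytes):
                        val = val.decode()
                    if isinstance(val, np.integer):
                        val = int(val)
                    setattr(sq, f, val)
            out.append(sq)
    return out


def _write_npz(path: Path, squiggles: list[Squiggle]) -> None:
    arrays = {}
    meta = {"version": _SIGNAL_VERSION, "ids": [], "attrs": {}}
    for sq in squiggles:
        meta["ids"].append(sq.read_id)
        meta["attrs"][sq.read_id] = _meta(sq)
        arrays[f"signal__{sq.read_id}"] = np.asarray(sq.samples, dtype=np.float32)
        if sq.segment_bounds is not None:
            arrays[f"bounds__{sq.read_id}"] = np.asarray(sq.segment_bounds, dtype=np.int64)
    arrays["meta"] = np.array(json.dumps(meta))
    np.savez(path, **arrays)


def _read_npz(path: Path) -> list[Squiggle]:
    data = np.load(path, allow_pickle=False)
    meta = json.loads(str(data["meta"]))
    out = []
    for rid in meta["ids"]:
        sq = Squiggle(
            read_id=rid,
            samples=np.asarray(data[f"signal__{rid}"], dtype=np.float32),
            segment_bounds=(
                np.asarray(data[f"bounds__{rid}"]) if f"bounds__{rid}" in data else None
            ),
        )
        for f, val in meta["attrs"].get(rid, {}).items():
            setattr(sq, f, val)
        out.append(sq)
    return out


def read_fast5(path: str | Path) -> list[Squiggle]:
    """Adapter for FAST5-style HDF5 files (same signature as read_signals).

    Walks the file for ``Signal`` datasets (single- and multi-read layouts),
    applying the standard ``(raw + offset) * range / digitisation`` pA
    conversion when channel calibration attributes are present.  Only raw
    signal is recovered; no ground-truth attributes.
    """
    path = Path(path)
    out: list[Squiggle] = []
    with h5py.File(path, "r") as fh:

        def visit(name, obj):
            if isinstance(obj, h5py.Dataset) and name.rsplit("/", 1)[-1] == "Signal":
                raw = np.asarray(obj[...], dtype=np.float64)
                parent = obj.parent
                # walk up looking for channel calibration
                node = parent
                cal = None
                while node is not None and cal is None:
                    for child_name in ("channel_id", "UniqueGlobalKey/channel_id"):
                        try:
                            child = node[child_name]
                        except (KeyError, TypeError):
                            continue
                        a = dict(child.attrs)
                        if {"digitisation", "offset", "range"} <= set(a):
                            cal = (float(a["digitisation"]), float(a["offset"]), float(a["range"]))
                    node = node.parent if node.name != "/" else None
                if cal is not None:
                    digitisation, offset, rng_ = cal
                    raw = (raw + offset) * rng_ / digitisation
                rid = parent.attrs.get("read_id", parent.name.lstrip("/"))
                if isinstance(rid, bytes):
                    rid = rid.decode()
                out.append(Squiggle(read_id=str(rid), samples=raw.astype(np.float32)))

        fh.visititems(visit)
    if not out:
        raise FormatError(f"no Signal datasets found in {path}")
    return out
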