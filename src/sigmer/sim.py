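"""Deterministic squiggle simulation.

A nanopore read is observed as a current trace ("squiggle"): while the DNA
strand ratchets through the pore, the ``model_k`` bases residing in the pore
set the electrical resistance, so each sequence context maps to a current
level.  This module provides a synthetic pore model (context -> level table)
and a simulator that turns base sequences into squiggles with ground-truth
base-to-sample segmentation, standing in for real MinION reads during
training and validation.

Simplifications relative to real devices: no signal drift, stalls, skips or
adapter signal, and i.i.d. Gaussian measurement noise.  Dwell times per
context are geometric with a configurable mean, matching the roughly
exponential residence times of the motor protein steps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

BASES = "ACGT"
_COMP = str.maketrans("ACGT", "TGCA")
_BASE_CODE = np.full(128, -1, dtype=np.int64)
for _i, _b in enumerate(BASES):
    _BASE_CODE[ord(_b)] = _i
    _BASE_CODE[ord(_b.lower())] = _i

#: pA range spanned by synthetic context levels, chosen to mimic the dynamic
#: range of an R9.4-style pore without shipping any proprietary level table.
LEVEL_RANGE = (60.0, 120.0)
DEFAULT_LEVEL_SPREAD = 1.5
DEFAULT_DWELL_MEAN = 10.0
DEFAULT_NOISE_SD = 2.0


class ParameterError(ValueError):
    """Invalid simulator parameter."""


class SequenceError(ValueError):
    """Sequence not simulatable (bad alphabet / too short)."""


def revcomp(seq: str) -> str:
    """Reverse complement of an ACGT string."""
    return seq.translate(_COMP)[::-1]


def encode_bases(seq: str) -> np.ndarray:
    """Map an ACGT string to integer codes 0..3; raises on other symbols."""
    codes = _BASE_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (codes < 0).any():
        bad = sorted({c for c in seq if c.upper() not in BASES})
        raise SequenceError(f"non-ACGT symbols in sequence: {bad}")
    return codes


@dataclass(frozen=True)
class PoreModel:
    """Synthetic k-mer -> current model.

    ``level_means[i]`` is the mean current (pA) emitted while context ``i``
    (base-4 encoded ``model_k``-mer) resides in the pore; ``level_spreads``
    is the per-context level standard deviation (constant by default).
    """

    model_k: int
    level_means: np.ndarray
    level_spreads: np.ndarray
    dwell_mean: float = DEFAULT_DWELL_MEAN
    noise_sd: float = DEFAULT_NOISE_SD
    seed: int = 0

    @property
    def n_contexts(self) -> int:
        return 4 ** self.model_k

    @property
    def level_table(self) -> dict[str, tuple[float, float]]:
        """Context string -> (mean pA, spread pA) mapping (built on demand)."""
        out = {}
        for code in range(self.n_contexts):
            ctx = decode_kmer(code, self.model_k)
            out[ctx] = (float(self.level_means[code]), float(self.level_spreads[code]))
        return out

    def context_codes(self, sequence: str) -> np.ndarray:
        """Base-4 codes of all ``model_k`` windows of ``sequence``."""
        codes = encode_bases(sequence)
        if codes.size < self.model_k:
            raise SequenceError(
                f"sequence length {codes.size} < model_k {self.model_k}"
            )
        win = np.lib.stride_tricks.sliding_window_view(codes, self.model_k)
        powers = 4 ** np.arange(self.model_k - 1, -1, -1, dtype=np.int64)
        return win @ powers

    def levels_for(self, sequence: str) -> np.ndarray:
        """Noise-free level sequence (one mean per context window)."""
        return self.level_means[self.context_codes(sequence)]


def decode_kmer(code: int, k: int) -> str:
    out = []
    for _ in range(k):
        out.append(BASES[code % 4])
        code //= 4
    return "".join(reversed(out))


def make_pore_model(
    seed: int,
    model_k: int = 6,
    dwell_mean: float = DEFAULT_DWELL_MEAN,
    noise_sd: float = DEFAULT_NOISE_SD,
) -> PoreModel:
    """Build a reproducible synthetic pore model.

    Level means are drawn i.i.d. uniform on ``LEVEL_RANGE`` from a
    counter-based (Philox) generator keyed by ``seed``, so identical
    ``(seed, model_k)`` always yields a bit-identical table.
    """
    if not 3 <= model_k <= 8:
        raise ParameterError(f"model_k must be in [3, 8], got {model_k}")
    if dwell_mean < 1:
        raise ParameterError(f"dwell_mean must be >= 1, got {dwell_mean}")
    if noise_sd < 0:
        raise ParameterError(f"noise_sd must be >= 0, got {noise_sd}")
    rng = np.random.Generator(np.random.Philox(key=seed))
    means = rng.uniform(*LEVEL_RANGE, size=4 ** model_k)
    spreads = np.full(4 ** model_k, DEFAULT_LEVEL_SPREAD)
    return PoreModel(
        model_k=model_k,
        level_means=means,
        level_spreads=spreads,
        dwell_mean=float(dwell_mean),
        noise_sd=float(noise_sd),
        seed=int(seed),
    )


@dataclass
class Squiggle:
    """One read's current trace plus optional ground truth.

    ``segment_bounds[i]`` is the end (exclusive) sample index of context
    segment ``i``; segment ``i`` therefore spans
    ``[segment_bounds[i-1], segment_bounds[i])`` with an implicit 0 start.
    When ``source_sequence`` is present there are
    ``len(source_sequence) - model_k + 1`` segments.
    """

    read_id: str
    samples: np.ndarray
    source_sequence: str | None = None
    segment_bounds: np.ndarray | None = None
    model_k: int | None = None
    source_ref: int | None = None
    source_start: int | None = None
    source_end: int | None = None
    strand: str | None = None

    def __len__(self) -> int:
        return int(self.samples.size)

    @property
    def n_segments(self) -> int:
        return 0 if self.segment_bounds is None else int(self.segment_bounds.size)

    def segment_range(self, first_ctx: int, last_ctx: int) -> tuple[int, int]:
        """Sample span [start, end) covering contexts first_ctx..last_ctx."""
        b = self.segment_bounds
        start = 0 if first_ctx == 0 else int(b[first_ctx - 1])
        return start, int(b[last_ctx])


def simulate_squiggle(
    sequence: str,
    pore: PoreModel,
    seed: int,
    fixed_dwell: int | None = None,
    read_id: str = "read",
) -> Squiggle:
    """Simulate the squiggle of ``sequence`` through ``pore``.

    Each context emits a run of geometric(mean ``pore.dwell_mean``) samples
    at its level mean plus Gaussian noise of sd ``pore.noise_sd``; pass
    ``fixed_dwell`` to pin every run length (useful for exact oracles).
    Deterministic in ``(sequence, pore, seed)``.
    """
    levels = pore.levels_for(sequence)
    n = levels.size
    rng = np.random.default_rng(seed)
    if fixed_dwell is not None:
        if fixed_dwell < 1:
            raise ParameterError("fixed_dwell must be >= 1")
        dwells = np.full(n, int(fixed_dwell))
    else:
        dwells = rng.geometric(1.0 / pore.dwell_mean, size=n)
    samples = np.repeat(levels, dwells)
    if pore.noise_sd > 0:
        samples = samples + rng.normal(0.0, pore.noise_sd, size=samples.size)
    return Squiggle(
        read_id=read_id,
        samples=samples.astype(np.float32),
        source_sequence=sequence,
        segment_bounds=np.cumsum(dwells),
        model_k=pore.model_k,
    )


def simulate_readset(
    references: list[str],
    n_reads: int,
    read_length_dist: tuple[float, float],
    pore: PoreModel,
    seed: int,
    strand: str | None = None,
) -> list[Squiggle]:
    """Simulate reads as random substrings of random references.

    Reads take a random strand (reverse complement for '-') unless
    ``strand`` pins it; lengths are truncated-normal, clipped to what the
    references can supply.  Each read records its source reference index,
    coordinates and strand so tests can regenerate it exactly.
    """
    if n_reads < 1:
        raise ParameterError("n_reads must be >= 1")
    if not references:
        raise ParameterError("references must be non-empty")
    mean_len, sd_len = read_length_dist
    max_len = max(len(r) for r in references)
    if mean_len > max_len:
        raise SequenceError(
            f"requested mean read length {mean_len} exceeds every reference "
            f"(longest is {max_len})"
        )
    rng = np.random.default_rng(seed)
    min_len = max(pore.model_k, 2 * pore.model_k)
    reads: list[Squiggle] = []
    for i in range(n_reads):
        length = int(np.clip(rng.normal(mean_len, sd_len), min_len, max_len))
        eligible = [j for j, r in enumerate(references) if len(r) >= length]
        ref_idx = int(eligible[rng.integers(len(eligible))])
        ref = references[ref_idx]
        start = int(rng.integers(0, len(ref) - length + 1))
        seq = ref[start : start + length]
        st = strand if strand is not None else ("+", "-")[int(rng.integers(2))]
        if st == "-":
            seq = revcomp(seq)
        sq = simulate_squiggle(
            seq,
            pore,
            seed=int(rng.integers(2 ** 31)),
            read_id=f"read{i:05d}",
        )
        sq.source_ref = ref_idx
        sq.source_start = start
        sq.source_end = start + length
        sq.strand = st
        reads.append(sq)
    return reads


def random_sequence(length: int, seed: int) -> str:
    """Uniform random ACGT sequence (convenience for synthetic references)."""
    rng = np.random.default_rng(seed)
    return "".join(BASES[c] for c in rng.integers(0, 4, size=length))
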