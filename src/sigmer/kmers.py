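"""K-mer selection machinery.

Three concerns live here:

* a Poisson false-positive model that guides the choice of k — how likely a
  random (non-target) read is to contain, by chance, every k-mer a detector
  library selected from the target sequence;
* discriminative-abundance selection for abundance-mode classification —
  k-mers whose frequency in the target genome departs most from the
  background genomes, in either direction;
* an evolutionary designer for detection-mode libraries — k-mers that are
  mutually dissimilar both in sequence (Smith-Waterman cap) and in signal
  (DTW between simulated squiggles), avoid long homopolymer runs, and sit
  in the mid range of abundance over a reference set.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .seqio import InputError, KmerProfile, count_kmers
from .sim import BASES, PoreModel

# ---------------------------------------------------------------------------
# Poisson false-positive model


@dataclass(frozen=True)
class FprConfig:
    """Inputs of the false-positive model.

    ``L_read``: length (bases) of a non-target read being scanned;
    ``L_target``: length of the target sequence the library was drawn from;
    ``library_size``: number of k-mer detectors available (|A|).
    """

    k: int
    L_read: float
    L_target: float
    library_size: int

    def __post_init__(self):
        if self.k < 1 or self.L_read < 0 or self.L_target < 0 or self.library_size < 0:
            raise InputError(f"invalid FprConfig: {self}")


def expected_occurrences(L: float, k: int) -> float:
    """Expected occurrences of one canonical k-mer in a random read: L*2*4^-k."""
    if L < 0 or k < 1:
        raise InputError("L must be >= 0 and k >= 1")
    return L * 2.0 * 4.0 ** (-k)


def p_at_least_one(L: float, k: int) -> float:
    """Poisson probability that a k-mer occurs at least once in length L."""
    return -np.expm1(-expected_occurrences(L, k))


def expected_hits(L_target: float, k: int, library_size: int) -> float:
    """Expected number of library k-mers present in the target: P(X>=1)*|A|."""
    if library_size < 0:
        raise InputError("library_size must be >= 0")
    return p_at_least_one(L_target, k) * library_size


def false_positive_rate(cfg: FprConfig) -> float:
    """Chance a random read contains all selected k-mers: P(X>=1)^E.

    Treats per-k-mer occurrences as independent; the Monte-Carlo check in
    the test-suite quantifies that approximation.
    """
    p = p_at_least_one(cfg.L_read, cfg.k)
    e = expected_hits(cfg.L_target, cfg.k, cfg.library_size)
    if e == 0:
        return 1.0
    if p == 0:
        return 0.0
    return float(p ** e)


def fpr_table(
    k_candidates,
    read_lengths=(30_000, 50_000),
    target_lengths=(600, 1_500, 30_000),
    library_size: int = 1_500,
) -> pd.DataFrame:
    """Full FPR grid over representative read/target lengths."""
    rows = []
    for k, lr, lt in itertools.product(k_candidates, read_lengths, target_lengths):
        rows.append(
            {
                "k": k,
                "L_read": lr,
                "L_target": lt,
                "fpr": false_positive_rate(FprConfig(k, lr, lt, library_size)),
            }
        )
    return pd.DataFrame(rows)


def choose_k(
    k_candidates,
    read_lengths=(30_000, 50_000),
    target_lengths=(600, 1_500, 30_000),
    library_size: int = 1_500,
) -> tuple[int, pd.DataFrame]:
    """Candidate k minimizing the worst-case FPR over the length grid."""
    k_candidates = list(k_candidates)
    if not k_candidates:
        raise InputError("k_candidates must be non-empty")
    table = fpr_table(k_candidates, read_lengths, target_lengths, library_size)
    worst = table.groupby("k")["fpr"].max()
    best = int(worst.idxmin())
    return best, table


def fpr_monte_carlo(
    k: int,
    L_read: int,
    n_selected: int,
    n_reads: int = 10_000,
    seed: int = 0,
) -> tuple[float, float]:
    """Empirical false-positive fraction for a fixed selected k-mer set.

    For each of ``n_reads`` uniform random reads of length ``L_read``,
    draws ``n_selected`` distinct random k-mers (the library k-mers found
    in the target, here saturated by construction) and tests whether the
    read contains every one of them on either strand — the event the
    closed form prices as P(X>=1)^E with E = n_selected.  The selected set
    is redrawn per read so the estimate averages over k-mer identity,
    matching the model's all-k-mers-equal premise (individual words
    deviate through their self-overlap structure).  Returns (empirical
    fraction, closed-form value); the gap measures the Poisson and
    independence approximations.
    """
    from .sim import revcomp

    rng = np.random.default_rng(seed)
    base_arr = np.frombuffer(b"ACGT", dtype=np.uint8)
    hits = 0
    for _ in range(n_reads):
        kmers: set[str] = set()
        while len(kmers) < n_selected:
            kmers.add("".join(BASES[c] for c in rng.integers(0, 4, size=k)))
        read = base_arr[rng.integers(0, 4, size=L_read)].tobytes().decode()
        if all(w in read or revcomp(w) in read for w in kmers):
            hits += 1
    # closed form with selection saturated: E = |A| exactly
    p = p_at_least_one(L_read, k)
    return hits / n_reads, float(p ** n_selected)


# ---------------------------------------------------------------------------
# discriminative-abundance selection (abundance mode)


def select_discriminative_kmers(
    target: KmerProfile,
    backgrounds: list[KmerProfile],
    n: int,
) -> list[str]:
    """Top-n k-mers separating the target genome from the backgrounds.

    Frequencies use a pseudo-frequency of 1/(total + 4^k) so absent k-mers
    score sensibly.  Each k-mer gets a signed, variance-stabilized score
    (f_target - mean(f_backgrounds)) / sqrt(pooled mean frequency), so both
    over- and under-represented k-mers ("vice versa") surface; the top n is
    split between the two tails in proportion to their sizes, topping up
    from the overall |score| order.  Ties break lexicographically.
    """
    if n < 1:
        raise InputError("n must be >= 1")
    if not backgrounds:
        raise InputError("need at least one background profile")
    k = target.k
    if any(b.k != k for b in backgrounds):
        raise InputError("profiles must share k")
    universe = sorted(set(target.counts) | set().union(*(set(b.counts) for b in backgrounds)))
    if n > len(universe):
        raise InputError(f"n={n} exceeds the {len(universe)} distinct k-mers available")

    def freqs(profile: KmerProfile) -> np.ndarray:
        total = profile.total
        denom = total + 4.0 ** k
        return np.array([(profile.counts.get(m, 0) + 1.0) / denom for m in universe])

    f_t = freqs(target)
    f_b = np.mean([freqs(b) for b in backgrounds], axis=0)
    pooled = (f_t + f_b) / 2.0
    score = (f_t - f_b) / np.sqrt(pooled)

    order = np.lexsort((universe, -np.abs(score)))  # |score| desc, kmer asc
    over = [i for i in order if score[i] > 0]
    under = [i for i in order if score[i] < 0]
    n_over_total, n_under_total = len(over), len(under)
    if n_over_total + n_under_total == 0:
        return [universe[i] for i in order[:n]]
    # overall |score| order decides; the proportional tail split only tops
    # up whichever tail the plain top-n would leave short
    picked = {int(i) for i in order[:n]}
    n_over = int(round(n * n_over_total / (n_over_total + n_under_total)))
    n_under = min(n - min(n_over, n_over_total), n_under_total)
    have_under = sum(1 for i in picked if score[i] < 0)
    for i in under:
        if have_under >= n_under or len(picked) > n:
            break
        if int(i) not in picked:
            picked.add(int(i))
            have_under += 1
    chosen = [int(i) for i in order if int(i) in picked]
    # drop weakest overall entries if the top-up overfilled
    return [universe[i] for i in chosen[:n]]


# ---------------------------------------------------------------------------
# sequence / signal dissimilarity kernels


def smith_waterman(
    a: str,
    b: str,
    match: int = 1,
    mismatch: int = -1,
    gap: int = -4,
) -> int:
    """Best local-alignment score (linear gap penalty); always >= 0."""
    n, m = len(a), len(b)
    prev = [0] * (m + 1)
    best = 0
    for i in range(1, n + 1):
        cur = [0] * (m + 1)
        ai = a[i - 1]
        for j in range(1, m + 1):
            s = prev[j - 1] + (match if ai == b[j - 1] else mismatch)
            s = max(s, prev[j] + gap, cur[j - 1] + gap, 0)
            cur[j] = s
            if s > best:
                best = s
        prev = cur
    return best


def dtw_distance(s1, s2) -> float:
    """Classic DTW with squared-difference local cost and symmetric steps.

    Full window, no band; 0 iff the two series are warp-identical.
    """
    s1 = np.asarray(s1, dtype=float)
    s2 = np.asarray(s2, dtype=float)
    if s1.size == 0 or s2.size == 0:
        raise InputError("dtw_distance requires non-empty vectors")
    n, m = s1.size, s2.size
    D = np.full((n + 1, m + 1), np.inf)
    D[0, 0] = 0.0
    for i in range(1, n + 1):
        cost = (s1[i - 1] - s2) ** 2
        row = D[i]
        prev = D[i - 1]
        for j in range(1, m + 1):
            row[j] = cost[j - 1] + min(prev[j], row[j - 1], prev[j - 1])
    return float(D[n, m])


def passes_homopolymer_filter(
    kmer: str,
    gc_run_max: int = 3,
    at_run_max: int = 4,
    combine_groups: bool = False,
) -> bool:
    """Reject k-mers with >= 4 G/C or >= 5 A/T of one base in a row.

    Homopolymer stretch lengths are hard to resolve in raw signal (the level
    does not change within the run).  ``combine_groups=True`` switches to
    counting runs of the combined {G,C} / {A,T} groups instead of runs of a
    single base.
    """
    group = {"G": "S", "C": "S", "A": "W", "T": "W"}
    key = (lambda c: group[c]) if combine_groups else (lambda c: c)
    for _, run in itertools.groupby(kmer, key=key):
        run = list(run)
        limit = gc_run_max if run[0] in "GC" else at_run_max
        if len(run) > limit:
            return False
    return True


def abundance_percentile_filter(
    candidates: list[str],
    reference_sequences: list[str],
    lower_pct: float = 10.0,
    upper_pct: float = 90.0,
    two_sided: bool = True,
    counts: dict[str, int] | None = None,
) -> list[str]:
    """Drop candidates in the outer abundance percentiles over the references.

    Counts each candidate (canonically) across ``reference_sequences`` and
    removes those below the ``lower_pct`` or above the ``upper_pct``
    percentile of the candidate count distribution — such k-mers are either
    too rare to be informative or too ubiquitous to discriminate.  With
    ``two_sided=False`` only the abundant side is removed.  Degenerate
    (all-equal) distributions retain everything.
    """
    if not reference_sequences and counts is None:
        raise InputError("reference set must be non-empty")
    if counts is None:
        k = len(candidates[0]) if candidates else 0
        profile = count_kmers(reference_sequences, k=k, canonical=True)
        counts = {m: profile.get(m) for m in candidates}
    values = np.array([counts[m] for m in candidates], dtype=float)
    if values.size == 0:
        return []
    hi = np.percentile(values, upper_pct)
    lo = np.percentile(values, lower_pct) if two_sided else -np.inf
    return [m for m, v in zip(candidates, values) if lo <= v <= hi]


# ---------------------------------------------------------------------------
# evolutionary library design (detection mode)


@dataclass
class LibraryDesignConfig:
    """Tunables of the evolutionary k-mer library designer.

    Defaults: 1500 k-mers of length 8, pairwise Smith-Waterman capped at 6
    under scores (match 1, mismatch -1, gap -4), single-base homopolymer
    runs capped at 3 (G/C) and 4 (A/T), outer-10-percentile abundance
    filter, and 10 mutation rounds whose per-sequence proposal count starts
    at 5 and drops by one every two rounds.
    """

    n_kmers: int = 1500
    k: int = 8
    sw_max: int = 6
    sw_match: int = 1
    sw_mismatch: int = -1
    sw_gap: int = -4
    gc_run_max: int = 3
    at_run_max: int = 4
    abundance_percentile: float = 10.0
    two_sided_percentile: bool = True
    rounds: int = 10
    mutation_schedule: tuple[int, ...] = (5, 5, 4, 4, 3, 3, 2, 2, 1, 1)
    seed: int = 0

    def __post_init__(self):
        if len(self.mutation_schedule) != self.rounds:
            raise InputError("mutation_schedule length must equal rounds")
        if any(a < b for a, b in zip(self.mutation_schedule, self.mutation_schedule[1:])):
            raise InputError("mutation_schedule must be non-increasing")


@dataclass
class LibraryDesignResult:
    kmers: list[str]
    dtw_trace: list[float]  # mean pairwise DTW after init and after each round
    accepted_per_round: list[int]
    feasible: bool
    messages: list[str] = field(default_factory=list)
    audit: pd.DataFrame | None = None
    #: fixed abundance thresholds (lo, hi) the percentile filter enforced
    percentile_bounds: tuple[float, float] | None = None


def _znorm(v: np.ndarray) -> np.ndarray:
    sd = v.std()
    if sd < 1e-9:
        return np.zeros_like(v)
    return (v - v.mean()) / sd


class _SquiggleCache:
    """z-normalized simulated level sequence per k-mer, memoized."""

    def __init__(self, pore: PoreModel):
        self.pore = pore
        self._cache: dict[str, np.ndarray] = {}

    def __call__(self, kmer: str) -> np.ndarray:
        if kmer not in self._cache:
            self._cache[kmer] = _znorm(self.pore.levels_for(kmer))
        return self._cache[kmer]


def _mutate(kmer: str, n_mut: int, rng: np.random.Generator) -> str:
    """Apply n point mutations at distinct positions, each to a new base."""
    seq = list(kmer)
    positions = rng.choice(len(seq), size=min(n_mut, len(seq)), replace=False)
    for p in positions:
        alternatives = [b for b in BASES if b != seq[p]]
        seq[p] = alternatives[int(rng.integers(3))]
    return "".join(seq)


def check_library_constraints(
    kmers: list[str],
    cfg: LibraryDesignConfig,
    reference_sequences: list[str],
    percentile_bounds: tuple[float, float] | None = None,
) -> pd.DataFrame:
    """Re-validate a designed library against its own hard constraints.

    Pass the ``percentile_bounds`` recorded by ``evolve_kmer_library`` to
    audit against the abundance band the design actually enforced;
    otherwise the band is recomputed from the member count distribution.
    """
    counts_profile = count_kmers(reference_sequences, k=cfg.k, canonical=True)
    counts = {m: counts_profile.get(m) for m in kmers}
    if percentile_bounds is not None:
        lo, hi = percentile_bounds
        kept = {m for m in kmers if lo <= counts[m] <= hi}
    else:
        kept = set(
            abundance_percentile_filter(
                kmers,
                reference_sequences=[],
                lower_pct=cfg.abundance_percentile,
                upper_pct=100.0 - cfg.abundance_percentile,
                two_sided=cfg.two_sided_percentile,
                counts=counts,
            )
        )
    rows = []
    for i, m in enumerate(kmers):
        sw_best = max(
            (
                smith_waterman(m, other, cfg.sw_match, cfg.sw_mismatch, cfg.sw_gap)
                for j, other in enumerate(kmers)
                if j != i
            ),
            default=0,
        )
        rows.append(
            {
                "kmer": m,
                "max_pairwise_sw": sw_best,
                "sw_ok": sw_best <= cfg.sw_max,
                "homopolymer_ok": passes_homopolymer_filter(m, cfg.gc_run_max, cfg.at_run_max),
                "abundance_count": counts[m],
                "percentile_ok": m in kept,
            }
        )
    return pd.DataFrame(rows)


def evolve_kmer_library(
    cfg: LibraryDesignConfig,
    pore: PoreModel,
    reference_sequences: list[str],
) -> LibraryDesignResult:
    """Evolve a library of mutually dissimilar k-mers.

    Starts from random k-mers satisfying the hard constraints, then runs
    ``cfg.rounds`` rounds; round r proposes ``mutation_schedule[r]`` point
    mutations per member and accepts a proposal only if (a) its maximum
    Smith-Waterman score to the rest stays <= ``sw_max``, (b) it passes the
    homopolymer filter, (c) its reference-set abundance lies inside the
    percentile band anchored to the candidate-pool distribution, and
    (d) both the minimum and the mean DTW distance between its simulated
    squiggle and the other members' squiggles strictly increase.  Rejected
    proposals are discarded outright (no repair); iteration order is by
    member index, so the run is fully determined by ``cfg.seed``.
    """
    if cfg.k < pore.model_k:
        raise InputError(f"k={cfg.k} must be >= pore model_k={pore.model_k}")
    if cfg.n_kmers > 4 ** cfg.k:
        raise InputError(f"n_kmers={cfg.n_kmers} exceeds 4^{cfg.k}")
    rng = np.random.default_rng(cfg.seed)
    squig = _SquiggleCache(pore)
    ref_profile = count_kmers(reference_sequences, k=cfg.k, canonical=True)
    messages: list[str] = []

    # --- initial population: pool of random homopolymer-clean k-mers,
    # percentile-filtered, then greedy SW-compatible selection
    pool_size = max(20 * cfg.n_kmers, 500)
    pool: list[str] = []
    seen: set[str] = set()
    attempts = 0
    while len(pool) < pool_size and attempts < 50 * pool_size:
        attempts += 1
        cand = "".join(BASES[c] for c in rng.integers(0, 4, size=cfg.k))
        if cand in seen:
            continue
        seen.add(cand)
        if passes_homopolymer_filter(cand, cfg.gc_run_max, cfg.at_run_max):
            pool.append(cand)
    # the abundance band is anchored once to the candidate-pool count
    # distribution (a fixed reference population), so the filter means the
    # same thing for every proposal in every round
    pool_counts = {m: ref_profile.get(m) for m in pool}
    pool_values = np.array(list(pool_counts.values()), dtype=float)
    hi = float(np.percentile(pool_values, 100.0 - cfg.abundance_percentile))
    lo = (
        float(np.percentile(pool_values, cfg.abundance_percentile))
        if cfg.two_sided_percentile
        else -np.inf
    )
    pool = [m for m in pool if lo <= pool_counts[m] <= hi]
    members: list[str] = []
    for cand in pool:
        if len(members) >= cfg.n_kmers:
            break
        if all(
            smith_waterman(cand, m, cfg.sw_match, cfg.sw_mismatch, cfg.sw_gap) <= cfg.sw_max
            for m in members
        ):
            members.append(cand)
    feasible = len(members) == cfg.n_kmers
    if not feasible:
        messages.append(
            f"could only seed {len(members)}/{cfg.n_kmers} k-mers under the "
            "hard constraints; returning partial library"
        )
        warnings.warn(messages[-1])
        if not members:
            return LibraryDesignResult([], [], [], False, messages, percentile_bounds=(lo, hi))

    def dtw_row(kmer: str, others: list[str]) -> np.ndarray:
        s = squig(kmer)
        return np.array([dtw_distance(s, squig(o)) for o in others])

    def mean_pairwise_dtw(kset: list[str]) -> float:
        if len(kset) < 2:
            return 0.0
        total, cnt = 0.0, 0
        for i in range(len(kset)):
            for j in range(i + 1, len(kset)):
                total += dtw_distance(squig(kset[i]), squig(kset[j]))
                cnt += 1
        return total / cnt

    dtw_trace = [mean_pairwise_dtw(members)]
    accepted_per_round: list[int] = []

    for n_mut in cfg.mutation_schedule:
        accepted = 0
        for i in range(len(members)):
            proposal = _mutate(members[i], n_mut, rng)
            if proposal in members:
                continue
            if not passes_homopolymer_filter(proposal, cfg.gc_run_max, cfg.at_run_max):
                continue
            others = members[:i] + members[i + 1 :]
            if any(
                smith_waterman(proposal, o, cfg.sw_match, cfg.sw_mismatch, cfg.sw_gap)
                > cfg.sw_max
                for o in others
            ):
                continue
            if not lo <= ref_profile.get(proposal) <= hi:
                continue
            if others:
                cur_row = dtw_row(members[i], others)
                new_row = dtw_row(proposal, others)
                if not (new_row.min() > cur_row.min() and new_row.mean() > cur_row.mean()):
                    continue
            members[i] = proposal
            accepted += 1
        accepted_per_round.append(accepted)
        dtw_trace.append(mean_pairwise_dtw(members))

    return LibraryDesignResult(
        kmers=members,
        dtw_trace=dtw_trace,
        accepted_per_round=accepted_per_round,
        feasible=feasible,
        messages=messages,
        percentile_bounds=(lo, hi),
    )
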