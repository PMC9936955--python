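"""Reproducible desk-scale studies on fully synthetic data.

Real validations of this kind of tool need MinION flowcells; these studies
reconstruct the same logic end to end with the built-in simulator:

* ``trio_abundance_study`` — three synthetic genomes with engineered
  marker-k-mer divergence (two "sister" genomes with similar marker
  profiles and one outgroup with a reshuffled profile), per-marker
  detectors trained on simulated squiggles, and one read stream per
  genome classified by minimal MSRD.
* ``amplicon_detection_study`` — a target amplicon against a random
  background, a k-mer library drawn from the amplicon, joint calibration
  of posterior threshold and read fraction, and read-level F1 on a fresh
  50/50 mixture with the flagged reads archived.

Every function is a pure function of its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import detector as det_mod
from .detector import (
    DetectorModel,
    ModelLibrary,
    calibrate_read_fraction,
    extract_examples,
    train_detector,
)
from .inference import SampleCall, run_abundance, run_read_detection
from .kmers import select_discriminative_kmers, smith_waterman
from .seqio import canonical_kmer, count_kmers, rank_by_abundance
from .sim import (
    BASES,
    PoreModel,
    Squiggle,
    make_pore_model,
    random_sequence,
    revcomp,
    simulate_readset,
    simulate_squiggle,
)


def _child_seed(rng: np.random.Generator) -> int:
    return int(rng.integers(2 ** 31))


def pick_marker_kmers(
    n: int,
    k: int,
    seed: int,
    sw_max: int = 6,
    forbidden: set[str] | None = None,
) -> list[str]:
    """Random marker k-mers: homopolymer-clean, distinct canonical forms,
    pairwise Smith-Waterman <= sw_max (so their squiggles stay separable)."""
    from .kmers import passes_homopolymer_filter

    rng = np.random.default_rng(seed)
    chosen: list[str] = []
    canon: set[str] = set(forbidden or ())
    attempts = 0
    while len(chosen) < n and attempts < 20000:
        attempts += 1
        cand = "".join(BASES[c] for c in rng.integers(0, 4, size=k))
        if canonical_kmer(cand) in canon:
            continue
        if not passes_homopolymer_filter(cand):
            continue
        if any(smith_waterman(cand, m) > sw_max for m in chosen):
            continue
        chosen.append(cand)
        canon.add(canonical_kmer(cand))
    if len(chosen) < n:
        raise RuntimeError(f"could not find {n} compatible marker k-mers")
    return chosen


def implant_markers(
    backbone: str,
    markers: list[str],
    copies: list[int],
    seed: int,
    slot: int = 50,
) -> str:
    """Overwrite non-overlapping slots of ``backbone`` with marker copies.

    The genome is partitioned into ``slot``-base slots; each implant
    overwrites a random offset inside its own slot, so implants never
    clobber each other.
    """
    total = sum(copies)
    n_slots = len(backbone) // slot
    if total > n_slots:
        raise ValueError(f"{total} implants do not fit in {n_slots} slots")
    rng = np.random.default_rng(seed)
    chosen_slots = rng.choice(n_slots, size=total, replace=False)
    seq = list(backbone)
    i = 0
    for marker, n_cop in zip(markers, copies):
        for _ in range(n_cop):
            s = int(chosen_slots[i]) * slot
            off = int(rng.integers(0, slot - len(marker) + 1))
            seq[s + off : s + off + len(marker)] = marker
            i += 1
    return "".join(seq)


@dataclass
class TrioStudy:
    genomes: dict[str, str]
    markers: list[str]
    copy_table: dict[str, list[int]]
    sisters: tuple[str, str]
    outgroup: str


def engineered_trio(
    seed: int,
    genome_length: int = 100_000,
    n_markers: int = 12,
    k: int = 9,
    base_copies: int = 25,
    copy_ratio: float = 1.3,
    sister_divergence: float = 0.02,
) -> TrioStudy:
    """Three synthetic genomes with engineered k-mer divergence.

    Genomes A and B are sisters: B's backbone is A's with point mutations
    at rate ``sister_divergence`` and its marker copy numbers are A's with
    three distance-4 rank swaps (clearly but moderately reshuffled).
    Outgroup C has an independent backbone and the copy-number vector
    reversed, so its marker ranking is maximally different.  Marker copy
    numbers grow geometrically (ratio ``copy_ratio``) so abundance ranks
    survive sampling noise; k defaults to 9 because the Poisson
    false-positive model favours k of 8-9 and the extra base gives each
    marker one more pore context of signal.
    """
    rng = np.random.default_rng(seed)
    markers = pick_marker_kmers(n_markers, k, _child_seed(rng))
    copies_a = [int(round(base_copies * copy_ratio ** i)) for i in range(n_markers)]
    copies_b = list(copies_a)
    # two disjoint distance-d rank swaps at the ends of the abundance range
    d = min(4, max(1, n_markers - 1))
    for i, j in ((0, d), (n_markers - 1 - d, n_markers - 1)):
        copies_b[i], copies_b[j] = copies_b[j], copies_b[i]
    copies_c = list(reversed(copies_a))

    backbone_a = random_sequence(genome_length, _child_seed(rng))
    # sister backbone: point-mutate A's
    arr = np.frombuffer(backbone_a.encode(), dtype=np.uint8).copy()
    n_mut = int(sister_divergence * genome_length)
    pos = rng.choice(genome_length, size=n_mut, replace=False)
    lut = {ord(b): [ord(x) for x in BASES if x != b] for b in BASES}
    for p in pos:
        arr[p] = lut[arr[p]][int(rng.integers(3))]
    backbone_b = arr.tobytes().decode()
    backbone_c = random_sequence(genome_length, _child_seed(rng))

    genomes = {
        "A": implant_markers(backbone_a, markers, copies_a, _child_seed(rng)),
        "B": implant_markers(backbone_b, markers, copies_b, _child_seed(rng)),
        "C": implant_markers(backbone_c, markers, copies_c, _child_seed(rng)),
    }
    return TrioStudy(
        genomes=genomes,
        markers=markers,
        copy_table={"A": copies_a, "B": copies_b, "C": copies_c},
        sisters=("A", "B"),
        outgroup="C",
    )


# ---------------------------------------------------------------------------
# detector training on simulated squiggles


def training_squiggles_for_kmer(
    kmer: str,
    pore: PoreModel,
    seed: int,
    n_positive_reads: int = 120,
    n_background_reads: int = 40,
    read_length: int = 400,
    flanked: str | None = None,
) -> list[Squiggle]:
    """Simulated ground-truth reads for one k-mer's detector.

    Positive reads are random sequences with the k-mer implanted at a
    random interior position; background reads are random sequences with
    any chance occurrence left in place (the extractor only uses verified
    non-overlapping windows as negatives).  Pass ``flanked`` (the k-mer
    with its native flanking bases, e.g. its amplicon neighbourhood) to
    implant the occurrence in the sequence context it will actually be
    scanned in.
    """
    insert = flanked if flanked is not None else kmer
    if kmer not in insert:
        raise ValueError("flanked sequence must contain the k-mer")
    rng = np.random.default_rng(seed)
    reads = []
    for i in range(n_positive_reads):
        seq = list(random_sequence(read_length, _child_seed(rng)))
        pos = int(rng.integers(50, read_length - 50 - len(insert)))
        seq[pos : pos + len(insert)] = insert
        reads.append(
            simulate_squiggle("".join(seq), pore, _child_seed(rng), read_id=f"pos{i:03d}")
        )
    for i in range(n_background_reads):
        reads.append(
            simulate_squiggle(
                random_sequence(read_length, _child_seed(rng)),
                pore,
                _child_seed(rng),
                read_id=f"bg{i:03d}",
            )
        )
    return reads


def _kmer_free_squiggles(
    kmer: str, pore: PoreModel, rng: np.random.Generator, n: int, length: int
) -> list[Squiggle]:
    out = []
    while len(out) < n:
        s = random_sequence(length, _child_seed(rng))
        if kmer in s:
            continue
        out.append(simulate_squiggle(s, pore, _child_seed(rng), read_id=f"bg{len(out)}"))
    return out


def train_kmer_detectors(
    kmers: list[str],
    pore: PoreModel,
    seed: int,
    window: int = det_mod.DEFAULT_WINDOW,
    epochs: int = 150,
    n_positive_reads: int = 120,
    n_eval_reads: int = 60,
    eval_read_length: int = 800,
    threshold_policy: str = "f1",
    fp_target: float = 0.5,
    flank_map: dict[str, str] | None = None,
    per_read_eval: int = 0,
    per_read_eval_length: int = 1_500,
    response_eval: bool = True,
) -> list[DetectorModel]:
    """Train one detector per k-mer on freshly simulated squiggles.

    Besides training, each detector gets (a) its posterior threshold
    calibrated on k-mer-free background reads and (b) a response
    calibration: per-occurrence sensitivity and background occurrence rate
    measured on ``n_eval_reads`` held-out simulated reads each.

    ``threshold_policy`` sets the operating point: ``"f1"`` grid-maximizes
    window-level F1 against negatives cut at scanning density (suits
    per-read detection, where the read fraction absorbs residual firing);
    ``"fp_target"`` picks the lowest grid threshold whose background firing
    stays at or below ``fp_target`` positions per ``eval_read_length``-base
    read (suits abundance counting, where uncorrected background dominates
    rank estimates).

    ``flank_map`` optionally supplies each k-mer's native flanking
    sequence for training positives.  With ``per_read_eval`` > 0, each
    detector additionally scans that many held-out positive/background
    reads of ``per_read_eval_length`` bases, stores the max-posterior
    distributions on the detector (``read_eval`` attribute), and moves its
    threshold to the grid point with the best read-level
    sensitivity-minus-background gap — the calibration that matters when
    single whole reads are being flagged.
    """
    rng = np.random.default_rng(seed)
    detectors = []
    for kmer in kmers:
        sqs = training_squiggles_for_kmer(
            kmer, pore, _child_seed(rng), n_positive_reads=n_positive_reads,
            flanked=(flank_map or {}).get(kmer),
        )
        pos, neg = extract_examples(
            sqs, kmer, window=window, neg_ratio=2.0, seed=_child_seed(rng),
            jitter_per_occurrence=3,
        )
        # scan-density negatives from dedicated background reads
        bg_cal = _kmer_free_squiggles(kmer, pore, rng, 20, eval_read_length)
        scan_neg = []
        for sq in bg_cal:
            x = det_mod.normalize_read(sq.samples)
            for s0 in range(0, x.size - window + 1, window // 4):
                scan_neg.append(x[s0 : s0 + window])
        det = train_detector(
            (pos, neg),
            arch_config={"target_kmer": kmer},
            seed=_child_seed(rng),
            epochs=epochs,
            scan_negatives=np.stack(scan_neg),
        )
        if threshold_policy == "fp_target":
            # strictest-necessary threshold: background firing positions per
            # read at or below fp_target, if any grid value achieves it
            posts = [det_mod.scan_posteriors(det, sq) for sq in bg_cal]
            posts = np.concatenate([p for p in posts if p is not None])
            grid = det_mod.THRESHOLD_GRID
            fp_per_read = (posts[None, :] >= grid[:, None]).sum(axis=1) / len(bg_cal)
            ok = np.flatnonzero(fp_per_read <= fp_target)
            det.posterior_threshold = float(grid[ok[0]] if ok.size else grid[-1])
        if response_eval:
            # response calibration on held-out reads (abundance mode needs it)
            hits = 0
            for i in range(n_eval_reads):
                seq = list(random_sequence(eval_read_length, _child_seed(rng)))
                p = int(rng.integers(50, eval_read_length - 50 - len(kmer)))
                seq[p : p + len(kmer)] = kmer
                sq = simulate_squiggle("".join(seq), pore, _child_seed(rng))
                hits += det_mod.scan_read(det, sq).count >= 1
            fp_occ, fp_samples = 0, 0
            for sq in _kmer_free_squiggles(kmer, pore, rng, n_eval_reads, eval_read_length):
                fp_occ += det_mod.scan_read(det, sq).count
                fp_samples += len(sq)
            det.sensitivity = hits / n_eval_reads
            det.fp_per_read = fp_occ / n_eval_reads
            det.fp_read_length = fp_samples / n_eval_reads
        if per_read_eval > 0:
            insert = (flank_map or {}).get(kmer, kmer)
            pos_max, neg_max = [], []
            for _ in range(per_read_eval):
                seq = list(random_sequence(per_read_eval_length, _child_seed(rng)))
                p = int(rng.integers(50, per_read_eval_length - 50 - len(insert)))
                seq[p : p + len(insert)] = insert
                post = det_mod.scan_posteriors(
                    det, simulate_squiggle("".join(seq), pore, _child_seed(rng))
                )
                pos_max.append(float(post.max()))
            for sq in _kmer_free_squiggles(kmer, pore, rng, per_read_eval, per_read_eval_length):
                post = det_mod.scan_posteriors(det, sq)
                neg_max.append(float(post.max()))
            pos_max = np.array(pos_max)
            neg_max = np.array(neg_max)
            gaps = (pos_max[None, :] >= det_mod.THRESHOLD_GRID[:, None]).mean(axis=1) - (
                neg_max[None, :] >= det_mod.THRESHOLD_GRID[:, None]
            ).mean(axis=1)
            j = int(np.argmax(gaps))
            det.posterior_threshold = float(det_mod.THRESHOLD_GRID[j])
            det.read_eval = {
                "gap": float(gaps[j]),
                "pos_max": pos_max,
                "neg_max": neg_max,
            }
        detectors.append(det)
    return detectors


def detector_response_ranking(
    genome: str,
    detectors: list[DetectorModel],
    pore: PoreModel,
    seed: int,
    n_reads: int,
    read_length: tuple[float, float],
):
    """Rank k-mers by the detector array's response to simulated genome reads.

    Accumulates each detector's merged occurrence count over ``n_reads``
    simulated reads of ``genome``, removes each detector's calibrated
    background baseline (scaled to the scanned signal amount) and divides
    by its sensitivity, then ranks the corrected totals (rank 1 = highest)
    — the same correction applied to observed streams, so reference and
    sample rankings live on the same scale.
    """
    from scipy.stats import rankdata

    from .seqio import KmerRanking

    reads = simulate_readset([genome], n_reads, read_length, pore, seed)
    kmers = [d.target_kmer for d in detectors]
    counts = np.zeros(len(detectors))
    for sq in reads:
        for j, det in enumerate(detectors):
            counts[j] += det_mod.scan_read(det, sq).count
    total_samples = sum(len(sq) for sq in reads)
    for j, det in enumerate(detectors):
        if det.has_response_calibration:
            baseline = det.fp_per_read * total_samples / max(det.fp_read_length, 1.0)
            counts[j] = max(counts[j] - baseline, 0.0) / max(det.sensitivity, 0.05)
    ranks = rankdata(-counts, method="average")
    return KmerRanking(kmers=kmers, rank=dict(zip(kmers, ranks.tolist())))


# ---------------------------------------------------------------------------
# abundance study


@dataclass
class TrioResult:
    trio: TrioStudy
    library: ModelLibrary
    calls: dict[str, SampleCall] = field(default_factory=dict)
    final_msrd: dict[str, dict[str, float]] = field(default_factory=dict)
    detector_f1: dict[str, float] = field(default_factory=dict)

    @property
    def correct_calls(self) -> int:
        return sum(1 for sp, call in self.calls.items() if call.best_species == sp)

    def sister_ordering_ok(self) -> bool:
        """For each sister stream, the non-source sister beats the outgroup."""
        a, b = self.trio.sisters
        c = self.trio.outgroup
        return (
            self.final_msrd[a][b] < self.final_msrd[a][c]
            and self.final_msrd[b][a] < self.final_msrd[b][c]
        )


def trio_abundance_study(
    seed: int,
    genome_length: int = 100_000,
    n_markers: int = 12,
    n_select: int = 12,
    n_reads: int = 500,
    read_length: tuple[float, float] = (1_200.0, 300.0),
    model_k: int = 6,
    epochs: int = 150,
    update_every: int = 50,
) -> TrioResult:
    """Full abundance-mode recovery experiment on the engineered trio.

    Selects discriminative k-mers from the genomes, trains per-k-mer
    detectors on simulated squiggles, then streams ``n_reads`` simulated
    reads per genome through the array; each stream should call its source
    genome (strictly minimal MSRD).
    """
    rng = np.random.default_rng(seed)
    pore = make_pore_model(_child_seed(rng), model_k=model_k)
    trio = engineered_trio(_child_seed(rng), genome_length=genome_length, n_markers=n_markers)

    profiles = {
        sp: count_kmers(g, k=len(trio.markers[0]), canonical=True, source_label=sp)
        for sp, g in trio.genomes.items()
    }
    # over-request candidates, then enforce mutual sequence dissimilarity:
    # implanted repeats make their shift-by-one k-mers discriminative too,
    # and an array of near-identical detectors carries no extra information
    candidates = select_discriminative_kmers(
        profiles["A"], [profiles["B"], profiles["C"]], n=min(8 * n_select, 4 ** len(trio.markers[0]))
    )
    marker_canon = {canonical_kmer(m): m for m in trio.markers}
    selected: list[str] = []
    seen_canon: set[str] = set()
    for cand in candidates:
        cand = marker_canon.get(canonical_kmer(cand), cand)
        if canonical_kmer(cand) in seen_canon:
            continue
        if any(smith_waterman(cand, m) > 6 or smith_waterman(cand, revcomp(m)) > 6 for m in selected):
            continue
        selected.append(cand)
        seen_canon.add(canonical_kmer(cand))
        if len(selected) == n_select:
            break

    detectors = train_kmer_detectors(selected, pore, _child_seed(rng), epochs=epochs)
    # reference rankings in detector-response space: the trained array is
    # run over simulated reads of each candidate genome, so detector
    # idiosyncrasies (sensitivity, genome-specific confusable loci) affect
    # reference and sample identically and cancel in the rank comparison
    rankings = {
        sp: detector_response_ranking(
            genome, detectors, pore, _child_seed(rng), n_reads, read_length
        )
        for sp, genome in trio.genomes.items()
    }
    library = ModelLibrary(
        detectors=detectors, mode="abundance", reference_rankings=rankings
    )

    result = TrioResult(
        trio=trio,
        library=library,
        detector_f1={d.target_kmer: d.training_f1 for d in detectors},
    )
    for sp, genome in trio.genomes.items():
        reads = simulate_readset(
            [genome], n_reads, read_length, pore, _child_seed(rng)
        )
        _state, call = run_abundance(reads, library, update_every=update_every)
        result.calls[sp] = call
        result.final_msrd[sp] = call.final_msrd
    return result


# ---------------------------------------------------------------------------
# read-detection study


def signal_distinctiveness(kmer: str, pore: PoreModel) -> float:
    """How confusable a k-mer's squiggle template is in unrelated signal.

    Spurious matches to a template level come from two sources: contexts
    whose level is similar, and — dominantly — level *transitions*, whose
    smoothed signal sweeps through every value between the two segment
    levels.  The probability that a random transition crosses a level at
    table quantile q is 2q(1-q), maximal mid-range and vanishing at the
    edges of the level range.  Each context of the k-mer scores
    -log(2q(1-q) + 0.05) and the scores add, so k-mers whose levels hug
    the edges of the current range (rarely swept, sparsely collided) score
    highest and make the most separable detectors.
    """
    codes = pore.context_codes(kmer)
    ranks = np.argsort(np.argsort(pore.level_means))
    q = (ranks[codes] + 0.5) / pore.level_means.size
    crossing = 2.0 * q * (1.0 - q)
    return float(-np.log(crossing + 0.05).sum())


def pick_amplicon_kmers(
    amplicon: str,
    n: int,
    k: int,
    seed: int,
    pore: PoreModel | None = None,
    sw_max: int = 6,
) -> list[str]:
    """Pick n mutually dissimilar k-mers from an amplicon.

    When a pore model is given, candidates are taken in order of signal
    distinctiveness (least-confusable squiggle templates first), which is
    what makes their detectors separable from background signal; otherwise
    candidate order is random.  Candidates sharing a canonical form,
    failing the homopolymer filter or locally aligning to an already
    chosen k-mer (Smith-Waterman > ``sw_max``) are skipped.
    """
    from .kmers import passes_homopolymer_filter

    rng = np.random.default_rng(seed)
    positions = np.arange(len(amplicon) - k + 1)
    if pore is not None:
        scores = np.array(
            [
                signal_distinctiveness(amplicon[p : p + k], pore)
                for p in positions
            ]
        )
        order = positions[np.argsort(-scores, kind="stable")]
    else:
        order = rng.permutation(positions)
    chosen: list[str] = []
    canon: set[str] = set()
    for p in order:
        cand = amplicon[p : p + k]
        if canonical_kmer(cand) in canon:
            continue
        if not passes_homopolymer_filter(cand):
            continue
        if any(smith_waterman(cand, m) > sw_max for m in chosen):
            continue
        chosen.append(cand)
        canon.add(canonical_kmer(cand))
        if len(chosen) == n:
            return chosen
    raise RuntimeError(f"amplicon yields only {len(chosen)} compatible k-mers")


@dataclass
class AmpliconResult:
    amplicon: str
    library: ModelLibrary
    posterior_threshold: float
    read_fraction: float
    calibration_f1: float
    test_f1: float
    test_precision: float
    test_recall: float
    call: SampleCall
    n_test_reads: int


def _amplicon_reads(
    amplicon: str,
    background_length: int,
    n_target: int,
    n_background: int,
    pore: PoreModel,
    rng: np.random.Generator,
    prefix: str,
) -> tuple[list[Squiggle], np.ndarray]:
    """Directional amplicon reads (plus strand, slightly truncated) mixed
    with random background reads of comparable length; labels returned."""
    reads, labels = [], []
    for i in range(n_target):
        lo = int(rng.integers(0, len(amplicon) // 10 + 1))
        hi = len(amplicon) - int(rng.integers(0, len(amplicon) // 10 + 1))
        sq = simulate_squiggle(
            amplicon[lo:hi], pore, _child_seed(rng), read_id=f"{prefix}_t{i:03d}"
        )
        reads.append(sq)
        labels.append(True)
    for i in range(n_background):
        sq = simulate_squiggle(
            random_sequence(background_length, _child_seed(rng)),
            pore,
            _child_seed(rng),
            read_id=f"{prefix}_b{i:03d}",
        )
        reads.append(sq)
        labels.append(False)
    order = rng.permutation(len(reads))
    return [reads[i] for i in order], np.array(labels)[order]


def amplicon_detection_study(
    seed: int,
    amplicon_length: int = 1_500,
    n_kmers: int = 16,
    n_candidates: int = 24,
    k: int = 9,
    n_calibration: int = 60,
    n_test: int = 60,
    model_k: int = 6,
    epochs: int = 150,
    output_path=None,
) -> AmpliconResult:
    """Read-detection experiment: target amplicon vs random background.

    ``n_candidates`` detector candidates are trained for the most
    signal-distinctive k-mers of a synthetic target amplicon (each trained
    on occurrences in its native amplicon context and given a read-level
    threshold from held-out reads); the ``n_kmers`` with the best held-out
    read-level gaps form the library — individual k-mer templates vary
    widely in how separable their squiggles are from background signal, so
    building a surplus and keeping the separable ones is part of library
    design.  Posterior thresholds and the read fraction are then jointly
    calibrated on a labeled mixture, and read-level precision/recall/F1
    are measured on a fresh 50/50 mixture, archiving flagged reads when
    ``output_path`` is given.  Amplicon reads are simulated in a fixed
    orientation, as for a directional (e.g. cDNA) protocol.
    """
    rng = np.random.default_rng(seed)
    pore = make_pore_model(_child_seed(rng), model_k=model_k)
    amplicon = random_sequence(amplicon_length, _child_seed(rng))
    kmers = pick_amplicon_kmers(amplicon, n_candidates, k, _child_seed(rng), pore=pore)
    flank_map = {}
    for m in kmers:
        p = amplicon.find(m)
        flank_map[m] = amplicon[max(0, p - 25) : p + len(m) + 25]

    candidates = train_kmer_detectors(
        kmers,
        pore,
        _child_seed(rng),
        epochs=epochs,
        flank_map=flank_map,
        per_read_eval=40,
        per_read_eval_length=amplicon_length,
        response_eval=False,
    )
    candidates.sort(key=lambda d: d.read_eval["gap"], reverse=True)
    detectors = candidates[:n_kmers]
    library = ModelLibrary(
        detectors=detectors,
        mode="read_detection",
        read_fraction_threshold=0.5,
        sample_fraction_threshold=0.1,
    )

    cal_reads, cal_labels = _amplicon_reads(
        amplicon, amplicon_length, n_calibration // 2, n_calibration - n_calibration // 2,
        pore, rng, "cal",
    )
    t, f, cal_f1 = calibrate_read_fraction(library, cal_reads, cal_labels)

    test_reads, test_labels = _amplicon_reads(
        amplicon, amplicon_length, n_test // 2, n_test - n_test // 2, pore, rng, "test"
    )
    call = run_read_detection(test_reads, library, output_path=output_path)
    flags = np.array([call.per_read_flags[sq.read_id] for sq in test_reads])
    tp = int((flags & test_labels).sum())
    fp = int((flags & ~test_labels).sum())
    fn = int((~flags & test_labels).sum())
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else 0.0
    return AmpliconResult(
        amplicon=amplicon,
        library=library,
        posterior_threshold=t,
        read_fraction=f,
        calibration_f1=cal_f1,
        test_f1=f1,
        test_precision=precision,
        test_recall=recall,
        call=call,
        n_test_reads=len(test_reads),
    )
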