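"""Per-k-mer detector networks and the serialized model library.

Each detector is a small conv net (see ``sigmer.nn``) that maps a fixed
window of median/MAD-normalized current samples to the posterior
probability that its target k-mer's signal lies inside.  Detectors are
independently trained and interchangeable: a library is just an ordered
collection of detectors plus aggregation-mode configuration, so detection
can be re-targeted by recombining saved detectors without retraining.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .nn import TinyConvNet, TrainingError
from .seqio import InputError, KmerRanking
from .sim import Squiggle

LIBRARY_VERSION = "sigmer-library-1"

#: posterior-threshold calibration grid: 0.75 .. 0.999 in steps of 0.001
THRESHOLD_GRID = np.round(np.linspace(0.75, 0.999, 250), 3)

DEFAULT_WINDOW = 200
DEFAULT_P_MAX = 50_000


class DataError(ValueError):
    """Unusable training/validation data."""


class CalibrationError(ValueError):
    """Calibration impossible (e.g. single-class validation set)."""


class LibraryFormatError(ValueError):
    """Unreadable or incompatible library artifact."""


def normalize_read(samples: np.ndarray) -> np.ndarray:
    """Median/MAD normalization of a read's current trace."""
    x = np.asarray(samples, dtype=np.float32)
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    return (x - med) / (1.4826 * mad + 1e-6)




def model_objective(f1: float, p_c: int, p_max: int, lam: float = 0.01) -> float:
    """Size-penalized model-selection loss: (1 - F1) + lam * p_c / p_max."""
    if not 0.0 <= f1 <= 1.0:
        raise InputError(f"f1 must be in [0, 1], got {f1}")
    if not 0 <= p_c <= p_max:
        raise InputError(f"need 0 <= p_c <= p_max, got p_c={p_c}, p_max={p_max}")
    return (1.0 - f1) + lam * p_c / p_max


# ---------------------------------------------------------------------------
# training-example extraction


def _occurrence_spans(sq: Squiggle, kmer: str, model_k: int) -> list[tuple[int, int]]:
    """Sample spans [s0, s1) of every exact occurrence of kmer in the read."""
    seq = sq.source_sequence
    spans = []
    start = seq.find(kmer)
    while start != -1:
        last_ctx = start + len(kmer) - model_k
        if last_ctx >= start:  # kmer at least model_k long
            spans.append(sq.segment_range(start, last_ctx))
        start = seq.find(kmer, start + 1)
    return spans


def extract_examples(
    squiggles: list[Squiggle],
    kmer: str,
    window: int = DEFAULT_WINDOW,
    neg_ratio: float = 1.0,
    seed: int = 0,
    jitter_per_occurrence: int = 2,
) -> tuple[np.ndarray, np.ndarray]:
    """Cut positive/negative training windows from ground-truth squiggles.

    Positives are windows containing the full signal span of an occurrence
    of ``kmer`` (placement jittered so the net cannot latch onto position);
    negatives are windows at least one window-length away from every
    occurrence.  Reads are median/MAD-normalized before cutting, matching
    what the detector sees when scanning.  Raises DataError if no squiggle
    contains the k-mer.
    """
    rng = np.random.default_rng(seed)
    positives, negatives = [], []
    for sq in squiggles:
        if sq.source_sequence is None or sq.segment_bounds is None:
            continue
        model_k = sq.model_k
        if model_k is None or len(kmer) < model_k:
            raise InputError("squiggles must carry model_k <= len(kmer)")
        x = normalize_read(sq.samples)
        if x.size < window:
            continue
        spans = _occurrence_spans(sq, kmer, model_k)
        for s0, s1 in spans:
            if s1 - s0 > window:
                continue  # pathologically long dwell; skip
            lo = max(0, s1 - window)
            hi = min(x.size - window, s0)
            if hi < lo:
                continue
            for _ in range(jitter_per_occurrence):
                start = int(rng.integers(lo, hi + 1))
                positives.append(x[start : start + window])
        for start in range(0, x.size - window + 1, window // 2):
            end = start + window
            if all(end + window <= s0 or start - window >= s1 for s0, s1 in spans):
                negatives.append(x[start:end])
    if not positives:
        raise DataError(f"no occurrences of k-mer {kmer} in the provided squiggles")
    if not negatives:
        raise DataError(f"no clean negative windows available for k-mer {kmer}")
    n_neg = max(1, int(round(neg_ratio * len(positives))))
    if n_neg < len(negatives):
        keep = rng.choice(len(negatives), size=n_neg, replace=False)
        negatives = [negatives[i] for i in sorted(keep)]
    return (
        np.stack(positives).astype(np.float32),
        np.stack(negatives).astype(np.float32),
    )


# ---------------------------------------------------------------------------
# detector model


@dataclass
class DetectorModel:
    """One trained per-k-mer classifier with its calibrated threshold.

    ``sensitivity`` (per-occurrence detection rate) and ``fp_per_read``
    (spurious occurrence count per background read, at the calibrated
    threshold, for the read length named by ``fp_read_length``) are
    response-calibration figures measured on held-out simulated reads at
    training time; abundance mode uses them to convert raw occurrence
    counts into unbiased abundance estimates.
    """

    target_kmer: str
    net: TinyConvNet
    posterior_threshold: float = float(THRESHOLD_GRID[0])
    training_f1: float = float("nan")
    sensitivity: float = float("nan")
    fp_per_read: float = float("nan")
    fp_read_length: float = float("nan")

    @property
    def input_window(self) -> int:
        return self.net.window

    @property
    def parameter_count(self) -> int:
        return self.net.n_params

    @property
    def has_response_calibration(self) -> bool:
        return np.isfinite(self.sensitivity) and np.isfinite(self.fp_per_read)


def _f1_from_preds(preds: np.ndarray, y: np.ndarray) -> np.ndarray:
    """F1 for each row of a (T, n) boolean prediction matrix."""
    y = y.astype(bool)
    tp = (preds & y).sum(axis=-1)
    fp = preds.sum(axis=-1) - tp
    fn = y.sum() - tp
    denom = 2 * tp + fp + fn
    out = np.zeros(np.shape(denom), dtype=float)
    np.divide(2 * tp, denom, out=out, where=denom > 0)
    return out


def train_detector(
    examples: tuple[np.ndarray, np.ndarray],
    arch_config: dict | None = None,
    seed: int = 0,
    epochs: int = 150,
    lr: float = 3e-3,
    p_max: int = DEFAULT_P_MAX,
    noise_aug: float = 0.08,
    scan_negatives: np.ndarray | None = None,
) -> DetectorModel:
    """Train one detector on (positive, negative) window arrays.

    Uses an 80/20 stratified split; training adds light Gaussian noise
    augmentation and keeps the weights with the best validation loss.  The
    held-out F1 (at posterior 0.5) is recorded and the posterior threshold
    is grid-calibrated on the held-out windows; pass ``scan_negatives``
    (extra negative windows cut at scanning density from background reads)
    to calibrate the threshold at a scan-realistic class balance.  Fully
    deterministic given ``seed``.
    """
    positives, negatives = examples
    if len(positives) == 0 or len(negatives) == 0:
        raise DataError("both classes must be non-empty")
    kmer = (arch_config or {}).get("target_kmer", "?")
    window = positives.shape[-1]
    in_channels = positives.shape[1] if positives.ndim == 3 else 1
    cfg = dict(arch_config or {})
    cfg.pop("target_kmer", None)
    net = TinyConvNet(
        window=window,
        in_channels=in_channels,
        seed=seed,
        **{k: v for k, v in cfg.items() if k in ("channels", "kernel", "pool")},
    )
    if net.n_params > p_max:
        raise InputError(f"architecture has {net.n_params} parameters > p_max={p_max}")

    rng = np.random.default_rng(seed)

    def split(arr):
        idx = rng.permutation(len(arr))
        n_val = max(1, int(round(0.2 * len(arr))))
        return arr[idx[n_val:]], arr[idx[:n_val]]

    pos_tr, pos_va = split(positives)
    neg_tr, neg_va = split(negatives)
    X_tr = np.concatenate([pos_tr, neg_tr])
    y_tr = np.concatenate([np.ones(len(pos_tr)), np.zeros(len(neg_tr))])
    X_va = np.concatenate([pos_va, neg_va])
    y_va = np.concatenate([np.ones(len(pos_va)), np.zeros(len(neg_va))])

    net.fit(
        X_tr, y_tr, epochs=epochs, lr=lr, seed=seed,
        noise_aug=noise_aug, X_val=X_va, y_val=y_va, loss_tol=5e-4,
    )
    post_va = net.predict_proba(X_va)
    f1 = float(_f1_from_preds(post_va >= 0.5, y_va))
    det = DetectorModel(target_kmer=kmer, net=net, training_f1=f1)
    if scan_negatives is not None and len(scan_negatives):
        X_cal = np.concatenate([pos_va, np.asarray(scan_negatives, dtype=np.float32)])
        y_cal = np.concatenate([np.ones(len(pos_va)), np.zeros(len(scan_negatives))])
    else:
        X_cal, y_cal = X_va, y_va
    det.posterior_threshold = calibrate_threshold(det, X_cal, y_cal)
    return det


def random_architecture_search(
    examples: tuple[np.ndarray, np.ndarray],
    n_trials: int = 5,
    seed: int = 0,
    p_max: int = DEFAULT_P_MAX,
    lam: float = 0.01,
    epochs: int = 60,
) -> tuple[DetectorModel, list[dict]]:
    """Optional hook: minimize the size-penalized objective over random nets.

    Samples small conv architectures (channel widths and kernel size),
    trains each on ``examples`` and scores it with
    ``model_objective(F1, p_c, p_max, lam)``; returns the best detector
    and the per-trial audit trail.  Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    widths = (4, 8, 16, 32)
    trials: list[dict] = []
    best: tuple[float, DetectorModel] | None = None
    for t in range(n_trials):
        n_blocks = int(rng.integers(2, 4))
        arch = {
            "channels": tuple(int(widths[i]) for i in rng.integers(0, len(widths), n_blocks)),
            "kernel": int(rng.choice((7, 9, 11))),
        }
        det = train_detector(
            examples, arch_config=arch, seed=int(rng.integers(2 ** 31)),
            epochs=epochs, p_max=p_max,
        )
        score = model_objective(det.training_f1, det.parameter_count, p_max, lam)
        trials.append({**arch, "f1": det.training_f1, "p_c": det.parameter_count, "objective": score})
        if best is None or score < best[0]:
            best = (score, det)
    return best[1], trials


def grid_search_threshold(posteriors: np.ndarray, labels: np.ndarray) -> float:
    """Grid value maximizing F1; ties break toward the lowest threshold."""
    posteriors = np.asarray(posteriors, dtype=float)
    labels = np.asarray(labels).astype(bool)
    if labels.all() or not labels.any():
        raise CalibrationError("validation set must contain both classes")
    if np.ptp(posteriors) == 0:
        warnings.warn("degenerate posteriors (all equal); returning grid minimum")
        return float(THRESHOLD_GRID[0])
    preds = posteriors[None, :] >= THRESHOLD_GRID[:, None]
    f1 = _f1_from_preds(preds, labels)
    return float(THRESHOLD_GRID[int(np.argmax(f1))])


def calibrate_threshold(detector: DetectorModel, X_val: np.ndarray, y_val: np.ndarray) -> float:
    """Calibrate a detector's posterior threshold on validation windows."""
    return grid_search_threshold(detector.net.predict_proba(X_val), y_val)


# ---------------------------------------------------------------------------
# scanning


@dataclass
class ScanResult:
    count: int
    max_posterior: float
    n_positions: int = 0
    short_read: bool = False


def scan_posteriors(detector: DetectorModel, squiggle: Squiggle) -> np.ndarray | None:
    """Posterior per window position over the whole read (None if too short).

    The convolution stack runs once over the full normalized read; each
    position's posterior is the head applied to a window-sized max-pooled
    span of the feature map, equivalent to scanning with a dense stride.
    """
    if len(squiggle) < detector.input_window:
        return None
    net = detector.net
    x = normalize_read(squiggle.samples)
    feats = net.conv_features(x[None, :])[0]  # (F, M)
    wu = net.window_units
    if feats.shape[1] < wu:
        return None
    wins = np.lib.stride_tricks.sliding_window_view(feats, wu, axis=1)  # (F, P, wu)
    pooled = wins.max(axis=2).T  # (P, F)
    return net.head(pooled)


def scan_read(detector: DetectorModel, squiggle: Squiggle) -> ScanResult:
    """Count merged occurrences of the detector's k-mer in one read.

    Window positions whose posterior clears the calibrated threshold are
    merged when closer than one window-length, so one physical occurrence
    seen by several overlapping windows counts once.
    """
    post = scan_posteriors(detector, squiggle)
    if post is None:
        return ScanResult(count=0, max_posterior=0.0, short_read=True)
    fire = np.flatnonzero(post >= detector.posterior_threshold)
    wu = detector.net.window_units
    if fire.size == 0:
        count = 0
    else:
        count = 1 + int((np.diff(fire) >= wu).sum())
    return ScanResult(count=count, max_posterior=float(post.max()), n_positions=post.size)


def max_posterior_matrix(
    detectors: list[DetectorModel], reads: list[Squiggle]
) -> np.ndarray:
    """(reads x detectors) max window posterior; -inf for too-short reads."""
    M = np.full((len(reads), len(detectors)), -np.inf)
    for i, sq in enumerate(reads):
        for j, det in enumerate(detectors):
            post = scan_posteriors(det, sq)
            if post is not None:
                M[i, j] = post.max()
    return M


# ---------------------------------------------------------------------------
# library


@dataclass
class ModelLibrary:
    """Ordered detector array plus aggregation-mode configuration."""

    detectors: list[DetectorModel]
    mode: str  # "abundance" | "read_detection"
    read_fraction_threshold: float | None = None
    sample_fraction_threshold: float = 0.1
    reference_rankings: dict[str, KmerRanking] = field(default_factory=dict)

    def __post_init__(self):
        if self.mode not in ("abundance", "read_detection"):
            raise InputError(f"unknown mode: {self.mode}")
        kmers = [d.target_kmer for d in self.detectors]
        if len(set(kmers)) != len(kmers):
            raise InputError("detector target k-mers must be unique")

    @property
    def kmers(self) -> list[str]:
        return [d.target_kmer for d in self.detectors]


def _logit(p):
    p = np.clip(p, 1e-6, 1 - 1e-6)
    return np.log(p / (1 - p))


def calibrate_read_fraction(
    library: ModelLibrary,
    reads: list[Squiggle],
    labels: np.ndarray,
    fraction_grid: np.ndarray | None = None,
    offset_grid: np.ndarray | None = None,
) -> tuple[float, float, float]:
    """Jointly calibrate posterior thresholds and read fraction on labeled reads.

    The posterior dimension of the search is a shared logit offset applied
    to every detector's own calibrated threshold — detectors calibrate to
    quite different posterior scales, so shifting them in concert explores
    strict-to-lenient operating points without collapsing them onto one
    number.  Shifted thresholds are snapped to the 0.75-0.999 grid.
    Read-level F1 is maximized over offsets crossed with a fraction grid;
    ties break toward the smallest offset then the lowest fraction.  The
    winning per-detector thresholds are written back and the fraction is
    stored on the library.  Returns (mean threshold, fraction, best F1).
    """
    labels = np.asarray(labels).astype(bool)
    if labels.all() or not labels.any():
        raise CalibrationError("need both target and non-target reads to calibrate")
    if fraction_grid is None:
        fraction_grid = np.round(np.arange(0.05, 1.0001, 0.05), 2)
    if offset_grid is None:
        offset_grid = np.linspace(-2.0, 8.0, 41)
    M = max_posterior_matrix(library.detectors, reads)
    base = _logit(np.array([det.posterior_threshold for det in library.detectors]))

    def thresholds(delta):
        t = 1.0 / (1.0 + np.exp(-(base + delta)))
        return np.clip(np.round(t, 3), THRESHOLD_GRID[0], THRESHOLD_GRID[-1])

    best = (-1.0, None, None)
    for delta in offset_grid:
        tau = thresholds(delta)
        frac = (M >= tau[None, :]).mean(axis=1)
        flags = frac[None, :] >= fraction_grid[:, None]  # (F, R)
        f1 = _f1_from_preds(flags, labels)
        j = int(np.argmax(f1))
        if f1[j] > best[0] + 1e-12:
            best = (float(f1[j]), float(delta), float(fraction_grid[j]))
    best_f1, delta, f = best
    prevalence = labels.mean()
    chance_f1 = 2 * prevalence / (prevalence + 1)
    if best_f1 <= chance_f1 + 1e-9:
        warnings.warn(
            f"calibrated read-level F1 {best_f1:.3f} does not beat the "
            f"always-flag baseline {chance_f1:.3f}; detectors may be uninformative"
        )
    tau = thresholds(delta)
    for det, t in zip(library.detectors, tau):
        det.posterior_threshold = float(t)
    library.read_fraction_threshold = f
    return float(tau.mean()), f, best_f1


# ---------------------------------------------------------------------------
# serialization


def save_library(library: ModelLibrary, path: str | Path) -> None:
    """Write a library as a directory: JSON manifest + one npz blob per detector."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    manifest = {
        "version": LIBRARY_VERSION,
        "mode": library.mode,
        "read_fraction_threshold": library.read_fraction_threshold,
        "sample_fraction_threshold": library.sample_fraction_threshold,
        "reference_rankings": {
            sp: {"kmers": r.kmers, "rank": r.rank}
            for sp, r in library.reference_rankings.items()
        },
        "detectors": [],
    }
    for i, det in enumerate(library.detectors):
        blob = f"weights_{i:04d}.npz"
        np.savez(path / blob, **det.net.get_weights())
        manifest["detectors"].append(
            {
                "target_kmer": det.target_kmer,
                "posterior_threshold": det.posterior_threshold,
                "training_f1": det.training_f1,
                "sensitivity": det.sensitivity,
                "fp_per_read": det.fp_per_read,
                "fp_read_length": det.fp_read_length,
                "parameter_count": det.parameter_count,
                "arch": det.net.arch,
                "weights": blob,
            }
        )
    (path / "manifest.json").write_text(json.dumps(manifest, indent=1))


def load_library(path: str | Path) -> ModelLibrary:
    path = Path(path)
    mf = path / "manifest.json"
    if not mf.exists():
        raise LibraryFormatError(f"no manifest.json under {path}")
    manifest = json.loads(mf.read_text())
    if manifest.get("version") != LIBRARY_VERSION:
        raise LibraryFormatError(
            f"library version {manifest.get('version')!r} != {LIBRARY_VERSION!r}"
        )
    detectors = []
    for meta in manifest["detectors"]:
        blob = path / meta["weights"]
        if not blob.exists():
            raise LibraryFormatError(f"missing weights blob: {blob}")
        arch = meta["arch"]
        net = TinyConvNet(
            window=arch["window"],
            channels=tuple(arch["channels"]),
            kernel=arch["kernel"],
            pool=arch["pool"],
            in_channels=arch.get("in_channels", 1),
        )
        with np.load(blob) as data:
            net.set_weights({k: data[k] for k in data.files})
        def _num(x):
            return float("nan") if x is None else float(x)

        detectors.append(
            DetectorModel(
                target_kmer=meta["target_kmer"],
                net=net,
                posterior_threshold=meta["posterior_threshold"],
                training_f1=meta["training_f1"],
                sensitivity=_num(meta.get("sensitivity")),
                fp_per_read=_num(meta.get("fp_per_read")),
                fp_read_length=_num(meta.get("fp_read_length")),
            )
        )
    rankings = {
        sp: KmerRanking(kmers=r["kmers"], rank=r["rank"])
        for sp, r in manifest.get("reference_rankings", {}).items()
    }
    return ModelLibrary(
        detectors=detectors,
        mode=manifest["mode"],
        read_fraction_threshold=manifest["read_fraction_threshold"],
        sample_fraction_threshold=manifest["sample_fraction_threshold"],
        reference_rankings=rankings,
    )


def merge_libraries(
    sources: list[tuple[ModelLibrary, list[str]]],
    mode: str,
    **config,
) -> ModelLibrary:
    """Recombine detectors from saved libraries into a new one, no retraining.

    ``sources`` pairs each library with the k-mers to take from it.
    """
    detectors = []
    for lib, kmers in sources:
        by_kmer = {d.target_kmer: d for d in lib.detectors}
        for m in kmers:
            if m not in by_kmer:
                raise LookupError(f"k-mer {m} not in source library")
            detectors.append(by_kmer[m])
    return ModelLibrary(detectors=detectors, mode=mode, **config)
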