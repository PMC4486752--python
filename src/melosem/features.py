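"""The 12 musical dimensions of an improvisation.

Three families:

* acoustical -- roughness (sensory dissonance from beating partials,
  Plomp-Levelt/Sethares kernel on a harmonic spectrum model), brightness
  (fraction of spectral energy above a cutoff), attack time (velocity-mapped
  proxy for the time to peak intensity);
* information complexity -- windowed pitch-class entropy of all notes and of
  the melodic (skyline) line;
* compositional -- ambitus, lowest note, mean note duration, articulation
  (legato 1 .. staccato 0), mean velocity, harmonic dissonance (interval-class
  rank table) and gradus (Euler's gradus suavitatis of melodic intervals).

Roughness and brightness work on a symbolic spectrum model rather than
rendered audio, so their absolute scales are model-dependent; within-corpus
contrasts and ratios are the meaningful quantities.  Externally computed
acoustic features can replace any column via :func:`load_feature_table`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .corpus_io import (
    Corpus,
    Improvisation,
    NoteEvent,
    onset_clusters,
    skyline,
    sounding_frames,
)

FEATURE_NAMES = [
    "roughness",
    "brightness",
    "attack_time",
    "entropy",
    "melodic_entropy",
    "ambitus",
    "lowest_note",
    "duration",
    "articulation",
    "velocity",
    "dissonance",
    "gradus",
]

#: features that change under uniform velocity scaling; all others are invariant
VELOCITY_DEPENDENT = ("velocity", "attack_time")

# Interval-class dissonance ranks (0 = most consonant), indexed by interval
# mod 12: unison/octave, then P5, P4, M3, m6, m3, M6, M2, m7, M7, m2, tritone
# in the classical consonance ordering.  Editable via FeatureConfig.
DEFAULT_DISSONANCE_RANKS = {
    0: 0, 7: 1, 5: 2, 4: 3, 8: 4, 3: 5, 9: 6, 2: 7, 10: 8, 11: 9, 1: 10, 6: 11,
}

# Just-intonation ratios for intervals 0..12 semitones (gradus computation).
DEFAULT_JUST_RATIOS = {
    0: (1, 1), 1: (16, 15), 2: (9, 8), 3: (6, 5), 4: (5, 4), 5: (4, 3),
    6: (45, 32), 7: (3, 2), 8: (8, 5), 9: (5, 3), 10: (9, 5), 11: (15, 8),
    12: (2, 1),
}


@dataclass(frozen=True)
class SpectrumModel:
    """Harmonic partial model standing in for the rendered piano timbre.

    Each pitch contributes ``n_partials`` partials at integer multiples of its
    equal-tempered fundamental (A4 = ``reference_hz``), with amplitude
    ``amplitude_law(k)`` for the k-th partial (k = 1..n).
    """

    n_partials: int = 6
    reference_hz: float = 440.0
    amplitude_law: Callable[[int], float] = lambda k: 1.0 / k

    def __post_init__(self) -> None:
        if self.n_partials < 1:
            raise ValueError("need at least one partial")
        amps = [self.amplitude_law(k) for k in range(1, self.n_partials + 1)]
        if any(a <= 0 for a in amps) or any(b > a for a, b in zip(amps, amps[1:])):
            raise ValueError("partial amplitudes must be positive and non-increasing")

    def fundamental(self, pitch: int) -> float:
        return self.reference_hz * 2.0 ** ((pitch - 69) / 12.0)

    def partials(self, pitches: Sequence[int]) -> tuple[np.ndarray, np.ndarray]:
        """(frequencies, amplitudes) for all partials of all pitches."""
        k = np.arange(1, self.n_partials + 1)
        amps = np.array([self.amplitude_law(int(i)) for i in k], dtype=float)
        f0 = np.array([self.fundamental(p) for p in pitches], dtype=float)
        freqs = (f0[:, None] * k[None, :]).ravel()
        return freqs, np.tile(amps, len(f0))


@dataclass(frozen=True)
class FeatureConfig:
    window: float = 7.0            # entropy window, s (auditory sensory memory scale)
    overlap: float = 2.0           # entropy window overlap, s (hop = window - overlap)
    frame_step: float = 0.05       # s, grid for all frame-based features
    brightness_cutoff_hz: float = 1500.0
    attack_min: float = 0.005      # s, attack time at velocity 127
    attack_max: float = 0.050      # s, attack time as velocity -> 0
    cluster_threshold: float = 0.030  # s, chord simultaneity window
    dissonance_ranks: dict[int, int] = field(
        default_factory=lambda: dict(DEFAULT_DISSONANCE_RANKS)
    )
    just_ratios: dict[int, tuple[int, int]] = field(
        default_factory=lambda: dict(DEFAULT_JUST_RATIOS)
    )

    def __post_init__(self) -> None:
        if not self.window > self.overlap >= 0:
            raise ValueError("need window > overlap >= 0")
        if self.frame_step <= 0:
            raise ValueError("frame step must be positive")

    @property
    def hop(self) -> float:
        return self.window - self.overlap


DEFAULT_MODEL = SpectrumModel()
DEFAULT_CONFIG = FeatureConfig()


# ---------------------------------------------------------------------------
# compositional features
# ---------------------------------------------------------------------------


def ambitus(notes: Sequence[NoteEvent]) -> float:
    """Pitch range: highest minus lowest note, semitones."""
    pitches = [n.pitch for n in notes]
    return float(max(pitches) - min(pitches))


def lowest_note(notes: Sequence[NoteEvent]) -> float:
    return float(min(n.pitch for n in notes))


def mean_duration(notes: Sequence[NoteEvent]) -> float:
    return float(np.mean([n.duration for n in notes]))


def mean_velocity(notes: Sequence[NoteEvent]) -> float:
    return float(np.mean([n.velocity for n in notes]))


def articulation(
    notes: Sequence[NoteEvent], cluster_threshold: float = DEFAULT_CONFIG.cluster_threshold
) -> float:
    """Continuity between successive attacks: 1 = legato, 0 = staccato.

    For each successive pair of onset clusters, the sounding fraction of the
    inter-onset interval, capped at 1, averaged over pairs.  Undefined (NaN)
    for single-attack pieces.
    """
    clusters = onset_clusters(notes, cluster_threshold)
    if len(clusters) < 2:
        return float("nan")
    ratios = []
    for cur, nxt in zip(clusters, clusters[1:]):
        ioi = nxt[0].onset - cur[0].onset
        sounding = max(n.offset for n in cur) - cur[0].onset
        ratios.append(min(1.0, sounding / ioi))
    return float(np.mean(ratios))


def attack_time(
    notes: Sequence[NoteEvent],
    a_min: float = DEFAULT_CONFIG.attack_min,
    a_max: float = DEFAULT_CONFIG.attack_max,
) -> float:
    """Velocity-mapped attack proxy: louder keystrokes reach peak sooner.

    Each note maps to ``a_max - (velocity/127) * (a_max - a_min)``; the piece
    value is the mean.  This is the weakest stand-in for the audio measure and
    is the first candidate for an external-feature override.
    """
    per_note = [a_max - (n.velocity / 127.0) * (a_max - a_min) for n in notes]
    return float(np.mean(per_note))


# ---------------------------------------------------------------------------
# information-complexity features
# ---------------------------------------------------------------------------


def _entropy_bits(counts: np.ndarray) -> float:
    total = counts.sum()
    p = counts[counts > 0] / total
    return float(-(p * np.log2(p)).sum())


def _windowed_pc_entropy(
    onsets: np.ndarray, pitch_classes: np.ndarray, window: float, hop: float
) -> float:
    t0, t_last = onsets[0], onsets[-1]
    values = []
    start = t0
    while True:
        in_window = (onsets >= start) & (onsets < start + window)
        if in_window.any():
            counts = np.bincount(pitch_classes[in_window], minlength=12)
            values.append(_entropy_bits(counts))
        start += hop
        if start > t_last:
            break
    return float(np.mean(values))


def pitch_entropy(
    notes: Sequence[NoteEvent],
    window: float = DEFAULT_CONFIG.window,
    overlap: float = DEFAULT_CONFIG.overlap,
) -> float:
    """Mean windowed Shannon entropy (bits) of the pitch-class histogram.

    Notes are assigned to windows by onset; windows of length ``window``
    advance by ``window - overlap`` from the first onset; windows containing
    no notes are skipped.  0 for a single repeated pitch, log2(12) for
    uniformly distributed pitch classes.
    """
    if not window > overlap >= 0:
        raise ValueError("need window > overlap >= 0")
    onsets = np.array([n.onset for n in notes])
    pcs = np.array([n.pitch_class for n in notes])
    order = np.argsort(onsets, kind="stable")
    return _windowed_pc_entropy(onsets[order], pcs[order], window, window - overlap)


def melodic_entropy(
    notes: Sequence[NoteEvent],
    window: float = DEFAULT_CONFIG.window,
    overlap: float = DEFAULT_CONFIG.overlap,
    cluster_threshold: float = DEFAULT_CONFIG.cluster_threshold,
) -> float:
    """Windowed pitch-class entropy of the skyline (highest-voice) line."""
    if not window > overlap >= 0:
        raise ValueError("need window > overlap >= 0")
    clusters = onset_clusters(notes, cluster_threshold)
    onsets = np.array([c[0].onset for c in clusters])
    pcs = np.array([max(n.pitch for n in c) % 12 for c in clusters])
    return _windowed_pc_entropy(onsets, pcs, window, window - overlap)


# ---------------------------------------------------------------------------
# frame-based acoustical / harmonic features
# ---------------------------------------------------------------------------


def _frame_pitch_sets(
    notes: Sequence[NoteEvent], step: float
) -> tuple[list[tuple[int, ...]], int]:
    """Distinct sounding pitch sets over the frame grid, with multiplicities.

    Returns (unique sorted pitch tuples repeated per count is avoided --
    instead a list of (tuple) per frame is collapsed to unique tuples) -- see
    caller: we return the per-frame tuples so callers can weight by frame.
    """
    frames = sounding_frames(notes, step)
    return [tuple(sorted(s)) for _, s in frames], len(frames)


def plomp_levelt_pair(f1: float, f2: float, a1: float = 1.0, a2: float = 1.0) -> float:
    """Roughness contribution of one partial pair (Sethares parameterization).

    Dissonance peaks when the frequency separation is about a quarter of the
    critical bandwidth at the lower frequency and vanishes for unisons and
    wide separations.
    """
    fmin, d = min(f1, f2), abs(f2 - f1)
    s = 0.24 / (0.021 * fmin + 19.0)
    return a1 * a2 * (math.exp(-3.5 * s * d) - math.exp(-5.75 * s * d))


def _chord_roughness(pitches: tuple[int, ...], model: SpectrumModel) -> float:
    freqs, amps = model.partials(pitches)
    if len(freqs) < 2:
        return 0.0
    i, j = np.triu_indices(len(freqs), k=1)
    f1, f2 = freqs[i], freqs[j]
    fmin = np.minimum(f1, f2)
    d = np.abs(f2 - f1)
    s = 0.24 / (0.021 * fmin + 19.0)
    return float(np.sum(amps[i] * amps[j] * (np.exp(-3.5 * s * d) - np.exp(-5.75 * s * d))))


def roughness(
    notes: Sequence[NoteEvent],
    model: SpectrumModel = DEFAULT_MODEL,
    frame_step: float = DEFAULT_CONFIG.frame_step,
) -> float:
    """Sensory dissonance: Plomp-Levelt beating between all partial pairs.

    Every 50 ms frame expands its sounding pitches into model partials; the
    pairwise kernel is summed over all distinct partial pairs and the result
    averaged over frames.  0 for a lone pure tone (no partial pairs).
    """
    per_frame, n_frames = _frame_pitch_sets(notes, frame_step)
    if n_frames == 0:
        return 0.0
    cache: dict[tuple[int, ...], float] = {}
    total = 0.0
    for chord in per_frame:
        if chord not in cache:
            cache[chord] = _chord_roughness(chord, model) if chord else 0.0
        total += cache[chord]
    return total / n_frames


def brightness(
    notes: Sequence[NoteEvent],
    model: SpectrumModel = DEFAULT_MODEL,
    cutoff_hz: float = DEFAULT_CONFIG.brightness_cutoff_hz,
    frame_step: float = DEFAULT_CONFIG.frame_step,
) -> float:
    """Fraction of spectral energy (amplitude squared) above the cutoff,
    averaged over frames with at least one sounding pitch."""
    per_frame, _ = _frame_pitch_sets(notes, frame_step)
    cache: dict[tuple[int, ...], float] = {}
    values = []
    for chord in per_frame:
        if not chord:
            continue
        if chord not in cache:
            freqs, amps = model.partials(chord)
            energy = amps**2
            cache[chord] = float(energy[freqs > cutoff_hz].sum() / energy.sum())
        values.append(cache[chord])
    return float(np.mean(values)) if values else 0.0


def harmonic_dissonance(
    notes: Sequence[NoteEvent],
    ranks: dict[int, int] | None = None,
    frame_step: float = DEFAULT_CONFIG.frame_step,
) -> float:
    """Mean interval-class dissonance rank over all sounding pairs.

    Frames with fewer than two distinct sounding pitches contribute nothing;
    a piece with no simultaneities scores 0.
    """
    ranks = ranks or DEFAULT_DISSONANCE_RANKS
    per_frame, _ = _frame_pitch_sets(notes, frame_step)
    total, n_pairs = 0.0, 0
    cache: dict[tuple[int, ...], tuple[float, int]] = {}
    for chord in per_frame:
        if len(chord) < 2:
            continue
        if chord not in cache:
            s, c = 0.0, 0
            for a in range(len(chord)):
                for b in range(a + 1, len(chord)):
                    s += ranks[(chord[b] - chord[a]) % 12]
                    c += 1
            cache[chord] = (s, c)
        s, c = cache[chord]
        total += s
        n_pairs += c
    return total / n_pairs if n_pairs else 0.0


# ---------------------------------------------------------------------------
# gradus suavitatis
# ---------------------------------------------------------------------------


def euler_gradus(n: int) -> int:
    """Euler's gradus suavitatis of a positive integer: 1 + sum k*(p-1) over
    the prime factorization p^k."""
    if n < 1:
        raise ValueError("gradus is defined for positive integers")
    g, p = 1, 2
    while n > 1:
        while n % p == 0:
            g += p - 1
            n //= p
        p += 1 if p == 2 else 2
    return g


def gradus(
    notes: Sequence[NoteEvent],
    ratios: dict[int, tuple[int, int]] | None = None,
    cluster_threshold: float = DEFAULT_CONFIG.cluster_threshold,
) -> float:
    """Melodic dissonance: mean gradus suavitatis of successive skyline
    intervals, mapped to just-intonation ratios (intervals reduced mod 12).

    Undefined (NaN) when the skyline has fewer than two elements.
    """
    ratios = ratios or DEFAULT_JUST_RATIOS
    line = skyline(notes, cluster_threshold)
    if len(line) < 2:
        return float("nan")
    values = []
    for a, b in zip(line, line[1:]):
        interval = abs(b - a)
        if interval > 12:
            interval %= 12
        num, den = ratios[interval]
        values.append(euler_gradus((num // math.gcd(num, den)) * (den // math.gcd(num, den))))
    return float(np.mean(values))


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------


def extract_features(
    improv: Improvisation,
    model: SpectrumModel = DEFAULT_MODEL,
    config: FeatureConfig = DEFAULT_CONFIG,
) -> dict[str, float]:
    """All 12 dimensions of one improvisation; undefined features are NaN."""
    notes = improv.notes
    return {
        "roughness": roughness(notes, model, config.frame_step),
        "brightness": brightness(notes, model, config.brightness_cutoff_hz, config.frame_step),
        "attack_time": attack_time(notes, config.attack_min, config.attack_max),
        "entropy": pitch_entropy(notes, config.window, config.overlap),
        "melodic_entropy": melodic_entropy(
            notes, config.window, config.overlap, config.cluster_threshold
        ),
        "ambitus": ambitus(notes),
        "lowest_note": lowest_note(notes),
        "duration": mean_duration(notes),
        "articulation": articulation(notes, config.cluster_threshold),
        "velocity": mean_velocity(notes),
        "dissonance": harmonic_dissonance(notes, config.dissonance_ranks, config.frame_step),
        "gradus": gradus(notes, config.just_ratios, config.cluster_threshold),
    }


LABEL_COLUMNS = ["file", "pianist_id", "word", "valence", "category"]


def feature_table(
    corpus: Corpus,
    model: SpectrumModel = DEFAULT_MODEL,
    config: FeatureConfig = DEFAULT_CONFIG,
) -> pd.DataFrame:
    """One row per improvisation: label columns plus the 12 feature columns."""
    rows = []
    for imp in corpus.improvisations:
        row = {
            "file": f"{imp.pianist_id}_{imp.word}.mid",
            "pianist_id": imp.pianist_id,
            "word": imp.word,
            "valence": imp.valence,
            "category": imp.category,
        }
        row.update(extract_features(imp, model, config))
        rows.append(row)
    return pd.DataFrame(rows, columns=LABEL_COLUMNS + FEATURE_NAMES)


def load_feature_table(path: str | Path) -> pd.DataFrame:
    """Read an external per-file feature CSV (``file`` key plus any subset of
    the 12 feature columns); rejects unknown columns and non-numeric cells."""
    table = pd.read_csv(path)
    if "file" not in table.columns:
        raise ValueError("external feature table needs a 'file' column")
    unknown = set(table.columns) - {"file"} - set(FEATURE_NAMES)
    if unknown:
        raise ValueError(f"unknown feature columns {sorted(unknown)}")
    for col in table.columns:
        if col == "file":
            continue
        if not pd.api.types.is_numeric_dtype(table[col]):
            raise ValueError(f"non-numeric values in column {col!r}")
    return table


def merge_feature_overrides(table: pd.DataFrame, overrides: pd.DataFrame) -> pd.DataFrame:
    """Overlay externally computed features onto a symbolic feature table.

    External values take precedence wherever present (non-NaN); every file key
    in the override must exist in the base table.
    """
    missing = set(overrides["file"]) - set(table["file"])
    if missing:
        raise ValueError(f"override file keys not in table: {sorted(missing)[:5]}")
    merged = table.set_index("file")
    ext = overrides.set_index("file")
    for col in ext.columns:
        values = ext[col].dropna()
        merged.loc[values.index, col] = values
    return merged.reset_index()[table.columns]
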