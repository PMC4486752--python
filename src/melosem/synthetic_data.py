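"""Class-conditioned synthetic improvisation corpora.

The generator emulates the study design -- n pianists x 32 stimulus words,
pieces of at most 20 s -- with per-cell control over register, range,
pitch-class concentration, note timing, articulation, loudness and the
make-up of simultaneities.  It is calibrated on what the feature extractors
recover, not on any claim about pianists' cognition: the default preset
injects the reported effect directions (valence effects on register, range,
pitch order, consonance and attack; a category effect on articulation only;
a morality-only valence contrast in roughness targeting the ~8x
negative/positive ratio on the package's own roughness scale).

Simultaneities come in four flavors so that sensory roughness and rank-table
dissonance can be steered separately: semitone clusters (very rough, high
rank) whose *size* scales roughness at nearly constant rank, whole-tone
clusters (rough but mid-rank), tritone-family dyads (high rank, mild
roughness) and weighted consonant dyads (the background texture).

Pianist individuality is modeled as Gaussian per-pianist offsets on cell
parameters (shared across cells, so they act as the subject blocking factor
and make pianist-disjoint classification genuinely harder); piece-to-piece
variation comes from per-improvisation centers for loudness, articulation,
tempo and tonal concentration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .corpus_io import (
    CATEGORIES,
    VALENCES,
    Corpus,
    Improvisation,
    NoteEvent,
    WordSet,
    default_word_set,
)

__all__ = [
    "ClassParams",
    "GeneratorConfig",
    "default_word_set",
    "sample_improvisation",
    "generate_corpus",
    "study_params",
    "null_config",
]

# pitch classes ranked along the circle of fifths from the tonic; the
# concentration weight decays along this ranking
_PC_RANK_ORDER = (0, 7, 4, 5, 9, 2, 11, 3, 8, 1, 6, 10)

_DISSONANT_INTERVALS = (6, 10, 11)
_CONSONANT_INTERVALS = (12, 7, 5, 4, 3, 8, 9)
_CONSONANT_WEIGHTS = (0.30, 0.30, 0.15, 0.10, 0.05, 0.05, 0.05)


@dataclass(frozen=True)
class ClassParams:
    """Generative parameters of one valence x category cell."""

    lowest_note_mean: float      # MIDI number of the register floor
    lowest_note_sd: float
    ambitus_mean: float          # semitones of available range
    ambitus_sd: float
    pc_concentration: float      # decay rate of pitch-class weights (higher = more peaked)
    pc_concentration_sd: float   # piece-to-piece spread of tonal focus
    duration_target: float       # s, intended mean sounding length of a note
    ioi_log_sd: float            # per-note spread of the inter-onset interval
    ioi_jitter_log_sd: float     # piece-to-piece tempo spread
    legato_mean: float           # target sounding fraction of the inter-onset interval
    legato_sd: float             # per-note spread around the piece's legato center
    legato_center_sd: float      # piece-to-piece spread of the legato center
    velocity_mean: float
    velocity_center_sd: float    # piece-to-piece spread of the loudness center
    velocity_sd: float           # per-note spread
    chord_prob: float            # a melody attack carries extra simultaneous notes
    cluster_prob: float          # the simultaneity is a semitone cluster ...
    cluster_size: int            # ... of this many added notes
    wholetone_prob: float        # the simultaneity is a 3-note whole-tone cluster
    dissonant_prob: float        # the simultaneity is a tritone-family dyad
    chord_prob_sd: float = 0.10  # piece-to-piece spread of chord density
    mix_sd: float = 0.06         # piece-to-piece spread of the simultaneity-type mix
    chromatic_prob: float = 0.0  # a melody note ignores the tonal profile
    consonant_bias: float = 0.0  # consonant chord partners prefer off-profile pitch classes
    piece_length: float = 18.0   # s of generated onsets (hard cap 20 s)

    def __post_init__(self) -> None:
        for name in ("chord_prob", "cluster_prob", "wholetone_prob", "dissonant_prob", "chromatic_prob", "consonant_bias"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability, got {v}")
        if self.cluster_prob + self.wholetone_prob + self.dissonant_prob > 1.0 + 1e-9:
            raise ValueError("simultaneity-type probabilities exceed 1")
        if self.cluster_size < 1:
            raise ValueError("cluster_size must be >= 1")
        if self.duration_target <= 0 or self.piece_length <= 0:
            raise ValueError("duration target and piece length must be positive")
        if not 0 < self.legato_mean <= 1.5:
            raise ValueError("legato_mean out of range")

    @property
    def rate(self) -> float:
        """Nominal attacks per second implied by duration target and legato."""
        return _clipped_mean(self.legato_mean, self._legato_total_sd) / self.duration_target

    @property
    def _legato_total_sd(self) -> float:
        return math.hypot(self.legato_sd, self.legato_center_sd)

    @property
    def ioi_mean(self) -> float:
        """Mean inter-onset interval chosen so the realized mean note
        duration (= legato fraction x IOI, after clipping) hits the target,
        decoupling the duration dimension from articulation."""
        return self.duration_target / _clipped_mean(self.legato_mean, self._legato_total_sd)


def _clipped_mean(mu: float, sigma: float, lo: float = 0.05, hi: float = 1.0) -> float:
    """E[clip(N(mu, sigma), lo, hi)] -- closed form via the normal cdf/pdf."""
    if sigma <= 0:
        return min(max(mu, lo), hi)
    from scipy.stats import norm

    a, b = (lo - mu) / sigma, (hi - mu) / sigma
    return float(
        lo * norm.cdf(a)
        + hi * norm.sf(b)
        + mu * (norm.cdf(b) - norm.cdf(a))
        - sigma * (norm.pdf(b) - norm.pdf(a))
    )


#: per-parameter sd of the Gaussian pianist offsets (about a quarter of the
#: corresponding cell contrast in the default preset)
DEFAULT_OFFSET_SDS = {
    "lowest_note_mean": 1.75,
    "ambitus_mean": 1.75,
    "pc_concentration": 0.09,
    "duration_target": 0.015,
    "legato_mean": 0.012,
    "velocity_mean": 3.0,
    "cluster_prob": 0.08,
    "wholetone_prob": 0.08,
    "dissonant_prob": 0.06,
}


@dataclass(frozen=True)
class GeneratorConfig:
    cells: dict[tuple[str, str], ClassParams]
    n_pianists: int = 19
    seed: int = 0
    word_set: WordSet = field(default_factory=default_word_set)
    offset_sds: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_OFFSET_SDS))

    def __post_init__(self) -> None:
        if self.n_pianists < 2:
            raise ValueError("need at least 2 pianists")
        expected = {(v, c) for v in VALENCES for c in CATEGORIES}
        if set(self.cells) != expected:
            raise ValueError("cells must cover all 4 valence x category pairs")


def study_params() -> GeneratorConfig:
    """The default preset reproducing the reported effect pattern.

    Valence steers register, range, tonal concentration, loudness (hence the
    attack-time proxy), note duration and the tritone-flavored rank
    dissonance; category steers articulation only (reported cell means,
    corrected for clipping so the *extracted* values land on them); the
    semitone/whole-tone cluster mix gives roughness its morality-only valence
    contrast while keeping its category means balanced.
    """

    def cell(valence: str, category: str) -> ClassParams:
        pos = valence == "positive"
        legato = {
            ("positive", "morality"): 0.978,
            ("positive", "logic"): 0.905,
            ("negative", "morality"): 0.904,
            ("negative", "logic"): 0.868,
        }[(valence, category)]
        # simultaneity mix per cell: (cluster_prob, cluster_size,
        # wholetone_prob, dissonant_prob)
        mix = {
            ("positive", "morality"): (0.09, 1, 0.00, 0.075),
            ("negative", "morality"): (0.55, 3, 0.12, 0.28),
            ("positive", "logic"): (0.00, 1, 0.76, 0.00),
            ("negative", "logic"): (0.20, 2, 0.56, 0.12),
        }[(valence, category)]
        cluster, size, wholetone, dissonant = mix
        chromatic = 0.0
        bias = 1.0 if (valence, category) == ("positive", "morality") else 0.0
        return ClassParams(
            lowest_note_mean=50.0 if pos else 43.0,
            lowest_note_sd=4.0,
            ambitus_mean=22.0 if pos else 29.0,
            ambitus_sd=5.0,
            pc_concentration=0.65 if pos else 0.30,
            pc_concentration_sd=0.16,
            duration_target=0.37 if pos else 0.31,
            ioi_log_sd=0.35,
            ioi_jitter_log_sd=0.12,
            legato_mean=legato,
            legato_sd=0.05,
            legato_center_sd=0.03,
            velocity_mean=58.0 if pos else 70.0,
            velocity_center_sd=8.0,
            velocity_sd=6.0,
            chord_prob=0.35,
            cluster_prob=cluster,
            cluster_size=size,
            wholetone_prob=wholetone,
            dissonant_prob=dissonant,
            chromatic_prob=chromatic,
            consonant_bias=bias,
        )

    return GeneratorConfig(
        cells={(v, c): cell(v, c) for v in VALENCES for c in CATEGORIES}
    )


def null_config() -> GeneratorConfig:
    """All four cells identical: the no-effect generator for type-I checks."""
    neutral = ClassParams(
        lowest_note_mean=46.0,
        lowest_note_sd=4.0,
        ambitus_mean=26.0,
        ambitus_sd=5.0,
        pc_concentration=0.45,
        pc_concentration_sd=0.08,
        duration_target=0.34,
        ioi_log_sd=0.35,
        ioi_jitter_log_sd=0.12,
        legato_mean=0.91,
        legato_sd=0.05,
        legato_center_sd=0.03,
        velocity_mean=64.0,
        velocity_center_sd=8.0,
        velocity_sd=6.0,
        chord_prob=0.35,
        cluster_prob=0.20,
        cluster_size=2,
        wholetone_prob=0.30,
        dissonant_prob=0.15,
        chromatic_prob=0.05,
    )
    return GeneratorConfig(
        cells={(v, c): neutral for v in VALENCES for c in CATEGORIES}
    )


def _apply_offsets(params: ClassParams, offsets: dict[str, float]) -> ClassParams:
    updates: dict[str, float] = {}
    for name, off in offsets.items():
        value = getattr(params, name) + off
        if name in ("cluster_prob", "wholetone_prob", "dissonant_prob"):
            value = float(np.clip(value, 0.0, 1.0))
        elif name == "pc_concentration":
            value = max(0.0, value)
        elif name == "duration_target":
            value = max(0.05, value)
        elif name == "legato_mean":
            value = float(np.clip(value, 0.1, 1.2))
        updates[name] = value
    cp = updates.get("cluster_prob", params.cluster_prob)
    wp = updates.get("wholetone_prob", params.wholetone_prob)
    dp = updates.get("dissonant_prob", params.dissonant_prob)
    total = cp + wp + dp
    if total > 1.0:  # keep the mix a probability after clipping
        updates["cluster_prob"] = cp / total
        updates["wholetone_prob"] = wp / total
        updates["dissonant_prob"] = dp / total
    return replace(params, **updates)


def _simultaneity_intervals(
    params: ClassParams,
    rng: np.random.Generator,
    pitch: int | None = None,
    pc_weight: dict[int, float] | None = None,
) -> list[int]:
    """Intervals (semitones below the melody note) of one simultaneity.

    With ``consonant_bias`` > 0, consonant partners are drawn by a small
    tournament that favors off-profile pitch classes (anti-tonal voicing):
    this perturbs the pitch-class histogram without altering the interval
    family, the melodic line or the beating structure appreciably.
    """
    u = rng.random()
    if u < params.cluster_prob:
        return list(range(1, params.cluster_size + 1))
    u -= params.cluster_prob
    if u < params.wholetone_prob:
        return [2, 4]
    u -= params.wholetone_prob
    if u < params.dissonant_prob:
        return [int(rng.choice(_DISSONANT_INTERVALS))]
    if (
        params.consonant_bias > 0
        and pitch is not None
        and pc_weight is not None
        and rng.random() < params.consonant_bias
    ):
        candidates = rng.choice(_CONSONANT_INTERVALS, size=3, p=_CONSONANT_WEIGHTS)
        return [int(min(candidates, key=lambda iv: pc_weight[(pitch - iv) % 12]))]
    return [int(rng.choice(_CONSONANT_INTERVALS, p=_CONSONANT_WEIGHTS))]


def sample_improvisation(
    params: ClassParams,
    pianist_id: str,
    word: str,
    valence: str,
    category: str,
    rng: np.random.Generator,
    offsets: dict[str, float] | None = None,
) -> Improvisation:
    """Draw one improvisation from a cell's generative distribution."""
    if offsets:
        params = _apply_offsets(params, offsets)

    # attack grid: lognormal IOIs around the cell's tempo, with a
    # per-piece tempo jitter
    ioi_log_center = math.log(params.ioi_mean) + rng.normal(0.0, params.ioi_jitter_log_sd)
    onsets = [0.0]
    while True:
        ioi = float(rng.lognormal(ioi_log_center - params.ioi_log_sd**2 / 2, params.ioi_log_sd))
        t = onsets[-1] + max(0.05, ioi)
        if t > params.piece_length:
            break
        onsets.append(t)
    if len(onsets) < 2:
        onsets.append(min(params.piece_length, onsets[-1] + 0.5))
    onsets_arr = np.array(onsets)
    iois = np.diff(onsets_arr)
    mean_ioi = float(iois.mean()) if len(iois) else params.ioi_mean

    # register and available pitch range
    lowest = int(np.clip(round(rng.normal(params.lowest_note_mean, params.lowest_note_sd)), 21, 96))
    amb = int(np.clip(round(rng.normal(params.ambitus_mean, params.ambitus_sd)), 1, 60))
    highest = min(lowest + amb, 108)

    # pitch-class weights decay along the circle of fifths from a random tonic
    tonic = int(rng.integers(12))
    concentration = max(0.0, rng.normal(params.pc_concentration, params.pc_concentration_sd))
    rank_of_pc = {pc: rank for rank, pc in enumerate(_PC_RANK_ORDER)}
    candidates = np.arange(lowest, highest + 1)
    weights = np.exp(
        -concentration * np.array([rank_of_pc[(p - tonic) % 12] for p in candidates])
    )
    weights /= weights.sum()
    pc_profile = {pc: math.exp(-concentration * rank_of_pc[(pc - tonic) % 12]) for pc in range(12)}

    legato_center = rng.normal(params.legato_mean, params.legato_center_sd)
    velocity_center = rng.normal(params.velocity_mean, params.velocity_center_sd)
    chord_p = float(np.clip(rng.normal(params.chord_prob, params.chord_prob_sd), 0.0, 0.9))
    if params.mix_sd > 0:  # piece-level texture drift of the simultaneity mix
        cp = float(np.clip(rng.normal(params.cluster_prob, params.mix_sd), 0.0, 1.0))
        wp = float(np.clip(rng.normal(params.wholetone_prob, params.mix_sd), 0.0, 1.0))
        dp = float(np.clip(rng.normal(params.dissonant_prob, params.mix_sd), 0.0, 1.0))
        total = cp + wp + dp
        if total > 1.0:
            cp, wp, dp = cp / total, wp / total, dp / total
        params = replace(params, cluster_prob=cp, wholetone_prob=wp, dissonant_prob=dp)

    notes: list[NoteEvent] = []
    flat = np.full(len(candidates), 1.0 / len(candidates))
    for i, onset in enumerate(onsets_arr):
        melody_w = flat if rng.random() < params.chromatic_prob else weights
        pitch = int(rng.choice(candidates, p=melody_w))
        ioi = iois[i] if i < len(iois) else mean_ioi
        r = float(np.clip(rng.normal(legato_center, params.legato_sd), 0.05, 1.0))
        duration = max(0.02, r * ioi)
        velocity = int(np.clip(round(rng.normal(velocity_center, params.velocity_sd)), 1, 127))
        chord_intervals: list[int] = []
        if rng.random() < chord_p:
            chord_intervals = _simultaneity_intervals(params, rng, pitch, pc_profile)
            # keep the whole simultaneity inside the register: raise the
            # melody note rather than letting chord tones sink below the floor
            span = max(chord_intervals)
            if pitch < lowest + span:  # raise by whole octaves: pitch class kept
                k = -(-(lowest + span - pitch) // 12)
                if pitch + 12 * k <= highest:
                    pitch = pitch + 12 * k
        notes.append(NoteEvent(onset=float(onset), offset=float(onset + duration), pitch=pitch, velocity=velocity))
        for interval in chord_intervals:
            extra_vel = int(np.clip(velocity + rng.integers(-3, 4), 1, 127))
            notes.append(
                NoteEvent(
                    onset=float(onset),
                    offset=float(onset + duration),
                    pitch=max(lowest, pitch - interval),
                    velocity=extra_vel,
                )
            )

    # hard cap at the study's 20 s limit
    t0 = notes[0].onset
    notes = [
        n if n.offset - t0 <= 20.0 else replace(n, offset=t0 + 20.0)
        for n in notes
    ]
    notes.sort(key=lambda n: (n.onset, -n.pitch))
    return Improvisation(
        pianist_id=pianist_id,
        word=word,
        valence=valence,
        category=category,
        notes=tuple(notes),
    )


def _draw_offsets(offset_sds: dict[str, float], rng: np.random.Generator) -> dict[str, float]:
    return {name: float(rng.normal(0.0, sd)) for name, sd in sorted(offset_sds.items())}


def generate_corpus(config: GeneratorConfig) -> Corpus:
    """One improvisation per pianist x word; byte-deterministic given the seed."""
    rng = np.random.default_rng(config.seed)
    improvisations = []
    for p in range(config.n_pianists):
        pianist_id = f"p{p + 1:02d}"
        offsets = _draw_offsets(config.offset_sds, rng)
        for entry in config.word_set:
            params = config.cells[(entry.valence, entry.category)]
            improvisations.append(
                sample_improvisation(
                    params,
                    pianist_id,
                    entry.word_en,
                    entry.valence,
                    entry.category,
                    rng,
                    offsets=offsets,
                )
            )
    return Corpus(tuple(improvisations), config.word_set)
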